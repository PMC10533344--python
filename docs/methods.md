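# Methods

`gexkb` builds a knowledge base (KB) of fine-grained gene expression–cancer
associations from per-sentence relation annotations. This note documents the
model, its assumptions, the tunable parameters, the synthetic-data model used
for testing, and the numerical choices the implementation makes.

## The annotation model

A sentence mentioning one gene and one cancer is described by four categorical
*aspects*:

| aspect | domain | meaning |
|---|---|---|
| CGE | up, down, notinf | change of gene expression |
| CCS | progression, regression, notinf | change of cancer status |
| GCI | causality, correlation, notinf | kind of gene–cancer interaction |
| GCC | expression, other | is the sentence about expression–cancer at all |

`notinf` means the sentence does not state the aspect. `observation` is
accepted everywhere as an input alias of the GCI value `correlation` and is
canonicalized on entry; the canonical label was chosen because it is the
domain's defining label, while the alias appears in rule tables and older
corpora (CoMAGC/OncoSearch lineage).

Evidence for a sentence is a *score vector* per aspect: a probability
distribution over the aspect's values (sum 1 within 1e-9). Manual expert
annotations are exact one-hot vectors (stored as exact 0/1 floats, never
values near them); automatic annotations come from any scorer satisfying the
per-aspect scorer contract. The scorer is deliberately pluggable: the bundled
baseline is a transparent additive keyword-lexicon scorer (smoothed, then
normalized), which exists so the whole pipeline can run and be inspected
without a trained model. Production deployments are expected to plug in a
trained classifier per aspect; each can be retrained or replaced
independently. Scoring always masks the gene and cancer surface forms
(`@GENE@` / `@CANCER@`, configurable) so a scorer cannot key on entity
identity.

## Filtering

Only sentences with GCC argmax exactly `{expression}` and without `notinf`
in the CGE argmax set are used for KB population; GCC separates
expression-related associations from everything else, and not-informative CGE
is excluded because CGE is the driving aspect of these associations. Ties are
read conservatively: a GCC tie or a CGE tie involving `notinf` rejects the
sentence. The filter is a pure partition and reports rejection counts by
reason.

## Evidence aggregation

Retained sentences are grouped by `(gene_id, CUI)`; all of a pair's sentences
across documents form one fact. Duplicate evidence — identical
(document, text) for the same pair, as happens when the same sentence is
harvested from two sources — counts once. For aspect value *a* over the
evidence set *T*:

    Pr(a) = Σ_{t∈T} score(a, t)·1(a, t)  /  Σ_{t∈T} max_k score(a_k, t)

where the indicator `1(a, t)` is `1/|argmax(t)|` if *a* is among the
sentence's top-scoring values and 0 otherwise. Consequences worth knowing:

* the likelihoods over a domain always sum to 1 (each sentence contributes
  exactly its max score to the numerator mass, tie or no tie);
* only the top value(s) and the top score of each sentence matter — how the
  residual mass is distributed is provably irrelevant (the property-test
  "residual-mass invariance" checks this with random redistributions), which
  also justifies encoding worked examples from their printed top values only;
* after filtering, `Pr(CGE = notinf)` is exactly 0 by construction;
* adding a one-hot sentence for value *a* never decreases `Pr(a)`, and
  sentence order never matters.

The fact carries the triple (AP_CGE, AP_CCS, AP_GCI); GCC is consumed by the
filter and is not part of the fact.

## Gene-class inference and reliability

The inference rules map value tuples to three mutually exclusive classes:
causality tuples with concordant CGE/CCS direction (`up`+`progression`,
`down`+`regression`) are **oncogene**; discordant causality tuples are
**tumor suppressor gene**; all four `correlation` tuples are **biomarker**.
Tuples containing `notinf` map to no class. Treating aspects as independent,

    Pr(class) = Σ_{tuples → class} Π_i Pr(a_i)

implemented in closed form and verified against brute-force enumeration of
all 27 tuples (< 1e-12 over 1,000 random facts). Class mass is
sub-normalized — `notinf` tuples carry the remainder — and is deliberately
**not** renormalized before testing: with `Pr(CGE=notinf)=0` the total class
mass equals `(Pr(prog)+Pr(regr))·(Pr(caus)+Pr(corr))`.

Tagging is two-stage, and the comparisons are strict exactly as specified:

1. **sufficiency** — fail (`insufficient`) iff `Pr(CCS=notinf) > α` or
   `Pr(GCI=notinf) > α`. Equality with α passes.
2. **consistency** — fail (`inconsistent`) unless `top1 − top2 > β` over the
   class likelihoods. Equality with β fails, and an exact top-two tie can
   never be reliable — no tie-break ever manufactures a reliable fact.

Facts passing both are `reliable` and carry the top class (which necessarily
equals the consistency candidate) as their signature type. Defaults
α = 0.7, β = 0.4.

## Active learning

Unreliable facts get a reliability score

    rel = −((Pr(CCS=notinf) + Pr(GCI=notinf)) / 2) · H(S),
    H(S) = −Σ_class Pr(class)·log Pr(class),  0·log 0 := 0.

H is applied to the sub-normalized class likelihoods exactly as computed; it
is still non-negative since every term has p ≤ 1. rel ≤ 0 always, and rel = 0
iff the not-informative mass or the entropy vanishes. The logarithm defaults
to natural log and is configurable, but since a base change rescales every
score by the same positive constant, the ranking is base-invariant (tested on
random fact sets under ln and log2).

Facts are ranked ascending (most negative = most uncertain first), ties
broken by `(gene_id, CUI)`; sentences are collected fact-by-fact, within a
fact in `(document_id, sentence_id)` order, until the batch holds k sentences
(default k = 250; the last fact may be truncated). The batch counts
*sentences*, not facts.

Each iteration rebuilds the KB from scratch over the union of all manual and
automatic annotations, with manual re-annotations taking precedence by
sentence id. Versions are compared by fact key; the unreliable-overlap
statistic counts, per tag, the fact keys unreliable in both versions.

## Ingestion

PubTator-native blocks are parsed with the standard offset convention (title
mentions index the title; abstract mentions index `title + " " + abstract`);
malformed annotation lines are skipped with a warning, never fatally. Disease
mentions are mapped MeSH → UMLS CUI through a user-supplied 3-column TSV and
gated on the neoplastic-process semantic type (default `T191`, configurable);
a MeSH id mapping to several surviving CUIs yields one mention per CUI,
counted in the ingest report. The table is user-supplied so the package
carries no UMLS licensing burden.

Sentence segmentation is a deterministic rule-based splitter (terminal
punctuation followed by whitespace and an upper-case letter or digit, with a
short abbreviation guard); the title is always a single sentence, which
avoids merging unpunctuated titles into the first abstract sentence. Mentions
crossing a sentence boundary are dropped, never truncated — truncation would
fabricate spans. Pair expansion is the full Cartesian product of a sentence's
gene and cancer mentions; offsets are 0-based half-open character spans, and
`text[start:end]` always equals the mention surface form.

## Synthetic data model

The generator emulates the pipeline inputs with controlled ground truth.
Each pair draws a gene class uniformly (oncogene / TSG / biomarker by
default) and one canonical aspect tuple uniformly among the rule tuples for
that class; all sentences of a pair share that tuple, so disagreement enters
only through score noise. Sentences use several phrasing templates and are
spread over multiple synthetic documents (two sentences per document), so
deduplication treats them as distinct evidence, as it would real literature.

Score vectors are Dirichlet draws with concentration *c* on the true value
and 1 elsewhere (*c* = ∞ gives exact one-hot); with probability equal to the
contamination rate, an aspect's true value is swapped for `notinf` before
drawing, emulating sentences that do not state the aspect. Defaults: 200
pairs, 4–8 sentences per pair, c = 100 (a confident scorer), contamination
0.10. All randomness flows from the single seed in the spec.

What the synthetic model does *not* emulate: real PubMed text statistics,
entity-linking errors, inter-pair correlation, class imbalance, or scorers
whose errors are systematic rather than symmetric-noise — so passing recovery
tests demonstrates the aggregation/reliability machinery, not real-corpus
extraction quality. Under the default conditions the pipeline recovers the
true class for 98% of pairs (100% with noiseless one-hot scores); the
residual misses are pairs whose contaminated evidence legitimately fails a
reliability check.

## Numerical choices and edge cases

* Argmax sets use an absolute tolerance of 1e-9 (configurable), so
  numerically tied scores share indicator mass.
* The aggregation denominator is strictly positive for valid vectors
  (every per-sentence max ≥ 1/|domain|); a zero denominator is rejected
  defensively.
* Likelihoods are kept at full precision; 2-decimal rounding is
  presentation-only (KB statistics ratios are reported to 2 decimals).
* Empty KB versions report ratios as absent rather than dividing by zero.
* JSON export is key-sorted and fact-sorted, hence byte-deterministic;
  N-Triples export is line-sorted for the same guarantee. Turtle goes through
  rdflib's serializer.
* Problem sizes in the test suite (e.g. 200 synthetic pairs, 500–1,000
  random cases per property) were chosen to exercise the statistical claims
  while keeping the suite fast to run routinely.

## Known limitations

* The bundled lexicon scorer is illustrative, not competitive; it exists to
  make the pipeline runnable and debuggable end to end.
* Gene identifiers are taken from the input annotations as-is; there is no
  mention normalization model and no species filtering.
* The batch truncates the last fact's sentences at the k boundary; a partial
  fact's remaining sentences wait for the next iteration.
* Entropy over sub-normalized class mass is not a true Shannon entropy of a
  distribution; it is used as specified, as a flatness penalty for ranking
  only, where only the induced order matters.
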
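# gexkb

Probabilistic knowledge-base construction for **fine-grained gene
expression–cancer associations** mined from the biomedical literature.

Experimental resources (microarray / NGS compendia) tell you *that* a gene's
expression differs in a tumor; the literature additionally tells you *how the
association is asserted* — direction of expression change, direction of the
cancer-status change, and whether the link is causal or correlational.
`gexkb` is for text-mining and bioinformatics groups who already run named
entity recognition and relation scoring over abstracts and need the back end:
turning noisy, contradictory per-sentence evidence into a versioned,
reliability-tested knowledge graph of gene roles in cancer, with an
active-learning loop that spends scarce expert annotation where it helps
most.

## The model

Each sentence with one gene and one cancer mention carries a probability
distribution over four aspects: CGE (up / down / notinf), CCS (progression /
regression / notinf), GCI (causality / correlation / notinf) and GCC
(expression / other, a utility filter). Sentences with GCC ≠ expression or
CGE = notinf are discarded. For a gene–cancer pair with evidence set *T*, the
likelihood of aspect value *a* is

    Pr(a) = Σ_{t∈T} score(a,t)·𝟙(a,t) / Σ_{t∈T} max_k score(a_k,t)

with the tie-sharing indicator 𝟙(a,t) = 1/|argmax(t)| when *a* is among the
sentence's top-scoring values. Fixed inference rules map value tuples to
mutually exclusive gene classes (oncogene, tumor suppressor gene, biomarker),
giving class likelihoods Pr(class) = Σ_{tuples→class} Π Pr(aᵢ). A fact is
**reliable** iff it passes

* sufficiency: Pr(CCS=notinf) ≤ α and Pr(GCI=notinf) ≤ α   (α = 0.7)
* consistency: top class beats the runner-up by more than β  (β = 0.4)

Unreliable facts are ranked by the reliability score
rel = −(mean notinf likelihood)·H(class likelihoods) and the top-k sentences
(k = 250) go back to experts; each KB version is then rebuilt from scratch
from all accumulated annotations. See `docs/methods.md` for the full account.

## Worked example

Twenty synthetic gene–cancer pairs scored by a noisy automatic scorer
(Dirichlet concentration 8, 25% not-informative contamination), one
pipeline pass, one oracle-expert round:

```python
from gexkb import (Config, SyntheticSpec, generate_corpus, generate_scores,
                   run_iteration, merge_annotations, oracle_expert,
                   class_recovery, kb_stats)

spec = SyntheticSpec(n_pairs=20, sentences_per_pair=(4, 8),
                     concentration=8.0, contamination=0.25, seed=7)
records, truth = generate_corpus(spec)
scored = generate_scores(records, truth, spec)

kb0, batch = run_iteration(scored, Config(k=20))
print(kb_stats(kb0)["absolute"], kb_stats(kb0)["unreliable"])
print("recovery:", class_recovery(kb0, truth))
print("batch:", len(batch.sentence_ids), "sentences over", len(batch.entries), "facts")

manual = oracle_expert(batch, truth)                   # experts fix the batch
kb1, _ = run_iteration(merge_annotations(scored, manual), Config(k=20), version=1)
print("after re-annotation:", kb_stats(kb1)["unreliable"],
      "recovery:", class_recovery(kb1, truth))
```

prints

```
{'sentences': 69, 'articles': 48, 'genes': 16, 'cancers': 16, 'facts': 16} {'insufficient': 1, 'inconsistent': 3}
recovery: 0.8
batch: 18 sentences over 4 facts
after re-annotation: {'insufficient': 0, 'inconsistent': 0} recovery: 1.0
```

Read: the noisy scorer leaves 16 of 20 facts reliable (80% of true gene
classes recovered); the 4 unreliable facts contribute 18 sentences to the
annotation batch; after the oracle expert re-annotates exactly those
sentences and the KB is rebuilt, every fact is reliable and every true class
is recovered — the active-learning loop repaired precisely the uncertain
evidence.

The same stages are available from the shell:

```
gexkb simulate --pairs 20 --seed 7 --out work/
gexkb iterate --in work/corpus.jsonl --out-kb work/kb.json --out-batch work/batch.json
gexkb stats --kb work/kb.json
gexkb export --kb work/kb.json --format turtle --out work/kb.ttl
```

plus `ingest` (PubTator + MeSH→UMLS TSV → sentence JSONL), `score`,
`filter`, `enrich`, `check` and `rank` for running stages individually.

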
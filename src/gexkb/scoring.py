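"""Relation scoring: from entity-annotated sentences to aspect score vectors.

Any scorer satisfying :class:`Scorer` can be plugged in per aspect — one
method per aspect, each retrainable or replaceable without touching the
others.  The package ships two transparent reference scorers:

* :class:`UniformScorer` — maximal-uncertainty dummy, handy in tests;
* :class:`LexiconScorer` — additive keyword weights normalized to a
  distribution, so the whole pipeline is exercisable without a trained
  model.

Scoring always masks the gene and cancer surface forms first
(``@GENE@`` / ``@CANCER@``) so the scorer cannot key on entity identity.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Protocol, Sequence, runtime_checkable

from .schema import (
    ASPECTS, CCS, CGE, GCC, GCI,
    AspectScoreVector,
    EntityAnnotatedSentence,
    RelationAnnotatedSentence,
    SchemaError,
    canonicalize_aspect_value,
    validate_score_vector,
)

__all__ = [
    "GENE_TOKEN", "CANCER_TOKEN",
    "Scorer", "UniformScorer", "LexiconScorer", "DEFAULT_LEXICONS",
    "mask_entities", "manual_to_scores", "score_sentence",
    "argmax_values", "retain_for_kb", "FilterReport",
]

GENE_TOKEN = "@GENE@"
CANCER_TOKEN = "@CANCER@"


def mask_entities(
    s: EntityAnnotatedSentence,
    gene_token: str = GENE_TOKEN,
    cancer_token: str = CANCER_TOKEN,
) -> str:
    """Replace the gene and cancer spans with placeholder tokens.

    Replacement proceeds right-to-left so earlier offsets stay valid; the
    input record is not modified.  Overlapping spans are rejected upstream
    by :class:`EntityAnnotatedSentence`.
    """
    spans = sorted(
        [(s.gene_mention, gene_token), (s.cancer_mention, cancer_token)],
        key=lambda it: it[0].start,
        reverse=True,
    )
    text = s.text
    for mention, token in spans:
        text = text[: mention.start] + token + text[mention.end:]
    return text


@runtime_checkable
class Scorer(Protocol):
    """Scorer contract: one aspect, masked text in, distribution out."""

    name: str
    aspect: str
    version: str

    def score(self, masked_text: str) -> AspectScoreVector:  # pragma: no cover
        ...


@dataclass
class UniformScorer:
    """Maximal-entropy dummy scorer (1/|domain| everywhere)."""

    aspect: str
    name: str = "uniform"
    version: str = "1"

    def score(self, masked_text: str) -> AspectScoreVector:
        return AspectScoreVector.uniform(self.aspect)


# Keyword -> (value, weight).  Deliberately small and inspectable; matching
# is case-insensitive on word boundaries, multiword keys allowed.
DEFAULT_LEXICONS: Mapping[str, Mapping[str, tuple[str, float]]] = {
    CGE: {
        "upregulated": ("up", 2.0), "up-regulated": ("up", 2.0),
        "overexpressed": ("up", 2.0), "overexpression": ("up", 2.0),
        "increased": ("up", 1.0), "elevated": ("up", 1.0),
        "downregulated": ("down", 2.0), "down-regulated": ("down", 2.0),
        "underexpressed": ("down", 2.0), "decreased": ("down", 1.0),
        "reduced": ("down", 1.0), "silenced": ("down", 1.5),
    },
    CCS: {
        "progression": ("progression", 2.0), "growth": ("progression", 1.0),
        "proliferation": ("progression", 1.5), "metastasis": ("progression", 1.5),
        "invasion": ("progression", 1.0),
        "regression": ("regression", 2.0), "apoptosis": ("regression", 1.5),
        "suppressed tumor": ("regression", 2.0), "inhibited growth": ("regression", 2.0),
    },
    GCI: {
        "causes": ("causality", 2.0), "induces": ("causality", 2.0),
        "drives": ("causality", 2.0), "promotes": ("causality", 1.5),
        "leads to": ("causality", 1.5),
        "associated": ("correlation", 2.0), "correlated": ("correlation", 2.0),
        "observed": ("correlation", 1.0), "linked": ("correlation", 1.0),
    },
    GCC: {
        "expression": ("expression", 2.0), "expressed": ("expression", 2.0),
        "upregulated": ("expression", 1.5), "downregulated": ("expression", 1.5),
        "mrna levels": ("expression", 1.5),
        "mutation": ("other", 1.5), "polymorphism": ("other", 1.5),
        "methylation": ("other", 1.0),
    },
}


@dataclass
class LexiconScorer:
    """Additive keyword-lexicon scorer normalized to a distribution.

    Every domain value starts with a smoothing weight so the output is a
    proper distribution even with zero keyword hits (then uniform).
    """

    aspect: str
    lexicon: Optional[Mapping[str, tuple[str, float]]] = None
    smoothing: float = 0.5
    name: str = "baseline-lexicon"
    version: str = "1"

    def __post_init__(self) -> None:
        if self.lexicon is None:
            self.lexicon = DEFAULT_LEXICONS[self.aspect]
        for key, (value, weight) in self.lexicon.items():
            if canonicalize_aspect_value(self.aspect, value) != value:
                raise SchemaError(f"lexicon value {value!r} not canonical")
            if weight <= 0:
                raise SchemaError(f"non-positive weight for keyword {key!r}")

    def score(self, masked_text: str) -> AspectScoreVector:
        low = masked_text.lower()
        weights = {v: self.smoothing for v in ASPECTS[self.aspect]}
        for keyword, (value, weight) in self.lexicon.items():
            if re.search(rf"(?<!\w){re.escape(keyword)}(?!\w)", low):
                weights[value] += weight
        total = sum(weights.values())
        return AspectScoreVector(self.aspect, {v: w / total for v, w in weights.items()})


def manual_to_scores(labels: Mapping[str, str]) -> dict[str, AspectScoreVector]:
    """Expert labels (one value per aspect) -> exact one-hot score vectors."""
    missing = set(ASPECTS) - set(labels)
    if missing:
        raise SchemaError(f"manual annotation missing aspects: {sorted(missing)}")
    return {
        aspect: AspectScoreVector.one_hot(aspect, labels[aspect])
        for aspect in ASPECTS
    }


def score_sentence(
    s: EntityAnnotatedSentence,
    scorers: Mapping[str, Scorer],
    gene_token: str = GENE_TOKEN,
    cancer_token: str = CANCER_TOKEN,
) -> RelationAnnotatedSentence:
    """Mask, score all four aspects, validate, record provenance."""
    missing = set(ASPECTS) - set(scorers)
    if missing:
        raise SchemaError(f"no scorer for aspects: {sorted(missing)}")
    masked = mask_entities(s, gene_token, cancer_token)
    vectors: dict[str, AspectScoreVector] = {}
    for aspect in ASPECTS:
        scorer = scorers[aspect]
        vec = scorer.score(masked)
        if vec.aspect != aspect:
            raise SchemaError(
                f"scorer {scorer.name!r} returned aspect {vec.aspect!r} for {aspect}"
            )
        try:
            validate_score_vector(vec)
        except SchemaError as exc:
            raise SchemaError(f"scorer {scorer.name!r} emitted invalid vector: {exc}")
        vectors[aspect] = vec
    version = ";".join(
        f"{scorers[a].name}:{scorers[a].version}" for a in sorted(ASPECTS)
    )
    return RelationAnnotatedSentence(
        sentence=s,
        cge=vectors[CGE], ccs=vectors[CCS], gci=vectors[GCI], gcc=vectors[GCC],
        provenance="automatic",
        scorer_version=version,
    )


def argmax_values(
    r: RelationAnnotatedSentence, tolerance: float = 1e-9
) -> dict[str, frozenset[str]]:
    """Per aspect, the set of values attaining the maximum score."""
    return {aspect: r.vector(aspect).argmax_set(tolerance) for aspect in ASPECTS}


@dataclass
class FilterReport:
    """Rejection bookkeeping for the KB retention filter."""

    kept: int = 0
    rejected_gcc_other: int = 0
    rejected_cge_notinf: int = 0

    @property
    def total(self) -> int:
        return self.kept + self.rejected_gcc_other + self.rejected_cge_notinf


def retain_for_kb(
    rs: Iterable[RelationAnnotatedSentence], tolerance: float = 1e-9
) -> tuple[list[RelationAnnotatedSentence], FilterReport]:
    """Keep only sentences usable for knowledge enrichment.

    A sentence is retained iff its GCC argmax set is exactly
    ``{expression}`` and ``notinf`` is not in its CGE argmax set: sentences
    not about gene-expression-cancer associations are discarded, and
    not-informative expression changes are excluded to limit noise.  Ties
    are read conservatively — a GCC tie or a CGE tie involving ``notinf``
    rejects.  The filter is pure: kept + rejected partition the input.
    """
    kept: list[RelationAnnotatedSentence] = []
    report = FilterReport()
    for r in rs:
        if r.gcc.argmax_set(tolerance) != frozenset({"expression"}):
            report.rejected_gcc_other += 1
            continue
        if "notinf" in r.cge.argmax_set(tolerance):
            report.rejected_cge_notinf += 1
            continue
        kept.append(r)
        report.kept += 1
    return kept, report
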
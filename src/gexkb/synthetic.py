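"""Synthetic corpora with controlled ground truth.

The generator emulates the pipeline's inputs end to end: templated
sentences carrying exactly one gene and one cancer mention, plus
per-aspect score vectors drawn around each pair's true aspect tuple.
Every pair is assigned a gene class; its canonical (CGE, CCS, GCI) tuple
is drawn uniformly among the inference-rule tuples mapping to that class
(pairs with class ``None`` get a not-informative tuple).  All sentences
of a pair share the pair's tuple — the synthetic literature is
internally consistent; disagreement enters only through score noise.

Score noise is Dirichlet-distributed on the simplex with concentration
``c`` on the true value and 1 elsewhere (``c = inf`` gives exact one-hot
vectors), so every vector satisfies the distribution invariant by
construction.  With probability ``contamination`` an aspect's true value
is swapped for ``notinf`` before drawing — emulating sentences that do
not state the aspect.

All randomness flows from the single seed in the spec; no global state.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .active_learning import AnnotationBatch
from .enrichment import Fact
from .kb import KBVersion
from .reliability import GENE_CLASSES, INFERENCE_RULES
from .schema import (
    ASPECTS, CCS, CGE, GCC, GCI, RELATION_ASPECTS,
    AspectScoreVector,
    CancerEntity,
    EntityAnnotatedSentence,
    GeneEntity,
    Mention,
    RelationAnnotatedSentence,
    SchemaError,
)
from .scoring import manual_to_scores

__all__ = [
    "SyntheticSpec", "GroundTruth",
    "generate_corpus", "generate_scores", "oracle_expert", "class_recovery",
]

_CGE_WORD = {"up": "upregulated", "down": "downregulated", "notinf": "studied"}
_CCS_WORD = {
    "progression": "tumor progression",
    "regression": "tumor regression",
    "notinf": "clinical outcome",
}
_GCI_WORD = {
    "causality": "drives",
    "correlation": "is correlated with",
    "notinf": "was examined alongside",
}

#: Tuples per class, in deterministic order.
_CLASS_TUPLES: Mapping[Optional[str], tuple[tuple[str, str, str], ...]] = {
    **{
        cls: tuple(sorted(t for t, c in INFERENCE_RULES.items() if c == cls))
        for cls in GENE_CLASSES
    },
    None: (("up", "notinf", "notinf"), ("down", "notinf", "notinf")),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for a synthetic corpus.

    n_pairs
        number of distinct gene-cancer pairs.
    sentences_per_pair
        inclusive (low, high) bounds; per-pair counts drawn uniformly.
    concentration
        Dirichlet concentration on the true value; ``inf`` = one-hot.
    contamination
        probability that an aspect's true value is replaced by
        ``notinf`` before drawing the score vector.
    classes
        pool of per-pair true classes, drawn uniformly (may include
        ``None``).
    """

    n_pairs: int = 200
    sentences_per_pair: tuple[int, int] = (4, 8)
    concentration: float = 100.0
    contamination: float = 0.1
    seed: int = 0
    classes: tuple[Optional[str], ...] = GENE_CLASSES

    def __post_init__(self) -> None:
        if self.n_pairs < 0:
            raise SchemaError("n_pairs must be >= 0")
        lo, hi = self.sentences_per_pair
        if not (1 <= lo <= hi):
            raise SchemaError(f"invalid sentences_per_pair bounds {self.sentences_per_pair}")
        if not (self.concentration > 0):
            raise SchemaError("concentration must be positive")
        if not (0.0 <= self.contamination <= 1.0):
            raise SchemaError("contamination must lie in [0,1]")
        for cls in self.classes:
            if cls is not None and cls not in GENE_CLASSES:
                raise SchemaError(f"unknown gene class {cls!r}")


@dataclass
class GroundTruth:
    """Everything the generator knows: classes, tuples and labels."""

    pair_class: dict[tuple[int, str], Optional[str]] = field(default_factory=dict)
    pair_tuple: dict[tuple[int, str], tuple[str, str, str]] = field(default_factory=dict)
    sentences: dict[str, EntityAnnotatedSentence] = field(default_factory=dict)
    labels: dict[str, dict[str, str]] = field(default_factory=dict)


#: Phrasing variants so repeated evidence for a pair reads like distinct
#: sentences from distinct studies (duplicate evidence is deduplicated
#: downstream, so identical texts would collapse to one sentence).
_TEMPLATES = (
    "{symbol} is significantly {cge} and {gci} {ccs} in {cancer}.",
    "We found that {symbol} was {cge} and {gci} {ccs} in {cancer}.",
    "In {cancer}, {symbol} is {cge} and {gci} {ccs}.",
    "{symbol} was markedly {cge} and {gci} {ccs} in patients with {cancer}.",
    "Analysis showed {symbol} to be {cge} and it {gci} {ccs} in {cancer}.",
)


def _sentence_text(
    symbol: str, cancer_name: str, t: tuple[str, str, str], variant: int
) -> str:
    cge, ccs, gci = t
    return _TEMPLATES[variant % len(_TEMPLATES)].format(
        symbol=symbol, cancer=cancer_name,
        cge=_CGE_WORD[cge], ccs=_CCS_WORD[ccs], gci=_GCI_WORD[gci],
    )


def generate_corpus(spec: SyntheticSpec) -> tuple[list[EntityAnnotatedSentence], GroundTruth]:
    """Templated entity-annotated sentences plus their ground truth."""
    rng = np.random.default_rng([spec.seed, 0])
    truth = GroundTruth()
    records: list[EntityAnnotatedSentence] = []
    for i in range(spec.n_pairs):
        gene = GeneEntity(gene_id=1000 + i, symbol=f"GENE{i}")
        cancer = CancerEntity(cui=f"C{i:07d}", preferred_name=f"cancer type {i}")
        key = (gene.gene_id, cancer.cui)
        cls = spec.classes[int(rng.integers(len(spec.classes)))]
        tuples = _CLASS_TUPLES[cls]
        t = tuples[int(rng.integers(len(tuples)))]
        truth.pair_class[key] = cls
        truth.pair_tuple[key] = t
        lo, hi = spec.sentences_per_pair
        n_sentences = int(rng.integers(lo, hi + 1))
        for s in range(n_sentences):
            text = _sentence_text(gene.symbol, cancer.preferred_name, t, s)
            # spread a pair's evidence over articles, two sentences apiece
            doc_id = f"SYN{i:05d}-{s // 2}"
            sid = f"{doc_id}:{s}"
            g_start = text.index(gene.symbol)
            c_start = text.rindex(cancer.preferred_name)
            rec = EntityAnnotatedSentence(
                sentence_id=sid,
                document_id=doc_id,
                text=text,
                gene_mention=Mention(gene, g_start, g_start + len(gene.symbol)),
                cancer_mention=Mention(cancer, c_start, c_start + len(cancer.preferred_name)),
            )
            records.append(rec)
            truth.sentences[sid] = rec
            truth.labels[sid] = {
                CGE: t[0], CCS: t[1], GCI: t[2], GCC: "expression",
            }
    return records, truth


def _draw_vector(
    aspect: str, true_value: str, concentration: float, rng: np.random.Generator
) -> AspectScoreVector:
    values = ASPECTS[aspect]
    if math.isinf(concentration):
        return AspectScoreVector.one_hot(aspect, true_value)
    alpha = [concentration if v == true_value else 1.0 for v in values]
    draw = rng.dirichlet(alpha)
    draw = draw / draw.sum()  # pin the sum-to-one invariant against fp drift
    return AspectScoreVector(aspect, dict(zip(values, draw.tolist())))


def generate_scores(
    records: Iterable[EntityAnnotatedSentence],
    truth: GroundTruth,
    spec: SyntheticSpec,
) -> list[RelationAnnotatedSentence]:
    """Score vectors emulating an automatic scorer around the truth."""
    rng = np.random.default_rng([spec.seed, 1])
    out: list[RelationAnnotatedSentence] = []
    for rec in records:
        labels = truth.labels[rec.sentence_id]
        vectors: dict[str, AspectScoreVector] = {}
        for aspect in RELATION_ASPECTS:
            target = labels[aspect]
            if spec.contamination > 0 and rng.random() < spec.contamination:
                target = "notinf"
            vectors[aspect] = _draw_vector(aspect, target, spec.concentration, rng)
        vectors[GCC] = _draw_vector(GCC, labels[GCC], spec.concentration, rng)
        out.append(
            RelationAnnotatedSentence(
                sentence=rec,
                cge=vectors[CGE], ccs=vectors[CCS],
                gci=vectors[GCI], gcc=vectors[GCC],
                provenance="automatic",
                scorer_version="synthetic:1",
            )
        )
    return out


def oracle_expert(
    batch: AnnotationBatch, truth: GroundTruth
) -> list[RelationAnnotatedSentence]:
    """Perfect expert: one-hot manual annotations equal to ground truth."""
    out: list[RelationAnnotatedSentence] = []
    for sid in batch.sentence_ids:
        if sid not in truth.sentences:
            raise SchemaError(f"unknown sentence id {sid!r} in batch")
        vectors = manual_to_scores(truth.labels[sid])
        out.append(
            RelationAnnotatedSentence(
                sentence=truth.sentences[sid],
                cge=vectors[CGE], ccs=vectors[CCS],
                gci=vectors[GCI], gcc=vectors[GCC],
                provenance="manual",
                scorer_version="oracle:1",
            )
        )
    return out


def class_recovery(kb: KBVersion, truth: GroundTruth) -> float:
    """Fraction of classed pairs whose reliable fact carries the true class.

    Pairs with true class ``None`` are excluded from the denominator; a
    pair whose fact ends up unreliable (or absent) counts as a miss.
    """
    classed = {k: c for k, c in truth.pair_class.items() if c is not None}
    if not classed:
        raise SchemaError("ground truth contains no classed pairs")
    hits = sum(
        1 for key, cls in classed.items()
        if key in kb.reliable and kb.reliable[key].signature_type == cls
    )
    return hits / len(classed)
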
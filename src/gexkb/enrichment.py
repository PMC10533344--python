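"""Knowledge enrichment: aggregate per-sentence scores into facts.

All retained sentences mentioning the same (gene, cancer) pair form its
evidence set T.  For each relation aspect, the likelihood of value a_j is

    Pr(a_j) = sum_t score(a_j, t) * 1(a_j, t) / sum_t max_k score(a_k, t)

where the indicator 1(a_j, t) is 1/|argmax(t)| if a_j is among the
sentence's top-scoring values and 0 otherwise (ties share mass equally).
The likelihoods over a domain sum to one, so each fact carries a proper
distribution per aspect — the more the evidence agrees and the more
confident the scorers are, the more mass the consensus value receives.

GCC is consumed by the retention filter and is not part of a fact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .schema import (
    RELATION_ASPECTS,
    AspectScoreVector,
    CancerEntity,
    GeneEntity,
    RelationAnnotatedSentence,
    SchemaError,
)

__all__ = [
    "PairEvidence", "AspectProbabilitySet", "Fact",
    "group_by_pair", "indicator", "aspect_value_likelihood",
    "build_fact", "enrich",
]

logger = logging.getLogger(__name__)

FACT_TAGS = ("untested", "reliable", "insufficient", "inconsistent")


@dataclass(frozen=True)
class AspectProbabilitySet:
    """Aggregated likelihoods over one aspect's values for one fact."""

    aspect: str
    likelihoods: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "likelihoods", dict(self.likelihoods))

    def __getitem__(self, value: str) -> float:
        return self.likelihoods[value]


@dataclass(frozen=True)
class PairEvidence:
    """All retained sentences supporting one (gene, cancer) pair."""

    gene: GeneEntity
    cancer: CancerEntity
    sentences: tuple[RelationAnnotatedSentence, ...]

    def __post_init__(self) -> None:
        if not self.sentences:
            raise SchemaError("PairEvidence requires at least one sentence")
        for r in self.sentences:
            if r.sentence.pair_key != (self.gene.gene_id, self.cancer.cui):
                raise SchemaError(
                    f"sentence {r.sentence_id} does not mention pair "
                    f"({self.gene.gene_id}, {self.cancer.cui})"
                )


@dataclass(frozen=True)
class Fact:
    """A gene-cancer edge with aggregated aspect likelihoods.

    ``aspect_probabilities`` maps CGE/CCS/GCI to their probability sets;
    ``class_likelihoods`` and the reliability ``tag``/``signature_type``
    are filled by the reliability stage.  ``support`` holds
    (document_id, sentence_id) pairs of the underlying evidence.
    """

    gene: GeneEntity
    cancer: CancerEntity
    aspect_probabilities: Mapping[str, AspectProbabilitySet]
    support: tuple[tuple[str, str], ...]
    class_likelihoods: Optional[Mapping[str, float]] = None
    tag: str = "untested"
    signature_type: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "aspect_probabilities", dict(self.aspect_probabilities))
        if self.class_likelihoods is not None:
            object.__setattr__(self, "class_likelihoods", dict(self.class_likelihoods))
        if set(self.aspect_probabilities) != set(RELATION_ASPECTS):
            raise SchemaError(
                f"fact must carry exactly the aspects {RELATION_ASPECTS}"
            )
        if not self.support:
            raise SchemaError("fact requires non-empty support")
        if self.tag not in FACT_TAGS:
            raise SchemaError(f"unknown fact tag {self.tag!r}")
        if self.tag == "reliable" and self.signature_type is None:
            raise SchemaError("reliable fact requires a signature type")

    @property
    def key(self) -> tuple[int, str]:
        return (self.gene.gene_id, self.cancer.cui)

    @property
    def support_sentences(self) -> tuple[str, ...]:
        return tuple(sid for _, sid in self.support)

    @property
    def support_documents(self) -> tuple[str, ...]:
        return tuple(sorted({doc for doc, _ in self.support}))

    def likelihood(self, aspect: str, value: str) -> float:
        return self.aspect_probabilities[aspect][value]


def group_by_pair(
    rs: Iterable[RelationAnnotatedSentence],
) -> list[PairEvidence]:
    """Partition retained sentences by (gene_id, cui).

    Duplicate evidence — identical (document, text) for the same pair,
    e.g. the same sentence harvested from two sources — is counted once;
    the number of duplicates dropped is logged.  Groups are returned in
    sorted key order for determinism.
    """
    groups: dict[tuple[int, str], list[RelationAnnotatedSentence]] = {}
    seen: set[tuple[str, str, int, str]] = set()
    duplicates = 0
    for r in rs:
        gid, cui = r.sentence.pair_key
        dedup_key = (r.sentence.document_id, r.sentence.text, gid, cui)
        if dedup_key in seen:
            duplicates += 1
            continue
        seen.add(dedup_key)
        groups.setdefault((gid, cui), []).append(r)
    if duplicates:
        logger.info("group_by_pair dropped %d duplicate sentences", duplicates)
    out: list[PairEvidence] = []
    for key in sorted(groups):
        sentences = groups[key]
        out.append(
            PairEvidence(
                gene=sentences[0].sentence.gene,
                cancer=sentences[0].sentence.cancer,
                sentences=tuple(sentences),
            )
        )
    return out


def indicator(value: str, v: AspectScoreVector, tolerance: float = 1e-9) -> float:
    """Tie-sharing indicator: 1/|argmax| if ``value`` is top-scoring, else 0."""
    top = v.argmax_set(tolerance)
    return 1.0 / len(top) if value in top else 0.0


def aspect_value_likelihood(
    ev: PairEvidence, aspect: str, tolerance: float = 1e-9
) -> AspectProbabilitySet:
    """Aggregate one aspect's evidence into a probability set.

    The denominator sums each sentence's maximum score and is strictly
    positive for valid vectors (every max >= 1/|domain|); a zero
    denominator is rejected defensively.
    """
    vectors = [r.vector(aspect) for r in ev.sentences]
    denom = sum(max(v.scores.values()) for v in vectors)
    if denom <= 0.0:
        raise SchemaError(
            f"zero likelihood denominator for aspect {aspect} — invalid score vectors"
        )
    domain = vectors[0].scores.keys()
    likelihoods = {
        value: sum(v.scores[value] * indicator(value, v, tolerance) for v in vectors) / denom
        for value in domain
    }
    return AspectProbabilitySet(aspect, likelihoods)


def build_fact(ev: PairEvidence, tolerance: float = 1e-9) -> Fact:
    """Assemble the untested fact for one pair: the (CGE, CCS, GCI) triple."""
    aps = {
        aspect: aspect_value_likelihood(ev, aspect, tolerance)
        for aspect in RELATION_ASPECTS
    }
    support = tuple(
        sorted((r.sentence.document_id, r.sentence_id) for r in ev.sentences)
    )
    return Fact(
        gene=ev.gene,
        cancer=ev.cancer,
        aspect_probabilities=aps,
        support=support,
    )


def enrich(
    rs: Iterable[RelationAnnotatedSentence], tolerance: float = 1e-9
) -> list[Fact]:
    """Group retained sentences by pair and emit one fact per pair."""
    return [build_fact(ev, tolerance) for ev in group_by_pair(rs)]
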
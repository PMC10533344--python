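"""Active learning: uncertainty sampling over unreliable facts.

Each unreliable fact gets a reliability score

    rel = -((Pr(CCS=notinf) + Pr(GCI=notinf)) / 2) * H(S)

where H(S) is the entropy of the gene-class likelihoods (taken as
computed, without renormalization; 0*log 0 := 0).  rel is always <= 0;
the most negative facts combine heavy not-informative mass with a flat
class distribution — exactly the facts whose evidence experts can fix
fastest.  Facts are ranked by ascending rel and sentences are collected
fact-by-fact until the batch holds k of them.

The logarithm base only rescales every score by the same positive factor,
so the ranking is base-invariant; the default is the natural log.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .enrichment import Fact, enrich
from .kb import KBVersion, populate
from .reliability import tag_facts
from .schema import CCS, GCI, Config, RelationAnnotatedSentence, SchemaError
from .scoring import retain_for_kb

__all__ = [
    "signature_entropy", "reliability_score",
    "BatchEntry", "AnnotationBatch", "rank_and_select",
    "merge_annotations", "run_iteration",
]


def signature_entropy(
    likelihoods: Mapping[str, float], log_base: Optional[float] = None
) -> float:
    """Entropy of the gene-class likelihoods, H = -sum p log p.

    Applied to the likelihoods as computed (possibly sub-normalized);
    zero-probability terms contribute nothing.  Always >= 0 since every
    p <= 1.
    """
    h = 0.0
    for p in likelihoods.values():
        if p < 0:
            raise SchemaError(f"negative class likelihood {p!r}")
        if p > 0.0:
            h -= p * (math.log(p) if log_base is None else math.log(p, log_base))
    return h


def reliability_score(f: Fact, cfg: Config) -> float:
    """rel(e) = -(mean not-informative CCS/GCI likelihood) * H(S); <= 0."""
    if f.class_likelihoods is None:
        raise SchemaError(f"fact {f.key} has no class likelihoods; tag it first")
    notinf = (f.likelihood(CCS, "notinf") + f.likelihood(GCI, "notinf")) / 2.0
    return -notinf * signature_entropy(f.class_likelihoods, cfg.log_base)


@dataclass(frozen=True)
class BatchEntry:
    fact_key: tuple[int, str]
    score: float
    sentence_ids: tuple[str, ...]


@dataclass(frozen=True)
class AnnotationBatch:
    """Ranked re-annotation batch: at most k sentences, most uncertain first."""

    version: int
    entries: tuple[BatchEntry, ...]

    @property
    def sentence_ids(self) -> tuple[str, ...]:
        return tuple(sid for e in self.entries for sid in e.sentence_ids)

    @property
    def fact_keys(self) -> tuple[tuple[int, str], ...]:
        return tuple(e.fact_key for e in self.entries)


def rank_and_select(
    unreliable: Iterable[Fact], cfg: Config, version: int = 0
) -> AnnotationBatch:
    """Rank unreliable facts ascending by rel and gather up to k sentences.

    Ties are broken by fact key (gene_id, cui) for reproducibility.
    Within a fact, sentences enter in (document_id, sentence_id) order;
    the last fact's sentences may be truncated to honor the budget.
    """
    scored = sorted(
        ((reliability_score(f, cfg), f) for f in unreliable),
        key=lambda it: (it[0], it[1].key),
    )
    entries: list[BatchEntry] = []
    budget = cfg.k
    for score, f in scored:
        if budget <= 0:
            break
        sids = [sid for _, sid in sorted(f.support)][:budget]
        budget -= len(sids)
        entries.append(BatchEntry(fact_key=f.key, score=score, sentence_ids=tuple(sids)))
    return AnnotationBatch(version=version, entries=tuple(entries))


def merge_annotations(
    automatic: Iterable[RelationAnnotatedSentence],
    manual: Iterable[RelationAnnotatedSentence] = (),
) -> list[RelationAnnotatedSentence]:
    """Union of annotations keyed by sentence id; manual wins on conflict."""
    merged: dict[str, RelationAnnotatedSentence] = {}
    for r in automatic:
        merged[r.sentence_id] = r
    for r in manual:
        if r.provenance != "manual":
            raise SchemaError(f"expected manual provenance for {r.sentence_id}")
        merged[r.sentence_id] = r
    return [merged[sid] for sid in sorted(merged)]


def run_iteration(
    annotations: Iterable[RelationAnnotatedSentence],
    cfg: Config,
    version: int = 0,
) -> tuple[KBVersion, AnnotationBatch]:
    """One bootstrap/deploy pass: filter, enrich, test, populate, rank.

    ``annotations`` is the union of all manual and automatic
    relation-annotated sentences available at this iteration (use
    :func:`merge_annotations` to give manual re-annotations precedence).
    The KB version is rebuilt from scratch; the returned batch samples the
    new version's unreliable facts for the next round of expert
    annotation.
    """
    annotations = list(annotations)
    retained, _ = retain_for_kb(annotations, cfg.tolerance)
    facts = tag_facts(enrich(retained, cfg.tolerance), cfg)
    manual = sum(1 for r in retained if r.provenance == "manual")
    kb = populate(
        facts, cfg, version=version,
        manual_sentences=manual,
        automatic_sentences=len(retained) - manual,
    )
    batch = rank_and_select(kb.unreliable.values(), cfg, version=version)
    return kb, batch
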
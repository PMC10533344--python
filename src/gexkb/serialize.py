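"""JSON Lines exchange formats for sentences and annotations.

One JSON object per line.  Entity-annotated sentence fields::

    {"sentence_id": ..., "document_id": ..., "text": ...,
     "gene": {"gene_id": int, "symbol": str, "start": int, "end": int},
     "cancer": {"cui": str, "preferred_name": str, "semantic_type": str,
                "start": int, "end": int}}

A relation-annotated sentence nests the above under ``"sentence"`` and
adds ``"scores"`` (aspect -> value -> score), ``"provenance"`` and
``"scorer_version"``.
"""

from __future__ import annotations

import json
from typing import IO, Iterable, Iterator, Mapping

from .schema import (
    ASPECTS, CCS, CGE, GCC, GCI,
    AspectScoreVector,
    CancerEntity,
    EntityAnnotatedSentence,
    GeneEntity,
    Mention,
    RelationAnnotatedSentence,
)

__all__ = [
    "sentence_to_dict", "sentence_from_dict",
    "relation_to_dict", "relation_from_dict",
    "write_jsonl", "read_jsonl",
]


def sentence_to_dict(s: EntityAnnotatedSentence) -> dict:
    g, c = s.gene_mention, s.cancer_mention
    return {
        "sentence_id": s.sentence_id,
        "document_id": s.document_id,
        "text": s.text,
        "gene": {
            "gene_id": g.entity.gene_id, "symbol": g.entity.symbol,
            "start": g.start, "end": g.end,
        },
        "cancer": {
            "cui": c.entity.cui, "preferred_name": c.entity.preferred_name,
            "semantic_type": c.entity.semantic_type,
            "start": c.start, "end": c.end,
        },
    }


def sentence_from_dict(d: Mapping) -> EntityAnnotatedSentence:
    g, c = d["gene"], d["cancer"]
    return EntityAnnotatedSentence(
        sentence_id=d["sentence_id"],
        document_id=d["document_id"],
        text=d["text"],
        gene_mention=Mention(
            GeneEntity(g["gene_id"], g.get("symbol", "")), g["start"], g["end"]
        ),
        cancer_mention=Mention(
            CancerEntity(c["cui"], c.get("preferred_name", ""),
                         c.get("semantic_type", "T191")),
            c["start"], c["end"],
        ),
    )


def relation_to_dict(r: RelationAnnotatedSentence) -> dict:
    return {
        "sentence": sentence_to_dict(r.sentence),
        "scores": {a: dict(r.vector(a).scores) for a in ASPECTS},
        "provenance": r.provenance,
        "scorer_version": r.scorer_version,
    }


def relation_from_dict(d: Mapping) -> RelationAnnotatedSentence:
    vectors = {
        a: AspectScoreVector(a, d["scores"][a]) for a in ASPECTS
    }
    return RelationAnnotatedSentence(
        sentence=sentence_from_dict(d["sentence"]),
        cge=vectors[CGE], ccs=vectors[CCS], gci=vectors[GCI], gcc=vectors[GCC],
        provenance=d.get("provenance", "automatic"),
        scorer_version=d.get("scorer_version", ""),
    )


def write_jsonl(items: Iterable[dict], stream: IO[str]) -> None:
    for item in items:
        stream.write(json.dumps(item, sort_keys=True) + "\n")


def read_jsonl(stream: IO[str]) -> Iterator[dict]:
    for line in stream:
        if line.strip():
            yield json.loads(line)
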
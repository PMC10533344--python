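"""Versioned knowledge-base store, statistics and export.

A KB version is the graph rebuilt from scratch at iteration j: its edges
are the *reliable* facts only; facts tagged ``insufficient`` or
``inconsistent`` are retained separately — they feed the next
active-learning batch and cross-version reduction reports.

Exports: JSON (full fidelity, byte-deterministic) and RDF (Turtle and
N-Triples; the N-Triples dialect is line-sorted and therefore
byte-deterministic as well).  Gene and cancer resources link out to NCBI
Gene and UMLS via identifiers.org IRIs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

from rdflib import RDF, Graph, Literal, Namespace, URIRef
from rdflib.namespace import XSD

from .enrichment import AspectProbabilitySet, Fact
from .schema import RELATION_ASPECTS, CancerEntity, Config, GeneEntity, SchemaError

__all__ = [
    "KBVersion", "populate", "kb_stats", "unreliable_overlap",
    "export_json", "import_json", "export_rdf", "fact_to_dict", "fact_from_dict",
]

GEXKB = Namespace("https://w3id.org/gexkb/vocab#")
NCBIGENE = "https://identifiers.org/ncbigene:"
UMLS = "https://identifiers.org/umls:"

UNRELIABLE_TAGS = ("insufficient", "inconsistent")


@dataclass(frozen=True)
class KBVersion:
    """One build of the knowledge base.

    ``reliable`` facts constitute the published graph; ``unreliable``
    facts (keyed identically) are kept for the next annotation batch and
    for overlap reports.  Fact identity across versions is the
    (gene_id, cui) key.
    """

    version: int
    reliable: Mapping[tuple[int, str], Fact]
    unreliable: Mapping[tuple[int, str], Fact]
    alpha: float
    beta: float
    k: int
    manual_sentences: int = 0
    automatic_sentences: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "reliable", dict(self.reliable))
        object.__setattr__(self, "unreliable", dict(self.unreliable))

    @property
    def facts(self) -> list[Fact]:
        return list(self.reliable.values()) + list(self.unreliable.values())

    @property
    def genes(self) -> dict[int, GeneEntity]:
        return {f.gene.gene_id: f.gene for f in self.facts}

    @property
    def cancers(self) -> dict[str, CancerEntity]:
        return {f.cancer.cui: f.cancer for f in self.facts}


def populate(
    tagged_facts: Iterable[Fact],
    cfg: Config,
    version: int = 0,
    manual_sentences: int = 0,
    automatic_sentences: int = 0,
) -> KBVersion:
    """Partition tagged facts into a KB version.

    Untested facts and duplicate fact keys are rejected; content is
    deterministic for identical input.
    """
    reliable: dict[tuple[int, str], Fact] = {}
    unreliable: dict[tuple[int, str], Fact] = {}
    for f in tagged_facts:
        if f.tag == "untested":
            raise SchemaError(f"fact {f.key} is untested; run reliability tagging first")
        bucket = reliable if f.tag == "reliable" else unreliable
        if f.key in reliable or f.key in unreliable:
            raise SchemaError(f"duplicate fact key {f.key}")
        bucket[f.key] = f
    return KBVersion(
        version=version,
        reliable={k: reliable[k] for k in sorted(reliable)},
        unreliable={k: unreliable[k] for k in sorted(unreliable)},
        alpha=cfg.alpha,
        beta=cfg.beta,
        k=cfg.k,
        manual_sentences=manual_sentences,
        automatic_sentences=automatic_sentences,
    )


def kb_stats(v: KBVersion) -> dict:
    """Descriptive statistics of a version.

    Absolute counts (sentences, articles, genes, cancers, facts), the
    manual/automatic partition, conditional ratios (rounded to 2
    decimals; ``None`` when undefined) and per-class reliable-fact
    counts.  Counts cover the published (reliable) graph.
    """
    facts = list(v.reliable.values())
    sentences = {sid for f in facts for sid in f.support_sentences}
    articles = {doc for f in facts for doc in f.support_documents}
    per_class: dict[str, int] = {}
    for f in facts:
        per_class[f.signature_type] = per_class.get(f.signature_type, 0) + 1

    def ratio(a: int, b: int) -> Optional[float]:
        return round(a / b, 2) if b else None

    n_f, n_s, n_a = len(facts), len(sentences), len(articles)
    return {
        "version": v.version,
        "thresholds": {"alpha": v.alpha, "beta": v.beta, "k": v.k},
        "partition": {
            "manual": v.manual_sentences,
            "automatic": v.automatic_sentences,
        },
        "absolute": {
            "sentences": n_s,
            "articles": n_a,
            "genes": len({f.gene.gene_id for f in facts}),
            "cancers": len({f.cancer.cui for f in facts}),
            "facts": n_f,
        },
        "conditional": {
            "sentence_per_article": ratio(n_s, n_a),
            "sentence_per_fact": ratio(n_s, n_f),
            "article_per_fact": ratio(n_a, n_f),
        },
        "signature_types": dict(sorted(per_class.items())),
        "unreliable": {
            tag: sum(1 for f in v.unreliable.values() if f.tag == tag)
            for tag in UNRELIABLE_TAGS
        },
    }


def unreliable_overlap(v_a: KBVersion, v_b: KBVersion) -> dict[str, int]:
    """Per tag, how many of v_a's unreliable facts stay unreliable in v_b.

    A fact key counts under tag t if it is unreliable with tag t in v_a
    and unreliable with tag t in v_b — the cross-version reduction
    statistic that tracks whether re-annotation shrinks the unreliable
    pool.
    """
    out: dict[str, int] = {}
    for tag in UNRELIABLE_TAGS:
        keys_a = {k for k, f in v_a.unreliable.items() if f.tag == tag}
        keys_b = {k for k, f in v_b.unreliable.items() if f.tag == tag}
        out[tag] = len(keys_a & keys_b)
    return out


# ---------------------------------------------------------------------------
# JSON export / import (full fidelity)
# ---------------------------------------------------------------------------

def fact_to_dict(f: Fact) -> dict:
    return {
        "gene": {"gene_id": f.gene.gene_id, "symbol": f.gene.symbol},
        "cancer": {
            "cui": f.cancer.cui,
            "preferred_name": f.cancer.preferred_name,
            "semantic_type": f.cancer.semantic_type,
        },
        "aspect_probabilities": {
            a: dict(f.aspect_probabilities[a].likelihoods) for a in RELATION_ASPECTS
        },
        "class_likelihoods": dict(f.class_likelihoods)
        if f.class_likelihoods is not None else None,
        "tag": f.tag,
        "signature_type": f.signature_type,
        "support": [list(pair) for pair in f.support],
    }


def fact_from_dict(d: Mapping) -> Fact:
    return Fact(
        gene=GeneEntity(**d["gene"]),
        cancer=CancerEntity(**d["cancer"]),
        aspect_probabilities={
            a: AspectProbabilitySet(a, probs)
            for a, probs in d["aspect_probabilities"].items()
        },
        class_likelihoods=d.get("class_likelihoods"),
        tag=d.get("tag", "untested"),
        signature_type=d.get("signature_type"),
        support=tuple((doc, sid) for doc, sid in d["support"]),
    )


def export_json(v: KBVersion) -> str:
    """Deterministic JSON serialization of a full version."""
    payload = {
        "version": v.version,
        "thresholds": {"alpha": v.alpha, "beta": v.beta, "k": v.k},
        "partition": {
            "manual": v.manual_sentences,
            "automatic": v.automatic_sentences,
        },
        "reliable": [fact_to_dict(v.reliable[k]) for k in sorted(v.reliable)],
        "unreliable": [fact_to_dict(v.unreliable[k]) for k in sorted(v.unreliable)],
    }
    return json.dumps(payload, sort_keys=True, indent=1)


def import_json(text: Union[str, IO[str]]) -> KBVersion:
    """Inverse of :func:`export_json`."""
    data = json.loads(text.read() if hasattr(text, "read") else text)
    reliable = {f.key: f for f in map(fact_from_dict, data["reliable"])}
    unreliable = {f.key: f for f in map(fact_from_dict, data["unreliable"])}
    return KBVersion(
        version=data["version"],
        reliable=reliable,
        unreliable=unreliable,
        alpha=data["thresholds"]["alpha"],
        beta=data["thresholds"]["beta"],
        k=data["thresholds"]["k"],
        manual_sentences=data["partition"]["manual"],
        automatic_sentences=data["partition"]["automatic"],
    )


# ---------------------------------------------------------------------------
# RDF export
# ---------------------------------------------------------------------------

def _rdf_graph(v: KBVersion, include_unreliable: bool = False) -> Graph:
    g = Graph()
    g.bind("gexkb", GEXKB)
    facts = list(v.reliable.values())
    if include_unreliable:
        facts += list(v.unreliable.values())
    for f in sorted(facts, key=lambda f: f.key):
        gene_iri = URIRef(f"{NCBIGENE}{f.gene.gene_id}")
        cancer_iri = URIRef(f"{UMLS}{f.cancer.cui}")
        fact_iri = URIRef(f"https://w3id.org/gexkb/fact/{f.gene.gene_id}-{f.cancer.cui}")
        g.add((gene_iri, RDF.type, GEXKB.Gene))
        if f.gene.symbol:
            g.add((gene_iri, GEXKB.symbol, Literal(f.gene.symbol)))
        g.add((cancer_iri, RDF.type, GEXKB.Cancer))
        if f.cancer.preferred_name:
            g.add((cancer_iri, GEXKB.preferredName, Literal(f.cancer.preferred_name)))
        g.add((fact_iri, RDF.type, GEXKB.Fact))
        g.add((fact_iri, GEXKB.gene, gene_iri))
        g.add((fact_iri, GEXKB.cancer, cancer_iri))
        g.add((fact_iri, GEXKB.tag, Literal(f.tag)))
        if f.signature_type is not None:
            g.add((fact_iri, GEXKB.signatureType, Literal(f.signature_type)))
        if f.class_likelihoods is not None:
            for cls, p in sorted(f.class_likelihoods.items()):
                g.add((
                    fact_iri,
                    GEXKB[f"{cls}Likelihood"],
                    Literal(float(p), datatype=XSD.double),
                ))
        for doc, sid in f.support:
            g.add((fact_iri, GEXKB.supportSentence, Literal(sid)))
            g.add((fact_iri, GEXKB.supportDocument, Literal(doc)))
    return g


def export_rdf(
    v: KBVersion, fmt: str = "turtle", include_unreliable: bool = False
) -> str:
    """Serialize a version as RDF.

    ``fmt`` is ``turtle`` or ``ntriples``; the N-Triples output is sorted
    line-wise, making two exports of one version byte-identical.
    """
    g = _rdf_graph(v, include_unreliable)
    if fmt in ("ntriples", "nt"):
        body = g.serialize(format="nt")
        lines = sorted(line for line in body.splitlines() if line.strip())
        return "\n".join(lines) + "\n"
    if fmt == "turtle":
        return g.serialize(format="turtle")
    raise SchemaError(f"unknown RDF format {fmt!r}")
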
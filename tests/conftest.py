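"""Shared fixtures: worked-example evidence sets and random-fact builders."""

from __future__ import annotations

import numpy as np
import pytest

from gexkb.enrichment import AspectProbabilitySet, Fact
from gexkb.schema import (
    ASPECTS, CCS, CGE, GCC, GCI,
    AspectScoreVector,
    CancerEntity,
    EntityAnnotatedSentence,
    GeneEntity,
    Mention,
    RelationAnnotatedSentence,
)


def make_sentence(
    doc: str,
    gene_id: int = 7157,
    cui: str = "C0000001",
    text: str = "GENE expression rises in tumor",
    index: int = 0,
) -> EntityAnnotatedSentence:
    """Minimal well-formed entity-annotated sentence for one pair."""
    return EntityAnnotatedSentence(
        sentence_id=f"{doc}:{index}",
        document_id=doc,
        text=text,
        gene_mention=Mention(GeneEntity(gene_id, "GENE"), 0, 4),
        cancer_mention=Mention(CancerEntity(cui, "tumor"), len(text) - 5, len(text)),
    )


def peaked_vector(aspect: str, top: str, score: float) -> AspectScoreVector:
    """Top value at ``score``; residual mass uniform over the rest.

    How the residual is spread is irrelevant to the enrichment formula
    (residual-mass invariance), so this is the canonical encoding of the
    worked examples, which print only each aspect's top value and score.
    """
    rest = [v for v in ASPECTS[aspect] if v != top]
    r = (1.0 - score) / len(rest)
    return AspectScoreVector(aspect, {top: score, **{v: r for v in rest}})


def make_relation(
    doc: str,
    cge: tuple[str, float],
    ccs: tuple[str, float],
    gci: tuple[str, float],
    gcc: tuple[str, float] = ("expression", 1.0),
    gene_id: int = 7157,
    cui: str = "C0000001",
) -> RelationAnnotatedSentence:
    return RelationAnnotatedSentence(
        sentence=make_sentence(doc, gene_id, cui),
        cge=peaked_vector(CGE, *cge),
        ccs=peaked_vector(CCS, *ccs),
        gci=peaked_vector(GCI, *gci),
        gcc=peaked_vector(GCC, *gcc),
    )


@pytest.fixture
def example3_sentences() -> list[RelationAnnotatedSentence]:
    """The four-sentence evidence set of the worked aggregation example.

    Per-sentence top values/scores: t1 CGE(up,.7) CCS(progression,.6)
    GCI(notinf,.9); t2 CGE(down,.8) CCS(regression,.9) GCI(causality,.6);
    t3 CGE(notinf,.8) CCS(progression,.9) GCI(notinf,.9); t4 one-hot
    (up, regression, correlation).  t3 is expected to be filtered out.
    """
    return [
        make_relation("t1", ("up", 0.7), ("progression", 0.6), ("notinf", 0.9)),
        make_relation("t2", ("down", 0.8), ("regression", 0.9), ("causality", 0.6)),
        make_relation("t3", ("notinf", 0.8), ("progression", 0.9), ("notinf", 0.9)),
        make_relation("t4", ("up", 1.0), ("regression", 1.0), ("correlation", 1.0)),
    ]


def make_fact(
    cge: dict[str, float],
    ccs: dict[str, float],
    gci: dict[str, float],
    gene_id: int = 7157,
    cui: str = "C0000001",
    class_likelihoods: dict[str, float] | None = None,
    tag: str = "untested",
    signature_type: str | None = None,
) -> Fact:
    return Fact(
        gene=GeneEntity(gene_id, "GENE"),
        cancer=CancerEntity(cui, "tumor"),
        aspect_probabilities={
            CGE: AspectProbabilitySet(CGE, cge),
            CCS: AspectProbabilitySet(CCS, ccs),
            GCI: AspectProbabilitySet(GCI, gci),
        },
        support=(("doc1", "doc1:0"),),
        class_likelihoods=class_likelihoods,
        tag=tag,
        signature_type=signature_type,
    )


@pytest.fixture
def example4_facts() -> tuple[Fact, Fact]:
    """Two facts mirroring the worked reliability example.

    f1: Pr(CCS=notinf)=0.1, Pr(GCI=notinf)=0.3, classes 0.7/0.2/0.1;
    f2: Pr(CCS=notinf)=0.6, Pr(GCI=notinf)=0.5, classes 0.5/0.4/0.1.
    Class likelihoods are supplied directly, as the example states them.
    """
    f1 = make_fact(
        cge={"up": 0.6, "down": 0.4, "notinf": 0.0},
        ccs={"progression": 0.5, "regression": 0.4, "notinf": 0.1},
        gci={"causality": 0.4, "correlation": 0.3, "notinf": 0.3},
        gene_id=1001, cui="C0000011",
        class_likelihoods={
            "oncogene": 0.7, "tumor_suppressor_gene": 0.2, "biomarker": 0.1,
        },
    )
    f2 = make_fact(
        cge={"up": 0.5, "down": 0.5, "notinf": 0.0},
        ccs={"progression": 0.3, "regression": 0.1, "notinf": 0.6},
        gci={"causality": 0.3, "correlation": 0.2, "notinf": 0.5},
        gene_id=1002, cui="C0000012",
        class_likelihoods={
            "oncogene": 0.5, "tumor_suppressor_gene": 0.4, "biomarker": 0.1,
        },
    )
    return f1, f2


def random_fact(rng: np.random.Generator, cge_notinf_zero: bool = True) -> Fact:
    """A fact with Dirichlet-random aspect-probability sets.

    ``cge_notinf_zero`` pins Pr(CGE=notinf)=0, as holds for every fact
    built from filtered evidence.
    """

    def draw(aspect: str, zero: str | None = None) -> dict[str, float]:
        values = [v for v in ASPECTS[aspect] if v != zero]
        probs = rng.dirichlet(np.ones(len(values)))
        out = dict(zip(values, probs.tolist()))
        if zero is not None:
            out[zero] = 0.0
        return out

    return make_fact(
        cge=draw(CGE, zero="notinf" if cge_notinf_zero else None),
        ccs=draw(CCS),
        gci=draw(GCI),
        gene_id=int(rng.integers(1, 10_000)),
        cui=f"C{int(rng.integers(0, 10_000_000)):07d}",
    )
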
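"""Reliability testing: gene-class inference and fact tagging.

A multi-aspect value tuple (CGE, CCS, GCI) maps to one of three mutually
exclusive gene classes:

=====  =============  ===========  =====================
CGE    CCS            GCI          class
=====  =============  ===========  =====================
up     progression    causality    oncogene
up     regression     causality    tumor suppressor gene
down   regression     causality    oncogene
down   progression    causality    tumor suppressor gene
up|down progr.|regr.  correlation  biomarker
=====  =============  ===========  =====================

Tuples containing ``notinf`` map to no class.  Treating aspects as
independent, the class likelihood sums the products of aspect-value
likelihoods over the tuples mapping to that class; class mass is
sub-normalized (notinf tuples carry the remainder) and is deliberately
not renormalized before the checks.

A fact is tagged in two stages:

1. *sufficiency*: fail (tag ``insufficient``) if Pr(CCS=notinf) > alpha
   or Pr(GCI=notinf) > alpha — too much of the evidence is not
   informative;
2. *consistency*: fail (tag ``inconsistent``) unless the top class
   likelihood exceeds the runner-up by strictly more than beta —
   contradictory evidence supports competing classes.

Facts passing both are ``reliable`` and carry the top class as their
signature type.  Comparisons are strict, so equality with a threshold
passes sufficiency and fails consistency, and a top-two tie never
produces a reliable fact.
"""

from __future__ import annotations

import itertools
from dataclasses import replace
from typing import Mapping, Optional, Sequence

from .enrichment import Fact
from .schema import ASPECTS, CCS, CGE, GCI, Config, SchemaError, canonicalize_aspect_value

__all__ = [
    "GENE_CLASSES", "INFERENCE_RULES",
    "signature", "class_likelihoods", "sufficiency_check",
    "consistency_check", "tag_fact", "tag_facts",
]

ONCOGENE = "oncogene"
TSG = "tumor_suppressor_gene"
BIOMARKER = "biomarker"
GENE_CLASSES: tuple[str, ...] = (ONCOGENE, TSG, BIOMARKER)


def _build_rules() -> dict[tuple[str, str, str], str]:
    rules = {
        ("up", "progression", "causality"): ONCOGENE,
        ("up", "regression", "causality"): TSG,
        ("down", "regression", "causality"): ONCOGENE,
        ("down", "progression", "causality"): TSG,
    }
    for cge, ccs in itertools.product(("up", "down"), ("progression", "regression")):
        rules[(cge, ccs, "correlation")] = BIOMARKER
    return rules


#: Tuple (cge, ccs, gci) -> gene class; eight mapped tuples in total.
INFERENCE_RULES: Mapping[tuple[str, str, str], str] = _build_rules()


def signature(values: Sequence[str]) -> Optional[str]:
    """Map a (CGE, CCS, GCI) value tuple to its gene class, or ``None``.

    Aliases are canonicalized (``observation`` -> ``correlation``); any
    tuple containing ``notinf`` has no class.
    """
    cge, ccs, gci = values
    key = (
        canonicalize_aspect_value(CGE, cge),
        canonicalize_aspect_value(CCS, ccs),
        canonicalize_aspect_value(GCI, gci),
    )
    return INFERENCE_RULES.get(key)


def class_likelihoods(f: Fact) -> dict[str, float]:
    """Signature-type likelihood per gene class.

    Pr(class) = sum over tuples mapping to the class of the product of
    aspect-value likelihoods; written in closed form over the rule table:

        Pr(oncogene)  = (Pr(up)Pr(prog) + Pr(down)Pr(regr)) Pr(caus)
        Pr(tsg)       = (Pr(up)Pr(regr) + Pr(down)Pr(prog)) Pr(caus)
        Pr(biomarker) = (Pr(up)+Pr(down)) (Pr(prog)+Pr(regr)) Pr(corr)
    """
    cge = f.aspect_probabilities[CGE]
    ccs = f.aspect_probabilities[CCS]
    gci = f.aspect_probabilities[GCI]
    up, down = cge["up"], cge["down"]
    prog, regr = ccs["progression"], ccs["regression"]
    caus, corr = gci["causality"], gci["correlation"]
    return {
        ONCOGENE: (up * prog + down * regr) * caus,
        TSG: (up * regr + down * prog) * caus,
        BIOMARKER: (up + down) * (prog + regr) * corr,
    }


def sufficiency_check(f: Fact, alpha: float) -> bool:
    """Pass iff neither not-informative likelihood strictly exceeds alpha."""
    return not (
        f.likelihood(CCS, "notinf") > alpha or f.likelihood(GCI, "notinf") > alpha
    )


def consistency_check(
    likelihoods: Mapping[str, float], beta: float
) -> tuple[bool, Optional[str]]:
    """Pass iff the top class beats the runner-up by strictly more than beta.

    Returns (pass, candidate class); the candidate is the top class on
    pass and ``None`` on failure.  For beta >= 0 at most one class can
    satisfy the margin, so the candidate is unambiguous.
    """
    if set(likelihoods) != set(GENE_CLASSES):
        raise SchemaError(f"expected likelihoods for {GENE_CLASSES}")
    ranked = sorted(likelihoods.items(), key=lambda it: (-it[1], it[0]))
    (top_class, top), (_, second) = ranked[0], ranked[1]
    if top - second > beta:
        return True, top_class
    return False, None


def tag_fact(f: Fact, cfg: Config) -> Fact:
    """Run both checks and tag the fact; deterministic and idempotent.

    Class likelihoods are computed from the aspect-probability sets unless
    already present on the fact (e.g. supplied externally), and are stored
    on the returned fact in every case.  Sufficiency is evaluated first;
    only facts passing it are inspected for consistency.
    """
    cls = dict(f.class_likelihoods) if f.class_likelihoods is not None \
        else class_likelihoods(f)
    if not sufficiency_check(f, cfg.alpha):
        return replace(f, class_likelihoods=cls, tag="insufficient", signature_type=None)
    ok, candidate = consistency_check(cls, cfg.beta)
    if not ok:
        return replace(f, class_likelihoods=cls, tag="inconsistent", signature_type=None)
    # the reliable signature type is the highest-likelihood class, which
    # coincides with the consistency candidate by construction
    return replace(f, class_likelihoods=cls, tag="reliable", signature_type=candidate)


def tag_facts(facts: Sequence[Fact], cfg: Config) -> list[Fact]:
    """Tag every fact in a collection."""
    return [tag_fact(f, cfg) for f in facts]
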
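"""Gene-class inference rules, class likelihoods, reliability checks."""

import itertools

import numpy as np
import pytest

from gexkb.enrichment import enrich
from gexkb.reliability import (
    GENE_CLASSES,
    INFERENCE_RULES,
    class_likelihoods,
    consistency_check,
    signature,
    sufficiency_check,
    tag_fact,
    tag_facts,
)
from gexkb.schema import ASPECTS, CCS, CGE, GCI, Config, SchemaError
from gexkb.scoring import retain_for_kb

from conftest import make_fact, random_fact


def brute_force_class_likelihoods(fact):
    """Independent oracle: enumerate all 27 value tuples, sum by class."""
    cge = fact.aspect_probabilities[CGE]
    ccs = fact.aspect_probabilities[CCS]
    gci = fact.aspect_probabilities[GCI]
    out = {cls: 0.0 for cls in GENE_CLASSES}
    for t in itertools.product(ASPECTS[CGE], ASPECTS[CCS], ASPECTS[GCI]):
        cls = signature(t)
        if cls is not None:
            out[cls] += cge[t[0]] * ccs[t[1]] * gci[t[2]]
    return out


class TestSignature:
    @pytest.mark.parametrize(
        "tup, expected",
        [
            (("up", "progression", "causality"), "oncogene"),
            (("down", "regression", "causality"), "oncogene"),
            (("up", "regression", "causality"), "tumor_suppressor_gene"),
            (("down", "progression", "causality"), "tumor_suppressor_gene"),
            (("up", "progression", "correlation"), "biomarker"),
            (("up", "regression", "correlation"), "biomarker"),
            (("down", "progression", "correlation"), "biomarker"),
            (("down", "regression", "correlation"), "biomarker"),
            (("up", "progression", "observation"), "biomarker"),  # alias
            (("up", "notinf", "causality"), None),
            (("notinf", "progression", "causality"), None),
            (("up", "progression", "notinf"), None),
        ],
    )
    def test_rule_table(self, tup, expected):
        assert signature(tup) == expected

    def test_rule_table_has_eight_mapped_tuples(self):
        assert len(INFERENCE_RULES) == 8
        counts = {cls: 0 for cls in GENE_CLASSES}
        for cls in INFERENCE_RULES.values():
            counts[cls] += 1
        assert counts == {"oncogene": 2, "tumor_suppressor_gene": 2, "biomarker": 4}

    def test_non_domain_value_rejected(self):
        with pytest.raises(SchemaError):
            signature(("sideways", "progression", "causality"))


class TestClassLikelihoods:
    def test_degenerate_oncogene(self):
        f = make_fact(
            cge={"up": 1.0, "down": 0.0, "notinf": 0.0},
            ccs={"progression": 1.0, "regression": 0.0, "notinf": 0.0},
            gci={"causality": 1.0, "correlation": 0.0, "notinf": 0.0},
        )
        assert class_likelihoods(f) == {
            "oncogene": 1.0, "tumor_suppressor_gene": 0.0, "biomarker": 0.0,
        }

    def test_worked_example_classes(self, example3_sentences):
        """The aggregated example fact yields the hand-enumerated class mass."""
        kept, _ = retain_for_kb(example3_sentences)
        (fact,) = enrich(kept)
        cls = class_likelihoods(fact)
        assert cls["oncogene"] == pytest.approx(0.097536, abs=1e-9)
        assert cls["tumor_suppressor_gene"] == pytest.approx(0.142464, abs=1e-9)
        assert cls["biomarker"] == pytest.approx(0.400000, abs=1e-9)

    def test_all_notinf_gci_gives_zero_mass(self):
        f = make_fact(
            cge={"up": 0.5, "down": 0.5, "notinf": 0.0},
            ccs={"progression": 0.5, "regression": 0.5, "notinf": 0.0},
            gci={"causality": 0.0, "correlation": 0.0, "notinf": 1.0},
        )
        assert all(p == 0.0 for p in class_likelihoods(f).values())

    def test_closed_form_matches_brute_force(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            f = random_fact(rng, cge_notinf_zero=bool(rng.integers(2)))
            closed = class_likelihoods(f)
            brute = brute_force_class_likelihoods(f)
            for cls in GENE_CLASSES:
                assert abs(closed[cls] - brute[cls]) < 1e-12

    def test_class_mass_decomposition(self):
        """With Pr(CGE=notinf)=0, total class mass factorizes over CCS/GCI."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            f = random_fact(rng, cge_notinf_zero=True)
            ccs = f.aspect_probabilities[CCS]
            gci = f.aspect_probabilities[GCI]
            expected = (ccs["progression"] + ccs["regression"]) * (
                gci["causality"] + gci["correlation"]
            )
            assert sum(class_likelihoods(f).values()) == pytest.approx(
                expected, abs=1e-12
            )


class TestSufficiency:
    @pytest.mark.parametrize(
        "ccs_notinf, gci_notinf, alpha, expected",
        [
            (0.1, 0.3, 0.7, True),   # worked example f1
            (0.6, 0.5, 0.7, True),   # worked example f2
            (0.8, 0.1, 0.7, False),
            (0.1, 0.8, 0.7, False),
            (0.7, 0.7, 0.7, True),   # strict: equality passes
        ],
    )
    def test_threshold_is_strict(self, ccs_notinf, gci_notinf, alpha, expected):
        f = make_fact(
            cge={"up": 1.0, "down": 0.0, "notinf": 0.0},
            ccs={"progression": 1 - ccs_notinf, "regression": 0.0, "notinf": ccs_notinf},
            gci={"causality": 1 - gci_notinf, "correlation": 0.0, "notinf": gci_notinf},
        )
        assert sufficiency_check(f, alpha) is expected


class TestConsistency:
    def test_worked_example_margins(self):
        ok, candidate = consistency_check(
            {"oncogene": 0.7, "tumor_suppressor_gene": 0.2, "biomarker": 0.1}, 0.4
        )
        assert ok and candidate == "oncogene"
        ok, candidate = consistency_check(
            {"oncogene": 0.5, "tumor_suppressor_gene": 0.4, "biomarker": 0.1}, 0.4
        )
        assert not ok and candidate is None

    def test_degenerate_passes(self):
        ok, candidate = consistency_check(
            {"oncogene": 1.0, "tumor_suppressor_gene": 0.0, "biomarker": 0.0}, 0.4
        )
        assert ok and candidate == "oncogene"

    def test_margin_equality_fails(self):
        ok, _ = consistency_check(
            {"oncogene": 0.6, "tumor_suppressor_gene": 0.2, "biomarker": 0.2}, 0.4
        )
        assert not ok

    def test_exact_tie_never_reliable(self):
        ok, candidate = consistency_check(
            {"oncogene": 0.5, "tumor_suppressor_gene": 0.5, "biomarker": 0.0}, 0.0
        )
        assert not ok and candidate is None

    def test_at_most_one_class_satisfies_margin(self):
        """For beta >= 0 no two classes can both beat all others by beta."""
        rng = np.random.default_rng(13)
        for _ in range(500):
            probs = rng.dirichlet(np.ones(3))
            likelihoods = dict(zip(GENE_CLASSES, probs.tolist()))
            beta = float(rng.uniform(0, 1))
            winners = [
                cls for cls in GENE_CLASSES
                if all(likelihoods[cls] - likelihoods[o] > beta
                       for o in GENE_CLASSES if o != cls)
            ]
            assert len(winners) <= 1
            ok, candidate = consistency_check(likelihoods, beta)
            assert ok == bool(winners)
            if ok:
                assert candidate == winners[0]


class TestTagging:
    def test_worked_example_tags(self, example4_facts):
        f1, f2 = example4_facts
        cfg = Config()
        tagged1 = tag_fact(f1, cfg)
        assert tagged1.tag == "reliable"
        assert tagged1.signature_type == "oncogene"
        tagged2 = tag_fact(f2, cfg)
        assert tagged2.tag == "inconsistent"
        assert tagged2.signature_type is None

    def test_insufficient_shadows_inconsistent(self):
        f = make_fact(
            cge={"up": 1.0, "down": 0.0, "notinf": 0.0},
            ccs={"progression": 0.1, "regression": 0.0, "notinf": 0.9},
            gci={"causality": 0.5, "correlation": 0.5, "notinf": 0.0},
        )
        tagged = tag_fact(f, Config())
        assert tagged.tag == "insufficient"
        assert tagged.class_likelihoods is not None

    def test_tagging_idempotent_and_deterministic(self, example4_facts):
        f1, _ = example4_facts
        cfg = Config()
        once = tag_fact(f1, cfg)
        assert tag_fact(once, cfg) == once
        assert tag_fact(f1, cfg) == once

    def test_reliable_signature_is_top_class(self):
        rng = np.random.default_rng(17)
        cfg = Config()
        for f in tag_facts([random_fact(rng) for _ in range(200)], cfg):
            if f.tag == "reliable":
                top = max(f.class_likelihoods, key=f.class_likelihoods.get)
                assert f.signature_type == top
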
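"""Evidence aggregation: grouping, the tie-aware indicator, likelihoods."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gexkb.enrichment import (
    PairEvidence,
    aspect_value_likelihood,
    build_fact,
    enrich,
    group_by_pair,
    indicator,
)
from gexkb.schema import ASPECTS, CCS, CGE, GCI, AspectScoreVector, SchemaError
from gexkb.scoring import retain_for_kb

from conftest import make_relation, peaked_vector


def evidence(*relations):
    return PairEvidence(
        gene=relations[0].sentence.gene,
        cancer=relations[0].sentence.cancer,
        sentences=tuple(relations),
    )


class TestGrouping:
    def test_partition_by_pair(self):
        rs = [
            make_relation("d1", ("up", 0.9), ("progression", 0.9), ("causality", 0.9),
                          gene_id=1, cui="C0000001"),
            make_relation("d2", ("up", 0.9), ("progression", 0.9), ("causality", 0.9),
                          gene_id=1, cui="C0000001"),
            make_relation("d3", ("down", 0.9), ("regression", 0.9), ("causality", 0.9),
                          gene_id=2, cui="C0000002"),
        ]
        groups = group_by_pair(rs)
        assert [len(g.sentences) for g in groups] == [2, 1]

    def test_same_gene_two_cuis_two_groups(self):
        rs = [
            make_relation("d1", ("up", 0.9), ("progression", 0.9), ("causality", 0.9),
                          gene_id=1, cui="C0000001"),
            make_relation("d2", ("up", 0.9), ("progression", 0.9), ("causality", 0.9),
                          gene_id=1, cui="C0000002"),
        ]
        assert len(group_by_pair(rs)) == 2

    def test_empty_input(self):
        assert group_by_pair([]) == []

    def test_duplicate_sentences_deduplicated(self):
        r = make_relation("d1", ("up", 0.9), ("progression", 0.9), ("causality", 0.9))
        twin = dataclasses.replace(
            r, sentence=dataclasses.replace(r.sentence, sentence_id="other-source")
        )
        (group,) = group_by_pair([r, twin])
        assert len(group.sentences) == 1

    def test_mismatched_pair_rejected(self):
        a = make_relation("d1", ("up", 0.9), ("progression", 0.9), ("causality", 0.9),
                          gene_id=1)
        b = make_relation("d2", ("up", 0.9), ("progression", 0.9), ("causality", 0.9),
                          gene_id=2)
        with pytest.raises(SchemaError):
            PairEvidence(gene=a.sentence.gene, cancer=a.sentence.cancer,
                         sentences=(a, b))


class TestIndicator:
    @pytest.mark.parametrize(
        "value, scores, expected",
        [
            ("up", {"up": 0.7, "down": 0.2, "notinf": 0.1}, 1.0),
            ("down", {"up": 0.7, "down": 0.2, "notinf": 0.1}, 0.0),
            ("up", {"up": 0.5, "down": 0.5, "notinf": 0.0}, 0.5),
            ("down", {"up": 0.5, "down": 0.5, "notinf": 0.0}, 0.5),
            ("notinf", {"up": 0.5, "down": 0.5, "notinf": 0.0}, 0.0),
        ],
    )
    def test_indicator_shares_tie_mass(self, value, scores, expected):
        assert indicator(value, AspectScoreVector(CGE, scores)) == expected


class TestLikelihood:
    def test_worked_example_aggregation(self, example3_sentences):
        """Three retained sentences reproduce the printed likelihoods exactly."""
        kept, _ = retain_for_kb(example3_sentences)
        (ev,) = group_by_pair(kept)
        cge = aspect_value_likelihood(ev, CGE)
        assert cge["up"] == pytest.approx(1.7 / 2.5, abs=1e-12)
        assert cge["down"] == pytest.approx(0.8 / 2.5, abs=1e-12)
        assert cge["notinf"] == 0.0
        ccs = aspect_value_likelihood(ev, CCS)
        assert ccs["progression"] == pytest.approx(0.6 / 2.5, abs=1e-12)
        assert ccs["regression"] == pytest.approx(1.9 / 2.5, abs=1e-12)
        assert ccs["notinf"] == 0.0
        gci = aspect_value_likelihood(ev, GCI)
        assert gci["correlation"] == pytest.approx(1.0 / 2.5, abs=1e-12)
        assert gci["causality"] == pytest.approx(0.6 / 2.5, abs=1e-12)
        assert gci["notinf"] == pytest.approx(0.9 / 2.5, abs=1e-12)

    def test_tie_indicator_arithmetic(self):
        """A 0.5/0.5 tie contributes half its score to each tied value."""
        a = make_relation("d1", ("up", 0.9), ("progression", 0.9), ("causality", 0.9))
        a = dataclasses.replace(
            a, cge=AspectScoreVector(CGE, {"up": 0.5, "down": 0.5, "notinf": 0.0})
        )
        b = make_relation("d2", ("up", 1.0), ("progression", 1.0), ("causality", 1.0))
        cge = aspect_value_likelihood(evidence(a, b), CGE)
        assert cge["up"] == pytest.approx((0.25 + 1.0) / 1.5, abs=1e-12)
        assert cge["down"] == pytest.approx(0.25 / 1.5, abs=1e-12)

    def test_unanimous_one_hot(self):
        r = make_relation("d1", ("up", 1.0), ("progression", 1.0), ("causality", 1.0))
        cge = aspect_value_likelihood(evidence(r), CGE)
        assert cge.likelihoods == {"up": 1.0, "down": 0.0, "notinf": 0.0}

    def test_build_fact_carries_triple_and_support(self, example3_sentences):
        kept, _ = retain_for_kb(example3_sentences)
        (fact,) = enrich(kept)
        assert set(fact.aspect_probabilities) == {CGE, CCS, GCI}
        assert fact.tag == "untested"
        assert sorted(fact.support_documents) == ["t1", "t2", "t4"]
        assert len(fact.support_sentences) == 3


# -- property tests ---------------------------------------------------------

aspect_strategy = st.sampled_from([CGE, CCS, GCI])


@st.composite
def evidence_strategy(draw, min_sentences=1, max_sentences=6):
    n = draw(st.integers(min_sentences, max_sentences))
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    relations = []
    for i in range(n):
        def vec(aspect):
            p = rng.dirichlet(np.ones(len(ASPECTS[aspect])))
            return AspectScoreVector(aspect, dict(zip(ASPECTS[aspect], p.tolist())))
        base = make_relation(f"d{i}", ("up", 0.9), ("progression", 0.9),
                             ("causality", 0.9))
        relations.append(dataclasses.replace(
            base, cge=vec(CGE), ccs=vec(CCS), gci=vec(GCI)
        ))
    return evidence(*relations)


class TestProperties:
    @given(evidence_strategy(), aspect_strategy)
    @settings(derandomize=True, max_examples=100)
    def test_likelihoods_normalize(self, ev, aspect):
        """Aggregated likelihoods are a distribution over the domain."""
        ap = aspect_value_likelihood(ev, aspect)
        assert abs(sum(ap.likelihoods.values()) - 1.0) <= 1e-9
        assert all(0.0 <= p <= 1.0 + 1e-12 for p in ap.likelihoods.values())

    @given(evidence_strategy(), aspect_strategy, st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=100)
    def test_residual_mass_invariance(self, ev, aspect, seed):
        """Redistributing non-argmax mass never moves any likelihood."""
        before = aspect_value_likelihood(ev, aspect)
        rng = np.random.default_rng(seed)
        shuffled = []
        for r in ev.sentences:
            v = r.vector(aspect)
            top = v.argmax_set()
            residual_values = [x for x in v.scores if x not in top]
            residual_mass = sum(v.scores[x] for x in residual_values)
            if residual_values:
                w = rng.dirichlet(np.ones(len(residual_values)))
                # cap each redistributed share at the max so argmax is unchanged
                top_score = max(v.scores.values())
                shares = (w * residual_mass).tolist()
                if all(s < top_score - 1e-9 for s in shares):
                    new_scores = {x: v.scores[x] for x in top}
                    new_scores.update(dict(zip(residual_values, shares)))
                    v = AspectScoreVector(aspect, new_scores)
            shuffled.append(dataclasses.replace(r, **{aspect.lower(): v}))
        after = aspect_value_likelihood(evidence(*shuffled), aspect)
        for value in before.likelihoods:
            assert after[value] == pytest.approx(before[value], abs=1e-9)

    @given(evidence_strategy(), aspect_strategy)
    @settings(derandomize=True, max_examples=100)
    def test_support_monotonicity(self, ev, aspect):
        """Appending a one-hot sentence for a value never lowers its likelihood."""
        value = ASPECTS[aspect][0]
        before = aspect_value_likelihood(ev, aspect)[value]
        extra = make_relation("extra", ("up", 1.0), ("progression", 1.0),
                              ("causality", 1.0))
        extra = dataclasses.replace(
            extra, **{aspect.lower(): AspectScoreVector.one_hot(aspect, value)}
        )
        after = aspect_value_likelihood(evidence(*ev.sentences, extra), aspect)[value]
        assert after >= before - 1e-12

    @given(evidence_strategy(min_sentences=2), aspect_strategy,
           st.randoms(use_true_random=False))
    @settings(derandomize=True, max_examples=100)
    def test_permutation_invariance(self, ev, aspect, rnd):
        """Likelihoods do not depend on sentence order."""
        before = aspect_value_likelihood(ev, aspect)
        order = list(ev.sentences)
        rnd.shuffle(order)
        after = aspect_value_likelihood(evidence(*order), aspect)
        for value in before.likelihoods:
            assert after[value] == pytest.approx(before[value], abs=1e-12)
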
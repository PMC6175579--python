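"""Interaction-set classification: significance rules, set algebra, summaries."""

import numpy as np
import pandas as pd
import pytest

import barseqfit as bf
from barseqfit.interactions import (
    CrossClassification,
    classify_vs_alone,
    core_set,
    cross_classify,
    higher_order_summary,
    partner_breakdown,
    pool_timepoints,
    significant_negative,
)


def records_from(rows):
    return pd.DataFrame(rows, columns=["locus_tag", "condition", "timepoint", "fitness", "t"])


class TestSignificantNegative:
    @pytest.mark.parametrize(
        "fitness,t,included",
        [
            (-1.2, -4.0, True),    # strong negative effect
            (-0.5, -2.9, False),   # below the t cutoff
            (0.8, 4.2, False),     # reliable but positive
            (-0.4, -3.0, True),    # cutoff is inclusive
        ],
    )
    def test_significance_rule(self, fitness, t, included):
        records = records_from([["gA", "alone", "day1", fitness, t]])
        sets = significant_negative(records, t_threshold=3.0)
        assert (("gA" in sets[("alone", "day1")]) is included)

    def test_empty_condition_yields_empty_set(self):
        records = records_from([["gA", "alone", "day1", -0.1, -0.5]])
        assert significant_negative(records)[("alone", "day1")] == frozenset()


class TestPoolTimepoints:
    def test_union_with_provenance(self):
        pooled = pool_timepoints({"day1": {"a", "b"}, "day2": {"b", "c"}}, "alone")
        assert pooled.genes == {"a", "b", "c"}
        assert pooled.provenance["b"] == {"day1", "day2"}

    def test_adding_a_timepoint_never_shrinks_the_set(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        for _ in range(20):
            tps = {f"day{d}": set(rng.choice(genes, rng.integers(0, 10), replace=False))
                   for d in range(1, 4)}
            base = pool_timepoints({k: tps[k] for k in ("day1", "day2")}, "c").genes
            extended = pool_timepoints(tps, "c").genes
            assert base <= extended

    def test_empty_sets_pool_to_empty(self):
        assert pool_timepoints({"day1": set(), "day2": set()}, "c").genes == frozenset()


class TestClassifyVsAlone:
    def test_single_context_matches_printed_community_comparison(self):
        """With |A| = 160, |C| = 126 and an overlap of 89, the comparison
        yields 89 conserved, 37 induced and 71 alleviated genes."""
        shared = {f"s{i}" for i in range(89)}
        A = shared | {f"a{i}" for i in range(71)}
        C = shared | {f"c{i}" for i in range(37)}
        conserved, induced, alleviated = classify_vs_alone(A, [C])
        assert (len(conserved), len(induced), len(alleviated)) == (89, 37, 71)

    def test_disjoint_context_sets(self):
        A = {"a", "b"}
        conserved, induced, alleviated = classify_vs_alone(A, [{"x"}, {"y"}])
        assert conserved == frozenset()
        assert alleviated == A
        assert induced == {"x", "y"}

    def test_partition_identities_on_random_instances(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(60)]
        for _ in range(100):
            A = frozenset(rng.choice(genes, rng.integers(0, 40), replace=False))
            sets = [frozenset(rng.choice(genes, rng.integers(0, 40), replace=False))
                    for _ in range(3)]
            for rule in ("all", "any"):
                conserved, induced, alleviated = classify_vs_alone(A, sets, rule)
                union = frozenset().union(*sets)
                assert conserved | alleviated == A and not conserved & alleviated
                assert induced == union - A
                # brute-force oracle, gene by gene
                inter = sets[0] & sets[1] & sets[2]
                ref = inter if rule == "all" else union
                for g in genes:
                    assert (g in conserved) == (g in A and g in ref)

    def test_any_rule_is_weaker(self):
        A = {"a", "b"}
        contexts = [{"a"}, {"b"}]
        cons_all, _, _ = classify_vs_alone(A, contexts, "all")
        cons_any, _, _ = classify_vs_alone(A, contexts, "any")
        assert cons_all == frozenset() and cons_any == A


class TestPartnerBreakdown:
    PARTNERS = {"p1": {"x", "k"}, "p2": {"y", "k"}, "p3": {"z", "k"}}

    def test_alleviated_attribution(self):
        A = {"all1", "x", "k"}
        out = partner_breakdown("alleviated", A, self.PARTNERS)
        assert out["all"] == {"all1"}            # absent from every partner set
        assert out["specific:p1"] == frozenset() # x absent from p2,p3 too -> not specific
        assert out["other"] == {"x"}
        # k present everywhere -> not alleviated at all
        assert not any("k" in s for s in out.values())

    def test_alleviated_specific_single_partner(self):
        out = partner_breakdown(
            "alleviated", {"g"}, {"p1": set(), "p2": {"g"}, "p3": {"g"}}
        )
        assert out["specific:p1"] == {"g"}

    def test_induced_attribution(self):
        out = partner_breakdown("induced", set(), self.PARTNERS)
        assert out["all"] == {"k"}
        assert out["specific:p1"] == {"x"}
        assert out["specific:p2"] == {"y"}
        assert out["specific:p3"] == {"z"}

    def test_counts_sum_to_family_size_on_random_instances(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(40)]
        for _ in range(100):
            A = set(rng.choice(genes, rng.integers(0, 25), replace=False))
            partners = {p: set(rng.choice(genes, rng.integers(0, 25), replace=False))
                        for p in ("p1", "p2", "p3")}
            for family in ("induced", "alleviated"):
                out = partner_breakdown(family, A, partners)
                if family == "alleviated":
                    members = {g for g in A if any(g not in s for s in partners.values())}
                else:
                    members = set().union(*partners.values()) - A
                assert frozenset().union(*out.values()) == members
                assert sum(len(s) for s in out.values()) == len(members)


class TestCrossClassify:
    def test_induced_family_printed_counts(self):
        """75 pairwise-induced vs 37 community-induced with overlap 29 give
        46 pairwise-specific and 8 community-specific genes."""
        shared = {f"s{i}" for i in range(29)}
        P = shared | {f"p{i}" for i in range(46)}
        C = shared | {f"c{i}" for i in range(8)}
        out = cross_classify(P, C)
        assert (len(out.conserved), len(out.pairwise_specific),
                len(out.community_specific)) == (29, 46, 8)

    def test_alleviated_family_printed_counts(self):
        """82 pairwise-alleviated vs 71 community-alleviated with overlap 68
        give 14 pairwise-specific and 3 community-specific genes."""
        shared = {f"s{i}" for i in range(68)}
        out = cross_classify(shared | {f"p{i}" for i in range(14)},
                             shared | {f"c{i}" for i in range(3)})
        assert (len(out.conserved), len(out.pairwise_specific),
                len(out.community_specific)) == (68, 14, 3)

    def test_equal_families_have_no_specific_parts(self):
        out = cross_classify({"a", "b"}, {"a", "b"})
        assert out.pairwise_specific == out.community_specific == frozenset()


class TestCoreSet:
    def test_intersection_semantics(self):
        assert core_set([{"a", "b"}, {"a", "b"}]) == {"a", "b"}
        assert core_set([{"a", "b"}, {"b"}, {"a", "b"}]) == {"b"}

    def test_matches_brute_force_intersection(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        for _ in range(50):
            sets = [frozenset(rng.choice(genes, rng.integers(0, 20), replace=False))
                    for _ in range(5)]
            expected = frozenset(g for g in genes if all(g in s for s in sets))
            assert core_set(sets) == expected


class TestHigherOrderSummary:
    @staticmethod
    def _cross(n_cons, n_pw, n_comm, prefix):
        return CrossClassification(
            conserved=frozenset(f"{prefix}c{i}" for i in range(n_cons)),
            pairwise_specific=frozenset(f"{prefix}p{i}" for i in range(n_pw)),
            community_specific=frozenset(f"{prefix}s{i}" for i in range(n_comm)),
        )

    def test_printed_decomposition(self):
        """29 + 68 conserved vs 46 + 14 + 8 + 3 context-specific interactions
        split 97 : 71, i.e. 58% pairwise-derived and 42% higher-order."""
        summary = higher_order_summary(self._cross(29, 46, 8, "i"),
                                       self._cross(68, 14, 3, "a"))
        assert summary.pairwise_derived == 97 and summary.higher_order == 71
        assert summary.fraction_pairwise == 58 and summary.fraction_higher == 42

    def test_all_conserved(self):
        summary = higher_order_summary(self._cross(5, 0, 0, "i"), self._cross(2, 0, 0, "a"))
        assert (summary.fraction_pairwise, summary.fraction_higher) == (100, 0)

    def test_none_conserved(self):
        summary = higher_order_summary(self._cross(0, 3, 1, "i"), self._cross(0, 2, 0, "a"))
        assert (summary.fraction_pairwise, summary.fraction_higher) == (0, 100)

    def test_empty_input_undefined_fractions(self):
        summary = higher_order_summary(self._cross(0, 0, 0, "i"), self._cross(0, 0, 0, "a"))
        assert summary.fraction_pairwise is None and summary.fraction_higher is None
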
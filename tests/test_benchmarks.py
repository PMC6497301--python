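"""Benchmark statistics, robustness machinery, scoring and clustering."""

import math

import numpy as np
import pandas as pd
import pytest

from gembench.benchmarks import (
    MethodPlugin,
    cross_validate,
    growth_error,
    noise_series,
    og_ts_fold_enrichment,
    predict_exchange_rate,
    resolution_power,
    score_methods,
    simulate_drug_response,
)
from gembench.stats import bh_adjust, correlate, hypergeom_enrichment, jaccard
from gembench.synthetic import FixtureSpec, make_toy_model


class TestGrowthError:
    def test_values(self):
        assert growth_error(1.0, 1.0) == 0.0
        assert growth_error(0.5, 0.25) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            growth_error(0.0, 1.0)


@pytest.fixture(scope="module")
def secreting_toy():
    return make_toy_model(FixtureSpec(seed=0, n_pathways=1, pathway_length=3))


class TestExchangePrediction:
    def test_overflow_secretion_hand_lp(self, secreting_toy):
        # uptake cap 10, biomass pinned to >= 9; the spare 1 unit of
        # M_0_2 can only leave through SEC/EX_sec
        flux = predict_exchange_rate(secreting_toy, "EX_sec", growth_fraction=0.9)
        assert flux == pytest.approx(1.0, abs=1e-6)

    def test_fraction_one_pins_growth(self, secreting_toy):
        assert predict_exchange_rate(
            secreting_toy, "EX_sec", growth_fraction=1.0
        ) == pytest.approx(0.0, abs=1e-6)

    def test_closed_exchange_predicts_zero(self, secreting_toy):
        m = secreting_toy.copy()
        m.ub[m.reaction_index("EX_sec")] = 0.0
        assert predict_exchange_rate(m, "EX_sec", 0.9) == pytest.approx(0.0, abs=1e-9)

    def test_reset_uptake_reopens_tested_exchange(self, secreting_toy):
        m = secreting_toy.copy()
        m.lb[m.reaction_index("EX_upt_0")] = 0.0  # cell-specific medium closed it
        flux = predict_exchange_rate(m, "EX_upt_0", 0.9, reset_uptake=10.0)
        assert flux == pytest.approx(-9.0, abs=1e-6)  # uptake at 90% growth

    def test_non_exchange_rejected(self, secreting_toy):
        with pytest.raises(KeyError):
            predict_exchange_rate(secreting_toy, "R_0_1", 0.9)


class TestDrugResponse:
    def test_biomass_pinned_hand_lp(self, chain_model):
        # max growth 10; biomass pinned to 5 forces CONV = 5
        assert simulate_drug_response(chain_model, "CONV") == pytest.approx(5.0)

    def test_absent_target_non_predictable(self, chain_model):
        assert simulate_drug_response(chain_model, "NOPE") is None

    def test_nongrowing_model_non_predictable(self, chain_model):
        closed = chain_model.copy()
        closed.lb[0] = 0.0
        assert simulate_drug_response(closed, "CONV") is None


class TestCorrelate:
    def test_monotone_and_reversed(self):
        rho, _ = correlate([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == pytest.approx(1.0)
        rho, _ = correlate([1, 2, 3, 4], [40, 30, 20, 10])
        assert rho == pytest.approx(-1.0)

    def test_five_point_hand_ranks(self):
        # pred ranks: [3,1,4,2,5]; meas ranks: [3,1,4,5,2]
        # d = [0,0,0,-3,3]; rho = 1 - 6*18 / (5*24) = 0.1
        rho, _ = correlate([3, 1, 4, 1.5, 5], [30, 10, 40, 50, 20])
        assert rho == pytest.approx(0.1)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            correlate([1, 2], [2, 1])


class TestHypergeom:
    def test_exact_combinatorial_value(self):
        # C(5,4)*C(5,0)/C(10,4) = 5/210
        assert hypergeom_enrichment(4, 4, 5, 10, "right") == pytest.approx(5 / 210)

    def test_empty_selection_right_tail_is_one(self):
        assert hypergeom_enrichment(0, 0, 7, 20, "right") == pytest.approx(1.0)

    def test_tails_sum_to_one_plus_point_mass(self):
        k, n, K, N = 3, 8, 10, 25
        right = hypergeom_enrichment(k, n, K, N, "right")
        left = hypergeom_enrichment(k, n, K, N, "left")
        point = math.comb(K, k) * math.comb(N - K, n - k) / math.comb(N, n)
        assert right + left == pytest.approx(1.0 + point)

    def test_matches_bigint_combinatorics(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            N = int(rng.integers(2, 61))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(max(0, n + K - N), min(n, K) + 1))
            exact = sum(
                math.comb(K, j) * math.comb(N - K, n - j)
                for j in range(k, min(n, K) + 1)
            ) / math.comb(N, n)
            assert hypergeom_enrichment(k, n, K, N, "right") == pytest.approx(
                exact, rel=1e-12
            )

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(5, 4, 5, 10)


def bh_textbook(p):
    """Oracle: literal step-up definition, O(n^2)."""
    p = list(p)
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    q = [None] * n
    for rank_pos in range(n):
        i = order[rank_pos]
        q[i] = min(
            min(n * p[order[j]] / (j + 1) for j in range(rank_pos, n)), 1.0
        )
    return q


class TestBH:
    def test_matches_textbook_stepup_exhaustively(self):
        rng = np.random.default_rng(0)
        for n in range(1, 21):
            p = rng.uniform(size=n)
            np.testing.assert_allclose(bh_adjust(p), bh_textbook(p), rtol=1e-12)

    def test_handles_ties(self):
        p = [0.01, 0.01, 0.5, 0.5]
        np.testing.assert_allclose(bh_adjust(p), bh_textbook(p))


class TestEnrichmentAndSimilarity:
    def test_fold_one_for_full_model(self):
        genes = {f"g{i}" for i in range(10)}
        ann = {"g0", "g1", "g2"}
        fold, _ = og_ts_fold_enrichment(genes, ann, genes)
        assert fold == pytest.approx(1.0)

    def test_hand_value_on_ten_gene_toy(self):
        model = {f"g{i}" for i in range(10)}
        ann = {"g0", "g1", "g2", "g3"}  # 40% of model
        pred = {"g0", "g1", "g2", "g3", "g4", "g5", "g6"}  # keeps all annotated
        fold, p = og_ts_fold_enrichment(pred, ann, model)
        assert fold == pytest.approx((4 / 7) / (4 / 10))
        assert 0 < p <= 1

    def test_no_annotated_genes_rejected(self):
        with pytest.raises(ValueError):
            og_ts_fold_enrichment({"g1"}, {"x"}, {"g1", "g2"})

    def test_jaccard_values(self):
        assert jaccard({"a"}, {"a"}) == 1.0
        assert jaccard({"a"}, {"b"}) == 0.0
        assert jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        with pytest.warns(UserWarning):
            assert jaccard(set(), set()) == 1.0

    def test_resolution_power_hand_case(self):
        groups = {
            "A": [{"a", "b"}, {"a", "b"}],
            "B": [{"c", "d"}, {"c", "d"}],
        }
        assert resolution_power(groups) == pytest.approx(1.0)
        mixed = {"A": [{"a"}, {"a"}], "B": [{"a"}, {"a"}]}
        assert resolution_power(mixed) == pytest.approx(0.0)


def parent_plugin():
    """Plugin that returns the untouched parent: recovers everything."""

    def build(model, expression, medium, phenotype, core=None):
        return model

    return MethodPlugin("parent", build, produces_subnetwork=True)


class TestCrossValidation:
    def test_model_count_is_k_times_repeats(self, toy_model, toy_panel):
        rep = cross_validate(
            parent_plugin(), toy_model, toy_panel[0],
            core_reactions=set(toy_model.reaction_ids) - {"B_1", "B_2"},
            k=5, repeats=15, seed=0,
        )
        assert rep.n_models == 75

    def test_parent_plugin_recovers_everything(self, toy_model, toy_panel):
        core = {"R_0_1", "R_0_2", "R_1_1", "R_1_2", "R_2_1", "R_2_2",
                "R_0_3", "R_1_3", "R_2_3", "R_2_4"}
        rep = cross_validate(
            parent_plugin(), toy_model, toy_panel[0], core_reactions=core,
            k=5, repeats=2, seed=1,
        )
        assert rep.recovered_per_fold == rep.removed_per_fold
        # closed-form pooled p: all K removed recovered from a selection
        # that includes the entire candidate pool -> p = 1 exactly
        assert rep.pooled_p == pytest.approx(1.0)

    def test_bound_setter_mode_tracks_growth(self, toy_model, toy_panel):
        def build(model, expression, medium, phenotype, core=None):
            return model

        plug = MethodPlugin("keeper", build, produces_subnetwork=False)
        rep = cross_validate(plug, toy_model, toy_panel[0], k=5, repeats=3, seed=0)
        assert rep.n_models == 15
        assert len(rep.growth_per_fold) == 15


@pytest.fixture(scope="module")
def series(toy_panel):
    return noise_series(toy_panel[0], n_sets=20, seed=4)


class TestNoiseSeries:
    def test_exactly_twenty_sets(self, series):
        assert len(series) == 20

    def test_distribution_preserved_in_every_set(self, series, toy_panel):
        orig = sorted(toy_panel[0].values.values())
        for prof, _ in series:
            assert sorted(prof.values.values()) == pytest.approx(orig)

    def test_endpoints_and_monotone_spacing(self, series):
        rs = [r for _, r in series]
        assert rs[-1] == 1.0
        assert rs[0] < 0.1
        assert all(rs[i] < rs[i + 1] for i in range(19))
        assert max(np.diff(rs)) < 0.2  # approximately evenly spaced

    def test_too_few_genes_rejected(self):
        from gembench.expression import ExpressionProfile

        with pytest.raises(ValueError):
            noise_series(ExpressionProfile("s", {"g": 1.0}), seed=0)


class TestScoring:
    def test_dominating_method_scores_one(self):
        raw = pd.DataFrame(
            {c: [0.1, 0.9] for c in range(1, 10)}, index=["good", "bad"]
        )
        hib = {c: False for c in range(1, 10)}  # lower raw is better
        rep = score_methods(raw, higher_is_better=hib)
        assert (rep.scores.loc["good"] == 1.0).all()
        assert (rep.scores.loc["bad"] == 0.0).all()

    def test_invariant_under_method_reordering(self):
        raw = pd.DataFrame(
            np.arange(27, dtype=float).reshape(3, 9),
            index=["a", "b", "c"], columns=range(1, 10),
        )
        r1 = score_methods(raw)
        r2 = score_methods(raw.iloc[[2, 0, 1]])
        for m in raw.index:
            assert (r1.scores.loc[m] == r2.scores.loc[m]).all()

    def test_missing_benchmark_scores_zero_and_flagged(self):
        raw = pd.DataFrame(
            {1: [0.1, 0.2], 2: [np.nan, 0.5]}, index=["a", "b"], dtype=float
        )
        rep = score_methods(raw, higher_is_better={1: False, 2: True})
        assert rep.scores.loc["a", 2] == 0.0
        assert rep.missing == {"a": [2]}

    def test_linkage_merge_order_matches_hand_distances(self):
        rows = {
            "A": [1.0] * 9,
            "B": [0.9] * 9,
            "C": [0.0] * 9,
        }
        raw = pd.DataFrame(rows, index=range(1, 10)).T
        rep = score_methods(raw)
        # scores: per benchmark A=1, B=0.5, C=0; dist(A,B)=dist(B,C)=1.5, dist(A,C)=3
        first = set(rep.linkage[0, :2].astype(int))
        assert first in ({0, 1}, {1, 2})  # B merges with a neighbor first
        nwk = rep.to_newick()
        assert nwk.endswith(";") and {"A", "B", "C"} <= set(
            nwk.replace("(", " ").replace(")", " ").replace(",", " ").split()
        ) | {"A", "B", "C"}
        for label in ("A", "B", "C"):
            assert label in nwk

    def test_single_method_rejected(self):
        with pytest.raises(ValueError):
            score_methods(pd.DataFrame({1: [0.5]}, index=["only"]))
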
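"""Expression-to-bound constraints, C sweep, QP slacks, calibration."""

import itertools

import numpy as np
import pytest

from gembench.expression import ExpressionProfile
from gembench.model import MetabolicModel
from gembench.stats import jaccard
from gembench.synthetic import FixtureSpec, make_expression_panel, make_toy_model
from gembench.trfba import (
    TRFBACore,
    TrfbaConstraints,
    build_trfba_model,
    compute_c_opt,
    count_small_slacks,
    detect_c_corr,
    detect_change_points,
    find_c_brk,
    growth_correlated_reactions,
    qp_slack_minimize,
    sweep_c,
)


def one_gene_two_rxn_model():
    """One gene catalyzes two irreversible reactions (A->B and A->C->out)."""
    return MetabolicModel(
        metabolite_ids=["A", "B"],
        reaction_ids=["EX_A", "R1", "R2", "BIOMASS"],
        S=np.array([[-1.0, -1.0, -1.0, 0.0], [0.0, 1.0, 1.0, -1.0]]),
        lb=np.array([-10.0, 0.0, 0.0, 0.0]),
        ub=np.array([1000.0] * 4),
        gene_ids=["g"],
        gpr=["", "g", "g", ""],
        objective_id="BIOMASS",
    )


class TestConstraintConstruction:
    def test_summed_bound_row(self):
        """E=2, C=3 -> v_R1 + v_R2 <= 6, a single row touching both."""
        m = one_gene_two_rxn_model()
        split, A, b = build_trfba_model(m, ExpressionProfile("s", {"g": 2.0}), 3.0)
        assert A.shape[0] == 1 and b[0] == pytest.approx(6.0)
        i1 = split.reaction_ids.index("R1__f")
        i2 = split.reaction_ids.index("R2__f")
        assert A[0, i1] == 1.0 and A[0, i2] == 1.0
        # uptake exchange is not associated with the gene
        assert A[0, split.reaction_ids.index("EX_A__b")] == 0.0

    def test_reversible_reactions_sum_magnitudes(self, chain_model):
        rev = chain_model.copy()
        rev.lb[1] = -1000.0  # CONV becomes reversible
        tc = TrfbaConstraints(rev, ExpressionProfile("s", {"g1": 1.0}))
        A, _ = tc.constraint_rows(1.0)
        f = tc.split.reaction_ids.index("CONV__f")
        bk = tc.split.reaction_ids.index("CONV__b")
        assert A[0, f] == 1.0 and A[0, bk] == 1.0

    def test_c_zero_blocks_gene_associated_growth(self, chain_model):
        tc = TrfbaConstraints(chain_model, ExpressionProfile("s", {"g1": 5.0}))
        assert tc.growth(0.0) == pytest.approx(0.0, abs=1e-9)

    def test_huge_c_recovers_unconstrained_optimum(self, chain_model):
        tc = TrfbaConstraints(chain_model, ExpressionProfile("s", {"g1": 5.0}))
        assert tc.growth(1e9) == pytest.approx(tc.growth(None))

def test_negative_expression_rejected(chain_model):
    prof = ExpressionProfile("s", {"g1": 1.0})
    prof.values["g1"] = -2.0  # bypass the constructor guard
    with pytest.raises(ValueError, match="negative"):
        TrfbaConstraints(chain_model, prof)


class TestCBrk:
    def test_chain_bottleneck_hand_value(self, chain_model):
        """E=1 on the only gene, uptake cap 10: the bound binds at v=10."""
        cb = find_c_brk(chain_model, ExpressionProfile("s", {"g1": 1.0}))
        assert cb == pytest.approx(10.0, rel=2e-2)

    def test_scale_invariance(self, chain_model):
        e1 = ExpressionProfile("s", {"g1": 1.0})
        e2 = ExpressionProfile("s", {"g1": 2.0})
        c1 = find_c_brk(chain_model, e1)
        c2 = find_c_brk(chain_model, e2)
        assert c2 == pytest.approx(c1 / 2.0, rel=2e-2)

    def test_zero_tol_rejected(self, chain_model):
        with pytest.raises(ValueError):
            find_c_brk(chain_model, ExpressionProfile("s", {"g1": 1.0}), tol=0.0)


@pytest.fixture(scope="module")
def sweep(toy_model, toy_panel):
    return sweep_c(toy_model, toy_panel[0], n_steps=40)


class TestSweep:
    def test_growth_monotone_nondecreasing(self, sweep):
        assert np.all(np.diff(sweep.growth) >= -1e-6)

    def test_endpoints(self, sweep):
        assert sweep.growth[0] == pytest.approx(0.0, abs=1e-9)
        assert sweep.growth[-1] >= (1 - 2e-3) * sweep.g_max
        assert sweep.c_grid[0] == 0.0 and sweep.c_grid[-1] == sweep.c_brk

    def test_columns_steady_state(self, sweep, toy_model):
        for k in (1, len(sweep.c_grid) // 2, -1):
            v = sweep.V[:, k]
            assert np.max(np.abs(toy_model.S @ v)) < 1e-8

    def test_step_size_stability_jaccard(self, toy_model, toy_panel):
        """Growth-correlated sets from different grid sizes agree."""
        sets = {}
        for n in (60, 120):
            sw = sweep_c(toy_model, toy_panel[0], n_steps=n, compute_slacks=False)
            sets[n] = set(growth_correlated_reactions(sw).reaction_ids)
        assert jaccard(sets[60], sets[120]) >= 0.9

    def test_too_few_steps_rejected(self, toy_model, toy_panel):
        with pytest.raises(ValueError):
            sweep_c(toy_model, toy_panel[0], n_steps=1)


class TestGrowthCorrelated:
    def test_tracking_and_constant_reactions(self, toy_model, toy_panel):
        sw = sweep_c(toy_model, toy_panel[0], n_steps=40, compute_slacks=False)
        gcs = growth_correlated_reactions(sw)
        # the biomass reaction trivially tracks growth
        assert "BIOMASS" in gcs.reaction_ids
        # blocked reactions carry constant (zero) flux: excluded
        assert "B_1" not in gcs.reaction_ids
        assert set(gcs.table["reaction_id"]) == set(gcs.reaction_ids)
        assert (gcs.table["q"] < 0.05).all()
        assert (gcs.table["rho"].abs() >= 0.9).all()

    def test_anticorrelated_flux_kept_sign_agnostic(self):
        from gembench.trfba import CSweepResult

        g = np.linspace(0, 10, 20)
        V = np.vstack([g, 5.0 - g, np.full(20, 3.0)])
        sw = CSweepResult(
            c_grid=np.linspace(0, 1, 20), V=V, growth=g,
            slacks=np.zeros((0, 20)), n_alpha=np.zeros(20, dtype=int),
            c_brk=1.0, g_max=10.0, genes=[],
            reaction_ids=["track", "anti", "flat"],
            statuses=["optimal"] * 20,
        )
        gcs = growth_correlated_reactions(sw)
        assert set(gcs.reaction_ids) == {"track", "anti"}
        rho = dict(zip(gcs.table["reaction_id"], gcs.table["rho"]))
        assert rho["track"] == pytest.approx(1.0)
        assert rho["anti"] == pytest.approx(-1.0)

    def test_constant_growth_rejected(self):
        from gembench.trfba import CSweepResult

        sw = CSweepResult(
            c_grid=np.linspace(0, 1, 12), V=np.zeros((1, 12)),
            growth=np.ones(12), slacks=np.zeros((0, 12)),
            n_alpha=np.zeros(12, dtype=int), c_brk=1.0, g_max=1.0,
            genes=[], reaction_ids=["r"], statuses=["optimal"] * 12,
        )
        with pytest.raises(ValueError, match="constant"):
            growth_correlated_reactions(sw)


# -- QP slack stage --------------------------------------------------------

def qp_bruteforce_oracle(M, d, S, lb, ub):
    """Dense active-set enumeration: fix every combination of bounds,
    solve the equality-KKT least squares, keep the best feasible value."""
    n = S.shape[1]
    best = np.inf
    for assign in itertools.product((0, 1, 2), repeat=n):
        fixed = {i: (lb[i] if a == 1 else ub[i]) for i, a in enumerate(assign) if a}
        free = [i for i in range(n) if i not in fixed]
        x = np.zeros(n)
        for i, val in fixed.items():
            x[i] = val
        if free:
            Mf = M[:, free]
            Sf = S[:, free]
            rhs_d = d - M @ x + Mf @ x[free] * 0 - M[:, list(fixed)] @ x[list(fixed)] * 0
            rhs_d = d - (M[:, list(fixed)] @ np.array([fixed[i] for i in fixed])
                         if fixed else 0.0)
            rhs_e = -(S[:, list(fixed)] @ np.array([fixed[i] for i in fixed])
                      if fixed else np.zeros(S.shape[0]))
            nf = len(free)
            K = np.zeros((nf + S.shape[0], nf + S.shape[0]))
            K[:nf, :nf] = 2.0 * Mf.T @ Mf
            K[:nf, nf:] = Sf.T
            K[nf:, :nf] = Sf
            r = np.concatenate([2.0 * Mf.T @ rhs_d, rhs_e])
            sol, *_ = np.linalg.lstsq(K, r, rcond=None)
            vf = sol[:nf]
            if np.any(vf < lb[free] - 1e-8) or np.any(vf > ub[free] + 1e-8):
                continue
            x[free] = vf
        if np.max(np.abs(S @ x)) > 1e-7:
            continue
        obj = float(np.sum((M @ x - d) ** 2))
        best = min(best, obj)
    return best


class TestQpSlack:
    def test_hand_cases_single_gene(self):
        m = MetabolicModel(
            metabolite_ids=["A"],
            reaction_ids=["EX_A", "R1"],
            S=np.array([[-1.0, -1.0]]),
            lb=np.array([-10.0, 0.0]),
            ub=np.array([1000.0, 5.0]),
            gene_ids=["g"],
            gpr=["", "g"],
            objective_id="R1",
        )
        e = ExpressionProfile("s", {"g": 1.0})
        assert qp_slack_minimize(m, e, 8.0)["g"] == pytest.approx(3.0, abs=1e-6)
        assert qp_slack_minimize(m, e, 0.0)["g"] == pytest.approx(0.0, abs=1e-8)
        assert qp_slack_minimize(m, e, 4.0)["g"] == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("C", [0.0, 1.0, 4.0, 12.0])
    def test_objective_matches_bruteforce_oracle(self, C):
        m = one_gene_two_rxn_model()
        tc = TrfbaConstraints(m, ExpressionProfile("s", {"g": 2.0}))
        alpha, _ = tc.slack_minimize(C)
        ours = float(np.sum(alpha**2))
        oracle = qp_bruteforce_oracle(
            tc.M, C * tc.E, tc.split.S, tc.split.lb, tc.split.ub
        )
        assert ours == pytest.approx(oracle, rel=1e-6, abs=1e-9)

    def test_reproducible_across_fresh_solves(self, chain_model):
        e = ExpressionProfile("s", {"g1": 3.0})
        a1 = qp_slack_minimize(chain_model, e, 7.0)
        a2 = qp_slack_minimize(chain_model, e, 7.0)
        assert a1["g1"] == pytest.approx(a2["g1"], rel=1e-6, abs=1e-10)


class TestSmallSlackCount:
    def test_examples(self):
        assert count_small_slacks([0.0, 1e-7, 1e-3]) == 2
        assert count_small_slacks(np.zeros(5)) == 5
        assert count_small_slacks([1e-5], threshold=1e-4) == 1

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            count_small_slacks([np.nan])


# -- change point ----------------------------------------------------------

def exhaustive_single_break(x):
    """Oracle: RSS-minimizing single breakpoint by full enumeration."""
    x = np.asarray(x, dtype=float)

    def rss(seg):
        return np.sum((seg - seg.mean()) ** 2) if len(seg) else 0.0

    return min(range(1, len(x)), key=lambda i: rss(x[:i]) + rss(x[i:]))


class TestChangePoint:
    def test_planted_single_step_exact(self):
        x = [0, 0, 0, 6, 6, 6]
        cps = detect_change_points(x)
        assert cps == [exhaustive_single_break(x)] == [3]
        assert detect_c_corr(x, np.arange(6)) == 3.0

    def test_constant_series_has_no_change(self):
        with pytest.raises(ValueError, match="no change"):
            detect_c_corr([5.0] * 8, np.arange(8))

    def test_two_planted_steps_first_returned(self):
        x = [0, 0, 0, 4, 4, 4, 9, 9, 9]
        # oracle: exhaustive two-breakpoint RSS minimization
        def rss(seg):
            seg = np.asarray(seg, dtype=float)
            return np.sum((seg - seg.mean()) ** 2) if len(seg) else 0.0

        best = min(
            ((i, j) for i in range(1, 9) for j in range(i + 1, 9)),
            key=lambda ij: rss(x[: ij[0]]) + rss(x[ij[0]: ij[1]]) + rss(x[ij[1]:]),
        )
        cps = detect_change_points(x)
        assert cps == list(best) == [3, 6]
        assert detect_c_corr(x, np.arange(9.0)) == 3.0
        assert detect_c_corr(x, np.arange(9.0), which="last") == 6.0

    def test_noisy_step_within_one_index(self):
        rng = np.random.default_rng(5)
        # step height 10, noise sd 2 -> signal-to-noise 5
        x = np.concatenate([np.zeros(15), np.full(15, 10.0)]) + 2.0 * rng.standard_normal(30)
        cps = detect_change_points(x)
        assert any(abs(c - 15) <= 1 for c in cps)
        assert abs(cps[0] - 15) <= 1


class TestCOpt:
    def test_identity_and_hand_value(self):
        assert compute_c_opt(7.5, 2.0, 2.0) == pytest.approx(7.5)
        assert compute_c_opt(10.0, 2.0, 1.0) == pytest.approx(5.0)
        assert compute_c_opt(10.0, 2.0, 0.0) == 0.0

    def test_nonpositive_gmax_rejected(self):
        with pytest.raises(ValueError):
            compute_c_opt(10.0, 0.0, 1.0)


@pytest.fixture(scope="module")
def result(toy_model, toy_panel):
    return TRFBACore(toy_model, toy_panel[0], n_steps=50).fit()


class TestPipeline:
    def test_extracted_model_contains_planted_pathways_and_grows(self, result, toy_spec):
        rxns = set(result.context_model.reaction_ids)
        for p in range(toy_spec.n_pathways):
            for k in range(1, toy_spec.pathway_length + 1):
                assert f"R_{p}_{k}" in rxns
        assert "BIOMASS" in rxns
        assert result.predicted_growth >= 0.0
        from gembench.lp import fba

        assert fba(result.context_model.model).objective_value > 0

    def test_blocked_reactions_never_extracted(self, result):
        assert {"B_1", "B_2"}.isdisjoint(result.context_model.reaction_ids)

    def test_determinism(self, toy_model, toy_panel, result):
        again = TRFBACore(toy_model, toy_panel[0], n_steps=50).fit()
        assert again.context_model.reaction_ids == result.context_model.reaction_ids
        assert again.c_final == result.c_final
        assert again.predicted_growth == result.predicted_growth

    def test_summary_mentions_key_quantities(self, result):
        s = result.summary()
        assert "C_brk" in s and "predicted growth" in s

    def test_copt_mode_prediction_close_to_measured(self, toy_model, toy_panel):
        res = TRFBACore(
            toy_model, toy_panel[2], growth_measured=4.0, n_steps=50
        ).fit(compute_slacks=False)
        assert res.calibration == "C_opt"
        assert res.parent_predicted_growth == pytest.approx(4.0, rel=5e-3)
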
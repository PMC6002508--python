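import itertools

import numpy as np
import pytest

import pbpkgsa as pg
from pbpkgsa.benchmarks import ishigami, ishigami_indices, sobol_g, sobol_g_indices
from pbpkgsa.gsa import (
    DesignConfig,
    efast_indices,
    evaluation_count,
    jansen,
    make_pbpk_adapter,
    morris,
    morris_design,
    morris_indices,
    owen,
    run_gsa,
    select_trajectories,
    sobol_bruteforce_oracle,
    _trajectory_distance,
)

S_ISH, ST_ISH = ishigami_indices()


class TestBudgets:
    @pytest.mark.parametrize(
        "method,n,p,expected",
        [
            ("morris", 1024, 21, 22_528),
            ("efast", 8192, 58, 475_136),
            ("owen", 10, 4, 140),
            ("jansen", 10, 4, 60),
        ],
    )
    def test_printed_formulas(self, method, n, p, expected):
        assert evaluation_count(method, n, p) == expected

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            evaluation_count("fourier", 10, 3)
        with pytest.raises(ValueError):
            DesignConfig(method="fourier")


class TestMorris:
    def test_design_is_one_at_a_time(self):
        traj = morris_design(p=5, r_trajectories=4, seed=0)
        assert traj.shape == (4, 6, 5)
        for t in traj:
            for a, b in zip(t[:-1], t[1:]):
                assert (np.abs(a - b) > 1e-12).sum() == 1
        assert traj.min() >= 0 and traj.max() <= 1

    def test_design_step_size(self):
        levels = 8
        traj = morris_design(p=3, r_trajectories=3, levels=levels, seed=1)
        delta = levels / (2 * (levels - 1))
        steps = np.abs(np.diff(traj, axis=1))
        assert steps[steps > 1e-12] == pytest.approx(delta)

    def test_odd_levels_rejected(self):
        with pytest.raises(ValueError):
            morris_design(3, 2, levels=7)

    def test_r_exceeding_pool_rejected(self):
        with pytest.raises(ValueError):
            morris_design(3, 5, pool_size=4)

    def test_campolongo_selection_matches_enumeration(self):
        """Selection over a small pool must equal brute force over all pairs."""
        rng = np.random.default_rng(3)
        pool = rng.uniform(size=(6, 3, 2))  # 6 candidate 2-parameter trajectories
        chosen = set(select_trajectories(pool, 2).tolist())
        best, best_val = None, -1.0
        for combo in itertools.combinations(range(6), 2):
            d = _trajectory_distance(pool[combo[0]], pool[combo[1]])
            if d * d > best_val:
                best_val, best = d * d, set(combo)
        assert chosen == best

    def test_linear_function_exact(self):
        idx = morris(lambda U: 3 * U[:, 0] + U[:, 1], p=2, r_trajectories=6, seed=4)
        assert idx.mu_star[:, 0] == pytest.approx([3.0, 1.0], abs=1e-12)
        assert idx.sigma[:, 0] == pytest.approx([0.0, 0.0], abs=1e-9)
        assert idx.mu[:, 0] == pytest.approx([3.0, 1.0], abs=1e-12)

    def test_interaction_gives_positive_sigma(self):
        idx = morris(lambda U: U[:, 0] * U[:, 1], p=2, r_trajectories=10, seed=5)
        assert idx.sigma[0, 0] > 0.01

    def test_constant_function_all_zero(self):
        idx = morris(lambda U: np.ones(U.shape[0]), p=3, r_trajectories=5, seed=6)
        assert np.allclose(idx.mu_star, 0) and np.allclose(idx.sigma, 0)

    def test_mu_star_bounds_mu(self):
        idx = morris(ishigami, p=3, r_trajectories=20, seed=7)
        assert (idx.mu_star >= np.abs(idx.mu) - 1e-12).all()

    def test_ranking_on_monotone_separable_function(self):
        f = lambda U: 5 * U[:, 0] + 2 * U[:, 1] ** 2 + 0.1 * U[:, 2]
        idx = morris(f, p=3, r_trajectories=12, seed=8)
        order = np.argsort(-idx.mu_star[:, 0])
        assert list(order) == [0, 1, 2]

    def test_mismatched_outputs_rejected(self):
        traj = morris_design(2, 3, seed=9)
        with pytest.raises(ValueError):
            morris_indices(traj, np.zeros((5, 3)))


class TestEfast:
    def test_ishigami_close_to_closed_form(self):
        idx = efast_indices(ishigami, p=3, n=2048, M=4, seed=1)
        assert idx.S[:, 0] == pytest.approx(S_ISH, abs=0.02)
        assert idx.ST[:, 0] == pytest.approx(ST_ISH, abs=0.05)

    def test_additive_function_has_no_interaction(self):
        idx = efast_indices(lambda U: U[:, 0] + U[:, 1], p=2, n=512, seed=2)
        assert idx.interaction[:, 0] == pytest.approx([0.0, 0.0], abs=0.02)

    def test_constant_function_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            efast_indices(lambda U: np.ones(U.shape[0]), p=2, n=128, seed=3)

    def test_too_small_n_reports_minimum(self):
        with pytest.raises(ValueError, match="65"):
            efast_indices(ishigami, p=3, n=32, M=4, seed=4)

    def test_resamples_stored(self):
        idx = efast_indices(ishigami, p=3, n=256, Nr=3, seed=5)
        assert idx.S_resamples.shape == (3, 3, 1)

    def test_seed_reproducible(self):
        a = efast_indices(ishigami, p=3, n=256, seed=6)
        b = efast_indices(ishigami, p=3, n=256, seed=6)
        assert np.array_equal(a.S, b.S)


class TestMonteCarloEstimators:
    def test_jansen_ishigami(self):
        idx = jansen(ishigami, p=3, n=8192, seed=1)
        assert idx.S[:, 0] == pytest.approx(S_ISH, abs=0.03)
        assert idx.ST[:, 0] == pytest.approx(ST_ISH, abs=0.03)

    def test_jansen_inert_parameter(self):
        idx = jansen(lambda U: U[:, 0], p=2, n=4096, seed=2)
        assert idx.S[1, 0] == pytest.approx(0.0, abs=0.02)
        assert idx.ST[1, 0] == pytest.approx(0.0, abs=0.02)

    def test_owen_ishigami(self):
        idx = owen(ishigami, p=3, n=8192, seed=3)
        assert idx.S[:, 0] == pytest.approx(S_ISH, abs=0.04)
        assert idx.ST[:, 0] == pytest.approx(ST_ISH, abs=0.04)

    def test_owen_g_function(self):
        S_true, _ = sobol_g_indices()
        idx = owen(sobol_g, p=2, n=8192, seed=4)
        assert idx.S[0, 0] == pytest.approx(S_true[0], abs=0.04)

    def test_owen_budget(self):
        calls = {"n": 0}

        def counted(U):
            calls["n"] += U.shape[0]
            return ishigami(U)

        owen(counted, p=3, n=64, seed=5)
        assert calls["n"] == evaluation_count("owen", 64, 3)

    def test_jansen_budget(self):
        calls = {"n": 0}

        def counted(U):
            calls["n"] += U.shape[0]
            return ishigami(U)

        jansen(counted, p=3, n=64, seed=6)
        assert calls["n"] == evaluation_count("jansen", 64, 3)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            jansen(lambda U: np.zeros(U.shape[0]), p=2, n=64, seed=7)

    def test_estimators_agree_pairwise_on_ishigami(self):
        e = efast_indices(ishigami, p=3, n=2048, seed=8).S[:, 0]
        j = jansen(ishigami, p=3, n=8192, seed=8).S[:, 0]
        o = owen(ishigami, p=3, n=8192, seed=8).S[:, 0]
        assert e == pytest.approx(j, abs=0.04)
        assert e == pytest.approx(o, abs=0.04)
        assert j == pytest.approx(o, abs=0.04)

    def test_clipping_invariant_every_estimator(self):
        for idx in (
            efast_indices(ishigami, 3, 256, seed=9),
            jansen(ishigami, 3, 256, seed=9),
            owen(ishigami, 3, 256, seed=9),
        ):
            assert (idx.S >= 0).all() and (idx.ST <= 1).all()
            assert (idx.ST >= idx.S).all()

    def test_main_effects_sum_below_one_plus_noise(self):
        idx = jansen(ishigami, p=3, n=4096, seed=10)
        assert idx.S[:, 0].sum() <= 1.05


class TestOracle:
    def test_additive_linear_sums_to_one(self):
        f = lambda U: U[:, 0] + 2 * U[:, 1]
        idx = sobol_bruteforce_oracle(f, p=2, n_outer=500, n_inner=200, seed=1)
        assert idx.S[:, 0].sum() == pytest.approx(1.0, abs=0.1)

    def test_matches_closed_form_ishigami(self):
        idx = sobol_bruteforce_oracle(ishigami, p=3, n_outer=2000, n_inner=200, seed=2)
        assert idx.S[:, 0] == pytest.approx(S_ISH, abs=0.06)
        assert idx.ST[:, 0] == pytest.approx(ST_ISH, abs=0.06)

    def test_matches_jansen_within_combined_error(self):
        orc = sobol_bruteforce_oracle(ishigami, p=3, n_outer=2000, n_inner=200, seed=3)
        jns = jansen(ishigami, p=3, n=8192, seed=3)
        assert orc.S[:, 0] == pytest.approx(jns.S[:, 0], abs=0.08)


class TestRunGsa:
    def _stub_adapter(self):
        def f(U):
            # second parameter deliberately inert across all outputs
            out = np.empty((U.shape[0], 6))
            for k in range(6):
                out[:, k] = (k + 1) * U[:, 0] + 0.5 * U[:, 2] ** 2
            return out

        f.output_index = [(c, t) for c in ("APAP", "AG") for t in (1.0, 2.0, 4.0)]
        return f

    def test_table_shape_and_inert_parameter(self, prior_table):
        names = ["Tg", "Tp", "CYP_Km"]
        df = run_gsa(
            self._stub_adapter(), prior_table,
            DesignConfig(method="jansen", n=2048, seed=1), names,
        )
        assert set(df["metric"]) == {"S", "ST", "interaction"}
        assert len(df) == 3 * 3 * 6
        inert = df[(df.parameter == "Tp") & (df.metric == "ST")]["value"]
        assert (inert < 0.02).all()

    def test_pbpk_efast_evaluation_count_and_reproducibility(self, prior_table):
        names = ["Tg", "CYP_VmaxC", "SULT_VmaxC"]
        times = (1.0, 4.0)
        adapter = make_pbpk_adapter(prior_table, names, times=times)
        cfg = DesignConfig(method="efast", n=65, efast_Nr=1, seed=2)
        df = run_gsa(adapter, prior_table, cfg, names)
        assert adapter.n_evaluations == evaluation_count("efast", 65, 3)
        adapter2 = make_pbpk_adapter(prior_table, names, times=times)
        df2 = run_gsa(adapter2, prior_table, cfg, names)
        assert df.equals(df2)

    def test_pbpk_morris_evaluation_count(self, prior_table):
        names = ["Tg", "CYP_VmaxC", "SULT_VmaxC"]
        adapter = make_pbpk_adapter(prior_table, names, times=(1.0, 4.0))
        run_gsa(adapter, prior_table, DesignConfig(method="morris", n=8, seed=3), names)
        assert adapter.n_evaluations == evaluation_count("morris", 8, 3)
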
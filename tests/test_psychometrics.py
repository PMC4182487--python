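"""Psychometric fitting, bootstrap intervals and repeated-measures ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vasmotion import observer as vo
from vasmotion import psychometrics as vp


def _expected_counts(pse, beta, lapse, velocity=100.0, n_per=1000.0):
    mu = np.array(vo.offsets_for(velocity))
    n = np.full(mu.size, n_per)
    k = n * vp.psychometric_function(mu, pse, beta, lapse)
    return mu, n, k


def _grid_refine_oracle(data, grid_pse, grid_beta, grid_lapse):
    """Independent optimum: exhaustive coarse grid, then local refinement."""
    from scipy import optimize

    def safe_nll(x):
        pse, beta, lapse = x
        if beta <= 0 or not 0.0 <= lapse <= 0.06:
            return np.inf
        return vp.neg_log_lik(x, data)

    best, best_nll = None, np.inf
    for p in grid_pse:
        for b in grid_beta:
            for lam in grid_lapse:
                nll = safe_nll((p, b, lam))
                if nll < best_nll:
                    best, best_nll = (p, b, lam), nll
    res = optimize.minimize(
        safe_nll,
        best,
        method="Nelder-Mead",
        options=dict(xatol=1e-8, fatol=1e-12, maxiter=5000),
    )
    return res.x, res.fun


class TestNegLogLik:
    def test_single_bernoulli_at_half_is_log_two(self):
        nll = vp.neg_log_lik((0.0, 1.0, 0.0), ([0.0], [1.0], [1.0]))
        assert nll == pytest.approx(np.log(2.0))

    def test_duplicated_row_doubles_contribution(self):
        one = vp.neg_log_lik((0.5, 2.0, 0.01), ([1.0, 3.0], [10, 10], [4, 8]))
        two = vp.neg_log_lik(
            (0.5, 2.0, 0.01), ([1.0, 3.0, 3.0], [10, 10, 10], [4, 8, 8])
        )
        single = vp.neg_log_lik((0.5, 2.0, 0.01), ([3.0], [10], [8]))
        assert two - one == pytest.approx(single)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            vp.neg_log_lik((0.0, -1.0, 0.0), ([0.0], [1], [1]))
        with pytest.raises(ValueError):
            vp.neg_log_lik((0.0, 1.0, 0.5), ([0.0], [1], [1]))

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError, match="counts"):
            vp.neg_log_lik((0.0, 1.0, 0.0), ([0.0], [1.0], [2.0]))


class TestFitPf:
    def test_noiseless_recovery_of_generating_parameters(self):
        data = _expected_counts(2.0, 3.0, 0.02)
        fit = vp.fit_pf(data)
        assert fit.pse == pytest.approx(2.0, abs=0.1)
        assert fit.beta == pytest.approx(3.0, abs=0.1)
        assert fit.lapse == pytest.approx(0.02, abs=0.005)

    def test_matches_grid_refinement_oracle(self):
        obs = vo.ObserverModel(pse=-1.0, sigma=4.0, lapse=0.03, seed=3)
        data = vo.run_block(obs, vo.build_schedule(50.0, "anechoic5", seed=3)).aggregate()
        fit = vp.fit_pf(data)
        _, oracle_nll = _grid_refine_oracle(
            data,
            np.linspace(-8, 8, 17),
            np.linspace(0.5, 10, 20),
            np.linspace(0.0, 0.06, 7),
        )
        assert fit.neg_log_likelihood <= oracle_nll + 1e-6

    def test_symmetric_data_give_zero_pse(self):
        mu = np.array([-10.0, -5.0, -2.5, 0.0, 2.5, 5.0, 10.0])
        n = np.full(mu.size, 100.0)
        k = n * vp.psychometric_function(mu, 0.0, 3.0, 0.0)
        fit = vp.fit_pf((mu, n, k))
        assert fit.pse == pytest.approx(0.0, abs=1e-6)

    def test_reflection_equivariance(self):
        mu, n, k = _expected_counts(1.5, 2.5, 0.02, velocity=50.0, n_per=200)
        fwd = vp.fit_pf((mu, n, k))
        # negating offsets and swapping response labels mirrors the fit
        rev = vp.fit_pf((-mu, n, n - k))
        assert rev.pse == pytest.approx(-fwd.pse, abs=1e-4)
        assert rev.beta == pytest.approx(fwd.beta, abs=1e-4)

    def test_accepts_dataframe_input(self):
        mu, n, k = _expected_counts(0.0, 3.0, 0.0, n_per=100)
        df = pd.DataFrame(
            dict(offset_deg=mu, n_trials=n, n_vision_leads=np.round(k))
        )
        assert vp.fit_pf(df).beta == pytest.approx(3.0, abs=0.25)

    def test_too_few_offsets_rejected(self):
        with pytest.raises(ValueError, match="offsets"):
            vp.fit_pf(([0.0, 1.0], [10, 10], [3, 8]))

    def test_one_sided_responses_rejected(self):
        with pytest.raises(ValueError, match="category"):
            vp.fit_pf(([-1.0, 0.0, 1.0], [10, 10, 10], [0, 0, 0]))

    def test_perfectly_separated_data_flagged(self):
        fit = vp.fit_pf(([-5.0, 0.0, 5.0], [10, 10, 10], [0, 0, 10]))
        assert fit.flagged


class TestBootstrapCi:
    def _block(self, seed):
        obs = vo.ObserverModel(pse=1.0, sigma=3.0, lapse=0.02, seed=seed)
        return vo.run_block(obs, vo.build_schedule(50.0, "anechoic5", seed=seed)).aggregate()

    def test_zero_bootstrap_leaves_fit_unchanged(self):
        data = self._block(0)
        fit = vp.fit_pf(data)
        assert vp.bootstrap_ci(fit, data, n_boot=0) is fit

    def test_intervals_contain_point_estimate_and_reproduce(self):
        data = self._block(1)
        fit = vp.fit_pf(data)
        a = vp.bootstrap_ci(fit, data, n_boot=100, seed=5)
        b = vp.bootstrap_ci(fit, data, n_boot=100, seed=5)
        assert a.ci95_pse == b.ci95_pse
        assert a.ci95_pse[0] <= fit.pse <= a.ci95_pse[1]
        assert a.ci95_beta[0] <= fit.beta <= a.ci95_beta[1]
        assert a.n_bootstrap == 100

    def test_ci_width_shrinks_with_sample_size(self):
        mu = np.array(vo.offsets_for(50.0))
        widths = {}
        for n_per in (10, 100):
            rng = np.random.default_rng(17)
            n = np.full(mu.size, float(n_per))
            k = rng.binomial(n_per, vp.psychometric_function(mu, 1.0, 3.0, 0.02))
            fit = vp.fit_pf((mu, n, k))
            fit = vp.bootstrap_ci(fit, (mu, n, k), n_boot=300, seed=2)
            widths[n_per] = fit.ci95_pse[1] - fit.ci95_pse[0]
        ratio = widths[10] / widths[100]
        assert np.sqrt(10) / 1.5 < ratio < np.sqrt(10) * 1.5


class TestRmAnova:
    def _brute_force(self, cube):
        """Explicit mean-decomposition sums of squares, written independently."""
        ns, na, nb = cube.shape
        grand = cube.mean()
        out = {}
        ss = lambda x: float(np.sum(x**2))
        m_s = cube.mean(axis=(1, 2), keepdims=True)
        m_a = cube.mean(axis=(0, 2), keepdims=True)
        m_b = cube.mean(axis=(0, 1), keepdims=True)
        m_sa = cube.mean(axis=2, keepdims=True)
        m_sb = cube.mean(axis=1, keepdims=True)
        m_ab = cube.mean(axis=0, keepdims=True)
        out["A"] = (ss(np.broadcast_to(m_a - grand, cube.shape)) , na - 1,
                    ss(np.broadcast_to(m_sa - m_s - m_a + grand, cube.shape)),
                    (na - 1) * (ns - 1))
        out["B"] = (ss(np.broadcast_to(m_b - grand, cube.shape)), nb - 1,
                    ss(np.broadcast_to(m_sb - m_s - m_b + grand, cube.shape)),
                    (nb - 1) * (ns - 1))
        out["AB"] = (ss(np.broadcast_to(m_ab - m_a - m_b + grand, cube.shape)),
                     (na - 1) * (nb - 1),
                     ss(cube - m_sa - m_sb - m_ab + m_s + m_a + m_b - grand),
                     (na - 1) * (nb - 1) * (ns - 1))
        return {
            key: (ss_eff / df_eff) / (ss_err / df_err)
            for key, (ss_eff, df_eff, ss_err, df_err) in out.items()
        }

    @given(st.integers(0, 200))
    def test_matches_brute_force_oracle(self, seed):
        cube = np.random.default_rng(seed).standard_normal((6, 2, 3))
        table = vp.rm_anova(cube)
        oracle = self._brute_force(cube)
        got = dict(zip(["A", "B", "AB"], table["F"]))
        for key in oracle:
            assert got[key] == pytest.approx(oracle[key], abs=1e-10)

    def test_matches_statsmodels(self):
        from statsmodels.stats.anova import AnovaRM

        cube = np.random.default_rng(99).standard_normal((8, 3, 4))
        rows = [
            dict(subject=s, A=a, B=b, y=cube[s, a, b])
            for s in range(8) for a in range(3) for b in range(4)
        ]
        sm = AnovaRM(pd.DataFrame(rows), "y", "subject", within=["A", "B"]).fit()
        table = vp.rm_anova(cube)
        assert table["F"].to_numpy() == pytest.approx(
            sm.anova_table["F Value"].to_numpy(), rel=1e-10
        )
        assert table["p"].to_numpy() == pytest.approx(
            sm.anova_table["Pr > F"].to_numpy(), rel=1e-8
        )

    def test_constant_table_gives_zero_f(self):
        table = vp.rm_anova(np.full((5, 2, 3), 3.7))
        assert (table["F"] == 0.0).all()
        assert (table["p"] == 1.0).all()

    def test_degrees_of_freedom(self):
        table = vp.rm_anova(np.random.default_rng(0).standard_normal((6, 2, 3)))
        assert table["df_num"].tolist() == [1, 2, 2]
        assert table["df_den"].tolist() == [5, 10, 10]

    def test_long_dataframe_input(self):
        cube = np.random.default_rng(3).standard_normal((4, 2, 3))
        rows = [
            dict(subject=s, condition=f"c{a}", velocity=v, value=cube[s, a, b])
            for s in range(4) for a in range(2) for b, v in enumerate((25, 50, 100))
        ]
        from_df = vp.rm_anova(pd.DataFrame(rows))
        from_cube = vp.rm_anova(cube)
        assert from_df["F"].to_numpy() == pytest.approx(from_cube["F"].to_numpy())

    def test_missing_cells_rejected(self):
        rows = [
            dict(subject=s, condition="a", velocity=v, value=1.0)
            for s in range(3) for v in (25, 50)
        ]
        rows.append(dict(subject=0, condition="b", velocity=25, value=1.0))
        with pytest.raises(ValueError, match="missing"):
            vp.rm_anova(pd.DataFrame(rows))


class TestSummarizeGroup:
    def test_hand_computed_mean_and_se(self):
        fits = pd.DataFrame(
            dict(
                subject=[1, 2, 1, 2],
                condition=["anechoic5"] * 2 + ["reverberant5"] * 2,
                velocity=[50.0] * 4,
                pse=[1.0, 1.0, 0.0, 2.0],
                beta=[2.0, 4.0, 3.0, 3.0],
            )
        )
        out = vp.summarize_group(fits)
        row = out[out.condition == "anechoic5"].iloc[0]
        assert row["beta_mean"] == 3.0 and row["beta_se"] == pytest.approx(1.0)
        assert row["pse_se"] == 0.0

    def test_cell_count_is_conditions_times_velocities(self):
        fits = pd.DataFrame(
            dict(
                subject=np.tile([1, 2], 6),
                condition=np.repeat(["anechoic1", "anechoic5"], 6),
                velocity=np.tile(np.repeat([25.0, 50.0, 100.0], 2), 2),
                pse=np.zeros(12),
                beta=np.ones(12),
            )
        )
        assert len(vp.summarize_group(fits)) == 6

    def test_single_subject_cell_rejected(self):
        fits = pd.DataFrame(
            dict(subject=[1], condition=["anechoic5"], velocity=[50.0],
                 pse=[0.0], beta=[1.0])
        )
        with pytest.raises(ValueError, match="subjects"):
            vp.summarize_group(fits)
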
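"""Penalized likelihood fitting: EE, PL, MF, and the analytic solution."""

import numpy as np
import pytest
from scipy.special import logit
from scipy.stats import chi2

from ddagwas import (EncodedMatrix, ModelParams, SimulationSpec,
                     carrier_frequency, cross_validate, fit, fit_ee,
                     fit_independent, fit_mf, fit_pl, penalized_loglik,
                     power_independent, sample_genotypes,
                     sample_parameters, simulate)
from ddagwas.models import pair_indices, suff_stats
from ddagwas.simulate import enumerate_distribution


class TestPenalizedLoglik:
    def test_uniform_model_value(self):
        rng = np.random.default_rng(0)
        vals = (rng.random((50, 3)) < 0.5).astype(np.int8)
        psi = ModelParams.zeros(3, "dominant")
        ll = penalized_loglik(psi, vals, 0.0)
        assert ll == pytest.approx(-50 * 3 * np.log(2.0))

    def test_bernoulli_oracle(self):
        f = 0.19
        vals = np.repeat([1, 0], [19, 81]).astype(np.int8)[:, None]
        psi = ModelParams(model="dominant", h=np.array([logit(f)]),
                          J=np.zeros((1, 1)))
        expected = 100 * (f * np.log(f) + (1 - f) * np.log(1 - f))
        assert penalized_loglik(psi, vals, 0.0) == pytest.approx(expected)

    def test_penalty_linear_in_lambda(self):
        # per-individual convention: doubling lambda lowers the total
        # objective by n * (lambda/2) * sum J^2
        rng = np.random.default_rng(1)
        vals = (rng.random((40, 3)) < 0.4).astype(np.int8)
        J = np.triu(rng.normal(0, 0.5, (3, 3)), 1)
        J += J.T
        psi = ModelParams(model="dominant", h=rng.normal(0, 1, 3), J=J)
        iu, ju = pair_indices(3)
        jsq = np.sum(J[iu, ju] ** 2)
        l1 = penalized_loglik(psi, vals, 1.0)
        l2 = penalized_loglik(psi, vals, 2.0)
        assert l1 - l2 == pytest.approx(40 * 0.5 * jsq)

    def test_shape_mismatch_rejected(self):
        psi = ModelParams.zeros(3, "dominant")
        with pytest.raises(ValueError, match="SNPs"):
            penalized_loglik(psi, np.zeros((5, 2), dtype=np.int8), 0.0)


class TestIndependent:
    def test_worked_example_frequencies(self):
        # dominant carrier frequencies from minor-allele freqs (0.1, 0.25)
        assert carrier_frequency(0.1) == pytest.approx(0.19)
        assert carrier_frequency(0.25) == pytest.approx(0.4375)
        n = 10_000
        ctrl = np.repeat([1, 0], [1900, 8100])
        case = np.repeat([1, 0], [4375, 5625])
        vals = np.concatenate([ctrl, case]).astype(np.int8)[:, None]
        labels = np.repeat([0, 1], n).astype(np.int8)
        fr = fit_independent(EncodedMatrix(vals, "dominant"), labels)
        assert round(float(fr.psi0.h[0]), 2) == -1.45
        assert round(float(fr.psi1.h[0]), 2) == -0.25
        beta = float(fr.psi1.h[0] - fr.psi0.h[0])
        assert round(beta, 4) == 1.1987

    def test_symmetric_frequency_gives_zero_field(self):
        vals = np.tile([0, 1, 1, 0], 25).astype(np.int8)[:, None]
        labels = np.tile([0, 1], 50).astype(np.int8)
        fr = fit_independent(EncodedMatrix(vals, "dominant"), labels)
        assert fr.psi0.h[0] == pytest.approx(0.0)
        assert fr.psi1.h[0] == pytest.approx(0.0)

    def test_two_by_two_log_odds_ratio(self):
        case = np.repeat([1, 0], [40, 60])
        ctrl = np.repeat([1, 0], [30, 70])
        vals = np.concatenate([case, ctrl]).astype(np.int8)[:, None]
        labels = np.repeat([1, 0], 100).astype(np.int8)
        fr = fit_independent(EncodedMatrix(vals, "dominant"), labels)
        beta = float(fr.psi1.h[0] - fr.psi0.h[0])
        assert beta == pytest.approx(np.log(40 * 70 / (60 * 30)),
                                     abs=1e-10)

    def test_boundary_frequency_stays_finite(self):
        vals = np.concatenate([np.ones(50), np.zeros(50)]) \
            .astype(np.int8)[:, None]
        labels = np.repeat([1, 0], 50).astype(np.int8)
        fr = fit_independent(EncodedMatrix(vals, "dominant"), labels)
        assert np.isfinite(fr.psi0.h).all()
        assert np.isfinite(fr.psi1.h).all()

    def test_genotypic_reference_category(self):
        vals = np.repeat([0, 1, 2], [50, 30, 20]).astype(np.int8)[:, None]
        labels = np.tile([0, 1], 50).astype(np.int8)
        fr = fit_independent(EncodedMatrix(vals, "genotypic"), labels)
        np.testing.assert_allclose(fr.psi_pooled.h[0],
                                   [np.log(0.3 / 0.5), np.log(0.2 / 0.5)],
                                   atol=1e-12)


class TestPowerIndependent:
    def test_null_equals_alpha(self):
        assert power_independent(0.3, 0.3, 1000, 0.05) == \
            pytest.approx(0.05)

    def test_monotone_in_n(self):
        p = [power_independent(0.19, 0.25, n) for n in (100, 400, 1600)]
        assert p[0] < p[1] < p[2]

    def test_matches_simulated_lr_test(self):
        f0, f1, n_side, alpha = 0.19, 0.4375, 500, 0.05
        rng = np.random.default_rng(29)
        reps = 4000
        k0 = rng.binomial(n_side, f0, reps)
        k1 = rng.binomial(n_side, f1, reps)
        # 2x2 G statistic per replicate
        def xlogy(x, y):
            return np.where(x > 0, x * np.log(np.where(x > 0, y, 1.0)),
                            0.0)
        tot = k0 + k1
        fbar = tot / (2 * n_side)
        ll_full = (xlogy(k0, k0 / n_side) + xlogy(n_side - k0,
                                                  1 - k0 / n_side)
                   + xlogy(k1, k1 / n_side) + xlogy(n_side - k1,
                                                    1 - k1 / n_side))
        ll_null = xlogy(tot, fbar) + xlogy(2 * n_side - tot, 1 - fbar)
        g = 2 * (ll_full - ll_null)
        crit = chi2.ppf(1 - alpha, df=1)
        sim_power = float(np.mean(g > crit))
        se = np.sqrt(sim_power * (1 - sim_power) / reps)
        assert power_independent(f0, f1, 2 * n_side, alpha) == \
            pytest.approx(sim_power, abs=2 * max(se, 1e-3))


class TestEE:
    def test_saturated_two_snp_closed_form(self, saturated_pair):
        enc, labels = saturated_pair
        psi = fit_ee(enc, labels, 0.0, "pooled")
        assert psi.h[0] == pytest.approx(np.log(0.5), abs=1e-6)
        assert psi.h[1] == pytest.approx(np.log(0.5), abs=1e-6)
        assert psi.J[0, 1] == pytest.approx(np.log(2.0), abs=1e-6)

    def test_uniform_counts_give_zero_parameters(self):
        vals = np.repeat(np.array([[0, 0], [1, 0], [0, 1], [1, 1]],
                                  dtype=np.int8), 25, axis=0)
        labels = np.tile([0, 1], 50).astype(np.int8)
        psi = fit_ee(EncodedMatrix(vals, "dominant"), labels, 0.0,
                     "pooled")
        assert np.abs(psi.h).max() < 1e-6
        assert np.abs(psi.J).max() < 1e-6

    def test_large_penalty_reaches_independent_limit(self, saturated_pair):
        enc, labels = saturated_pair
        psi = fit_ee(enc, labels, 1e3, "pooled")
        ind = fit_independent(enc, labels).psi_pooled
        assert np.abs(psi.J).max() < 1e-2
        assert np.abs(psi.h - ind.h).max() < 1e-2

    @pytest.mark.parametrize("model,m", [("dominant", 6),
                                         ("genotypic", 4)])
    def test_moment_matching_at_optimum(self, model, m):
        spec = SimulationSpec(m=m, n0=400, n1=400, hbar_y=(-1.0, -0.5),
                              jbar_y=(0.0, 0.15), sigma_h=0.3,
                              sigma_j=0.15, model=model, seed=31)
        enc, labels, *_ = simulate(spec)
        psi = fit_ee(enc, labels, 0.0, "case")
        emp = suff_stats(enc.values[labels == 1], model)
        table = enumerate_distribution(psi)
        mod = suff_stats(table.states, model,
                         weights=table.probabilities)
        assert np.abs(emp - mod).max() < 1e-6

    def test_identical_groups_agree_across_fits(self, saturated_pair):
        enc, _ = saturated_pair
        labels = np.tile([0, 1], 50).astype(np.int8)
        vals = np.vstack([enc.values, enc.values])
        lab2 = np.concatenate([np.zeros(100), np.ones(100)]) \
            .astype(np.int8)
        fr = fit(EncodedMatrix(vals, "dominant"), lab2, "EE", 0.01)
        assert np.abs(fr.psi0.h - fr.psi1.h).max() < 1e-6
        assert np.abs(fr.psi0.J - fr.psi_pooled.J).max() < 1e-6


class TestPL:
    def test_matches_ee_on_small_panel(self, saturated_pair):
        enc, labels = saturated_pair
        pl = fit_pl(enc, labels, 1e-4, "pooled")
        ee = fit_ee(enc, labels, 1e-4, "pooled")
        assert np.abs(pl.h - ee.h).max() < 0.05
        assert np.abs(pl.J - ee.J).max() < 0.05

    def test_large_penalty_reaches_independent_limit(self, sim_panel_m6):
        enc, labels, *_ = sim_panel_m6
        pl = fit_pl(enc, labels, 1e3, "pooled")
        ind = fit_independent(enc, labels).psi_pooled
        assert np.abs(pl.J).max() < 1e-2
        assert np.abs(pl.h - ind.h).max() < 2e-2

    def test_parameter_recovery_with_cv(self):
        spec = SimulationSpec(m=10, n0=50_000, n1=50_000,
                              hbar_y=(-1.0, -0.3), jbar_y=(0.0, 0.1),
                              sigma_h=0.2, sigma_j=0.2,
                              shared_noise=False, seed=37)
        psi0, psi1 = sample_parameters(spec)
        enc, labels = sample_genotypes(psi0, psi1, spec.n0, spec.n1,
                                       seed=37)
        cv = cross_validate(enc, labels, "PL",
                            grid=[1e-4, 1e-3, 1e-2], folds=3, seed=0)
        fitted = fit_pl(enc, labels, cv.best_penalizer, "case")
        iu, ju = pair_indices(10)
        r = np.corrcoef(fitted.J[iu, ju], psi1.J[iu, ju])[0, 1]
        assert r > 0.9

    def test_parallel_map_contract(self, sim_panel_m6):
        enc, labels, *_ = sim_panel_m6

        def reversed_map(fn, it):
            items = list(it)
            return reversed([fn(x) for x in reversed(items)])

        a = fit_pl(enc, labels, 0.01, "case")
        b = fit_pl(enc, labels, 0.01, "case", map_fn=reversed_map)
        np.testing.assert_allclose(a.h, b.h, atol=1e-12)
        np.testing.assert_allclose(a.J, b.J, atol=1e-12)


class TestMF:
    def test_epsilon_zero_is_independent_limit(self, sim_panel_m6):
        enc, labels, *_ = sim_panel_m6
        mf = fit_mf(enc, labels, 0.0, "control")
        ind = fit_independent(enc, labels).psi0
        assert np.abs(mf.J).max() < 1e-12
        np.testing.assert_allclose(mf.h, ind.h, atol=1e-10)

    def test_weak_coupling_tracks_ee(self):
        spec = SimulationSpec(m=3, n0=50_000, n1=50_000,
                              hbar_y=(-0.5, -0.5), jbar_y=(0.08, 0.08),
                              sigma_h=0.0, sigma_j=0.0, seed=41)
        enc, labels, *_ = simulate(spec)
        mf = fit_mf(enc, labels, 1.0, "pooled")
        ee = fit_ee(enc, labels, 0.0, "pooled")
        iu, ju = pair_indices(3)
        rel = np.abs(mf.J[iu, ju] - ee.J[iu, ju]) / np.abs(ee.J[iu, ju])
        assert rel.max() < 0.25

    def test_independent_columns_give_zero_coupling(self):
        rng = np.random.default_rng(43)
        vals = (rng.random((200, 3)) < 0.3).astype(np.int8)
        labels = np.tile([0, 1], 100).astype(np.int8)
        mf = fit_mf(EncodedMatrix(vals, "dominant"), labels, 0.0,
                    "pooled")
        assert np.abs(mf.J).max() < 1e-12
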
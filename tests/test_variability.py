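import numpy as np
import pandas as pd
import pytest
from scipy import stats

import skinrhythm as sr
from skinrhythm.cosinor import harmonic_design
from skinrhythm.synthetic import CohortConfig, simulate_cohort
from skinrhythm.variability import _LMMProblem, _codes, ols_loglik

from conftest import record_arrays

W = 2 * np.pi / 24
Z3 = np.zeros((3, 3))


def _cohort(seed, **kw):
    cfg = CohortConfig(seed=seed, n_genes=kw.pop("n_genes", 1),
                       frac_rhythmic=kw.pop("frac_rhythmic", 1.0), **kw)
    m, recs, truth = simulate_cohort(cfg)
    t, subj, lay, cols = record_arrays(recs)
    return m, t, subj, lay, cols, truth


class TestLikelihood:
    def test_loglik_matches_dense_multivariate_normal(self):
        # independent oracle: assemble V densely and evaluate the Gaussian
        # log-density with scipy at the fitted parameters
        m, t, subj, lay, cols, _ = _cohort(21, n_subjects=3,
                                           timepoints=(8.0, 14.0, 20.0, 26.0),
                                           resid_sd=0.2)
        y = m.iloc[0][cols].to_numpy()
        fit = sr.fit_gene_lmm(y, t, subj, lay)
        X = harmonic_design(t)
        sc, _ = _codes(subj)
        lc, _ = _codes(lay)
        n = y.size
        V = fit.resid_var * np.eye(n)
        for g, cov, codes in ((None, fit.sigma_subj, sc),
                              (None, fit.sigma_layer, lc)):
            for grp in np.unique(codes):
                mask = codes == grp
                Xg = X[mask]
                V[np.ix_(mask, mask)] += Xg @ cov @ Xg.T
        ref = stats.multivariate_normal.logpdf(y, mean=X @ fit.fixed, cov=V)
        assert fit.loglik == pytest.approx(ref, abs=1e-6)

    def test_loglik_never_below_ols(self):
        m, t, subj, lay, cols, _ = _cohort(22, n_genes=5)
        for g in m.index:
            y = m.loc[g, cols].to_numpy()
            fit = sr.fit_gene_lmm(y, t, subj, lay, gene_id=g)
            assert fit.loglik >= ols_loglik(y, t) - 1e-6


class TestFitGeneLmm:
    def test_noiseless_fixed_effects_exact(self):
        m, t, subj, lay, cols, _ = _cohort(23)
        y = 7 + 0.5 * np.cos(W * t) + 0.3 * np.sin(W * t)
        fit = sr.fit_gene_lmm(y, t, subj, lay)
        assert np.allclose(fit.fixed, [7, 0.5, 0.3], atol=1e-8)
        assert np.diag(fit.sigma_subj).max() < 1e-6
        assert np.diag(fit.sigma_layer).max() < 1e-6

    def test_zero_random_effect_truth_recovered_at_boundary(self):
        m, t, subj, lay, cols, _ = _cohort(24, sigma_subj=Z3, sigma_layer=Z3,
                                           resid_sd=0.1)
        fit = sr.fit_gene_lmm(m.iloc[0][cols].to_numpy(), t, subj, lay)
        assert np.abs(fit.sigma_subj).max() < 0.05
        assert np.abs(fit.sigma_layer).max() < 0.05

    def test_variance_recovery_across_cohorts(self):
        # mean over repeated study-size cohorts; subject components are
        # estimated well, 2-level layer variances carry a known downward bias
        true_s = np.array([0.2, 0.1, 0.1])
        true_l = np.array([0.3, 0.05, 0.05])
        est_s, est_l = [], []
        for k in range(40):
            m, t, subj, lay, cols, _ = _cohort(
                200 + k, sigma_subj=np.diag(true_s**2),
                sigma_layer=np.diag(true_l**2), resid_sd=0.15)
            fit = sr.fit_gene_lmm(m.iloc[0][cols].to_numpy(), t, subj, lay)
            est_s.append(np.diag(fit.sigma_subj))
            est_l.append(np.diag(fit.sigma_layer))
        sd_s = np.sqrt(np.mean(est_s, axis=0))
        sd_l = np.sqrt(np.mean(est_l, axis=0))
        assert np.all(np.abs(sd_s - true_s) / true_s < 0.25)
        assert np.all(np.abs(sd_l - true_l) / true_l < 0.35)

    def test_single_subject_or_layer_rejected(self):
        t = np.tile(np.arange(0, 24, 4.0), 2)
        y = np.ones(t.size)
        with pytest.raises(ValueError):
            sr.fit_gene_lmm(y, t, ["P1"] * t.size,
                            ["dermis"] * 6 + ["epidermis"] * 6)
        with pytest.raises(ValueError):
            sr.fit_gene_lmm(y, t, ["P1"] * 6 + ["P2"] * 6, ["dermis"] * t.size)


class TestSingleLayer:
    def test_reduces_to_pooled_cosinor_without_subject_effects(self):
        # balanced design (identical chronotypes) and zero subject effects:
        # GLS fixed effects coincide with the pooled OLS cosinor fit
        m, t, subj, lay, cols, _ = _cohort(25, sigma_subj=Z3, sigma_layer=Z3,
                                           msf_low_h=0.0, msf_high_h=0.0,
                                           resid_sd=0.15)
        keep = [i for i, l in enumerate(lay) if l == "dermis"]
        y = m.iloc[0][cols].to_numpy()[keep]
        td = t[keep]
        sd = [subj[i] for i in keep]
        fit = sr.fit_gene_lmm_single_layer(y, td, sd)
        ref = sr.fit_cosinor(y, td)
        assert np.allclose(fit.fixed, [ref.mesor_m, ref.coef_a, ref.coef_b],
                           atol=1e-6)

    def test_two_identical_subjects_have_zero_subject_variance(self):
        t_one = np.arange(0, 24, 4.0)
        y_one = 5 + 0.5 * np.cos(W * t_one)
        t = np.tile(t_one, 2)
        y = np.tile(y_one, 2) + 0.01 * np.sin(7 * t)  # tiny shared wiggle
        fit = sr.fit_gene_lmm_single_layer(y, t, ["P1"] * 6 + ["P2"] * 6)
        assert np.abs(fit.sigma_subj).max() < 1e-4


class TestDeltaMethod:
    def test_isotropic_ab_covariance_gives_sigma(self):
        sd = 0.07
        cov = np.diag([0.5**2, sd**2, sd**2])
        assert sr.propagate_amplitude_sd((1, 0.3, 0.4), cov) == pytest.approx(sd)

    def test_axis_aligned_amplitude(self):
        cov = np.zeros((3, 3))
        cov[1, 1] = 0.04
        assert sr.propagate_amplitude_sd((0, 1.0, 0.0), cov) == pytest.approx(0.2)

    def test_axis_aligned_phase(self):
        cov = np.zeros((3, 3))
        cov[1, 1] = 0.01
        # a=0, b=1: J_phi = (0, -1, 0) -> 0.1 rad -> 0.1 * 24 / 2pi hours
        expected = 0.1 * 24 / (2 * np.pi)
        assert sr.propagate_phase_sd((0, 0.0, 1.0), cov) == pytest.approx(expected)

    def test_phase_closed_form_isotropic(self):
        A, sd = 0.8, 0.06
        cov = np.diag([1.0, sd**2, sd**2])
        expected = (sd / A) * 24 / (2 * np.pi)
        got = sr.propagate_phase_sd((0, A, 0.0), cov)
        assert got == pytest.approx(expected)

    def test_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            sr.propagate_amplitude_sd((1, 0, 0), np.eye(3))
        with pytest.raises(ValueError):
            sr.propagate_phase_sd((1, 0, 0), np.eye(3))

    def test_monte_carlo_agreement_small_variance(self, rng):
        # quick MC cross-check; the full 1e6-draw version runs in acceptance
        for _ in range(3):
            a, b = rng.normal(0, 1, 2)
            A = np.hypot(a, b)
            sd = 0.1 * A
            cov = np.diag([0.1**2, sd**2, (0.7 * sd)**2])
            draws = rng.multivariate_normal([0, a, b], cov, 200_000)
            mcA = np.hypot(draws[:, 1], draws[:, 2]).std()
            dA = sr.propagate_amplitude_sd((0, a, b), cov)
            assert abs(dA - mcA) / mcA < 0.05

    def test_rotation_invariance_of_amplitude_sd(self, rng):
        for _ in range(10):
            a, b = rng.normal(0, 1, 2)
            S = rng.normal(size=(3, 3))
            cov = S @ S.T
            ang = rng.uniform(0, 2 * np.pi)
            R2 = np.array([[np.cos(ang), -np.sin(ang)],
                           [np.sin(ang), np.cos(ang)]])
            R = np.eye(3)
            R[1:, 1:] = R2
            ab_rot = R2 @ np.array([a, b])
            cov_rot = R @ cov @ R.T
            s0 = sr.propagate_amplitude_sd((0, a, b), cov)
            s1 = sr.propagate_amplitude_sd((0, *ab_rot), cov_rot)
            assert s1 == pytest.approx(s0, rel=1e-10)


class TestVarianceFraction:
    @pytest.mark.parametrize("vs,vl,f", [(3, 1, 0.75), (0, 2, 0.0), (5, 5, 0.5)])
    def test_known_values(self, vs, vl, f):
        assert sr.variance_fraction(vs, vl) == pytest.approx(f)

    def test_undefined_and_invalid(self):
        with pytest.raises(ValueError):
            sr.variance_fraction(0.0, 0.0)
        with pytest.raises(ValueError):
            sr.variance_fraction(-1.0, 1.0)


class TestVariabilityTable:
    def test_subject_dominated_amplitude_variance(self):
        cfg = CohortConfig(seed=26, n_genes=8, frac_rhythmic=1.0,
                           sigma_subj=np.diag([0.1**2, 0.15**2, 0.15**2]),
                           sigma_layer=np.diag([0.1**2, 0.02**2, 0.02**2]),
                           resid_sd=0.15)
        m, recs, _ = simulate_cohort(cfg)
        tab = sr.variability_table(m, recs, list(m.index))
        assert tab["f_A"].median() > 0.5

    def test_layer_shifted_mesor_only(self):
        cfg = CohortConfig(seed=27, n_genes=8, frac_rhythmic=1.0,
                           sigma_subj=np.diag([0.05**2, 0.08**2, 0.08**2]),
                           sigma_layer=np.diag([0.4**2, 0.02**2, 0.02**2]),
                           resid_sd=0.15)
        m, recs, _ = simulate_cohort(cfg)
        tab = sr.variability_table(m, recs, list(m.index))
        assert tab["f_m"].median() < 0.5

    def test_deterministic_output(self):
        cfg = CohortConfig(seed=28, n_genes=3, frac_rhythmic=1.0)
        m, recs, _ = simulate_cohort(cfg)
        t1 = sr.variability_table(m, recs, list(m.index))
        t2 = sr.variability_table(m, recs, list(m.index))
        pd.testing.assert_frame_equal(t1, t2)

    def test_empty_and_unknown_gene_list(self, study_cohort):
        m, recs, _ = study_cohort
        assert len(sr.variability_table(m, recs, [])) == 0
        with pytest.raises(ValueError):
            sr.variability_table(m, recs, ["not_a_gene"])
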
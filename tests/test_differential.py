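import numpy as np
import pandas as pd
import pytest
from scipy import stats

import skinrhythm as sr
from skinrhythm.cosinor import harmonic_design
from skinrhythm.differential import (rayleigh_p, rhythmic_gene_ids,
                                     wrap_phase_difference)
from skinrhythm.synthetic import CohortConfig, planted_category_frame, simulate_cohort

W = 2 * np.pi / 24


def _two_layer_design(n_per_layer=77, seed=7):
    rng = np.random.default_rng(seed)
    msf = rng.uniform(2.5, 6.0, 11)
    t_one = np.concatenate([np.arange(8, 33, 4.0) - m for m in msf])
    t = np.concatenate([t_one, t_one])
    lab = ["dermis"] * t_one.size + ["epidermis"] * t_one.size
    return t, np.asarray(lab)


class TestJointFit:
    def test_identical_noiseless_rhythms_give_zero_delta(self):
        t, lab = _two_layer_design()
        y = 5 + 0.7 * np.cos(W * t) + 0.2 * np.sin(W * t)
        fit = sr.fit_joint_model(y, t, lab)
        assert np.allclose(fit.delta_ab, 0.0, atol=1e-10)

    def test_one_flat_one_rhythmic_layer(self):
        t, lab = _two_layer_design()
        y = np.where(lab == "dermis", 5.0, 5 + np.cos(W * t))
        fit = sr.fit_joint_model(y, t, lab)
        m_d, a_d, b_d, m_e, a_e, b_e = fit.beta
        assert a_d == pytest.approx(0, abs=1e-10)
        assert b_d == pytest.approx(0, abs=1e-10)
        assert np.hypot(a_e, b_e) == pytest.approx(1.0, abs=1e-10)

    def test_joint_equals_per_layer_ols(self, rng):
        t, lab = _two_layer_design()
        y = rng.normal(size=t.size)
        fit = sr.fit_joint_model(y, t, lab)
        for layer, sl in (("dermis", slice(0, 3)), ("epidermis", slice(3, 6))):
            mask = lab == layer
            X = harmonic_design(t[mask])
            beta = np.linalg.lstsq(X, y[mask], rcond=None)[0]
            assert np.allclose(fit.beta[sl], beta, atol=1e-10)

    def test_missing_layer_rejected(self):
        t = np.arange(0, 24, 2.0)
        with pytest.raises(ValueError):
            sr.fit_joint_model(np.ones_like(t), t, ["dermis"] * t.size)


class TestFTests:
    def test_statistics_match_rss_oracle(self, rng):
        t, lab = _two_layer_design()
        is_epi = lab == "epidermis"
        for _ in range(5):
            y = rng.normal(size=t.size)
            fit = sr.fit_joint_model(y, t, lab)

            def rss_of(X):
                b = np.linalg.lstsq(X, y, rcond=None)[0]
                return np.sum((y - X @ b) ** 2)

            H = harmonic_design(t)
            ind = np.column_stack([(~is_epi) * 1.0, is_epi * 1.0])
            rss_any = rss_of(ind)
            rss_diff = rss_of(np.column_stack([ind, H[:, 1], H[:, 2]]))
            n = t.size
            f_any = ((rss_any - fit.rss) / 4) / (fit.rss / (n - 6))
            f_diff = ((rss_diff - fit.rss) / 2) / (fit.rss / (n - 6))
            assert sr.test_any_rhythm(fit) == pytest.approx(
                stats.f.sf(f_any, 4, n - 6), abs=1e-10)
            assert sr.test_differential(fit) == pytest.approx(
                stats.f.sf(f_diff, 2, n - 6), abs=1e-10)

    def test_power_one_rhythmic_layer(self):
        rng = np.random.default_rng(11)
        t, lab = _two_layer_design()
        y = 5 + np.where(lab == "epidermis", 0.5 * np.cos(W * t), 0.0)
        y = y + rng.normal(0, 0.2, t.size)
        fit = sr.fit_joint_model(y, t, lab)
        assert sr.test_any_rhythm(fit) < 1e-6

    def test_power_antiphase_layers(self):
        rng = np.random.default_rng(12)
        t, lab = _two_layer_design()
        sgn = np.where(lab == "epidermis", 1.0, -1.0)
        y = 5 + sgn * 0.5 * np.cos(W * t) + rng.normal(0, 0.2, t.size)
        fit = sr.fit_joint_model(y, t, lab)
        assert sr.test_differential(fit) < 1e-6

    def test_null_p_values_are_uniform(self):
        # equal coefficients in both layers; exact F null
        cfg = CohortConfig(seed=13, n_genes=300, frac_rhythmic=0.0,
                           sigma_subj=np.zeros((3, 3)),
                           sigma_layer=np.zeros((3, 3)), resid_sd=0.2)
        m, recs, _ = simulate_cohort(cfg)
        scan = sr.differential_scan(m, recs)
        assert stats.kstest(scan["p_any"], "uniform").pvalue > 0.01
        assert stats.kstest(scan["p_diff"], "uniform").pvalue > 0.01


class TestCategorize:
    def _row(self, gene, fc_d, fc_e, p_any, p_diff):
        return {"gene_id": gene, "fold_change_d": fc_d, "fold_change_e": fc_e,
                "p_any": p_any, "p_diff": p_diff}

    def test_subthreshold_inclusion_rule(self):
        # indistinguishable rhythms count in BOTH layers even when one layer's
        # fold change sits below the threshold
        scan = pd.DataFrame([
            self._row("g1", 1.6, 1.2, 1e-12, 0.5),
            self._row("g2", 2.0, 2.0, 1e-12, 1e-9),
            self._row("g3", 1.1, 1.1, 0.9, 0.9),
        ])
        cat = sr.categorize(scan).set_index("gene_id")["category"]
        assert cat["g1"] == "both_indistinguishable"
        assert cat["g2"] == "both_differential"
        assert cat["g3"] == "not_rhythmic"

    def test_all_flat_means_everything_not_rhythmic(self):
        cfg = CohortConfig(seed=14, n_genes=60, frac_rhythmic=0.0,
                           sigma_subj=np.zeros((3, 3)),
                           sigma_layer=np.zeros((3, 3)), resid_sd=0.2)
        m, recs, _ = simulate_cohort(cfg)
        cat = sr.categorize(sr.differential_scan(m, recs))
        assert (cat["category"] == "not_rhythmic").all()

    def test_invalid_thresholds_rejected(self, study_cohort):
        m, recs, _ = study_cohort
        scan = sr.differential_scan(m, recs)
        with pytest.raises(ValueError):
            sr.categorize(scan, fdr=1.5)
        with pytest.raises(ValueError):
            sr.categorize(scan, fc_threshold=0.9)

    def test_partition_and_per_layer_count_identity(self, study_cohort):
        m, recs, _ = study_cohort
        cat = sr.categorize(sr.differential_scan(m, recs))
        counts = cat["category"].value_counts()
        assert counts.sum() == len(cat)
        # dermis calls = indistinguishable + dermis_only + differential genes
        # whose dermis fold change clears the bar
        diff_d = ((cat["category"] == "both_differential")
                  & (cat["fold_change_d"] > 1.5)).sum()
        dermis_calls = (counts.get("both_indistinguishable", 0)
                        + counts.get("dermis_only", 0) + diff_d)
        s = sr.summarize_categories(cat)
        assert s["dermis_total"] == dermis_calls

    def test_swapping_layers_swaps_categories(self):
        planted = planted_category_frame(seed=15, n_shared=5, n_dermis_only=5,
                                         n_epidermis_only=3, n_phase_shift=2,
                                         n_flat=15)
        cfg = CohortConfig(seed=15, n_genes=len(planted), planted=planted,
                           sigma_subj=np.zeros((3, 3)),
                           sigma_layer=np.zeros((3, 3)), resid_sd=0.15)
        m, recs, _ = simulate_cohort(cfg)
        cat = sr.categorize(sr.differential_scan(m, recs))
        swapped_recs = [type(r)(r.sample_id, r.subject_id,
                                "dermis" if r.layer == "epidermis" else "epidermis",
                                r.wall_time_h, r.msf_sc_h, r.internal_time_h)
                        for r in recs]
        cat_sw = sr.categorize(sr.differential_scan(m, swapped_recs))
        c1 = cat["category"].value_counts()
        c2 = cat_sw["category"].value_counts()
        assert c1.get("dermis_only", 0) == c2.get("epidermis_only", 0)
        assert c1.get("epidermis_only", 0) == c2.get("dermis_only", 0)
        assert np.allclose(np.sort(cat["p_diff"]), np.sort(cat_sw["p_diff"]))

    def test_category_recovery_on_planted_truth(self):
        planted = planted_category_frame(seed=16)
        cfg = CohortConfig(seed=16, n_genes=len(planted), planted=planted,
                           sigma_subj=np.zeros((3, 3)),
                           sigma_layer=np.zeros((3, 3)), resid_sd=0.15)
        m, recs, _ = simulate_cohort(cfg)
        cat = sr.categorize(sr.differential_scan(m, recs))
        merged = planted.merge(cat[["gene_id", "category"]], on="gene_id",
                               suffixes=("_true", "_est"))
        acc = (merged["category_true"] == merged["category_est"]).mean()
        assert acc >= 0.90
        assert set(rhythmic_gene_ids(cat)) == set(
            cat.loc[cat["category"] != "not_rhythmic", "gene_id"])


class TestCircularPhaseStats:
    def test_identical_lists(self):
        d, R, p = sr.circular_phase_stats([1, 5, 9.5], [1, 5, 9.5])
        assert d == pytest.approx(0.0)
        assert R == pytest.approx(1.0)

    def test_symmetric_pair_vector_sum(self):
        # differences +3 and -3 -> mean 0, R = cos(3 * 2pi / 24)
        d, R, _ = sr.circular_phase_stats([3.0, -3.0], [0.0, 0.0])
        assert d == pytest.approx(0.0, abs=1e-12)
        assert R == pytest.approx(np.cos(3 * 2 * np.pi / 24))

    def test_uniform_differences_give_small_R(self):
        rng = np.random.default_rng(17)
        p1 = rng.uniform(0, 24, 10000)
        p2 = np.zeros(10000)
        _, R, p = sr.circular_phase_stats(p1, p2)
        assert R < 0.05
        assert p > 0.01

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sr.circular_phase_stats([1, 2], [1])

    def test_wrap_covers_half_open_interval(self):
        assert wrap_phase_difference(12.0) == 12.0
        assert wrap_phase_difference(-12.0) == 12.0
        assert wrap_phase_difference(13.0) == -11.0

    def test_rayleigh_p_matches_pingouin(self):
        import pingouin as pg
        rng = np.random.default_rng(18)
        ang = rng.vonmises(0.0, 1.0, 200)
        R = np.hypot(np.cos(ang).mean(), np.sin(ang).mean())
        _, p_ref = pg.circ_rayleigh(ang)
        assert rayleigh_p(R, ang.size) == pytest.approx(p_ref, abs=1e-6)
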
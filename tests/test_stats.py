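"""Statistical cascade: enrolment filter, demographics, screening, correlations."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from braincontrol.control import DeltaProfile
from braincontrol.stats import (
    ancova_region,
    ancova_table,
    chisq_2x2,
    cohort_filter,
    correlate_delta_outcome,
    improvement_rate,
    paired_t_region,
    pooled_t_from_summary,
    select_responsive_regions,
)
from braincontrol.synthetic import make_candidate_pool


class TestCohortFilter:
    def test_default_cascade_retains_39_of_50(self):
        pool = make_candidate_pool(seed=0)
        kept, ledger = cohort_filter(pool)
        assert len(kept) == 39
        assert ledger == {"no_surgery": 5, "unilateral_dbs": 2,
                          "rf_lesion": 1, "missing_data": 3}

    def test_unflagged_pool_passes_through(self):
        pool = make_candidate_pool(n_no_surgery=0, n_unilateral=0, n_lesion=0,
                                   n_missing=0, seed=1)
        kept, ledger = cohort_filter(pool)
        assert len(kept) == 50 and ledger == {}

    def test_fully_flagged_pool_empties(self):
        pool = make_candidate_pool(n_total=11, n_no_surgery=5, n_unilateral=2,
                                   n_lesion=1, n_missing=3, seed=2)
        kept, ledger = cohort_filter(pool)
        assert kept == [] and sum(ledger.values()) == 11


class TestImprovementRate:
    @pytest.mark.parametrize(
        "pre,post,expect",
        [(40.0, 40.0, 0.0), (40.0, 0.0, 100.0), (55.95, 17.54, 68.65), (40.0, 50.0, -25.0)],
    )
    def test_values(self, pre, post, expect):
        assert improvement_rate(pre, post) == pytest.approx(expect, abs=0.005)

    def test_zero_preoperative_score_rejected(self):
        with pytest.raises(ValueError):
            improvement_rate(0.0, 10.0)


class TestPooledT:
    def test_equal_means_give_zero(self):
        t, df, p = pooled_t_from_summary(5.0, 1.0, 10, 5.0, 2.0, 12)
        assert t == 0.0 and df == 20 and p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "summary,expect_t",
        [
            ((56.08, 15.83, 24, 55.73, 17.76, 15), 0.064),  # motor score, med-off
            ((16.96, 11.00, 24, 18.47, 9.32, 15), 0.441),  # motor score, stim-on
        ],
    )
    def test_cohort_table_statistics(self, summary, expect_t):
        t, df, _ = pooled_t_from_summary(*summary)
        assert df == 37
        assert round(t, 3) == expect_t

    def test_degenerate_zero_variance_unequal_means(self):
        with pytest.raises(ValueError, match="undefined"):
            pooled_t_from_summary(1.0, 0.0, 5, 2.0, 0.0, 5)


class TestChisq:
    @pytest.mark.parametrize(
        "table,expect",
        [
            ([[21, 18], [8, 21]], 4.689),  # sex, patients vs controls
            ([[12, 12], [9, 6]], 0.371),  # sex, STN vs GPi
            ([[10, 10], [10, 10]], 0.0),
        ],
    )
    def test_no_continuity_correction_values(self, table, expect):
        chi2, dof, _ = chisq_2x2(table)
        assert dof == 1
        assert round(chi2, 3) == expect

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chisq_2x2([[0, 0], [3, 4]])


class TestAncova:
    def test_identical_groups_null(self, rng):
        vals = rng.standard_normal(30)
        ages = np.full(60, 50.0)
        sexes = np.array(["male", "female"] * 30)
        F, p, _ = ancova_region(vals, vals, ages, sexes)
        assert F == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-8)

    def test_vectorized_table_matches_single_region_route(self, rng):
        n1, n2, R = 20, 15, 6
        pd_v = rng.standard_normal((n1, R))
        hc_v = rng.standard_normal((n2, R))
        ages = rng.uniform(40, 70, n1 + n2)
        sexes = rng.choice(["male", "female"], n1 + n2)
        F, p, d = ancova_table(pd_v, hc_v, ages, sexes)
        for j in range(R):
            Fj, pj, dj = ancova_region(pd_v[:, j], hc_v[:, j], ages, sexes)
            assert F[j] == pytest.approx(Fj, rel=1e-8)
            assert p[j] == pytest.approx(pj, rel=1e-6)
            assert d[j] == dj

    def test_rejection_rate_matches_noncentral_f_power(self, rng):
        # planted +0.3 SD group shift, n = 39 vs 29, many independent regions
        n1, n2, R = 39, 29, 2000
        shift = 0.3
        pd_v = rng.standard_normal((n1, R)) + shift
        hc_v = rng.standard_normal((n2, R))
        ages = np.concatenate([rng.uniform(45, 75, n1), rng.uniform(40, 70, n2)])
        sexes = rng.choice(["male", "female"], n1 + n2)
        _, p, _ = ancova_table(pd_v, hc_v, ages, sexes)
        rate = float(np.mean(p < 0.05))
        lam = shift**2 / (1 / n1 + 1 / n2)
        crit = scipy.stats.f.isf(0.05, 1, n1 + n2 - 4)
        power = scipy.stats.ncf.sf(crit, 1, n1 + n2 - 4, lam)
        ci = 3.0 * np.sqrt(power * (1 - power) / R)
        assert rate == pytest.approx(power, abs=ci)

    def test_age_confounded_effect_adjusted_away(self, rng):
        # group difference induced purely through an age gradient
        ages = np.concatenate([rng.uniform(60, 75, 25), rng.uniform(40, 55, 25)])
        vals = 0.1 * ages + rng.standard_normal(50) * 0.1
        sexes = rng.choice(["male", "female"], 50)
        F_adj, _, _ = ancova_region(vals[:25], vals[25:], ages, sexes)
        F_raw, _, _ = ancova_region(vals[:25], vals[25:],
                                    np.full(50, 50.0), sexes)
        assert F_adj < 0.1 * F_raw


class TestPairedT:
    def test_no_change_gives_zero(self):
        on = np.array([1.0, 2.0, 3.0, 4.0])
        t, p = paired_t_region(on, on)
        assert t == 0.0 and p == 1.0

    def test_constant_nonzero_difference_rejected(self):
        on = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="undefined"):
            paired_t_region(on + 0.5, on)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="3 pairs"):
            paired_t_region(np.array([1.0, 2.0]), np.array([0.0, 1.0]))

    def test_mean_statistic_matches_noncentral_t_expectation(self, rng):
        # differences ~ N(0.2, 1), n = 30: E[t] = δ√n · √(ν/2)·Γ((ν−1)/2)/Γ(ν/2)
        n, reps, delta = 30, 2000, 0.2
        diffs = rng.standard_normal((n, reps)) + delta
        off = rng.standard_normal((n, reps))
        t = scipy.stats.ttest_rel(off + diffs, off, axis=0).statistic
        nu = n - 1
        from scipy.special import gammaln

        ncp = delta * np.sqrt(n)
        expect = ncp * np.sqrt(nu / 2) * np.exp(gammaln((nu - 1) / 2) - gammaln(nu / 2))
        se = t.std(ddof=1) / np.sqrt(reps)
        assert t.mean() == pytest.approx(expect, abs=3.5 * se)


class TestSelectResponsive:
    def _frames(self, gp, mp):
        rows = [dict(region="Pallidum", hemisphere="L", metric="ac")]
        anc = pd.DataFrame([{**rows[0], "group_F": 5.0, "group_p": gp, "direction": "-"}])
        par = pd.DataFrame([{**rows[0], "med_t": 2.2, "med_p": mp}])
        return anc, par

    def test_nothing_significant_empty(self):
        anc, par = self._frames(0.4, 0.6)
        assert select_responsive_regions(anc, par).empty

    def test_group_only_excluded(self):
        anc, par = self._frames(0.01, 0.6)
        assert select_responsive_regions(anc, par).empty

    def test_both_significant_included(self):
        anc, par = self._frames(0.01, 0.03)
        out = select_responsive_regions(anc, par)
        assert len(out) == 1 and out.loc[0, "direction"] == "-"

    def test_planted_disease_nodes_detected_with_correct_direction(
        self, default_cohort, default_profiles
    ):
        from braincontrol.pipeline import screen_cohort

        profiles, _ = default_profiles
        _, _, responsive = screen_cohort(default_cohort, profiles, alpha=0.05)
        pal_ac = responsive.query("region == 'Pallidum' and metric == 'ac'")
        pal_mc = responsive.query("region == 'Pallidum' and metric == 'mc'")
        assert len(pal_ac) and set(pal_ac["direction"]) == {"-"}
        assert len(pal_mc) and set(pal_mc["direction"]) == {"+"}
        # medication moves metrics back toward control values
        assert (pal_ac["med_t"] > 0).all() and (pal_mc["med_t"] < 0).all()


def _delta_profiles_from_matrix(x, labels):
    out = {}
    for i, row in enumerate(x):
        out[f"P{i:03d}"] = DeltaProfile(
            delta_ac=row, delta_mc=np.zeros_like(row),
            node_labels=labels, subject_id=f"P{i:03d}",
        )
    return out


class TestCorrelateDeltaOutcome:
    labels = ["Thalamus_L", "Thalamus_R"]

    def test_perfect_affine_link_gives_unit_correlation(self, rng):
        x = rng.standard_normal((10, 2))
        deltas = _delta_profiles_from_matrix(x, self.labels)
        imps = {f"P{i:03d}": 50.0 - 3.0 * x[i, 0] for i in range(10)}
        df = correlate_delta_outcome(deltas, imps, roi_labels=self.labels)
        r_thal_l = df.query("region == 'Thalamus' and hemisphere == 'L' and metric == 'ac'")["r"].item()
        assert r_thal_l == pytest.approx(-1.0, abs=1e-10)

    def test_type_one_error_calibrated_under_independence(self, rng):
        hits = total = 0
        for _ in range(200):
            x = rng.standard_normal((12, 2))
            deltas = _delta_profiles_from_matrix(x, self.labels)
            imps = {f"P{i:03d}": float(v) for i, v in enumerate(rng.standard_normal(12))}
            df = correlate_delta_outcome(deltas, imps, roi_labels=self.labels)
            sub = df[df.metric == "ac"]
            hits += int(sub["significant"].sum())
            total += len(sub)
        rate = hits / total
        assert rate == pytest.approx(0.05, abs=3.0 * np.sqrt(0.05 * 0.95 / total))

    def test_zero_variance_delta_flagged_undefined(self):
        x = np.zeros((6, 2))
        deltas = _delta_profiles_from_matrix(x, self.labels)
        imps = {f"P{i:03d}": float(i) for i in range(6)}
        df = correlate_delta_outcome(deltas, imps, roi_labels=self.labels)
        assert df["undefined"].all() and df["r"].isna().all()

    def test_too_few_subjects_rejected(self, rng):
        x = rng.standard_normal((3, 2))
        deltas = _delta_profiles_from_matrix(x, self.labels)
        imps = {f"P{i:03d}": float(i) for i in range(3)}
        with pytest.raises(ValueError, match=">= 5"):
            correlate_delta_outcome(deltas, imps, roi_labels=self.labels)

    def test_default_roi_set_is_motor_circuit(self, default_cohort, default_profiles):
        _, deltas = default_profiles
        outcomes = {
            s.subject_id: s.improvement_rate
            for s in default_cohort.subjects
            if s.target == "STN" and s.improvement_rate is not None
        }
        grp = {s: d for s, d in deltas.items() if s in outcomes}
        df = correlate_delta_outcome(grp, outcomes)
        assert len(df) == 32  # 8 structures x 2 hemispheres x 2 metrics
        assert set(df["region"]) == {
            "Caudate", "Putamen", "Pallidum", "Thalamus", "Precentral",
            "Postcentral", "Supp_Motor_Area", "Paracentral_Lobule",
        }
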
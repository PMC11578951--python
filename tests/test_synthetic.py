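"""Synthetic cohort generator: networks, sessions, outcomes, ground truth."""

import numpy as np
import pytest
import scipy.stats

from braincontrol.atlas import AAL90_LABELS
from braincontrol.signal import pearson_fc
from braincontrol.synthetic import (
    CohortConfig,
    generate_cohort,
    make_base_network,
    make_candidate_pool,
    simulate_session,
    state_covariance,
    write_cohort,
)


class TestMakeBaseNetwork:
    def test_zero_between_strength_is_block_diagonal(self):
        net = make_base_network(n_nodes=4, n_modules=2, within_strength=0.6,
                                between_strength=0.0, seed=3)
        cov = net.base_cov
        assert cov[0, 2] == 0.0 and cov[0, 3] == 0.0 and cov[1, 2] == 0.0
        assert cov[0, 1] == 0.6 and cov[2, 3] == 0.6

    def test_deterministic_given_seed(self):
        a = make_base_network(n_nodes=90, n_modules=6, seed=1)
        b = make_base_network(n_nodes=90, n_modules=6, seed=1)
        np.testing.assert_array_equal(a.base_cov, b.base_cov)
        assert a.perturbed_nodes == b.perturbed_nodes

    def test_minimum_eigenvalue_floor(self):
        net = make_base_network(n_nodes=10, n_modules=2, within_strength=0.5,
                                between_strength=0.1, seed=0)
        assert np.linalg.eigvalsh(net.base_cov).min() >= 0.1 - 1e-12

    def test_default_disease_nodes_are_motor_slots(self):
        net = make_base_network(seed=0)
        labels = [AAL90_LABELS[i] for i in net.perturbed_nodes]
        assert "Pallidum_L" in labels and "Thalamus_R" in labels
        assert "Precuneus_L" not in labels

    def test_invalid_strengths_rejected(self):
        with pytest.raises(ValueError):
            make_base_network(within_strength=0.2, between_strength=0.3)


class TestStateCovariance:
    net = make_base_network(n_nodes=4, n_modules=1, within_strength=0.5,
                            between_strength=0.0, seed=2, perturbed_nodes=[0],
                            perturbation_scale=0.5)

    def test_full_recovery_restores_base(self):
        on = state_covariance(self.net, "patient", "on", recovery=1.0)
        np.testing.assert_allclose(on, self.net.base_cov, atol=1e-15)

    def test_zero_recovery_equals_off_state(self):
        on = state_covariance(self.net, "patient", "on", recovery=0.0)
        off = state_covariance(self.net, "patient", "off")
        np.testing.assert_array_equal(on, off)

    def test_perturbed_row_halved_off_diagonal_only(self):
        off = state_covariance(self.net, "patient", "off")
        base = self.net.base_cov
        for j in range(1, 4):
            assert off[0, j] == pytest.approx(0.5 * base[0, j])
            assert off[j, 0] == pytest.approx(0.5 * base[j, 0])
        assert off[0, 0] == base[0, 0]
        np.testing.assert_array_equal(off[1:, 1:], base[1:, 1:])

    def test_control_gets_base(self):
        np.testing.assert_array_equal(
            state_covariance(self.net, "control", "single"), self.net.base_cov
        )

    def test_recovery_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="recovery"):
            state_covariance(self.net, "patient", "on", recovery=1.2)

    def test_off_state_remains_positive_definite(self):
        net = make_base_network(seed=5, perturbation_scale=0.2)
        off = state_covariance(net, "patient", "off")
        assert np.linalg.eigvalsh(off).min() > 0


class TestSimulateSession:
    def test_same_seed_identical(self):
        cov = np.eye(3)
        a = simulate_session(cov, 50, seed=9)
        b = simulate_session(cov, 50, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_identity_covariance_uncorrelated(self):
        n = 50_000
        ts = simulate_session(np.eye(4), n, seed=0, ar_coef=0.0)
        r = np.corrcoef(ts.values, rowvar=False)
        off = r[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 4.0 / np.sqrt(n)

    def test_planted_correlation_recovered(self):
        cov = np.eye(3)
        cov[1, 2] = cov[2, 1] = 0.8
        ts = simulate_session(cov, 20_000, seed=1, ar_coef=0.3)
        r = np.corrcoef(ts.values, rowvar=False)
        assert r[1, 2] == pytest.approx(0.8, abs=0.02)

    def test_short_session_warns_rank_deficient(self):
        with pytest.warns(UserWarning, match="rank-deficient"):
            simulate_session(np.eye(20), 15, seed=0)

    def test_sample_fc_converges_to_generating_correlation(self):
        net = make_base_network(n_nodes=6, n_modules=2, within_strength=0.5,
                                between_strength=0.1, seed=4)
        cov = net.base_cov
        d = np.sqrt(np.diag(cov))
        truth = cov / np.outer(d, d)
        ts = simulate_session(cov, 20_000, seed=2, ar_coef=0.3)
        fc = pearson_fc(ts)
        off = ~np.eye(6, dtype=bool)
        assert np.max(np.abs(fc.values[off] - truth[off])) < 0.02


class TestGenerateCohort:
    cfg = CohortConfig(seed=7, include_motion=False, n_timepoints=30)
    net = make_base_network(n_nodes=6, n_modules=2, seed=7, perturbed_nodes=[0, 1])

    def test_stratum_counts_match_config(self):
        cohort = generate_cohort(self.cfg, self.net)
        targets = [s.target for s in cohort.subjects]
        assert targets.count("STN") == 24
        assert targets.count("GPi") == 15
        assert targets.count("none") == 29

    def test_improvement_formula_inverts_exactly(self):
        # worked numbers: pre 55.95 at 68.65% improvement leaves 17.54
        assert 55.95 * (1 - 68.65 / 100) == pytest.approx(17.54, abs=0.005)
        cohort = generate_cohort(self.cfg, self.net)
        for s in cohort.subjects:
            if s.cohort != "patient":
                continue
            expect = (s.updrs3_pre_off - s.updrs3_post_off_stim_on) / s.updrs3_pre_off * 100
            assert expect == pytest.approx(s.improvement_rate, abs=0.05)

    def test_zero_slope_zero_noise_constant_improvement(self):
        cfg = CohortConfig(seed=1, outcome_slope=0.0, outcome_noise_sd=0.0,
                           include_motion=False, n_timepoints=30)
        cohort = generate_cohort(cfg, self.net)
        imps = {s.improvement_rate for s in cohort.subjects if s.cohort == "patient"}
        assert len(imps) == 1

    def test_noise_free_link_is_perfectly_monotone(self):
        cfg = CohortConfig(seed=3, outcome_noise_sd=0.0, include_motion=False,
                           n_timepoints=30)
        cohort = generate_cohort(cfg, self.net)
        gt = cohort.ground_truth.set_index("subject_id")
        pats = [s for s in cohort.subjects if s.cohort == "patient"]
        rec = [gt.loc[s.subject_id, "recovery"] for s in pats]
        imp = [s.improvement_rate for s in pats]
        rho = scipy.stats.spearmanr(rec, imp).statistic
        assert rho == pytest.approx(np.sign(cfg.outcome_slope), abs=1e-12)

    def test_session_exclusions_applied(self):
        cohort = generate_cohort(self.cfg, self.net)
        missing_on = [s for s in cohort.subjects if s.cohort == "patient" and not s.has_on_session]
        missing_off = [s for s in cohort.subjects if s.cohort == "patient" and not s.has_off_session]
        assert len(missing_on) == 5 and len(missing_off) == 2
        for s in missing_on:
            assert (s.subject_id, "on") not in cohort.sessions
        for s in cohort.subjects:
            if s.cohort == "control":
                assert (s.subject_id, "single") in cohort.sessions

    def test_write_cohort_round_trip(self, tmp_path):
        import json

        import pandas as pd

        cohort = generate_cohort(self.cfg, self.net)
        mpath = write_cohort(cohort, tmp_path)
        manifest = json.loads(mpath.read_text())
        assert manifest["seed"] == 7
        sid, sess = next(iter(cohort.sessions))
        rel = manifest["paths"][f"session:{sid}:{sess}"]
        df = pd.read_csv(tmp_path / rel, sep="\t")
        assert df.shape == (30, 6)
        clin = pd.read_csv(tmp_path / "clinical.csv")
        assert len(clin) == 24 + 15 + 29


class TestCandidatePool:
    def test_default_pool_counts(self):
        pool = make_candidate_pool(seed=0)
        assert len(pool) == 50
        reasons = [c.exclusion_reason for c in pool]
        assert reasons.count("no_surgery") == 5
        assert reasons.count("unilateral_dbs") == 2
        assert reasons.count("rf_lesion") == 1
        assert reasons.count("missing_data") == 3
        assert reasons.count(None) == 39

    def test_overflagged_pool_rejected(self):
        with pytest.raises(ValueError):
            make_candidate_pool(n_total=5, n_no_surgery=10)
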
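import numpy as np
import pytest

import dtsleep as d
from dtsleep.scoring import ReferenceEstimationError, _two_means_1d, iter_runs

from bruteforce import brute_force_context, make_features

REFS = d.ScoringReferences(
    emg_wake_thresh=10.0,
    emg_atonia_thresh=5.0,
    nrem_delta_ref=100.0,
    dt_theta_ref=80.0,
)


def features_for(labels_spec):
    """Build a feature table from a compact per-epoch spec.

    Each element is one of: 'W' (high EMG), 'nr' (low EMG, delta-dominant),
    'r' (atonia, theta-dominant), 'dt' (atonia, high delta AND theta),
    'mid' (low EMG but above atonia, theta-dominant).
    """
    rows = {
        #        emg   delta theta  tf
        "W":   (20.0,  20.0, 10.0, 0.2),
        "nr":  (4.0,  120.0, 30.0, 0.3),
        "r":   (2.0,   20.0, 90.0, 0.7),
        "dt":  (2.0,   90.0, 90.0, 0.45),
        "mid": (7.0,   20.0, 90.0, 0.7),
    }
    vals = np.array([rows[s] for s in labels_spec])
    return make_features(vals[:, 0], vals[:, 1], vals[:, 2], vals[:, 3])


class TestClassifyBase:
    def test_wake_rule_overrides_spectrum(self):
        f = features_for(["W"] * 3)
        f.theta_fraction[:] = 0.9  # theta-dominant but muscle-active
        labels, _ = d.classify_base(f, REFS)
        assert list(labels) == ["W", "W", "W"]

    def test_theta_dominant_sleep_is_rem(self):
        labels, _ = d.classify_base(features_for(["r", "mid"]), REFS)
        assert list(labels) == ["R", "R"]

    def test_delta_dominant_sleep_is_nrem(self):
        labels, _ = d.classify_base(features_for(["nr"]), REFS)
        assert list(labels) == ["NR"]

    def test_zero_power_epoch_flagged_unscorable(self):
        f = features_for(["nr", "nr"])
        f.theta_fraction[1] = np.nan
        labels, unscorable = d.classify_base(f, REFS)
        assert list(unscorable) == [False, True]

    def test_base_counts_permutation_invariant(self):
        f = features_for(["W"] * 12 + ["r"] * 3 + ["W"] * 5 + ["nr"] * 4)
        base, _ = d.classify_base(f, REFS)
        rng = np.random.default_rng(0)
        perm = rng.permutation(f.n_epochs)
        fp = make_features(
            f.emg_integral[perm],
            f.band_power["delta"][perm],
            f.band_power["theta"][perm],
            f.theta_fraction[perm],
        )
        permuted, _ = d.classify_base(fp, REFS)
        assert sorted(base) == sorted(permuted)


class TestDetectCataplexy:
    def test_qualifying_run_relabeled(self):
        f = features_for(["W"] * 12 + ["r"] * 3 + ["W"])
        base, _ = d.classify_base(f, REFS)
        labels = d.detect_cataplexy(base, f, REFS)
        assert list(labels[12:15]) == ["C", "C", "C"]

    def test_short_antecedent_wake_blocks(self):
        f = features_for(["nr"] * 4 + ["W"] * 8 + ["r"] * 3 + ["W"])
        base, _ = d.classify_base(f, REFS)
        labels = d.detect_cataplexy(base, f, REFS)
        assert list(labels[12:15]) == ["R", "R", "R"]

    def test_run_below_ten_seconds_blocks(self):
        f = features_for(["W"] * 10 + ["r"] * 2 + ["W"])
        base, _ = d.classify_base(f, REFS)
        labels = d.detect_cataplexy(base, f, REFS)
        assert list(labels[10:12]) == ["R", "R"]

    def test_atonia_required(self):
        f = features_for(["W"] * 10 + ["mid"] * 3 + ["W"])  # low EMG, not atonia
        base, _ = d.classify_base(f, REFS)
        labels = d.detect_cataplexy(base, f, REFS)
        assert "C" not in labels


class TestDetectDtSleep:
    def run_pipeline(self, f):
        base, _ = d.classify_base(f, REFS)
        labels = d.detect_cataplexy(base, f, REFS)
        return d.detect_dt_sleep(labels, f, REFS)

    def test_qualifying_arrest_relabeled(self):
        f = features_for(["W"] * 10 + ["dt"] * 4 + ["W"])
        f.band_power["delta"][10:14] = 0.8 * REFS.nrem_delta_ref
        labels, _ = self.run_pipeline(f)
        assert list(labels[10:14]) == ["D", "D", "D", "D"]

    def test_low_delta_fails_criterion(self):
        f = features_for(["W"] * 10 + ["dt"] * 4 + ["W"])
        f.band_power["delta"][10:14] = 0.3 * REFS.nrem_delta_ref
        labels, _ = self.run_pipeline(f)
        assert "D" not in labels

    def test_must_return_to_wake(self):
        f = features_for(["W"] * 10 + ["dt"] * 4 + ["nr", "W"])
        labels, _ = self.run_pipeline(f)
        assert "D" not in labels

    def test_truncated_at_end_left_unlabeled(self):
        f = features_for(["W"] * 10 + ["dt"] * 4)
        labels, truncated = self.run_pipeline(f)
        assert "D" not in labels
        assert truncated == 1

    def test_cataplexy_takes_precedence(self):
        f = features_for(["W"] * 10 + ["r"] * 4 + ["W"])
        # epochs satisfy BOTH the cataplexy and DT criteria
        f.band_power["delta"][10:14] = REFS.nrem_delta_ref
        labels, _ = self.run_pipeline(f)
        assert list(labels[10:14]) == ["C"] * 4

    def test_missing_delta_reference_fails(self):
        f = features_for(["W"] * 12)
        refs = d.ScoringReferences(10.0, 5.0, np.nan, 80.0)
        with pytest.raises(ReferenceEstimationError, match="δ reference"):
            d.detect_dt_sleep(np.array(["W"] * 12), f, refs)

    def test_delta_ratio_monotonicity(self, oxmc_scored, oxmc_features):
        from dataclasses import replace

        base, _ = d.classify_base(oxmc_features, oxmc_scored.references)
        counts = []
        for ratio in (0.6, 0.7, 0.8):
            refs = replace(oxmc_scored.references, dt_delta_ratio=ratio)
            labels = d.detect_cataplexy(base, oxmc_features, refs)
            labels, _ = d.detect_dt_sleep(labels, oxmc_features, refs)
            counts.append(int(np.sum(labels == "D")))
        assert counts[0] >= counts[1] >= counts[2]


class TestEstimateReferences:
    def test_bimodal_emg_threshold_between_modes(self, rng):
        n = 1000
        emg = np.where(rng.random(n) < 0.5,
                       2.0 * np.exp(rng.normal(0, 0.25, n)),
                       20.0 * np.exp(rng.normal(0, 0.25, n)))
        f = make_features(emg, np.full(n, 100.0), np.full(n, 20.0), np.full(n, 0.2))
        f.band_fraction = {b: np.full(n, 0.25) for b in f.bands}
        f.band_fraction["delta"] = np.full(n, 0.5)
        refs = d.estimate_references(f)
        assert 4.0 <= refs.emg_wake_thresh <= 16.0
        assert refs.emg_atonia_thresh <= refs.emg_wake_thresh

    def test_all_wake_recording_fails(self, rng):
        n = 800
        emg = 20.0 * np.exp(rng.normal(0, 0.2, n))
        f = make_features(emg, np.full(n, 10.0), np.full(n, 10.0), np.full(n, 0.2))
        with pytest.raises(ReferenceEstimationError, match="unimodal"):
            d.estimate_references(f)

    def test_too_few_epochs(self):
        f = features_for(["W"] * 100)
        with pytest.raises(ValueError, match="at least 500"):
            d.estimate_references(f)

    def test_scale_equivariance(self, oxmc_features):
        refs = d.estimate_references(oxmc_features)
        scaled = make_features(
            oxmc_features.emg_integral * 2.0,
            oxmc_features.band_power["delta"] * 4.0,
            oxmc_features.band_power["theta"] * 4.0,
            oxmc_features.theta_fraction,
        )
        scaled.band_fraction = oxmc_features.band_fraction
        refs2 = d.estimate_references(scaled)
        assert refs2.emg_wake_thresh == pytest.approx(2 * refs.emg_wake_thresh)
        assert refs2.emg_atonia_thresh == pytest.approx(2 * refs.emg_atonia_thresh)
        assert refs2.nrem_delta_ref == pytest.approx(4 * refs.nrem_delta_ref)

    def test_two_means_split_is_exact(self, rng):
        x = np.concatenate([rng.normal(0, 1, 50), rng.normal(8, 1, 30)])
        lo, hi, high = _two_means_1d(x)
        assert lo < 3 < hi
        assert high.sum() == 30


class TestScoreRecording:
    def test_deterministic(self, oxmc_recording, oxmc_scored):
        again = d.score_recording(oxmc_recording)
        np.testing.assert_array_equal(again.labels, oxmc_scored.labels)

    def test_structural_invariants_hold(self, oxmc_scored):
        oxmc_scored.validate_structure()
        for s, i, j in iter_runs(oxmc_scored.labels):
            if s == "C":
                assert (j - i) * 4 >= 12

    def test_intact_recording_emits_no_c_or_d(self):
        cfg = d.preset_config("intact", "dark", duration=3600.0, seed=3)
        truth, rec = d.simulate_recording(cfg)
        hyp = d.score_recording(rec)
        assert "C" not in hyp.labels and "D" not in hyp.labels

    def test_no_context_flag_stops_at_base_rules(self, oxmc_recording):
        hyp = d.score_recording(oxmc_recording, context=False)
        assert set(np.unique(hyp.labels)) <= {"W", "NR", "R"}


class TestBruteForceEquivalence:
    def test_state_machine_matches_interval_enumeration(self, rng):
        for _ in range(25):
            n = int(rng.integers(30, 200))
            kinds = rng.choice(
                ["W", "nr", "r", "dt", "mid"], size=n, p=[0.45, 0.2, 0.15, 0.15, 0.05]
            )
            # insert a few long wake runs so antecedent-wake contexts occur
            for _k in range(3):
                i = int(rng.integers(0, max(1, n - 12)))
                kinds[i : i + 11] = "W"
            f = features_for(kinds)
            base, _ = d.classify_base(f, REFS)
            fast = d.detect_cataplexy(base, f, REFS)
            fast, _ = d.detect_dt_sleep(fast, f, REFS)
            slow = brute_force_context(base, f, REFS)
            np.testing.assert_array_equal(fast, slow)


class TestEvaluateScoring:
    def test_perfect_prediction(self):
        lab = np.array(["W"] * 5 + ["NR"] * 3 + ["R"] * 2)
        ev = d.evaluate_scoring(lab, lab)
        assert ev.accuracy == 1.0
        assert ev.recall["W"] == 1.0 and ev.recall["NR"] == 1.0
        assert np.trace(ev.confusion.values) == 10

    def test_all_wake_prediction(self):
        truth = np.array(["W"] * 4 + ["NR"] * 4 + ["R"] * 2)
        pred = np.array(["W"] * 10)
        ev = d.evaluate_scoring(pred, truth)
        assert ev.recall["W"] == 1.0
        assert ev.recall["NR"] == 0.0
        assert ev.confusion.loc["NR", "W"] == 4

    def test_rows_sum_to_true_counts(self, oxmc_scored, oxmc_truth):
        ev = d.evaluate_scoring(oxmc_scored, oxmc_truth)
        for s in d.STATES:
            assert ev.confusion.loc[s].sum() == int(np.sum(oxmc_truth.labels == s))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length mismatch"):
            d.evaluate_scoring(np.array(["W"]), np.array(["W", "W"]))

    def test_random_prediction_recall_near_chance(self, rng):
        truth = np.repeat(list(d.STATES), 400)
        pred = rng.choice(list(d.STATES), size=len(truth))
        ev = d.evaluate_scoring(pred, truth)
        assert np.allclose(ev.recall.values, 0.2, atol=0.06)
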
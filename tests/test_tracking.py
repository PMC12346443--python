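"""PCK metric, label filtering/smoothing, and kinematic summaries."""

import numpy as np
import pytest

from manimouse import (
    BehaviorLabelTrack,
    ConfigurationError,
    InputError,
    compute_velocity,
    kalman_label_filter,
    mode_smooth,
    occupancy_and_ethogram,
    pck,
)
from conftest import SEVEN_POINTS, make_track


def pck_counting_oracle(pred, truth, d_factor):
    """Per-point correctness counting, one frame and key point at a time."""
    n, k = truth.coordinates.shape[:2]
    le = truth.keypoint_names.index("left_ear")
    re = truth.keypoint_names.index("right_ear")
    pct = []
    for kp in range(k):
        hits = 0
        for t in range(n):
            d = np.linalg.norm(truth.coordinates[t, le] - truth.coordinates[t, re])
            err = np.linalg.norm(pred.coordinates[t, kp] - truth.coordinates[t, kp])
            if err <= d_factor * d:
                hits += 1
        pct.append(100.0 * hits / n)
    return pct


class TestPCK:
    def test_perfect_prediction_scores_100(self, random_track):
        res = pck(random_track, random_track)
        assert all(v == 100.0 for v in res.per_keypoint_pct.values())
        assert res.mean_pct == 100.0

    def test_displacement_beyond_radius_scores_0(self, random_track):
        d = np.linalg.norm(
            random_track.point("left_ear") - random_track.point("right_ear"), axis=1
        )
        # confidence radius is 0.25*D; a 0.3*D displacement always misses,
        # a 0.2*D displacement always hits
        shift = (0.3 * d)[:, None, None] * np.array([1.0, 0.0])[None, None, :]
        displaced = make_track(random_track.coordinates + shift)
        res = pck(displaced, random_track, d_factor=0.25)
        assert res.mean_pct == 0.0
        inside = make_track(
            random_track.coordinates
            + (0.2 * d)[:, None, None] * np.array([1.0, 0.0])[None, None, :]
        )
        assert pck(inside, random_track, d_factor=0.25).mean_pct == 100.0

    def test_matches_counting_oracle(self, random_track):
        rng = np.random.default_rng(7)
        pred = make_track(
            random_track.coordinates + rng.normal(0, 8, random_track.coordinates.shape)
        )
        res = pck(pred, random_track, d_factor=0.25)
        oracle = pck_counting_oracle(pred, random_track, 0.25)
        for name, want in zip(SEVEN_POINTS, oracle):
            assert res.per_keypoint_pct[name] == pytest.approx(want, abs=1e-12)
        assert res.mean_pct == pytest.approx(np.mean(oracle), abs=1e-12)

    def test_translation_invariance_and_scale_equivariance(self, random_track):
        rng = np.random.default_rng(8)
        pred = make_track(
            random_track.coordinates + rng.normal(0, 6, random_track.coordinates.shape)
        )
        base = pck(pred, random_track)
        shifted = pck(
            make_track(pred.coordinates + 123.4),
            make_track(random_track.coordinates + 123.4),
        )
        scaled = pck(
            make_track(pred.coordinates * 3.0),
            make_track(random_track.coordinates * 3.0),
        )
        for res in (shifted, scaled):
            assert res.per_keypoint_pct == base.per_keypoint_pct

    def test_frame_count_mismatch_rejected(self, random_track):
        short = make_track(random_track.coordinates[:-1])
        with pytest.raises(InputError, match="mismatch"):
            pck(short, random_track)


class TestKalmanLabelFilter:
    def test_identity_dynamics_with_one_hot_observations(self):
        obs = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 1, 0]], dtype=float)
        res = kalman_label_filter(obs, np.eye(3))
        assert list(res.labels) == ["running", "sitting", "grooming", "sitting"]

    def test_uniform_matrix_reproduces_observations(self):
        rng = np.random.default_rng(0)
        obs = rng.dirichlet(np.ones(3), size=50)
        res = kalman_label_filter(obs, np.full((3, 3), 1 / 3))
        np.testing.assert_allclose(res.filtered_probabilities, obs, atol=1e-12)

    def test_hand_computed_forward_step(self):
        """Two-state dynamics embedded in the 3-class filter, flat observation."""
        t_mat = np.array([[0.9, 0.1, 0.0], [0.2, 0.8, 0.0], [0.0, 0.0, 1.0]])
        obs = np.array([[1.0, 0.0, 0.0], [1 / 3, 1 / 3, 1 / 3]])
        res = kalman_label_filter(obs, t_mat)
        np.testing.assert_allclose(res.filtered_probabilities[1], [0.9, 0.1, 0.0], atol=1e-12)

    def test_simplex_preserved(self):
        rng = np.random.default_rng(3)
        obs = rng.dirichlet(np.ones(3) * 0.5, size=300)
        t_mat = rng.dirichlet(np.ones(3), size=3)
        res = kalman_label_filter(obs, t_mat)
        np.testing.assert_allclose(res.filtered_probabilities.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(res.filtered_probabilities >= 0)

    def test_zero_observation_row_names_frame(self):
        obs = np.array([[1, 0, 0], [0, 0, 0], [0, 1, 0]], dtype=float)
        with pytest.raises(InputError, match="frame 1"):
            kalman_label_filter(obs)

    def test_non_stochastic_matrix_rejected(self):
        obs = np.full((5, 3), 1 / 3)
        with pytest.raises(InputError):
            kalman_label_filter(obs, np.ones((3, 3)))


class TestModeSmooth:
    def test_constant_sequence_unchanged(self):
        seq = np.array(["sitting"] * 50, dtype=object)
        np.testing.assert_array_equal(mode_smooth(seq, 25), seq)

    def test_single_blip_removed(self):
        seq = np.array(["running"] * 25, dtype=object)
        seq[12] = "grooming"
        assert np.all(mode_smooth(seq, 25) == "running")

    def test_tie_breaks_to_central_frame_label(self):
        # 10 running + 10 sitting + 5 grooming: counts tie at 10; frame 12 is sitting
        seq = np.array(["running"] * 10 + ["sitting"] * 10 + ["grooming"] * 5, dtype=object)
        out = mode_smooth(seq, 25)
        assert np.all(out == "sitting")

    def test_idempotent(self):
        rng = np.random.default_rng(11)
        seq = rng.choice(["running", "sitting", "grooming"], size=321).astype(object)
        once = mode_smooth(seq, 25)
        np.testing.assert_array_equal(mode_smooth(once, 25), once)

    def test_even_window_rejected(self):
        with pytest.raises(ConfigurationError):
            mode_smooth(np.array(["running"] * 30, dtype=object), 24)


class TestVelocity:
    def test_stationary_track_zero(self):
        coords = np.tile(np.array([100.0, 100.0]), (60, len(SEVEN_POINTS), 1))
        summary = compute_velocity(make_track(coords), fps=15.0)
        assert np.all(summary.velocity_raw == 0)
        assert summary.total_distance == 0

    def test_constant_speed_line(self):
        t = np.arange(60)
        coords = np.zeros((60, len(SEVEN_POINTS), 2))
        coords[..., 0] = (2.0 * t)[:, None]  # 2 px/frame
        summary = compute_velocity(make_track(coords), fps=15.0)
        np.testing.assert_allclose(summary.velocity_raw, 30.0, atol=1e-9)
        assert summary.total_distance == pytest.approx(2.0 * 59)

    def test_savgol_reduces_noise_rmse(self):
        """Smoothed speed tracks a constant-velocity truth better than raw."""
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            t = np.arange(300)
            coords = np.zeros((300, len(SEVEN_POINTS), 2))
            coords[..., 0] = (3.0 * t)[:, None]
            noisy = coords + rng.normal(0, 1.0, coords.shape)
            summary = compute_velocity(make_track(noisy), fps=15.0)
            rmse_raw = np.sqrt(np.mean((summary.velocity_raw - 45.0) ** 2))
            rmse_smooth = np.sqrt(np.mean((summary.velocity_smooth - 45.0) ** 2))
            wins += rmse_smooth < rmse_raw
        assert wins == 5

    def test_unknown_reference_point_rejected(self, random_track):
        with pytest.raises(InputError):
            compute_velocity(random_track, reference_point="whisker")

    def test_time_reversal_preserves_distance(self, random_track):
        fwd = compute_velocity(random_track)
        rev = compute_velocity(make_track(random_track.coordinates[::-1].copy()))
        assert fwd.total_distance == pytest.approx(rev.total_distance)


class TestOccupancy:
    def test_central_track_and_label_fractions(self, arena):
        coords = np.tile(np.array([405.0, 400.0]), (90, len(SEVEN_POINTS), 1))
        labels = BehaviorLabelTrack(labels=np.array(["sitting"] * 90, dtype=object))
        summary = occupancy_and_ethogram(make_track(coords), labels, arena, fps=15.0)
        assert summary.zone_occupancy["central"] == pytest.approx(6.0)
        assert summary.behavior_fractions == {"running": 0.0, "sitting": 1.0, "grooming": 0.0}

    def test_zone_seconds_conserved(self, arena, random_track):
        labels = BehaviorLabelTrack(
            labels=np.array(["running"] * random_track.n_frames, dtype=object)
        )
        summary = occupancy_and_ethogram(random_track, labels, arena, fps=15.0)
        assert sum(summary.zone_occupancy.values()) == pytest.approx(
            random_track.n_frames / 15.0
        )

    def test_length_mismatch_rejected(self, arena, random_track):
        labels = BehaviorLabelTrack(labels=np.array(["running"] * 10, dtype=object))
        with pytest.raises(InputError):
            occupancy_and_ethogram(random_track, labels, arena)
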
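"""Window flattening, embeddings, intracluster distance, temporal surrogates."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from manimouse import (
    CalciumRecording,
    ConfigurationError,
    InputError,
    ParameterError,
    embed,
    flatten_windows,
    intracluster_distance,
    temporal_shuffle,
    unflatten_windows,
)


def labeled_recording(n=3, t=90):
    """f[j, t] = 100*t + j encodes both indices in every element."""
    frames = np.arange(t)[None, :] * 100.0 + np.arange(n)[:, None]
    return CalciumRecording(fluorescence=frames, fps=15.0, session_id="toy")


class TestFlattenWindows:
    def test_shape_contract(self):
        ws = flatten_windows(labeled_recording(3, 90), 30)
        assert ws.vectors.shape == (3, 90)

    def test_trailing_partial_window_dropped(self):
        ws = flatten_windows(labeled_recording(3, 59), 30)
        assert ws.n_windows == 1

    def test_frame_major_ordering_matches_index_oracle(self):
        n, w = 3, 30
        ws = flatten_windows(labeled_recording(n, 90), w)
        for wi in range(ws.n_windows):
            for i in range(w):
                for j in range(n):
                    # x[i*N + j] must equal f_{start+i}[j] = 100*(start+i) + j
                    assert ws.vectors[wi, i * n + j] == 100.0 * (wi * w + i) + j

    def test_unflatten_is_inverse_on_analyzed_frames(self):
        rec = labeled_recording(4, 100)
        ws = flatten_windows(rec, 30)
        np.testing.assert_array_equal(unflatten_windows(ws), rec.fluorescence[:, :90])

    def test_too_short_recording_rejected(self):
        with pytest.raises(InputError):
            flatten_windows(labeled_recording(3, 20), 30)

    def test_standardize_zscores_neurons(self):
        rng = np.random.default_rng(0)
        rec = CalciumRecording(rng.normal(5, 3, (4, 120)), fps=15.0)
        ws = flatten_windows(rec, 30, standardize=True)
        back = unflatten_windows(ws)
        np.testing.assert_allclose(back.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(back.std(axis=1), 1.0, atol=1e-9)


def toy_windows(x):
    from manimouse import WindowVectorSet

    x = np.asarray(x, dtype=float)
    return WindowVectorSet(
        vectors=x, window_len=1, n_neurons=x.shape[1],
        window_start_frames=np.arange(x.shape[0]),
    )


class TestEmbed:
    def test_pca_recovers_planted_low_dim_distances(self):
        rng = np.random.default_rng(0)
        low = rng.normal(size=(40, 2))
        padded = np.hstack([low, np.zeros((40, 8))])
        emb = embed(toy_windows(padded), method="pca", dim=2, seed=0)
        np.testing.assert_allclose(pdist(emb.points), pdist(low), atol=1e-9)

    def test_tsne_deterministic_given_seed(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(60, 20))
        a = embed(toy_windows(x), method="tsne", seed=3)
        b = embed(toy_windows(x), method="tsne", seed=3)
        np.testing.assert_array_equal(a.points, b.points)

    def test_mds_reproduces_unit_square_distances(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        emb = embed(toy_windows(square), method="mds", dim=2, seed=0)
        np.testing.assert_allclose(
            np.sort(pdist(emb.points)), np.sort(pdist(square)), atol=1e-3
        )

    def test_perplexity_clamped_for_small_sessions(self):
        rng = np.random.default_rng(2)
        emb = embed(toy_windows(rng.normal(size=(20, 10))), method="tsne", seed=0)
        assert emb.method_params["perplexity"] <= (20 - 1) / 3

    @pytest.mark.parametrize("method", ["ica", "umap"])
    def test_other_methods_produce_finite_aligned_output(self, method):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 12))
        emb = embed(toy_windows(x), method=method, dim=2, seed=1)
        assert emb.points.shape == (30, 2)
        assert np.all(np.isfinite(emb.points))

    def test_unknown_method_rejected(self):
        with pytest.raises(ConfigurationError):
            embed(toy_windows(np.zeros((10, 4))), method="sammon")

    def test_too_few_windows_rejected(self):
        with pytest.raises(ParameterError):
            embed(toy_windows(np.zeros((2, 4))), method="pca", dim=2)


class TestIntraclusterDistance:
    def test_single_pair(self):
        assert intracluster_distance([[0, 0], [3, 4]]).intracluster_distance == 5.0

    def test_equilateral_triangle(self):
        pts = [[0, 0], [2, 0], [1, np.sqrt(3)]]
        assert intracluster_distance(pts).intracluster_distance == pytest.approx(2.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(50, 2))
        n = len(pts)
        total = sum(
            np.linalg.norm(pts[i] - pts[j])
            for i in range(n) for j in range(n) if i != j
        )
        assert intracluster_distance(pts).intracluster_distance == pytest.approx(
            total / (n * (n - 1)), abs=1e-9
        )

    def test_translation_invariant_and_scale_linear(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(30, 2))
        base = intracluster_distance(pts).intracluster_distance
        shifted = intracluster_distance(pts + [100.0, -42.0]).intracluster_distance
        scaled = intracluster_distance(3.5 * pts).intracluster_distance
        assert shifted == pytest.approx(base, abs=1e-9)
        assert scaled == pytest.approx(3.5 * base, abs=1e-9)

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(InputError):
            intracluster_distance([[1.0, 2.0]])


class TestTemporalShuffle:
    def test_permute_frames_preserves_value_multisets(self):
        rng = np.random.default_rng(7)
        rec = CalciumRecording(rng.normal(size=(6, 200)), fps=15.0)
        shuf = temporal_shuffle(rec, "permute_frames", seed=0)
        np.testing.assert_allclose(
            np.sort(shuf.fluorescence, axis=1), np.sort(rec.fluorescence, axis=1)
        )
        assert not np.array_equal(shuf.fluorescence, rec.fluorescence)

    def test_phase_randomize_preserves_power_spectrum(self):
        rng = np.random.default_rng(8)
        for t in (200, 201):  # even and odd lengths
            rec = CalciumRecording(rng.normal(size=(4, t)), fps=15.0)
            shuf = temporal_shuffle(rec, "phase_randomize", seed=1)
            np.testing.assert_allclose(
                np.abs(np.fft.rfft(shuf.fluorescence, axis=1)),
                np.abs(np.fft.rfft(rec.fluorescence, axis=1)),
                atol=1e-8,
            )
            assert np.all(np.isreal(shuf.fluorescence))

    @pytest.mark.parametrize("mode", ["permute_frames", "phase_randomize"])
    def test_destroys_cross_neuron_correlation(self, mode):
        # two identical calcium-like traces (broadband event transients)
        from manimouse import SyntheticCohortConfig, generate_calcium

        t = 4500
        base = generate_calcium(
            SyntheticCohortConfig(n_neurons=1, n_frames=t, event_rate=1.0, seed=9)
        ).fluorescence[0]
        rec = CalciumRecording(np.vstack([base, base]), fps=15.0)
        rs = []
        for seed in range(10):
            shuf = temporal_shuffle(rec, mode, seed=seed)
            rs.append(abs(np.corrcoef(shuf.fluorescence)[0, 1]))
        assert np.mean(rs) < 0.1

    def test_deterministic_and_unknown_mode(self):
        rec = CalciumRecording(np.random.default_rng(10).normal(size=(3, 50)), fps=15.0)
        a = temporal_shuffle(rec, seed=4)
        b = temporal_shuffle(rec, seed=4)
        np.testing.assert_array_equal(a.fluorescence, b.fluorescence)
        with pytest.raises(ConfigurationError):
            temporal_shuffle(rec, mode="bootstrap")
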
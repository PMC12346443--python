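"""Neuronal-manifold construction: window flattening, embedding, compactness metric, surrogates.

A five-minute calcium session is segmented into non-overlapping windows of 30
frames (2 s at 15 Hz).  Each window is flattened frame-major into one
high-dimensional vector

    x_t = [f_t, f_{t+1}, ..., f_{t+W-1}]  in  R^(W*N),

where f_i is the length-N vector of all neurons' fluorescence at frame i.
These vectors are the manifold points; an interchangeable dimensionality-
reduction step (t-SNE by default, plus PCA/ICA/MDS/UMAP) maps them to a 2-D
embedding, and the **intracluster distance** — the mean pairwise Euclidean
distance among a session's embedded points —

    ICD(C_k) = 1 / (n_k (n_k - 1)) * sum_i sum_{j != i} d(x_i, x_j)

summarises ensemble variability: lower values mean a more compact (more
stereotyped, hypersynchronous) population trajectory.  Temporal-shuffling
surrogates destroy cross-neuron coordination while preserving single-neuron
statistics, providing the null against which group differences are judged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from scipy.spatial.distance import pdist

from .errors import ConfigurationError, InputError, ParameterError
from .synthetic import CalciumRecording

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 30  # frames: 2 s at 15 Hz
EMBED_METHODS = ("tsne", "pca", "ica", "mds", "umap")


@dataclass
class WindowVectorSet:
    """Flattened window vectors of one session: (n_windows, W*N)."""

    vectors: np.ndarray
    window_len: int
    n_neurons: int
    window_start_frames: np.ndarray
    fps: float = 15.0
    session_id: str = ""
    group_tag: str = ""

    @property
    def n_windows(self) -> int:
        return self.vectors.shape[0]


@dataclass
class EmbeddingResult:
    """Low-dimensional embedding row-aligned with its window set."""

    points: np.ndarray  # (n_windows, dim)
    method: str
    dim: int
    seed: int
    method_params: dict[str, Any] = field(default_factory=dict)
    session_id: str = ""
    group_tag: str = ""


@dataclass
class ClusterMetric:
    """Intracluster distance of one embedded session."""

    intracluster_distance: float
    n_points: int
    session_id: str = ""
    group_tag: str = ""


def flatten_windows(
    recording: CalciumRecording,
    window_len: int = DEFAULT_WINDOW,
    standardize: bool = False,
) -> WindowVectorSet:
    """Cut a recording into non-overlapping windows and flatten each frame-major.

    Windows start at frame 0; a trailing partial window is dropped (and
    logged).  Element ordering is ``x[i*N + j] = f_{start+i}[j]``.  With
    ``standardize=True`` each neuron's trace is z-scored before flattening
    (zero-variance neurons are left centred at 0).
    """
    if window_len < 1:
        raise ConfigurationError(f"window_len must be >= 1, got {window_len}")
    f = recording.fluorescence
    n, t = f.shape
    if t < window_len:
        raise InputError(
            f"recording has {t} frames, shorter than one window of {window_len}"
        )
    if standardize:
        mu = f.mean(axis=1, keepdims=True)
        sd = f.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        f = (f - mu) / sd
    n_windows = t // window_len
    dropped = t - n_windows * window_len
    if dropped:
        log.info("flatten_windows: dropping %d trailing frames", dropped)
    # (N, n_w*W) -> (n_w, W, N) frame-major -> flatten
    trimmed = f[:, : n_windows * window_len]
    vectors = (
        trimmed.reshape(n, n_windows, window_len)
        .transpose(1, 2, 0)
        .reshape(n_windows, window_len * n)
    )
    return WindowVectorSet(
        vectors=np.ascontiguousarray(vectors),
        window_len=window_len,
        n_neurons=n,
        window_start_frames=np.arange(n_windows) * window_len,
        fps=recording.fps,
        session_id=recording.session_id,
        group_tag=recording.group_tag,
    )


def unflatten_windows(windows: WindowVectorSet) -> np.ndarray:
    """Inverse of :func:`flatten_windows` on the analysed frames: (N, n_w*W)."""
    v = windows.vectors
    n_w, _ = v.shape
    w, n = windows.window_len, windows.n_neurons
    return v.reshape(n_w, w, n).transpose(2, 0, 1).reshape(n, n_w * w)


def embed(
    windows: WindowVectorSet,
    method: str = "tsne",
    dim: int = 2,
    seed: int = 0,
    params: dict[str, Any] | None = None,
) -> EmbeddingResult:
    """Embed window vectors with one of the supported DR methods.

    All methods delegate to established implementations (scikit-learn, or
    umap-learn for UMAP) with the given random seed; the parameters actually
    used are recorded in the result.  t-SNE uses the Barnes-Hut gradient with
    Euclidean pairwise distances and PCA initialisation; its perplexity is
    clamped to ``(n_windows - 1) / 3`` when the session is small, with a
    logged warning.
    """
    x = windows.vectors
    n = x.shape[0]
    if method not in EMBED_METHODS:
        raise ConfigurationError(
            f"unknown method {method!r}; supported: {EMBED_METHODS}"
        )
    if n < dim + 1:
        raise ParameterError(
            f"{n} windows cannot support a {dim}-D embedding; need at least {dim + 1}"
        )
    params = dict(params or {})

    if method == "pca":
        from sklearn.decomposition import PCA

        model = PCA(n_components=dim, random_state=seed, **params)
        pts = model.fit_transform(x)
        used = {"n_components": dim}
    elif method == "ica":
        from sklearn.decomposition import FastICA

        model = FastICA(
            n_components=dim, random_state=seed,
            **{"whiten": "unit-variance", **params},
        )
        pts = model.fit_transform(x)
        used = {"n_components": dim, "whiten": "unit-variance"}
    elif method == "mds":
        from sklearn.manifold import MDS

        model = MDS(
            n_components=dim, random_state=seed, dissimilarity="euclidean",
            normalized_stress=False, **params,
        )
        pts = model.fit_transform(x)
        used = {"n_components": dim, "algorithm": "SMACOF"}
    elif method == "umap":
        import umap  # deferred: numba compilation is expensive at import

        n_neighbors = int(params.pop("n_neighbors", min(15, max(2, n - 1))))
        model = umap.UMAP(
            n_components=dim, random_state=seed, n_neighbors=n_neighbors, **params
        )
        pts = model.fit_transform(x)
        used = {"n_components": dim, "n_neighbors": n_neighbors}
    else:  # tsne
        from sklearn.manifold import TSNE

        perplexity = float(params.pop("perplexity", 30.0))
        max_perp = (n - 1) / 3.0
        if perplexity > max_perp:
            log.warning(
                "t-SNE perplexity %.1f too large for %d windows; clamping to %.2f",
                perplexity, n, max_perp,
            )
            perplexity = max_perp
        if perplexity <= 0:
            raise ParameterError(
                f"session too small for t-SNE: {n} windows leave no valid perplexity; "
                "use more frames or a shorter window"
            )
        model = TSNE(
            n_components=dim, perplexity=perplexity, random_state=seed,
            metric="euclidean", method="barnes_hut", init="pca", **params,
        )
        pts = model.fit_transform(x)
        used = {
            "perplexity": perplexity, "metric": "euclidean",
            "method": "barnes_hut", "init": "pca",
        }
    used.update(params)
    pts = np.asarray(pts, dtype=float)
    if not np.all(np.isfinite(pts)):
        raise ParameterError(f"{method} produced non-finite coordinates")
    return EmbeddingResult(
        points=pts, method=method, dim=dim, seed=seed, method_params=used,
        session_id=windows.session_id, group_tag=windows.group_tag,
    )


def intracluster_distance(points: np.ndarray, **metadata: str) -> ClusterMetric:
    """Mean pairwise Euclidean distance of a point cloud.

    Defined as ``1/(n(n-1)) * sum_{i} sum_{j != i} ‖x_i - x_j‖``; the mean
    over ordered pairs equals the mean over unordered pairs, so this is
    simply the average of the condensed distance vector.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    n = pts.shape[0]
    if n < 2:
        raise InputError(f"intracluster distance needs >= 2 points, got {n}")
    value = float(pdist(pts).mean())
    return ClusterMetric(intracluster_distance=value, n_points=n, **metadata)


def temporal_shuffle(
    recording: CalciumRecording, mode: str = "permute_frames", seed: int = 0
) -> CalciumRecording:
    """Surrogate recording with cross-neuron temporal coordination destroyed.

    ``permute_frames`` applies an independent random permutation of the time
    axis to each neuron, preserving every neuron's value multiset exactly.
    ``phase_randomize`` replaces each neuron's Fourier phases with uniform
    random phases while keeping the amplitude spectrum (conjugate symmetry is
    maintained, so the output is real); single-neuron power spectra are
    untouched but all cross-neuron phase relations are scrambled.
    """
    rng = np.random.default_rng(seed)
    f = recording.fluorescence
    n, t = f.shape
    if mode == "permute_frames":
        out = np.empty_like(f)
        for i in range(n):
            out[i] = f[i, rng.permutation(t)]
    elif mode == "phase_randomize":
        spec = np.fft.rfft(f, axis=1)
        n_bins = spec.shape[1]
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(n, n_bins))
        phases[:, 0] = 0.0  # keep the mean
        if t % 2 == 0:
            # Nyquist bin must stay real: random sign only
            phases[:, -1] = np.pi * rng.integers(0, 2, size=n)
        out = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=t, axis=1)
    else:
        raise ConfigurationError(
            f"unknown shuffle mode {mode!r}; use 'permute_frames' or 'phase_randomize'"
        )
    return CalciumRecording(
        fluorescence=out,
        fps=recording.fps,
        session_id=recording.session_id,
        mouse_id=recording.mouse_id,
        group_tag=recording.group_tag,
    )
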
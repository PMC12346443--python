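"""Post-processing of tracking output: PCK evaluation, label denoising, kinematics.

Three concerns live here, all downstream of a pose/behavior network and all
network-agnostic:

* **PCK** — percentage of correct key points, the standard pose-estimation
  accuracy metric.  A predicted point is correct when it lies within a
  confidence radius of the ground-truth point; the radius is a fixed factor
  (default 0.25) times the animal's inter-ear distance, an anatomical scale
  that makes the metric invariant to camera zoom.
* **Label denoising** — a discrete-state forward (Bayes) filter driven by a
  row-stochastic behavior transition matrix, followed by block-wise mode
  smoothing, to remove transient misclassifications.
* **Kinematics** — per-frame speed (raw and Savitzky-Golay smoothed), total
  path length, arena-zone occupancy and behavior-fraction summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .arena import ArenaGeometry, ZONE_NAMES, classify_zone
from .errors import ConfigurationError, InputError
from .synthetic import BEHAVIORS, BehaviorLabelTrack, KeypointTrack

log = logging.getLogger(__name__)

EAR_MIDPOINT = "ear_midpoint"  # virtual reference point: mean of the two ears


@dataclass
class PCKResult:
    """Per-key-point and mean percentage of correct key points."""

    d_factor: float
    reference_distance: np.ndarray  # per-frame inter-ear distance D, px
    per_keypoint_pct: dict[str, float]
    mean_pct: float


@dataclass
class FilteredBehaviorTrack:
    """Denoised behavior stream with the probabilities that produced it."""

    labels: np.ndarray
    raw_probabilities: np.ndarray
    filtered_probabilities: np.ndarray
    transition_matrix: np.ndarray


@dataclass
class KinematicSummary:
    """Velocity, distance, zone-occupancy and behavior-fraction summaries."""

    velocity_raw: np.ndarray | None = None  # px/s per frame
    velocity_smooth: np.ndarray | None = None
    total_distance: float | None = None  # px
    zone_occupancy: dict[str, float] = field(default_factory=dict)  # seconds
    behavior_fractions: dict[str, float] = field(default_factory=dict)
    frame_table: pd.DataFrame | None = None  # per-frame x, y, zone, label


def pck(
    predicted: KeypointTrack, truth: KeypointTrack, d_factor: float = 0.25
) -> PCKResult:
    """Percentage of correct key points at a per-frame ear-distance threshold.

    For every frame the confidence radius is ``d_factor`` times that frame's
    ground-truth inter-ear distance; a prediction is correct when its
    Euclidean error is within the radius (boundary inclusive).  Percentages
    are per key point over frames; ``mean_pct`` averages over key points.
    """
    if predicted.n_frames != truth.n_frames:
        raise InputError(
            f"frame-count mismatch: predicted {predicted.n_frames} vs truth {truth.n_frames}"
        )
    if predicted.keypoint_names != truth.keypoint_names:
        raise InputError("predicted and truth tracks must share key-point names")
    if d_factor <= 0:
        raise ConfigurationError(f"d_factor must be > 0, got {d_factor}")

    d = np.linalg.norm(truth.point("left_ear") - truth.point("right_ear"), axis=1)
    radius = d_factor * d  # (n_frames,)
    err = np.linalg.norm(predicted.coordinates - truth.coordinates, axis=2)  # (T, K)
    correct = err <= radius[:, None]
    pct = 100.0 * correct.mean(axis=0)
    per_kp = {name: float(p) for name, p in zip(truth.keypoint_names, pct)}
    return PCKResult(
        d_factor=d_factor,
        reference_distance=d,
        per_keypoint_pct=per_kp,
        mean_pct=float(pct.mean()),
    )


def kalman_label_filter(
    probabilities: np.ndarray,
    transition_matrix: np.ndarray | None = None,
    labels: tuple[str, ...] = BEHAVIORS,
) -> FilteredBehaviorTrack:
    """Forward-filter per-frame class probabilities through a behavior matrix.

    The filter is the discrete-state analogue of a Kalman predict/update
    cycle: predict ``p' = T^t p`` (row-stochastic transition matrix ``T``),
    update ``p'' ∝ p' ⊙ obs_t``, renormalise.  The state is initialised from
    the first observation.  If a prediction and an observation have disjoint
    support (zero product), the filter resets to the observation row — this
    keeps hard one-hot streams usable under near-deterministic dynamics.

    The default transition matrix keeps 0.9 self-transition probability with
    the remainder split evenly, a mild prior for behavior persistence.
    """
    obs = np.asarray(probabilities, dtype=float)
    if obs.ndim != 2:
        raise InputError(f"probabilities must be 2-D, got shape {obs.shape}")
    k = obs.shape[1]
    if k != len(labels):
        raise InputError(f"probabilities have {k} columns but {len(labels)} labels given")
    if transition_matrix is None:
        transition_matrix = np.full((k, k), 0.1 / (k - 1))
        np.fill_diagonal(transition_matrix, 0.9)
    t_mat = np.asarray(transition_matrix, dtype=float)
    if t_mat.shape != (k, k) or not np.allclose(t_mat.sum(axis=1), 1.0, atol=1e-6):
        raise InputError("transition_matrix must be row-stochastic with matching size")
    rowsums = obs.sum(axis=1)
    zero_rows = np.nonzero(rowsums <= 0)[0]
    if len(zero_rows):
        raise InputError(f"all-zero observation row at frame {zero_rows[0]}")
    if not np.allclose(rowsums, 1.0, atol=1e-6):
        raise InputError("observation rows must each sum to 1")

    filtered = np.empty_like(obs)
    p = obs[0] / rowsums[0]
    filtered[0] = p
    for t in range(1, len(obs)):
        pred = t_mat.T @ p
        post = pred * obs[t]
        s = post.sum()
        if s <= 0:  # disjoint support: trust the observation
            post, s = obs[t].copy(), rowsums[t]
        p = post / s
        filtered[t] = p
    lab = np.asarray([labels[i] for i in filtered.argmax(axis=1)], dtype=object)
    return FilteredBehaviorTrack(
        labels=lab,
        raw_probabilities=obs,
        filtered_probabilities=filtered,
        transition_matrix=t_mat,
    )


def mode_smooth(labels, window: int = 25) -> np.ndarray:
    """Replace each non-overlapping block of ``window`` frames by its modal label.

    A trailing block shorter than ``window`` is smoothed with its own mode.
    Ties are broken by the label of the block's central frame.  ``window``
    must be odd so the central frame is well defined.
    """
    lab = np.asarray(labels, dtype=object)
    n = len(lab)
    if window < 1 or window % 2 == 0:
        raise ConfigurationError(f"window must be odd and >= 1, got {window}")
    if window > n:
        raise ConfigurationError(f"window {window} exceeds sequence length {n}")
    out = np.empty(n, dtype=object)
    for start in range(0, n, window):
        block = lab[start : start + window]
        values, counts = np.unique(block.astype(str), return_counts=True)
        top = counts.max()
        winners = set(values[counts == top])
        if len(winners) == 1:
            mode = next(iter(winners))
        else:
            mode = str(block[len(block) // 2])  # tie: central frame of the block
        out[start : start + window] = mode
    return out


def _reference_positions(track: KeypointTrack, reference_point: str) -> np.ndarray:
    if reference_point == EAR_MIDPOINT:
        return 0.5 * (track.point("left_ear") + track.point("right_ear"))
    return track.point(reference_point)


def compute_velocity(
    track: KeypointTrack,
    fps: float = 15.0,
    reference_point: str = EAR_MIDPOINT,
    savgol_window: int = 15,
    savgol_order: int = 3,
) -> KinematicSummary:
    """Per-frame speed of a reference point, raw and Savitzky-Golay smoothed.

    Raw speed is ``‖Δposition‖ × fps`` (the first frame copies the second);
    the smoothed series is a Savitzky-Golay filter of the raw one, clipped at
    zero.  ``total_distance`` is the summed step length of the raw track.
    The default reference point is the midpoint of the two ears, which is
    always present and robust to limb jitter.
    """
    if savgol_window % 2 == 0 or savgol_window <= savgol_order:
        raise ConfigurationError(
            f"savgol_window must be odd and > savgol_order, got "
            f"window={savgol_window}, order={savgol_order}"
        )
    pos = _reference_positions(track, reference_point)
    if len(pos) < 2:
        raise InputError("velocity needs at least 2 frames")
    step = np.linalg.norm(np.diff(pos, axis=0), axis=1)
    raw = np.empty(len(pos))
    raw[1:] = step * fps
    raw[0] = raw[1]
    window = min(savgol_window, len(raw) if len(raw) % 2 else len(raw) - 1)
    smooth = np.clip(savgol_filter(raw, window, savgol_order), 0.0, None)
    return KinematicSummary(
        velocity_raw=raw,
        velocity_smooth=smooth,
        total_distance=float(step.sum()),
    )


def occupancy_and_ethogram(
    track: KeypointTrack,
    labels: BehaviorLabelTrack,
    arena: ArenaGeometry,
    fps: float = 15.0,
    reference_point: str = EAR_MIDPOINT,
) -> KinematicSummary:
    """Zone-occupancy seconds, behavior fractions, and a per-frame table.

    The reference point of each frame is classified into an arena zone; zone
    seconds sum to the session duration.  Behavior fractions follow the
    (running, sitting, grooming) order and sum to 1.  ``frame_table`` holds
    per-frame position, zone and label, ready for CSV export or plotting.
    """
    if track.n_frames != labels.n_frames:
        raise InputError(
            f"length mismatch: track has {track.n_frames} frames, labels {labels.n_frames}"
        )
    pos = _reference_positions(track, reference_point)
    zones = classify_zone(pos, arena)
    zone_seconds = {z: 0.0 for z in ZONE_NAMES + ("outside",)}
    vals, counts = np.unique(zones.astype(str), return_counts=True)
    for z, c in zip(vals, counts):
        zone_seconds[z] = c / fps
    frac = {b: float(np.mean(labels.labels == b)) for b in BEHAVIORS}
    table = pd.DataFrame(
        {
            "frame": np.arange(track.n_frames),
            "x": pos[:, 0],
            "y": pos[:, 1],
            "zone": zones.astype(str),
            "behavior": labels.labels.astype(str),
        }
    )
    return KinematicSummary(
        zone_occupancy=zone_seconds,
        behavior_fractions=frac,
        frame_table=table,
    )
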
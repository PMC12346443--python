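"""Behavior-epoch geometry: mapping manifold points to behaviors and ellipse descriptors.

Each manifold point summarises one 2-s window; the window inherits the
behavior label that dominates its frames.  The sub-cloud of points belonging
to one behavior is then described by the covariance ellipse of its 2-D
embedding: eigenvalues λ1 ≥ λ2 of the sample covariance give

    area          S = π · λ1 · λ2
    eccentricity  c = sqrt(1 − λ2² / λ1²)

These are the descriptors used for group comparison.  The default
(``convention="eigenvalue"``) applies the formulas directly to the
eigenvalues: S multiplies the eigenvalues themselves rather than the axis
lengths, and c squares the eigenvalue ratio.  The conventional
95%-confidence ellipse — semi-axes ``sqrt(χ²₂,₀.₉₅ λ)``, area
``π χ² sqrt(λ1 λ2)``, eccentricity ``sqrt(1 − λ2/λ1)`` — is available as
``convention="standard"``.  All group comparisons are relative, so the
choice does not affect directions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .errors import DegenerateGeometryError, InputError
from .manifold import EmbeddingResult, WindowVectorSet
from .synthetic import BEHAVIORS, BehaviorLabelTrack

log = logging.getLogger(__name__)

CONVENTIONS = ("eigenvalue", "standard")
_CHI2_95_2D = float(chi2.ppf(0.95, df=2))


@dataclass
class EpochAssignment:
    """Per-window behavior labels and the winning label's frame fraction."""

    window_labels: np.ndarray  # (n_windows,) of str
    majority_fraction: np.ndarray  # (n_windows,) in (1/3, 1]


@dataclass
class EllipseDescriptor:
    """Covariance-ellipse summary of one behavior's manifold sub-cloud."""

    lambda1: float
    lambda2: float
    area: float
    eccentricity: float
    behavior: str = ""
    n_points: int = 0
    convention: str = "eigenvalue"


def assign_epochs(
    windows: WindowVectorSet, labels: BehaviorLabelTrack
) -> EpochAssignment:
    """Assign each window the behavior that dominates its frames.

    The label track must cover every frame of every window.  Ties between
    equally frequent labels are broken by the label of the window's central
    frame.
    """
    w = windows.window_len
    needed = int(windows.window_start_frames[-1]) + w
    if labels.n_frames < needed:
        raise InputError(
            f"label track covers {labels.n_frames} frames but windows need "
            f"{needed}; first uncovered frame is {labels.n_frames}"
        )
    lab = labels.labels
    out = np.empty(windows.n_windows, dtype=object)
    frac = np.empty(windows.n_windows)
    for i, start in enumerate(windows.window_start_frames):
        block = lab[start : start + w].astype(str)
        values, counts = np.unique(block, return_counts=True)
        top = counts.max()
        winners = set(values[counts == top])
        if len(winners) == 1:
            winner = next(iter(winners))
        else:
            winner = str(block[w // 2])  # central-frame tie-break
        out[i] = winner
        frac[i] = top / w
    return EpochAssignment(window_labels=out, majority_fraction=frac)


def fit_ellipse(points: np.ndarray, convention: str = "eigenvalue") -> EllipseDescriptor:
    """Fit the covariance ellipse of a 2-D point cloud.

    Uses the sample covariance (n−1 denominator).  ``convention="eigenvalue"``
    applies S = π λ1 λ2 and c = sqrt(1 − λ2²/λ1²); ``"standard"`` applies the
    usual 95% confidence ellipse with χ²(2) scaling and axis-length
    eccentricity.  A cloud with zero leading variance is degenerate.
    """
    if convention not in CONVENTIONS:
        raise InputError(f"unknown convention {convention!r}; use {CONVENTIONS}")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InputError(f"points must be (n, 2), got shape {pts.shape}")
    n = pts.shape[0]
    if n < 3:
        raise InputError(f"ellipse fit needs >= 3 points, got {n}")
    cov = np.cov(pts.T, ddof=1)
    lam = np.linalg.eigvalsh(cov)  # ascending
    lam2, lam1 = float(max(lam[0], 0.0)), float(max(lam[1], 0.0))
    if lam1 <= 0.0:
        raise DegenerateGeometryError("point cloud has zero total variance")
    if convention == "eigenvalue":
        area = float(np.pi * lam1 * lam2)
        ecc = float(np.sqrt(max(0.0, 1.0 - (lam2 / lam1) ** 2)))
    else:
        area = float(np.pi * _CHI2_95_2D * np.sqrt(lam1 * lam2))
        ecc = float(np.sqrt(max(0.0, 1.0 - lam2 / lam1)))
    return EllipseDescriptor(
        lambda1=lam1, lambda2=lam2, area=area, eccentricity=ecc,
        n_points=n, convention=convention,
    )


def per_behavior_descriptors(
    embedding: EmbeddingResult,
    epochs: EpochAssignment,
    min_points: int = 3,
    convention: str = "eigenvalue",
) -> list[EllipseDescriptor]:
    """One ellipse descriptor per behavior with at least ``min_points`` windows.

    Behaviors below the threshold are logged and omitted (absent, not an
    error).  Results are ordered by the canonical behavior alphabet.
    """
    if len(epochs.window_labels) != embedding.points.shape[0]:
        raise InputError(
            f"epoch labels ({len(epochs.window_labels)}) misaligned with embedding "
            f"points ({embedding.points.shape[0]})"
        )
    out: list[EllipseDescriptor] = []
    for behavior in BEHAVIORS:
        mask = epochs.window_labels == behavior
        n = int(mask.sum())
        if n < min_points:
            log.info(
                "behavior %r has %d window(s) < min_points=%d; skipped",
                behavior, n, min_points,
            )
            continue
        desc = fit_ellipse(embedding.points[mask], convention=convention)
        desc.behavior = behavior
        out.append(desc)
    return out
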
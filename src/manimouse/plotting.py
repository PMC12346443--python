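"""Figure export: kinematics, ethograms, embeddings with ellipse overlays.

All functions take an output path, write a PNG with a non-interactive
backend, and return the path.  PNG metadata is pinned so repeated runs of the
same analysis produce byte-identical files.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .arena import ArenaGeometry  # noqa: E402
from .ellipse import EllipseDescriptor  # noqa: E402
from .manifold import EmbeddingResult  # noqa: E402
from .synthetic import BEHAVIORS  # noqa: E402

_SAVEFIG = {"dpi": 110, "metadata": {"Software": "manimouse"}}
_BEHAVIOR_COLORS = {"running": "tab:red", "sitting": "tab:blue", "grooming": "tab:green"}


def _save(fig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, **_SAVEFIG)
    plt.close(fig)
    return path


def plot_velocity(raw: np.ndarray, smooth: np.ndarray, fps: float, path) -> Path:
    """Raw (green) and smoothed (red) speed over time."""
    t = np.arange(len(raw)) / fps
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(t, raw, color="green", lw=0.6, label="raw")
    ax.plot(t, smooth, color="red", lw=1.2, label="smoothed")
    ax.set(xlabel="time (s)", ylabel="speed (px/s)")
    ax.legend(frameon=False)
    fig.tight_layout()
    return _save(fig, path)


def plot_trajectory(frame_table, arena: ArenaGeometry | None, path) -> Path:
    """Path of the reference point, with zone circles if geometry is given."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(frame_table["x"], frame_table["y"], lw=0.5, color="black")
    if arena is not None:
        for r in arena.zone_radii:
            ax.add_patch(
                plt.Circle(arena.center, r, fill=False, color="tab:gray", lw=0.8)
            )
    ax.set_aspect("equal")
    ax.set(xlabel="x (px)", ylabel="y (px)")
    fig.tight_layout()
    return _save(fig, path)


def plot_position_heatmap(frame_table, path, bins: int = 40) -> Path:
    fig, ax = plt.subplots(figsize=(5, 4))
    h = ax.hist2d(frame_table["x"], frame_table["y"], bins=bins, cmap="viridis")
    fig.colorbar(h[3], ax=ax, label="frames")
    ax.set_aspect("equal")
    fig.tight_layout()
    return _save(fig, path)


def plot_ethogram(labels, fps: float, path) -> Path:
    """Behavior timeline as colored horizontal spans."""
    labels = np.asarray(labels, dtype=object)
    fig, ax = plt.subplots(figsize=(8, 1.8))
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            ax.axvspan(
                start / fps, i / fps,
                color=_BEHAVIOR_COLORS.get(str(labels[start]), "gray"), lw=0,
            )
            start = i
    ax.set(xlabel="time (s)", yticks=[], xlim=(0, len(labels) / fps))
    handles = [plt.Rectangle((0, 0), 1, 1, color=_BEHAVIOR_COLORS[b]) for b in BEHAVIORS]
    ax.legend(handles, BEHAVIORS, ncol=3, frameon=False, loc="upper right")
    fig.tight_layout()
    return _save(fig, path)


def plot_embedding(
    embedding: EmbeddingResult,
    window_labels=None,
    descriptors: list[EllipseDescriptor] | None = None,
    path=None,
):
    """2-D embedding scatter, colored by behavior, with ellipse outlines.

    Ellipse outlines are drawn at one standard deviation per axis
    (semi-axes ``sqrt(λ)``), oriented by the covariance eigenvectors of each
    behavior's sub-cloud.
    """
    pts = embedding.points
    fig, ax = plt.subplots(figsize=(5, 5))
    if window_labels is None:
        ax.scatter(pts[:, 0], pts[:, 1], s=8, color="black", alpha=0.7)
    else:
        window_labels = np.asarray(window_labels, dtype=object)
        for b in BEHAVIORS:
            mask = window_labels == b
            if mask.any():
                ax.scatter(
                    pts[mask, 0], pts[mask, 1], s=8, alpha=0.7,
                    color=_BEHAVIOR_COLORS[b], label=b,
                )
                if mask.sum() >= 3:
                    _draw_cov_ellipse(ax, pts[mask], _BEHAVIOR_COLORS[b])
        ax.legend(frameon=False)
    ax.set(xlabel=f"{embedding.method} 1", ylabel=f"{embedding.method} 2")
    fig.tight_layout()
    return _save(fig, path)


def _draw_cov_ellipse(ax, pts: np.ndarray, color: str) -> None:
    from matplotlib.patches import Ellipse as MplEllipse

    cov = np.cov(pts.T, ddof=1)
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    angle = float(np.degrees(np.arctan2(vec[1, 0], vec[0, 0])))
    ax.add_patch(
        MplEllipse(
            pts.mean(axis=0), 2 * np.sqrt(max(lam[0], 0)), 2 * np.sqrt(max(lam[1], 0)),
            angle=angle, fill=False, color=color, lw=1.5,
        )
    )


def plot_group_metric(values_by_group: dict[str, list[float]], ylabel: str, path) -> Path:
    """Strip plot of a per-session metric by group, with group means."""
    fig, ax = plt.subplots(figsize=(4, 4))
    rng = np.random.default_rng(0)  # fixed jitter for reproducible figures
    for i, (group, vals) in enumerate(values_by_group.items()):
        xs = i + rng.uniform(-0.12, 0.12, size=len(vals))
        ax.scatter(xs, vals, s=18, alpha=0.8)
        ax.hlines(np.mean(vals), i - 0.25, i + 0.25, color="black", lw=2)
    ax.set_xticks(range(len(values_by_group)), list(values_by_group))
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    return _save(fig, path)
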
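"""Composite RGB frames for behavior scoring.

A single video frame cannot carry the temporal context that distinguishes,
say, sitting from grooming.  The composite-frame construction encodes a
21-frame window into one RGB image: the green channel is the mean of the 10
preceding frames' green channels, the red channel is the scored (11th)
frame's red channel, and the blue channel is the mean of the 10 following
frames' blue channels.  Motion then shows up as colored fringes around the
animal while the static background stays gray.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .errors import InputError

log = logging.getLogger(__name__)

WINDOW = 21  # frames per composite
HALF = WINDOW // 2  # 10 frames of context on each side


@dataclass
class CompositeFrame:
    """One composite RGB image plus the index of the frame it scores."""

    image: np.ndarray  # (H, W, 3) uint8
    center_index: int  # 0-based index into the source video


def _validate_stack(frames: Sequence[np.ndarray]) -> np.ndarray:
    if len(frames) != WINDOW:
        raise InputError(f"composite needs exactly {WINDOW} frames, got {len(frames)}")
    try:
        stack = np.asarray(frames)
    except ValueError as exc:
        raise InputError(f"frames must share one (H, W, 3) shape: {exc}") from None
    if stack.ndim != 4 or stack.shape[-1] != 3:
        raise InputError(
            f"frames must share one (H, W, 3) shape; got stacked shape {stack.shape}"
        )
    return stack


def build_composite(frames: Sequence[np.ndarray], center_index: int = HALF) -> CompositeFrame:
    """Fuse 21 equally sized RGB frames into one composite frame.

    Channel means are computed in floating point and rounded half-up to the
    8-bit pixel depth of the output.
    """
    stack = _validate_stack(frames).astype(float)
    out = np.empty(stack.shape[1:3] + (3,), dtype=float)
    out[..., 0] = stack[HALF, ..., 0]                       # R: scored frame
    out[..., 1] = stack[:HALF, ..., 1].mean(axis=0)         # G: preceding 10
    out[..., 2] = stack[HALF + 1:, ..., 2].mean(axis=0)     # B: following 10
    image = np.floor(out + 0.5).clip(0, 255).astype(np.uint8)  # round half-up
    return CompositeFrame(image=image, center_index=center_index)


def composite_stream(
    video_frames: Sequence[np.ndarray], stride: int = 1
) -> Iterator[CompositeFrame]:
    """Yield composites over a whole video, one per valid center frame.

    Valid centers are frames with 10 full frames on each side; with 0-based
    indexing these are indices ``HALF .. T-1-HALF``, visited with step
    ``stride``.  The 20 frames whose window falls off either end are skipped
    and the skip count is logged.
    """
    t = len(video_frames)
    if t < WINDOW:
        raise InputError(f"video has {t} frames; composites need at least {WINDOW}")
    if stride < 1:
        raise InputError(f"stride must be >= 1, got {stride}")
    log.info("composite_stream: skipping %d edge frames (%d each end)", 2 * HALF, HALF)
    for center in range(HALF, t - HALF, stride):
        yield build_composite(
            video_frames[center - HALF : center + HALF + 1], center_index=center
        )


def composite_count(n_frames: int, stride: int = 1) -> int:
    """Number of composites :func:`composite_stream` yields for a video length."""
    if n_frames < WINDOW:
        return 0
    return (n_frames - WINDOW) // stride + 1
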
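"""Round-arena geometry: zone construction, segmentation from an image, point classification.

The open-field arena is a disc.  Analysis divides it into four concentric
zones: a central zone bounded by a painted marker circle, and three annuli of
equal width filling the gap between that marker and the arena wall.  Zone
geometry can be built directly from known radii or recovered from an overhead
arena photograph by circle detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DetectionError, InputError

ZONE_NAMES = ("central", "inner", "middle", "outer")


def _refine_circle(
    edges: np.ndarray, cx: float, cy: float, r: float, tol: float = 6.0
) -> tuple[float, float, float]:
    """Refine a coarse Hough circle with an algebraic (Kasa) least-squares fit.

    The boundary ring produces edge responses on both of its sides; fitting
    all edge pixels within ``tol`` of the coarse circle centres the estimate
    between them, removing the one-sided bias of the discrete Hough radius.
    """
    yy, xx = np.nonzero(edges)
    rr = np.hypot(xx - cx, yy - cy)
    sel = np.abs(rr - r) < tol
    if sel.sum() < 10:
        return cx, cy, r
    x, y = xx[sel].astype(float), yy[sel].astype(float)
    a = np.column_stack([x, y, np.ones_like(x)])
    b = x**2 + y**2
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    cx_f, cy_f = sol[0] / 2.0, sol[1] / 2.0
    r_f = float(np.sqrt(sol[2] + cx_f**2 + cy_f**2))
    return float(cx_f), float(cy_f), r_f


@dataclass(frozen=True)
class ArenaGeometry:
    """Center and the four increasing zone radii of a round arena.

    ``zone_radii = (r_central, r_inner, r_middle, r_outer)`` with equal annulus
    widths: ``r_inner - r_central == r_middle - r_inner == r_outer - r_middle``.
    """

    center: tuple[float, float]
    zone_radii: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        r = self.zone_radii
        if len(r) != 4 or not (0 < r[0] < r[1] < r[2] < r[3]):
            raise ConfigurationError(
                f"zone_radii must be 4 strictly increasing positive values, got {r}"
            )
        widths = np.diff(r)
        if not np.allclose(widths, widths[0], rtol=1e-6, atol=1e-6):
            raise ConfigurationError(
                f"annulus widths must be equal, got {tuple(widths)}"
            )

    @classmethod
    def from_bounds(cls, center: tuple[float, float], r_central: float, r_outer: float) -> "ArenaGeometry":
        """Build the 4-zone geometry from the central-marker and wall radii.

        The annulus between the two circles is split into three equal widths.
        """
        if not 0 < r_central < r_outer:
            raise ConfigurationError(
                f"need 0 < r_central < r_outer, got {r_central}, {r_outer}"
            )
        w = (r_outer - r_central) / 3.0
        return cls(
            center=(float(center[0]), float(center[1])),
            zone_radii=(r_central, r_central + w, r_central + 2 * w, r_outer),
        )


def classify_zone(point, arena: ArenaGeometry):
    """Label a point (or an (n, 2) array of points) by arena zone.

    Radial bins are half-open: ``[0, r_central)`` is central, ``[r_central,
    r_inner)`` inner, ``[r_inner, r_middle)`` middle, ``[r_middle, r_outer]``
    outer (outer edge inclusive); beyond ``r_outer`` the label is "outside".
    """
    pts = np.asarray(point, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 2:
        raise InputError(f"points must be (x, y) pairs, got shape {pts.shape}")
    cx, cy = arena.center
    r = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    rc, ri, rm, ro = arena.zone_radii
    labels = np.full(len(r), "outside", dtype=object)
    labels[r <= ro] = "outer"
    labels[r < rm] = "middle"
    labels[r < ri] = "inner"
    labels[r < rc] = "central"
    return labels[0] if scalar else labels


def segment_arena(
    image: np.ndarray,
    canny_sigma: float = 2.0,
    min_accumulator: float = 0.3,
) -> ArenaGeometry:
    """Recover arena geometry from a grayscale-convertible overhead image.

    The dominant circle (the arena wall) is found with a circular Hough
    transform on a Canny edge map.  The central-zone marker is then taken as
    the connected edge component nearest the detected center, searched within
    a region of interest a quarter the image size; its radius is the median
    radial distance of its pixels from the center.  The remaining two zone
    radii split the annulus into three equal widths.

    Raises
    ------
    DetectionError
        If no circle stands out in the Hough accumulator, or no interior
        contour is found near the center.
    """
    from skimage.feature import canny
    from skimage.measure import label as cc_label
    from skimage.transform import hough_circle, hough_circle_peaks

    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    if img.ndim != 2 or img.size == 0:
        raise InputError("image must be a 2-D (or RGB) array")
    span = img.max() - img.min()
    if span <= 0:
        raise DetectionError("no circle found: image has no contrast")
    img = (img - img.min()) / span

    edges = canny(img, sigma=canny_sigma)
    if not edges.any():
        raise DetectionError("no circle found: empty edge map")

    min_dim = min(img.shape)
    radii = np.arange(max(10, min_dim // 8), min_dim // 2, 2)
    accums = hough_circle(edges, radii)
    accum, cxs, cys, rads = hough_circle_peaks(accums, radii, total_num_peaks=1)
    if len(accum) == 0 or accum[0] < min_accumulator:
        raise DetectionError("no circle found: weak Hough accumulator response")
    cx, cy, r_outer = _refine_circle(edges, float(cxs[0]), float(cys[0]), float(rads[0]))

    # ROI a quarter of the image, centred on the detected circle center
    half = min_dim // 8
    y0, y1 = int(max(0, cy - half)), int(min(img.shape[0], cy + half))
    x0, x1 = int(max(0, cx - half)), int(min(img.shape[1], cx + half))
    roi = np.zeros_like(edges)
    roi[y0:y1, x0:x1] = edges[y0:y1, x0:x1]
    # exclude any wall pixels that leak into the ROI
    yy, xx = np.nonzero(roi)
    rr = np.hypot(xx - cx, yy - cy)
    keep = rr < 0.9 * r_outer
    if not keep.any():
        raise DetectionError("no interior contour found near the arena center")
    interior = np.zeros_like(edges)
    interior[yy[keep], xx[keep]] = True

    comps = cc_label(interior, connectivity=2)
    best, best_dist = None, np.inf
    for lab in range(1, comps.max() + 1):
        cyy, cxx = np.nonzero(comps == lab)
        d = np.hypot(cxx.mean() - cx, cyy.mean() - cy)
        if d < best_dist:
            best, best_dist = lab, d
    cyy, cxx = np.nonzero(comps == best)
    r0 = float(np.median(np.hypot(cxx - cx, cyy - cy)))
    # the marker ring yields edge responses on both sides; pool every interior
    # edge pixel within a band of the chosen contour to centre the estimate
    band = keep & (np.abs(rr - r0) < 5.0)
    if band.any():
        # midpoint of the two edge responses, robust to their pixel-count imbalance
        lo, hi = np.percentile(rr[band], [10, 90])
        r_central = float((lo + hi) / 2.0)
    else:
        r_central = r0
    if not 0 < r_central < r_outer:
        raise DetectionError("central marker radius not interior to the arena wall")
    return ArenaGeometry.from_bounds((cx, cy), r_central, r_outer)
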
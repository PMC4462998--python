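"""Cell detection, axis tracing and diameter profiling on phase contrast.

Cells appear as dark capsules on a bright background.  Detection thresholds
the inverted image (Otsu), labels connected components, and then applies
shape recognition: a slit-shaped window is walked from the region centroid
toward either pole to trace the (possibly curved) cell axis, the local
diameter is the chord through each axis sample perpendicular to the local
axis direction, and a set of shape criteria accepts or rejects the object.
Every rejection carries exactly one machine-readable primary reason code:
``border``, ``shape`` (solidity / too small), ``degenerate``, ``length``,
``diameter`` or ``bending``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu
from shapely.geometry import LineString, Point, Polygon

from ._errors import DegenerateShapeError

__all__ = [
    "ShapeCriteria",
    "CellObject",
    "detect_cells",
    "trace_axis",
    "measure_diameter_profile",
    "detect_constriction",
]


@dataclass(frozen=True)
class ShapeCriteria:
    """Accept/reject bounds for detected objects.

    Defaults are calibrated for ~1 μm wide rod cells at 14.98 px/μm; all are
    configurable and should be revisited for other organisms or optics.
    """

    min_length: float = 1.0  # μm
    diameter_range: tuple[float, float] = (0.5, 1.5)  # μm
    max_bending: float = 30.0  # degrees per μm of axis
    min_solidity: float = 0.85
    border_margin: int = 5  # px
    min_area_px: int = 30

    def __post_init__(self) -> None:
        lo, hi = self.diameter_range
        if not (lo > 0 and lo < hi):
            raise ValueError("diameter_range must satisfy 0 < lo < hi")
        if self.min_length <= 0 or self.max_bending <= 0 or self.min_solidity <= 0:
            raise ValueError("all bounds must be positive")


@dataclass
class CellObject:
    """One detected object: contour, axis, diameter profile, status."""

    id: int
    frame: int
    contour: np.ndarray  # (N, 2) subpixel (x, y) px, closed polygon
    axis: np.ndarray  # (M, 2) subpixel (x, y) px, pole to pole, ~1 px spacing
    diameters: np.ndarray  # μm at each axis sample
    status: str = "accepted"  # "accepted" | "rejected"
    reason: Optional[str] = None
    scale: float = 14.98  # px per μm
    mask: Optional[np.ndarray] = None  # bool crop of the cell region
    bbox: Optional[tuple[int, int, int, int]] = None  # (y0, x0, y1, x1) of mask

    @property
    def accepted(self) -> bool:
        return self.status == "accepted"

    @property
    def axis_length_px(self) -> float:
        if len(self.axis) < 2:
            return 0.0
        return float(np.sum(np.hypot(*np.diff(self.axis, axis=0).T)))

    @property
    def axis_length_um(self) -> float:
        return self.axis_length_px / self.scale

    @property
    def step_um(self) -> float:
        """Axial sampling step in μm (samples are disk centers)."""
        n = len(self.diameters)
        return self.axis_length_um / n if n else 0.0

    @property
    def mean_diameter_um(self) -> float:
        """Mean diameter excluding polar samples (within one radius of a pole)."""
        d = self.interior_diameters
        return float(np.mean(d)) if d.size else 0.0

    @property
    def interior_diameters(self) -> np.ndarray:
        """Diameter samples with the polar caps excluded."""
        d = self.diameters
        if d.size < 3:
            return d
        r_px = 0.5 * float(np.nanmax(d)) * self.scale
        k = int(np.ceil(r_px * len(d) / max(self.axis_length_px, 1e-9)))
        k = min(k, (d.size - 1) // 2)
        return d[k : d.size - k] if k > 0 else d


# ---------------------------------------------------------------------------
# low-level sampling helpers


def _bilinear(img: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Sample image at subpixel (x, y) points (order-1 interpolation)."""
    pts = np.atleast_2d(xy)
    return ndimage.map_coordinates(
        img, [pts[:, 1], pts[:, 0]], order=1, mode="constant", cval=0.0
    )


def _edge_crossing(img: np.ndarray, p: np.ndarray, d: np.ndarray,
                   level: float = 0.5, step: float = 0.25,
                   max_dist: float = 60.0) -> Optional[float]:
    """Distance along ``d`` from ``p`` to the first crossing below ``level``."""
    ts = np.arange(0.0, max_dist, step)
    vals = _bilinear(img, p[None, :] + ts[:, None] * d[None, :])
    below = np.nonzero(vals < level)[0]
    if below.size == 0 or below[0] == 0:
        return None if below.size == 0 else 0.0
    i = below[0]
    v0, v1 = vals[i - 1], vals[i]
    frac = (v0 - level) / (v0 - v1) if v1 != v0 else 0.5
    return float(ts[i - 1] + frac * step)


def _perp(d: np.ndarray) -> np.ndarray:
    return np.array([-d[1], d[0]])


def _walk(mask_f: np.ndarray, edt: np.ndarray, start: np.ndarray,
          d: np.ndarray, support_stop: float = 0.2,
          max_turn_px: float = 0.3) -> list[np.ndarray]:
    """Walk 1-px steps from ``start`` along ``d``, re-centering in a slit.

    At each step the next axis point is the mask-weighted centroid inside a
    slit of width 1.5 × local diameter (from the distance transform ``edt``)
    and thickness 3 px, oriented perpendicular to the walking direction.
    The perpendicular correction is clamped to ``max_turn_px`` per step
    (≈17°/px turn rate) so the trace cannot reverse inside the cell.  Stops
    when the slit's mask support drops below ``support_stop`` or less than
    one tube radius of mask remains ahead (the polar cap), then extends
    straight to the pole tip (0.5-crossing of the mask).
    """
    pts: list[np.ndarray] = []
    p = np.asarray(start, dtype=float)
    d = np.asarray(d, dtype=float)
    d = d / np.linalg.norm(d)
    max_steps = int(3 * np.hypot(*mask_f.shape)) + 10
    r_ref = float(edt.max())  # tube radius of the region
    for _ in range(max_steps):
        q = p + d
        nvec = _perp(d)
        r_loc = float(_bilinear(edt, q)[0])
        if r_loc <= 0.25:
            break
        # inside the polar cap (less than one radius of mask left ahead):
        # stop re-centering, the tip extension below finishes the axis
        ahead = _edge_crossing(mask_f, p, d)
        if ahead is not None and ahead < r_ref:
            break
        half = 1.5 * max(r_loc, 1.0)
        ts = np.arange(-half, half + 1e-9, 0.5)
        longit = np.array([-1.0, 0.0, 1.0])
        grid = (
            q[None, None, :]
            + ts[:, None, None] * nvec[None, None, :]
            + longit[None, :, None] * d[None, None, :]
        )
        vals = _bilinear(mask_f, grid.reshape(-1, 2)).reshape(len(ts), len(longit))
        support = float(vals.mean())
        if support < support_stop:
            break
        tw = vals.sum(axis=1)
        tbar = float(np.dot(tw, ts) / tw.sum())
        tbar = float(np.clip(tbar, -max_turn_px, max_turn_px))
        newp = q + tbar * nvec
        step_vec = newp - p
        norm = np.linalg.norm(step_vec)
        if norm < 1e-6:
            break
        d = step_vec / norm
        pts.append(newp)
        p = newp
    pts.extend(_extend_to_tip(mask_f, pts or [p], p, d, r_ref))
    return pts


def _axis_curvature(pts: list[np.ndarray], window: int = 12) -> float:
    """Mean signed turn rate (rad/px) over the last ``window`` axis points."""
    if len(pts) < 5:
        return 0.0
    tail = np.asarray(pts[-window:])
    seg = np.diff(tail, axis=0)
    theta = np.unwrap(np.arctan2(seg[:, 1], seg[:, 0]))
    arclen = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    s_mid = 0.5 * (arclen[:-1] + arclen[1:])
    if s_mid[-1] - s_mid[0] < 1e-6:
        return 0.0
    slope = np.polyfit(s_mid, theta, 1)[0]
    return float(np.clip(slope, -0.05, 0.05))


def _extend_to_tip(mask_f: np.ndarray, pts: list[np.ndarray], p: np.ndarray,
                   d: np.ndarray, r_ref: float) -> list[np.ndarray]:
    """Continue from the cap-entry point to the pole tip.

    Marches in 0.5-px steps along the heading, rotating it by the curvature
    estimated from the already-traced axis (so curved cells keep turning
    through the cap), and ends at the subpixel 0.5-crossing of the mask.
    """
    out: list[np.ndarray] = []
    step = 0.5
    kappa = _axis_curvature(pts)
    ca, sa = np.cos(kappa * step), np.sin(kappa * step)
    p = p.copy()
    d = d.copy()
    for _ in range(int(6 * r_ref) + 12):
        d = np.array([d[0] * ca - d[1] * sa, d[0] * sa + d[1] * ca])
        q = p + step * d
        if _bilinear(mask_f, q)[0] < 0.5:
            t = _edge_crossing(mask_f, p, d)
            if t is not None and t > 0:
                out.append(p + t * d)
            return out
        out.append(q)
        p = q
    return out


def _resample_polyline(pts: np.ndarray, spacing: float = 1.0) -> np.ndarray:
    """Resample a polyline to uniform ~``spacing`` arclength steps."""
    seg = np.hypot(*np.diff(pts, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    n = max(int(round(total / spacing)) + 1, 2)
    s = np.linspace(0.0, total, n)
    x = np.interp(s, arclen, pts[:, 0])
    y = np.interp(s, arclen, pts[:, 1])
    return np.column_stack([x, y])


def trace_axis(mask: np.ndarray, smooth_sigma: float = 1.0) -> np.ndarray:
    """Trace the pole-to-pole medial axis of a single cell region.

    ``mask`` is a boolean (or float in [0, 1]) image of one connected
    region.  Returns an (M, 2) polyline of subpixel (x, y) points spaced
    ~1 px in arclength.  Raises :class:`DegenerateShapeError` for regions
    with no usable elongation (e.g. circles) or thinner than 2 px.
    """
    mask_f = np.asarray(mask, dtype=float)
    ys, xs = np.nonzero(mask_f > 0.5)
    if xs.size < 5:
        raise DegenerateShapeError("region too small to trace")
    if ndimage.distance_transform_edt(mask_f > 0.5).max() < 1.0:
        raise DegenerateShapeError("region thinner than 2 px everywhere")
    c = np.array([xs.mean(), ys.mean()])
    cov = np.cov(np.stack([xs, ys]).astype(float))
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0 or np.sqrt(evals[1] / max(evals[0], 1e-12)) < 1.25:
        raise DegenerateShapeError("region has no principal elongation axis")
    d0 = evecs[:, np.argmax(evals)]

    edt = ndimage.distance_transform_edt(mask_f > 0.5)
    fwd = _walk(mask_f, edt, c, d0)
    bwd = _walk(mask_f, edt, c, -d0)
    pts = np.array(list(reversed(bwd)) + [c] + fwd)
    if len(pts) < 3:
        raise DegenerateShapeError("axis trace collapsed")
    axis = _resample_polyline(pts, 1.0)
    chord = np.linalg.norm(axis[-1] - axis[0])
    width = 2.0 * ndimage.distance_transform_edt(mask_f > 0.5).max()
    if chord <= width * 0.9:
        raise DegenerateShapeError("axis not longer than cell width")
    return axis


def _axis_normals(axis: np.ndarray) -> np.ndarray:
    """Unit normals at each axis sample (central differences)."""
    tang = np.gradient(axis, axis=0)
    norm = np.linalg.norm(tang, axis=1, keepdims=True)
    tang = tang / np.maximum(norm, 1e-12)
    return np.column_stack([-tang[:, 1], tang[:, 0]])


def measure_diameter_profile(
    contour: np.ndarray, axis: np.ndarray, scale: float
) -> np.ndarray:
    """Local diameter (μm) at each axis sample.

    The diameter at sample *i* is the length of the chord through the sample
    perpendicular to the local axis direction, clipped to the (subpixel)
    contour.  Samples whose perpendicular fails to intersect the contour on
    both sides are interpolated from their neighbours.
    """
    poly = Polygon(np.asarray(contour, dtype=float))
    if not poly.is_valid:
        poly = poly.buffer(0)
    normals = _axis_normals(axis)
    reach = 2.0 * np.sqrt(max(poly.area, 1.0))
    out = np.full(len(axis), np.nan)
    for i, (p, nvec) in enumerate(zip(axis, normals)):
        line = LineString([p - reach * nvec, p + reach * nvec])
        inter = line.intersection(poly)
        if inter.is_empty:
            continue
        pieces = getattr(inter, "geoms", [inter])
        pt = Point(p)
        best = None
        for g in pieces:
            if g.geom_type != "LineString":
                continue
            if g.distance(pt) < 0.75:
                if best is None or g.length > best.length:
                    best = g
        if best is not None:
            out[i] = best.length
    # endpoints sit on the contour: chord tapers to 0 there
    if np.isnan(out[0]):
        out[0] = 0.0
    if np.isnan(out[-1]):
        out[-1] = 0.0
    bad = np.isnan(out)
    if bad.any():
        idx = np.arange(len(out))
        out[bad] = np.interp(idx[bad], idx[~bad], out[~bad])
    return out / scale


def detect_constriction(
    diameters: np.ndarray, central_fraction: float = 0.5
) -> Optional[tuple[float, float]]:
    """Minimal central diameter and its relative axis position.

    The diameter profile is smoothed with a 3-sample moving average and the
    minimum is searched in the central ``central_fraction`` of the axis only
    (the polar tapers never count as constriction).  Returns
    ``(min_diameter, position)`` with position as a fraction of the axis, or
    ``None`` when fewer than 5 interior samples are available.
    """
    d = np.asarray(diameters, dtype=float)
    if d.size < 5:
        return None
    sm = np.convolve(d, np.ones(3) / 3.0, mode="same")
    sm[0], sm[-1] = d[0], d[-1]
    n = d.size
    lo = int(np.floor(n * (0.5 - central_fraction / 2.0)))
    hi = int(np.ceil(n * (0.5 + central_fraction / 2.0)))
    window = sm[lo:hi]
    if window.size == 0:
        return None
    i = int(np.argmin(window))
    return float(window[i]), float((lo + i) / (n - 1))


def _bending_deg_per_um(axis: np.ndarray, length_um: float) -> float:
    """Net curvature of the axis in degrees per μm.

    Estimated from the chord/arclength ratio of the polyline, which for a
    circular arc of total turn θ satisfies chord/arc = sinc(θ/2); this is
    insensitive to subpixel tracing jitter, unlike summed segment angles.
    """
    if len(axis) < 3 or length_um <= 0:
        return 0.0
    seg = np.diff(axis, axis=0)
    arc = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
    chord = float(np.linalg.norm(axis[-1] - axis[0]))
    if arc <= 0 or chord >= arc:
        return 0.0
    ratio = chord / arc
    theta = np.sqrt(24.0 * (1.0 - ratio))  # small-angle inversion of sinc
    # refine by fixed-point iteration on chord/arc = sin(θ/2)/(θ/2)
    for _ in range(20):
        half = theta / 2.0
        if half < 1e-9:
            break
        f = np.sin(half) / half - ratio
        df = (np.cos(half) * half - np.sin(half)) / (2 * half**2)
        if abs(df) < 1e-12:
            break
        theta = max(theta - f / df, 0.0)
    return float(np.degrees(theta)) / length_um


def detect_cells(
    phase_image: np.ndarray,
    scale: float,
    criteria: ShapeCriteria = ShapeCriteria(),
    frame: int = 0,
) -> list[CellObject]:
    """Detect cells in a phase-contrast image (dark cells, bright background).

    Returns a :class:`CellObject` per connected dark component, accepted or
    rejected with a single primary reason code.  A blank image yields an
    empty list.
    """
    img = np.asarray(phase_image, dtype=float)
    work = img.max() - img  # cells bright
    if work.std() < 1e-9:
        return []
    try:
        th = threshold_otsu(work)
    except ValueError:
        return []
    binary = work > th
    if binary.all() or not binary.any():
        return []
    # re-level at the midpoint between the two class medians so the subpixel
    # contour of a symmetrically blurred edge sits on the true boundary
    level = 0.5 * (np.median(work[binary]) + np.median(work[~binary]))
    binary = work > level
    binary = ndimage.binary_fill_holes(binary)
    labels, n_obj = ndimage.label(binary)
    cells: list[CellObject] = []
    H, W = img.shape
    m = criteria.border_margin
    for lab in range(1, n_obj + 1):
        region_mask = labels == lab
        area = int(region_mask.sum())
        ys, xs = np.nonzero(region_mask)
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        pad = 3
        cy0, cy1 = max(y0 - pad, 0), min(y1 + pad, H)
        cx0, cx1 = max(x0 - pad, 0), min(x1 + pad, W)
        crop_mask = region_mask[cy0:cy1, cx0:cx1]
        bbox = (cy0, cx0, cy1, cx1)

        def _rejected(reason: str, axis=None, diam=None, contour=None) -> CellObject:
            return CellObject(
                id=lab, frame=frame,
                contour=contour if contour is not None else np.empty((0, 2)),
                axis=axis if axis is not None else np.empty((0, 2)),
                diameters=diam if diam is not None else np.empty(0),
                status="rejected", reason=reason, scale=scale,
                mask=crop_mask, bbox=bbox,
            )

        if y0 < m or x0 < m or y1 > H - m or x1 > W - m:
            cells.append(_rejected("border"))
            continue
        if area < criteria.min_area_px:
            cells.append(_rejected("shape"))
            continue
        rp = measure.regionprops(crop_mask.astype(np.uint8))[0]
        if rp.solidity < criteria.min_solidity:
            cells.append(_rejected("shape"))
            continue
        # subpixel contour on the inverted image at the re-estimated level
        crop_work = np.where(
            ndimage.binary_dilation(crop_mask, iterations=2),
            work[cy0:cy1, cx0:cx1],
            0.0,
        )
        contours = measure.find_contours(crop_work, level)
        if not contours:
            cells.append(_rejected("shape"))
            continue
        cont_rc = max(contours, key=len)
        contour = np.column_stack([cont_rc[:, 1] + cx0, cont_rc[:, 0] + cy0])
        try:
            axis_local = trace_axis(crop_mask)
        except DegenerateShapeError:
            cells.append(_rejected("degenerate", contour=contour))
            continue
        axis = axis_local + np.array([cx0, cy0])
        diam = measure_diameter_profile(contour, axis, scale)
        cell = CellObject(
            id=lab, frame=frame, contour=contour, axis=axis, diameters=diam,
            status="accepted", scale=scale, mask=crop_mask, bbox=bbox,
        )
        if cell.axis_length_um < criteria.min_length:
            cell.status, cell.reason = "rejected", "length"
        elif not (
            criteria.diameter_range[0]
            <= cell.mean_diameter_um
            <= criteria.diameter_range[1]
        ):
            cell.status, cell.reason = "rejected", "diameter"
        elif _bending_deg_per_um(axis, cell.axis_length_um) > criteria.max_bending:
            cell.status, cell.reason = "rejected", "bending"
        cells.append(cell)
    return cells
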
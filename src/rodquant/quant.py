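"""Scalar quantification: background, registration, ages, calibration, stats.

Implements the per-cell results table (integrated fluorescence,
concentrations per volume or per envelope area, the midcell surplus FCPlus
and its molecule-count conversion MolsCPlus), steady-state age assignment
from the cell-length rank, modal background subtraction, cross-correlation
channel registration, qualifiers, and age-binned mean ± 95% CI statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

from ._errors import NotComputableError
from . import geometry
from .geometry import midcell_partition
from .profiles import ProfileMap
from .segment import CellObject, detect_constriction

__all__ = [
    "CalibrationFactor",
    "subtract_modal_background",
    "register_fluorescence",
    "assign_ages",
    "build_results_table",
    "fc_plus",
    "calibration_factor",
    "mols_cplus",
    "age_binned_stats",
    "qualify",
    "clear_qualifiers",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationFactor:
    """Proteins per fluorescence unit.

    ``F = n_avg / mean(FluorTotal)`` over qualified cells, where ``n_avg``
    is the known copy number of the average cell (an external input, e.g.
    from ribosome profiling).  ``MolsCPlus = FCPlus · F``.
    """

    F: float
    n_avg: float
    mean_fluortotal: float

    def __post_init__(self) -> None:
        if self.F <= 0:
            raise ValueError("F must be positive")


# ---------------------------------------------------------------------------
# image preprocessing


def estimate_modal_background(image: np.ndarray, bins: int = 256) -> float:
    """Modal pixel value via a coarse histogram refined by the modal-bin median."""
    img = np.asarray(image, dtype=float).ravel()
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return lo
    hist, edges = np.histogram(img, bins=bins, range=(lo, hi))
    k = int(np.argmax(hist))
    width = edges[1] - edges[0]
    sel = (img >= edges[k] - width) & (img <= edges[k + 1] + width)
    return float(np.median(img[sel]))


def subtract_modal_background(
    image: np.ndarray, clip_negative: bool = True
) -> np.ndarray:
    """Subtract the modal (background) value; clip negatives at 0 by default."""
    mode = estimate_modal_background(image)
    out = np.asarray(image, dtype=float) - mode
    if clip_negative:
        np.clip(out, 0.0, None, out=out)
    return out


def _contour_mask(
    cells: Sequence[CellObject], shape: tuple[int, int]
) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    for c in cells:
        if c.mask is None or c.bbox is None:
            continue
        y0, x0, y1, x1 = c.bbox
        m[y0:y1, x0:x1] |= c.mask
    return m


def register_fluorescence(
    cells: Sequence[CellObject],
    fluor_image: np.ndarray,
    max_shift: int = 5,
) -> tuple[int, int]:
    """Translation (dx, dy) of the fluorescence image that maximizes the
    fluorescence summed under all cell contours.

    The objective over integer shifts is the cross-correlation of the
    fluorescence with the cell mask, evaluated in the Fourier domain; the
    argmax inside ``±max_shift`` is returned.  A flat objective (no cells or
    a blank channel) returns (0, 0) with a warning.
    """
    img = np.asarray(fluor_image, dtype=float)
    mask = _contour_mask(cells, img.shape).astype(float)
    if mask.sum() == 0 or img.std() < 1e-12:
        warnings.warn("flat registration objective; returning zero shift",
                      stacklevel=2)
        return (0, 0)
    # C(t) = Σ_x mask(x) · img(x − t), computed for all t via FFT:
    # irfft2(M · conj(I))[t] = Σ_z mask(z + t) · img(z) = C(t)
    corr = np.fft.irfft2(
        np.fft.rfft2(mask) * np.conj(np.fft.rfft2(img)), s=img.shape
    )
    shifts = np.arange(-max_shift, max_shift + 1)
    window = corr[np.ix_(shifts % img.shape[0], shifts % img.shape[1])]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    if np.ptp(window) < 1e-9 * max(abs(window).max(), 1.0):
        warnings.warn("flat registration objective; returning zero shift",
                      stacklevel=2)
        return (0, 0)
    return (int(shifts[ix]), int(shifts[iy]))


def apply_shift(image: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Apply an integer (dx, dy) translation, zero-filling exposed borders."""
    dx, dy = shift
    out = np.roll(np.roll(image, dy, axis=0), dx, axis=1)
    if dy > 0:
        out[:dy] = 0
    elif dy < 0:
        out[dy:] = 0
    if dx > 0:
        out[:, :dx] = 0
    elif dx < 0:
        out[:, dx:] = 0
    return out


# ---------------------------------------------------------------------------
# steady-state age assignment


def assign_ages(lengths: Sequence[float]) -> np.ndarray:
    """Division-cycle age (%) from cell-length rank in a steady-state culture.

    Lengths are ranked ascending (stable, ties keep input order) and the age
    of rank *i* (0-based) among *n* cells is::

        age_i = ln(1 − 0.5·i/(n−1)) / ln(0.5)

    reported in percent.  This is exactly the inverse CDF of the
    steady-state age distribution evaluated on the uniform rank grid, so
    rank 0 → 0% and rank n−1 → 100%.
    """
    lengths = np.asarray(lengths, dtype=float)
    n = lengths.size
    if n < 2:
        raise NotComputableError("age assignment needs at least 2 cells")
    order = np.argsort(lengths, kind="stable")
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(n)
    return np.log(1.0 - 0.5 * ranks / (n - 1)) / np.log(0.5) * 100.0 + 0.0


# ---------------------------------------------------------------------------
# per-cell metrics


def fc_plus(
    fluor_profile: np.ndarray,
    diameters_um: np.ndarray,
    step_um: float,
    halfwidth: float = 0.4,
) -> Optional[float]:
    """Surplus fluorescence at midcell (signed).

    ``FCPlus = (F_mid/V_mid − F_rest/V_rest) · V_mid`` where F and V are the
    fluorescence and disk volume integrated over the central ±``halfwidth``
    μm window and over the remainder.  Returns None (undefined) for cells
    shorter than the window.
    """
    vols = geometry.disk_volumes(diameters_um, step_um)
    fsplit = midcell_partition(fluor_profile, step_um, halfwidth)
    vsplit = midcell_partition(vols, step_um, halfwidth)
    if fsplit.whole_cell or vsplit.rest <= 0 or vsplit.mid <= 0:
        return None
    return float(
        (fsplit.mid / vsplit.mid - fsplit.rest / vsplit.rest) * vsplit.mid
    )


def build_results_table(
    cells: Sequence[CellObject],
    pmap: ProfileMap,
    channel_classes: Optional[dict[int, str]] = None,
    midcell_halfwidth: float = 0.4,
) -> pd.DataFrame:
    """One row per accepted cell with all scalar quantities.

    Columns: ``cell``, ``frame``, ``axis_length_um``, ``mean_diameter_um``,
    ``min_diameter_um``, ``constriction_pos``, ``volume_um3`` (Volume),
    ``cell_wall_um2`` (CellWall), ``area_um2`` (Area, projected contour),
    ``midcell_volume_um3`` and, per channel *k*: ``fluortotal_ch{k}``,
    ``conctotal_ch{k}`` (per volume), ``concwall_ch{k}`` (per envelope
    area), ``fcplus_ch{k}``.  ``age_pct`` is filled by rank over qualified
    cells; ``qualified`` starts True.  ``channel_classes`` records whether a
    channel's protein is cytoplasmic (``"volume"``) or envelope-bound
    (``"wall"``) — both concentrations are always reported, the class picks
    the one used by downstream plots.
    """
    by_id = {c.cell_id: c for c in pmap.columns}
    rows = []
    for cell in cells:
        if not cell.accepted or cell.id not in by_id:
            continue
        col = by_id[cell.id]
        step = cell.step_um
        d = cell.diameters
        vol = geometry.cell_volume(d, step)
        wall = geometry.envelope_area(d, step)
        area = geometry.projection_area(cell.contour) / cell.scale**2
        vols = geometry.disk_volumes(d, step)
        vsplit = midcell_partition(vols, step, midcell_halfwidth)
        constr = detect_constriction(d)
        row = {
            "cell": cell.id,
            "frame": cell.frame,
            "axis_length_um": cell.axis_length_um,
            "mean_diameter_um": cell.mean_diameter_um,
            "min_diameter_um": np.nan if constr is None else constr[0],
            "constriction_pos": np.nan if constr is None else constr[1],
            "volume_um3": vol,
            "cell_wall_um2": wall,
            "area_um2": area,
            "midcell_volume_um3": vsplit.mid,
            "midcell_whole_cell_flag": vsplit.whole_cell,
            "qualified": True,
        }
        for ch, vec in col.fluor.items():
            ft = float(vec.sum())
            row[f"fluortotal_ch{ch}"] = ft
            row[f"conctotal_ch{ch}"] = ft / vol if vol > 0 else 0.0
            row[f"concwall_ch{ch}"] = ft / wall if wall > 0 else 0.0
            fcp = fc_plus(vec, d, step, midcell_halfwidth)
            row[f"fcplus_ch{ch}"] = np.nan if fcp is None else fcp
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table) >= 2:
        table["age_pct"] = assign_ages(table["axis_length_um"].to_numpy())
    elif len(table):
        table["age_pct"] = np.nan
    table.attrs["channel_classes"] = channel_classes or {}
    return table


# ---------------------------------------------------------------------------
# calibration to molecule counts


def calibration_factor(results: pd.DataFrame, n_avg: float,
                       channel: int) -> CalibrationFactor:
    """F = n_avg / mean(FluorTotal) over qualified cells."""
    if n_avg <= 0:
        raise ValueError("n_avg must be positive")
    qualified = results[results["qualified"]]
    if len(qualified) == 0:
        raise NotComputableError("no qualified cells for calibration")
    mean_ft = float(qualified[f"fluortotal_ch{channel}"].mean())
    if mean_ft <= 0:
        raise NotComputableError("mean FluorTotal is not positive")
    return CalibrationFactor(F=n_avg / mean_ft, n_avg=n_avg, mean_fluortotal=mean_ft)


def mols_cplus(fcplus: float | np.ndarray, calib: CalibrationFactor) -> float | np.ndarray:
    """Surplus molecule count at midcell: ``FCPlus · F``."""
    return fcplus * calib.F


# ---------------------------------------------------------------------------
# statistics and qualifiers


def age_binned_stats(
    results: pd.DataFrame,
    column: str,
    bin_pct: float = 5.0,
    confidence: float = 0.95,
) -> pd.DataFrame:
    """Per-age-bin mean and t-based confidence interval of ``column``.

    Bins cover [0, 100]% in ``bin_pct`` steps (last bin closed).  Rows carry
    ``age_mid``, ``n``, ``mean``, ``ci_lo``, ``ci_hi``; bins with n < 2 get
    NaN CIs.
    """
    qualified = results[results["qualified"]]
    edges = np.arange(0.0, 100.0 + bin_pct / 2, bin_pct)
    rows = []
    ages = qualified["age_pct"].to_numpy()
    vals = qualified[column].to_numpy()
    for i in range(len(edges) - 1):
        lo, hi = edges[i], edges[i + 1]
        if i == len(edges) - 2:
            sel = (ages >= lo) & (ages <= hi)
        else:
            sel = (ages >= lo) & (ages < hi)
        v = vals[sel]
        v = v[~np.isnan(v)]
        n = v.size
        mean = float(v.mean()) if n else np.nan
        if n >= 2:
            sem = v.std(ddof=1) / np.sqrt(n)
            tcrit = sstats.t.ppf(0.5 + confidence / 2.0, n - 1)
            ci_lo, ci_hi = mean - tcrit * sem, mean + tcrit * sem
        else:
            ci_lo = ci_hi = np.nan
        rows.append(
            {"age_mid": (lo + hi) / 2.0, "n": n, "mean": mean,
             "ci_lo": ci_lo, "ci_hi": ci_hi}
        )
    return pd.DataFrame(rows)


def qualify(
    results: pd.DataFrame,
    predicate: Callable[[pd.DataFrame], pd.Series] | str,
) -> pd.DataFrame:
    """Disqualify cells matched by ``predicate`` (rows are retained).

    ``predicate`` is either a pandas query string or a callable returning a
    boolean mask of cells to *disqualify*.  Statistics, sorting and maps use
    only qualified cells; flags can be cleared with
    :func:`clear_qualifiers`.
    """
    out = results.copy()
    if isinstance(predicate, str):
        mask = out.eval(predicate)
    else:
        mask = predicate(out)
    mask = np.asarray(mask, dtype=bool)
    out.loc[mask, "qualified"] = False
    if not out["qualified"].any():
        warnings.warn("all cells disqualified; statistics will be empty",
                      stacklevel=2)
    out.attrs = dict(results.attrs)
    return out


def clear_qualifiers(results: pd.DataFrame) -> pd.DataFrame:
    """Re-qualify every cell (restores the original statistics exactly)."""
    out = results.copy()
    out["qualified"] = True
    out.attrs = dict(results.attrs)
    return out
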
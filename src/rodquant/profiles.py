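"""The Map of Profiles: per-cell 1-px-wide axial vectors.

Each accepted cell contributes one column per channel: fluorescence channels
hold the disk-integrated brightness of the 1-px-thick band perpendicular to
the axis at each axis sample (including light slightly outside the contour,
out to a PSF-derived margin); the phase-derived channel holds the local
diameter in μm.  The map can be sorted (short → long), oriented so the
bright pole of a leader channel points to index 0, resampled to a normalized
100-point length, and averaged per age group into collective profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .segment import CellObject

__all__ = [
    "ProfileColumn",
    "ProfileMap",
    "build_profile_map",
    "sort_map",
    "orient_by_leader",
    "resample_to_norm",
    "collective_profiles",
]

log = logging.getLogger(__name__)


@dataclass
class ProfileColumn:
    """Per-channel axial vectors of one cell."""

    cell_id: int
    fluor: dict[int, np.ndarray]  # channel index -> vector (len = axis samples)
    diameter: np.ndarray  # μm per axis sample
    flipped: bool = False
    qualified: bool = True

    @property
    def length(self) -> int:
        return len(self.diameter)


@dataclass
class ProfileMap:
    """Ordered collection of per-cell profile columns.

    ``order`` is the current display permutation (indices into ``columns``).
    Rendering to an image pads each column symmetrically (vertical centering);
    the per-cell top padding is recorded for provenance.
    """

    columns: list[ProfileColumn] = field(default_factory=list)
    order: list[int] = field(default_factory=list)
    px_per_um: float = 14.98

    def __post_init__(self) -> None:
        if not self.order:
            self.order = list(range(len(self.columns)))

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def channels(self) -> list[int]:
        return sorted(self.columns[0].fluor) if self.columns else []

    def ordered_columns(self, qualified_only: bool = False) -> list[ProfileColumn]:
        cols = [self.columns[i] for i in self.order]
        if qualified_only:
            cols = [c for c in cols if c.qualified]
        return cols

    def fluor_totals(self, channel: int) -> dict[int, float]:
        """Σ of the fluorescence vector per cell id (equals FluorTotal)."""
        return {c.cell_id: float(c.fluor[channel].sum()) for c in self.columns}

    def to_image(
        self, channel: Optional[int] = None, qualified_only: bool = False
    ) -> tuple[np.ndarray, list[int]]:
        """Render one channel as a float32 image (cells as centered columns).

        ``channel=None`` renders the diameter channel.  Returns the image and
        the per-column top-padding counts.
        """
        cols = self.ordered_columns(qualified_only)
        if not cols:
            return np.zeros((0, 0), dtype=np.float32), []
        height = max(c.length for c in cols)
        img = np.zeros((height, len(cols)), dtype=np.float32)
        pads = []
        for j, c in enumerate(cols):
            vec = c.diameter if channel is None else c.fluor[channel]
            top = (height - len(vec)) // 2
            img[top : top + len(vec), j] = vec
            pads.append(top)
        return img, pads


def _assign_pixels_to_axes(
    cells: Sequence[CellObject],
    image_shape: tuple[int, int],
    margin_px: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Nearest-axis-sample assignment of every pixel near any cell.

    Returns flat pixel indices plus (cell index, axis sample) labels.  Pixels
    in the overlap of two dilated contours go to the nearest cell's axis.
    """
    H, W = image_shape
    union = np.zeros((H, W), dtype=bool)
    for cell in cells:
        y0, x0, y1, x1 = cell.bbox
        g = np.zeros((H, W), dtype=bool)
        g[y0:y1, x0:x1] = cell.mask
        union |= g
    if margin_px > 0:
        union = ndimage.binary_dilation(union, iterations=margin_px)
    pix_y, pix_x = np.nonzero(union)

    pts = []
    owner = []
    sample = []
    for ci, cell in enumerate(cells):
        pts.append(cell.axis)
        owner.append(np.full(len(cell.axis), ci))
        sample.append(np.arange(len(cell.axis)))
    tree = cKDTree(np.concatenate(pts))
    owner = np.concatenate(owner)
    sample = np.concatenate(sample)
    _, idx = tree.query(np.column_stack([pix_x, pix_y]), workers=-1)
    return pix_y, pix_x, owner[idx], sample[idx]


def build_profile_map(
    cells: Sequence[CellObject],
    fluorescence_images: dict[int, np.ndarray],
    px_per_um: float,
    margin_px: int = 4,
) -> ProfileMap:
    """Build the Map of Profiles from accepted cells.

    For each axis sample, the profile value integrates all fluorescence in
    the 1-px-thick band perpendicular to the axis, implemented as a
    nearest-axis-sample assignment of every pixel within the cell contour
    dilated by ``margin_px`` (the PSF margin).  Overlapping dilated regions
    of neighbouring cells are split by nearest-cell assignment, so the total
    signal in the image is conserved across columns.  Cells whose dilated
    footprint touches the image border are excluded and logged.
    """
    accepted = [c for c in cells if c.accepted]
    if not fluorescence_images:
        raise ValueError("at least one fluorescence channel is required")
    shape = next(iter(fluorescence_images.values())).shape
    H, W = shape

    usable = []
    for c in accepted:
        y0, x0, y1, x1 = c.bbox
        if (
            y0 - margin_px < 0
            or x0 - margin_px < 0
            or y1 + margin_px > H
            or x1 + margin_px > W
        ):
            log.warning("cell %d touches the border within the PSF margin; excluded", c.id)
            continue
        usable.append(c)
    if not usable:
        return ProfileMap([], [], px_per_um)

    pix_y, pix_x, owner, sample = _assign_pixels_to_axes(usable, shape, margin_px)
    columns = []
    for ci, cell in enumerate(usable):
        n = len(cell.axis)
        sel = owner == ci
        fluor = {}
        for ch, img in fluorescence_images.items():
            vec = np.zeros(n)
            np.add.at(vec, sample[sel], img[pix_y[sel], pix_x[sel]].astype(float))
            fluor[ch] = vec
        columns.append(
            ProfileColumn(cell_id=cell.id, fluor=fluor, diameter=cell.diameters.copy())
        )
    return ProfileMap(columns, list(range(len(columns))), px_per_um)


def sort_map(
    pmap: ProfileMap,
    key: Optional[dict[int, float] | Callable[[ProfileColumn], float]] = None,
    qualified_only: bool = False,
) -> ProfileMap:
    """Return a map sorted ascending by ``key`` (default: axis length).

    ``key`` may be a per-cell-id mapping (e.g. a results-table column) or a
    callable on columns.  Sorting is stable: equal keys keep the original
    order.  With ``qualified_only``, disqualified columns are dropped.
    """
    cols = [pmap.columns[i] for i in pmap.order]
    if qualified_only:
        cols = [c for c in cols if c.qualified]
    if key is None:
        keyfunc = lambda c: c.length  # noqa: E731
    elif callable(key):
        keyfunc = key
    else:
        keyfunc = lambda c: key[c.cell_id]  # noqa: E731
    cols = sorted(cols, key=keyfunc)  # python sort is stable
    return ProfileMap(cols, list(range(len(cols))), pmap.px_per_um)


def orient_by_leader(pmap: ProfileMap, leader_channel: int) -> ProfileMap:
    """Flip cells so the bright pole of the leader channel is at index 0.

    A cell is reversed (all channels and the diameter vector together) when
    the summed leader fluorescence in its second half exceeds the first
    half; ties keep the original orientation.  Idempotent.
    """
    new_cols = []
    for c in pmap.ordered_columns():
        vec = c.fluor[leader_channel]
        half = len(vec) // 2
        first = float(vec[:half].sum())
        second = float(vec[len(vec) - half :].sum())
        if second > first:
            new_cols.append(
                ProfileColumn(
                    cell_id=c.cell_id,
                    fluor={ch: v[::-1].copy() for ch, v in c.fluor.items()},
                    diameter=c.diameter[::-1].copy(),
                    flipped=not c.flipped,
                    qualified=c.qualified,
                )
            )
        else:
            new_cols.append(c)
    return ProfileMap(new_cols, list(range(len(new_cols))), pmap.px_per_um)


def resample_to_norm(profile: np.ndarray, npoints: int = 100) -> np.ndarray:
    """Resample a profile to ``npoints`` bins, conserving the total signal.

    Implemented as linear interpolation of the cumulative sum at the new bin
    edges followed by differencing, so Σ output = Σ input to machine
    precision regardless of the length ratio.
    """
    v = np.asarray(profile, dtype=float)
    if v.size < 2:
        raise ValueError("profile must have at least 2 samples")
    cum = np.concatenate([[0.0], np.cumsum(v)])
    edges_in = np.linspace(0.0, 1.0, v.size + 1)
    edges_out = np.linspace(0.0, 1.0, npoints + 1)
    return np.diff(np.interp(edges_out, edges_in, cum))


def collective_profiles(
    pmap: ProfileMap,
    channel: int,
    ages: dict[int, float],
    n_age_groups: int = 10,
    npoints: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean normalized profiles per age group.

    ``ages`` maps cell id → age in % (0..100).  Cells are binned into
    ``n_age_groups`` equal age intervals (half-open, last closed); each
    group's 100-point resampled profiles are averaged.  Empty groups yield
    NaN profiles with count 0 (logged).  Returns ``(stack, counts)`` with
    ``stack`` of shape (n_age_groups, npoints).
    """
    if n_age_groups < 1:
        raise ValueError("n_age_groups must be >= 1")
    edges = np.linspace(0.0, 100.0, n_age_groups + 1)
    stack = np.full((n_age_groups, npoints), np.nan)
    counts = np.zeros(n_age_groups, dtype=int)
    groups: list[list[np.ndarray]] = [[] for _ in range(n_age_groups)]
    for c in pmap.ordered_columns(qualified_only=True):
        if c.cell_id not in ages:
            continue
        a = ages[c.cell_id]
        g = int(np.searchsorted(edges, a, side="right")) - 1
        g = min(max(g, 0), n_age_groups - 1)
        groups[g].append(resample_to_norm(c.fluor[channel], npoints))
    for g, profs in enumerate(groups):
        if profs:
            stack[g] = np.mean(profs, axis=0)
            counts[g] = len(profs)
        else:
            log.warning("age group %d/%d is empty", g + 1, n_age_groups)
    return stack, counts
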
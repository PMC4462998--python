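"""Synthetic steady-state populations of capsule-shaped cells.

Renders phase-contrast + fluorescence hyperstacks with full per-cell ground
truth, so the whole measurement chain (segmentation, geometry, profiling,
quantification) can be validated without any acquired data.

The population model is the classical steady-state age distribution of an
exponentially growing culture: the age density is ``2 ln2 · 2^(−a)`` on
``a ∈ [0, 1)``, with CDF ``2(1 − 2^(−a))``.  Individual cells grow
exponentially in length at constant diameter; a dividing cell develops a
central constriction modelled as a Gaussian notch in the local diameter.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from ._errors import CapacityError

__all__ = [
    "GrowthParams",
    "PatternSpec",
    "OpticsSpec",
    "SyntheticScene",
    "sample_population",
    "render_scene",
    "steady_state_age_cdf",
    "steady_state_age_ppf",
]

#: Localization pattern kinds understood by the renderer.
PATTERN_KINDS = (
    "cytoplasmic_uniform",
    "membrane_uniform",
    "midcell_ring",
    "polar_gradient",
)


def steady_state_age_cdf(age: np.ndarray | float) -> np.ndarray | float:
    """CDF of division-cycle age in a steady-state culture: ``2(1 − 2^(−a))``."""
    return 2.0 * (1.0 - np.exp2(-np.asarray(age, dtype=float)))


def steady_state_age_ppf(u: np.ndarray | float) -> np.ndarray | float:
    """Inverse CDF: ``a = 1 − log2(2 − u)`` for ``u ∈ [0, 1)``."""
    return 1.0 - np.log2(2.0 - np.asarray(u, dtype=float))


@dataclass(frozen=True)
class GrowthParams:
    """Single-cell growth geometry over one division cycle.

    Parameters
    ----------
    birth_length:
        Pole-to-pole length of a newborn cell, μm.
    birth_diameter:
        Cell diameter, μm; constant over the cycle apart from constriction.
    doubling:
        Length at division divided by birth length (2 for binary fission).
    constriction_onset_age:
        Cycle age (fraction, 0..1) at which the septum starts to close.
    constriction_depth:
        Fractional diameter reduction at the constriction site reached at
        division (age 1); ramps linearly from onset.
    constriction_sigma:
        Axial half-width (Gaussian sigma, μm) of the diameter notch.
    length_cv:
        Multiplicative lognormal-ish noise on length (coefficient of
        variation); 0 gives the deterministic length–age relation.
    """

    birth_length: float = 2.0
    birth_diameter: float = 1.0
    doubling: float = 2.0
    constriction_onset_age: float = 0.6
    constriction_depth: float = 0.5
    constriction_sigma: float = 0.15
    length_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.birth_length <= 0:
            raise ValueError("birth_length must be positive")
        if not 0.0 < self.constriction_onset_age < 1.0:
            raise ValueError("constriction_onset_age must lie in (0, 1)")
        if not 0.0 <= self.constriction_depth < 1.0:
            raise ValueError("constriction_depth must lie in [0, 1)")


@dataclass(frozen=True)
class PatternSpec:
    """Fluorescence localization pattern for one channel.

    ``molecules`` is the copy number of the *average* cell; per cell the count
    scales with cell volume (cytoplasmic/polar kinds) or envelope area
    (membrane kind) so that the population has constant concentration, except
    for ``midcell_ring`` where the ring holds a fixed count per cell.
    ``ramp`` adds a linear fractional concentration change over the cycle
    (+0.3 = 30% higher concentration at division than at birth).
    ``onset_age`` delays the pattern (used for rings that assemble mid-cycle).
    """

    kind: str = "cytoplasmic_uniform"
    molecules: float = 1000.0
    ramp: float = 0.0
    onset_age: float = 0.0
    ring_sigma: float = 0.05  # axial spread of the midcell ring, μm
    gradient_scale: float = 0.25  # e-folding length of polar gradient, cell lengths

    def __post_init__(self) -> None:
        if self.kind not in PATTERN_KINDS:
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if self.molecules < 0:
            raise ValueError("molecules must be >= 0")
        if self.ramp < -1:
            raise ValueError("ramp must be >= -1")


@dataclass(frozen=True)
class OpticsSpec:
    """Imaging model: sampling, PSF, photon yield, background and noise."""

    px_per_um: float = 14.98
    psf_sigma: float = 0.08  # μm; ~wide-field 100x/1.35 oil
    photons_per_molecule: float = 20.0  # AU per molecule: per-pixel SNR >> 1
    background_level: float = 50.0
    noise_sd: float = 2.0
    channel_shift: tuple[float, float] = (0.0, 0.0)  # (dx, dy) px, fluor only
    poisson_noise: bool = False
    phase_background: float = 180.0
    phase_depth: float = 120.0

    def __post_init__(self) -> None:
        if self.px_per_um <= 0:
            raise ValueError("px_per_um must be positive")
        if self.psf_sigma < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma and noise_sd must be >= 0")


@dataclass
class SyntheticScene:
    """Rendered hyperstack plus ground truth.

    Attributes
    ----------
    hyperstack:
        float32 array, shape (channels, H, W); channel 0 is phase contrast.
    truth:
        One row per cell: position, orientation, age, true length/diameter,
        per-channel molecule totals and midcell surplus.
    seed:
        RNG seed used for rendering.
    params:
        All generation parameters, JSON-serializable.
    """

    hyperstack: np.ndarray
    truth: pd.DataFrame
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def px_per_um(self) -> float:
        return float(self.params.get("optics", {}).get("px_per_um", 14.98))

    def save(self, directory: str | Path, stem: str = "scene") -> dict[str, Path]:
        """Write TIFF hyperstack, truth CSV and parameter JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        tiff_path = directory / f"{stem}.tif"
        res = self.px_per_um
        tifffile.imwrite(
            tiff_path,
            self.hyperstack.astype(np.float32),
            imagej=True,
            resolution=(res, res),
            metadata={"unit": "um", "axes": "CYX"},
        )
        csv_path = directory / f"{stem}_truth.csv"
        self.truth.to_csv(csv_path, index=False)
        json_path = directory / f"{stem}_params.json"
        with open(json_path, "w") as fh:
            json.dump({"seed": self.seed, **self.params}, fh, indent=2)
        return {"tiff": tiff_path, "truth": csv_path, "params": json_path}


# ---------------------------------------------------------------------------
# population sampling


def sample_population(
    n: int,
    growth: GrowthParams = GrowthParams(),
    seed: int = 0,
) -> pd.DataFrame:
    """Draw ``n`` cells from the steady-state age distribution.

    Returns a DataFrame with columns ``age`` (0..1), ``length_um``,
    ``diameter_um`` and ``constriction_depth`` (fractional notch depth at the
    sampled age).  Length follows ``birth_length · doubling^age`` with
    optional multiplicative noise of coefficient of variation ``length_cv``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    age = np.asarray(steady_state_age_ppf(u), dtype=float)
    length = growth.birth_length * growth.doubling**age
    if growth.length_cv > 0:
        sigma = np.sqrt(np.log1p(growth.length_cv**2))
        length = length * rng.lognormal(-0.5 * sigma**2, sigma, size=n)
    depth = np.where(
        age >= growth.constriction_onset_age,
        growth.constriction_depth
        * (age - growth.constriction_onset_age)
        / (1.0 - growth.constriction_onset_age),
        0.0,
    )
    return pd.DataFrame(
        {
            "age": age,
            "length_um": length,
            "diameter_um": np.full(n, growth.birth_diameter),
            "constriction_depth": depth,
        }
    )


# ---------------------------------------------------------------------------
# capsule geometry helpers (axial coordinate s in μm, s ∈ [0, L])


def _radius_profile(
    s: np.ndarray, length: float, radius: float, depth: float, notch_sigma: float
) -> np.ndarray:
    """Local radius of a capsule with hemispherical caps and a midcell notch."""
    s = np.asarray(s, dtype=float)
    r_cyl = radius * (
        1.0 - depth * np.exp(-((s - length / 2.0) ** 2) / (2.0 * notch_sigma**2))
    )
    cap0 = np.where(s < radius, np.sqrt(np.maximum(radius**2 - (radius - s) ** 2, 0.0)), np.inf)
    cap1 = np.where(
        s > length - radius,
        np.sqrt(np.maximum(radius**2 - (s - (length - radius)) ** 2, 0.0)),
        np.inf,
    )
    r = np.minimum(r_cyl, np.minimum(cap0, cap1))
    return np.where((s < 0) | (s > length), 0.0, np.maximum(r, 0.0))


def _cell_volume_area(length: float, radius: float, depth: float, notch_sigma: float,
                      ds: float = 0.005) -> tuple[float, float]:
    """True volume (μm³) and envelope area (μm²) by fine disk/frustum sums."""
    s = np.arange(ds / 2, length, ds)
    r = _radius_profile(s, length, radius, depth, notch_sigma)
    vol = float(np.sum(np.pi * r**2) * ds)
    dr = np.gradient(r, ds)
    area = float(np.sum(2.0 * np.pi * r * np.sqrt(1.0 + dr**2)) * ds)
    return vol, area


def _segment_distance(p0, p1, q0, q1) -> float:
    """Minimum distance between two 2D segments."""
    from shapely.geometry import LineString

    return float(LineString([tuple(p0), tuple(p1)]).distance(LineString([tuple(q0), tuple(q1)])))


# ---------------------------------------------------------------------------
# molecule sampling per pattern


def _sample_axial(rng, length, radius, depth, notch_sigma, n, weight):
    """Rejection-sample axial positions with density ∝ ``weight(r(s), s)``."""
    out = np.empty(0)
    # proposal: uniform on [0, L]; bound the weight on a fine grid
    grid = np.linspace(0, length, 512)
    rg = _radius_profile(grid, length, radius, depth, notch_sigma)
    wmax = float(np.max(weight(rg, grid))) or 1.0
    while out.size < n:
        m = max(int((n - out.size) * 2.5), 64)
        s = rng.random(m) * length
        r = _radius_profile(s, length, radius, depth, notch_sigma)
        keep = rng.random(m) * wmax < weight(r, s)
        out = np.concatenate([out, s[keep]])
    return out[:n]


def _molecule_positions(
    rng: np.random.Generator,
    pattern: PatternSpec,
    n_mol: int,
    length: float,
    radius: float,
    depth: float,
    notch_sigma: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (s, t) positions in μm: s axial from pole 0, t in-plane offset.

    3D placement is reduced to its 2D projection: cytoplasmic molecules are
    uniform in the capsule volume, membrane molecules uniform on the surface,
    and the projection keeps the in-plane component of the radial offset.
    """
    if n_mol == 0:
        return np.empty(0), np.empty(0)
    kind = pattern.kind
    if kind == "cytoplasmic_uniform":
        s = _sample_axial(rng, length, radius, depth, notch_sigma, n_mol,
                          lambda r, _s: r**2)
        r_loc = _radius_profile(s, length, radius, depth, notch_sigma)
        # uniform in the disk cross-section, projected onto the image plane
        rho = np.sqrt(rng.random(n_mol))
        phi = rng.random(n_mol) * 2 * np.pi
        t = r_loc * rho * np.cos(phi)
    elif kind == "membrane_uniform":
        def w(r, s):
            dr = np.gradient(_radius_profile(
                np.linspace(0, length, 512), length, radius, depth, notch_sigma),
                length / 511)
            slope = np.interp(s, np.linspace(0, length, 512), dr)
            return r * np.sqrt(1 + slope**2)
        s = _sample_axial(rng, length, radius, depth, notch_sigma, n_mol, w)
        r_loc = _radius_profile(s, length, radius, depth, notch_sigma)
        phi = rng.random(n_mol) * 2 * np.pi
        t = r_loc * np.sin(phi)
    elif kind == "midcell_ring":
        s = np.clip(rng.normal(length / 2.0, pattern.ring_sigma, n_mol), 0, length)
        r_loc = _radius_profile(s, length, radius, depth, notch_sigma)
        phi = rng.random(n_mol) * 2 * np.pi
        t = r_loc * np.sin(phi)
    elif kind == "polar_gradient":
        lam = pattern.gradient_scale * length
        s = _sample_axial(rng, length, radius, depth, notch_sigma, n_mol,
                          lambda r, sv: r**2 * np.exp(-sv / lam))
        r_loc = _radius_profile(s, length, radius, depth, notch_sigma)
        rho = np.sqrt(rng.random(n_mol))
        phi = rng.random(n_mol) * 2 * np.pi
        t = r_loc * rho * np.cos(phi)
    else:  # pragma: no cover - guarded by PatternSpec
        raise ValueError(kind)
    return s, t


def _molecule_count(
    pattern: PatternSpec,
    age: float,
    volume: float,
    area: float,
    mean_volume: float,
    mean_area: float,
) -> int:
    """Per-cell copy number implied by the pattern's concentration model."""
    if age < pattern.onset_age:
        return 0
    ramp_factor = (1.0 + pattern.ramp * age) / (1.0 + 0.5 * pattern.ramp)
    if pattern.kind == "midcell_ring":
        n = pattern.molecules * ramp_factor
    elif pattern.kind == "membrane_uniform":
        n = pattern.molecules * (area / mean_area) * ramp_factor
    else:
        n = pattern.molecules * (volume / mean_volume) * ramp_factor
    return int(round(n))


# ---------------------------------------------------------------------------
# scene rendering


def _place_cells(
    cells: pd.DataFrame,
    px_per_um: float,
    shape: tuple[int, int] | None,
    clearance_px: float,
    edge_margin_px: float,
    rng: np.random.Generator,
    touching_pairs: int = 0,
    max_tries: int = 400,
) -> tuple[pd.DataFrame, tuple[int, int]]:
    """Assign random non-overlapping positions/orientations; append touching pairs."""
    n = len(cells)
    lengths_px = cells["length_um"].to_numpy() * px_per_um
    radii_px = cells["diameter_um"].to_numpy() / 2.0 * px_per_um
    if shape is None:
        # target packing fraction ~0.22 of bounding boxes incl. clearance
        boxes = (lengths_px + 2 * radii_px + 2 * clearance_px) * (
            2 * radii_px + 2 * clearance_px
        )
        budget = boxes.sum()
        if touching_pairs:
            budget += touching_pairs * 6 * float(np.median(boxes))
        side = int(np.ceil(np.sqrt(budget / 0.22))) + int(2 * edge_margin_px) + 4
        side = max(side, 128)
        shape = (side, side)
    H, W = shape

    placed: list[tuple[np.ndarray, np.ndarray, float]] = []  # (p0, p1, radius)
    xs, ys, thetas = [], [], []
    for i in range(n):
        L, r = lengths_px[i], radii_px[i]
        half = L / 2.0
        lo = edge_margin_px + half + r
        ok = False
        for _ in range(max_tries):
            cx = rng.uniform(lo, W - lo)
            cy = rng.uniform(lo, H - lo)
            th = rng.uniform(0, np.pi)
            u = np.array([np.cos(th), np.sin(th)])
            p0 = np.array([cx, cy]) - half * u
            p1 = np.array([cx, cy]) + half * u
            if all(
                _segment_distance(p0, p1, q0, q1) >= r + rr + clearance_px
                for q0, q1, rr in placed
            ):
                placed.append((p0, p1, r))
                xs.append(cx)
                ys.append(cy)
                thetas.append(th)
                ok = True
                break
        if not ok:
            raise CapacityError(
                f"could not place cell {i} of {n} in a {H}x{W} image after "
                f"{max_tries} tries; enlarge the image or reduce n"
            )
    out = cells.copy()
    out["x_px"] = xs
    out["y_px"] = ys
    out["theta"] = thetas
    out["touching_pair"] = -1

    # deliberately fused pairs appended after the main population
    pair_rows = []
    med = cells.median(numeric_only=True)
    for k in range(touching_pairs):
        L_um, d_um = float(med["length_um"]), float(med["diameter_um"])
        L, r = L_um * px_per_um, d_um / 2.0 * px_per_um
        lo_pair = edge_margin_px + L + 2 * r
        for _ in range(max_tries):
            cx = rng.uniform(lo_pair, W - lo_pair)
            cy = rng.uniform(lo_pair, H - lo_pair)
            th = rng.uniform(0, np.pi)
            dth = np.deg2rad(40.0)
            # two capsules joined at one pole, bent by 40 degrees
            u1 = np.array([np.cos(th), np.sin(th)])
            u2 = np.array([np.cos(th + dth), np.sin(th + dth)])
            joint = np.array([cx, cy])
            c1 = joint - u1 * L / 2.0
            c2 = joint + u2 * L / 2.0
            segs = [
                (joint - u1 * L, joint, r),
                (joint, joint + u2 * L, r),
            ]
            if all(
                _segment_distance(s0, s1, q0, q1) >= r + rr + clearance_px
                for (s0, s1, _r2) in segs
                for (q0, q1, rr) in placed
            ):
                placed.extend(segs)
                for cc, uu in ((c1, u1), (c2, u2)):
                    pair_rows.append(
                        {
                            "age": 0.5,
                            "length_um": L_um,
                            "diameter_um": d_um,
                            "constriction_depth": 0.0,
                            "x_px": cc[0],
                            "y_px": cc[1],
                            "theta": float(np.arctan2(uu[1], uu[0])),
                            "touching_pair": k,
                        }
                    )
                break
        else:
            raise CapacityError("could not place touching pair")
    if pair_rows:
        out = pd.concat([out, pd.DataFrame(pair_rows)], ignore_index=True)
    return out, shape


def _splat(img: np.ndarray, x: np.ndarray, y: np.ndarray, w: float) -> None:
    """Bilinear deposition of unit masses × w at subpixel (x, y)."""
    H, W = img.shape
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx = x - x0
    fy = y - y0
    for dx, dy, wt in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        xi = x0 + dx
        yi = y0 + dy
        ok = (xi >= 0) & (xi < W) & (yi >= 0) & (yi < H)
        np.add.at(img, (yi[ok], xi[ok]), w * wt[ok])


def _render_capsule_coverage(
    shape: tuple[int, int],
    cx: float,
    cy: float,
    theta: float,
    length_px: float,
    radius_px: float,
    depth: float,
    notch_sigma_px: float,
) -> tuple[slice, slice, np.ndarray]:
    """Analytic per-pixel coverage (0..1) of one capsule, on a local crop."""
    H, W = shape
    pad = int(np.ceil(length_px / 2 + radius_px + 3))
    x0 = max(int(cx) - pad, 0)
    x1 = min(int(cx) + pad + 1, W)
    y0 = max(int(cy) - pad, 0)
    y1 = min(int(cy) + pad + 1, H)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    u = np.array([np.cos(theta), np.sin(theta)])
    nvec = np.array([-u[1], u[0]])
    relx = xx - cx
    rely = yy - cy
    s = relx * u[0] + rely * u[1] + length_px / 2.0  # axial coord, px
    t = relx * nvec[0] + rely * nvec[1]
    r = _radius_profile(s, length_px, radius_px, depth, notch_sigma_px)
    cov = np.clip(r - np.abs(t) + 0.5, 0.0, 1.0)
    # pole regions beyond the axis: distance to the pole tip
    return slice(y0, y1), slice(x0, x1), cov


def render_scene(
    cells: pd.DataFrame,
    patterns: Sequence[PatternSpec],
    optics: OpticsSpec = OpticsSpec(),
    seed: int = 0,
    shape: tuple[int, int] | None = None,
    clearance_px: float = 3.0,
    touching_pairs: int = 0,
    notch_sigma_um: float = 0.15,
    midcell_halfwidth_um: float = 0.4,
) -> SyntheticScene:
    """Render a population into a phase + fluorescence hyperstack.

    ``cells`` comes from :func:`sample_population` (positions are assigned
    here unless ``x_px``/``y_px``/``theta`` columns are already present).
    ``patterns`` gives one :class:`PatternSpec` (or a list of them, summed)
    per fluorescence channel; the hyperstack has ``1 + len(patterns)``
    channels with phase contrast first.

    Before noise, each fluorescence channel integrates to
    ``Σ molecules × photons_per_molecule`` (photon conservation under PSF
    blur, up to truncation at the image border).  ``optics.channel_shift``
    is applied to fluorescence channels only.
    """
    rng = np.random.default_rng(seed)
    s_px = optics.px_per_um

    # normalize patterns: each channel may be a single spec or a list
    chan_patterns: list[list[PatternSpec]] = [
        list(p) if isinstance(p, (list, tuple)) else [p] for p in patterns
    ]

    edge_margin = 3.0 * optics.psf_sigma * s_px + 3.0
    if {"x_px", "y_px", "theta"}.issubset(cells.columns):
        truth = cells.copy()
        if "touching_pair" not in truth:
            truth["touching_pair"] = -1
        if shape is None:
            ext = (truth["length_um"] / 2 + truth["diameter_um"] / 2) * s_px
            side = int(np.ceil(max(
                (truth["x_px"] + ext).max(), (truth["y_px"] + ext).max()
            ) + edge_margin)) + 2
            shape = (side, side)
    else:
        truth, shape = _place_cells(
            cells, s_px, shape, clearance_px, edge_margin, rng, touching_pairs
        )
    H, W = shape
    n_chan = 1 + len(chan_patterns)
    stack = np.zeros((n_chan, H, W), dtype=np.float64)

    notch_sigma_px = notch_sigma_um * s_px
    lengths = truth["length_um"].to_numpy()
    radii = truth["diameter_um"].to_numpy() / 2.0
    depths = truth["constriction_depth"].to_numpy()
    ages = truth["age"].to_numpy()

    # true volume / envelope area per cell (μm units)
    vols = np.empty(len(truth))
    areas = np.empty(len(truth))
    for i in range(len(truth)):
        vols[i], areas[i] = _cell_volume_area(
            lengths[i], radii[i], depths[i], notch_sigma_um
        )
    truth = truth.assign(volume_um3=vols, envelope_um2=areas)
    mean_vol = float(vols.mean())
    mean_area = float(areas.mean())

    # phase channel: dark capsules on bright background
    phase = np.full((H, W), 0.0)
    for i in range(len(truth)):
        ys, xs, cov = _render_capsule_coverage(
            shape,
            truth["x_px"].iat[i],
            truth["y_px"].iat[i],
            truth["theta"].iat[i],
            lengths[i] * s_px,
            radii[i] * s_px,
            depths[i],
            notch_sigma_px,
        )
        phase[ys, xs] = np.maximum(phase[ys, xs], cov)
    stack[0] = optics.phase_background - optics.phase_depth * phase

    # fluorescence channels: molecule splats, then PSF blur
    mol_totals = np.zeros((len(truth), len(chan_patterns)))
    surpluses = np.zeros((len(truth), len(chan_patterns)))
    hw = midcell_halfwidth_um
    for ci, specs in enumerate(chan_patterns):
        img = stack[1 + ci]
        for i in range(len(truth)):
            L, r, dep = lengths[i], radii[i], depths[i]
            u = np.array([np.cos(truth["theta"].iat[i]), np.sin(truth["theta"].iat[i])])
            nvec = np.array([-u[1], u[0]])
            pole0 = (
                np.array([truth["x_px"].iat[i], truth["y_px"].iat[i]])
                - u * L * s_px / 2.0
            )
            # midcell/remainder true volumes for the surplus bookkeeping
            ds = 0.005
            sgrid = np.arange(ds / 2, L, ds)
            rg = _radius_profile(sgrid, L, r, dep, notch_sigma_um)
            in_mid = np.abs(sgrid - L / 2.0) <= hw
            v_mid = float(np.sum(np.pi * rg[in_mid] ** 2) * ds)
            v_rest = float(np.sum(np.pi * rg[~in_mid] ** 2) * ds)
            for spec in specs:
                n_mol = _molecule_count(spec, ages[i], vols[i], areas[i],
                                        mean_vol, mean_area)
                if n_mol == 0:
                    continue
                s_um, t_um = _molecule_positions(
                    rng, spec, n_mol, L, r, dep, notch_sigma_um
                )
                pos = (
                    pole0[None, :]
                    + np.outer(s_um * s_px, u)
                    + np.outer(t_um * s_px, nvec)
                )
                _splat(img, pos[:, 0], pos[:, 1], optics.photons_per_molecule)
                mol_totals[i, ci] += n_mol
                n_mid = int(np.sum(np.abs(s_um - L / 2.0) <= hw))
                n_rest = n_mol - n_mid
                if v_rest > 0:
                    surpluses[i, ci] += n_mid - n_rest * v_mid / v_rest
                else:
                    surpluses[i, ci] += n_mid
        if optics.psf_sigma > 0:
            ndimage.gaussian_filter(
                img, optics.psf_sigma * s_px, output=img, mode="constant"
            )
        dx, dy = optics.channel_shift
        if dx or dy:
            f = np.fft.rfft2(img)
            f = ndimage.fourier_shift(f, shift=(dy, dx), n=W)
            img[:] = np.fft.irfft2(f, s=img.shape)
        img += optics.background_level

    # phase PSF blur
    if optics.psf_sigma > 0:
        ndimage.gaussian_filter(
            stack[0], optics.psf_sigma * s_px, output=stack[0], mode="nearest"
        )

    # noise
    if optics.poisson_noise:
        stack[1:] = rng.poisson(np.maximum(stack[1:], 0.0)).astype(float)
    if optics.noise_sd > 0:
        stack += rng.normal(0.0, optics.noise_sd, stack.shape)

    for ci in range(len(chan_patterns)):
        truth[f"molecules_ch{ci + 1}"] = mol_totals[:, ci]
        truth[f"midcell_surplus_ch{ci + 1}"] = surpluses[:, ci]

    params = {
        "optics": dataclasses.asdict(optics),
        "patterns": [[dataclasses.asdict(s) for s in specs] for specs in chan_patterns],
        "shape": list(shape),
        "clearance_px": clearance_px,
        "touching_pairs": touching_pairs,
        "notch_sigma_um": notch_sigma_um,
    }
    truth.insert(0, "cell", np.arange(len(truth)))
    return SyntheticScene(
        hyperstack=stack.astype(np.float32), truth=truth, seed=seed, params=params
    )
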
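"""End-to-end analysis pipeline.

Order of operations (one frame at a time): modal background subtraction →
cell detection on phase contrast → fluorescence registration → profile map →
age assignment → per-cell metrics → qualifiers → age-binned statistics →
outputs.  Deterministic given (config, input): reruns produce byte-identical
CSVs.
"""

from __future__ import annotations

import collections
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as rio
from . import quant
from .config import RunConfig
from .profiles import ProfileMap, build_profile_map, collective_profiles, orient_by_leader, sort_map
from .segment import CellObject, detect_cells

__all__ = ["PipelineResult", "analyze_stack", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """All in-memory products of one analysis run."""

    results: pd.DataFrame
    pmap: ProfileMap
    cells: list[CellObject]
    shifts: dict[int, tuple[int, int]]
    rejection_tally: dict[str, int]
    collective: dict[int, np.ndarray] = field(default_factory=dict)
    collective_counts: dict[int, np.ndarray] = field(default_factory=dict)


def analyze_stack(stack: np.ndarray, config: RunConfig) -> PipelineResult:
    """Analyze a (C, H, W) or (C, T, H, W) hyperstack in memory."""
    if stack.ndim == 3:
        stack = stack[:, None, :, :]
    n_chan, n_frames = stack.shape[:2]
    scale = config.px_per_um
    if scale is None:
        raise ValueError("px_per_um must be resolved before analysis")

    all_cells: list[CellObject] = []
    columns = []
    shifts: dict[int, tuple[int, int]] = {}
    tally: collections.Counter = collections.Counter()
    id_offset = 0
    for t in range(n_frames):
        phase = stack[config.phase_channel, t]
        cells = detect_cells(phase, scale, config.criteria, frame=t)
        for c in cells:
            c.id += id_offset
            if not c.accepted:
                tally[c.reason] += 1
        id_offset += len(cells) + 1
        accepted = [c for c in cells if c.accepted]
        fluor_images = {}
        for ch in config.fluor_channels:
            img = quant.subtract_modal_background(stack[ch, t])
            if accepted:
                shift = quant.register_fluorescence(
                    accepted, img, config.registration_max_shift
                )
                shifts[ch] = shift
                img = quant.apply_shift(img, shift)
            fluor_images[ch] = img
        if accepted:
            fmap = build_profile_map(
                accepted, fluor_images, scale, margin_px=config.psf_margin_px
            )
            columns.extend(fmap.columns)
        all_cells.extend(cells)

    pmap = ProfileMap(columns, list(range(len(columns))), scale)
    results = quant.build_results_table(
        all_cells, pmap, config.channel_classes, config.midcell_halfwidth
    )
    if config.qualifier and len(results):
        results = quant.qualify(results, config.qualifier)
    for col in pmap.columns:
        if len(results):
            row = results[results["cell"] == col.cell_id]
            if len(row):
                col.qualified = bool(row["qualified"].iloc[0])

    if config.leader_channel is not None and len(pmap):
        pmap = orient_by_leader(pmap, config.leader_channel)
    if len(results):
        key = dict(zip(results["cell"], results["axis_length_um"]))
        pmap = sort_map(pmap, key=key, qualified_only=False)

    result = PipelineResult(
        results=results,
        pmap=pmap,
        cells=all_cells,
        shifts=shifts,
        rejection_tally=dict(tally),
    )
    if len(results) >= 2:
        ages = dict(zip(results.loc[results["qualified"], "cell"],
                        results.loc[results["qualified"], "age_pct"]))
        for ch in config.fluor_channels:
            stack_profiles, counts = collective_profiles(
                pmap, ch, ages, config.n_age_groups
            )
            result.collective[ch] = stack_profiles
            result.collective_counts[ch] = counts
    return result


def _write_plots(result: PipelineResult, config: RunConfig, outdir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    res = result.results
    if len(res) < 2:
        return paths
    for ch in config.fluor_channels:
        cls = config.channel_classes.get(ch, "volume")
        col = f"conctotal_ch{ch}" if cls == "volume" else f"concwall_ch{ch}"
        stats = quant.age_binned_stats(res, col, config.age_bin_pct)
        fig, ax = plt.subplots(figsize=(5, 4))
        q = res[res["qualified"]]
        ax.plot(q["age_pct"], q[col], "k.", ms=2, alpha=0.4)
        ax.errorbar(
            stats["age_mid"], stats["mean"],
            yerr=[stats["mean"] - stats["ci_lo"], stats["ci_hi"] - stats["mean"]],
            fmt="o-", color="crimson", lw=1.2, ms=3, capsize=2,
        )
        ax.set_xlabel("cell age (%)")
        unit = "FluorUnit/μm³" if cls == "volume" else "FluorUnit/μm²"
        ax.set_ylabel(f"concentration ({unit})")
        ax.set_title(f"channel {ch}: concentration vs age")
        p = outdir / f"concentration_vs_age_ch{ch}.png"
        fig.tight_layout()
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)

        if ch in result.collective:
            fig, ax = plt.subplots(figsize=(5, 4))
            prof = result.collective[ch]
            for g in range(prof.shape[0]):
                ax.plot(np.linspace(0, 100, prof.shape[1]),
                        prof[g] + 0.1 * g * np.nanmax(prof),
                        label=f"group {g + 1}")
            ax.set_xlabel("relative axis position (%)")
            ax.set_ylabel("mean profile (stacked)")
            ax.set_title(f"channel {ch}: collective profiles")
            p = outdir / f"collective_profiles_ch{ch}.png"
            fig.tight_layout()
            fig.savefig(p, dpi=120)
            plt.close(fig)
            paths.append(p)
    return paths


def run_pipeline(config: RunConfig) -> int:
    """Run the full pipeline from a hyperstack file; returns exit status."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        stack, scale = rio.read_hyperstack(config.input_path, config.px_per_um)
        config.px_per_um = scale
        result = analyze_stack(stack, config)
    except Exception as exc:  # noqa: BLE001 - CLI boundary
        log.error("pipeline failed: %s", exc)
        return 1
    rio.write_results_csv(outdir / "results.csv", result.results)
    rio.write_profile_map_tiff(outdir / "profile_map.tif", result.pmap)
    _write_plots(result, config, outdir)
    rio.write_run_log(
        outdir / "run_log.json",
        {
            "config": config.to_dict(),
            "n_cells_total": len(result.cells),
            "n_accepted": int(sum(c.accepted for c in result.cells)),
            "rejection_tally": result.rejection_tally,
            "registration_shifts": {str(k): list(v) for k, v in result.shifts.items()},
        },
    )
    log.info(
        "analyzed %d objects (%d accepted) -> %s",
        len(result.cells), sum(c.accepted for c in result.cells), outdir,
    )
    return 0
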
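"""Shared fixtures: small synthetic scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import rodquant as rq
from rodquant.synthgen import OpticsSpec, PatternSpec

SCALE = 14.98  # px per μm used throughout the fixtures


@pytest.fixture(scope="session")
def clean_scene():
    """50 well-separated cells, uniform cytoplasmic label, no noise."""
    pop = rq.sample_population(50, seed=11)
    return rq.render_scene(
        pop,
        [PatternSpec("cytoplasmic_uniform", molecules=1000)],
        OpticsSpec(noise_sd=0.0),
        seed=12,
    )


@pytest.fixture(scope="session")
def clean_cells(clean_scene):
    """Accepted CellObjects detected on the clean scene's phase channel."""
    return [
        c
        for c in rq.detect_cells(clean_scene.hyperstack[0], SCALE)
        if c.accepted
    ]


@pytest.fixture(scope="session")
def clean_pmap(clean_scene, clean_cells):
    fl = rq.subtract_modal_background(clean_scene.hyperstack[1])
    return rq.build_profile_map(clean_cells, {1: fl}, SCALE, margin_px=4)


@pytest.fixture(scope="session")
def ring_analysis():
    """100 cells with a midcell ring assembling at age >= 0.5; full analysis."""
    pop = rq.sample_population(100, seed=21)
    scene = rq.render_scene(
        pop,
        [PatternSpec("midcell_ring", molecules=300, onset_age=0.5)],
        OpticsSpec(noise_sd=1.0),
        seed=22,
    )
    cells = [
        c for c in rq.detect_cells(scene.hyperstack[0], SCALE) if c.accepted
    ]
    fl = rq.subtract_modal_background(scene.hyperstack[1])
    pmap = rq.build_profile_map(cells, {1: fl}, SCALE, margin_px=4)
    results = rq.build_results_table(cells, pmap)
    return scene, cells, pmap, results
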
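"""Shared fixtures: toy gene models, a small designed library and a
counts-level simulated screen.  All data is generated programmatically."""

from __future__ import annotations

import pandas as pd
import pytest

from pegsensor import simdata
from pegsensor.pipeline import DesignParams, design_library
from pegsensor.sensor import export_library
from pegsensor.variant_io import (
    GeneModel,
    dedupe_variants,
    generate_silent_controls,
    parse_variant_table,
)


@pytest.fixture(scope="session")
def toy_gene() -> GeneModel:
    return simdata.simulate_gene(seed=7, length=300)


@pytest.fixture(scope="session")
def dense_gene() -> GeneModel:
    """Poly-G coding gene: a plus-strand NGG PAM at every interior position,
    so any nick offset is reachable for a mid-gene variant."""
    sequence = "ATG" + "GGG" * 78 + "TAA"
    return GeneModel("dense", sequence, [(0, len(sequence))])


@pytest.fixture(scope="session")
def small_screen_library():
    """Designed library on a toy gene: patient-style variants plus silent
    controls, three designs per variant; returns (gene, variants, manifest)."""
    gene = simdata.simulate_gene(seed=11, length=2400)
    table = simdata.simulate_variant_table(
        gene, n_snv=80, n_ins=10, n_del=10, seed=11
    )
    variants, _ = parse_variant_table(table, gene)
    variants = dedupe_variants(
        variants + generate_silent_controls(gene, 95)
    )
    designs, _ = design_library(
        gene, variants, DesignParams(max_per_variant=3)
    )
    manifest = export_library(
        designs, variant_classes={v.id: v.vclass for v in variants}
    )
    return gene, variants, manifest


@pytest.fixture(scope="session")
def counts_screen(small_screen_library):
    """Counts-level simulated screen with known truth on the small library."""
    _, _, manifest = small_screen_library
    truth = simdata.SimTruth.generate(manifest, seed=3, depth=300)
    counts, summaries, design_truth = simdata.simulate_counts(manifest, truth)
    return manifest, truth, counts, summaries, design_truth


CONTROLS = ["ctrl_r1", "ctrl_r2", "ctrl_r3"]
TREATED = ["trt_r1", "trt_r2", "trt_r3"]


@pytest.fixture(scope="session")
def sample_names():
    return CONTROLS, TREATED
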
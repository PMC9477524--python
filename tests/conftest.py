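"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from clonesift.benchmark import run_two_clone_study
from clonesift.pileup_io import BASE_TO_CODE, Pileup, build_pileup_from_arrays
from clonesift.sim import CloneSpec, SimConfig, simulate_population


def make_pileup(
    records: list[tuple[int, int, int, str, int]],
    n_cells: int,
    genome_length: int = 10_000,
    min_base_qual: int = 0,
) -> Pileup:
    """Hand-built pileup from (gpos, cell, frag, base, qual) rows."""
    if records:
        gpos, cell, frag, base, qual = zip(*records)
    else:
        gpos = cell = frag = base = qual = ()
    return build_pileup_from_arrays(
        np.array(gpos, dtype=np.int64),
        np.array(cell, dtype=np.int32),
        np.array(frag, dtype=np.int32),
        np.array([BASE_TO_CODE[b] for b in base], dtype=np.uint8),
        np.array(qual, dtype=np.uint8),
        chrom_names=["chr1"],
        chrom_lengths=[genome_length],
        n_cells=n_cells,
        min_base_qual=min_base_qual,
    )


def locus_with_counts(counts_by_base: dict[str, int], gpos: int, start_cell: int = 0):
    """Observation rows realizing the given pooled counts, one cell each."""
    rows = []
    cell = start_cell
    for base, n in counts_by_base.items():
        for _ in range(n):
            rows.append((gpos, cell, 0, base, 37))
            cell += 1
    return rows, cell


@pytest.fixture(scope="session")
def small_two_clone():
    """Two clones of 100 cells on 200 kb at 0.1x with 200 private SNVs."""
    config = SimConfig(
        genome_length_bp=200_000,
        clone_specs=[
            CloneSpec("healthy", None, 100, 0),
            CloneSpec("tumor", "healthy", 100, 200),
        ],
        per_cell_coverage=0.1,
        seed=11,
    )
    result = simulate_population(config)
    return config, result, result.pileup()


@pytest.fixture(scope="session")
def study():
    """The standard two-subclone study at full desk scale (seed 1).

    One full pipeline run shared by the integration and acceptance
    tests: 500 + 500 cells, 2 Mb genome, 600 clone-private SNVs,
    0.05x per-cell coverage, 1% sequencing error.
    """
    return run_two_clone_study(seed=1)
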
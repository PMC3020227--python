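"""Shared fixtures: hand-built toy panels and small simulated panels."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from panelpop import GenotypePanel, SimConfig, make_panel


def build_panel(calls, chroms=None, positions=None, pops=None, habits=None,
                genomes=None):
    """Assemble a panel from plain lists; sensible defaults everywhere.

    ``calls`` is an (n_lines x n_loci) array-like with entries in
    {0,1,2,-1}; loci default to a single chromosome '1A' at 1 cM spacing;
    lines default to two populations split evenly between winter/spring.
    """
    calls = np.asarray(calls, dtype=np.int8)
    n_lines, n_loci = calls.shape
    if chroms is None:
        chroms = ["1A"] * n_loci
    if positions is None:
        positions = [float(j) for j in range(n_loci)]
    if genomes is None:
        genomes = [c[-1] for c in chroms]
    loci = pd.DataFrame(
        {
            "locus_id": [f"L{j:03d}" for j in range(n_loci)],
            "genome": genomes,
            "chromosome": chroms,
            "position_cM": positions,
        }
    )
    if pops is None:
        half = n_lines // 2
        pops = ["P1"] * half + ["P2"] * (n_lines - half)
    if habits is None:
        habit_of = {}
        for p in pops:
            habit_of.setdefault(p, "winter" if len(habit_of) % 2 == 0 else "spring")
        habits = [habit_of[p] for p in pops]
    lines = pd.DataFrame(
        {
            "line_id": [f"I{i:03d}" for i in range(n_lines)],
            "population": pops,
            "growth_habit": habits,
        }
    )
    return make_panel(lines, loci, calls)


def small_sim_config(seed, **overrides) -> SimConfig:
    """A fast simulation config: 4 pops x 25 lines, 4 chromosomes."""
    defaults = dict(
        group_labels=("winter", "spring"),
        lines_per_population=((25, 25), (25, 25)),
        chromosomes=tuple(
            (f"{i}{g}", g, 100.0) for g in ("A", "B") for i in (1, 2)
        ),
        loci_per_chromosome=50,
        planted_regions=(("2A", 40.0, 60.0, 0.4),),
    )
    defaults.update(overrides)
    return SimConfig(seed=seed, **defaults)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def random_panel(rng) -> GenotypePanel:
    """A 40-line x 30-locus random panel over 2 chromosomes, 4 populations."""
    calls = rng.choice([0, 1, 2, -1], size=(40, 30), p=[0.45, 0.02, 0.5, 0.03])
    pops = (["A1"] * 10 + ["A2"] * 10 + ["B1"] * 10 + ["B2"] * 10)
    habits = ["winter"] * 20 + ["spring"] * 20
    chroms = ["1A"] * 15 + ["2B"] * 15
    positions = [float(3 * j) for j in range(15)] * 2
    return build_panel(calls, chroms=chroms, positions=positions,
                       pops=pops, habits=habits)
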
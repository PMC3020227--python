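"""Report-table helpers: assay accounting and panel-level arithmetic.

These functions compute the bookkeeping percentages a genotyping-panel
survey reports — assay conversion rates, polymorphism percentages per
genome, call-state fractions, and the share of loci polymorphic in both
growth-habit groups — either from a panel or from printed counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GenotypePanel

__all__ = [
    "assay_accounting",
    "prop_polymorphic_in_both",
    "shared_polymorphism_from_counts",
]


def assay_accounting(rows) -> pd.DataFrame:
    """Genome-level assay accounting (Total assayed / failed / good /
    polymorphic) with derived percentages and a totals row.

    ``rows`` is an iterable of dicts with keys ``genome, n_assayed,
    n_failed, n_polymorphic``.  Derived columns: ``n_good = n_assayed -
    n_failed``, ``pct_conversion = 100 * n_good / n_assayed`` and
    ``pct_polymorphic = 100 * n_polymorphic / n_good``.
    """
    df = pd.DataFrame(list(rows))
    df["n_good"] = df["n_assayed"] - df["n_failed"]
    if (df["n_good"] < df["n_polymorphic"]).any():
        raise ValueError("more polymorphic than good SNPs")
    total = {
        "genome": "total",
        "n_assayed": int(df["n_assayed"].sum()),
        "n_failed": int(df["n_failed"].sum()),
        "n_polymorphic": int(df["n_polymorphic"].sum()),
        "n_good": int(df["n_good"].sum()),
    }
    df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    df["pct_conversion"] = 100.0 * df["n_good"] / df["n_assayed"]
    df["pct_polymorphic"] = 100.0 * df["n_polymorphic"] / df["n_good"]
    return df[
        ["genome", "n_assayed", "n_failed", "n_good", "n_polymorphic",
         "pct_conversion", "pct_polymorphic"]
    ]


def prop_polymorphic_in_both(panel: GenotypePanel, habits=("spring", "winter")) -> float:
    """Fraction of panel loci polymorphic within *each* growth-habit group."""
    both = np.ones(panel.n_loci, dtype=bool)
    for habit in habits:
        both &= panel.by_growth_habit(habit).n_observed_alleles() >= 2
    return float(both.mean())


def shared_polymorphism_from_counts(n_polymorphic: int, n_mono_a: int, n_mono_b: int) -> float:
    """Fraction polymorphic in both groups from per-group monomorphic counts.

    Assumes the two monomorphic sets are disjoint (each panel-polymorphic
    locus fixed in at most one group), so the shared-polymorphism count is
    ``n_polymorphic - n_mono_a - n_mono_b``.
    """
    shared = n_polymorphic - n_mono_a - n_mono_b
    if shared < 0:
        raise ValueError("monomorphic counts exceed polymorphic total")
    return shared / n_polymorphic
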
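"""Per-locus and per-stratum diversity statistics.

Covers the descriptive layer of a SNP-panel survey: polymorphism
information content (PIC), proportions of polymorphic loci, mean minor
allele frequency and mean observed alleles per locus, computed for the
whole panel, per growth-habit group or per breeding population, plus minor
allele frequency spectra and their chi-square comparison between groups.

For biallelic loci PIC = 1 - p^2 - (1-p)^2 equals the expected
heterozygosity (gene diversity); lines contribute one haploid allele copy
each, with heterozygous calls treated as missing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "pic",
    "diversity_table",
    "maf_spectrum",
    "spectrum_chi2",
    "MafSpectrum",
]


def pic(frequencies) -> float:
    """Polymorphism information content ``1 - sum(p_i^2)``.

    ``frequencies`` are allele frequencies summing to 1.  For a biallelic
    locus the maximum is 0.5, attained at p = 0.5; a monomorphic locus
    scores 0.
    """
    p = np.asarray(frequencies, dtype=float)
    if (p < 0).any():
        raise ValueError("negative allele frequency")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies sum to {p.sum()}, not 1")
    return float(1.0 - np.sum(p**2))


def _stratum_row(sub: GenotypePanel) -> dict:
    """Diversity statistics over one stratum of lines.

    Loci with no observed (homozygous) call in the stratum are counted as
    monomorphic: 1 allele, MAF 0, PIC 0.  Monomorphic loci stay in the
    denominators so that stratum means are comparable across strata sharing
    the same locus panel.
    """
    p = sub.allele_freq()
    n_alleles = sub.n_observed_alleles()
    n_alleles = np.maximum(n_alleles, 1)  # no-call loci count as monomorphic
    maf = np.where(np.isnan(p), 0.0, np.minimum(p, 1.0 - p))
    pic_vals = np.where(np.isnan(p), 0.0, 1.0 - p**2 - (1.0 - p) ** 2)
    poly = n_alleles >= 2
    return {
        "n_lines": sub.n_lines,
        "n_loci": sub.n_loci,
        "proportion_polymorphic": float(poly.mean()),
        "mean_maf": float(maf.mean()),
        "mean_alleles_per_locus": float(n_alleles.mean()),
        "mean_pic": float(pic_vals.mean()),
    }


def diversity_table(
    panel: GenotypePanel,
    stratification: str = "population",
    min_lines: int = 5,
) -> pd.DataFrame:
    """Diversity statistics per stratum.

    ``stratification`` is ``"population"``, ``"growth_habit"`` or
    ``"total"``.  Strata with fewer than ``min_lines`` lines are excluded
    with a logged warning (small samples make polymorphism proportions
    incomparable).  The returned frame has one row per stratum with columns
    ``stratum, growth_habit, n_lines, proportion_polymorphic, mean_maf,
    mean_alleles_per_locus, mean_pic``.
    """
    rows = []
    if stratification == "total":
        rows.append({"stratum": "total", "growth_habit": "", **_stratum_row(panel)})
    elif stratification in ("population", "growth_habit"):
        for value in pd.unique(panel.lines[stratification]):
            mask = (panel.lines[stratification] == value).to_numpy()
            sub = panel.subset_lines(mask)
            habit = sub.lines["growth_habit"].iloc[0] if stratification == "population" else value
            if sub.n_lines < min_lines:
                logger.warning(
                    "stratum %r excluded: %d lines < min_lines=%d",
                    value, sub.n_lines, min_lines,
                )
                continue
            rows.append({"stratum": value, "growth_habit": habit, **_stratum_row(sub)})
    else:
        raise ValueError(f"unknown stratification {stratification!r}")
    if not rows:
        raise ValueError("no stratum satisfies min_lines")
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MafSpectrum:
    """Histogram of minor allele frequencies over polymorphic loci."""

    group: str
    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def n_loci(self) -> int:
        return int(self.counts.sum())


def maf_spectrum(
    panel: GenotypePanel, group: str | None = None, bin_width: float = 0.05
) -> MafSpectrum:
    """MAF histogram for one growth-habit group (or the pooled panel).

    Bins partition [0, 0.5] with half-open intervals ``[lo, hi)`` and a
    closed last bin so MAF = 0.5 is counted.  Only loci polymorphic within
    the group (MAF > 0) enter the histogram.
    """
    sub = panel if group is None else panel.by_growth_habit(group)
    maf = sub.maf()
    maf = maf[~np.isnan(maf) & (maf > 0)]
    if maf.size == 0:
        raise ValueError("no polymorphic loci in group")
    n_bins = int(round(0.5 / bin_width))
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    counts, _ = np.histogram(maf, bins=edges)  # np.histogram closes the last bin
    return MafSpectrum(group=group or "total", bin_edges=edges, counts=counts)


def spectrum_chi2(spec_a: MafSpectrum, spec_b: MafSpectrum) -> tuple[float, int, float]:
    """Pearson chi-square comparing two MAF spectra.

    The two histograms form a 2 x B contingency table; bins empty in both
    groups are dropped before computing degrees of freedom.  Returns
    ``(chi2, df, p)``.
    """
    if not np.allclose(spec_a.bin_edges, spec_b.bin_edges):
        raise ValueError("spectra have different bin edges")
    obs = np.vstack([spec_a.counts, spec_b.counts]).astype(float)
    keep = obs.sum(axis=0) > 0
    obs = obs[:, keep]
    if obs.shape[1] < 2:
        raise ValueError("fewer than 2 informative bins; use coarser bins")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    expected = row @ col / obs.sum()
    if (expected == 0).any():
        raise ValueError("zero expected count; use coarser bins")
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = obs.shape[1] - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    return chi2, df, p
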
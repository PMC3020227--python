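"""Pairwise linkage disequilibrium on a mapped inbred-line panel.

Because the lines are (near-)fully homozygous, a line's genotype at a
locus identifies its haplotype allele, so two-locus haplotype counts are
read directly from the genotype matrix — no phasing.  For a pair of
biallelic loci with haplotype counts ``(n11, n12, n21, n22)`` over the
lines complete at both loci:

* ``D = f11 - p q`` with ``f11 = n11/n``, ``p``/``q`` the allele-1
  margins; ``r^2 = D^2 / (p(1-p) q(1-q))``, the squared allele-frequency
  correlation.
* ``D' = |D| / D_max`` with the usual frequency-dependent bound, and a
  two-sided 90% confidence interval from the normalized multinomial
  likelihood over a |D'| grid (the Gabriel/Haploview convention).
* Significance by the two-sided Fisher exact probability of the 2x2 table,
  with Benjamini-Hochberg control of the false discovery rate across the
  whole pair universe.

On top of the pair table the module computes intra/inter-chromosomal LD
summaries, the loess decay curve with its half-decay distance, background
LD (95th percentile of inter-chromosomal r^2) and haplotype blocks by the
Gabriel D'-confidence-bound rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import GenotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "GabrielParams",
    "haplotype_counts",
    "r_squared",
    "d_prime",
    "d_prime_ci",
    "exact_test",
    "bh_fdr",
    "ld_pair_table",
    "ld_summary",
    "decay_curve",
    "DecayCurve",
    "gabriel_blocks",
]

#: Sentinel for a half-decay distance the fitted curve never reaches.
NOT_REACHED = float("inf")


def haplotype_counts(panel: GenotypePanel, locus_i: str, locus_j: str) -> np.ndarray:
    """2x2 haplotype count table for a pair of loci.

    Counts lines homozygous (non-missing, non-het) at *both* loci, as
    ``[[n_11, n_12], [n_21, n_22]]`` where index 1 is allele 1 (call 0)
    and index 2 is allele 2 (call 2).
    """
    ji = int(np.flatnonzero(panel.locus_ids == locus_i)[0])
    jj = int(np.flatnonzero(panel.locus_ids == locus_j)[0])
    a, b = panel.calls[:, ji], panel.calls[:, jj]
    return _counts_from_calls(a, b)


def _counts_from_calls(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ok = ((a == 0) | (a == 2)) & ((b == 0) | (b == 2))
    a, b = a[ok] == 2, b[ok] == 2
    return np.array(
        [
            [int((~a & ~b).sum()), int((~a & b).sum())],
            [int((a & ~b).sum()), int((a & b).sum())],
        ]
    )


def _margins(counts: np.ndarray):
    n = counts.sum()
    p1 = counts[0].sum() / n  # allele 1 at locus i
    q1 = counts[:, 0].sum() / n  # allele 1 at locus j
    D = counts[0, 0] / n - p1 * q1
    return n, p1, q1, D


def r_squared(counts) -> float:
    """Squared allele-frequency correlation r^2 from a 2x2 haplotype table.

    Equals the squared Pearson correlation of the two 0/1 allele vectors.
    Raises ``ValueError`` if either margin is monomorphic.
    """
    counts = np.asarray(counts, dtype=float)
    n, p1, q1, D = _margins(counts)
    denom = p1 * (1 - p1) * q1 * (1 - q1)
    if denom == 0:
        raise ValueError("monomorphic margin: r^2 undefined")
    return float(D * D / denom)


def d_prime(counts) -> float:
    """Normalized disequilibrium coefficient |D'| in [0, 1]."""
    counts = np.asarray(counts, dtype=float)
    n, p1, q1, D = _margins(counts)
    if p1 in (0.0, 1.0) or q1 in (0.0, 1.0):
        raise ValueError("monomorphic margin: D' undefined")
    d_max = _d_max(p1, q1, D)
    return float(abs(D) / d_max) if d_max > 0 else 0.0


def _d_max(p1: float, q1: float, D: float) -> float:
    if D < 0:
        return min(p1 * q1, (1 - p1) * (1 - q1))
    return min(p1 * (1 - q1), (1 - p1) * q1)


def d_prime_ci(counts, grid_size: int = 1000, level: float = 0.90):
    """|D'| with a two-sided likelihood confidence interval.

    The multinomial likelihood of the observed table is evaluated on a
    grid of |D'| values in [0, 1] (margins fixed at their MLEs, sign of D
    fixed at the observed sign), normalized to a unit mass, and the CI
    bounds are taken where the cumulative mass crosses ``(1-level)/2`` and
    ``1-(1-level)/2`` (5% and 95% for the default 90% interval).  Returns
    ``(dprime, low, high)``.
    """
    counts = np.asarray(counts, dtype=float)
    n, p1, q1, D = _margins(counts)
    if p1 in (0.0, 1.0) or q1 in (0.0, 1.0):
        raise ValueError("monomorphic margin: D' undefined")
    d_max = _d_max(p1, q1, D)
    point = float(abs(D) / d_max) if d_max > 0 else 0.0
    sign = -1.0 if D < 0 else 1.0

    grid = np.linspace(0.0, 1.0, grid_size + 1)
    d_vals = sign * grid * d_max
    # haplotype frequencies as a function of D' (clipped away from 0 for logs)
    f11 = p1 * q1 + d_vals
    f12 = p1 * (1 - q1) - d_vals
    f21 = (1 - p1) * q1 - d_vals
    f22 = (1 - p1) * (1 - q1) + d_vals
    freqs = np.clip(np.stack([f11, f12, f21, f22]), 1e-12, None)
    loglik = (counts.reshape(4, 1) * np.log(freqs)).sum(axis=0)
    lik = np.exp(loglik - loglik.max())
    post = lik / lik.sum()
    cum = np.cumsum(post)
    alpha = (1.0 - level) / 2.0
    low = float(grid[int(np.searchsorted(cum, alpha))])
    high = float(grid[int(np.searchsorted(cum, 1.0 - alpha))])
    return point, low, high


def exact_test(counts) -> float:
    """Two-sided Fisher exact probability of a 2x2 haplotype table.

    Sums the hypergeometric probabilities (margins fixed) of every table
    whose probability does not exceed that of the observed table (with a
    relative tolerance of 1e-7 for ties).
    """
    counts = np.asarray(counts, dtype=int)
    n = int(counts.sum())
    r1 = int(counts[0].sum())
    c1 = int(counts[:, 0].sum())
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[int(counts[0, 0]) - lo]
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def bh_fdr(p_values, q: float = 0.01):
    """Benjamini-Hochberg step-up at level ``q``.

    Returns ``(reject, q_values)``: boolean flags and monotone-adjusted
    q-values ``min_{k>=rank}(m p_(k) / k)`` capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    qvals_sorted = np.minimum.accumulate((m * ranked / np.arange(1, m + 1))[::-1])[::-1]
    qvals_sorted = np.minimum(qvals_sorted, 1.0)
    below = ranked <= q * np.arange(1, m + 1) / m
    k_max = int(np.flatnonzero(below)[-1]) + 1 if below.any() else 0
    reject_sorted = np.zeros(m, dtype=bool)
    reject_sorted[:k_max] = True
    reject = np.empty(m, dtype=bool)
    qvals = np.empty(m)
    reject[order] = reject_sorted
    qvals[order] = qvals_sorted
    return reject, qvals


# ---------------------------------------------------------------------- #
# the pair table
# ---------------------------------------------------------------------- #
def ld_pair_table(
    panel: GenotypePanel,
    min_complete: int = 10,
    fdr_q: float = 0.01,
    with_dprime_ci: bool = False,
    max_span_cM: float | None = None,
) -> pd.DataFrame:
    """All pairwise LD records for a (pre-filtered) panel.

    One row per locus pair with enough complete lines: r^2, |D'|, exact-
    test p, BH q-value and rejection flag (FDR applied once over the whole
    intra+inter pair universe), and the pair distance in cM
    (``NaN`` for inter-chromosomal pairs, flagged by ``intra=False``).
    D' confidence bounds are computed on request, optionally only for
    intra-chromosomal pairs within ``max_span_cM`` (they are only needed
    for block detection).
    """
    L = panel.n_loci
    calls = panel.calls
    chrom = panel.loci["chromosome"].to_numpy()
    pos = panel.loci["position_cM"].to_numpy()
    ids = panel.locus_ids
    rows = []
    n_skipped = 0
    for i in range(L):
        for j in range(i + 1, L):
            counts = _counts_from_calls(calls[:, i], calls[:, j])
            n = int(counts.sum())
            if n < min_complete:
                n_skipped += 1
                continue
            if counts[0].sum() in (0, n) or counts[:, 0].sum() in (0, n):
                n_skipped += 1  # monomorphic margin among complete lines
                continue
            intra = chrom[i] == chrom[j]
            dist = abs(pos[i] - pos[j]) if intra else np.nan
            row = {
                "locus_i": ids[i],
                "locus_j": ids[j],
                "chromosome_i": chrom[i],
                "chromosome_j": chrom[j],
                "intra": bool(intra),
                "distance_cM": dist,
                "n_complete": n,
                "r2": r_squared(counts),
                "p_exact": exact_test(counts),
            }
            if with_dprime_ci and (
                intra and (max_span_cM is None or dist <= max_span_cM)
            ):
                dp, lo, hi = d_prime_ci(counts)
                row.update({"dprime": dp, "dprime_low": lo, "dprime_high": hi})
            else:
                row["dprime"] = d_prime(counts)
            rows.append(row)
    if n_skipped:
        logger.info("skipped %d pairs (too few complete lines or monomorphic margin)",
                    n_skipped)
    pairs = pd.DataFrame(rows)
    if len(pairs):
        reject, qvals = bh_fdr(pairs["p_exact"].to_numpy(), q=fdr_q)
        pairs["q_bh"] = qvals
        pairs["significant"] = reject
    return pairs


def ld_summary(pairs: pd.DataFrame, per_locus: bool = False) -> dict:
    """Summary of significant LD and background LD from a pair table.

    * mean/median cM distance of BH-significant intra-chromosomal pairs
      (the "extent of significant LD"); with ``per_locus=True`` the
      mean/median is taken over each locus's maximum significant distance
      instead of over pairs;
    * proportion of loci with at least one significant linked pair;
    * proportion of inter-chromosomal pairs significant;
    * background LD: the 95th percentile of all inter-chromosomal r^2;
    * realized r^2 significance cutoff: the smallest r^2 among significant
      pairs (the panel-specific threshold the FDR implies).
    """
    intra = pairs[pairs["intra"]]
    inter = pairs[~pairs["intra"]]
    sig_intra = intra[intra["significant"]]

    if len(sig_intra):
        if per_locus:
            both = pd.concat(
                [
                    sig_intra[["locus_i", "distance_cM"]].rename(columns={"locus_i": "locus"}),
                    sig_intra[["locus_j", "distance_cM"]].rename(columns={"locus_j": "locus"}),
                ]
            )
            dist = both.groupby("locus")["distance_cM"].max()
        else:
            dist = sig_intra["distance_cM"]
        mean_extent = float(dist.mean())
        median_extent = float(dist.median())
    else:
        mean_extent = median_extent = np.nan

    loci_linked = set(intra["locus_i"]) | set(intra["locus_j"])
    loci_sig = set(sig_intra["locus_i"]) | set(sig_intra["locus_j"])
    prop_loci_sig = len(loci_sig) / len(loci_linked) if loci_linked else np.nan
    prop_inter_sig = float(inter["significant"].mean()) if len(inter) else np.nan
    background = (
        float(np.percentile(inter["r2"].to_numpy(), 95)) if len(inter) else np.nan
    )
    sig_all = pairs[pairs["significant"]]
    r2_cutoff = float(sig_all["r2"].min()) if len(sig_all) else np.nan
    return {
        "n_pairs": len(pairs),
        "n_intra": len(intra),
        "n_inter": len(inter),
        "n_significant_intra": len(sig_intra),
        "mean_extent_cM": mean_extent,
        "median_extent_cM": median_extent,
        "prop_loci_with_significant_linked_pair": prop_loci_sig,
        "prop_inter_significant": prop_inter_sig,
        "background_ld": background,
        "realized_r2_cutoff": r2_cutoff,
    }


# ---------------------------------------------------------------------- #
# decay curve
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class DecayCurve:
    """Loess fit of r^2 against distance with its half-decay distance.

    ``half_decay_cM`` is ``NOT_REACHED`` (inf) when the fitted curve never
    falls to half its initial value.
    """

    grid_cM: np.ndarray
    fitted_r2: np.ndarray
    initial_ld: float
    half_decay_cM: float

    @property
    def reached(self) -> bool:
        return np.isfinite(self.half_decay_cM)


def decay_curve(pairs: pd.DataFrame, span: float = 0.5, min_pairs: int = 30) -> DecayCurve:
    """Loess decay of intra-chromosomal r^2 with genetic distance.

    Locally weighted linear regression (degree 1, tricube weights,
    ``span`` fraction of points per fit) of r^2 on cM distance.  The
    initial LD is the fitted value at the smallest observed distance and
    the half-decay distance is where the curve first drops to half of it,
    linearly interpolated between grid points.
    """
    intra = pairs[pairs["intra"]]
    if len(intra) < min_pairs:
        raise ValueError(
            f"need at least {min_pairs} intra-chromosomal pairs, have {len(intra)}"
        )
    x = intra["distance_cM"].to_numpy(dtype=float)
    y = intra["r2"].to_numpy(dtype=float)
    fit = lowess(y, x, frac=span, return_sorted=True)
    grid, fitted = fit[:, 0], fit[:, 1]
    # collapse duplicate distances (lowess returns one row per point)
    grid, idx = np.unique(grid, return_index=True)
    fitted = fitted[idx]
    initial = float(fitted[0])
    target = 0.5 * initial
    half = NOT_REACHED
    below = fitted <= target
    if below.any():
        k = int(np.flatnonzero(below)[0])
        if k == 0:
            half = float(grid[0])
        else:
            x0, x1 = grid[k - 1], grid[k]
            y0, y1 = fitted[k - 1], fitted[k]
            half = float(x0 + (target - y0) * (x1 - x0) / (y1 - y0)) if y1 != y0 else float(x1)
    return DecayCurve(grid_cM=grid, fitted_r2=fitted, initial_ld=initial,
                      half_decay_cM=half)


# ---------------------------------------------------------------------- #
# Gabriel blocks
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class GabrielParams:
    """Thresholds of the D'-confidence-bound block rule.

    A pair is "strong LD" when its CI is ``[>= ci_low_strong,
    >= ci_high_strong]``, "strong recombination" when the CI upper bound
    is below ``ci_high_recomb``; a candidate run is accepted when at least
    ``min_informative_frac`` of its informative pairs are strong-LD.
    """

    ci_low_strong: float = 0.70
    ci_high_strong: float = 0.98
    ci_high_recomb: float = 0.90
    min_informative_frac: float = 0.95
    max_span_cM: float = 30.0


def gabriel_blocks(
    pairs: pd.DataFrame,
    loci: pd.DataFrame,
    params: GabrielParams = GabrielParams(),
) -> pd.DataFrame:
    """Haplotype blocks by the Gabriel D'-confidence-bound rule.

    A candidate block is a map-contiguous run of loci whose outermost pair
    is strong-LD; it is accepted when >= ``min_informative_frac`` of its
    informative pairs (strong-LD or strong-recombination) are strong-LD.
    Overlapping candidates are resolved longest-span-first, ties leftmost.
    Returns ``chromosome, start_cM, end_cM, n_loci, locus_ids``.
    """
    need = {"dprime_low", "dprime_high"}
    if not need <= set(pairs.columns):
        raise ValueError("pairs table lacks D' confidence bounds; "
                         "build it with with_dprime_ci=True")
    usable = pairs[pairs["intra"] & pairs["dprime_low"].notna()]
    strength = {}
    for rec in usable.itertuples():
        strong = (
            rec.dprime_low >= params.ci_low_strong
            and rec.dprime_high >= params.ci_high_strong
        )
        recomb = rec.dprime_high < params.ci_high_recomb
        strength[(rec.locus_i, rec.locus_j)] = (
            "strong" if strong else "recomb" if recomb else "uninformative"
        )

    def pair_class(a: str, b: str):
        return strength.get((a, b)) or strength.get((b, a))

    candidates = []
    for chrom, sub in loci.groupby("chromosome", sort=False):
        ids = sub["locus_id"].to_numpy()
        pos = sub["position_cM"].to_numpy()
        L = len(ids)
        for i in range(L):
            for j in range(i + 1, L):
                if pos[j] - pos[i] > params.max_span_cM:
                    break
                if pair_class(ids[i], ids[j]) != "strong":
                    continue
                n_strong = n_inform = 0
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        cls = pair_class(ids[a], ids[b])
                        if cls == "strong":
                            n_strong += 1
                            n_inform += 1
                        elif cls == "recomb":
                            n_inform += 1
                if n_inform == 0:
                    continue
                if n_strong / n_inform >= params.min_informative_frac:
                    candidates.append(
                        {
                            "chromosome": chrom,
                            "i": i,
                            "j": j,
                            "start_cM": float(pos[i]),
                            "end_cM": float(pos[j]),
                            "n_loci": j - i + 1,
                            "locus_ids": ",".join(ids[i : j + 1]),
                            "span": float(pos[j] - pos[i]),
                        }
                    )

    # longest-first, ties leftmost; drop candidates overlapping accepted ones
    candidates.sort(key=lambda c: (-c["span"], c["chromosome"], c["i"]))
    accepted, taken = [], {}
    for c in candidates:
        used = taken.setdefault(c["chromosome"], set())
        span_idx = set(range(c["i"], c["j"] + 1))
        if span_idx & used:
            continue
        used |= span_idx
        accepted.append(c)
    accepted.sort(key=lambda c: (c["chromosome"], c["i"]))
    return pd.DataFrame(
        [{k: c[k] for k in ("chromosome", "start_cM", "end_cM", "n_loci", "locus_ids")}
         for c in accepted],
        columns=["chromosome", "start_cM", "end_cM", "n_loci", "locus_ids"],
    )


def r2_matrix(panel: GenotypePanel, chromosome: str, min_complete: int = 10) -> pd.DataFrame:
    """Square per-chromosome r^2 matrix (heatmap-ready TSV export)."""
    sub = panel.subset_loci((panel.loci["chromosome"] == chromosome).to_numpy())
    L = sub.n_loci
    mat = np.full((L, L), np.nan)
    np.fill_diagonal(mat, 1.0)
    for i in range(L):
        for j in range(i + 1, L):
            counts = _counts_from_calls(sub.calls[:, i], sub.calls[:, j])
            n = counts.sum()
            if n < min_complete:
                continue
            if counts[0].sum() in (0, n) or counts[:, 0].sum() in (0, n):
                continue
            mat[i, j] = mat[j, i] = r_squared(counts)
    return pd.DataFrame(mat, index=sub.locus_ids, columns=sub.locus_ids)
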
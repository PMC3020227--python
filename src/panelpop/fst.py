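"""Weir-Cockerham F_ST, hierarchical variance components and the
sliding-window differentiation scan.

All estimators treat an inbred line as a single haploid allele copy:
heterozygous calls (rare in the target panels and recoded to missing
upstream) never contribute.  For ``r`` groups with per-group sample sizes
``n_i`` and allele-2 frequencies ``p_i`` at a locus, the haploid
Weir-Cockerham ANOVA estimator is

    MSP = sum n_i (p_i - p_bar)^2 / (r - 1)
    MSG = sum n_i p_i (1 - p_i) / sum(n_i - 1)
    n_c = (N - sum n_i^2 / N) / (r - 1)
    theta = (MSP - MSG) / (MSP + (n_c - 1) MSG)

where ``p_bar`` is the weighted mean frequency and ``N = sum n_i``.  The
estimate is undefined (flagged) when the pooled locus is monomorphic or
the denominator vanishes.

The scan averages theta in a sliding window of ``W`` consecutive mapped
loci per chromosome and calls a window elevated when its mean exceeds the
chosen percentile of a bootstrap null built from ``B`` resamples of ``W``
loci drawn with replacement from all defined loci genome-wide — a null of
"W random SNPs", deliberately ignoring linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypePanel

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "wc_theta_loci",
    "wc_theta_locus",
    "fst_summary",
    "hierarchical_components",
    "sliding_window_means",
    "bootstrap_threshold",
    "elevated_regions",
    "fst_scan",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Fixed constants of the analysis pipeline.

    Defaults: 5-SNP windows, 1000 bootstrap replicates, 95th-percentile
    threshold, FDR 0.01, MAF cutoff 0.05, 4-cM thinning for structure-style
    subsets, populations below 5 lines excluded.
    """

    W: int = 5
    B: int = 1000
    percentile: float = 95.0
    fdr_q: float = 0.01
    maf_min: float = 0.05
    thin_cM: float = 4.0
    min_lines: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.W < 2:
            raise ValueError("window size W must be >= 2")
        if self.B < 1:
            raise ValueError("bootstrap replicates B must be >= 1")


def _group_counts(panel: GenotypePanel, labels: np.ndarray):
    """Per-group allele-2 and total haploid counts at each locus.

    Returns ``(groups, n, c)`` with ``n`` and ``c`` of shape
    ``(n_groups, n_loci)``: counted copies and allele-2 copies (homozygous
    calls only).
    """
    groups = pd.unique(labels)
    obs = (panel.calls == 0) | (panel.calls == 2)
    alt = panel.calls == 2
    n = np.empty((len(groups), panel.n_loci))
    c = np.empty((len(groups), panel.n_loci))
    for k, g in enumerate(groups):
        mask = labels == g
        n[k] = obs[mask].sum(axis=0)
        c[k] = alt[mask].sum(axis=0)
    return groups, n, c


def wc_theta_loci(panel: GenotypePanel, grouping: str = "growth_habit") -> pd.DataFrame:
    """Single-locus Weir-Cockerham theta for every locus.

    ``grouping`` names a line-metadata column (``growth_habit`` or
    ``population``) or is an array of group labels, one per line.  Returns
    a frame aligned with ``panel.loci``: ``locus_id, theta, msp, msg, n_c,
    n_pops_used, n_total, defined``.
    """
    if isinstance(grouping, str):
        labels = panel.lines[grouping].to_numpy()
    else:
        labels = np.asarray(grouping)
        if labels.shape[0] != panel.n_lines:
            raise ValueError("grouping labels must match number of lines")
    if len(pd.unique(labels)) < 2:
        raise ValueError("grouping must define at least 2 groups")

    _, n, c = _group_counts(panel, labels)
    used = n >= 1
    r = used.sum(axis=0)
    n = np.where(used, n, 0.0)
    c = np.where(used, c, 0.0)
    N = n.sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, c / np.maximum(n, 1.0), 0.0)
        pbar = np.where(N > 0, c.sum(axis=0) / np.maximum(N, 1.0), np.nan)
        msp = (n * (p - pbar) ** 2).sum(axis=0) / np.maximum(r - 1, 1)
        denom_g = N - r  # sum of (n_i - 1) over used groups
        msg = (n * p * (1.0 - p)).sum(axis=0) / np.maximum(denom_g, 1)
        n_c = (N - (n**2).sum(axis=0) / np.maximum(N, 1.0)) / np.maximum(r - 1, 1)
        denom = msp + (n_c - 1.0) * msg
        theta = np.where(denom != 0, (msp - msg) / np.where(denom != 0, denom, 1.0), np.nan)

    poly = (pbar > 0) & (pbar < 1)
    defined = (r >= 2) & (denom_g >= 1) & poly & (denom != 0) & np.isfinite(theta)
    theta = np.where(defined, theta, np.nan)
    return pd.DataFrame(
        {
            "locus_id": panel.locus_ids,
            "theta": theta,
            "msp": msp,
            "msg": msg,
            "n_c": n_c,
            "n_pops_used": r.astype(int),
            "n_total": N.astype(int),
            "defined": defined,
        }
    )


def wc_theta_locus(panel: GenotypePanel, grouping, locus_id: str) -> dict:
    """Theta and estimator components for a single locus (see module doc)."""
    sub = panel.subset_loci(np.asarray([locus_id]))
    row = wc_theta_loci(sub, grouping).iloc[0]
    if isinstance(grouping, str):
        labels = panel.lines[grouping].to_numpy()
    else:
        labels = np.asarray(grouping)
    _, n, _ = _group_counts(sub, labels)
    return {**row.to_dict(), "group_sizes": n[:, 0].astype(int).tolist()}


# ---------------------------------------------------------------------- #
# summaries
# ---------------------------------------------------------------------- #
def fst_summary(results: pd.DataFrame, loci: pd.DataFrame, W: int = 5) -> pd.DataFrame:
    """Mean and SD of single-locus theta per chromosome and per genome.

    Also reports the SD of W-locus sliding-window means ("window SD"),
    which shows the variance reduction from local averaging.  SD values are
    NaN when fewer than 2 observations exist.
    """
    df = loci.merge(results, on="locus_id")
    windows = sliding_window_means(results, loci, W)
    rows = []

    def _summary(unit_label, unit_value, sub, wsub):
        t = sub["theta"].dropna()
        wt = wsub["mean_theta"].dropna() if len(wsub) else pd.Series(dtype=float)
        rows.append(
            {
                "level": unit_label,
                "unit": unit_value,
                "n_loci": int(len(t)),
                "mean_fst": float(t.mean()) if len(t) else np.nan,
                "sd_single_locus": float(t.std(ddof=1)) if len(t) > 1 else np.nan,
                "sd_windows": float(wt.std(ddof=1)) if len(wt) > 1 else np.nan,
            }
        )

    for chrom, sub in df.groupby("chromosome", sort=False):
        _summary("chromosome", chrom, sub, windows[windows["chromosome"] == chrom])
    for genome, sub in df.groupby("genome", sort=False):
        chroms = sub["chromosome"].unique()
        _summary("genome", genome, sub, windows[windows["chromosome"].isin(chroms)])
    _summary("total", "all", df, windows)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# hierarchical variance components
# ---------------------------------------------------------------------- #
def hierarchical_components(
    panel: GenotypePanel,
    group_level: str | None = "growth_habit",
    pop_level: str = "population",
    min_lines: int = 5,
) -> dict:
    """Nested random-effects ANOVA on haploid allele indicators.

    Partitions allelic variance into within-population,
    among-populations-within-group and (when ``group_level`` is given and
    more than one group is present) among-group components, using the
    standard unbalanced nested-ANOVA coefficients.  Raw components are
    summed over loci; negative sums are truncated to 0 (flagged) before
    converting to percentages.

    Populations with fewer than ``min_lines`` lines are dropped first.
    Returns a dict with raw sums, percentages and flags.
    """
    sizes = panel.lines.groupby(pop_level)["line_id"].count()
    keep_pops = sizes[sizes >= min_lines].index
    if len(keep_pops) < len(sizes):
        logger.warning(
            "excluding %d population(s) below min_lines=%d: %s",
            len(sizes) - len(keep_pops), min_lines,
            sorted(set(sizes.index) - set(keep_pops)),
        )
    sub = panel.subset_lines(panel.lines[pop_level].isin(keep_pops).to_numpy())

    pops = sub.lines[pop_level].to_numpy()
    groups = (
        sub.lines[group_level].to_numpy()
        if group_level is not None
        else np.full(sub.n_lines, "all")
    )
    pop_ids = pd.unique(pops)
    group_of = {p: groups[pops == p][0] for p in pop_ids}
    group_ids = pd.unique(np.array([group_of[p] for p in pop_ids]))
    two_level = len(group_ids) >= 2
    flags = []
    if group_level is not None and not two_level:
        flags.append("single_group:among_group_component_reported_as_0")

    obs = (sub.calls == 0) | (sub.calls == 2)
    x = (sub.calls == 2).astype(float)

    # per-population counts and sums: (P, L)
    n_pl = np.stack([obs[pops == p].sum(axis=0) for p in pop_ids]).astype(float)
    s_pl = np.stack([(x * obs)[pops == p].sum(axis=0) for p in pop_ids])
    g_index = np.array([list(group_ids).index(group_of[p]) for p in pop_ids])

    n_gl = np.zeros((len(group_ids), n_pl.shape[1]))
    s_gl = np.zeros_like(n_gl)
    for k in range(len(pop_ids)):
        n_gl[g_index[k]] += n_pl[k]
        s_gl[g_index[k]] += s_pl[k]

    sigma_w_sum = sigma_p_sum = sigma_g_sum = 0.0
    n_loci_used = 0
    for j in range(sub.n_loci):
        n_p, s_p = n_pl[:, j], s_pl[:, j]
        active = n_p >= 1
        if active.sum() < 2:
            continue
        n_p, s_p = n_p[active], s_p[active]
        gi = g_index[active]
        g_active = np.unique(gi)
        N = n_p.sum()
        total_mean = s_p.sum() / N
        if total_mean in (0.0, 1.0):
            continue
        P, G = len(n_p), len(g_active)

        mean_p = s_p / n_p
        n_g = np.array([n_p[gi == g].sum() for g in g_active])
        s_g = np.array([s_p[gi == g].sum() for g in g_active])
        mean_g = s_g / n_g
        mean_g_of_pop = np.array([mean_g[list(g_active).index(g)] for g in gi])

        ss_w = float((s_p - s_p**2 / n_p).sum())  # sum x^2 = sum x for 0/1 data
        ss_p = float((n_p * (mean_p - mean_g_of_pop) ** 2).sum())
        ss_g = float((n_g * (mean_g - total_mean) ** 2).sum())

        df_w, df_p, df_g = N - P, P - G, G - 1
        if df_w < 1:
            continue
        ms_w = ss_w / df_w
        sigma_w = ms_w
        sigma_p = sigma_g = 0.0

        sum_n2_within_g = np.array([(n_p[gi == g] ** 2).sum() for g in g_active])
        if df_p >= 1:
            k1 = (N - (sum_n2_within_g / n_g).sum()) / df_p
            ms_p = ss_p / df_p
            sigma_p = (ms_p - ms_w) / k1 if k1 > 0 else 0.0
        if two_level and df_g >= 1:
            k2 = ((sum_n2_within_g / n_g).sum() - (n_p**2).sum() / N) / df_g
            k3 = (N - (n_g**2).sum() / N) / df_g
            ms_g = ss_g / df_g
            sigma_g = (ms_g - ms_w - k2 * sigma_p) / k3 if k3 > 0 else 0.0

        sigma_w_sum += sigma_w
        sigma_p_sum += sigma_p
        sigma_g_sum += sigma_g
        n_loci_used += 1

    raw = {
        "within_pop": sigma_w_sum,
        "among_pop_within_group": sigma_p_sum,
        "among_group": sigma_g_sum,
    }
    truncated = {}
    for key, value in raw.items():
        if value < 0:
            flags.append(f"negative_component_truncated:{key}")
            truncated[key] = 0.0
        else:
            truncated[key] = value
    total = sum(truncated.values())
    percents = {
        key: (100.0 * value / total if total > 0 else np.nan)
        for key, value in truncated.items()
    }
    if group_level is None or not two_level:
        percents["among_group"] = 0.0 if total > 0 else np.nan
    return {
        "raw": raw,
        "percent": percents,
        "n_loci_used": n_loci_used,
        "n_populations": len(pop_ids),
        "n_groups": len(group_ids),
        "flags": flags,
    }


# ---------------------------------------------------------------------- #
# sliding-window scan
# ---------------------------------------------------------------------- #
def sliding_window_means(results: pd.DataFrame, loci: pd.DataFrame, W: int = 5) -> pd.DataFrame:
    """Step-1 windows of ``W`` consecutive defined loci per chromosome.

    Loci with undefined theta are excluded before windowing; chromosomes
    left with fewer than ``W`` defined loci yield no windows (logged).
    Returns ``chromosome, window_index, start_cM, end_cM, mean_theta,
    locus_ids`` with windows in map order.
    """
    df = loci.merge(results, on="locus_id")
    df = df[df["defined"]].reset_index(drop=True)
    rows = []
    for chrom, sub in df.groupby("chromosome", sort=False):
        sub = sub.reset_index(drop=True)
        if len(sub) < W:
            logger.info("chromosome %s has %d defined loci < W=%d; no windows",
                        chrom, len(sub), W)
            continue
        theta = sub["theta"].to_numpy()
        pos = sub["position_cM"].to_numpy()
        ids = sub["locus_id"].to_numpy()
        means = np.convolve(theta, np.ones(W) / W, mode="valid")
        for w in range(len(means)):
            rows.append(
                {
                    "chromosome": chrom,
                    "window_index": w,
                    "start_cM": float(pos[w]),
                    "end_cM": float(pos[w + W - 1]),
                    "mean_theta": float(means[w]),
                    "locus_ids": ",".join(ids[w : w + W]),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["chromosome", "window_index", "start_cM", "end_cM",
                 "mean_theta", "locus_ids"],
    )


def bootstrap_threshold(
    results: pd.DataFrame, W: int = 5, B: int = 1000,
    percentile: float = 95.0, seed: int = 0,
) -> float:
    """Percentile of means of ``W`` loci resampled genome-wide.

    Each of the ``B`` replicates draws ``W`` defined single-locus theta
    values with replacement, ignoring the map, and takes their mean; the
    returned threshold is the empirical ``percentile`` of those means.
    """
    theta = results.loc[results["defined"], "theta"].to_numpy()
    if len(theta) < W:
        raise ValueError(f"need at least W={W} defined loci, have {len(theta)}")
    rng = np.random.default_rng(seed)
    means = rng.choice(theta, size=(B, W), replace=True).mean(axis=1)
    return float(np.percentile(means, percentile))


def elevated_regions(windows: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Merge maximal runs of consecutive above-threshold windows.

    Returns one row per interval: ``chromosome, start_cM, end_cM,
    n_windows, mean_theta`` where ``mean_theta`` averages the member
    window means.
    """
    rows = []
    for chrom, sub in windows.groupby("chromosome", sort=False):
        sub = sub.sort_values("window_index").reset_index(drop=True)
        above = sub["mean_theta"].to_numpy() > threshold
        start = None
        for i in range(len(sub) + 1):
            if i < len(sub) and above[i]:
                if start is None:
                    start = i
            elif start is not None:
                run = sub.iloc[start:i]
                rows.append(
                    {
                        "chromosome": chrom,
                        "start_cM": float(run["start_cM"].min()),
                        "end_cM": float(run["end_cM"].max()),
                        "n_windows": len(run),
                        "mean_theta": float(run["mean_theta"].mean()),
                    }
                )
                start = None
    return pd.DataFrame(
        rows, columns=["chromosome", "start_cM", "end_cM", "n_windows", "mean_theta"]
    )


def fst_scan(
    panel: GenotypePanel,
    grouping: str = "growth_habit",
    config: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Full differentiation scan: per-locus theta, windows, bootstrap
    threshold and elevated intervals, bundled in a dict."""
    results = wc_theta_loci(panel, grouping)
    windows = sliding_window_means(results, panel.loci, config.W)
    threshold = bootstrap_threshold(
        results, W=config.W, B=config.B, percentile=config.percentile, seed=config.seed
    )
    regions = elevated_regions(windows, threshold)
    return {
        "per_locus": results,
        "windows": windows,
        "threshold": threshold,
        "regions": regions,
        "summary": fst_summary(results, panel.loci, config.W),
    }
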
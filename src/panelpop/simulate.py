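"""Synthetic structured panels of inbred lines with known truth.

The generator emulates a diversity panel of (near-)fully inbred cultivars
drawn from several breeding populations nested in two growth-habit groups,
genotyped at biallelic SNPs on a centimorgan map:

* **Differentiation** follows the Balding-Nichols model: each population's
  allele frequency at a locus is drawn from
  ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around the ancestral frequency ``p``,
  which makes the expected among-population variance ``F * p(1-p)`` — i.e.
  ``F`` is the target F_ST, exactly recoverable by a Weir-Cockerham
  estimator.
* **Linkage disequilibrium** comes from a founder-mosaic model: each
  population has a small pool of founder haplotypes (Bernoulli draws at the
  population frequencies) and every line's single haplotype is a mosaic of
  founders, switching between adjacent loci with the Haldane recombination
  fraction compounded over a number of generations.  Few founders and few
  generations give long-range LD; the defaults place the r^2 half-decay
  distance in the 5-10 cM range typical of inbreeding-crop panels.
* **Planted differentiated regions** shift population frequencies by +delta
  in the first growth-habit group and -delta in the second, creating
  localized elevated-F_ST intervals the window scan should recover.
* **Noise**: calls are flipped to heterozygous and to missing at fixed
  rates, and loci are then ascertained by pooled minor allele frequency,
  mirroring how fixed genotyping assays report only panel-polymorphic SNPs.

All randomness flows from a single seed through named, per-stage child
streams, so the same config reproduces a byte-identical panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypePanel, make_panel

__all__ = [
    "SimConfig",
    "SimTruth",
    "default_config",
    "draw_population_frequencies",
    "simulate_panel",
    "write_truth",
    "read_truth",
]

# Default panel composition mirroring a 478-line, 17-program US/CIMMYT
# spring-winter wheat panel: 9 winter + 8 spring populations with the
# observed per-program line counts.
WINTER_SIZES = (21, 49, 40, 11, 30, 38, 34, 4, 10)   # sums to 237
SPRING_SIZES = (30, 40, 30, 40, 30, 10, 30, 31)      # sums to 241

#: 21 wheat chromosomes, 7 per genome; 150 cM is a round figure for the
#: mapped portion of a wheat chromosome.
DEFAULT_CHROMOSOMES = tuple(
    (f"{i}{g}", g, 150.0) for g in ("A", "B", "D") for i in range(1, 8)
)

#: Strongly differentiated regions planted between the growth-habit groups,
#: shaped like the flowering-time intervals a spring/winter contrast finds
#: (one large-effect region on 5A, smaller ones on 2A and 2B).
DEFAULT_PLANTED = (
    ("5A", 80.0, 138.0, 0.40),
    ("2B", 76.0, 97.0, 0.30),
    ("2A", 114.0, 124.0, 0.30),
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the structured-panel generator.

    ``lines_per_population`` is a tuple of tuples, one per growth-habit
    group; ``planted_regions`` entries are ``(chromosome, start_cM, end_cM,
    delta)`` with the frequency shift ``delta`` applied +/- between the two
    groups.
    """

    seed: int
    group_labels: tuple[str, ...] = ("winter", "spring")
    lines_per_population: tuple[tuple[int, ...], ...] = (WINTER_SIZES, SPRING_SIZES)
    chromosomes: tuple[tuple[str, str, float], ...] = DEFAULT_CHROMOSOMES
    loci_per_chromosome: int = 42
    fst_target: float = 0.10
    n_founders: int = 10
    generations: int = 5
    planted_regions: tuple[tuple[str, float, float, float], ...] = DEFAULT_PLANTED
    het_rate: float = 0.005
    missing_rate: float = 0.009
    ascertain_maf_min: float = 0.05
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95

    def __post_init__(self):
        if not 0 < self.fst_target < 1:
            raise ValueError("fst_target must lie in (0,1)")
        for rate in (self.het_rate, self.missing_rate, self.ascertain_maf_min):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0,1]")
        if len(self.lines_per_population) != len(self.group_labels):
            raise ValueError("one lines_per_population tuple per group required")
        if any(length <= 0 for _, _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        chrom_names = {c for c, _, _ in self.chromosomes}
        for chrom, lo, hi, delta in self.planted_regions:
            if chrom not in chrom_names:
                raise ValueError(f"planted region on unknown chromosome {chrom!r}")
            if not 0 < delta < 1:
                raise ValueError("planted delta must lie in (0,1)")
            length = next(l for c, _, l in self.chromosomes if c == chrom)
            if lo < 0 or hi > length or lo >= hi:
                raise ValueError(
                    f"planted region {chrom}:{lo}-{hi} outside chromosome (0-{length})"
                )

    @property
    def n_populations(self) -> int:
        return sum(len(g) for g in self.lines_per_population)

    @property
    def n_lines(self) -> int:
        return sum(sum(g) for g in self.lines_per_population)


def default_config(seed: int, **overrides) -> SimConfig:
    """The study conditions: 478 lines, 17 populations, 21 chromosomes."""
    return SimConfig(seed=seed, **overrides)


@dataclass
class SimTruth:
    """Generating-model truth recorded before noise and ascertainment.

    ``loci`` covers every simulated locus (including those later dropped by
    MAF ascertainment; ``kept`` flags the survivors) with the ancestral
    frequency, the planted flag and the realized per-locus F_ST implied by
    the drawn population frequencies.  ``pop_freqs`` is loci x populations.
    """

    config: SimConfig
    loci: pd.DataFrame          # locus_id, chromosome, position_cM, ancestral_p, planted, kept, realized_fst
    pop_freqs: np.ndarray       # (n_loci_total, n_pops) post-shift frequencies
    pop_labels: list            # (population, group) per column
    founders: dict              # population -> founder haplotype matrix

    @property
    def planted_locus_ids(self) -> list:
        return self.loci.loc[self.loci["planted"], "locus_id"].tolist()

    @property
    def planted_intervals(self):
        return [(c, lo, hi) for c, lo, hi, _ in self.config.planted_regions]


def draw_population_frequencies(p: float, fst_target: float, n_pops: int, rng) -> np.ndarray:
    """Balding-Nichols draw of population frequencies around ``p``.

    Frequencies are iid ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` so that
    ``E[q_i] = p`` and ``Var[q_i] = F p (1-p)``.  Degenerate ancestral
    frequencies (0 or 1) are returned unchanged.
    """
    if not 0 < fst_target < 1:
        raise ValueError("fst_target must lie in (0,1)")
    if p <= 0.0 or p >= 1.0:
        return np.full(n_pops, float(np.clip(p, 0.0, 1.0)))
    scale = (1.0 - fst_target) / fst_target
    return rng.beta(p * scale, (1.0 - p) * scale, size=n_pops)


def _mosaic_haplotypes(founders: np.ndarray, n_lines: int, switch_prob: np.ndarray,
                       new_chrom: np.ndarray, rng) -> np.ndarray:
    """Compose line haplotypes as founder mosaics.

    ``switch_prob[j]`` is the probability that the founder changes between
    locus ``j-1`` and locus ``j``; ``new_chrom[j]`` forces an independent
    founder draw at chromosome starts.
    """
    n_founders, n_loci = founders.shape
    idx = np.empty((n_lines, n_loci), dtype=np.int64)
    current = rng.integers(0, n_founders, size=n_lines)
    for j in range(n_loci):
        if new_chrom[j]:
            current = rng.integers(0, n_founders, size=n_lines)
        else:
            switch = rng.random(n_lines) < switch_prob[j]
            current = np.where(
                switch, rng.integers(0, n_founders, size=n_lines), current
            )
        idx[:, j] = current
    return founders[idx, np.arange(n_loci)]


def simulate_panel(config: SimConfig) -> tuple[GenotypePanel, SimTruth]:
    """Generate a structured inbred-line panel and its generating truth.

    Stages (each on its own child RNG stream): ancestral frequencies,
    Balding-Nichols population frequencies, planted-region shifts, founder
    haplotypes, founder-mosaic line haplotypes, het/missing noise, pooled
    MAF ascertainment.  Truth is recorded before the last two stages.
    """
    root = np.random.SeedSequence(config.seed)
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            ("ancestral", "popfreq", "founders", "mosaic", "noise"),
            root.spawn(5),
        )
    }

    # --- map ----------------------------------------------------------- #
    loci_rows = []
    for chrom, genome, length in config.chromosomes:
        # evenly spaced loci with a half-step margin at each end
        step = length / config.loci_per_chromosome
        for k in range(config.loci_per_chromosome):
            pos = round(step * (k + 0.5), 6)
            loci_rows.append(
                {
                    "locus_id": f"S{chrom}_{k:03d}",
                    "genome": genome,
                    "chromosome": chrom,
                    "position_cM": pos,
                }
            )
    loci = pd.DataFrame(loci_rows)
    n_loci = len(loci)
    pos = loci["position_cM"].to_numpy()
    chrom_arr = loci["chromosome"].to_numpy()
    new_chrom = np.ones(n_loci, dtype=bool)
    new_chrom[1:] = chrom_arr[1:] != chrom_arr[:-1]

    planted = np.zeros(n_loci, dtype=bool)
    delta_arr = np.zeros(n_loci)
    for chrom, lo, hi, delta in config.planted_regions:
        in_region = (chrom_arr == chrom) & (pos >= lo) & (pos <= hi)
        planted |= in_region
        delta_arr[in_region] = delta

    # --- frequencies ---------------------------------------------------- #
    ancestral = streams["ancestral"].uniform(
        config.ancestral_low, config.ancestral_high, size=n_loci
    )
    pops, pop_labels, group_of_pop = [], [], []
    for g_idx, (g_label, sizes) in enumerate(
        zip(config.group_labels, config.lines_per_population)
    ):
        for p_idx, n in enumerate(sizes):
            pops.append((f"{g_label}_{p_idx + 1:02d}", g_label, n))
            pop_labels.append((f"{g_label}_{p_idx + 1:02d}", g_label))
            group_of_pop.append(g_idx)
    n_pops = len(pops)

    pop_freqs = np.empty((n_loci, n_pops))
    rng_pf = streams["popfreq"]
    for j in range(n_loci):
        pop_freqs[j] = draw_population_frequencies(
            ancestral[j], config.fst_target, n_pops, rng_pf
        )
    # planted shifts: +delta in group 0, -delta in group 1 (then clipped)
    sign = np.where(np.asarray(group_of_pop) == 0, 1.0, -1.0)
    shift = delta_arr[:, None] * sign[None, :]
    pop_freqs = np.clip(pop_freqs + shift * planted[:, None], 0.02, 0.98)

    # realized per-locus F_ST implied by the drawn frequencies
    pbar = pop_freqs.mean(axis=1)
    var_pop = pop_freqs.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        realized = np.where(pbar * (1 - pbar) > 0, var_pop / (pbar * (1 - pbar)), 0.0)

    # --- haplotypes ------------------------------------------------------ #
    d = np.diff(pos, prepend=pos[0])
    r1 = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))          # Haldane, one meiosis
    switch = 0.5 * (1.0 - (1.0 - 2.0 * r1) ** config.generations)
    rng_f, rng_m = streams["founders"], streams["mosaic"]
    hap_blocks, line_rows, founders = [], [], {}
    for (pop_name, g_label, n_lines_pop) in pops:
        k = pop_labels.index((pop_name, g_label))
        # Frequency-matched founder pool: the pool carries
        # round(q * n_founders) copies of allele 2 (stochastic rounding, so
        # the expectation stays q), placed on random founders per locus.
        # This removes founder-pool drift, so the among-population variance
        # of line frequencies stays at the Balding-Nichols target and the
        # F_ST estimator recovers fst_target; LD still arises from shared
        # founder identity along the mosaic, not from pool composition.
        k_exact = pop_freqs[:, k] * config.n_founders
        k_int = np.floor(k_exact).astype(np.int64)
        k_int += (rng_f.random(n_loci) < (k_exact - k_int)).astype(np.int64)
        rank = rng_f.random((config.n_founders, n_loci)).argsort(axis=0).argsort(axis=0)
        fh = (rank < k_int[None, :]).astype(np.int8)
        founders[pop_name] = fh
        haps = _mosaic_haplotypes(fh, n_lines_pop, switch, new_chrom, rng_m)
        hap_blocks.append(haps)
        for i in range(n_lines_pop):
            line_rows.append(
                {
                    "line_id": f"{pop_name}_L{i + 1:03d}",
                    "population": pop_name,
                    "growth_habit": g_label,
                }
            )
    haplotypes = np.vstack(hap_blocks)           # (n_lines, n_loci), alleles 0/1
    calls = (2 * haplotypes).astype(np.int8)     # homozygous genotypes

    # --- noise ----------------------------------------------------------- #
    rng_n = streams["noise"]
    het_mask = rng_n.random(calls.shape) < config.het_rate
    miss_mask = rng_n.random(calls.shape) < config.missing_rate
    calls = np.where(het_mask, 1, calls)
    calls = np.where(miss_mask, MISSING, calls).astype(np.int8)

    lines = pd.DataFrame(line_rows)
    panel_full = make_panel(lines, loci, calls)

    # --- ascertainment ---------------------------------------------------- #
    maf = panel_full.maf()
    kept_by_id = dict(
        zip(panel_full.locus_ids, np.nan_to_num(maf) >= config.ascertain_maf_min)
    )
    kept = np.array([kept_by_id[lid] for lid in loci["locus_id"]])
    panel = panel_full.subset_loci(
        np.array([kept_by_id[lid] for lid in panel_full.locus_ids])
    )

    truth_loci = loci.assign(
        ancestral_p=ancestral,
        planted=planted,
        kept=kept,
        realized_fst=realized,
    )
    truth = SimTruth(
        config=config,
        loci=truth_loci,
        pop_freqs=pop_freqs,
        pop_labels=pop_labels,
        founders=founders,
    )
    return panel, truth


def write_truth(truth: SimTruth, path) -> None:
    """Per-locus truth table as TSV: ancestral and population frequencies,
    planted/kept flags and realized F_ST; round-trips via :func:`read_truth`."""
    out = truth.loci.copy()
    for k, (pop_name, _) in enumerate(truth.pop_labels):
        out[f"p_{pop_name}"] = truth.pop_freqs[:, k]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# synthetic panel truth, seed={truth.config.seed}\n")
        out.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_truth(path) -> pd.DataFrame:
    """Read back a truth TSV written by :func:`write_truth`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df["planted"] = df["planted"].astype(bool)
    df["kept"] = df["kept"].astype(bool)
    return df
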
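"""Data model and I/O for inbred-line SNP panels.

A panel couples three pieces of information:

* a call matrix (lines x loci) with entries ``0`` (homozygous for allele 1),
  ``1`` (heterozygous), ``2`` (homozygous for allele 2) and ``-1`` (missing),
* a genetic map assigning every locus to a genome, a chromosome and a
  position in centimorgans,
* line metadata assigning every line to a population (breeding program) and
  a growth-habit group (spring or winter).

The on-disk representation is a trio of UTF-8 tab-separated files: a matrix
file (header row of locus ids, first column ``line_id``, cells in
``{0,1,2,NA}``), a map file (``locus_id, genome, chromosome, cM``) and a
metadata file (``line_id, population, growth_habit``).  A biallelic-SNP VCF
can substitute for the matrix file, with cM positions supplied through the
side map because VCF ``POS`` is a physical, not genetic, coordinate.

Because the panels this package targets are (near-)fully inbred, allele
frequencies are computed treating each line as a single haploid allele copy;
heterozygous calls are by default treated as missing (they can optionally
count as half an allele copy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing call in the int8 call matrix.
MISSING: int = -1

#: Valid call codes (besides MISSING).
_VALID_CALLS = frozenset({0, 1, 2})

LOCUS_COLUMNS = ["locus_id", "genome", "chromosome", "position_cM"]
LINE_COLUMNS = ["line_id", "population", "growth_habit"]


class PanelFormatError(ValueError):
    """Raised when panel files violate the format contract."""


@dataclass(frozen=True)
class CallSummary:
    """Tally of call states over a (sub)matrix."""

    n_hom: int
    n_het: int
    n_missing: int

    @property
    def n_total(self) -> int:
        return self.n_hom + self.n_het + self.n_missing

    @property
    def frac_hom(self) -> float:
        return self.n_hom / self.n_total

    @property
    def frac_het(self) -> float:
        return self.n_het / self.n_total

    @property
    def frac_missing(self) -> float:
        return self.n_missing / self.n_total

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_hom": self.n_hom,
            "n_het": self.n_het,
            "n_missing": self.n_missing,
            "frac_hom": self.frac_hom,
            "frac_het": self.frac_het,
            "frac_missing": self.frac_missing,
        }


@dataclass(frozen=True)
class FilterReport:
    """Loci removed by each rule of :func:`filter_loci`, in application order."""

    n_input: int
    n_removed_maf: int
    n_removed_missing: int
    n_removed_monomorphic: int
    n_kept: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class GenotypePanel:
    """Lines x loci SNP call matrix with map and population metadata.

    Attributes
    ----------
    lines : pandas.DataFrame
        One row per line, columns ``line_id, population, growth_habit``.
    loci : pandas.DataFrame
        One row per locus, columns ``locus_id, genome, chromosome,
        position_cM`` (plus optional ``allele1/allele2`` labels), sorted by
        ``(genome, chromosome, position_cM, locus_id)``.
    calls : numpy.ndarray
        int8 matrix of shape ``(n_lines, n_loci)`` with entries in
        ``{0, 1, 2, MISSING}``.
    """

    lines: pd.DataFrame
    loci: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.lines = self.lines.reset_index(drop=True)
        self.loci = self.loci.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # ------------------------------------------------------------------ #
    # validation and basic accessors
    # ------------------------------------------------------------------ #
    def validate(self) -> None:
        for col in LINE_COLUMNS:
            if col not in self.lines.columns:
                raise PanelFormatError(f"line metadata lacks column {col!r}")
        for col in LOCUS_COLUMNS:
            if col not in self.loci.columns:
                raise PanelFormatError(f"locus map lacks column {col!r}")
        if self.calls.shape != (len(self.lines), len(self.loci)):
            raise PanelFormatError(
                f"call matrix shape {self.calls.shape} does not match "
                f"{len(self.lines)} lines x {len(self.loci)} loci"
            )
        bad = ~np.isin(self.calls, [0, 1, 2, MISSING])
        if bad.any():
            raise PanelFormatError(
                f"call matrix contains invalid codes: "
                f"{sorted(set(self.calls[bad].tolist()))}"
            )
        if self.lines["line_id"].duplicated().any():
            dup = self.lines.loc[self.lines["line_id"].duplicated(), "line_id"].iloc[0]
            raise PanelFormatError(f"duplicate line_id {dup!r}")
        if self.loci["locus_id"].duplicated().any():
            dup = self.loci.loc[self.loci["locus_id"].duplicated(), "locus_id"].iloc[0]
            raise PanelFormatError(f"duplicate locus_id {dup!r}")
        if (self.loci["position_cM"] < 0).any():
            raise PanelFormatError("negative cM position in map")
        # chromosome label must carry its genome label as suffix ("5A" in "A")
        chrom = self.loci["chromosome"].astype(str)
        genome = self.loci["genome"].astype(str)
        mismatch = ~np.array([c.endswith(g) for c, g in zip(chrom, genome)])
        if mismatch.any():
            i = int(np.flatnonzero(mismatch)[0])
            raise PanelFormatError(
                f"chromosome {chrom.iloc[i]!r} inconsistent with genome "
                f"{genome.iloc[i]!r} at locus {self.loci['locus_id'].iloc[i]!r}"
            )
        # every population maps to exactly one growth habit
        habs = self.lines.groupby("population")["growth_habit"].nunique()
        if (habs > 1).any():
            pop = habs[habs > 1].index[0]
            raise PanelFormatError(
                f"population {pop!r} assigned to more than one growth habit"
            )

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def line_ids(self) -> np.ndarray:
        return self.lines["line_id"].to_numpy()

    @property
    def locus_ids(self) -> np.ndarray:
        return self.loci["locus_id"].to_numpy()

    def copy(self) -> "GenotypePanel":
        return GenotypePanel(self.lines.copy(), self.loci.copy(), self.calls.copy())

    # ------------------------------------------------------------------ #
    # subsetting
    # ------------------------------------------------------------------ #
    def subset_lines(self, mask) -> "GenotypePanel":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            mask = np.isin(self.line_ids, mask)
        return GenotypePanel(self.lines[mask], self.loci, self.calls[mask, :])

    def subset_loci(self, mask) -> "GenotypePanel":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            mask = np.isin(self.locus_ids, mask)
        return GenotypePanel(self.lines, self.loci[mask], self.calls[:, mask])

    def by_growth_habit(self, habit: str) -> "GenotypePanel":
        mask = (self.lines["growth_habit"] == habit).to_numpy()
        if not mask.any():
            raise KeyError(f"no lines with growth habit {habit!r}")
        return self.subset_lines(mask)

    def by_population(self, population: str) -> "GenotypePanel":
        mask = (self.lines["population"] == population).to_numpy()
        if not mask.any():
            raise KeyError(f"no lines in population {population!r}")
        return self.subset_lines(mask)

    # ------------------------------------------------------------------ #
    # allele frequencies (haploid convention: one allele copy per line)
    # ------------------------------------------------------------------ #
    def allele_counts(self, het: str = "missing"):
        """Per-locus count of allele-2 copies and of counted copies.

        With ``het="missing"`` only homozygous calls contribute (one copy
        each); with ``het="half"`` a heterozygous call contributes half a
        copy of each allele.  Returns ``(n2, n)`` float arrays.
        """
        c = self.calls
        n_hom2 = (c == 2).sum(axis=0).astype(float)
        n_hom1 = (c == 0).sum(axis=0).astype(float)
        if het == "missing":
            return n_hom2, n_hom1 + n_hom2
        if het == "half":
            n_het = (c == 1).sum(axis=0).astype(float)
            return n_hom2 + 0.5 * n_het, n_hom1 + n_hom2 + n_het
        raise ValueError(f"unknown het policy {het!r}")

    def allele_freq(self, het: str = "missing") -> np.ndarray:
        """Frequency of allele 2 per locus; NaN where no calls are observed."""
        n2, n = self.allele_counts(het=het)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, n2 / np.maximum(n, 1), np.nan)

    def maf(self, het: str = "missing") -> np.ndarray:
        """Minor allele frequency min(p, 1-p) per locus; NaN if no calls."""
        p = self.allele_freq(het=het)
        return np.minimum(p, 1.0 - p)

    def n_observed_alleles(self) -> np.ndarray:
        """Number of distinct alleles observed per locus (0, 1 or 2).

        Heterozygous calls are ignored, consistent with the haploid reading
        of inbred lines.
        """
        has1 = (self.calls == 0).any(axis=0)
        has2 = (self.calls == 2).any(axis=0)
        return has1.astype(int) + has2.astype(int)


# ---------------------------------------------------------------------- #
# construction helpers
# ---------------------------------------------------------------------- #
def sort_loci(loci: pd.DataFrame) -> pd.DataFrame:
    """Canonical locus order: (genome, chromosome, cM, locus_id)."""
    return loci.sort_values(
        ["genome", "chromosome", "position_cM", "locus_id"],
        kind="mergesort",
    ).reset_index(drop=True)


def make_panel(lines: pd.DataFrame, loci: pd.DataFrame, calls: np.ndarray) -> GenotypePanel:
    """Build a panel, sorting loci into canonical map order."""
    loci = loci.reset_index(drop=True)
    order = sort_loci(loci.assign(_i=np.arange(len(loci))))
    calls = np.asarray(calls, dtype=np.int8)[:, order["_i"].to_numpy()]
    return GenotypePanel(lines, order.drop(columns="_i"), calls)


# ---------------------------------------------------------------------- #
# readers / writers
# ---------------------------------------------------------------------- #
def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_panel(panel_tsv_path, map_tsv_path, meta_tsv_path) -> GenotypePanel:
    """Read the panel TSV trio; loci come back in canonical map order.

    Raises :class:`PanelFormatError` naming the offending id when a matrix
    column lacks a map entry, a matrix row lacks metadata, or a cell holds a
    code outside ``{0,1,2,NA}``.
    """
    mat = pd.read_csv(panel_tsv_path, sep="\t", comment="#", dtype=str)
    if mat.columns[0] != "line_id":
        raise PanelFormatError("matrix file must start with a line_id column")
    locus_ids = list(mat.columns[1:])

    gmap = _read_tsv(map_tsv_path)
    gmap = gmap.rename(columns={"cM": "position_cM"})
    missing_cols = [c for c in LOCUS_COLUMNS if c not in gmap.columns]
    if missing_cols:
        raise PanelFormatError(f"map file lacks columns {missing_cols}")
    gmap["position_cM"] = gmap["position_cM"].astype(float)
    map_ids = set(gmap["locus_id"])
    for lid in locus_ids:
        if lid not in map_ids:
            raise PanelFormatError(f"matrix column {lid!r} has no map entry")

    meta = _read_tsv(meta_tsv_path)
    missing_cols = [c for c in LINE_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise PanelFormatError(f"metadata file lacks columns {missing_cols}")
    meta_ids = set(meta["line_id"])
    for lid in mat["line_id"]:
        if lid not in meta_ids:
            raise PanelFormatError(f"matrix line {lid!r} has no metadata entry")

    cells = mat[locus_ids].to_numpy()
    calls = np.full(cells.shape, MISSING, dtype=np.int8)
    for code, value in (("0", 0), ("1", 1), ("2", 2)):
        calls[cells == code] = value
    bad = ~np.isin(cells, ["0", "1", "2", "NA"]) & ~pd.isna(cells)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise PanelFormatError(
            f"invalid call code {cells[i, j]!r} for line "
            f"{mat['line_id'].iloc[i]!r}, locus {locus_ids[j]!r}"
        )

    lines = (
        meta.set_index("line_id")
        .loc[mat["line_id"], LINE_COLUMNS[1:]]
        .reset_index()
    )
    loci = gmap.set_index("locus_id").loc[locus_ids].reset_index()
    return make_panel(lines, loci[gmap.columns.tolist()], calls)


def write_panel(panel: GenotypePanel, panel_tsv_path, map_tsv_path, meta_tsv_path,
                comment: str | None = None) -> None:
    """Write the TSV trio; `read_panel` of the result reproduces the panel."""
    header = f"# {comment}\n" if comment else ""
    cells = np.empty(panel.calls.shape, dtype=object)
    for code, value in (("0", 0), ("1", 1), ("2", 2), ("NA", MISSING)):
        cells[panel.calls == value] = code
    mat = pd.DataFrame(cells, columns=panel.locus_ids)
    mat.insert(0, "line_id", panel.line_ids)
    for path, frame in (
        (panel_tsv_path, mat),
        (map_tsv_path, panel.loci),
        (meta_tsv_path, panel.lines[LINE_COLUMNS]),
    ):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(header)
            frame.to_csv(fh, sep="\t", index=False)


def read_vcf(vcf_path, meta_tsv_path, cm_map) -> GenotypePanel:
    """Read a biallelic-SNP VCF into a panel.

    ``cm_map`` is a map TSV path or DataFrame with the genetic-map columns;
    a VCF record's ``ID`` names the locus.  GT fields are recoded
    ``0/0 -> 0``, ``0/1 or 1/0 -> 1``, ``1/1 -> 2``, ``./. -> MISSING``.
    Records with more than one ALT allele or non-SNP alleles are dropped
    with a logged count.
    """
    from cyvcf2 import VCF

    if isinstance(cm_map, (str, bytes)) or hasattr(cm_map, "__fspath__"):
        gmap = _read_tsv(cm_map).rename(columns={"cM": "position_cM"})
        gmap["position_cM"] = gmap["position_cM"].astype(float)
    else:
        gmap = cm_map.copy()

    meta = _read_tsv(meta_tsv_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    overlap = set(samples) & set(meta["line_id"])
    if not overlap:
        raise PanelFormatError("no overlap between VCF samples and metadata line ids")

    rows, ids, n_dropped = [], [], 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_dropped += 1
            continue
        # gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = rec.gt_types
        col = np.full(len(samples), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        rows.append(col)
        ids.append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}")
    if n_dropped:
        logger.warning("dropped %d non-biallelic/non-SNP VCF records", n_dropped)
    if not rows:
        raise PanelFormatError("VCF contains no biallelic SNP records")

    calls = np.stack(rows, axis=1)
    map_ids = set(gmap["locus_id"])
    for lid in ids:
        if lid not in map_ids:
            raise PanelFormatError(f"VCF locus {lid!r} has no map entry")
    loci = gmap.set_index("locus_id").loc[ids].reset_index()

    keep = [i for i, s in enumerate(samples) if s in overlap]
    lines = (
        meta.set_index("line_id")
        .loc[[samples[i] for i in keep], LINE_COLUMNS[1:]]
        .reset_index()
    )
    return make_panel(lines, loci, calls[keep, :])


def write_vcf(panel: GenotypePanel, path, bp_per_cM: float = 1e6) -> None:
    """Emit the panel as an uncompressed VCF 4.2 with dummy bp positions.

    Physical positions are ``round(position_cM * bp_per_cM)`` since the
    panel carries only genetic coordinates; alleles default to A/B labels
    mapped onto A and T nucleotides when the map carries no allele columns.
    """
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    loci = panel.loci
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(loci["chromosome"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.line_ids)
            + "\n"
        )
        for j in range(panel.n_loci):
            row = loci.iloc[j]
            ref = str(row.get("allele1", "A"))
            alt = str(row.get("allele2", "T"))
            if ref not in "ACGT":
                ref, alt = "A", "T"
            pos = int(round(row["position_cM"] * bp_per_cM)) + 1
            gts = "\t".join(gt_of[int(c)] for c in panel.calls[:, j])
            fh.write(
                f"{row['chromosome']}\t{pos}\t{row['locus_id']}\t{ref}\t{alt}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------- #
# transformations
# ---------------------------------------------------------------------- #
def recode_het_missing(panel: GenotypePanel) -> GenotypePanel:
    """Return a copy with every heterozygous call recoded as missing.

    Idempotent; the standard preprocessing step before any statistic that
    treats inbred lines as haploid allele copies.
    """
    calls = panel.calls.copy()
    calls[calls == 1] = MISSING
    return GenotypePanel(panel.lines, panel.loci, calls)


def summarize_calls(panel: GenotypePanel, loci_subset=None) -> CallSummary:
    """Tally hom / het / missing calls, optionally over a locus subset."""
    p = panel if loci_subset is None else panel.subset_loci(loci_subset)
    if p.n_loci == 0 or p.n_lines == 0:
        raise ValueError("cannot summarize an empty matrix")
    c = p.calls
    n_het = int((c == 1).sum())
    n_missing = int((c == MISSING).sum())
    n_hom = int(c.size - n_het - n_missing)
    return CallSummary(n_hom=n_hom, n_het=n_het, n_missing=n_missing)


def filter_loci(
    panel: GenotypePanel,
    maf_min: float = 0.05,
    max_missing: float = 1.0,
    keep_polymorphic_only: bool = True,
    maf_inclusive: bool = False,
    het: str = "missing",
) -> tuple[GenotypePanel, FilterReport]:
    """Apply MAF, missingness and polymorphism filters, in that order.

    The MAF rule is strict (``MAF > maf_min``) by default, matching the
    convention of keeping alleles *above* the cutoff; ``maf_inclusive=True``
    switches to ``MAF >= maf_min``.  Monomorphic loci (MAF 0 or undefined)
    always fail the MAF rule when ``maf_min > 0``.
    """
    if not 0 <= maf_min < 0.5:
        raise ValueError("maf_min must lie in [0, 0.5)")
    maf = panel.maf(het=het)
    maf_filled = np.where(np.isnan(maf), 0.0, maf)
    if maf_inclusive:
        pass_maf = maf_filled >= maf_min
    else:
        pass_maf = maf_filled > maf_min
    n_removed_maf = int((~pass_maf).sum())

    frac_missing = (panel.calls == MISSING).mean(axis=0)
    pass_missing = frac_missing <= max_missing
    n_removed_missing = int((pass_maf & ~pass_missing).sum())

    keep = pass_maf & pass_missing
    if keep_polymorphic_only:
        poly = panel.n_observed_alleles() >= 2
        n_removed_mono = int((keep & ~poly).sum())
        keep &= poly
    else:
        n_removed_mono = 0

    if not keep.any():
        raise ValueError(
            "all loci removed by filtering; review maf_min/max_missing thresholds"
        )
    report = FilterReport(
        n_input=panel.n_loci,
        n_removed_maf=n_removed_maf,
        n_removed_missing=n_removed_missing,
        n_removed_monomorphic=n_removed_mono,
        n_kept=int(keep.sum()),
    )
    return panel.subset_loci(keep), report


def thin_by_distance(panel: GenotypePanel, min_cM: float) -> GenotypePanel:
    """Greedy per-chromosome thinning to loci >= ``min_cM`` apart.

    Walking each chromosome left to right in map order, the first locus is
    kept and every subsequent locus is kept iff it lies at least ``min_cM``
    from the last kept locus.  Deterministic given the canonical locus
    order (cM ties broken by locus_id).
    """
    keep = np.zeros(panel.n_loci, dtype=bool)
    loci = panel.loci
    for _, idx in loci.groupby("chromosome", sort=False).indices.items():
        last = None
        for j in idx:  # idx already in map order within chromosome
            pos = loci["position_cM"].iloc[j]
            if last is None or pos - last >= min_cM:
                keep[j] = True
                last = pos
    return panel.subset_loci(keep)


def exclude_regions(panel: GenotypePanel, regions) -> GenotypePanel:
    """Drop loci inside closed (chromosome, start_cM, end_cM) intervals."""
    drop = np.zeros(panel.n_loci, dtype=bool)
    for chrom, lo, hi in regions:
        drop |= (
            (panel.loci["chromosome"] == chrom)
            & (panel.loci["position_cM"] >= lo)
            & (panel.loci["position_cM"] <= hi)
        ).to_numpy()
    return panel.subset_loci(~drop)
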
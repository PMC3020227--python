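"""End-to-end pipeline: simulate/read -> filter -> diversity -> F_ST scan
-> LD, with deterministic outputs and a checksummed manifest.

Every stochastic stage consumes a sub-seed derived from the run seed, so
re-running with the same configuration reproduces byte-identical output
files.  Stage outputs land under ``<out_dir>/stages/``, report-shaped
tables under ``<out_dir>/report/``, and ``MANIFEST.tsv`` lists every file
with its SHA-256 checksum.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import diversity_table, maf_spectrum, spectrum_chi2
from .fst import AnalysisConfig, fst_scan, hierarchical_components
from .io import (
    GenotypePanel,
    filter_loci,
    read_panel,
    recode_het_missing,
    summarize_calls,
    write_panel,
)
from .ld import GabrielParams, decay_curve, gabriel_blocks, ld_pair_table, ld_summary
from .simulate import SimConfig, simulate_panel, write_truth

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "make_report"]


@dataclass
class RunConfig:
    """One pipeline run: either input paths or a simulation config.

    Exactly one of ``input_paths`` (dict with keys ``panel, map, meta``)
    and ``sim`` must be set.
    """

    out_dir: str
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    sim: SimConfig | None = None
    input_paths: dict | None = None
    ld_min_complete: int = 10
    gabriel: GabrielParams = field(default_factory=GabrielParams)
    group_column: str = "growth_habit"

    def __post_init__(self):
        if (self.sim is None) == (self.input_paths is None):
            raise ValueError("exactly one of sim and input_paths must be given")

    def config_hash(self) -> str:
        text = json.dumps(
            {
                "analysis": self.analysis.__dict__,
                "sim": self.sim.__dict__ if self.sim else None,
                "input_paths": self.input_paths,
                "ld_min_complete": self.ld_min_complete,
                "gabriel": self.gabriel.__dict__,
                "group_column": self.group_column,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, header_lines) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return a dict of in-memory results.

    Stage order: acquire panel, het->missing recode, locus filtering,
    diversity, differentiation scan plus hierarchical components, LD.
    Any stage error aborts the run (exceptions carry the stage in their
    message).  See the module docstring for the on-disk layout.
    """
    out = Path(config.out_dir)
    stages = out / "stages"
    stages.mkdir(parents=True, exist_ok=True)
    header = [
        f"panelpop {__version__}",
        f"config_hash {config.config_hash()}",
        f"seed {config.analysis.seed}",
    ]
    results: dict = {}

    # --- stage 1: panel ------------------------------------------------ #
    if config.sim is not None:
        panel, truth = simulate_panel(config.sim)
        write_truth(truth, stages / "truth.tsv")
        results["truth"] = truth
    else:
        panel = read_panel(
            config.input_paths["panel"],
            config.input_paths["map"],
            config.input_paths["meta"],
        )
    write_panel(
        panel,
        stages / "panel_matrix.tsv",
        stages / "panel_map.tsv",
        stages / "panel_meta.tsv",
        comment=f"panelpop {__version__} config_hash {config.config_hash()}",
    )
    summary = summarize_calls(panel)
    _write_tsv(pd.DataFrame([summary.as_dict()]), stages / "call_summary.tsv", header)
    results["panel"] = panel
    results["call_summary"] = summary

    # --- stage 2: recode + filter -------------------------------------- #
    panel = recode_het_missing(panel)
    filtered, report = filter_loci(
        panel, maf_min=config.analysis.maf_min, keep_polymorphic_only=True
    )
    _write_tsv(pd.DataFrame([report.as_dict()]), stages / "filter_report.tsv", header)
    results["filtered"] = filtered
    results["filter_report"] = report

    # --- stage 3: diversity -------------------------------------------- #
    tables = []
    for strat in ("population", "growth_habit", "total"):
        t = diversity_table(filtered, strat, min_lines=config.analysis.min_lines)
        t.insert(0, "stratification", strat)
        tables.append(t)
    div = pd.concat(tables, ignore_index=True)
    _write_tsv(div, stages / "diversity.tsv", header)
    results["diversity"] = div

    habits = pd.unique(filtered.lines[config.group_column])
    if len(habits) == 2:
        spec_a = maf_spectrum(filtered, habits[0])
        spec_b = maf_spectrum(filtered, habits[1])
        chi2, df, p = spectrum_chi2(spec_a, spec_b)
        spectra = pd.DataFrame(
            {
                "bin_low": spec_a.bin_edges[:-1],
                "bin_high": spec_a.bin_edges[1:],
                f"count_{habits[0]}": spec_a.counts,
                f"count_{habits[1]}": spec_b.counts,
            }
        )
        _write_tsv(spectra, stages / "maf_spectrum.tsv",
                   header + [f"chi2 {chi2:.6g} df {df} p {p:.6g}"])
        results["maf_chi2"] = (chi2, df, p)

    # --- stage 4: differentiation --------------------------------------- #
    scan = fst_scan(filtered, config.group_column, config.analysis)
    _write_tsv(scan["per_locus"], stages / "fst_per_locus.tsv", header)
    _write_tsv(scan["windows"], stages / "fst_windows.tsv",
               header + [f"threshold {scan['threshold']:.10g}"])
    _write_tsv(scan["regions"], stages / "fst_regions.tsv",
               header + [f"threshold {scan['threshold']:.10g}"])
    _write_tsv(scan["summary"], stages / "fst_summary.tsv", header)
    results["scan"] = scan

    comps = {"combined": hierarchical_components(
        filtered, config.group_column, min_lines=config.analysis.min_lines)}
    for habit in habits:
        sub = filtered.subset_lines(
            (filtered.lines[config.group_column] == habit).to_numpy()
        )
        comps[habit] = hierarchical_components(
            sub, None, min_lines=config.analysis.min_lines
        )
    comp_rows = []
    for name, c in comps.items():
        comp_rows.append(
            {
                "sample": name,
                "n_groups": c["n_groups"],
                "n_subpopulations": c["n_populations"],
                "pct_within_subpop": c["percent"]["within_pop"],
                "pct_among_subpop_within_group": c["percent"]["among_pop_within_group"],
                "pct_among_group": c["percent"]["among_group"],
                "flags": ";".join(c["flags"]),
            }
        )
    comp_df = pd.DataFrame(comp_rows)
    _write_tsv(comp_df, stages / "variance_components.tsv", header)
    results["variance_components"] = comp_df

    # --- stage 5: LD ----------------------------------------------------- #
    pairs = ld_pair_table(
        filtered,
        min_complete=config.ld_min_complete,
        fdr_q=config.analysis.fdr_q,
        with_dprime_ci=True,
        max_span_cM=config.gabriel.max_span_cM,
    )
    _write_tsv(pairs, stages / "ld_pairs.tsv", header)
    summary_ld = ld_summary(pairs)
    _write_tsv(pd.DataFrame([summary_ld]), stages / "ld_summary.tsv", header)
    results["ld_pairs"] = pairs
    results["ld_summary"] = summary_ld
    try:
        curve = decay_curve(pairs)
        _write_tsv(
            pd.DataFrame({"distance_cM": curve.grid_cM, "fitted_r2": curve.fitted_r2}),
            stages / "ld_decay.tsv",
            header + [
                f"initial_ld {curve.initial_ld:.10g}",
                f"half_decay_cM {curve.half_decay_cM:.10g}",
            ],
        )
        results["decay"] = curve
    except ValueError as err:
        logger.warning("decay curve skipped: %s", err)
    blocks = gabriel_blocks(pairs, filtered.loci, config.gabriel)
    _write_tsv(blocks, stages / "ld_blocks.tsv", header)
    results["blocks"] = blocks

    # --- report + manifest ----------------------------------------------- #
    make_report(out)
    manifest = _manifest(out)
    manifest.to_csv(out / "MANIFEST.tsv", sep="\t", index=False)
    results["manifest"] = manifest
    return results


def _manifest(out: Path) -> pd.DataFrame:
    rows = []
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "MANIFEST.tsv":
            rows.append(
                {"path": str(path.relative_to(out)), "sha256": _sha256(path)}
            )
    return pd.DataFrame(rows)


def make_report(out_dir) -> None:
    """Re-emit report-shaped tables from stage outputs.

    Reads only files under ``<out_dir>/stages/`` and writes the
    table-shaped summaries under ``<out_dir>/report/``; running it twice
    produces identical files.
    """
    out = Path(out_dir)
    stages = out / "stages"
    report = out / "report"
    report.mkdir(parents=True, exist_ok=True)

    def _read(name):
        p = stages / name
        return pd.read_csv(p, sep="\t", comment="#") if p.exists() else None

    def _copy(src_name, dst_name):
        df = _read(src_name)
        if df is not None:
            df.to_csv(report / dst_name, sep="\t", index=False, float_format="%.10g")

    div = _read("diversity.tsv")
    if div is not None:
        div.to_csv(report / "table_diversity.tsv", sep="\t", index=False,
                   float_format="%.10g")
    _copy("variance_components.tsv", "table_variance_components.tsv")
    _copy("fst_summary.tsv", "table_fst_summary.tsv")
    _copy("fst_regions.tsv", "table_elevated_regions.tsv")
    _copy("ld_summary.tsv", "table_ld_summary.tsv")
    _copy("ld_blocks.tsv", "table_ld_blocks.tsv")
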
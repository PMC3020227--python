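"""Weir-Cockerham theta, hierarchical components, windows, bootstrap
threshold and elevated-region calling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panelpop import (
    AnalysisConfig,
    bootstrap_threshold,
    elevated_regions,
    fst_scan,
    fst_summary,
    hierarchical_components,
    recode_het_missing,
    simulate_panel,
    sliding_window_means,
    wc_theta_loci,
    wc_theta_locus,
)

from conftest import build_panel, small_sim_config


def brute_force_theta(groups: list[np.ndarray]) -> float:
    """One-way ANOVA variance-component route on 0/1 allele indicators."""
    r = len(groups)
    n = np.array([len(g) for g in groups], dtype=float)
    means = np.array([g.mean() for g in groups])
    N = n.sum()
    grand = np.concatenate(groups).mean()
    msp = sum(ni * (mi - grand) ** 2 for ni, mi in zip(n, means)) / (r - 1)
    ssw = sum(((g - m) ** 2).sum() for g, m in zip(groups, means))
    msg = ssw / (N - r)
    n_c = (N - (n**2).sum() / N) / (r - 1)
    denom = msp + (n_c - 1) * msg
    return (msp - msg) / denom


class TestWcTheta:
    def test_fixed_opposite_alleles_gives_one(self):
        calls = np.array([[0] * 2] * 10 + [[2] * 2] * 10)
        panel = build_panel(calls, pops=["P1"] * 10 + ["P2"] * 10)
        res = wc_theta_loci(panel, "population")
        np.testing.assert_allclose(res["theta"], 1.0)

    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 7), (5, 12)])
    def test_fixed_opposite_any_sizes(self, n1, n2):
        calls = np.array([[0]] * n1 + [[2]] * n2)
        panel = build_panel(calls, pops=["P1"] * n1 + ["P2"] * n2)
        assert wc_theta_loci(panel, "population")["theta"].iloc[0] == pytest.approx(1.0)

    def test_equal_sample_frequencies_nonpositive(self):
        col = [0, 0, 2, 2]  # p = 0.5 in both populations
        panel = build_panel(
            np.array([col + col]).reshape(8, 1), pops=["P1"] * 4 + ["P2"] * 4
        )
        assert wc_theta_loci(panel, "population")["theta"].iloc[0] <= 0

    def test_monomorphic_locus_flagged_undefined(self):
        panel = build_panel(np.zeros((8, 1), dtype=int), pops=["P1"] * 4 + ["P2"] * 4)
        res = wc_theta_loci(panel, "population")
        assert not res["defined"].iloc[0]
        assert np.isnan(res["theta"].iloc[0])

    def test_single_group_is_error(self):
        panel = build_panel([[0], [2]], pops=["P1", "P1"], habits=["winter"] * 2)
        with pytest.raises(ValueError, match="2 groups"):
            wc_theta_loci(panel, "population")

    def test_matches_anova_oracle_on_random_instances(self, rng):
        """100 random instances, <=4 pops x <=6 lines, equality to 1e-9."""
        checked = 0
        while checked < 100:
            r = int(rng.integers(2, 5))
            sizes = rng.integers(2, 7, size=r)
            groups = [rng.integers(0, 2, size=s).astype(float) for s in sizes]
            flat = np.concatenate(groups)
            if flat.min() == flat.max():
                continue  # pooled monomorphic: estimator undefined
            calls = (2 * flat).astype(int).reshape(-1, 1)
            pops = sum([[f"P{k}"] * s for k, s in enumerate(sizes)], [])
            habits = ["winter" if k % 2 else "spring" for k, p in enumerate(pops)]
            panel = build_panel(calls, pops=pops, habits=None)
            res = wc_theta_loci(panel, "population")
            expected = brute_force_theta(groups)
            if not res["defined"].iloc[0]:
                continue
            assert res["theta"].iloc[0] == pytest.approx(expected, abs=1e-9)
            checked += 1

    def test_example_frequencies_against_oracle(self):
        # n1 = n2 = 4, p1 = 0.75, p2 = 0.25
        g1 = np.array([1.0, 1.0, 1.0, 0.0])
        g2 = np.array([0.0, 0.0, 0.0, 1.0])
        calls = (2 * np.concatenate([g1, g2])).astype(int).reshape(-1, 1)
        panel = build_panel(calls, pops=["P1"] * 4 + ["P2"] * 4)
        res = wc_theta_locus(panel, "population", "L000")
        assert res["theta"] == pytest.approx(brute_force_theta([g1, g2]), abs=1e-12)
        assert res["group_sizes"] == [4, 4]

    def test_permuted_labels_average_to_zero(self, rng):
        p = rng.uniform(0.1, 0.9, size=500)
        calls = (2 * (rng.random((200, 500)) < p)).astype(int)
        panel = build_panel(
            calls,
            chroms=["1A"] * 500,
            positions=[float(j) for j in range(500)],
            pops=["P1"] * 100 + ["P2"] * 100,
        )
        means = []
        for _ in range(100):
            labels = rng.permutation(np.array(["g1"] * 100 + ["g2"] * 100))
            res = wc_theta_loci(panel, labels)
            means.append(np.nanmean(res["theta"]))
        assert abs(np.mean(means)) < 0.01


class TestFstSummary:
    def test_constant_theta_gives_zero_sd(self):
        loci = pd.DataFrame(
            {
                "locus_id": [f"L{j}" for j in range(6)],
                "genome": ["A"] * 6,
                "chromosome": ["1A"] * 6,
                "position_cM": list(map(float, range(6))),
            }
        )
        results = pd.DataFrame(
            {"locus_id": loci["locus_id"], "theta": [0.3] * 6, "defined": True}
        )
        summary = fst_summary(results, loci, W=5)
        row = summary[summary["unit"] == "1A"].iloc[0]
        assert row["mean_fst"] == pytest.approx(0.3)
        assert row["sd_single_locus"] == pytest.approx(0.0)

    def test_single_locus_chromosome_sd_flagged(self):
        loci = pd.DataFrame(
            {
                "locus_id": ["L0"],
                "genome": ["A"],
                "chromosome": ["1A"],
                "position_cM": [0.0],
            }
        )
        results = pd.DataFrame({"locus_id": ["L0"], "theta": [0.2], "defined": True})
        row = fst_summary(results, loci).iloc[0]
        assert np.isnan(row["sd_single_locus"])

    def test_mean_sd_against_numpy(self, rng):
        theta = rng.uniform(0, 0.5, size=20)
        loci = pd.DataFrame(
            {
                "locus_id": [f"L{j}" for j in range(20)],
                "genome": ["A"] * 20,
                "chromosome": ["1A"] * 20,
                "position_cM": list(map(float, range(20))),
            }
        )
        results = pd.DataFrame(
            {"locus_id": loci["locus_id"], "theta": theta, "defined": True}
        )
        row = fst_summary(results, loci).iloc[0]
        assert row["mean_fst"] == pytest.approx(theta.mean())
        assert row["sd_single_locus"] == pytest.approx(theta.std(ddof=1))


class TestHierarchical:
    def test_opposite_fixed_groups_all_among_group(self):
        calls = np.array([[0] * 4] * 10 + [[2] * 4] * 10)
        pops = ["W1"] * 5 + ["W2"] * 5 + ["S1"] * 5 + ["S2"] * 5
        habits = ["winter"] * 10 + ["spring"] * 10
        panel = build_panel(calls, pops=pops, habits=habits)
        comp = hierarchical_components(panel)
        assert comp["percent"]["among_group"] == pytest.approx(100.0, abs=0.5)

    def test_no_structure_small_among_components(self, rng):
        p = rng.uniform(0.2, 0.8, size=500)
        calls = (2 * (rng.random((80, 500)) < p)).astype(int)
        pops = sum([[f"P{k}"] * 20 for k in range(4)], [])
        habits = ["winter"] * 40 + ["spring"] * 40
        panel = build_panel(
            calls, chroms=["1A"] * 500,
            positions=[float(j) for j in range(500)],
            pops=pops, habits=habits,
        )
        comp = hierarchical_components(panel)
        assert comp["percent"]["among_pop_within_group"] < 2.0
        assert comp["percent"]["among_group"] < 2.0

    def test_matches_sums_of_squares_oracle(self, rng):
        """2 groups x 2 pops, balanced: raw components equal a hand nested
        ANOVA within 1e-9 (balanced coefficients are simple)."""
        n = 6  # lines per population
        calls = (2 * (rng.random((4 * n, 3)) < 0.5)).astype(int)
        pops = sum([[f"P{k}"] * n for k in range(4)], [])
        habits = ["winter"] * (2 * n) + ["spring"] * (2 * n)
        panel = build_panel(calls, pops=pops, habits=habits)
        comp = hierarchical_components(panel, min_lines=1)

        sw = sp = sg = 0.0
        for j in range(3):
            x = (panel.calls[:, j] == 2).astype(float)
            groups = [x[: 2 * n], x[2 * n :]]
            pops_x = [x[i * n : (i + 1) * n] for i in range(4)]
            grand = x.mean()
            ss_w = sum(((p - p.mean()) ** 2).sum() for p in pops_x)
            ss_p = sum(
                n * (pops_x[i].mean() - groups[i // 2].mean()) ** 2 for i in range(4)
            )
            ss_g = sum(2 * n * (g.mean() - grand) ** 2 for g in groups)
            ms_w = ss_w / (4 * n - 4)
            ms_p = ss_p / 2
            ms_g = ss_g / 1
            var_w = ms_w
            var_p = (ms_p - ms_w) / n
            var_g = (ms_g - ms_w - n * var_p) / (2 * n)
            sw += var_w
            sp += var_p
            sg += var_g
        assert comp["raw"]["within_pop"] == pytest.approx(sw, abs=1e-9)
        assert comp["raw"]["among_pop_within_group"] == pytest.approx(sp, abs=1e-9)
        assert comp["raw"]["among_group"] == pytest.approx(sg, abs=1e-9)

    def test_percentages_sum_to_100(self, random_panel):
        comp = hierarchical_components(random_panel, min_lines=1)
        assert sum(comp["percent"].values()) == pytest.approx(100.0, abs=0.01)

    def test_single_group_reports_zero_among_group(self, random_panel):
        sub = random_panel.by_growth_habit("winter")
        comp = hierarchical_components(sub, None, min_lines=1)
        assert comp["percent"]["among_group"] == 0.0


class TestWindows:
    def _results(self, theta, chroms=None):
        n = len(theta)
        loci = pd.DataFrame(
            {
                "locus_id": [f"L{j}" for j in range(n)],
                "genome": ["A"] * n,
                "chromosome": chroms or ["1A"] * n,
                "position_cM": list(map(float, range(n))),
            }
        )
        results = pd.DataFrame(
            {
                "locus_id": loci["locus_id"],
                "theta": theta,
                "defined": [not np.isnan(t) for t in theta],
            }
        )
        return results, loci

    def test_worked_example(self):
        results, loci = self._results([0, 0, 1, 0, 0, 0, 0])
        win = sliding_window_means(results, loci, W=5)
        np.testing.assert_allclose(win["mean_theta"], [0.2, 0.2, 0.2])
        assert list(win["start_cM"]) == [0.0, 1.0, 2.0]
        assert list(win["end_cM"]) == [4.0, 5.0, 6.0]

    def test_constant_theta(self):
        results, loci = self._results([0.4] * 8)
        win = sliding_window_means(results, loci, W=5)
        np.testing.assert_allclose(win["mean_theta"], 0.4)

    def test_rolling_mean_oracle_and_conservation(self, rng):
        theta = rng.uniform(0, 1, size=30)
        results, loci = self._results(list(theta))
        win = sliding_window_means(results, loci, W=5)
        expected = pd.Series(theta).rolling(5).mean().dropna().to_numpy()
        np.testing.assert_allclose(win["mean_theta"], expected, atol=1e-12)
        # conservation: each window mean equals the mean of its member loci
        by_id = dict(zip(results["locus_id"], results["theta"]))
        for rec in win.itertuples():
            members = [by_id[i] for i in rec.locus_ids.split(",")]
            assert rec.mean_theta == pytest.approx(np.mean(members))

    def test_windows_never_span_chromosomes(self, rng):
        theta = list(rng.uniform(0, 1, size=12))
        results, loci = self._results(theta, chroms=["1A"] * 6 + ["2A"] * 6)
        win = sliding_window_means(results, loci, W=5)
        assert len(win) == 4  # 2 per chromosome
        for rec in win.itertuples():
            chrom_of = dict(zip(loci["locus_id"], loci["chromosome"]))
            assert len({chrom_of[i] for i in rec.locus_ids.split(",")}) == 1

    def test_short_chromosome_yields_no_windows(self):
        results, loci = self._results([0.1, 0.2, 0.3])
        assert len(sliding_window_means(results, loci, W=5)) == 0

    def test_undefined_loci_excluded(self):
        results, loci = self._results([0.0, np.nan, 1.0, 0.0, 0.0, 0.0])
        win = sliding_window_means(results, loci, W=5)
        assert len(win) == 1
        assert win["mean_theta"].iloc[0] == pytest.approx(0.2)


class TestBootstrap:
    def _frame(self, theta):
        return pd.DataFrame({"theta": theta, "defined": np.isfinite(theta)})

    def test_degenerate_distribution(self):
        res = self._frame(np.full(50, 0.1))
        assert bootstrap_threshold(res, W=5, B=100, seed=1) == pytest.approx(0.1)

    def test_deterministic_under_seed(self, rng):
        res = self._frame(rng.uniform(0, 1, 100))
        a = bootstrap_threshold(res, W=5, B=1000, seed=42)
        b = bootstrap_threshold(res, W=5, B=1000, seed=42)
        assert a == b

    def test_uniform_theta_matches_irwin_hall(self, rng):
        """Mean of 5 iid U(0,1) has a known 95th percentile (Irwin-Hall)."""
        res = self._frame(rng.uniform(0, 1, size=20_000))
        observed = bootstrap_threshold(res, W=5, B=200_000, percentile=95, seed=7)
        expected = stats.irwinhall(5).ppf(0.95) / 5
        assert observed == pytest.approx(expected, abs=0.005)

    def test_too_few_loci_is_error(self):
        with pytest.raises(ValueError, match="at least"):
            bootstrap_threshold(self._frame(np.array([0.1, 0.2])), W=5)


class TestElevatedRegions:
    def _windows(self, means, chrom="1A"):
        n = len(means)
        return pd.DataFrame(
            {
                "chromosome": [chrom] * n,
                "window_index": range(n),
                "start_cM": [float(10 * j) for j in range(n)],
                "end_cM": [float(10 * j + 8) for j in range(n)],
                "mean_theta": means,
                "locus_ids": [""] * n,
            }
        )

    def test_nothing_above_threshold(self):
        regions = elevated_regions(self._windows([0.1, 0.2]), threshold=0.5)
        assert len(regions) == 0

    def test_single_window_interval(self):
        win = self._windows([0.1, 0.6, 0.1])
        regions = elevated_regions(win, threshold=0.5)
        assert len(regions) == 1
        rec = regions.iloc[0]
        assert (rec["start_cM"], rec["end_cM"]) == (10.0, 18.0)
        assert rec["mean_theta"] == pytest.approx(0.6)

    def test_consecutive_windows_merge(self):
        win = self._windows([0.6, 0.7, 0.1, 0.8])
        regions = elevated_regions(win, threshold=0.5)
        assert len(regions) == 2
        first = regions.iloc[0]
        assert (first["start_cM"], first["end_cM"]) == (0.0, 18.0)
        assert first["mean_theta"] == pytest.approx(0.65)


class TestScanOnSimulatedPanel:
    def test_recovers_planted_region_and_variance_reduction(self):
        panel, truth = simulate_panel(small_sim_config(21))
        panel = recode_het_missing(panel)
        scan = fst_scan(panel, "growth_habit", AnalysisConfig(seed=21))
        hit = any(
            r.chromosome == "2A" and r.end_cM >= 40 and r.start_cM <= 60
            for r in scan["regions"].itertuples()
        )
        assert hit
        summary = scan["summary"]
        per_chrom = summary[summary["level"] == "chromosome"].dropna(
            subset=["sd_single_locus", "sd_windows"]
        )
        assert (per_chrom["sd_windows"] <= per_chrom["sd_single_locus"] + 1e-12).all()
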
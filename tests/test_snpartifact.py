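import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from coexnet.snpartifact import (
    GeneRegion,
    ModuleSnpCounts,
    count_snps_in_regions,
    eqtl_concordance,
    fisher_exact_2x2,
    flag_probe_snps,
    module_enrichment_report,
)


def catalog(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "cls"])


def fisher_bruteforce(a, b, c, d):
    """Two-sided exact p by full enumeration of tables with fixed margins."""
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    probs = {x: hypergeom.pmf(x, n, row1, col1) for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestGeneRegion:
    def test_validation(self):
        with pytest.raises(ValueError, match="start"):
            GeneRegion("p", "chr1", 100, 50)
        with pytest.raises(ValueError, match="margin"):
            GeneRegion("p", "chr1", 1, 10, margin=-1)
        with pytest.raises(ValueError, match="1-based"):
            GeneRegion("p", "chr1", 0, 10)


class TestCountSnpsInRegions:
    def test_empty_catalog(self):
        regions = [GeneRegion("p0", "chr1", 1000, 20_999)]
        asg = pd.Series({"p0": "m"})
        out = count_snps_in_regions(regions, catalog([]), asg)
        assert out["m"].total_snps == 0
        assert out["m"].pct_bp == 0.0

    def test_window_margin_and_left_clip(self):
        # region 1,000-20,999 with 10 kb margin: window clipped to [1, 30,999]
        regions = [GeneRegion("p0", "chr1", 1000, 20_999, margin=10_000)]
        asg = pd.Series({"p0": "m"})
        cat = catalog([("chr1", 500, "other"), ("chr1", 31_500, "other")])
        out = count_snps_in_regions(regions, cat, asg)
        assert out["m"].bp_checked == 40_000
        assert out["m"].total_snps == 1  # 500 inside, 31,500 outside

    def test_boundary_positions_inclusive(self):
        regions = [GeneRegion("p0", "chr1", 5000, 6000, margin=0)]
        asg = pd.Series({"p0": "m"})
        cat = catalog([("chr1", 5000, "other"), ("chr1", 6000, "other"),
                       ("chr1", 4999, "other"), ("chr1", 6001, "other")])
        out = count_snps_in_regions(regions, cat, asg)
        assert out["m"].total_snps == 2

    def test_undeclared_chromosome_rejected(self):
        regions = [GeneRegion("p0", "chrX", 1, 100)]
        with pytest.raises(ValueError, match="chrX"):
            count_snps_in_regions(regions, catalog([("chr1", 5, "other")]), pd.Series({"p0": "m"}))

    def test_published_count_table_percentages(self):
        # counts as printed for the three trait-associated modules
        rows = {
            "magenta": ModuleSnpCounts("magenta", 21_218_367, 7128, 59),
            "pink": ModuleSnpCounts("pink", 8_637_477, 8193, 19),
            "red": ModuleSnpCounts("red", 15_909_861, 10_464, 49),
        }
        expect = {"magenta": (0.03, 0.83), "pink": (0.09, 0.23), "red": (0.07, 0.47)}
        for name, counts in rows.items():
            assert counts.pct_bp == expect[name][0]
            assert counts.pct_nonsyn_of_snps == expect[name][1]


class TestFlagProbeSnps:
    @staticmethod
    def probes(start=1000, end=1049):
        return pd.DataFrame(
            {"chrom": ["chr1"], "probe_start": [start], "probe_end": [end]}, index=["p0"]
        )

    def test_boundaries(self):
        assert flag_probe_snps(self.probes(), catalog([("chr1", 1000, "other")]))["snp_in_probe"].iloc[0]
        assert flag_probe_snps(self.probes(), catalog([("chr1", 1049, "other")]))["snp_in_probe"].iloc[0]
        assert not flag_probe_snps(self.probes(), catalog([("chr1", 1050, "other")]))["snp_in_probe"].iloc[0]
        assert not flag_probe_snps(self.probes(), catalog([("chr1", 999, "other")]))["snp_in_probe"].iloc[0]

    def test_generator_roundtrip(self, default_dataset):
        ds = default_dataset
        flagged = flag_probe_snps(ds.probe_records, ds.snp_catalog)
        pd.testing.assert_series_equal(
            flagged["snp_in_probe"], ds.probe_records["snp_in_probe"]
        )
        rate = flagged["snp_in_probe"].groupby(ds.truth).mean()
        assert abs(rate["strain_artifact"] - 0.4) < 0.15
        assert rate["none"] < 0.05


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, expected, tol",
        [
            ((13, 19, 7, 37), 0.0195, 0.0005),  # printed as 0.02
            ((59, 7069, 19, 8174), 2.58e-07, None),  # printed as 2.6e-07
            ((32, 44, 1, 83), 1.28e-11, None),  # printed as 1.3e-11
        ],
    )
    def test_published_pvalues(self, table, expected, tol):
        _, p = fisher_exact_2x2(*table)
        if tol is None:
            assert p == pytest.approx(expected, rel=0.02)
        else:
            assert p == pytest.approx(expected, abs=tol)

    @pytest.mark.parametrize("table, bound", [((32, 44, 3, 195), 2.2e-16), ((16, 28, 3, 29), 0.01)])
    def test_published_bounds(self, table, bound):
        _, p = fisher_exact_2x2(*table)
        assert p < bound

    def test_empty_first_column_gives_one(self):
        _, p = fisher_exact_2x2(0, 12, 0, 30)
        assert p == pytest.approx(1.0)

    def test_invalid_tables(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError, match="zero"):
            fisher_exact_2x2(0, 0, 0, 0)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 21, size=4)
            if a + b + c + d == 0 or (a + c == 0 and b + d == 0):
                continue
            _, p = fisher_exact_2x2(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(fisher_bruteforce(a, b, c, d), abs=1e-10)

    def test_symmetry_invariances(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            a, b, c, d = (int(v) for v in rng.integers(0, 15, size=4))
            if a + b + c + d == 0:
                continue
            _, p = fisher_exact_2x2(a, b, c, d)
            _, p_t = fisher_exact_2x2(a, c, b, d)  # transpose
            _, p_s = fisher_exact_2x2(d, c, b, a)  # swap both rows and columns
            assert p == pytest.approx(p_t, abs=1e-12)
            assert p == pytest.approx(p_s, abs=1e-12)

    def test_odds_ratio(self):
        odds, _ = fisher_exact_2x2(10, 5, 2, 8)
        assert odds == pytest.approx((10 * 8) / (5 * 2))


class TestEnrichmentReport:
    @staticmethod
    def probe_table(flags_by_module):
        rows = []
        for module, flags in flags_by_module.items():
            for i, f in enumerate(flags):
                rows.append((f"{module}_{i}", module, f))
        return pd.DataFrame(rows, columns=["probe", "module", "snp_in_probe"]).set_index("probe")

    def test_identical_modules_give_p_one(self):
        counts = {
            "a": ModuleSnpCounts("a", 10_000, 50, 5),
            "b": ModuleSnpCounts("b", 10_000, 50, 5),
        }
        probes = self.probe_table({"a": [True] * 5 + [False] * 5, "b": [True] * 5 + [False] * 5})
        report = module_enrichment_report(counts, probes)
        assert np.allclose(report["p"], 1.0)

    def test_report_structure_and_tables(self):
        counts = {
            "a": ModuleSnpCounts("a", 10_000, 100, 10),
            "b": ModuleSnpCounts("b", 20_000, 50, 2),
        }
        probes = self.probe_table({"a": [True] * 8 + [False] * 2, "b": [False] * 10})
        report = module_enrichment_report(counts, probes)
        assert set(report["test"]) == {"snp_density", "nonsyn_fraction", "probe_snp"}
        row = report[report["test"] == "probe_snp"].iloc[0]
        assert (row["a"], row["b"], row["c"], row["d"]) == (8, 2, 0, 10)
        dens = report[report["test"] == "snp_density"].iloc[0]
        assert dens["b"] == 10_000 - 100

    def test_untestable_pair_marked(self):
        counts = {
            "a": ModuleSnpCounts("a", 10_000, 0, 0),
            "b": ModuleSnpCounts("b", 10_000, 0, 0),
        }
        probes = self.probe_table({"a": [False] * 3, "b": [False] * 3})
        report = module_enrichment_report(counts, probes)
        row = report[report["test"] == "nonsyn_fraction"].iloc[0]
        assert not row["testable"]


class TestEqtlConcordance:
    @staticmethod
    def module_probes():
        # 32 SNP-flagged probes (13 false-cis, 3 real-cis) and 44 unflagged
        # (7 false-cis, 16 real-cis): the published concordance pattern
        rows = []
        status_flagged = ["false_cis"] * 13 + ["real_cis"] * 3 + ["none"] * 16
        status_unflagged = ["false_cis"] * 7 + ["real_cis"] * 16 + ["none"] * 21
        for i, st in enumerate(status_flagged):
            rows.append((f"f{i}", "m", True, st))
        for i, st in enumerate(status_unflagged):
            rows.append((f"u{i}", "m", False, st))
        return pd.DataFrame(rows, columns=["probe", "module", "snp_in_probe", "eqtl_status"]).set_index("probe")

    def test_published_concordance_tables(self):
        out = eqtl_concordance(self.module_probes(), "m")
        odds_f, p_f, table_f = out["false_cis"]
        assert table_f == (13, 19, 7, 37)
        assert p_f == pytest.approx(0.0195, abs=0.0005)
        _, p_r, table_r = out["real_cis"]
        assert table_r == (16, 28, 3, 29)
        assert p_r < 0.01

    def test_missing_status_errors(self):
        probes = self.module_probes()
        probes["eqtl_status"] = "unknown"
        with pytest.raises(ValueError, match="eQTL"):
            eqtl_concordance(probes, "m")

    def test_null_statuses_give_conservative_p(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            n = 76
            probes = pd.DataFrame(
                {
                    "module": "m",
                    "snp_in_probe": rng.random(n) < 0.42,
                    "eqtl_status": np.where(rng.random(n) < 0.26, "false_cis", "none"),
                },
                index=[f"p{i}" for i in range(n)],
            )
            out = eqtl_concordance(probes, "m")
            ps.append(out["false_cis"][1])
        ps = np.array(ps)
        # exact-test p-values under the null are discrete and conservative:
        # they should never reject in excess of the nominal rate
        assert (ps < 0.05).mean() <= 0.075
        assert (ps < 0.2).mean() <= 0.25
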
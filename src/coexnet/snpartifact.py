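"""SNP enrichment diagnostics for hybridization artifacts.

Probes are short (50-mer) oligos designed against one reference strain; a
sequence polymorphism between strains inside a probe's target weakens
hybridization in the non-reference strain and shows up as spurious
strain-differential expression.  This module counts SNPs in module target
genes (with a flanking margin), flags SNP-containing probes, runs pairwise
Fisher exact enrichment tests between modules, and tests whether SNP-flagged
probes are enriched for apparent ("false cis") versus real cis-eQTL signals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

DEFAULT_MARGIN = 10_000
SNP_CLASSES = ("non_synonymous", "synonymous", "other")
EQTL_STATUSES = ("real_cis", "false_cis", "none", "unknown")


@dataclass(frozen=True)
class GeneRegion:
    """A probe's target-gene interval (1-based inclusive) plus flank margin."""

    probe: str
    chrom: str
    start: int
    end: int
    margin: int = DEFAULT_MARGIN

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region for {self.probe}: start {self.start} > end {self.end}")
        if self.margin < 0:
            raise ValueError("margin must be >= 0")
        if self.start < 1:
            raise ValueError("coordinates are 1-based; start must be >= 1")


@dataclass(frozen=True)
class ModuleSnpCounts:
    """Per-module totals in the style of a SNP-count summary table."""

    module: str
    bp_checked: int
    total_snps: int
    nonsyn_snps: int

    @property
    def pct_bp(self) -> float:
        """SNPs as a percentage of interrogated bp, rounded half-up to 2 dp."""
        return _round2(100.0 * self.total_snps / self.bp_checked) if self.bp_checked else 0.0

    @property
    def pct_nonsyn_of_snps(self) -> float:
        """Non-synonymous SNPs as a percentage of total SNPs, 2 dp."""
        return _round2(100.0 * self.nonsyn_snps / self.total_snps) if self.total_snps else 0.0


def _round2(x: float) -> float:
    # round half away from zero, to match printed-table formatting
    return float(np.floor(x * 100.0 + 0.5) / 100.0)


def _validate_catalog(catalog: pd.DataFrame) -> pd.DataFrame:
    if (catalog["pos"] < 1).any():
        raise ValueError("SNP positions are 1-based; found position < 1")
    bad = set(catalog["cls"]) - set(SNP_CLASSES)
    if bad:
        raise ValueError(f"unknown SNP classes: {sorted(bad)}")
    return catalog


def count_snps_in_regions(
    regions: list[GeneRegion],
    catalog: pd.DataFrame,
    assignment: pd.Series,
) -> dict[str, ModuleSnpCounts]:
    """Per-module SNP totals over target-gene regions extended by the margin.

    bp_checked sums (end - start + 1 + 2 * margin) over a module's regions
    (overlaps counted additively); a SNP is counted when its position lies in
    [start - margin, end + margin], with windows clipped at position 1.
    """
    _validate_catalog(catalog)
    declared = set(catalog["chrom"])
    by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in catalog.groupby("chrom")}
    nonsyn_by_chrom = {
        c: np.sort(g.loc[g["cls"] == "non_synonymous", "pos"].to_numpy())
        for c, g in catalog.groupby("chrom")
    }
    out: dict[str, dict[str, int]] = {}
    for reg in regions:
        if declared and reg.chrom not in declared:
            raise ValueError(f"region for {reg.probe} on undeclared chromosome {reg.chrom!r}")
        module = assignment.get(reg.probe)
        if module is None:
            continue
        acc = out.setdefault(module, {"bp": 0, "total": 0, "nonsyn": 0})
        lo = max(1, reg.start - reg.margin)
        hi = reg.end + reg.margin
        acc["bp"] += reg.end - reg.start + 1 + 2 * reg.margin
        for key, pool in (("total", by_chrom), ("nonsyn", nonsyn_by_chrom)):
            pos = pool.get(reg.chrom)
            if pos is not None and pos.size:
                acc[key] += int(np.searchsorted(pos, hi, "right") - np.searchsorted(pos, lo, "left"))
    return {
        m: ModuleSnpCounts(module=m, bp_checked=a["bp"], total_snps=a["total"], nonsyn_snps=a["nonsyn"])
        for m, a in out.items()
    }


def flag_probe_snps(probes: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Set ``snp_in_probe`` where >= 1 SNP lies within the probe's interval.

    Probe intervals are 1-based inclusive on both ends.  Returns a copy of
    ``probes`` with the flag column rewritten from the catalog.
    """
    _validate_catalog(catalog)
    by_chrom = {c: np.sort(g["pos"].to_numpy()) for c, g in catalog.groupby("chrom")}
    flags = np.zeros(len(probes), dtype=bool)
    for i, (_, rec) in enumerate(probes.iterrows()):
        pos = by_chrom.get(rec["chrom"])
        if pos is None or not pos.size:
            continue
        n = np.searchsorted(pos, rec["probe_end"], "right") - np.searchsorted(pos, rec["probe_start"], "left")
        flags[i] = n > 0
    out = probes.copy()
    out["snp_in_probe"] = flags
    return out


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Fisher's exact test for the 2x2 table [[a, b], [c, d]].

    Returns (sample odds ratio a*d / (b*c), two-sided p).  The two-sided p
    follows the minimum-likelihood convention: the probabilities of all
    tables with the same margins that are no more likely than the observed
    table are summed (the convention of standard count-data software).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all-zero table is untestable")
    odds, p = fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(odds), float(p)


def module_enrichment_report(
    counts: dict[str, ModuleSnpCounts],
    probes: pd.DataFrame,
    assignment: pd.Series | None = None,
) -> pd.DataFrame:
    """Pairwise module comparisons: SNP density, non-synonymous fraction,
    and SNP-containing-probe enrichment.

    For each ordered module pair three 2x2 Fisher tests are reported:
    (i) total SNPs vs interrogated bp, (ii) non-synonymous vs other SNPs,
    (iii) SNP-flagged vs unflagged probes.  Each row carries the full 2x2
    table, the odds ratio and the p-value; untestable rows (a zero margin)
    are marked.
    """
    modules = sorted(counts, key=lambda m: (-counts[m].total_snps, m))
    if len(modules) < 2:
        raise ValueError("need at least 2 modules to compare")
    module_of = assignment if assignment is not None else probes["module"]
    flags = probes["snp_in_probe"]

    rows = []
    for i, m1 in enumerate(modules):
        for m2 in modules[i + 1 :]:
            c1, c2 = counts[m1], counts[m2]
            f1 = int(flags[module_of == m1].sum())
            n1 = int((module_of == m1).sum())
            f2 = int(flags[module_of == m2].sum())
            n2 = int((module_of == m2).sum())
            tables = {
                "snp_density": (c1.total_snps, c1.bp_checked - c1.total_snps,
                                c2.total_snps, c2.bp_checked - c2.total_snps),
                "nonsyn_fraction": (c1.nonsyn_snps, c1.total_snps - c1.nonsyn_snps,
                                    c2.nonsyn_snps, c2.total_snps - c2.nonsyn_snps),
                "probe_snp": (f1, n1 - f1, f2, n2 - f2),
            }
            for test, (a, b, c, d) in tables.items():
                row = {"module_1": m1, "module_2": m2, "test": test,
                       "a": a, "b": b, "c": c, "d": d}
                try:
                    row["odds_ratio"], row["p"] = fisher_exact_2x2(a, b, c, d)
                    row["testable"] = True
                except ValueError:
                    row["odds_ratio"], row["p"], row["testable"] = np.nan, np.nan, False
                rows.append(row)
    return pd.DataFrame(rows)


def eqtl_concordance(
    probes: pd.DataFrame, module: str, assignment: pd.Series | None = None
) -> dict[str, tuple[float, float, tuple[int, int, int, int]]]:
    """Within one module, test whether probe-SNP flags track eQTL status.

    Test ``false_cis``: are apparent-cis eQTLs enriched among SNP-flagged
    probes?  Test ``real_cis``: are real cis eQTLs enriched among unflagged
    probes?  Returns {test: (odds_ratio, p, (a, b, c, d))}.
    """
    module_of = assignment if assignment is not None else probes["module"]
    sub = probes[module_of == module]
    if "eqtl_status" not in sub.columns or (sub["eqtl_status"] == "unknown").all():
        raise ValueError(f"no eQTL status data for module {module!r}")
    flagged = sub[sub["snp_in_probe"].astype(bool)]
    unflagged = sub[~sub["snp_in_probe"].astype(bool)]
    out = {}
    for test, first, second in (
        ("false_cis", flagged, unflagged),
        ("real_cis", unflagged, flagged),
    ):
        a = int((first["eqtl_status"] == test).sum())
        b = len(first) - a
        c = int((second["eqtl_status"] == test).sum())
        d = len(second) - c
        odds, p = fisher_exact_2x2(a, b, c, d)
        out[test] = (odds, p, (a, b, c, d))
    return out
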
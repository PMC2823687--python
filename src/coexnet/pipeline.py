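"""End-to-end pipeline: preprocessing -> network -> modules -> traits ->
preservation -> SNP-artifact diagnostics, with a human-readable report.

The per-module verdict encodes the study's core logic: a module whose probes
are enriched for SNP-containing probes (Fisher p < 0.05 vs the rest of the
network, odds ratio > 1) is flagged "suspect: probe-SNP enrichment" — its
trait association likely reflects a hybridization artifact rather than
biology; otherwise a module whose eigengene correlates with a trait
(p < 0.01) is "trait-associated: <trait>".
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coexnet import preprocess as pp
from coexnet import network as net
from coexnet import traits as tr
from coexnet import preservation as pres
from coexnet import snpartifact as snp
from coexnet.network import GREY

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    preprocess: pp.PreprocessConfig = field(default_factory=pp.PreprocessConfig)
    network: net.NetworkConfig = field(default_factory=net.NetworkConfig)
    margin: int = snp.DEFAULT_MARGIN
    n_perm: int = 200
    seed: int = 0
    interaction_alpha: float = 0.01
    significance_alpha: float = 0.01
    enrichment_alpha: float = 0.05
    run_permutations: bool = True


@dataclass
class PipelineResult:
    assignment: pd.Series
    module_table: pd.DataFrame
    eigengenes: pd.DataFrame  # modules x samples
    significance: pd.DataFrame
    kme: pd.DataFrame
    interaction: pd.DataFrame
    preservation: pd.DataFrame
    enrichment: pd.DataFrame
    probe_table: pd.DataFrame
    verdicts: dict
    expr_network: pd.DataFrame
    traits: pd.DataFrame


def _stage_seed(seed: int, stage: int) -> int:
    # stage fan-out keeps stages reproducible independently of each other
    return (seed + stage) % (2**31 - 1)


def run_pipeline(
    expression: pd.DataFrame,
    detection: pd.DataFrame,
    sample_traits: pd.DataFrame,
    probe_annotation: pd.DataFrame,
    snp_catalog: pd.DataFrame,
    eqtl_status: pd.Series | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    t0 = time.perf_counter()

    def stage(name):
        log.info("[%6.1fs] stage: %s", time.perf_counter() - t0, name)

    try:
        stage("preprocess")
        pcfg = cfg.preprocess
        expr = pp.detection_filter(expression, detection, pcfg)
        expr = pp.transform_normalize(expr, pcfg)
        top_k = min(pcfg.top_k, len(expr))
        expr = pp.select_top_variance(expr, top_k)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'preprocess' failed: {e}") from e

    try:
        stage("network")
        ncfg = cfg.network
        cor = net.correlation_matrix(expr)
        adj = net.soft_threshold_adjacency(cor, ncfg.beta)
        expr_net, kept = net.filter_by_scaled_connectivity(
            expr, adj, ncfg.connectivity_tau, scaled=ncfg.tau_scaled
        )
        adj_net = adj.loc[kept, kept]
        tom = net.topological_overlap(adj_net)
        assignment, _ = net.detect_modules(tom, ncfg)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'network' failed: {e}") from e

    try:
        stage("traits")
        egs = tr.module_eigengene(expr_net, assignment)
        eg_frame = pd.DataFrame({eg.module: eg.scores for eg in egs}).T
        eg_frame.index.name = "module"
        sig_rows = []
        for eg in egs:
            for trait_name in ("strain", "tissue"):
                s = tr.eigengene_significance(eg, sample_traits[trait_name], trait_name)
                sig_rows.append((s.module, s.trait, s.r, s.p))
        significance = pd.DataFrame(sig_rows, columns=["module", "trait", "r", "p"])
        kme = tr.module_membership(expr, egs)
        interaction = tr.interaction_scan(
            expr, sample_traits["strain"], sample_traits["tissue"], alpha=cfg.interaction_alpha
        )
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'traits' failed: {e}") from e

    try:
        stage("preservation")
        # permutation null sets are drawn from the variance-filtered probe
        # set, not just the connectivity-filtered network probes: the latter
        # is dominated by module members, which would make null sets nearly
        # as "preserved" as real modules
        preservation = _preservation_table(expr, assignment, sample_traits, cfg)
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'preservation' failed: {e}") from e

    try:
        stage("snpartifact")
        probe_table, enrichment = _snp_stage(
            expr_net, assignment, probe_annotation, snp_catalog, eqtl_status, cfg
        )
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'snpartifact' failed: {e}") from e

    stage("verdicts")
    verdicts = _verdicts(assignment, significance, probe_table, cfg)
    module_table = _module_table(assignment, significance, preservation, verdicts)

    return PipelineResult(
        assignment=assignment,
        module_table=module_table,
        eigengenes=eg_frame,
        significance=significance,
        kme=kme,
        interaction=interaction,
        preservation=preservation,
        enrichment=enrichment,
        probe_table=probe_table,
        verdicts=verdicts,
        expr_network=expr_net,
        traits=sample_traits,
    )


def _preservation_table(expr, assignment, sample_traits, cfg) -> pd.DataFrame:
    rows = []
    modules = [m for m in assignment.unique() if m != GREY]
    for stage_i, split_col in enumerate(("strain", "tissue")):
        levels = sorted(sample_traits[split_col].unique())
        if len(levels) != 2:
            continue
        s1 = sample_traits.index[sample_traits[split_col] == levels[0]]
        s2 = sample_traits.index[sample_traits[split_col] == levels[1]]
        e1, e2 = expr[s1], expr[s2]
        for m in sorted(modules):
            try:
                kim = pres.connectivity_preservation(e1, e2, assignment, m, cfg.network.beta)
            except ValueError as err:
                log.warning("preservation skipped for %s/%s: %s", m, split_col, err)
                continue
            p = np.nan
            if cfg.run_permutations:
                r = pres.preservation_permutation_p(
                    e1, e2, assignment, m,
                    n_perm=max(cfg.n_perm, 100),
                    seed=_stage_seed(cfg.seed, 3 + stage_i),
                    beta=cfg.network.beta,
                )
                p = r.permutation_p
            rows.append((m, split_col, f"{levels[0]}|{levels[1]}", kim, p))
    return pd.DataFrame(
        rows, columns=["module", "split_by", "subsets", "kim_correlation", "permutation_p"]
    )


def _snp_stage(expr_net, assignment, probe_annotation, snp_catalog, eqtl_status, cfg):
    annot = probe_annotation.loc[probe_annotation.index.intersection(assignment.index)].copy()
    probes = snp.flag_probe_snps(annot, snp_catalog)
    probes["module"] = assignment.loc[probes.index]
    if eqtl_status is not None:
        probes["eqtl_status"] = eqtl_status.reindex(probes.index).fillna("unknown")

    regions = [
        snp.GeneRegion(p, rec["chrom"], int(rec["gene_start"]), int(rec["gene_end"]), cfg.margin)
        for p, rec in probes.iterrows()
    ]
    counts = snp.count_snps_in_regions(regions, snp_catalog, probes["module"])
    counts = {m: c for m, c in counts.items() if m != GREY}
    enrichment = (
        snp.module_enrichment_report(counts, probes)
        if len(counts) >= 2
        else pd.DataFrame(
            columns=["module_1", "module_2", "test", "a", "b", "c", "d", "odds_ratio", "p", "testable"]
        )
    )
    return probes, enrichment


def _module_vs_rest_probe_snp(probe_table: pd.DataFrame, module: str):
    in_mod = probe_table["module"] == module
    a = int(probe_table.loc[in_mod, "snp_in_probe"].sum())
    b = int(in_mod.sum()) - a
    c = int(probe_table.loc[~in_mod, "snp_in_probe"].sum())
    d = int((~in_mod).sum()) - c
    return snp.fisher_exact_2x2(a, b, c, d) + ((a, b, c, d),)


def _verdicts(assignment, significance, probe_table, cfg) -> dict:
    verdicts = {}
    for m in sorted(set(assignment) - {GREY}):
        labels = []
        try:
            odds, p, table = _module_vs_rest_probe_snp(probe_table, m)
            if p < cfg.enrichment_alpha and odds > 1:
                labels.append("suspect: probe-SNP enrichment")
        except ValueError:
            pass
        sig_m = significance[significance["module"] == m]
        hits = sig_m[sig_m["p"] < cfg.significance_alpha]
        if not labels:
            for _, row in hits.sort_values("p").iterrows():
                labels.append(f"trait-associated: {row['trait']}")
                break
        elif not hits.empty:
            # a suspect module's trait link is reported, but as suspect
            labels[0] += f" (correlates with {hits.sort_values('p').iloc[0]['trait']})"
        verdicts[m] = "; ".join(labels) if labels else "unremarkable"
    return verdicts


def _module_table(assignment, significance, preservation, verdicts) -> pd.DataFrame:
    rows = []
    sizes = assignment.value_counts()
    for m in sorted(set(assignment) - {GREY}):
        row = {"module": m, "size": int(sizes.get(m, 0)), "verdict": verdicts.get(m, "")}
        for trait_name in ("strain", "tissue"):
            hit = significance[(significance["module"] == m) & (significance["trait"] == trait_name)]
            row[f"r_{trait_name}"] = float(hit["r"].iloc[0]) if len(hit) else np.nan
            row[f"p_{trait_name}"] = float(hit["p"].iloc[0]) if len(hit) else np.nan
        for split in ("strain", "tissue"):
            hit = preservation[(preservation["module"] == m) & (preservation["split_by"] == split)]
            row[f"kim_r_split_{split}"] = (
                float(hit["kim_correlation"].iloc[0]) if len(hit) else np.nan
            )
        rows.append(row)
    grey_n = int(sizes.get(GREY, 0))
    df = pd.DataFrame(rows).sort_values("size", ascending=False) if rows else pd.DataFrame()
    df.attrs["n_grey"] = grey_n
    return df


def write_report(result: PipelineResult, outdir: str, heatmaps: bool = False) -> list[str]:
    """Write per-stage TSVs, a plain-text summary, and optional per-module
    probe x sample heatmaps (rows by kME, columns by strain then tissue).

    Every number in the summary also appears in a TSV; the 2x2 table behind
    each Fisher p-value is included.  Returns the written paths.
    """
    os.makedirs(outdir, exist_ok=True)
    written = []

    def put(df: pd.DataFrame, name: str, **kw):
        path = os.path.join(outdir, name)
        df.to_csv(path, sep="\t", float_format="%.6g", **kw)
        written.append(path)

    put(result.module_table, "modules.tsv", index=False)
    put(result.eigengenes, "eigengenes.tsv")
    put(result.significance, "eigengene_significance.tsv", index=False)
    put(result.kme, "module_membership.tsv", index_label="probe")
    put(result.interaction, "interaction_scan.tsv", index_label="probe")
    put(result.preservation, "preservation.tsv", index=False)
    put(result.enrichment, "snp_enrichment.tsv", index=False)
    put(
        result.probe_table.assign(module=result.assignment.loc[result.probe_table.index]),
        "probes.tsv",
        index_label="probe",
    )

    lines = ["co-expression network report", "=" * 30, ""]
    if result.module_table.empty:
        lines.append("no modules detected")
    else:
        for _, row in result.module_table.iterrows():
            lines.append(
                f"module {row['module']} (n={row['size']}): "
                f"r_strain={row['r_strain']:+.2f} (p={row['p_strain']:.2g}), "
                f"r_tissue={row['r_tissue']:+.2f} (p={row['p_tissue']:.2g}) -> {row['verdict']}"
            )
        lines.append("")
        lines.append("pairwise SNP enrichment (2x2 tables a,b,c,d and Fisher p):")
        for _, row in result.enrichment.iterrows():
            lines.append(
                f"  {row['module_1']} vs {row['module_2']} [{row['test']}] "
                f"({row['a']},{row['b']},{row['c']},{row['d']}) "
                f"OR={row['odds_ratio']:.3g} p={row['p']:.3g}"
            )
    summary = os.path.join(outdir, "summary.txt")
    with open(summary, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    written.append(summary)

    if heatmaps and not result.module_table.empty:
        written.extend(_write_heatmaps(result, outdir))
    return written


def _write_heatmaps(result: PipelineResult, outdir: str) -> list[str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = result.traits.sort_values(["strain", "tissue"]).index
    paths = []
    for m in result.module_table["module"]:
        members = result.assignment.index[result.assignment == m]
        sub = result.expr_network.loc[members, order]
        if m in result.kme.columns:
            sub = sub.loc[result.kme.loc[members, m].sort_values(ascending=False).index]
        z = ((sub.T - sub.mean(axis=1)) / sub.std(axis=1)).T
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.imshow(z.to_numpy(), aspect="auto", cmap="RdYlGn_r", vmin=-3, vmax=3)
        ax.set_title(f"module {m}")
        ax.set_xlabel("samples (by strain, tissue)")
        ax.set_ylabel("probes (by kME)")
        path = os.path.join(outdir, f"heatmap_{m}.png")
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
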
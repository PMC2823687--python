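"""Readers and writers for the package's plain-text file dialects.

Expression and detection matrices are probe x sample TSV with a header row of
sample IDs; traits are a sample/strain/tissue TSV; gene and probe intervals
travel as BED (0-based, half-open on disk, converted to 1-based inclusive in
memory); the SNP catalog is a chrom/pos/cls TSV with 1-based positions; the
eQTL status table is a 2-column probe/status TSV.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import pandas as pd

from coexnet.snpartifact import EQTL_STATUSES, SNP_CLASSES
from coexnet.synthdata import SyntheticDataset


class FormatError(ValueError):
    """A malformed input file; message carries file and line number."""


def _fail(path: str, line: int, reason: str):
    raise FormatError(f"{path}:{line}: {reason}")


def write_matrix(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="probe", float_format="%.10g")


def read_matrix(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate probe ID {dup!r}")
    return df


def write_traits(traits: pd.DataFrame, path: str) -> None:
    traits.to_csv(path, sep="\t", index_label="sample")


def read_traits(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "sample"
    for col in ("strain", "tissue"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    return df


def write_bed(intervals: pd.DataFrame, path: str, start_col: str, end_col: str) -> None:
    """Write name + 1-based inclusive interval columns as 0-based half-open BED."""
    bed = pd.DataFrame(
        {
            "chrom": intervals["chrom"],
            "start": intervals[start_col] - 1,
            "end": intervals[end_col],
            "name": intervals.index,
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    """Read BED into 1-based inclusive (chrom, start, end) indexed by name."""
    rows = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            if not raw.strip() or raw.startswith(("#", "track", "browser")):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 4:
                _fail(path, ln, f"expected >= 4 BED columns, got {len(parts)}")
            chrom, start, end, name = parts[:4]
            try:
                s, e = int(start), int(end)
            except ValueError:
                _fail(path, ln, f"malformed coordinates {start!r}, {end!r}")
            if s < 0 or e < s:
                _fail(path, ln, f"invalid interval [{s}, {e})")
            rows.append((name, chrom, s + 1, e))
    return pd.DataFrame(rows, columns=["name", "chrom", "start", "end"]).set_index("name")


def write_snp_catalog(catalog: pd.DataFrame, path: str) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_snp_catalog(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("chrom", "pos", "cls"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if (df["pos"] < 1).any():
        ln = int(df.index[df["pos"] < 1][0]) + 2  # header line is 1
        _fail(path, ln, "SNP position < 1 (positions are 1-based)")
    bad = set(df["cls"]) - set(SNP_CLASSES)
    if bad:
        raise FormatError(f"{path}: unknown SNP classes {sorted(bad)}")
    return df


def write_eqtl_table(probes: pd.DataFrame, path: str) -> None:
    probes[["eqtl_status"]].to_csv(path, sep="\t", index_label="probe")


def read_eqtl_table(path: str) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    col = df.columns[0]
    bad = set(df[col]) - set(EQTL_STATUSES)
    if bad:
        raise FormatError(f"{path}: unknown eQTL statuses {sorted(bad)}")
    return df[col].rename("eqtl_status")


@dataclass
class DatasetPaths:
    expression: str
    detection: str
    traits: str
    genes_bed: str
    probes_bed: str
    snp_catalog: str
    eqtl_table: str | None = None

    @classmethod
    def in_dir(cls, directory: str) -> "DatasetPaths":
        j = lambda name: os.path.join(directory, name)
        return cls(
            expression=j("expression.tsv"),
            detection=j("detection.tsv"),
            traits=j("traits.tsv"),
            genes_bed=j("genes.bed"),
            probes_bed=j("probes.bed"),
            snp_catalog=j("snps.tsv"),
            eqtl_table=j("eqtl.tsv"),
        )


def write_dataset(dataset: SyntheticDataset, directory: str) -> DatasetPaths:
    os.makedirs(directory, exist_ok=True)
    paths = DatasetPaths.in_dir(directory)
    write_matrix(dataset.expression, paths.expression)
    write_matrix(dataset.detection, paths.detection)
    write_traits(dataset.traits, paths.traits)
    rec = dataset.probe_records
    write_bed(rec, paths.genes_bed, "gene_start", "gene_end")
    write_bed(rec, paths.probes_bed, "probe_start", "probe_end")
    write_snp_catalog(dataset.snp_catalog, paths.snp_catalog)
    write_eqtl_table(rec, paths.eqtl_table)
    return paths


def load_dataset(paths: DatasetPaths):
    """Load and cross-validate a dataset from disk.

    Returns (expression, detection, traits, probe_annotation, snp_catalog,
    eqtl_status-or-None).  The probe annotation merges gene and probe
    intervals per probe ID.
    """
    expr = read_matrix(paths.expression)
    detection = read_matrix(paths.detection)
    if not expr.index.equals(detection.index) or not expr.columns.equals(detection.columns):
        raise FormatError("expression and detection matrices disagree on probes/samples")
    traits = read_traits(paths.traits)
    missing = [s for s in expr.columns if s not in traits.index]
    if missing:
        raise FormatError(f"{paths.traits}: missing samples {missing[:5]}")
    traits = traits.loc[expr.columns]
    traits.index.name = "sample"

    genes = read_bed(paths.genes_bed).rename(columns={"start": "gene_start", "end": "gene_end"})
    probes = read_bed(paths.probes_bed).rename(columns={"start": "probe_start", "end": "probe_end"})
    if set(genes["chrom"]) != set(probes["chrom"]):
        raise FormatError("gene and probe BED files disagree on chromosomes")
    annot = genes.join(probes[["probe_start", "probe_end"]], how="inner")
    annot.index.name = "probe"

    catalog = read_snp_catalog(paths.snp_catalog)
    eqtl = None
    if paths.eqtl_table and os.path.exists(paths.eqtl_table):
        eqtl = read_eqtl_table(paths.eqtl_table)
    return expr, detection, traits, annot, catalog, eqtl
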
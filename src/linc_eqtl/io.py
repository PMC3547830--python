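"""Readers and writers for the pipeline's on-disk formats.

All tabular files are TSV with a header row.  Genotypes: rows = SNPs,
columns = samples, values 0/1/2 (empty = missing), with a companion SNP map
(snp_id, chrom, pos 1-based, ref, alt[, maf]).  Expression: rows = probes,
columns = samples, companion probe map (probe_id, chrom, start, end, class;
0-based half-open).  Interval tracks and the lincRNA exon catalog are BED
(0-based half-open); catalog BED names encode ``transcript_id;gene_id``.
Expression normalization state travels in a JSON sidecar next to the matrix.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix


def write_genotypes(geno: GenotypeMatrix, dosage_path, map_path) -> None:
    geno.dosages.to_csv(dosage_path, sep="\t", index_label="snp_id", float_format="%g")
    cols = [c for c in ("chrom", "pos", "ref", "alt", "maf") if c in geno.snp_map.columns]
    geno.snp_map[cols].to_csv(map_path, sep="\t", index_label="snp_id")


def read_genotypes(dosage_path, map_path) -> GenotypeMatrix:
    dos = pd.read_csv(dosage_path, sep="\t", index_col="snp_id")
    snp_map = pd.read_csv(map_path, sep="\t", index_col="snp_id")
    snp_map["pos"] = snp_map["pos"].astype(int)
    return GenotypeMatrix(dos, snp_map)


def write_expression(expr: ExpressionMatrix, matrix_path, probe_map_path) -> None:
    expr.intensities.to_csv(matrix_path, sep="\t", index_label="probe_id")
    cols = [c for c in ("chrom", "start", "end", "center", "transcript_class")
            if c in expr.probe_map.columns]
    expr.probe_map[cols].to_csv(probe_map_path, sep="\t", index_label="probe_id")
    sidecar = Path(str(matrix_path) + ".meta.json")
    sidecar.write_text(
        json.dumps({"normalization_state": expr.normalization_state}, indent=0) + "\n"
    )


def read_expression(matrix_path, probe_map_path) -> ExpressionMatrix:
    mat = pd.read_csv(matrix_path, sep="\t", index_col="probe_id")
    probe_map = pd.read_csv(probe_map_path, sep="\t", index_col="probe_id")
    state = "raw"
    sidecar = Path(str(matrix_path) + ".meta.json")
    if sidecar.exists():
        state = json.loads(sidecar.read_text()).get("normalization_state", "raw")
    return ExpressionMatrix(mat, probe_map, state)


def write_bed(intervals: pd.DataFrame, path, name_col: str | None = None) -> None:
    """Write chrom/start/end (+ optional name column) as BED."""
    cols = ["chrom", "start", "end"] + ([name_col] if name_col else [])
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    """Read a 3+ column BED file into chrom/start/end[/name]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: df.shape[1]]
    df.columns = names
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_catalog_bed(exons: pd.DataFrame, path) -> None:
    """Write catalog exons; BED name field is ``transcript_id;gene_id[;strand]``."""
    out = exons.copy()
    out["name"] = out["transcript_id"] + ";" + out["gene_id"]
    out["score"] = 0
    cols = ["chrom", "start", "end", "name", "score"]
    if "strand" in out.columns:
        cols.append("strand")
    out[cols].to_csv(path, sep="\t", header=False, index=False)


def read_catalog_bed(path) -> pd.DataFrame:
    df = read_bed(path)
    parts = df["name"].str.split(";", expand=True)
    df["transcript_id"] = parts[0]
    df["gene_id"] = parts[1]
    if "strand" not in df.columns:
        df["strand"] = "+"
    return df[["transcript_id", "gene_id", "chrom", "strand", "start", "end"]]


def write_gwas_catalog(catalog: pd.DataFrame, path) -> None:
    cols = ["snp_id", "trait", "p_reported"]
    if "source_version" in catalog.columns:
        cols.append("source_version")
    catalog[cols].to_csv(path, sep="\t", index=False)


def read_gwas_catalog(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["p_reported"] = df["p_reported"].astype(float)
    return df
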
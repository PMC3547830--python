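"""Probe-to-lincRNA mapping and SNP location classification.

All intervals are 0-based half-open.  A probe is assigned to the lincRNA
class iff its alignment interval overlaps at least one catalog exon by at
least one base; overlap is resolved with per-chromosome interval trees and
is strand-agnostic (array probes detect the transcript regardless of the
annotation's strand convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .errors import DistanceError, ParameterError

logger = logging.getLogger(__name__)

SNP_CATEGORIES = ("mRNA-exonic", "intronic", "intergenic", "TSS-proximal")


@dataclass
class LincRNACatalog:
    """Exon catalog of lincRNA transcripts.

    ``exons`` rows: transcript_id, gene_id, chrom, strand, start, end
    (0-based half-open).  Exons must be valid, sorted and non-overlapping
    within a transcript.
    """

    exons: pd.DataFrame
    set_label: str = "provisional"

    def __post_init__(self) -> None:
        ex = self.exons
        if (ex["end"] <= ex["start"]).any() or (ex["start"] < 0).any():
            raise ParameterError("catalog contains empty or negative exon intervals")
        for tid, grp in ex.groupby("transcript_id", sort=False):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]).any():
                raise ParameterError(f"overlapping exons within transcript {tid}")

    @property
    def n_transcripts(self) -> int:
        return self.exons["transcript_id"].nunique()

    @property
    def n_genes(self) -> int:
        return self.exons["gene_id"].nunique()

    def trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval tree of exons; data = gene_id."""
        out: dict[str, IntervalTree] = {}
        for chrom, grp in self.exons.groupby("chrom", sort=False):
            out[chrom] = IntervalTree.from_tuples(
                (int(s), int(e), g)
                for s, e, g in zip(grp["start"], grp["end"], grp["gene_id"])
            )
        return out


def map_probes_to_catalog(
    probe_map: pd.DataFrame, catalog: LincRNACatalog
) -> tuple[pd.DataFrame, dict]:
    """Label each probe lincRNA iff its alignment overlaps >=1 catalog exon.

    Returns an annotated copy of ``probe_map`` (transcript_class set to
    ``lincRNA`` on overlap; probes without overlap keep a prior
    ``protein_coding`` label, otherwise become ``unassigned``) plus a
    ``mapped_gene_ids`` column of comma-joined overlapping gene ids, and a
    summary dict with the unique probe and gene counts.
    """
    trees = catalog.trees()
    out = probe_map.copy()
    classes, mapped = [], []
    all_genes: set[str] = set()
    for probe_id, rec in probe_map.iterrows():
        chrom = rec["chrom"]
        genes: set[str] = set()
        if chrom not in trees:
            logger.warning("probe %s on chromosome %s absent from catalog", probe_id, chrom)
        else:
            genes = {iv.data for iv in trees[chrom].overlap(int(rec["start"]), int(rec["end"]))}
        if genes:
            classes.append("lincRNA")
            all_genes |= genes
        elif rec.get("transcript_class") == "protein_coding":
            classes.append("protein_coding")
        else:
            classes.append("unassigned")
        mapped.append(",".join(sorted(genes)))
    out["transcript_class"] = classes
    out["mapped_gene_ids"] = mapped
    summary = {
        "n_lincRNA_probes": int(sum(c == "lincRNA" for c in classes)),
        "n_unique_genes": len(all_genes),
    }
    return out, summary


def classify_snp_location(
    snp_pos0: int,
    chrom: str,
    gene_models: pd.DataFrame,
    tss_window: int = 5000,
) -> str:
    """Classify one SNP against (protein-coding) gene models.

    ``gene_models`` rows are exons with transcript_id, gene_id, chrom,
    strand, start, end.  Precedence: mRNA-exonic (inside any exon) >
    intronic (inside a transcript span but no exon) > TSS-proximal (within
    ``tss_window`` of a strand-aware transcription start, outside gene
    bodies) > intergenic.  Exactly one category is returned.
    """
    gm = gene_models[gene_models["chrom"] == chrom]
    if gm.empty:
        logger.warning("chromosome %s absent from gene models; classifying intergenic", chrom)
        return "intergenic"
    p = int(snp_pos0)
    in_exon = ((gm["start"] <= p) & (p < gm["end"])).any()
    if in_exon:
        return "mRNA-exonic"
    spans = gm.groupby("transcript_id").agg(
        start=("start", "min"), end=("end", "max"), strand=("strand", "first")
    )
    if ((spans["start"] <= p) & (p < spans["end"])).any():
        return "intronic"
    tss = np.where(spans["strand"] == "-", spans["end"] - 1, spans["start"])
    if (np.abs(tss - p) <= tss_window).any():
        return "TSS-proximal"
    return "intergenic"


def classify_snps(
    snp_map: pd.DataFrame, gene_models: pd.DataFrame, tss_window: int = 5000
) -> pd.Series:
    """Vector version of :func:`classify_snp_location` over a SNP map."""
    pos0 = snp_map["pos"].astype(int) - 1
    return pd.Series(
        [
            classify_snp_location(p, c, gene_models, tss_window)
            for p, c in zip(pos0, snp_map["chrom"])
        ],
        index=snp_map.index,
        name="category",
    )


def probe_snp_distance(probe: pd.Series, snp: pd.Series) -> int:
    """Signed distance snp_pos0 - probe_center; requires a shared chromosome."""
    if probe["chrom"] != snp["chrom"]:
        raise DistanceError(
            f"probe on {probe['chrom']} and SNP on {snp['chrom']}: distance undefined"
        )
    snp_pos0 = int(snp["pos"]) - 1 if "pos" in snp.index else int(snp["pos0"])
    return snp_pos0 - int(probe["center"])
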
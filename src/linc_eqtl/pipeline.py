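"""End-to-end study orchestration.

``run_study`` sequences the stages on fixture or user data: probe
annotation, expression normalization, discovery cis-eQTL mapping with
permutation FDR, optional replication cohort, per-tissue mapping and
tissue-specificity, lincRNA-vs-coding specificity, GWAS-catalog
intersection through LD proxies, and regulatory-track enrichment.  Every
stage writes its TSV next to a JSON summary and an effective-config copy;
all seeds and thresholds are logged.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation, enrichment, eqtl, expression, io, ldgwas
from .errors import ParameterError, PipelineError

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Declarative description of one study run.

    ``tissues`` maps tissue name to its expression TSV; the first entry is
    the discovery tissue.  ``replication_expression`` is optional; when
    absent the replication stage is skipped.
    """

    genotypes: str
    snp_map: str
    probe_map: str
    tissues: dict[str, str]            # tissue name -> expression TSV
    lincRNA_catalog: str | None = None
    gwas_catalog: str | None = None
    tracks: dict[str, str] = field(default_factory=dict)  # track name -> BED
    replication_genotypes: str | None = None
    replication_snp_map: str | None = None
    replication_expression: str | None = None

    window: int = 250_000
    fdr_level: float = 0.05
    n_perm: int = 100
    unit: str = "probe"
    r2_proxy: float = 0.8
    r2_perfect: float = 1.0
    gwas_p_max: float = 9.9e-6
    min_samples: int = 30
    maf_min: float = 0.05
    quantile: bool = True
    log2: bool = False
    remove_pcs: int = 0
    enrichment_top: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_level < 1):
            raise ParameterError("fdr_level must be in (0,1)")
        if not (0 < self.r2_proxy <= 1) or not (0 < self.gwas_p_max < 1):
            raise ParameterError("threshold out of range")
        if not self.tissues:
            raise ParameterError("at least one tissue is required")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _normalize(expr, config: StudyConfig):
    if config.log2:
        expr = expression.log2_transform(expr)
    if config.quantile:
        expr = expression.quantile_normalize(expr)
    if config.remove_pcs:
        expr = expression.remove_principal_components(expr, config.remove_pcs)
    return expr


def distance_histogram(
    records: pd.DataFrame, window: int = 250_000, n_bins: int = 50
) -> pd.DataFrame:
    """Fractions of records per signed-distance bin across [-window, window]."""
    if records.empty:
        raise ParameterError("no records to histogram")
    edges = np.linspace(-window, window, n_bins + 1)
    counts, _ = np.histogram(records["distance"], bins=edges)
    frac = counts / counts.sum()
    return pd.DataFrame(
        {"bin_left": edges[:-1].astype(int), "bin_right": edges[1:].astype(int),
         "fraction": frac}
    )


def run_study(config: StudyConfig, outdir) -> dict:
    """Execute every configured stage; returns (and writes) the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "effective_config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    summary: dict = {"seed": config.seed, "fdr_level": config.fdr_level,
                     "window": config.window, "tissues": list(config.tissues)}

    def stage(name):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    def done(name, t0):
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)

    try:
        t0 = stage("load")
        geno = io.read_genotypes(config.genotypes, config.snp_map)
        exprs = {
            t: io.read_expression(path, config.probe_map)
            for t, path in config.tissues.items()
        }
        done("load", t0)

        t0 = stage("annotation")
        probe_map = next(iter(exprs.values())).probe_map
        if config.lincRNA_catalog:
            catalog = annotation.LincRNACatalog(io.read_catalog_bed(config.lincRNA_catalog))
            probe_map, map_summary = annotation.map_probes_to_catalog(probe_map, catalog)
            summary["annotation"] = map_summary
            probe_map.to_csv(outdir / "probe_annotation.tsv", sep="\t")
            for t in exprs:
                exprs[t].probe_map = probe_map
        done("annotation", t0)

        t0 = stage("normalize")
        for t in exprs:
            exprs[t] = _normalize(exprs[t], config)
        done("normalize", t0)

        discovery_tissue = next(iter(config.tissues))
        linc_probes = probe_map[probe_map["transcript_class"] == "lincRNA"]
        coding_probes = probe_map[probe_map["transcript_class"] == "protein_coding"]
        if linc_probes.empty:
            raise PipelineError("eqtl", "no lincRNA probes after annotation")

        t0 = stage("eqtl-discovery")
        seeds = {t: config.seed + 1000 * i for i, t in enumerate(config.tissues)}
        per_tissue: dict[str, eqtl.FdrResult] = {}
        for t, expr_t in exprs.items():
            pairs = eqtl.enumerate_cis_pairs(linc_probes, geno.snp_map, config.window)
            per_tissue[t] = eqtl.permutation_fdr(
                expr_t, geno, pairs, n_perm=config.n_perm, level=config.fdr_level,
                unit=config.unit, seed=seeds[t], tissue=t,
                min_samples=config.min_samples, maf_min=config.maf_min,
            )
            logger.info("tissue %s: %d significant units, p-threshold %.3g (perm seed %d)",
                        t, per_tissue[t].observed_count, per_tissue[t].p_threshold, seeds[t])
        discovery = per_tissue[discovery_tissue]
        discovery.records.to_csv(outdir / "eqtl_discovery.tsv", sep="\t", index=False)
        summary["significant_probes"] = discovery.observed_count
        summary["p_threshold"] = discovery.p_threshold
        summary["significant_pairs"] = int(
            (discovery.records["p"] <= discovery.p_threshold).sum()
        )
        done("eqtl-discovery", t0)

        sig_records = discovery.records[
            discovery.records["probe_id"].isin(discovery.significant_units)
            & (discovery.records["p"] <= discovery.p_threshold)
        ]
        if not sig_records.empty:
            distance_histogram(sig_records, config.window).to_csv(
                outdir / "distance_histogram.tsv", sep="\t", index=False
            )

        if config.replication_expression:
            t0 = stage("replication")
            rep_geno = (
                io.read_genotypes(config.replication_genotypes, config.replication_snp_map)
                if config.replication_genotypes else geno
            )
            rep_expr = _normalize(
                io.read_expression(config.replication_expression, config.probe_map), config
            )
            rep = eqtl.replicate(
                discovery, rep_expr, rep_geno, discovery_snp_map=geno.snp_map,
                level=config.fdr_level, n_perm=config.n_perm, seed=config.seed + 77,
                min_samples=config.min_samples, maf_min=config.maf_min,
            )
            rep.table.to_csv(outdir / "replication.tsv", sep="\t", index=False)
            concordant = rep.table.loc[rep.table["replicated"], "concordant"]
            summary["replication"] = {
                "fraction": rep.fraction,
                "n_replicated": rep.n_replicated,
                "direction_concordance": float(concordant.mean()) if len(concordant) else None,
            }
            done("replication", t0)

        if len(per_tissue) > 1:
            t0 = stage("tissue-specificity")
            tissue_table = eqtl.compare_tissues(per_tissue)
            tissue_table.to_csv(outdir / "tissue_specificity.tsv", sep="\t", index=False)
            summary["tissue_specific_counts"] = (
                tissue_table["specificity_class"].value_counts().to_dict()
            )
            done("tissue-specificity", t0)

        if not coding_probes.empty and discovery.observed_count > 0:
            t0 = stage("specificity")
            coding_pairs = eqtl.enumerate_cis_pairs(coding_probes, geno.snp_map, config.window)
            coding_records = eqtl.map_cis_eqtls(
                exprs[discovery_tissue], geno, coding_pairs, tissue=discovery_tissue,
                min_samples=config.min_samples, maf_min=config.maf_min,
            )
            spec_table = eqtl.specificity_analysis(
                discovery.records, coding_records, discovery.p_threshold
            )
            spec_table.to_csv(outdir / "specificity.tsv", sep="\t", index=False)
            if len(spec_table):
                summary["fraction_lincRNA_specific"] = float((~spec_table["shared"]).mean())
            done("specificity", t0)
        else:
            coding_records = None

        if config.gwas_catalog and discovery.observed_count > 0:
            t0 = stage("gwas")
            catalog = io.read_gwas_catalog(config.gwas_catalog)
            top = eqtl.top_eqtl_per_probe(sig_records)
            gwas_table = ldgwas.intersect_gwas(
                top, geno, catalog, r2_threshold=config.r2_proxy,
                gwas_p_max=config.gwas_p_max,
                coding_records=coding_records, coding_p_threshold=discovery.p_threshold,
            )
            gwas_table.to_csv(outdir / "gwas_intersection.tsv", sep="\t", index=False)
            summary["gwas_rows"] = len(gwas_table)
            done("gwas", t0)

        if config.tracks and discovery.observed_count > 0:
            t0 = stage("enrichment")
            n_top = config.enrichment_top or discovery.observed_count
            pairs = eqtl.enumerate_cis_pairs(linc_probes, geno.snp_map, config.window)
            rows = []
            for name, bed in config.tracks.items():
                track = enrichment.AnnotationTrack(name, name, io.read_bed(bed))
                res = enrichment.permutation_enrichment_significance(
                    exprs[discovery_tissue], geno, pairs, track, n_top=n_top,
                    n_perm=config.n_perm, seed=config.seed + 555,
                    min_samples=config.min_samples, maf_min=config.maf_min,
                )
                rows.append(dataclasses.asdict(res))
            enr = pd.DataFrame(rows)
            enr.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            summary["enrichment"] = {
                r["track"]: {"fold": r["observed_fold"], "p": r["p_one_sided"]} for r in rows
            }
            done("enrichment", t0)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap with the failing stage retained
        raise PipelineError("run_study", str(exc)) from exc

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
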
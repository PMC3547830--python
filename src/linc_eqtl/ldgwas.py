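"""Linkage disequilibrium from dosages, proxy-SNP expansion, GWAS intersection.

LD is the composite (dosage-correlation) r-squared: the squared Pearson
correlation of the two unphased 0/1/2 dosage vectors.  Proxy sets expand an
index SNP to every nearby SNP above an r-squared threshold; the GWAS
intersection reports every (eQTL SNP, catalog hit) pair where the trait SNP
is the eQTL SNP itself or one of its proxies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix
from .errors import ParameterError

logger = logging.getLogger(__name__)

_PERFECT_TOL = 1e-12


def ld_r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Composite LD: squared Pearson correlation of dosage vectors.

    Missing entries are removed pairwise.  Returns NaN (undefined LD) if
    either vector is monomorphic after deletion.
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ParameterError("dosage vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class LdProxySet:
    """Proxies of one index SNP at a given r-squared threshold."""

    index_snp: str
    proxies: pd.DataFrame  # snp_id index, column r2; includes the index at 1.0
    threshold: float

    @property
    def snp_ids(self) -> list[str]:
        return list(self.proxies.index)


def find_proxies(
    index_snp: str,
    geno: GenotypeMatrix,
    threshold: float = 0.8,
    max_distance: int = 500_000,
    strict: bool = False,
) -> LdProxySet:
    """All SNPs within ``max_distance`` whose r2 with the index passes the
    threshold.

    ``threshold=1.0`` selects perfect proxies (r2 = 1 within 1e-12);
    ``strict`` switches the 0.8-style comparison from >= to >.  A
    monomorphic index SNP yields an empty set with a warning.
    """
    if index_snp not in geno.snp_ids:
        raise ParameterError(f"unknown index SNP {index_snp!r}")
    rec = geno.snp_map.loc[index_snp]
    d_index = geno.dosages.loc[index_snp].to_numpy(dtype=float)
    if np.ptp(d_index[~np.isnan(d_index)]) == 0:
        logger.warning("index SNP %s is monomorphic; no proxies defined", index_snp)
        return LdProxySet(index_snp, pd.DataFrame(columns=["r2"]), threshold)

    sm = geno.snp_map
    near = sm[(sm["chrom"] == rec["chrom"]) & ((sm["pos"] - rec["pos"]).abs() <= max_distance)]
    cand = geno.dosages.loc[near.index].to_numpy(dtype=float)
    rows = {}
    if not np.isnan(cand).any() and not np.isnan(d_index).any():
        # vectorized Pearson r^2 against all candidates at once
        x = d_index - d_index.mean()
        c = cand - cand.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(x) * np.linalg.norm(c, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2s = np.where(denom > 0, (c @ x) / np.where(denom > 0, denom, 1.0), np.nan) ** 2
        for snp, r2 in zip(near.index, r2s):
            rows[snp] = 1.0 if snp == index_snp else float(r2)
    else:
        for snp in near.index:
            rows[snp] = (
                1.0 if snp == index_snp else ld_r2(d_index, geno.dosages.loc[snp].to_numpy())
            )
    for snp in list(rows):
        r2 = rows[snp]
        if np.isnan(r2):
            del rows[snp]
            continue
        if threshold >= 1.0 - _PERFECT_TOL:
            keep = r2 >= 1.0 - _PERFECT_TOL
        else:
            keep = r2 > threshold if strict else r2 >= threshold
        if not keep:
            del rows[snp]
    proxies = pd.DataFrame({"r2": pd.Series(rows)}).sort_values("r2", ascending=False)
    proxies.index.name = "snp_id"
    return LdProxySet(index_snp, proxies, threshold)


def intersect_gwas(
    top_records: pd.DataFrame,
    geno: GenotypeMatrix,
    catalog: pd.DataFrame,
    r2_threshold: float = 0.8,
    gwas_p_max: float = 9.9e-6,
    max_distance: int = 500_000,
    strict: bool = False,
    coding_records: pd.DataFrame | None = None,
    coding_p_threshold: float | None = None,
) -> pd.DataFrame:
    """Rows pairing top eQTL SNPs (or their LD proxies) with GWAS hits.

    ``catalog`` needs columns snp_id, trait, p_reported and is filtered to
    ``p_reported < gwas_p_max``.  Catalog SNPs absent from the genotype
    panel can only match the eQTL SNP by identity (logged).  When
    ``coding_records`` and ``coding_p_threshold`` are supplied, each row is
    flagged with whether the eQTL SNP also affects a protein-coding probe
    at that threshold.
    """
    cat = catalog[catalog["p_reported"] < gwas_p_max]
    absent = set(cat["snp_id"]) - set(geno.snp_ids)
    if absent:
        logger.info("%d catalog SNPs absent from the genotype panel; identity match only",
                    len(absent))
    coding_sig_snps: set = set()
    if coding_records is not None and coding_p_threshold is not None:
        coding_sig_snps = set(
            coding_records.loc[coding_records["p"] <= coding_p_threshold, "snp_id"]
        )
    rows = []
    for rec in top_records.itertuples(index=False):
        proxy = find_proxies(rec.snp_id, geno, r2_threshold, max_distance, strict)
        r2_by_snp = proxy.proxies["r2"].to_dict()
        for hit in cat.itertuples(index=False):
            if hit.snp_id == rec.snp_id:
                r2 = 1.0
            elif hit.snp_id in r2_by_snp:
                r2 = float(r2_by_snp[hit.snp_id])
            else:
                continue
            rows.append(
                (rec.snp_id, rec.probe_id, getattr(rec, "tissue", ""), rec.p,
                 hit.snp_id, r2, hit.trait, hit.p_reported,
                 rec.snp_id in coding_sig_snps)
            )
    out = pd.DataFrame(
        rows,
        columns=["eqtl_snp", "probe_id", "tissue", "eqtl_p", "proxy_snp", "r2",
                 "trait", "gwas_p", "affects_coding"],
    )
    if "source_version" in catalog.columns and not catalog.empty:
        out.attrs["catalog_version"] = str(catalog["source_version"].iloc[0])
    return out
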
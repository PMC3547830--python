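"""Cis-eQTL mapping: Spearman association with permutation-based FDR.

The association statistic is the midrank Spearman correlation between a
SNP's allele dosage (0/1/2) and a probe's intensity.  Two-sided P values
come from the t approximation on ``n-2`` degrees of freedom, or from
exhaustive permutation enumeration for very small samples.  Multiple
testing is controlled by an empirical FDR: sample labels of the whole
expression matrix are shuffled relative to the genotypes (preserving the
probe-probe correlation structure), the association scan is repeated on
each of the permuted datasets, and the observed P value distribution is
compared with the permuted one.  The default counting unit is the probe,
whose statistic is the minimum P over its cis pairs.

Bulk scans run on a vectorized path (standardized midranks + matrix
products); per-pair pairwise deletion of missing dosages falls back to a
scalar path.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, GenotypeMatrix
from .errors import ParameterError, PipelineError

logger = logging.getLogger(__name__)

RECORD_COLUMNS = (
    "probe_id", "snp_id", "chrom", "pos", "distance", "n_used", "rho", "p", "z", "tissue",
)

_P_FLOOR = 1e-300


class SpearmanResult(NamedTuple):
    rho: float
    p: float
    z: float
    n_used: int


def enumerate_cis_pairs(
    probe_map: pd.DataFrame, snp_map: pd.DataFrame, window: int = 250_000
) -> pd.DataFrame:
    """All probe-SNP pairs with |snp_pos0 - probe_center| <= window (inclusive).

    Returns columns probe_id, snp_id, chrom, pos (1-based), distance
    (signed, snp - probe center), sorted by (probe_id, pos).
    """
    rows = []
    for chrom, snps in snp_map.groupby("chrom", sort=False):
        snps = snps.sort_values("pos")
        pos0 = snps["pos"].to_numpy(dtype=np.int64) - 1
        ids = snps.index.to_numpy()
        probes = probe_map[probe_map["chrom"] == chrom]
        for probe_id, rec in probes.iterrows():
            c = int(rec["center"])
            lo = np.searchsorted(pos0, c - window, side="left")
            hi = np.searchsorted(pos0, c + window, side="right")
            for k in range(lo, hi):
                rows.append((probe_id, ids[k], chrom, int(pos0[k]) + 1, int(pos0[k]) - c))
    out = pd.DataFrame(rows, columns=["probe_id", "snp_id", "chrom", "pos", "distance"])
    return out.sort_values(["probe_id", "pos"], kind="stable").reset_index(drop=True)


def _standardize_ranks(x: np.ndarray) -> np.ndarray:
    """Midranks of each row, centred and scaled to unit norm.

    Rows with zero variance come back all-zero (their correlations are 0
    and must be filtered by the caller's testability mask).
    """
    r = stats.rankdata(x, axis=1)
    r = r - r.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(r, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    return r / norm


def _p_from_rho(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided P via the t approximation with n-2 degrees of freedom."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-15))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.clip(p, _P_FLOOR, 1.0)


def _z_from_p(p: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Signed standard-normal equivalent of a two-sided P."""
    z = stats.norm.isf(np.asarray(p) / 2.0)
    return z * np.sign(rho)


def spearman_test(
    dosage: np.ndarray,
    expression: np.ndarray,
    min_samples: int = 30,
    min_minor_carriers: int = 3,
    exact_below: int = 10,
) -> SpearmanResult | None:
    """Midrank Spearman test of one dosage vector against one probe.

    Missing entries are removed pairwise.  Returns None (not testable) if
    fewer than ``min_samples`` complete pairs remain, the genotype is
    monomorphic, fewer than ``min_minor_carriers`` samples carry the minor
    allele, or the expression is constant.  P values are exact (exhaustive
    permutation enumeration) when ``n_used < exact_below``, otherwise from
    the t approximation.
    """
    d = np.asarray(dosage, dtype=float)
    e = np.asarray(expression, dtype=float)
    if d.shape != e.shape:
        raise ParameterError("dosage and expression must have equal length")
    keep = ~(np.isnan(d) | np.isnan(e))
    d, e = d[keep], e[keep]
    n = d.size
    if n < min_samples:
        return None
    if np.unique(d).size < 2 or np.ptp(e) == 0:
        return None
    freq = d.mean() / 2.0
    carriers = int((d > 0).sum()) if freq <= 0.5 else int((d < 2).sum())
    if carriers < min_minor_carriers:
        return None

    ds = _standardize_ranks(d[None, :])[0]
    es = _standardize_ranks(e[None, :])[0]
    rho = float(np.dot(ds, es))
    if n < exact_below:
        perms = np.array(list(itertools.permutations(range(n))))
        rho_null = es[perms] @ ds
        p = float(np.mean(np.abs(rho_null) >= abs(rho) - 1e-12))
        p = max(p, _P_FLOOR)
    else:
        p = float(_p_from_rho(np.array([rho]), n)[0])
    z = float(_z_from_p(np.array([p]), np.array([rho]))[0])
    return SpearmanResult(rho, p, z, n)


class CisScanner:
    """Precomputed vectorized scan over a fixed set of cis pairs.

    Builds standardized midrank matrices for the probes and SNPs occurring
    in ``pairs``, applies the testability filters once (MAF, minor-allele
    carriers, non-constant expression), and evaluates per-pair rho / P for
    the observed data or any column permutation of the expression matrix.
    Requires complete (no-missing) matrices; callers with missing dosages
    use the scalar path in :func:`map_cis_eqtls`.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        geno: GenotypeMatrix,
        pairs: pd.DataFrame,
        min_samples: int = 30,
        min_minor_carriers: int = 3,
        maf_min: float = 0.05,
    ):
        samples = [s for s in expr.sample_ids if s in set(geno.sample_ids)]
        if not samples:
            raise PipelineError("cis-scan", "empty sample intersection")
        if len(samples) < min_samples:
            raise PipelineError(
                "cis-scan", f"{len(samples)} shared samples < min_samples={min_samples}"
            )
        self.samples = samples
        self.n = len(samples)

        probe_ids = pd.Index(pairs["probe_id"].unique())
        snp_ids = pd.Index(pairs["snp_id"].unique())
        E = expr.intensities.loc[probe_ids, samples].to_numpy(dtype=float)
        G = geno.dosages.loc[snp_ids, samples].to_numpy(dtype=float)
        if np.isnan(E).any() or np.isnan(G).any():
            raise ParameterError("CisScanner requires complete matrices")

        freq = G.mean(axis=1) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        carriers = np.where(freq <= 0.5, (G > 0).sum(axis=1), (G < 2).sum(axis=1))
        snp_ok = (
            (maf >= maf_min)
            & (carriers >= min_minor_carriers)
            & (np.ptp(G, axis=1) > 0)
        )
        probe_ok = np.ptp(E, axis=1) > 0

        pi = probe_ids.get_indexer(pairs["probe_id"])
        si = snp_ids.get_indexer(pairs["snp_id"])
        keep = probe_ok[pi] & snp_ok[si]
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.debug("cis-scan: %d pairs not testable (QC filters)", n_dropped)
        self.pairs = pairs.loc[keep].reset_index(drop=True)
        self.pi = pi[keep]
        self.si = si[keep]
        self.Er = _standardize_ranks(E)
        self.Gr = _standardize_ranks(G)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def scan(self, perm: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-pair (rho, p); ``perm`` permutes expression sample columns."""
        Er = self.Er if perm is None else self.Er[:, perm]
        if Er.shape[0] * self.Gr.shape[0] <= 50_000_000:
            rho = (Er @ self.Gr.T)[self.pi, self.si]
        else:
            rho = np.einsum("ij,ij->i", Er[self.pi], self.Gr[self.si])
        return rho, _p_from_rho(rho, self.n)


def map_cis_eqtls(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    pairs: pd.DataFrame,
    tissue: str = "blood",
    min_samples: int = 30,
    min_minor_carriers: int = 3,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Spearman-test every testable cis pair; one record per pair.

    Returns a DataFrame with columns probe_id, snp_id, chrom, pos,
    distance, n_used, rho, p, z, tissue, ordered by (probe_id, pos).
    Falls back to per-pair pairwise deletion when dosages are missing.
    """
    has_missing = (
        expr.intensities.isna().to_numpy().any() or geno.dosages.isna().to_numpy().any()
    )
    if not has_missing:
        scanner = CisScanner(expr, geno, pairs, min_samples, min_minor_carriers, maf_min)
        rho, p = scanner.scan()
        out = scanner.pairs.copy()
        out["n_used"] = scanner.n
        out["rho"] = rho
        out["p"] = p
        out["z"] = _z_from_p(p, rho)
        out["tissue"] = tissue
        return out[list(RECORD_COLUMNS)]

    samples = [s for s in expr.sample_ids if s in set(geno.sample_ids)]
    if not samples:
        raise PipelineError("cis-scan", "empty sample intersection")
    rows = []
    E = expr.intensities[samples]
    G = geno.dosages[samples]
    freqs = G.mean(axis=1, skipna=True) / 2.0
    for rec in pairs.itertuples(index=False):
        maf = min(freqs[rec.snp_id], 1 - freqs[rec.snp_id])
        if maf < maf_min:
            continue
        res = spearman_test(
            G.loc[rec.snp_id].to_numpy(),
            E.loc[rec.probe_id].to_numpy(),
            min_samples=min_samples,
            min_minor_carriers=min_minor_carriers,
        )
        if res is None:
            continue
        rows.append(
            (rec.probe_id, rec.snp_id, rec.chrom, rec.pos, rec.distance,
             res.n_used, res.rho, res.p, res.z, tissue)
        )
    return pd.DataFrame(rows, columns=list(RECORD_COLUMNS))


@dataclass
class FdrResult:
    """Permutation-FDR decision for one scan.

    ``unit_pvalues`` carries the per-unit observed statistic (min P over a
    probe's cis pairs for unit='probe', per-pair P for unit='pair'),
    ``significant`` the per-unit flags at ``p_threshold``, and ``curve``
    the realized-FDR step function over observed candidate thresholds.
    """

    nominal_fdr: float
    unit: str
    p_threshold: float
    observed_count: int
    mean_null_count: float
    unit_pvalues: pd.Series
    significant: pd.Series
    curve: pd.DataFrame
    records: pd.DataFrame
    perm_seeds: list[int] = field(default_factory=list)

    @property
    def significant_units(self) -> list:
        return list(self.significant.index[self.significant])


def _unit_pvalues(records: pd.DataFrame, unit: str) -> pd.Series:
    if unit == "probe":
        return records.groupby("probe_id")["p"].min().sort_index()
    if unit == "pair":
        s = records.set_index(["probe_id", "snp_id"])["p"]
        return s.sort_index()
    raise ParameterError(f"unknown FDR unit {unit!r}")


def permutation_fdr(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    pairs: pd.DataFrame,
    n_perm: int = 100,
    level: float = 0.05,
    unit: str = "probe",
    seed: int = 0,
    tissue: str = "blood",
    min_samples: int = 30,
    min_minor_carriers: int = 3,
    maf_min: float = 0.05,
) -> FdrResult:
    """Empirical FDR by shuffling expression sample labels n_perm times.

    Each permutation relabels the whole expression matrix's samples
    relative to the genotypes (columns move together, preserving
    probe-probe correlation).  The estimated FDR at threshold t is
    ``mean_perm count(null unit P <= t) / max(1, count(observed unit P <= t))``
    and the significance threshold is the largest observed unit P whose
    estimated FDR stays at or below ``level``.
    """
    if n_perm < 10:
        raise ParameterError("n_perm must be at least 10")
    if not (0 < level < 1):
        raise ParameterError("level must be in (0,1)")
    scanner = CisScanner(expr, geno, pairs, min_samples, min_minor_carriers, maf_min)
    rho, p = scanner.scan()
    records = scanner.pairs.copy()
    records["n_used"] = scanner.n
    records["rho"] = rho
    records["p"] = p
    records["z"] = _z_from_p(p, rho)
    records["tissue"] = tissue
    records = records[list(RECORD_COLUMNS)]

    obs = _unit_pvalues(records, unit)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_perm)
    perm_seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    null_ps = []
    base = records[["probe_id", "snp_id"]]
    for child in children:
        rng = np.random.default_rng(child)
        perm = rng.permutation(scanner.n)
        _, p_null = scanner.scan(perm)
        null_rec = base.assign(p=p_null)
        null_ps.append(_unit_pvalues(null_rec, unit).to_numpy())
    null_all = np.sort(np.concatenate(null_ps))

    cand = np.sort(obs.to_numpy())
    obs_le = np.searchsorted(cand, cand, side="right")
    null_le = np.searchsorted(null_all, cand, side="right") / n_perm
    est = null_le / np.maximum(obs_le, 1)
    ok = est <= level
    if ok.any():
        p_threshold = float(cand[ok][-1])
    else:
        p_threshold = 0.0
    significant = obs <= p_threshold
    curve = pd.DataFrame({"threshold": cand, "estimated_fdr": est})
    mean_null = float(np.searchsorted(null_all, p_threshold, side="right") / n_perm)
    return FdrResult(
        nominal_fdr=level,
        unit=unit,
        p_threshold=p_threshold,
        observed_count=int(significant.sum()),
        mean_null_count=mean_null,
        unit_pvalues=obs,
        significant=significant,
        curve=curve,
        records=records,
        perm_seeds=perm_seeds,
    )


def top_eqtl_per_probe(records: pd.DataFrame) -> pd.DataFrame:
    """Best record per probe: smallest P, then largest |rho|, then smallest position."""
    if records.empty:
        raise ParameterError("no records")
    r = records.assign(_absrho=records["rho"].abs())
    r = r.sort_values(
        ["probe_id", "p", "_absrho", "pos"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    out = r.groupby("probe_id", sort=True).head(1).drop(columns="_absrho")
    return out.reset_index(drop=True)


def harmonize_alleles(
    geno: GenotypeMatrix, reference_map: pd.DataFrame
) -> tuple[GenotypeMatrix, list[str]]:
    """Flip dosages of SNPs whose ref/alt are swapped w.r.t. a reference map.

    Returns the harmonized matrix and the list of flipped SNP ids.
    """
    flipped = []
    dos = geno.dosages.copy()
    shared = geno.snp_map.index.intersection(reference_map.index)
    for snp in shared:
        a = (geno.snp_map.loc[snp, "ref"], geno.snp_map.loc[snp, "alt"])
        b = (reference_map.loc[snp, "ref"], reference_map.loc[snp, "alt"])
        if a == (b[1], b[0]):
            dos.loc[snp] = 2 - dos.loc[snp]
            flipped.append(snp)
    if flipped:
        logger.info("harmonized %d SNPs with swapped allele encoding", len(flipped))
    new_map = geno.snp_map.copy()
    for snp in flipped:
        new_map.loc[snp, ["ref", "alt"]] = reference_map.loc[snp, ["ref", "alt"]].to_numpy()
    return GenotypeMatrix(dos, new_map), flipped


@dataclass
class ReplicationResult:
    n_discovery: int
    n_replicated: int
    fraction: float
    table: pd.DataFrame  # per discovery unit: z_disc, z_rep, replicated, concordant
    fdr: FdrResult


def replicate(
    discovery_fdr: FdrResult,
    repl_expr: ExpressionMatrix,
    repl_geno: GenotypeMatrix,
    discovery_snp_map: pd.DataFrame | None = None,
    level: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
    tissue: str = "replication",
    **test_kwargs,
) -> ReplicationResult:
    """Re-test the discovery-significant units in an independent cohort.

    Only the cis pairs of discovery-significant units enter the replication
    scan; the permutation FDR is applied restricted to those units.  For
    each replicated unit the allelic direction concordance is
    ``sign(z_discovery) * sign(z_replication)`` for the discovery top pair,
    after harmonizing allele encodings between the cohorts.
    """
    disc_records = discovery_fdr.records
    sig_units = discovery_fdr.significant_units
    if not sig_units:
        raise ParameterError("no discovery-significant units to replicate")

    if discovery_snp_map is not None:
        repl_geno, _ = harmonize_alleles(repl_geno, discovery_snp_map)

    if discovery_fdr.unit == "probe":
        sig_records = disc_records[disc_records["probe_id"].isin(sig_units)]
    else:
        key = disc_records.set_index(["probe_id", "snp_id"]).index
        sig_records = disc_records[key.isin(sig_units)]
    pairs = sig_records[["probe_id", "snp_id", "chrom", "pos", "distance"]].reset_index(drop=True)
    pairs = pairs[pairs["snp_id"].isin(repl_geno.snp_ids)
                  & pairs["probe_id"].isin(repl_expr.probe_ids)].reset_index(drop=True)

    fdr = permutation_fdr(
        repl_expr, repl_geno, pairs, n_perm=n_perm, level=level,
        unit=discovery_fdr.unit, seed=seed, tissue=tissue, **test_kwargs,
    )

    disc_top = top_eqtl_per_probe(sig_records).set_index("probe_id")
    rep_by_pair = fdr.records.set_index(["probe_id", "snp_id"])
    rows = []
    for unit in sig_units:
        probe = unit if discovery_fdr.unit == "probe" else unit[0]
        if probe not in disc_top.index:
            continue
        snp = disc_top.loc[probe, "snp_id"]
        z_disc = float(disc_top.loc[probe, "z"])
        replicated = bool(fdr.significant.get(unit, False))
        z_rep = np.nan
        if (probe, snp) in rep_by_pair.index:
            z_rep = float(rep_by_pair.loc[(probe, snp), "z"])
        concordant = bool(np.sign(z_disc) * np.sign(z_rep) > 0) if np.isfinite(z_rep) else None
        rows.append((unit, snp, z_disc, z_rep, replicated, concordant))
    table = pd.DataFrame(
        rows, columns=["unit", "top_snp", "z_discovery", "z_replication",
                       "replicated", "concordant"]
    )
    n_disc = len(sig_units)
    n_rep = int(table["replicated"].sum())
    return ReplicationResult(n_disc, n_rep, n_rep / n_disc, table, fdr)


def specificity_analysis(
    linc_records: pd.DataFrame,
    coding_records: pd.DataFrame,
    p_threshold: float,
) -> pd.DataFrame:
    """Classify each lincRNA top eQTL SNP as lincRNA-specific or shared.

    Both record sets must have been computed at the same significance
    threshold.  A SNP is shared when it also passes the threshold for at
    least one protein-coding probe; shared SNPs get a same/opposite
    direction label (sign of z_linc * z_coding for the strongest coding
    association) and a flag for whether the SNP is also the strongest eQTL
    of some significant protein-coding probe.
    """
    sig_linc = linc_records[linc_records["p"] <= p_threshold]
    if sig_linc.empty:
        return pd.DataFrame(
            columns=["probe_id", "snp_id", "z", "shared", "direction", "strongest_for_coding"]
        )
    linc_top = top_eqtl_per_probe(sig_linc)

    sig_coding = coding_records[coding_records["p"] <= p_threshold]
    coding_by_snp = dict(tuple(sig_coding.groupby("snp_id"))) if not sig_coding.empty else {}
    top_coding_snps: set = set()
    if not sig_coding.empty:
        top_coding_snps = set(top_eqtl_per_probe(sig_coding)["snp_id"])

    rows = []
    for rec in linc_top.itertuples(index=False):
        hits = coding_by_snp.get(rec.snp_id)
        shared = hits is not None
        direction = None
        if shared:
            best = hits.loc[hits["p"].idxmin()]
            direction = "same" if np.sign(rec.z) * np.sign(best["z"]) > 0 else "opposite"
        rows.append(
            (rec.probe_id, rec.snp_id, rec.z, shared, direction, rec.snp_id in top_coding_snps)
        )
    return pd.DataFrame(
        rows, columns=["probe_id", "snp_id", "z", "shared", "direction", "strongest_for_coding"]
    )


def compare_tissues(per_tissue: dict[str, FdrResult]) -> pd.DataFrame:
    """Tissue-specificity table over the per-tissue significant units.

    Rows are units significant in at least one tissue; columns give the
    tissue set and a class label: single-tissue-specific, multi-tissue, or
    all-tissue.
    """
    if len(per_tissue) < 2:
        raise ParameterError("need at least two tissues to compare")
    n_tissues = len(per_tissue)
    membership: dict = {}
    for tissue, fdr in per_tissue.items():
        for unit in fdr.significant_units:
            membership.setdefault(unit, set()).add(tissue)
    rows = []
    for unit, tset in sorted(membership.items(), key=lambda kv: str(kv[0])):
        if len(tset) == 1:
            cls = "single-tissue-specific"
        elif len(tset) == n_tissues:
            cls = "all-tissue"
        else:
            cls = "multi-tissue"
        rows.append((unit, ",".join(sorted(tset)), len(tset), cls))
    return pd.DataFrame(rows, columns=["unit", "tissues", "n_tissues", "specificity_class"])


def venn_counts(table: pd.DataFrame) -> pd.Series:
    """Counts of units per exact tissue combination (Venn-style)."""
    if table.empty:
        return pd.Series(dtype=int)
    return table.groupby("tissues").size().sort_index()
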
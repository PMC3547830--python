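"""Regulatory-region enrichment of eQTL SNP sets.

An eQTL hit is a *set*: the top SNP of a significant probe together with
its perfect proxies (r2 = 1), counted once no matter how many of its
members fall in the annotation track (avoids LD double-counting).  Fold
enrichment is the fraction of query sets hitting the track divided by the
fraction of background SNPs inside it.  Significance comes from the
permutation scheme used for the eQTL FDR: expression sample labels are
shuffled, the cis scan repeated, the same top-probe / top-SNP / perfect
proxy expansion applied, and a normal distribution fitted to the
log-transformed permuted enrichment scores gives the one-sided P of the
observed fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .containers import GenotypeMatrix, ExpressionMatrix
from .errors import ParameterError
from .eqtl import CisScanner, top_eqtl_per_probe, _z_from_p, RECORD_COLUMNS
from .ldgwas import find_proxies

logger = logging.getLogger(__name__)


@dataclass
class AnnotationTrack:
    """Named interval track (0-based half-open), e.g. enhancers of one cell type."""

    name: str
    cell_type: str
    intervals: pd.DataFrame  # chrom, start, end; may overlap

    def __post_init__(self) -> None:
        if (self.intervals["end"] <= self.intervals["start"]).any():
            raise ParameterError(f"track {self.name}: invalid intervals")
        self._trees: dict[str, IntervalTree] = {}
        for chrom, grp in self.intervals.groupby("chrom", sort=False):
            self._trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e)) for s, e in zip(grp["start"], grp["end"])
            )

    def contains(self, chrom: str, pos0: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree.overlaps_point(int(pos0))) if tree is not None else False


def snp_track_overlap(snp_map: pd.DataFrame, track: AnnotationTrack) -> pd.Series:
    """Per-SNP membership flag: position inside >=1 track interval."""
    pos0 = snp_map["pos"].astype(int) - 1
    flags = [track.contains(c, p) for c, p in zip(snp_map["chrom"], pos0)]
    return pd.Series(flags, index=snp_map.index, name="in_track")


@dataclass
class EnrichmentResult:
    track: str
    observed_fold: float
    n_query: int
    n_query_in_track: int
    background_fraction: float
    null_log_mean: float | None = None
    null_log_sd: float | None = None
    p_one_sided: float | None = None
    zero_replacement: float | None = None


def _set_hits(query_sets: list[list[tuple[str, int]]], track: AnnotationTrack) -> int:
    """Number of query sets with >=1 member (chrom, pos0) inside the track."""
    return sum(
        any(track.contains(c, p) for c, p in members) for members in query_sets
    )


def fold_enrichment(
    query_sets: list[list[tuple[str, int]]],
    background: pd.DataFrame,
    track: AnnotationTrack,
) -> EnrichmentResult:
    """Set-hit fraction over background-SNP in-track fraction.

    ``query_sets`` are lists of (chrom, pos0) members (an index SNP with
    its perfect proxies); ``background`` is a SNP map.  An empty track
    yields fold 0 with a warning; an empty background fraction yields a
    NaN (undefined) fold.
    """
    if not query_sets or background.empty:
        raise ParameterError("query sets and background must be non-empty")
    if track.intervals.empty:
        logger.warning("empty track %s; fold set to 0", track.name)
        return EnrichmentResult(track.name, 0.0, len(query_sets), 0, 0.0)
    bg_frac = float(snp_track_overlap(background, track).mean())
    n_hit = _set_hits(query_sets, track)
    q_frac = n_hit / len(query_sets)
    fold = q_frac / bg_frac if bg_frac > 0 else float("nan")
    return EnrichmentResult(track.name, fold, len(query_sets), n_hit, bg_frac)


def eqtl_query_sets(
    records: pd.DataFrame,
    geno: GenotypeMatrix,
    n_top: int,
    max_distance: int = 500_000,
    proxy_cache: dict | None = None,
) -> list[list[tuple[str, int]]]:
    """Top-``n_top`` probes' top SNPs expanded by their perfect proxies.

    Probes are ranked by their minimum P; each selected probe contributes
    one set of (chrom, pos0) positions: its top SNP plus every perfect
    proxy (r2 = 1).  ``proxy_cache`` (snp_id -> member list) memoizes the
    proxy expansion across repeated calls.
    """
    top = top_eqtl_per_probe(records).sort_values(["p", "probe_id"]).head(n_top)
    sets = []
    for snp in top["snp_id"]:
        if proxy_cache is not None and snp in proxy_cache:
            sets.append(proxy_cache[snp])
            continue
        proxy = find_proxies(snp, geno, threshold=1.0, max_distance=max_distance)
        ids = proxy.snp_ids or [snp]
        sm = geno.snp_map.loc[ids]
        members = list(zip(sm["chrom"], sm["pos"].astype(int) - 1))
        if proxy_cache is not None:
            proxy_cache[snp] = members
        sets.append(members)
    return sets


def permutation_enrichment_significance(
    expr: ExpressionMatrix,
    geno: GenotypeMatrix,
    pairs: pd.DataFrame,
    track: AnnotationTrack,
    n_top: int,
    n_perm: int = 100,
    seed: int = 0,
    max_distance: int = 500_000,
    **scan_kwargs,
) -> EnrichmentResult:
    """One-sided enrichment P from a normal fit to log permuted folds.

    The observed fold uses the real top-``n_top`` probes' top SNPs plus
    perfect proxies.  Each permutation shuffles the expression sample
    labels, re-maps the cis scan, applies the identical top-probe/top-SNP/
    perfect-proxy expansion and recomputes the fold.  A maximum-likelihood
    normal fit to the ``n_perm`` log folds gives
    ``p = P(N(mu, sd) >= log observed)``; zero folds are replaced by half
    the smallest positive fold before the log (recorded in the result).
    """
    scanner = CisScanner(expr, geno, pairs, **scan_kwargs)

    def records_from(perm=None) -> pd.DataFrame:
        rho, p = scanner.scan(perm)
        rec = scanner.pairs.copy()
        rec["n_used"] = scanner.n
        rec["rho"] = rho
        rec["p"] = p
        rec["z"] = _z_from_p(p, rho)
        rec["tissue"] = ""
        return rec[list(RECORD_COLUMNS)]

    background = geno.snp_map
    cache: dict = {}
    observed_sets = eqtl_query_sets(records_from(), geno, n_top, max_distance, cache)
    obs = fold_enrichment(observed_sets, background, track)

    rng_children = np.random.SeedSequence(seed).spawn(n_perm)
    null_folds = []
    for child in rng_children:
        rng = np.random.default_rng(child)
        perm = rng.permutation(scanner.n)
        sets = eqtl_query_sets(records_from(perm), geno, n_top, max_distance, cache)
        null_folds.append(fold_enrichment(sets, background, track).observed_fold)
    null_folds = np.asarray(null_folds, dtype=float)

    positive = null_folds[null_folds > 0]
    if positive.size == 0:
        logger.warning("all permuted folds are zero; significance not estimable")
        return EnrichmentResult(
            track.name, obs.observed_fold, obs.n_query, obs.n_query_in_track,
            obs.background_fraction,
        )
    zero_rep = float(positive.min() / 2.0)
    adj = np.where(null_folds > 0, null_folds, zero_rep)
    logs = np.log(adj)
    mu, sd = float(logs.mean()), float(logs.std(ddof=0))
    obs_fold_adj = obs.observed_fold if obs.observed_fold > 0 else zero_rep
    if sd == 0:
        p = 0.5 if np.log(obs_fold_adj) == mu else (0.0 if np.log(obs_fold_adj) > mu else 1.0)
        p = max(p, np.finfo(float).tiny)
    else:
        p = float(stats.norm.sf(np.log(obs_fold_adj), loc=mu, scale=sd))
        p = max(p, np.finfo(float).tiny)
    return EnrichmentResult(
        track.name, obs.observed_fold, obs.n_query, obs.n_query_in_track,
        obs.background_fraction, mu, sd, p, zero_rep,
    )
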
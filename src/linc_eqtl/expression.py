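"""Expression normalization, abundance comparison and control-probe selection.

Normalization follows the microarray eQTL convention: quantile
normalization across samples (every sample column receives the identical
value multiset, the across-sample mean of order statistics), log2
transformation, and optional removal of leading principal components to
strip broad non-genetic structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix
from .errors import InsufficientDataError, MatchingError, ParameterError

logger = logging.getLogger(__name__)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the mean order-statistic distribution.

    Ties within a column receive the mean of the target quantile values
    their sorted positions span; probe and sample order are preserved.
    The operation is idempotent.
    """
    x = m.intensities.to_numpy(dtype=float)
    n_probes, n_samples = x.shape
    target = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(n_samples):
        col = x[:, j]
        if np.ptp(col) == 0:
            logger.warning("sample column %d is constant; set to target mean", j)
            out[:, j] = target.mean()
            continue
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_probes)
        assigned[order] = target
        # average the target values across each tie group
        s = pd.Series(assigned).groupby(col).transform("mean").to_numpy()
        out[:, j] = s
    return m.with_values(out, state="quantile_log")


def log2_transform(m: ExpressionMatrix, offset: float = 0.0) -> ExpressionMatrix:
    """Elementwise log2, optionally after adding a pseudo-offset."""
    x = m.intensities.to_numpy(dtype=float) + offset
    if (x <= 0).any():
        raise ParameterError("non-positive intensities; supply a positive offset")
    return m.with_values(np.log2(x))


def remove_principal_components(
    m: ExpressionMatrix, k: int, protect_genetic: bool = False
) -> ExpressionMatrix:
    """Residualize the matrix against its top-k singular components.

    Uses the plain (uncentred) SVD so k=0 is an exact identity and an
    exactly rank-k matrix is annihilated by removing k components.
    ``protect_genetic`` is accepted for interface compatibility; component
    protection requires genotype data and is a no-op here.
    """
    if k == 0:
        return m
    x = m.intensities.to_numpy(dtype=float)
    if k >= min(x.shape):
        raise ParameterError(f"k={k} must be smaller than min(matrix dims)={min(x.shape)}")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    recon = (u[:, :k] * s[:k]) @ vt[:k]
    return m.with_values(x - recon, state="pc_corrected")


@dataclass
class AbundanceComparison:
    """Two-group comparison of per-probe mean intensity and variance."""

    group_labels: tuple[str, str]
    mean_a: float
    mean_b: float
    mean_stat: float
    mean_p: float
    var_stat: float
    var_p: float


def compare_abundance(
    group_a: list[str],
    group_b: list[str],
    m: ExpressionMatrix,
    labels: tuple[str, str] = ("A", "B"),
) -> AbundanceComparison:
    """Mann-Whitney comparison of per-probe means and variances.

    Exact null distribution for small groups, normal approximation with tie
    correction otherwise (scipy's automatic policy).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise InsufficientDataError("each group needs at least 2 probes")
    if set(group_a) & set(group_b):
        raise ParameterError("probe groups must be disjoint")
    a = m.intensities.loc[group_a]
    b = m.intensities.loc[group_b]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    var_a, var_b = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    mstat, mp = stats.mannwhitneyu(mean_a, mean_b, alternative="two-sided", method="auto")
    vstat, vp = stats.mannwhitneyu(var_a, var_b, alternative="two-sided", method="auto")
    return AbundanceComparison(
        labels,
        float(mean_a.mean()),
        float(mean_b.mean()),
        float(mstat),
        float(max(mp, np.finfo(float).tiny)),
        float(vstat),
        float(max(vp, np.finfo(float).tiny)),
    )


def _probe_stats(m: ExpressionMatrix, probes: list[str], statistic: str) -> np.ndarray:
    x = m.intensities.loc[probes]
    loc = x.median(axis=1) if statistic == "median" else x.mean(axis=1)
    return np.column_stack([loc.to_numpy(), x.std(axis=1, ddof=1).to_numpy()])


def select_matched_probes(
    reference: list[str],
    pool: list[str],
    m: ExpressionMatrix,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Greedy nearest-neighbour matching in standardized (location, SD) space.

    Selects ``len(reference)`` pool probes, each the nearest unused pool
    probe to one reference probe; ``statistic`` chooses mean (default) or
    median as the location measure.  Returns the matched pairs plus the
    post-match group deltas as DataFrame attrs.
    """
    if set(reference) & set(pool):
        raise ParameterError("pool must be disjoint from the reference set")
    if len(pool) < len(reference):
        raise MatchingError("candidate pool smaller than the reference set")
    ref = _probe_stats(m, reference, statistic)
    cand = _probe_stats(m, pool, statistic)
    both = np.vstack([ref, cand])
    scale = both.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    refz, candz = ref / scale, cand / scale

    available = np.ones(len(pool), dtype=bool)
    matches = np.empty(len(reference), dtype=int)
    # match hardest-first: reference probes sorted by distance to their
    # nearest candidate so extremes are not starved by earlier picks
    d_nearest = np.array(
        [np.min(np.linalg.norm(candz - r, axis=1)) for r in refz]
    )
    for i in np.argsort(-d_nearest):
        d = np.linalg.norm(candz - refz[i], axis=1)
        d[~available] = np.inf
        j = int(np.argmin(d))
        if not available[j]:
            raise MatchingError("candidate pool exhausted")
        matches[i] = j
        available[j] = False
    matched_ids = [pool[j] for j in matches]
    out = pd.DataFrame({"reference": reference, "matched": matched_ids})
    out.attrs["delta_location"] = float(np.mean(cand[matches, 0]) - np.mean(ref[:, 0]))
    out.attrs["delta_sd"] = float(np.mean(cand[matches, 1]) - np.mean(ref[:, 1]))
    return out


def select_top_expressed(pool: list[str], m: ExpressionMatrix, n: int) -> list[str]:
    """Top ``n`` pool probes by per-probe mean; ties broken by probe_id."""
    if n > len(pool):
        raise ParameterError(f"requested {n} probes from a pool of {len(pool)}")
    means = m.intensities.loc[pool].mean(axis=1)
    order = sorted(pool, key=lambda p: (-means[p], p))
    return order[:n]
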
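"""Core in-memory containers: genotype dosage matrix and expression matrix.

Both wrap pandas DataFrames oriented the way the on-disk TSV formats are:
genotypes are SNPs x samples (dosage 0/1/2, NaN for missing), expression is
probes x samples.  Coordinates are 0-based half-open internally; the SNP map
stores the conventional 1-based ``pos`` and a derived 0-based ``pos0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError

#: Valid normalization states for an expression matrix.
NORMALIZATION_STATES = ("raw", "quantile_log", "pc_corrected")

#: Transcript class labels carried by probe records.
PROBE_CLASSES = ("lincRNA", "protein_coding", "unassigned")

SNP_MAP_COLUMNS = ("chrom", "pos", "ref", "alt", "maf")
PROBE_MAP_COLUMNS = ("chrom", "start", "end", "center", "transcript_class")


def probe_center(start: int, end: int) -> int:
    """Midpoint of a probe alignment interval, ``floor((start+end)/2)``."""
    return (int(start) + int(end)) // 2


@dataclass
class GenotypeMatrix:
    """SNPs x samples dosage matrix plus its SNP map.

    Parameters
    ----------
    dosages
        DataFrame indexed by snp_id with sample_id columns; values in
        {0, 1, 2} or NaN.
    snp_map
        DataFrame indexed by snp_id with columns chrom, pos (1-based),
        ref, alt and optionally maf.
    """

    dosages: pd.DataFrame
    snp_map: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.index.equals(self.snp_map.index):
            self.snp_map = self.snp_map.loc[self.dosages.index]
        vals = self.dosages.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ParameterError("dosages must be 0, 1, 2 or missing")
        if "pos0" not in self.snp_map.columns:
            self.snp_map = self.snp_map.assign(pos0=self.snp_map["pos"].astype(int) - 1)

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[0]

    def sample_allele_freq(self) -> pd.Series:
        """Observed alternate-allele frequency per SNP (missing excluded)."""
        return self.dosages.mean(axis=1, skipna=True) / 2.0

    def subset_samples(self, sample_ids) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages.loc[:, list(sample_ids)], self.snp_map.copy())


@dataclass
class ExpressionMatrix:
    """Probes x samples intensity matrix with probe alignment records.

    ``probe_map`` is indexed by probe_id and carries chrom, start, end,
    center (floor midpoint of the alignment) and transcript_class
    (lincRNA / protein_coding / unassigned).
    """

    intensities: pd.DataFrame
    probe_map: pd.DataFrame
    normalization_state: str = "raw"
    mapped_gene_ids: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.normalization_state not in NORMALIZATION_STATES:
            raise ParameterError(
                f"unknown normalization_state {self.normalization_state!r}"
            )
        if not self.intensities.index.equals(self.probe_map.index):
            self.probe_map = self.probe_map.loc[self.intensities.index]
        if "center" not in self.probe_map.columns:
            self.probe_map = self.probe_map.assign(
                center=[
                    probe_center(s, e)
                    for s, e in zip(self.probe_map["start"], self.probe_map["end"])
                ]
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    def probes_of_class(self, transcript_class: str) -> list[str]:
        mask = self.probe_map["transcript_class"] == transcript_class
        return list(self.probe_map.index[mask])

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.intensities.loc[:, list(sample_ids)],
            self.probe_map.copy(),
            self.normalization_state,
            dict(self.mapped_gene_ids),
        )

    def with_values(self, values: np.ndarray, state: str | None = None) -> "ExpressionMatrix":
        """Copy carrying new intensity values (same probes/samples)."""
        df = pd.DataFrame(values, index=self.intensities.index, columns=self.intensities.columns)
        return ExpressionMatrix(
            df, self.probe_map.copy(), state or self.normalization_state, dict(self.mapped_gene_ids)
        )
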
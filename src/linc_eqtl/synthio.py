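"""Seeded synthetic genotype / expression / annotation generators.

The generators emulate the statistical structure a blood cis-eQTL study of
lincRNA microarray probes relies on, at desk scale:

* unphased dosage genotypes under Hardy-Weinberg proportions, organised in
  LD blocks by a block-copy model (each SNP copies the previous block
  member's dosage per individual with probability ``ld_decay``, otherwise it
  is redrawn from the block's Hardy-Weinberg distribution, so the dosage
  correlation between SNPs at lag k within a block is ``ld_decay**k``);
* microarray-like expression on a log-intensity scale where lincRNA probes
  sit ``abundance_shift`` intensity units below protein-coding probes
  (defaults reproduce the 6.67 vs 6.92 class means of a blood cohort),
  with planted additive cis effects (``beta`` intensity units per allele
  copy) and Gaussian noise;
* multiple tissues sharing the same genotyped individuals, with effects
  optionally restricted to a subset of tissues;
* GWAS-catalog and enhancer-track fixtures with planted truth for the
  downstream intersection and enrichment stages.

Every generator draws from a `numpy` Generator seeded from the spec's
master seed plus a fixed per-generator salt, so simulations are
reproducible and the tissue matrices stay consistent with each other.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix, probe_center
from .errors import ParameterError, SpecificationError
from . import io

_NUCS = np.array(list("ACGT"))

# salts for the independent seeded streams of each generator step
_SALT_GENO, _SALT_PROBES, _SALT_TISSUE, _SALT_NOISE, _SALT_TRACKS = 11, 23, 37, 53, 71


@dataclass(frozen=True)
class EffectSpec:
    """One planted cis effect: ``beta`` intensity units per allele copy.

    ``tissues_active`` of None means the effect is present in every tissue.
    """

    probe_id: str
    snp_id: str
    beta: float
    tissues_active: frozenset | None = None

    def active_in(self, tissue: str) -> bool:
        return self.tissues_active is None or tissue in self.tissues_active


@dataclass
class SimulationSpec:
    """Parameters of one synthetic study.

    Defaults are desk-scale stand-ins for a blood microarray eQTL cohort:
    protein-coding probes centred at intensity 6.92 with lincRNA probes
    0.25 units lower, unit-variance noise, MAF uniform on [0.05, 0.5],
    LD blocks of 10 SNPs with adjacent-dosage correlation 0.9.
    """

    n_samples: int = 200
    n_snps: int = 2000
    n_probes: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_decay: float = 0.9
    planted_effects: list[EffectSpec] = field(default_factory=list)
    lincRNA_fraction: float = 0.5
    baseline: float = 6.92
    abundance_shift: float = 0.25
    noise_sd: float = 1.0
    tissues: tuple[tuple[str, int], ...] | None = None
    mean_snp_spacing: int = 5000
    probe_length: int = 50
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ParameterError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        for name in ("n_samples", "n_snps", "n_probes", "ld_block_size"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not (0 <= self.ld_decay < 1):
            raise ParameterError("ld_decay must be in [0, 1)")
        if not (0 <= self.lincRNA_fraction <= 1):
            raise ParameterError("lincRNA_fraction must be a proportion")
        if self.tissues is None:
            self.tissues = (("blood", self.n_samples),)
        for name, n_sub in self.tissues:
            if not (0 < n_sub <= self.n_samples):
                raise ParameterError(
                    f"tissue {name!r} subset size {n_sub} exceeds sample universe"
                )

    @property
    def tissue_names(self) -> list[str]:
        return [name for name, _ in self.tissues]


def _rng(spec: SimulationSpec, *salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec.seed, *salt)))


def simulate_genotypes(spec: SimulationSpec) -> GenotypeMatrix:
    """Draw Hardy-Weinberg dosages with block-copy LD.

    SNP positions are a cumulative sum of spacings uniform on
    [1, 2*mean_snp_spacing], so positions are strictly increasing with the
    requested mean density.  Within a block all SNPs share one MAF drawn
    uniformly from ``maf_range``; the lag-k dosage correlation inside a
    block is ``ld_decay**k`` and blocks are independent.
    """
    rng = _rng(spec, _SALT_GENO)
    n, m = spec.n_samples, spec.n_snps
    dosages = np.empty((m, n), dtype=np.int8)
    mafs = np.empty(m)
    i = 0
    while i < m:
        size = min(spec.ld_block_size, m - i)
        maf = rng.uniform(*spec.maf_range)
        fresh = rng.binomial(2, maf, size=(size, n)).astype(np.int8)
        block = fresh.copy()
        if size > 1 and spec.ld_decay > 0:
            copy = rng.random((size - 1, n)) < spec.ld_decay
            for j in range(1, size):
                block[j] = np.where(copy[j - 1], block[j - 1], fresh[j])
        dosages[i : i + size] = block
        mafs[i : i + size] = maf
        i += size

    spacings = rng.integers(1, 2 * spec.mean_snp_spacing, size=m)
    pos = np.cumsum(spacings)  # 1-based positions
    ref = rng.choice(_NUCS, size=m)
    alt = np.array([rng.choice(_NUCS[_NUCS != r]) for r in ref])
    snp_ids = [f"snp{k:06d}" for k in range(m)]
    snp_map = pd.DataFrame(
        {"chrom": spec.chrom, "pos": pos, "ref": ref, "alt": alt, "maf": mafs},
        index=pd.Index(snp_ids, name="snp_id"),
    )
    sample_ids = [f"sample{k:04d}" for k in range(n)]
    dos = pd.DataFrame(dosages, index=snp_map.index, columns=sample_ids)
    return GenotypeMatrix(dos, snp_map)


def place_probes(spec: SimulationSpec, geno: GenotypeMatrix) -> pd.DataFrame:
    """Place probe alignment intervals near SNPs and assign transcript classes.

    Each probe centre is drawn within 50 kb of a random SNP so every probe
    has cis SNPs; the class split follows ``lincRNA_fraction`` exactly
    (rounded).  Deterministic given the spec seed and the genotype map.
    """
    rng = _rng(spec, _SALT_PROBES)
    snp_pos = geno.snp_map["pos"].to_numpy()
    anchors = rng.choice(snp_pos, size=spec.n_probes, replace=True)
    centers = np.maximum(anchors + rng.integers(-50_000, 50_001, size=spec.n_probes),
                         spec.probe_length)
    half = spec.probe_length // 2
    start0 = centers - 1 - half  # 0-based half-open
    end0 = start0 + spec.probe_length
    n_linc = int(round(spec.lincRNA_fraction * spec.n_probes))
    classes = np.array(["protein_coding"] * spec.n_probes, dtype=object)
    classes[rng.choice(spec.n_probes, size=n_linc, replace=False)] = "lincRNA"
    probe_ids = [f"probe{k:05d}" for k in range(spec.n_probes)]
    return pd.DataFrame(
        {
            "chrom": spec.chrom,
            "start": start0,
            "end": end0,
            "center": [probe_center(s, e) for s, e in zip(start0, end0)],
            "transcript_class": classes,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )


def plant_cis_effects(
    geno: GenotypeMatrix,
    probe_map: pd.DataFrame,
    n_effects: int,
    beta: float,
    seed: int,
    window: int = 250_000,
    probe_class: str | None = None,
    tissues_active: frozenset | None = None,
) -> list[EffectSpec]:
    """Pick ``n_effects`` distinct probes and one cis SNP each (|d| <= window).

    Helper for building ``SimulationSpec.planted_effects``; probes without
    any SNP in their window are skipped.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 97)))
    pm = probe_map
    if probe_class is not None:
        pm = pm[pm["transcript_class"] == probe_class]
    pos = geno.snp_map["pos"].to_numpy()
    pos0 = pos - 1
    snp_ids = geno.snp_map.index.to_numpy()
    effects: list[EffectSpec] = []
    order = rng.permutation(len(pm))
    for idx in order:
        if len(effects) >= n_effects:
            break
        probe_id = pm.index[idx]
        center = int(pm["center"].iloc[idx])
        in_win = np.flatnonzero(np.abs(pos0 - center) <= window)
        if in_win.size == 0:
            continue
        snp_id = snp_ids[rng.choice(in_win)]
        effects.append(EffectSpec(probe_id, snp_id, beta, tissues_active))
    if len(effects) < n_effects:
        raise SpecificationError(
            f"could only plant {len(effects)} of {n_effects} requested effects"
        )
    return effects


def tissue_samples(spec: SimulationSpec, geno: GenotypeMatrix) -> dict[str, list[str]]:
    """Sample subset per tissue, drawn once from the shared individuals."""
    out: dict[str, list[str]] = {}
    samples = list(geno.sample_ids)
    for k, (name, n_sub) in enumerate(spec.tissues):
        rng = _rng(spec, _SALT_TISSUE, k)
        if n_sub == len(samples):
            out[name] = samples
        else:
            idx = np.sort(rng.choice(len(samples), size=n_sub, replace=False))
            out[name] = [samples[i] for i in idx]
    return out


def simulate_expression(
    geno: GenotypeMatrix, spec: SimulationSpec, tissue: str | None = None
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate probe intensities for one tissue and return the truth table.

    intensity = class baseline + beta * dosage (for planted, tissue-active
    pairs) + N(0, noise_sd).  lincRNA probes sit ``abundance_shift`` below
    the protein-coding baseline.  The truth table has one row per planted
    effect with columns probe_id, snp_id, beta, tissues_active.
    """
    if tissue is None:
        tissue = spec.tissue_names[0]
    if tissue not in spec.tissue_names:
        raise SpecificationError(f"unknown tissue {tissue!r}")
    probe_map = place_probes(spec, geno)
    samples = tissue_samples(spec, geno)[tissue]
    n = len(samples)
    base = np.full((spec.n_probes, n), spec.baseline, dtype=float)
    is_linc = (probe_map["transcript_class"] == "lincRNA").to_numpy()
    base[is_linc] -= spec.abundance_shift

    probe_index = {p: i for i, p in enumerate(probe_map.index)}
    dos = geno.dosages[samples]
    for eff in spec.planted_effects:
        if eff.probe_id not in probe_index:
            raise SpecificationError(f"effect references unknown probe {eff.probe_id!r}")
        if eff.snp_id not in geno.snp_ids:
            raise SpecificationError(f"effect references unknown SNP {eff.snp_id!r}")
        if not np.isfinite(eff.beta):
            raise SpecificationError("effect beta must be finite")
        if eff.active_in(tissue):
            base[probe_index[eff.probe_id]] += eff.beta * dos.loc[eff.snp_id].to_numpy()

    tissue_idx = spec.tissue_names.index(tissue)
    rng = _rng(spec, _SALT_NOISE, tissue_idx)
    if spec.noise_sd > 0:
        base += rng.normal(0.0, spec.noise_sd, size=base.shape)
    expr = ExpressionMatrix(
        pd.DataFrame(base, index=probe_map.index, columns=samples), probe_map, "raw"
    )
    truth = pd.DataFrame(
        {
            "probe_id": [e.probe_id for e in spec.planted_effects],
            "snp_id": [e.snp_id for e in spec.planted_effects],
            "beta": [e.beta for e in spec.planted_effects],
            "tissues_active": [
                "*" if e.tissues_active is None else ",".join(sorted(e.tissues_active))
                for e in spec.planted_effects
            ],
        }
    )
    return expr, truth


def make_lincRNA_catalog(probe_map: pd.DataFrame, spec: SimulationSpec) -> pd.DataFrame:
    """Build a transcript catalog whose exons cover the lincRNA probes.

    Each lincRNA probe gets a two-exon transcript containing its alignment
    interval, so mapping probes back to the catalog recovers the planted
    classes.  Returns exon rows (transcript_id, gene_id, chrom, strand,
    start, end).
    """
    rows = []
    linc = probe_map[probe_map["transcript_class"] == "lincRNA"]
    for k, (probe_id, rec) in enumerate(linc.iterrows()):
        tid, gid = f"TCONS_{k:05d}", f"XLOC_{k:05d}"
        strand = "+" if k % 2 == 0 else "-"
        s, e = int(rec["start"]), int(rec["end"])
        rows.append((tid, gid, rec["chrom"], strand, max(0, s - 200), e + 100))
        rows.append((tid, gid, rec["chrom"], strand, e + 600, e + 1200))
    return pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "chrom", "strand", "start", "end"]
    )


def make_gwas_catalog(
    spec: SimulationSpec,
    trait_snps: list[str],
    n_decoys: int = 5,
    inclusion_p: float = 9.9e-6,
    source_version: str = "synthetic-v1",
) -> pd.DataFrame:
    """GWAS-catalog fixture: each trait SNP gets p_reported below the
    inclusion threshold; decoys sit just above it."""
    rng = _rng(spec, _SALT_TRACKS, 1)
    rows = [
        (s, f"trait_{i % 3}", float(10 ** -rng.uniform(6.5, 12)))
        for i, s in enumerate(trait_snps)
    ]
    for j in range(n_decoys):
        rows.append((f"snp_decoy{j:03d}", "decoy_trait",
                     float(inclusion_p * rng.uniform(1.5, 10))))
    df = pd.DataFrame(rows, columns=["snp_id", "trait", "p_reported"])
    df["source_version"] = source_version
    return df


def make_enhancer_tracks(
    spec: SimulationSpec,
    geno: GenotypeMatrix,
    causal_snps: list[str] | None = None,
    cell_types: tuple[str, ...] = ("K562", "GM12878"),
    coverage: float = 0.1,
) -> dict[str, pd.DataFrame]:
    """Random enhancer interval tracks, one per cell type, covering roughly
    ``coverage`` of the SNP-bearing region; if ``causal_snps`` is given an
    extra ``causal`` track contains a 1 kb interval around each of them."""
    rng = _rng(spec, _SALT_TRACKS, 2)
    length = int(geno.snp_map["pos"].max()) + 10_000
    tracks: dict[str, pd.DataFrame] = {}
    iv_len = 2000
    n_iv = max(1, int(coverage * length / iv_len))
    for ct in cell_types:
        starts = np.sort(rng.integers(0, length - iv_len, size=n_iv))
        tracks[ct] = pd.DataFrame(
            {"chrom": spec.chrom, "start": starts, "end": starts + iv_len}
        )
    if causal_snps:
        pos0 = geno.snp_map.loc[causal_snps, "pos"].to_numpy() - 1
        tracks["causal"] = pd.DataFrame(
            {"chrom": spec.chrom, "start": np.maximum(pos0 - 500, 0), "end": pos0 + 500}
        )
    return tracks


@dataclass
class Dataset:
    """Bundle of one simulated study: genotypes, per-tissue expression, truth."""

    spec: SimulationSpec
    geno: GenotypeMatrix
    expression: dict[str, ExpressionMatrix]
    truth: pd.DataFrame

    @property
    def blood(self) -> ExpressionMatrix:
        return self.expression[self.spec.tissue_names[0]]


def simulate_dataset(spec: SimulationSpec) -> Dataset:
    """Genotypes plus expression for every tissue in the spec."""
    geno = simulate_genotypes(spec)
    expression = {}
    truth = None
    for name in spec.tissue_names:
        expression[name], truth = simulate_expression(geno, spec, tissue=name)
    return Dataset(spec, geno, expression, truth)


def make_fixture_suite(spec: SimulationSpec, outdir) -> dict:
    """Write the full fixture suite to ``outdir`` and return the manifest.

    Files: genotype dosage + SNP map TSV, per-tissue expression TSV + probe
    map, lincRNA catalog BED, GWAS catalog TSV, one enhancer BED per cell
    type.  The manifest records every file with its row count and sha256,
    plus the master seed; re-running with the same spec is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(spec)

    files: dict[str, dict] = {}

    def _register(name: str, path: Path, n_rows: int) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        files[name] = {"path": path.name, "rows": int(n_rows), "sha256": digest}

    geno_path, map_path = outdir / "genotypes.tsv", outdir / "snp_map.tsv"
    io.write_genotypes(ds.geno, geno_path, map_path)
    _register("genotypes", geno_path, ds.geno.n_snps)
    _register("snp_map", map_path, ds.geno.n_snps)

    probe_map_path = outdir / "probe_map.tsv"
    for name, expr in ds.expression.items():
        p = outdir / f"expression_{name}.tsv"
        io.write_expression(expr, p, probe_map_path)
        _register(f"expression_{name}", p, expr.intensities.shape[0])
    _register("probe_map", probe_map_path, spec.n_probes)

    catalog = make_lincRNA_catalog(place_probes(spec, ds.geno), spec)
    cat_path = outdir / "lincRNA_catalog.bed"
    io.write_catalog_bed(catalog, cat_path)
    _register("lincRNA_catalog", cat_path, len(catalog))

    trait_snps = sorted({e.snp_id for e in spec.planted_effects})
    gwas = make_gwas_catalog(spec, trait_snps)
    gwas_path = outdir / "gwas_catalog.tsv"
    io.write_gwas_catalog(gwas, gwas_path)
    _register("gwas_catalog", gwas_path, len(gwas))

    tracks = make_enhancer_tracks(spec, ds.geno, causal_snps=trait_snps or None)
    for ct, track in tracks.items():
        p = outdir / f"enhancers_{ct}.bed"
        io.write_bed(track, p)
        _register(f"enhancers_{ct}", p, len(track))

    truth_path = outdir / "truth.tsv"
    ds.truth.to_csv(truth_path, sep="\t", index=False)
    _register("truth", truth_path, len(ds.truth))

    manifest = {"seed": spec.seed, "tissues": spec.tissue_names, "files": files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def expected_adjacent_r2(ld_decay: float) -> float:
    """Closed-form population r^2 between adjacent block SNPs.

    Under the block-copy construction an adjacent pair has dosage
    correlation ``ld_decay`` (identical marginals, copy with probability
    ``ld_decay``), so the squared correlation is ``ld_decay**2``; at lag k
    it is ``ld_decay**(2k)``.
    """
    return ld_decay ** 2
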
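"""Cis-pair enumeration, Spearman testing, permutation FDR, replication,
and specificity classification."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from linc_eqtl import (
    EffectSpec,
    SimulationSpec,
    compare_tissues,
    enumerate_cis_pairs,
    map_cis_eqtls,
    permutation_fdr,
    replicate,
    simulate_expression,
    simulate_genotypes,
    spearman_test,
    specificity_analysis,
    top_eqtl_per_probe,
)
from linc_eqtl.containers import GenotypeMatrix
from linc_eqtl.eqtl import CisScanner, harmonize_alleles
from linc_eqtl.synthio import place_probes
from conftest import build_study


class TestCisPairEnumeration:
    def test_window_edge_inclusive(self):
        pm = pd.DataFrame(
            {"chrom": ["chr1"], "center": [1_000_000]},
            index=pd.Index(["p1"], name="probe_id"),
        )
        sm = pd.DataFrame(
            {"chrom": "chr1", "pos": [1_250_001, 1_250_002, 750_001, 750_000]},
            index=pd.Index(["edge_hi", "out_hi", "edge_lo", "out_lo"], name="snp_id"),
        )
        pairs = enumerate_cis_pairs(pm, sm, window=250_000)
        assert set(pairs["snp_id"]) == {"edge_hi", "edge_lo"}
        assert set(pairs["distance"]) == {250_000, -250_000}

    def test_probe_without_cis_snps(self):
        pm = pd.DataFrame({"chrom": ["chr2"], "center": [100]},
                          index=pd.Index(["p1"], name="probe_id"))
        sm = pd.DataFrame({"chrom": "chr1", "pos": [100]},
                          index=pd.Index(["s1"], name="snp_id"))
        assert enumerate_cis_pairs(pm, sm).empty

    def test_matches_quadratic_bruteforce(self, rng):
        n_probes, n_snps, window = 100, 1000, 50_000
        pm = pd.DataFrame(
            {"chrom": rng.choice(["chr1", "chr2"], n_probes),
             "center": rng.integers(0, 2_000_000, n_probes)},
            index=pd.Index([f"p{i}" for i in range(n_probes)], name="probe_id"),
        )
        sm = pd.DataFrame(
            {"chrom": rng.choice(["chr1", "chr2"], n_snps),
             "pos": rng.integers(1, 2_000_001, n_snps)},
            index=pd.Index([f"s{i}" for i in range(n_snps)], name="snp_id"),
        )
        got = set(zip(*enumerate_cis_pairs(pm, sm, window)[["probe_id", "snp_id"]].T.values))
        expected = {
            (p, s)
            for p in pm.index for s in sm.index
            if pm.loc[p, "chrom"] == sm.loc[s, "chrom"]
            and abs(int(sm.loc[s, "pos"]) - 1 - int(pm.loc[p, "center"])) <= window
        }
        assert got == expected


class TestSpearman:
    def test_perfect_monotone(self):
        # expression strictly increasing in dosage: rho = 1 up to midranks
        d = np.repeat([0, 1, 2], 10)
        e = np.arange(30, dtype=float)
        res = spearman_test(d, e, min_samples=10)
        assert res.rho > 0.9 and res.p < 1e-6 and res.z > 0

    def test_exact_permutation_oracle_small_n(self):
        d = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        e = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        res = spearman_test(d, e, min_samples=4, min_minor_carriers=1)
        rho_exp = stats.spearmanr(d, e).statistic
        assert res.rho == pytest.approx(rho_exp, abs=1e-12)
        # independent exhaustive-permutation oracle
        null = [
            stats.spearmanr(d, perm).statistic
            for perm in itertools.permutations(e)
        ]
        p_exp = np.mean(np.abs(null) >= abs(rho_exp) - 1e-12)
        assert res.p == pytest.approx(p_exp, abs=1e-12)

    def test_null_pvalues_uniform(self, rng):
        # 1,000 independent null tests at n=100; KS against U(0,1) at alpha=0.01
        n, reps = 100, 1000
        ps = []
        for _ in range(reps):
            d = rng.binomial(2, 0.3, n).astype(float)
            e = rng.normal(size=n)
            ps.append(spearman_test(d, e).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_not_testable_sentinels(self):
        n = 40
        assert spearman_test(np.zeros(n), np.random.default_rng(0).normal(size=n)) is None
        assert spearman_test(np.tile([0, 1, 2], 10), np.ones(30)) is None
        assert spearman_test(np.array([0.0, 1.0] * 10), np.arange(20.0)) is None  # n < 30
        d = np.zeros(50); d[0] = 1  # only one minor-allele carrier
        assert spearman_test(d, np.arange(50.0)) is None

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.binomial(2, 0.4, 60).astype(float)
        e = rng.normal(size=60) + 0.4 * d
        base = spearman_test(d, e)
        for f in (np.exp, lambda x: x**3, lambda x: 5 * x - 2):
            res = spearman_test(d, f(e))
            assert res.rho == pytest.approx(base.rho, abs=1e-12)
            assert res.p == pytest.approx(base.p, rel=1e-9)


class TestMapCisEqtls:
    def test_planted_pair_has_smallest_p_in_window(self):
        hits = 0
        for seed in range(10):
            study = build_study(seed=100 + seed, n_samples=200, n_snps=300,
                                n_probes=20, n_effects=1, beta=1.0)
            rec = map_cis_eqtls(study["expr"], study["geno"], study["pairs"])
            eff = study["spec"].planted_effects[0]
            probe_rec = rec[rec["probe_id"] == eff.probe_id]
            best_snp = probe_rec.loc[probe_rec["p"].idxmin(), "snp_id"]
            # the planted SNP or a near-perfect LD partner must win
            if best_snp == eff.snp_id:
                hits += 1
            else:
                from linc_eqtl import ld_r2
                r2 = ld_r2(study["geno"].dosages.loc[best_snp].to_numpy(),
                           study["geno"].dosages.loc[eff.snp_id].to_numpy())
                if r2 > 0.9:
                    hits += 1
        assert hits >= 9

    def test_duplicated_snp_columns_give_identical_records(self, small_study):
        geno = small_study["geno"]
        dup_dos = pd.concat([geno.dosages, geno.dosages.iloc[[0]].set_axis(["dup0"])])
        dup_map = pd.concat([geno.snp_map, geno.snp_map.iloc[[0]].set_axis(["dup0"])])
        dup = GenotypeMatrix(dup_dos, dup_map)
        pairs = enumerate_cis_pairs(small_study["probe_map"], dup.snp_map)
        rec = map_cis_eqtls(small_study["expr"], dup, pairs)
        orig_id = geno.snp_map.index[0]
        a = rec[rec["snp_id"] == orig_id].set_index("probe_id")
        b = rec[rec["snp_id"] == "dup0"].set_index("probe_id")
        assert len(b) and (a["rho"] - b["rho"]).abs().max() < 1e-12
        assert (a["p"] - b["p"]).abs().max() < 1e-12

    def test_scan_of_permuted_matrix_equals_permuted_scan(self, small_study):
        scanner = CisScanner(small_study["expr"], small_study["geno"],
                             small_study["pairs"])
        rng = np.random.default_rng(5)
        perm = rng.permutation(scanner.n)
        rho_perm, _ = scanner.scan(perm)
        permuted_expr = small_study["expr"].with_values(
            small_study["expr"].intensities.to_numpy()[:, perm]
        )
        scanner2 = CisScanner(permuted_expr, small_study["geno"], small_study["pairs"])
        rho_direct, _ = scanner2.scan()
        np.testing.assert_allclose(rho_perm, rho_direct, atol=1e-12)


class TestPermutationFdr:
    def test_deterministic_given_seed(self, small_study):
        kw = dict(n_perm=20, level=0.05, seed=42)
        a = permutation_fdr(small_study["expr"], small_study["geno"],
                            small_study["pairs"], **kw)
        b = permutation_fdr(small_study["expr"], small_study["geno"],
                            small_study["pairs"], **kw)
        assert a.p_threshold == b.p_threshold
        assert a.perm_seeds == b.perm_seeds
        pd.testing.assert_series_equal(a.significant, b.significant)

    def test_overwhelming_effect_always_flagged(self):
        study = build_study(seed=55, n_samples=100, n_snps=200, n_probes=20,
                            n_effects=1, beta=5.0, noise_sd=0.1)
        fdr = permutation_fdr(study["expr"], study["geno"], study["pairs"],
                              n_perm=30, seed=1)
        eff = study["spec"].planted_effects[0]
        assert bool(fdr.significant[eff.probe_id])
        assert fdr.p_threshold >= fdr.unit_pvalues[eff.probe_id]

    def test_threshold_monotone_in_level(self, small_study):
        t = {}
        for level in (0.01, 0.05):
            t[level] = permutation_fdr(
                small_study["expr"], small_study["geno"], small_study["pairs"],
                n_perm=20, level=level, seed=9,
            ).p_threshold
        assert t[0.01] <= t[0.05]

    def test_pure_null_calibration(self):
        # with no planted effects, mean false probes <= level * n_probes
        # within binomial error
        declared = []
        for seed in range(5):
            study = build_study(seed=500 + seed, n_samples=100, n_snps=300,
                                n_probes=50, n_effects=0)
            fdr = permutation_fdr(study["expr"], study["geno"], study["pairs"],
                                  n_perm=50, level=0.05, seed=seed)
            declared.append(fdr.observed_count)
        mean_declared = np.mean(declared)
        bound = 0.05 * 50
        assert mean_declared <= bound + 2 * np.sqrt(bound * 5) / 5 + 1

    def test_pair_unit_supported(self, small_study):
        fdr = permutation_fdr(small_study["expr"], small_study["geno"],
                              small_study["pairs"], n_perm=15, unit="pair", seed=3)
        assert isinstance(fdr.unit_pvalues.index, pd.MultiIndex)
        planted = {(e.probe_id, e.snp_id) for e in small_study["spec"].planted_effects}
        flagged = set(fdr.significant.index[fdr.significant])
        assert len(planted & flagged) >= len(planted) // 2


class TestReplication:
    @staticmethod
    def _two_cohorts(seed=31, beta=2.0):
        # one generating process, two expression draws over the same genotypes
        spec = SimulationSpec(
            n_samples=200, n_snps=400, n_probes=40, seed=seed,
            tissues=(("discovery", 200), ("replication", 200)),
        )
        geno = simulate_genotypes(spec)
        pm = place_probes(spec, geno)
        from linc_eqtl import plant_cis_effects, quantile_normalize

        spec.planted_effects = plant_cis_effects(geno, pm, 8, beta, seed=seed)
        disc, _ = simulate_expression(geno, spec, tissue="discovery")
        rep, _ = simulate_expression(geno, spec, tissue="replication")
        pairs = enumerate_cis_pairs(pm, geno.snp_map)
        return spec, geno, quantile_normalize(disc), quantile_normalize(rep), pairs

    def test_strong_effects_replicate_with_full_concordance(self):
        spec, geno, disc, rep, pairs = self._two_cohorts()
        fdr = permutation_fdr(disc, geno, pairs, n_perm=30, seed=1)
        assert fdr.observed_count > 0
        res = replicate(fdr, rep, geno, n_perm=30, seed=2)
        # every planted (true) discovery replicates; a stray false
        # discovery may not, so the overall fraction can fall below 1
        planted = {e.probe_id for e in spec.planted_effects}
        rep_units = set(res.table.loc[res.table["replicated"], "unit"])
        assert planted & set(res.table["unit"]) <= rep_units
        assert res.fraction >= 0.8
        conc = res.table.loc[res.table["replicated"], "concordant"]
        assert conc.all() and len(conc) == res.n_replicated

    def test_flipped_allele_encoding_harmonized(self):
        spec, geno, disc, rep, pairs = self._two_cohorts(seed=32)
        fdr = permutation_fdr(disc, geno, pairs, n_perm=30, seed=1)
        snp = fdr.records.loc[fdr.records["p"].idxmin(), "snp_id"]
        flipped_dos = geno.dosages.copy()
        flipped_dos.loc[snp] = 2 - flipped_dos.loc[snp]
        flipped_map = geno.snp_map.copy()
        flipped_map.loc[snp, ["ref", "alt"]] = geno.snp_map.loc[snp, ["alt", "ref"]].to_numpy()
        flipped = GenotypeMatrix(flipped_dos, flipped_map)

        harmonized, flipped_ids = harmonize_alleles(flipped, geno.snp_map)
        assert flipped_ids == [snp]
        pd.testing.assert_frame_equal(
            harmonized.dosages.astype(float), geno.dosages.astype(float)
        )

        res_orig = replicate(fdr, rep, geno, n_perm=30, seed=2)
        res_flip = replicate(fdr, rep, flipped, discovery_snp_map=geno.snp_map,
                             n_perm=30, seed=2)
        assert res_orig.fraction == res_flip.fraction
        pd.testing.assert_frame_equal(res_orig.table, res_flip.table)

    def test_null_replication_fraction_near_level(self):
        spec, geno, disc, rep, pairs = self._two_cohorts(seed=33, beta=2.0)
        fdr = permutation_fdr(disc, geno, pairs, n_perm=30, seed=1)
        # null replication cohort: independent expression with no effects
        null_spec = SimulationSpec(
            n_samples=200, n_snps=400, n_probes=40, seed=999,
            tissues=(("discovery", 200),),
        )
        null_geno = simulate_genotypes(null_spec)
        null_expr, _ = simulate_expression(null_geno, null_spec)
        from linc_eqtl import quantile_normalize

        # reuse the discovery genotypes so SNP/sample ids line up
        null_expr = null_expr.with_values(null_expr.intensities.to_numpy())
        null_expr.intensities.columns = geno.sample_ids
        res = replicate(fdr, quantile_normalize(null_expr), geno, n_perm=30, seed=4)
        assert res.fraction <= 0.25


class TestTopAndSpecificity:
    def _records(self, rows):
        return pd.DataFrame(
            rows,
            columns=["probe_id", "snp_id", "chrom", "pos", "distance",
                     "n_used", "rho", "p", "z", "tissue"],
        )

    def test_single_record_is_its_own_top(self):
        rec = self._records([("p1", "s1", "chr1", 10, 0, 100, 0.5, 1e-4, 3.9, "blood")])
        assert top_eqtl_per_probe(rec).iloc[0]["snp_id"] == "s1"

    def test_tie_broken_by_absolute_rho_then_position(self):
        rec = self._records([
            ("p1", "s1", "chr1", 10, 0, 100, 0.4, 1e-4, 3.9, "blood"),
            ("p1", "s2", "chr1", 20, 0, 100, -0.5, 1e-4, -3.9, "blood"),
            ("p1", "s3", "chr1", 5, 0, 100, -0.5, 1e-4, -3.9, "blood"),
        ])
        assert top_eqtl_per_probe(rec).iloc[0]["snp_id"] == "s3"

    def test_agreement_with_sort_oracle(self, small_study):
        rec = map_cis_eqtls(small_study["expr"], small_study["geno"],
                            small_study["pairs"])
        top = top_eqtl_per_probe(rec).set_index("probe_id")
        for probe, grp in rec.groupby("probe_id"):
            oracle = min(
                grp.itertuples(index=False),
                key=lambda r: (r.p, -abs(r.rho), r.pos),
            )
            assert top.loc[probe, "snp_id"] == oracle.snp_id

    def test_independent_coding_expression_gives_full_specificity(self):
        linc = self._records([
            ("L1", "s1", "chr1", 10, 0, 100, 0.5, 1e-6, 4.9, "blood"),
            ("L2", "s2", "chr1", 20, 0, 100, 0.6, 1e-7, 5.2, "blood"),
        ])
        coding = self._records([
            ("C1", "s1", "chr1", 10, 0, 100, 0.01, 0.9, 0.1, "blood"),
        ])
        table = specificity_analysis(linc, coding, p_threshold=1e-3)
        assert (~table["shared"]).all()

    def test_shared_opposite_direction_detected(self):
        linc = self._records([("L1", "s1", "chr1", 10, 0, 100, 0.5, 1e-6, 4.9, "blood")])
        coding = self._records([("C1", "s1", "chr1", 10, 0, 100, -0.4, 1e-5, -4.4, "blood")])
        table = specificity_analysis(linc, coding, p_threshold=1e-3)
        row = table.iloc[0]
        assert row["shared"] and row["direction"] == "opposite"
        assert row["strongest_for_coding"]

    def test_planted_shared_vs_specific_proportions_recovered(self):
        # 6 shared + 14 lincRNA-specific planted effects
        spec = SimulationSpec(n_samples=250, n_snps=600, n_probes=80, seed=71,
                              noise_sd=0.5)
        geno = simulate_genotypes(spec)
        pm = place_probes(spec, geno)
        from linc_eqtl import plant_cis_effects, quantile_normalize

        linc_eff = plant_cis_effects(geno, pm, 20, beta=1.5, seed=71,
                                     probe_class="lincRNA")
        effects = list(linc_eff)
        coding_probes = pm[pm["transcript_class"] == "protein_coding"]
        pos0 = geno.snp_map["pos"] - 1
        shared_planted = 0
        for eff in linc_eff:
            if shared_planted == 6:
                break
            near = coding_probes[
                (pos0.loc[eff.snp_id] - coding_probes["center"]).abs() <= 250_000
            ]
            near = near[~near.index.isin([e.probe_id for e in effects])]
            if near.empty:
                continue
            effects.append(EffectSpec(near.index[0], eff.snp_id, -1.5))
            shared_planted += 1
        assert shared_planted >= 4
        spec.planted_effects = effects
        expr, _ = simulate_expression(geno, spec)
        expr = quantile_normalize(expr)
        pairs = enumerate_cis_pairs(pm, geno.snp_map)
        rec = map_cis_eqtls(expr, geno, pairs)
        linc_probes = set(pm.index[pm["transcript_class"] == "lincRNA"])
        linc_rec = rec[rec["probe_id"].isin(linc_probes)]
        coding_rec = rec[~rec["probe_id"].isin(linc_probes)]
        table = specificity_analysis(linc_rec, coding_rec, p_threshold=1e-5)
        planted_linc = {e.probe_id for e in linc_eff}
        got = table[table["probe_id"].isin(planted_linc)]
        shared_snps = {e.snp_id for e in effects[len(linc_eff):]}
        expected_shared = got["snp_id"].isin(shared_snps)
        # shared flags should largely agree with the planted assignment
        agreement = (got["shared"] == expected_shared).mean()
        assert agreement >= 0.8
        opp = got.loc[got["shared"] & expected_shared, "direction"]
        if len(opp):
            assert (opp == "opposite").mean() >= 0.8


class TestTissueComparison:
    def test_planted_tissue_restriction_classified(self):
        spec = SimulationSpec(
            n_samples=240, n_snps=400, n_probes=40, seed=81, noise_sd=0.5,
            tissues=(("blood", 240), ("SAT", 120), ("liver", 120)),
        )
        geno = simulate_genotypes(spec)
        pm = place_probes(spec, geno)
        from linc_eqtl import plant_cis_effects, quantile_normalize

        all_eff = plant_cis_effects(geno, pm, 2, beta=2.5, seed=81)
        sat_eff = [
            EffectSpec(e.probe_id, e.snp_id, 2.5, frozenset({"SAT"}))
            for e in plant_cis_effects(geno, pm.drop([e.probe_id for e in all_eff]),
                                       2, beta=2.5, seed=82)
        ]
        spec.planted_effects = all_eff + sat_eff
        results = {}
        for i, t in enumerate(spec.tissue_names):
            expr, _ = simulate_expression(geno, spec, tissue=t)
            pairs = enumerate_cis_pairs(pm, geno.snp_map)
            results[t] = permutation_fdr(quantile_normalize(expr), geno, pairs,
                                         n_perm=20, seed=i, tissue=t,
                                         min_samples=30)
        table = compare_tissues(results).set_index("unit")
        for e in sat_eff:
            if e.probe_id in table.index:
                assert table.loc[e.probe_id, "tissues"] == "SAT"
                assert table.loc[e.probe_id, "specificity_class"] == "single-tissue-specific"
        assert any(e.probe_id in table.index for e in sat_eff)
        for e in all_eff:
            assert table.loc[e.probe_id, "specificity_class"] == "all-tissue"

    def test_empty_significant_sets_give_empty_table(self, null_study):
        fdr = permutation_fdr(null_study["expr"], null_study["geno"],
                              null_study["pairs"], n_perm=15, seed=1)
        other = permutation_fdr(null_study["expr"], null_study["geno"],
                                null_study["pairs"], n_perm=15, seed=2, tissue="SAT")
        if fdr.observed_count == 0 and other.observed_count == 0:
            table = compare_tissues({"blood": fdr, "SAT": other})
            assert table.empty
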
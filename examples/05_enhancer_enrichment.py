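"""Test whether top eQTL SNPs are enriched in an enhancer track.

The observed fold enrichment (fraction of top-SNP sets, each expanded by
perfect proxies, hitting the track, over the background SNP in-track
fraction) is compared against permutations of the expression sample
labels: a normal distribution fitted to the log permuted folds yields the
one-sided P.  A track built around the planted causal SNPs should come out
strongly enriched; a random track should not.
"""

from linc_eqtl import (
    AnnotationTrack, SimulationSpec, enumerate_cis_pairs, plant_cis_effects,
    quantile_normalize, simulate_expression, simulate_genotypes,
)
from linc_eqtl.enrichment import permutation_enrichment_significance
from linc_eqtl.synthio import make_enhancer_tracks, place_probes

spec = SimulationSpec(n_samples=150, n_snps=500, n_probes=50, noise_sd=0.5, seed=7)
geno = simulate_genotypes(spec)
pm = place_probes(spec, geno)
spec.planted_effects = plant_cis_effects(geno, pm, 15, beta=1.5, seed=7)
expr, truth = simulate_expression(geno, spec)
expr = quantile_normalize(expr)
pairs = enumerate_cis_pairs(pm, geno.snp_map)

tracks = make_enhancer_tracks(spec, geno, causal_snps=list(truth["snp_id"]))
for name in ("causal", "K562"):
    track = AnnotationTrack(name, name, tracks[name])
    res = permutation_enrichment_significance(
        expr, geno, pairs, track, n_top=15, n_perm=100, seed=9)
    print(f"{name:8s} fold={res.observed_fold:6.2f}  "
          f"hits={res.n_query_in_track}/{res.n_query}  "
          f"background={res.background_fraction:.3f}  "
          f"p={res.p_one_sided:.2e}" if res.p_one_sided is not None else
          f"{name:8s} fold={res.observed_fold:6.2f} (p not estimable)")
print("\nThe causal track contains every planted SNP, so its fold is far")
print("above the permutation null; the random K562-style track is not")
print("distinguishable from the null.")
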
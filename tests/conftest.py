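import numpy as np
import pytest

from linc_eqtl import (
    SimulationSpec,
    enumerate_cis_pairs,
    plant_cis_effects,
    quantile_normalize,
    simulate_expression,
    simulate_genotypes,
)
from linc_eqtl.synthio import place_probes


def build_study(
    seed,
    n_samples=200,
    n_snps=2000,
    n_probes=200,
    n_effects=50,
    beta=0.8,
    noise_sd=1.0,
    ld_block_size=10,
    window=250_000,
    probe_class=None,
    normalize=True,
    **spec_kwargs,
):
    """One simulated cohort with planted cis effects, ready for the scan.

    Returns a dict with spec, geno, probe_map, expr (quantile-normalized),
    truth and the enumerated cis pairs.
    """
    spec = SimulationSpec(
        n_samples=n_samples,
        n_snps=n_snps,
        n_probes=n_probes,
        noise_sd=noise_sd,
        ld_block_size=ld_block_size,
        seed=seed,
        **spec_kwargs,
    )
    geno = simulate_genotypes(spec)
    probe_map = place_probes(spec, geno)
    if n_effects:
        spec.planted_effects = plant_cis_effects(
            geno, probe_map, n_effects, beta, seed=seed, window=window,
            probe_class=probe_class,
        )
    expr, truth = simulate_expression(geno, spec)
    if normalize:
        expr = quantile_normalize(expr)
    pairs = enumerate_cis_pairs(probe_map, geno.snp_map, window)
    return {
        "spec": spec, "geno": geno, "probe_map": probe_map,
        "expr": expr, "truth": truth, "pairs": pairs,
    }


@pytest.fixture(scope="session")
def small_study():
    """Modest cohort with strong planted effects, shared across tests."""
    return build_study(
        seed=7, n_samples=150, n_snps=600, n_probes=60, n_effects=10, beta=1.0
    )


@pytest.fixture(scope="session")
def null_study():
    """Cohort with no planted effects (pure-null expression)."""
    return build_study(seed=13, n_samples=120, n_snps=400, n_probes=40, n_effects=0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
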
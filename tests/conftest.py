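import numpy as np
import pytest

from transmap import (
    AssocResult,
    CausalModel,
    PipelineConfig,
    derive_population_pool,
    sim_ancestral_pool,
    simulate_study,
)
from transmap.fixedmeta import FixedMetaResult
from transmap.transmeta import BayesMetaResult


@pytest.fixture(scope="session")
def ancestral_pool():
    return sim_ancestral_pool(
        n_variants=60, region_length=100_000, n_haplotypes=1000, seed=1
    )


@pytest.fixture(scope="session")
def population_pools(ancestral_pool):
    params = [("EAsia", 0.05, 1e-4), ("Eur", 0.10, 2e-4), ("Afr", 0.15, 4e-4)]
    return [
        derive_population_pool(ancestral_pool, anc, f, sw, 1000, seed=10 + k)
        for k, (anc, f, sw) in enumerate(params)
    ]


@pytest.fixture(scope="session")
def small_study(population_pools):
    """One modest study with a single planted effect (OR 1.3)."""
    pool = population_pools[0]
    j = int(np.argmin(np.abs(pool.frequencies - 0.5)))
    causal = CausalModel((pool.variant_ids[j],), np.array([np.log(1.3)]), alpha=-1.0)
    study = simulate_study(pool, causal, 1500, 1500, n_covariates=2, seed=42)
    return study, causal


def make_assoc(snpid="v", pos=1, beta=0.1, se=0.1, eaf=0.3, n=1000, **kw):
    return AssocResult(
        snpid=snpid, pos=pos, beta=beta, se=se, p=0.5, eaf=eaf, n=n, **kw
    )


def make_bayes_result(snpid, pos, log10_bf, p=1e-10, shadow=False):
    fixed = FixedMetaResult(
        snpid=snpid, beta=0.2, se=0.03, z=6.7, p=p, or_=1.22,
        ci_low=1.15, ci_high=1.3, q=0.0, q_df=1, q_p=1.0, n_studies=2,
    )
    return BayesMetaResult(
        snpid=snpid, pos=pos, log10_bf=log10_bf, log10_bf_het=0.0,
        partition_weights=(1.0,), fixed=fixed, shadow=shadow,
    )


@pytest.fixture(scope="session")
def demo_config():
    return PipelineConfig(seed=7)
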
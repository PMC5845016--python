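import numpy as np
import pytest

from uvphos import (
    CoverageSimConfig,
    SimConfig,
    call_dependency,
    call_uv_regulation,
    compute_prr,
    differential_prr,
    simulate_phospho_experiment,
    simulate_polii_coverage,
)

# 6-feature x 3-replicate log2-ratio matrix with heterogeneous variances;
# frozen so the empirical-Bayes hyperparameter fit is reproducible.
EBAYES_FIXTURE = np.array(
    [
        [0.03047170797544314, -0.10399841062404956, 0.07504511958064573],
        [1.188112943278243, 0.6097929622692326, 0.7395640986275364],
        [-0.44886383873308583, -0.6264970369374329, -0.5067204630017155],
        [1.3175648579411359, 2.703518379890263, 2.622233548343159],
        [0.20990460463418242, 0.36908618104520496, 0.27012640133780685],
        [-0.25778773886497147, 0.11062523522474965, -0.2876647802486997],
    ]
)

# Reference values for EBAYES_FIXTURE computed independently with
# limma::eBayes (lmFit against an intercept-only design, limma 3.58.1).
LIMMA_REFERENCE = {
    "d0": 2.06961342981,
    "s02": 0.0335948564203,
    "t": np.array(
        [0.00599912900429, 5.86764140576, -6.28545301175, 6.84063811615,
         3.44424386525, -1.23579576572]
    ),
    "p": np.array(
        [0.995496007215, 0.00399077209248, 0.00308763340243, 0.00224326578977,
         0.0254837445649, 0.283075823726]
    ),
}


@pytest.fixture(scope="session")
def null_matrix():
    """Canonical null simulation for type-I calibration: 10^4 features,
    2 replicates, sigma 0.35, no planted effects.

    Calibration at two replicates is checked on one fixed draw because
    the p-value calls share the estimated hyperparameters (d0, s02):
    that common estimation noise makes the rejection fraction slightly
    over-dispersed relative to a pure binomial across repeated draws.
    """
    rng = np.random.default_rng(10)
    return rng.normal(0, 0.35, size=(10_000, 2))


@pytest.fixture(scope="session")
def phospho_sim():
    """Full-scale phospho simulation at the reference site count."""
    cfg = SimConfig(seed=1)
    table, truth = simulate_phospho_experiment(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def phospho_calls(phospho_sim):
    cfg, table, truth = phospho_sim
    calls = call_uv_regulation(table)
    calls = call_dependency(table, calls, "p38i+UV/mock")
    calls = call_dependency(
        table, calls, "MKi+UV/mock", among="dependency", column="mk_dependency"
    )
    return calls


@pytest.fixture(scope="session")
def coverage_sim():
    """Pol II coverage simulation with planted release on 30% of genes."""
    cfg = CoverageSimConfig(seed=2, n_genes=500)
    genes, tracks, truth = simulate_polii_coverage(cfg)
    return cfg, genes, tracks, truth


@pytest.fixture(scope="session")
def prr_results(coverage_sim):
    cfg, genes, tracks, truth = coverage_sim
    table = compute_prr(tracks, genes, baseline_condition="mock")
    table, global_test = differential_prr(table, "mock", "UV")
    return table, global_test, truth
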
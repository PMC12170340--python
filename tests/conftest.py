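"""Shared fixtures: small synthetic cohorts reused across test modules."""

import dataclasses

import pytest

from polkinetics import AnalysisParams, SimConfig, run_cohort_pipeline, simulate_cohort
from polkinetics.synth import simulate_truth


@pytest.fixture(scope="session")
def unit_cohort():
    """Noiseless unit-calibrated cohort: every estimator should be exact."""
    return simulate_cohort(SimConfig(n_genes=80, noise="none", seed=17))


@pytest.fixture(scope="session")
def unit_params():
    # shallow unit-depth signals: the antisense estimator needs a low
    # coverage threshold; fewer bootstrap rounds keep the suite fast
    return AnalysisParams(antisense_min_coverage=0.0, kmeans_boot=30)


@pytest.fixture(scope="session")
def unit_results(unit_cohort, unit_params):
    return run_cohort_pipeline(unit_cohort, unit_params)


def make_noisy_cohort(n_genes: int = 500, seed: int = 23):
    """Poisson-noise cohort at sequencing depths giving expected
    promoter-proximal ChIP-nexus window counts of at least 200."""
    base = SimConfig(n_genes=n_genes, seed=seed, noise="poisson",
                     tt_depth=10.0, mnet_depth=20.0)
    truth = simulate_truth(base)
    p0_min = min(truth.df[f"p0_{t}"].min() for t in base.nexus_time_points_h)
    cfg = dataclasses.replace(base, nexus_depth=max(100.0, 200.0 / p0_min))
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_cohort():
    return make_noisy_cohort()


@pytest.fixture(scope="session")
def noisy_results(noisy_cohort):
    return run_cohort_pipeline(
        noisy_cohort, AnalysisParams(antisense_min_coverage=0.0, seed=0)
    )
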
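import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import methdriver as md

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: seed of the reference synthetic cohort shared across the suite
COHORT_SEED = 11


@pytest.fixture(scope="session")
def default_sim():
    """The reference planted cohort at generator defaults."""
    return md.simulate_cohort(md.SimConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def default_run(default_sim):
    """Full two-layer pipeline run on the reference cohort (shared:
    several end-to-end checks read different aspects of the same run)."""
    sim = default_sim
    return md.run_full(sim.expression, sim.methylation, sim.sample_sheet,
                       sim.manifest, sim.signatures,
                       md.PrimaryConfig(seed=COHORT_SEED),
                       md.GmaConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def small_cfg():
    """A reduced cohort configuration for fast unit-level runs."""
    return md.SimConfig(n_tumor=14, n_normal=10, n_null_genes=30,
                        n_hypo_ocg=3, n_hyper_tsg=3, n_targets_per_process=6,
                        n_decoy_signature=6, seed=5)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    return md.simulate_cohort(small_cfg)


@pytest.fixture()
def tiny_cohort():
    """A hand-sized aligned cohort for io/dea-level tests."""
    rng = np.random.default_rng(0)
    samples = [f"N{i}" for i in range(10)] + [f"T{i}" for i in range(10)]
    expr = pd.DataFrame(rng.normal(8, 1, size=(5, 20)),
                        index=[f"G{i}" for i in range(5)], columns=samples)
    sheet = pd.DataFrame({"sample_id": samples,
                          "group": ["normal"] * 10 + ["tumor"] * 10})
    cohort = md.AlignedCohort(samples=tuple(sorted(samples)),
                              tumor=tuple(sorted(samples[10:])),
                              normal=tuple(sorted(samples[:10])))
    return expr, sheet, cohort
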
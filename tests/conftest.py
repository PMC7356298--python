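import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def destrieux():
    from iscn.atlas import destrieux_registry

    return destrieux_registry()


@pytest.fixture(scope="session")
def worked_fixture():
    from iscn.simulate import make_worked_fixture

    return make_worked_fixture()


def _global_comparison_replicate(seed: int, deviation: float, affected):
    """One full simulate -> build -> metrics -> ANCOVA+FDR replicate.

    Returns (n_significant_indices, group mean table, affected region ids,
    fdr-significant region names).
    """
    import pandas as pd

    from iscn.metrics import metrics_tables
    from iscn.network import build_cohort_scns
    from iscn.simulate import GROUP_A, GROUP_B, GROUP_CONTROL, SimulationConfig, simulate_cohort
    from iscn.stats import compare_global, compare_nodal

    cfg = SimulationConfig(
        deviation_sd={GROUP_A: deviation, GROUP_B: deviation, GROUP_CONTROL: 0.0},
        affected_regions={GROUP_A: affected, GROUP_B: affected, GROUP_CONTROL: []},
        score_effect=0.0,
        seed=seed,
    )
    sim = simulate_cohort(cfg)
    cohort = sim.cohort
    matrices, _ = build_cohort_scns(cohort)
    global_df, nodal_df = metrics_tables(matrices)
    covariate = cohort.covariate_vector("premorbid_iq")
    results = compare_global(global_df, cohort.groups, covariate)
    n_sig = sum(r.p_fdr < 0.05 for r in results)
    means = global_df.groupby(pd.Index(cohort.groups, name="group")).mean()
    nodal_results, _ = compare_nodal(nodal_df, cohort.groups, covariate)
    sig_regions = {
        r.index_name for r in nodal_results if r.p_fdr is not None and r.p_fdr < 0.05
    }
    affected = {
        g: sim.ground_truth.affected_regions[g] for g in (GROUP_A, GROUP_B)
    }
    return n_sig, means, affected, sig_regions


@pytest.fixture(scope="session")
def replicate_runner():
    return _global_comparison_replicate


@pytest.fixture(scope="session")
def null_replicates(replicate_runner):
    """Null-cohort replicates (no planted effect) shared across calibration tests."""
    return [replicate_runner(30_000 + i, 0.0, [])[0] for i in range(500)]
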
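"""Shared fixtures: small study configurations and Monte-Carlo pools.

The expensive Monte-Carlo pools (null-calibration p-values, edge-recovery
replicates, null bootstrap-ratio pool) are session-scoped so the unit tests
and the acceptance checks draw on the same computations.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import statecoh as sc
from statecoh.recovery import edge_recovery

settings.register_profile(
    "ci",
    max_examples=25,
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def spec60():
    return sc.SpectralConfig(analysis_duration=60.0)


@pytest.fixture(scope="session")
def spec30():
    return sc.SpectralConfig(analysis_duration=30.0)


def make_null_features(rng, n_cond=4, n_subj=8, n_feat=50):
    """Feature matrix with iid Gaussian features (label-free null)."""
    return sc.FeatureMatrix(
        rng.standard_normal((n_cond * n_subj, n_feat)),
        np.repeat([f"c{k}" for k in range(n_cond)], n_subj),
        np.tile([f"s{i}" for i in range(n_subj)], n_cond),
    )


@pytest.fixture(scope="session")
def null_pipeline_pvalues(spec30):
    """LV1 permutation p-values from 120 null synthetic datasets.

    Small study conditions (4 subjects, 6 nodes, 30-s blocks, 256
    permutations) keep the replication affordable while exercising the full
    generator -> coherence -> PLS chain.
    """
    ps = []
    for seed in range(120):
        cfg = sc.null_config(seed=seed, n_subjects=4, n_nodes=6, block_duration=30.0)
        ds, _ = sc.generate_dataset(cfg)
        coh, _ = sc.build_tensors(ds, spec30)
        res = sc.run_pls(coh, n_perm=256, n_boot=0, seed=10_000 + seed)
        ps.append(res.perm_p[0])
    return np.array(ps)


@pytest.fixture(scope="session")
def edge_recovery_runs():
    """20 replicates of the strong-coupling beta-edge recovery experiment."""
    return [edge_recovery(sc.strong_edge_config(seed=s), seed=s) for s in range(20)]


@pytest.fixture(scope="session")
def bsr_null_pool():
    """Pooled bootstrap ratios from pure-noise designs (16 subjects).

    16 subjects give the bootstrap SD estimate enough effective degrees of
    freedom for the standard-normal approximation to apply (at 8 subjects
    the pooled sd inflates to ~1.24; see the methods note).
    """
    rng = np.random.default_rng(2024)
    pool = []
    for rep in range(6):
        X = make_null_features(rng, n_cond=4, n_subj=16, n_feat=300)
        pool.append(sc.bootstrap_bsr(X, n_boot=512, seed=rep).ravel())
    return np.concatenate(pool)


@pytest.fixture(scope="session")
def task_coherence_run(spec60):
    """One strong task-coupling dataset analysed end to end (coherence track)."""
    cfg = sc.coupling_task_config(seed=3)
    ds, truth = sc.generate_dataset(cfg)
    coh, power = sc.build_tensors(ds, spec60)
    res = sc.run_pls(coh, n_perm=512, n_boot=512, seed=11)
    return {"config": cfg, "truth": truth, "coh": coh, "power": power, "res": res}
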
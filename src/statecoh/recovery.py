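"""Recovery experiments: score the pipeline against the generator's ground truth.

These routines run the full analysis chain on synthetic data with known
injected effects and measure how well the effects are recovered — the
package's substitute for group-level results on real (undeposited) recordings.
"""

from __future__ import annotations

import numpy as np

from .network import band_range, build_band_network, bsr_threshold
from .pls import run_pls
from .simulate import (
    SimulationConfig,
    gamma_power_config,
    generate_dataset,
    strong_edge_config,
)
from .spectral import SpectralConfig, build_tensors, enumerate_pairs

__all__ = [
    "percent_power_change",
    "power_increase_recovery",
    "edge_recovery",
]


def _task_rest(config: SimulationConfig) -> tuple[list, list]:
    task = [b for b in config.block_labels if config.is_task_block(b)]
    rest = [b for b in config.block_labels if not config.is_task_block(b)]
    if not task or not rest:
        raise ValueError("config must define both task and rest blocks")
    return task, rest


def percent_power_change(power, task_blocks, rest_blocks) -> np.ndarray:
    """Percent task-vs-rest power change per (freq, node).

    Group means (over subjects and blocks of each state) are formed first,
    then the percent change ``100 * (task - rest) / rest``.
    """
    p_task = power.sel(block=list(task_blocks)).mean(["block", "subject"]).values
    p_rest = power.sel(block=list(rest_blocks)).mean(["block", "subject"]).values
    return 100.0 * (p_task - p_rest) / p_rest


def power_increase_recovery(
    config: SimulationConfig | None = None,
    band: str = "gamma",
    percentile: float = 99.0,
    n_boot: int = 512,
    seed: int = 0,
) -> dict:
    """Re-estimate an injected task-state power increase from one synthetic run.

    Runs the power track (tensor -> mean-centered PLS -> BSR -> percentile
    threshold), orients LV1 so task blocks load positive, and averages the
    percent task-vs-rest power change over positive supra-threshold
    (node, bin) combinations in ``band``.

    Returns a dict with ``pct`` (the mean percent change), ``n_supra`` and
    the LV1 permutation p-value slot left None (permutation is not needed
    here; see :func:`statecoh.pls.run_pls` for the significance track).
    """
    if config is None:
        config = gamma_power_config(seed=seed)
    dataset, _truth = generate_dataset(config)
    spec = SpectralConfig(
        fs=config.fs, analysis_duration=min(config.block_duration, 360.0)
    )
    _, power = build_tensors(dataset, spec)
    task, rest = _task_rest(config)
    res = run_pls(power, n_perm=0, n_boot=n_boot, seed=seed).oriented(task)
    bsr = res.bsr_map(0)
    threshold = bsr_threshold(bsr, percentile)
    lo, hi = band_range(band)
    in_band = (res.freqs >= lo) & (res.freqs <= hi)
    supra = (bsr >= threshold) & in_band[:, None]
    pct_map = percent_power_change(power, task, rest)
    return {
        "pct": float(pct_map[supra].mean()) if supra.any() else float("nan"),
        "n_supra": int(supra.sum()),
        "threshold": threshold,
    }


def edge_recovery(
    config: SimulationConfig | None = None,
    band: str = "beta",
    percentile: float = 99.9,
    n_boot: int = 512,
    seed: int = 0,
) -> dict:
    """Sensitivity and false-discovery proportion of the task-positive network.

    Runs the coherence track on a synthetic dataset with injected edges and
    compares the recovered positive ``band`` network with the ground truth.
    """
    if config is None:
        config = strong_edge_config(seed=seed)
    dataset, truth = generate_dataset(config)
    spec = SpectralConfig(
        fs=config.fs, analysis_duration=min(config.block_duration, 360.0)
    )
    coh, _ = build_tensors(dataset, spec)
    task, _rest = _task_rest(config)
    res = run_pls(coh, n_perm=0, n_boot=n_boot, seed=seed).oriented(task)
    net = build_band_network(
        res.bsr_map(0), res.freqs, enumerate_pairs(config.n_nodes), percentile
    )
    detected = net.edge_set("+", band)
    true_edges = truth.edge_set(band)
    tp = len(detected & true_edges)
    return {
        "sensitivity": tp / len(true_edges) if true_edges else float("nan"),
        "fdp": (len(detected) - tp) / len(detected) if detected else 0.0,
        "n_detected": len(detected),
    }
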
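"""End-to-end orchestration: simulate -> spectra -> PLS -> networks -> report.

A run is driven by a flat key=value config file whose defaults mirror the
analysis parameters of the emulated study (512 permutations, 512 bootstrap
iterations, 99.9th percentile BSR threshold for coherence, 99th for power,
minimum tabulated degree 3).  Both analysis tracks always run together: a
coherence change is only interpretable alongside any concomitant power
change, so the report juxtaposes them per band.

Provenance: the canonical config text is hashed and the hash is embedded in
every artifact; a resumed run refuses to mix artifacts from a different
configuration, and re-running with the same config and seed reproduces the
report byte-for-byte (no timestamps in the report body; wall times go to the
log only).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .atlas import NodeAtlas, default_atlas, load_atlas
from .dataset import VirtualElectrodeDataset
from .io import load_pls_result, load_tensor, save_pls_result, save_tensor
from .network import DEFAULT_BANDS, band_supra_counts, build_band_network
from .pls import run_pls
from .simulate import PowerEffect, SimulationConfig, TaskEdge, generate_dataset
from .spectral import SpectralConfig, build_tensors, enumerate_pairs

__all__ = ["RunConfig", "RunReport", "run_pipeline", "parse_config", "load_atlas"]

log = logging.getLogger("statecoh")


def parse_edges(text: str) -> tuple[TaskEdge, ...]:
    """Parse ``"i-j:band:coupling,..."`` into task edges."""
    edges = []
    for item in filter(None, (s.strip() for s in text.split(","))):
        nodes, band, coupling = item.split(":")
        i, j = (int(x) for x in nodes.split("-"))
        edges.append(TaskEdge(i, j, band, float(coupling)))
    return tuple(edges)


def parse_power_effects(text: str) -> tuple[PowerEffect, ...]:
    """Parse ``"n1,n2:band:factor;..."`` into power effects."""
    effects = []
    for item in filter(None, (s.strip() for s in text.split(";"))):
        nodes, band, factor = item.split(":")
        effects.append(
            PowerEffect(tuple(int(x) for x in nodes.split(",")), band, float(factor))
        )
    return tuple(effects)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on (hashed for provenance)."""

    simulation: SimulationConfig | None = None
    dataset_path: str = ""
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    n_perm: int = 512
    n_boot: int = 512
    seed: int = 0
    ccc_percentile: float = 99.9
    power_percentile: float = 99.0
    min_degree: int = 3
    task_blocks: tuple[str, ...] | None = None
    atlas_path: str = ""

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.dataset_path == ""):
            pass  # exactly one source is preferred but a path may override
        if self.simulation is None and not self.dataset_path:
            raise ValueError("config must provide a simulation or a dataset path")
        for p in (self.ccc_percentile, self.power_percentile):
            if not 0 < p <= 100:
                raise ValueError("percentiles must be in (0, 100]")
        if self.min_degree < 1:
            raise ValueError("min_degree must be >= 1")

    def canonical(self) -> str:
        items = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                v = str(sorted(dataclasses.asdict(v).items()))
            items[f.name] = str(v)
        return "\n".join(f"{k}={items[k]}" for k in sorted(items))

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]

    def is_task_block(self, label: str) -> bool:
        if self.task_blocks is not None:
            return label in self.task_blocks
        if self.simulation is not None:
            return self.simulation.is_task_block(label)
        return label.startswith("test")


_SIM_KEYS = {
    "n_subjects": int,
    "n_nodes": int,
    "block_duration": float,
    "fs": float,
    "background_exponent": float,
    "subject_variability": float,
}
_SPEC_KEYS = {
    "n_fft": int,
    "hop": int,
    "window": str,
    "f_min": float,
    "f_max": float,
    "analysis_duration": float,
}
_RUN_KEYS = {
    "n_perm": int,
    "n_boot": int,
    "seed": int,
    "ccc_percentile": float,
    "power_percentile": float,
    "min_degree": int,
}


def parse_config(path: str | Path) -> RunConfig:
    """Read a flat ``key = value`` config file ('#' starts a comment)."""
    path = Path(path)
    raw: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key = value, got {line!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        raw[key] = value

    sim_kw, spec_kw, run_kw = {}, {}, {}
    for key, value in raw.items():
        if key in _SIM_KEYS:
            sim_kw[key] = _SIM_KEYS[key](value)
        elif key in _SPEC_KEYS:
            spec_kw[key] = _SPEC_KEYS[key](value)
        elif key in _RUN_KEYS:
            run_kw[key] = _RUN_KEYS[key](value)
        elif key == "block_labels":
            sim_kw["block_labels"] = tuple(s.strip() for s in value.split(","))
        elif key == "task_edges":
            sim_kw["task_edges"] = parse_edges(value)
        elif key == "task_power_effects":
            sim_kw["task_power_effects"] = parse_power_effects(value)
        elif key == "sim_seed":
            sim_kw["seed"] = int(value)
        elif key == "task_blocks":
            run_kw["task_blocks"] = tuple(s.strip() for s in value.split(","))
        elif key == "dataset":
            run_kw["dataset_path"] = value
        elif key == "atlas":
            run_kw["atlas_path"] = value
        elif key == "simulate":
            if value.lower() not in ("true", "false"):
                raise ValueError(f"simulate must be true/false, got {value!r}")
            if value.lower() == "false":
                sim_kw["__disabled__"] = True
        else:
            raise ValueError(f"{path}: unknown config key {key!r}")

    disabled = sim_kw.pop("__disabled__", False)
    simulation = None
    if not disabled and (sim_kw or not run_kw.get("dataset_path")):
        if "seed" not in sim_kw:
            sim_kw["seed"] = run_kw.get("seed", 0)
        simulation = SimulationConfig(**sim_kw)
    spec_kw.setdefault(
        "analysis_duration",
        simulation.block_duration if simulation is not None else 360.0,
    )
    if simulation is not None:
        spec_kw.setdefault("fs", simulation.fs)
    return RunConfig(simulation=simulation, spectral=SpectralConfig(**spec_kw), **run_kw)


@dataclass
class RunReport:
    """Summary of one pipeline run; serialises deterministically."""

    body: dict

    def to_json(self) -> str:
        return json.dumps(self.body, indent=2, sort_keys=True) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kw):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1f s", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def _track_summary(res, percentile, bands=DEFAULT_BANDS):
    from .network import bsr_threshold

    threshold = bsr_threshold(res.bsr_map(0), percentile)
    counts = band_supra_counts(res.bsr_map(0), res.freqs, threshold, bands)
    return threshold, counts


def run_pipeline(
    config: RunConfig, out_dir: str | Path, resume: bool = False
) -> RunReport:
    """Execute the full analysis chain, writing artifacts under ``out_dir``.

    With ``resume=True``, stages whose artifacts already exist for this
    exact configuration are loaded instead of recomputed; artifacts from a
    different configuration raise.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    (out / "config.txt").write_text(config.canonical() + "\n")

    n_nodes, atlas = None, None

    @_stage("dataset")
    def stage_dataset() -> VirtualElectrodeDataset:
        ds_path = out / "dataset.h5"
        hash_path = out / "dataset.hash"
        if config.simulation is not None:
            sim_hash = hashlib.sha256(
                str(sorted(dataclasses.asdict(config.simulation).items())).encode()
            ).hexdigest()[:16]
            if resume and ds_path.exists():
                found = hash_path.read_text().strip() if hash_path.exists() else None
                if found != sim_hash:
                    raise ValueError(
                        f"{ds_path}: dataset was simulated under a different "
                        "configuration; refusing to mix artifacts"
                    )
                return VirtualElectrodeDataset.load(ds_path)
            dataset, truth = generate_dataset(config.simulation)
            dataset.save(ds_path)
            hash_path.write_text(sim_hash + "\n")
            truth.save(out)
            return dataset
        return VirtualElectrodeDataset.load(config.dataset_path)

    dataset = stage_dataset()
    n_nodes = dataset.n_nodes
    if config.atlas_path:
        atlas = load_atlas(config.atlas_path)
    elif n_nodes <= 80:
        atlas = default_atlas().head(n_nodes)
    if atlas is not None:
        atlas.save(out / "nodes.tsv")

    @_stage("spectra")
    def stage_spectra():
        paths = out / "coherence.h5", out / "power.h5"
        if resume and all(p.exists() for p in paths):
            return tuple(load_tensor(p, expect_hash=chash) for p in paths)
        coh, pw = build_tensors(dataset, config.spectral)
        save_tensor(coh, paths[0], chash)
        save_tensor(pw, paths[1], chash)
        return coh, pw

    coh, power = stage_spectra()
    task_blocks = [b for b in dataset.block_labels if config.is_task_block(b)]
    if not task_blocks or len(task_blocks) == len(dataset.block_labels):
        raise RuntimeError(
            f"cannot split blocks {list(dataset.block_labels)} into task and rest"
        )

    @_stage("pls")
    def stage_pls():
        paths = out / "pls_ccc.h5", out / "pls_power.h5"
        if resume and all(p.exists() for p in paths):
            return tuple(load_pls_result(p, expect_hash=chash) for p in paths)
        res_c = run_pls(coh, config.n_perm, config.n_boot, config.seed)
        res_p = run_pls(power, config.n_perm, config.n_boot, config.seed)
        save_pls_result(res_c, paths[0], chash)
        save_pls_result(res_p, paths[1], chash)
        return res_c, res_p

    res_ccc, res_pow = stage_pls()
    res_ccc_o = res_ccc.oriented(task_blocks)
    res_pow_o = res_pow.oriented(task_blocks)

    @_stage("network")
    def stage_network():
        net = build_band_network(
            res_ccc_o.bsr_map(0),
            res_ccc_o.freqs,
            enumerate_pairs(n_nodes),
            percentile=config.ccc_percentile,
            min_degree=config.min_degree,
            atlas=atlas,
        )
        net.save(out / "ccc_edges.tsv")
        net.high_degree_positive.to_csv(
            out / "ccc_high_degree_positive.tsv", sep="\t", index=False
        )
        net.high_degree_negative.to_csv(
            out / "ccc_high_degree_negative.tsv", sep="\t", index=False
        )
        return net

    net = stage_network()
    pow_threshold, pow_counts = _track_summary(res_pow_o, config.power_percentile)
    ccc_counts = band_supra_counts(
        res_ccc_o.bsr_map(0), res_ccc_o.freqs, net.threshold
    )
    pow_counts.to_csv(out / "power_band_counts.tsv", sep="\t", index=False)

    report = RunReport(
        body={
            "version": __version__,
            "config_hash": chash,
            "seed": config.seed,
            "n_nodes": int(n_nodes),
            "task_blocks": task_blocks,
            "ccc": {
                "singular_values": [round(float(s), 9) for s in res_ccc.singular_values],
                "perm_p": [round(float(p), 9) for p in res_ccc.perm_p],
                "bsr_threshold": round(float(net.threshold), 9),
                "supra_counts": ccc_counts.to_dict(orient="records"),
                "high_degree_positive": net.high_degree_positive.to_dict(
                    orient="records"
                ),
                "high_degree_negative": net.high_degree_negative.to_dict(
                    orient="records"
                ),
            },
            "power": {
                "singular_values": [round(float(s), 9) for s in res_pow.singular_values],
                "perm_p": [round(float(p), 9) for p in res_pow.perm_p],
                "bsr_threshold": round(float(pow_threshold), 9),
                "supra_counts": pow_counts.to_dict(orient="records"),
            },
        }
    )
    report.save(out / "report.json")
    return report
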
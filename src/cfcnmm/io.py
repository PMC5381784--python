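"""Configuration files, result serialization and run manifests.

Configs are flat YAML/JSON mappings whose keys are the printed parameter
symbols (``C_pq1``, ``K_12``, ``tau_f1``, ``P1``, ``dt``, ...); missing keys
fall back to the shipped defaults and unknown keys are rejected.  Time
series are written as TSV, reports and manifests as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Any, Dict, Union

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .analysis import SpectralPeak
from .experiments import CFCReport
from .integrate import SimulationResult
from .model import (CouplingConfig, DendriticParams, ModelConfig, NodeConfig,
                    NoiseConfig, SigmoidParams)

__all__ = ["RunManifest", "config_to_dict", "config_from_dict",
           "load_config", "save_config", "write_results", "read_series"]


@dataclasses.dataclass
class RunManifest:
    """Everything needed to regenerate a result directory bit-for-bit."""

    config: Dict[str, Any]
    seed: int
    version: str
    created_utc: str
    outputs: Dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# flat symbol schema <-> ModelConfig
# ---------------------------------------------------------------------------

_NODE_KEYS = ("C_pq", "C_qp", "C_sp", "C_ps", "C_fp", "C_pf", "C_fs", "C_ff",
              "K_p", "K_f", "tau_f")
_NODE_DENDRITES = {"G_p": ("dendritic_p", "G"), "omega_p": ("dendritic_p", "omega"),
                   "G_q": ("dendritic_q", "G"), "omega_q": ("dendritic_q", "omega"),
                   "G_s": ("dendritic_s", "G"), "omega_s": ("dendritic_s", "omega"),
                   "G_f": ("dendritic_f", "G"), "omega_f": ("dendritic_f", "omega")}
_SIGMOID_KEYS = ("v_max", "v_theta", "r")
_COUPLING_KEYS = ("K_12", "K_21", "G_p12", "omega_p12", "G_p21", "omega_p21")
_NOISE_KEYS = ("P1", "P2", "sigma2_1", "sigma2_2", "seed")
_SIM_KEYS = ("dt", "duration", "transient")


def _known_keys() -> set:
    keys = set(_SIGMOID_KEYS) | set(_COUPLING_KEYS) | set(_NOISE_KEYS) | set(_SIM_KEYS)
    for x in ("1", "2"):
        keys |= {f"{k}{x}" for k in _NODE_KEYS}
        keys |= {f"{k}{x}" for k in _NODE_DENDRITES}
    return keys


def config_to_dict(cfg: ModelConfig) -> Dict[str, Any]:
    """Flatten a ModelConfig into the symbol-keyed mapping."""
    d: Dict[str, Any] = {}
    for x, node in (("1", cfg.node1), ("2", cfg.node2)):
        for k in _NODE_KEYS:
            d[f"{k}{x}"] = getattr(node, k)
        for k, (dend, attr) in _NODE_DENDRITES.items():
            d[f"{k}{x}"] = getattr(getattr(node, dend), attr)
    sg = cfg.node1.sigmoid
    d.update(v_max=sg.v_max, v_theta=sg.v_theta, r=sg.r)
    cp = cfg.coupling
    d.update(K_12=cp.K_12, K_21=cp.K_21,
             G_p12=cp.dendritic_p12.G, omega_p12=cp.dendritic_p12.omega,
             G_p21=cp.dendritic_p21.G, omega_p21=cp.dendritic_p21.omega)
    ns = cfg.noise
    d.update(P1=ns.P1, P2=ns.P2, sigma2_1=ns.sigma2_1, sigma2_2=ns.sigma2_2,
             seed=ns.seed)
    d.update(dt=cfg.dt, duration=cfg.duration, transient=cfg.transient)
    return d


def config_from_dict(overrides: Dict[str, Any]) -> ModelConfig:
    """Build a ModelConfig from a (possibly partial) flat mapping.

    Missing keys take the shipped defaults; unknown keys raise ``ValueError``.
    Invariant violations surface as ``ValueError`` naming the field.
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - _known_keys()
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    base = config_to_dict(ModelConfig())
    base.update(overrides)

    sigmoid = SigmoidParams(v_max=float(base["v_max"]),
                            v_theta=float(base["v_theta"]), r=float(base["r"]))

    def node(x: str) -> NodeConfig:
        kw = {k: float(base[f"{k}{x}"]) for k in _NODE_KEYS}
        dend = {}
        for name in ("p", "q", "s", "f"):
            dend[f"dendritic_{name}"] = DendriticParams(
                G=float(base[f"G_{name}{x}"]),
                omega=float(base[f"omega_{name}{x}"]))
        return NodeConfig(sigmoid=sigmoid, **kw, **dend)

    coupling = CouplingConfig(
        K_12=float(base["K_12"]), K_21=float(base["K_21"]),
        dendritic_p12=DendriticParams(G=float(base["G_p12"]),
                                      omega=float(base["omega_p12"])),
        dendritic_p21=DendriticParams(G=float(base["G_p21"]),
                                      omega=float(base["omega_p21"])))
    noise = NoiseConfig(P1=float(base["P1"]), P2=float(base["P2"]),
                        sigma2_1=float(base["sigma2_1"]),
                        sigma2_2=float(base["sigma2_2"]),
                        seed=int(base["seed"]))
    return ModelConfig(node1=node("1"), node2=node("2"), coupling=coupling,
                       noise=noise, dt=float(base["dt"]),
                       duration=float(base["duration"]),
                       transient=float(base["transient"]))


def load_config(path: Union[str, Path]) -> ModelConfig:
    """Parse a YAML or JSON config file into a validated ModelConfig."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
        else json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return config_from_dict(data)


def save_config(cfg: ModelConfig, path: Union[str, Path]) -> None:
    path = Path(path)
    d = config_to_dict(cfg)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=True))
    else:
        path.write_text(json.dumps(d, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# result serialization
# ---------------------------------------------------------------------------

def _series_tsv(result: SimulationResult, path: Path) -> None:
    arr = np.column_stack([result.t, result.vm_p1, result.vm_p2])
    # 17 significant digits: float64 round-trips exactly through text
    np.savetxt(path, arr, delimiter="\t", header="t\tvm_p1\tvm_p2",
               comments="", fmt="%.17g")


def read_series(path: Union[str, Path]):
    """Load a TSV written by :func:`write_results`; returns (t, vm_p1, vm_p2)."""
    arr = np.loadtxt(path, delimiter="\t", skiprows=1)
    return arr[:, 0], arr[:, 1], arr[:, 2]


def _report_json(report: CFCReport) -> str:
    def default(o):
        if isinstance(o, SpectralPeak):
            return dataclasses.asdict(o)
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    return json.dumps(report.to_dict(), indent=2, sort_keys=True,
                      default=default)


def write_results(result: Union[SimulationResult, CFCReport],
                  out_dir: Union[str, Path]) -> RunManifest:
    """Write a simulation series (TSV) or a coupling report (JSON) plus a
    manifest sufficient to reproduce the run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, str] = {}
    if isinstance(result, SimulationResult):
        series = out / "series.tsv"
        _series_tsv(result, series)
        outputs["series"] = series.name
        config = config_to_dict(result.config_echo)
        seed = result.seed_used
    elif isinstance(result, CFCReport):
        report = out / "report.json"
        report.write_text(_report_json(result))
        outputs["report"] = report.name
        config = config_to_dict(_preset_echo(result))
        seed = result.seeds[0] if result.seeds else 0
    else:
        raise TypeError(f"cannot write {type(result).__name__}")

    manifest = RunManifest(
        config=config, seed=int(seed), version=_pkg_version,
        created_utc=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        outputs=outputs)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest


def _preset_echo(report: CFCReport) -> ModelConfig:
    from .experiments import preset_config

    seed = report.seeds[0] if report.seeds else 0
    return preset_config(report.preset.name, seed=seed)
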
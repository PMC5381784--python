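"""Model definition: configuration types and the deterministic vector field.

The model couples two identical nodes, each made of four neural populations
(pyramidal, excitatory interneuron, slow inhibitory interneuron, fast
inhibitory interneuron with dynamic self-feedback).  Each population is a
sigmoid rate function feeding a critically damped second-order "dendritic"
filter.  Two relay populations carry activity between the nodes and two more
second-order filters shape the external Gaussian noise.

The full state has 26 scalar components (see :data:`STATE_NAMES`); the
vector field is written once in :func:`vector_field` and compiled with numba
when available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


__all__ = [
    "SigmoidParams",
    "DendriticParams",
    "NodeConfig",
    "CouplingConfig",
    "NoiseConfig",
    "ModelConfig",
    "STATE_NAMES",
    "N_STATE",
    "default_node_config",
    "default_model_config",
    "sigmoid_rate",
    "dendritic_deriv",
    "membrane_potentials",
    "vector_field",
    "pack_params",
]


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SigmoidParams:
    """Logistic rate function parameters.

    Attributes
    ----------
    v_max : float
        Maximum population firing rate (1/s).
    v_theta : float
        Potential at which half of ``v_max`` is reached (mV).
    r : float
        Slope of the logistic at ``v_theta`` (1/mV).
    """

    v_max: float = 5.0
    v_theta: float = 5.0
    r: float = 1.12

    def __post_init__(self) -> None:
        if self.v_max <= 0:
            raise ValueError(f"v_max must be > 0, got {self.v_max}")
        if self.r <= 0:
            raise ValueError(f"r must be > 0, got {self.r}")


@dataclass(frozen=True)
class DendriticParams:
    """Second-order dendritic filter G*w / (s^2 + 2*w*s + w^2).

    ``G`` is the gain (mV) and ``omega`` the inverse time constant (rad/s).
    """

    G: float
    omega: float

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")


@dataclass(frozen=True)
class NodeConfig:
    """All parameters of a single four-population node.

    Synaptic gain naming follows the target<-source convention: ``C_pq`` is
    the gain from the excitatory interneuron (q) onto the pyramidal
    population (p).
    """

    C_pq: float = 108.0
    C_qp: float = 135.0
    C_sp: float = 33.75
    C_ps: float = 33.75
    C_fp: float = 40.5
    C_pf: float = 27.0
    C_fs: float = 10.8
    C_ff: float = 135.0
    K_p: float = 40.0
    K_f: float = 108.0
    dendritic_p: DendriticParams = field(
        default_factory=lambda: DendriticParams(G=0.32, omega=10.0))
    dendritic_q: DendriticParams = field(
        default_factory=lambda: DendriticParams(G=3.2, omega=100.0))
    dendritic_s: DendriticParams = field(
        default_factory=lambda: DendriticParams(G=22.0, omega=50.0))
    dendritic_f: DendriticParams = field(
        default_factory=lambda: DendriticParams(G=50.0, omega=200.0))
    tau_f: float = 0.005
    sigmoid: SigmoidParams = field(default_factory=SigmoidParams)

    def __post_init__(self) -> None:
        for name in ("C_pq", "C_qp", "C_sp", "C_ps", "C_fp", "C_pf",
                     "C_fs", "C_ff", "K_p", "K_f"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.tau_f <= 0:
            raise ValueError(f"tau_f must be > 0, got {self.tau_f}")


@dataclass(frozen=True)
class CouplingConfig:
    """Between-node coupling gains and relay dendritic filters."""

    K_12: float = 40.0
    K_21: float = 40.0
    dendritic_p12: DendriticParams = field(
        default_factory=lambda: DendriticParams(G=3.2, omega=100.0))
    dendritic_p21: DendriticParams = field(
        default_factory=lambda: DendriticParams(G=3.2, omega=100.0))

    def __post_init__(self) -> None:
        if self.K_12 < 0 or self.K_21 < 0:
            raise ValueError("K_12 and K_21 must be >= 0")


@dataclass(frozen=True)
class NoiseConfig:
    """Gaussian input noise: one independent stream per node."""

    P1: float = 7.0
    P2: float = 7.0
    sigma2_1: float = 0.5
    sigma2_2: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma2_1 < 0 or self.sigma2_2 < 0:
            raise ValueError("noise variances must be >= 0")


@dataclass(frozen=True)
class ModelConfig:
    """Complete model + integration configuration."""

    # tau_f tunes each node's gamma frequency: 5 ms -> ~51 Hz, 10 ms -> ~42 Hz
    node1: NodeConfig = field(default_factory=lambda: NodeConfig(tau_f=0.005))
    node2: NodeConfig = field(default_factory=lambda: NodeConfig(tau_f=0.01))
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    dt: float = 1e-4
    duration: float = 70.0
    transient: float = 10.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.transient < 0:
            raise ValueError(f"transient must be >= 0, got {self.transient}")
        if self.duration <= self.transient:
            raise ValueError(
                f"duration ({self.duration}) must exceed transient ({self.transient})")

    @property
    def fs(self) -> float:
        """Sampling rate of the simulated output (Hz)."""
        return 1.0 / self.dt


def default_node_config(tau_f: float = 0.005) -> NodeConfig:
    return NodeConfig(tau_f=tau_f)


def default_model_config(**kwargs) -> ModelConfig:
    return replace(ModelConfig(), **kwargs) if kwargs else ModelConfig()


# ---------------------------------------------------------------------------
# state layout
# ---------------------------------------------------------------------------

#: Names of the 26 state components, in storage order.  ``v`` are potentials
#: (mV), ``z`` their time derivatives (mV/s).
STATE_NAMES: Tuple[str, ...] = (
    "v_p1", "z_p1", "v_q1", "z_q1", "v_s1", "z_s1", "v_f1", "z_f1", "v_ff1",
    "v_p2", "z_p2", "v_q2", "z_q2", "v_s2", "z_s2", "v_f2", "z_f2", "v_ff2",
    "v_p12", "z_p12", "v_p21", "z_p21",
    "v_n1", "z_n1", "v_n2", "z_n2",
)

N_STATE: int = len(STATE_NAMES)

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}


# ---------------------------------------------------------------------------
# parameter packing for the compiled kernel
# ---------------------------------------------------------------------------

# per-node slice layout (19 values per node)
_NODE_PARAM_NAMES = (
    "C_pq", "C_qp", "C_sp", "C_ps", "C_fp", "C_pf", "C_fs", "C_ff",
    "K_p", "K_f",
    "G_p", "w_p", "G_q", "w_q", "G_s", "w_s", "G_f", "w_f",
    "tau_f",
)
_N_NODE = len(_NODE_PARAM_NAMES)
# global tail: K_12, K_21, G_p12, w_p12, G_p21, w_p21, v_max, v_theta, r
_N_PARAMS = 2 * _N_NODE + 9


def _pack_node(node: NodeConfig) -> np.ndarray:
    return np.array([
        node.C_pq, node.C_qp, node.C_sp, node.C_ps, node.C_fp, node.C_pf,
        node.C_fs, node.C_ff, node.K_p, node.K_f,
        node.dendritic_p.G, node.dendritic_p.omega,
        node.dendritic_q.G, node.dendritic_q.omega,
        node.dendritic_s.G, node.dendritic_s.omega,
        node.dendritic_f.G, node.dendritic_f.omega,
        node.tau_f,
    ], dtype=np.float64)


def pack_params(cfg: ModelConfig) -> np.ndarray:
    """Flatten a :class:`ModelConfig` into the parameter vector used by the
    compiled vector field.  The sigmoid is shared by all populations; node 1's
    sigmoid parameters are used (the two nodes are identically parametrized
    in every shipped configuration)."""
    sg = cfg.node1.sigmoid
    tail = np.array([
        cfg.coupling.K_12, cfg.coupling.K_21,
        cfg.coupling.dendritic_p12.G, cfg.coupling.dendritic_p12.omega,
        cfg.coupling.dendritic_p21.G, cfg.coupling.dendritic_p21.omega,
        sg.v_max, sg.v_theta, sg.r,
    ], dtype=np.float64)
    return np.concatenate([_pack_node(cfg.node1), _pack_node(cfg.node2), tail])


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

@njit(cache=True)
def _sig(vm: float, v_max: float, v_theta: float, r: float) -> float:
    # overflow-safe logistic
    x = r * (vm - v_theta)
    if x >= 0.0:
        return v_max / (1.0 + math.exp(-x))
    e = math.exp(x)
    return v_max * e / (1.0 + e)


def sigmoid_rate(vm, p: SigmoidParams):
    """Population firing rate (1/s) for membrane potential ``vm`` (mV).

    ``v_max / (1 + exp(-r * (vm - v_theta)))``; monotone, bounded in
    ``(0, v_max)`` and overflow-safe for arbitrarily large ``|vm|``.
    Accepts scalars or arrays.
    """
    x = p.r * (np.asarray(vm, dtype=np.float64) - p.v_theta)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = p.v_max / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = p.v_max * e / (1.0 + e)
    if np.isscalar(vm) or np.ndim(vm) == 0:
        return float(out)
    return out


def dendritic_deriv(v: float, z: float, u: float, p: DendriticParams):
    """Time derivative of one second-order dendritic block.

    Returns ``(dv/dt, dz/dt)`` with ``dv/dt = z`` and
    ``dz/dt = G*w*u - 2*w*z - w^2*v`` for input rate ``u``.
    """
    return z, p.G * p.omega * u - 2.0 * p.omega * z - p.omega ** 2 * v


# ---------------------------------------------------------------------------
# membrane potentials and full vector field
# ---------------------------------------------------------------------------

def membrane_potentials(state: np.ndarray, cfg: ModelConfig):
    """The eight population membrane potentials (mV).

    Returns ``(vm_p1, vm_q1, vm_s1, vm_f1, vm_p2, vm_q2, vm_s2, vm_f2)``.
    Inhibitory inputs (from the slow and fast inhibitory populations) enter
    with a negative sign; the fast population's self-inhibition uses the
    dynamic feedback state ``v_ff``, not ``v_f`` itself.
    """
    s = np.asarray(state, dtype=np.float64)
    n1, n2, cp = cfg.node1, cfg.node2, cfg.coupling
    vm_p1 = (n1.C_pq * s[_IDX["v_q1"]] - n1.C_ps * s[_IDX["v_s1"]]
             - n1.C_pf * s[_IDX["v_f1"]] + cp.K_12 * s[_IDX["v_p12"]]
             + n1.K_p * s[_IDX["v_n1"]])
    vm_q1 = n1.C_qp * s[_IDX["v_p1"]]
    vm_s1 = n1.C_sp * s[_IDX["v_p1"]]
    vm_f1 = (n1.C_fp * s[_IDX["v_p1"]] - n1.C_fs * s[_IDX["v_s1"]]
             - n1.C_ff * s[_IDX["v_ff1"]] + n1.K_f * s[_IDX["v_n1"]])
    vm_p2 = (n2.C_pq * s[_IDX["v_q2"]] - n2.C_ps * s[_IDX["v_s2"]]
             - n2.C_pf * s[_IDX["v_f2"]] + cp.K_21 * s[_IDX["v_p21"]]
             + n2.K_p * s[_IDX["v_n2"]])
    vm_q2 = n2.C_qp * s[_IDX["v_p2"]]
    vm_s2 = n2.C_sp * s[_IDX["v_p2"]]
    vm_f2 = (n2.C_fp * s[_IDX["v_p2"]] - n2.C_fs * s[_IDX["v_s2"]]
             - n2.C_ff * s[_IDX["v_ff2"]] + n2.K_f * s[_IDX["v_n2"]])
    return vm_p1, vm_q1, vm_s1, vm_f1, vm_p2, vm_q2, vm_s2, vm_f2


@njit(cache=True)
def _vector_field(state, n1s, n2s, prm, out):
    """Compiled core: writes d(state)/dt into ``out``.

    ``n1s``/``n2s`` are the instantaneous noise rates (1/s) for the two
    nodes.  State layout per STATE_NAMES; parameter layout per pack_params.
    """
    o = _N_NODE
    K_12 = prm[2 * o + 0]
    K_21 = prm[2 * o + 1]
    G_p12 = prm[2 * o + 2]
    w_p12 = prm[2 * o + 3]
    G_p21 = prm[2 * o + 4]
    w_p21 = prm[2 * o + 5]
    v_max = prm[2 * o + 6]
    v_th = prm[2 * o + 7]
    r = prm[2 * o + 8]

    v_p1, z_p1 = state[0], state[1]
    v_q1, z_q1 = state[2], state[3]
    v_s1, z_s1 = state[4], state[5]
    v_f1, z_f1 = state[6], state[7]
    v_ff1 = state[8]
    v_p2, z_p2 = state[9], state[10]
    v_q2, z_q2 = state[11], state[12]
    v_s2, z_s2 = state[13], state[14]
    v_f2, z_f2 = state[15], state[16]
    v_ff2 = state[17]
    v_p12, z_p12 = state[18], state[19]
    v_p21, z_p21 = state[20], state[21]
    v_n1, z_n1 = state[22], state[23]
    v_n2, z_n2 = state[24], state[25]

    # node 1 membrane potentials
    vm_p1 = (prm[0] * v_q1 - prm[3] * v_s1 - prm[5] * v_f1
             + K_12 * v_p12 + prm[8] * v_n1)
    vm_q1 = prm[1] * v_p1
    vm_s1 = prm[2] * v_p1
    vm_f1 = prm[4] * v_p1 - prm[6] * v_s1 - prm[7] * v_ff1 + prm[9] * v_n1
    # node 2
    vm_p2 = (prm[o + 0] * v_q2 - prm[o + 3] * v_s2 - prm[o + 5] * v_f2
             + K_21 * v_p21 + prm[o + 8] * v_n2)
    vm_q2 = prm[o + 1] * v_p2
    vm_s2 = prm[o + 2] * v_p2
    vm_f2 = (prm[o + 4] * v_p2 - prm[o + 6] * v_s2 - prm[o + 7] * v_ff2
             + prm[o + 9] * v_n2)

    # node 1 populations
    out[0] = z_p1
    out[1] = (prm[10] * prm[11] * _sig(vm_p1, v_max, v_th, r)
              - 2.0 * prm[11] * z_p1 - prm[11] * prm[11] * v_p1)
    out[2] = z_q1
    out[3] = (prm[12] * prm[13] * _sig(vm_q1, v_max, v_th, r)
              - 2.0 * prm[13] * z_q1 - prm[13] * prm[13] * v_q1)
    out[4] = z_s1
    out[5] = (prm[14] * prm[15] * _sig(vm_s1, v_max, v_th, r)
              - 2.0 * prm[15] * z_s1 - prm[15] * prm[15] * v_s1)
    out[6] = z_f1
    out[7] = (prm[16] * prm[17] * _sig(vm_f1, v_max, v_th, r)
              - 2.0 * prm[17] * z_f1 - prm[17] * prm[17] * v_f1)
    out[8] = (v_f1 - v_ff1) / prm[18]
    # node 2 populations
    out[9] = z_p2
    out[10] = (prm[o + 10] * prm[o + 11] * _sig(vm_p2, v_max, v_th, r)
               - 2.0 * prm[o + 11] * z_p2 - prm[o + 11] * prm[o + 11] * v_p2)
    out[11] = z_q2
    out[12] = (prm[o + 12] * prm[o + 13] * _sig(vm_q2, v_max, v_th, r)
               - 2.0 * prm[o + 13] * z_q2 - prm[o + 13] * prm[o + 13] * v_q2)
    out[13] = z_s2
    out[14] = (prm[o + 14] * prm[o + 15] * _sig(vm_s2, v_max, v_th, r)
               - 2.0 * prm[o + 15] * z_s2 - prm[o + 15] * prm[o + 15] * v_s2)
    out[15] = z_f2
    out[16] = (prm[o + 16] * prm[o + 17] * _sig(vm_f2, v_max, v_th, r)
               - 2.0 * prm[o + 17] * z_f2 - prm[o + 17] * prm[o + 17] * v_f2)
    out[17] = (v_f2 - v_ff2) / prm[o + 18]

    # between-node relays: p12 carries node 2 activity into node 1
    out[18] = z_p12
    out[19] = (G_p12 * w_p12 * _sig(vm_p2, v_max, v_th, r)
               - 2.0 * w_p12 * z_p12 - w_p12 * w_p12 * v_p12)
    out[20] = z_p21
    out[21] = (G_p21 * w_p21 * _sig(vm_p1, v_max, v_th, r)
               - 2.0 * w_p21 * z_p21 - w_p21 * w_p21 * v_p21)

    # noise filters (raw rate in, no sigmoid)
    out[22] = z_n1
    out[23] = G_p12 * w_p12 * n1s - 2.0 * w_p12 * z_n1 - w_p12 * w_p12 * v_n1
    out[24] = z_n2
    out[25] = G_p21 * w_p21 * n2s - 2.0 * w_p21 * z_n2 - w_p21 * w_p21 * v_n2
    return out


def vector_field(state: np.ndarray, noise_samples, cfg: ModelConfig,
                 params: np.ndarray | None = None) -> np.ndarray:
    """Time derivative of the full 26-component state.

    Parameters
    ----------
    state : array of shape (26,)
    noise_samples : (n1, n2)
        Instantaneous noise rates (1/s) for the two nodes.
    cfg : ModelConfig
    params : optional pre-packed parameter vector (pack_params(cfg)).

    Raises
    ------
    FloatingPointError
        If the state or noise contains non-finite values (numerical blow-up).
    """
    state = np.asarray(state, dtype=np.float64)
    if state.shape != (N_STATE,):
        raise ValueError(f"state must have shape ({N_STATE},), got {state.shape}")
    n1s, n2s = float(noise_samples[0]), float(noise_samples[1])
    if not (np.all(np.isfinite(state)) and math.isfinite(n1s) and math.isfinite(n2s)):
        raise FloatingPointError("non-finite state or noise sample")
    if params is None:
        params = pack_params(cfg)
    out = np.empty(N_STATE, dtype=np.float64)
    _vector_field(state, n1s, n2s, params, out)
    return out
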
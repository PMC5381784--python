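"""Fixed-step RK4 integration with per-step Gaussian noise streams.

The noise sample for each step is drawn once and held constant through the
four RK4 sub-evaluations (zero-order hold); this is insensitive to sub-step
interpolation because the noise is pre-filtered by a 100 rad/s second-order
block before it reaches any population.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .model import (
    N_STATE,
    ModelConfig,
    njit,
    pack_params,
    vector_field,
    _N_NODE,
    _vector_field,
)

__all__ = ["SimulationResult", "DivergenceError", "sample_noise",
           "rk4_step", "simulate"]

#: any |state component| beyond this is treated as numerical blow-up
DIVERGENCE_LIMIT = 1e6


class DivergenceError(RuntimeError):
    """Raised when the integrated state leaves the finite/bounded domain."""

    def __init__(self, step: int, t: float):
        self.step = step
        self.t = t
        super().__init__(
            f"simulation diverged (non-finite or |state| > {DIVERGENCE_LIMIT:g}) "
            f"at step {step} (t = {t:.4f} s)")


@dataclass
class SimulationResult:
    """Post-transient output of one simulation run.

    ``vm_p1`` / ``vm_p2`` are the pyramidal membrane potentials of the two
    nodes (the model outputs), sampled at ``1/dt``.
    """

    t: np.ndarray
    vm_p1: np.ndarray
    vm_p2: np.ndarray
    config_echo: ModelConfig
    seed_used: int
    full_state: Optional[np.ndarray] = None  # (n_samples, 26) if requested

    @property
    def fs(self) -> float:
        return 1.0 / self.config_echo.dt

    def __len__(self) -> int:
        return len(self.t)


def _node_streams(seed: int) -> Tuple[np.random.Generator, np.random.Generator]:
    """Two independent generators derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    c1, c2 = ss.spawn(2)
    return np.random.default_rng(c1), np.random.default_rng(c2)


def sample_noise(rng: np.random.Generator, P: float, sigma2: float,
                 n_steps: int) -> np.ndarray:
    """i.i.d. Gaussian rate samples, one per integration step.

    Mean ``P`` (1/s), variance ``sigma2``.  ``sigma2 = 0`` yields the
    constant sequence ``P``.  Draws are sequential, so extending ``n_steps``
    with the same generator state reproduces the shorter sequence as a
    prefix.
    """
    if sigma2 < 0:
        raise ValueError(f"sigma2 must be >= 0, got {sigma2}")
    if sigma2 == 0.0:
        return np.full(n_steps, P, dtype=np.float64)
    return P + np.sqrt(sigma2) * rng.standard_normal(n_steps)


@njit(cache=True)
def _rk4_step(state, n1s, n2s, dt, prm, k1, k2, k3, k4, tmp):
    _vector_field(state, n1s, n2s, prm, k1)
    for i in range(state.shape[0]):
        tmp[i] = state[i] + 0.5 * dt * k1[i]
    _vector_field(tmp, n1s, n2s, prm, k2)
    for i in range(state.shape[0]):
        tmp[i] = state[i] + 0.5 * dt * k2[i]
    _vector_field(tmp, n1s, n2s, prm, k3)
    for i in range(state.shape[0]):
        tmp[i] = state[i] + dt * k3[i]
    _vector_field(tmp, n1s, n2s, prm, k4)
    for i in range(state.shape[0]):
        state[i] += dt / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])


@njit(cache=True)
def _run_loop(state, noise1, noise2, dt, prm, out_p1, out_p2, full_state,
              keep_full, limit):
    """Integrate n_steps, recording both node outputs after each step.

    Returns the index of the first divergent step, or -1 on success.
    """
    n_steps = noise1.shape[0]
    n = state.shape[0]
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    o = _N_NODE
    for step in range(n_steps):
        _rk4_step(state, noise1[step], noise2[step], dt, prm, k1, k2, k3, k4, tmp)
        for i in range(n):
            if not np.isfinite(state[i]) or abs(state[i]) > limit:
                return step
        # pyramidal membrane potentials = node outputs
        out_p1[step] = (prm[0] * state[2] - prm[3] * state[4]
                        - prm[5] * state[6] + prm[2 * o] * state[18]
                        + prm[8] * state[22])
        out_p2[step] = (prm[o] * state[11] - prm[o + 3] * state[13]
                        - prm[o + 5] * state[15] + prm[2 * o + 1] * state[20]
                        + prm[o + 8] * state[24])
        if keep_full:
            for i in range(n):
                full_state[step, i] = state[i]
    return -1


def rk4_step(state: np.ndarray, t: float, dt: float, noise_samples,
             cfg: ModelConfig, params: np.ndarray | None = None) -> np.ndarray:
    """One classical RK4 step of the model vector field.

    The noise pair is held constant across the four sub-evaluations.  The
    model is autonomous, so ``t`` only labels the step.
    """
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if params is None:
        params = pack_params(cfg)
    k1 = vector_field(state, noise_samples, cfg, params)
    k2 = vector_field(state + 0.5 * dt * k1, noise_samples, cfg, params)
    k3 = vector_field(state + 0.5 * dt * k2, noise_samples, cfg, params)
    k4 = vector_field(state + dt * k3, noise_samples, cfg, params)
    nxt = state + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    if not np.all(np.isfinite(nxt)):
        raise DivergenceError(step=0, t=t)
    return nxt


def simulate(cfg: ModelConfig, keep_full_state: bool = False,
             initial_state: np.ndarray | None = None) -> SimulationResult:
    """Integrate the model and return the post-transient node outputs.

    Starts from the zero state (unless ``initial_state`` is given),
    integrates ``duration/dt`` steps of classical RK4 with one Gaussian
    noise draw per node per step, then discards the first ``transient``
    seconds.  Fully reproducible from ``cfg.noise.seed``.
    """
    dt = cfg.dt
    n_steps = int(round(cfg.duration / dt))
    n_skip = int(round(cfg.transient / dt))
    rng1, rng2 = _node_streams(cfg.noise.seed)
    noise1 = sample_noise(rng1, cfg.noise.P1, cfg.noise.sigma2_1, n_steps)
    noise2 = sample_noise(rng2, cfg.noise.P2, cfg.noise.sigma2_2, n_steps)

    state = np.zeros(N_STATE) if initial_state is None else \
        np.array(initial_state, dtype=np.float64)
    prm = pack_params(cfg)
    out_p1 = np.empty(n_steps)
    out_p2 = np.empty(n_steps)
    full = np.empty((n_steps if keep_full_state else 1, N_STATE))
    bad = _run_loop(state, noise1, noise2, dt, prm, out_p1, out_p2,
                    full, keep_full_state, DIVERGENCE_LIMIT)
    if bad >= 0:
        raise DivergenceError(step=int(bad), t=(bad + 1) * dt)

    t = dt * np.arange(1, n_steps + 1)
    return SimulationResult(
        t=t[n_skip:],
        vm_p1=out_p1[n_skip:],
        vm_p2=out_p2[n_skip:],
        config_echo=cfg,
        seed_used=cfg.noise.seed,
        full_state=full[n_skip:] if keep_full_state else None,
    )
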
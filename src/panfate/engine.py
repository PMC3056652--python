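"""Euler–Maruyama integration of the stochastic gene circuit.

Single cells and ensembles share one vectorised integrator: an ensemble of
m cells is an (m, 11) state advanced in lock-step, each cell drawing from
an independent RNG stream spawned from the master seed.  Noise is additive
Gaussian white noise on the ten TF components with autocorrelation
<xi_i(t) xi_j(t')> = 2 D delta_ij delta(t - t'), so each step adds
sqrt(2 D dt) * z.  Nonnegativity is enforced by clipping at zero after
every step; the maturation component advances deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .network import (
    GENES,
    GENE_INDEX,
    MATURATION,
    N_STATE,
    N_TF,
    GeneNetwork,
    ParameterSet,
    RateKernel,
    compile_kernel,
)
from .perturb import Schedule

__all__ = [
    "NoiseModel",
    "Trajectory",
    "Ensemble",
    "em_step",
    "simulate_cell",
    "simulate_ensemble",
    "find_attractor",
    "progenitor_state",
    "ensemble_to_frame",
    "frame_to_ensemble",
]


@dataclass(frozen=True)
class NoiseModel:
    """State-independent additive noise of magnitude D on TF components."""

    D: float = 0.05

    def increment(self, rng: np.random.Generator, shape: tuple, dt: float) -> np.ndarray:
        if self.D == 0:
            return np.zeros(shape)
        return np.sqrt(2.0 * self.D * dt) * rng.standard_normal(shape)


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped states of one cell: times (T,), states (T, 11)."""

    times: np.ndarray
    states: np.ndarray
    cell_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape != (len(self.times), N_STATE):
            raise ValueError("states must be (len(times), 11)")

    def gene(self, name: str) -> np.ndarray:
        if name == MATURATION:
            return self.states[:, N_TF]
        return self.states[:, GENE_INDEX[name]]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]


@dataclass(frozen=True)
class Ensemble:
    """A population of trajectories sharing network, parameters, schedule."""

    trajectories: tuple[Trajectory, ...]
    network: GeneNetwork
    params: ParameterSet
    schedule: Schedule = field(default_factory=Schedule)

    def __post_init__(self) -> None:
        ids = [t.cell_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise ValueError("cell_ids must be unique")

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def times(self) -> np.ndarray:
        return self.trajectories[0].times

    def terminal_states(self) -> np.ndarray:
        return np.stack([t.final_state for t in self.trajectories])

    def states_array(self) -> np.ndarray:
        """All saved states as (n_cells, T, 11)."""
        return np.stack([t.states for t in self.trajectories])


def em_step(
    state: np.ndarray,
    drift_fn: Callable[[np.ndarray], np.ndarray],
    noise: NoiseModel,
    dt: float,
    rng: np.random.Generator,
    clip: bool = True,
) -> np.ndarray:
    """One Euler–Maruyama step of an (m, 11) state (or a single state).

    TF components receive the stochastic increment; the maturation
    component advances deterministically.  With D=0 this reduces exactly to
    a forward-Euler step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    single = state.ndim == 1
    x = state[None, :] if single else state
    d = drift_fn(x)
    if not np.all(np.isfinite(d)):
        bad = np.argwhere(~np.isfinite(d))
        cell, comp = bad[0]
        name = GENES[comp] if comp < N_TF else MATURATION
        raise FloatingPointError(
            f"non-finite drift for gene {name} in cell {cell}")
    out = x + d * dt
    out[:, :N_TF] += noise.increment(rng, (x.shape[0], N_TF), dt)
    if clip:
        np.maximum(out, 0.0, out=out)
    return out[0] if single else out


def progenitor_state(params: ParameterSet) -> np.ndarray:
    """The developmental initial condition: Hnf6 and Pdx1 high, rest zero."""
    x0 = np.zeros(N_STATE)
    x0[GENE_INDEX["Hnf6"]] = params.a["Hnf6"] / params.k
    x0[GENE_INDEX["Pdx1"]] = params.a["Pdx1"] / params.k
    return x0


def _integrate(
    kernel: RateKernel,
    schedule: Schedule,
    x0: np.ndarray,
    rngs: Sequence[np.random.Generator],
    t_end: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance an (m, 11) ensemble; returns (times, saved (T, m, 11))."""
    p = kernel.params
    t_end = p.t_end if t_end is None else t_end
    schedule.validate_horizon(t_end)
    dt = p.dt
    steps = int(round(t_end / dt))
    per_save = max(1, int(round(p.save_interval / dt)))
    m = x0.shape[0]
    base_noise = NoiseModel(p.D)

    x = x0.copy()
    saved = [x.copy()]
    times = [0.0]
    has_sched = bool(schedule.events)
    mods = schedule.modifiers(0.0) if has_sched else None
    boundaries = schedule.boundaries() if has_sched else []

    # apply initial clamps
    if has_sched:
        x[:, np.flatnonzero(mods.clamp)] = 0.0

    sqrt2dt = np.sqrt(2.0 * dt)
    chunk = 1000
    buf = np.empty((0, m, N_TF))
    buf_pos = 0
    for s in range(1, steps + 1):
        t = (s - 1) * dt
        if has_sched and any(abs(t - b) < dt / 2 for b in boundaries):
            mods = schedule.modifiers(t)
        d = kernel.drift(x)
        if has_sched:
            d[:, :N_TF] += mods.gain - mods.extra_degradation * x[:, :N_TF]
            nulled = np.flatnonzero(mods.null_production)
            if nulled.size:
                d[:, nulled] = -p.k * x[:, nulled]
            D_now = mods.noise_override if mods.noise_override is not None else p.D
        else:
            D_now = p.D
        x = x + d * dt
        if D_now > 0:
            if buf_pos >= buf.shape[0]:
                n_draw = min(chunk, steps - s + 1)
                # one block per cell keeps the per-cell streams independent
                buf = np.stack(
                    [r.standard_normal((n_draw, N_TF)) for r in rngs], axis=1
                )
                buf_pos = 0
            x[:, :N_TF] += np.sqrt(D_now) * sqrt2dt * buf[buf_pos]
            buf_pos += 1
        np.maximum(x, 0.0, out=x)
        if has_sched:
            x[:, np.flatnonzero(mods.clamp)] = 0.0
        if s % per_save == 0:
            saved.append(x.copy())
            times.append(s * dt)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError("integration diverged")
    return np.asarray(times), np.stack(saved)


def simulate_cell(
    network: GeneNetwork,
    params: ParameterSet,
    schedule: Schedule | None = None,
    initial: np.ndarray | None = None,
    seed: int | np.random.SeedSequence | None = None,
    t_end: float | None = None,
) -> Trajectory:
    """Simulate a single cell and return its sampled trajectory."""
    schedule = schedule or Schedule()
    kernel = compile_kernel(network, params)
    x0 = (progenitor_state(params) if initial is None else np.asarray(initial, float))
    seed = params.seed if seed is None else seed
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.Generator(np.random.PCG64(ss))
    times, saved = _integrate(kernel, schedule, x0[None, :], [rng], t_end)
    return Trajectory(times, saved[:, 0, :], cell_id=0,
                      seed=seed if isinstance(seed, int) else -1)


def simulate_ensemble(
    n_cells: int,
    network: GeneNetwork,
    params: ParameterSet,
    schedule: Schedule | None = None,
    master_seed: int | None = None,
    initial: np.ndarray | None = None,
    t_end: float | None = None,
) -> Ensemble:
    """Simulate n_cells with identical initial conditions.

    Per-cell RNG streams are spawned deterministically from the master seed
    so results are reproducible and independent of evaluation order.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    schedule = schedule or Schedule()
    kernel = compile_kernel(network, params)
    master_seed = params.seed if master_seed is None else master_seed
    children = np.random.SeedSequence(master_seed).spawn(n_cells)
    rngs = [np.random.Generator(np.random.PCG64(c)) for c in children]
    x0 = (progenitor_state(params) if initial is None else np.asarray(initial, float))
    X0 = np.tile(x0, (n_cells, 1))
    times, saved = _integrate(kernel, schedule, X0, rngs, t_end)
    trajs = tuple(
        Trajectory(times, saved[:, i, :], cell_id=i, seed=master_seed)
        for i in range(n_cells)
    )
    return Ensemble(trajs, network, params, schedule)


@dataclass(frozen=True)
class AttractorResult:
    state: np.ndarray
    converged: bool
    residual: float


def find_attractor(
    network: GeneNetwork,
    params: ParameterSet,
    x0: np.ndarray,
    tol: float = 1e-6,
    t_max: float | None = None,
) -> AttractorResult:
    """Relax a state deterministically (D=0) until max |drift| < tol.

    Non-convergence within t_max (default 10 * t_end) is flagged, not
    raised.  The maturation component is frozen during relaxation: it has
    no restoring dynamics (monotone clock) and is not part of the
    expression pattern that defines an attractor.
    """
    kernel = compile_kernel(network, params)
    t_max = 10.0 * params.t_end if t_max is None else t_max
    dt = params.dt
    x = np.asarray(x0, float)[None, :].copy()
    steps = int(round(t_max / dt))
    check = max(1, int(round(1.0 / dt)))
    residual = np.inf
    for s in range(steps):
        d = kernel.drift(x)
        d[:, N_TF] = 0.0
        if s % check == 0:
            residual = float(np.max(np.abs(d)))
            if residual < tol:
                return AttractorResult(x[0].copy(), True, residual)
        x = np.maximum(x + d * dt, 0.0)
    d = kernel.drift(x)
    d[:, N_TF] = 0.0
    residual = float(np.max(np.abs(d)))
    return AttractorResult(x[0].copy(), residual < tol, residual)


def ensemble_to_frame(ens: Ensemble) -> pd.DataFrame:
    """Tidy long-format table: cell_id, time, one column per gene."""
    frames = []
    for tr in ens.trajectories:
        df = pd.DataFrame(tr.states, columns=list(GENES) + [MATURATION])
        df.insert(0, "time", tr.times)
        df.insert(0, "cell_id", tr.cell_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def frame_to_ensemble(
    df: pd.DataFrame, network: GeneNetwork, params: ParameterSet,
    schedule: Schedule | None = None,
) -> Ensemble:
    """Reconstruct an Ensemble from a tidy trajectory table."""
    cols = list(GENES) + [MATURATION]
    trajs = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time")
        trajs.append(
            Trajectory(grp["time"].to_numpy(), grp[cols].to_numpy(), cell_id=int(cid))
        )
    return Ensemble(tuple(trajs), network, params, schedule or Schedule())
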
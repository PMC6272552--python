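"""Born-Oppenheimer MD, dual-topology FEP and Hamiltonian replica exchange.

The integrator is velocity Verlet; the canonical ensemble is sampled with a
BAOAB-split Langevin thermostat.  Alchemical states are mixed linearly,
H(lambda) = lambda H_A + (1 - lambda) H_B (lambda = 1 is state A), free
energies are estimated by exponential averaging per window with
block-averaged standard errors, and replica exchange follows the
odd/even nearest-neighbor schedule with the Metropolis criterion
min{1, exp(-beta [U_i(q_j) + U_j(q_i) - U_i(q_i) - U_j(q_j)])}.

Interface units: time steps in fs, temperatures in K, masses in amu;
everything is converted to hartree atomic units internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .units import AMU_TO_ME, FS_TO_AUT, KB_HARTREE


# ---------------------------------------------------------------------------
# MD state and integrators
# ---------------------------------------------------------------------------

@dataclass
class MDState:
    positions: np.ndarray       # (N, 3) bohr
    velocities: np.ndarray      # (N, 3) bohr / a.u. time
    masses: np.ndarray          # (N,) electron masses (converted from amu)
    step: int = 0
    time_fs: float = 0.0
    forces: np.ndarray | None = None
    potential: float | None = None

    @classmethod
    def initialize(cls, positions, masses_amu, T: float = 0.0, seed: int = 0):
        pos = np.asarray(positions, dtype=float)
        m = np.asarray(masses_amu, dtype=float) * AMU_TO_ME
        v = np.zeros_like(pos)
        if T > 0:
            rng = np.random.default_rng(seed)
            v = rng.standard_normal(pos.shape) * np.sqrt(
                KB_HARTREE * T / m
            )[:, None]
            # remove center-of-mass drift
            v -= np.average(v, axis=0, weights=m)[None, :]
        return cls(positions=pos, velocities=v, masses=m)

    @property
    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.masses[:, None] * self.velocities ** 2))

    def temperature(self, n_dof: int | None = None) -> float:
        dof = n_dof or 3 * len(self.masses)
        return 2.0 * self.kinetic_energy / (dof * KB_HARTREE)


def vv_step(state: MDState, force_fn, dt_fs: float) -> MDState:
    """One velocity-Verlet step; deterministic, time-reversible.

    ``force_fn(positions) -> (E, gradient)``; forces are the negative
    gradient.  The force at the end of the step is cached on the state.
    """
    if dt_fs <= 0:
        raise ValueError("time step must be positive")
    dt = dt_fs * FS_TO_AUT
    m = state.masses[:, None]
    if state.forces is None:
        e, g = force_fn(state.positions)
        state.forces = -np.asarray(g)
        state.potential = e
    v_half = state.velocities + 0.5 * dt * state.forces / m
    x_new = state.positions + dt * v_half
    e, g = force_fn(x_new)
    f_new = -np.asarray(g)
    v_new = v_half + 0.5 * dt * f_new / m
    return MDState(
        positions=x_new, velocities=v_new, masses=state.masses,
        step=state.step + 1, time_fs=state.time_fs + dt_fs,
        forces=f_new, potential=e,
    )


def quench(positions, force_fn, n_steps: int = 200, max_step: float = 0.1):
    """Crude steepest-descent relaxation (droplet setup before dynamics).

    Moves along the normalized force with a capped step length (bohr);
    accepts only energy-lowering moves, halving the step on rejection.
    """
    pos = np.asarray(positions, dtype=float).copy()
    e, g = force_fn(pos)
    step = max_step
    for _ in range(n_steps):
        f = -np.asarray(g)
        fmax = float(np.max(np.abs(f)))
        if fmax < 1e-8:
            break
        trial = pos + f * (step / fmax)
        e_t, g_t = force_fn(trial)
        if e_t < e:
            pos, e, g = trial, e_t, g_t
            step = min(step * 1.2, max_step)
        else:
            step *= 0.5
            if step < 1e-6:
                break
    return pos


@dataclass
class ThermostatSettings:
    kind: str = "none"          # none | langevin
    T: float = 300.0            # K
    friction: float = 0.01      # fs^-1
    seed: int = 0

    def __post_init__(self):
        if self.T < 0:
            raise ValueError("temperature must be >= 0")
        if self.kind not in ("none", "langevin"):
            raise ValueError(f"unknown thermostat {self.kind!r}")


def _baoab_step(state: MDState, force_fn, dt_fs, gamma_fs, T, rng) -> MDState:
    dt = dt_fs * FS_TO_AUT
    gamma = gamma_fs / FS_TO_AUT  # fs^-1 -> a.u.^-1
    m = state.masses[:, None]
    if state.forces is None:
        e, g = force_fn(state.positions)
        state.forces = -np.asarray(g)
        state.potential = e
    v = state.velocities + 0.5 * dt * state.forces / m
    x = state.positions + 0.5 * dt * v
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(1.0 - c1 * c1, 0.0))
    sigma = np.sqrt(KB_HARTREE * T / m)
    v = c1 * v + c2 * sigma * rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    e, g = force_fn(x)
    f = -np.asarray(g)
    v = v + 0.5 * dt * f / m
    return MDState(
        positions=x, velocities=v, masses=state.masses,
        step=state.step + 1, time_fs=state.time_fs + dt_fs,
        forces=f, potential=e,
    )


@dataclass
class Trajectory:
    frames: list = field(default_factory=list)      # positions per saved frame
    energies: list = field(default_factory=list)    # dicts per step

    def as_arrays(self):
        return np.array(self.frames), self.energies


def run_md(state: MDState, force_fn, n_steps: int, dt_fs: float = 1.0,
           thermostat: ThermostatSettings | None = None,
           save_every: int = 1, max_force: float = 10.0,
           callback=None) -> tuple[MDState, Trajectory]:
    """Propagate n_steps of dynamics; deterministic under a fixed seed.

    Divergent forces (|F| component above ``max_force`` hartree/bohr) abort
    with the offending frame attached to the exception.
    """
    thermostat = thermostat or ThermostatSettings()
    rng = np.random.default_rng(thermostat.seed)
    traj = Trajectory()
    for _ in range(n_steps):
        if thermostat.kind == "langevin":
            state = _baoab_step(
                state, force_fn, dt_fs, thermostat.friction, thermostat.T, rng
            )
        else:
            state = vv_step(state, force_fn, dt_fs)
        fmax = float(np.max(np.abs(state.forces)))
        if fmax > max_force:
            exc = RuntimeError(
                f"divergent forces at step {state.step}: |F|max = {fmax:.3e}"
            )
            exc.frame = state.positions.copy()
            raise exc
        if state.step % save_every == 0:
            traj.frames.append(state.positions.copy())
            traj.energies.append(
                {
                    "step": state.step,
                    "potential": state.potential,
                    "kinetic": state.kinetic_energy,
                    "temperature": state.temperature(),
                }
            )
        if callback is not None:
            callback(state)
    return state, traj


# ---------------------------------------------------------------------------
# dual-topology mixing and FEP
# ---------------------------------------------------------------------------

@dataclass
class DualTopology:
    """Linear alchemical mixture of two full-system evaluators.

    ``engine_A``/``engine_B``: callables positions -> (E, gradient) over the
    same coordinates (both endpoint topologies coexist); lambda = 1 is pure
    state A.
    """

    engine_A: object
    engine_B: object
    lam: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.lam <= 1.0):
            raise ValueError("lambda must lie in [0, 1]")

    def __call__(self, positions):
        ea, ga = self.engine_A(positions)
        eb, gb = self.engine_B(positions)
        lam = self.lam
        return (
            mixed_hamiltonian(lam, ea, eb),
            lam * np.asarray(ga) + (1.0 - lam) * np.asarray(gb),
        )


def mixed_hamiltonian(lam: float, E_A, E_B):
    """H(lambda) = lambda H_A + (1 - lambda) H_B."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError("lambda must lie in [0, 1]")
    return lam * E_A + (1.0 - lam) * E_B


@dataclass
class FEPEstimate:
    window_dF: np.ndarray       # hartree, per window
    window_se: np.ndarray
    direction: str

    @property
    def total(self) -> float:
        return float(np.sum(self.window_dF))

    @property
    def total_se(self) -> float:
        return float(np.sqrt(np.sum(self.window_se ** 2)))

    def total_kcal(self):
        from .units import HARTREE_TO_KCALMOL

        return self.total * HARTREE_TO_KCALMOL, self.total_se * HARTREE_TO_KCALMOL


def fep_estimate(window_samples, kT: float, direction: str = "forward",
                 n_blocks: int = 3) -> FEPEstimate:
    """Exponential-averaging free energy from per-window Delta-U samples.

    ``window_samples``: list of arrays of Delta U = U_next - U_current
    (hartree) sampled in each window; Delta F_w = -kT ln <exp(-Delta U/kT)>.
    Standard errors by block averaging (default three blocks).
    """
    if len(window_samples) < 1:
        raise ValueError("need at least one window of samples")
    dF = np.empty(len(window_samples))
    se = np.empty(len(window_samples))
    for w, du in enumerate(window_samples):
        du = np.asarray(du, dtype=float)
        if du.size == 0:
            raise ValueError(f"window {w} has no samples")
        dF[w] = _exp_avg(du, kT)
        blocks = np.array_split(du, n_blocks)
        vals = np.array([_exp_avg(b, kT) for b in blocks if b.size])
        se[w] = (
            float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
            if len(vals) > 1 else 0.0
        )
    return FEPEstimate(window_dF=dF, window_se=se, direction=direction)


def _exp_avg(du, kT):
    # log-sum-exp for numerical safety
    a = -du / kT
    amax = float(np.max(a))
    return -kT * (amax + math.log(float(np.mean(np.exp(a - amax)))))


# ---------------------------------------------------------------------------
# Hamiltonian replica exchange
# ---------------------------------------------------------------------------

@dataclass
class Replica:
    config: object              # instantaneous configuration q
    parameter: float            # lambda (or any ladder parameter)
    potential: object           # callable U(q) for this replica's Hamiltonian


@dataclass
class ReplicaSet:
    """Replicas ordered along the parameter ladder, plus the exchange log."""

    replicas: list
    phase: int = 0              # alternates 0 (odd<->even) / 1 (even<->odd)
    attempts: np.ndarray | None = None
    accepts: np.ndarray | None = None

    def __post_init__(self):
        params = [r.parameter for r in self.replicas]
        if sorted(params) != params and sorted(params, reverse=True) != params:
            raise ValueError(
                "replicas must be sorted so nearest neighbors have the "
                "smallest parameter differences"
            )
        n = len(self.replicas)
        if self.attempts is None:
            self.attempts = np.zeros(max(n - 1, 0), dtype=int)
        if self.accepts is None:
            self.accepts = np.zeros(max(n - 1, 0), dtype=int)

    @property
    def acceptance_rates(self):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.attempts > 0, self.accepts / self.attempts, np.nan)


def hremd_attempt(replicas: ReplicaSet, beta: float, rng) -> ReplicaSet:
    """One sweep of nearest-neighbor exchange attempts.

    The schedule alternates: first 1<->2, 3<->4, ... then 2<->3, 4<->5, ...
    On acceptance the instantaneous configurations are swapped.  The
    Metropolis exponent includes beta = 1/kT (energies in physical units).
    """
    n = len(replicas.replicas)
    if n < 2:
        raise ValueError("replica exchange needs at least two replicas")
    start = 0 if replicas.phase == 0 else 1
    for i in range(start, n - 1, 2):
        ri, rj = replicas.replicas[i], replicas.replicas[i + 1]
        delta = (
            ri.potential(rj.config) + rj.potential(ri.config)
            - ri.potential(ri.config) - rj.potential(rj.config)
        )
        replicas.attempts[i] += 1
        p_acc = 1.0 if beta * delta <= 0 else math.exp(-beta * delta)
        if rng.random() < p_acc:
            ri.config, rj.config = rj.config, ri.config
            replicas.accepts[i] += 1
    replicas.phase = 1 - replicas.phase
    return replicas
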
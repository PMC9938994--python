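"""DPD equations of motion: forces, integrators/thermostats, observables.

Everything is in reduced DPD units: cutoff length 1, bead mass 1, and one
energy unit = k_B · 300 K (see :mod:`mesodpd.parameters`).  Newton's
equations are driven by three pairwise contributions — soft conservative
repulsion a_ij (1 − r) ê for r < 1 plus harmonic bonds, pairwise friction
−γ ω^D(r) (ê·v_ij) ê and pairwise noise σ ω^R(r) ζ Δt^{-1/2} ê — with
γ = σ² / (2 k_BT) and ω^D = (ω^R)² = (1 − r)², so that the dissipative and
random forces together act as a momentum-conserving thermostat.

Four integration schemes are provided:

``gwmvv``
    Groot–Warren modified velocity-Verlet with prediction weight λ; at
    λ = 0.5 and σ = 0 it degenerates to plain velocity-Verlet.
``scmvv`` / ``dpdmvv``
    Self-consistent scheme: the dissipative force is re-evaluated against
    the updated velocities ``n_iter`` times inside the velocity update;
    a single iteration is the DPDMVV variant.
``s1mvv``
    Shardlow's S1 splitting: a pairwise exact (semi-implicit) sweep of the
    dissipative + random dynamics composed with a velocity-Verlet
    conservative step.
``pnhln``
    Pairwise Nosé–Hoover–Langevin thermostat with an auxiliary friction
    variable ξ driven by negative feedback toward the kinetic set point
    (coupling parameter μ, thermal mass of ξ).

Boundaries are either fully periodic or periodic in x/y with specular
reflective walls in z; the latter biases lamellae to form perpendicular
to z and is the configuration used for bilayer-formation runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .chem import ParticleSet
from .parameters import TemperatureConvention, dpd_to_kelvin, kelvin_to_dpd

__all__ = [
    "BoxSpec",
    "BoxState",
    "SimulationConfig",
    "ObservableRecord",
    "SimulationResult",
    "SimulationDiverged",
    "conservative_forces",
    "thermostat_pair_terms",
    "apply_boundaries",
    "observables",
    "run_simulation",
    "step_gwmvv",
    "step_scmvv",
    "step_s1mvv",
    "step_pnhln",
    "thermal_velocities",
]

INTEGRATORS = ("gwmvv", "scmvv", "dpdmvv", "s1mvv", "pnhln")


class SimulationDiverged(RuntimeError):
    """A bead left the box by more than one box length in a single step,
    or the state became non-finite."""


@dataclass(frozen=True)
class BoxSpec:
    """Simulation box: edge lengths in DPD units and the boundary mode."""

    lengths: tuple[float, float, float]
    boundary_mode: str = "periodic_xyz"

    def __post_init__(self) -> None:
        if self.boundary_mode not in ("periodic_xyz", "periodic_xy_reflective_z"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")
        for L in self.lengths:
            if not (L > 0):
                raise ValueError("box lengths must be > 0")
            if L < 3.0:
                raise ValueError(
                    f"box length {L} < 3 cutoff lengths (cell-list constraint)"
                )

    @property
    def periodic_z(self) -> bool:
        return self.boundary_mode == "periodic_xyz"

    @property
    def volume(self) -> float:
        lx, ly, lz = self.lengths
        return lx * ly * lz

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.lengths, dtype=float)


@dataclass
class BoxState:
    """Positions/velocities/types/bonds of all beads in a box.

    ``bonds`` lists each bonded pair once as 0-based (i, j), i < j.
    ``type_names`` maps type ids back to particle tokens.
    """

    positions: np.ndarray
    velocities: np.ndarray
    type_ids: np.ndarray
    molecule_ids: np.ndarray
    bonds: np.ndarray
    box: BoxSpec
    type_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        self.type_ids = np.ascontiguousarray(self.type_ids, dtype=np.int64)
        self.molecule_ids = np.ascontiguousarray(self.molecule_ids, dtype=np.int64)
        self.bonds = np.ascontiguousarray(
            np.asarray(self.bonds, dtype=np.int64).reshape(-1, 2))

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "BoxState":
        return BoxState(self.positions.copy(), self.velocities.copy(),
                        self.type_ids.copy(), self.molecule_ids.copy(),
                        self.bonds.copy(), self.box, list(self.type_names))


@dataclass
class SimulationConfig:
    """All physical and numerical settings of one run.

    Defaults follow common DPD practice: density ρ = 3, noise amplitude
    σ = 3, bond spring k = 4, bond length 1, bead mass 1.  ``integrator``
    is one of ``gwmvv``/``scmvv``/``dpdmvv``/``s1mvv``/``pnhln``;
    ``integrator_param`` carries λ (gwmvv, default 0.65), the number of
    self-consistent iterations (scmvv, default 1 = dpdmvv), or the PNHLN
    coupling μ (default 500).
    """

    temperature: float = 298.0
    rho: float = 3.0
    sigma: float = 3.0
    k_bond: float = 4.0
    r_bond: float = 1.0
    dt: float = 0.04
    n_steps: int = 1000
    integrator: str = "s1mvv"
    integrator_param: float | None = None
    seed: int = 0
    sample_interval: int = 100
    convention: TemperatureConvention = field(default_factory=TemperatureConvention)

    def __post_init__(self) -> None:
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.integrator not in INTEGRATORS:
            raise ValueError(
                f"unknown integrator {self.integrator!r}; choose from {INTEGRATORS}")
        if self.sample_interval < 1:
            raise ValueError("sample_interval must be >= 1")

    @property
    def kbt(self) -> float:
        return kelvin_to_dpd(self.temperature, self.convention)

    @property
    def gamma(self) -> float:
        """Friction is never an independent input: γ = σ²/(2 k_BT)."""
        return self.sigma ** 2 / (2.0 * self.kbt)


@dataclass(frozen=True)
class ObservableRecord:
    step: int
    t_dpd: float
    t_kelvin: float
    e_pot_dpd: float
    e_pot_bond: float
    px: float
    py: float
    pz: float
    pxx: float
    pyy: float
    pzz: float
    surface_tension_z: float


@dataclass
class SimulationResult:
    frames: list[np.ndarray]
    frame_steps: list[int]
    records: list[ObservableRecord]
    final_state: BoxState

    def observables_frame(self):
        import pandas as pd

        return pd.DataFrame([r.__dict__ for r in self.records])


def thermal_velocities(n: int, kbt: float, seed: int) -> np.ndarray:
    """Maxwell–Boltzmann velocities (mass 1) with the net momentum removed."""
    rng = np.random.default_rng(seed)
    v = rng.normal(0.0, math.sqrt(kbt), size=(n, 3))
    v -= v.mean(axis=0, keepdims=True)
    return v


# ---------------------------------------------------------------------------
# pair bookkeeping
# ---------------------------------------------------------------------------

def _build_pairs(pos, box_arr, pbc_z, cap_hint):
    cap = cap_hint
    while True:
        pi = np.empty(cap, dtype=np.int64)
        pj = np.empty(cap, dtype=np.int64)
        count = K.build_pairs_cells(pos, box_arr, pbc_z, pi, pj)
        if count <= cap:
            return pi[:count], pj[:count], cap
        cap = 2 * count


class _Context:
    """Mutable per-run arrays plus cached forces between steps."""

    def __init__(self, config: SimulationConfig, state: BoxState,
                 pset: ParticleSet):
        self.config = config
        self.pos = state.positions.copy()
        self.vel = state.velocities.copy()
        self.tid = state.type_ids.copy()
        self.bonds = state.bonds
        self.bi = np.ascontiguousarray(self.bonds[:, 0])
        self.bj = np.ascontiguousarray(self.bonds[:, 1])
        self.box_arr = state.box.array
        self.pbc_z = state.box.periodic_z
        self.boxspec = state.box
        self.amat = np.ascontiguousarray(pset.repulsion)
        self.kbt = config.kbt
        self.gamma = config.gamma
        self.sigma = config.sigma
        self.dt = config.dt
        self.seed = np.uint64(config.seed & 0x7FFFFFFF)
        self.cap = max(256, 16 * self.pos.shape[0])
        self._pbuf_i = np.empty(self.cap, dtype=np.int64)
        self._pbuf_j = np.empty(self.cap, dtype=np.int64)
        self.step_index = 0
        self.xi = config.gamma  # PNHLN auxiliary friction, started at γ
        self.f_prev: np.ndarray | None = None
        self.e_dpd = 0.0
        self.e_bond = 0.0
        self.virial = np.zeros(3)
        self.n_overlap = 0

    def pairs(self):
        while True:
            count = K.build_pairs_cells(self.pos, self.box_arr, self.pbc_z,
                                        self._pbuf_i, self._pbuf_j)
            if count <= self.cap:
                return self._pbuf_i[:count], self._pbuf_j[:count]
            self.cap = 2 * count
            self._pbuf_i = np.empty(self.cap, dtype=np.int64)
            self._pbuf_j = np.empty(self.cap, dtype=np.int64)

    def key(self, lane: int = 0) -> np.uint64:
        return np.uint64(K.derive_step_key(
            self.seed, np.uint64(2 * self.step_index + lane)))

    def conservative(self, pi, pj):
        f = np.zeros_like(self.pos)
        virial = np.zeros(3)
        e_dpd, e_bond, n_ov = K.conservative_forces(
            self.pos, self.box_arr, self.pbc_z, self.tid, self.amat,
            self.bi, self.bj, self.config.k_bond, self.config.r_bond,
            pi, pj, f, virial)
        self.e_dpd, self.e_bond, self.virial = e_dpd, e_bond, virial
        self.n_overlap += n_ov
        return f

    def apply_boundaries(self):
        worst = K.apply_boundaries_kernel(self.pos, self.vel, self.box_arr,
                                          self.pbc_z)
        if worst > 1.0:
            raise SimulationDiverged(
                f"bead left the box by {worst:.2f} box lengths at step "
                f"{self.step_index}; reduce dt or check the configuration")


# ---------------------------------------------------------------------------
# integrator steps (operate on a context)
# ---------------------------------------------------------------------------

def _total_force_mvv(ctx: _Context, pi, pj, v_for_diss, key) -> np.ndarray:
    f = ctx.conservative(pi, pj)
    K.random_forces(ctx.pos, ctx.box_arr, ctx.pbc_z, pi, pj, ctx.sigma,
                    ctx.dt, key, f)
    K.dissipative_forces(ctx.pos, v_for_diss, ctx.box_arr, ctx.pbc_z, pi, pj,
                         ctx.gamma, f)
    return f


def _step_gwmvv(ctx: _Context, lam: float) -> None:
    dt = ctx.dt
    if ctx.f_prev is None:
        pi, pj = ctx.pairs()
        ctx.f_prev = _total_force_mvv(ctx, pi, pj, ctx.vel, ctx.key(0))
    v_pred = ctx.vel + lam * dt * ctx.f_prev
    v_half = ctx.vel + 0.5 * dt * ctx.f_prev
    ctx.pos += dt * v_half
    ctx.vel = v_half  # so wall reflections flip the half-kicked velocity
    ctx.apply_boundaries()
    pi, pj = ctx.pairs()
    f_new = _total_force_mvv(ctx, pi, pj, v_pred, ctx.key(1))
    ctx.vel = ctx.vel + 0.5 * dt * f_new
    ctx.f_prev = f_new


def _step_scmvv(ctx: _Context, n_iter: int) -> None:
    dt = ctx.dt
    if ctx.f_prev is None:
        pi, pj = ctx.pairs()
        ctx.f_prev = _total_force_mvv(ctx, pi, pj, ctx.vel, ctx.key(0))
    v_half = ctx.vel + 0.5 * dt * ctx.f_prev
    ctx.pos += dt * v_half
    ctx.vel = v_half
    ctx.apply_boundaries()
    v_half = ctx.vel
    pi, pj = ctx.pairs()
    f_cr = ctx.conservative(pi, pj)
    K.random_forces(ctx.pos, ctx.box_arr, ctx.pbc_z, pi, pj, ctx.sigma,
                    ctx.dt, ctx.key(1), f_cr)
    v_guess = v_half
    f_d = np.zeros_like(ctx.pos)
    for _ in range(max(1, n_iter)):
        f_d = np.zeros_like(ctx.pos)
        K.dissipative_forces(ctx.pos, v_guess, ctx.box_arr, ctx.pbc_z,
                             pi, pj, ctx.gamma, f_d)
        v_guess = v_half + 0.5 * dt * (f_cr + f_d)
    ctx.vel = v_guess
    ctx.f_prev = f_cr + f_d


def _vv_conservative(ctx: _Context) -> None:
    dt = ctx.dt
    if ctx.f_prev is None:
        pi, pj = ctx.pairs()
        ctx.f_prev = ctx.conservative(pi, pj)
    v_half = ctx.vel + 0.5 * dt * ctx.f_prev
    ctx.pos += dt * v_half
    ctx.vel = v_half
    ctx.apply_boundaries()
    pi, pj = ctx.pairs()
    f_new = ctx.conservative(pi, pj)
    ctx.vel = ctx.vel + 0.5 * dt * f_new
    ctx.f_prev = f_new


def _step_s1mvv(ctx: _Context) -> None:
    pi, pj = ctx.pairs()
    pi, pj = K.sort_pairs(pi, pj, ctx.pos.shape[0])
    K.shardlow_sweep(ctx.pos, ctx.vel, ctx.box_arr, ctx.pbc_z, pi, pj,
                     ctx.gamma, ctx.sigma, ctx.dt, ctx.key(0))
    _vv_conservative(ctx)


def _step_pnhln(ctx: _Context, coupling: float) -> None:
    pi, pj = ctx.pairs()
    pi, pj = K.sort_pairs(pi, pj, ctx.pos.shape[0])
    G = K.pnhln_sweep(ctx.pos, ctx.vel, ctx.box_arr, ctx.pbc_z, pi, pj,
                      ctx.xi, ctx.sigma, ctx.dt, ctx.kbt, ctx.key(0))
    ctx.xi += ctx.dt * G / coupling
    # Langevin piece: OU relaxation of ξ toward γ = σ²/(2k_BT) at the
    # vanishing rate 1/μ² with stationary spread sqrt(k_BT/μ) — ergodicity
    # noise only; the integral feedback term sets the working point, so at
    # stationarity E[G] ≈ 0 and the pair kinetic level sits on the set point
    c = math.exp(-ctx.dt / coupling ** 2)
    eta = K.scalar_normal(ctx.key(1), np.int64(0))
    ctx.xi = (ctx.gamma + c * (ctx.xi - ctx.gamma)
              + math.sqrt(ctx.kbt * (1.0 - c * c) / coupling) * eta)
    _vv_conservative(ctx)


def _advance(ctx: _Context) -> None:
    cfg = ctx.config
    if cfg.integrator == "gwmvv":
        lam = 0.65 if cfg.integrator_param is None else float(cfg.integrator_param)
        if not (0.0 < lam <= 1.0):
            raise ValueError("gwmvv lambda must be in (0, 1]")
        _step_gwmvv(ctx, lam)
    elif cfg.integrator in ("scmvv", "dpdmvv"):
        n_iter = 1 if cfg.integrator_param is None else int(cfg.integrator_param)
        if cfg.integrator == "dpdmvv":
            n_iter = 1
        if n_iter < 1:
            raise ValueError("scmvv needs n_iter >= 1")
        _step_scmvv(ctx, n_iter)
    elif cfg.integrator == "s1mvv":
        _step_s1mvv(ctx)
    else:
        mu = 500.0 if cfg.integrator_param is None else float(cfg.integrator_param)
        if not (mu > 0):
            raise ValueError("pnhln coupling must be > 0")
        _step_pnhln(ctx, mu)
    ctx.step_index += 1


# -- public single-step wrappers (used by unit tests and small studies) -----

def _run_steps(state: BoxState, config: SimulationConfig, pset: ParticleSet,
               n: int) -> BoxState:
    ctx = _Context(config, state, pset)
    for _ in range(n):
        _advance(ctx)
    return BoxState(ctx.pos, ctx.vel, ctx.tid, state.molecule_ids.copy(),
                    state.bonds.copy(), state.box, list(state.type_names))


def step_gwmvv(state, config, lam: float, pset, n_steps: int = 1) -> BoxState:
    cfg = _with(config, integrator="gwmvv", integrator_param=lam)
    return _run_steps(state, cfg, pset, n_steps)


def step_scmvv(state, config, n_iter: int, pset, n_steps: int = 1) -> BoxState:
    cfg = _with(config, integrator="scmvv", integrator_param=n_iter)
    return _run_steps(state, cfg, pset, n_steps)


def step_s1mvv(state, config, pset, n_steps: int = 1) -> BoxState:
    cfg = _with(config, integrator="s1mvv")
    return _run_steps(state, cfg, pset, n_steps)


def step_pnhln(state, config, coupling: float, pset, n_steps: int = 1) -> BoxState:
    cfg = _with(config, integrator="pnhln", integrator_param=coupling)
    return _run_steps(state, cfg, pset, n_steps)


def _with(config: SimulationConfig, **kw) -> SimulationConfig:
    from dataclasses import replace

    return replace(config, **kw)


# ---------------------------------------------------------------------------
# standalone force/boundary/observable operations
# ---------------------------------------------------------------------------

def conservative_forces(state: BoxState, pset: ParticleSet,
                        k_bond: float = 4.0, r_bond: float = 1.0,
                        method: str = "cells"):
    """Per-bead conservative forces plus (e_pot_dpd, e_pot_bond).

    ``method`` selects the neighbor search: ``"cells"`` (default) or
    ``"all_pairs"`` (O(N²) oracle; identical result).
    """
    pos = state.positions
    box_arr = state.box.array
    pbc_z = state.box.periodic_z
    if method == "all_pairs":
        pi, pj = K.build_pairs_all(pos, box_arr, pbc_z)
    else:
        pi, pj, _ = _build_pairs(pos, box_arr, pbc_z, max(256, 16 * len(pos)))
    pi, pj = K.sort_pairs(pi, pj)
    f = np.zeros_like(pos)
    virial = np.zeros(3)
    e_dpd, e_bond, n_ov = K.conservative_forces(
        pos, box_arr, pbc_z, state.type_ids, np.ascontiguousarray(pset.repulsion),
        np.ascontiguousarray(state.bonds[:, 0]),
        np.ascontiguousarray(state.bonds[:, 1]),
        k_bond, r_bond, pi, pj, f, virial)
    if n_ov:
        import warnings

        warnings.warn(f"{n_ov} coincident bead pair(s): deterministic "
                      "fallback force direction used", stacklevel=2)
    return f, e_dpd, e_bond, virial


def thermostat_pair_terms(state: BoxState, sigma: float, dt: float,
                          T: float, seed: int, step: int = 0,
                          convention: TemperatureConvention | None = None):
    """Per-bead sums of the dissipative and random pair forces.

    γ is derived internally as σ²/(2 k_BT); the random force carries the
    Δt^{-1/2} scaling and a symmetric per-pair draw ζ_ij = ζ_ji.
    """
    kbt = kelvin_to_dpd(T, convention)
    gamma = sigma ** 2 / (2.0 * kbt)
    pos = state.positions
    box_arr = state.box.array
    pbc_z = state.box.periodic_z
    pi, pj, _ = _build_pairs(pos, box_arr, pbc_z, max(256, 16 * len(pos)))
    f_d = np.zeros_like(pos)
    f_r = np.zeros_like(pos)
    K.dissipative_forces(pos, state.velocities, box_arr, pbc_z, pi, pj,
                         gamma, f_d)
    key = np.uint64(K.derive_step_key(np.uint64(seed & 0x7FFFFFFF),
                                      np.uint64(step)))
    K.random_forces(pos, box_arr, pbc_z, pi, pj, sigma, dt, key, f_r)
    return f_d, f_r


def apply_boundaries(state: BoxState) -> BoxState:
    """Wrap periodic coordinates into [0, L); fold and v_z-flip at z walls."""
    out = state.copy()
    K.apply_boundaries_kernel(out.positions, out.velocities, out.box.array,
                              out.box.periodic_z)
    return out


def observables(state: BoxState, pset: ParticleSet,
                config: SimulationConfig, step: int = 0) -> ObservableRecord:
    """Kinetic temperature, energies, momentum, pressure diagonal and the
    instantaneous z surface tension γ_z = Lz (Pzz − (Pxx + Pyy)/2).

    The pressure tensor combines the kinetic term with the conservative
    pair virial (DPD + bond forces) at the current configuration.
    """
    _, e_dpd, e_bond, virial = conservative_forces(
        state, pset, config.k_bond, config.r_bond)
    return _record(state, config, step, e_dpd, e_bond, virial)


def _record(state_or_ctx, config, step, e_dpd, e_bond, virial) -> ObservableRecord:
    if isinstance(state_or_ctx, BoxState):
        vel = state_or_ctx.velocities
        vol = state_or_ctx.box.volume
        lz = state_or_ctx.box.lengths[2]
    else:
        vel = state_or_ctx.vel
        vol = state_or_ctx.boxspec.volume
        lz = state_or_ctx.boxspec.lengths[2]
    n = vel.shape[0]
    ke_diag = (vel ** 2).sum(axis=0)
    t_dpd = ke_diag.sum() / (3.0 * n)
    p_diag = (ke_diag + virial) / vol
    gamma_z = lz * (p_diag[2] - 0.5 * (p_diag[0] + p_diag[1]))
    mom = vel.sum(axis=0)
    return ObservableRecord(
        step=step, t_dpd=float(t_dpd),
        t_kelvin=float(dpd_to_kelvin(t_dpd, config.convention)),
        e_pot_dpd=float(e_dpd), e_pot_bond=float(e_bond),
        px=float(mom[0]), py=float(mom[1]), pz=float(mom[2]),
        pxx=float(p_diag[0]), pyy=float(p_diag[1]), pzz=float(p_diag[2]),
        surface_tension_z=float(gamma_z))


def run_simulation(config: SimulationConfig, state: BoxState,
                   pset: ParticleSet, store_frames: bool = True,
                   progress: bool = False) -> SimulationResult:
    """Advance ``config.n_steps`` steps, sampling observables (and frames)
    every ``config.sample_interval`` steps.

    Exactly ``n_steps // sample_interval`` records are produced; identical
    (config, state, seed) yield identical outputs.  Non-finite coordinates
    abort with :class:`SimulationDiverged`.
    """
    ctx = _Context(config, state, pset)
    frames: list[np.ndarray] = []
    frame_steps: list[int] = []
    records: list[ObservableRecord] = []
    for s in range(config.n_steps):
        _advance(ctx)
        done = s + 1
        if done % config.sample_interval == 0:
            if not np.isfinite(ctx.pos).all() or not np.isfinite(ctx.vel).all():
                raise SimulationDiverged(
                    f"non-finite state at step {done}; partial outputs kept")
            rec = _record(ctx, config, done, ctx.e_dpd, ctx.e_bond, ctx.virial)
            records.append(rec)
            if store_frames:
                frames.append(ctx.pos.copy())
                frame_steps.append(done)
            if progress:
                print(f"step {done:>8d}  T = {rec.t_kelvin:7.2f} K  "
                      f"E_dpd = {rec.e_pot_dpd:12.2f}  "
                      f"E_bond = {rec.e_pot_bond:10.2f}  "
                      f"gamma_z = {rec.surface_tension_z:8.3f}")
    final = BoxState(ctx.pos, ctx.vel, ctx.tid, state.molecule_ids.copy(),
                     state.bonds.copy(), state.box, list(state.type_names))
    return SimulationResult(frames=frames, frame_steps=frame_steps,
                            records=records, final_state=final)
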
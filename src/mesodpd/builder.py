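"""Build simulation boxes: composition mapping, start geometries, minimization.

The mapping from a binary mass-fraction composition to molecule numbers in
the box is *volume scaled*: species are weighted by their physical fragment
volumes, not by molar mass alone.  With physical mole numbers
n_k ∝ w_k / M_k (true molecular molar masses) and molecular volumes V_k
(sum of the fragment volumes), the bead-count share of species k in the box
is matched to its physical volume fraction, which gives molecule counts

    N_k ∝ n_k · V_k / (beads per molecule of k).

Neglecting volume scaling (``volume_scaling=False``) falls back to the plain
molar-ratio counts N_k ∝ n_k, which over-represents the smallest particles
(water) and shifts the effective phase-diagram position of the mixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .chem import (MoleculeSpec, ParticleSet, ValidationError, molecule_volume,
                   physical_molar_mass, resolve_types)
from .engine import BoxSpec, BoxState, thermal_velocities
from .parameters import kelvin_to_dpd

__all__ = [
    "Composition",
    "volume_scaled_counts",
    "random_start",
    "layered_start",
    "minimize",
]


@dataclass
class Composition:
    """Mixture entries as (molecule, mass fraction) at a temperature."""

    entries: list[tuple[MoleculeSpec, float]]
    temperature: float = 298.0

    def __post_init__(self) -> None:
        fracs = [w for _, w in self.entries]
        if not fracs:
            raise ValidationError("composition has no entries")
        for (mol, w) in self.entries:
            if not (0.0 < w <= 1.0):
                raise ValidationError(
                    f"mass fraction {w} of {mol.name!r} outside (0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValidationError(
                f"mass fractions sum to {sum(fracs)!r}, expected 1")


def volume_scaled_counts(composition: Composition, n_reference: int,
                         pset: ParticleSet,
                         volume_scaling: bool = True) -> dict[str, int]:
    """Molecule counts realizing the composition, scaled to ``n_reference``
    molecules of the first entry.

    With volume scaling (default) the counts realize the physical volume
    fractions of the species; without it they are plain molar ratios.
    Counts are rounded to the nearest integer (the reference entry stays
    exact); the residual is absorbed by the non-reference species.
    """
    if n_reference <= 0:
        raise ValueError("n_reference must be > 0")
    weights = []
    for mol, w in composition.entries:
        m = physical_molar_mass(mol, pset)
        moles = w / m
        if volume_scaling:
            v_mol = molecule_volume(mol, pset)  # raises on unknown token
            weights.append(moles * v_mol / mol.n_beads)
        else:
            weights.append(moles)
    ref = weights[0]
    counts: dict[str, int] = {}
    for (mol, _), wt in zip(composition.entries, weights):
        if mol is composition.entries[0][0]:
            counts[mol.name] = int(n_reference)
        else:
            counts[mol.name] = int(round(n_reference * wt / ref))
    return counts


def _total_beads(counts: dict[str, int],
                 molecules: list[MoleculeSpec]) -> int:
    by_name = {m.name: m for m in molecules}
    return sum(n * by_name[name].n_beads for name, n in counts.items())


def _assemble(placed, pset, box, temperature, seed):
    """Stack per-molecule placements into a BoxState with thermal velocities."""
    pos = np.concatenate([p for p, _m in placed])
    tids = np.concatenate([resolve_types(m, pset) for _p, m in placed])
    mol_ids = np.concatenate([
        np.full(m.n_beads, k, dtype=np.int64)
        for k, (_p, m) in enumerate(placed)])
    bonds = []
    off = 0
    for _p, m in placed:
        for i, j in m.bonds:
            bonds.append((off + i, off + j))
        off += m.n_beads
    bonds_arr = (np.array(bonds, dtype=np.int64) if bonds
                 else np.empty((0, 2), dtype=np.int64))
    vel = thermal_velocities(pos.shape[0], kelvin_to_dpd(temperature),
                             seed=(seed ^ 0x5EED) & 0x7FFFFFFF)
    state = BoxState(pos, vel, tids.astype(np.int64), mol_ids, bonds_arr, box,
                     type_names=pset.names)
    from .engine import apply_boundaries

    return apply_boundaries(state)


def _check_density(counts, molecules, box: BoxSpec, rho: float) -> None:
    n = _total_beads(counts, molecules)
    target = rho * box.volume
    slack = max(max(m.n_beads for m in molecules), 0.01 * target)
    if abs(n - target) > slack:
        raise ValidationError(
            f"bead count {n} inconsistent with rho*V = {target:.1f} "
            f"for box {box.lengths} (slack {slack:.1f})")


def box_for_counts(counts: dict[str, int], molecules: list[MoleculeSpec],
                   rho: float = 3.0, aspect_z: float = 2.0,
                   boundary_mode: str = "periodic_xy_reflective_z") -> BoxSpec:
    """A box whose volume matches the bead count at density ``rho``,
    with Lz = aspect_z · Lx and Lx = Ly."""
    n = _total_beads(counts, molecules)
    v = n / rho
    lx = (v / aspect_z) ** (1.0 / 3.0)
    return BoxSpec((lx, lx, aspect_z * lx), boundary_mode=boundary_mode)


def random_start(counts: dict[str, int], box: BoxSpec, pset: ParticleSet,
                 molecules: list[MoleculeSpec], seed: int,
                 temperature: float = 298.0, rho: float = 3.0) -> BoxState:
    """Random-mixture start geometry: each molecule is grown as a random
    walk with unit (bond-length) steps from a uniform anchor.

    Identical seeds give bitwise-identical states.  Raises if the bead count
    is inconsistent with rho·V or the box cannot hold a molecule's extent.
    """
    _check_density(counts, molecules, box, rho)
    by_name = {m.name: m for m in molecules}
    longest = max(m.n_beads for m in molecules)
    if min(box.lengths) < math.sqrt(max(longest - 1, 1)):
        raise ValidationError(
            f"box {box.lengths} too small for a {longest}-bead molecule")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    L = box.array
    placed = []
    for name in counts:
        mol = by_name[name]
        nb = mol.n_beads
        for _ in range(counts[name]):
            p = np.empty((nb, 3))
            p[0] = rng.random(3) * L
            if nb > 1:
                steps = rng.normal(size=(nb - 1, 3))
                steps /= np.linalg.norm(steps, axis=1, keepdims=True)
                p[1:] = p[0] + np.cumsum(steps, axis=0)
            placed.append((p, mol))
    return _assemble(placed, pset, box, temperature, seed)


def layered_start(counts: dict[str, int], box: BoxSpec, n_layers: int,
                  pset: ParticleSet, molecules: list[MoleculeSpec], seed: int,
                  temperature: float = 298.0, rho: float = 3.0) -> BoxState:
    """Layered start geometry: surfactant chains stratified into ``n_layers``
    z-slabs (two opposing leaflets each, chain ends pointing outward) with
    water filling the space between slabs.

    Single-bead molecules are treated as solvent; multi-bead molecules as
    the layer-forming species.
    """
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    _check_density(counts, molecules, box, rho)
    by_name = {m.name: m for m in molecules}
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    lx, ly, lz = box.lengths
    surf_names = [n for n in counts if by_name[n].n_beads > 1]
    wat_names = [n for n in counts if by_name[n].n_beads == 1]
    n_surf_beads = sum(counts[n] * by_name[n].n_beads for n in surf_names)
    total_beads = _total_beads(counts, molecules)
    phi = n_surf_beads / total_beads
    slab_t = phi * lz / n_layers           # full slab (bilayer) thickness
    max_chain = max((by_name[n].n_beads for n in surf_names), default=1)
    if surf_names and slab_t / 2.0 < 0.10 * max(max_chain - 1, 1):
        raise ValidationError(
            f"slab thickness {slab_t:.2f} too small for a {max_chain}-bead "
            "chain; use fewer layers or a taller box")
    placed = []
    # surfactant slabs centred at (k + 1/2) Lz / n_layers
    for name in surf_names:
        mol = by_name[name]
        nb = mol.n_beads
        dz = (slab_t / 2.0) / nb
        n_mol = counts[name]
        for idx in range(n_mol):
            k = idx % n_layers
            center = (k + 0.5) * lz / n_layers
            up = (idx // n_layers) % 2 == 0   # leaflet
            x, y = rng.random(2) * np.array([lx, ly])
            p = np.empty((nb, 3))
            # chain runs tail(first beads)->head(last bead); heads at the
            # slab faces, tails meeting at the slab midplane
            for b in range(nb):
                depth = (b + 0.5) * dz            # head (last) at slab face
                z = center - depth if not up else center + depth
                p[b] = (x + 0.05 * rng.standard_normal(),
                        y + 0.05 * rng.standard_normal(), z)
            placed.append((p, mol))
    # water fills the complement of the slabs
    gaps = []
    for k in range(n_layers + 1):
        lo = 0.0 if k == 0 else (k - 0.5) * lz / n_layers + slab_t / 2.0
        hi = lz if k == n_layers else (k + 0.5) * lz / n_layers - slab_t / 2.0
        if hi > lo:
            gaps.append((lo, hi))
    widths = np.array([hi - lo for lo, hi in gaps])
    for name in wat_names:
        mol = by_name[name]
        n_mol = counts[name]
        per_gap = np.floor(widths / widths.sum() * n_mol).astype(int)
        per_gap[-1] += n_mol - per_gap.sum()
        for (lo, hi), ng in zip(gaps, per_gap):
            xy = rng.random((ng, 2)) * np.array([lx, ly])
            z = lo + rng.random(ng) * (hi - lo)
            for i in range(ng):
                placed.append((np.array([[xy[i, 0], xy[i, 1], z[i]]]), mol))
    return _assemble(placed, pset, box, temperature, seed)


def _fold_positions(pos: np.ndarray, box: BoxSpec) -> None:
    """Wrap/reflect coordinates without touching velocities."""
    L = box.array
    pos[:, 0] %= L[0]
    pos[:, 1] %= L[1]
    if box.periodic_z:
        pos[:, 2] %= L[2]
    else:
        z = pos[:, 2] % (2.0 * L[2])
        pos[:, 2] = np.where(z < L[2], z, 2.0 * L[2] - z)
        np.clip(pos[:, 2], 0.0, np.nextafter(L[2], 0.0), out=pos[:, 2])


def minimize(state: BoxState, pset: ParticleSet, n_steps: int,
             k_bond: float = 4.0, r_bond: float = 1.0,
             max_disp: float = 0.1) -> BoxState:
    """Energy minimization with "force steps": steepest descent along the
    conservative forces, per-step bead displacement capped at ``max_disp``
    cutoff lengths, with backtracking so the potential energy never
    increases across the call.  Velocities are untouched.
    """
    from . import _kernels as K
    from .engine import conservative_forces

    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    out = state.copy()
    if n_steps == 0:
        return out
    f, e_dpd, e_bond, _ = conservative_forces(out, pset, k_bond, r_bond)
    energy = e_dpd + e_bond
    step = max_disp
    for _ in range(n_steps):
        disp = f * step
        norms = np.linalg.norm(disp, axis=1)
        big = norms > max_disp
        if big.any():
            disp[big] *= (max_disp / norms[big])[:, None]
        trial = out.copy()
        trial.positions += disp
        _fold_positions(trial.positions, trial.box)
        f_t, e_dpd_t, e_bond_t, _ = conservative_forces(trial, pset, k_bond,
                                                        r_bond)
        e_t = e_dpd_t + e_bond_t
        if e_t <= energy:
            out, f, energy = trial, f_t, e_t
            step = min(step * 1.2, max_disp)
        else:
            step *= 0.5
            if step < 1e-6:
                break
    return out
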
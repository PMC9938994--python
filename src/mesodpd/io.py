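"""File round-tripping: XYZ trajectories, bond sidecars, observable CSVs,
YAML run configuration, HDF5 trajectories and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chem import ParticleSet
from .engine import (BoxSpec, BoxState, ObservableRecord, SimulationConfig,
                     SimulationResult)

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_bonds",
    "read_bonds",
    "write_observables",
    "read_observables",
    "write_hdf5_trajectory",
    "write_manifest",
    "load_run_config",
]


def write_xyz(path, frames, type_names_per_bead, comments=None) -> None:
    """Multi-frame XYZ; the element column carries the bead token."""
    path = Path(path)
    with path.open("w") as fh:
        for k, fr in enumerate(frames):
            fh.write(f"{fr.shape[0]}\n")
            fh.write((comments[k] if comments else f"frame {k}") + "\n")
            for tok, (x, y, z) in zip(type_names_per_bead, fr):
                fh.write(f"{tok} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path):
    """Returns (frames: list[(N,3) array], tokens: list[str], comments)."""
    frames, comments = [], []
    tokens: list[str] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        comments.append(lines[i + 1])
        block = lines[i + 2: i + 2 + n]
        toks = [ln.split()[0] for ln in block]
        coords = np.array([[float(v) for v in ln.split()[1:4]]
                           for ln in block])
        if not tokens:
            tokens = toks
        frames.append(coords)
        i += 2 + n
    return frames, tokens, comments


def write_bonds(path, bonds) -> None:
    """Bond sidecar: one 0-based 'i j' pair per line."""
    with Path(path).open("w") as fh:
        fh.write("# bonds: 0-based bead index pairs\n")
        for i, j in np.asarray(bonds).reshape(-1, 2):
            fh.write(f"{int(i)} {int(j)}\n")


def read_bonds(path) -> np.ndarray:
    rows = [ln.split() for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.startswith("#")]
    if not rows:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(rows, dtype=np.int64)


_OBS_COLUMNS = ["step", "t_dpd", "t_kelvin", "e_pot_dpd", "e_pot_bond",
                "px", "py", "pz", "pxx", "pyy", "pzz", "surface_tension_z"]


def write_observables(path, records) -> None:
    df = pd.DataFrame([r.__dict__ for r in records], columns=_OBS_COLUMNS)
    df.to_csv(path, index=False)


def read_observables(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_hdf5_trajectory(path, result: SimulationResult) -> None:
    """Optional binary container: positions per frame + final velocities."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("positions",
                          data=np.stack(result.frames) if result.frames
                          else np.empty((0, 0, 3)))
        h5.create_dataset("frame_steps", data=np.asarray(result.frame_steps))
        h5.create_dataset("final_velocities",
                          data=result.final_state.velocities)
        h5.create_dataset("type_ids", data=result.final_state.type_ids)


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_manifest(path, config: SimulationConfig | None, seed: int,
                   inputs=(), outputs=(), extra=None) -> None:
    """Run manifest: config snapshot, input digests, seed, version, clock."""
    from . import __version__

    doc = {
        "package": "mesodpd",
        "version": __version__,
        "seed": int(seed),
        "wall_clock": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {str(p): _digest(p) for p in inputs if Path(p).exists()},
        "outputs": [str(p) for p in outputs],
    }
    if config is not None:
        cfg = dict(config.__dict__)
        cfg["convention"] = config.convention.reference_kelvin
        doc["config"] = cfg
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_run_config(path):
    """Parse a YAML run configuration.

    Layout::

        system:
          particle_set: demo-range20        # demo-range<x> or a YAML path
          scheme: A                         # A | B | a spices string
          mass_fraction: 0.75
          n_surfactant: 150
          boundary: periodic_xy_reflective_z
          box: null                         # [Lx, Ly, Lz] or null (auto)
          morph: {source: Me2O, target: MeOH, percent: 20}   # optional
        simulation:
          integrator: s1mvv
          integrator_param: null
          dt: 0.04
          n_steps: 2000
          sample_interval: 100
          seed: 1
          temperature: 298.0

    Returns (SimulationConfig, BoxState, ParticleSet, raw_dict).
    """
    from .builder import Composition, box_for_counts, random_start, volume_scaled_counts
    from .chem import load_particle_set, parse_spices
    from .fixtures import (M_C10E4, M_H2O, demo_particle_set, scheme_a,
                           scheme_b, water)
    from .parameters import morph_particle

    raw = yaml.safe_load(Path(path).read_text())
    sysc = raw.get("system", {})
    simc = raw.get("simulation", {})

    set_name = str(sysc.get("particle_set", "demo-range20"))
    if set_name.startswith("demo-range"):
        pset = demo_particle_set(range_x=float(set_name[len("demo-range"):]),
                                 T=float(simc.get("temperature", 298.0)))
    else:
        pset = load_particle_set(Path(set_name).read_text())
    morph = sysc.get("morph")
    if morph:
        pset = morph_particle(pset, morph["source"], morph["target"],
                              float(morph.get("percent", 0)) / 100.0)

    scheme = str(sysc.get("scheme", "A"))
    if scheme.upper() == "A":
        surf = scheme_a()
    elif scheme.upper() == "B":
        surf = scheme_b()
    else:
        surf = parse_spices(scheme)
    wat = water()
    w = float(sysc.get("mass_fraction", 0.75))
    comp = Composition([(surf, w), (wat, 1.0 - w)],
                       temperature=float(simc.get("temperature", 298.0)))
    n_surf = int(sysc.get("n_surfactant", 150))
    counts = volume_scaled_counts(
        comp, n_surf, pset,
        volume_scaling=bool(sysc.get("volume_scaling", True)))
    boundary = str(sysc.get("boundary", "periodic_xy_reflective_z"))
    if sysc.get("box"):
        box = BoxSpec(tuple(float(v) for v in sysc["box"]),
                      boundary_mode=boundary)
        counts[wat.name] = max(
            0, round(3.0 * box.volume) - counts[surf.name] * surf.n_beads)
    else:
        box = box_for_counts(counts, [surf, wat], boundary_mode=boundary)
    seed = int(simc.get("seed", 0))
    state = random_start(counts, box, pset, [surf, wat], seed=seed,
                         temperature=comp.temperature)
    cfg = SimulationConfig(
        temperature=comp.temperature,
        sigma=float(simc.get("sigma", 3.0)),
        k_bond=float(simc.get("k_bond", 4.0)),
        r_bond=float(simc.get("r_bond", 1.0)),
        dt=float(simc.get("dt", 0.04)),
        n_steps=int(simc.get("n_steps", 1000)),
        integrator=str(simc.get("integrator", "s1mvv")),
        integrator_param=(None if simc.get("integrator_param") is None
                          else float(simc["integrator_param"])),
        seed=seed,
        sample_interval=int(simc.get("sample_interval", 100)),
    )
    return cfg, state, pset, raw
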
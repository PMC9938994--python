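"""Coarse-grained chemistry: particle types, particle sets and molecule fragmentation.

A DPD *particle* (bead) stands for one small fragment molecule — methane,
dimethyl ether, methanol, water — carrying a physical volume (Å³) and a molar
mass (g/mol).  A *particle set* bundles the bead types with the symmetric
matrix of maximum isotropic pair repulsions ``a_ij`` (DPD units) at a stated
reference temperature.  Larger molecules are written as linear fragmentation
strings, e.g. ``"9Me-4Me2O-MeOH"`` for the non-ionic surfactant C10E4:
nine methane beads, four dimethyl-ether beads and one methanol bead joined
by harmonic bonds into a chain.

Only linear chains with repeat counts are supported; branching syntax is
rejected.  Bead and bond indices are 0-based throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "ParticleType",
    "ParticleSet",
    "MoleculeSpec",
    "ParseError",
    "ValidationError",
    "parse_spices",
    "serialize_spices",
    "load_particle_set",
    "dump_particle_set",
    "load_molecule",
    "molecule_mass",
    "molecule_volume",
]

#: Boltzmann "unit" convention: one DPD energy unit corresponds to k_B times
#: this many kelvin (see :mod:`mesodpd.parameters`).
_TOKEN_RE = re.compile(r"^(\d*)([A-Za-z][A-Za-z0-9]*)$")


class ParseError(ValueError):
    """Malformed fragmentation string."""


class ValidationError(ValueError):
    """A particle-set or molecule document violates its invariants."""


@dataclass(frozen=True)
class ParticleType:
    """One coarse-grained bead type.

    Parameters
    ----------
    name:
        Short token such as ``Me``, ``Et``, ``Me2O``, ``MeOH``, ``H2O``.
        Must not contain ``-`` and must not start with a digit (both would
        collide with the fragmentation-string syntax).
    volume:
        Physical fragment volume in Å³ (used only for unit conversions and
        volume-scaled composition mapping).
    molar_mass:
        Fragment molar mass in g/mol.
    """

    name: str
    volume: float
    molar_mass: float

    def __post_init__(self) -> None:
        if not self.name or "-" in self.name or self.name[0].isdigit():
            raise ValidationError(
                f"invalid particle name {self.name!r}: must not contain '-' "
                "or start with a digit"
            )
        if not (self.volume > 0):
            raise ValidationError(f"particle {self.name}: volume must be > 0")
        if not (self.molar_mass > 0):
            raise ValidationError(f"particle {self.name}: molar_mass must be > 0")


@dataclass
class ParticleSet:
    """Ordered bead types plus the symmetric pair-repulsion matrix a_ij.

    ``repulsion[i, j]`` is the maximum isotropic repulsion between bead types
    ``i`` and ``j`` in DPD units at ``reference_temperature`` (kelvin).  The
    diagonal is tied to ``75 k_BT / rho`` under the package temperature
    convention; see :func:`mesodpd.parameters.diagonal_repulsion`.
    """

    types: list[ParticleType]
    repulsion: np.ndarray
    reference_temperature: float = 298.0
    rho: float = 3.0
    comment: str = ""
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.repulsion = np.asarray(self.repulsion, dtype=float)
        self._index = {t.name: i for i, t in enumerate(self.types)}
        self.validate()

    # -- queries -----------------------------------------------------------
    @property
    def names(self) -> list[str]:
        return [t.name for t in self.types]

    def index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise KeyError(f"unknown particle token {token!r}; "
                           f"set defines {self.names}") from None

    @property
    def n_types(self) -> int:
        return len(self.types)

    @property
    def volumes(self) -> np.ndarray:
        return np.array([t.volume for t in self.types])

    @property
    def molar_masses(self) -> np.ndarray:
        return np.array([t.molar_mass for t in self.types])

    @property
    def v_min(self) -> float:
        """Volume of the smallest particle, in Å³."""
        return float(self.volumes.min())

    def a(self, i: str, j: str) -> float:
        return float(self.repulsion[self.index(i), self.index(j)])

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        from .parameters import TemperatureConvention, diagonal_repulsion

        problems: list[str] = []
        names = self.names
        if len(set(names)) != len(names):
            problems.append(f"duplicate particle names in {names}")
        a = self.repulsion
        n = len(self.types)
        if a.shape != (n, n):
            problems.append(f"repulsion matrix shape {a.shape} != ({n}, {n})")
        else:
            if not np.all(np.isfinite(a)):
                problems.append("repulsion matrix contains non-finite entries")
            if np.abs(a - a.T).max(initial=0.0) > 1e-12:
                problems.append("repulsion matrix is not symmetric (tol 1e-12)")
            diag_target = diagonal_repulsion(
                self.reference_temperature, self.rho, TemperatureConvention()
            )
            bad = np.abs(np.diag(a) - diag_target) > 1e-2
            if bad.any():
                problems.append(
                    f"diagonal entries {np.diag(a)[bad]} deviate from "
                    f"75*k_BT/rho = {diag_target:.4f} at "
                    f"{self.reference_temperature} K"
                )
        if problems:
            raise ValidationError("; ".join(problems))


@dataclass(frozen=True)
class MoleculeSpec:
    """A molecule expanded from a fragmentation string into a bonded chain.

    ``beads`` lists bead type tokens in chain order; ``bonds`` lists 0-based
    ``(i, j)`` pairs with ``i < j``.  ``molar_mass`` optionally records the
    molecule's true molar mass (g/mol); fragment masses double-count the
    capping hydrogens, so composition mapping prefers this value when set.
    """

    name: str
    spices: str
    beads: tuple[str, ...]
    bonds: tuple[tuple[int, int], ...]
    molar_mass: float | None = None

    def __post_init__(self) -> None:
        if not self.beads:
            raise ValidationError(f"molecule {self.name!r} has no beads")
        n = len(self.beads)
        for i, j in self.bonds:
            if not (0 <= i < j < n):
                raise ValidationError(
                    f"molecule {self.name!r}: bond ({i}, {j}) out of range "
                    f"for {n} beads"
                )

    @property
    def n_beads(self) -> int:
        return len(self.beads)


def parse_spices(spices: str, name: str | None = None,
                 molar_mass: float | None = None) -> MoleculeSpec:
    """Parse a linear fragmentation string into a :class:`MoleculeSpec`.

    The string is a ``-``-separated sequence of tokens, each an optional
    positive repeat count followed by a bead type token
    (``"9Me-4Me2O-MeOH"`` → 9×Me, 4×Me2O, 1×MeOH).  Consecutive beads are
    bonded into a linear chain.

    Raises
    ------
    ParseError
        For empty/malformed tokens, zero repeat counts, or branching syntax
        (``(``, ``)``, ``[``, ``]``), which this package does not support.
    """
    if not isinstance(spices, str) or not spices.strip():
        raise ParseError("empty fragmentation string")
    s = spices.strip()
    for ch in "()[]{}":
        if ch in s:
            raise ParseError(
                f"branching syntax {ch!r} in {s!r} is not supported: "
                "only linear chains with repeat counts are accepted"
            )
    beads: list[str] = []
    for token in s.split("-"):
        m = _TOKEN_RE.match(token)
        if m is None:
            raise ParseError(f"malformed token {token!r} in {s!r}")
        count_s, type_token = m.groups()
        count = int(count_s) if count_s else 1
        if count == 0:
            raise ParseError(f"zero repeat count in token {token!r}")
        beads.extend([type_token] * count)
    bonds = tuple((i, i + 1) for i in range(len(beads) - 1))
    return MoleculeSpec(name=name or s, spices=s, beads=tuple(beads),
                        bonds=bonds, molar_mass=molar_mass)


def serialize_spices(spec: MoleculeSpec) -> str:
    """Write a normalized fragmentation string (run-length encoded beads)."""
    out: list[str] = []
    i = 0
    beads = spec.beads
    while i < len(beads):
        j = i
        while j < len(beads) and beads[j] == beads[i]:
            j += 1
        n = j - i
        out.append(beads[i] if n == 1 else f"{n}{beads[i]}")
        i = j
    return "-".join(out)


def resolve_types(spec: MoleculeSpec, pset: ParticleSet) -> np.ndarray:
    """Map the molecule's bead tokens to type indices of ``pset``."""
    return np.array([pset.index(b) for b in spec.beads], dtype=np.int32)


def molecule_mass(spec: MoleculeSpec, pset: ParticleSet) -> float:
    """Sum of fragment molar masses over the molecule's beads (g/mol)."""
    masses = pset.molar_masses
    return float(masses[resolve_types(spec, pset)].sum())


def molecule_volume(spec: MoleculeSpec, pset: ParticleSet) -> float:
    """Sum of fragment volumes over the molecule's beads (Å³)."""
    vols = pset.volumes
    return float(vols[resolve_types(spec, pset)].sum())


def physical_molar_mass(spec: MoleculeSpec, pset: ParticleSet) -> float:
    """Molar mass used for composition mapping: the molecule's stated value
    if present, otherwise the fragment sum."""
    if spec.molar_mass is not None:
        return float(spec.molar_mass)
    return molecule_mass(spec, pset)


# ---------------------------------------------------------------------------
# file round-tripping (YAML dialect)
# ---------------------------------------------------------------------------

def load_particle_set(document: str) -> ParticleSet:
    """Load a particle set from a YAML document (text, not a path).

    Layout::

        reference_temperature: 298.0
        rho: 3.0
        types:
          - {name: H2O, volume_A3: 30.0, molar_mass: 18.02}
          - ...
        repulsion:      # full matrix or row-major lower triangle
          - [24.83]
          - [30.0, 24.83]

    The matrix is symmetrized only if the asymmetry is below 1e-9;
    a larger asymmetry is rejected.  All invariant violations are collected
    into a single :class:`ValidationError`.
    """
    doc = yaml.safe_load(document)
    if not isinstance(doc, dict) or "types" not in doc or "repulsion" not in doc:
        raise ValidationError("document must declare 'types' and 'repulsion'")
    problems: list[str] = []
    types: list[ParticleType] = []
    for row in doc["types"]:
        try:
            types.append(ParticleType(name=str(row["name"]),
                                      volume=float(row["volume_A3"]),
                                      molar_mass=float(row["molar_mass"])))
        except (KeyError, TypeError) as exc:
            problems.append(f"type entry {row!r}: missing field ({exc})")
        except ValidationError as exc:
            problems.append(str(exc))
    n = len(doc["types"])
    rows = doc["repulsion"]
    a = np.full((n, n), np.nan)
    if len(rows) != n:
        problems.append(f"repulsion has {len(rows)} rows for {n} types")
    else:
        triangle = all(len(row) == i + 1 for i, row in enumerate(rows))
        for i, row in enumerate(rows):
            if triangle:                   # row-major lower triangle
                a[i, : i + 1] = row
                a[: i + 1, i] = row
            elif len(row) == n:            # full matrix
                a[i, :] = row
            else:
                problems.append(f"repulsion row {i} has length {len(row)}")
        if np.isnan(a).any() and not problems:
            problems.append("repulsion matrix has missing pairs")
        if not np.isnan(a).any():
            asym = np.abs(a - a.T).max()
            if asym > 1e-9:
                problems.append(
                    f"repulsion matrix asymmetric by {asym:.3g} (> 1e-9)"
                )
            else:
                a = 0.5 * (a + a.T)
    if problems:
        raise ValidationError("; ".join(problems))
    try:
        return ParticleSet(
            types=types,
            repulsion=a,
            reference_temperature=float(doc.get("reference_temperature", 298.0)),
            rho=float(doc.get("rho", 3.0)),
            comment=str(doc.get("comment", "")),
        )
    except ValidationError:
        raise


def dump_particle_set(pset: ParticleSet) -> str:
    """Serialize a particle set to the YAML dialect read by
    :func:`load_particle_set` (full matrix form)."""
    doc = {
        "comment": pset.comment,
        "reference_temperature": float(pset.reference_temperature),
        "rho": float(pset.rho),
        "types": [
            {"name": t.name, "volume_A3": float(t.volume),
             "molar_mass": float(t.molar_mass)}
            for t in pset.types
        ],
        "repulsion": [[float(x) for x in row] for row in pset.repulsion],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def load_molecule(document: str) -> MoleculeSpec:
    """Load a molecule file carrying ``name:`` and ``spices:`` (and optionally
    ``molar_mass:``)."""
    doc = yaml.safe_load(document)
    if not isinstance(doc, dict) or "spices" not in doc:
        raise ValidationError("molecule document must declare 'spices'")
    mm = doc.get("molar_mass")
    return parse_spices(str(doc["spices"]), name=doc.get("name"),
                        molar_mass=float(mm) if mm is not None else None)
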
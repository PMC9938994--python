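"""Repulsion-parameter engine: χ → a_ij, range scaling, particle morphing.

DPD pair repulsions may be derived from Flory–Huggins interaction parameters:

    a_ij(T) = 75 k_BT / rho + 3.4965 k_BT χ_ij,      χ_ii = 0,

with everything in reduced (DPD) units.  This module owns the package's
temperature convention — one DPD energy unit corresponds to k_B · 300 K —
which is what makes the diagonal come out as a_ii = 75 · (298/300) / 3
= 24.83 (2 d.p.) at 298 K and DPD density 3.

Two matrix transformations used in bilayer-formation studies live here:

* *range-x scaling*: all off-diagonal χ contributions are multiplied by one
  common positive factor so that the smallest a_ij sits exactly ``x`` DPD
  units below the diagonal value ("range 10/15/20" particle sets);
* *morphing*: the repulsion row of one bead type is linearly interpolated
  toward another type's row, with the mutual entry running toward the
  diagonal value, so that at 100 % the two types repel identically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .chem import ParticleSet, ValidationError

__all__ = [
    "CHI_TO_A",
    "TemperatureConvention",
    "ChiMatrix",
    "kelvin_to_dpd",
    "diagonal_repulsion",
    "repulsion_from_chi",
    "scale_to_range",
    "morph_particle",
]

#: coefficient of the χ term in the repulsion mapping (Groot–Warren, rho = 3)
CHI_TO_A = 3.4965


@dataclass(frozen=True)
class TemperatureConvention:
    """Maps kelvin to dimensionless DPD energy: k_BT_dpd = T / reference_kelvin."""

    reference_kelvin: float = 300.0

    def __post_init__(self) -> None:
        if not (self.reference_kelvin > 0):
            raise ValueError("reference_kelvin must be > 0")


def kelvin_to_dpd(T: float, convention: TemperatureConvention | None = None) -> float:
    """Dimensionless DPD k_BT for a thermodynamic temperature in kelvin."""
    convention = convention or TemperatureConvention()
    if not (T > 0):
        raise ValueError(f"temperature must be > 0 K, got {T}")
    return T / convention.reference_kelvin


def dpd_to_kelvin(kbt: float, convention: TemperatureConvention | None = None) -> float:
    convention = convention or TemperatureConvention()
    return kbt * convention.reference_kelvin


@dataclass(frozen=True)
class ChiMatrix:
    """Symmetric matrix of Flory–Huggins parameters with exactly zero diagonal."""

    chi: np.ndarray

    def __post_init__(self) -> None:
        chi = np.asarray(self.chi, dtype=float)
        if chi.ndim != 2 or chi.shape[0] != chi.shape[1]:
            raise ValidationError(f"chi must be square, got shape {chi.shape}")
        if np.abs(chi - chi.T).max(initial=0.0) > 1e-12:
            raise ValidationError("chi matrix must be symmetric")
        if np.any(np.diag(chi) != 0.0):
            raise ValidationError("chi diagonal must be exactly zero")
        object.__setattr__(self, "chi", chi)

    @property
    def n(self) -> int:
        return self.chi.shape[0]


def diagonal_repulsion(T: float, rho: float = 3.0,
                       convention: TemperatureConvention | None = None) -> float:
    """a_ii = 75 k_BT / rho in DPD units (k_BT under the package convention)."""
    if not (rho > 0):
        raise ValueError("rho must be > 0")
    return 75.0 * kelvin_to_dpd(T, convention) / rho


def repulsion_from_chi(chi: ChiMatrix, T: float, rho: float = 3.0,
                       convention: TemperatureConvention | None = None) -> np.ndarray:
    """Repulsion matrix a_ij = 75 k_BT/rho + 3.4965 k_BT χ_ij.

    Linear and strictly increasing in χ entry-wise; the diagonal equals
    75 k_BT/rho exactly because χ_ii = 0.
    """
    kbt = kelvin_to_dpd(T, convention)
    a_ii = diagonal_repulsion(T, rho, convention)
    return a_ii + CHI_TO_A * kbt * chi.chi


def scale_to_range(base_chi: ChiMatrix, x: float, T: float, rho: float = 3.0,
                   convention: TemperatureConvention | None = None) -> np.ndarray:
    """Scale off-diagonal χ contributions so min a_ij = a_ii − x ("range x").

    One common positive factor multiplies every off-diagonal χ entry, so the
    relative ordering and sign pattern of the deviations from the diagonal
    are preserved; the factor is fixed by anchoring the smallest resulting
    a_ij exactly ``x`` DPD units below the diagonal.

    ``x = 0`` returns the uniform matrix (every entry a_ii).  ``x > 0``
    requires at least one negative χ entry, else the range is unsatisfiable.
    """
    if x < 0:
        raise ValueError("range x must be >= 0")
    kbt = kelvin_to_dpd(T, convention)
    a_ii = diagonal_repulsion(T, rho, convention)
    chi = base_chi.chi
    if x == 0:
        return np.full_like(chi, a_ii)
    chi_min = chi.min()
    if chi_min >= 0:
        raise ValidationError(
            f"range {x} unsatisfiable: no negative chi entry, so no a_ij "
            "can fall below the diagonal"
        )
    s = x / (CHI_TO_A * kbt * (-chi_min))
    return a_ii + CHI_TO_A * kbt * s * chi


def morph_particle(pset: ParticleSet, source: str, target: str,
                   fraction: float) -> ParticleSet:
    """Shift the repulsions of ``source`` toward those of ``target``.

    For every third type k: a'(s,k) = a(s,k) + f·(a(t,k) − a(s,k)).
    The mutual entry runs against the diagonal: a'(s,t) = a(s,t) +
    f·(a_ii − a(s,t)).  At f = 1 the two types exhibit equal repulsions.
    All other entries are unchanged; symmetry is preserved.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError(f"morph fraction must be in [0, 1], got {fraction}")
    s = pset.index(source)
    t = pset.index(target)
    if s == t:
        raise ValueError("source and target must differ")
    a = pset.repulsion.copy()
    a_ii = a[s, s]
    for k in range(pset.n_types):
        if k in (s, t):
            continue
        a_sk = a[s, k] + fraction * (a[t, k] - a[s, k])
        a[s, k] = a[k, s] = a_sk
    a_st = a[s, t] + fraction * (a_ii - a[s, t])
    a[s, t] = a[t, s] = a_st
    comment = (f"{pset.comment + '; ' if pset.comment else ''}"
               f"morphed {source}->{target} fraction {fraction:g}")
    return replace(pset, repulsion=a, comment=comment)
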
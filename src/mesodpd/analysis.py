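"""Trajectory and observable analysis: z-density profiles, bilayer counting
and thickness, temperature drift, convergence detection, unit conversions.

Bilayer thickness is a *definition*, not a measurement primitive: here a
bilayer's thickness is the distance between the two flanking headgroup
density maxima plus one headgroup full-width-at-half-maximum, converted to
Å through the conversion radius r_c.  The definition is deliberately simple
and testable on synthetic profiles; swap in another callable if a different
protocol is wanted.

Physical-unit mapping: one DPD length equals

    r_c = (V_min · ρ · ⟨V_i / V_min⟩_N)^{1/3}   [Å]

(number-weighted mean over all beads in the box) and one DPD time equals
f_soft · r_c · sqrt(⟨M⟩_N / (R·T)) seconds, with f_soft ≈ 1000 accounting
for the enhanced diffusivity of soft potentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DensityProfile",
    "BilayerReport",
    "UnitConversion",
    "density_profile",
    "detect_bilayers",
    "bilayer_thickness",
    "classify_tension_rise",
    "temperature_drift",
    "convergence_step",
    "conversion_radius",
    "physical_time",
]

GAS_CONSTANT = 8.31446261815324  # J / (mol K)

_AXIS = {"x": 0, "y": 1, "z": 2}


@dataclass
class DensityProfile:
    """Time-averaged number density along one axis for a bead selection."""

    axis: str
    bin_edges: np.ndarray
    density: np.ndarray          # number density per bin (DPD units)
    n_selected: float            # beads in the selection (per frame)
    n_frames: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass
class BilayerReport:
    n_bilayers: int
    slabs: list[tuple[float, float]]      # DPD lengths
    thicknesses: list[float] = field(default_factory=list)  # Å
    diagnostic: str = ""


def density_profile(frames, type_ids, box, select, axis: str = "z",
                    n_bins: int = 40, type_names=None) -> DensityProfile:
    """Per-type number density along an axis, averaged over frames.

    ``select`` is a set of type ids, or of type tokens if ``type_names``
    is given.  The profile integrates back to the selection's bead count:
    Σ density·bin_volume = n_selected.
    """
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    frames = list(frames)
    if not frames:
        raise ValueError("need at least one frame")
    ax = _AXIS[axis]
    lengths = np.asarray(getattr(box, "lengths", box), dtype=float)
    L = lengths[ax]
    if type_names is not None and select is not None:
        name_to_id = {n: i for i, n in enumerate(type_names)}
        sel_ids = {name_to_id[s] if isinstance(s, str) else int(s)
                   for s in select}
    elif select is None:
        sel_ids = set(np.unique(type_ids).tolist())
    else:
        sel_ids = {int(s) for s in select}
    mask = np.isin(type_ids, list(sel_ids))
    if not mask.any():
        raise ValueError(f"empty selection {select!r}")
    edges = np.linspace(0.0, L, n_bins + 1)
    other = [d for d in range(3) if d != ax]
    bin_volume = (L / n_bins) * lengths[other[0]] * lengths[other[1]]
    hist = np.zeros(n_bins)
    for fr in frames:
        x = fr[mask, ax]
        h, _ = np.histogram(np.clip(x, 0.0, np.nextafter(L, 0.0)), bins=edges)
        hist += h
    hist /= len(frames)
    return DensityProfile(axis=axis, bin_edges=edges,
                          density=hist / bin_volume,
                          n_selected=float(mask.sum()),
                          n_frames=len(frames))


def detect_bilayers(profile: DensityProfile, periodic: bool = False,
                    min_contrast: float = 0.25,
                    min_width: float = 1.0) -> BilayerReport:
    """Contiguous above-threshold runs of the (surfactant) profile = slabs.

    The threshold is the midpoint of the profile's bimodal levels
    ((max + min)/2).  A profile whose peak-to-trough contrast
    (max − min)/max falls below ``min_contrast`` is judged non-bimodal
    (flat / well-mixed): 0 slabs with a diagnostic.  Runs narrower than
    ``min_width`` (DPD lengths) are noise and are dropped.  With
    ``periodic`` the first and last runs merge across the boundary.
    """
    d = profile.density
    if d.max() <= 0 or (d.max() - d.min()) < min_contrast * d.max():
        return BilayerReport(0, [], diagnostic=(
            f"profile not bimodal: contrast {(d.max() - d.min()):.3g} < "
            f"{min_contrast} x max {d.max():.3g}"))
    thr = 0.5 * (d.max() + d.min())
    above = d > thr
    slabs: list[tuple[float, float]] = []
    edges = profile.bin_edges
    start = None
    for i, hi in enumerate(above):
        if hi and start is None:
            start = i
        elif not hi and start is not None:
            slabs.append((edges[start], edges[i]))
            start = None
    if start is not None:
        slabs.append((edges[start], edges[-1]))
    if periodic and len(slabs) >= 2 and above[0] and above[-1]:
        first, last = slabs[0], slabs.pop()
        slabs[0] = (last[0], first[1])   # wrapped slab
    L = edges[-1] - edges[0]
    slabs = [(lo, hi) for lo, hi in slabs
             if (hi - lo if hi > lo else L - (lo - hi)) >= min_width]
    return BilayerReport(len(slabs), slabs)


def bilayer_thickness(headgroup_profile: DensityProfile,
                      report: BilayerReport,
                      conversion: "UnitConversion") -> list[float]:
    """Thickness per detected bilayer, in Å.

    Within each slab (± a margin of 25 % of the slab width) the two
    outermost headgroup density maxima are located; thickness = (peak
    separation + one mean headgroup FWHM) · r_c.
    """
    if report.n_bilayers < 1:
        raise ValueError("no detected bilayer to measure")
    d = headgroup_profile.density
    z = headgroup_profile.bin_centers
    dz = headgroup_profile.bin_width
    out = []
    for lo, hi in report.slabs:
        margin = 0.25 * (hi - lo) + dz
        mid = 0.5 * (lo + hi)
        left = np.nonzero((z >= lo - margin) & (z < mid))[0]
        right = np.nonzero((z >= mid) & (z <= hi + margin))[0]
        if len(left) == 0 or len(right) == 0:
            raise ValueError(
                f"slab ({lo:.2f}, {hi:.2f}): fewer than two flanking "
                "headgroup peaks")
        p1 = left[np.argmax(d[left])]
        p2 = right[np.argmax(d[right])]
        if p1 == p2 or d[p1] <= 0 or d[p2] <= 0:
            raise ValueError(
                f"slab ({lo:.2f}, {hi:.2f}): fewer than two flanking "
                "headgroup peaks")
        sep = (p2 - p1) * dz
        out.append((sep + 0.5 * (_fwhm(d, p1, dz) + _fwhm(d, p2, dz)))
                   * conversion.r_c)
    return out


def _fwhm(d, peak, dz) -> float:
    """Full width of the peak at half its height, by linear interpolation
    of the nearest half-max crossings on each side."""
    half = 0.5 * d[peak]
    i = peak
    while i > 0 and d[i - 1] > half:
        i -= 1
    if i == 0:
        left = float(i)
    else:
        frac = (d[i] - half) / max(d[i] - d[i - 1], 1e-300)
        left = i - frac
    j = peak
    n = len(d)
    while j < n - 1 and d[j + 1] > half:
        j += 1
    if j == n - 1:
        right = float(j)
    else:
        frac = (d[j] - half) / max(d[j] - d[j + 1], 1e-300)
        right = j + frac
    return (right - left) * dz


#: boundaries of the surface-tension-rise classification, DPD units:
#: a rise below RISE_UPPER is a moderate "rise", above STRONG_RISE_LOWER a
#: "strong_rise"; the open interval between them is left unassigned.
RISE_UPPER = 6.0
STRONG_RISE_LOWER = 7.0


def classify_tension_rise(rise: float) -> dict:
    """Classify a z-surface-tension rise as a bilayer-formation signal.

    Returns the raw rise together with a label: ``no_change`` (<= 0),
    ``rise`` (positive, below 6 DPD units), ``strong_rise`` (above 7), or
    ``ambiguous`` for the unassigned 6–7 interval.
    """
    if rise <= 0.0:
        label = "no_change"
    elif rise < RISE_UPPER:
        label = "rise"
    elif rise > STRONG_RISE_LOWER:
        label = "strong_rise"
    else:
        label = "ambiguous"
    return {"rise": float(rise), "label": label,
            "boundaries": (RISE_UPPER, STRONG_RISE_LOWER)}


def temperature_drift(t_kelvin, set_point: float,
                      window: tuple[int, int] | None = None) -> float:
    """Mean kinetic temperature over the window minus the set point (K).

    ``window`` is an index range into the series; default = final 50 %.
    """
    t = np.asarray(t_kelvin, dtype=float)
    if window is None:
        window = (len(t) // 2, len(t))
    lo, hi = window
    if hi > len(t) or lo < 0 or lo >= hi:
        raise ValueError(f"window {window} outside series of length {len(t)}")
    return float(t[lo:hi].mean() - set_point)


def convergence_step(series, steps=None, slope_tol: float = 1e-4,
                     window: int = 5):
    """First step at which the sliding-window least-squares slope of the
    series stays below ``slope_tol`` (absolute, per step) for all later
    windows; None if it never settles.
    """
    y = np.asarray(series, dtype=float)
    if steps is None:
        steps = np.arange(len(y))
    steps = np.asarray(steps, dtype=float)
    if len(y) < window + 1:
        raise ValueError("series shorter than one window")
    n_win = len(y) - window + 1
    slopes = np.empty(n_win)
    for k in range(n_win):
        xs = steps[k:k + window]
        ys = y[k:k + window]
        xm = xs - xs.mean()
        denom = (xm ** 2).sum()
        slopes[k] = (xm * (ys - ys.mean())).sum() / denom if denom > 0 else 0.0
    ok = np.abs(slopes) < slope_tol
    # last False, then everything after is True
    bad = np.nonzero(~ok)[0]
    if len(bad) == 0:
        return float(steps[0])
    if bad[-1] == n_win - 1:
        return None
    return float(steps[bad[-1] + 1])


@dataclass(frozen=True)
class UnitConversion:
    """DPD ↔ physical units: r_c in Å, seconds per DPD time, f_soft."""

    r_c: float
    time_unit: float = 0.0
    f_soft: float = 1000.0

    def __post_init__(self) -> None:
        if not (self.r_c > 0):
            raise ValueError("r_c must be > 0")
        if not (self.f_soft > 0):
            raise ValueError("f_soft must be > 0")


def conversion_radius(counts, volumes, rho: float = 3.0) -> float:
    """r_c = (V_min · ρ · ⟨V_i/V_min⟩_number)^{1/3} in Å.

    ``counts``: beads of each type in the box; ``volumes``: per-type
    physical volumes in Å³.  Permutation invariant; scales as ρ^{1/3}.
    """
    n = np.asarray(counts, dtype=float)
    v = np.asarray(volumes, dtype=float)
    if np.any(v <= 0) or np.any(n < 0) or n.sum() <= 0:
        raise ValueError("counts must be >= 0 (sum > 0) and volumes > 0")
    v_min = v.min()
    mean_rel = (n * (v / v_min)).sum() / n.sum()
    return float((v_min * rho * mean_rel) ** (1.0 / 3.0))


def physical_time(t_dpd: float, counts, molar_masses, volumes,
                  T: float, f_soft: float = 1000.0,
                  rho: float = 3.0) -> float:
    """Physical duration (seconds) of ``t_dpd`` DPD time units:

        t_phys = t_dpd · f_soft · r_c · sqrt(⟨M⟩_N / (R·T))

    with r_c converted to meters and ⟨M⟩ (number-weighted mean bead molar
    mass) to kg/mol.
    """
    if not (f_soft > 0):
        raise ValueError("f_soft must be > 0")
    n = np.asarray(counts, dtype=float)
    m = np.asarray(molar_masses, dtype=float) / 1000.0   # kg/mol
    r_c_m = conversion_radius(n, volumes, rho) * 1e-10   # Å -> m
    mean_m = (n * m).sum() / n.sum()
    return float(t_dpd * f_soft * r_c_m * np.sqrt(mean_m / (GAS_CONSTANT * T)))
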
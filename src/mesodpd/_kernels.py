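"""Numba kernels: neighbor search, pair forces, pairwise thermostats.

All kernels are single-threaded and use a counter-based random stream keyed
on (step, pair), so a run is bit-reproducible for a given seed regardless of
how pairs were enumerated.  Positions are in [0, L) on periodic axes; the
z axis may instead carry reflective walls (``pbc_z = False``), in which case
no minimum image is applied along z.

The DPD cutoff is 1 in reduced units and is hard-coded where it matters
(weight functions, cell size).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# splitmix64 constants
_G = np.uint64(0x9E3779B97F4A7C15)
_M1 = np.uint64(0xBF58476D1CE4E5B9)
_M2 = np.uint64(0x94D049BB133111EB)
_TWO_PI = 2.0 * np.pi


@njit(cache=True, inline="always")
def _mix(z):
    z = (z ^ (z >> np.uint64(30))) * _M1
    z = (z ^ (z >> np.uint64(27))) * _M2
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def pair_normal(key, i, j):
    """Standard normal draw for pair (i, j) under stream ``key``.

    Symmetric by construction when called with i < j; deterministic in
    (key, i, j) only, so enumeration order is irrelevant.
    """
    h = _mix((key + _G * (np.uint64(i) + np.uint64(1))) ^ _G)
    h = _mix(h + _G * (np.uint64(j) + np.uint64(1)))
    h2 = _mix(h + _G)
    u1 = (np.float64(h >> np.uint64(11)) + 1.0) / 9007199254740993.0
    u2 = np.float64(h2 >> np.uint64(11)) / 9007199254740992.0
    return np.sqrt(-2.0 * np.log(u1)) * np.cos(_TWO_PI * u2)


@njit(cache=True, inline="always")
def scalar_normal(key, tag):
    return pair_normal(key, tag, np.int64(2) ** 40 + tag)


@njit(cache=True)
def derive_step_key(seed, step):
    return _mix(np.uint64(seed) * _G + np.uint64(step) + np.uint64(1))


# ---------------------------------------------------------------------------
# neighbor enumeration
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _minimum_image(d, L, periodic):
    if periodic:
        if d > 0.5 * L:
            d -= L
        elif d < -0.5 * L:
            d += L
    return d


_OFFS = np.array([
    [0, 0, 0],
    [1, 0, 0], [-1, 1, 0], [0, 1, 0], [1, 1, 0],
    [-1, -1, 1], [0, -1, 1], [1, -1, 1], [-1, 0, 1],
    [0, 0, 1], [1, 0, 1], [-1, 1, 1], [0, 1, 1], [1, 1, 1],
], dtype=np.int64)


@njit(cache=True)
def build_pairs_cells(pos, box, pbc_z, pi, pj):
    """Cell-list enumeration of all pairs with r < 1 into the preallocated
    buffers ``pi``/``pj``; each pair once, stored with i < j (enumeration
    order arbitrary — use sort_pairs when sweep order matters).

    Returns the pair count; a count above the buffer capacity signals an
    overflow, in which case the caller must retry with larger buffers.
    """
    n = pos.shape[0]
    cap = pi.shape[0]
    ncx = max(int(box[0]), 1)
    ncy = max(int(box[1]), 1)
    ncz = max(int(box[2]), 1)
    ncells = ncx * ncy * ncz
    head = np.full(ncells, -1, dtype=np.int64)
    nxt = np.empty(n, dtype=np.int64)
    for p in range(n):
        cx = min(int(pos[p, 0] / box[0] * ncx), ncx - 1)
        cy = min(int(pos[p, 1] / box[1] * ncy), ncy - 1)
        cz = min(int(pos[p, 2] / box[2] * ncz), ncz - 1)
        if cx < 0:
            cx = 0
        if cy < 0:
            cy = 0
        if cz < 0:
            cz = 0
        c = (cz * ncy + cy) * ncx + cx
        nxt[p] = head[c]
        head[c] = p

    offs = _OFFS  # half stencil: self cell plus 13 neighbor offsets
    count = 0
    for cz in range(ncz):
        for cy in range(ncy):
            for cx in range(ncx):
                c = (cz * ncy + cy) * ncx + cx
                for k in range(offs.shape[0]):
                    ox, oy, oz = offs[k, 0], offs[k, 1], offs[k, 2]
                    nx = cx + ox
                    ny = cy + oy
                    nz = cz + oz
                    if nx < 0:
                        nx += ncx
                    elif nx >= ncx:
                        nx -= ncx
                    if ny < 0:
                        ny += ncy
                    elif ny >= ncy:
                        ny -= ncy
                    if pbc_z:
                        if nz < 0:
                            nz += ncz
                        elif nz >= ncz:
                            nz -= ncz
                    else:
                        if nz < 0 or nz >= ncz:
                            continue
                    c2 = (nz * ncy + ny) * ncx + nx
                    if k == 0:
                        a = head[c]
                        while a >= 0:
                            b = nxt[a]
                            while b >= 0:
                                dx = _minimum_image(pos[a, 0] - pos[b, 0], box[0], True)
                                dy = _minimum_image(pos[a, 1] - pos[b, 1], box[1], True)
                                dz = _minimum_image(pos[a, 2] - pos[b, 2], box[2], pbc_z)
                                if dx * dx + dy * dy + dz * dz < 1.0:
                                    if count < cap:
                                        if a < b:
                                            pi[count] = a
                                            pj[count] = b
                                        else:
                                            pi[count] = b
                                            pj[count] = a
                                    count += 1
                                b = nxt[b]
                            a = nxt[a]
                    else:
                        if c2 == c:
                            continue  # small box: offset wrapped onto self
                        a = head[c]
                        while a >= 0:
                            b = head[c2]
                            while b >= 0:
                                dx = _minimum_image(pos[a, 0] - pos[b, 0], box[0], True)
                                dy = _minimum_image(pos[a, 1] - pos[b, 1], box[1], True)
                                dz = _minimum_image(pos[a, 2] - pos[b, 2], box[2], pbc_z)
                                if dx * dx + dy * dy + dz * dz < 1.0:
                                    if count < cap:
                                        if a < b:
                                            pi[count] = a
                                            pj[count] = b
                                        else:
                                            pi[count] = b
                                            pj[count] = a
                                    count += 1
                                b = nxt[b]
                            a = nxt[a]
    return count


@njit(cache=True)
def build_pairs_all(pos, box, pbc_z):
    """O(N²) enumeration of all pairs with r < 1 (oracle / small boxes)."""
    n = pos.shape[0]
    cap = n * (n - 1) // 2
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    count = 0
    for a in range(n):
        for b in range(a + 1, n):
            dx = _minimum_image(pos[a, 0] - pos[b, 0], box[0], True)
            dy = _minimum_image(pos[a, 1] - pos[b, 1], box[1], True)
            dz = _minimum_image(pos[a, 2] - pos[b, 2], box[2], pbc_z)
            if dx * dx + dy * dy + dz * dz < 1.0:
                pi[count] = a
                pj[count] = b
                count += 1
    return pi[:count], pj[:count]


@njit(cache=True)
def _radix_sort_pairs(pi, pj, n, qi, qj):
    """Stable two-pass counting sort into ascending (i, j); O(P + N)."""
    m = pi.shape[0]
    countj = np.zeros(n + 1, dtype=np.int64)
    for k in range(m):
        countj[pj[k] + 1] += 1
    for v in range(1, n + 1):
        countj[v] += countj[v - 1]
    ti = np.empty(m, dtype=np.int64)
    tj = np.empty(m, dtype=np.int64)
    for k in range(m):
        p = countj[pj[k]]
        countj[pj[k]] = p + 1
        ti[p] = pi[k]
        tj[p] = pj[k]
    counti = np.zeros(n + 1, dtype=np.int64)
    for k in range(m):
        counti[ti[k] + 1] += 1
    for v in range(1, n + 1):
        counti[v] += counti[v - 1]
    for k in range(m):
        p = counti[ti[k]]
        counti[ti[k]] = p + 1
        qi[p] = ti[k]
        qj[p] = tj[k]


def sort_pairs(pi, pj, n_beads=None):
    """Ascending (i, j) order — fixes the sweep order of pairwise updates."""
    if n_beads is None:
        n_beads = int(max(pi.max(initial=0), pj.max(initial=0))) + 1
    qi = np.empty_like(pi)
    qj = np.empty_like(pj)
    _radix_sort_pairs(pi, pj, n_beads, qi, qj)
    return qi, qj


# ---------------------------------------------------------------------------
# forces
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _pair_geom(pos, box, pbc_z, a, b):
    dx = _minimum_image(pos[a, 0] - pos[b, 0], box[0], True)
    dy = _minimum_image(pos[a, 1] - pos[b, 1], box[1], True)
    dz = _minimum_image(pos[a, 2] - pos[b, 2], box[2], pbc_z)
    r = np.sqrt(dx * dx + dy * dy + dz * dz)
    if r < 1e-12:
        # coincident beads: deterministic fallback direction by index parity
        s = 1.0 if ((a + b) & 1) == 0 else -1.0
        return 0.0, s, 0.0, 0.0, dx, dy, dz
    return r, dx / r, dy / r, dz / r, dx, dy, dz


@njit(cache=True)
def conservative_forces(pos, box, pbc_z, tid, amat, bi, bj, k_bond, r_bond,
                        pi, pj, forces, virial):
    """Soft DPD repulsion + harmonic bonds; accumulates into ``forces``.

    Returns (e_dpd, e_bond, n_overlap).  ``virial`` (3,) accumulates the
    diagonal pair-virial sum F·dr for the pressure tensor.
    """
    e_dpd = 0.0
    e_bond = 0.0
    n_overlap = 0
    for k in range(pi.shape[0]):
        a = pi[k]
        b = pj[k]
        r, ex, ey, ez, dx, dy, dz = _pair_geom(pos, box, pbc_z, a, b)
        if r >= 1.0:
            continue
        if r == 0.0:
            n_overlap += 1
        aij = amat[tid[a], tid[b]]
        fmag = aij * (1.0 - r)
        fx = fmag * ex
        fy = fmag * ey
        fz = fmag * ez
        forces[a, 0] += fx
        forces[a, 1] += fy
        forces[a, 2] += fz
        forces[b, 0] -= fx
        forces[b, 1] -= fy
        forces[b, 2] -= fz
        e_dpd += 0.5 * aij * (1.0 - r) * (1.0 - r)
        virial[0] += fx * dx
        virial[1] += fy * dy
        virial[2] += fz * dz
    for k in range(bi.shape[0]):
        a = bi[k]
        b = bj[k]
        r, ex, ey, ez, dx, dy, dz = _pair_geom(pos, box, pbc_z, a, b)
        if r == 0.0:
            n_overlap += 1
        fmag = -k_bond * (r - r_bond)
        fx = fmag * ex
        fy = fmag * ey
        fz = fmag * ez
        forces[a, 0] += fx
        forces[a, 1] += fy
        forces[a, 2] += fz
        forces[b, 0] -= fx
        forces[b, 1] -= fy
        forces[b, 2] -= fz
        e_bond += 0.5 * k_bond * (r - r_bond) * (r - r_bond)
        virial[0] += fx * dx
        virial[1] += fy * dy
        virial[2] += fz * dz
    return e_dpd, e_bond, n_overlap


@njit(cache=True)
def random_forces(pos, box, pbc_z, pi, pj, sigma, dt, key, forces):
    """Pairwise random force σ ω^R(r) ζ_ij Δt^{-1/2} ê_ij (antisymmetric)."""
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    for k in range(pi.shape[0]):
        a = pi[k]
        b = pj[k]
        r, ex, ey, ez, dx, dy, dz = _pair_geom(pos, box, pbc_z, a, b)
        if r >= 1.0:
            continue
        w = 1.0 - r
        zeta = pair_normal(key, a, b)
        fmag = sigma * w * zeta * inv_sqrt_dt
        forces[a, 0] += fmag * ex
        forces[a, 1] += fmag * ey
        forces[a, 2] += fmag * ez
        forces[b, 0] -= fmag * ex
        forces[b, 1] -= fmag * ey
        forces[b, 2] -= fmag * ez


@njit(cache=True)
def dissipative_forces(pos, vel, box, pbc_z, pi, pj, gamma, forces):
    """Pairwise friction −γ ω^D(r) (ê·v_ij) ê (antisymmetric)."""
    for k in range(pi.shape[0]):
        a = pi[k]
        b = pj[k]
        r, ex, ey, ez, dx, dy, dz = _pair_geom(pos, box, pbc_z, a, b)
        if r >= 1.0:
            continue
        w = 1.0 - r
        u = (ex * (vel[a, 0] - vel[b, 0]) + ey * (vel[a, 1] - vel[b, 1])
             + ez * (vel[a, 2] - vel[b, 2]))
        fmag = -gamma * w * w * u
        forces[a, 0] += fmag * ex
        forces[a, 1] += fmag * ey
        forces[a, 2] += fmag * ez
        forces[b, 0] -= fmag * ex
        forces[b, 1] -= fmag * ey
        forces[b, 2] -= fmag * ez


# ---------------------------------------------------------------------------
# pairwise thermostat sweeps
# ---------------------------------------------------------------------------

@njit(cache=True)
def shardlow_sweep(pos, vel, box, pbc_z, pi, pj, gamma, sigma, dt, key):
    """Shardlow S1 update of the dissipative + random pair dynamics.

    For each pair in the given order: an explicit half step followed by an
    implicit half step of the pair's relative-velocity Ornstein–Uhlenbeck
    dynamics, sharing one noise draw.  Updates velocities in place; exactly
    momentum conserving pair by pair.
    """
    sqrt_dt = np.sqrt(dt)
    for k in range(pi.shape[0]):
        a = pi[k]
        b = pj[k]
        r, ex, ey, ez, dx, dy, dz = _pair_geom(pos, box, pbc_z, a, b)
        if r >= 1.0:
            continue
        w = 1.0 - r
        w2 = w * w
        zeta = pair_normal(key, a, b)
        noise = sigma * w * zeta * sqrt_dt
        u = (ex * (vel[a, 0] - vel[b, 0]) + ey * (vel[a, 1] - vel[b, 1])
             + ez * (vel[a, 2] - vel[b, 2]))
        dv = 0.5 * (-gamma * w2 * u * dt + noise)
        vel[a, 0] += dv * ex
        vel[a, 1] += dv * ey
        vel[a, 2] += dv * ez
        vel[b, 0] -= dv * ex
        vel[b, 1] -= dv * ey
        vel[b, 2] -= dv * ez
        u2 = (ex * (vel[a, 0] - vel[b, 0]) + ey * (vel[a, 1] - vel[b, 1])
              + ez * (vel[a, 2] - vel[b, 2]))
        g = gamma * w2 * dt
        dv2 = 0.5 * (noise - g * u2) / (1.0 + g)
        vel[a, 0] += dv2 * ex
        vel[a, 1] += dv2 * ey
        vel[a, 2] += dv2 * ez
        vel[b, 0] -= dv2 * ex
        vel[b, 1] -= dv2 * ey
        vel[b, 2] -= dv2 * ez


@njit(cache=True)
def pnhln_sweep(pos, vel, box, pbc_z, pi, pj, xi, sigma, dt, kbt, key):
    """Pairwise Nosé–Hoover–Langevin friction sweep with adaptive friction ξ.

    One semi-implicit (unconditionally stable) kick per pair with friction
    ξ and fixed noise amplitude σ.  The control signal is the weighted
    relative-velocity energy excess over equipartition,

        G = Σ_pairs ω^D(r) [ |v_ij|² − 6 k_BT ],

    evaluated on the incoming velocities.  Using the full relative velocity
    (not only its longitudinal projection) lets the feedback sense heating
    stored in transverse pair modes, which the longitudinal friction then
    drains through collisional mixing; dξ/dt = G/μ shifts ξ until the
    discretization heating is cancelled.  Returns G.
    """
    sqrt_dt = np.sqrt(dt)
    G = 0.0
    for k in range(pi.shape[0]):
        a = pi[k]
        b = pj[k]
        r, ex, ey, ez, dx, dy, dz = _pair_geom(pos, box, pbc_z, a, b)
        if r >= 1.0:
            continue
        w = 1.0 - r
        w2 = w * w
        zeta = pair_normal(key, a, b)
        noise = sigma * w * zeta * sqrt_dt
        rvx = vel[a, 0] - vel[b, 0]
        rvy = vel[a, 1] - vel[b, 1]
        rvz = vel[a, 2] - vel[b, 2]
        u = ex * rvx + ey * rvy + ez * rvz
        G += w2 * (rvx * rvx + rvy * rvy + rvz * rvz - 6.0 * kbt)
        c = xi * w2 * dt
        denom = 1.0 + c
        if denom < 0.05:
            denom = 0.05  # guard against strongly negative transient ξ
        dv = 0.5 * (noise - c * u) / denom
        vel[a, 0] += dv * ex
        vel[a, 1] += dv * ey
        vel[a, 2] += dv * ez
        vel[b, 0] -= dv * ex
        vel[b, 1] -= dv * ey
        vel[b, 2] -= dv * ez
    return G


# ---------------------------------------------------------------------------
# boundaries
# ---------------------------------------------------------------------------

@njit(cache=True)
def apply_boundaries_kernel(pos, vel, box, pbc_z):
    """Wrap periodic axes into [0, L); reflect specularly at z walls.

    Returns the largest absolute out-of-box excursion seen before folding,
    in units of the corresponding box length (divergence diagnostic).
    """
    n = pos.shape[0]
    worst = 0.0
    for p in range(n):
        for d in range(2):
            L = box[d]
            x = pos[p, d]
            exc = abs(x - 0.5 * L) / L - 0.5
            if exc > worst:
                worst = exc
            x = x % L
            if x < 0.0:
                x += L
            if x >= L:
                x = 0.0
            pos[p, d] = x
        L = box[2]
        z = pos[p, 2]
        exc = abs(z - 0.5 * L) / L - 0.5
        if exc > worst:
            worst = exc
        if pbc_z:
            z = z % L
            if z < 0.0:
                z += L
            if z >= L:
                z = 0.0
            pos[p, 2] = z
        else:
            # fold into [0, 2L) then reflect; flip v_z on odd reflections
            z = z % (2.0 * L)
            if z < 0.0:
                z += 2.0 * L
            if z >= L:
                z = 2.0 * L - z
                vel[p, 2] = -vel[p, 2]
                if z >= L:  # z was exactly L
                    z = 0.0
            pos[p, 2] = z
    return worst
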
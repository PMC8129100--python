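"""Numba-compiled pairwise force kernel.

All-pairs evaluation of the exponential attraction/repulsion/adhesion forces
is the cost driver of a run (up to 8000 cells x 350 steps).  The kernel
exploits two things:

* a cutoff radius at which every force has decayed below 1e-4 of its
  strength (= 2 * tau for a 1%-at-tau exponential) — pairs beyond it are
  skipped;
* cells sorted by x so that for each cell only a contiguous window of
  partners needs inspection (the slit is long and thin, so the x-window is
  the effective neighbor list).

The shared exponential magnitude of a pair is computed once and applied to
both members (attraction differs only by the type-pair constant).
"""

from __future__ import annotations

import numpy as np
from numba import njit

LN001 = float(np.log(0.01))


@njit(cache=True, fastmath=True)
def _pair_forces_sorted(pos, types, as_mat, A, tau_a, R, tau_r, cutoff, forces):
    """Accumulate cell-cell forces; ``pos`` must be sorted by x."""
    n = pos.shape[0]
    ca = LN001 / tau_a
    cr = LN001 / tau_r
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        ti = types[i]
        for j in range(i + 1, n):
            dx = pos[j, 0] - xi
            if dx > cutoff:
                break
            dy = pos[j, 1] - yi
            dz = pos[j, 2] - zi
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > cutoff * cutoff:
                continue
            d = np.sqrt(d2)
            if d < 1e-9:
                # coincident cells: full repulsion along a deterministic
                # pseudo-random direction derived from the index pair
                h = np.float64((i * 2654435761 + j * 40503) % 10007)
                ux = np.cos(h)
                uy = np.sin(h)
                forces[i, 0] -= R * ux
                forces[i, 1] -= R * uy
                forces[j, 0] += R * ux
                forces[j, 1] += R * uy
                continue
            inv = 1.0 / d
            ux = dx * inv
            uy = dy * inv
            uz = dz * inv
            attr = A * np.exp(ca * d)
            rep = R * np.exp(cr * d)
            tj = types[j]
            fi = as_mat[ti, tj] * attr - rep  # on i, toward j
            fj = as_mat[tj, ti] * attr - rep  # on j, toward i
            forces[i, 0] += fi * ux
            forces[i, 1] += fi * uy
            forces[i, 2] += fi * uz
            forces[j, 0] -= fj * ux
            forces[j, 1] -= fj * uy
            forces[j, 2] -= fj * uz


@njit(cache=True, fastmath=True)
def _anchor_forces_sorted(pos, anchors_sorted, S, tau_s, cutoff, forces):
    """Accumulate substrate-adhesion forces; anchors sorted by x."""
    n = pos.shape[0]
    m = anchors_sorted.shape[0]
    cs = LN001 / tau_s
    for i in range(n):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        lo = np.searchsorted(anchors_sorted[:, 0], xi - cutoff)
        for a in range(lo, m):
            dx = anchors_sorted[a, 0] - xi
            if dx > cutoff:
                break
            dy = anchors_sorted[a, 1] - yi
            dz = -zi
            d2 = dx * dx + dy * dy + dz * dz
            if d2 > cutoff * cutoff or d2 < 1e-18:
                continue
            d = np.sqrt(d2)
            mag = S * np.exp(cs * d) / d
            forces[i, 0] += mag * dx
            forces[i, 1] += mag * dy
            forces[i, 2] += mag * dz


def compute_forces(positions, types, anchors, params):
    """Net force on every cell (N x 3 array).

    Parameters
    ----------
    positions : (N, 3) float array
    types : (N,) int array of CellType values
    anchors : (M, 2) float array of substrate anchor coordinates, or None
    params : model_core.ForceParameters
    """
    positions = np.ascontiguousarray(positions, dtype=np.float64)
    types = np.ascontiguousarray(types, dtype=np.int64)
    n = positions.shape[0]
    forces = np.zeros((n, 3))

    order = np.argsort(positions[:, 0], kind="stable")
    pos_s = np.ascontiguousarray(positions[order])
    types_s = types[order]
    forces_s = np.zeros((n, 3))
    cutoff = 2.0 * max(params.tau_a, params.tau_r)
    _pair_forces_sorted(
        pos_s, types_s, params.as_matrix(), params.A, params.tau_a,
        params.R, params.tau_r, cutoff, forces_s,
    )
    if anchors is not None and len(anchors):
        anchors = np.asarray(anchors, dtype=np.float64)
        a_s = np.ascontiguousarray(anchors[np.argsort(anchors[:, 0], kind="stable")])
        _anchor_forces_sorted(pos_s, a_s, params.S, params.tau_s, 2.0 * params.tau_s, forces_s)
    forces[order] = forces_s
    if not np.all(np.isfinite(forces)):
        bad = np.where(~np.isfinite(forces).all(axis=1))[0]
        raise FloatingPointError(f"non-finite force on cells {bad[:5].tolist()}")
    return forces
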
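"""Compiled inner loops of the folding dynamics.

The constrained joining dynamics is position-based: each step the two
selected beads take a displacement toward each other, after which a local
Gauss–Seidel relaxation restores every geometric constraint —

* bond constraints (equality): linked beads i, j are held at their contact
  distance r_i + r_j;
* volume exclusion (inequality): unlinked beads may not come closer than
  their contact distance.

The relaxation is *local*: it starts from the beads that moved and follows
the constraint graph outward until no violation above the projection
tolerance remains.  When the relaxation queue drains, every constraint is
satisfied (constraints away from moved beads were satisfied at the start
of the step by induction), so the step invariants hold without a global
pass.  A Verlet-style candidate pair list with a safety margin keeps the
exclusion constraints that need checking to O(N).

All functions here are ``numba.njit``-compiled and operate on preallocated
arrays owned by :class:`geofold.folding._SimState`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by _attempt
SUCCESS = 1
FAIL = 0

_LCG_MULT = np.int64(6364136223846793005)
_LCG_INC = np.int64(1442695040888963407)


@njit(cache=True, inline="always")
def _lcg(state):
    """64-bit LCG; returns (new_state, uniform in [-1, 1))."""
    state = state * _LCG_MULT + _LCG_INC
    # use the high 32 bits for the uniform deviate
    u = np.float64((state >> np.int64(33)) & np.int64(0x7FFFFFFF))
    return state, u / np.float64(0x40000000) - 1.0


@njit(cache=True)
def _rebuild_candidates(pos, radii, adj, margin, cand):
    """Fill ``cand`` with all non-bonded pairs within contact + margin.

    Returns the number of candidate pairs, or -1 on capacity overflow.
    """
    n = pos.shape[0]
    cap = cand.shape[0]
    m = 0
    for a in range(n):
        xa = pos[a, 0]
        ya = pos[a, 1]
        za = pos[a, 2]
        ra = radii[a]
        for b in range(a + 1, n):
            if adj[a, b] != 0:
                continue
            dx = pos[b, 0] - xa
            dy = pos[b, 1] - ya
            dz = pos[b, 2] - za
            cut = ra + radii[b] + margin
            if dx * dx + dy * dy + dz * dz < cut * cut:
                if m >= cap:
                    return -1
                cand[m, 0] = a
                cand[m, 1] = b
                m += 1
    return m


@njit(cache=True)
def _build_csr(n, bonds, n_bonds, cand, n_cand, indptr, nbr, ntype):
    """Per-bead CSR over bond (type 1) and candidate-overlap (type 0) pairs.

    Returns total entries written, or -1 on capacity overflow.
    """
    total = 2 * (n_bonds + n_cand)
    if total > nbr.shape[0]:
        return -1
    for a in range(n + 1):
        indptr[a] = 0
    for e in range(n_bonds):
        indptr[bonds[e, 0] + 1] += 1
        indptr[bonds[e, 1] + 1] += 1
    for m in range(n_cand):
        indptr[cand[m, 0] + 1] += 1
        indptr[cand[m, 1] + 1] += 1
    for a in range(n):
        indptr[a + 1] += indptr[a]
    cursor = indptr[:n].copy()
    for e in range(n_bonds):
        a = bonds[e, 0]
        b = bonds[e, 1]
        nbr[cursor[a]] = b
        ntype[cursor[a]] = 1
        cursor[a] += 1
        nbr[cursor[b]] = a
        ntype[cursor[b]] = 1
        cursor[b] += 1
    for m in range(n_cand):
        a = cand[m, 0]
        b = cand[m, 1]
        nbr[cursor[a]] = b
        ntype[cursor[a]] = 0
        cursor[a] += 1
        nbr[cursor[b]] = a
        ntype[cursor[b]] = 0
        cursor[b] += 1
    return total


#: Gauss–Seidel over-relaxation factor; >1 accelerates convergence on the
#: stiff, rigidly packed clusters where plain projection rings for long.
_SOR_OMEGA = 1.2


@njit(cache=True)
def _relax(pos, radii, indptr, nbr, ntype, queue, inq, seeds, n_seeds,
           tol_bond_half, tol_over_half, max_ops):
    """Local Gauss–Seidel constraint relaxation seeded at the given beads.

    Returns the number of corrections applied, or -1 if ``max_ops`` was
    exhausted before convergence.
    """
    qcap = queue.shape[0]
    head = 0
    tail = 0
    for s in range(n_seeds):
        a = seeds[s]
        if inq[a] == 0:
            queue[tail % qcap] = a
            inq[a] = 1
            tail += 1
    ops = 0
    while head < tail:
        a = queue[head % qcap]
        head += 1
        inq[a] = 0
        for p in range(indptr[a], indptr[a + 1]):
            b = nbr[p]
            dx = pos[b, 0] - pos[a, 0]
            dy = pos[b, 1] - pos[a, 1]
            dz = pos[b, 2] - pos[a, 2]
            d2 = dx * dx + dy * dy + dz * dz
            d0 = radii[a] + radii[b]
            if ntype[p] == 0 and d2 >= d0 * d0:
                continue  # non-overlapping candidate pair: nothing to do
            d = np.sqrt(d2)
            viol = d - d0
            if ntype[p] == 0:
                if -viol <= tol_over_half:
                    continue
            else:
                # bonds: may stretch up to the bond tolerance but may only
                # compress within the (tighter) exclusion tolerance
                if -tol_over_half <= viol <= tol_bond_half:
                    continue
            if ops >= max_ops:
                # drain bookkeeping so inq is clean for the next call
                while head < tail:
                    inq[queue[head % qcap]] = 0
                    head += 1
                return -1
            ops += 1
            if d < 1e-12:
                # coincident beads: separate along an arbitrary axis
                dx = d0
                dy = 0.0
                dz = 0.0
                d = d0
                viol = 0.0 - d0
            # over-relax equality (bond) corrections only: overshooting an
            # inequality would fling barely-touching beads apart
            omega = _SOR_OMEGA if ntype[p] != 0 else 1.0
            c = 0.5 * omega * viol / d
            pos[a, 0] += c * dx
            pos[a, 1] += c * dy
            pos[a, 2] += c * dz
            pos[b, 0] -= c * dx
            pos[b, 1] -= c * dy
            pos[b, 2] -= c * dz
            if inq[a] == 0:
                queue[tail % qcap] = a
                inq[a] = 1
                tail += 1
            if inq[b] == 0:
                queue[tail % qcap] = b
                inq[b] = 1
                tail += 1
    return ops


@njit(cache=True)
def _relax_all(pos, radii, indptr, nbr, ntype, queue, inq,
               tol_bond_half, tol_over_half, max_ops):
    """Relaxation seeded at every bead (used to settle a fresh chain)."""
    n = pos.shape[0]
    seeds = np.empty(1, dtype=np.int64)
    total = 0
    for a in range(n):
        seeds[0] = a
        r = _relax(pos, radii, indptr, nbr, ntype, queue, inq, seeds, 1,
                   tol_bond_half, tol_over_half, max_ops)
        if r < 0:
            return -1
        total += r
    return total


@njit(cache=True)
def _slide_and_limit(pos, radii, indptr, nbr, ntype, a, partner,
                     mx, my, mz, over_budget, bond_budget):
    """Clip the proposed move of bead ``a`` against its constraints.

    Two stages, both excepting the joining partner:

    1. *sliding*: for every constraint already at its budget boundary the
       move component along the forbidden normal direction is removed, so a
       bead pressed against its cage can still slide tangentially;
    2. *limiting*: the remaining move is scaled so that no candidate
       neighbor is penetrated deeper than ``over_budget`` and no bond of
       ``a`` is stretched or compressed beyond ``bond_budget``.

    Bounding the per-step constraint violation at the source keeps the
    relaxation wake small: a fully caged bead simply stops instead of being
    projected back out of its cage.  Returns the applied move vector.
    """
    # ---- stage 1: slide along active contact planes (two sweeps) --------
    for _ in range(2):
        if mx * mx + my * my + mz * mz < 1e-30:
            return 0.0, 0.0, 0.0
        for p in range(indptr[a], indptr[a + 1]):
            b = nbr[p]
            if b == partner:
                continue
            px = pos[b, 0] - pos[a, 0]
            py = pos[b, 1] - pos[a, 1]
            pz = pos[b, 2] - pos[a, 2]
            d = np.sqrt(px * px + py * py + pz * pz)
            if d < 1e-12:
                continue
            d0 = radii[a] + radii[b]
            # bonds compress only within the exclusion band but may
            # stretch up to the bond budget (same asymmetry as the relax)
            in_budget = over_budget
            out_budget = bond_budget
            act = 0.25 * in_budget
            md = (mx * px + my * py + mz * pz) / d
            if d <= d0 - in_budget + act and md > 0.0:
                # at the approach boundary and pushing in: slide
                mx -= md * px / d
                my -= md * py / d
                mz -= md * pz / d
            elif ntype[p] != 0 and d >= d0 + out_budget - 0.25 * out_budget and md < 0.0:
                # bond at the stretch boundary and pulling away: slide
                mx -= md * px / d
                my -= md * py / d
                mz -= md * pz / d

    # ---- stage 2: scale so no constraint crosses its budget mid-step ----
    alpha = 1.0
    mm = mx * mx + my * my + mz * mz
    if mm < 1e-30:
        return 0.0, 0.0, 0.0
    for p in range(indptr[a], indptr[a + 1]):
        b = nbr[p]
        if b == partner:
            continue
        px = pos[b, 0] - pos[a, 0]
        py = pos[b, 1] - pos[a, 1]
        pz = pos[b, 2] - pos[a, 2]
        pp = px * px + py * py + pz * pz
        pm = px * mx + py * my + pz * mz
        d0 = radii[a] + radii[b]
        # approach bound: |alpha*m - p| >= d0 - over_budget (for bonds the
        # compression band is the exclusion band, not the stretch band)
        r_in = d0 - over_budget
        if r_in > 0.0 and pm > 0.0 and pp > r_in * r_in:
            disc = pm * pm - mm * (pp - r_in * r_in)
            if disc > 0.0:
                t = (pm - np.sqrt(disc)) / mm
                if 0.0 <= t < alpha:
                    alpha = t
        if ntype[p] != 0:
            # bonds also bound the stretch: |alpha*m - p| <= d0 + budget
            r_out = d0 + bond_budget
            if pp < r_out * r_out:
                t = (pm + np.sqrt(pm * pm + mm * (r_out * r_out - pp))) / mm
                if t < alpha:
                    alpha = t
    return alpha * mx, alpha * my, alpha * mz


@njit(cache=True)
def _measure_violations(pos, radii, adj, bonds, n_bonds):
    """Exhaustive O(N^2) constraint check.

    Returns (max bond deviation |d - d0|, max overlap depth d0 - d), both
    absolute lengths.
    """
    n = pos.shape[0]
    max_bond = 0.0
    max_over = 0.0
    for e in range(n_bonds):
        a = bonds[e, 0]
        b = bonds[e, 1]
        dx = pos[b, 0] - pos[a, 0]
        dy = pos[b, 1] - pos[a, 1]
        dz = pos[b, 2] - pos[a, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        dev = abs(d - (radii[a] + radii[b]))
        if dev > max_bond:
            max_bond = dev
    for a in range(n):
        for b in range(a + 1, n):
            # volume exclusion applies to every pair, bonded or not
            dx = pos[b, 0] - pos[a, 0]
            dy = pos[b, 1] - pos[a, 1]
            dz = pos[b, 2] - pos[a, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            over = (radii[a] + radii[b]) - d
            if over > max_over:
                max_over = over
    return max_bond, max_over


@njit(cache=True)
def _assign_sides(n, indptr, nbr, ntype, i, j, side, dist, queue):
    """Two-source BFS over the bond graph: side[a] = 0 if a is closer to i,
    1 if closer to j (ties go to the i side).  The bond graph is connected
    (backbone), so every bead gets a side."""
    for a in range(n):
        side[a] = -1
        dist[a] = -1
    qcap = queue.shape[0]
    head = 0
    tail = 0
    side[i] = 0
    dist[i] = 0
    queue[tail % qcap] = i
    tail += 1
    side[j] = 1
    dist[j] = 0
    queue[tail % qcap] = j
    tail += 1
    while head < tail:
        a = queue[head % qcap]
        head += 1
        for p in range(indptr[a], indptr[a + 1]):
            if ntype[p] != 1:
                continue
            b = nbr[p]
            if side[b] < 0:
                side[b] = side[a]
                dist[b] = dist[a] + 1
                queue[tail % qcap] = b
                tail += 1


@njit(cache=True)
def _collect_crossing(n, indptr, nbr, ntype, side, cross, cross_type):
    """Pairs (a, b) with side[a] = 0, side[b] = 1 from the constraint CSR.

    Returns the number of crossing pairs, or -1 on overflow.
    """
    cap = cross.shape[0]
    m = 0
    for a in range(n):
        if side[a] != 0:
            continue
        for p in range(indptr[a], indptr[a + 1]):
            b = nbr[p]
            if side[b] != 1:
                continue
            if m >= cap:
                return -1
            cross[m, 0] = a
            cross[m, 1] = b
            cross_type[m] = ntype[p]
            m += 1
    return m


@njit(cache=True)
def _side_screw(pos, prev, radii, side, cross, cross_type, n_cross, i, j,
                ux, uy, uz, s, v_cap, over_budget, bond_budget, delta):
    """Hinge rotation of the two bond-graph sides toward each other.

    Each side rotates rigidly about its *hinge anchor* — the centroid of
    its beads that carry bonds across the cut — with the torque the pull
    force exerts at the selected bead.  This is the motion an articulated
    pair of lobes actually performs when folding shut (for a mid-chain cut
    it is the classic hinge fold; for a terminal bead it is an orbit
    around its bonded neighbor).  The common scale factor alpha is chosen
    so no crossing constraint leaves its budget band; the rotation itself
    is applied exactly (Rodrigues), so intra-side geometry is untouched.
    ``prev`` is co-transformed: the hinge motion is a forcing renewed each
    step, not a velocity.  Returns alpha (0 when jammed)."""
    n = pos.shape[0]
    # hinge anchors: centroid of each side's crossing-bond endpoints
    a0x = a0y = a0z = 0.0
    a1x = a1y = a1z = 0.0
    n0 = 0
    n1 = 0
    for c in range(n_cross):
        if cross_type[c] != 1:
            continue
        a = cross[c, 0]
        b = cross[c, 1]
        a0x += pos[a, 0]
        a0y += pos[a, 1]
        a0z += pos[a, 2]
        n0 += 1
        a1x += pos[b, 0]
        a1y += pos[b, 1]
        a1z += pos[b, 2]
        n1 += 1
    if n0 == 0 or n1 == 0:
        # no crossing bonds (cannot happen for a connected backbone)
        return 0.0
    a0x /= n0
    a0y /= n0
    a0z /= n0
    a1x /= n1
    a1y /= n1
    a1z /= n1

    # farthest side bead from each anchor bounds the linearization error
    rmax0 = 1.0
    rmax1 = 1.0
    for a in range(n):
        if side[a] == 0:
            rx = pos[a, 0] - a0x
            ry = pos[a, 1] - a0y
            rz = pos[a, 2] - a0z
        else:
            rx = pos[a, 0] - a1x
            ry = pos[a, 1] - a1y
            rz = pos[a, 2] - a1z
        rr = np.sqrt(rx * rx + ry * ry + rz * rz)
        if side[a] == 0 and rr > rmax0:
            rmax0 = rr
        elif side[a] != 0 and rr > rmax1:
            rmax1 = rr

    # rotation axes: torque of the pull about each hinge anchor
    r0x = pos[i, 0] - a0x
    r0y = pos[i, 1] - a0y
    r0z = pos[i, 2] - a0z
    w0x = r0y * uz - r0z * uy
    w0y = r0z * ux - r0x * uz
    w0z = r0x * uy - r0y * ux
    w0n = np.sqrt(w0x * w0x + w0y * w0y + w0z * w0z)
    r0n = np.sqrt(r0x * r0x + r0y * r0y + r0z * r0z)
    th0 = 0.0
    if w0n > 1e-12 and r0n > 1e-9:
        w0x /= w0n
        w0y /= w0n
        w0z /= w0n
        th0 = s / r0n
        cap = np.sqrt(0.2 * over_budget / rmax0)
        if th0 > cap:
            th0 = cap
        if th0 * rmax0 > v_cap:
            th0 = v_cap / rmax0
    r1x = pos[j, 0] - a1x
    r1y = pos[j, 1] - a1y
    r1z = pos[j, 2] - a1z
    w1x = -(r1y * uz - r1z * uy)
    w1y = -(r1z * ux - r1x * uz)
    w1z = -(r1x * uy - r1y * ux)
    w1n = np.sqrt(w1x * w1x + w1y * w1y + w1z * w1z)
    r1n = np.sqrt(r1x * r1x + r1y * r1y + r1z * r1z)
    th1 = 0.0
    if w1n > 1e-12 and r1n > 1e-9:
        w1x /= w1n
        w1y /= w1n
        w1z /= w1n
        th1 = s / r1n
        cap = np.sqrt(0.2 * over_budget / rmax1)
        if th1 > cap:
            th1 = cap
        if th1 * rmax1 > v_cap:
            th1 = v_cap / rmax1
    if th0 == 0.0 and th1 == 0.0:
        return 0.0

    # linearized displacement field, for the alpha limit only
    for a in range(n):
        if side[a] == 0:
            rx = pos[a, 0] - a0x
            ry = pos[a, 1] - a0y
            rz = pos[a, 2] - a0z
            delta[a, 0] = th0 * (w0y * rz - w0z * ry)
            delta[a, 1] = th0 * (w0z * rx - w0x * rz)
            delta[a, 2] = th0 * (w0x * ry - w0y * rx)
        else:
            rx = pos[a, 0] - a1x
            ry = pos[a, 1] - a1y
            rz = pos[a, 2] - a1z
            delta[a, 0] = th1 * (w1y * rz - w1z * ry)
            delta[a, 1] = th1 * (w1z * rx - w1x * rz)
            delta[a, 2] = th1 * (w1x * ry - w1y * rx)

    # limit the common scale so every crossing constraint stays in band
    alpha = 1.0
    for c in range(n_cross):
        a = cross[c, 0]
        b = cross[c, 1]
        if (a == i and b == j) or (a == j and b == i):
            continue
        mx = delta[a, 0] - delta[b, 0]
        my = delta[a, 1] - delta[b, 1]
        mz = delta[a, 2] - delta[b, 2]
        mm = mx * mx + my * my + mz * mz
        if mm < 1e-30:
            continue
        px = pos[b, 0] - pos[a, 0]
        py = pos[b, 1] - pos[a, 1]
        pz = pos[b, 2] - pos[a, 2]
        pp = px * px + py * py + pz * pz
        pm = px * mx + py * my + pz * mz
        d0 = radii[a] + radii[b]
        r_in = d0 - over_budget
        if r_in > 0.0 and pm > 0.0:
            if pp <= r_in * r_in:
                return 0.0
            disc = pm * pm - mm * (pp - r_in * r_in)
            if disc > 0.0:
                t = (pm - np.sqrt(disc)) / mm
                if 0.0 <= t < alpha:
                    alpha = t
        if cross_type[c] != 0:
            r_out = d0 + bond_budget
            if pp < r_out * r_out:
                t = (pm + np.sqrt(pm * pm + mm * (r_out * r_out - pp))) / mm
                if t < alpha:
                    alpha = t
            elif pm <= 0.0:
                return 0.0
    if alpha <= 0.0:
        return 0.0

    # exact rigid application to pos and prev
    a0t = alpha * th0
    a1t = alpha * th1
    c0t = np.cos(a0t)
    s0t = np.sin(a0t)
    c1t = np.cos(a1t)
    s1t = np.sin(a1t)
    for a in range(n):
        if side[a] == 0:
            cxc, cyc, czc = a0x, a0y, a0z
            wx, wy, wz = w0x, w0y, w0z
            ct, st = c0t, s0t
        else:
            cxc, cyc, czc = a1x, a1y, a1z
            wx, wy, wz = w1x, w1y, w1z
            ct, st = c1t, s1t
        rx = pos[a, 0] - cxc
        ry = pos[a, 1] - cyc
        rz = pos[a, 2] - czc
        wdr = wx * rx + wy * ry + wz * rz
        cx = wy * rz - wz * ry
        cy = wz * rx - wx * rz
        cz = wx * ry - wy * rx
        pos[a, 0] = cxc + rx * ct + cx * st + wx * wdr * (1.0 - ct)
        pos[a, 1] = cyc + ry * ct + cy * st + wy * wdr * (1.0 - ct)
        pos[a, 2] = czc + rz * ct + cz * st + wz * wdr * (1.0 - ct)
        rx = prev[a, 0] - cxc
        ry = prev[a, 1] - cyc
        rz = prev[a, 2] - czc
        wdr = wx * rx + wy * ry + wz * rz
        cx = wy * rz - wz * ry
        cy = wz * rx - wx * rz
        cz = wx * ry - wy * rx
        prev[a, 0] = cxc + rx * ct + cx * st + wx * wdr * (1.0 - ct)
        prev[a, 1] = cyc + ry * ct + cy * st + wy * wdr * (1.0 - ct)
        prev[a, 2] = czc + rz * ct + cz * st + wz * wdr * (1.0 - ct)
    return alpha


@njit(cache=True)
def _coast_limit(base, vel, radii, indptr, nbr, ntype, a,
                 over_budget, bond_budget):
    """Clip bead ``a``'s coasting velocity against its constraints,
    evaluated at the *predicted* positions of its neighbors (base + their
    own velocity).  Co-moving groups (a dragged arm, a rotating side)
    pass untouched because their relative motion is zero, while a bead
    coasting into a static cage is stopped at the budget boundary.
    Bonds may stretch up to ``bond_budget`` but compress only within the
    ``over_budget`` exclusion band.  Returns the clipped velocity."""
    mx = vel[a, 0]
    my = vel[a, 1]
    mz = vel[a, 2]
    for _ in range(2):
        if mx * mx + my * my + mz * mz < 1e-30:
            return 0.0, 0.0, 0.0
        for p in range(indptr[a], indptr[a + 1]):
            b = nbr[p]
            px = base[b, 0] + vel[b, 0] - base[a, 0]
            py = base[b, 1] + vel[b, 1] - base[a, 1]
            pz = base[b, 2] + vel[b, 2] - base[a, 2]
            d = np.sqrt(px * px + py * py + pz * pz)
            if d < 1e-12:
                continue
            d0 = radii[a] + radii[b]
            act = 0.25 * over_budget
            md = (mx * px + my * py + mz * pz) / d
            if d <= d0 - over_budget + act and md > 0.0:
                mx -= md * px / d
                my -= md * py / d
                mz -= md * pz / d
            elif ntype[p] != 0 and d >= d0 + 0.75 * bond_budget and md < 0.0:
                mx -= md * px / d
                my -= md * py / d
                mz -= md * pz / d
    alpha = 1.0
    mm = mx * mx + my * my + mz * mz
    if mm < 1e-30:
        return 0.0, 0.0, 0.0
    for p in range(indptr[a], indptr[a + 1]):
        b = nbr[p]
        px = base[b, 0] + vel[b, 0] - base[a, 0]
        py = base[b, 1] + vel[b, 1] - base[a, 1]
        pz = base[b, 2] + vel[b, 2] - base[a, 2]
        pp = px * px + py * py + pz * pz
        pm = px * mx + py * my + pz * mz
        d0 = radii[a] + radii[b]
        r_in = d0 - over_budget
        if r_in > 0.0 and pm > 0.0 and pp > r_in * r_in:
            disc = pm * pm - mm * (pp - r_in * r_in)
            if disc > 0.0:
                t = (pm - np.sqrt(disc)) / mm
                if 0.0 <= t < alpha:
                    alpha = t
        if ntype[p] != 0:
            r_out = d0 + bond_budget
            if pp < r_out * r_out:
                t = (pm + np.sqrt(pm * pm + mm * (r_out * r_out - pp))) / mm
                if t < alpha:
                    alpha = t
            elif pm <= 0.0:
                alpha = 0.0
    return alpha * mx, alpha * my, alpha * mz



@njit(cache=True)
def _dirty_beads(pos, start, radii, indptr, nbr, thresh, mask):
    """Mark beads whose local geometry changed between ``start`` and
    ``pos``: any constraint-graph neighbor distance that moved by more
    than ``thresh``.  Rigid motions of whole regions leave their interior
    clean, so after a successful link only the rearranged neighborhood is
    marked."""
    n = pos.shape[0]
    for a in range(n):
        mask[a] = 0
    for a in range(n):
        for p in range(indptr[a], indptr[a + 1]):
            b = nbr[p]
            if b < a:
                continue
            dxn = pos[b, 0] - pos[a, 0]
            dyn = pos[b, 1] - pos[a, 1]
            dzn = pos[b, 2] - pos[a, 2]
            dn = np.sqrt(dxn * dxn + dyn * dyn + dzn * dzn)
            dxo = start[b, 0] - start[a, 0]
            dyo = start[b, 1] - start[a, 1]
            dzo = start[b, 2] - start[a, 2]
            do = np.sqrt(dxo * dxo + dyo * dyo + dzo * dzo)
            if abs(dn - do) > thresh:
                mask[a] = 1
                mask[b] = 1
    return 0

@njit(cache=True)
def _max_disp(pos, ref):
    m = 0.0
    for k in range(pos.shape[0]):
        dx = pos[k, 0] - ref[k, 0]
        dy = pos[k, 1] - ref[k, 1]
        dz = pos[k, 2] - ref[k, 2]
        d2 = dx * dx + dy * dy + dz * dz
        if d2 > m:
            m = d2
    return np.sqrt(m)


@njit(cache=True)
def _attempt(
    pos,
    radii,
    adj,
    bonds,
    n_bonds,
    cand,
    meta,  # int64[3]: [n_cand, csr_valid, reserved]
    pos_ref,
    indptr,
    nbr,
    ntype,
    queue,
    inq,
    step_buf,
    prev,  # float64[n, 3]: previous-step positions (inertia)
    mid,  # float64[n, 3] scratch: positions after intentional moves
    vel,  # float64[n, 3] scratch: damped velocities
    seeds,  # int64[2n + 4] scratch for relaxation seeding
    move_budget,  # float64[n]: per-bead bond stretch/compress budget
    side,  # int8[n] scratch: bond-graph side of each bead
    sdist,  # int64[n] scratch: BFS distances
    cross,  # int64[cap, 2] scratch: crossing constraint pairs
    cross_type,  # int8[cap]
    i,
    j,
    # scalar parameters
    step_size,
    step_gain,
    step_cap,
    kick_frac,
    push_depth,
    inertia_damp,
    v_cap,
    v_floor,
    tol_contact,
    tol_bond_half,
    tol_over_half,
    margin,
    max_steps,
    stall_window,
    min_rate,
    blocked_limit,
    max_relax_ops,
    kick_seed,
    validate,
    viol_out,  # float64[2]: running max bond / overlap violation (validate mode)
    diag,  # int64[4]: rebuilds, relax corrections, relax calls, reserved
):
    """Attempt to join beads i and j.  Returns (status, steps taken).

    ``pos`` is advanced in place; the caller owns rollback on failure.
    The dynamics is position-Verlet with strong damping: beads keep a
    damped fraction of their last displacement, so a pulled chain arm or a
    bonded cluster coasts instead of being dragged diffusively bond by
    bond.  The relaxation is seeded at every bead that moved this step.
    """
    n = pos.shape[0]
    contact_ij = radii[i] + radii[j]
    succ_dist = contact_ij * (1.0 + tol_contact)
    best = 1e300
    hist = np.empty(stall_window, dtype=np.float64)
    rng_state = np.int64(kick_seed)
    blocked = 0
    net_tol = 0.1 * step_size
    prev[:, :] = pos
    cross_budget = 0.9 * tol_bond_half
    cross_over = 0.9 * tol_over_half  # interface stays inside the band
    n_cross = -1  # crossing set recomputed after every CSR rebuild
    sides_ready = False

    for step in range(max_steps):
        # ---- keep the candidate list valid (Verlet skin logic) ----------
        # worst per-step motion: capped pull plus kick, or coasting cap
        step_reach = step_cap * (1.0 + 1.8 * kick_frac) + v_cap
        disp = _max_disp(pos, pos_ref)
        if meta[1] == 0 or 2.0 * (disp + step_reach) + 0.05 > margin:
            m = _rebuild_candidates(pos, radii, adj, margin, cand)
            if m < 0:
                return -2, step  # capacity overflow -> caller grows arrays
            diag[0] += 1
            meta[0] = m
            pos_ref[:, :] = pos
            if _build_csr(pos.shape[0], bonds, n_bonds, cand, m, indptr, nbr, ntype) < 0:
                return -2, step
            meta[1] = 1
            # pairs that entered the candidate list mid-flight may already
            # violate: sweep every bead once so no overlap goes unseen
            for a in range(n):
                seeds[a] = a
            rr = _relax(pos, radii, indptr, nbr, ntype, queue, inq, seeds, n,
                        tol_bond_half, tol_over_half, 100 * max_relax_ops)
            if rr > 0:
                diag[3] += rr
            n_cross = -1

        if not sides_ready:
            # the bond graph is fixed for the whole attempt: split it once
            _assign_sides(n, indptr, nbr, ntype, i, j, side, sdist, queue)
            sides_ready = True
            n_cross = -1
        if n_cross < 0:
            n_cross = _collect_crossing(n, indptr, nbr, ntype, side, cross, cross_type)
            if n_cross < 0:
                return -2, step

        # ---- success / stall bookkeeping --------------------------------
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d <= succ_dist:
            return SUCCESS, step
        if d < best:
            best = d
        if step >= stall_window:
            if hist[step % stall_window] - best < stall_window * min_rate:
                return FAIL, step
        hist[step % stall_window] = best

        # ---- inertial coasting of every bead moved recently ---------------
        step_buf[:, :] = pos
        n_seeds = 0
        any_v = False
        for a in range(n):
            vx = inertia_damp * (pos[a, 0] - prev[a, 0])
            vy = inertia_damp * (pos[a, 1] - prev[a, 1])
            vz = inertia_damp * (pos[a, 2] - prev[a, 2])
            v2 = vx * vx + vy * vy + vz * vz
            if v2 > v_floor * v_floor:
                if v2 > v_cap * v_cap:
                    f = v_cap / np.sqrt(v2)
                    vx *= f
                    vy *= f
                    vz *= f
                vel[a, 0] = vx
                vel[a, 1] = vy
                vel[a, 2] = vz
                any_v = True
            else:
                vel[a, 0] = 0.0
                vel[a, 1] = 0.0
                vel[a, 2] = 0.0
        if any_v:
            for a in range(n):
                if vel[a, 0] == 0.0 and vel[a, 1] == 0.0 and vel[a, 2] == 0.0:
                    continue
                cvx, cvy, cvz = _coast_limit(step_buf, vel, radii, indptr, nbr,
                                             ntype, a, push_depth, move_budget[a])
                if cvx * cvx + cvy * cvy + cvz * cvz > 1e-24:
                    pos[a, 0] = step_buf[a, 0] + cvx
                    pos[a, 1] = step_buf[a, 1] + cvy
                    pos[a, 2] = step_buf[a, 2] + cvz
                    seeds[n_seeds] = a
                    n_seeds += 1
        # ---- rigid relative translation of the two graph sides -----------
        ux = dx / d
        uy = dy / d
        uz = dz / d
        gap = d - contact_ij
        t_mag = step_size
        if t_mag > 0.4 * gap:
            t_mag = 0.4 * gap
        screw_alpha = _side_screw(pos, prev, radii, side, cross, cross_type, n_cross,
                                  i, j, ux, uy, uz, t_mag, v_cap,
                                  cross_over, cross_budget, vel)
        if screw_alpha > 1e-6:
            diag[4] += 1
            # rigid rotations leave second-order residuals everywhere:
            # give the relaxation a full sweep's worth of seeds
            n_seeds = 0
            for a in range(n):
                seeds[a] = a
            n_seeds = n

        # ---- displacement toward each other + transverse kick ------------
        dx = pos[j, 0] - pos[i, 0]
        dy = pos[j, 1] - pos[i, 1]
        dz = pos[j, 2] - pos[i, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d > 1e-12:
            ux = dx / d
            uy = dy / d
            uz = dz / d
        gap = d - contact_ij
        s = step_gain * gap
        if s < step_size:
            s = step_size
        if s > step_cap:
            s = step_cap
        if s > 0.4 * gap and gap > 0.0:
            s = 0.4 * gap  # close pairs converge without overshooting contact
        elif gap <= 0.0:
            s = 0.0
        rng_state, k1 = _lcg(rng_state)
        rng_state, k2 = _lcg(rng_state)
        rng_state, k3 = _lcg(rng_state)
        rng_state, k4 = _lcg(rng_state)
        rng_state, k5 = _lcg(rng_state)
        rng_state, k6 = _lcg(rng_state)
        ka = kick_frac * s
        mix = s * ux + ka * k1
        miy = s * uy + ka * k2
        miz = s * uz + ka * k3
        mjx = -s * ux + ka * k4
        mjy = -s * uy + ka * k5
        mjz = -s * uz + ka * k6
        mix, miy, miz = _slide_and_limit(pos, radii, indptr, nbr, ntype, i, j,
                                         mix, miy, miz, push_depth, move_budget[i])
        mjx, mjy, mjz = _slide_and_limit(pos, radii, indptr, nbr, ntype, j, i,
                                         mjx, mjy, mjz, push_depth, move_budget[j])
        pos[i, 0] += mix
        pos[i, 1] += miy
        pos[i, 2] += miz
        pos[j, 0] += mjx
        pos[j, 1] += mjy
        pos[j, 2] += mjz
        seeds[n_seeds] = i
        seeds[n_seeds + 1] = j
        n_seeds += 2
        mid[:, :] = pos
        # crossing endpoints felt the side translation: seed them too
        for c in range(n_cross):
            if n_seeds >= seeds.shape[0] - 1:
                break
            seeds[n_seeds] = cross[c, 0]
            seeds[n_seeds + 1] = cross[c, 1]
            n_seeds += 2

        # ---- restore all constraints locally ------------------------------
        r = _relax(pos, radii, indptr, nbr, ntype, queue, inq, seeds, n_seeds,
                   tol_bond_half, tol_over_half, max_relax_ops)
        diag[2] += 1
        if r > 0:
            diag[1] += r
        if r < 0:
            # relaxation did not converge: reject the step, kill momentum
            pos[:, :] = step_buf
            prev[:, :] = step_buf
        if r >= 0 and validate != 0:
            mb, mo = _measure_violations(pos, radii, adj, bonds, n_bonds)
            if mb > viol_out[0]:
                viol_out[0] = mb
            if mo > viol_out[1]:
                viol_out[1] = mo

        # ---- fast failure: neither bead actually moved --------------------
        nix = pos[i, 0] - step_buf[i, 0]
        niy = pos[i, 1] - step_buf[i, 1]
        niz = pos[i, 2] - step_buf[i, 2]
        njx = pos[j, 0] - step_buf[j, 0]
        njy = pos[j, 1] - step_buf[j, 1]
        njz = pos[j, 2] - step_buf[j, 2]
        net = np.sqrt(nix * nix + niy * niy + niz * niz) + np.sqrt(
            njx * njx + njy * njy + njz * njz
        )
        if net < net_tol:
            blocked += 1
            if blocked >= blocked_limit:
                return FAIL, step + 1
        else:
            blocked = 0

    return FAIL, max_steps
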
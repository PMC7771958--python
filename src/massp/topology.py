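"""Digital topology: simple points, topology-preserving fast marching, and
volume-constrained concurrent region growing.

Connectivity follows the standard digital duality (26 for foreground, 6 for
background). A voxel is *simple* when adding it to the foreground changes
neither the component/tunnel/cavity structure of the foreground nor of the
background; the test uses the local characterization by connectivity numbers
(one 26-component of foreground in the 26-neighborhood, one 6-component of
background in the 18-neighborhood touching a face neighbor).

The fast marching pass accepts voxels in decreasing posterior order, only
when acceptance preserves simple-point topology, and forces the corrected
value of each accepted voxel down to the smallest value accepted before it —
so every superlevel set of the output is a single 26-connected component
with simply connected complement ("spherical object topology"). Voxels that
are popped while non-simple are re-queued whenever one of their neighbors is
accepted; voxels never acceptable are capped below the smallest accepted
value.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["is_simple_point", "topology_correct_field", "grow_regions"]


def _build_tables():
    offs26 = np.array(
        [
            (dx, dy, dz)
            for dx in (-1, 0, 1)
            for dy in (-1, 0, 1)
            for dz in (-1, 0, 1)
            if (dx, dy, dz) != (0, 0, 0)
        ],
        dtype=np.int64,
    )
    n26 = len(offs26)
    adj26 = np.zeros((n26, n26), dtype=np.bool_)
    for i in range(n26):
        for j in range(n26):
            if i != j and np.max(np.abs(offs26[i] - offs26[j])) <= 1:
                adj26[i, j] = True
    # 18-neighborhood (face + edge neighbors) as indices into offs26
    idx18 = np.array(
        [i for i in range(n26) if np.sum(np.abs(offs26[i])) <= 2], dtype=np.int64
    )
    n18 = len(idx18)
    adj6_18 = np.zeros((n18, n18), dtype=np.bool_)
    for a in range(n18):
        for b in range(n18):
            if a != b and np.sum(np.abs(offs26[idx18[a]] - offs26[idx18[b]])) == 1:
                adj6_18[a, b] = True
    face18 = np.array(
        [np.sum(np.abs(offs26[idx18[a]])) == 1 for a in range(n18)], dtype=np.bool_
    )
    return offs26, adj26, idx18, n18, adj6_18, face18


_OFFS26, _ADJ26, _IDX18, _N18, _ADJ6_18, _FACE18 = _build_tables()


@njit(cache=True)
def _connectivity_numbers(fg26):
    """(T26 of foreground, T6 of background) from the 26-neighborhood mask."""
    # T26: 26-components of the foreground among the 26 neighbors
    seen = np.zeros(26, dtype=np.bool_)
    stack = np.empty(26, dtype=np.int64)
    t26 = 0
    for i in range(26):
        if fg26[i] and not seen[i]:
            t26 += 1
            top = 0
            stack[top] = i
            top += 1
            seen[i] = True
            while top > 0:
                top -= 1
                u = stack[top]
                for v in range(26):
                    if fg26[v] and not seen[v] and _ADJ26[u, v]:
                        seen[v] = True
                        stack[top] = v
                        top += 1
    # T6: 6-components of the background within the 18-neighborhood that
    # contain a face neighbor of the center
    seen18 = np.zeros(_N18, dtype=np.bool_)
    stack18 = np.empty(_N18, dtype=np.int64)
    t6 = 0
    for a in range(_N18):
        ia = _IDX18[a]
        if (not fg26[ia]) and (not seen18[a]) and _FACE18[a]:
            # flood the component; count it once (it contains a face neighbor)
            t6 += 1
            top = 0
            stack18[top] = a
            top += 1
            seen18[a] = True
            while top > 0:
                top -= 1
                u = stack18[top]
                for v in range(_N18):
                    if (not fg26[_IDX18[v]]) and not seen18[v] and _ADJ6_18[u, v]:
                        seen18[v] = True
                        stack18[top] = v
                        top += 1
    return t26, t6


@njit(cache=True)
def _simple_from_accepted(accepted, x, y, z, nx, ny, nz):
    fg = np.zeros(26, dtype=np.bool_)
    for k in range(26):
        xx = x + _OFFS26[k, 0]
        yy = y + _OFFS26[k, 1]
        zz = z + _OFFS26[k, 2]
        if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
            fg[k] = accepted[xx, yy, zz]
    t26, t6 = _connectivity_numbers(fg)
    return t26 == 1 and t6 == 1


def is_simple_point(foreground: np.ndarray, voxel: tuple[int, int, int]) -> bool:
    """True if adding ``voxel`` to ``foreground`` preserves (26, 6) topology."""
    fgm = np.ascontiguousarray(np.asarray(foreground, dtype=bool))
    x, y, z = voxel
    return bool(
        _simple_from_accepted(fgm, x, y, z, fgm.shape[0], fgm.shape[1], fgm.shape[2])
    )


@njit(cache=True)
def _heap_less(v1, i1, v2, i2):
    # max-heap priority: higher value first, then lower flat index
    if v1 != v2:
        return v1 > v2
    return i1 < i2


@njit(cache=True)
def _heap_push(hv, hi, n, v, i):
    hv[n] = v
    hi[n] = i
    c = n
    while c > 0:
        p = (c - 1) >> 1
        if _heap_less(hv[c], hi[c], hv[p], hi[p]):
            hv[c], hv[p] = hv[p], hv[c]
            hi[c], hi[p] = hi[p], hi[c]
            c = p
        else:
            break
    return n + 1


@njit(cache=True)
def _heap_pop(hv, hi, n):
    v = hv[0]
    i = hi[0]
    n -= 1
    hv[0] = hv[n]
    hi[0] = hi[n]
    c = 0
    while True:
        l = 2 * c + 1
        r = l + 1
        best = c
        if l < n and _heap_less(hv[l], hi[l], hv[best], hi[best]):
            best = l
        if r < n and _heap_less(hv[r], hi[r], hv[best], hi[best]):
            best = r
        if best == c:
            break
        hv[c], hv[best] = hv[best], hv[c]
        hi[c], hi[best] = hi[best], hi[c]
        c = best
    return v, i, n


@njit(cache=True)
def _march(values, corrected, accepted):
    nx, ny, nz = values.shape
    flat = values.ravel()
    inq_flat = np.zeros(flat.size, dtype=np.bool_)
    npos = 0
    for f in range(flat.size):
        if flat[f] > 0.0:
            npos += 1
    if npos == 0:
        return -1.0
    cap = 27 * npos + 64
    hv = np.empty(cap, dtype=np.float64)
    hi = np.empty(cap, dtype=np.int64)
    hn = 0
    blocked = np.zeros(values.shape, dtype=np.bool_)

    # seed: global maximum, first flat index on ties
    best = -1.0
    seed = -1
    for f in range(flat.size):
        if flat[f] > best:
            best = flat[f]
            seed = f
    hn = _heap_push(hv, hi, hn, best, seed)
    inq_flat[seed] = True
    minacc = np.inf
    first = True
    while hn > 0:
        v, f, hn = _heap_pop(hv, hi, hn)
        x = f // (ny * nz)
        y = (f // nz) % ny
        z = f % nz
        if accepted[x, y, z]:
            continue
        ok = first or _simple_from_accepted(accepted, x, y, z, nx, ny, nz)
        if ok:
            first = False
            accepted[x, y, z] = True
            if v < minacc:
                minacc = v
            corrected[x, y, z] = minacc
            for k in range(26):
                xx = x + _OFFS26[k, 0]
                yy = y + _OFFS26[k, 1]
                zz = z + _OFFS26[k, 2]
                if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz:
                    fn = xx * ny * nz + yy * nz + zz
                    if not accepted[xx, yy, zz] and values[xx, yy, zz] > 0.0:
                        # (re-)queue; a previously blocked voxel gets a new
                        # chance now that a neighbor has been accepted
                        if blocked[xx, yy, zz] or not inq_flat[fn]:
                            blocked[xx, yy, zz] = False
                            if hn >= cap:
                                # grow storage (rare)
                                nhv = np.empty(2 * cap, dtype=np.float64)
                                nhi = np.empty(2 * cap, dtype=np.int64)
                                nhv[:hn] = hv[:hn]
                                nhi[:hn] = hi[:hn]
                                hv = nhv
                                hi = nhi
                                cap = 2 * cap
                            hn = _heap_push(hv, hi, hn, values[xx, yy, zz], fn)
                            inq_flat[fn] = True
        else:
            blocked[x, y, z] = True
            inq_flat[f] = False
    return minacc


def topology_correct_field(values: np.ndarray) -> np.ndarray:
    """Topology-preserving monotone correction of a posterior field.

    Returns a field whose superlevel sets are all single 26-connected
    components with 6-connected simply connected complement. Idempotent on
    compliant input. Raises on an all-zero field.
    """
    values = np.ascontiguousarray(np.asarray(values, dtype=np.float64))
    if not (values > 0).any():
        raise ValueError("cannot topology-correct an all-zero field")
    corrected = np.zeros_like(values)
    accepted = np.zeros(values.shape, dtype=bool)
    minacc = _march(values, corrected, accepted)
    leftover = (values > 0) & ~accepted
    if leftover.any():
        cap = np.nextafter(minacc, -np.inf)
        corrected[leftover] = np.minimum(values[leftover], cap)
    return corrected


@njit(cache=True)
def _grow_less(p1, q1, f1, s1, p2, q2, f2, s2):
    # priority desc, candidate posterior desc, flat index asc, structure asc
    if p1 != p2:
        return p1 > p2
    if q1 != q2:
        return q1 > q2
    if f1 != f2:
        return f1 < f2
    return s1 < s2


@njit(cache=True)
def _grow(post, skel, budgets, seeds, labels):
    ns = post.shape[0]
    nx, ny, nz = post.shape[1:]
    nv = nx * ny * nz
    counts = np.zeros(ns, dtype=np.int64)
    total_budget = 0
    for i in range(ns):
        total_budget += budgets[i]
    cap = 27 * total_budget + 26 * ns + 64
    hp = np.empty(cap, dtype=np.float64)
    hq = np.empty(cap, dtype=np.float64)
    hf = np.empty(cap, dtype=np.int64)
    hs = np.empty(cap, dtype=np.int64)
    hn = 0

    def push(p, q, f, s, hn):
        hp[hn] = p
        hq[hn] = q
        hf[hn] = f
        hs[hn] = s
        c = hn
        while c > 0:
            par = (c - 1) >> 1
            if _grow_less(hp[c], hq[c], hf[c], hs[c], hp[par], hq[par], hf[par], hs[par]):
                hp[c], hp[par] = hp[par], hp[c]
                hq[c], hq[par] = hq[par], hq[c]
                hf[c], hf[par] = hf[par], hf[c]
                hs[c], hs[par] = hs[par], hs[c]
                c = par
            else:
                break
        return hn + 1

    def pop(hn):
        p = hp[0]
        q = hq[0]
        f = hf[0]
        s = hs[0]
        hn -= 1
        hp[0] = hp[hn]
        hq[0] = hq[hn]
        hf[0] = hf[hn]
        hs[0] = hs[hn]
        c = 0
        while True:
            l = 2 * c + 1
            r = l + 1
            b = c
            if l < hn and _grow_less(hp[l], hq[l], hf[l], hs[l], hp[b], hq[b], hf[b], hs[b]):
                b = l
            if r < hn and _grow_less(hp[r], hq[r], hf[r], hs[r], hp[b], hq[b], hf[b], hs[b]):
                b = r
            if b == c:
                break
            hp[c], hp[b] = hp[b], hp[c]
            hq[c], hq[b] = hq[b], hq[c]
            hf[c], hf[b] = hf[b], hf[c]
            hs[c], hs[b] = hs[b], hs[c]
            c = b
        return p, q, f, s, hn

    def candidate_priority(i, fx, fy, fz, sx, sy, sz):
        pi = post[i, fx, fy, fz]
        other = -np.inf
        for j in range(ns):
            if j != i and post[j, fx, fy, fz] > other:
                other = post[j, fx, fy, fz]
        if ns == 1:
            other = 0.0
        return (pi - other) - abs(skel[i, fx, fy, fz] - skel[i, sx, sy, sz]), pi

    # seed each structure at its posterior maximum
    for i in range(ns):
        f = seeds[i]
        x = f // (ny * nz)
        y = (f // nz) % ny
        z = f % nz
        if labels[x, y, z] < 0 and budgets[i] > 0:
            labels[x, y, z] = i
            counts[i] += 1
        for k in range(26):
            xx = x + _OFFS26[k, 0]
            yy = y + _OFFS26[k, 1]
            zz = z + _OFFS26[k, 2]
            if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz and labels[xx, yy, zz] < 0:
                pr, q = candidate_priority(i, xx, yy, zz, x, y, z)
                if hn < cap:
                    hn = push(pr, q, xx * ny * nz + yy * nz + zz, i, hn)

    while hn > 0:
        p, q, f, s, hn = pop(hn)
        x = f // (ny * nz)
        y = (f // nz) % ny
        z = f % nz
        if labels[x, y, z] >= 0:
            continue
        if counts[s] >= budgets[s]:
            continue
        labels[x, y, z] = s
        counts[s] += 1
        for k in range(26):
            xx = x + _OFFS26[k, 0]
            yy = y + _OFFS26[k, 1]
            zz = z + _OFFS26[k, 2]
            if 0 <= xx < nx and 0 <= yy < ny and 0 <= zz < nz and labels[xx, yy, zz] < 0:
                pr, qq = candidate_priority(s, xx, yy, zz, x, y, z)
                if hn >= cap:
                    continue
                hn = push(pr, qq, xx * ny * nz + yy * nz + zz, s, hn)
    return counts


def grow_regions(
    posteriors: np.ndarray,
    skeleton_priors: np.ndarray,
    budgets: np.ndarray,
    seeds: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Concurrent volume-constrained region growing.

    Parameters
    ----------
    posteriors : (S, X, Y, Z) float64
        Topology-corrected per-structure posteriors.
    skeleton_priors : (S, X, Y, Z) float64
        Skeleton prior fields; growth is modulated to follow their
        isocontours (penalty ``|S_i(y) - S_i(x)|``).
    budgets : (S,) int
        Maximum voxel count per structure (round(target volume / voxel
        volume)).
    seeds : (S,) int
        Flat index of each structure's starting maximum.

    Returns
    -------
    labels : (X, Y, Z) int32
        Structure index per voxel, -1 for background.
    counts : (S,) int64
        Achieved voxel counts (never exceed budgets).
    """
    post = np.ascontiguousarray(np.asarray(posteriors, dtype=np.float64))
    skel = np.ascontiguousarray(np.asarray(skeleton_priors, dtype=np.float64))
    if post.shape != skel.shape:
        raise ValueError("posteriors and skeleton priors must share shapes")
    labels = np.full(post.shape[1:], -1, dtype=np.int64)
    counts = _grow(
        post,
        skel,
        np.asarray(budgets, dtype=np.int64),
        np.asarray(seeds, dtype=np.int64),
        labels,
    )
    return labels.astype(np.int32), counts
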
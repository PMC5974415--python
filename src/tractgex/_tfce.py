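"""Threshold-free cluster enhancement on an arbitrary voxel graph.

TFCE replaces a fixed cluster-forming threshold by integrating, for every
voxel p, the cluster extent and height over all thresholds h below the
voxel's value:

    TFCE(p) = sum_h  e(p, h)^E * h^H * dh

where e(p, h) is the voxel count of the connected component containing p in
the supra-threshold set {v : stat(v) >= h}.  The sum runs over thresholds
h = dh, 2*dh, ..., up to the map maximum.  Only positive values are
enhanced; a signed map's negative side is enhanced by passing its negation.

The graph is given in CSR form (indptr/indices), which covers both a full
3D 26-connected grid and a skeleton restricted to its own voxels.  The
sweep activates voxels in decreasing height order and merges components
with a union-find, so one evaluation costs O(V log V + n_thresh * V); it is
JIT-compiled with numba because the permutation null distribution needs
hundreds of thousands of evaluations.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _tfce_sweep(vals, order, indptr, indices, E, H, dh):  # pragma: no cover - jitted
    n = vals.shape[0]
    out = np.zeros(n, dtype=np.float64)
    if n == 0:
        return out
    vmax = vals[order[0]]
    if vmax <= 0.0 or dh <= 0.0:
        return out
    parent = np.full(n, -1, dtype=np.int64)
    size = np.zeros(n, dtype=np.int64)
    active = np.empty(n, dtype=np.int64)
    n_active = 0
    nxt = 0
    K = int(np.floor(vmax / dh + 1e-12))
    for k in range(K, 0, -1):
        h = k * dh
        while nxt < n and vals[order[nxt]] >= h:
            v = order[nxt]
            parent[v] = v
            size[v] = 1
            active[n_active] = v
            n_active += 1
            for j in range(indptr[v], indptr[v + 1]):
                u = indices[j]
                if parent[u] != -1:
                    # union(v, u) with path compression
                    r1 = v
                    while parent[r1] != r1:
                        parent[r1] = parent[parent[r1]]
                        r1 = parent[r1]
                    r2 = u
                    while parent[r2] != r2:
                        parent[r2] = parent[parent[r2]]
                        r2 = parent[r2]
                    if r1 != r2:
                        if size[r1] < size[r2]:
                            r1, r2 = r2, r1
                        parent[r2] = r1
                        size[r1] += size[r2]
            nxt += 1
        inc = (h ** H) * dh
        for a in range(n_active):
            v = active[a]
            r = v
            while parent[r] != r:
                parent[r] = parent[parent[r]]
                r = parent[r]
            out[v] += (size[r] ** E) * inc
    return out


def tfce_graph(
    values: np.ndarray,
    indptr: np.ndarray,
    indices: np.ndarray,
    E: float,
    H: float,
    dh: float | None = None,
    n_steps: int = 100,
) -> np.ndarray:
    """Enhance ``values`` on the CSR graph (positive side only).

    ``dh`` defaults to ``max(values) / n_steps``.  Non-positive values score
    zero and never join a component.
    """
    vals = np.ascontiguousarray(values, dtype=np.float64)
    if vals.ndim != 1:
        raise ValueError("values must be 1D (one entry per graph node)")
    vmax = float(vals.max()) if vals.size else 0.0
    if vmax <= 0.0:
        return np.zeros_like(vals)
    step = float(dh) if dh is not None else vmax / float(n_steps)
    if step <= 0:
        raise ValueError("dh must be > 0")
    order = np.argsort(-vals, kind="stable").astype(np.int64)
    return _tfce_sweep(
        vals, order,
        np.ascontiguousarray(indptr, dtype=np.int64),
        np.ascontiguousarray(indices, dtype=np.int64),
        float(E), float(H), step,
    )


def grid_graph_csr(mask: np.ndarray, connectivity: int = 26):
    """CSR adjacency of True voxels of a 3D mask under 6/18/26-connectivity."""
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    idx = np.flatnonzero(mask.ravel())
    node_id = -np.ones(mask.size, dtype=np.int64)
    node_id[idx] = np.arange(idx.size)
    coords = np.array(np.unravel_index(idx, mask.shape)).T
    offsets = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                if (di, dj, dk) == (0, 0, 0):
                    continue
                o = abs(di) + abs(dj) + abs(dk)
                if connectivity == 6 and o > 1:
                    continue
                if connectivity == 18 and o > 2:
                    continue
                offsets.append((di, dj, dk))
    rows, cols = [], []
    shape = mask.shape
    for di, dj, dk in offsets:
        nb = coords + np.array([di, dj, dk])
        ok = np.all((nb >= 0) & (nb < np.array(shape)), axis=1)
        flat = np.ravel_multi_index(nb[ok].T, shape)
        nid = node_id[flat]
        valid = nid >= 0
        rows.append(np.flatnonzero(ok)[valid])
        cols.append(nid[valid])
    if rows:
        r = np.concatenate(rows)
        c = np.concatenate(cols)
    else:
        r = np.empty(0, dtype=np.int64)
        c = np.empty(0, dtype=np.int64)
    order = np.argsort(r, kind="stable")
    r, c = r[order], c[order]
    indptr = np.zeros(idx.size + 1, dtype=np.int64)
    np.add.at(indptr, r + 1, 1)
    indptr = np.cumsum(indptr)
    return indptr, c.astype(np.int64), idx
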
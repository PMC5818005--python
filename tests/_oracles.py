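"""Independent reference implementations used to cross-check the package."""

import numpy as np
import scipy.spatial.distance


def brute_force_average_linkage(x):
    """O(n^3) agglomeration oracle: repeatedly merge the pair of clusters
    with the smallest average pairwise Euclidean distance; returns the
    merge sequence as (members_a, members_b, height) frozensets."""
    d = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(x))
    clusters = {i: [i] for i in range(len(x))}
    merges = []
    while len(clusters) > 1:
        best, best_d = None, np.inf
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                dist = np.mean([d[i, j] for i in clusters[a] for j in clusters[b]])
                if dist < best_d:
                    best, best_d = (a, b), dist
        a, b = best
        merges.append((frozenset(clusters[a]), frozenset(clusters[b]), best_d))
        clusters[a] = clusters[a] + clusters.pop(b)
    return merges


def simplex_grid(step, lo=None, hi=None, k=4):
    """All points of the k-simplex lattice with the given step, optionally
    restricted to a box."""
    lo = np.zeros(k) if lo is None else np.asarray(lo)
    hi = np.ones(k) if hi is None else np.asarray(hi)
    ticks = [np.arange(max(0.0, lo[i]), min(1.0, hi[i]) + step / 2, step)
             for i in range(k - 1)]
    grids = np.meshgrid(*ticks, indexing="ij")
    F = np.stack([g.ravel() for g in grids], axis=1)
    last = 1.0 - F.sum(axis=1)
    ok = (last >= max(lo[k - 1], 0.0) - 1e-12) & (last <= hi[k - 1] + 1e-12)
    return np.column_stack([F[ok], last[ok]])


def _best_on_grid(S, x, G, chunk=20000):
    """argmin over grid rows of ||S f - x||^2, evaluated in chunks."""
    best_r, best_f = np.inf, None
    for i in range(0, len(G), chunk):
        block = G[i:i + chunk]
        r = ((S @ block.T - x[:, None]) ** 2).sum(axis=0)
        j = int(np.argmin(r))
        if r[j] < best_r:
            best_r, best_f = r[j], block[j]
    return best_f


def grid_search_oracle(S, x, coarse=0.02, fine=0.001):
    """Exhaustive simplex search at the coarse step, refined locally to the
    fine step (0.001 by default)."""
    f0 = _best_on_grid(S, x, simplex_grid(coarse, k=S.shape[1]))
    G2 = simplex_grid(fine, lo=f0 - 2 * coarse, hi=f0 + 2 * coarse, k=S.shape[1])
    return _best_on_grid(S, x, G2)
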
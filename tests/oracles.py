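"""Independent brute-force oracles used by the test suite.

Each oracle deliberately avoids the implementation path it checks:
voxel traversal by dense supersampling, the Liebermeister tail by
exact integer enumeration, connected components by breadth-first
flood fill, AUC by exhaustive pair counting, and dominance by
averaging over all predictor orderings.
"""

import itertools
import math
from collections import deque

import numpy as np


def supersampled_voxels(streamline_mm, grid, step=0.01):
    """Voxels visited by dense sampling of each segment (0.01-voxel steps)."""
    u = grid.world_to_voxel(np.asarray(streamline_mm, float))
    samples = [u[0]]
    for p0, p1 in zip(u[:-1], u[1:]):
        seg_len = np.max(np.abs(p1 - p0))
        n = max(int(np.ceil(seg_len / step)), 1)
        t = np.linspace(0.0, 1.0, n + 1)
        samples.append(p0 + t[:, None] * (p1 - p0))
    pts = np.vstack([np.atleast_2d(s) for s in samples])
    vox = np.floor(pts).astype(int)
    inside = np.all((vox >= 0) & (vox < np.asarray(grid.shape)), axis=1)
    return {tuple(v) for v in vox[inside]}


def segment_box_chord(p0, p1, voxel):
    """Length (voxel units) of a segment's chord through box [v, v+1).

    Independent slab-clipping computation used to adjudicate voxels
    that dense sampling misses (corner cuts shorter than the sampling
    step).
    """
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    tmin, tmax = 0.0, 1.0
    for ax in range(3):
        if d[ax] == 0.0:
            if not voxel[ax] <= p0[ax] < voxel[ax] + 1:
                return 0.0
        else:
            t1 = (voxel[ax] - p0[ax]) / d[ax]
            t2 = (voxel[ax] + 1 - p0[ax]) / d[ax]
            if t1 > t2:
                t1, t2 = t2, t1
            tmin, tmax = max(tmin, t1), min(tmax, t2)
    return float(np.linalg.norm(d) * max(tmax - tmin, 0.0))


def polyline_box_chord(polyline_vox, voxel):
    """Maximum chord of any polyline segment through one voxel box."""
    return max(
        segment_box_chord(p0, p1, voxel)
        for p0, p1 in zip(polyline_vox[:-1], polyline_vox[1:])
    )


def liebermeister_oracle(a, b, c, d):
    """Exact integer enumeration of the augmented hypergeometric tail."""
    M = a + b + c + d + 2
    K = a + b + 1     # affected in the augmented table
    n = a + c + 1     # events in the augmented table
    num = sum(
        math.comb(K, j) * math.comb(M - K, n - j)
        for j in range(a + 1, min(K, n) + 1)
    )
    return num / math.comb(M, n)


def flood_fill_components(binary_vol, connectivity=26):
    """Connected components by BFS; returns a label volume (0 background)."""
    vol = np.asarray(binary_vol, bool)
    offsets = [
        off
        for off in itertools.product((-1, 0, 1), repeat=3)
        if off != (0, 0, 0)
        and (connectivity == 26 or sum(abs(o) for o in off) == 1)
    ]
    labels = np.zeros(vol.shape, dtype=int)
    current = 0
    for start in map(tuple, np.argwhere(vol)):
        if labels[start]:
            continue
        current += 1
        queue = deque([start])
        labels[start] = current
        while queue:
            x, y, z = queue.popleft()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if all(0 <= nb[i] < vol.shape[i] for i in range(3)):
                    if vol[nb] and not labels[nb]:
                        labels[nb] = current
                        queue.append(nb)
    return labels, current


def auc_pair_counting(predicted, outcome):
    """AUC by exhaustive concordant/discordant pair enumeration."""
    p = np.asarray(predicted, float)
    y = np.asarray(outcome, int)
    pos = p[y == 1]
    neg = p[y == 0]
    wins = ties = 0
    for u in pos:
        for v in neg:
            if u > v:
                wins += 1
            elif u == v:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def dominance_by_orderings(r2_by_subset, predictors):
    """General dominance = mean incremental contribution over all p! orderings."""
    totals = {j: 0.0 for j in predictors}
    orderings = list(itertools.permutations(predictors))
    for order in orderings:
        seen = frozenset()
        for j in order:
            totals[j] += r2_by_subset[seen | {j}] - r2_by_subset[seen]
            seen = seen | {j}
    return {j: totals[j] / len(orderings) for j in predictors}


def bh_step_up(p_values):
    """Benjamini-Hochberg adjusted p-values by the sort-and-scan definition."""
    p = np.asarray(p_values, float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
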
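"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain Python loops over
voxels / pairs / zones, independent of the vectorized implementations
in the package, so agreement on micro-volumes is meaningful evidence.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

DIRS_13 = [(i, j, k)
           for i in (0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
           if (i, j, k) > (0, 0, 0)]

NEIGH_26 = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]


def discretize(values, mask, bins):
    levels = np.zeros(values.shape, dtype=int)
    inside = values[mask]
    lo, hi = inside.min(), inside.max()
    for idx in zip(*np.nonzero(mask)):
        if hi > lo:
            g = int(math.floor(bins * (values[idx] - lo) / (hi - lo))) + 1
            levels[idx] = min(g, bins)
        else:
            levels[idx] = 1
    return levels


def glcm_counts(levels, bins, distance=1):
    """Exhaustive symmetric pair enumeration over 13 directions."""
    counts = np.zeros((bins, bins))
    shape = levels.shape
    for idx in zip(*np.nonzero(levels)):
        for d in DIRS_13:
            nb = tuple(i + distance * o for i, o in zip(idx, d))
            if all(0 <= n < s for n, s in zip(nb, shape)) and levels[nb] > 0:
                a, b = levels[idx], levels[nb]
                counts[a - 1, b - 1] += 1
                counts[b - 1, a - 1] += 1
    return counts


def glrlm_counts(levels, bins):
    """Exhaustive run enumeration over 13 directions."""
    shape = levels.shape
    max_run = max(shape)
    counts = np.zeros((bins, max_run))
    for d in DIRS_13:
        for idx in zip(*np.nonzero(levels)):
            prev = tuple(i - o for i, o in zip(idx, d))
            if (all(0 <= p < s for p, s in zip(prev, shape))
                    and levels[prev] == levels[idx]):
                continue  # not a run start
            length = 1
            cur = idx
            while True:
                nxt = tuple(i + o for i, o in zip(cur, d))
                if (all(0 <= n < s for n, s in zip(nxt, shape))
                        and levels[nxt] == levels[idx]):
                    length += 1
                    cur = nxt
                else:
                    break
            counts[levels[idx] - 1, length - 1] += 1
    return counts


def zones(levels):
    """Flood-fill enumeration of 26-connected same-level zones."""
    visited = np.zeros(levels.shape, dtype=bool)
    out = []
    for idx in zip(*np.nonzero(levels)):
        if visited[idx]:
            continue
        g = levels[idx]
        stack, zone = [idx], []
        visited[idx] = True
        while stack:
            cur = stack.pop()
            zone.append(cur)
            for d in NEIGH_26:
                nb = tuple(i + o for i, o in zip(cur, d))
                if (all(0 <= n < s for n, s in zip(nb, levels.shape))
                        and not visited[nb] and levels[nb] == g):
                    visited[nb] = True
                    stack.append(nb)
        out.append((g, zone))
    return out


def glszm_counts(levels, bins):
    n_in = int((levels > 0).sum())
    counts = np.zeros((bins, max(1, n_in)))
    for g, zone in zones(levels):
        counts[g - 1, len(zone) - 1] += 1
    return counts


def border_distance(mask, idx):
    """Chebyshev distance of one in-mask voxel to the mask border
    (background or array edge), >= 1, by growing cubes."""
    shape = mask.shape
    for d in range(1, max(shape) + 2):
        for off in itertools.product(range(-d, d + 1), repeat=3):
            if max(abs(o) for o in off) != d:
                continue
            nb = tuple(i + o for i, o in zip(idx, off))
            if not all(0 <= n < s for n, s in zip(nb, shape)) or not mask[nb]:
                return d
    return max(shape)


def gldzm_counts(levels, mask, bins):
    dists = {idx: border_distance(mask, idx) for idx in zip(*np.nonzero(mask))}
    max_d = max(dists.values())
    counts = np.zeros((bins, max_d))
    for g, zone in zones(levels):
        d = min(dists[v] for v in zone)
        counts[g - 1, d - 1] += 1
    return counts


def ngtdm_tables(levels, bins):
    """Per-level occupancy p_g and grey tone difference s_g by explicit
    neighbourhood loops."""
    shape = levels.shape
    s = np.zeros(bins)
    n = np.zeros(bins)
    nvc = 0
    for idx in zip(*np.nonzero(levels)):
        nb_vals = []
        for d in NEIGH_26:
            nb = tuple(i + o for i, o in zip(idx, d))
            if all(0 <= c < sz for c, sz in zip(nb, shape)) and levels[nb] > 0:
                nb_vals.append(levels[nb])
        if not nb_vals:
            continue
        nvc += 1
        g = levels[idx]
        n[g - 1] += 1
        s[g - 1] += abs(g - sum(nb_vals) / len(nb_vals))
    return n / nvc, s, nvc


def pairwise_auc(scores, truths):
    """AUC by exhaustive positive-negative pair counting, ties = 1/2."""
    pos = [s for s, t in zip(scores, truths) if t == 1]
    neg = [s for s, t in zip(scores, truths) if t == 0]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0)
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def check_retained_set(df, retained, threshold):
    """Verify the redundancy-reduction contract pairwise: retained
    features mutually below threshold; every dropped feature exceeds the
    threshold against at least one retained feature of higher priority."""
    corr = df.corr().abs()
    for a in retained:
        for b in retained:
            if a != b and corr.loc[a, b] > threshold + 1e-12:
                return False
    variances = df.var(ddof=0)
    prio = sorted(df.columns, key=lambda c: (-variances[c], c))
    for col in df.columns:
        if col in retained or variances[col] <= 0:
            continue
        earlier = [r for r in retained if prio.index(r) < prio.index(col)]
        if not any(corr.loc[col, r] > threshold for r in earlier):
            return False
    return True
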
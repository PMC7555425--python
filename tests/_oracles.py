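"""Independent brute-force oracles for metrics and texture matrices.

Everything here is deliberately naive — plain Python loops and full
distance matrices — so the vectorized implementations can be checked
against straightforward enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

SIX_NEIGHBOURS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]

OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


def brute_surface(mask: np.ndarray) -> np.ndarray:
    pts = []
    for p in np.argwhere(mask):
        for d in SIX_NEIGHBOURS:
            q = p + d
            if np.any(q < 0) or np.any(q >= mask.shape) or not mask[tuple(q)]:
                pts.append(p)
                break
    return np.array(pts)


def brute_distance_lists(a: np.ndarray, b: np.ndarray, spacing):
    sp = np.asarray(spacing, dtype=float)
    pa = brute_surface(a) * sp
    pb = brute_surface(b) * sp
    d = cdist(pa, pb)
    return d.min(axis=1), d.min(axis=0)


def brute_hd95(a, b, spacing) -> float:
    d_ab, d_ba = brute_distance_lists(a, b, spacing)
    return max(np.percentile(d_ab, 95), np.percentile(d_ba, 95))


def brute_asd(a, b, spacing) -> float:
    d_ab, d_ba = brute_distance_lists(a, b, spacing)
    return float(np.concatenate([d_ab, d_ba]).mean())


def brute_dice(a, b) -> float:
    na, nb = a.sum(), b.sum()
    if na + nb == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / (na + nb)


def _inside(shape, p) -> bool:
    return all(0 <= c < n for c, n in zip(p, shape))


def brute_glcm(labels: np.ndarray, ng: int, direction) -> np.ndarray:
    p = np.zeros((ng, ng))
    for v in np.argwhere(labels > 0):
        for sign in (1, -1):
            q = v + sign * np.array(direction)
            if _inside(labels.shape, q) and labels[tuple(q)] > 0:
                p[labels[tuple(v)] - 1, labels[tuple(q)] - 1] += 1
    return p


def brute_glrlm(labels: np.ndarray, ng: int, direction) -> np.ndarray:
    d = np.array(direction)
    max_len = max(labels.shape)
    r = np.zeros((ng, max_len))
    for v in np.argwhere(labels > 0):
        prev = v - d
        g = labels[tuple(v)]
        if _inside(labels.shape, prev) and labels[tuple(prev)] == g:
            continue  # not a run start
        length = 1
        q = v + d
        while _inside(labels.shape, q) and labels[tuple(q)] == g:
            length += 1
            q = q + d
        r[g - 1, length - 1] += 1
    return r


def brute_glszm(labels: np.ndarray, ng: int) -> np.ndarray:
    visited = np.zeros(labels.shape, dtype=bool)
    zones = []
    for start in map(tuple, np.argwhere(labels > 0)):
        if visited[start]:
            continue
        g = labels[start]
        stack, size = [start], 0
        visited[start] = True
        while stack:
            v = stack.pop()
            size += 1
            for d in OFFSETS_26:
                q = tuple(np.array(v) + d)
                if (
                    _inside(labels.shape, q)
                    and not visited[q]
                    and labels[q] == g
                ):
                    visited[q] = True
                    stack.append(q)
        zones.append((g, size))
    max_size = max(s for _, s in zones)
    out = np.zeros((ng, max_size))
    for g, s in zones:
        out[g - 1, s - 1] += 1
    return out


def brute_gldm(labels: np.ndarray, ng: int) -> np.ndarray:
    entries = []
    for v in np.argwhere(labels > 0):
        g = labels[tuple(v)]
        dep = 1  # centre voxel counts itself
        for d in OFFSETS_26:
            q = v + d
            if _inside(labels.shape, q) and labels[tuple(q)] == g:
                dep += 1
        entries.append((g, dep))
    max_dep = max(d for _, d in entries)
    out = np.zeros((ng, max_dep))
    for g, dep in entries:
        out[g - 1, dep - 1] += 1
    return out


def brute_ngtdm(labels: np.ndarray, ng: int):
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    total = 0
    for v in np.argwhere(labels > 0):
        g = labels[tuple(v)]
        nb = []
        for d in OFFSETS_26:
            q = v + d
            if _inside(labels.shape, q) and labels[tuple(q)] > 0:
                nb.append(labels[tuple(q)])
        if not nb:
            continue
        total += 1
        n_i[g - 1] += 1
        s_i[g - 1] += abs(g - np.mean(nb))
    p_i = n_i / total if total else n_i
    return p_i, s_i, total


def random_mask(rng, shape, p=0.5, nonempty=True) -> np.ndarray:
    m = rng.random(shape) < p
    if nonempty and not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m


def random_labels(rng, shape, ng, p_mask=0.8) -> np.ndarray:
    mask = random_mask(rng, shape, p_mask)
    labels = np.zeros(shape, dtype=np.int64)
    labels[mask] = rng.integers(1, ng + 1, int(mask.sum()))
    return labels
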
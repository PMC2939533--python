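"""Independent brute-force oracles used to cross-check the vectorized code.

Deliberately written as plain triple loops / path-following so they share
no code with the implementation under test.
"""

from __future__ import annotations

import math

import numpy as np

FACE_OFFSETS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


def edge_bruteforce(a: np.ndarray) -> np.ndarray:
    """Max |intensity difference| over in-bounds face neighbors, per voxel."""
    nx, ny, nz = a.shape
    out = np.zeros_like(a, dtype=float)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                best = 0.0
                for dx, dy, dz in FACE_OFFSETS:
                    x, y, z = i + dx, j + dy, k + dz
                    if 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
                        best = max(best, abs(a[i, j, k] - a[x, y, z]))
                out[i, j, k] = best
    return out


def dense_gaussian_smooth(a: np.ndarray, sigma: float) -> np.ndarray:
    """Direct dense convolution with the truncated normalized Gaussian kernel.

    Kernel half-width int(4*sigma + 0.5); symmetric (reflect) boundary
    padding.
    """
    half = int(4 * sigma + 0.5)
    x = np.arange(-half, half + 1, dtype=float)
    k1 = np.exp(-(x**2) / (2 * sigma**2))
    kernel = k1[:, None, None] * k1[None, :, None] * k1[None, None, :]
    kernel /= kernel.sum()
    padded = np.pad(a, half, mode="symmetric")
    out = np.zeros_like(a, dtype=float)
    w = 2 * half + 1
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            for k in range(a.shape[2]):
                out[i, j, k] = np.sum(padded[i:i + w, j:j + w, k:k + w] * kernel)
    return out


def minima_bruteforce(a: np.ndarray) -> np.ndarray:
    """Seed labels by exhaustive plateau search (6-connected, equal value).

    A plateau is a seed when no border neighbor is strictly smaller.
    Seeds are labeled 1..K in scan order of their smallest flat index,
    matching the production convention.
    """
    shape = a.shape
    visited = np.zeros(shape, dtype=bool)
    plateaus = []
    for start in np.ndindex(shape):
        if visited[start]:
            continue
        val = a[start]
        stack, members = [start], []
        visited[start] = True
        is_min = True
        while stack:
            p = stack.pop()
            members.append(p)
            for off in FACE_OFFSETS:
                q = tuple(p[d] + off[d] for d in range(3))
                if all(0 <= q[d] < shape[d] for d in range(3)):
                    if a[q] == val and not visited[q]:
                        visited[q] = True
                        stack.append(q)
                    elif a[q] < val:
                        is_min = False
        if is_min:
            plateaus.append(members)
    plateaus.sort(key=lambda m: min(np.ravel_multi_index(p, shape) for p in m))
    seeds = np.zeros(shape, dtype=int)
    for label, members in enumerate(plateaus, start=1):
        for p in members:
            seeds[p] = label
    return seeds


def steepest_descent_labels(a: np.ndarray) -> np.ndarray:
    """Basin label per voxel by per-voxel steepest-descent path following.

    Assumes a tie-free volume (all values distinct), so every minimum is a
    single voxel and every descent step is unique given the fixed neighbor
    order.  Minima are labeled 1..K in scan order.
    """
    shape = a.shape
    minima = []
    for p in np.ndindex(shape):
        lowest = _lowest_neighbor(a, p)
        if lowest is None:
            minima.append(p)
    label_of_min = {p: i + 1 for i, p in enumerate(minima)}
    out = np.zeros(shape, dtype=int)
    for p in np.ndindex(shape):
        q = p
        while True:
            nxt = _lowest_neighbor(a, q)
            if nxt is None:
                break
            q = nxt
        out[p] = label_of_min[q]
    return out


def _lowest_neighbor(a, p):
    shape = a.shape
    best, best_val = None, a[p]
    for off in FACE_OFFSETS:
        q = tuple(p[d] + off[d] for d in range(3))
        if all(0 <= q[d] < shape[d] for d in range(3)) and a[q] < best_val:
            best, best_val = q, a[q]
    return best


def pooled_t(a, b):
    """Textbook pooled two-sample t statistic and degrees of freedom."""
    a, b = list(a), list(b)
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    s1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    s2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    return t, n1 + n2 - 2
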
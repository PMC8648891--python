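"""Independent brute-force oracles shared across test modules."""

from collections import deque

import numpy as np


def brute_force_dilate(p):
    """Per-pixel max over the 5x5 neighbourhood excluding the centre."""
    nf, nt = p.shape
    out = np.full_like(p, -np.inf)
    for i in range(nf):
        for j in range(nt):
            best = -np.inf
            for di in range(-2, 3):
                for dj in range(-2, 3):
                    if di == 0 and dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < nf and 0 <= jj < nt:
                        best = max(best, p[ii, jj])
            out[i, j] = best
    return out


def strict_peak_scan(p):
    """Cells strictly greater than every in-bounds 5x5 neighbour."""
    d = brute_force_dilate(p)
    return {(i, j) for i in range(p.shape[0]) for j in range(p.shape[1])
            if p[i, j] > d[i, j]}


def flood_fill_label(mask, connectivity):
    """BFS connected-component labelling of a 3-D binary mask."""
    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    labels = np.zeros(mask.shape, dtype=int)
    nxt = 0
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        nxt += 1
        q = deque([start])
        labels[start] = nxt
        while q:
            x, y, z = q.popleft()
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= p[i] < mask.shape[i] for i in range(3)) \
                        and mask[p] and not labels[p]:
                    labels[p] = nxt
                    q.append(p)
    return labels, nxt


def bh_step_up(p, q):
    """Brute-force Benjamini-Hochberg scan over all k."""
    p = np.asarray(p, dtype=float)
    order = np.argsort(p)
    m = p.size
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= q * k / m:
            k_star = k
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_star]] = True
    return mask


def mann_whitney_u(a, b):
    return float(sum((x > y) + 0.5 * (x == y) for x in a for y in b))
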
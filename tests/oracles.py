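"""Independent brute-force oracles shared across test modules.

Everything here is deliberately naive (loops, BFS, direct DFT) and never
calls the implementation it is used to check.
"""

import numpy as np


def naive_pearson(x, y):
    """Two-pass covariance / (sigma_x * sigma_y)."""
    mx, my = np.mean(x), np.mean(y)
    cov = np.mean((x - mx) * (y - my))
    return cov / (np.sqrt(np.mean((x - mx) ** 2)) * np.sqrt(np.mean((y - my) ** 2)))


def bfs_components_18(coords):
    """Connected components under face+edge adjacency, by breadth-first search.

    Returns the partition as a sorted list of sorted member-index lists.
    """
    coords = [tuple(int(v) for v in c) for c in coords]
    index = {c: i for i, c in enumerate(coords)}
    seen = set()
    comps = []
    for start in coords:
        if start in seen:
            continue
        comp, queue = [], [start]
        seen.add(start)
        while queue:
            cur = queue.pop()
            comp.append(cur)
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        if (dx, dy, dz) == (0, 0, 0):
                            continue
                        if abs(dx) + abs(dy) + abs(dz) > 2:
                            continue  # corner offsets are not neighbors
                        nb = (cur[0] + dx, cur[1] + dy, cur[2] + dz)
                        if nb in index and nb not in seen:
                            seen.add(nb)
                            queue.append(nb)
        comps.append(sorted(index[c] for c in comp))
    return sorted(comps)


def partition_from_labels(labels):
    labels = np.asarray(labels)
    return sorted(
        sorted(np.flatnonzero(labels == k).tolist()) for k in np.unique(labels)
    )


def dft_alff_oracle(series, tr, band=(0.01, 0.08)):
    """O(T^2) direct DFT computation of band-averaged sqrt power."""
    t_len = len(series)
    vals = []
    for k in range(t_len // 2 + 1):
        freq = k / (t_len * tr)
        if band[0] <= freq <= band[1]:
            re = sum(
                series[t] * np.cos(2 * np.pi * k * t / t_len) for t in range(t_len)
            )
            im = sum(
                -series[t] * np.sin(2 * np.pi * k * t / t_len) for t in range(t_len)
            )
            vals.append(np.sqrt((re**2 + im**2) / t_len))
    return float(np.mean(vals))
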
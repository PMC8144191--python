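"""Independent brute-force oracles used to validate the package's algorithms.

These deliberately avoid the implementation's vectorised code paths:
double loops, explicit BFS, and exhaustive grid search.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def moving_average_bruteforce(values, window: int) -> np.ndarray:
    """Centred moving average with shrinking edge windows, via a double loop."""
    values = list(map(float, values))
    n = len(values)
    half = window // 2
    out = []
    for i in range(n):
        acc = 0.0
        count = 0
        for j in range(i - half, i + half + 1):
            if 0 <= j < n:
                acc += values[j]
                count += 1
        out.append(acc / count)
    return np.asarray(out)


def holm_bruteforce(p_values) -> np.ndarray:
    """Holm step-down: sort, scale by (m - rank), running max, unsort, cap."""
    p = list(map(float, p_values))
    m = len(p)
    indexed = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 0.0
    for rank, idx in enumerate(indexed):
        scaled = p[idx] * (m - rank)
        running = max(running, scaled)
        adjusted[idx] = min(running, 1.0)
    return np.asarray(adjusted)


def flood_fill_count(mask: np.ndarray, connectivity: int = 8) -> int:
    """Count connected components of a binary mask by explicit BFS."""
    mask = np.asarray(mask, dtype=bool)
    visited = np.zeros_like(mask)
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    rows, cols = mask.shape
    count = 0
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and not visited[r, c]:
                count += 1
                queue = deque([(r, c)])
                visited[r, c] = True
                while queue:
                    rr, cc = queue.popleft()
                    for dr, dc in steps:
                        nr, nc = rr + dr, cc + dc
                        if 0 <= nr < rows and 0 <= nc < cols and mask[nr, nc] and not visited[nr, nc]:
                            visited[nr, nc] = True
                            queue.append((nr, nc))
    return count


def relaxation_gridsearch(times, ar_values, tau_grid, ar_inf_grid):
    """Exhaustive least-squares over (tau, ar_inf) with ar_0 fixed to the
    first sample; returns the grid-optimal (tau, ar_inf)."""
    t = np.asarray(times, dtype=float)
    t = t - t[0]
    ar = np.asarray(ar_values, dtype=float)
    ar_0 = ar[0]
    best = (np.inf, None, None)
    for tau in tau_grid:
        decay = np.exp(-t / tau)
        for ar_inf in ar_inf_grid:
            model = ar_inf + (ar_0 - ar_inf) * decay
            rss = float(np.sum((model - ar) ** 2))
            if rss < best[0]:
                best = (rss, tau, ar_inf)
    return best[1], best[2]
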
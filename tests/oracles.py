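"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration of simple
paths, O(n^2) pair counting, literal step-up arithmetic — and shares no code
with the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

TIE_TOL = 1e-10


def all_simple_paths(w: np.ndarray, s: int, t: int):
    """All simple s-t paths in the graph with weight matrix ``w`` (|w| used)."""
    n = len(w)
    paths = []

    def extend(path):
        last = path[-1]
        if last == t:
            paths.append(list(path))
            return
        for nxt in range(n):
            if w[last, nxt] != 0 and nxt not in path:
                path.append(nxt)
                extend(path)
                path.pop()

    extend([s])
    return paths


def path_length(w: np.ndarray, path) -> float:
    return sum(1.0 / abs(w[a, b]) for a, b in zip(path, path[1:]))


def brute_distances(w: np.ndarray) -> np.ndarray:
    n = len(w)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = all_simple_paths(w, s, t)
            if paths:
                d[s, t] = min(path_length(w, p) for p in paths)
    return d


def brute_betweenness(w: np.ndarray) -> np.ndarray:
    """Fractional shortest-path census over all unordered pairs."""
    n = len(w)
    b = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_simple_paths(w, s, t)
        if not paths:
            continue
        lengths = [path_length(w, p) for p in paths]
        best = min(lengths)
        shortest = [p for p, L in zip(paths, lengths) if L <= best + TIE_TOL]
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in shortest if v in p[1:-1])
            b[v] += through / len(shortest)
    return b


def brute_closeness(w: np.ndarray) -> np.ndarray:
    d = brute_distances(w)
    n = len(w)
    c = np.zeros(n)
    for i in range(n):
        others = np.delete(d[i], i)
        finite = others[np.isfinite(others)]
        if len(finite) and finite.sum() > 0:
            c[i] = len(finite) / finite.sum()
    return c


def brute_strength(w: np.ndarray) -> np.ndarray:
    return np.abs(w).sum(axis=1)


def brute_zhang_horvath(w: np.ndarray) -> np.ndarray:
    """Triple-loop Zhang–Horvath clustering on max-normalized |w|."""
    wa = np.abs(np.array(w, dtype=float))
    np.fill_diagonal(wa, 0.0)
    if wa.max() == 0:
        return np.zeros(len(wa))
    wh = wa / wa.max()
    n = len(wh)
    c = np.zeros(n)
    for i in range(n):
        numer = 0.0
        for j in range(n):
            for k in range(n):
                if len({i, j, k}) == 3:
                    numer += wh[i, j] * wh[j, k] * wh[i, k]
        s = sum(wh[i, j] for j in range(n) if j != i)
        s2 = sum(wh[i, j] ** 2 for j in range(n) if j != i)
        denom = s * s - s2
        c[i] = numer / denom if denom > 0 else 0.0
    return c


def brute_kendall_tau_b(x, y) -> float:
    """O(n^2) pair counting with the tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    concordant = discordant = tied_x = tied_y = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tied_x += 1
            tied_y += 1
        elif dx == 0:
            tied_x += 1
        elif dy == 0:
            tied_y += 1
        elif dx * dy > 0:
            concordant += 1
        else:
            discordant += 1
    n0 = n * (n - 1) // 2
    denom = np.sqrt((n0 - tied_x) * (n0 - tied_y))
    return (concordant - discordant) / denom


def step_up_hochberg(p) -> np.ndarray:
    """Literal Hochberg step-up adjustment, applied by hand."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)[::-1]  # descending
    adjusted = np.empty(m)
    running = np.inf
    for rank_from_top, idx in enumerate(order):
        multiplier = rank_from_top + 1  # m - (ascending rank) + 1
        running = min(running, multiplier * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


def random_weighted_graph(rng: np.random.Generator, max_nodes: int = 6) -> np.ndarray:
    """Random symmetric weight matrix with signed weights and random sparsity."""
    n = int(rng.integers(2, max_nodes + 1))
    w = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        if rng.random() < 0.7:
            mag = rng.uniform(0.1, 1.0)
            sign = -1.0 if rng.random() < 0.3 else 1.0
            w[i, j] = w[j, i] = sign * mag
    return w
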
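"""Independent brute-force oracles used to validate the implementations.

Everything here is deliberately naive: exhaustive path enumeration for graph
metrics, literal step-up scans for FDR, a from-scratch greedy loop for LD
clumping.  None of it shares code with the package.
"""

from itertools import combinations, permutations

import numpy as np

TIE_RTOL = 1e-9


def enumerate_shortest_paths(w, s, t):
    """All simple shortest paths s->t by exhaustive enumeration (lengths 1/w).

    Returns (distance, list_of_paths); distance is inf if unreachable.
    """
    n = w.shape[0]
    others = [v for v in range(n) if v not in (s, t)]
    best, paths = np.inf, []
    for k in range(len(others) + 1):
        for middle in permutations(others, k):
            path = (s, *middle, t)
            length = 0.0
            ok = True
            for a, b in zip(path[:-1], path[1:]):
                if w[a, b] <= 0:
                    ok = False
                    break
                length += 1.0 / w[a, b]
            if not ok:
                continue
            if length < best * (1 - TIE_RTOL):
                best, paths = length, [path]
            elif length <= best * (1 + TIE_RTOL):
                paths.append(path)
    return best, paths


def distance_matrix(w):
    n = w.shape[0]
    d = np.zeros((n, n))
    for s in range(n):
        for t in range(n):
            if s != t:
                d[s, t] = enumerate_shortest_paths(w, s, t)[0]
    return d


def characteristic_path_length(w):
    d = distance_matrix(w)
    vals = d[np.triu_indices(d.shape[0], k=1)]
    finite = vals[np.isfinite(vals)]
    return finite.mean(), int(np.sum(~np.isfinite(vals)))


def global_efficiency(w):
    d = distance_matrix(w)
    n = d.shape[0]
    total = 0.0
    for s in range(n):
        for t in range(n):
            if s != t and np.isfinite(d[s, t]) and d[s, t] > 0:
                total += 1.0 / d[s, t]
    return total / (n * (n - 1))


def betweenness(w):
    """Fractional-credit betweenness over enumerated tied geodesics."""
    n = w.shape[0]
    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        dist, paths = enumerate_shortest_paths(w, s, t)
        if not np.isfinite(dist) or not paths:
            continue
        share = 1.0 / len(paths)
        for path in paths:
            for v in path[1:-1]:
                bc[v] += share
    return bc


def clustering_binary(w):
    """Edges-among-neighbours ratio for binary graphs."""
    a = (w > 0).astype(int)
    n = a.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        k = len(nb)
        if k < 2:
            continue
        links = sum(a[u, v] for u, v in combinations(nb, 2))
        c[i] = 2.0 * links / (k * (k - 1))
    return c


def clustering_weighted(w):
    """Geometric-mean triangle clustering, max-normalised, literal triple loop."""
    n = w.shape[0]
    wmax = w.max()
    if wmax <= 0:
        return np.zeros(n)
    c = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(w[i] > 0)
        k = len(nb)
        if k < 2:
            continue
        s = 0.0
        for u, v in combinations(nb, 2):
            s += ((w[i, u] / wmax) * (w[i, v] / wmax) * (w[u, v] / wmax)) ** (1.0 / 3.0)
        c[i] = 2.0 * s / (k * (k - 1))
    return c


def local_efficiency(w):
    n = w.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(w[i] > 0)
        if len(nb) < 2:
            continue
        eff[i] = global_efficiency(w[np.ix_(nb, nb)])
    return eff


def random_weighted_graph(rng, n=None, density=None, integer=False):
    """Random symmetric nonnegative test graph with zero diagonal."""
    n = n if n is not None else int(rng.integers(3, 7))
    density = density if density is not None else float(rng.uniform(0.3, 1.0))
    w = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < density
    vals = rng.integers(1, 20, len(iu[0])).astype(float) if integer else rng.uniform(0.1, 5.0, len(iu[0]))
    w[iu] = np.where(present, vals, 0.0)
    return w + w.T


# ---------------------------------------------------------------------------
# Non-graph oracles
# ---------------------------------------------------------------------------

def bh_stepup(p, q):
    """Literal Benjamini-Hochberg: find the largest rank passing, flag below it."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    kmax = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= q * rank / m:
            kmax = rank
    flags = np.zeros(m, dtype=bool)
    flags[order[:kmax]] = True
    return flags


def greedy_clump(snps, r2_fn, window_bp, r2_cutoff):
    """Greedy clumping oracle over (id, chrom, pos, p) tuples.

    ``r2_fn(id_a, id_b)`` returns the dosage r-squared between two SNPs;
    retained ids are returned in visit (ascending-p) order.
    """
    remaining = sorted(snps, key=lambda s: (s[3], s[1], s[2], s[0]))
    kept = []
    removed = set()
    for snp in remaining:
        if snp[0] in removed:
            continue
        kept.append(snp[0])
        for other in remaining:
            if other[0] in removed or other[0] == snp[0]:
                continue
            if other[1] == snp[1] and abs(other[2] - snp[2]) <= window_bp:
                if r2_fn(snp[0], other[0]) >= r2_cutoff:
                    removed.add(other[0])
    return kept
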
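"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a quantity by the most direct method available
(exhaustive enumeration, naive O(n^3) agglomeration, explicit series), kept
deliberately separate from the library code paths it checks.
"""

import itertools
import math

import numpy as np


def count_length2_paths(graph):
    """Triplet total by direct enumeration of bonded atom pairs sharing a
    common neighbour (each unordered 2-path counted once)."""
    edges = {b.key for b in graph.bonds}
    n = len(graph.atoms)
    total = 0
    for u, center, w in itertools.permutations(range(n), 3):
        if u < w and (min(u, center), max(u, center)) in edges and (
            min(center, w),
            max(center, w),
        ) in edges:
            total += 1
    return total


def upgma_cophenetic(D):
    """Naive O(n^3) UPGMA: cophenetic matrix via explicit member-pair means."""
    D = np.asarray(D, dtype=float)
    n = len(D)
    clusters = {i: [i] for i in range(n)}
    C = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for i, j in itertools.combinations(keys, 2):
            d = float(
                np.mean([D[a, b] for a in clusters[i] for b in clusters[j]])
            )
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        for a in clusters[i]:
            for b in clusters[j]:
                C[a, b] = C[b, a] = d
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        next_id += 1
    return C


def yates_chi2(table):
    """Cell-by-cell Yates-corrected chi-squared by explicit loops."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    chi2 = 0.0
    for r in range(table.shape[0]):
        for c in range(table.shape[1]):
            e = table[r].sum() * table[:, c].sum() / total
            if e > 0:
                chi2 += max(abs(table[r, c] - e) - 0.5, 0.0) ** 2 / e
    return chi2


def hypergeom_upper_tail(observed, population, carriers, draws):
    """P(X >= observed) by exhaustive enumeration of all draws."""
    hits = 0
    total = 0
    items = range(population)
    for combo in itertools.combinations(items, draws):
        total += 1
        if sum(1 for x in combo if x < carriers) >= observed:
            hits += 1
    return hits / total


def poisson_upper_tail(observed, lam, terms=200):
    """P(X >= observed) by truncated series for the lower tail."""
    lower = sum(math.exp(-lam) * lam**k / math.factorial(k) for k in range(observed))
    return 1.0 - lower
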
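"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the library code paths under test: plain-Python
dynamic programming for local alignment, exhaustive chain enumeration for
duplex pairing, a triple loop for DPI pruning, and combinatorial counting
for the hypergeometric tail.
"""

from __future__ import annotations

import itertools
import math

from xkmir.energy import EnergyTable, pair_type

# --- local alignment -------------------------------------------------------


def sw_bruteforce(a: str, b: str, match: float, mismatch: float, gap: float) -> float:
    """Textbook Smith-Waterman recurrence in plain Python (linear gaps)."""
    n, m = len(a), len(b)
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, H[i - 1][j] - gap, H[i][j - 1] - gap)
            best = max(best, H[i][j])
    return best


def sw_matrix_bruteforce(a: str, b: str, matrix, gap: float) -> float:
    best = 0.0
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, H[i - 1][j] - gap, H[i][j - 1] - gap)
            best = max(best, H[i][j])
    return best


# --- duplex MFE ------------------------------------------------------------


def duplex_enumeration(m: str, t: str, table: EnergyTable, max_loop: int = 15) -> float:
    """Minimum energy over every legal antiparallel pairing chain.

    A duplex is a chain of pairable (i, j) positions, strictly increasing in
    the miRNA and strictly decreasing in the target, with at most
    ``max_loop`` unpaired bases per strand between consecutive pairs. All
    chains are enumerated explicitly and scored pair by pair.
    """
    r = t[::-1]
    pairable = [
        (i, j, pair_type(m[i], r[j]))
        for i in range(len(m))
        for j in range(len(r))
        if pair_type(m[i], r[j]) >= 0
    ]
    best = math.inf

    def extend(last_i: int, last_j: int, last_p: int, energy: float) -> None:
        nonlocal best
        best = min(best, energy)
        for i, j, p in pairable:
            n1, n2 = i - last_i - 1, j - last_j - 1
            if n1 < 0 or n2 < 0:
                continue
            if n1 > max_loop or n2 > max_loop:
                continue
            extend(i, j, p, energy + table.loop_energy(n1, n2, last_p, p))

    for i, j, p in pairable:
        extend(i, j, p, 0.0)
    return best


# --- DPI -------------------------------------------------------------------


def dpi_bruteforce(mi, eps: float, threshold: float) -> set[tuple[int, int]]:
    """Surviving edges (i < j) after thresholding + the triplet rule."""
    n = len(mi)
    present = {
        (i, j) for i in range(n) for j in range(i + 1, n) if mi[i][j] > threshold
    }

    def has(a, b):
        return (min(a, b), max(a, b)) in present

    kept = set()
    for i, j in present:
        doomed = False
        for k in range(n):
            if k in (i, j) or not (has(i, k) and has(j, k)):
                continue
            if mi[i][j] <= min(mi[i][k], mi[j][k]) - eps:
                doomed = True
                break
        if not doomed:
            kept.add((i, j))
    return kept


# --- hypergeometric right tail --------------------------------------------


def hypergeom_enumeration(k: int, K: int, n: int, N: int) -> float:
    """P(overlap >= k) by enumerating every n-subset of an N-universe."""
    universe = list(range(N))
    special = set(range(K))
    total = 0
    hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    return hits / total
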
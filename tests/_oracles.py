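"""Brute-force oracles for the built-in folding engine.

These enumerate every nested secondary structure explicitly and compute
energies, Boltzmann sums, pair probabilities and ensemble expectations by
direct summation.  They are deliberately independent of the dynamic-
programming code they check: no partition-function recursions, no scaling.
"""

from __future__ import annotations

import math
from functools import lru_cache

PAIR_ENERGIES = {
    frozenset("GC"): -3.0,
    frozenset("AU"): -2.0,
    frozenset("GU"): -1.0,
}
KT = 0.6163
MIN_LOOP = 3


def _pairable(s: str, i: int, j: int, nick: int | None) -> bool:
    if frozenset((s[i], s[j])) not in PAIR_ENERGIES:
        return False
    if j - i > MIN_LOOP:
        return True
    return nick is not None and i < nick <= j


def enumerate_structures(s: str, nick: int | None = None) -> list[list[tuple[int, int]]]:
    """All nested structures (as sorted pair lists) of sequence s."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> tuple[tuple[tuple[int, int], ...], ...]:
        if i > j:
            return ((),)
        out = [s_rest for s_rest in rec(i + 1, j)]
        for k in range(i + 1, j + 1):
            if _pairable(s, i, k, nick):
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        out.append(((i, k),) + inner + outer)
        return tuple(out)

    structures = [sorted(p) for p in rec(0, len(s) - 1)]
    rec.cache_clear()
    return structures


def pairs_energy(s: str, pairs) -> float:
    return sum(PAIR_ENERGIES[frozenset((s[i], s[j]))] for i, j in pairs)


def dotbracket(pairs, n: int) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i], chars[j] = "(", ")"
    return "".join(chars)


def mfe_oracle(s: str, nick: int | None = None) -> tuple[float, str]:
    """Exact MFE and the lexicographically smallest optimal dot-bracket."""
    n = len(s)
    best_e, best_structs = 0.0, ["." * n]
    for pairs in enumerate_structures(s, nick):
        e = pairs_energy(s, pairs)
        if e < best_e - 1e-12:
            best_e, best_structs = e, [dotbracket(pairs, n)]
        elif abs(e - best_e) <= 1e-12:
            best_structs.append(dotbracket(pairs, n))
    return best_e, min(best_structs)


def boltzmann_oracle(s: str, nick: int | None = None):
    """Exact partition function, structure probabilities and bpp matrix."""
    n = len(s)
    structures = enumerate_structures(s, nick)
    weights = [math.exp(-pairs_energy(s, p) / KT) for p in structures]
    z = sum(weights)
    probs = {
        dotbracket(p, n): w / z for p, w in zip(structures, weights)
    }
    bpp = [[0.0] * n for _ in range(n)]
    for p, w in zip(structures, weights):
        for i, j in p:
            bpp[i][j] += w / z
            bpp[j][i] += w / z
    ensemble_energy = -KT * math.log(z)
    return z, probs, bpp, ensemble_energy


def opening_energy_oracle(s: str, a: int, b: int) -> float:
    """Exact opening energy of target interval [a, b] (inclusive)."""
    structures = enumerate_structures(s, None)
    z = z_open = 0.0
    for p in structures:
        w = math.exp(-pairs_energy(s, p) / KT)
        z += w
        if all(not (a <= i <= b or a <= j <= b) for i, j in p):
            z_open += w
    return -KT * math.log(z_open / z)


def duplex_oracle(query: str, target: str, footprint: tuple[int, int]) -> float:
    """Best antiparallel intermolecular-only hybridisation energy with target
    footprint exactly [a, b] (both endpoints paired), by exhaustive matching."""
    a, b = footprint
    best = [0.0]

    def rec(qi: int, tj: int, acc: float, used_a: bool, used_b: bool):
        if used_a and used_b and acc < best[0]:
            best[0] = acc
        if qi >= len(query) or tj < a:
            return
        # skip query position
        rec(qi + 1, tj, acc, used_a, used_b)
        for j in range(tj, a - 1, -1):
            e = PAIR_ENERGIES.get(frozenset((query[qi], target[j])))
            if e is not None and a <= j <= b:
                rec(qi + 1, j - 1, acc + e, used_a or j == a, used_b or j == b)

    rec(0, b, 0.0, False, False)
    return best[0]
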
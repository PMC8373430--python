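"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: loads are computed by
literal substring enumeration, BH by a literal step-up, depth by an
explicit indicator matrix.
"""

from __future__ import annotations

import math


def brute_haplotype_load(reads: list[str], state: str, exponent: int) -> float:
    """Literal enumeration of gapless substrings over all lengths."""
    if not reads:
        return math.nan
    L = len(reads[0])
    num: dict[int, int] = {}
    den: dict[int, int] = {}
    for l in range(1, L + 1):
        for r in reads:
            for i in range(L - l + 1):
                sub = r[i : i + l]
                if "." in sub:
                    continue
                den[l] = den.get(l, 0) + 1
                if sub == state * l:
                    num[l] = num.get(l, 0) + 1
    wsum = 0.0
    total = 0.0
    for l, d in den.items():
        w = float(l**exponent)
        wsum += w * num.get(l, 0) / d
        total += w
    return wsum / total if total else math.nan


def brute_bh(p: list[float]) -> list[float]:
    """Literal Benjamini–Hochberg step-up: sort, scale by m/rank, cumulative
    minimum from the largest rank, clip at 1, undo the sort."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    scaled = [p[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        scaled[i] = min(scaled[i], scaled[i + 1])
    out = [0.0] * m
    for i, idx in enumerate(order):
        out[idx] = min(scaled[i], 1.0)
    return out


def brute_depth(reads: list[tuple[int, str]], n_slots: int) -> list[int]:
    """Column sums of an explicit read × slot indicator matrix."""
    matrix = [[0] * n_slots for _ in reads]
    for row, (start, calls) in zip(matrix, reads):
        for i, c in enumerate(calls):
            if c != ".":
                row[start + i] = 1
    return [sum(row[j] for row in matrix) for j in range(n_slots)]
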
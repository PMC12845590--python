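"""Independent brute-force oracles for the complexity features and statistics.

Deliberately naive implementations (explicit loops, textbook definitions)
kept free of any code shared with the package, so they can serve as
ground truth in equivalence tests.
"""

from __future__ import annotations

import math

import numpy as np


def lz76_phrase_count_bruteforce(bits: str) -> int:
    """LZ76 parsing by explicit substring search: a phrase ends at the first
    position where the running word is not a substring of everything before
    the current position."""
    n = len(bits)
    if n == 0:
        return 0
    phrases = 0
    i = 0
    while i < n:
        length = 1
        while i + length <= n and bits[i : i + length] in bits[: i + length - 1]:
            length += 1
        phrases += 1
        i += length
    return phrases


def permutation_entropy_bruteforce(x: np.ndarray, order: int = 3, delay: int = 1) -> float:
    """Normalized ordinal-pattern entropy; ties broken by index order by
    sorting on (value, index) pairs."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd > 1e-12:
        x = (x - x.mean()) / sd
    counts: dict[tuple, int] = {}
    n = len(x) - (order - 1) * delay
    for start in range(n):
        window = [x[start + k * delay] for k in range(order)]
        pattern = tuple(sorted(range(order), key=lambda k: (window[k], k)))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    h = -sum((c / total) * math.log2(c / total) for c in counts.values())
    return h / math.log2(math.factorial(order))


def sample_entropy_bruteforce(x: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """-ln(A/B) with explicit pairwise Chebyshev comparisons over the first
    n-m template positions (same matching convention as the package, which
    is part of the documented definition)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd < 1e-12:
        raise ValueError("constant input")
    x = (x - x.mean()) / sd
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if b == 0 or a == 0:
        raise ValueError("no matches; oracle undefined")
    return -math.log(a / b)


def cliffs_delta_bruteforce(x, y) -> float:
    gt = sum(1 for xi in x for yi in y if xi > yi)
    lt = sum(1 for xi in x for yi in y if xi < yi)
    return (gt - lt) / (len(x) * len(y))


def kruskal_h_bruteforce(groups) -> float:
    """Kruskal–Wallis H with tie correction from explicit mid-ranks."""
    flat = [v for g in groups for v in g]
    n = len(flat)
    order = sorted(range(n), key=lambda i: flat[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and flat[order[j + 1]] == flat[order[i]]:
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    pos = 0
    h = 0.0
    for g in groups:
        r_sum = sum(ranks[pos : pos + len(g)])
        h += r_sum**2 / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    ties = {}
    for v in flat:
        ties[v] = ties.get(v, 0) + 1
    correction = 1 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / correction if correction > 0 else h
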
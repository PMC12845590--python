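"""Numba-compiled inner loops for the quadratic-time complexity features.

Sample entropy needs an all-pairs template comparison (O(n^2) at the
3750-sample analysis window) and LZ76 parsing is a tight scan; both are
kept here as plain nopython kernels so the public feature functions in
:mod:`earmotion.features` stay readable.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Count template matches for sample entropy.

    B counts pairs (i < j) of length-``m`` templates with Chebyshev
    distance <= r; A counts the same pairs extended to length ``m + 1``.
    Templates are drawn from the first ``n - m`` positions so every
    length-m template has a defined m+1 extension (Richman–Moorman
    convention).
    """
    n = x.shape[0]
    a = 0
    b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            d = abs(x[i] - x[j])
            if d > r:
                continue
            match = True
            for k in range(1, m):
                dk = abs(x[i + k] - x[j + k])
                if dk > r:
                    match = False
                    break
            if not match:
                continue
            b += 1
            if abs(x[i + m] - x[j + m]) <= r:
                a += 1
    return a, b


@njit(cache=True)
def lz76_phrases(s: np.ndarray) -> int:
    """LZ76 phrase count of a binary (0/1 uint8) sequence.

    Kaspar–Schuster scanning formulation: a new phrase starts whenever
    the current extension cannot be copied from the existing prefix.
    """
    n = s.shape[0]
    if n == 0:
        return 0
    i = 0
    k = 1
    l = 1
    k_max = 1
    c = 1
    while True:
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
            if l + k > n:
                c += 1
                break
        else:
            if k > k_max:
                k_max = k
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i = 0
                k = 1
                k_max = 1
            else:
                k = 1
    return c
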
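"""Maximum-weight nested RNA secondary structure for hairpin screening.

A deliberately simple pairing model: Watson–Crick and G:U wobble pairs
with weights GC=3, AU=2, GU=1 and a minimum hairpin loop of 3 unpaired
bases.  The reported folding score is the negative of the total pair
weight, so more stable structures score lower (energy-like, arbitrary
units).  This is a screening surrogate, not a thermodynamic model.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MIN_FOLD_LEN = 40
MAX_FOLD_LEN = 320
MIN_LOOP = 3

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}

# pair weight matrix over codes (A,C,G,U); 0 = cannot pair
_W = np.zeros((5, 5), dtype=np.int64)
_W[2, 1] = _W[1, 2] = 3  # G:C
_W[0, 3] = _W[3, 0] = 2  # A:U
_W[2, 3] = _W[3, 2] = 1  # G:U wobble


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE[b] for b in seq.upper()], dtype=np.int64)


def pair_weight(a: str, b: str) -> int:
    return int(_W[_CODE[a.upper()], _CODE[b.upper()]])


@njit(cache=True)
def _fill(codes, W, min_loop):  # pragma: no cover - exercised via fold_window
    n = codes.shape[0]
    dp = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1, j]
            if dp[i, j - 1] > best:
                best = dp[i, j - 1]
            w = W[codes[i], codes[j]]
            if w > 0:
                v = w + (dp[i + 1, j - 1] if j - i >= 2 else 0)
                if v > best:
                    best = v
            for k in range(i + 1, j):
                v = dp[i, k] + dp[k + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    return dp


def _traceback(dp: np.ndarray, codes: np.ndarray) -> list[tuple[int, int]]:
    """Deterministic traceback: prefer pairing (i, j), then dropping i,
    then dropping j, then the leftmost bifurcation — equal-score ties go
    to the structure whose pairs start at the smaller left index."""
    pairs: list[tuple[int, int]] = []
    stack = [(0, dp.shape[0] - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= MIN_LOOP:
            continue
        target = dp[i, j]
        if target == 0:
            continue
        w = int(_W[codes[i], codes[j]])
        if w > 0 and w + (dp[i + 1, j - 1] if j - i >= 2 else 0) == target:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        if dp[i + 1, j] == target:
            stack.append((i + 1, j))
            continue
        if dp[i, j - 1] == target:
            stack.append((i, j - 1))
            continue
        for k in range(i + 1, j):
            if dp[i, k] + dp[k + 1, j] == target:
                stack.append((k + 1, j))
                stack.append((i, k))
                break
    pairs.sort()
    return pairs


def fold_window(seq: str) -> tuple[list[tuple[int, int]], float]:
    """Fold a precursor window.

    Returns (pairs, score): the list of paired (i, j) index pairs of one
    maximum-weight nested structure, and the score = −(total pair weight).
    """
    n = len(seq)
    if n < 1 or n > MAX_FOLD_LEN:
        raise ValueError(f"fold window length {n} outside [1, {MAX_FOLD_LEN}]")
    codes = encode(seq)
    dp = _fill(codes, _W, MIN_LOOP)
    pairs = _traceback(dp, codes)
    score = -float(dp[0, n - 1])
    return pairs, score


def fold_score_only(seq: str) -> float:
    codes = encode(seq)
    dp = _fill(codes, _W, MIN_LOOP)
    return -float(dp[0, len(seq) - 1])
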
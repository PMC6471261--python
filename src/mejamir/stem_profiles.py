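"""Short time-series profile clustering over the four timepoints.

A fixed catalogue of model profiles — integer-step shape vectors of
length 4 starting at 0, with successive differences in [−c, c] — is
reduced to k representatives by greedy maximin selection (the flat
profile is always profile 0).  Each miRNA's log2 ratio-to-control vector
is assigned to the best-correlated profile; profile over-occupancy is
tested by permuting each gene's timepoint values, with a Bonferroni
correction across profiles (the correction standard for this procedure).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_TIMEPOINTS = 4
DEFAULT_C = 2
DEFAULT_K = 20


@dataclass
class ModelProfile:
    profile_id: int
    values: tuple[int, int, int, int]
    gene_count: int = 0
    p_value: float = float("nan")

    def __post_init__(self) -> None:
        if self.values[0] != 0:
            raise ValueError("profile must start at 0")


@dataclass
class ProfileAssignment:
    mirna: str
    vector: np.ndarray          # standardized expression, starts at 0
    profile_id: int
    correlation: float


def candidate_profiles(c: int) -> list[tuple[int, ...]]:
    """All (2c+1)^3 shape vectors over 4 points starting at 0."""
    if c < 1:
        raise ValueError("c must be >= 1")
    out = []
    for steps in itertools.product(range(-c, c + 1), repeat=N_TIMEPOINTS - 1):
        v = [0]
        for s in steps:
            v.append(v[-1] + s)
        out.append(tuple(v))
    return out


def enumerate_profiles(c: int = DEFAULT_C, k: int = DEFAULT_K) -> list[ModelProfile]:
    """k representative profiles by greedy maximin Euclidean distance.

    Selection starts from the flat profile; each round adds the candidate
    maximizing the minimum distance to the already-selected set, breaking
    ties by lexicographically smallest shape vector.
    """
    cands = candidate_profiles(c)
    if k > len(cands):
        raise ValueError(f"k={k} exceeds the {len(cands)} candidates for c={c}")
    flat = tuple([0] * N_TIMEPOINTS)
    selected = [flat]
    remaining = sorted(set(cands) - {flat})
    arr = {v: np.array(v, dtype=float) for v in cands}
    while len(selected) < k:
        best, best_d = None, -1.0
        for v in remaining:
            d = min(float(np.linalg.norm(arr[v] - arr[s])) for s in selected)
            if d > best_d:
                best, best_d = v, d
        selected.append(best)
        remaining.remove(best)
    return [ModelProfile(i, v) for i, v in enumerate(selected)]


def standardize(tpm_by_timepoint: np.ndarray, pseudocount: float = 0.01) -> np.ndarray:
    """Mean TPM per timepoint → log2 ratio to the first timepoint (CK)."""
    x = np.asarray(tpm_by_timepoint, dtype=float) + pseudocount
    return np.log2(x / x[0])


def _profile_matrix(profiles: list[ModelProfile]) -> np.ndarray:
    return np.array([p.values for p in profiles], dtype=float)


def _assign_vectors(vectors: np.ndarray, pmat: np.ndarray) -> np.ndarray:
    """Profile index per row of `vectors` by maximum Pearson correlation.

    Zero-variance vectors go to the flat profile (index of the flat shape
    in `pmat`); zero-variance profiles are never matched by correlation.
    Ties break to the smaller profile id.
    """
    n, t = vectors.shape
    pc = pmat - pmat.mean(axis=1, keepdims=True)
    pn = np.linalg.norm(pc, axis=1)
    valid = pn > 0
    vc = vectors - vectors.mean(axis=1, keepdims=True)
    vn = np.linalg.norm(vc, axis=1)
    flat_idx = int(np.argmin(pn))  # the flat profile has zero norm
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (vc @ pc.T) / np.outer(vn, pn)
    corr[:, ~valid] = -np.inf
    # argmax takes the first (smallest id) on ties up to float equality
    out = np.argmax(np.round(corr, 12), axis=1)
    out[vn == 0] = flat_idx
    return out


def assign(
    vectors: dict[str, np.ndarray], profiles: list[ModelProfile]
) -> list[ProfileAssignment]:
    names = list(vectors)
    mat = np.array([vectors[m] for m in names], dtype=float)
    if not np.isfinite(mat).all():
        raise ValueError("expression vectors must be finite")
    pmat = _profile_matrix(profiles)
    idx = _assign_vectors(mat, pmat)
    assignments = []
    for i, name in enumerate(names):
        vc = mat[i] - mat[i].mean()
        pc = pmat[idx[i]] - pmat[idx[i]].mean()
        denom = np.linalg.norm(vc) * np.linalg.norm(pc)
        r = float(vc @ pc / denom) if denom > 0 else 1.0
        assignments.append(ProfileAssignment(name, mat[i], int(idx[i]), r))
    return assignments


def profile_significance(
    assignments: list[ProfileAssignment],
    profiles: list[ModelProfile],
    n_permutations: int = 10_000,
    seed: int = 0,
    alpha: float = 0.02,
) -> pd.DataFrame:
    """Permutation test of profile over-occupancy.

    Each round permutes every gene's timepoint values independently
    (re-anchoring the permuted vector at its first value), reassigns all
    genes, and records per-profile counts.  The raw p-value is the
    fraction of rounds (plus-one corrected) with count >= observed; the
    reported p is Bonferroni-corrected by the number of profiles and a
    profile is significant at p <= alpha.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    pmat = _profile_matrix(profiles)
    k = len(profiles)
    mat = np.array([a.vector for a in assignments], dtype=float)
    n = mat.shape[0]
    observed = np.bincount([a.profile_id for a in assignments], minlength=k)
    exceed = np.zeros(k, dtype=int)
    expected = np.zeros(k, dtype=float)
    for _ in range(n_permutations):
        perm = rng.permuted(mat, axis=1)
        perm = perm - perm[:, :1]  # re-anchor at the first timepoint
        idx = _assign_vectors(perm, pmat)
        cnt = np.bincount(idx, minlength=k)
        exceed += cnt >= observed
        expected += cnt
    raw = (exceed + 1) / (n_permutations + 1)
    p = np.minimum(1.0, raw * k)
    rows = []
    for j, prof in enumerate(profiles):
        prof.gene_count = int(observed[j])
        prof.p_value = float(p[j])
        rows.append({
            "profile_id": j,
            "shape": ",".join(str(v) for v in prof.values),
            "gene_count": int(observed[j]),
            "expected": expected[j] / n_permutations,
            "p_value": float(p[j]),
            "significant": bool(p[j] <= alpha and observed[j] > 0),
        })
    assert int(observed.sum()) == n
    return pd.DataFrame(rows)
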
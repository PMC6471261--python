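"""Rule-based plant miRNA target prediction and anti-correlation pairing.

A candidate site is an ungapped duplex between a miRNA (5'→3') and an
equal-length mRNA window read in the complementary orientation: miRNA
position 1 (the 5' end) pairs with the window's 3'-most base.  Each
position is Watson–Crick, G:U wobble, or a mismatch; G:U counts as half a
mismatch.  A site must satisfy, in order:

1. total mismatch score <= 4, and no two adjacent positions whose
   mismatch weights sum above 1.5 (i.e. no adjacent full mismatches);
2. within miRNA positions 2–12: no two adjacent non-Watson-Crick
   positions, and positions 10–11 perfectly paired (no mismatch, no G:U);
3. mismatch score over positions 1–12 <= 2.5;
4. duplex energy at least 74% of the perfect-complement energy,
   |E_dup| / |E_perf| >= 0.74.

The energy model is an explicit additive surrogate (GC −3, AU −2, GU −1,
mismatch 0, +1 per maximal mismatch run); swap in `energy_fn` for an
external folding engine if thermodynamic energies are wanted.

Predicted pairs are then tested for expression anti-correlation across
the eight libraries: Pearson r with the two-sided t-transform p-value,
a pair qualifying at r < −0.50 and p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.stats import t as t_dist

WC, GU, MM = "wc", "gu", "mm"

_COMP = {"A": "T", "T": "A", "U": "A", "G": "C", "C": "G"}
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# pair-state lookup over (miRNA base code, target base code)
_STATE = np.full((4, 4), 2, dtype=np.int8)  # 0=wc 1=gu 2=mm
for _a, _b in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
    _STATE[_CODE[_a], _CODE[_b]] = 0
_STATE[_CODE["G"], _CODE["T"]] = 1  # G:U
_STATE[_CODE["T"], _CODE["G"]] = 1  # U:G

_PAIR_ENERGY = {("G", "C"): -3, ("C", "G"): -3, ("A", "T"): -2, ("T", "A"): -2,
                ("G", "T"): -1, ("T", "G"): -1}
MISMATCH_RUN_PENALTY = 1.0

MAX_SCORE = 4.0
MAX_SCORE_1_12 = 2.5
SEED_START, SEED_END = 2, 12        # 1-based, inclusive
CLEAVAGE_START, CLEAVAGE_END = 10, 11
MIN_ENERGY_RATIO = 0.74
ADJ_WEIGHT_LIMIT = 1.5


@dataclass
class DuplexAlignment:
    """Position-wise miRNA:target pairing; states indexed 0..L−1 for
    miRNA positions 1..L (1 = miRNA 5' end)."""

    mirna_seq: str
    site_seq: str               # mRNA window, sense strand 5'→3'
    site_start: int             # 0-based half-open on the transcript
    site_end: int
    states: list[str]
    mismatch_score: float
    e_dup: float = 0.0
    e_perf: float = 0.0

    @property
    def ratio(self) -> float:
        return max(0.0, -self.e_dup) / (-self.e_perf) if self.e_perf < 0 else 0.0


@dataclass
class TargetPair:
    mirna: str
    gene: str
    alignment: DuplexAlignment
    verdict: str                       # 'pass' or the first violated rule
    r: Optional[float] = None
    cor_p: Optional[float] = None
    anti_correlated: bool = False


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def align_site(mirna: str, window: str) -> DuplexAlignment:
    """Classify each miRNA position against the reversed window."""
    m = _norm(mirna)
    w = _norm(window)
    if len(m) != len(w):
        raise ValueError("miRNA and window must have equal length")
    states = []
    for i, base in enumerate(m):
        targ = w[len(w) - 1 - i]  # miRNA 5' pairs the window's 3' end
        if _COMP[base] == targ:
            states.append(WC)
        elif (base, targ) in (("G", "T"), ("T", "G")):
            states.append(GU)
        else:
            states.append(MM)
    score = states.count(MM) + 0.5 * states.count(GU)
    return DuplexAlignment(m, w, 0, len(w), states, score)


def perfect_energy(mirna: str) -> float:
    """Energy of the miRNA bound to its perfect complement."""
    m = _norm(mirna)
    return float(sum(_PAIR_ENERGY[(b, _COMP[b])] for b in m))


def duplex_energy(aln: DuplexAlignment) -> float:
    """Additive surrogate energy of the aligned duplex.

    Paired positions contribute their pair energy; each maximal run of
    mismatch positions opens with a +1 penalty.  Not capped: an (already
    rule-failing) duplex of mostly mismatches can score above zero.
    """
    e = 0.0
    prev_mm = False
    for i, st in enumerate(aln.states):
        if st == MM:
            if not prev_mm:
                e += MISMATCH_RUN_PENALTY
            prev_mm = True
        else:
            prev_mm = False
            base = aln.mirna_seq[i]
            targ = aln.site_seq[len(aln.site_seq) - 1 - i]
            e += _PAIR_ENERGY[(base, targ)]
    return e


def fill_energies(aln: DuplexAlignment,
                  energy_fn: Callable[[DuplexAlignment], float] | None = None) -> None:
    aln.e_dup = (energy_fn or duplex_energy)(aln)
    aln.e_perf = perfect_energy(aln.mirna_seq)


_WEIGHT = {WC: 0.0, GU: 0.5, MM: 1.0}


def check_rules(aln: DuplexAlignment) -> str:
    """Evaluate rules 1–4 in order; returns 'pass' or the first failure."""
    w = [_WEIGHT[s] for s in aln.states]
    L = len(w)
    if aln.mismatch_score > MAX_SCORE:
        return "rule1:score"
    for i in range(L - 1):
        if w[i] + w[i + 1] > ADJ_WEIGHT_LIMIT:
            return "rule1:adjacent"
    hi = min(SEED_END, L)
    for i in range(SEED_START - 1, hi - 1):  # adjacent pairs within 2..12
        if w[i] > 0 and w[i + 1] > 0:
            return "rule2:adjacent-2-12"
    for pos in (CLEAVAGE_START, CLEAVAGE_END):
        if pos <= L and w[pos - 1] > 0:
            return "rule2:position-10-11"
    if sum(w[: min(12, L)]) > MAX_SCORE_1_12:
        return "rule3:score-1-12"
    if aln.ratio < MIN_ENERGY_RATIO:
        return "rule4:energy-ratio"
    return "pass"


def _encode(seq: str) -> np.ndarray:
    return np.array([_CODE[b] for b in _norm(seq)], dtype=np.int8)


def scan_transcriptome(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    energy_fn: Callable[[DuplexAlignment], float] | None = None,
) -> list[TargetPair]:
    """Slide each miRNA over every transcript (sense strand) and keep, per
    (miRNA, gene), the best rule-passing site (lowest mismatch score,
    then lowest duplex energy, then leftmost)."""
    pairs: list[TargetPair] = []
    enc_tx = {g: _encode(s) for g, s in transcripts.items()}
    for mid in sorted(mirnas):
        mseq = _norm(mirnas[mid])
        mcode = _encode(mseq)[::-1]  # reversed: position L..1 along the window
        L = len(mcode)
        for gene in sorted(transcripts):
            tx = enc_tx[gene]
            if len(tx) < L:
                continue
            windows = sliding_window_view(tx, L)
            states = _STATE[mcode[np.newaxis, ::-1], windows[:, ::-1]]
            scores = (states == 2).sum(axis=1) + 0.5 * (states == 1).sum(axis=1)
            best: Optional[tuple[float, float, int, DuplexAlignment]] = None
            for start in np.nonzero(scores <= MAX_SCORE)[0]:
                window = transcripts[gene][start: start + L]
                aln = align_site(mseq, window)
                aln.site_start, aln.site_end = int(start), int(start) + L
                fill_energies(aln, energy_fn)
                if check_rules(aln) != "pass":
                    continue
                key = (aln.mismatch_score, aln.e_dup, int(start))
                if best is None or key < best[:3]:
                    best = (*key, aln)
            if best is not None:
                pairs.append(TargetPair(mid, gene, best[3], "pass"))
    return pairs


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and the two-sided p from t = r·sqrt(n−2)/sqrt(1−r²)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0:
        raise ValueError("zero variance")
    r = float(np.clip(xc @ yc / denom, -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r * r)
    p = 2 * float(t_dist.sf(abs(t), n - 2))
    return r, p


def anti_correlate(
    pairs: list[TargetPair],
    mirna_tpm: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    cor_threshold: float = -0.50,
    cor_p: float = 0.05,
) -> list[TargetPair]:
    """Fill correlation fields over the shared 8-sample column order.

    Pairs whose miRNA or gene is absent from a matrix, or whose vector
    has zero variance, are dropped (with a log line in the pipeline)."""
    if list(mirna_tpm.columns) != list(mrna_expr.columns):
        raise ValueError("miRNA and mRNA matrices must share sample order")
    kept = []
    for pair in pairs:
        if pair.mirna not in mirna_tpm.index or pair.gene not in mrna_expr.index:
            continue
        x = mirna_tpm.loc[pair.mirna].to_numpy(float)
        y = mrna_expr.loc[pair.gene].to_numpy(float)
        try:
            r, p = pearson(x, y)
        except ValueError:
            continue
        pair.r, pair.cor_p = r, p
        pair.anti_correlated = bool(r < cor_threshold and p <= cor_p)
        kept.append(pair)
    return kept


def pairs_frame(pairs: list[TargetPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        a = p.alignment
        rows.append({
            "mirna": p.mirna, "gene": p.gene,
            "site_start": a.site_start + 1, "site_end": a.site_end,  # 1-based closed
            "mismatch_score": a.mismatch_score,
            "e_dup": a.e_dup, "e_perf": a.e_perf, "ratio": a.ratio,
            "r": p.r, "cor_p": p.cor_p, "anti_correlated": p.anti_correlated,
        })
    return pd.DataFrame(rows)
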
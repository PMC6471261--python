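"""Target-prediction rules checked against an independent literal evaluator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mejamir.targets import (
    DuplexAlignment, GU, MM, WC, align_site, anti_correlate, check_rules,
    duplex_energy, fill_energies, pearson, perfect_energy, scan_transcriptome,
    TargetPair,
)

COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def revcomp(s):
    return "".join(COMP[b] for b in reversed(s))


def literal_rules(states, ratio):
    """Independent re-statement of the four site rules, written directly
    from their text, over 1-based positions."""
    w = {WC: 0.0, GU: 0.5, MM: 1.0}
    L = len(states)
    score = sum(w[s] for s in states)
    if score > 4:
        return "rule1:score"
    # no adjacent pair of full mismatches anywhere
    for p in range(1, L):
        if states[p - 1] == MM and states[p] == MM:
            return "rule1:adjacent"
    # positions 2..12: no two adjacent non-Watson-Crick positions
    for p in range(2, min(12, L)):
        if states[p - 1] != WC and states[p] != WC:
            return "rule2:adjacent-2-12"
    # positions 10 and 11 perfectly paired
    for p in (10, 11):
        if p <= L and states[p - 1] != WC:
            return "rule2:position-10-11"
    if sum(w[s] for s in states[:12]) > 2.5:
        return "rule3:score-1-12"
    if ratio < 0.74:
        return "rule4:energy-ratio"
    return "pass"


def random_duplex(rng):
    """A miRNA with a window that is its complement corrupted at k spots."""
    L = int(rng.integers(18, 25))
    mirna = "".join("ACGT"[i] for i in rng.integers(0, 4, L))
    site = list(revcomp(mirna))
    for _ in range(int(rng.integers(0, 8))):
        pos = int(rng.integers(0, L))
        site[pos] = "ACGT"[int(rng.integers(0, 4))]
    aln = align_site(mirna, "".join(site))
    fill_energies(aln)
    return aln


class TestAlignSite:
    def test_perfect_complement_all_wc(self):
        m = "TGACGATCGATCCGATCGTAC"
        aln = align_site(m, revcomp(m))
        assert aln.states == [WC] * len(m)
        assert aln.mismatch_score == 0

    def test_single_gu_scores_half(self):
        m = "AAAAGAAAAAAAAAAAAAAAA"  # G at position 5
        site = list(revcomp(m))
        site[len(m) - 5] = "T"  # G:U wobble
        aln = align_site(m, "".join(site))
        assert aln.states[4] == GU
        assert aln.mismatch_score == 0.5

    def test_five_mismatches_score_five(self):
        m = "A" * 21
        site = list(revcomp(m))
        for i in range(5):
            site[i * 2] = "C"  # A:C mismatches
        aln = align_site(m, "".join(site))
        assert aln.mismatch_score == 5.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            align_site("ACGT" * 5, "ACGT" * 6)


class TestCheckRules:
    def _fabricate(self, states, ratio=1.0):
        L = len(states)
        mirna = "G" * L
        aln = DuplexAlignment(mirna, "C" * L, 0, L, list(states),
                              sum({WC: 0, GU: 0.5, MM: 1.0}[s] for s in states))
        aln.e_perf = -3.0 * L
        aln.e_dup = ratio * aln.e_perf
        return aln

    def test_perfect_complement_passes(self):
        assert check_rules(self._fabricate([WC] * 21)) == "pass"

    def test_mismatch_at_position_10_fails_rule2(self):
        states = [WC] * 21
        states[9] = MM   # position 10
        states[13] = MM  # position 14 (irrelevant to the verdict)
        assert check_rules(self._fabricate(states)) == "rule2:position-10-11"

    def test_derived_pass_case(self):
        """G:U at 3, 5, 7, 9, 12 plus a mismatch at 20 with ratio 0.80:
        score 3.5 <= 4, seed score 2.5 <= 2.5, no adjacency — passes."""
        states = [WC] * 21
        for p in (3, 5, 7, 9, 12):
            states[p - 1] = GU
        states[19] = MM
        aln = self._fabricate(states, ratio=0.80)
        assert aln.mismatch_score == 3.5
        assert check_rules(aln) == "pass"

    def test_three_consecutive_mismatches_fail_rule1(self):
        states = [WC] * 21
        for p in (18, 19, 20):
            states[p - 1] = MM
        assert check_rules(self._fabricate(states)) == "rule1:adjacent"

    def test_adjacent_gu_allowed_outside_seed(self):
        states = [WC] * 21
        states[14] = states[15] = GU  # positions 15-16
        assert check_rules(self._fabricate(states)) == "pass"

    def test_adjacent_gu_in_seed_fails_rule2(self):
        states = [WC] * 21
        states[2] = states[3] = GU  # positions 3-4
        assert check_rules(self._fabricate(states)) == "rule2:adjacent-2-12"

    def test_agrees_with_literal_evaluator(self):
        rng = np.random.default_rng(12)
        mismatching = 0
        for _ in range(10_000):
            aln = random_duplex(rng)
            got = check_rules(aln)
            want = literal_rules(aln.states, aln.ratio)
            assert got == want
            mismatching += got != "pass"
        assert 0 < mismatching < 10_000  # both verdicts exercised

    def test_monotone_under_degradation(self):
        """Degrading any position of a failing duplex never turns it into
        a pass (1,000 random degradation walks)."""
        rng = np.random.default_rng(5)
        walks = 0
        while walks < 1000:
            aln = random_duplex(rng)
            state0 = check_rules(aln)
            pos = int(rng.integers(0, len(aln.states)))
            if aln.states[pos] == MM:
                continue
            site = list(aln.site_seq)
            site[len(site) - 1 - pos] = {"A": "C", "C": "A", "G": "A",
                                         "T": "C"}[aln.mirna_seq[pos]]
            worse = align_site(aln.mirna_seq, "".join(site))
            fill_energies(worse)
            if state0 != "pass":
                assert check_rules(worse) != "pass"
            assert worse.e_dup >= aln.e_dup
            walks += 1


class TestEnergy:
    def test_all_gc_perfect_duplex(self):
        m = "G" * 11 + "C" * 11
        aln = align_site(m, revcomp(m))
        fill_energies(aln)
        assert aln.e_perf == -66.0
        assert aln.e_dup == -66.0
        assert aln.ratio == 1.0

    def test_one_mismatch_opens_a_run(self):
        m = "G" * 11 + "C" * 11
        site = list(revcomp(m))
        site[3] = "T"  # mismatch against C at miRNA position 19 (G:... no, C:T)
        aln = align_site(m, "".join(site))
        fill_energies(aln)
        assert aln.e_dup == -66.0 + 3.0 + 1.0
        assert aln.ratio == pytest.approx(62 / 66)

    def test_perfect_energy_composition(self):
        assert perfect_energy("GGCC") == -12.0
        assert perfect_energy("AATT") == -8.0
        assert perfect_energy("GAUC") == -10.0


class TestScan:
    def test_planted_site_recovered_at_coordinate(self):
        rng = np.random.default_rng(2)
        m = "".join("ACGT"[i] for i in rng.integers(0, 4, 21))
        tx = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
        site = revcomp(m)
        planted = tx[:120] + site + tx[120 + len(site):]
        pairs = scan_transcriptome({"mir1": m}, {"g1": planted})
        assert len(pairs) == 1
        assert pairs[0].alignment.site_start == 120
        assert pairs[0].alignment.mismatch_score == 0

    def test_best_site_kept(self):
        rng = np.random.default_rng(3)
        m = "".join("ACGT"[i] for i in rng.integers(0, 4, 21))
        perfect = revcomp(m)
        wobbly = list(perfect)
        # G:U at miRNA position 15 (if possible), else a mismatch
        p = 15
        wobbly[len(m) - p] = {"G": "T", "T": "G"}.get(m[p - 1], "C")
        tx = ("".join("ACGT"[i] for i in rng.integers(0, 4, 50))
              + "".join(wobbly)
              + "".join("ACGT"[i] for i in rng.integers(0, 4, 50))
              + perfect
              + "".join("ACGT"[i] for i in rng.integers(0, 4, 50)))
        pairs = scan_transcriptome({"mir1": m}, {"g1": tx})
        assert len(pairs) == 1
        assert pairs[0].alignment.mismatch_score == 0.0

    def test_random_transcripts_rarely_hit(self):
        """A 22-nt miRNA against shuffled 300-nt transcripts: almost all
        shuffles yield zero rule-passing sites."""
        rng = np.random.default_rng(4)
        m = "".join("ACGT"[i] for i in rng.integers(0, 4, 22))
        zero = 0
        n = 60
        for _ in range(n):
            tx = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
            zero += not scan_transcriptome({"m": m}, {"g": tx})
        assert zero >= n - 1


class TestAntiCorrelate:
    def _pair(self, mirna="m1", gene="g1"):
        aln = align_site("ACGTACGTACGTACGTACGTA",
                         revcomp("ACGTACGTACGTACGTACGTA"))
        fill_energies(aln)
        return TargetPair(mirna, gene, aln, "pass")

    def test_perfect_anticorrelation_flagged(self):
        z = np.array([1, 5, 2, 8, 3, 9, 4, 7], float)
        tpm = pd.DataFrame([z], index=["m1"], columns=list("abcdefgh"))
        expr = pd.DataFrame([100 - z], index=["g1"], columns=list("abcdefgh"))
        [p] = anti_correlate([self._pair()], tpm, expr)
        assert p.r == pytest.approx(-1.0)
        assert p.anti_correlated

    def test_positive_correlation_not_flagged(self):
        z = np.array([1, 5, 2, 8, 3, 9, 4, 7], float)
        tpm = pd.DataFrame([z], index=["m1"], columns=list("abcdefgh"))
        expr = pd.DataFrame([z * 2], index=["g1"], columns=list("abcdefgh"))
        [p] = anti_correlate([self._pair()], tpm, expr)
        assert p.r == pytest.approx(1.0)
        assert not p.anti_correlated

    def test_zero_variance_pair_dropped(self):
        z = np.ones(8)
        tpm = pd.DataFrame([z], index=["m1"], columns=list("abcdefgh"))
        expr = pd.DataFrame([z], index=["g1"], columns=list("abcdefgh"))
        assert anti_correlate([self._pair()], tpm, expr) == []

    def test_r_exactly_minus_half_is_not_a_pair(self):
        """r = −0.50 at n = 8 gives p ≈ 0.207: fails both conditions."""
        r, p = -0.5, 2 * stats.t.sf(0.5 * np.sqrt(6) / np.sqrt(0.75), 6)
        assert p == pytest.approx(0.2070, abs=2e-4)
        assert not (r < -0.50 and p <= 0.05)

    def test_pearson_matches_scipy(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0, 1, 8)
            r, p = pearson(x, y)
            want = stats.pearsonr(x, y)
            assert r == pytest.approx(want.statistic, rel=1e-9)
            assert p == pytest.approx(want.pvalue, rel=1e-6)
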
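"""Exact two-library count test, checked against exact rational arithmetic."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mejamir.diffexpr import ac_probability, ac_pvalue, call_dems


def exact_probability(x: int, y: int, n1: int, n2: int) -> Fraction:
    """p(x|y) in exact rational arithmetic."""
    r = Fraction(n2, n1)
    return (r ** y) * comb(x + y, y) / (1 + r) ** (x + y + 1)


def exact_pvalue(x: int, y: int, n1: int, n2: int) -> Fraction:
    c = sum(exact_probability(x, yy, n1, n2) for yy in range(0, y + 1))
    d = 1 - c + exact_probability(x, y, n1, n2)
    return min(Fraction(1), 2 * min(c, d))


class TestProbability:
    def test_closed_form_cases(self):
        assert ac_probability(0, 0, 10**6, 10**6) == pytest.approx(0.5)
        assert ac_probability(5, 0, 10**6, 10**6) == pytest.approx(2.0 ** -6)

    def test_matches_exact_arithmetic(self):
        val = ac_probability(3, 7, 10**6, 2 * 10**6)
        assert val == pytest.approx(float(exact_probability(3, 7, 10**6, 2 * 10**6)),
                                    rel=1e-12)

    @pytest.mark.parametrize("n1,n2", [(10**6, 10**6), (10**6, 2 * 10**6),
                                       (5 * 10**5, 3 * 10**6)])
    def test_sums_to_one_over_y(self, n1, n2):
        from mejamir.diffexpr import ac_log_probability
        for x in range(0, 51):
            logs = ac_log_probability(x, np.arange(0, 2000), n1, n2)
            assert np.exp(logs).sum() == pytest.approx(1.0, abs=1e-9)

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            ac_probability(-1, 0, 10, 10)
        with pytest.raises(ValueError):
            ac_probability(0, 0, 0, 10)

    def test_agrees_with_negative_binomial(self):
        """Independent route: y | x is NB(r=x+1, p=N1/(N1+N2))."""
        for x, y, n1, n2 in [(3, 7, 10**6, 2 * 10**6), (0, 4, 10, 30),
                             (12, 2, 1000, 500)]:
            p_success = n1 / (n1 + n2)
            assert ac_probability(x, y, n1, n2) == pytest.approx(
                stats.nbinom.pmf(y, x + 1, p_success), rel=1e-10)


class TestPvalue:
    def test_symmetric_point_is_one(self):
        assert ac_pvalue(7, 7, 10**6, 10**6) == 1.0

    def test_far_tail_is_tiny(self):
        assert ac_pvalue(0, 20, 10**6, 10**6) < 1e-4

    def test_mass_function_swap_identity(self):
        """p(x|y) under (x,N1)<->(y,N2) swap differs exactly by the
        N1/N2 factor —
        the pointwise identity the conditional construction implies."""
        for x, y in [(3, 9), (0, 5), (14, 2)]:
            a = ac_probability(x, y, 10**6, 3 * 10**6)
            b = ac_probability(y, x, 3 * 10**6, 10**6)
            assert a == pytest.approx(b / 3, rel=1e-9)

    def test_matches_exact_oracle_on_random_cases(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            x = int(rng.integers(0, 80))
            y = int(rng.integers(0, 80))
            n1 = int(rng.integers(10**5, 5 * 10**6))
            n2 = int(rng.integers(10**5, 5 * 10**6))
            got = ac_pvalue(x, y, n1, n2)
            want = float(exact_pvalue(x, y, n1, n2))
            assert got == pytest.approx(want, rel=1e-9, abs=1e-300)

    def test_monotone_in_distance_from_expectation(self):
        x, n1, n2 = 20, 10**6, 2 * 10**6
        center = int(x * n2 / n1)
        ps_right = [ac_pvalue(x, y, n1, n2) for y in range(center + 1, 200)]
        assert all(a >= b - 1e-12 for a, b in zip(ps_right, ps_right[1:]))
        ps_left = [ac_pvalue(x, y, n1, n2) for y in range(center - 1, 0, -1)]
        assert all(a >= b - 1e-12 for a, b in zip(ps_left, ps_left[1:]))

    def test_in_unit_interval(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = ac_pvalue(int(rng.integers(0, 50)), int(rng.integers(0, 50)),
                          int(rng.integers(1, 10**6)), int(rng.integers(1, 10**6)))
            assert 0 < p <= 1


def _matrices(tpm_rows, count_rows, libs=("A-1", "A-2", "B-1", "B-2")):
    tpm = pd.DataFrame.from_dict(tpm_rows, orient="index", columns=list(libs))
    counts = pd.DataFrame.from_dict(count_rows, orient="index", columns=list(libs))
    return tpm, counts


class TestCallDems:
    def test_fold_change_arithmetic(self):
        tpm, counts = _matrices({"m1": [10, 10, 40, 40]},
                                {"m1": [1000, 1000, 4000, 4000]})
        totals = {l: 10**6 for l in tpm.columns}
        res = call_dems(tpm, counts, totals, ["A-1", "A-2"], ["B-1", "B-2"],
                        "A_vs_B")[0]
        assert res.log2fc == pytest.approx(2.0, abs=5e-3)  # 0.01-TPM pseudocount
        assert res.direction == "up"
        assert res.significant  # huge counts, 4-fold

    def test_small_fold_never_significant(self):
        tpm, counts = _matrices({"m1": [10, 10, 15, 15]},
                                {"m1": [10000, 10000, 15000, 15000]})
        totals = {l: 10**6 for l in tpm.columns}
        res = call_dems(tpm, counts, totals, ["A-1", "A-2"], ["B-1", "B-2"],
                        "A_vs_B")[0]
        assert res.p_value < 0.05  # the counts do differ...
        assert not res.significant  # ...but |log2FC| < 1

    def test_unknown_library_errors(self):
        tpm, counts = _matrices({"m1": [1, 1, 1, 1]}, {"m1": [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="unknown library"):
            call_dems(tpm, counts, {l: 10 for l in tpm.columns},
                      ["A-1"], ["Z-9"], "bad")

    def test_null_type_one_error_controlled(self):
        """Poisson null at equal rates: rejection rate at p < 0.05 stays
        within nominal + 2 Monte-Carlo s.e. (fold gate not applied)."""
        rng = np.random.default_rng(3)
        n, depth = 2000, 10**6
        lam = rng.lognormal(3.0, 1.0, size=n)
        x = rng.poisson(lam)
        y = rng.poisson(lam)
        rej = sum(ac_pvalue(int(a), int(b), depth, depth) < 0.05
                  for a, b in zip(x, y))
        se = np.sqrt(0.05 * 0.95 / n)
        assert rej / n <= 0.05 + 2 * se

    def test_planted_recovery_and_direction_accounting(self, study_scale_run):
        """Up + down = total DEMs per comparison on the study-scale run."""
        out, _ = study_scale_run
        dem = pd.read_csv(out / "dem_CK_vs_T1.tsv", sep="\t")
        sig = dem[dem["significant"]]
        n_up = (sig["direction"] == "up").sum()
        n_down = (sig["direction"] == "down").sum()
        assert n_up + n_down == len(sig)
        assert n_up > 0 and n_down > 0
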
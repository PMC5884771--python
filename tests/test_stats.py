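import math
from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from semiqaf.phantoms import gen_cohort
from semiqaf.stats import (agreement_band, correlation_matrix, fisher_exact,
                           icc_agreement, mann_whitney_exact,
                           nir_group_analysis, spearman, wilcoxon_paired)

# Ages of the two NIR-AF groups in the clinical reference cohort.
AGES_HYPO = [39.0, 35.0, 18.0, 44.0, 21.0, 32.0, 31.0]
AGES_NORMAL = [19.0, 10.0, 10.0, 12.0, 29.0, 14.0, 15.0]


# ---------------------------------------------------------------------------
# Independent oracles


def mw_oracle_two_sided(a, b):
    """Exact two-sided Mann-Whitney p by pairwise-comparison counting
    over all group assignments (independent of the midrank route)."""
    pooled = list(a) + list(b)
    n1, n = len(a), len(pooled)

    def u_of(idx):
        group = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(n) if i not in set(idx)]
        return sum((x > y) + 0.5 * (x == y) for x in group for y in rest)

    u_obs = u_of(tuple(range(n1)))
    us = [u_of(idx) for idx in combinations(range(n), n1)]
    lo = sum(u <= u_obs + 1e-9 for u in us) / len(us)
    hi = sum(u >= u_obs - 1e-9 for u in us) / len(us)
    return min(1.0, 2 * min(lo, hi))


def fisher_oracle(table, one_sided_greater):
    """One-sided hypergeometric tail from first principles."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return (math.comb(c1, k) * math.comb(n - c1, r1 - k)
                / math.comb(n, r1))

    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    if one_sided_greater:
        return sum(pmf(k) for k in support if k >= a)
    return sum(pmf(k) for k in support if k <= a)


def wilcoxon_oracle(x, y):
    d = [xi - yi for xi, yi in zip(x, y) if xi != yi]
    r = sps.rankdata([abs(v) for v in d])
    w_obs = sum(ri for ri, di in zip(r, d) if di > 0)
    totals = [sum(ri for ri, s in zip(r, signs) if s)
              for signs in product([0, 1], repeat=len(d))]
    lo = sum(t <= w_obs + 1e-9 for t in totals) / len(totals)
    hi = sum(t >= w_obs - 1e-9 for t in totals) / len(totals)
    return min(1.0, 2 * min(lo, hi))


def icc_a1_oracle(m):
    """Single-measure absolute-agreement ICC from ANOVA mean squares."""
    m = np.asarray(m, float)
    n, k = m.shape
    msr = k * np.var(m.mean(axis=1), ddof=1)
    msc = n * np.var(m.mean(axis=0), ddof=1)
    mse = (np.sum((m - m.mean(axis=1, keepdims=True)
                   - m.mean(axis=0, keepdims=True) + m.mean()) ** 2)
           / ((n - 1) * (k - 1)))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


# ---------------------------------------------------------------------------
# Spearman


class TestSpearman:
    def test_cohort_acuities(self, cohort16):
        rho, p = spearman([r.logmar_od for r in cohort16],
                          [r.logmar_os for r in cohort16])
        assert round(rho, 2) == 0.82
        assert p < 0.05

    def test_perfect_monotone(self):
        rho, p = spearman([1, 2, 3, 4, 5], [10, 20, 25, 40, 100])
        assert rho == 1.0

    def test_tie_heavy_matches_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.integers(0, 4, size=12).astype(float)
            y = rng.integers(0, 4, size=12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(sps.spearmanr(x, y).statistic,
                                        abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


# ---------------------------------------------------------------------------
# Mann-Whitney


class TestMannWhitney:
    def test_age_comparison(self):
        res = mann_whitney_exact(AGES_HYPO, AGES_NORMAL)
        assert round(res.p_value, 3) == 0.004
        assert res.p_value == pytest.approx(14 / 3432)

    def test_identical_multisets(self):
        res = mann_whitney_exact([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0

    def test_separated_groups(self):
        res = mann_whitney_exact([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)

    def test_refuses_large_samples(self):
        with pytest.raises(ValueError, match="refused"):
            mann_whitney_exact(list(range(11)), list(range(10)))

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(15):
            n1 = int(rng.integers(2, 7))
            n2 = int(rng.integers(2, 13 - n1))
            a = rng.integers(0, 6, n1).astype(float)
            b = rng.integers(0, 6, n2).astype(float)
            assert mann_whitney_exact(a, b).p_value == pytest.approx(
                mw_oracle_two_sided(a, b), abs=1e-12)

    def test_null_calibration(self):
        # Type-I error of the exact test at alpha=0.05 under the null,
        # 200 continuous-data replicates, within binomial 95% bounds.
        rng = np.random.default_rng(99)
        rejections = sum(
            mann_whitney_exact(rng.normal(size=6),
                               rng.normal(size=6)).p_value <= 0.05
            for _ in range(200))
        # 200 trials at p=0.05: mean 10, 95% interval approx [4, 16]
        assert 3 <= rejections <= 17


# ---------------------------------------------------------------------------
# Fisher


class TestFisher:
    def test_stage_contingency_one_sided(self):
        res = fisher_exact([[5, 2], [1, 6]], sidedness="one")
        assert round(res.p_value, 3) == 0.051
        assert res.p_value == pytest.approx(176 / 3432)

    def test_no_association(self):
        assert fisher_exact([[1, 1], [1, 1]]).p_value == 1.0

    def test_matches_hypergeometric_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            t = rng.integers(0, 8, size=(2, 2))
            if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
                continue
            expected = t.sum(axis=1)[0] * t.sum(axis=0)[0] / t.sum()
            one = fisher_exact(t, "one").p_value
            assert one == pytest.approx(
                fisher_oracle(t, t[0, 0] >= expected), abs=1e-12)
            two = fisher_exact(t, "two").p_value
            assert two == pytest.approx(_two_sided_oracle(t), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.integers(0, 10), min_size=4, max_size=4))
    def test_one_sided_not_larger_than_two_sided(self, cells):
        t = [[cells[0], cells[1]], [cells[2], cells[3]]]
        tt = np.array(t)
        if (tt.sum(axis=0) == 0).any() or (tt.sum(axis=1) == 0).any():
            return
        assert fisher_exact(t, "one").p_value <= \
            fisher_exact(t, "two").p_value + 1e-12

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[0, 0], [2, 3]])


def _two_sided_oracle(t):
    (a, b), (c, d) = t
    r1, c1, n = a + b, a + c, a + b + c + d

    def pmf(k):
        return (math.comb(c1, k) * math.comb(n - c1, r1 - k)
                / math.comb(n, r1))

    support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
    p_obs = pmf(a)
    return min(1.0, sum(pmf(k) for k in support
                        if pmf(k) <= p_obs * (1 + 1e-12)))


# ---------------------------------------------------------------------------
# Wilcoxon


class TestWilcoxon:
    def test_uniform_shift(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        y = [xi - 0.5 for xi in x]
        assert wilcoxon_paired(x, y).p_value == pytest.approx(2 / 64)

    def test_degenerate(self):
        with pytest.raises(ValueError):
            wilcoxon_paired([1.0, 2.0], [1.0, 2.0])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        checked = 0
        while checked < 40:
            n = int(rng.integers(3, 11))
            x = rng.integers(0, 8, n).astype(float)
            y = rng.integers(0, 8, n).astype(float)
            if np.all(x == y):
                continue
            assert wilcoxon_paired(x, y).p_value == pytest.approx(
                wilcoxon_oracle(x, y), abs=1e-12)
            checked += 1

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        y = x + 0.8 + rng.normal(scale=0.3, size=30)
        res = wilcoxon_paired(x, y)
        assert "approximation" in res.method
        assert res.p_value < 0.01


# ---------------------------------------------------------------------------
# ICC


class TestICC:
    def test_perfect_agreement(self):
        m = np.tile(np.arange(1.0, 9.0)[:, None], (1, 2))
        res = icc_agreement(m)
        assert res.icc == pytest.approx(1.0)
        assert res.band == "excellent"

    def test_closed_form_oracle(self):
        m = np.column_stack([np.arange(1.0, 6.0), np.arange(2.0, 7.0)])
        res = icc_agreement(m)
        assert res.icc == pytest.approx(icc_a1_oracle(m), abs=1e-10)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(17)
        m = rng.normal(size=(10, 3)) + rng.normal(size=(10, 1)) * 2
        res = icc_agreement(m)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(10), 3),
            "rater": np.tile(np.arange(3), 10),
            "score": m.ravel(),
        })
        table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="score").set_index("Type")
        row = table.loc["ICC(A,1)"] if "ICC(A,1)" in table.index \
            else table.loc["ICC2"]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-6)
        ci_col = "CI95" if "CI95" in row.index else "CI95%"
        lo, hi = row[ci_col]  # pingouin rounds the CI to 2 decimals
        assert res.ci_low == pytest.approx(lo, abs=0.02)
        assert res.ci_high == pytest.approx(hi, abs=0.02)

    def test_noise_decreases_icc(self):
        subjects = np.arange(0.0, 10.0)[:, None]
        base = icc_agreement(np.tile(subjects, (1, 2))).icc
        rng = np.random.default_rng(31)
        noisy = [icc_agreement(np.tile(subjects, (1, 2))
                               + rng.normal(scale=1.0, size=(10, 2))).icc
                 for _ in range(50)]
        assert np.mean(noisy) < base

    @pytest.mark.parametrize("ci_low,band", [
        (0.944, "excellent"), (0.91, "excellent"), (0.90, "good"),
        (0.75, "good"), (0.749, "moderate"), (0.50, "moderate"),
        (0.49, "poor"), (-0.2, "poor"),
    ])
    def test_band_thresholds(self, ci_low, band):
        assert agreement_band(ci_low) == band

    def test_zero_between_subject_variance(self):
        with pytest.raises(ValueError):
            icc_agreement(np.zeros((6, 2)))


# ---------------------------------------------------------------------------
# Cohort-level analyses


class TestCorrelationMatrix:
    def test_simulated_structure(self):
        sim = gen_cohort(60, render=False, seed=12)
        cm = correlation_matrix(sim.cohort)
        rho, p = cm.cell("age", "hypo_diameter_deg")
        assert rho > 0 and p <= 0.05
        rho2, p2 = cm.cell("hypo_diameter_deg", "ise_width_deg")
        assert rho2 > 0 and p2 <= 0.05

    def test_symmetry(self):
        sim = gen_cohort(30, render=False, seed=13)
        cm = correlation_matrix(sim.cohort)
        assert np.allclose(cm.rho.to_numpy(), cm.rho.to_numpy().T,
                           equal_nan=True)
        assert np.allclose(cm.p.to_numpy(), cm.p.to_numpy().T,
                           equal_nan=True)

    def test_constant_column_skipped(self, cohort16):
        import dataclasses
        recs = tuple(dataclasses.replace(r, age=30) for r in cohort16)
        cohort = dataclasses.replace(cohort16, records=recs)
        with pytest.warns(UserWarning, match="age"):
            cm = correlation_matrix(cohort)
        assert "age" not in cm.variables


class TestNIRGroups:
    def test_reference_cohort(self, cohort16):
        rep = nir_group_analysis(cohort16)
        assert round(rep.mann_whitney.p_value, 3) == 0.004
        assert round(rep.fisher.p_value, 3) == 0.051
        assert rep.contingency.tolist() == [[5, 2], [1, 6]]
        assert rep.mean_age_present == pytest.approx(31.43, abs=0.01)
        assert rep.mean_age_absent == pytest.approx(15.57, abs=0.01)

    def test_borderline_excluded(self, cohort16):
        rep = nir_group_analysis(cohort16)
        assert len(rep.ages_present) == 7
        assert len(rep.ages_absent) == 7

    def test_identical_distributions(self, cohort16):
        import dataclasses
        recs = []
        for i, r in enumerate(cohort16):
            status = "present" if i % 2 == 0 else "absent"
            recs.append(dataclasses.replace(r, age=30 + i // 2,
                                            niraf_hypo=status,
                                            ise_width_deg=None
                                            if r.oct_stage > 1 else 0.0))
        cohort = dataclasses.replace(cohort16, records=tuple(recs))
        rep = nir_group_analysis(cohort)
        assert rep.mann_whitney.p_value > 0.5
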
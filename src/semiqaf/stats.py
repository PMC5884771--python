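"""Nonparametric statistics for small clinical cohorts.

The comparisons reported for the cohort rely on small-sample exact
tests: a tie-aware exact Mann-Whitney test (complete enumeration of
group assignments), Fisher's exact test, the exact Wilcoxon signed-rank
test for inter-eye symmetry, Spearman rank correlations, and two-way
absolute-agreement intraclass correlation coefficients whose agreement
band is read off the lower end of the 95% confidence interval.

Exact Mann-Whitney and Wilcoxon p-values are computed by enumeration in
this module so that tied observations are handled by permutation of the
observed values rather than by an asymptotic tie correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .cohort import CohortTable

__all__ = [
    "TestResult",
    "ICCResult",
    "spearman",
    "mann_whitney_exact",
    "fisher_exact",
    "wilcoxon_paired",
    "icc_agreement",
    "agreement_band",
    "correlation_matrix",
    "CorrelationMatrix",
    "nir_group_analysis",
    "NIRGroupReport",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    sidedness: str  # "one" or "two"
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of range: {self.p_value}")


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float

    def __iter__(self):
        return iter((self.rho, self.p_value))


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    rho is the Pearson correlation of midranks; the two-sided p-value
    uses the t-approximation with n-2 degrees of freedom (adequate for
    the cohort sizes here; an exact permutation p is impractical with
    ties at n = 16).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if len(x) < 4:
        raise ValueError("need at least 4 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rho = float(np.clip(np.mean(rx * ry), -1.0, 1.0))
    if 1.0 - abs(rho) < 1e-12:  # snap float round-off on exact rank ties
        rho = math.copysign(1.0, rho)
    n = len(x)
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    return SpearmanResult(rho, min(p, 1.0))


def _u_statistic(ranks: np.ndarray, idx: Iterable[int], n1: int) -> float:
    return float(sum(ranks[i] for i in idx)) - n1 * (n1 + 1) / 2.0


def mann_whitney_exact(a: Sequence[float], b: Sequence[float],
                       sidedness: str = "two",
                       max_total: int = 20) -> TestResult:
    """Exact Mann-Whitney test by complete enumeration.

    U is computed from midranks of the pooled sample; the null
    distribution enumerates all C(n1+n2, n1) assignments of the observed
    pooled values to the first group, which handles ties naturally.
    The two-sided p is twice the smaller tail, capped at 1.  Refuses
    (rather than silently approximating) when n1+n2 exceeds
    ``max_total``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(a), len(b)
    if n1 + n2 > max_total:
        raise ValueError(
            f"exact enumeration refused for n1+n2 = {n1 + n2} > {max_total}")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks, range(n1), n1)
    us = np.fromiter(
        (_u_statistic(ranks, idx, n1)
         for idx in combinations(range(n1 + n2), n1)),
        dtype=float,
    )
    eps = 1e-9
    p_low = float(np.mean(us <= u_obs + eps))
    p_high = float(np.mean(us >= u_obs - eps))
    if sidedness == "two":
        p = min(1.0, 2.0 * min(p_low, p_high))
    elif sidedness == "greater":  # a tends larger than b
        p = p_high
    elif sidedness == "less":
        p = p_low
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    side = "two" if sidedness == "two" else "one"
    return TestResult(u_obs, p, side, "Mann-Whitney exact (enumeration)")


def fisher_exact(table, sidedness: str = "two") -> TestResult:
    """Fisher's exact test on a 2x2 table of counts.

    One-sided: hypergeometric tail of tables as or more extreme in the
    observed direction of association.  Two-sided: sum of probabilities
    of all tables no more probable than the observed one.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be 2x2 non-negative integer counts")
    t = t.astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("Fisher test undefined with an empty margin")
    if sidedness == "two":
        _, p = sps.fisher_exact(t, alternative="two-sided")
        side = "two"
    elif sidedness == "one":
        # Observed direction: compare the top-left cell with its
        # expectation under independence.
        expected = t.sum(axis=1)[0] * t.sum(axis=0)[0] / t.sum()
        alt = "greater" if t[0, 0] >= expected else "less"
        _, p = sps.fisher_exact(t, alternative=alt)
        side = "one"
    else:
        raise ValueError(f"unknown sidedness {sidedness!r}")
    odds = math.inf if t[0, 1] * t[1, 0] == 0 else \
        (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return TestResult(float(odds), float(min(p, 1.0)), side, "Fisher exact")


def wilcoxon_paired(x: Sequence[float], y: Sequence[float],
                    exact_limit: int = 15) -> TestResult:
    """Wilcoxon signed-rank test for paired samples (two-sided).

    Zero differences are dropped.  For n <= ``exact_limit`` nonzero
    differences the p-value enumerates all 2^n sign assignments of the
    midranks of |d| (tie-aware); beyond that a normal approximation with
    tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all paired differences are zero; test degenerate")
    r = sps.rankdata(np.abs(d))
    w_obs = float(r[d > 0].sum())
    if n <= exact_limit:
        totals = np.fromiter(
            (float(np.dot(signs, r))
             for signs in product((0.0, 1.0), repeat=n)),
            dtype=float,
        )
        eps = 1e-9
        p_low = float(np.mean(totals <= w_obs + eps))
        p_high = float(np.mean(totals >= w_obs - eps))
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "Wilcoxon signed-rank exact (enumeration)"
    else:
        mean = n * (n + 1) / 4.0
        ties = np.unique(r, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 \
            - float(((ties ** 3 - ties) / 48.0).sum())
        z = (w_obs - mean) / math.sqrt(var)
        p = 2.0 * float(sps.norm.sf(abs(z)))
        method = "Wilcoxon signed-rank normal approximation"
    return TestResult(w_obs, min(p, 1.0), "two", method)


# ---------------------------------------------------------------------------
# Intraclass correlation


_BANDS = ("poor", "moderate", "good", "excellent")


def agreement_band(ci_low: float) -> str:
    """Agreement band determined by the lower 95% CI bound of the ICC.

    poor < 0.50 <= moderate < 0.75 <= good <= 0.90 < excellent.  The
    synonym "substantial" is sometimes used for the good band.
    """
    if ci_low > 0.90:
        return "excellent"
    if ci_low >= 0.75:
        return "good"
    if ci_low >= 0.50:
        return "moderate"
    return "poor"


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    band: str
    model: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.icc + 1e-12
                and self.icc <= self.ci_high + 1e-12):
            raise ValueError("CI must bracket the ICC estimate")


def icc_agreement(ratings, model: str = "inter",
                  alpha: float = 0.05) -> ICCResult:
    """Single-measure, absolute-agreement, two-way random-effects ICC.

    ``ratings`` is a subjects x raters matrix (for intra-observer
    agreement the columns are repeated measurements by one observer;
    the computation is identical and ``model`` only labels the result).
    The confidence interval is the standard F-based interval with
    Satterthwaite degrees of freedom; the agreement band comes from the
    lower CI bound.
    """
    if model not in ("inter", "intra"):
        raise ValueError("model must be 'inter' or 'intra'")
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValueError("ratings must be a 2-D matrix")
    n, k = m.shape
    if n < 5 or k < 2:
        raise ValueError("need >= 5 subjects and >= 2 raters/repeats")
    if np.isnan(m).any():
        raise ValueError("missing cells are not supported")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    if msr <= 1e-300:
        raise ValueError("zero between-subject variance; ICC undefined")

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom

    # F-based interval (single-measure absolute agreement).
    if mse == 0.0 and msc == 0.0:
        lo = hi = 1.0
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1.0 else math.inf
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1.0 \
            else math.inf
        if math.isinf(a):
            lo = hi = 1.0
        else:
            num = (a * msc + b * mse) ** 2
            den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
            v = num / den
            f_star = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_lower = sps.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_star * mse) / (
                f_star * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f_lower * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_lower * msr)
    lo = float(np.clip(lo, -1.0, 1.0))
    hi = float(np.clip(hi, -1.0, 1.0))
    lo, icc, hi = sorted((lo, float(icc), hi))
    return ICCResult(icc, lo, hi, agreement_band(lo), model)


# ---------------------------------------------------------------------------
# Cohort-level composite analyses


#: Variables entering the cohort correlation matrix, in display order.
CORRELATION_VARIABLES = (
    "age", "logmar", "oct_stage", "ise_width_deg",
    "ring_diameter_deg", "hypo_diameter_deg",
)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Spearman correlations with pairwise deletion of missing
    values.  No multiple-testing correction is applied; raw p-values are
    reported."""

    variables: tuple[str, ...]
    rho: "object"   # pandas DataFrame
    p: "object"     # pandas DataFrame
    n: "object"     # pandas DataFrame of complete-pair counts

    def cell(self, a: str, b: str) -> tuple[float, float]:
        return float(self.rho.loc[a, b]), float(self.p.loc[a, b])


def correlation_matrix(cohort: CohortTable,
                       variables: Sequence[str] = CORRELATION_VARIABLES,
                       min_pairs: int = 4) -> CorrelationMatrix:
    """Spearman correlation matrix over clinical/imaging variables.

    Columns that are entirely missing or constant are skipped with a
    warning.  Cells with fewer than ``min_pairs`` complete pairs are NaN.
    """
    import pandas as pd

    df = cohort.to_dataframe()
    df["logmar"] = [r.logmar_study_eye for r in cohort]
    cols = {}
    for v in variables:
        series = pd.to_numeric(df[v], errors="coerce")
        valid = series.dropna()
        if valid.empty or valid.nunique() == 1:
            warnings.warn(f"column {v!r} skipped (all-missing or constant)")
            continue
        cols[v] = series
    kept = tuple(cols)
    size = len(kept)
    rho = pd.DataFrame(np.full((size, size), np.nan), index=kept, columns=kept)
    p = rho.copy()
    npairs = pd.DataFrame(np.zeros((size, size), dtype=int),
                          index=kept, columns=kept)
    for i, a in enumerate(kept):
        for j, b in enumerate(kept):
            if j < i:
                continue
            mask = cols[a].notna() & cols[b].notna()
            npairs.loc[a, b] = npairs.loc[b, a] = int(mask.sum())
            if a == b:
                rho.loc[a, b], p.loc[a, b] = 1.0, 0.0
                continue
            if mask.sum() < min_pairs:
                continue
            xa = cols[a][mask].to_numpy()
            xb = cols[b][mask].to_numpy()
            if np.ptp(xa) == 0 or np.ptp(xb) == 0:
                continue
            res = spearman(xa, xb)
            rho.loc[a, b] = rho.loc[b, a] = res.rho
            p.loc[a, b] = p.loc[b, a] = res.p_value
    return CorrelationMatrix(kept, rho, p, npairs)


@dataclass(frozen=True)
class NIRGroupReport:
    """Comparison of patients with vs without the central NIR-AF
    hypoautofluorescent area (borderline cases excluded from both
    groups)."""

    ages_present: tuple[float, ...]
    ages_absent: tuple[float, ...]
    mean_age_present: float
    sd_age_present: float
    mean_age_absent: float
    sd_age_absent: float
    mann_whitney: TestResult
    contingency: "object"  # 2x2 ndarray [[adv+,not adv+],[adv-,not adv-]]
    fisher: TestResult

    def as_dict(self) -> dict:
        return {
            "n_present": len(self.ages_present),
            "n_absent": len(self.ages_absent),
            "mean_age_present": self.mean_age_present,
            "sd_age_present": self.sd_age_present,
            "mean_age_absent": self.mean_age_absent,
            "sd_age_absent": self.sd_age_absent,
            "mann_whitney_p": self.mann_whitney.p_value,
            "contingency": np.asarray(self.contingency).tolist(),
            "fisher_p": self.fisher.p_value,
            "fisher_sidedness": self.fisher.sidedness,
        }


def nir_group_analysis(cohort: CohortTable,
                       fisher_sidedness: str = "one") -> NIRGroupReport:
    """Compare ages and advanced OCT stage between NIR-AF groups.

    Ages are compared with the exact two-sided Mann-Whitney test.
    Advanced outer-retinal alteration (stage 3 or 4) is cross-tabulated
    against group membership; the Fisher test is one-sided by default
    (the direction of more advanced stages in the hypoautofluorescent
    group), configurable via ``fisher_sidedness``.
    """
    present = [r for r in cohort if r.niraf_hypo == "present"]
    absent = [r for r in cohort if r.niraf_hypo == "absent"]
    if len(present) < 2 or len(absent) < 2:
        raise ValueError("need >= 2 categorized patients per NIR-AF group")
    ages_p = tuple(float(r.age) for r in present)
    ages_a = tuple(float(r.age) for r in absent)
    mw = mann_whitney_exact(ages_p, ages_a, sidedness="two")
    adv_p = sum(r.oct_stage >= 3 for r in present)
    adv_a = sum(r.oct_stage >= 3 for r in absent)
    table = np.array([[adv_p, len(present) - adv_p],
                      [adv_a, len(absent) - adv_a]])
    fisher = fisher_exact(table, sidedness=fisher_sidedness)
    return NIRGroupReport(
        ages_present=ages_p,
        ages_absent=ages_a,
        mean_age_present=float(np.mean(ages_p)),
        sd_age_present=float(np.std(ages_p, ddof=1)),
        mean_age_absent=float(np.mean(ages_a)),
        sd_age_absent=float(np.std(ages_a, ddof=1)),
        mann_whitney=mw,
        contingency=table,
        fisher=fisher,
    )
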
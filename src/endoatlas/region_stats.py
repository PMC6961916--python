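"""Cross-region statistical battery.

Paired nonparametric and parametric location tests between regions,
goodness-of-fit and binomial count tests on detection/exclusivity
tallies, case-bootstrap confidence intervals for between-region
correlations of arcsine-square-root transformed normalized expression,
and the Dunn–Šidák family-wise correction.

All tests are two-sided. Test statistics follow the R conventions the
field reports: the Wilcoxon signed-rank statistic is V, the sum of the
ranks of the positive differences (zeros dropped, average ranks for
ties).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .regions import ConfigurationError, UndefinedTestError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    """A named test statistic with its p-value and sample size."""

    method: str
    statistic_name: str  # V, t, chi2, z, ...
    statistic: float
    p: float
    n: int
    df: float | None = None
    sidedness: str = "two-sided"

    def as_dict(self) -> dict:
        return {"method": self.method, "statistic_name": self.statistic_name,
                "statistic": self.statistic, "df": self.df, "p": self.p,
                "n": self.n, "sidedness": self.sidedness}


@dataclass(frozen=True)
class BootstrapCI:
    """A percentile bootstrap confidence interval for an estimate."""

    estimate: float
    lower: float
    upper: float
    confidence: float = 0.95
    replicates: int = 10_000
    method: str = "case-bootstrap percentile"

    def covers(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def wilcoxon_paired(x, y) -> TestResult:
    """Wilcoxon signed-rank test on paired per-gene values.

    V = sum of the ranks of positive differences after dropping zero
    differences, with average ranks for ties. The p-value is exact for
    n' <= 25 with no tied |differences|, otherwise from the normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise UndefinedTestError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    return TestResult(method=f"Wilcoxon signed rank ({method})", statistic_name="V",
                      statistic=v, p=float(res.pvalue), n=n)


def paired_t(x, y) -> TestResult:
    """Paired t test on per-gene differences (two-sided, df = n - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise UndefinedTestError("paired t needs >= 2 pairs of equal length")
    d = x - y
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d, 0):
            return TestResult(method="paired t", statistic_name="t", statistic=0.0,
                              p=1.0, n=len(x), df=float(len(x) - 1))
        raise UndefinedTestError("zero variance of nonzero differences")
    res = stats.ttest_rel(x, y)
    return TestResult(method="paired t", statistic_name="t", statistic=float(res.statistic),
                      p=float(res.pvalue), n=len(x), df=float(len(x) - 1))


def chisq_equal(counts) -> TestResult:
    """Chi-square goodness of fit against equal expected counts.

    No continuity correction; df = k - 1.
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) < 2 or (counts < 0).any():
        raise UndefinedTestError("need >= 2 non-negative category counts")
    total = counts.sum()
    if total == 0:
        raise UndefinedTestError("total count is zero")
    chi2, p = stats.chisquare(counts)
    return TestResult(method="chi-square goodness of fit", statistic_name="chi2",
                      statistic=float(chi2), p=float(p), n=int(total),
                      df=float(len(counts) - 1))


def binomial_detected(k_region1: int, k_region2: int) -> TestResult:
    """Exact two-sided binomial test comparing two detection counts.

    Tests ``k_region1`` successes in ``k_region1 + k_region2`` trials
    against success probability 0.5 — i.e. whether genes detected in
    either region split evenly between the two.
    """
    k1, k2 = int(k_region1), int(k_region2)
    if k1 < 0 or k2 < 0:
        raise UndefinedTestError("counts must be non-negative")
    if k1 + k2 == 0:
        raise UndefinedTestError("both counts are zero")
    res = stats.binomtest(k1, k1 + k2, 0.5, alternative="two-sided")
    return TestResult(method="exact binomial", statistic_name="k",
                      statistic=float(k1), p=float(res.pvalue), n=k1 + k2)


def arcsine_sqrt(values_pct) -> np.ndarray:
    """arcsin(sqrt(x / 100)) variance-stabilizing transform of percentages."""
    v = np.asarray(values_pct, dtype=float)
    if (v < 0).any() or (v > 100).any():
        raise UndefinedTestError("normalized values must lie in [0, 100]")
    return np.arcsin(np.sqrt(v / 100.0))


def bootstrap_correlation(a, b, reps: int = 10_000, seed: int = 0,
                          confidence: float = 0.95) -> BootstrapCI:
    """Pearson correlation of arcsine-sqrt transformed normalized values,
    with a case-bootstrap (genes resampled with replacement) percentile
    confidence interval.
    """
    if reps < 1:
        raise ConfigurationError("replicates must be >= 1")
    ta, tb = arcsine_sqrt(a), arcsine_sqrt(b)
    if len(ta) != len(tb) or len(ta) < 3:
        raise UndefinedTestError("need >= 3 paired values of equal length")
    if np.allclose(ta.std(), 0) or np.allclose(tb.std(), 0):
        raise UndefinedTestError("zero variance after transform; correlation undefined")
    r = float(np.corrcoef(ta, tb)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(ta)
    idx = rng.integers(0, n, size=(reps, n))
    xa, xb = ta[idx], tb[idx]
    xa = xa - xa.mean(axis=1, keepdims=True)
    xb = xb - xb.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = (xa * xb).sum(axis=1) / np.sqrt((xa ** 2).sum(axis=1) * (xb ** 2).sum(axis=1))
    rs = rs[np.isfinite(rs)]  # degenerate resamples (constant column) dropped
    lo, hi = np.percentile(rs, [100 * (1 - confidence) / 2, 100 * (1 + confidence) / 2])
    return BootstrapCI(estimate=r, lower=float(lo), upper=float(hi),
                       confidence=confidence, replicates=reps)


def dunn_sidak(alpha: float, m: int) -> float:
    """Dunn–Šidák per-comparison critical level 1 - (1 - alpha)^(1/m)."""
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie in (0, 1)")
    if m < 1:
        raise ConfigurationError("number of comparisons must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def pairwise_region_tests(profiles: pd.DataFrame, regions, test: str = "wilcoxon") -> list[TestResult]:
    """Run the paired location test between every pair of regions.

    ``test`` is ``wilcoxon`` (whole-brain regions, unnormalized data)
    or ``paired_t`` (hippocampal subfields). Genes with a missing value
    in either region of a pair are dropped from that pair.
    """
    fn = {"wilcoxon": wilcoxon_paired, "paired_t": paired_t}[test]
    results = []
    for r1, r2 in itertools.combinations(regions, 2):
        sub = profiles[[r1, r2]].dropna()
        try:
            res = fn(sub[r1].to_numpy(), sub[r2].to_numpy())
        except UndefinedTestError as exc:
            logger.info("%s vs %s: %s test undefined (%s); skipped", r1, r2, test, exc)
            continue
        results.append(TestResult(method=f"{res.method} [{r1} vs {r2}]",
                                  statistic_name=res.statistic_name,
                                  statistic=res.statistic, p=res.p, n=res.n, df=res.df))
    return results


def pairwise_correlations(normalized: pd.DataFrame, regions, reps: int = 10_000,
                          seed: int = 0) -> pd.DataFrame:
    """Case-bootstrap correlation CIs for every pair of regions."""
    rows = []
    for i, (r1, r2) in enumerate(itertools.combinations(regions, 2)):
        sub = normalized[[r1, r2]].dropna()
        try:
            ci = bootstrap_correlation(sub[r1], sub[r2], reps=reps, seed=seed + i)
        except UndefinedTestError as exc:
            logger.info("%s vs %s: correlation undefined (%s); skipped", r1, r2, exc)
            continue
        rows.append({"region1": r1, "region2": r2, "r": ci.estimate,
                     "ci_lower": ci.lower, "ci_upper": ci.upper,
                     "replicates": ci.replicates, "n": len(sub)})
    return pd.DataFrame(rows)


def results_table(results: list[TestResult]) -> pd.DataFrame:
    """One row per test: method, statistic, df, p, n."""
    return pd.DataFrame([r.as_dict() for r in results])


__all__ = [
    "TestResult", "BootstrapCI", "wilcoxon_paired", "paired_t", "chisq_equal",
    "binomial_detected", "bootstrap_correlation", "arcsine_sqrt", "dunn_sidak",
    "pairwise_region_tests", "pairwise_correlations", "results_table",
]
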
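"""Ligand-effect meta-comparison between receptor groups.

Literature-derived effects of each receptor's ligand on long-term
potentiation (LTP) and on neurogenesis are coded −1 (inhibit), 0
(mixed/none), +1 (promote) or unknown. The question is whether effect
direction differs between challenge (group A, DG-enriched) and
sufficiency (group B, CA-enriched) receptors: group means of the codes
are compared by Student's unpaired (pooled-variance) t test on the full
scores, and by a Pearson chi-square test (no continuity correction) on
the 2x2 inhibit-vs-promote table with 0-coded and unknown entries
excluded — the chi-square contrasts inhibition versus stimulation,
while the t test uses the full graded score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import require_columns
from .regions import UndefinedTestError
from .region_stats import TestResult

PARAMETERS = ("ltp", "neurogenesis")


def _known_codes(effects: pd.DataFrame, parameter: str, group: str) -> np.ndarray:
    require_columns(effects, ["gene", "group", parameter], "effects table")
    sel = (effects["group"] == group) & effects[parameter].notna()
    codes = effects.loc[sel, parameter].to_numpy(dtype=float)
    bad = ~np.isin(codes, (-1.0, 0.0, 1.0))
    if bad.any():
        raise UndefinedTestError(f"effect codes must be -1/0/+1/NA; got {codes[bad][0]}")
    return codes


def group_mean_scores(effects: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Mean effect code per group (unknowns excluded), with group n."""
    rows = []
    for group in ("A", "B"):
        codes = _known_codes(effects, parameter, group)
        if len(codes) == 0:
            raise UndefinedTestError(f"group {group} has no known {parameter} codes")
        rows.append({"group": group, "parameter": parameter,
                     "mean_score": float(codes.mean()), "n": len(codes)})
    return pd.DataFrame(rows)


def compare_groups(effects: pd.DataFrame, parameter: str) -> tuple[TestResult, TestResult]:
    """Intergroup comparison of effect codes for one parameter.

    Returns ``(t_result, chi2_result)``. The t test is Student's
    unpaired pooled-variance t on all known codes (including 0); the
    chi-square is Pearson's test without continuity correction on the
    2x2 table (inhibit vs promote) x (group A vs B), excluding zeros.
    Either test may be undefined on degenerate data, in which case that
    member raises; callers wanting both should catch per test.
    """
    a = _known_codes(effects, parameter, "A")
    b = _known_codes(effects, parameter, "B")

    if len(a) < 2 or len(b) < 2:
        raise UndefinedTestError("both groups need >= 2 known codes for the t test")
    if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
        t_res = None  # surfaced below; chi-square may still be valid
    else:
        t = stats.ttest_ind(a, b, equal_var=True)
        t_res = TestResult(method=f"Student unpaired t [{parameter}]", statistic_name="t",
                           statistic=float(t.statistic), p=float(t.pvalue),
                           n=len(a) + len(b), df=float(len(a) + len(b) - 2))

    table = np.array([[(a == -1).sum(), (a == 1).sum()],
                      [(b == -1).sum(), (b == 1).sum()]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        chi_res = None
    else:
        chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
        chi_res = TestResult(method=f"chi-square 2x2 [{parameter}]", statistic_name="chi2",
                             statistic=float(chi2), p=float(p),
                             n=int(table.sum()), df=float(df))

    if t_res is None and chi_res is None:
        raise UndefinedTestError("both tests undefined on degenerate codes")
    if t_res is None:
        raise UndefinedTestError(
            "pooled variance is zero; t undefined "
            f"(chi-square remains valid: chi2={chi_res.statistic:.3g}, p={chi_res.p:.3g})"
        )
    if chi_res is None:
        raise UndefinedTestError(
            "empty margin in the 2x2 inhibit/promote table; chi-square undefined "
            f"(t remains valid: t={t_res.statistic:.3g}, p={t_res.p:.3g})"
        )
    return t_res, chi_res


def chi2_2x2(effects: pd.DataFrame, parameter: str) -> TestResult:
    """The chi-square half of :func:`compare_groups`, usable alone when
    the t test is degenerate (e.g. zero pooled variance)."""
    a = _known_codes(effects, parameter, "A")
    b = _known_codes(effects, parameter, "B")
    table = np.array([[(a == -1).sum(), (a == 1).sum()],
                      [(b == -1).sum(), (b == 1).sum()]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise UndefinedTestError("empty margin in the 2x2 inhibit/promote table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return TestResult(method=f"chi-square 2x2 [{parameter}]", statistic_name="chi2",
                      statistic=float(chi2), p=float(p), n=int(table.sum()), df=float(df))


def effect_summary(effects: pd.DataFrame) -> pd.DataFrame:
    """Mean scores and both intergroup tests for LTP and neurogenesis."""
    rows = []
    for parameter in PARAMETERS:
        means = group_mean_scores(effects, parameter)
        t_res, chi_res = compare_groups(effects, parameter)
        rows.append({
            "parameter": parameter,
            "mean_A": float(means.loc[means["group"] == "A", "mean_score"].iloc[0]),
            "mean_B": float(means.loc[means["group"] == "B", "mean_score"].iloc[0]),
            "n_A": int(means.loc[means["group"] == "A", "n"].iloc[0]),
            "n_B": int(means.loc[means["group"] == "B", "n"].iloc[0]),
            "t": t_res.statistic, "t_p": t_res.p,
            "chi2": chi_res.statistic, "chi2_p": chi_res.p,
        })
    return pd.DataFrame(rows)


__all__ = ["group_mean_scores", "compare_groups", "chi2_2x2", "effect_summary", "PARAMETERS"]
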
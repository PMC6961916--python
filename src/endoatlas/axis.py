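"""The dentate gyrus vs cornu ammonis enrichment axis.

For each gene the statistic is the log expression ratio between DG and
the mean of the CA fields,

    delta = log10(DG + c) - log10(meanCA + c),   c in {1, 2},

computed on normalized (percent-of-maximum) subfield values; the small
offset c accommodates zeros, and group-level conclusions are required to
be stable across both offsets. Group A ("challenge") and group B
("sufficiency") gene sets are compared by Welch's unequal-variance t
test and by a two-stage permutation test: the observed between-group
difference of mean delta is referred to a null distribution built by
randomizing the group labels (10 000 replicates by default, exhaustive
enumeration of all label assignments when the gene count is small).

The same machinery applies to subfield RNA-seq FPKM tables after
flooring sub-detection values (FPKM < 4) to zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import require_columns
from .regions import CA_FIELDS, SUBFIELDS, ConfigurationError, SchemaError, UndefinedTestError
from .region_stats import TestResult

#: FPKM below this floor is treated as undetected (set to 0); the floor
#: is inclusive — exactly 4 FPKM is retained.
FPKM_FLOOR = 4.0

#: Exhaustive label enumeration is used at or below this many genes.
EXHAUSTIVE_LIMIT = 12


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of the label-randomization test on the group contrast."""

    observed: float          # mean delta(A) - mean delta(B)
    p: float
    replicates: int
    null_mean: float
    null_sd: float
    exhaustive: bool
    seed: int | None = None

    def summary(self) -> str:
        mode = "exhaustive" if self.exhaustive else f"{self.replicates} replicates"
        return (f"permutation test ({mode}): observed diff {self.observed:.4f}, "
                f"p = {self.p:.4g}")


def compute_delta(normalized: pd.DataFrame, groups: pd.DataFrame | None = None,
                  offset: int = 1, log_base: float = 10.0,
                  ca_fields: tuple[str, ...] = CA_FIELDS) -> pd.DataFrame:
    """Per-gene DG vs mean-CA log ratios from a normalized subfield table.

    Returns columns gene, dg, mean_ca, offset, delta and (when a
    group-label table is given) group. Genes with a missing subfield
    value are excluded, with the exclusion count recorded in
    ``result.attrs['n_excluded']``.
    """
    if offset not in (1, 2):
        raise ConfigurationError("offset must be 1 or 2")
    require_columns(normalized, list(ca_fields) + ["DG"], "normalized table")
    sub = normalized[["gene", *ca_fields, "DG"]].copy()
    complete = sub[[*ca_fields, "DG"]].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    sub = sub[complete]
    mean_ca = sub[list(ca_fields)].mean(axis=1)
    delta = (np.log(sub["DG"] + offset) - np.log(mean_ca + offset)) / math.log(log_base)
    out = pd.DataFrame({"gene": sub["gene"], "dg": sub["DG"], "mean_ca": mean_ca,
                        "offset": offset, "delta": delta})
    if groups is not None:
        require_columns(groups, ["gene", "group"], "group table")
        out = out.merge(groups[["gene", "group"]], on="gene", how="left")
    out = out.reset_index(drop=True)
    out.attrs["n_excluded"] = n_excluded
    out.attrs["log_base"] = log_base
    return out


def _group_values(delta: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if "group" not in delta.columns:
        raise SchemaError("delta table carries no group labels")
    a = delta.loc[delta["group"] == "A", "delta"].to_numpy(dtype=float)
    b = delta.loc[delta["group"] == "B", "delta"].to_numpy(dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ConfigurationError("both groups must be non-empty")
    return a, b


def welch_t(delta_a, delta_b) -> TestResult:
    """Welch's unequal-variance t test with Welch–Satterthwaite df."""
    a = np.asarray(delta_a, dtype=float)
    b = np.asarray(delta_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise UndefinedTestError("each group needs >= 2 values")
    if np.allclose(a.std(ddof=1), 0) and np.allclose(b.std(ddof=1), 0):
        if np.isclose(a.mean(), b.mean()):
            return TestResult(method="Welch t", statistic_name="t", statistic=0.0,
                              p=1.0, n=len(a) + len(b), df=float(len(a) + len(b) - 2))
        raise UndefinedTestError("zero variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(method="Welch t", statistic_name="t", statistic=float(res.statistic),
                      p=float(res.pvalue), n=len(a) + len(b), df=float(res.df))


def permutation_test(delta: pd.DataFrame, reps: int = 10_000, seed: int = 0) -> PermutationResult:
    """Two-stage permutation test on the A-vs-B difference of mean delta.

    Stage one computes the observed difference of group means; stage two
    randomizes delta values among the groups (group sizes preserved) and
    recomputes the difference, ``reps`` times, to build the null. The
    two-sided p-value uses add-one smoothing, p = (1 + #{|null| >=
    |observed|}) / (reps + 1). With ``EXHAUSTIVE_LIMIT`` or fewer genes
    all label assignments are enumerated instead and p is the exact
    fraction of assignments at least as extreme.
    """
    if reps < 1:
        raise ConfigurationError("replicates must be >= 1")
    a, b = _group_values(delta)
    pooled = np.concatenate([a, b])
    n, na = len(pooled), len(a)
    observed = float(a.mean() - b.mean())

    if n <= EXHAUSTIVE_LIMIT:
        diffs = np.array([
            pooled[list(idx)].mean() - np.delete(pooled, list(idx)).mean()
            for idx in itertools.combinations(range(n), na)
        ])
        p = float((np.abs(diffs) >= abs(observed) - 1e-12).mean())
        return PermutationResult(observed=observed, p=p, replicates=len(diffs),
                                 null_mean=float(diffs.mean()), null_sd=float(diffs.std()),
                                 exhaustive=True)

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (reps, 1)), axis=1)
    diffs = perms[:, :na].mean(axis=1) - perms[:, na:].mean(axis=1)
    k = int((np.abs(diffs) >= abs(observed) - 1e-12).sum())
    p = (1 + k) / (reps + 1)
    return PermutationResult(observed=observed, p=p, replicates=reps,
                             null_mean=float(diffs.mean()), null_sd=float(diffs.std()),
                             exhaustive=False, seed=seed)


def fold_difference(delta: pd.DataFrame, log_base: float = 10.0) -> float:
    """Between-group fold: base^(mean delta(A) - mean delta(B)).

    Invariant to the log base used consistently throughout.
    """
    a, b = _group_values(delta)
    return float(log_base ** (a.mean() - b.mean()))


def group_fold(delta: pd.DataFrame, group: str = "A", log_base: float = 10.0) -> float:
    """Realized within-group enrichment fold.

    For group A this is base^(mean delta), the geometric-mean DG/CA
    ratio; for group B the reciprocal orientation base^(-mean delta),
    i.e. the CA/DG enrichment. This is the quantity that recovers a
    generator's configured per-group fold.
    """
    vals = delta.loc[delta["group"] == group, "delta"].to_numpy(dtype=float)
    if len(vals) == 0:
        raise ConfigurationError(f"group {group} is empty")
    sign = 1.0 if group == "A" else -1.0
    return float(log_base ** (sign * vals.mean()))


@dataclass(frozen=True)
class AxisResult:
    """Bundle of the axis analysis under one offset."""

    delta: pd.DataFrame
    welch: TestResult
    permutation: PermutationResult
    fold: float
    fold_a: float
    fold_b: float
    offset: int

    def summary(self) -> str:
        w = self.welch
        lines = [
            f"DG vs CA axis (offset {self.offset}, n = {len(self.delta)} genes)",
            f"  Welch t = {w.statistic:.2f}, df = {w.df:.2f}, p = {w.p:.3g}",
            f"  {self.permutation.summary()}",
            f"  between-group fold = {self.fold:.2f} "
            f"(group A DG/CA {self.fold_a:.2f}, group B CA/DG {self.fold_b:.2f})",
        ]
        return "\n".join(lines)


def analyze_axis(normalized: pd.DataFrame, groups: pd.DataFrame, offset: int = 1,
                 reps: int = 10_000, seed: int = 0, log_base: float = 10.0) -> AxisResult:
    """Run the full axis analysis on a normalized subfield table."""
    delta = compute_delta(normalized, groups, offset=offset, log_base=log_base)
    informative = delta[delta["group"].isin(["A", "B"])].reset_index(drop=True)
    a, b = _group_values(informative)
    return AxisResult(
        delta=informative,
        welch=welch_t(a, b),
        permutation=permutation_test(informative, reps=reps, seed=seed),
        fold=fold_difference(informative, log_base=log_base),
        fold_a=group_fold(informative, "A", log_base=log_base),
        fold_b=group_fold(informative, "B", log_base=log_base),
        offset=offset,
    )


def floor_fpkm(fpkm: pd.DataFrame, floor: float = FPKM_FLOOR,
               subfields: tuple[str, ...] = SUBFIELDS) -> pd.DataFrame:
    """Set sub-detection FPKM values (< floor) to zero; floor inclusive."""
    out = fpkm.copy()
    for col in subfields:
        if col in out.columns:
            v = out[col].astype(float)
            out[col] = v.where(v >= floor, 0.0)
    return out


def fpkm_axis(fpkm: pd.DataFrame, groups: pd.DataFrame, floor: float = FPKM_FLOOR,
              offset: int = 1, reps: int = 10_000, seed: int = 0,
              normalize: bool = True) -> AxisResult:
    """Axis analysis on a subfield FPKM table.

    FPKM below the detection floor is zeroed, the table is normalized to
    percent-of-maximum per gene (so that delta lives on the same scale
    as the intensity-based analysis), and the same delta / Welch /
    permutation machinery runs on the result.
    """
    from .expression import normalize_profiles

    require_columns(fpkm, list(SUBFIELDS), "FPKM table")
    floored = floor_fpkm(fpkm, floor=floor)
    detected = floored[list(SUBFIELDS)].sum(axis=1) > 0
    floored = floored[detected].reset_index(drop=True)
    table = normalize_profiles(floored, regions=list(SUBFIELDS)) if normalize else floored
    return analyze_axis(table, groups, offset=offset, reps=reps, seed=seed)


__all__ = [
    "compute_delta", "welch_t", "permutation_test", "fold_difference", "group_fold",
    "analyze_axis", "fpkm_axis", "floor_fpkm", "AxisResult", "PermutationResult",
    "FPKM_FLOOR", "EXHAUSTIVE_LIMIT",
]
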
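"""Normalization and detection/prominence classification of profiles.

Per-gene intensities are normalized to the gene's maximum region
(= 100%), a transformation that removes probe-specific hybridization
efficiency and leaves the inter-regional pattern. Genes are then called
expressed or absent per region, and classified across HPC/CX/CB as
exclusively expressed in one region, most prominently expressed in one
region, or shared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regions import ALL_REGIONS, BRAIN_REGIONS, EndoatlasError

logger = logging.getLogger(__name__)

#: Default detection threshold on the 0–255 intensity scale. The original
#: detection call was made by eye; the threshold is exposed in config and
#: echoed in output metadata.
DETECTION_THRESHOLD = 10.0

#: Pixel-intensity coefficient of variation above which expression is
#: treated as punctate/irreproducible and called absent.
PUNCTATE_CV = 3.0


def normalize_profiles(profiles: pd.DataFrame, regions: list[str] | None = None) -> pd.DataFrame:
    """Express each gene's intensities as a percentage of its maximum.

    The per-gene maximum maps to exactly 100; an all-zero gene stays all
    zero (and is flagged absent downstream). Idempotent, and invariant to
    rescaling a gene's raw intensities by any positive constant.
    """
    regions = regions or [c for c in profiles.columns if c in ALL_REGIONS]
    vals = profiles[regions].to_numpy(dtype=float)
    if np.isnan(vals).all(axis=1).any():
        raise EndoatlasError("gene with no region measurements cannot be normalized")
    if np.nanmin(vals) < 0:
        raise EndoatlasError("negative intensities are not valid input")
    mx = np.nanmax(vals, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        # ratio first: v/max is exactly 1.0 at the max, so the row max is
        # exactly 100 and nothing exceeds it by a rounding ulp
        normed = np.where(mx > 0, (vals / mx) * 100.0, 0.0)
    out = profiles.copy()
    out[regions] = normed
    return out


@dataclass(frozen=True)
class DetectionParams:
    threshold: float = DETECTION_THRESHOLD
    punctate_cv: float = PUNCTATE_CV


def call_detection(
    profiles: pd.DataFrame,
    threshold: float = DETECTION_THRESHOLD,
    punctate_cv: float = PUNCTATE_CV,
    regions: list[str] | None = None,
) -> pd.DataFrame:
    """Call each gene expressed or absent per region.

    A region is called expressed iff its mean intensity is at or above
    ``threshold`` (boundary inclusive) and, when per-ROI pixel statistics
    are available (``cv_<region>`` columns from image quantification),
    the pixel coefficient of variation does not exceed ``punctate_cv``
    (high CV = a few bright puncta rather than reproducible signal).

    Returns long-form rows (gene, region, status, reason) with
    status in {expressed, absent} and reason in {none, below-threshold,
    punctate}.
    """
    if threshold < 0:
        raise EndoatlasError("detection threshold must be non-negative")
    regions = regions or [c for c in profiles.columns if c in ALL_REGIONS]
    rows = []
    for _, row in profiles.iterrows():
        for region in regions:
            mean = row[region]
            if pd.isna(mean):
                continue  # not assessed, not absent
            cv = row.get(f"cv_{region}", np.nan)
            if mean < threshold:
                status, reason = "absent", "below-threshold"
            elif not pd.isna(cv) and cv > punctate_cv:
                status, reason = "absent", "punctate"
            else:
                status, reason = "expressed", "none"
            rows.append({"gene": row["gene"], "region": region, "status": status, "reason": reason})
    return pd.DataFrame(rows)


def detection_matrix(calls: pd.DataFrame, regions: list[str]) -> pd.DataFrame:
    """Pivot long-form calls to a boolean gene x region matrix."""
    if calls.empty:
        return pd.DataFrame(columns=regions).rename_axis("gene")
    wide = (calls[calls["region"].isin(regions)]
            .assign(expressed=lambda d: d["status"] == "expressed")
            .pivot(index="gene", columns="region", values="expressed"))
    return wide.reindex(columns=regions)


def classify_prominence(
    calls: pd.DataFrame,
    normalized: pd.DataFrame,
    regions: tuple[str, ...] = BRAIN_REGIONS,
) -> pd.DataFrame:
    """Classify each gene across the whole-brain regions.

    category: ``exclusive:R`` (expressed in exactly one region R),
    ``prominent:R`` (expressed in 2+ regions, unique maximum in R),
    ``shared`` (tie on the maximum), or ``absent``. The ``prominent``
    column separately records the region of maximum normalized
    expression among expressed regions for *every* expressed gene
    (so exclusive genes also count as prominent in their region),
    with ties recorded as no prominent region.
    """
    det = detection_matrix(calls, list(regions))
    norm = normalized.set_index("gene")
    rows = []
    for gene, flags in det.iterrows():
        avail = flags.dropna()
        if len(avail) < len(regions):
            logger.warning("gene %s missing %d region(s); classified from available regions",
                           gene, len(regions) - len(avail))
        expressed = [r for r in avail.index if avail[r]]
        if not expressed:
            rows.append({"gene": gene, "category": "absent", "prominent": None})
            continue
        vals = norm.loc[gene, expressed].astype(float)
        top = vals.max()
        winners = [r for r in expressed if vals[r] == top]
        prominent = winners[0] if len(winners) == 1 else None
        if len(expressed) == 1:
            category = f"exclusive:{expressed[0]}"
        elif prominent is None:
            category = "shared"
        else:
            category = f"prominent:{prominent}"
        rows.append({"gene": gene, "category": category, "prominent": prominent})
    return pd.DataFrame(rows)


def tabulate_counts(
    categories: pd.DataFrame,
    calls: pd.DataFrame,
    regions: tuple[str, ...] = BRAIN_REGIONS,
    panel_size: int | None = None,
) -> pd.DataFrame:
    """Summary counts and percentages per region.

    detectable percentages use the full panel size as denominator;
    exclusive and prominent percentages use the number of brain-expressed
    genes (expressed in at least one of the compared regions), matching
    the reporting convention of the source analysis.
    """
    n_panel = panel_size or categories["gene"].nunique()
    det = detection_matrix(calls, list(regions))
    n_brain = int((det.fillna(False).sum(axis=1) > 0).sum())
    rows = []
    for region in regions:
        n_det = int(det[region].fillna(False).sum())
        n_exc = int((categories["category"] == f"exclusive:{region}").sum())
        n_prom = int((categories["prominent"] == region).sum())
        rows.append({
            "region": region,
            "n_detectable": n_det,
            "pct_detectable": round(100.0 * n_det / n_panel, 1) if n_panel else 0.0,
            "n_exclusive": n_exc,
            "pct_exclusive": round(100.0 * n_exc / n_brain, 1) if n_brain else 0.0,
            "n_prominent": n_prom,
            "pct_prominent": round(100.0 * n_prom / n_brain, 1) if n_brain else 0.0,
        })
    out = pd.DataFrame(rows)
    out.attrs["panel_size"] = n_panel
    out.attrs["n_brain_expressed"] = n_brain
    return out


__all__ = [
    "normalize_profiles", "call_detection", "detection_matrix",
    "classify_prominence", "tabulate_counts",
    "DETECTION_THRESHOLD", "PUNCTATE_CV", "DetectionParams",
]
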
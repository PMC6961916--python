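"""End-to-end orchestration: quantify → normalize → classify → statistics.

The pipeline runs on synthetic data, on user-supplied tables, or on
pseudocolored images plus masks. Stages whose inputs are absent are
skipped with a logged notice. Every run is deterministic given the root
seed, and every output directory carries run metadata (config hash,
seed, package version).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .axis import FPKM_FLOOR, AxisResult, analyze_axis, fpkm_axis
from .effects import effect_summary
from .expression import (
    DETECTION_THRESHOLD,
    PUNCTATE_CV,
    call_detection,
    classify_prominence,
    detection_matrix,
    normalize_profiles,
    tabulate_counts,
)
from .imagequant import AtlasImage, quantify_atlas
from .io import read_table, stage_rng, write_table
from .region_stats import (
    binomial_detected,
    chisq_equal,
    dunn_sidak,
    pairwise_correlations,
    pairwise_region_tests,
    results_table,
)
from .regions import BRAIN_REGIONS, SUBFIELDS, ConfigurationError
from .synthetic import SyntheticConfig, generate_all

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; hashable to a stable run fingerprint."""

    mode: str = "synthetic"                  # synthetic | tables | images
    profiles_path: str | None = None
    fpkm_path: str | None = None
    effects_path: str | None = None
    groups_path: str | None = None
    images_dir: str | None = None
    detection_threshold: float = DETECTION_THRESHOLD
    punctate_cv: float = PUNCTATE_CV
    rater_tolerance: float = 10.0
    raters: int = 1
    fpkm_floor: float = FPKM_FLOOR
    offset: int = 1
    bootstrap_reps: int = 10_000
    permutation_reps: int = 10_000
    seed: int = 0
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "tables", "images"):
            raise ConfigurationError(f"unknown mode '{self.mode}'")
        if self.bootstrap_reps < 1 or self.permutation_reps < 1:
            raise ConfigurationError("replicate counts must be >= 1")
        for name in ("detection_threshold", "punctate_cv", "rater_tolerance", "fpkm_floor"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.offset not in (1, 2):
            raise ConfigurationError("offset must be 1 or 2")
        for name in ("profiles_path", "fpkm_path", "effects_path", "groups_path", "images_dir"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigurationError(f"{name}: no such file {p}")

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class PipelineRun:
    """Tables and test results produced by one pipeline execution."""

    config: PipelineConfig
    tables: dict[str, pd.DataFrame]
    results: dict[str, Any]
    axis: dict[int, AxisResult]
    out_dir: Path | None = None

    def summary(self) -> str:
        lines = [f"endoatlas run {self.config.digest()} (seed {self.config.seed})"]
        if "summary" in self.tables:
            lines.append(self.tables["summary"].to_string(index=False))
        for off, res in sorted(self.axis.items()):
            lines.append(res.summary())
        return "\n".join(lines)


def _load_inputs(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    if config.mode == "synthetic":
        data = generate_all(dataclasses.replace(config.synthetic, seed=config.seed))
        return {k: v for k, v in data.items()}
    tables: dict[str, pd.DataFrame] = {}
    if config.mode == "images":
        if not config.images_dir:
            raise ConfigurationError("images mode requires images_dir")
        images = {}
        img_dir = Path(config.images_dir)
        for img_path in sorted(img_dir.glob("*_expression.png")):
            gene = img_path.name.removesuffix("_expression.png")
            mask_path = img_dir / f"{gene}_mask.png"
            if not mask_path.exists():
                logger.warning("gene %s: mask missing; recorded as not assessed", gene)
                continue
            images[gene] = AtlasImage.load(img_path, mask_path)
        rng = stage_rng(config.seed, "raters")
        profiles, flags = quantify_atlas(
            images, raters=config.raters, tolerance=config.rater_tolerance,
            seed=int(rng.integers(2**31)),
        )
        tables["profiles"] = profiles
        tables["rater_flags"] = flags
    else:
        if not config.profiles_path:
            raise ConfigurationError("tables mode requires profiles_path")
        tables["profiles"] = read_table(config.profiles_path, "intensity")
    if config.groups_path:
        tables["groups"] = read_table(config.groups_path, "groups")
    if config.fpkm_path:
        tables["fpkm"] = read_table(config.fpkm_path, "fpkm")
    if config.effects_path:
        tables["effects"] = read_table(config.effects_path, "effects")
    return tables


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineRun:
    """Execute all stages whose inputs are present; write a run directory.

    Stage order: quantify → normalize → classify → region statistics →
    axis statistics (offsets 1 and 2) → FPKM cross-validation → ligand
    effects. The FPKM and effects stages are skipped with a notice when
    their tables are absent.
    """
    inputs = _load_inputs(config)
    profiles = inputs["profiles"]
    tables: dict[str, pd.DataFrame] = {"profiles": profiles}
    if "truth" in inputs:
        tables["truth"] = inputs["truth"]
    if "rater_flags" in inputs:
        tables["rater_flags"] = inputs["rater_flags"]
    results: dict[str, Any] = {"seed": config.seed, "config_digest": config.digest()}

    # --- normalize and classify ------------------------------------------
    normalized = normalize_profiles(profiles, regions=list(BRAIN_REGIONS))
    calls = call_detection(profiles, threshold=config.detection_threshold,
                           punctate_cv=config.punctate_cv, regions=list(BRAIN_REGIONS))
    categories = classify_prominence(calls, normalized)
    summary = tabulate_counts(categories, calls, panel_size=len(profiles))
    tables.update(normalized=normalized, detection_calls=calls,
                  categories=categories, summary=summary)
    results["detection"] = {
        "panel_size": summary.attrs["panel_size"],
        "n_brain_expressed": summary.attrs["n_brain_expressed"],
        "pct_brain_expressed": round(100.0 * summary.attrs["n_brain_expressed"]
                                     / max(summary.attrs["panel_size"], 1), 1),
        "per_region": summary.to_dict(orient="records"),
    }

    # --- region statistics ------------------------------------------------
    det = detection_matrix(calls, list(BRAIN_REGIONS)).fillna(False)
    brain_genes = det.index[det.any(axis=1)]
    brain_profiles = profiles[profiles["gene"].isin(brain_genes)]
    region_tests = pairwise_region_tests(brain_profiles, BRAIN_REGIONS, test="wilcoxon")

    sub_calls = call_detection(profiles, threshold=config.detection_threshold,
                               punctate_cv=config.punctate_cv, regions=list(SUBFIELDS))
    sub_det = detection_matrix(sub_calls, list(SUBFIELDS)).fillna(False)
    hpc_genes = sub_det.index[sub_det.any(axis=1)]
    hpc_profiles = profiles[profiles["gene"].isin(hpc_genes)]
    subfield_tests = pairwise_region_tests(hpc_profiles, SUBFIELDS, test="paired_t")

    counts = {r: int(det[r].sum()) for r in BRAIN_REGIONS}
    binom_tests = []
    for r1, r2 in (("HPC", "CX"), ("HPC", "CB"), ("CX", "CB")):
        res = binomial_detected(counts[r1], counts[r2])
        binom_tests.append(dataclasses.replace(res, method=f"{res.method} [{r1} vs {r2}]"))
    chisq_tests = []
    excl_counts = [int((categories["category"] == f"exclusive:{r}").sum()) for r in BRAIN_REGIONS]
    prom_counts = [int((categories["prominent"] == r).sum()) for r in BRAIN_REGIONS]
    for kind, c in (("exclusive", excl_counts), ("prominent", prom_counts)):
        if sum(c) > 0:
            res = chisq_equal(c)
            chisq_tests.append(dataclasses.replace(res, method=f"{res.method} [{kind}]"))

    rng = stage_rng(config.seed, "bootstrap")
    norm_sub = normalize_profiles(hpc_profiles, regions=list(SUBFIELDS))
    corr_brain = pairwise_correlations(
        normalized[normalized["gene"].isin(brain_genes)], BRAIN_REGIONS,
        reps=config.bootstrap_reps, seed=int(rng.integers(2**31)))
    corr_sub = pairwise_correlations(norm_sub, SUBFIELDS,
                                     reps=config.bootstrap_reps, seed=int(rng.integers(2**31)))

    all_tests = region_tests + subfield_tests + binom_tests + chisq_tests
    tables["region_tests"] = results_table(all_tests)
    tables["correlations_brain"] = corr_brain
    tables["correlations_subfields"] = corr_sub
    results["region_tests"] = [t.as_dict() for t in all_tests]
    results["dunn_sidak"] = {"alpha": 0.05,
                             "crit_3": dunn_sidak(0.05, 3),
                             "crit_6": dunn_sidak(0.05, 6)}

    # --- axis statistics ---------------------------------------------------
    groups = inputs.get("groups")
    if groups is None and "truth" in inputs:
        truth = inputs["truth"]
        groups = truth.loc[truth["group"].isin(["A", "B"]), ["gene", "group"]]
    axis_results: dict[int, AxisResult] = {}
    if groups is not None and len(groups):
        arng = stage_rng(config.seed, "permutation")
        perm_seed = int(arng.integers(2**31))
        for off in (1, 2):
            axis_results[off] = analyze_axis(norm_sub, groups, offset=off,
                                             reps=config.permutation_reps, seed=perm_seed)
        tables["delta"] = axis_results[config.offset].delta
        results["axis"] = {
            str(off): {
                "welch": res.welch.as_dict(),
                "permutation_p": res.permutation.p,
                "observed_diff": res.permutation.observed,
                "fold_difference": res.fold,
                "fold_A": res.fold_a,
                "fold_B": res.fold_b,
            } for off, res in axis_results.items()
        }
    else:
        logger.info("no group labels: axis stage skipped")

    # --- FPKM cross-validation --------------------------------------------
    fpkm = inputs.get("fpkm")
    if fpkm is not None and groups is not None and len(groups):
        frng = stage_rng(config.seed, "fpkm-permutation")
        fres = fpkm_axis(fpkm, groups, floor=config.fpkm_floor, offset=config.offset,
                         reps=config.permutation_reps, seed=int(frng.integers(2**31)))
        results["fpkm_axis"] = {
            "welch": fres.welch.as_dict(),
            "permutation_p": fres.permutation.p,
            "fold_difference": fres.fold,
            "fold_A": fres.fold_a,
            "fold_B": fres.fold_b,
        }
        tables["fpkm_delta"] = fres.delta
    else:
        logger.info("FPKM table absent: cross-validation stage skipped")

    # --- ligand effects ----------------------------------------------------
    effects = inputs.get("effects")
    if effects is not None and effects[["ltp", "neurogenesis"]].notna().any().any():
        eff = effect_summary(effects)
        tables["effect_summary"] = eff
        results["effects"] = eff.to_dict(orient="records")
    else:
        logger.info("effects table absent: ligand-effect stage skipped")

    run = PipelineRun(config=config, tables=tables, results=results, axis=axis_results)
    if out_dir is not None:
        run.out_dir = _write_run(run, Path(out_dir))
    return run


def _write_run(run: PipelineRun, out_dir: Path) -> Path:
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, df in run.tables.items():
        write_table(df.reset_index(drop=True) if df.index.name else df, out_dir / f"{name}.tsv")
    with open(out_dir / "results.json", "w") as fh:
        json.dump(run.results, fh, indent=2, default=_jsonable)
    meta = {
        "package": "endoatlas",
        "version": __version__,
        "seed": run.config.seed,
        "config_digest": run.config.digest(),
        "config": dataclasses.asdict(run.config),
        "detection_threshold": run.config.detection_threshold,
        "punctate_cv": run.config.punctate_cv,
    }
    with open(out_dir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return out_dir


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)


__all__ = ["PipelineConfig", "PipelineRun", "run_pipeline"]
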
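"""Synthetic expression atlases with known ground truth.

Generates the four kinds of input the analysis pipeline consumes —
per-gene region intensity tables, pseudocolored images with region
masks, subfield FPKM tables, and ligand-effect tables — carrying the
statistical structure the analysis assumes: a panel of endocrine-like
receptor genes of which a configurable informative subset is enriched
along the dentate gyrus (DG) vs cornu ammonis (CA) axis, with group A
("challenge") genes DG-enriched and group B ("sufficiency") genes
CA-enriched at a configurable fold before noise.

Defaults mirror the study conditions of the mouse-brain receptor
survey the pipeline re-implements: 253 genes, 98 expressed somewhere in
brain, 86 in hippocampus (76 cortex, 53 cerebellum), 32 informative
genes split 16/16, and an 8.33-fold DG/CA enrichment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .imagequant import AtlasImage, ColorScale
from .io import stage_rng
from .regions import ALL_REGIONS, MASK_LABELS, SUBFIELDS, ConfigurationError

#: Version tag of the deterministic cartoon region layout.
LAYOUT_VERSION = "1"


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of a synthetic receptor-expression atlas.

    Parameters
    ----------
    n_genes : total receptor panel size.
    n_informative : genes with a known A/B (challenge/sufficiency) label,
        split evenly between the groups.
    dg_fold_A : true DG/CA intensity ratio of group A genes (before noise).
    ca_fold_B : true CA/DG intensity ratio of group B genes.
    base_intensity : true intensity (0–255) of the *low* side of an
        informative gene's axis (the CA fields of an A gene, DG of a B gene).
    noise_sd : additive Gaussian noise, intensity units, applied to
        expressed measurements and truncated to [0, 255].
    frac_brain_expressed / frac_hpc_expressed / frac_cx_expressed /
    frac_cb_expressed : fractions of the panel detectably expressed in
        brain overall and per region; realized as exact counts.
    effect_concordance : probability that an informative gene's ligand
        effect on LTP / neurogenesis has the group-typical sign.
    seed : root seed; each generator stage draws from its own substream.
    """

    n_genes: int = 253
    n_informative: int = 32
    dg_fold_A: float = 8.33
    ca_fold_B: float = 8.33
    base_intensity: float = 24.0
    noise_sd: float = 5.0
    frac_brain_expressed: float = 98 / 253
    frac_hpc_expressed: float = 86 / 253
    frac_cx_expressed: float = 76 / 253
    frac_cb_expressed: float = 53 / 253
    effect_concordance: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dg_fold_A <= 0 or self.ca_fold_B <= 0:
            raise ConfigurationError("enrichment folds must be positive")
        for name in ("frac_brain_expressed", "frac_hpc_expressed",
                     "frac_cx_expressed", "frac_cb_expressed", "effect_concordance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.n_informative > self.n_genes:
            raise ConfigurationError("n_informative exceeds n_genes")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not 0 <= self.base_intensity <= 255:
            raise ConfigurationError("base_intensity outside [0, 255]")


def generate_profiles(config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an observed intensity table and its ground truth.

    Returns ``(profiles, truth)``. ``profiles`` has columns
    gene, HPC, CX, CB, CA1, CA2, CA3, DG with observed mean intensities
    (true mean plus truncated Gaussian noise on expressed entries; true
    zeros observe as exact zeros, since undetected probes render black).
    ``truth`` carries per-gene true means (``true_<region>``), the group
    label (A / B / uninformative) and per-region detection status.
    """
    cfg = config
    rng = stage_rng(cfg.seed, "profiles")
    n = cfg.n_genes
    genes = np.array([f"G{i + 1:04d}" for i in range(n)])

    n_brain = int(round(cfg.frac_brain_expressed * n))
    n_hpc = min(int(round(cfg.frac_hpc_expressed * n)), n_brain)
    n_cx = min(int(round(cfg.frac_cx_expressed * n)), n_brain)
    n_cb = min(int(round(cfg.frac_cb_expressed * n)), n_brain)
    if cfg.n_informative > n_hpc:
        raise ConfigurationError("informative genes must fit inside the HPC-expressed set")

    brain = rng.choice(n, size=n_brain, replace=False)
    hpc = rng.choice(brain, size=n_hpc, replace=False)
    cx = rng.choice(brain, size=n_cx, replace=False)
    # every brain-expressed gene must be expressed somewhere: genes in
    # neither HPC nor CX are folded into the CB draw
    uncovered = np.setdiff1d(brain, np.union1d(hpc, cx))
    if len(uncovered) > n_cb:
        raise ConfigurationError("region fractions leave brain-expressed genes undetectable everywhere")
    pool = np.setdiff1d(brain, uncovered)
    cb = np.concatenate([uncovered, rng.choice(pool, size=n_cb - len(uncovered), replace=False)])

    informative = rng.choice(hpc, size=cfg.n_informative, replace=False)
    n_a = cfg.n_informative // 2
    group = np.full(n, "uninformative", dtype=object)
    group[informative[:n_a]] = "A"
    group[informative[n_a:]] = "B"

    in_hpc = np.isin(np.arange(n), hpc)
    true_sub = np.zeros((n, 4))  # CA1, CA2, CA3, DG
    for i in np.flatnonzero(in_hpc):
        if group[i] == "A":
            true_sub[i] = [cfg.base_intensity] * 3 + [min(cfg.base_intensity * cfg.dg_fold_A, 255.0)]
        elif group[i] == "B":
            true_sub[i] = [min(cfg.base_intensity * cfg.ca_fold_B, 255.0)] * 3 + [cfg.base_intensity]
        else:
            present = rng.random(4) < 0.7
            if not present.any():
                present[rng.integers(4)] = True
            true_sub[i, present] = rng.uniform(30.0, 220.0, size=present.sum())

    true_region = np.zeros((n, 3))  # HPC, CX, CB
    true_region[:, 0] = np.where(in_hpc, true_sub.mean(axis=1), 0.0)
    for j, members in ((1, cx), (2, cb)):
        sel = np.isin(np.arange(n), members)
        true_region[sel, j] = rng.uniform(30.0, 220.0, size=sel.sum())

    true_all = np.column_stack([true_region, true_sub])  # canonical region order
    noise = rng.normal(0.0, cfg.noise_sd, size=true_all.shape) if cfg.noise_sd > 0 else 0.0
    observed = np.where(true_all > 0, np.clip(true_all + noise, 0.0, 255.0), 0.0)

    profiles = pd.DataFrame({"gene": genes})
    truth = pd.DataFrame({"gene": genes, "group": group})
    for j, region in enumerate(ALL_REGIONS):
        profiles[region] = observed[:, j]
        truth[f"true_{region}"] = true_all[:, j]
        truth[f"detected_{region}"] = true_all[:, j] > 0
    return profiles, truth


def default_layout(width: int = 192, height: int = 128) -> np.ndarray:
    """Deterministic cartoon region mask: nested CA1/CA2/CA3/DG bands plus
    disjoint cortex and cerebellum blocks. No anatomical claim is made;
    the geometry exists so that render → quantify round-trips are testable.
    """
    mask = np.zeros((height, width), dtype=np.int64)
    sy, sx = height / 128.0, width / 192.0

    def rect(label, y0, y1, x0, x1):
        mask[int(y0 * sy):int(y1 * sy), int(x0 * sx):int(x1 * sx)] = MASK_LABELS[label]

    rect("CX", 8, 40, 8, 184)
    rect("CB", 88, 120, 136, 184)
    yy, xx = np.mgrid[0:height, 0:width]
    r = np.hypot((yy - 72 * sy) / sy, (xx - 64 * sx) / sx)
    for label, r0, r1 in (("HPC:CA1", 18, 26), ("HPC:CA2", 14, 18), ("HPC:CA3", 8, 14), ("HPC:DG", 0, 8)):
        mask[(r >= r0) & (r < r1)] = MASK_LABELS[label]
    return mask


def render_image(
    profile: Mapping[str, float],
    layout: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    scale: ColorScale | None = None,
) -> AtlasImage:
    """Render one gene's region intensities through the forward colormap.

    ``profile`` maps region names to intensities. Subfield values paint
    the four hippocampal bands; if only a whole-HPC value is given it
    paints all four uniformly. Background encodes intensity 0 (black).
    Per-pixel Gaussian noise (``noise_sd``) is added to the intensity
    field before encoding and clipped to [0, 255].
    """
    from .regions import GeometryError, SUBFIELD_MASK

    layout = default_layout() if layout is None else layout
    scale = scale or ColorScale()
    rng = np.random.default_rng(seed)
    field_ = np.zeros(layout.shape, dtype=float)
    label_for: dict[str, list[str]] = {}
    has_subfields = any(s in profile for s in SUBFIELDS)
    for region, value in profile.items():
        if region in SUBFIELD_MASK:
            label_for[SUBFIELD_MASK[region]] = value
        elif region == "HPC":
            if not has_subfields:
                for lab in SUBFIELD_MASK.values():
                    label_for[lab] = value
        elif region in MASK_LABELS:
            label_for[region] = value
        else:
            raise GeometryError(f"region '{region}' not in the mask vocabulary")
    for lab, value in label_for.items():
        sel = layout == MASK_LABELS[lab]
        if not sel.any():
            raise GeometryError(f"region label '{lab}' missing from layout")
        field_[sel] = value
    if noise_sd > 0:
        field_ = np.where(field_ > 0, field_ + rng.normal(0.0, noise_sd, size=field_.shape), 0.0)
    field_ = np.clip(field_, 0.0, 255.0)
    pixels = scale.encode(field_)
    pixels[layout == MASK_LABELS["background"]] = 0
    return AtlasImage(pixels=pixels, mask=layout)


def render_images(
    profiles: pd.DataFrame,
    layout: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> dict[str, AtlasImage]:
    """Render every row of an intensity table; per-gene derived seeds."""
    layout = default_layout() if layout is None else layout
    regions = [c for c in profiles.columns if c in ALL_REGIONS]
    out = {}
    for i, row in profiles.reset_index(drop=True).iterrows():
        out[row["gene"]] = render_image(
            {r: float(row[r]) for r in regions}, layout=layout,
            noise_sd=noise_sd, seed=seed * 100003 + i,
        )
    return out


def generate_fpkm(
    truth: pd.DataFrame,
    slope: float = 1.0,
    intercept: float = 0.0,
    log_noise_sd: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Subfield FPKM table log-linearly coupled to true intensity.

    ``log FPKM = intercept + slope * log(true intensity + 1) + noise``
    (natural log). With the default intercept a true intensity of zero
    yields FPKM near 1, below the detection floor of 4.
    """
    if slope <= 0:
        raise ConfigurationError("slope must be positive")
    rng = stage_rng(seed, "fpkm")
    out = pd.DataFrame({"gene": truth["gene"]})
    for sub in SUBFIELDS:
        mu = intercept + slope * np.log(truth[f"true_{sub}"].to_numpy(dtype=float) + 1.0)
        eps = rng.normal(0.0, log_noise_sd, size=len(mu)) if log_noise_sd > 0 else 0.0
        out[sub] = np.exp(mu + eps)
    return out


def generate_effects(truth: pd.DataFrame, concordance: float = 0.9, seed: int = 0) -> pd.DataFrame:
    """Ligand-effect table: per-gene coded effect on LTP and neurogenesis.

    Group A genes receive the challenge-typical code −1 (inhibit) and
    group B the sufficiency-typical +1 (promote), independently per
    parameter with probability ``concordance``, else the opposite sign.
    Uninformative genes get unknown (NA) codes.
    """
    if not 0.0 <= concordance <= 1.0:
        raise ConfigurationError("concordance must lie in [0, 1]")
    rng = stage_rng(seed, "effects")
    group = truth["group"].to_numpy()
    n = len(group)
    out = pd.DataFrame({"gene": truth["gene"], "group": np.where(group == "uninformative", pd.NA, group)})
    for param in ("ltp", "neurogenesis"):
        typical = np.where(group == "A", -1.0, 1.0)
        flip = rng.random(n) >= concordance
        codes = np.where(flip, -typical, typical)
        out[param] = np.where(group == "uninformative", np.nan, codes)
    return out


def generate_all(config: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Generate the full synthetic input set from one config/seed."""
    profiles, truth = generate_profiles(config)
    fpkm = generate_fpkm(truth, seed=config.seed)
    effects = generate_effects(truth, concordance=config.effect_concordance, seed=config.seed)
    groups = truth.loc[truth["group"].isin(["A", "B"]), ["gene", "group"]].reset_index(drop=True)
    return {"profiles": profiles, "truth": truth, "fpkm": fpkm,
            "effects": effects, "groups": groups}


__all__ = [
    "SyntheticConfig", "generate_profiles", "generate_fpkm", "generate_effects",
    "render_image", "render_images", "default_layout", "generate_all", "LAYOUT_VERSION",
]
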
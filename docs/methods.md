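# Methods

## The measurement model

Pseudocolored ISH expression images encode signal through a
piecewise-linear color path anchored at intensity 0 = black (0,0,0),
85 = red (255,0,0), 170 = yellow (255,255,0), 255 = white
(255,255,255), interpolated linearly in RGB between anchors. Because
the anchor spacing is 85 and each segment spans one RGB channel's full
range, the 256-entry lookup table advances in exact steps of 3 per
channel; every entry is distinct, so nearest-neighbour inversion in
Euclidean RGB distance is an exact inverse for on-path colors and a
robust, parameter-free inverse for off-path colors (anti-aliasing,
lossy compression). Region means are arithmetic means of per-pixel
decoded intensities — the ImageJ 'Mean' analogue — and are therefore
invariant to pixel order and to nearest-neighbour upscaling; at
constant image size relative values across regions are preserved, which
is why 'Mean' rather than integrated density is the right surrogate.

Pixel coordinates are 0-based, origin top-left; rectangles are
half-open `[y0, y0+h) × [x0, x0+w)`. The default cursor box, when
rectangle ROIs are built by hand, is 10% of image width (the original
measurement protocol fixed a constant box but did not publish its
size); mask-fitted ROIs are used for subfields. Two-rater mode repeats
each measurement with an independently jittered ROI and flags pairs
differing by more than a tolerance (default 10 intensity units),
resolving both flagged and unflagged pairs by averaging — an
operationalization of "two independent researchers, consensus on
disparity".

## Normalization and classification

Each gene's intensities are expressed as percent of that gene's maximum
region (max = 100 exactly; all-zero genes stay zero). Normalization is
idempotent and invariant to positive rescaling of a gene's raw row,
which is the property that removes probe-specific hybridization
efficiency.

Detection calls: expressed iff mean ≥ τ (boundary inclusive), with
τ = 10 on the 0–255 scale by default. The original call was made by
eye, so τ is exposed in configuration and echoed in run metadata.
Punctate/irreproducible expression is operationalized as a per-ROI
pixel coefficient of variation above 3.0 (a region whose "signal" is a
few bright puncta has CV far above that of genuine regional signal);
the rule only engages when pixel statistics exist, i.e. in the image
path. Prominence: among expressed regions, the unique maximum of the
normalized profile; ties yield no prominent region ("shared"),
avoiding an arbitrary region preference. Exclusive: expressed in
exactly one of HPC/CX/CB. Percentages are reported against the full
panel (detection) or against the brain-expressed count (exclusive,
prominent).

## The DG–CA axis

Δ = log10(DG + c) − log10(meanCA + c) on normalized subfield values,
meanCA the arithmetic mean of CA1–CA3 (CA2 included; configurable),
c ∈ {1, 2} to accommodate zeros. Base 10 is used throughout; the
between-group fold `base^(meanΔ_A − meanΔ_B)` is base-invariant.
Conclusions (sign of the group contrast, permutation significance) are
required to be stable across both offsets, and the test suite enforces
this on synthetic defaults.

The permutation test randomizes Δ values among the two groups
preserving group sizes, 10 000 replicates, two-sided via the absolute
difference of group means, with add-one smoothing
p = (1 + #{|null| ≥ |observed|}) / (reps + 1) so that finite resampling
never reports p = 0. With ≤ 12 genes all label assignments are
enumerated and p is the exact tail fraction (the smoothing convention
disappears). Welch's t with Welch–Satterthwaite df is the parametric
companion; sidedness is two-sided everywhere, since the source analysis
reports two-sided-style p-values without stating sidedness.

Two fold summaries are exposed deliberately. The generator fixes the
*within-group* enrichment (a group A gene's true DG/CA ratio); the
statistic that recovers that configured value is the per-group realized
fold `base^(meanΔ_A)` (reciprocal orientation for group B). The
*between-group* fold `base^(meanΔ_A − meanΔ_B)` compounds both groups'
enrichment (≈ f² when both groups are enriched at f) and is reported
alongside as the headline contrast. With offset 1 on normalized
profiles the realized per-group fold at configured 8.33 is ≈ 7.8–8.0
(the offset compresses ratios slightly); the 15% recovery band in the
tests reflects this known attenuation plus sampling noise, not a free
tolerance.

FPKM cross-validation: subfield FPKM below the detection floor of 4
(exclusive — exactly 4 is retained) is zeroed as undetected, rows with
no detected subfield are dropped, the table is normalized per gene, and
the identical Δ machinery runs. This mirrors calibrating RNA-seq
readcounts against the ISH detection limit.

## Cross-region battery

Wilcoxon signed-rank on unnormalized paired per-gene values between
HPC/CX/CB (gene universe: brain-expressed genes), reporting V = sum of
ranks of positive differences with zeros dropped and average ranks for
ties; p exact for n′ ≤ 25 without ties, else normal approximation with
continuity correction. Paired t between subfields. Chi-square goodness
of fit (equal expected, no continuity correction) on exclusive and
prominent counts. Detection-count comparisons use an exact two-sided
binomial of k₁ successes in k₁+k₂ trials against 0.5 — the published
construction of these tests is not stated, so ours is documented rather
than reverse-engineered; on the published counts it reproduces the
printed CX-vs-CB p (0.052) but gives 0.0064 rather than 0.0101 for
HPC-vs-CB. Correlations use arcsin(√(x/100)) transformed normalized
values (the transform requires proportions), Pearson r, and a
case-bootstrap (genes resampled with replacement) percentile 95% CI at
10 000 replicates; degenerate resamples with a constant column are
dropped from the percentile computation. Dunn–Šidák critical levels
1 − (1 − α)^(1/m) control family-wise error over the m = 3 region and
m = 6 subfield comparisons.

Ligand-effect comparison: codes −1/0/+1/unknown per gene and parameter
(LTP, neurogenesis). Group means exclude unknowns. Student's pooled
t test uses the full graded score including zeros; the chi-square
contrasts inhibition versus stimulation, so zeros and unknowns are
excluded from the 2×2 table (how the original analysis handled them is
unstated; this rule is our documented convention). When perfect
segregation makes the pooled variance zero, the t is reported undefined
and the chi-square — which remains valid — is available separately.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical* structure the analysis
assumes, with exact marginal counts rather than Bernoulli draws so that
detection percentages are stable run to run: 98 of 253 genes expressed
somewhere in brain, 86/76/53 in HPC/CX/CB (genes covered by no region
are folded into the cerebellum draw to keep every brain-expressed gene
detectable somewhere), 16+16 informative genes inside the HPC set.
Group A genes have true subfield means (base, base, base, base·fold)
with base 24 and fold 8.33 by default — chosen so the enriched subfield
sits near 200, well inside the 0–255 range — and group B the mirror
image. Uninformative HPC genes get uniform-random subfield patterns;
expressed means are drawn uniformly on [30, 220] so that detection at
τ = 10 is essentially noiseless. Noise is additive Gaussian (sd 5 by
default, the scale of a few gray levels) truncated to [0, 255], applied
to expressed entries only: a truly absent probe renders black and reads
0, so background carries no measurement noise in this model. The whole-HPC
true mean is the unweighted mean of the four subfield means.

FPKM is coupled log-linearly to true intensity,
log FPKM = intercept + slope·log(intensity + 1) + ε (natural log,
slope 1, intercept 0, ε ~ N(0, 0.2)), so zero-intensity genes land near
1 FPKM, below the detection floor. Effect codes are the group-typical
sign (−1 for A, +1 for B) independently per parameter with probability
0.9, else flipped; uninformative genes are unknown.

Not emulated: anatomy (the region mask is a deterministic cartoon —
nested CA1/CA2/CA3/DG bands and disjoint CX/CB blocks, versioned in
code), probe chemistry, cell-type composition, replicate-animal
variance (the source atlas typically has one animal per probe, so noise
defaults are conventions, not estimates), and inter-gene correlation.
Passing tests therefore demonstrate that the *pipeline* recovers known
structure under its own assumptions, not that real atlases satisfy
those assumptions.

All randomness flows from one root seed; each stage derives its own
substream by folding a CRC-32 of the stage name into the seed sequence,
so stage outputs are reproducible independently of execution order.

## Problem sizes and determinism

Default replicate counts are 10 000 for both permutation and bootstrap.
The test suite runs reduced panels (60 genes) for structural checks and
the full 253-gene panel for the recovery and stability checks (3 folds
× 10 seeds × 10 000 replicates completes in about a second, the full
suite in well under a minute). Fixed seeds make every reported number
reproducible; run directories record the config hash and seed.

## Known limitations

* The true atlas colormap may deviate from piecewise-linear between the
  four published anchors; only the anchors are certain.
* The binomial-test construction and the Wilcoxon gene universe are
  documented choices where the original description is ambiguous (the
  universe is configurable).
* The punctate CV rule is a quantitative stand-in for a qualitative
  judgement; its cutoff has no empirical calibration.
* Exhaustive permutation switches on at ≤ 12 genes; between 13 genes
  and a few tens, Monte-Carlo p-values near the add-one floor
  1/(reps+1) are resolution-limited.
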
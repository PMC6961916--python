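# endoatlas

Region-level quantification and statistics for pseudocolored *in situ*
hybridization (ISH) expression atlases, built around one scientific
question: **how is endocrine-receptor expression distributed across
mouse brain regions and hippocampal subfields?**

Expression atlases render ISH signal as a black → red → yellow → white
pseudocolor image. `endoatlas` inverts that color scale to a 0–255
intensity reading per region of interest (the ImageJ-style 'Mean'
measurement), normalizes each gene to its maximum region, classifies
genes by detection / exclusive / most-prominent expression across
hippocampus (HPC), cortex (CX) and cerebellum (CB), and tests the
spatial structure of expression inside the hippocampus.

The centrepiece is the **dentate gyrus (DG) vs cornu ammonis (CA)
axis**. For each gene with normalized subfield values,

```
Δ = log10(DG + c) − log10(meanCA + c),   meanCA = (CA1 + CA2 + CA3)/3,  c ∈ {1, 2}
```

so Δ > 0 means DG enrichment. Receptors whose ligands signal
physiological **challenge** (stress hormones, inflammatory cytokines;
"group A") are contrasted with receptors for **sufficiency** signals
(growth factors, sex steroids; "group B"):

* Welch's unequal-variance *t* test on Δ between groups,
* a two-stage permutation test — observed difference of group mean Δ
  referred to a null built by randomizing group labels (10 000
  replicates; exact enumeration for ≤ 12 genes),
* realized enrichment folds, `10^(mean Δ_A)` per group and
  `10^(mean Δ_A − mean Δ_B)` between groups,
* the same analysis on subfield RNA-seq FPKM tables (detection floor
  4 FPKM) as a cross-validation,
* Wilcoxon signed-rank / paired *t* / binomial / chi-square batteries
  across regions, arcsine-square-root case-bootstrap correlations, and
  Dunn–Šidák corrected critical levels,
* an intergroup comparison of literature-coded ligand effects on LTP
  and neurogenesis (−1 inhibit / 0 mixed / +1 promote).

A synthetic-atlas generator produces all inputs (intensity tables,
pseudocolor images with masks, FPKM tables, effect codes) with known
ground truth, so the whole pipeline is testable end to end.

## Worked example

```bash
endoatlas all --seed 1 --out runs/demo
```

runs the synthetic pipeline at the default study conditions (253 genes;
98 brain-expressed, of which 86/76/53 in HPC/CX/CB; 32 informative
genes split 16 A / 16 B at 8.33-fold enrichment; noise sd 5) and prints:

```
endoatlas run 2f97538d97cbbc17 (seed 1)
region  n_detectable  pct_detectable  n_exclusive  pct_exclusive  n_prominent  pct_prominent
   HPC            86            34.0            7            7.1           26           26.5
    CX            76            30.0            4            4.1           41           41.8
    CB            53            20.9            3            3.1           31           31.6
DG vs CA axis (offset 1, n = 32 genes)
  Welch t = 80.63, df = 26.05, p = 8.83e-33
  permutation test (10000 replicates): observed diff 1.7740, p = 9.999e-05
  between-group fold = 59.43 (group A DG/CA 8.02, group B CA/DG 7.41)
DG vs CA axis (offset 2, n = 32 genes)
  Welch t = 84.13, df = 25.97, p = 3.53e-33
  permutation test (10000 replicates): observed diff 1.7176, p = 9.999e-05
  between-group fold = 52.19 (group A DG/CA 7.50, group B CA/DG 6.96)
```

Reading this: 86 of 253 genes (34.0%) are detected in HPC, more than CX
or CB; the informative genes separate sharply along the DG–CA axis
(group A genes are DG-enriched at a realized 8.02-fold, recovering the
configured 8.33 within sampling noise), the permutation p is at the
resolution floor of 10 000 replicates, and conclusions are identical
for log offsets 1 and 2. The run directory holds every intermediate
table (TSV), `results.json`, and `metadata.json` with the config hash
and seed.

Other subcommands: `endoatlas simulate` (write synthetic inputs,
optionally rendered PNGs), `endoatlas quantify` (images + masks → intensity
table), `endoatlas analyze` (user tables → full statistics). The same
functionality is available as a library:

```python
from endoatlas import PipelineConfig, run_pipeline
run = run_pipeline(PipelineConfig(seed=1))
print(run.axis[1].summary())
```

## Documentation

`docs/methods.md` describes the model, the synthetic generator's
assumptions, numerical conventions (tie handling, offsets, detection
thresholds) and known limitations.
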
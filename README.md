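# gliomaconn

Lesion-as-node resting-state fMRI analysis for **multifocal glioma**, with
a synthetic BOLD cohort simulator.

Multifocal gliomas present two spatially distinct lesions of common clonal
origin in one brain; the larger lesion can be read as a later stage of the
tumor's natural progression and the smaller as an earlier one.  Comparing
the two *within* each patient isolates progression effects from treatment
effects and inter-subject variability.  `gliomaconn` implements that
within-subject comparison chain for researchers in cancer neuroscience and
clinical neuroimaging:

* **Preprocessing & QC** — volume trimming, nuisance regression (6 motion
  + WM + CSF), 5 mm FWHM smoothing, 0.01–0.1 Hz band-pass; framewise
  displacement, DVARS and tSNR gates.
* **Local activity** — voxel-wise ALFF (integrated 0.01–0.1 Hz
  periodogram power), fALFF (fraction of 0–0.25 Hz power) and ReHo
  (Kendall's W over 3×3×3 neighbourhoods), z-scored within subject and
  summarized over lesion masks and their **mirrored contralateral
  controls**.
* **Seed connectivity** — tumor-excluded parcel series, seed-to-parcel
  Pearson r with Fisher z = atanh(r), Bonferroni parcel selection, mean FC
  and centroid-distance summaries.
* **Graph topology** — each lesion (or its mirror control) joins the
  cortical parcels as a network node; edges are the strongest Fisher-z
  weights at a sparsity threshold validated by no-isolate and small-world
  (σ = (C/C_rand)/(L/L_rand) > 1.1) criteria over 0.15–0.40; nodal degree,
  betweenness, closeness and clustering.
* **Paired statistics** — Shapiro–Wilk-gated paired t / Wilcoxon tests
  with Cohen's d or r = |Z|/√n, run on raw values AND on control-subtracted
  values; a finding is positive only when **both** survive the Bonferroni
  family threshold α/m (m = metrics × 2 approaches); dual-positive metrics
  are re-examined with a random-intercept linear mixed model adjusting for
  volume, tSNR and intersected-network count.
* **Progression genes** — Benjamini–Hochberg adjustment plus the
  dual-transition filter (log2FC ≥ 0.25 and q < 0.05 in both the
  mid-vs-early and end-vs-mid transitions) over stage-wise
  differential-expression tables; a 42-gene reference table ships with the
  package.
* **Synthetic cohorts** — midline-symmetric parcellated atlases and
  paired-lesion BOLD subjects with known tumor–cortex coupling κ
  (band-limited factor-model signals, AR(1)+white voxel noise, confound
  series), so every stage is testable without any download.

## Worked example

Simulate a 24-subject cohort at desk scale (40-parcel atlas, coupling
κ = 0.6 for the larger vs 0.2 for the smaller lesion) and run the paired
workflow:

```python
import gliomaconn as gc
from gliomaconn.pipeline import run_cohort_analysis

atlas = gc.make_atlas(n_parcels=40, grid_shape=(24, 28, 20), seed=0)
params = gc.SimulationParams.desk_scale(seed=1)      # kappa 0.6 vs 0.2
table, report = run_cohort_analysis(params, atlas=atlas, mode="parcel")

fc = report.results["connectivity"]["mean_fc"]
print("test:", fc.raw.test_used)
print("raw p = %.2e, effect = %.3f" % (fc.raw.p_two_sided, fc.raw.effect_size))
print("control-subtracted p = %.2e" % fc.control_subtracted.p_two_sided)
print("family threshold = %.5f, dual-criterion positive: %s" % (fc.threshold, fc.positive))
print("LMM group beta = %.3f" % report.lmm["mean_fc"]["raw"].coefficients["group"])
```

prints

```
test: paired-t
raw p = 4.16e-15, effect = 3.697
control-subtracted p = 2.67e-08
family threshold = 0.00833, dual-criterion positive: True
LMM group beta = 0.138
```

The larger lesion's mean cortical FC beats the smaller lesion's in both
analytical approaches at the 0.05/6 family threshold, and the group effect
survives adjustment for volume, tSNR and network count — the simulated
coupling gap is recovered.  (Effect sizes are large here because the
simulator's desk-scale noise is mild; on κ-equal cohorts the same workflow
stays at its nominal false-positive level.)

The gene filter has a one-line CLI:

```
$ gliomaconn genes
42 sequentially upregulated gene(s)
max end-vs-mid log2FC: Capza2 = 2.53
```

Other subcommands: `gliomaconn simulate --config cfg.yaml --out dir/`
writes NIfTI BOLD + masks, confound TSVs and truth sidecars;
`gliomaconn stats --out dir/` runs the cohort workflow and writes the long
metric table and a JSON stats report.

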
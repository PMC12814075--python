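# Methods

`gliomaconn` analyses the macroscale imaging signature of natural glioma
progression in patients with *multifocal* glioma: two spatially distinct
lesions of common clonal origin, where the larger lesion is taken to
represent a later progression stage and the smaller one an earlier stage.
Because the two stages coexist in one brain and one scan, progression
effects can be tested with paired statistics, untouched by treatment
effects.  The package implements the full analysis chain on resting-state
BOLD data in a common registered space, a microscale gene-filter companion,
and a synthetic cohort generator that makes the entire chain testable with
known ground truth.

## The generative model behind the simulator

Each simulated subject is built from latent band-limited signals combined
through a factor model.  All latent series are unit-variance Gaussian
processes constructed in the frequency domain with support restricted to
0.01–0.1 Hz (the resting-state band), so their spectral content is exact by
construction.

For parcel *j* in resting-state network *n*:

    x_j = sqrt(b) g + sqrt(a) f_n + sqrt(1 - a - b) e_j

where `g` is a global cortical factor, `f_n` a per-network factor and `e_j`
idiosyncratic.  A lesion with coupling strength κ follows

    t = κ g + sqrt(1 - κ²) e_t

so the latent tumor–parcel correlation is `κ·sqrt(b)` and rises
monotonically with κ.  Voxel BOLD is `100 + latent + AR(1)+white noise`
plus a small confound leak (white-matter, CSF and a motion-linked drift)
so that nuisance regression removes something real.

Default parameters and why:

| parameter | default | rationale |
|---|---|---|
| `n_subjects` | 24 | the cohort size of the study design emulated |
| `tr_seconds` / `n_volumes` | 1.6 s / 500 | the acquisition protocol (≈13 min run); 5 volumes are trimmed downstream |
| `n_parcels` / networks | 400 / 7 | Schaefer-400-style cortex with Yeo-7-style network labels |
| `vol_mean_larger` / `vol_mean_smaller` | 2911 / 922 voxels | 78.6 and 24.9 cm³ at 3 mm isotropic — the cohort's group means; only the ≈3.16:1 ratio matters downstream |
| `vol_cv` | 0.35 | lognormal spread of drawn volumes, same order as the cohort SDs |
| `kappa_larger` / `kappa_smaller` | 0.6 / 0.2 | a coupling gap of 0.4, the effect size used in the recovery suites |
| `global_weight` (b) / `network_weight` (a) | 0.1 / 0.2 | gives within-network parcel r ≈ 0.3, cross-network r ≈ 0.1, tumor–cortex r = κ·0.316 — typical resting-state magnitudes. Fixed by a Monte-Carlo calibration run before the defaults were frozen: the package requires the default coupling gap to be recoverable by the dual-criterion workflow in ≥ 90% of pilot cohorts. A larger global share makes the degree centrality of mirrored control regions scale strongly with control size, swamping the paired contrast |
| `ar1_rho` / `noise_sd` | 0.3 / 1.0 | mildly autocorrelated voxel noise at the latent-signal scale |
| `baseline` | 100 | arbitrary signal units; gives realistic positive tSNR |

Lesions are spheroids with jittered semi-axes placed off-midline in the
left hemisphere (so their mirror controls fall in healthy right-hemisphere
cortex), contiguous by convexity, disjoint by construction.  Real lesions
are irregular; shape does not enter any tested contract.  Lesion placement
bounds are not modelled anatomically — placement is uniform over the
admissible hemisphere interior.

**Two resolutions.**  The simulator emits either full 4D voxel BOLD
(`mode="voxel"`) or parcel-resolution subjects (`mode="parcel"`) that share
the identical latent covariance and lesion geometry; at parcel resolution
the mean series of an n-voxel region carries noise of sd `noise_sd/sqrt(n)`,
exactly the average of the voxel path's independent voxel noise.  Replicate
calibration and recovery suites run at parcel resolution with a 40-parcel
atlas on a 24×28×20 grid — the package's chosen desk-scale problem size —
while the voxel path is exercised end to end at small cohort sizes.  One
asymmetry: on the voxel path a control-seed analysis additionally excludes
the control's own voxels from parcel extraction; at parcel resolution this
is a no-op because remaining member voxels share the parcel latent.

**What the simulator does not emulate:** hemodynamic response convolution,
scanner artifacts and field inhomogeneity, spatial autocorrelation of
noise, within-parcel signal heterogeneity, anatomical lesion distribution,
multi-site effects.  Passing tests therefore demonstrate correctness and
calibration of the *analysis chain* under a known band-limited factor
model — not performance on real BOLD.

## Preprocessing and quality control

Fixed stage order: trim (5 volumes) → nuisance regression (intercept, 6
motion parameters, WM, CSF; least squares, pseudoinverse on rank-deficient
designs) → Gaussian smoothing (5 mm FWHM, reflective boundaries) → ideal
FFT band-pass (0.01–0.1 Hz, DC removed).  Framewise displacement uses the
Power formulation with a 50 mm rotation radius; DVARS is the
unstandardized RMS frame difference over brain voxels (the 20-unit gate
implies raw units).  A subject is excluded when mean FD > 0.2 mm AND mean
DVARS > 20; a single breach only warns (the conjunctive reading of the
exclusion rule; a disjunctive gate is available via `rule="or"`).  tSNR is
mean/SD (sample SD, n−1 — used everywhere in the package) of the ROI mean
series, computed on the trimmed run, which still carries the baseline.

## Local activity metrics

ALFF is the integrated raw-periodogram power over 0.01–0.1 Hz (literally
power, not amplitude; an amplitude variant would only rescale the z-maps).
fALFF divides by the 0–0.25 Hz total power with the DC bin excluded; the
0.25 Hz ceiling is retained even though Nyquist at TR 1.6 s is 0.3125 Hz.
Both are computed on the nuisance-regressed, smoothed but *unfiltered*
run — band-passing first would force fALFF toward 1 and void it as a
metric.  ReHo is Kendall's W of each voxel's band-passed series with its
3×3×3 neighbourhood (average ranks for ties, no tie-correction term; edge
voxels use only in-mask neighbours, K < 27).  All maps are z-scored within
the brain mask before ROI summaries (mask means).  The contralateral
control of a mask is its reflection across the midsagittal plane, an
involution that preserves voxel count.

## Seed connectivity

Parcel mean series are extracted with both tumor masks excluded; a parcel
emptied by exclusion becomes a NaN sentinel that can never reach
significance.  Seed-to-parcel Pearson r is Fisher-transformed
(z = atanh r, capped at |r| = 1 − 1e-15) with two-sided p from
t = r·sqrt((T−2)/(1−r²)) on T−2 df.  Bonferroni selection divides α by the
*usable* parcel count by default (a fixed denominator such as 400 is
available).  Summaries per seed: mean Fisher z over all usable parcels
(not only significant ones), the significant-parcel count, and the mean
Euclidean distance in world mm between the seed centroid and significant
parcel centroids (NaN when none).  Controls run through the identical
code path as tumors.

## Graph topology

Each seed (tumor or control) joins the usable parcels as one node; edges
are the K = round(s·N(N−1)/2) largest *signed* Fisher-z weights at sparsity
s, ties broken by lexicographic node-pair order, binarized.  Signed
ranking favours strong positive correlations; absolute ranking is a
config option (the treatment of negative edges is a genuinely open choice,
flagged for sensitivity analysis).  Nodal metrics: degree/(N−1),
normalized shortest-path betweenness, Wasserman–Faust component-scaled
closeness, and the local clustering coefficient — the seed node is scored
by the same path as parcels.  The small-world index is
σ = (C/C_rand)/(L/L_rand) against degree-preserving rewirings (10 double
edge swaps per edge, 10 reference graphs, seeded); disconnected graphs use
the largest component with a warning, and graphs with no swappable pair
(complete graphs) keep themselves as reference, giving σ = 1 exactly.  The
sparsity sweep examines 0.15–0.40 in steps of 0.05 and admits the levels
at which every subject's graph has no isolates and σ > 1.1; nodal
statistics are reported at 0.15.

## Paired statistics

Each metric is compared larger-vs-smaller twice: raw, and after
subtracting each lesion's mirrored control (absorbing spatial
heterogeneity).  Shapiro–Wilk on the pair differences gates the test:
paired t when p ≥ 0.05, Wilcoxon signed-rank otherwise (normal
approximation with continuity correction for n ≥ 10, exact below).
Effect sizes: Cohen's d = mean(d)/SD(d) for t; r = |Z|/sqrt(n) for
Wilcoxon, with |Z| recovered from the two-sided p so both Wilcoxon modes
share a scale.  A finding is positive only when BOTH approaches beat the
Bonferroni family threshold α/m, with m = metrics × 2 approaches per
results family (activity 3×2 = 6, connectivity 3×2 = 6, topology 4×2 = 8;
the 6-member families reproduce the reported 0.008 threshold at 3
decimals).  Dual-positive metrics are re-fit with a linear mixed model —
random intercept per subject; fixed effects: lesion group, volume, tSNR,
intersected-network count — by REML with Wald p-values (no df
correction), falling back to ML when REML fails; covariates are z-scored
inside the fit for conditioning, which leaves the group coefficient and
all p-values unchanged.  Degenerate inputs: identical x and y give a
well-defined "no effect" result (p = 1); a constant nonzero shift has
zero-variance differences and is an error; collinear fixed effects flag
the fit as singular.

## Progression-gene filter

Stage-wise differential-expression tables (mid-vs-early and
end-vs-mid transitions) are Benjamini–Hochberg adjusted per transition; a
gene is sequentially upregulated when log2FC ≥ 0.25 and q < 0.05 in BOTH
transitions.  The threshold is conventionally stated on the absolute fold
change, but the filter targets *up*regulation, so the default requires
positive log2FC (a signed-absolute mode exists).  The packaged 42-gene
reference table carries the two transition fold changes with p = 0.001
placeholders, since no per-gene p-values accompany them — the worked
example isolates the fold-change logic.  Upstream per-cell DE testing is out of
scope; the module is agnostic to which test produced the p-values.

## Numerical choices and limitations

* SD uses the n−1 denominator everywhere; distances are world-mm via the
  affine, never voxel indices.
* The ideal FFT band-pass has sharp bin edges; tones off the DFT grid leak
  slightly (tests use on-grid frequencies where exactness is asserted).
* Atlas construction partitions a convex half-ellipsoid into k-means
  Voronoi cells — convex, contiguous and non-empty — mirrored to the other
  hemisphere; network labels (1–7) are assigned by spatial rank and shared
  between mirror pairs.  On odd-width grids the self-mirroring central
  column is blanked.
* Per-subject seeds derive from the master seed via `SeedSequence`, so
  cohorts are bit-reproducible, including every stochastic reference in
  the small-world computation.
* Calibration suites estimate rates from finite replicates; thresholds in
  the acceptance suite include no slack beyond the nominal levels, so the
  suites are conservative Monte-Carlo checks, not exact guarantees.
* The paired workflow assumes exchangeable subjects and complete pairs;
  subjects missing one side of a pair are dropped with a note.
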
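# Methods

This note documents the models, calibrations, and numerical choices behind
`striocomp`: what the phantom generates and why, how each analysis stage is
defined, and what the passing tests do and do not demonstrate about real
data.

## Phantom tissue model

One hemisphere is modelled as two deterministic ellipsoidal nuclei (caudate
dorsomedial-rostral, putamen lateral) on a high-resolution grid (default
1 mm cells, 40×48×40 mm). Internal axes are hemisphere-local millimetres:
x = lateral+, y = rostral+, z = dorsal+; voxel index *i* has its centre at
(*i* + 0.5)·voxel size. The striosome is the excursion set of a score field

```
score = G_sigma(white noise) / sd  +  w_r·ŷ + w_m·(1−x̂) + w_v·(1−ẑ)
```

— a Gaussian random field smoothed at `smoothing_scale_mm` (default 3 mm,
the correlation length of the labyrinth) plus a deterministic enrichment
gradient (defaults w = 1.1, 1.1, 0.9 in field-SD units) that concentrates
striosome rostrally, medially, and ventrally, as in histology. The
excursion threshold is calibrated by bisection on the excursion quantile so
the achieved striosome share of striatal cells lands within ±0.005 of
`striosome_fraction_target` (default 0.15, the histologic 15:85 ratio);
calibration failure raises with the achieved fraction. Because diffusion
voxels exceed the diameter of striosome tubules, cells deeper than
`tubule_cap_mm`/2 (default 1.9 mm, kept below the largest diffusion voxel
edge) from the nearest non-striosome cell are carved out iteratively,
hollowing oversized cores into tubular webs; the cap is honoured to within
one high-res cell, the limit of the grid.

The defaults above were calibrated once, jointly with the bias-transfer
exponent (below), so that a default cohort reproduces the observed
morphology of the bias distribution: a relative striosome share of highly
biased voxels near 15% (achieved ≈ 14%, stable to ~0.4 points across
subjects) while total striosome tissue is exactly 15%. They are not
re-tuned per experiment.

## Diffusion sampling and connectivity simulation

`sample_to_diffusion` bins high-res cells into diffusion voxels (default
2 mm isotropic; any voxel size at or above the high-res cell is supported,
so anisotropic protocols can be emulated). Each voxel's striosome fraction
*f* is the striosome share of its striatal cells; voxels with under 50%
striatal content are dropped from the striatal mask (partial-volume edge
rule). Caudate/putamen membership is by majority of striatal cells; the two
nucleus masks partition the striatal mask exactly.

The noise-free striosome-side connection probability of a voxel is

```
q_S = g(f),   g(f) = f^γ / (f^γ + (1−f)^γ)
```

with `bias_sharpness` γ = 4 by default and γ = 1 reducing to q_S = f. The
sharpening emulates the winner-take-most character of streamline
classification: a voxel whose tissue is 65% striosome sends nearly all of
its classified streamlines to the striosome-favoring composite, which is
what makes observed bias distributions bimodal even though voxels are
tissue blends. q_S (and q_M = 1 − q_S) is split across the five regions of
each composite by fixed somatotopic weight maps (softmax of axis-aligned
gradients, `somatotopy_kappa` = 0 for uniform), scaled by an overall reach
probability (default 0.6; the unclassified remainder emulates streamlines
that reach no bait region — the real fraction is unreported, so this is a
free parameter), and per-voxel counts are drawn from one multinomial with
N = `streamlines_per_voxel` (default 5000). Path-level tractography
stochasticity is not modelled.

FA and RD are compartment-dependent tissue properties applied to every
subject: base values (0.30 / 0.60 µm²/ms) elevated by
`fa_striosome_contrast` (default 0.189) and `rd_striosome_contrast` (0.054)
in striosome-dominant voxels (f > 0.5), plus additive per-study offsets
(emulating acquisition differences) and Gaussian noise. Head size enters as
a positive scalar per subject (normalization stand-in for intracranial
volume).

## Injectable group effects

* **Global striosome depletion** (`global_striosome_scale` s < 1): striatal
  voxels are ranked by an independent smoothed random field (correlation
  ~6 mm) and depleted in rank order — whole contiguous territories lose
  their striosome — until exactly (1−s) of the subject's striosome volume
  is removed (the final voxel partially, so the removal is exact). Patchy
  removal is the biological reading of "depletion" and makes the measured
  high-bias volume scale linearly with s; a uniform thinning would instead
  collapse every voxel's f below the high-bias range and a threshold
  rescale changes excursion-tail geometry nonlinearly.
* **Zone bias reduction** (`rpz_bias_scale` r ≤ 1): q_S is multiplied by r
  inside a designated sphere (default: a rostral/medial/ventral locus in
  the putamen, radius 6 mm). Per-severity values can be supplied via
  `severity_levels`.
* **Location shift** (`location_shift_mm`): a displacement of the striosome
  distribution. A rigid translation of a texture that fills the nucleus
  leaves the within-nucleus mean position essentially unchanged (the
  overflow is clipped at one border and backfilled at the other, and a
  linear gradient shift is absorbed by the threshold recalibration), so the
  shift is realized as a tilt of the enrichment profile. The tilt amplitude
  is calibrated in two stages against the ground-truth analogue of the
  location statistic (mean position of the top-6.68%-density striatal
  voxels in the putamen): a coarse slope probe fixes the working amplitude,
  and the response is re-probed at that amplitude over a 60-seed reference
  bank; the calibration is deterministic and cached per geometry. The
  ground-truth striosome centroid moves by somewhat less than the nominal
  shift (the dense cores respond more than the bulk); the high-bias
  location statistic — the quantity the analyses report — moves by the
  nominal amount in expectation.

Cohorts draw per-subject seeds from one master `SeedSequence`; a manifest
records them all, and `regenerate_cohort` rebuilds a cohort bit-identically.
By default every subject has independent compartment geometry. The
`matched_pairs` option instead gives each affected subject the tissue seed
of a control from the same study block (sampling noise stays independent),
emulating directly matched control:affected designs. The zone-mean and
location-shift recovery experiments use it: those statistics have
between-subject geometric dispersion (cv up to ~0.7 for the 6 mm zone mean)
that no 30-per-group unmatched design can average below the ±2-point /
±0.3 mm recovery bands, which is precisely why matched designs exist.

## Parcellation

`compute_bias` forms p = S/(S+M) per voxel from the composite counts;
voxels with S+M = 0 are flagged invalid and excluded everywhere (0/0 is
absence of evidence, not balanced bias). Matrix-side bias is derived as
1 − p, never stored, making the sum-to-one invariant structural. `classify`
uses closed compartment boundaries (striosome-like at p ≥ 0.55, matrix-like
at p ≤ 0.45, indeterminate strictly between). `equal_volume_masks` lowers
each compartment's threshold from 1.0 in steps of 0.01 until
round(`volume_fraction` × striatal voxels) qualify — `volume_fraction`
defaults to 0.0668, the one-sided normal tail beyond 1.5 SD, and is exposed
because other readings of an "uppermost 1.5 SD" target count are possible —
then trims overshoot back to the exact target by descending bias with ties
broken by flat voxel index (deterministic). Thresholds never cross into the
indeterminate range; if the floor is reached first the maximal mask is
returned with a `truncated` flag. The target count is computed per
subject-hemisphere.

## Metrics

Volumes are voxel counts × voxel volume. The relative striosome/matrix
percentages are computed among highly biased voxels (|bias| ≥ 0.87 toward
either side, the published working range; configurable) and flagged NaN
when no voxel qualifies. FA/RD are averaged within the equal-volume masks
and over the whole striatum; mean-centering divides by the study's
all-subject mean of a reference column (whole-striatum FA/RD), pooling
groups, so between-study acquisition offsets cancel. Location statistics
use the unweighted nucleus centroid in millimetres (weighting is a
convention choice; unweighted is the simpler default) and report per-axis
mean offsets plus RMS Euclidean distance. Coronal-plane profiles bin
striosome-like volume into 2 mm rostro-caudal slabs, caudate and putamen
separately, with right-hemisphere profiles shifted one slab rostrally
before pooling (template-offset compensation; the span adapts to the
phantom's own axes). Bias histograms use 50 half-open 0.02 bins with the
p = 1.0 endpoint closed; per-bin group tests are delegated to the shared
kernels with BH-FDR per family.

## Voxelwise inference

The group comparison runs on matrix-side bias (the striosome-side map is
its complement) with a two-sample pooled-variance t whose variance image —
not the means — is Gaussian-smoothed at 2 mm FWHM (renormalized inside the
mask so edges are not diluted). TFCE uses the canonical E = 0.5, H = 2 with
100 integration steps (dh = max/100, 6-connected clusters, each sign
enhanced separately for the two-sided test). The null distribution is the
max |TFCE| over the mask across group-label permutations: full enumeration
when the number of distinct assignments fits the permutation budget,
otherwise Monte Carlo with fwe_p = (1 + #{null max ≥ tfce})/(n_perm + 1),
so p-values never reach zero and never fall below 1/(n_perm+1). The
significant volume (fwe_p < α) dilated by 1 mm per plane — ceil(1/voxel)
voxels per axis, a diamond structuring element — defines the RPZ.
Hemispheres are combined side-by-side with a one-voxel gap (no averaging;
the gap prevents clusters bridging the midline) and split afterwards.

The TFCE evaluator is an exact single-sweep union-find implementation of
the discretized transform (voxels activated in descending order, cluster
roots accruing extent^E·height^H·dh per step, member sums recovered through
offset union-find); it matches the step-and-label reference to 1e-10 and is
itself cross-checked against that reference in the suite. One numerical
consequence of hard TFCE thresholds: reordering subjects permutes float
summation order, and the resulting 1e-14 t-map differences can move
knife-edge voxels across a threshold step, so permutation p-values are
reproducible to a couple of permutation quanta (the significant mask is
stable); exact bit-reproducibility holds for a fixed input order and seed.

## Regional, severity, and leave-one-out analyses

Zone means are plain voxel means of striosome-side bias inside and outside
the RPZ; group contrasts use one-tailed pooled-variance t-tests with the
direction declared by the caller, and percent differences are
(control − affected)/control × 100. Seeded-count ratios are computed from
the stored per-region counts (the phantom's generative equivalent of
bait-seeded streamline runs): per composite, counts into RPZ vs non-RPZ
striatum, and matrix-favoring:striosome-favoring within each zone; zero
denominators yield NaN rather than an error.

Severity categories follow the published instrument cutoffs (GAD-7, BAI,
STAI trait). Two instruments print overlapping ranges (GAD-7 "5–9 mild" vs
"6–10 moderate"; STAI "38–44" vs "44–80"); a score claimed by two ranges
goes to the more severe category — a documented tie rule, conservative for
detecting severity effects. The severity ANOVA models the zone mean on
ordered severity categories with study of origin as a nuisance factor
(type-II sums of squares; the study term is dropped automatically for
single-study cohorts) and reports the severity F, p, and model R².

Leave-one-out parcellation recomputes bias and equal-volume masks from the
nine remaining regions, so the tenth can be scored against masks it did not
shape. Phantom bait regions have no voxel extent, so the "biased volume
within the bait region" statistic is realized as the left-out region's
classified-count share reaching its target-side N−1 mask (pooled over
striatal voxels); it is mean-centered across the whole cohort per region
and summed over each composite's five regions. Zone contributions are
full-minus-N−1 bias difference maps averaged over the RPZ, compared between
groups with two-tailed t-tests under BH-FDR across the 10-region family.

## Statistical kernels

t-tests default to the pooled-variance (equal-variance) form with Welch
behind a flag; one-tailed tests require an explicit declared direction.
Zero-variance degeneracies follow stated conventions (equal means → p = 1,
unequal → p = 0, flagged) instead of NaNs. The one-sample test defaults to
the 15% histologic striosome share as reference. BH-FDR is the step-up
procedure over one explicit family per call, returning the rejection set
and the implied data-dependent p cutoff (the "p < 0.014"-style family
threshold). Kernels wrap scipy/statsmodels and are verified against
hand-formula and brute-force step-up oracles in the suite.

## Problem sizes and experiment design

The recovery experiments run at the conditions the package is designed
around: 30 controls / 30 affected for the depletion, zone, and shift
recoveries; 40 subjects over two studies for the FA contrast; 10
calibration phantoms; and 200 null cohorts of 10/10 at 500 permutations for
the family-wise-error study, which uses a reduced 24×28×24 mm phantom so
hundreds of cohorts remain tractable on one CPU. Null-error validity is a
property of the inference code, not of phantom size. The whole acceptance
run takes roughly ten minutes on a single core.

## Limitations

The phantom emulates classification counts, not diffusion physics: no
streamline propagation, no registration error, no head motion, no
path-length or distance bias, and scanner differences reduce to voxel size
plus additive FA/RD offsets. Nucleus geometry is deterministic across
subjects (only the compartment texture varies), which understates real
anatomical variability and is one reason injected effects are recoverable
at n = 30 when the source analyses needed hundreds of subjects. The
somatotopic weight maps are stylized gradients, not measured projection
topographies. Passing recoveries therefore demonstrate that the pipeline's
estimators are unbiased and its inference calibrated under a faithful
generative model of classification-count data — not that effects of these
sizes are detectable in any particular real cohort.
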
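# striocomp

Connectivity-based parcellation of the striatum into striosome-like and
matrix-like compartments, with a synthetic phantom generator and the full
downstream inference suite.

## The problem

The striatum is built from two interdigitated tissue compartments: the
**striosome**, a web-like labyrinth occupying roughly 15% of striatal volume
and enriched rostrally, medially, and ventrally, and the surrounding
**matrix**. The compartments have segregated connectivity, so striatal voxels
can be assigned a compartment-like identity from diffusion-MRI tractography:
each seed voxel's streamlines are classified by whether they reach composite
"bait" masks built from five striosome-favoring regions (posterior
orbitofrontal, anterior insula, basolateral amygdala, basal operculum,
posterior temporal fusiform) or five matrix-favoring regions (caudodorsal IFG
pars opercularis, primary motor, supplementary motor, primary somatosensory,
superior parietal). The per-voxel bias

```
p = S / (S + M)
```

(S, M: streamline counts reaching the striosome- and matrix-favoring
composites) classifies voxels as striosome-like (p ≥ 0.55), matrix-like
(p ≤ 0.45), or indeterminate. Because diffusion voxels are larger than
striosome tubules, only the most biased voxels are trusted: per hemisphere,
**equal-volume** striosome-like and matrix-like masks are grown from p = 1.0
downward until each holds the same target voxel count (a configurable
fraction of striatal volume, default 6.68% — the normal tail beyond 1.5 SD).

On top of the parcellation the package implements the group-analysis suite
used to study compartment abnormalities (e.g., in youth-onset anxiety):
compartment volumes and the relative share of highly biased (p ≥ 0.87)
voxels, FA/RD within the equal-volume masks with study-wise mean-centering,
intrastriate location (offsets from nucleus centroids, RMS dispersion), 2 mm
coronal-plane striosome profiles, 0.02-unit bias histograms, voxelwise
permutation inference on matrix-like bias (variance smoothing 2 mm FWHM,
TFCE with E = 0.5 / H = 2, max-statistic FWE, 1 mm dilation of the
significant volume defining the rostral putaminal zone, RPZ), zone-centric
means and seeded-count ratios, severity-covaried ANOVA, leave-one-out (N−1)
re-parcellation for circularity-free bait-region statistics, and shared
t-test / Benjamini–Hochberg kernels.

Real tractography data cannot ship with the package, so a first-class
**phantom generator** emulates the study: labyrinthine striosome tissue
calibrated to a 15:85 volume ratio inside two deterministic nuclei,
partial-volume sampling onto diffusion grids, multinomial streamline
classification (5000 streamlines/voxel), compartment-dependent FA/RD, study
offsets, and injectable group effects (global striosome depletion,
zone-restricted bias reduction, millimetre location shifts, severity
gradients). Injected effects are recovered end-to-end through the same code
paths a real cohort would use.

## Worked example

```python
from striocomp import PhantomSpec, EffectSpec, generate_cohort
from striocomp.parcellation import compute_bias, classify, equal_volume_masks
from striocomp.metrics import summarize_volumes

spec = PhantomSpec()                      # 15% striosome target, 2 mm voxels
effect = EffectSpec(global_striosome_scale=0.714)   # deplete 28.6% of striosome
cohort = generate_cohort(
    spec, effect,
    [{"study_id": "A", "n_control": 10, "n_affected": 10}],
    master_seed=1,
)
for group in ("control", "anxiety"):
    vols = []
    for s in cohort.subjects:
        if s.group != group:
            continue
        bias = compute_bias(s)
        summ = summarize_volumes(bias, classify(bias), equal_volume_masks(bias), s)
        vols.append(summ.vol_high_striosome_mm3)
    print(group, round(sum(vols) / len(vols), 1), "mm^3")
```

prints

```
control 1116.8 mm^3
anxiety 788.8 mm^3
```

i.e., the affected group's highly biased (p ≥ 0.87) striosome-like volume is
reduced by 29.4% — recovering the injected 28.6% depletion to within
sampling error of this small demonstration cohort. The same flow is
available from the shell:

```bash
striocomp run --config config.yaml --seed 1 --out report/
```

which writes the full report bundle (covariate and summary CSVs, NIfTI
statistic maps, an RPZ mask, and a JSON summary keyed by the config hash).

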
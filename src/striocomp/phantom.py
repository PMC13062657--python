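"""Synthetic striatal phantom: tissue, connectivity counts, and cohorts.

The phantom stands in for the scanner, preprocessing, and probabilistic-
tractography stages of a compartment-parcellation study.  It generates

1. a high-resolution ground-truth labeling of one striatal hemisphere into
   striosome and matrix tissue (two nuclei, caudate and putamen), with the
   striosome forming a web-like labyrinth at a calibrated volume fraction
   (default 15%, the histologic striosome:matrix ratio) and enriched
   rostrally, medially, and ventrally;
2. a diffusion-resolution sampling of that tissue (partial-volume fractions
   per diffusion voxel, with a 50%-striatal-content edge rule);
3. per-voxel streamline-classification counts toward ten bait regions
   (five striosome-favoring, five matrix-favoring) with multinomial sampling
   noise at a fixed streamline budget per seed voxel, plus FA/RD volumes with
   compartment-dependent contrast and study-of-origin offsets;
4. whole cohorts with injectable group effects: global striosome depletion,
   zone-restricted connectivity-bias reduction, millimetre-scale location
   shifts, and severity-graded effects.

Internal axes are hemisphere-local millimetres: x = lateral+, y = rostral+,
z = dorsal+.  Voxel index ``i`` has its centre at ``(i + 0.5) * voxel_mm``.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .regions import ALL_REGIONS, MATRIX_FAVORING, STRIOSOME_FAVORING

# label codes on the high-resolution grid
BG, STRIOSOME, MATRIX = 0, 1, 2
NONE, CAUDATE, PUTAMEN = 0, 1, 2

#: additive FA / RD offsets emulating acquisition differences between the
#: three studies of origin (normalized FA units; RD in um^2/ms).
DEFAULT_STUDY_OFFSETS: dict[str, tuple[float, float]] = {
    "A": (0.0, 0.0),
    "B": (0.010, -0.020),
    "C": (-0.010, 0.020),
}

# Nucleus geometry as fractions of the grid extent, so the same anatomy
# scales to any grid size.  Putamen sits lateral; caudate dorsomedial-rostral.
_PUTAMEN_CENTER = (0.65, 0.46, 0.42)
_PUTAMEN_SEMI = (0.20, 0.31, 0.27)
_CAUDATE_CENTER = (0.33, 0.63, 0.65)
_CAUDATE_SEMI = (0.16, 0.25, 0.21)


class CalibrationError(RuntimeError):
    """Striosome-fraction calibration failed; carries the achieved fraction."""

    def __init__(self, msg: str, achieved: float):
        super().__init__(msg)
        self.achieved = achieved


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and sampling parameters of the synthetic striatum.

    ``bias_sharpness`` is the exponent of the symmetric tissue-to-bias
    transfer ``g(f) = f^g / (f^g + (1-f)^g)`` that maps a voxel's striosome
    tissue fraction onto its striosome-side connection probability;
    ``bias_sharpness=1`` makes bias equal tissue fraction, larger values
    emulate the winner-take-most amplification of streamline classification.
    """

    grid_shape_highres: tuple[int, int, int] = (40, 48, 40)
    highres_voxel_mm: float = 1.0
    diffusion_voxel_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    striosome_fraction_target: float = 0.15
    gradient_weights: tuple[float, float, float] = (1.1, 1.1, 0.9)
    smoothing_scale_mm: float = 3.0
    tubule_cap_mm: float = 1.9
    bias_sharpness: float = 4.0
    reach_probability: float = 0.6
    streamlines_per_voxel: int = 5000
    base_fa: float = 0.30
    fa_noise_sd: float = 0.015
    base_rd: float = 0.60
    rd_noise_sd: float = 0.03
    somatotopy_kappa: float = 1.0
    random_seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.striosome_fraction_target < 1.0:
            raise ValueError(
                "striosome_fraction_target must lie strictly in (0, 1), got "
                f"{self.striosome_fraction_target}"
            )
        if self.highres_voxel_mm <= 0 or self.smoothing_scale_mm <= 0:
            raise ValueError("voxel and smoothing scales must be positive")
        if min(self.diffusion_voxel_mm) <= 0:
            raise ValueError("diffusion voxel sizes must be positive")
        if not self.tubule_cap_mm < max(self.diffusion_voxel_mm):
            raise ValueError(
                "tubule_cap_mm must be smaller than the largest diffusion "
                "voxel edge (diffusion voxels exceed tubule diameter)"
            )
        if self.streamlines_per_voxel <= 0:
            raise ValueError("streamlines_per_voxel must be positive")
        if not 0.0 < self.reach_probability <= 1.0:
            raise ValueError("reach_probability must lie in (0, 1]")

    @property
    def grid_extent_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape_highres, float) * self.highres_voxel_mm


@dataclass(frozen=True)
class EffectSpec:
    """Injectable group effects and tissue contrasts.

    ``global_striosome_scale`` multiplies the affected subject's striosome
    tissue volume (patchy depletion: contiguous territories are removed until
    the target volume is reached).  ``rpz_bias_scale`` multiplies the
    striosome-side connection probability inside the designated zone.
    ``fa_striosome_contrast`` / ``rd_striosome_contrast`` are fractional
    elevations of FA / RD in striosome-dominant voxels and apply to every
    subject (they are tissue properties, not group effects).
    """

    global_striosome_scale: float = 1.0
    rpz_bias_scale: float = 1.0
    rpz_center_mm: tuple[float, float, float] | None = None
    rpz_radius_mm: float = 6.0
    location_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    severity_levels: dict[str, float] | None = None
    fa_striosome_contrast: float = 0.189
    rd_striosome_contrast: float = 0.054
    depletion_patch_mm: float = 6.0

    def __post_init__(self):
        if self.global_striosome_scale <= 0:
            raise ValueError("global_striosome_scale must be positive")
        if not 0.0 < self.rpz_bias_scale <= 1.0:
            raise ValueError("rpz_bias_scale must lie in (0, 1]")
        if self.fa_striosome_contrast <= -1 or self.rd_striosome_contrast <= -1:
            raise ValueError("FA/RD contrasts must exceed -1")
        if self.rpz_radius_mm <= 0 or self.depletion_patch_mm <= 0:
            raise ValueError("zone and patch scales must be positive")

    def null_group_effects(self) -> "EffectSpec":
        """The same tissue contrasts with every group effect switched off."""
        return replace(
            self,
            global_striosome_scale=1.0,
            rpz_bias_scale=1.0,
            location_shift_mm=(0.0, 0.0, 0.0),
            severity_levels=None,
        )


@dataclass
class TissueLabelGrid:
    """High-resolution ground-truth striosome/matrix/nucleus labels."""

    labels: np.ndarray  # uint8 {BG, STRIOSOME, MATRIX}
    nucleus: np.ndarray  # uint8 {NONE, CAUDATE, PUTAMEN}
    hemisphere: str
    voxel_mm: float

    @property
    def affine(self) -> np.ndarray:
        a = np.diag([self.voxel_mm] * 3 + [1.0])
        a[:3, 3] = self.voxel_mm / 2.0
        return a

    def striosome_fraction(self) -> float:
        striatal = self.nucleus != NONE
        n = int(striatal.sum())
        return float((self.labels[striatal] == STRIOSOME).sum()) / n if n else 0.0

    def striosome_centroid_mm(self, nucleus: int | None = None) -> np.ndarray:
        sel = self.labels == STRIOSOME
        if nucleus is not None:
            sel &= self.nucleus == nucleus
        idx = np.argwhere(sel)
        return (idx.mean(axis=0) + 0.5) * self.voxel_mm


@dataclass
class DiffusionSample:
    """Partial-volume sampling of the tissue grid at diffusion resolution."""

    striosome_fraction: np.ndarray  # of striatal tissue within the voxel
    striatal_content: np.ndarray  # fraction of the voxel that is striatal
    striatal_mask: np.ndarray
    caudate_mask: np.ndarray
    putamen_mask: np.ndarray
    voxel_mm: tuple[float, float, float]
    hemisphere: str


@dataclass
class SubjectConnectivity:
    """Per-voxel bait-region streamline counts plus scalar maps for a subject."""

    counts: np.ndarray  # (X, Y, Z, 10) uint16, region order = ALL_REGIONS
    region_names: tuple[str, ...]
    streamlines_per_voxel: int
    fa: np.ndarray
    rd: np.ndarray
    striatal_mask: np.ndarray
    caudate_mask: np.ndarray
    putamen_mask: np.ndarray
    true_striosome_fraction: np.ndarray  # ground truth after group effects
    true_bias: np.ndarray  # noise-free striosome-side probability q_S
    striatal_content: np.ndarray  # striatal share of each voxel (ground truth)
    head_size_scalar: float
    subject_id: str
    study_id: str
    group: str
    severity_category: str | None
    hemisphere: str
    voxel_mm: tuple[float, float, float]

    @property
    def affine(self) -> np.ndarray:
        a = np.diag(list(self.voxel_mm) + [1.0])
        a[:3, 3] = np.asarray(self.voxel_mm) / 2.0
        return a

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_mm))

    def counts_for(self, names) -> np.ndarray:
        idx = [self.region_names.index(n) for n in names]
        return self.counts[..., idx]


@dataclass
class Cohort:
    subjects: list[SubjectConnectivity]
    covariates: pd.DataFrame
    manifest: dict


# ---------------------------------------------------------------------------
# tissue generation


def _ellipsoid(shape, voxel_mm, center_frac, semi_frac) -> np.ndarray:
    extent = np.asarray(shape, float) * voxel_mm
    coords = [
        (np.arange(n) + 0.5) * voxel_mm for n in shape
    ]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    c = np.asarray(center_frac) * extent
    s = np.asarray(semi_frac) * extent
    return (
        ((x - c[0]) / s[0]) ** 2 + ((y - c[1]) / s[1]) ** 2 + ((z - c[2]) / s[2]) ** 2
    ) <= 1.0


def nucleus_masks(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic (caudate, putamen) masks on the high-res grid."""
    shape, v = spec.grid_shape_highres, spec.highres_voxel_mm
    putamen = _ellipsoid(shape, v, _PUTAMEN_CENTER, _PUTAMEN_SEMI)
    caudate = _ellipsoid(shape, v, _CAUDATE_CENTER, _CAUDATE_SEMI) & ~putamen
    return caudate, putamen


def default_rpz_center(spec: PhantomSpec) -> tuple[float, float, float]:
    """A rostral/medial/ventral locus inside the putamen (zone for effects)."""
    extent = spec.grid_extent_mm
    c = np.asarray(_PUTAMEN_CENTER) * extent
    s = np.asarray(_PUTAMEN_SEMI) * extent
    center = c + np.array([-0.30 * s[0], 0.55 * s[1], -0.35 * s[2]])
    return tuple(float(x) for x in center)


def _enforce_tubule_cap(strio: np.ndarray, voxel_mm: float, cap_mm: float) -> np.ndarray:
    """Carve oversized striosome cores so local thickness stays near the cap.

    Thickness at a cell is ~2*(EDT - voxel/2); cells deeper than the cap
    radius are removed (iterated), hollowing solid blobs into tubular webs.
    The cap is honoured to within one high-res cell.
    """
    limit = cap_mm / 2.0 + voxel_mm / 2.0
    strio = strio.copy()
    for _ in range(6):
        if not strio.any():
            break
        edt = ndimage.distance_transform_edt(strio, sampling=voxel_mm)
        viol = edt > limit + 1e-9
        if not viol.any():
            break
        strio[viol] = False
    return strio


def tissue_score_field(spec: PhantomSpec, rng: np.random.Generator):
    """Smoothed random field plus deterministic enrichment gradient."""
    shape = spec.grid_shape_highres
    sigma = spec.smoothing_scale_mm / spec.highres_voxel_mm
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    caudate, putamen = nucleus_masks(spec)
    nucleus = caudate | putamen
    noise /= max(noise[nucleus].std(), 1e-12)

    idx = np.indices(shape).astype(float)
    lo = [idx[i][nucleus].min() for i in range(3)]
    hi = [idx[i][nucleus].max() for i in range(3)]
    hat = [(idx[i] - lo[i]) / max(hi[i] - lo[i], 1.0) for i in range(3)]
    w_r, w_m, w_v = spec.gradient_weights
    grad = w_r * hat[1] + w_m * (1.0 - hat[0]) + w_v * (1.0 - hat[2])
    grad -= grad[nucleus].mean()
    return noise + grad, caudate, putamen


def _calibrate_striosome(score, nucleus_bool, spec: PhantomSpec) -> np.ndarray:
    """Threshold the score field so the striosome fraction hits its target.

    Fixed-point iteration on the excursion quantile, with the thickness-cap
    carving inside the loop so the achieved (post-carve) fraction lands
    within +/-0.005 of ``striosome_fraction_target``.
    """
    n_nucleus = int(nucleus_bool.sum())
    target = spec.striosome_fraction_target
    vals = score[nucleus_bool]

    def attempt(quant_target):
        tau = np.quantile(vals, 1.0 - quant_target)
        cand = nucleus_bool & (score > tau)
        cand = _enforce_tubule_cap(cand, spec.highres_voxel_mm, spec.tubule_cap_mm)
        return cand, cand.sum() / n_nucleus

    # achieved fraction is monotone in the excursion quantile; bisect it
    lo, hi = target / 4.0, min(0.95, target * 3.0)
    cand, a_hi = attempt(hi)
    if a_hi < target:
        raise CalibrationError(
            f"striosome fraction calibration failed: target {target:.4f} "
            f"unreachable, achieved {a_hi:.4f} at quantile {hi:.3f}",
            achieved=float(a_hi),
        )
    achieved = a_hi
    for _ in range(40):
        if abs(achieved - target) <= 0.0045:
            return cand
        mid = 0.5 * (lo + hi)
        cand, achieved = attempt(mid)
        if achieved < target:
            lo = mid
        else:
            hi = mid
    raise CalibrationError(
        f"striosome fraction calibration failed: target {target:.4f}, "
        f"achieved {achieved:.4f}",
        achieved=float(achieved),
    )


def _masked_centroid_mm(mask: np.ndarray, voxel_mm: float) -> np.ndarray:
    return (np.argwhere(mask).mean(axis=0) + 0.5) * voxel_mm


def _dense_voxel_position_mm(
    strio: np.ndarray, spec: PhantomSpec, top_fraction: float = 0.0668
) -> np.ndarray:
    """Ground-truth analogue of the high-bias location statistic.

    Samples the striosome labels to diffusion resolution, takes the top
    ``top_fraction`` of striatal voxels by striosome tissue fraction
    (competing across both nuclei, like the equal-volume high-bias masks
    they become), and returns the mean position (mm) of the putaminal
    members.
    """
    caudate, putamen = nucleus_masks(spec)
    labels = np.zeros(spec.grid_shape_highres, dtype=np.uint8)
    labels[caudate | putamen] = MATRIX
    labels[strio] = STRIOSOME
    nucleus = np.zeros_like(labels)
    nucleus[caudate] = CAUDATE
    nucleus[putamen] = PUTAMEN
    grid = TissueLabelGrid(labels, nucleus, "left", spec.highres_voxel_mm)
    samp = sample_to_diffusion(grid, spec)
    f = samp.striosome_fraction.copy()
    f[~samp.striatal_mask] = -1.0
    nsel = int(round(top_fraction * samp.striatal_mask.sum()))
    flat = np.argsort(f, axis=None, kind="stable")[::-1][:nsel]
    ijk = np.stack(np.unravel_index(flat, f.shape), axis=1)
    inside = samp.putamen_mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]]
    if not inside.any():
        return _masked_centroid_mm(strio & putamen, spec.highres_voxel_mm)
    return ((ijk[inside] + 0.5) * np.asarray(samp.voxel_mm)).mean(axis=0)


_TILT_STAGE1_SEEDS = tuple(range(911, 917))
_TILT_STAGE2_SEEDS = tuple(range(931, 991))
_TILT_PROBE_BETA = 0.8
_tilt_cache: dict = {}


def _axis_hat(spec: PhantomSpec, nucleus_bool: np.ndarray, axis: int) -> np.ndarray:
    idx = np.indices(spec.grid_shape_highres).astype(float)[axis]
    lo = idx[nucleus_bool].min()
    hi = idx[nucleus_bool].max()
    return (idx - lo) / max(hi - lo, 1.0)


def _tilt_response(spec: PhantomSpec, axis: int, beta: float, seeds) -> float:
    """Mean displacement (mm) of the location statistic for a given tilt.

    Paired within seed (same noise field with and without the tilt), so the
    average isolates the re-thresholding response of the dense-voxel
    position statistic.
    """
    diffs = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        score, caudate, putamen = tissue_score_field(spec, rng)
        nucleus_bool = caudate | putamen
        hat = _axis_hat(spec, nucleus_bool, axis)
        s0 = _calibrate_striosome(score, nucleus_bool, spec)
        s1 = _calibrate_striosome(score + beta * hat, nucleus_bool, spec)
        c0 = _dense_voxel_position_mm(s0, spec)
        c1 = _dense_voxel_position_mm(s1, spec)
        diffs.append(c1[axis] - c0[axis])
    return float(np.mean(diffs))


def _tilt_for_shift(spec: PhantomSpec, axis: int, shift: float) -> float:
    """Tilt amplitude whose expected location response equals ``shift``.

    Two-stage deterministic calibration, cached per spec geometry, axis and
    shift: a coarse slope from a unit-scale probe sets the working
    amplitude, then the response is re-probed at that amplitude over a
    larger bank of reference seeds and the amplitude is corrected
    proportionally (the response passes through the origin and is close to
    linear over this range).
    """
    key = (spec.grid_shape_highres, spec.highres_voxel_mm,
           spec.diffusion_voxel_mm, spec.striosome_fraction_target,
           spec.gradient_weights, spec.smoothing_scale_mm,
           spec.tubule_cap_mm, axis, round(float(shift), 4))
    if key in _tilt_cache:
        return _tilt_cache[key]
    probe = _TILT_PROBE_BETA * np.sign(shift)
    r0 = _tilt_response(spec, axis, probe, _TILT_STAGE1_SEEDS)
    slope = r0 / probe
    if not np.isfinite(slope) or abs(slope) < 0.2:
        raise CalibrationError(
            f"location-shift calibration failed on axis {axis}: tilt "
            f"response too weak ({slope:.3f} mm per unit tilt)",
            achieved=float("nan"),
        )
    beta1 = shift / slope
    r1 = _tilt_response(spec, axis, beta1, _TILT_STAGE2_SEEDS)
    if not np.isfinite(r1) or abs(r1) < 0.1 * abs(shift):
        raise CalibrationError(
            f"location-shift calibration failed on axis {axis}: response "
            f"{r1:.3f} mm at working amplitude",
            achieved=float("nan"),
        )
    beta = float(np.clip(beta1 * shift / r1, -3 * abs(beta1), 3 * abs(beta1)))
    _tilt_cache[key] = beta
    return beta


def generate_tissue(
    spec: PhantomSpec,
    seed: int | None = None,
    striosome_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0),
    hemisphere: str = "left",
) -> TissueLabelGrid:
    """Generate ground-truth striosome/matrix labels for one hemisphere.

    The striosome is the excursion set of the score field above a threshold
    calibrated (fixed-point iteration on the quantile, after thickness-cap
    carving) so the achieved striosome fraction of striatal tissue lands
    within +/-0.005 of ``striosome_fraction_target``.

    ``striosome_shift_mm`` displaces the striosome distribution (the
    location-shift group effect).  Because the striosome texture fills the
    nuclei, a rigid translation of the field would leave the within-nucleus
    centroid unchanged; the displacement is instead realized as a tilt of
    the enrichment profile whose amplitude comes from a cached, per-geometry
    calibration of the dense-voxel location response (the volume fraction is
    recalibrated after tilting).
    """
    if seed is None:
        seed = spec.random_seed
    rng = np.random.default_rng(seed)
    score, caudate, putamen = tissue_score_field(spec, rng)
    nucleus_bool = caudate | putamen

    shift = np.asarray(striosome_shift_mm, float)
    if np.any(np.abs(shift) > 0):
        for axis in range(3):
            if abs(shift[axis]) <= 0:
                continue
            beta = _tilt_for_shift(spec, axis, float(shift[axis]))
            score = score + beta * _axis_hat(spec, nucleus_bool, axis)

    strio = _calibrate_striosome(score, nucleus_bool, spec)
    labels = np.zeros(spec.grid_shape_highres, dtype=np.uint8)
    labels[nucleus_bool] = MATRIX
    labels[strio] = STRIOSOME
    nucleus = np.zeros_like(labels)
    nucleus[caudate] = CAUDATE
    nucleus[putamen] = PUTAMEN
    return TissueLabelGrid(
        labels=labels,
        nucleus=nucleus,
        hemisphere=hemisphere,
        voxel_mm=spec.highres_voxel_mm,
    )


# ---------------------------------------------------------------------------
# diffusion-resolution sampling


def sample_to_diffusion(grid: TissueLabelGrid, spec: PhantomSpec) -> DiffusionSample:
    """Partial-volume sample of the tissue grid onto the diffusion grid.

    Each diffusion voxel's striosome fraction is the share of its striatal
    high-res cells labeled striosome; voxels with under 50% striatal content
    are dropped from the striatal mask (partial-volume edge rule).
    """
    dv = np.asarray(spec.diffusion_voxel_mm, float)
    hv = grid.voxel_mm
    if np.any(dv < hv - 1e-9):
        raise ValueError("diffusion voxel must be >= high-res voxel on every axis")

    shape_h = grid.labels.shape
    extent = np.asarray(shape_h, float) * hv
    shape_d = tuple(int(np.ceil(extent[i] / dv[i] - 1e-9)) for i in range(3))

    centers = [(np.arange(n) + 0.5) * hv for n in shape_h]
    bins = [
        np.minimum((centers[i] / dv[i]).astype(int), shape_d[i] - 1) for i in range(3)
    ]
    bx, by, bz = np.meshgrid(*bins, indexing="ij")
    flat = (bx * shape_d[1] + by) * shape_d[2] + bz
    flat = flat.ravel()
    nvox = int(np.prod(shape_d))

    def acc(w):
        return np.bincount(flat, weights=w.ravel(), minlength=nvox).reshape(shape_d)

    total = acc(np.ones(shape_h))
    striatal = acc((grid.nucleus != NONE).astype(float))
    strio = acc((grid.labels == STRIOSOME).astype(float))
    caud = acc((grid.nucleus == CAUDATE).astype(float))
    put = acc((grid.nucleus == PUTAMEN).astype(float))

    with np.errstate(invalid="ignore", divide="ignore"):
        content = np.where(total > 0, striatal / total, 0.0)
        frac = np.where(striatal > 0, strio / np.maximum(striatal, 1e-12), 0.0)
    mask = content >= 0.5
    if not mask.any():
        raise ValueError("empty striatal mask after diffusion sampling")
    caudate_mask = mask & (caud >= put)
    putamen_mask = mask & (put > caud)
    return DiffusionSample(
        striosome_fraction=frac.astype(np.float32),
        striatal_content=content.astype(np.float32),
        striatal_mask=mask,
        caudate_mask=caudate_mask,
        putamen_mask=putamen_mask,
        voxel_mm=tuple(float(x) for x in dv),
        hemisphere=grid.hemisphere,
    )


def voxel_centers_mm(shape, voxel_mm) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    coords = [(np.arange(n) + 0.5) * v for n, v in zip(shape, voxel_mm)]
    return np.meshgrid(*coords, indexing="ij")


# ---------------------------------------------------------------------------
# subject simulation


def bias_transfer(f: np.ndarray, gamma: float) -> np.ndarray:
    """Map tissue fraction f to striosome-side connection probability.

    Symmetric sharpening g(f) = f^gamma / (f^gamma + (1-f)^gamma); gamma=1 is
    the identity.  Fixed points at 0, 0.5, 1 for every gamma.
    """
    f = np.clip(np.asarray(f, float), 0.0, 1.0)
    a = f**gamma
    b = (1.0 - f) ** gamma
    with np.errstate(invalid="ignore"):
        out = a / (a + b)
    return np.where(a + b > 0, out, 0.5)


def _somatotopic_weights(shape, voxel_mm, mask, directions, kappa) -> np.ndarray:
    """(V_masked, k) soft weight maps; each region dominates one sector."""
    x, y, z = voxel_centers_mm(shape, voxel_mm)
    pts = np.stack([c[mask] for c in (x, y, z)], axis=1)
    span = pts.max(axis=0) - pts.min(axis=0)
    hat = (pts - pts.min(axis=0)) / np.maximum(span, 1e-9)  # in [0,1]^3
    d = np.asarray(directions, float)
    logits = kappa * (hat @ d.T)
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    return w / w.sum(axis=1, keepdims=True)


_STRIO_DIRS = ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1))
_MATRIX_DIRS = ((0, 0, -1), (1, 1, 0), (-1, 1, 0), (1, 0, 1), (0, -1, -1))


def _deplete_striosome(
    frac: np.ndarray,
    mask: np.ndarray,
    striatal_content: np.ndarray,
    scale: float,
    patch_mm: float,
    voxel_mm,
    rng: np.random.Generator,
) -> np.ndarray:
    """Remove (1 - scale) of striosome tissue in contiguous patches.

    Striatal voxels are ranked by a smoothed random field (correlation length
    ``patch_mm``, independent of the tissue); whole voxels are depleted in
    rank order until the removed striosome volume reaches the target, with
    the final voxel depleted partially so the removal is exact.
    """
    sigma = patch_mm / np.asarray(voxel_mm, float)
    fld = ndimage.gaussian_filter(rng.standard_normal(frac.shape), sigma)
    idx = np.argwhere(mask)
    order = np.argsort(-fld[mask], kind="stable")
    content = striatal_content[mask][order]
    s = (frac[mask][order] * content).astype(float)  # striosome volume per voxel
    budget = (1.0 - scale) * s.sum()
    cum = np.cumsum(s)
    k = int(np.searchsorted(cum, budget))
    out = frac.copy()
    sel = idx[order[:k]]
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = 0.0
    if k < len(order) and s[k] > 0:
        short = budget - (cum[k - 1] if k > 0 else 0.0)
        i, j, l = idx[order[k]]
        out[i, j, l] *= 1.0 - short / s[k]
    return out


def simulate_subject(
    grid: TissueLabelGrid,
    spec: PhantomSpec,
    effect: EffectSpec,
    *,
    subject_id: str,
    group: str = "control",
    study_id: str = "A",
    severity_category: str | None = None,
    seed: int = 0,
    study_offsets: dict[str, tuple[float, float]] | None = None,
) -> SubjectConnectivity:
    """Simulate bait-region streamline counts and FA/RD for one subject.

    For each striatal voxel with (post-effect) striosome tissue fraction f,
    the striosome-side probability is q_S = g(f) scaled by ``rpz_bias_scale``
    inside the designated zone; q_S and q_M = 1 - q_S are spread over the
    five regions of each composite by fixed somatotopic weight maps, scaled
    by the overall reach probability, and counts are drawn multinomially at
    ``streamlines_per_voxel`` per voxel.
    """
    if spec.streamlines_per_voxel <= 0:
        raise ValueError("streamlines per voxel must be positive")
    rng = np.random.default_rng(seed)
    offsets = DEFAULT_STUDY_OFFSETS if study_offsets is None else study_offsets

    # the location-shift effect is a tissue-level translation and is applied
    # when the tissue grid is generated (see generate_tissue/field_shift_mm)
    samp = sample_to_diffusion(grid, spec)
    frac = samp.striosome_fraction.astype(float)

    if effect.global_striosome_scale < 1.0:
        frac = _deplete_striosome(
            frac,
            samp.striatal_mask,
            samp.striatal_content,
            effect.global_striosome_scale,
            effect.depletion_patch_mm,
            samp.voxel_mm,
            rng,
        )

    q = bias_transfer(frac, spec.bias_sharpness)

    zone_scale = effect.rpz_bias_scale
    if effect.severity_levels and severity_category in effect.severity_levels:
        zone_scale = effect.severity_levels[severity_category]
    if zone_scale < 1.0:
        center = effect.rpz_center_mm or default_rpz_center(spec)
        x, y, z = voxel_centers_mm(frac.shape, samp.voxel_mm)
        zone = (
            (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
        ) <= effect.rpz_radius_mm**2
        q = np.where(zone, q * zone_scale, q)
    if q.min() < -1e-9 or q.max() > 1 + 1e-9:
        warnings.warn("striosome-side probability clamped to [0, 1]")
    q = np.clip(q, 0.0, 1.0)

    mask = samp.striatal_mask
    qm = q[mask]
    w_s = _somatotopic_weights(
        frac.shape, samp.voxel_mm, mask, _STRIO_DIRS, spec.somatotopy_kappa
    )
    w_m = _somatotopic_weights(
        frac.shape, samp.voxel_mm, mask, _MATRIX_DIRS, spec.somatotopy_kappa
    )
    r = spec.reach_probability
    pvals = np.empty((qm.size, 11))
    pvals[:, :5] = r * qm[:, None] * w_s
    pvals[:, 5:10] = r * (1.0 - qm)[:, None] * w_m
    pvals[:, 10] = np.maximum(1.0 - pvals[:, :10].sum(axis=1), 0.0)
    pvals /= pvals.sum(axis=1, keepdims=True)  # guard r=1 rounding
    draws = rng.multinomial(spec.streamlines_per_voxel, pvals)[:, :10]

    counts = np.zeros(frac.shape + (10,), dtype=np.uint16)
    counts[mask] = draws.astype(np.uint16)

    fa_off, rd_off = offsets.get(study_id, (0.0, 0.0))
    dominant = (frac > 0.5).astype(float)
    fa = spec.base_fa * np.ones(frac.shape)
    fa[mask] = spec.base_fa * (1.0 + effect.fa_striosome_contrast * dominant[mask])
    fa += fa_off + rng.normal(0.0, spec.fa_noise_sd, frac.shape)
    fa = np.clip(fa, 0.0, 1.0)
    rd = spec.base_rd * np.ones(frac.shape)
    rd[mask] = spec.base_rd * (1.0 + effect.rd_striosome_contrast * dominant[mask])
    rd += rd_off + rng.normal(0.0, spec.rd_noise_sd, frac.shape)
    rd = np.maximum(rd, 0.0)

    head = float(np.clip(rng.normal(1.0, 0.05), 0.8, 1.2))
    return SubjectConnectivity(
        counts=counts,
        region_names=ALL_REGIONS,
        streamlines_per_voxel=spec.streamlines_per_voxel,
        fa=fa.astype(np.float32),
        rd=rd.astype(np.float32),
        striatal_mask=mask,
        caudate_mask=samp.caudate_mask,
        putamen_mask=samp.putamen_mask,
        true_striosome_fraction=frac.astype(np.float32),
        true_bias=q.astype(np.float32),
        striatal_content=samp.striatal_content,
        head_size_scalar=head,
        subject_id=subject_id,
        study_id=study_id,
        group=group,
        severity_category=severity_category,
        hemisphere=grid.hemisphere,
        voxel_mm=samp.voxel_mm,
    )


# ---------------------------------------------------------------------------
# cohorts


def generate_cohort(
    spec: PhantomSpec,
    effect: EffectSpec,
    design: list[dict],
    master_seed: int = 0,
    affected_label: str = "anxiety",
    matched_pairs: bool = False,
    hemisphere: str = "left",
) -> Cohort:
    """Simulate a cohort: one phantom per subject.

    ``design`` is a list of per-study blocks, e.g.
    ``{"study_id": "A", "n_control": 10, "n_affected": 10,
       "severity": ["moderate", "severe"]}``; severity labels are cycled over
    the affected subjects of the block.  Group effects in ``effect`` apply to
    affected subjects only; tissue contrasts apply to everyone.

    With ``matched_pairs=False`` (default) every subject gets independent
    compartment geometry.  With ``matched_pairs=True`` each affected subject
    shares its tissue seed with a control of the same study block (cycled),
    emulating a directly matched control:affected design; connectivity
    sampling noise stays independent.
    """
    n_control = sum(int(d.get("n_control", 0)) for d in design)
    n_affected = sum(int(d.get("n_affected", 0)) for d in design)
    for n, name in ((n_control, "control"), (n_affected, affected_label)):
        if n == 1:
            raise ValueError(f"group {name!r} needs at least 2 subjects (got 1)")

    ss = np.random.SeedSequence(master_seed)
    plan = []
    subject_seeds = []
    for block in design:
        study = block["study_id"]
        nc = int(block.get("n_control", 0))
        na = int(block.get("n_affected", 0))
        if matched_pairs and na > 0 and nc == 0:
            raise ValueError(f"matched_pairs needs controls in study {study!r}")
        severities = block.get("severity", ["severe"])
        if isinstance(severities, str):
            severities = [severities]
        block_seeds = [int(s) for s in ss.spawn(1)[0].generate_state(nc + na) % (2**31)]
        subject_seeds.extend(block_seeds)
        ctrl_tissue = []
        for i in range(nc):
            t, n = (
                int(s)
                for s in np.random.SeedSequence(block_seeds[i]).generate_state(2)
                % (2**31)
            )
            ctrl_tissue.append(t)
            plan.append((study, "control", None, t, n))
        for j in range(na):
            t, n = (
                int(s)
                for s in np.random.SeedSequence(block_seeds[nc + j]).generate_state(2)
                % (2**31)
            )
            if matched_pairs:
                t = ctrl_tissue[j % nc]
            plan.append((study, affected_label, severities[j % len(severities)], t, n))

    manifest = {
        "master_seed": int(master_seed),
        "spec": dataclasses.asdict(spec),
        "effect": dataclasses.asdict(effect),
        "design": design,
        "affected_label": affected_label,
        "matched_pairs": matched_pairs,
        "hemisphere": hemisphere,
        "subject_seeds": subject_seeds,
    }
    return _build_cohort(spec, effect, plan, affected_label, manifest, hemisphere)


def regenerate_cohort(manifest: dict) -> Cohort:
    """Rebuild a cohort byte-identically from its manifest."""
    spec = PhantomSpec(
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in manifest["spec"].items()
        }
    )
    eff = {
        k: tuple(v) if isinstance(v, list) else v
        for k, v in manifest["effect"].items()
    }
    if eff.get("rpz_center_mm") is not None:
        eff["rpz_center_mm"] = tuple(eff["rpz_center_mm"])
    effect = EffectSpec(**eff)
    cohort = generate_cohort(
        spec,
        effect,
        manifest["design"],
        manifest["master_seed"],
        manifest.get("affected_label", "anxiety"),
        manifest.get("matched_pairs", False),
        manifest.get("hemisphere", "left"),
    )
    if cohort.manifest["subject_seeds"] != list(manifest["subject_seeds"]):
        raise RuntimeError("manifest seed mismatch on regeneration")
    return cohort


def _build_cohort(spec, effect, plan, affected_label, manifest, hemisphere="left"):
    subjects, rows, seen = [], [], set()
    null_effect = effect.null_group_effects()
    for study, group, severity, tissue_seed, noise_seed in plan:
        sid = f"{study}_{group}_{len(rows):03d}"
        if sid in seen:
            raise ValueError(f"duplicate subject_id {sid!r}")
        seen.add(sid)
        eff = effect if group == affected_label else null_effect
        grid = generate_tissue(
            spec,
            seed=tissue_seed,
            striosome_shift_mm=eff.location_shift_mm,
            hemisphere=hemisphere,
        )
        subj = simulate_subject(
            grid,
            spec,
            eff,
            subject_id=sid,
            group=group,
            study_id=study,
            severity_category=severity,
            seed=noise_seed,
        )
        subjects.append(subj)
        rows.append(
            {
                "subject_id": sid,
                "study_id": study,
                "group": group,
                "severity_category": severity,
                "hemisphere": subj.hemisphere,
                "head_size_scalar": subj.head_size_scalar,
                "tissue_seed": tissue_seed,
                "noise_seed": noise_seed,
            }
        )
    return Cohort(subjects=subjects, covariates=pd.DataFrame(rows), manifest=manifest)


def true_zone_mask(
    spec: PhantomSpec, effect: EffectSpec, shape, voxel_mm
) -> np.ndarray:
    """Boolean mask of the designated (ground-truth) zone on a diffusion grid."""
    center = effect.rpz_center_mm or default_rpz_center(spec)
    x, y, z = voxel_centers_mm(shape, voxel_mm)
    return (
        (x - center[0]) ** 2 + (y - center[1]) ** 2 + (z - center[2]) ** 2
    ) <= effect.rpz_radius_mm**2
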
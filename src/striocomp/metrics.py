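"""Per-subject compartment measurements.

Volumes of the striosome-like / matrix-like / indeterminate probability
ranges, the relative share of highly biased (p >= 0.87) voxels, FA/RD means
within the equal-volume masks, study-wise mean-centering, intrastriate
location relative to nucleus centroids, 2 mm coronal-plane striosome
profiles, and the 0.02-unit bias histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parcellation import (
    LABEL_INDETERMINATE,
    LABEL_MATRIX,
    LABEL_STRIOSOME,
    BiasMap,
    CompartmentMasks,
)
from .phantom import SubjectConnectivity

#: voxels at or beyond this bias toward either compartment are "highly biased"
HIGH_BIAS_CUTOFF = 0.87


@dataclass
class CompartmentSummary:
    subject_id: str
    study_id: str
    group: str
    hemisphere: str
    vol_striosome_mm3: float
    vol_matrix_mm3: float
    vol_indeterminate_mm3: float
    vol_high_striosome_mm3: float
    vol_high_matrix_mm3: float
    relative_striosome_pct: float  # NaN when no highly biased voxels at all
    relative_matrix_pct: float
    striatal_vol_mm3: float
    striatal_vol_norm: float
    fa_striosome: float
    fa_matrix: float
    fa_striatum: float
    rd_striosome: float
    rd_matrix: float
    rd_striatum: float


def summarize_volumes(
    bias: BiasMap,
    labels: np.ndarray,
    masks: CompartmentMasks,
    subject: SubjectConnectivity,
    high_bias_cutoff: float = HIGH_BIAS_CUTOFF,
) -> CompartmentSummary:
    """Compartment volumes, relative high-bias share, and mask diffusivity.

    Volumes are voxel counts times voxel volume.  The relative striosome /
    matrix percentages are computed among voxels highly biased (bias >=
    ``high_bias_cutoff``) toward either side; if no voxel qualifies on
    either side they are flagged NaN.  FA/RD means are taken within the
    equal-volume masks and over the whole striatum (raw; mean-centering
    across a cohort is a separate step).
    """
    vv = bias.voxel_volume_mm3
    p = bias.p_striosome
    valid = bias.valid_mask
    high_s = int((valid & (p >= high_bias_cutoff)).sum())
    high_m = int((valid & (p <= 1.0 - high_bias_cutoff)).sum())
    if high_s + high_m > 0:
        rel_s = 100.0 * high_s / (high_s + high_m)
        rel_m = 100.0 - rel_s
    else:
        rel_s = rel_m = float("nan")
    striatal_vol = float(subject.striatal_mask.sum()) * vv
    return CompartmentSummary(
        subject_id=subject.subject_id,
        study_id=subject.study_id,
        group=subject.group,
        hemisphere=subject.hemisphere,
        vol_striosome_mm3=float((labels == LABEL_STRIOSOME).sum()) * vv,
        vol_matrix_mm3=float((labels == LABEL_MATRIX).sum()) * vv,
        vol_indeterminate_mm3=float((labels == LABEL_INDETERMINATE).sum()) * vv,
        vol_high_striosome_mm3=high_s * vv,
        vol_high_matrix_mm3=high_m * vv,
        relative_striosome_pct=rel_s,
        relative_matrix_pct=rel_m,
        striatal_vol_mm3=striatal_vol,
        striatal_vol_norm=striatal_vol / subject.head_size_scalar,
        fa_striosome=_mean_or_nan(subject.fa, masks.striosome_like),
        fa_matrix=_mean_or_nan(subject.fa, masks.matrix_like),
        fa_striatum=_mean_or_nan(subject.fa, subject.striatal_mask),
        rd_striosome=_mean_or_nan(subject.rd, masks.striosome_like),
        rd_matrix=_mean_or_nan(subject.rd, masks.matrix_like),
        rd_striatum=_mean_or_nan(subject.rd, subject.striatal_mask),
    )


def _mean_or_nan(vol: np.ndarray, mask: np.ndarray) -> float:
    return float(vol[mask].mean()) if mask.any() else float("nan")


def mean_center(
    df: pd.DataFrame,
    value_cols: list[str],
    study_col: str = "study_id",
    reference_col: str | None = None,
) -> pd.DataFrame:
    """Normalize values to each study's mean (1.0 = study mean).

    Each value is divided by its study's all-subject mean of
    ``reference_col`` (default: the column itself), pooling groups, so
    cross-study acquisition offsets drop out.  ``<col>_pct`` columns give
    the percentage above/below the study mean.
    """
    out = df.copy()
    for study, sub in df.groupby(study_col):
        if len(sub) < 2:
            raise ValueError(f"study {study!r} needs at least 2 subjects")
        for col in value_cols:
            ref = reference_col or col
            m = sub[ref].mean()
            if m == 0:
                raise ValueError(f"zero study mean for {ref!r} in study {study!r}")
            out.loc[sub.index, f"{col}_norm"] = sub[col] / m
    for col in value_cols:
        out[f"{col}_pct"] = (out[f"{col}_norm"] - 1.0) * 100.0
    return out


@dataclass
class LocationSummary:
    nucleus: str
    compartment: str
    n_voxels: int
    mean_offset_mm: tuple[float, float, float]  # x lateral+, y rostral+, z dorsal+
    rms_distance_mm: float


def location_stats(
    compartment_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    voxel_mm,
    nucleus: str = "putamen",
    compartment: str = "striosome",
) -> LocationSummary:
    """Offsets of compartment voxels from their nucleus centroid.

    The centroid is the unweighted mean of nucleus voxel centres (mm); the
    summary reports per-axis mean offsets of the compartment voxels inside
    that nucleus and the root-mean-square Euclidean distance to the
    centroid.
    """
    if not nucleus_mask.any():
        raise ValueError("empty nucleus mask")
    sel = compartment_mask & nucleus_mask
    if not sel.any():
        return LocationSummary(nucleus, compartment, 0,
                               (float("nan"),) * 3, float("nan"))
    v = np.asarray(voxel_mm, float)
    centroid = (np.argwhere(nucleus_mask) + 0.5).mean(axis=0) * v
    pts = (np.argwhere(sel) + 0.5) * v
    d = pts - centroid
    rms = float(np.sqrt((d**2).sum(axis=1).mean()))
    return LocationSummary(
        nucleus,
        compartment,
        int(sel.sum()),
        tuple(float(x) for x in d.mean(axis=0)),
        rms,
    )


def plane_profile(
    striosome_mask: np.ndarray,
    caudate_mask: np.ndarray,
    putamen_mask: np.ndarray,
    voxel_mm,
    hemisphere: str,
    plane_thickness_mm: float = 2.0,
) -> pd.DataFrame:
    """Striosome-like volume per coronal (rostro-caudal) plane and nucleus.

    Voxels are binned into ``plane_thickness_mm`` slabs along y (rostral+),
    caudate and putamen separately (their extents overlap in the coronal
    plane).  Right-hemisphere profiles are shifted rostrally by one slab
    before any cross-hemisphere pooling, compensating the template offset
    between hemispheric masks.
    """
    v = np.asarray(voxel_mm, float)
    vv = float(np.prod(v))
    ny = striosome_mask.shape[1]
    y_mm = (np.arange(ny) + 0.5) * v[1]
    slab = np.floor(y_mm / plane_thickness_mm).astype(int)
    if hemisphere == "right":
        slab = slab + 1  # one-slab rostral shift
    n_slabs = slab.max() + 2
    rows = []
    for name, nucleus_mask in (("caudate", caudate_mask), ("putamen", putamen_mask)):
        sel = striosome_mask & nucleus_mask
        if nucleus_mask.any() and not (
            0 <= slab.min() and slab.max() < n_slabs
        ):  # pragma: no cover - guarded by construction
            raise ValueError("plane span does not cover the mask")
        counts = np.zeros(n_slabs)
        ys = np.argwhere(sel)[:, 1]
        np.add.at(counts, slab[ys], 1.0)
        for k in range(n_slabs):
            rows.append(
                {
                    "plane_index": k,
                    "plane_y_mm": k * plane_thickness_mm,
                    "nucleus": name,
                    "hemisphere": hemisphere,
                    "striosome_volume_mm3": counts[k] * vv,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class BiasHistogram:
    """Volume per 0.02-unit bias bin over a restriction mask.

    ``edges`` has 51 entries for 50 half-open bins [lo, hi) covering
    [0, 1], with the final bin closed at 1.0.  Stored in ascending bias
    order; the striosome-like range is 0.55-1.0, matrix-like 0-0.45,
    indeterminate strictly between.
    """

    edges: np.ndarray
    volumes_mm3: np.ndarray

    @property
    def total_mm3(self) -> float:
        return float(self.volumes_mm3.sum())

    def range_volume(self, lo: float, hi: float) -> float:
        """Total volume of bins whose span lies within [lo, hi]."""
        sel = (self.edges[:-1] >= lo - 1e-12) & (self.edges[1:] <= hi + 1e-12)
        return float(self.volumes_mm3[sel].sum())

    @property
    def indeterminate_mm3(self) -> float:
        return self.range_volume(0.45, 0.55)


def bias_histogram(
    bias: BiasMap, restriction: np.ndarray | None = None, n_bins: int = 50
) -> BiasHistogram:
    """Histogram of striosome-side bias over a mask (default: whole striatum)."""
    if restriction is None:
        restriction = bias.striatal_mask
    elif np.any(restriction & ~bias.striatal_mask):
        raise ValueError("restriction mask must lie within the striatal mask")
    vals = bias.p_striosome[restriction & bias.valid_mask]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    hist, _ = np.histogram(vals, bins=edges)
    return BiasHistogram(edges=edges, volumes_mm3=hist * bias.voxel_volume_mm3)
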
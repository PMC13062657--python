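"""Classification-targets parcellation: bias maps and equal-volume masks.

Per-voxel streamline counts toward the striosome-favoring and matrix-favoring
composite bait masks are converted to a striosome-side connection probability
(the bias), classified into striosome-like / matrix-like / indeterminate
ranges, and reduced to equal-volume high-bias compartment masks by iterative
threshold descent from p = 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import SubjectConnectivity
from .regions import MATRIX_FAVORING, STRIOSOME_FAVORING

#: three-way classification codes
LABEL_OUTSIDE, LABEL_STRIOSOME, LABEL_MATRIX, LABEL_INDETERMINATE = 0, 1, 2, 3

#: closed compartment boundaries: striosome-like at p >= 0.55, matrix-like at
#: p <= 0.45, indeterminate strictly between
STRIOSOME_LIKE_MIN = 0.55
MATRIX_LIKE_MAX = 0.45

#: share of striatal volume in each equal-volume mask; the one-sided normal
#: tail beyond 1.5 standard deviations (the "uppermost 1.5 SD" target count)
DEFAULT_VOLUME_FRACTION = 0.0668


@dataclass
class BiasMap:
    """Striosome-side connection probability on the striatal mask.

    ``p_striosome`` is NaN outside ``valid_mask``; the matrix-side bias is
    ``1 - p_striosome`` and is never stored, which makes the sum-to-one
    invariant structural.  Voxels whose counts to both composites are zero
    are flagged invalid (0/0 is absence of evidence, not balanced bias).
    """

    p_striosome: np.ndarray
    valid_mask: np.ndarray
    striatal_mask: np.ndarray
    source_regions: tuple[str, ...]
    hemisphere: str
    subject_id: str
    voxel_mm: tuple[float, float, float]

    @property
    def p_matrix(self) -> np.ndarray:
        return 1.0 - self.p_striosome

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_mm))


@dataclass
class CompartmentMasks:
    """Equal-volume high-bias striosome-like and matrix-like voxel sets."""

    striosome_like: np.ndarray
    matrix_like: np.ndarray
    threshold_striosome: float
    threshold_matrix: float
    target_voxel_count: int
    hemisphere: str
    truncated: bool = False  # target unreachable before the 0.55/0.45 floor


def compute_bias(
    subject: SubjectConnectivity, regions: tuple[str, ...] | None = None
) -> BiasMap:
    """Striosome-side bias p = S / (S + M) from composite bait counts.

    ``regions`` restricts the composites (for leave-one-out parcellation);
    it must keep at least one region on each side.
    """
    regions = tuple(regions) if regions is not None else subject.region_names
    strio = [r for r in regions if r in STRIOSOME_FAVORING]
    matrix = [r for r in regions if r in MATRIX_FAVORING]
    if not strio or not matrix:
        raise ValueError(
            "need at least one striosome-favoring and one matrix-favoring region"
        )
    S = subject.counts_for(strio).sum(axis=-1).astype(np.float64)
    M = subject.counts_for(matrix).sum(axis=-1).astype(np.float64)
    total = S + M
    valid = subject.striatal_mask & (total > 0)
    p = np.full(S.shape, np.nan, dtype=np.float64)
    p[valid] = S[valid] / total[valid]
    return BiasMap(
        p_striosome=p,
        valid_mask=valid,
        striatal_mask=subject.striatal_mask,
        source_regions=tuple(strio) + tuple(matrix),
        hemisphere=subject.hemisphere,
        subject_id=subject.subject_id,
        voxel_mm=subject.voxel_mm,
    )


def classify(bias: BiasMap) -> np.ndarray:
    """Three-way label volume: striosome-like / matrix-like / indeterminate."""
    labels = np.full(bias.p_striosome.shape, LABEL_OUTSIDE, dtype=np.uint8)
    p = bias.p_striosome
    v = bias.valid_mask
    labels[v & (p >= STRIOSOME_LIKE_MIN)] = LABEL_STRIOSOME
    labels[v & (p <= MATRIX_LIKE_MAX)] = LABEL_MATRIX
    labels[v & (p > MATRIX_LIKE_MAX) & (p < STRIOSOME_LIKE_MIN)] = LABEL_INDETERMINATE
    return labels


def _descend_threshold(values: np.ndarray, flat_idx: np.ndarray, target: int,
                       floor: float, step: float):
    """Lower the threshold from 1.0 until >= target voxels qualify.

    Returns (selected flat indices, threshold reached, truncated flag).
    Overshoot is trimmed back to exactly ``target`` voxels by descending
    value, ties broken by lexicographic (flat) voxel index.
    """
    thr = 1.0
    while thr > floor + 1e-12:
        if (values >= thr - 1e-12).sum() >= target:
            break
        thr = round(thr - step, 12)
    thr = max(thr, floor)
    qual = values >= thr - 1e-12
    truncated = qual.sum() < target
    sel_vals = values[qual]
    sel_idx = flat_idx[qual]
    # sort by descending value, then ascending flat index
    order = np.lexsort((sel_idx, -sel_vals))
    keep = order if truncated else order[:target]
    return sel_idx[keep], float(thr), truncated


def equal_volume_masks(
    bias: BiasMap,
    volume_fraction: float = DEFAULT_VOLUME_FRACTION,
    step: float = 0.01,
) -> CompartmentMasks:
    """Equal-cardinality high-bias masks by iterative threshold descent.

    The target count is ``round(volume_fraction * striatal voxel count)``;
    each compartment's probability threshold starts at 1.0 and is reduced in
    decrements of ``step`` until the count of qualifying voxels reaches the
    target, never crossing into the indeterminate range (0.45-0.55).  If the
    floor is hit first the maximal mask is returned with ``truncated=True``.
    """
    if not 0.0 < volume_fraction < 0.5:
        raise ValueError("volume_fraction must lie in (0, 0.5)")
    n_striatal = int(bias.striatal_mask.sum())
    target = int(round(volume_fraction * n_striatal))
    flat_idx = np.flatnonzero(bias.valid_mask.ravel())
    p = bias.p_striosome.ravel()[flat_idx]

    sel_s, thr_s, trunc_s = _descend_threshold(
        p, flat_idx, target, STRIOSOME_LIKE_MIN, step
    )
    # matrix-side values are 1 - p; the floor 1 - 0.45 = 0.55 mirrors the
    # striosome floor so neither mask crosses into the indeterminate range
    sel_m, thr_m, trunc_m = _descend_threshold(
        1.0 - p, flat_idx, target, 1.0 - MATRIX_LIKE_MAX, step
    )

    strio_mask = np.zeros(bias.p_striosome.shape, dtype=bool)
    strio_mask.ravel()[sel_s] = True
    matrix_mask = np.zeros_like(strio_mask)
    matrix_mask.ravel()[sel_m] = True
    return CompartmentMasks(
        striosome_like=strio_mask,
        matrix_like=matrix_mask,
        threshold_striosome=thr_s,
        threshold_matrix=thr_m,
        target_voxel_count=target,
        hemisphere=bias.hemisphere,
        truncated=trunc_s or trunc_m,
    )
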
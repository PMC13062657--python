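"""Bait-region vocabulary for classification-targets parcellation.

Ten cortical/subcortical regions with known compartment-biased projections
onto the striatum: five favor the striosome compartment, five favor matrix.
Per-voxel streamline counts are stored in this fixed order (striosome-favoring
first), and every module indexes counts through these names.
"""

from __future__ import annotations

STRIOSOME_FAVORING: tuple[str, ...] = (
    "posterior_orbitofrontal",
    "anterior_insula",
    "basolateral_amygdala",
    "basal_operculum",
    "posterior_temporal_fusiform",
)

MATRIX_FAVORING: tuple[str, ...] = (
    "ifg_pars_opercularis",
    "primary_motor",
    "supplementary_motor",
    "primary_somatosensory",
    "superior_parietal",
)

ALL_REGIONS: tuple[str, ...] = STRIOSOME_FAVORING + MATRIX_FAVORING


def region_index(name: str) -> int:
    """Position of a bait region in the canonical count ordering."""
    try:
        return ALL_REGIONS.index(name)
    except ValueError:
        raise KeyError(f"unknown bait region: {name!r}") from None


def favored_compartment(name: str) -> str:
    """'striosome' or 'matrix', the compartment this bait region favors."""
    if name in STRIOSOME_FAVORING:
        return "striosome"
    if name in MATRIX_FAVORING:
        return "matrix"
    raise KeyError(f"unknown bait region: {name!r}")
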
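import numpy as np
import pytest

from striocomp.phantom import (
    EffectSpec,
    PhantomSpec,
    generate_cohort,
    generate_tissue,
    simulate_subject,
)
from striocomp.regions import ALL_REGIONS

SMALL_SPEC = PhantomSpec(grid_shape_highres=(24, 28, 24))


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC


@pytest.fixture(scope="session")
def small_grid():
    return generate_tissue(SMALL_SPEC, seed=11)


@pytest.fixture(scope="session")
def small_subject(small_grid):
    return simulate_subject(
        small_grid, SMALL_SPEC, EffectSpec(), subject_id="s0", seed=21
    )


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(
        SMALL_SPEC,
        EffectSpec(),
        [{"study_id": "A", "n_control": 4, "n_affected": 4}],
        master_seed=77,
    )


def make_subject(counts, striatal_mask=None, voxel_mm=(2.0, 2.0, 2.0), **kw):
    """Hand-built SubjectConnectivity for arithmetic-level tests."""
    from striocomp.phantom import SubjectConnectivity

    counts = np.asarray(counts, dtype=np.uint16)
    shape = counts.shape[:3]
    if striatal_mask is None:
        striatal_mask = np.ones(shape, dtype=bool)
    caudate = kw.pop("caudate_mask", np.zeros(shape, dtype=bool))
    putamen = kw.pop("putamen_mask", striatal_mask & ~caudate)
    defaults = dict(
        counts=counts,
        region_names=ALL_REGIONS,
        streamlines_per_voxel=5000,
        fa=np.full(shape, 0.3, dtype=np.float32),
        rd=np.full(shape, 0.6, dtype=np.float32),
        striatal_mask=striatal_mask,
        caudate_mask=caudate,
        putamen_mask=putamen,
        true_striosome_fraction=np.zeros(shape, dtype=np.float32),
        true_bias=np.zeros(shape, dtype=np.float32),
        striatal_content=striatal_mask.astype(np.float32),
        head_size_scalar=1.0,
        subject_id="toy",
        study_id="A",
        group="control",
        severity_category=None,
        hemisphere="left",
        voxel_mm=voxel_mm,
    )
    defaults.update(kw)
    return SubjectConnectivity(**defaults)


def make_bias(p, valid=None, striatal=None, voxel_mm=(2.0, 2.0, 2.0),
              subject_id="toy", hemisphere="left"):
    """Hand-built BiasMap with explicit probabilities."""
    from striocomp.parcellation import BiasMap
    from striocomp.regions import ALL_REGIONS

    p = np.asarray(p, float)
    if striatal is None:
        striatal = np.ones(p.shape, dtype=bool)
    if valid is None:
        valid = striatal & ~np.isnan(p)
    pm = np.where(valid, p, np.nan)
    return BiasMap(
        p_striosome=pm,
        valid_mask=valid,
        striatal_mask=striatal,
        source_regions=ALL_REGIONS,
        hemisphere=hemisphere,
        subject_id=subject_id,
        voxel_mm=voxel_mm,
    )
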
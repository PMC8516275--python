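"""Shared fixtures: a small synthetic segment for fast geometry/transport tests.

The "tiny" segment is deliberately not a registry entry: a 0.8 cm round
cylinder with a spongiosa of mid-range microstructure keeps every grid below
~100^3 voxels so the full unit suite stays fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from osteodose.pipeline import build_phantom
from osteodose.registry import MicroSpec, SegmentSpec


@pytest.fixture(scope="session")
def tiny_micro() -> MicroSpec:
    return MicroSpec(
        site_name="synthetic",
        key="tiny",
        age_group="adult",
        bvtv=0.30,
        bvtv_min=0.20,
        bvtv_max=0.40,
        tb_th=0.15,
        tb_th_cv=10.0,
        tb_sp=0.50,
        tb_sp_cv=10.0,
    )


@pytest.fixture(scope="session")
def tiny_spec() -> SegmentSpec:
    return SegmentSpec(
        site_name="synthetic",
        segment_name="tiny_rc",
        age_group="adult",
        sex="both",
        shape="RC",
        h=0.8,
        h_cv=5.0,
        d1=0.8,
        d1_cv=5.0,
        ct_th=0.06,
        ct_th_cv=10.0,
        capped_faces=("lateral", "axial_top", "axial_bottom"),
    )


@pytest.fixture(scope="session")
def tiny_bundle(tiny_spec, tiny_micro):
    """Calibrated, voxelized, cortex-capped phantom of the tiny segment."""
    return build_phantom(tiny_spec, tiny_micro, seed=42, resolution_um=100.0)


@pytest.fixture(scope="session")
def tiny_phantom(tiny_bundle):
    return tiny_bundle.phantom


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
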
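"""Shared fixtures: deterministic phantoms and small expression matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tumorio.biophysics import TISSUE_CODE_BOOK, LabelVolume
from tumorio.signatures import ExpressionMatrix, GeneSignature


def shell_phantom(
    extent_mm: float = 33.0,
    voxel_size_mm: float = 1.0,
    tumor_radius_mm: float = 6.0,
    vessel_shell_radius_mm: float = 10.0,
    vessel_shell_halfwidth_mm: float = 0.75,
) -> tuple[LabelVolume, np.ndarray]:
    """Resolution-independent phantom: central spherical tumor inside a
    spherical vessel shell, gland elsewhere.

    Geometry is defined in mm so halving the voxel size refines the same
    object.  Vessel leakiness ramps linearly with the z coordinate, so
    the fraction of leaky vessels is also resolution-independent.
    """
    n = int(round(extent_mm / voxel_size_mm))
    coords = (np.arange(n) + 0.5) * voxel_size_mm - extent_mm / 2.0
    zz, yy, xx = np.meshgrid(coords, coords, coords, indexing="ij")
    r = np.sqrt(zz**2 + yy**2 + xx**2)

    labels = np.full((n, n, n), TISSUE_CODE_BOOK["gland"], dtype=np.uint8)
    vessel = np.abs(r - vessel_shell_radius_mm) <= vessel_shell_halfwidth_mm
    labels[vessel] = TISSUE_CODE_BOOK["vasculature"]
    labels[r <= tumor_radius_mm] = TISSUE_CODE_BOOK["tumor"]

    leakiness = np.zeros_like(r)
    # linear ramp in z spanning (0, 1) across the vessel shell, so the
    # fraction above any leakiness cutoff is a spherical-cap area ratio,
    # independent of voxel size
    span = vessel_shell_radius_mm + vessel_shell_halfwidth_mm
    ramp = np.clip((zz + span) / (2 * span), 0.0, 1.0)
    leakiness[vessel & (r > tumor_radius_mm)] = ramp[vessel & (r > tumor_radius_mm)]
    return LabelVolume(labels, voxel_size_mm=voxel_size_mm), leakiness


def slab_volume(
    nx: int = 160, voxel_size_mm: float = 0.25, cross: int = 3
) -> LabelVolume:
    """Pseudo-1D slab: a vessel plane at x = 0, gland elsewhere.

    With no-flux side walls the solution is constant across the slab
    cross-section, so the solver can be compared against the closed-form
    1D profile exp(-x * sqrt(k/D))."""
    labels = np.full((nx, cross, cross), TISSUE_CODE_BOOK["gland"], dtype=np.uint8)
    labels[0, :, :] = TISSUE_CODE_BOOK["vasculature"]
    return LabelVolume(labels, voxel_size_mm=voxel_size_mm)


@pytest.fixture
def phantom():
    return shell_phantom()


@pytest.fixture
def slab():
    return slab_volume()


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """A 4-gene x 4-cell TPM matrix with hand-checkable values."""
    df = pd.DataFrame(
        {
            "c1": [0.5, 9.0, 0.0, 99.0],
            "c2": [2.0, 9.0, 9.0, 0.0],
            "c3": [3.0, 0.0, 99.0, 9.0],
            "c4": [0.0, 99.0, 9.0, 9.0],
        },
        index=["CD274", "G1", "G2", "G3"],
    )
    return ExpressionMatrix(df, unit="TPM")


@pytest.fixture
def simple_signature() -> GeneSignature:
    return GeneSignature([("G1", 1.0), ("G2", 2.0), ("G3", -1.0)], name="toy")
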
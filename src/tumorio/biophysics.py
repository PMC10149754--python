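"""Biophysical feature maps from segmented virtual tumors.

Two spatial biomarker maps are derived from a segmented 3D label volume:

* **Metabolic activity** — a steady-state nutrient field is computed by a
  linear-uptake reaction-diffusion model,

      D laplacian(c) = k * m(class) * c,

  with the relative concentration clamped to 1 on vasculature voxels
  (Dirichlet source), no-flux boundaries, and a per-tissue-class uptake
  multiplier m.  Tumor voxels whose nutrient level clears a growth
  threshold count as metabolically active; the scalar feature is the
  active fraction of the tumor.

* **Angiogenesis** — vessel leakiness is an input scalar field; the
  feature is the fraction of vasculature voxels inside the tumor
  microenvironment (a band of configurable width around the tumor) whose
  leakiness exceeds 90% of a maximal reference leakiness L_max.

The solver discretizes the operator with the standard 7-point stencil on
the voxel grid (spacing = voxel size, mm) and solves the resulting sparse
symmetric positive-definite system by preconditioned conjugate gradients.
The discrete maximum principle guarantees all values lie in [0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg

__all__ = [
    "TISSUE_CODE_BOOK",
    "LabelVolume",
    "NutrientField",
    "MetabolicActivityMap",
    "AngiogenesisMap",
    "BiophysFeatures",
    "DEFAULT_CONSUMPTION_MULTIPLIERS",
    "solve_nutrient_field",
    "metabolic_activity_map",
    "metabolic_activity_fraction",
    "tme_mask",
    "angiogenesis_fraction",
    "calibrate_leakiness_max",
    "extract_features",
]

#: Integer codes for the seven segmentation classes.
TISSUE_CODE_BOOK: dict[str, int] = {
    "air": 0,
    "chest": 1,
    "skin": 2,
    "fat": 3,
    "gland": 4,
    "vasculature": 5,
    "tumor": 6,
}

#: Relative nutrient uptake per tissue class (tumor consumes fastest;
#: air consumes nothing).
DEFAULT_CONSUMPTION_MULTIPLIERS: dict[str, float] = {
    "air": 0.0,
    "chest": 0.3,
    "skin": 0.3,
    "fat": 0.1,
    "gland": 0.3,
    "vasculature": 0.0,
    "tumor": 1.0,
}


@dataclass
class LabelVolume:
    """3D tissue-label grid with its voxel size in mm."""

    voxels: np.ndarray  # integer labels
    voxel_size_mm: float = 1.0
    code_book: dict[str, int] = field(default_factory=lambda: dict(TISSUE_CODE_BOOK))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("label volume must be 3D")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel size must be positive")
        known = set(self.code_book.values())
        present = set(np.unique(self.voxels).tolist())
        if not present <= known:
            raise ValueError(f"labels outside code book: {sorted(present - known)}")

    def mask(self, cls: str) -> np.ndarray:
        return self.voxels == self.code_book[cls]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    # ---- NIfTI I/O ----------------------------------------------------

    def to_nifti(self, path: str | Path) -> None:
        """Write labels as uint8 NIfTI plus a ``.labels.json`` code-book
        sidecar."""
        import nibabel as nib

        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.voxels.astype(np.uint8), affine), str(path))
        sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".labels.json")
        sidecar.write_text(json.dumps(self.code_book, indent=2) + "\n")

    @classmethod
    def from_nifti(cls, path: str | Path, code_book: Optional[dict] = None) -> "LabelVolume":
        import nibabel as nib

        img = nib.load(str(path))
        vox = np.asarray(img.dataobj).astype(int)
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0]):
            raise ValueError("anisotropic voxels are not supported")
        if code_book is None:
            sidecar = Path(str(path).replace(".nii.gz", "").replace(".nii", "") + ".labels.json")
            code_book = json.loads(sidecar.read_text()) if sidecar.exists() else dict(TISSUE_CODE_BOOK)
        return cls(vox, voxel_size_mm=float(zooms[0]), code_book=code_book)


def save_scalar_field(values: np.ndarray, voxel_size_mm: float, path: str | Path) -> None:
    """Write a float32 scalar field as NIfTI on an isotropic grid."""
    import nibabel as nib

    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(values.astype(np.float32), affine), str(path))


def load_scalar_field(path: str | Path) -> tuple[np.ndarray, float]:
    import nibabel as nib

    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), float(img.header.get_zooms()[0])


@dataclass
class NutrientField:
    """Steady-state relative nutrient concentration (vessel source = 1)."""

    values: np.ndarray
    diffusivity: float
    consumption: float
    multipliers: dict[str, float]
    residual: float

    def __post_init__(self) -> None:
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("nutrient values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)


@dataclass
class MetabolicActivityMap:
    """Nutrient field restricted to the tumor and thresholded for growth."""

    values: np.ndarray
    glucose_threshold: float


@dataclass
class AngiogenesisMap:
    """Vessel leakiness with the reference maximum and TME cutoff."""

    leakiness: np.ndarray
    leakiness_max: float = 1.0
    cutoff_fraction: float = 0.9

    def __post_init__(self) -> None:
        if self.leakiness.min() < 0 or self.leakiness.max() > 1:
            raise ValueError("leakiness must lie in [0, 1]")
        if not 0 < self.cutoff_fraction <= 1:
            raise ValueError("cutoff_fraction must lie in (0, 1]")
        if self.leakiness_max <= 0:
            raise ValueError("leakiness_max must be positive")


@dataclass(frozen=True)
class BiophysFeatures:
    """The two scalar regressors of the linear pCR score."""

    metabolic_activity: float
    angiogenesis: float
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name in ("metabolic_activity", "angiogenesis"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def solve_nutrient_field(
    vol: LabelVolume,
    diffusivity: float = 1.0,
    consumption: float = 0.25,
    multipliers: Optional[Mapping[str, float]] = None,
    rtol: float = 1e-8,
    maxiter: int = 100_000,
) -> NutrientField:
    """Solve D lap(c) = k m c with c = 1 on vasculature, no-flux walls.

    Parameters
    ----------
    diffusivity
        Nutrient diffusivity D, mm^2 per unit time.
    consumption
        Base uptake rate k, per unit time.  The decay length away from a
        vessel is sqrt(D / (k m)); the defaults give 2 mm in tumor tissue.
    multipliers
        Per-class uptake multipliers m; defaults to
        :data:`DEFAULT_CONSUMPTION_MULTIPLIERS`.
    rtol
        Relative residual tolerance of the linear solve.
    """
    if diffusivity <= 0 or consumption < 0:
        raise ValueError("need diffusivity > 0 and consumption >= 0")
    mult = dict(DEFAULT_CONSUMPTION_MULTIPLIERS)
    if multipliers:
        mult.update(multipliers)

    vessel = vol.mask("vasculature")
    if not vessel.any():
        raise ValueError("volume contains no vasculature voxel")

    h = vol.voxel_size_mm
    shape = vol.shape
    n = int(np.prod(shape))
    idx = np.arange(n).reshape(shape)
    free = ~vessel.ravel()
    free_idx = -np.ones(n, dtype=np.int64)
    free_idx[free] = np.arange(free.sum())

    # uptake coefficient per voxel
    m = np.zeros(shape)
    for cls, code in vol.code_book.items():
        m[vol.voxels == code] = mult.get(cls, 0.0)
    kk = (consumption * m).ravel()

    w = diffusivity / h**2
    rows, cols, vals = [], [], []
    rhs = np.zeros(free.sum())
    diag = kk[free].copy()

    flat_vessel = vessel.ravel()
    for axis in range(3):
        for shift in (-1, 1):
            nb = np.roll(idx, -shift, axis=axis)
            # mirror (no-flux): edge voxels lack this neighbor entirely
            sl = [slice(None)] * 3
            sl[axis] = slice(-1, None) if shift == 1 else slice(0, 1)
            valid = np.ones(shape, dtype=bool)
            valid[tuple(sl)] = False
            src = idx[valid].ravel()
            dst = nb[valid].ravel()
            keep = ~flat_vessel[src]  # rows only for free voxels
            src, dst = src[keep], dst[keep]
            diag_add = np.zeros(free.sum())
            np.add.at(diag_add, free_idx[src], w)
            diag += diag_add
            to_vessel = flat_vessel[dst]
            # neighbor is a vessel: its known value 1 moves to the RHS
            rhs_add = np.zeros(free.sum())
            np.add.at(rhs_add, free_idx[src[to_vessel]], w)
            rhs += rhs_add
            rows.append(free_idx[src[~to_vessel]])
            cols.append(free_idx[dst[~to_vessel]])
            vals.append(np.full((~to_vessel).sum(), -w))

    A = sparse.coo_matrix(
        (
            np.concatenate(vals + [diag]),
            (
                np.concatenate(rows + [np.arange(free.sum())]),
                np.concatenate(cols + [np.arange(free.sum())]),
            ),
        ),
        shape=(free.sum(), free.sum()),
    ).tocsr()

    # Jacobi-preconditioned CG; the system is SPD by construction.
    M = sparse.diags(1.0 / A.diagonal())
    x0 = np.full(free.sum(), 0.5)
    x, info = cg(A, rhs, x0=x0, rtol=rtol, maxiter=maxiter, M=M)
    resid = float(np.linalg.norm(A @ x - rhs) / max(np.linalg.norm(rhs), 1e-300))
    if info != 0 or resid > max(rtol * 10, 1e-6):
        raise RuntimeError(
            f"nutrient solve did not converge (info={info}, relative "
            f"residual {resid:.3e})"
        )

    c = np.ones(n)
    c[free] = x
    c = np.clip(c, 0.0, 1.0).reshape(shape)
    return NutrientField(
        values=c,
        diffusivity=diffusivity,
        consumption=consumption,
        multipliers=mult,
        residual=resid,
    )


def metabolic_activity_map(
    nutrient: NutrientField, vol: LabelVolume, threshold: float = 0.2
) -> MetabolicActivityMap:
    """Zero out tumor voxels starving below the growth threshold.

    The map equals the nutrient level on tumor voxels at or above the
    threshold, 0 on starving tumor voxels and 0 outside the tumor.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    if nutrient.values.shape != vol.shape:
        raise ValueError("nutrient field and label volume shapes differ")
    tumor = vol.mask("tumor")
    out = np.where(tumor & (nutrient.values >= threshold), nutrient.values, 0.0)
    return MetabolicActivityMap(values=out, glucose_threshold=threshold)


def metabolic_activity_fraction(amap: MetabolicActivityMap, vol: LabelVolume) -> float:
    """Fraction of tumor voxels with metabolic activity > 0."""
    tumor = vol.mask("tumor")
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise ValueError("volume contains no tumor voxel")
    return float((amap.values[tumor] > 0).sum() / n_tumor)


def tme_mask(vol: LabelVolume, radius_mm: float = 5.0) -> np.ndarray:
    """Voxels within ``radius_mm`` of the tumor surface, tumor excluded.

    Distances are Euclidean in mm from each non-tumor voxel center to the
    nearest tumor voxel center.
    """
    if radius_mm < 0:
        raise ValueError("radius must be >= 0")
    tumor = vol.mask("tumor")
    if not tumor.any():
        return np.zeros(vol.shape, dtype=bool)
    dist = ndimage.distance_transform_edt(
        ~tumor, sampling=[vol.voxel_size_mm] * 3
    )
    return (dist > 0) & (dist <= radius_mm)


def angiogenesis_fraction(
    amap: AngiogenesisMap, vol: LabelVolume, tme: np.ndarray
) -> float:
    """Fraction of TME vasculature leakier than cutoff * L_max (strict >)."""
    vessels = vol.mask("vasculature") & tme
    n = int(vessels.sum())
    if n == 0:
        warnings.warn(
            "no vasculature inside the TME; angiogenesis fraction set to 0",
            stacklevel=2,
        )
        return 0.0
    cut = amap.cutoff_fraction * amap.leakiness_max
    return float((amap.leakiness[vessels] > cut).sum() / n)


def calibrate_leakiness_max(
    leakiness_fields: list[np.ndarray],
    vessel_masks: list[np.ndarray],
    percentile: float = 99.0,
) -> float:
    """Estimate the maximal reference leakiness L_max across a cohort.

    Takes the given percentile of pooled vessel-voxel leakiness over a
    sample of patients, mirroring a reference-cohort calibration.
    """
    pooled = np.concatenate(
        [f[m] for f, m in zip(leakiness_fields, vessel_masks) if m.any()]
    )
    if pooled.size == 0:
        raise ValueError("no vessel voxels in calibration cohort")
    return float(np.percentile(pooled, percentile))


def extract_features(
    vol: LabelVolume,
    leakiness: np.ndarray,
    diffusivity: float = 1.0,
    consumption: float = 0.25,
    multipliers: Optional[Mapping[str, float]] = None,
    glucose_threshold: float = 0.2,
    tme_radius_mm: float = 5.0,
    leakiness_max: float = 1.0,
    cutoff_fraction: float = 0.9,
) -> BiophysFeatures:
    """End-to-end feature extraction from one segmented virtual tumor.

    Runs the nutrient solve, thresholds the metabolic map, builds the TME
    band and reduces both maps to their scalar fractions.  The returned
    provenance dict records every parameter used.
    """
    nutrient = solve_nutrient_field(
        vol, diffusivity=diffusivity, consumption=consumption, multipliers=multipliers
    )
    mmap = metabolic_activity_map(nutrient, vol, threshold=glucose_threshold)
    metab = metabolic_activity_fraction(mmap, vol)
    amap = AngiogenesisMap(
        leakiness=leakiness,
        leakiness_max=leakiness_max,
        cutoff_fraction=cutoff_fraction,
    )
    band = tme_mask(vol, radius_mm=tme_radius_mm)
    angio = angiogenesis_fraction(amap, vol, band)
    return BiophysFeatures(
        metabolic_activity=metab,
        angiogenesis=angio,
        provenance={
            "diffusivity": diffusivity,
            "consumption": consumption,
            "multipliers": dict(multipliers or DEFAULT_CONSUMPTION_MULTIPLIERS),
            "glucose_threshold": glucose_threshold,
            "tme_radius_mm": tme_radius_mm,
            "leakiness_max": leakiness_max,
            "cutoff_fraction": cutoff_fraction,
            "solver_residual": nutrient.residual,
        },
    )
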
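"""Volume container, NIfTI I/O and the pre-processing chain.

Pre-processing for paired post-contrast gradient-echo (GRE) and black-blood
(BB) brain volumes comprises three steps: rigid registration of the BB volume
onto the GRE grid, intensity normalization to [0, 1] by the volume maximum,
and brain extraction by thresholding + morphological closing + largest
connected component.

Coordinate convention: volumes are numpy arrays indexed (x, y, z) with
0-based voxel indices, matching the NIfTI data layout returned by nibabel.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .errors import DegenerateInputError, ShapeMismatchError

MODALITIES = ("GRE", "BB", "SYNTH_BB", "DL_BB", "OTHER")

_STRUCT26 = np.ones((3, 3, 3), bool)


@dataclass
class Volume3D:
    """A 3D scalar intensity grid with spacing and modality metadata.

    Parameters
    ----------
    data:
        3D array of finite scalars.
    spacing_mm:
        Per-axis voxel size in millimetres.
    modality:
        One of ``GRE, BB, SYNTH_BB, DL_BB, OTHER``.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = "OTHER"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite voxels")
        if np.isscalar(self.spacing_mm):
            self.spacing_mm = (float(self.spacing_mm),) * 3
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def intensity_range(self) -> tuple[float, float]:
        return float(self.data.min()), float(self.data.max())

    def copy(self, data: np.ndarray | None = None, modality: str | None = None) -> "Volume3D":
        return Volume3D(
            data=self.data.copy() if data is None else data,
            spacing_mm=self.spacing_mm,
            modality=self.modality if modality is None else modality,
        )


@dataclass
class StudyPair:
    """A co-registered GRE/BB volume pair with an optional brain mask."""

    gre: Volume3D
    bb: Volume3D
    brain_mask: np.ndarray | None = None
    registered: bool = False

    def __post_init__(self) -> None:
        if self.gre.shape != self.bb.shape:
            raise ShapeMismatchError(f"GRE {self.gre.shape} vs BB {self.bb.shape}")
        if self.gre.spacing_mm != self.bb.spacing_mm:
            raise ShapeMismatchError("GRE and BB spacing differ")
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, bool)
            if self.brain_mask.shape != self.gre.shape:
                raise ShapeMismatchError("brain mask shape differs from volumes")
            if not self.brain_mask.any():
                raise ValueError("brain mask is empty")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_volume(path: str | Path, modality: str = "OTHER") -> Volume3D:
    """Read a NIfTI volume from disk.

    Raises on missing files, non-3D images and non-finite voxel values.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D image, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume3D(data=data, spacing_mm=spacing, modality=modality)


def write_volume(vol: Volume3D, path: str | Path) -> Path:
    """Write a volume as NIfTI; the affine encodes the voxel spacing."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# Intensity normalization
# ---------------------------------------------------------------------------

def normalize_intensity(vol: Volume3D, mode: str = "max", percentile: float = 99.9) -> Volume3D:
    """Scale intensities into [0, 1].

    ``mode='max'`` divides by the volume maximum, so the maximum maps to 1
    exactly and voxel ordering is preserved (the operation is idempotent and
    monotone).  ``mode='percentile'`` divides by the given upper percentile and
    clips the (rare) voxels above it — more robust on noisy acquisitions.
    """
    data = vol.data
    if mode == "max":
        scale = float(data.max())
    elif mode == "percentile":
        scale = float(np.percentile(data, percentile))
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    if scale <= 0:
        raise DegenerateInputError("volume maximum is not positive; cannot normalize")
    out = data / scale
    if mode == "percentile":
        out = np.clip(out, 0.0, 1.0)
    return vol.copy(data=out)


# ---------------------------------------------------------------------------
# Rigid registration
# ---------------------------------------------------------------------------

@dataclass
class RigidResult:
    """A 6-parameter rigid registration outcome.

    ``matrix`` is the homogeneous 4x4 world-coordinate (mm) transform mapping
    fixed-image points to moving-image points, with world axes parallel to the
    array axes (x, y, z).
    """

    matrix: np.ndarray
    rotation_rad: tuple[float, float, float]
    translation_mm: tuple[float, float, float]
    metric_before: float
    metric_after: float
    converged: bool

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "matrix": self.matrix.tolist(),
                    "rotation_rad": list(self.rotation_rad),
                    "translation_mm": list(self.translation_mm),
                    "metric_before": self.metric_before,
                    "metric_after": self.metric_after,
                    "converged": self.converged,
                },
                indent=2,
            )
        )


def _to_sitk(vol: Volume3D):
    import SimpleITK as sitk

    # transpose so that sitk's (x, y, z) indexing matches our array axes
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T.astype(np.float64)))
    img.SetSpacing(tuple(vol.spacing_mm))
    return img


def _from_sitk(img, like: Volume3D) -> Volume3D:
    import SimpleITK as sitk

    arr = sitk.GetArrayFromImage(img).T
    return like.copy(data=np.ascontiguousarray(arr))


def register_rigid(moving: Volume3D, fixed: Volume3D) -> tuple[Volume3D, RigidResult]:
    """Rigidly align ``moving`` to ``fixed`` (6 DOF, multi-resolution, NCC).

    Returns the moving volume resampled onto the fixed grid and the recovered
    transform.  When the optimization does not improve the similarity metric
    (or fails outright), the best-effort result is returned with
    ``converged=False``.
    """
    import SimpleITK as sitk

    if moving.data.ndim != fixed.data.ndim:
        raise ShapeMismatchError("dimensionality mismatch")

    f_img = _to_sitk(fixed)
    m_img = _to_sitk(moving)

    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(), sitk.CenteredTransformInitializerFilter.GEOMETRY
    )

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0, minStep=1e-4, numberOfIterations=200, relaxationFactor=0.6
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel([4, 2, 1])
    reg.SetSmoothingSigmasPerLevel([2.0, 1.0, 0.0])
    reg.SetInitialTransform(initial, inPlace=False)

    identityish = sitk.Euler3DTransform(initial)
    try:
        metric_before = reg.MetricEvaluate(f_img, m_img)
        final = reg.Execute(f_img, m_img)
        reg.SetInitialTransform(final, inPlace=False)
        metric_after = reg.MetricEvaluate(f_img, m_img)
    except RuntimeError as exc:  # e.g. no overlapping samples
        warnings.warn(f"registration failed ({exc}); returning identity transform")
        final = identityish
        metric_before = metric_after = float("nan")

    # sitk minimizes negative normalized cross-correlation; a final value
    # near zero means the volumes share no intensity structure at all
    converged = bool(
        np.isfinite(metric_after)
        and metric_after <= metric_before + 1e-12
        and metric_after < -0.01
    )
    if not converged:
        warnings.warn("registration did not improve the similarity metric; flagged")
        final = identityish
        metric_after = metric_before

    if final.GetName() == "CompositeTransform":
        comp = sitk.CompositeTransform(final)
        final = comp.GetNthTransform(comp.GetNumberOfTransforms() - 1)
    euler = sitk.Euler3DTransform(final)
    rot = (euler.GetAngleX(), euler.GetAngleY(), euler.GetAngleZ())
    trans = euler.GetTranslation()
    mat = np.eye(4)
    mat[:3, :3] = np.asarray(euler.GetMatrix()).reshape(3, 3)
    mat[:3, 3] = trans
    center = np.asarray(euler.GetCenter())
    mat[:3, 3] += center - mat[:3, :3] @ center

    resampled = sitk.Resample(m_img, f_img, final, sitk.sitkLinear, 0.0)
    out = _from_sitk(resampled, fixed).copy(modality=moving.modality)

    return out, RigidResult(
        matrix=mat,
        rotation_rad=tuple(float(a) for a in rot),
        translation_mm=tuple(float(t) for t in trans),
        metric_before=float(metric_before),
        metric_after=float(metric_after),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# Brain extraction
# ---------------------------------------------------------------------------

def extract_brain(vol: Volume3D, closing_radius_vox: int = 2) -> np.ndarray:
    """Binary brain mask: Otsu threshold, closing, largest 26-connected component.

    On head-like volumes a bright scalp/skull rim separated from the brain by
    a dark gap ends up in its own connected component and is discarded.
    """
    data = vol.data
    try:
        thr = threshold_otsu(data)
    except ValueError as exc:
        raise DegenerateInputError(f"cannot threshold volume: {exc}") from exc
    fg = data > thr
    if not fg.any():
        raise DegenerateInputError("thresholding produced an empty mask")
    fg = ndimage.binary_closing(fg, structure=ball(closing_radius_vox))
    labels, n = ndimage.label(fg, structure=_STRUCT26)
    if n == 0:
        raise DegenerateInputError("no connected tissue component found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


# ---------------------------------------------------------------------------
# Convenience pipeline
# ---------------------------------------------------------------------------

def preprocess_pair(
    gre: Volume3D,
    bb: Volume3D,
    skip_register: bool = False,
) -> tuple[StudyPair, RigidResult | None]:
    """Normalize both volumes, register BB onto GRE, extract the brain mask."""
    gre_n = normalize_intensity(gre)
    bb_n = normalize_intensity(bb)
    result = None
    if not skip_register:
        bb_n, result = register_rigid(bb_n, gre_n)
    mask = extract_brain(gre_n)
    pair = StudyPair(gre=gre_n, bb=bb_n, brain_mask=mask, registered=True)
    return pair, result
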
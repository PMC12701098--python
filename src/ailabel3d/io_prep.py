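"""Volume I/O, dimension matching, intensity normalisation and cohort splitting.

Volumes are kept in ``(H, W, D)`` index order (rows, columns, slices), 0-based,
with the third axis as depth.  NIfTI (.nii / .nii.gz) is the only on-disk
format; binary masks are stored as uint8 in {0,1} and cluster maps as uint16.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError, DimensionalityError

DEFAULT_TARGET_SHAPE = (512, 512, 32)


@dataclass
class VolumePair:
    """Co-registered T1-/T2-weighted volumes of one case, with voxel spacing in mm."""

    t1: np.ndarray
    t2: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    case_id: str = ""
    patient_id: str = ""

    def __post_init__(self):
        if self.t1.ndim != 3 or self.t2.ndim != 3:
            raise DimensionalityError("VolumePair requires 3D arrays")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.t1.shape


@dataclass
class CohortSplit:
    train: list[str] = field(default_factory=list)
    val: list[str] = field(default_factory=list)
    test: list[str] = field(default_factory=list)


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3D NIfTI volume; returns the array in (H, W, D) order and its spacing.

    Raises ``FileNotFoundError`` for a missing file and ``DimensionalityError``
    (naming the observed rank) for non-3D images.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(f"expected a 3D image, got rank {data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data), spacing


def write_volume(path, vol: np.ndarray, spacing=(1.0, 1.0, 1.0), dtype=None) -> None:
    """Write a 3D array as NIfTI with a diagonal affine built from the spacing."""
    if vol.ndim != 3:
        raise DimensionalityError(f"expected a 3D array, got rank {vol.ndim}")
    data = vol.astype(dtype) if dtype is not None else vol
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def resize_volume(vol: np.ndarray, target_shape, order: int = 1) -> np.ndarray:
    """Resample a 3D volume to ``target_shape``; trilinear (order=1) for
    intensities, nearest (order=0) for label volumes."""
    target_shape = tuple(int(s) for s in target_shape)
    if len(target_shape) != 3 or any(s < 1 for s in target_shape):
        raise ValueError(f"target_shape must be 3 positive integers, got {target_shape}")
    if vol.shape == target_shape:
        return vol.copy()
    factors = [t / s for t, s in zip(target_shape, vol.shape)]
    out = ndimage.zoom(vol.astype(np.float64), factors, order=order, mode="nearest", grid_mode=True)
    # grid_mode zoom guarantees the exact output shape for integer-free factors
    assert out.shape == target_shape
    if order == 0:
        out = out.astype(vol.dtype)
    return out


def match_dimensions(
    t1_raw: np.ndarray,
    t2_raw: np.ndarray,
    target_shape=DEFAULT_TARGET_SHAPE,
    t1_spacing=(1.0, 1.0, 1.0),
    t2_spacing=(1.0, 1.0, 1.0),
    case_id: str = "",
    patient_id: str = "",
) -> VolumePair:
    """Resample both modalities to a common grid (trilinear interpolation).

    The output spacing is the T1 spacing rescaled by the shape change, so the
    physical extent of the volume is preserved.
    """
    if t1_raw.ndim != 3 or t2_raw.ndim != 3:
        raise DimensionalityError("match_dimensions requires 3D inputs")
    target_shape = tuple(int(s) for s in target_shape)
    if any(s < 1 for s in target_shape):
        raise ValueError(f"non-positive target dimension in {target_shape}")
    t1 = resize_volume(t1_raw, target_shape, order=1)
    t2 = resize_volume(t2_raw, target_shape, order=1)
    spacing = tuple(sp * old / new for sp, old, new in zip(t1_spacing, t1_raw.shape, target_shape))
    return VolumePair(t1=t1, t2=t2, spacing=spacing, case_id=case_id, patient_id=patient_id)


def znormalize(vol: np.ndarray) -> np.ndarray:
    """Standardise a volume to zero mean and unit (population) standard deviation."""
    v = np.asarray(vol, dtype=np.float64)
    if v.size < 2:
        raise DegenerateInputError("z-normalization needs at least 2 voxels")
    sd = v.std()
    if sd == 0.0:
        raise DegenerateInputError("constant volume: zero intensity variance")
    return (v - v.mean()) / sd


def split_cohort(cases, ratios=(0.8, 0.1, 0.1), rng_seed: int = 0) -> CohortSplit:
    """Patient-level train/val/test split.

    All cases of a patient land in the same partition; partition sizes follow
    ``ratios`` as closely as integer patient counts allow (largest remainder).
    """
    cases = list(cases)
    if not cases:
        raise ValueError("empty cohort")
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or abs(sum(ratios) - 1.0) > 1e-9 or any(r < 0 for r in ratios):
        raise ValueError(f"ratios must be 3 non-negative reals summing to 1, got {ratios}")

    by_patient: dict[str, list[str]] = {}
    for case_id, patient_id in cases:
        by_patient.setdefault(patient_id, []).append(case_id)

    patients = sorted(by_patient)
    rng = np.random.default_rng(rng_seed)
    rng.shuffle(patients)

    n = len(patients)
    raw = [r * n for r in ratios]
    sizes = [int(np.floor(x)) for x in raw]
    remainders = [x - s for x, s in zip(raw, sizes)]
    for _ in range(n - sum(sizes)):
        i = int(np.argmax(remainders))
        sizes[i] += 1
        remainders[i] = -1.0

    split = CohortSplit()
    bounds = np.cumsum([0] + sizes)
    for part, lo, hi in zip((split.train, split.val, split.test), bounds[:-1], bounds[1:]):
        for patient in patients[lo:hi]:
            part.extend(by_patient[patient])
    return split
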
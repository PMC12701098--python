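"""Synthetic multi-modal 3D cases with known tissue/tumor ground truth.

The phantoms emulate the statistical structure the labeling framework relies
on rather than MR physics: nested anatomical regions (background shell, fat
layer, muscle bulk, a bone cylinder, thin vessel tubes), modality-specific
tissue contrast, one ellipsoidal tumor at a randomised position whose
intensity variance is made the highest of all tissues (cartilaginous tumors
are heterogeneous and T2-bright), and per-modality "expert" labels derived
from the ground truth by controlled boundary perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError
from .io_prep import VolumePair

__all__ = [
    "TissueSpec",
    "PhantomCase",
    "DEFAULT_TISSUES",
    "TISSUE_INDEX",
    "make_phantom",
    "simulate_expert_label",
    "make_cohort",
]

TISSUE_INDEX = {"background": 0, "fat": 1, "muscle": 2, "bone": 3, "vessel": 4, "tumor": 5}


@dataclass(frozen=True)
class TissueSpec:
    """Per-tissue intensity model: modality-specific normal distributions."""

    name: str
    mean_t1: float
    sd_t1: float
    mean_t2: float
    sd_t2: float

    def __post_init__(self):
        if self.name not in TISSUE_INDEX:
            raise ValueError(f"unknown tissue {self.name!r}")
        if self.sd_t1 < 0 or self.sd_t2 < 0:
            raise ValueError("standard deviations must be >= 0")


# Means separated by >= 2 pooled SDs between any two non-tumor tissues in at
# least one modality; tumor SD strictly exceeds every other tissue's SD in
# both modalities (tumor heterogeneity).
DEFAULT_TISSUES = (
    TissueSpec("background", 5.0, 2.0, 5.0, 2.0),
    TissueSpec("fat", 90.0, 5.0, 60.0, 5.0),
    TissueSpec("muscle", 45.0, 5.0, 35.0, 5.0),
    TissueSpec("bone", 70.0, 5.0, 20.0, 5.0),
    TissueSpec("vessel", 25.0, 4.0, 75.0, 5.0),
    TissueSpec("tumor", 60.0, 12.0, 85.0, 12.0),
)


@dataclass
class PhantomCase:
    pair: VolumePair
    tissue_map: np.ndarray
    tumor_mask: np.ndarray
    el_t1: np.ndarray
    el_t2: np.ndarray
    rng_seed: int


def _validate_tissues(tissues) -> dict[str, TissueSpec]:
    specs = {t.name: t for t in tissues}
    missing = set(TISSUE_INDEX) - set(specs)
    if missing:
        raise ValueError(f"missing tissue specs: {sorted(missing)}")
    tumor = specs["tumor"]
    for t in specs.values():
        if t.name == "tumor":
            continue
        if tumor.sd_t1 <= t.sd_t1 or tumor.sd_t2 <= t.sd_t2:
            raise ValueError("tumor SD must strictly exceed every other tissue's SD in both modalities")
    return specs


def _six_connected():
    return ndimage.generate_binary_structure(3, 1)


def make_phantom(
    shape=(48, 48, 16),
    tissues=DEFAULT_TISSUES,
    tumor_radius_range=(4.0, 7.0),
    rng_seed: int = 0,
    case_id: str | None = None,
    patient_id: str | None = None,
) -> PhantomCase:
    """Generate one synthetic case; deterministic given ``rng_seed``.

    The tumor is an ellipsoid placed at a seed-dependent position inside bone
    or muscle; its voxels are additionally modulated by a smooth low-frequency
    field so that intra-tumor variance exceeds every other tissue's.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 8 for s in shape):
        raise ValueError(f"each dimension must be >= 8, got {shape}")
    r_lo, r_hi = float(tumor_radius_range[0]), float(tumor_radius_range[1])
    if not (0 < r_lo <= r_hi):
        raise ValueError("tumor_radius_range must be 0 < lo <= hi")
    if 2 * r_hi + 2 > min(shape[:2]):
        raise ValueError(f"tumor radius {r_hi} does not fit inside in-plane extent {shape[:2]}")
    specs = _validate_tissues(tissues)
    rng = np.random.default_rng(rng_seed)

    h, w, d = shape
    ii, jj, kk = np.indices(shape, dtype=np.float64)
    ch, cw = (h - 1) / 2.0, (w - 1) / 2.0

    tissue_map = np.zeros(shape, dtype=np.int16)  # background
    body = ((ii - ch) / (0.46 * h)) ** 2 + ((jj - cw) / (0.46 * w)) ** 2 <= 1.0
    tissue_map[body] = TISSUE_INDEX["fat"]
    muscle = ((ii - ch) / (0.38 * h)) ** 2 + ((jj - cw) / (0.38 * w)) ** 2 <= 1.0
    tissue_map[muscle] = TISSUE_INDEX["muscle"]
    bone_r = 0.16 * min(h, w)
    bone = (ii - ch) ** 2 + (jj - cw) ** 2 <= bone_r ** 2
    tissue_map[bone] = TISSUE_INDEX["bone"]
    vessel_r = max(1.0, 0.035 * min(h, w))
    for oi, oj in ((0.24, 0.12), (-0.22, -0.18)):
        vi, vj = ch + oi * h, cw + oj * w
        vessel = (ii - vi) ** 2 + (jj - vj) ** 2 <= vessel_r ** 2
        tissue_map[vessel & (tissue_map == TISSUE_INDEX["muscle"])] = TISSUE_INDEX["vessel"]

    # Tumor center: rejection-sample until it falls on bone or muscle with
    # enough margin for the drawn radii to stay inside the volume.
    r_h = rng.uniform(r_lo, r_hi)
    r_w = rng.uniform(r_lo, r_hi)
    r_d = max(2.0, min(r_h, (d - 4) / 2.0))
    allowed = (tissue_map == TISSUE_INDEX["bone"]) | (tissue_map == TISSUE_INDEX["muscle"])
    for _ in range(1000):
        ci = rng.uniform(r_h + 1, h - r_h - 2)
        cj = rng.uniform(r_w + 1, w - r_w - 2)
        ck = rng.uniform(r_d + 1, d - r_d - 2)
        if allowed[int(round(ci)), int(round(cj)), int(round(ck))]:
            break
    else:  # pragma: no cover - default geometry always has bone/muscle in range
        raise RuntimeError("could not place tumor inside bone or muscle")
    tumor = ((ii - ci) / r_h) ** 2 + ((jj - cj) / r_w) ** 2 + ((kk - ck) / r_d) ** 2 <= 1.0
    tissue_map[tumor] = TISSUE_INDEX["tumor"]
    tumor_mask = (tissue_map == TISSUE_INDEX["tumor"]).astype(np.uint8)

    order = sorted(TISSUE_INDEX, key=TISSUE_INDEX.get)
    t1 = np.zeros(shape, dtype=np.float64)
    t2 = np.zeros(shape, dtype=np.float64)
    for name in order:
        vox = tissue_map == TISSUE_INDEX[name]
        n = int(vox.sum())
        if n == 0:
            continue
        spec = specs[name]
        t1[vox] = rng.normal(spec.mean_t1, spec.sd_t1, size=n)
        t2[vox] = rng.normal(spec.mean_t2, spec.sd_t2, size=n)

    # Smooth low-frequency modulation raises intra-tumor variance well above
    # the per-voxel noise of any other tissue.
    tum = tumor_mask.astype(bool)
    for vol, spec_sd in ((t1, specs["tumor"].sd_t1), (t2, specs["tumor"].sd_t2)):
        field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=2.5)
        sd = field.std()
        if sd > 0:
            vol[tum] += (field[tum] / sd) * (1.5 * spec_sd)

    seed_el = rng.integers(0, 2 ** 31, size=2)
    el_t1 = simulate_expert_label(tumor_mask, bias_voxels=-1, jitter_prob=0.05, rng_seed=int(seed_el[0]))
    el_t2 = simulate_expert_label(tumor_mask, bias_voxels=1, jitter_prob=0.05, rng_seed=int(seed_el[1]))

    pair = VolumePair(
        t1=t1,
        t2=t2,
        spacing=(1.0, 1.0, 1.0),
        case_id=case_id if case_id is not None else f"case_{rng_seed}",
        patient_id=patient_id if patient_id is not None else f"pat_{rng_seed}",
    )
    return PhantomCase(pair=pair, tissue_map=tissue_map, tumor_mask=tumor_mask,
                       el_t1=el_t1, el_t2=el_t2, rng_seed=rng_seed)


def simulate_expert_label(
    tumor_mask: np.ndarray,
    bias_voxels: int = 0,
    jitter_prob: float = 0.0,
    rng_seed: int = 0,
) -> np.ndarray:
    """Simulated manual label: systematic under-/over-segmentation plus boundary noise.

    Erodes (``bias_voxels`` < 0) or dilates (> 0) the true mask by
    ``|bias_voxels|`` iterations of the 6-connected structuring element, then
    flips boundary voxels independently with probability ``jitter_prob``.
    """
    mask = np.asarray(tumor_mask).astype(bool)
    if not mask.any():
        raise DegenerateInputError("empty tumor mask")
    if not (0.0 <= jitter_prob <= 1.0):
        raise ValueError("jitter_prob must be in [0, 1]")
    struct = _six_connected()
    out = mask.copy()
    if bias_voxels < 0:
        out = ndimage.binary_erosion(out, structure=struct, iterations=-bias_voxels)
    elif bias_voxels > 0:
        out = ndimage.binary_dilation(out, structure=struct, iterations=bias_voxels)
    if jitter_prob > 0.0:
        inner = out & ~ndimage.binary_erosion(out, structure=struct)
        outer = ndimage.binary_dilation(out, structure=struct) & ~out
        boundary = inner | outer
        rng = np.random.default_rng(rng_seed)
        flips = boundary & (rng.random(out.shape) < jitter_prob)
        out = out ^ flips
    return out.astype(np.uint8)


def make_cohort(
    n_cases: int,
    shape=(48, 48, 16),
    tissues=DEFAULT_TISSUES,
    rng_seed: int = 0,
    tumor_radius_range=(4.0, 7.0),
) -> list[PhantomCase]:
    """Generate ``n_cases`` independent phantoms with distinct sub-seeds and ids."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    children = np.random.SeedSequence(rng_seed).spawn(n_cases)
    cohort = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cohort.append(
            make_phantom(
                shape=shape,
                tissues=tissues,
                tumor_radius_range=tumor_radius_range,
                rng_seed=sub_seed,
                case_id=f"case_{i:03d}",
                patient_id=f"pat_{i:03d}",
            )
        )
    return cohort
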
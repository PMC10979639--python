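"""Region dataset construction (core / edema / overall) and augmentation.

``extract_region`` crops each slice to the bounding box of the requested
region mask, pads to square, resizes to the network input size and
min-max normalizes.  ``augment_dataset`` expands a slice list by a
configurable factor using random rotation, translation and linear
contrast jitter; originals are always retained and every variant records
the seed that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .errors import ConfigurationError, DataError, InputError
from .synthetic_mri import CaseRecord

__all__ = [
    "SliceRecord",
    "AugmentationConfig",
    "extract_region",
    "normalize_and_center",
    "augment_dataset",
    "apply_affine",
]

REGIONS = ("core", "edema", "overall")


@dataclass
class SliceRecord:
    """One model-ready 2-D image with its provenance."""

    case_id: str
    class_label: str
    region: str
    image: np.ndarray  # float32 in [0, 1]
    pixel_mean: float = 0.0  # recorded for centering at batch assembly
    provenance: str = "original"
    seed_used: int | None = None
    slice_idx: int = 0


@dataclass(frozen=True)
class AugmentationConfig:
    """Parameters of the random augmentation pipeline."""

    factor: int = 3  # total output multiple: original + (factor-1) variants
    rotation_range: float = 15.0  # degrees, +/-
    translation_range: float = 8.0  # pixels, +/-
    contrast_range: tuple[float, float] = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ConfigurationError("augmentation factor must be >= 1")
        lo, hi = self.contrast_range
        if not 0 < lo <= hi:
            raise ConfigurationError("contrast_range must satisfy 0 < lo <= hi")


def normalize_and_center(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Min-max rescale to [0, 1]; constant images map to all-zeros.

    Returns the rescaled image and its mean (recorded so batches can be
    centered at assembly time without re-scanning the image).
    """
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise InputError("image contains non-finite values")
    lo, hi = image.min(), image.max()
    if hi - lo == 0:
        out = np.zeros_like(image, dtype=np.float32)
        return out, 0.0
    out = ((image - lo) / (hi - lo)).astype(np.float32)
    return out, float(out.mean())


def region_mask(case: CaseRecord, region: str, i: int) -> np.ndarray:
    if region == "core":
        return case.core_masks[i]
    if region == "edema":
        return case.edema_masks[i]
    if region == "overall":
        return case.core_masks[i] | case.edema_masks[i]
    raise ConfigurationError(f"region must be one of {REGIONS}, got {region!r}")


def crop_bbox(mask: np.ndarray, margin: int = 2) -> tuple[int, int, int, int]:
    """(row0, row1, col0, col1) bounding box of a mask, margin-expanded."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    r0 = max(0, rows[0] - margin)
    r1 = min(mask.shape[0], rows[-1] + 1 + margin)
    c0 = max(0, cols[0] - margin)
    c1 = min(mask.shape[1], cols[-1] + 1 + margin)
    return int(r0), int(r1), int(c0), int(c1)


def extract_region(
    case: CaseRecord,
    region: str,
    out_size: int = 128,
    margin: int = 2,
    mask_outside: bool = False,
) -> list[SliceRecord]:
    """Crop every slice of a case to the requested region.

    The crop is the bounding box of the region mask (``overall`` = core
    union edema) expanded by ``margin``, zero-padded to square, resized to
    ``out_size`` and min-max normalized.  With ``mask_outside`` pixels
    outside the region mask are zeroed before cropping.
    """
    records = []
    for i, img in enumerate(case.slices):
        mask = region_mask(case, region, i)
        if not mask.any():
            raise DataError(f"case {case.case_id}: empty {region!r} mask on slice {i}")
        r0, r1, c0, c1 = crop_bbox(mask, margin)
        src = np.where(mask, img, 0.0) if mask_outside else img
        crop = np.asarray(src[r0:r1, c0:c1], dtype=np.float64)
        h, w = crop.shape
        side = max(h, w)
        if (h, w) != (side, side):  # pad to square, centered
            pt = (side - h) // 2
            pl = (side - w) // 2
            crop = np.pad(crop, ((pt, side - h - pt), (pl, side - w - pl)))
        if side != out_size:
            crop = resize(crop, (out_size, out_size), anti_aliasing=side > out_size)
        norm, mean = normalize_and_center(crop)
        records.append(
            SliceRecord(
                case_id=case.case_id,
                class_label=case.class_label,
                region=region,
                image=norm,
                pixel_mean=mean,
                slice_idx=i,
            )
        )
    return records


def apply_affine(image: np.ndarray, angle_deg: float, shift: tuple[float, float]) -> np.ndarray:
    """Rotate about the center then translate; constant zero fill."""
    out = ndimage.rotate(
        image, angle_deg, reshape=False, order=1, mode="constant", cval=0.0
    )
    out = ndimage.shift(out, shift, order=1, mode="constant", cval=0.0)
    return out.astype(np.float32)


def _contrast(image: np.ndarray, factor: float) -> np.ndarray:
    mean = image.mean()
    return np.clip(mean + factor * (image - mean), 0.0, 1.0).astype(np.float32)


def augment_one(record: SliceRecord, cfg: AugmentationConfig, seed: int) -> SliceRecord:
    """One random variant of a slice, reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    angle = rng.uniform(-cfg.rotation_range, cfg.rotation_range)
    shift = rng.uniform(-cfg.translation_range, cfg.translation_range, size=2)
    contrast = rng.uniform(*cfg.contrast_range)
    img = apply_affine(record.image, angle, (shift[0], shift[1]))
    img = _contrast(img, contrast)
    return replace(
        record,
        image=img,
        pixel_mean=float(img.mean()),
        provenance="augmented",
        seed_used=seed,
    )


def augment_dataset(
    slices: list[SliceRecord], cfg: AugmentationConfig
) -> list[SliceRecord]:
    """Expand a slice list to exactly ``cfg.factor`` times its size.

    Originals are kept (provenance ``"original"``); each of the
    ``factor - 1`` variants per slice is generated from a child seed of
    ``cfg.seed``, so identical configs give bitwise-identical output.
    """
    out: list[SliceRecord] = []
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(len(slices))
    for record, child in zip(slices, children):
        out.append(record)
        variant_seeds = child.generate_state(cfg.factor - 1)
        for vseed in variant_seeds:
            out.append(augment_one(record, cfg, int(vseed)))
    return out
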
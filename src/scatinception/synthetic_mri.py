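"""Seeded two-class synthetic lesion-slice generator.

Produces per-case sets of 3 grayscale slices with nested core/edema
masks, emulating the appearance classes of contrast-enhanced brain-tumor
MRI: the GBM-like phenotype is an irregular ring-enhancing lesion with a
dark necrotic center and a broad edema halo, the MET-like phenotype a
round, homogeneously enhancing lesion with an edema halo.  Boundary
irregularity is realized as a radial perturbation by low-order random
harmonics; every case is fully reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

__all__ = [
    "PhenotypeParams",
    "CaseRecord",
    "generate_case",
    "generate_cohort",
    "save_case",
    "load_case",
]

SLICES_PER_CASE = 3
CLASSES = ("GBM", "MET")


@dataclass(frozen=True)
class PhenotypeParams:
    """Appearance parameters of one lesion class."""

    class_label: str
    core_radius_range: tuple[float, float] = (10.0, 16.0)
    rim_intensity: float = 0.9
    center_intensity: float = 0.35
    edema_intensity: float = 0.55
    background_intensity: float = 0.12
    boundary_irregularity: float = 0.25
    edema_halo_ratio: float = 1.8
    noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.class_label not in CLASSES:
            raise ConfigurationError(f"class_label must be one of {CLASSES}")
        lo, hi = self.core_radius_range
        if not 0 < lo <= hi:
            raise ConfigurationError("core_radius_range must satisfy 0 < lo <= hi")
        if self.edema_halo_ratio <= 1.0:
            raise ConfigurationError("edema_halo_ratio must exceed 1")
        if self.boundary_irregularity < 0 or self.noise_sd < 0:
            raise ConfigurationError("irregularity and noise_sd must be >= 0")

    @classmethod
    def default(cls, class_label: str, noise_sd: float = 0.02) -> "PhenotypeParams":
        if class_label == "GBM":
            return cls(
                class_label="GBM",
                core_radius_range=(10.0, 16.0),
                rim_intensity=0.9,
                center_intensity=0.35,
                boundary_irregularity=0.25,
                edema_halo_ratio=1.8,
                noise_sd=noise_sd,
            )
        return cls(
            class_label="MET",
            core_radius_range=(8.0, 14.0),
            rim_intensity=0.82,
            center_intensity=0.8,
            boundary_irregularity=0.02,
            edema_halo_ratio=1.7,
            noise_sd=noise_sd,
        )


@dataclass
class CaseRecord:
    """One synthetic case: 3 slices with per-slice core/edema masks."""

    case_id: str
    class_label: str
    slices: list[np.ndarray]
    core_masks: list[np.ndarray]
    edema_masks: list[np.ndarray]

    def __post_init__(self) -> None:
        if len(self.slices) != SLICES_PER_CASE:
            raise ConfigurationError(
                f"a case holds exactly {SLICES_PER_CASE} slices, got {len(self.slices)}"
            )

    def validate(self) -> None:
        for img, core, edema in zip(self.slices, self.core_masks, self.edema_masks):
            assert img.min() >= 0.0 and img.max() <= 1.0
            assert not np.any(core & edema), "core and edema masks overlap"
            assert core.any() and edema.any(), "empty region mask"


def _radial_boundary(theta: np.ndarray, radius: float, irregularity: float, rng) -> np.ndarray:
    """Radius as a function of angle, perturbed by harmonics k = 2..5."""
    r = np.full_like(theta, radius)
    if irregularity > 0:
        for k in range(2, 6):
            amp = rng.uniform(0.2, 1.0) * irregularity / 4.0
            phase = rng.uniform(0, 2 * np.pi)
            r *= 1.0 + amp * np.cos(k * theta + phase)
    return r


def generate_case(
    params: PhenotypeParams,
    seed: int,
    case_id: str | None = None,
    image_size: int = 128,
) -> CaseRecord:
    """Generate one case (3 slices) reproducibly from ``seed``."""
    lo, hi = params.core_radius_range
    max_extent = hi * params.edema_halo_ratio * (1.0 + params.boundary_irregularity)
    jitter_max = image_size / 8.0
    if max_extent + jitter_max >= image_size / 2.0:
        raise ConfigurationError(
            f"lesion (extent ~{max_extent:.1f}px + jitter) does not fit a "
            f"{image_size}x{image_size} image"
        )
    rng = np.random.default_rng(seed)
    case_radius = rng.uniform(lo, hi)
    gain = rng.uniform(0.9, 1.1)  # per-case intensity variation
    slices, cores, edemas = [], [], []
    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(np.float64)
    for _ in range(SLICES_PER_CASE):
        cy = image_size / 2.0 + rng.uniform(-jitter_max, jitter_max)
        cx = image_size / 2.0 + rng.uniform(-jitter_max, jitter_max)
        radius = case_radius * rng.uniform(0.9, 1.1)
        dy, dx = yy - cy, xx - cx
        r = np.hypot(dy, dx)
        theta = np.arctan2(dy, dx)
        core_b = _radial_boundary(theta, radius, params.boundary_irregularity, rng)
        edema_b = _radial_boundary(
            theta, radius * params.edema_halo_ratio, params.boundary_irregularity / 2.0, rng
        )
        core = r <= core_b
        edema = (r <= np.maximum(edema_b, core_b)) & ~core
        img = np.full((image_size, image_size), params.background_intensity)
        img[edema] = params.edema_intensity
        rim = core & (r >= 0.6 * core_b)
        center = core & ~rim
        img[rim] = params.rim_intensity
        img[center] = params.center_intensity
        img *= gain
        if params.noise_sd > 0:
            img += rng.normal(0.0, params.noise_sd, size=img.shape)
        img = np.clip(img, 0.0, 1.0).astype(np.float32)
        slices.append(img)
        cores.append(core)
        edemas.append(edema)
    if case_id is None:
        case_id = f"{params.class_label}_{seed}"
    return CaseRecord(case_id, params.class_label, slices, cores, edemas)


MANIFEST_COLUMNS = [
    "case_id",
    "class_label",
    "split",
    "slice_idx",
    "slice_path",
    "core_mask_path",
    "edema_mask_path",
]


def _nifti_save(path: Path, arr: np.ndarray) -> None:
    import nibabel as nib

    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), np.eye(4)), str(path))


def save_case(case: CaseRecord, out_dir: Path, png: bool = False) -> list[dict]:
    """Write the case's slices and masks as NIfTI; return manifest rows."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, core, edema) in enumerate(
        zip(case.slices, case.core_masks, case.edema_masks)
    ):
        stem = f"{case.case_id}_s{i}"
        paths = {
            "slice_path": out_dir / f"{stem}.nii.gz",
            "core_mask_path": out_dir / f"{stem}_core.nii.gz",
            "edema_mask_path": out_dir / f"{stem}_edema.nii.gz",
        }
        _nifti_save(paths["slice_path"], img)
        _nifti_save(paths["core_mask_path"], core.astype(np.uint8))
        _nifti_save(paths["edema_mask_path"], edema.astype(np.uint8))
        if png:
            import imageio.v3 as iio

            iio.imwrite(
                out_dir / f"{stem}.png", (img * 255).round().astype(np.uint8)
            )
        rows.append(
            {
                "case_id": case.case_id,
                "class_label": case.class_label,
                "split": "",
                "slice_idx": i,
                **{k: str(v) for k, v in paths.items()},
            }
        )
    return rows


def load_case(manifest: pd.DataFrame, case_id: str) -> CaseRecord:
    """Rebuild a CaseRecord from manifest rows pointing at NIfTI files."""
    import nibabel as nib

    rows = manifest[manifest["case_id"] == case_id].sort_values("slice_idx")
    if rows.empty:
        raise KeyError(f"case {case_id!r} not in manifest")
    slices, cores, edemas = [], [], []
    for _, row in rows.iterrows():
        slices.append(np.asarray(nib.load(row["slice_path"]).get_fdata(), np.float32))
        cores.append(np.asarray(nib.load(row["core_mask_path"]).get_fdata()) > 0.5)
        edemas.append(np.asarray(nib.load(row["edema_mask_path"]).get_fdata()) > 0.5)
    return CaseRecord(case_id, rows.iloc[0]["class_label"], slices, cores, edemas)


def generate_cohort(
    n_gbm: int,
    n_met: int,
    seed: int,
    out_dir: Path | None = None,
    image_size: int = 128,
    noise_sd: float = 0.02,
    gbm_params: PhenotypeParams | None = None,
    met_params: PhenotypeParams | None = None,
    png: bool = False,
    id_prefix: str = "",
) -> tuple[pd.DataFrame, list[CaseRecord]]:
    """Generate a cohort of cases; per-case seeds derive from ``seed``.

    Returns the per-slice manifest (one row per slice, 3 per case) and the
    in-memory case records.  When ``out_dir`` is given, slices and masks
    are additionally written as NIfTI files and the manifest as
    ``manifest.csv``.
    """
    if n_gbm < 0 or n_met < 0:
        raise ConfigurationError("case counts must be >= 0")
    gbm_params = gbm_params or PhenotypeParams.default("GBM", noise_sd=noise_sd)
    met_params = met_params or PhenotypeParams.default("MET", noise_sd=noise_sd)
    specs = [("GBM", gbm_params)] * n_gbm + [("MET", met_params)] * n_met
    children = np.random.SeedSequence(seed).spawn(len(specs))
    cases: list[CaseRecord] = []
    rows: list[dict] = []
    counters = {"GBM": 0, "MET": 0}
    for (label, params), child in zip(specs, children):
        counters[label] += 1
        case_id = f"{id_prefix}{label.lower()}{counters[label]:04d}"
        case_seed = int(child.generate_state(1)[0])
        case = generate_case(params, case_seed, case_id=case_id, image_size=image_size)
        cases.append(case)
        if out_dir is not None:
            rows.extend(save_case(case, Path(out_dir), png=png))
        else:
            rows.extend(
                {
                    "case_id": case_id,
                    "class_label": label,
                    "split": "",
                    "slice_idx": i,
                    "slice_path": "",
                    "core_mask_path": "",
                    "edema_mask_path": "",
                }
                for i in range(SLICES_PER_CASE)
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return manifest, cases
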
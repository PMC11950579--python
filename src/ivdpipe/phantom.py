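"""Synthetic lumbar-spine phantom: volumes, label masks, and Pfirrmann grades.

The phantom emulates a sagittal T2-weighted lumbar acquisition: six
vertebral bodies (L1–S1) modelled as rounded cuboids stacked
cranio-caudally, with five intervertebral discs (L1/2–L5/S1) modelled as
flattened super-ellipsoids in the gaps between them.  Each disc carries a
Pfirrmann grade drawn from a configurable distribution, and the grade
drives morphology the way degeneration does on T2 imaging: higher grades
lose disc height, overall signal intensity, and nucleus–annulus contrast.

Arrays are indexed (slice, row, col), 0-based; rows run cranio-caudally,
columns antero-posteriorly, slices left–right.  World millimetre
coordinates place voxel centres at index x spacing.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "LEVELS",
    "CLASS_MAP",
    "DISC_CLASS_CODES",
    "VERTEBRA_CLASS_CODES",
    "DEFAULT_GRADE_DISTRIBUTION",
    "PhantomSpec",
    "VolumeStack",
    "LabelVolume",
    "GradeRecord",
    "MorphologyParams",
    "grade_morphology",
    "sample_grades",
    "generate_patient",
    "generate_cohort",
    "simulate_ratings",
    "write_slice_pngs",
]

LEVELS = ("L1/2", "L2/3", "L3/4", "L4/5", "L5/S1")
_VERTEBRAE = ("L1", "L2", "L3", "L4", "L5", "S1")

CLASS_MAP: dict[int, str] = {0: "background"}
CLASS_MAP.update({i + 1: name for i, name in enumerate(_VERTEBRAE)})
CLASS_MAP.update({i + 7: f"disc_{lvl}" for i, lvl in enumerate(LEVELS)})

VERTEBRA_CLASS_CODES = tuple(range(1, 7))
DISC_CLASS_CODES = tuple(range(7, 12))

# Cohort shares for grades I–IV with the remainder assigned to grade V.
DEFAULT_GRADE_DISTRIBUTION = (0.15, 0.27, 0.30, 0.20, 0.08)

# Grade -> morphology slopes (per grade step above I), floored at 0.1.
_HEIGHT_SLOPE = 0.12
_INTENSITY_SLOPE = 0.18
_CONTRAST_SLOPE = 0.22


class MorphologyParams(NamedTuple):
    height_factor: float
    intensity_factor: float
    nucleus_contrast: float


def grade_morphology(grade: int) -> MorphologyParams:
    """Map a Pfirrmann grade (1–5) to multiplicative morphology factors.

    Grade I is the identity reference (all factors 1.0); each factor
    decreases strictly with grade, mirroring the loss of disc height,
    T2 signal, and nucleus–annulus distinction as degeneration advances.
    """
    if not isinstance(grade, (int, np.integer)) or isinstance(grade, bool):
        raise ValueError(f"grade must be an integer in 1..5, got {grade!r}")
    if not 1 <= grade <= 5:
        raise ValueError(f"grade must be in 1..5, got {grade}")
    step = grade - 1
    return MorphologyParams(
        height_factor=max(1.0 - _HEIGHT_SLOPE * step, 0.1),
        intensity_factor=max(1.0 - _INTENSITY_SLOPE * step, 0.1),
        nucleus_contrast=max(1.0 - _CONTRAST_SLOPE * step, 0.1),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic cohort; the cohort is a pure function of it."""

    n_patients: int
    slices_per_patient: int = 15
    slice_shape: tuple[int, int] = (192, 192)
    pixel_spacing_mm: tuple[float, float] = (0.68, 0.68)
    slice_spacing_mm: float = 4.4
    grade_distribution: tuple[float, ...] = DEFAULT_GRADE_DISTRIBUTION
    noise_sd: float = 0.03
    noise_model: str = "gaussian"  # or "rician"
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.slices_per_patient < 3:
            raise ValueError("slices_per_patient must be >= 3")
        if any(s < 8 for s in self.slice_shape):
            raise ValueError("slice_shape too small")
        if any(s <= 0 for s in self.pixel_spacing_mm) or self.slice_spacing_mm <= 0:
            raise ValueError("spacings must be strictly positive")
        gd = np.asarray(self.grade_distribution, dtype=float)
        if gd.shape != (5,) or (gd < 0).any() or abs(gd.sum() - 1.0) > 1e-9:
            raise ValueError("grade_distribution must be 5 nonnegative probabilities summing to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError("noise_model must be 'gaussian' or 'rician'")


@dataclass
class VolumeStack:
    """Ordered sagittal intensity slices with physical spacing."""

    patient_id: str
    intensities: np.ndarray  # (slice, row, col), nonnegative
    pixel_spacing_mm: tuple[float, float]
    slice_spacing_mm: float

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D (slice, row, col) array")
        if not np.isfinite(self.intensities).all() or (self.intensities < 0).any():
            raise ValueError("intensities must be finite and nonnegative")

    @property
    def spacing_mm(self) -> tuple[float, float, float]:
        """Voxel spacing in array-axis order (slice, row, col)."""
        return (self.slice_spacing_mm, *self.pixel_spacing_mm)


@dataclass
class LabelVolume:
    """Per-voxel anatomy labels aligned voxel-for-voxel with a VolumeStack."""

    labels: np.ndarray  # (slice, row, col) integers in {0..11}
    class_map: dict[int, str] = field(default_factory=lambda: dict(CLASS_MAP))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-valued")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.class_map)
        if missing:
            raise ValueError(f"labels contain codes absent from class_map: {sorted(missing)}")


@dataclass(frozen=True)
class GradeRecord:
    patient_id: str
    level: str
    grade: int
    rater: str = "truth"

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValueError(f"unknown disc level {self.level!r}")
        if not 1 <= int(self.grade) <= 5:
            raise ValueError(f"grade must be in 1..5, got {self.grade}")


def _patient_rng(spec: PhantomSpec, patient_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed & 0x7FFFFFFF, patient_index, stream])


def sample_grades(spec: PhantomSpec, patient_index: int) -> np.ndarray:
    """Draw the five per-level Pfirrmann grades for one patient (deterministic)."""
    rng = _patient_rng(spec, patient_index, 11)
    return rng.choice(5, size=5, p=np.asarray(spec.grade_distribution)) + 1


def _superellipsoid(dr, dc, ds, ar, ac, as_, pr, pc, ps):
    return (
        np.abs(dr / ar) ** pr + np.abs(dc / ac) ** pc + np.abs(ds / as_) ** ps
    ) <= 1.0


def generate_patient(
    spec: PhantomSpec, patient_index: int
) -> tuple[VolumeStack, LabelVolume, list[GradeRecord]]:
    """Synthesize one patient: intensity volume, label volume, grade records.

    Deterministic given (spec.seed, patient_index).  Disc thickness and
    signal scale with ``grade_morphology`` of the sampled grade, so the
    grade is recoverable from geometry and intensity by construction.
    """
    if patient_index >= spec.n_patients or patient_index < 0:
        raise ValueError("patient_index out of range for spec.n_patients")
    rows, cols = spec.slice_shape
    n_slices = spec.slices_per_patient
    grades = sample_grades(spec, patient_index)
    rng = _patient_rng(spec, patient_index, 7)

    s_ax, r_ax, c_ax = np.ogrid[0:n_slices, 0:rows, 0:cols]
    s_ax = s_ax.astype(float)
    r_ax = r_ax.astype(float)
    c_ax = c_ax.astype(float)

    intens = np.full((n_slices, rows, cols), 0.05)
    labels = np.zeros((n_slices, rows, cols), dtype=np.int16)

    # column layout: vertebrae and discs share one spinal axis down the rows
    margin = 0.06 * rows * (1.0 + rng.uniform(-0.2, 0.2))
    disc_h = 0.055 * rows  # grade-I (reference) full disc height in voxels
    vert_h = (rows - 2 * margin - 5 * disc_h) / 6.0
    c0 = 0.5 * cols + rng.uniform(-0.02, 0.02) * cols
    s0 = (n_slices - 1) / 2.0
    lat_scale = rng.uniform(0.95, 1.05)

    y = margin
    records: list[GradeRecord] = []
    pid = f"P{patient_index:04d}"
    for v in range(6):
        rc = y + vert_h / 2.0
        inside = _superellipsoid(
            r_ax - rc, c_ax - c0, s_ax - s0,
            0.46 * vert_h, 0.30 * cols * lat_scale, max(0.45 * n_slices, 1.5),
            6, 6, 6,
        )
        labels[inside] = v + 1
        intens[inside] = 0.45
        y += vert_h
        if v < 5:
            grade = int(grades[v])
            morph = grade_morphology(grade)
            dc_ = y + disc_h / 2.0
            ar = max(0.5 * disc_h * morph.height_factor, 0.6)
            ac = 0.34 * cols * lat_scale
            as_ = max(0.42 * n_slices, 1.2)
            disc = _superellipsoid(r_ax - dc_, c_ax - c0, s_ax - s0, ar, ac, as_, 2, 4, 4)
            nucleus = _superellipsoid(
                r_ax - dc_, c_ax - c0, s_ax - s0,
                0.6 * ar, 0.55 * ac, 0.55 * as_, 2, 4, 4,
            )
            annulus_val = 0.25 + 0.15 * morph.intensity_factor
            nucleus_val = annulus_val + 0.55 * morph.nucleus_contrast
            labels[disc] = 7 + v
            intens[disc] = annulus_val
            intens[disc & nucleus] = nucleus_val
            records.append(GradeRecord(pid, LEVELS[v], grade))
            y += disc_h

    if spec.noise_sd > 0:
        sd = spec.noise_sd * intens.max()
        if spec.noise_model == "rician":
            # magnitude of a complex signal with iid Gaussian channel noise
            re = intens + rng.normal(0.0, sd, intens.shape)
            im = rng.normal(0.0, sd, intens.shape)
            intens = np.hypot(re, im)
        else:
            intens = intens + rng.normal(0.0, sd, intens.shape)
    intens = np.clip(intens, 0.0, None)

    stack = VolumeStack(pid, intens, spec.pixel_spacing_mm, spec.slice_spacing_mm)
    return stack, LabelVolume(labels), records


def generate_cohort(spec: PhantomSpec, out_dir: str | Path) -> dict:
    """Write a full cohort to disk and return its manifest.

    Per patient: intensity volume and label volume as NIfTI (.nii.gz);
    one grades CSV (patient_id, level, grade, rater) for the whole cohort;
    a JSON manifest listing every artifact.
    """
    import nibabel as nib

    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover
        raise OSError(f"cannot create cohort directory {out}: {exc}") from exc

    rows: list[dict] = []
    patients = []
    for i in range(spec.n_patients):
        stack, labelvol, records = generate_patient(spec, i)
        affine = np.diag([*stack.spacing_mm, 1.0])
        vol_path = out / f"{stack.patient_id}_volume.nii.gz"
        lab_path = out / f"{stack.patient_id}_labels.nii.gz"
        nib.save(nib.Nifti1Image(stack.intensities.astype(np.float32), affine), vol_path)
        nib.save(nib.Nifti1Image(labelvol.labels.astype(np.int16), affine), lab_path)
        patients.append(
            {
                "patient_id": stack.patient_id,
                "volume": vol_path.name,
                "labels": lab_path.name,
                "pixel_spacing_mm": list(spec.pixel_spacing_mm),
                "slice_spacing_mm": spec.slice_spacing_mm,
            }
        )
        rows.extend(
            {"patient_id": r.patient_id, "level": r.level, "grade": r.grade, "rater": r.rater}
            for r in records
        )
    grades = pd.DataFrame(rows, columns=["patient_id", "level", "grade", "rater"])
    grades_path = out / "grades.csv"
    grades.to_csv(grades_path, index=False)
    manifest = {
        "root": str(out),
        "n_patients": spec.n_patients,
        "patients": patients,
        "grades_csv": grades_path.name,
        "seed": spec.seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_slice_pngs(volume: np.ndarray, out_dir: str | Path, prefix: str,
                     is_labels: bool = False) -> list[Path]:
    """Export each sagittal slice as an 8-bit PNG (intensity or label codes)."""
    import imageio.v3 as iio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vol = np.asarray(volume)
    if is_labels:
        # spread the 12 label codes over the gray range for visibility
        img8 = (vol.astype(float) * (255 // max(int(vol.max()), 1))).astype(np.uint8)
    else:
        peak = vol.max() or 1.0
        img8 = np.clip(vol / peak * 255, 0, 255).astype(np.uint8)
    paths = []
    for s in range(vol.shape[0]):
        p = out / f"{prefix}_slice{s:02d}.png"
        iio.imwrite(p, img8[s])
        paths.append(p)
    return paths


def load_patient(manifest: dict, index: int) -> tuple[VolumeStack, LabelVolume]:
    """Read one patient of a written cohort back into memory."""
    import nibabel as nib

    entry = manifest["patients"][index]
    root = Path(manifest["root"])
    vol = np.asarray(nib.load(root / entry["volume"]).dataobj, dtype=float)
    lab = np.asarray(nib.load(root / entry["labels"]).dataobj).astype(np.int16)
    stack = VolumeStack(
        entry["patient_id"], vol, tuple(entry["pixel_spacing_mm"]), entry["slice_spacing_mm"]
    )
    return stack, LabelVolume(lab)


def simulate_ratings(
    records: list[GradeRecord],
    rater_names: tuple[str, ...] = ("rater_A", "rater_B"),
    disagreement_sd: float = 0.45,
    seed: int = 0,
) -> list[GradeRecord]:
    """Simulate human raters as ordinal-noisy readings of the true grade.

    Each rater reports round(truth + N(0, disagreement_sd)) clipped to 1..5,
    which yields the single-grade discrepancies typical of Pfirrmann reads;
    the default noise level places two raters in the moderate-agreement
    band (mean per-level Cohen's kappa near 0.5) seen between surgeons.
    """
    rng = np.random.default_rng(seed)
    out: list[GradeRecord] = []
    for rater in rater_names:
        for rec in records:
            noisy = int(np.clip(np.rint(rec.grade + rng.normal(0.0, disagreement_sd)), 1, 5))
            out.append(GradeRecord(rec.patient_id, rec.level, noisy, rater))
    return out
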
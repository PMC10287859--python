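"""Synthetic DCE-MRI phantom cohorts.

Generates 3-D two-phase ("early"/"peak") volumes with ellipsoidal enhancing
lesions, two noisy reader segmentations, and a recurrence score per subject
(binary risk label at the > 25 cutoff).  Class effects are injected as

* lesion-internal correlated texture whose amplitude and correlation length
  scale with ``texture_effect`` for positive subjects, and
* a multiplicative enhancement of a 4-mm shell just outside the true lesion
  boundary, scaled by ``rim_effect`` for positive subjects.

With both effects at zero the images are statistically independent of the
label, which is what the null-calibration tests rely on.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, EmptyMaskError
from .grids import BinaryMask, Volume

__all__ = [
    "CohortConfig",
    "SyntheticPatient",
    "generate_cohort",
    "simulate_reader_mask",
    "assign_scores",
    "write_cohort",
    "read_cohort",
]

RS_CUTOFF = 25

_BASE_TISSUE = 100.0
_LESION_CONTRAST = 60.0
_TEXTURE_AMPLITUDE = 12.0
_TEXTURE_SIGMA_MM = 1.5
_RIM_SHELL_MM = 4.0
_RIM_GAIN = 0.10
_BACKGROUND_AMPLITUDE = 4.0
_BACKGROUND_SIGMA_MM = 8.0


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort."""

    n_subjects: int = 62
    prevalence: float = 15 / 62
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 2.0)
    lesion_radius_mm: tuple[float, float] = (8.0, 14.0)
    texture_effect: float = 1.0
    rim_effect: float = 1.0
    enhancement_ratio: float = 1.6
    noise_sd: float = 2.0
    reader_perturb_mm: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ConfigurationError(f"n_subjects must be >= 4, got {self.n_subjects}")
        if not (0.0 < self.prevalence < 1.0):
            raise ConfigurationError(f"prevalence must be in (0, 1), got {self.prevalence}")
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise ConfigurationError(f"grid_shape must be 3 axes of >= 8 voxels, got {self.grid_shape}")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ConfigurationError(f"spacing_mm components must be > 0, got {self.spacing_mm}")
        lo, hi = self.lesion_radius_mm
        if not (0 < lo <= hi):
            raise ConfigurationError(f"lesion_radius_mm must satisfy 0 < min <= max, got {self.lesion_radius_mm}")
        if self.texture_effect < 0:
            raise ConfigurationError(f"texture_effect must be >= 0, got {self.texture_effect}")
        if self.rim_effect < 0:
            raise ConfigurationError(f"rim_effect must be >= 0, got {self.rim_effect}")
        if self.enhancement_ratio <= 1.0:
            raise ConfigurationError(f"enhancement_ratio must be > 1, got {self.enhancement_ratio}")
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.reader_perturb_mm < 0:
            raise ConfigurationError(f"reader_perturb_mm must be >= 0, got {self.reader_perturb_mm}")


@dataclass
class SyntheticPatient:
    id: str
    early_volume: Volume
    peak_volume: Volume
    true_mask: BinaryMask
    reader1_mask: BinaryMask
    reader2_mask: BinaryMask
    recurrence_score: int
    label: int

    def __post_init__(self) -> None:
        assert self.label == int(self.recurrence_score > RS_CUTOFF)


def assign_scores(labels, seed: int) -> np.ndarray:
    """Draw recurrence scores consistent with the binary labels.

    Positives get a score uniform on 26–100, negatives on 0–25; the > 25
    cutoff therefore reproduces the labels exactly.
    """
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    rng = np.random.default_rng(seed)
    low = rng.integers(0, RS_CUTOFF + 1, size=labels.shape)
    high = rng.integers(RS_CUTOFF + 1, 101, size=labels.shape)
    return np.where(labels == 1, high, low).astype(int)


def _smooth_field(rng: np.random.Generator, shape, spacing, sigma_mm: float) -> np.ndarray:
    """Unit-variance correlated Gaussian field (smoothed white noise)."""
    field = ndimage.gaussian_filter(
        rng.standard_normal(shape), sigma=[sigma_mm / s for s in spacing]
    )
    sd = field.std()
    return field / sd if sd > 0 else field


def _signed_distance_mm(mask_bool: np.ndarray, spacing) -> np.ndarray:
    """Positive inside the mask, negative outside, in millimetres."""
    inside = ndimage.distance_transform_edt(mask_bool, sampling=spacing)
    outside = ndimage.distance_transform_edt(~mask_bool, sampling=spacing)
    return inside - outside


def simulate_reader_mask(true_mask: BinaryMask, perturb_mm: float, seed: int) -> BinaryMask:
    """Perturb a mask boundary by a smooth random displacement field.

    The signed distance to the boundary is offset by a correlated random
    field scaled to ``perturb_mm``, producing patchy dilations/erosions of
    roughly that physical magnitude.  ``perturb_mm = 0`` returns the input
    unchanged.
    """
    true_mask.require_nonempty("true mask")
    if perturb_mm < 0:
        raise ValueError(f"perturb_mm must be >= 0, got {perturb_mm}")
    if perturb_mm == 0:
        return BinaryMask(values=true_mask.values.copy(), spacing=true_mask.spacing, origin=true_mask.origin)

    rng = np.random.default_rng(seed)
    d = _signed_distance_mm(true_mask.bool(), true_mask.spacing)
    noise = _smooth_field(rng, true_mask.shape, true_mask.spacing, sigma_mm=3.0)
    amplitude = perturb_mm
    for _ in range(6):  # shrink amplitude if the perturbed mask vanishes
        out = (d + amplitude * noise) > 0
        if out.any():
            return BinaryMask(values=out.astype(np.uint8), spacing=true_mask.spacing, origin=true_mask.origin)
        amplitude *= 0.5
    return BinaryMask(values=true_mask.values.copy(), spacing=true_mask.spacing, origin=true_mask.origin)


def _ellipsoid_mask(shape, spacing, center_mm, semiaxes_mm) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    u = ((xx - center_mm[0]) / semiaxes_mm[0]) ** 2
    v = ((yy - center_mm[1]) / semiaxes_mm[1]) ** 2
    w = ((zz - center_mm[2]) / semiaxes_mm[2]) ** 2
    return u + v + w <= 1.0


def _generate_patient(config: CohortConfig, index: int, label: int, score: int,
                      seed_seq: np.random.SeedSequence) -> SyntheticPatient:
    child = seed_seq.spawn(4)
    rng = np.random.default_rng(child[0])
    shape = tuple(int(n) for n in config.grid_shape)
    spacing = tuple(float(s) for s in config.spacing_mm)
    extent = np.array([n * s for n, s in zip(shape, spacing)])

    lo, hi = config.lesion_radius_mm
    semiaxes = rng.uniform(lo, hi, size=3)
    center = extent / 2 + rng.uniform(-2.0, 2.0, size=3)
    mask_bool = _ellipsoid_mask(shape, spacing, center, semiaxes)
    if not mask_bool.any():
        raise EmptyMaskError(f"subject {index}: lesion does not intersect the grid")

    background = _BASE_TISSUE + _BACKGROUND_AMPLITUDE * _smooth_field(
        rng, shape, spacing, _BACKGROUND_SIGMA_MM
    )

    # class-linked internal texture: amplitude and correlation length grow
    # with texture_effect for positive subjects
    tex_amp = _TEXTURE_AMPLITUDE * (1.0 + config.texture_effect * label)
    tex_sigma = _TEXTURE_SIGMA_MM * (1.0 + 0.5 * config.texture_effect * label)
    texture = tex_amp * _smooth_field(rng, shape, spacing, tex_sigma)

    lesion = np.zeros(shape)
    lesion[mask_bool] = _LESION_CONTRAST + texture[mask_bool]

    # class-linked rim: multiplicative gain in a 4-mm shell outside the lesion
    dist_out = ndimage.distance_transform_edt(~mask_bool, sampling=spacing)
    shell = (dist_out > 0) & (dist_out <= _RIM_SHELL_MM)
    rim_gain = np.ones(shape)
    rim_gain[shell] = 1.0 + _RIM_GAIN * config.rim_effect * label

    early = (background + lesion) * rim_gain
    peak = (background + lesion * config.enhancement_ratio) * rim_gain
    if config.noise_sd > 0:
        early = early + config.noise_sd * rng.standard_normal(shape)
        peak = peak + config.noise_sd * rng.standard_normal(shape)

    true_mask = BinaryMask(values=mask_bool.astype(np.uint8), spacing=spacing)
    r1 = simulate_reader_mask(true_mask, config.reader_perturb_mm, child[1].generate_state(1)[0])
    r2 = simulate_reader_mask(true_mask, config.reader_perturb_mm, child[2].generate_state(1)[0])

    return SyntheticPatient(
        id=f"sub-{index:03d}",
        early_volume=Volume(values=early, spacing=spacing),
        peak_volume=Volume(values=peak, spacing=spacing),
        true_mask=true_mask,
        reader1_mask=r1,
        reader2_mask=r2,
        recurrence_score=int(score),
        label=int(label),
    )


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Generate a deterministic cohort with exactly
    ``round(n_subjects * prevalence)`` positive subjects."""
    config.validate()
    n = config.n_subjects
    n_pos = int(round(n * config.prevalence))
    master = np.random.SeedSequence(config.seed)
    rng = np.random.default_rng(master.spawn(1)[0])

    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_pos]] = 1
    scores = assign_scores(labels, seed=int(master.generate_state(1)[0]))

    subject_seeds = master.spawn(n)
    return [
        _generate_patient(config, i, int(labels[i]), int(scores[i]), subject_seeds[i])
        for i in range(n)
    ]


def read_cohort(indir: str, score_cutoff: int = RS_CUTOFF) -> list[SyntheticPatient]:
    """Load a cohort from per-subject NIfTI directories and a labels CSV.

    Expects the layout produced by :func:`write_cohort`: ``cohort.csv`` with
    columns ``id`` plus ``recurrence_score`` and/or ``label``, and per
    subject ``early.nii``, ``peak.nii``, ``mask_reader1.nii``,
    ``mask_reader2.nii`` (an optional ``mask_true.nii`` falls back to
    reader 1).
    """
    from .grids import read_mask, read_volume

    csv_path = os.path.join(indir, "cohort.csv")
    if not os.path.exists(csv_path):
        raise FileNotFoundError(f"labels CSV not found: {csv_path}")
    cohort: list[SyntheticPatient] = []
    with open(csv_path, newline="") as fh:
        for row in csv.DictReader(fh):
            sub = os.path.join(indir, row["id"])
            if "recurrence_score" in row and row["recurrence_score"] != "":
                score = int(row["recurrence_score"])
                label = int(score > score_cutoff)
            elif "label" in row and row["label"] != "":
                label = int(row["label"])
                score = score_cutoff + 1 if label else score_cutoff
            else:
                raise ValueError(f"subject {row['id']}: no recurrence_score or label column")
            true_path = os.path.join(sub, "mask_true.nii")
            r1 = read_mask(os.path.join(sub, "mask_reader1.nii"))
            cohort.append(SyntheticPatient(
                id=row["id"],
                early_volume=read_volume(os.path.join(sub, "early.nii")),
                peak_volume=read_volume(os.path.join(sub, "peak.nii")),
                true_mask=read_mask(true_path) if os.path.exists(true_path) else r1,
                reader1_mask=r1,
                reader2_mask=read_mask(os.path.join(sub, "mask_reader2.nii")),
                recurrence_score=score,
                label=label,
            ))
    if not cohort:
        raise ValueError(f"no subjects listed in {csv_path}")
    return cohort


def write_cohort(cohort: list[SyntheticPatient], outdir: str) -> str:
    """Write per-subject NIfTI volumes/masks and a cohort CSV; returns the
    CSV path."""
    os.makedirs(outdir, exist_ok=True)
    csv_path = os.path.join(outdir, "cohort.csv")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "recurrence_score", "label"])
        for pat in cohort:
            sub = os.path.join(outdir, pat.id)
            os.makedirs(sub, exist_ok=True)
            pat.early_volume.to_nifti(os.path.join(sub, "early.nii"))
            pat.peak_volume.to_nifti(os.path.join(sub, "peak.nii"))
            pat.reader1_mask.to_nifti(os.path.join(sub, "mask_reader1.nii"))
            pat.reader2_mask.to_nifti(os.path.join(sub, "mask_reader2.nii"))
            pat.true_mask.to_nifti(os.path.join(sub, "mask_true.nii"))
            writer.writerow([pat.id, pat.recurrence_score, pat.label])
    return csv_path
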
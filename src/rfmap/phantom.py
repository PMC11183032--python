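"""Seeded phantom cohorts: paired pseudo-CT/PET lesion patches.

Each subject is an elliptical lesion on a smooth background, rendered in two
modalities sharing geometry.  The class label (PM vs NM) is written into
*texture*, not intensity:

* within-lesion texture is Gaussian-filtered noise whose correlation length
  differs by class (PM lesions are rougher); the texture field is demeaned
  and variance-normalized inside the lesion, so the two classes have equal
  mean and equal marginal variance there by construction;
* PM lesions additionally carry a graded peri-lesional "infiltration" band —
  an alpha-blend of lesion intensity into the surroundings at the mask
  boundary — while NM margins stay sharp;
* the pseudo-PET channel adds uptake with class-dependent heterogeneity and
  a resolution blur.

Because mean intensity carries no label information, a grayscale-only
classifier must exploit texture, which is exactly what the radiomic feature
map channels make explicit for the boosted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["PhantomConfig", "PhantomSubject", "PhantomCohort", "generate_cohort"]


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions of the synthetic cohort (defaults are fixed)."""

    n_per_class: int = 25
    image_size: int = 64
    axis_range: tuple[float, float] = (8.0, 13.0)
    lesion_mean: float = 0.6
    background_mean: float = 0.25
    lesion_mean_jitter: float = 0.1
    background_jitter: float = 0.05
    texture_amp: float = 0.18
    corr_len_nm: float = 2.0
    corr_len_pm: float = 0.8
    band_px_nm: float = 0.0
    band_px_pm: float = 3.0
    pet_uptake_mean: float = 2.0
    pet_heterogeneity_nm: float = 0.25
    pet_heterogeneity_pm: float = 0.55
    pet_blur: float = 1.0
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        for name in ("texture_amp", "noise_sd", "pet_heterogeneity_nm",
                     "pet_heterogeneity_pm", "band_px_nm", "band_px_pm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PhantomSubject:
    subject_id: str
    ct: np.ndarray
    pet: np.ndarray
    mask: np.ndarray
    label: str  # "PM" or "NM"

    @property
    def y(self) -> int:
        return 1 if self.label == "PM" else 0


@dataclass
class PhantomCohort:
    subjects: list[PhantomSubject]
    config: PhantomConfig

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.y for s in self.subjects])

    def manifest(self) -> pd.DataFrame:
        return pd.DataFrame({
            "subject_id": [s.subject_id for s in self.subjects],
            "image_path": [f"{s.subject_id}_ct.npy" for s in self.subjects],
            "mask_path": [f"{s.subject_id}_mask.npy" for s in self.subjects],
            "modality": "CT",
            "label": [s.label for s in self.subjects],
        })

    def write(self, out_dir: str | Path) -> Path:
        """Write images, masks and the manifest CSV the patch reader consumes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for s in self.subjects:
            np.save(out / f"{s.subject_id}_ct.npy", s.ct)
            np.save(out / f"{s.subject_id}_pet.npy", s.pet)
            np.save(out / f"{s.subject_id}_mask.npy", s.mask.astype(np.uint8))
            for modality in ("CT", "PET"):
                rows.append({
                    "subject_id": s.subject_id,
                    "image_path": str(out / f"{s.subject_id}_{modality.lower()}.npy"),
                    "mask_path": str(out / f"{s.subject_id}_mask.npy"),
                    "modality": modality,
                    "label": s.label,
                })
        manifest = out / "manifest.csv"
        pd.DataFrame(rows).to_csv(manifest, index=False)
        return manifest


def _ellipse_mask(size: int, a: float, b: float, theta: float,
                  center: tuple[float, float]) -> np.ndarray:
    r, c = np.mgrid[:size, :size].astype(float)
    dr, dc = r - center[0], c - center[1]
    u = dr * np.cos(theta) + dc * np.sin(theta)
    v = -dr * np.sin(theta) + dc * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _correlated_noise(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise, normalized to unit marginal variance."""
    field_ = ndimage.gaussian_filter(rng.standard_normal((size, size)), sigma)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _render_subject(rng: np.random.Generator, cfg: PhantomConfig, label: str,
                    subject_id: str) -> PhantomSubject:
    size = cfg.image_size
    a = rng.uniform(*cfg.axis_range)
    b = rng.uniform(*cfg.axis_range)
    theta = rng.uniform(0, np.pi)
    center = (size / 2 + rng.uniform(-3, 3), size / 2 + rng.uniform(-3, 3))
    mask = _ellipse_mask(size, a, b, theta, center)

    corr_len = cfg.corr_len_pm if label == "PM" else cfg.corr_len_nm
    band = cfg.band_px_pm if label == "PM" else cfg.band_px_nm
    het = cfg.pet_heterogeneity_pm if label == "PM" else cfg.pet_heterogeneity_nm

    # per-subject acquisition-style nuisance: contrast and background jitter,
    # independent of the class label so intensity stays uninformative
    lesion_mean = cfg.lesion_mean + rng.uniform(-1, 1) * cfg.lesion_mean_jitter
    background_mean = cfg.background_mean + rng.uniform(-1, 1) * cfg.background_jitter

    # background: smooth low-amplitude structure
    ct = background_mean + 0.04 * _correlated_noise(rng, size, 6.0)

    # lesion body with class-coded texture; demeaned + unit-variance inside
    tex = _correlated_noise(rng, size, corr_len)
    inside = tex[mask]
    tex = (tex - inside.mean()) / (inside.std() if inside.std() > 0 else 1.0)
    lesion_img = lesion_mean + cfg.texture_amp * tex

    if band > 0:
        # graded alpha-blend of lesion intensity into a peri-lesional band
        dist_out = ndimage.distance_transform_edt(~mask)
        alpha = np.clip(1.0 - dist_out / band, 0.0, 1.0)
    else:
        alpha = mask.astype(float)
    ct = ct * (1 - alpha) + lesion_img * alpha

    # pseudo-PET: shared geometry, uptake heterogeneity, resolution blur
    pet = 0.2 + 0.05 * _correlated_noise(rng, size, 6.0)
    pet_tex = _correlated_noise(rng, size, 1.2)
    pet_inside = pet_tex[mask]
    pet_tex = (pet_tex - pet_inside.mean()) / (pet_inside.std() or 1.0)
    uptake = cfg.pet_uptake_mean + het * pet_tex
    pet = pet * (1 - alpha) + uptake * alpha
    pet = ndimage.gaussian_filter(pet, cfg.pet_blur)

    ct = ct + rng.normal(0, cfg.noise_sd, ct.shape)
    pet = pet + rng.normal(0, cfg.noise_sd, pet.shape)
    return PhantomSubject(subject_id, ct, pet, mask, label)


def generate_cohort(cfg: PhantomConfig | None = None) -> PhantomCohort:
    """Generate a balanced, seeded PM/NM cohort.

    Identical seed + config reproduce the cohort bit for bit.  Subjects are
    emitted in interleaved label order (NM, PM, NM, ...) so any prefix is
    close to balanced.
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    subjects = []
    for i in range(cfg.n_per_class):
        for label in ("NM", "PM"):
            sid = f"s{2 * i + (label == 'PM'):03d}_{label.lower()}"
            subjects.append(_render_subject(rng, cfg, label, sid))
    return PhantomCohort(subjects, cfg)
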
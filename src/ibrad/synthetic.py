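"""Synthetic two-scanner cohort generator with an outcome-linked texture effect.

Each patient is an ellipsoidal "tumour" on a dark background. The tumour
interior carries a smoothed Gaussian random field whose correlation length
is governed by a per-patient latent heterogeneity parameter ``h``:
responders draw ``h ~ N(-effect_size, 1)``, non-responders ``h ~ N(0, 1)``,
so ``effect_size`` is the class separation of the latent parameter in SD
units and the binormal equal-variance AUC of ``h`` itself is
``Phi(effect_size / sqrt(2))``. Low ``h`` means finer texture (shorter
correlation length), which run-length, fractal and histogram features all
respond to — the planted signal is therefore recoverable through several
feature families, as in real heterogeneity imaging.

The two cohort configurations emulate two acquisitions that differ in
in-plane resolution (0.703 vs 0.45 mm), slice thickness (3 vs 3.5 mm),
global intensity scale/offset and noise level, with pCR prevalences of 0.22
and 0.25. The scanner transform is ``gain * (signal + noise) + offset``, so
two patients generated from the same random stream under different
gain/offset are related by the exact affine map — the invariance the IB
filter is supposed to neutralise.

Every generated patient records its generating truth (``h``, axes, class),
which downstream recovery studies use as ground truth.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .imaging import ROIMask, ScanImage, write_nifti


@dataclass
class CohortConfig:
    """Generating conditions for one scanner cohort."""

    n_patients: int = 136
    prevalence: float = 0.22
    inplane_spacing_mm: float = 0.703
    slice_thickness_mm: float = 3.0
    image_size: tuple[int, int, int] = (96, 96, 10)  # rows, cols, slices
    gain: float = 1.0
    offset: float = 0.0
    noise_sd: float = 5.0
    effect_size: float = 1.19  # latent separation; Phi(1.19/sqrt 2) ~ 0.80
    seed: int = 0
    cohort: str = "1.5T"
    tumour_axes_mm: tuple[float, float] = (10.0, 25.0)  # full axis length range
    base_intensity: float = 200.0
    background: float = 40.0
    texture_amplitude: float = 25.0
    corr_length_px: float = 1.2  # correlation length at h = 0
    corr_length_slope: float = 0.35  # ell = corr_length_px * exp(slope * h)

    def __post_init__(self) -> None:
        if self.n_patients < 4:
            raise ValueError("n_patients must be >= 4")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if round(self.prevalence * self.n_patients) < 1:
            raise ValueError("expected at least one event (prevalence * n >= 1)")
        if self.noise_sd < 0 or self.gain <= 0 or self.effect_size < 0:
            raise ValueError("invalid gain/noise/effect configuration")


@dataclass
class SyntheticPatient:
    image: ScanImage
    mask: ROIMask
    outcome: int
    truth: dict = field(default_factory=dict)


def theoretical_auc(effect_size: float) -> float:
    """Binormal equal-variance AUC of the latent parameter: Phi(d / sqrt 2)."""
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    return float(norm.cdf(effect_size / np.sqrt(2.0)))


def generate_patient(
    config: CohortConfig,
    rng: np.random.Generator,
    outcome: int | None = None,
    patient_id: str = "P000",
) -> SyntheticPatient:
    """One synthetic patient: image + ellipsoidal mask + outcome + truth.

    All randomness is drawn from ``rng`` in a fixed order, so the same
    generator state reproduces the patient bit-for-bit, and two configs
    differing only in gain/offset yield exactly affine-related images.
    """
    rows, cols, slices = config.image_size
    shape = (slices, rows, cols)
    sp = config.inplane_spacing_mm

    outcome_drawn = int(rng.random() < config.prevalence)
    if outcome is None:
        outcome = outcome_drawn
    h = rng.normal(-config.effect_size if outcome == 1 else 0.0, 1.0)

    # ellipsoid semi-axes (mm): full axes drawn in the configured range
    lo, hi = config.tumour_axes_mm
    semi_r = rng.uniform(lo, hi) / 2.0
    semi_c = rng.uniform(lo, hi) / 2.0
    semi_s = rng.uniform(lo, hi) / 2.0
    max_semi_s = max(config.slice_thickness_mm * 0.6, (slices - 1) * config.slice_thickness_mm / 2.0)
    semi_s = min(semi_s, max_semi_s)
    max_inplane = (min(rows, cols) / 2.0 - 2.0) * sp
    semi_r, semi_c = min(semi_r, max_inplane), min(semi_c, max_inplane)

    jitter = rng.uniform(-0.05, 0.05, size=2)
    centre = (
        (slices - 1) / 2.0,
        (rows - 1) / 2.0 + jitter[0] * rows,
        (cols - 1) / 2.0 + jitter[1] * cols,
    )
    zz = np.arange(slices, dtype=np.float64)[:, None, None]
    rr = np.arange(rows, dtype=np.float64)[None, :, None]
    cc = np.arange(cols, dtype=np.float64)[None, None, :]
    dist = (
        ((zz - centre[0]) * config.slice_thickness_mm / semi_s) ** 2
        + ((rr - centre[1]) * sp / semi_r) ** 2
        + ((cc - centre[2]) * sp / semi_c) ** 2
    )
    mask = dist <= 1.0
    if not mask.any():  # pathological config (tiny grid): keep the centre voxel
        mask[tuple(int(round(c)) for c in centre)] = True

    ell = config.corr_length_px * np.exp(config.corr_length_slope * h)
    white = rng.standard_normal(shape)
    field3d = gaussian_filter(white, sigma=(0.5, ell, ell))
    inside = field3d[mask]
    sd = inside.std()
    if sd > 0:
        field3d = (field3d - inside.mean()) / sd
    texture = config.texture_amplitude * field3d

    base = np.full(shape, config.background, dtype=np.float64)
    base[mask] = config.base_intensity + texture[mask]
    noise = rng.normal(0.0, config.noise_sd, size=shape) if config.noise_sd > 0 else 0.0
    voxels = config.gain * (base + noise) + config.offset

    spacing = (sp, sp, config.slice_thickness_mm)
    return SyntheticPatient(
        image=ScanImage(voxels, spacing, patient_id=patient_id, cohort=config.cohort),
        mask=ROIMask(mask, spacing),
        outcome=int(outcome),
        truth={
            "h": float(h),
            "corr_length_px": float(ell),
            "semi_axes_mm": (float(semi_r), float(semi_c), float(semi_s)),
            "outcome": int(outcome),
        },
    )


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """A full cohort with exactly ``round(prevalence * n)`` responders.

    Outcome labels are assigned deterministically in count and shuffled by
    the cohort seed; each patient then draws from an independently spawned
    substream, so cohorts are reproducible patient-by-patient.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients + 1)
    label_rng = np.random.default_rng(children[0])
    n_pos = int(round(config.prevalence * config.n_patients))
    outcomes = np.zeros(config.n_patients, dtype=int)
    outcomes[:n_pos] = 1
    label_rng.shuffle(outcomes)
    patients = []
    for i, sub in enumerate(children[1:]):
        rng = np.random.default_rng(sub)
        pid = f"{config.cohort}_{i:04d}"
        patients.append(generate_patient(config, rng, outcome=int(outcomes[i]), patient_id=pid))
    return patients


def cohort_manifest(patients: list[SyntheticPatient]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": p.image.patient_id,
            "cohort": p.image.cohort,
            "outcome": p.outcome,
            "h": p.truth["h"],
        }
        for p in patients
    ]
    return pd.DataFrame(rows)


def generate_two_cohorts(
    config_a: CohortConfig, config_b: CohortConfig, out_dir: str | os.PathLike
) -> str:
    """Write both cohorts as NIfTI image/mask pairs plus a manifest CSV.

    Returns the manifest path. The manifest carries patient id, cohort,
    outcome, file paths and the generating truth ``h``.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    records = []
    for config in (config_a, config_b):
        for p in generate_cohort(config):
            img_path = os.path.join(out_dir, f"{p.image.patient_id}_img.nii")
            msk_path = os.path.join(out_dir, f"{p.image.patient_id}_msk.nii")
            write_nifti(img_path, p.image)
            write_nifti(
                msk_path,
                ScanImage(p.mask.voxels.astype(np.float64), p.mask.spacing, p.image.patient_id, p.image.cohort),
            )
            records.append(
                {
                    "patient_id": p.image.patient_id,
                    "cohort": p.image.cohort,
                    "outcome": p.outcome,
                    "image": img_path,
                    "mask": msk_path,
                    "h": p.truth["h"],
                }
            )
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest


def default_cohort_configs(
    seed: int = 0,
    effect_size: float = 1.19,
    n_a: int = 136,
    n_b: int = 59,
    reduced: bool = False,
) -> tuple[CohortConfig, CohortConfig]:
    """The paired study conditions: a 1.5 T-like and a 3 T-like cohort.

    ``reduced=True`` shrinks the image grids and tumour axes (not the
    statistical conditions) for desk-scale runs.
    """
    ss = np.random.SeedSequence(seed)
    seed_a, seed_b = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(2)]
    size_a = (64, 64, 6) if reduced else (96, 96, 10)
    size_b = (104, 104, 6) if reduced else (150, 150, 10)
    axes = (8.0, 18.0) if reduced else (10.0, 25.0)
    cfg_a = CohortConfig(
        n_patients=n_a, prevalence=0.22, inplane_spacing_mm=0.703, slice_thickness_mm=3.0,
        image_size=size_a, gain=1.0, offset=0.0, noise_sd=5.0, effect_size=effect_size,
        seed=seed_a, cohort="1.5T", tumour_axes_mm=axes,
    )
    cfg_b = CohortConfig(
        n_patients=n_b, prevalence=0.25, inplane_spacing_mm=0.45, slice_thickness_mm=3.5,
        image_size=size_b, gain=1.8, offset=300.0, noise_sd=8.0, effect_size=effect_size,
        seed=seed_b, cohort="3T", tumour_axes_mm=axes,
    )
    return cfg_a, cfg_b


def with_scanner_transform(config: CohortConfig, gain: float, offset: float) -> CohortConfig:
    """Same cohort, different scanner transform (for invariance experiments)."""
    return replace(config, gain=gain, offset=offset)
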
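"""Desk-scale thoracic phantoms with linked discrete-time survival outcomes.

A phantom is a body ellipsoid in air with two lung ellipsoids and an optional
spherical lesion whose size and axial depth drive a constant per-month hazard
through a logistic link. Censoring is independent and uniform over the
24-month horizon. Everything is reproducible from a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .imaging_io import CTVolume, LungMask
from .survival_head import T_MAX, SurvivalRecord

__all__ = [
    "PhantomConfig",
    "HazardModelConfig",
    "PatientTruth",
    "CohortPatient",
    "CohortDataset",
    "generate_phantom",
    "constant_hazard",
    "sample_survival_record",
    "generate_cohort",
    "true_risk_ctd",
]


@dataclass(frozen=True)
class PhantomConfig:
    grid: tuple[int, int, int] = (48, 48, 40)  # (nx, ny, nz)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.0)
    body_hu: float = 40.0
    lung_hu: float = -800.0
    air_hu: float = -1000.0
    lesion_hu: float = -740.0  # lung + 60 HU so threshold segmentation keeps it
    lung_height_frac: float = 0.38  # lung semi-axis along z, as fraction of nz
    lesion_radius_mm: float = 6.0
    lesion_elongation: float = 1.0  # in-plane aspect ratio (spiculation proxy)
    lesion_relative_depth: float = 0.5
    lesion_present: bool = True
    clutter_blobs: int = 0          # lesion-like blobs independent of outcome
    clutter_radius_mm: float = 3.5  # (anatomical clutter / benign nodules)
    clutter_zone: str = "apical"    # "apical" band or "full" lung extent
    apical_noise_sigma: float = 0.0    # optional streak-artifact texture in the apical band
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.air_hu < self.lung_hu < self.body_hu:
            raise ValueError("intensity ordering must be air < lung < body")
        if any(g < 32 for g in self.grid):
            raise ValueError(f"grid must be at least 32 per axis, got {self.grid}")
        if not 0.0 <= self.lesion_relative_depth <= 1.0:
            raise ValueError("lesion_relative_depth must be in [0, 1]")
        if self.lesion_radius_mm <= 0:
            raise ValueError("lesion radius must be positive")


@dataclass(frozen=True)
class HazardModelConfig:
    beta0: float = -3.8        # baseline log-odds of dying in a given month
    beta_size: float = 1.1     # per cm^3 of lesion volume
    beta_depth: float = 1.0    # per unit relative depth (1 = lung base)
    beta_shape: float = 0.0    # per unit of in-plane elongation above 1
    censor_rate: float = 0.3
    t_max: int = T_MAX
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        for b in (self.beta0, self.beta_size, self.beta_depth, self.beta_shape):
            if not np.isfinite(b):
                raise ValueError("hazard coefficients must be finite")


@dataclass(frozen=True)
class PatientTruth:
    lesion_present: bool
    lesion_radius_mm: float
    lesion_volume_cm3: float
    lesion_depth: float
    lesion_elongation: float
    hazard: float


@dataclass(frozen=True)
class CohortPatient:
    patient_id: str
    phantom: PhantomConfig
    record: SurvivalRecord
    truth: PatientTruth

    def volume(self) -> tuple[CTVolume, LungMask, set[int]]:
        return generate_phantom(self.phantom, patient_id=self.patient_id)


@dataclass(frozen=True)
class CohortDataset:
    patients: tuple[CohortPatient, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.patients)

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": [p.patient_id for p in self.patients],
            "time_months": [p.record.s for p in self.patients],
            "event": [p.record.k for p in self.patients],
        })

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "patient_id": [p.patient_id for p in self.patients],
            "lesion_present": [p.truth.lesion_present for p in self.patients],
            "lesion_radius_mm": [p.truth.lesion_radius_mm for p in self.patients],
            "lesion_volume_cm3": [p.truth.lesion_volume_cm3 for p in self.patients],
            "lesion_depth": [p.truth.lesion_depth for p in self.patients],
            "lesion_elongation": [p.truth.lesion_elongation for p in self.patients],
            "hazard": [p.truth.hazard for p in self.patients],
        })


def _ellipsoid(shape_zyx, center_zyx, semi_zyx) -> np.ndarray:
    nz, ny, nx = shape_zyx
    z, y, x = np.ogrid[:nz, :ny, :nx]
    cz, cy, cx = center_zyx
    az, ay, ax = semi_zyx
    return ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0


def generate_phantom(cfg: PhantomConfig, patient_id: str = "phantom"
                     ) -> tuple[CTVolume, LungMask, set[int]]:
    """Build the phantom; returns (volume, ground-truth lung mask, set of axial
    slice indices intersecting the lesion)."""
    nx, ny, nz = cfg.grid
    shape = (nz, ny, nx)
    vox = np.full(shape, cfg.air_hu, dtype=np.float64)

    body = _ellipsoid(shape, (nz / 2 - 0.5, ny / 2 - 0.5, nx / 2 - 0.5),
                      (max(0.52, cfg.lung_height_frac + 0.14) * nz, 0.44 * ny, 0.46 * nx))
    vox[body] = cfg.body_hu

    lung_semi = (cfg.lung_height_frac * nz, 0.30 * ny, 0.16 * nx)
    centers = [(nz / 2 - 0.5, ny / 2 - 0.5, nx / 2 - 0.5 - 0.22 * nx),
               (nz / 2 - 0.5, ny / 2 - 0.5, nx / 2 - 0.5 + 0.22 * nx)]
    lungs = np.zeros(shape, dtype=bool)
    for c in centers:
        lungs |= _ellipsoid(shape, c, lung_semi)
    vox[lungs] = cfg.lung_hu

    lesion_slices: set[int] = set()
    if cfg.lesion_present:
        sx, sy, sz = cfg.spacing
        # the lesion center runs along the left lung's axis from apex (0) to
        # base (1); the sphere is clipped to lung tissue (pleural lesions)
        lung_z = np.nonzero(lungs.any(axis=(1, 2)))[0]
        z0, z1 = lung_z[0], lung_z[-1]
        cz = z0 + cfg.lesion_relative_depth * (z1 - z0)
        cy = ny / 2 - 0.5
        cx = centers[0][2]
        e = math.sqrt(cfg.lesion_elongation)
        rz = cfg.lesion_radius_mm / sz
        ry = cfg.lesion_radius_mm * e / sy
        rx = cfg.lesion_radius_mm / e / sx
        lesion = _ellipsoid(shape, (cz, cy, cx), (rz, ry, rx)) & lungs
        if not lesion.any() or not lungs[
            min(int(round(cz)), nz - 1), int(round(cy)), int(round(cx))
        ]:
            raise ValueError("lesion center lies outside the lungs; shrink it or move it")
        vox[lesion] = cfg.lesion_hu
        lesion_slices = set(np.nonzero(lesion.any(axis=(1, 2)))[0].tolist())

    rng = np.random.default_rng(cfg.seed)
    if cfg.clutter_blobs > 0:
        # satellite nodules: lesion-like blobs scattered through both lungs
        # that carry no outcome information. They confound any readout that
        # sums lesion-like content over the volume; only the largest (primary)
        # lesion drives the hazard.
        lung_z = np.nonzero(lungs.any(axis=(1, 2)))[0]
        z0, z1 = lung_z[0], lung_z[-1]
        z_hi = z0 + max(1, int(0.3 * (z1 - z0))) if cfg.clutter_zone == "apical" else z1 - 1
        sx, sy, sz = cfg.spacing
        for _ in range(int(rng.integers(1, cfg.clutter_blobs + 1))):
            r = cfg.clutter_radius_mm * rng.uniform(0.5, 1.1)
            cz = rng.uniform(z0 + 1, z_hi)
            c = centers[int(rng.integers(0, 2))]
            cy = c[1] + rng.uniform(-0.3, 0.3) * lung_semi[1]
            cx = c[2] + rng.uniform(-0.3, 0.3) * lung_semi[2]
            blob = _ellipsoid(shape, (cz, cy, cx), (r / sz, r / sy, r / sx)) & lungs
            vox[blob] = cfg.lesion_hu

    if cfg.apical_noise_sigma > 0:
        # streak-artifact-like texture over the apical band, with a random
        # per-phantom amplitude; carries no outcome information
        lung_z = np.nonzero(lungs.any(axis=(1, 2)))[0]
        z0, z1 = lung_z[0], lung_z[-1]
        hi = z0 + max(1, int(0.3 * (z1 - z0)))
        amp = cfg.apical_noise_sigma * rng.uniform(0.5, 1.5)
        vox[z0:hi] += rng.normal(0.0, amp, size=vox[z0:hi].shape)

    if cfg.noise_sigma > 0:
        vox = vox + rng.normal(0.0, cfg.noise_sigma, size=shape)

    return (
        CTVolume(vox, cfg.spacing, patient_id=patient_id),
        LungMask(lungs.astype(np.uint8)),
        lesion_slices,
    )


def constant_hazard(truth_volume_cm3: float, depth: float, hz: HazardModelConfig,
                    elongation: float = 1.0) -> float:
    logit = (hz.beta0 + hz.beta_size * truth_volume_cm3 + hz.beta_depth * depth
             + hz.beta_shape * (elongation - 1.0))
    return float(1.0 / (1.0 + math.exp(-logit)))


def sample_survival_record(h, censor_rate: float, t_max: int,
                           rng: np.random.Generator) -> SurvivalRecord:
    """First-hitting-time draw over monthly Bernoulli trials, with independent
    uniform censoring applied with probability ``censor_rate``. When neither
    fires by t_max the record is censored at t_max."""
    h = np.broadcast_to(np.asarray(h, dtype=float), (t_max,))
    if np.any((h < 0) | (h > 1)):
        raise ValueError("hazards must be probabilities")
    hits = rng.random(t_max) < h
    event_month = int(np.argmax(hits)) + 1 if hits.any() else None
    censor_month = None
    if rng.random() < censor_rate:
        censor_month = int(rng.integers(1, t_max + 1))
    if event_month is not None and (censor_month is None or event_month <= censor_month):
        return SurvivalRecord(s=event_month, k=1)
    if censor_month is not None and (event_month is None or censor_month < event_month):
        return SurvivalRecord(s=censor_month, k=0)
    return SurvivalRecord(s=t_max, k=0)


def generate_cohort(n: int, phantom_template: PhantomConfig | None = None,
                    hz: HazardModelConfig | None = None,
                    rng: np.random.Generator | int | None = None,
                    *, lesion_probability: float = 0.85,
                    radius_range_mm: tuple[float, float] = (4.0, 9.0),
                    depth_beta: tuple[float, float] = (3.5, 1.3),
                    elongation_range: tuple[float, float] = (1.0, 1.0),
                    lung_height_range: tuple[float, float] = (0.38, 0.38)) -> CohortDataset:
    """Sample a cohort of phantoms with randomized lesion presence, size and
    depth, and survival records driven by the logistic hazard model.

    ``depth_beta`` are Beta-distribution parameters for the lesion's relative
    depth (the default skews lesions toward the lung base).
    """
    if n < 2:
        raise ValueError("need at least 2 patients")
    phantom_template = phantom_template or PhantomConfig()
    hz = hz or HazardModelConfig()
    if not isinstance(rng, np.random.Generator):
        seed = hz.seed if rng is None else int(rng)
        rng = np.random.default_rng(seed)
    else:
        seed = hz.seed

    covariates = []
    for _ in range(n):
        present = bool(rng.random() < lesion_probability)
        radius = float(rng.uniform(*radius_range_mm)) if present else 0.0
        depth = float(rng.beta(*depth_beta)) if present else 0.0
        elong = float(rng.uniform(*elongation_range)) if present else 1.0
        vol_cm3 = 4.0 / 3.0 * math.pi * radius**3 / 1000.0
        covariates.append((present, radius, depth, elong, vol_cm3,
                           constant_hazard(vol_cm3, depth, hz, elong)))

    # Calibrate the probability of drawing a censoring month so that the
    # realized censored fraction P(k=0) matches censor_rate: patients with no
    # event by t_max are censored regardless, so
    # P(k=0) = P0 + q * E[(E-1)/t_max | event], solved for q analytically.
    hs = np.array([c[-1] for c in covariates])
    months = np.arange(1, hz.t_max + 1)
    pmf = (1 - hs[:, None]) ** (months - 1) * hs[:, None]
    p_no_event = float(np.mean((1 - hs) ** hz.t_max))
    mean_pre_event = float(np.mean((pmf * (months - 1) / hz.t_max).sum(axis=1)))
    if mean_pre_event > 0:
        q = (hz.censor_rate - p_no_event) / mean_pre_event
    else:
        q = 0.0
    q = float(np.clip(q, 0.0, 1.0))

    patients = []
    for i in range(n):
        present, radius, depth, elong, vol_cm3, hazard = covariates[i]
        record = sample_survival_record(hazard, q, hz.t_max, rng)
        phantom = replace(
            phantom_template,
            lesion_present=present,
            lesion_radius_mm=radius if present else phantom_template.lesion_radius_mm,
            lesion_relative_depth=depth,
            lesion_elongation=elong,
            lung_height_frac=float(rng.uniform(*lung_height_range)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        patients.append(CohortPatient(
            patient_id=f"SYN-{i:04d}",
            phantom=phantom,
            record=record,
            truth=PatientTruth(present, radius, vol_cm3, depth, elong, hazard),
        ))
    return CohortDataset(patients=tuple(patients), seed=seed)


def save_cohort(cohort: CohortDataset, out_dir) -> None:
    """Write NIfTI phantom volumes plus records.csv and truth.csv."""
    from pathlib import Path

    from .imaging_io import save_nifti

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for patient in cohort.patients:
        vol, _, _ = patient.volume()
        save_nifti(vol, out / f"{patient.patient_id}.nii.gz")
    cohort.records_frame().to_csv(out / "records.csv", index=False)
    cohort.truth_frame().to_csv(out / "truth.csv", index=False)


def true_risk_ctd(cohort: CohortDataset) -> float:
    """Concordance ceiling of the generator: the time-dependent concordance of
    the true hazards used as risk scores (constant hazard means the CIF
    ordering equals the hazard ordering at every time)."""
    from .metrics_stats import ModelPredictions, ctd_index
    from .survival_head import SurvivalDistribution

    dists = []
    for p in cohort.patients:
        h = p.truth.hazard
        months = np.arange(1, T_MAX + 1)
        pmf = (1 - h) ** (months - 1) * h
        pmf[-1] += (1 - h) ** T_MAX  # fold the tail into the last bin
        dists.append(SurvivalDistribution(pmf))
    preds = ModelPredictions(
        patient_ids=tuple(p.patient_id for p in cohort.patients),
        distributions=tuple(dists),
        records=tuple(p.record for p in cohort.patients),
    )
    return ctd_index(preds)
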
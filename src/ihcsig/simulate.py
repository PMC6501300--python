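"""Synthetic cohorts and chromogenic-IHC-like images with known ground truth.

The generators here emulate the statistical structure the downstream analysis
assumes so that every stage (density quantification, cutoff optimization,
survival evaluation, prevalence transfer) can be tested against a known truth:

* patient cohorts with correlated, right-skewed CD8+ / PD-L1+ cell densities,
  a RECIST-style binary response whose probability rises with the density
  product, and exponential proportional-hazards OS/PFS with independent
  right censoring;
* RGB images of DAB-stained (brown) cells on a hematoxylin (blue) background,
  composited in optical-density space, with a tumor-region mask and a sidecar
  listing every true cell centroid.

All randomness flows through an explicit integer seed; there is no global
RNG state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "ImageConfig",
    "SyntheticTruth",
    "PatientRecord",
    "COHORT_COLUMNS",
    "generate_cohort",
    "generate_ihc_image",
    "write_cohort_csv",
    "read_cohort_csv",
    "write_image_bundle",
]


# Categorical covariates and their default category probabilities. Liver
# metastasis and previous lines of therapy are stored as integers but drawn
# from the same categorical machinery.
DEFAULT_COVARIATE_PREVALENCES: Mapping[str, Mapping[str, float]] = {
    "histology": {"nonsquamous": 0.6, "squamous": 0.4},
    "smoking_status": {"ever": 0.75, "never": 0.25},
    "gender": {"male": 0.6, "female": 0.4},
    "tumor_stage": {"III": 0.3, "IV": 0.7},
    "liver_metastasis": {"0": 0.8, "1": 0.2},
    "prior_lines": {"1": 0.5, "2": 0.3, "3": 0.2},
}

COHORT_COLUMNS = [
    "patient_id",
    "cd8_density",
    "pdl1_density",
    "pdl1_tc_pct",
    "response",
    "os_time",
    "os_event",
    "pfs_time",
    "pfs_event",
    "histology",
    "smoking_status",
    "gender",
    "tumor_stage",
    "age",
    "liver_metastasis",
    "prior_lines",
]


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid CohortConfig.{field_name}: {msg}")


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic patient cohort.

    Densities are bivariate log-normal (cells/mm²); response is logistic in
    the standardized log density product; OS/PFS are exponential proportional
    hazards (events/month) with the log hazard ratio acting on the binary
    indicator ``log(cd8*pdl1) > population median`` and on liver metastasis;
    censoring is an independent exponential clock.

    Defaults place the published component cutoffs (297 and 644 cells/mm²)
    and the signature cutoff (1.54e5 cells²/mm⁴) at positive prevalences of
    roughly 0.38, 0.31 and 0.36 respectively.
    """

    n_patients: int = 163
    log_mean_cd8: float = 5.39
    log_sd_cd8: float = 1.0
    log_mean_pdl1: float = 5.97
    log_sd_pdl1: float = 1.0
    density_correlation: float = 0.33
    response_intercept: float = -1.66
    response_slope: float = 1.1
    baseline_hazard_os: float = math.log(2) / 8.0
    baseline_hazard_pfs: float = math.log(2) / 2.5
    log_hr_signature: float = -1.0
    log_hr_liver_met: float = 0.7
    covariate_prevalences: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_COVARIATE_PREVALENCES
    )
    censor_rate: float = 0.04
    seed: int = 0

    def __post_init__(self) -> None:
        _require(int(self.n_patients) > 0, "n_patients", "must be a positive integer")
        _require(self.log_sd_cd8 > 0, "log_sd_cd8", "must be > 0")
        _require(self.log_sd_pdl1 > 0, "log_sd_pdl1", "must be > 0")
        _require(
            abs(self.density_correlation) <= 1,
            "density_correlation",
            "must lie in [-1, 1]",
        )
        _require(self.baseline_hazard_os > 0, "baseline_hazard_os", "must be > 0")
        _require(self.baseline_hazard_pfs > 0, "baseline_hazard_pfs", "must be > 0")
        _require(self.censor_rate > 0, "censor_rate", "must be > 0")
        for cov, cats in self.covariate_prevalences.items():
            probs = np.array(list(cats.values()), dtype=float)
            _require(
                np.all((probs >= 0) & (probs <= 1)),
                "covariate_prevalences",
                f"probabilities for {cov!r} must be in [0, 1]",
            )
            _require(
                abs(probs.sum() - 1.0) < 1e-9,
                "covariate_prevalences",
                f"probabilities for {cov!r} must sum to 1",
            )

    @property
    def signature_log_mean(self) -> float:
        return self.log_mean_cd8 + self.log_mean_pdl1

    @property
    def signature_log_sd(self) -> float:
        return math.sqrt(
            self.log_sd_cd8**2
            + self.log_sd_pdl1**2
            + 2 * self.density_correlation * self.log_sd_cd8 * self.log_sd_pdl1
        )


@dataclass(frozen=True)
class PatientRecord:
    """One patient: densities, endpoints and clinical covariates."""

    patient_id: str
    cd8_density: float
    pdl1_density: float
    pdl1_tc_pct: float
    response: int
    os_time: float
    os_event: int
    pfs_time: float
    pfs_event: int
    histology: str
    smoking_status: str
    gender: str
    tumor_stage: str
    age: float
    liver_metastasis: int
    prior_lines: int


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a synthetic cohort as a DataFrame with ``COHORT_COLUMNS``.

    The same config (including its seed) always produces an identical frame.
    """
    n = int(config.n_patients)
    rng = np.random.default_rng(config.seed)

    # Correlated log densities via an explicit Cholesky factor (deterministic
    # across platforms, unlike multivariate_normal's SVD path).
    s1, s2, rho = config.log_sd_cd8, config.log_sd_pdl1, config.density_correlation
    cov = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    z = rng.standard_normal((n, 2))
    log_d = np.array([config.log_mean_cd8, config.log_mean_pdl1]) + z @ chol.T
    cd8 = np.exp(log_d[:, 0])
    pdl1 = np.exp(log_d[:, 1])

    # Standardized log signature (population standardization from the config).
    log_sig = log_d.sum(axis=1)
    z_sig = (log_sig - config.signature_log_mean) / config.signature_log_sd

    # Manual tumor-cell PD-L1 % as a noisy monotone transform of PD-L1 density.
    z_pdl1 = (log_d[:, 1] - config.log_mean_pdl1) / config.log_sd_pdl1
    tc_noise = rng.normal(0.0, 0.5, size=n)
    pdl1_tc = 100.0 / (1.0 + np.exp(-(z_pdl1 - 0.88 + tc_noise)))

    # RECIST response: logistic in the standardized log signature.
    p_resp = 1.0 / (1.0 + np.exp(-(config.response_intercept + config.response_slope * z_sig)))
    response = (rng.uniform(size=n) < p_resp).astype(int)

    # Covariates.
    cats: dict[str, np.ndarray] = {}
    for cov_name, levels in config.covariate_prevalences.items():
        names = list(levels.keys())
        probs = np.array(list(levels.values()), dtype=float)
        idx = rng.choice(len(names), size=n, p=probs / probs.sum())
        cats[cov_name] = np.array(names, dtype=object)[idx]
    age = np.clip(rng.normal(64.0, 9.0, size=n), 30.0, 90.0)
    liver = cats.pop("liver_metastasis").astype(int)
    prior_lines = cats.pop("prior_lines").astype(int)

    # Exponential proportional hazards; the signature enters as the binary
    # indicator of an above-median log product so that a Cox fit of that
    # indicator recovers log_hr_signature directly.
    sig_pos = (z_sig > 0).astype(float)
    lin = config.log_hr_signature * sig_pos + config.log_hr_liver_met * liver
    haz_mult = np.exp(lin)
    os_latent = rng.exponential(1.0 / (config.baseline_hazard_os * haz_mult))
    pfs_latent = rng.exponential(1.0 / (config.baseline_hazard_pfs * haz_mult))
    censor = rng.exponential(1.0 / config.censor_rate, size=n)

    pfs_latent = np.minimum(pfs_latent, os_latent)  # progression or death
    os_time = np.minimum(os_latent, censor)
    os_event = (os_latent <= censor).astype(int)
    pfs_time = np.minimum(pfs_latent, censor)
    pfs_event = (pfs_latent <= censor).astype(int)
    floor = 1e-6
    os_time = np.maximum(os_time, floor)
    pfs_time = np.maximum(pfs_time, floor)

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "cd8_density": cd8,
            "pdl1_density": pdl1,
            "pdl1_tc_pct": pdl1_tc,
            "response": response,
            "os_time": os_time,
            "os_event": os_event,
            "pfs_time": pfs_time,
            "pfs_event": pfs_event,
            "histology": cats["histology"],
            "smoking_status": cats["smoking_status"],
            "gender": cats["gender"],
            "tumor_stage": cats["tumor_stage"],
            "age": age,
            "liver_metastasis": liver,
            "prior_lines": prior_lines,
        },
        columns=COHORT_COLUMNS,
    )
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a cohort with the fixed documented header."""
    cohort.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return df[COHORT_COLUMNS]


# --------------------------------------------------------------------------
# Images
# --------------------------------------------------------------------------


class PlacementError(RuntimeError):
    """Raised when the requested cell count cannot be placed without overlap."""


@dataclass(frozen=True)
class ImageConfig:
    """Parameters of a synthetic single-stain IHC field of view.

    ``dab_intensity`` and ``hematoxylin_intensity`` are optical-density
    amplitudes of the brown chromogen disks and the blue counterstain wash;
    ``noise_sd`` is additive Gaussian noise in 8-bit intensity units.
    """

    width_px: int = 512
    height_px: int = 512
    microns_per_pixel: float = 0.5
    n_cells: int = 50
    cell_radius_px: float = 6.0
    stain_name: str = "CD8"
    dab_intensity: float = 0.8
    hematoxylin_intensity: float = 0.35
    noise_sd: float = 1.5
    mask_shape: str = "ellipse"  # {"ellipse", "rect", "full"}
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("invalid ImageConfig.width_px/height_px: must be positive")
        if self.microns_per_pixel <= 0:
            raise ValueError("invalid ImageConfig.microns_per_pixel: must be > 0")
        if self.n_cells < 0:
            raise ValueError("invalid ImageConfig.n_cells: must be non-negative")
        if self.cell_radius_px <= 0:
            raise ValueError("invalid ImageConfig.cell_radius_px: must be > 0")
        if self.cell_radius_px >= min(self.width_px, self.height_px) / 4:
            raise ValueError(
                "invalid ImageConfig.cell_radius_px: must be < min(width, height)/4"
            )
        if self.stain_name not in ("CD8", "PD-L1"):
            raise ValueError("invalid ImageConfig.stain_name: must be 'CD8' or 'PD-L1'")
        if self.dab_intensity <= 0 or self.hematoxylin_intensity <= 0:
            raise ValueError("invalid ImageConfig intensities: must be > 0")
        if self.noise_sd < 0:
            raise ValueError("invalid ImageConfig.noise_sd: must be >= 0")
        if self.mask_shape not in ("ellipse", "rect", "full"):
            raise ValueError("invalid ImageConfig.mask_shape: ellipse|rect|full")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one synthetic image."""

    centroids: tuple
    count: int
    mask_area_mm2: float
    true_density: float

    def to_json(self) -> str:
        d = asdict(self)
        d["centroids"] = [list(c) for c in self.centroids]
        return json.dumps(d)


def _make_mask(config: ImageConfig) -> np.ndarray:
    h, w = config.height_px, config.width_px
    if config.mask_shape == "full":
        return np.ones((h, w), dtype=bool)
    rr, cc = np.mgrid[0:h, 0:w]
    if config.mask_shape == "rect":
        mh, mw = int(0.1 * h), int(0.1 * w)
        mask = np.zeros((h, w), dtype=bool)
        mask[mh : h - mh, mw : w - mw] = True
        return mask
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = 0.45 * h, 0.45 * w
    return ((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2 <= 1.0


def _place_cells(config: ImageConfig, mask: np.ndarray, rng: np.random.Generator):
    """Rejection-sample non-overlapping disk centers strictly inside the mask."""
    r = config.cell_radius_px
    min_sep = 2 * r + 2.0
    centers: list[tuple[float, float]] = []
    max_attempts = max(10_000, 400 * config.n_cells)
    attempts = 0
    h, w = mask.shape
    while len(centers) < config.n_cells:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {config.n_cells} non-overlapping cells of radius "
                f"{r} after {max_attempts} attempts"
            )
        attempts += 1
        row = rng.uniform(r + 1, h - r - 2)
        col = rng.uniform(r + 1, w - r - 2)
        # require the whole disk inside the mask (check center + 4 extremes)
        pts = [(row, col), (row - r, col), (row + r, col), (row, col - r), (row, col + r)]
        if not all(mask[int(round(p)), int(round(q))] for p, q in pts):
            continue
        if any((row - cr) ** 2 + (col - cc) ** 2 < min_sep**2 for cr, cc in centers):
            continue
        centers.append((row, col))
    return centers


# Optical-density direction of hematoxylin and DAB (Ruifrok & Johnston).
_HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
_DAB_OD = np.array([0.268, 0.570, 0.776])


def generate_ihc_image(config: ImageConfig):
    """Render one synthetic field of view.

    Returns ``(rgb, mask, truth)``: an 8-bit H×W×3 image of brown (DAB-like)
    disks on a bluish (hematoxylin-like) background composited in optical-
    density space, the boolean tumor-region mask, and the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    mask = _make_mask(config)
    centers = _place_cells(config, mask, rng)

    h, w = config.height_px, config.width_px
    dab_conc = np.zeros((h, w), dtype=float)
    if centers:
        rr, cc = np.mgrid[0:h, 0:w]
        for row, col in centers:
            disk = (rr - row) ** 2 + (cc - col) ** 2 <= config.cell_radius_px**2
            dab_conc[disk] = 1.0

    od = (
        config.hematoxylin_intensity * _HEMATOXYLIN_OD[None, None, :]
        + config.dab_intensity * dab_conc[:, :, None] * _DAB_OD[None, None, :]
    )
    rgb = 255.0 * np.power(10.0, -od)
    if config.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, config.noise_sd, size=rgb.shape)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    area_mm2 = float(mask.sum()) * (config.microns_per_pixel / 1000.0) ** 2
    truth = SyntheticTruth(
        centroids=tuple((float(r), float(c)) for r, c in centers),
        count=len(centers),
        mask_area_mm2=area_mm2,
        true_density=len(centers) / area_mm2,
    )
    return rgb, mask, truth


def write_image_bundle(rgb: np.ndarray, mask: np.ndarray, truth: SyntheticTruth, stem) -> None:
    """Write ``<stem>.png`` (RGB), ``<stem>_mask.png`` (0/255) and ``<stem>_truth.json``."""
    import imageio.v3 as iio

    stem = str(stem)
    iio.imwrite(stem + ".png", rgb)
    iio.imwrite(stem + "_mask.png", (mask.astype(np.uint8) * 255))
    with open(stem + "_truth.json", "w") as fh:
        fh.write(truth.to_json())
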
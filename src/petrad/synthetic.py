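"""Synthetic phantoms and cohorts with known ground truth.

Every pipeline stage is testable without patient data: spherical FDG-avid
phantoms with a Gaussian-random-field intra-tumor texture stand in for PET
acquisitions, and simulated cohorts carry survival times driven by a known
linear predictor of two designated texture features, so that discovery and
inference can be checked against planted truth.  All generators are
seed-deterministic.
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .signature import CohortTable, FVModel, FVTerm, published_fvx
from .volume import PETVolume, ScannerMeta, save_mask_nifti, save_nifti

#: Scanner models named in multi-centre NSCLC PET studies; used as the
#: default pool for simulated acquisitions.
DEFAULT_SCANNER_POOL = (
    ScannerMeta("Philips", "Allegro Body", 4.0, 144, 144),
    ScannerMeta("Philips", "Gemini TF TOF 16", 4.0, 144, 144),
    ScannerMeta("Siemens", "Biograph 64 mCT", 3.0, 200, 200),
    ScannerMeta("Siemens", "Biograph 128 mCT", 2.0, 200, 200),
    ScannerMeta("GE", "Discovery ST", 3.27, 128, 128),
    ScannerMeta("GE", "Discovery STE", 3.27, 128, 128),
    ScannerMeta("CTI", "ECAT HR+", 5.15, 128, 128),
    ScannerMeta("CPS/Siemens", "Sensation 16", 5.0, 128, 128),
)


@dataclass(frozen=True)
class PhantomSpec:
    """A spherical hot lesion on warm background.

    Defaults emulate a medium-large NSCLC primary: ~30 ml tumor (radius
    19.3 mm) with SUVmax ~16 on background SUV 1, 4 mm isotropic voxels,
    mild intra-tumor heterogeneity (correlation length 8 mm) and Gaussian
    image noise.
    """

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_suv: float = 1.0
    tumor_center: tuple[int, int, int] | None = None  # defaults to grid center
    tumor_radius: float = 19.3  # mm
    tumor_suv_max: float = 16.0
    texture_correlation_length: float = 8.0  # mm
    texture_amplitude: float = 2.0  # SUV (1 SD of the random field)
    noise_sd: float = 0.3  # SUV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_radius <= 0:
            raise ValueError("tumor radius must be positive")
        if self.noise_sd < 0 or self.texture_amplitude < 0:
            raise ValueError("noise/texture amplitudes must be >= 0")


def radius_for_volume_ml(volume_ml: float) -> float:
    """Sphere radius (mm) enclosing the requested volume."""
    return (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


def make_phantom(spec: PhantomSpec) -> tuple[PETVolume, np.ndarray]:
    """Generate a phantom volume and its analytic truth mask.

    The tumor is a hard-edged sphere at ``tumor_suv_max`` with a zero-mean
    Gaussian random field (correlation length in mm, amplitude = 1 SD)
    added inside the sphere, Gaussian noise added everywhere, and the
    result clipped at 0.  The truth mask contains the voxels whose centers
    lie within the analytic sphere.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(int(n) for n in spec.grid_shape)
    center = (
        tuple(int(c) for c in spec.tumor_center)
        if spec.tumor_center is not None
        else tuple(n // 2 for n in shape)
    )
    ax = [
        (np.arange(n) - c) * s
        for n, c, s in zip(shape, center, spec.spacing)
    ]
    dist2 = ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2 + ax[2][None, None, :] ** 2
    truth = dist2 <= spec.tumor_radius**2
    if not truth.any():
        raise ValueError("tumor sphere contains no voxel centers")
    if any(
        center[i] * spec.spacing[i] - spec.tumor_radius < 0
        or center[i] * spec.spacing[i] + spec.tumor_radius > (shape[i] - 1) * spec.spacing[i]
        for i in range(3)
    ):
        raise ValueError("tumor sphere extends outside the grid")

    vox = np.full(shape, float(spec.background_suv))
    vox[truth] = spec.tumor_suv_max
    if spec.texture_amplitude > 0:
        white = rng.standard_normal(shape)
        sigma = [spec.texture_correlation_length / s for s in spec.spacing]
        grf = ndimage.gaussian_filter(white, sigma=sigma)
        sd = grf.std()
        if sd > 0:
            grf = grf / sd * spec.texture_amplitude
        vox[truth] += grf[truth]
    if spec.noise_sd > 0:
        vox += rng.normal(0.0, spec.noise_sd, size=shape)
    vox = np.clip(vox, 0.0, None)
    return PETVolume(vox, spec.spacing), truth


# ---------------------------------------------------------------------------
# cohorts


def _default_true_model() -> FVModel:
    # two planted texture features at HR ~= 1.8 per SD, with the signs of
    # the published classifier (size-zone variance harmful, complexity
    # protective)
    b = math.log(1.8)
    return FVModel(
        (FVTerm("GLSZM_SzVarianc", 64, b), FVTerm("NGTDM_Complex", 64, -b)),
        provenance="synthetic_truth",
    )


@dataclass(frozen=True)
class CohortSpec:
    """A simulated cohort emulating a validation-scale NSCLC dataset.

    Defaults follow the scale of a ~200-patient radiotherapy cohort:
    median OS 21 months, ~70% deaths within an 85-month administrative
    window, stage mix dominated by stage III, scanners drawn from a
    multi-centre pool.  ``true_model`` weights are log-hazards per SD of
    the (standardized) planted features.
    """

    n_patients: int = 204
    n_features: int = 50
    true_model: FVModel = field(default_factory=_default_true_model)
    baseline_median_months: float = 21.0
    censor_rate: float = 0.001  # per month (~0.012 per year)
    admin_cutoff_months: float = 85.0
    stage_distribution: tuple[float, float, float] = (0.162, 0.181, 0.657)
    feature_rho: float = 0.3  # AR(1) correlation between adjacent features
    scanner_pool: tuple[ScannerMeta, ...] = DEFAULT_SCANNER_POOL
    gray_level: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if abs(sum(self.stage_distribution) - 1.0) > 1e-9:
            raise ValueError("stage probabilities must sum to 1")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be >= 0")
        if self.n_features < len(self.true_model.terms):
            raise ValueError("need at least as many features as planted terms")


def make_cohort(spec: CohortSpec) -> tuple[CohortTable, dict]:
    """Simulate a cohort with survival driven by planted features.

    Features are jointly Gaussian with AR(1) correlation ``feature_rho``
    between adjacent columns; the planted columns are renamed to the
    ``true_model`` term names.  Survival times are exponential with rate
    ``(ln 2 / baseline_median) * exp(lp)`` where ``lp`` is the centered
    linear predictor of the planted (standardized) features; censoring is
    independent exponential at ``censor_rate`` plus an administrative
    cut-off.  Returns the cohort and a truth record with every latent
    quantity.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_patients, spec.n_features

    # AR(1) correlated standard-normal features
    rho = spec.feature_rho
    X = np.empty((n, p))
    X[:, 0] = rng.standard_normal(n)
    for j in range(1, p):
        X[:, j] = rho * X[:, j - 1] + math.sqrt(1 - rho**2) * rng.standard_normal(n)

    terms = spec.true_model.terms
    planted_idx = list(range(len(terms)))
    suffix = f"_{spec.gray_level}gl"
    names = []
    for j in range(p):
        if j < len(terms):
            names.append(terms[j].column)
        else:
            names.append(f"SIM_F{j:03d}{suffix}")
    beta = np.zeros(p)
    for j, t in enumerate(terms):
        beta[j] = t.weight
    lp = X @ beta
    lp = lp - lp.mean()

    base_rate = math.log(2.0) / spec.baseline_median_months
    t_death = rng.exponential(1.0, size=n) / (base_rate * np.exp(lp))
    t_drop = (
        rng.exponential(1.0 / spec.censor_rate, size=n)
        if spec.censor_rate > 0
        else np.full(n, np.inf)
    )
    t_cens = np.minimum(t_drop, spec.admin_cutoff_months)
    os_months = np.minimum(t_death, t_cens)
    event = (t_death <= t_cens).astype(int)

    stages = rng.choice(["I", "II", "III"], size=n, p=spec.stage_distribution)
    scanners = [spec.scanner_pool[i] for i in rng.integers(0, len(spec.scanner_pool), size=n)]
    volume_ml = np.exp(rng.normal(math.log(35.0), 0.6, size=n)).clip(5.0, 550.0)

    df = pd.DataFrame(X, columns=names)
    df.index = [f"P{i:04d}" for i in range(n)]
    df["os_months"] = os_months
    df["event"] = event
    df["stage"] = stages
    df["volume_ml"] = volume_ml
    df["scanner_manufacturer"] = [s.manufacturer for s in scanners]
    df["scanner_model"] = [s.model for s in scanners]
    df["slice_thickness"] = [s.slice_thickness for s in scanners]
    truth = {
        "beta": beta,
        "planted_columns": [names[j] for j in planted_idx],
        "linear_predictor": lp,
        "death_times": t_death,
        "censor_times": t_cens,
        "seed": spec.seed,
    }
    return CohortTable(df), truth


# ---------------------------------------------------------------------------
# fixture bundles


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_bundle(
    out_dir,
    phantom_spec: PhantomSpec | None = None,
    cohort_spec: CohortSpec | None = None,
) -> dict:
    """Write a complete end-to-end test bundle.

    Emits a phantom volume and truth mask (NIfTI), the simulated cohort as
    ``clinical.csv`` + ``features.csv``, the published FV model JSON, and a
    manifest listing seeds and SHA-256 hashes.  Returns the manifest.
    """
    out_dir = os.fspath(out_dir)
    if not os.path.isdir(out_dir):
        raise FileNotFoundError(f"output directory {out_dir!r} does not exist")
    phantom_spec = phantom_spec or PhantomSpec()
    cohort_spec = cohort_spec or CohortSpec()

    vol, truth_mask = make_phantom(phantom_spec)
    cohort, _ = make_cohort(cohort_spec)

    paths = {
        "phantom": os.path.join(out_dir, "phantom.nii"),
        "truth_mask": os.path.join(out_dir, "phantom_mask.nii"),
        "clinical": os.path.join(out_dir, "clinical.csv"),
        "features": os.path.join(out_dir, "features.csv"),
        "model": os.path.join(out_dir, "fvx_published.json"),
    }
    save_nifti(vol, paths["phantom"])
    save_mask_nifti(truth_mask, phantom_spec.spacing, paths["truth_mask"])
    clinical_cols = [
        "os_months", "event", "stage", "volume_ml",
        "scanner_manufacturer", "scanner_model", "slice_thickness",
    ]
    cohort.data[clinical_cols].to_csv(paths["clinical"], index_label="patient_id")
    cohort.data[cohort.feature_columns()].to_csv(paths["features"], index_label="patient_id")
    published_fvx().to_json(paths["model"])

    manifest = {
        "phantom_seed": phantom_spec.seed,
        "cohort_seed": cohort_spec.seed,
        "files": {k: {"path": os.path.basename(v), "sha256": _sha256(v)} for k, v in paths.items()},
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
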
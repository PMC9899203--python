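"""Synthetic CT cohorts for exercising the phenotyping pipeline.

The patient LDCT data the analysis was designed for are not publicly
deposited, so every downstream stage is validated on phantoms generated
here.  Three generators are provided:

* :func:`make_phantom_volume` — a lung-shaped phantom: an ellipsoidal
  two-lobe low-attenuation parenchyma (~ -850 HU) inside a soft-tissue
  shell (~ +40 HU) surrounded by exterior air (-1000 HU), textured with
  Poisson-distributed hyperattenuating Gaussian blobs on voxel noise.
  Two texture phenotypes differ in blob density and size (phenotype 2 is
  coarser and more heterogeneous).  Each acquisition is rendered under
  two reconstruction kernels — "medium" (Gaussian smoothing) and
  "sharp" (unsharp masking) — applied to the same pre-filter volume, so
  the anatomy is identical and only the kernel differs, mimicking paired
  smooth/sharp reconstructions of one raw acquisition.

* :func:`generate_cohort` — a cohort of such phantoms plus a covariate
  table (age, BMI, pack-years, sex, smoking status, Lung-RADS group,
  cancer flag) drawn with screening-cohort means/SDs, with an optional
  additive BMI shift linked to phenotype 2.

* :func:`generate_feature_table` — a fast feature-level simulator that
  bypasses imaging entirely: 26-feature vectors from two multivariate
  normal populations with configurable between-population shifts and
  per-batch location/scale distortions following the ComBat generative
  model.  Used for harmonization and clustering unit tests.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .features import FEATURE_NAMES, N_FEATURES
from .volume import CtVolume, LungMask

# Covariate generating parameters: screening-cohort means (SDs) — age in
# years, BMI in kg/m^2, smoking pack-years — and the observed category
# frequencies for Lung-RADS group B and biopsy-confirmed cancer.
DEFAULT_COVARIATES = {
    "age": (64.8, 5.84),
    "bmi": (27.08, 6.04),
    "pack_years": (52.47, 24.85),
}
LUNGRADS_B_PROB = 46 / 308
CANCER_PROB = 15 / 308


@dataclass
class TextureParams:
    """Blob-texture parameters of one parenchymal phenotype."""

    blob_density_per_cm3: float = 2.0
    blob_radius_mm: float = 1.5
    parenchyma_hu: float = -850.0
    noise_sd_hu: float = 40.0
    blob_amplitude_hu: float = 100.0

    def __post_init__(self) -> None:
        if self.blob_radius_mm <= 0:
            raise ValueError("blob_radius_mm must be positive")
        if self.noise_sd_hu <= 0:
            raise ValueError("noise_sd_hu must be positive")


#: Phenotype 2 is the coarser, more heterogeneous parenchyma: larger
#: hyperattenuating blobs on a lower-attenuation (emphysema-like), noisier
#: background.  Summed blob attenuation stays below the vessel-exclusion
#: threshold so texture is never mistaken for vasculature.
DEFAULT_TEXTURES = {
    1: TextureParams(blob_density_per_cm3=2.0, blob_radius_mm=1.5,
                     parenchyma_hu=-850.0, noise_sd_hu=40.0, blob_amplitude_hu=100.0),
    2: TextureParams(blob_density_per_cm3=2.0, blob_radius_mm=2.5,
                     parenchyma_hu=-880.0, noise_sd_hu=50.0, blob_amplitude_hu=120.0),
}


@dataclass
class KernelPair:
    """Reconstruction-kernel emulation: smooth vs sharp filtering."""

    medium_sigma_mm: float = 1.0
    sharp_amount: float = 1.0
    sharp_radius_mm: float = 1.0


@dataclass
class CohortConfig:
    """Configuration of a synthetic two-kernel cohort.

    ``phenotype_fraction`` is the probability that a scan belongs to
    phenotype 2 (the coarse-textured one); ``bmi_effect`` is an additive
    BMI shift (kg/m^2) applied to phenotype-2 subjects, giving the
    covariate table a phenotype-linked BMI association.
    """

    n_scans: int = 60
    phenotype_fraction: float = 0.4
    texture_params: dict[int, TextureParams] = field(
        default_factory=lambda: {k: TextureParams(**vars(v)) for k, v in DEFAULT_TEXTURES.items()}
    )
    kernel_pair: KernelPair = field(default_factory=KernelPair)
    covariate_means_sds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    bmi_effect: float = 4.0
    lungrads_b_prob: float = LUNGRADS_B_PROB
    cancer_prob: float = CANCER_PROB
    include_obstruction: bool = False
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_scans < 4:
            raise ValueError("n_scans must be >= 4")
        if not 0 <= self.phenotype_fraction <= 1:
            raise ValueError("phenotype_fraction must be in [0, 1]")
        for name, (_, sd) in self.covariate_means_sds.items():
            if sd <= 0:
                raise ValueError(f"SD for covariate {name!r} must be positive")


@dataclass
class SyntheticScan:
    """One phantom rendering with its ground truth."""

    volume: CtVolume
    truth_mask: LungMask
    phenotype_label: int
    kernel_label: str
    scan_id: str


def _ellipsoid(shape, spacing, center_mm, semiaxes_mm) -> np.ndarray:
    grids = np.meshgrid(
        *[(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)],
        indexing="ij",
    )
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center_mm, semiaxes_mm):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def _build_anatomy(shape, spacing):
    """Body shell and two lung lobes, scaled to the grid extent."""
    extent = [n * s for n, s in zip(shape, spacing)]
    body_ax = [0.44 * e for e in extent]
    body = _ellipsoid(shape, spacing, (0, 0, 0), body_ax)
    lobe_ax = (0.17 * extent[0], 0.24 * extent[1], 0.34 * extent[2])
    dx = 0.20 * extent[0]
    left = _ellipsoid(shape, spacing, (-dx, 0, 0), lobe_ax)
    right = _ellipsoid(shape, spacing, (+dx, 0, 0), lobe_ax)
    lungs = left | right
    return body, lungs


def make_phantom_volume(
    phenotype: int,
    kernel: str,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    shape: tuple[int, int, int] = (64, 64, 64),
    texture: TextureParams | None = None,
    kernel_pair: KernelPair | None = None,
    scan_id: str = "",
) -> SyntheticScan:
    """Render one lung phantom under one reconstruction kernel.

    The pre-filter volume depends only on ``(phenotype, spacing, shape,
    texture, seed)``; the kernel filter is applied afterwards, so the
    "medium" and "sharp" renderings of the same seed share their
    anatomy and truth mask exactly.
    """
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")
    if phenotype not in (1, 2):
        raise ValueError("phenotype must be 1 or 2")
    if kernel not in ("medium", "sharp"):
        raise ValueError(f"unknown kernel {kernel!r}")
    tex = texture if texture is not None else DEFAULT_TEXTURES[phenotype]
    kp = kernel_pair if kernel_pair is not None else KernelPair()
    rng = np.random.default_rng(seed)

    body, lungs = _build_anatomy(shape, spacing)
    vol = np.full(shape, -1000.0)
    vol[body] = 40.0
    vol[lungs] = tex.parenchyma_hu

    # hyperattenuating blobs (vessel-/opacity-like texture elements)
    voxel_cm3 = spacing[0] * spacing[1] * spacing[2] / 1000.0
    lung_cm3 = lungs.sum() * voxel_cm3
    n_blobs = rng.poisson(tex.blob_density_per_cm3 * lung_cm3)
    lung_idx = np.argwhere(lungs)
    if n_blobs > 0 and len(lung_idx) > 0:
        centers = lung_idx[rng.integers(0, len(lung_idx), n_blobs)]
        sigma_vox = [tex.blob_radius_mm / s for s in spacing]
        reach = [int(np.ceil(3 * sv)) for sv in sigma_vox]
        for cx, cy, cz in centers:
            sl = tuple(
                slice(max(0, c - r), min(n, c + r + 1))
                for c, r, n in zip((cx, cy, cz), reach, shape)
            )
            local = np.meshgrid(
                *[np.arange(s.start, s.stop) - c for s, c in zip(sl, (cx, cy, cz))],
                indexing="ij",
            )
            d2 = sum((g / sv) ** 2 for g, sv in zip(local, sigma_vox))
            vol[sl] += tex.blob_amplitude_hu * np.exp(-0.5 * d2)

    vol += rng.normal(0.0, tex.noise_sd_hu, shape)

    if kernel == "medium":
        sig = [kp.medium_sigma_mm / s for s in spacing]
        vol = ndimage.gaussian_filter(vol, sigma=sig)
    else:
        sig = [kp.sharp_radius_mm / s for s in spacing]
        vol = vol + kp.sharp_amount * (vol - ndimage.gaussian_filter(vol, sigma=sig))

    return SyntheticScan(
        volume=CtVolume(vol, spacing, scan_id=scan_id),
        truth_mask=LungMask(lungs, scan_id=scan_id),
        phenotype_label=phenotype,
        kernel_label=kernel,
        scan_id=scan_id,
    )


def generate_cohort(config: CohortConfig) -> tuple[list[SyntheticScan], pd.DataFrame]:
    """Generate a paired two-kernel phantom cohort with covariates.

    Returns ``2 * n_scans`` scans (each acquisition rendered under both
    kernels) and a covariate table with one row per rendering.  Age,
    BMI and pack-years are Normal draws with the default screening-cohort
    parameters; BMI gains ``bmi_effect`` for phenotype-2 subjects; sex
    and smoking status are balanced Bernoulli; Lung-RADS group B and
    cancer use the observed cohort frequencies.  Values are clipped to
    plausibility bounds (age >= 40 y, BMI >= 15 kg/m^2, pack-years >= 0).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_scans
    phenos = np.where(rng.random(n) < config.phenotype_fraction, 2, 1)
    scan_seeds = rng.integers(0, 2**31 - 1, size=n)
    per_subject = generate_covariates(phenos, config, rng)

    scans: list[SyntheticScan] = []
    rows = []
    for i in range(n):
        scan_id = f"scan{i:04d}"
        for kernel in ("medium", "sharp"):
            scans.append(
                make_phantom_volume(
                    phenotype=int(phenos[i]),
                    kernel=kernel,
                    spacing=config.spacing,
                    seed=int(scan_seeds[i]),
                    shape=config.shape,
                    texture=config.texture_params[int(phenos[i])],
                    kernel_pair=config.kernel_pair,
                    scan_id=scan_id,
                )
            )
            row = {"scan_id": scan_id, "kernel": kernel}
            row.update(per_subject.iloc[i].to_dict())
            rows.append(row)
    return scans, pd.DataFrame(rows)


def generate_covariates(
    phenotype_labels: np.ndarray,
    config: CohortConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-subject covariate table for given phenotype labels.

    Factored out of :func:`generate_cohort` so covariate-level analyses
    can be exercised at cohort sizes where rendering volumes would be
    wasteful.  One row per subject (no kernel column).
    """
    if config is None:
        config = CohortConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    phenos = np.asarray(phenotype_labels)
    n = len(phenos)
    mu_age, sd_age = config.covariate_means_sds["age"]
    mu_bmi, sd_bmi = config.covariate_means_sds["bmi"]
    mu_py, sd_py = config.covariate_means_sds["pack_years"]
    age = np.maximum(rng.normal(mu_age, sd_age, n), 40.0)
    bmi = np.maximum(rng.normal(mu_bmi, sd_bmi, n) + config.bmi_effect * (phenos == 2), 15.0)
    pack_years = np.maximum(rng.normal(mu_py, sd_py, n), 0.0)
    sex = rng.random(n) < 0.5
    smoking = rng.random(n) < 0.5
    lungrads_b = rng.random(n) < config.lungrads_b_prob
    cancer = rng.random(n) < config.cancer_prob
    obstruction = rng.random(n) < 0.5
    df = pd.DataFrame(
        {
            "age": age,
            "bmi": bmi,
            "pack_years": pack_years,
            "sex": np.where(sex, "male", "female"),
            "smoking_status": np.where(smoking, "current", "former"),
            "lungrads_group": np.where(lungrads_b, "B", "A"),
            "cancer": np.where(cancer, "yes", "no"),
            "true_phenotype": phenos.astype(int),
        }
    )
    if config.include_obstruction:
        df["obstruction"] = np.where(obstruction, "yes", "no")
    return df


def generate_feature_table(
    n: int,
    cluster_shift: np.ndarray | float = 0.0,
    batch_effects: dict[str, tuple[float | np.ndarray, float | np.ndarray]] | None = None,
    seed: int = 0,
    cluster_fraction: float = 0.5,
    batch_labels: tuple[str, str] = ("medium", "sharp"),
) -> pd.DataFrame:
    """Fast feature-level cohort: two MVN populations + batch distortion.

    Rows are drawn from ``N(0, I)`` in 26 dimensions; population 2
    (fraction ``cluster_fraction``) gains ``cluster_shift`` (scalar or
    per-feature vector) on its mean.  Batches are assigned alternately
    and each batch ``b`` applies ``x -> x * scale_b + loc_b``
    feature-wise — the location/spread distortion ComBat models.

    Returns a DataFrame with the 26 feature columns plus ``scan_id``,
    ``batch`` and ``population``.
    """
    if n < 4:
        raise ValueError("n must be >= 4")
    shift = np.broadcast_to(np.asarray(cluster_shift, dtype=float), (N_FEATURES,))
    rng = np.random.default_rng(seed)
    pop = np.where(rng.random(n) < cluster_fraction, 2, 1)
    X = rng.standard_normal((n, N_FEATURES))
    X[pop == 2] += shift
    batch = np.array([batch_labels[i % 2] for i in range(n)])
    if batch_effects:
        for b, (loc, scale) in batch_effects.items():
            loc_v = np.broadcast_to(np.asarray(loc, dtype=float), (N_FEATURES,))
            scale_v = np.broadcast_to(np.asarray(scale, dtype=float), (N_FEATURES,))
            if np.any(scale_v <= 0):
                raise ValueError(f"batch {b!r}: scale effects must be positive")
            sel = batch == b
            X[sel] = X[sel] * scale_v + loc_v
    df = pd.DataFrame(X, columns=FEATURE_NAMES)
    df.insert(0, "scan_id", [f"s{i:04d}" for i in range(n)])
    df["batch"] = batch
    df["population"] = pop
    return df
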
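"""Synthetic phantom cohorts for pipeline testing.

The three paediatric tumour types studied — pilocytic astrocytoma (PA, low
grade), medulloblastoma (MB) and ependymoma (EP, both high grade) — differ
in diffusion, perfusion and size: PA tumours show high ADC, MB low ADC, EP
intermediate ADC but large volumes.  Because no public cohort ships with
this package, this module generates phantoms at two levels:

* :func:`generate_cohort` builds raw image volumes (4-D DSC series, two
  DWI b-value volumes, tumour/NAWM/brain masks and voxel-wise ground truth)
  whose quantified maps carry the class-conditional structure, so every
  quantification stage can be tested end to end against known truth;
* :func:`sample_feature_table` draws subject-level 33-feature tables
  directly from the class-conditional feature distributions, for
  statistical and machine-learning experiments that need many cohorts.

Forward models are the exact inverses of the quantification stages: a
gamma-variate bolus (optionally with Boxerman-style leakage) for DSC, and
mono-exponential decay between two b-values for diffusion, with additive
Gaussian signal noise — so at ``noise_sd = 0`` the pipeline recovers the
ground truth to float precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dsc import DSCSeries, gamma_variate
from .features import FEATURE_COLUMNS, VOLUME_COLUMN, grade_of

__all__ = [
    "CLASS_NAMES",
    "CohortConfig",
    "ClassProfile",
    "SyntheticSubject",
    "default_class_profile",
    "gamma_variate_signal",
    "diffusion_signal",
    "generate_subject",
    "iter_cohort",
    "generate_cohort",
    "sample_feature_table",
]

CLASS_NAMES = ("pilocytic_astrocytoma", "medulloblastoma", "ependymoma")


@dataclass
class CohortConfig:
    """Cohort geometry, acquisition timing and noise level.

    Defaults reproduce the study's class sizes (PA 22, MB 17, EP 10).  DSC
    temporal sampling (TR 1.5 s, 60 timepoints) and the b-values
    (0 and 1000 s/mm^2) are configurable, as acquisitions vary by site.
    ``noise_sd`` is the SD of additive Gaussian noise in raw signal units
    (DSC baseline is 100, DWI b0 is 1000).
    """

    n_per_class: tuple[int, int, int] = (22, 17, 10)  # PA, MB, EP
    grid_shape: tuple[int, int, int] = (24, 24, 16)
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)
    n_timepoints: int = 60
    TR_s: float = 1.5
    TE_s: float = 0.03
    b_values_s_per_mm2: tuple[float, float] = (0.0, 1000.0)
    noise_sd: float = 0.5
    seed: int = 0
    dsc_s0: float = 100.0
    dwi_s0: float = 1000.0
    bolus_alpha: float = 3.0
    bolus_beta_s: float = 1.5
    bolus_t0_s: float = 10.0
    nawm_amplitude: float = 3.0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("all class counts must be >= 1")
        b0, b1 = self.b_values_s_per_mm2
        if not (b1 > b0 >= 0):
            raise ValueError("need exactly two b-values with b1 > b0 >= 0")
        if self.TR_s <= 0 or self.TE_s <= 0:
            raise ValueError("TR and TE must be positive")
        if self.n_timepoints < 10:
            raise ValueError("DSC series needs >= 10 timepoints")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def time_grid(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.TR_s

    @property
    def labels(self) -> list[str]:
        return [c for c, n in zip(CLASS_NAMES, self.n_per_class) for _ in range(n)]


@dataclass
class ClassProfile:
    """Class-conditional feature targets: ``{class: {feature: (mean, sd)}}``.

    ``class_targets`` carries the features that differ between tumour types
    (ADC ROI/WB mean, skewness and kurtosis, whole-brain corrected-CBV mean
    and tumour volume); ``shared_targets`` carries the remaining feature
    distributions, identical across classes.  ADC is on the 1e-3 mm^2/s
    scale, CBV in NAWM-normalised units, volume in cm^3.
    """

    class_targets: dict[str, dict[str, tuple[float, float]]]
    shared_targets: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cls, targets in self.class_targets.items():
            if cls not in CLASS_NAMES:
                raise ValueError(f"unknown class {cls!r}")
            for feat, (_, sd) in targets.items():
                if sd <= 0:
                    raise ValueError(f"non-positive SD for {cls}/{feat}")
        for feat, (_, sd) in self.shared_targets.items():
            if sd <= 0:
                raise ValueError(f"non-positive SD for shared/{feat}")

    def target(self, cls: str, feature: str) -> tuple[float, float]:
        try:
            return self.class_targets[cls][feature]
        except KeyError:
            return self.shared_targets[feature]


def default_class_profile() -> ClassProfile:
    """The default class-conditional feature targets (means +/- SD).

    The discriminative rows: PA tumours have high ADC (ROI 1.5 +/- 0.4) and
    low ADC skew/kurtosis; MB the lowest ADC (0.9 +/- 0.2) and highest
    shape moments; EP intermediate ADC but the largest volumes
    (9.0 +/- 11.2 cm^3) and each class a slightly different whole-brain
    corrected-CBV mean.
    """
    class_targets = {
        "pilocytic_astrocytoma": {
            "ADC_ROI_mean": (1.5, 0.4),
            "ADC_ROI_skewness": (0.9, 1.0),
            "ADC_ROI_kurtosis": (5.0, 3.0),
            "ADC_WB_mean": (0.9, 0.2),
            "ADC_WB_skewness": (1.2, 0.3),
            "ADC_WB_kurtosis": (5.0, 1.0),
            "CCBV_WB_mean": (1.1, 0.3),
            VOLUME_COLUMN: (2.3, 3.1),
        },
        "ependymoma": {
            "ADC_ROI_mean": (1.2, 0.1),
            "ADC_ROI_skewness": (2.0, 1.0),
            "ADC_ROI_kurtosis": (8.0, 5.0),
            "ADC_WB_mean": (0.7, 0.3),
            "ADC_WB_skewness": (1.5, 0.5),
            "ADC_WB_kurtosis": (6.0, 2.0),
            "CCBV_WB_mean": (1.2, 0.2),
            VOLUME_COLUMN: (9.0, 11.2),
        },
        "medulloblastoma": {
            "ADC_ROI_mean": (0.9, 0.2),
            "ADC_ROI_skewness": (1.9, 0.9),
            "ADC_ROI_kurtosis": (9.0, 5.0),
            "ADC_WB_mean": (0.6, 0.2),
            "ADC_WB_skewness": (1.6, 0.5),
            "ADC_WB_kurtosis": (7.0, 2.0),
            "CCBV_WB_mean": (1.3, 0.2),
            VOLUME_COLUMN: (3.3, 2.3),
        },
    }
    # non-discriminative feature distributions, identical across classes
    shared = {
        "ADC_ROI_sd": (0.30, 0.08),
        "ADC_WB_sd": (0.35, 0.05),
        "UCBV_ROI_mean": (1.6, 0.5),
        "UCBV_ROI_sd": (0.5, 0.15),
        "UCBV_ROI_skewness": (0.8, 0.5),
        "UCBV_ROI_kurtosis": (4.0, 1.5),
        "UCBV_WB_mean": (0.12, 0.03),
        "UCBV_WB_sd": (0.04, 0.01),
        "UCBV_WB_skewness": (1.0, 0.3),
        "UCBV_WB_kurtosis": (4.0, 1.0),
        "K2_ROI_mean": (0.015, 0.008),
        "K2_ROI_sd": (0.008, 0.003),
        "K2_ROI_skewness": (0.5, 0.4),
        "K2_ROI_kurtosis": (3.5, 1.0),
        "K2_WB_mean": (0.002, 0.001),
        "K2_WB_sd": (0.004, 0.002),
        "K2_WB_skewness": (1.5, 0.5),
        "K2_WB_kurtosis": (6.0, 2.0),
        "CCBV_ROI_mean": (1.8, 0.5),
        "CCBV_ROI_sd": (0.5, 0.15),
        "CCBV_ROI_skewness": (0.7, 0.4),
        "CCBV_ROI_kurtosis": (4.0, 1.5),
        "CCBV_WB_sd": (0.30, 0.08),
        "CCBV_WB_skewness": (1.0, 0.3),
        "CCBV_WB_kurtosis": (4.5, 1.5),
    }
    return ClassProfile(class_targets=class_targets, shared_targets=shared)


@dataclass
class SyntheticSubject:
    """One phantom subject: raw volumes, masks, label and voxel-wise truth."""

    subject_id: str
    label: str
    dsc_series: DSCSeries
    dwi_b0: np.ndarray
    dwi_b1: np.ndarray
    roi_mask: np.ndarray
    nawm_mask: np.ndarray
    brain_mask: np.ndarray
    ground_truth: dict[str, np.ndarray]
    b_values: tuple[float, float] = (0.0, 1000.0)
    voxel_size_mm: tuple[float, float, float] = (2.5, 2.5, 2.5)

    @property
    def grade(self) -> str:
        return grade_of(self.label)


# ---------------------------------------------------------------------------
# forward models


def gamma_variate_signal(
    A: float,
    alpha: float,
    beta: float,
    t0: float,
    t: np.ndarray,
    S0: float = 100.0,
    TE_s: float = 0.03,
    k2_true: float = 0.0,
    c_ref: np.ndarray | None = None,
) -> np.ndarray:
    """DSC signal of one voxel under gamma-variate bolus passage.

    The intravascular concentration is the gamma-variate
    ``C(t) = A (t-t0)^alpha exp(-(t-t0)/beta)``; leakage lowers the apparent
    relaxation-rate change by ``k2_true`` times the running integral of the
    reference (non-leaky tissue-mean) curve ``c_ref`` — T1-dominant
    extravasation, matching the sign convention the leakage-corrector
    estimates.  Returned as ``S(t) = S0 exp(-TE * dR2*(t))``.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if S0 <= 0:
        raise ValueError("S0 must be positive")
    t = np.asarray(t, dtype=float)
    if not (t[0] <= t0 <= t[-1]):
        raise ValueError("bolus arrival t0 must lie within the time grid")
    conc = gamma_variate(t, A, alpha, beta, t0)
    if k2_true != 0.0:
        ref = conc if c_ref is None else np.asarray(c_ref, dtype=float)
        ref_int = np.concatenate(
            [[0.0], np.cumsum(0.5 * (ref[1:] + ref[:-1]) * np.diff(t))]
        )
        conc = conc - k2_true * ref_int
    return S0 * np.exp(-TE_s * conc)


def diffusion_signal(adc_true: float | np.ndarray, b: float, S0: float | np.ndarray):
    """Mono-exponential DWI signal ``S0 exp(-b * ADC)``; ``adc_true`` in
    physical mm^2/s."""
    if b < 0:
        raise ValueError("b-value must be non-negative")
    adc_true = np.asarray(adc_true, dtype=float)
    if (adc_true < 0).any():
        raise ValueError("adc_true must be non-negative")
    if np.any(np.asarray(S0) <= 0):
        raise ValueError("S0 must be positive")
    return S0 * np.exp(-b * adc_true)


# ---------------------------------------------------------------------------
# phantom geometry helpers


def _ellipsoid_mask(shape: tuple[int, int, int], fraction: float = 0.9) -> np.ndarray:
    centre = (np.asarray(shape) - 1) / 2.0
    semi = fraction * np.asarray(shape) / 2.0
    grid = np.indices(shape).astype(float)
    d2 = sum(((grid[i] - centre[i]) / semi[i]) ** 2 for i in range(3))
    return d2 <= 1.0


def _sphere_mask(shape, centre, radius_vox) -> np.ndarray:
    grid = np.indices(shape).astype(float)
    d2 = sum((grid[i] - centre[i]) ** 2 for i in range(3))
    return d2 <= radius_vox**2


def _skewed_noise(rng: np.random.Generator, n: int, sd: float, shape_k: float) -> np.ndarray:
    """Zero-mean positively skewed (gamma) noise with given SD; skewness
    2/sqrt(shape_k)."""
    g = rng.gamma(shape_k, 1.0, size=n)
    g = (g - shape_k) / np.sqrt(shape_k)  # zero mean, unit sd
    return sd * g


def _centered(values: np.ndarray, target_mean: float, floor: float) -> np.ndarray:
    """Shift to the target mean, clip at the floor, re-centre once."""
    v = values - values.mean() + target_mean
    v = np.clip(v, floor, None)
    return v - v.mean() + target_mean


# ---------------------------------------------------------------------------
# cohort generation


def _truncated_normal(rng, mean, sd, lo, hi=np.inf, max_tries=100):
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def generate_subject(
    config: CohortConfig,
    profile: ClassProfile,
    label: str,
    subject_id: str,
    rng: np.random.Generator,
) -> SyntheticSubject:
    """Build one phantom subject for the given tumour class."""
    shape = tuple(config.grid_shape)
    voxel_vol_mm3 = float(np.prod(config.voxel_size_mm))
    brain = _ellipsoid_mask(shape)
    n_brain = int(brain.sum())
    brain_vol_cm3 = n_brain * voxel_vol_mm3 / 1000.0

    # --- tumour ROI: sphere with class-conditional volume -----------------
    vol_mean, vol_sd = profile.target(label, VOLUME_COLUMN)
    vol_cap = 0.25 * brain_vol_cm3
    if vol_cap < 0.15:
        raise ValueError(
            f"grid {shape} (brain volume {brain_vol_cm3:.2f} cm^3) is too "
            "small to host a tumour ROI"
        )
    vol_cm3 = _truncated_normal(rng, vol_mean, vol_sd, 0.15, vol_cap)
    radius_mm = (3.0 * vol_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    radius_vox = radius_mm / config.voxel_size_mm[0]
    if 2 * radius_vox >= min(shape):
        raise ValueError(
            f"tumour radius {radius_vox:.1f} voxels does not fit grid {shape}"
        )

    # NAWM reference: small sphere in one brain hemisphere
    centre = (np.asarray(shape) - 1) / 2.0
    nawm_centre = centre + np.array([-shape[0] * 0.22, -shape[1] * 0.22, 0.0])
    nawm = _sphere_mask(shape, nawm_centre, 2.2) & brain
    # place the ROI inside the brain, clear of the NAWM sphere
    for _ in range(200):
        offset = rng.uniform(-0.18, 0.18, size=3) * np.asarray(shape)
        roi_centre = centre + offset + np.array([shape[0] * 0.08, shape[1] * 0.08, 0.0])
        roi = _sphere_mask(shape, roi_centre, radius_vox)
        if (roi & ~brain).sum() == 0 and not (roi & nawm).any():
            break
    else:
        raise ValueError("could not place tumour ROI inside the brain mask")

    # --- ground-truth ADC (1e-3 mm^2/s scale) -----------------------------
    adc = np.zeros(shape)
    wb_mean = _truncated_normal(rng, *profile.target(label, "ADC_WB_mean"), 0.2)
    bg = brain & ~roi
    adc[bg] = _centered(
        wb_mean + _skewed_noise(rng, int(bg.sum()), 0.20, 4.0), wb_mean, 0.05
    )
    roi_mean = _truncated_normal(rng, *profile.target(label, "ADC_ROI_mean"), 0.2)
    adc[roi] = _centered(
        roi_mean + _skewed_noise(rng, int(roi.sum()), 0.25, 1.8), roi_mean, 0.05
    )

    # --- ground-truth bolus amplitude and leakage -------------------------
    a_wm = config.nawm_amplitude
    amp = np.zeros(shape)
    wb_ratio = _truncated_normal(rng, *profile.target(label, "CCBV_WB_mean"), 0.3)
    amp[bg] = _centered(
        wb_ratio * a_wm + _skewed_noise(rng, int(bg.sum()), 0.15 * a_wm, 4.0),
        wb_ratio * a_wm, 0.05 * a_wm,
    )
    roi_ratio = _truncated_normal(rng, 1.5, 0.3, 0.5)
    amp[roi] = _centered(
        roi_ratio * a_wm + _skewed_noise(rng, int(roi.sum()), 0.2 * a_wm, 3.0),
        roi_ratio * a_wm, 0.05 * a_wm,
    )
    amp[nawm] = a_wm  # NAWM is the homogeneous calibration reference

    k2_map = np.zeros(shape)
    k2_map[roi] = rng.uniform(0.005, 0.03)  # leaky tumour, intact BBB elsewhere

    # --- DWI volumes ------------------------------------------------------
    b0, b1 = config.b_values_s_per_mm2
    adc_phys = adc * 1e-3
    dwi_b0 = np.where(brain, diffusion_signal(adc_phys, b0, config.dwi_s0), 1.0)
    dwi_b1 = np.where(brain, diffusion_signal(adc_phys, b1, config.dwi_s0), 1.0)

    # --- DSC series -------------------------------------------------------
    t = config.time_grid
    shape_curve = gamma_variate(
        t, 1.0, config.bolus_alpha, config.bolus_beta_s, config.bolus_t0_s
    )
    # reference curve: mean non-leaky curve over non-enhancing brain tissue
    c_ref = float(amp[bg].mean()) * shape_curve
    ref_int = np.concatenate(
        [[0.0], np.cumsum(0.5 * (c_ref[1:] + c_ref[:-1]) * np.diff(t))]
    )
    conc = amp[..., None] * shape_curve - k2_map[..., None] * ref_int
    dsc = np.where(
        brain[..., None], config.dsc_s0 * np.exp(-config.TE_s * conc), 1.0
    )

    if config.noise_sd > 0:
        dsc = dsc + rng.normal(0.0, config.noise_sd, size=dsc.shape)
        dwi_b0 = dwi_b0 + rng.normal(0.0, config.noise_sd, size=shape)
        dwi_b1 = dwi_b1 + rng.normal(0.0, config.noise_sd, size=shape)

    baseline_end = max(2, int(np.floor(config.bolus_t0_s / config.TR_s)) - 1)
    series = DSCSeries(
        signal=dsc, t=t, TE_s=config.TE_s, baseline_window=(0, baseline_end)
    )
    return SyntheticSubject(
        subject_id=subject_id,
        label=label,
        dsc_series=series,
        dwi_b0=dwi_b0,
        dwi_b1=dwi_b1,
        roi_mask=roi,
        nawm_mask=nawm,
        brain_mask=brain,
        ground_truth={"adc": adc, "amplitude": amp, "k2": k2_map},
        b_values=(b0, b1),
        voxel_size_mm=tuple(config.voxel_size_mm),
    )


def iter_cohort(config: CohortConfig, profile: ClassProfile | None = None):
    """Yield phantom subjects one at a time (memory-friendly for large grids)."""
    profile = profile or default_class_profile()
    rng = np.random.default_rng(config.seed)
    for i, label in enumerate(config.labels):
        yield generate_subject(config, profile, label, f"sub-{i + 1:03d}", rng)


def generate_cohort(
    config: CohortConfig, profile: ClassProfile | None = None
) -> list[SyntheticSubject]:
    """Generate the full phantom cohort (deterministic under ``config.seed``)."""
    return list(iter_cohort(config, profile))


# ---------------------------------------------------------------------------
# feature-space sampling


def sample_feature_table(
    n_per_class: tuple[int, int, int] = (22, 17, 10),
    profile: ClassProfile | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a subjects x 33-features table directly from the class profiles.

    Each feature is drawn independently from its class-conditional (or
    shared) normal distribution; tumour volume is truncated at 0.1 cm^3.
    This is the fast path for statistical-power and classification
    experiments that need many cohort realisations.
    """
    profile = profile or default_class_profile()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    ids = []
    i = 0
    for cls, n in zip(CLASS_NAMES, n_per_class):
        for _ in range(n):
            i += 1
            row = {}
            for col in FEATURE_COLUMNS:
                mean, sd = profile.target(cls, col)
                val = rng.normal(mean, sd)
                if col == VOLUME_COLUMN:
                    val = max(val, 0.1)
                row[col] = val
            row["label"] = cls
            row["grade"] = grade_of(cls)
            rows.append(row)
            ids.append(f"sub-{i:03d}")
    table = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"))
    return table[list(FEATURE_COLUMNS) + ["label", "grade"]]
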
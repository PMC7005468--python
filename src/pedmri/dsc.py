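"""DSC-MRI perfusion quantification.

Converts dynamic susceptibility contrast signal time courses into
cerebral-blood-volume maps:

1. signal -> relaxation-rate change ``dR2*(t) = -ln(S/S_base)/TE``, which is
   proportional to contrast-agent concentration;
2. voxel-wise gamma-variate fit ``C(t) = A (t-t0)^a exp(-(t-t0)/b)`` of the
   first-pass bolus; the uncorrected CBV (UCBV) is its analytic time
   integral ``A b^(a+1) Gamma(a+1)``;
3. Boxerman-style leakage correction: each voxel's dR2* curve is regressed
   on the mean non-enhancing-tissue curve and its running integral; the
   negated coefficient on the integral term is the leakage rate K2, and the
   corrected CBV is ``CCBV = UCBV + K2 * double-integral of the reference
   curve``, so a leak-free voxel has CCBV == UCBV;
4. QC masking (fit-RMSE threshold and an absolute-CBV ceiling of
   3.0 mL/100g/min) and normalisation to normal-appearing white matter.

The absolute calibration from arbitrary relaxation-rate units to
mL/100g/min is a single per-subject scalar pinning the NAWM mean to a
reference value; because maps are subsequently NAWM-normalised, features
downstream are insensitive to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import gamma as gamma_fn

__all__ = [
    "DSCSeries",
    "GammaVariateFit",
    "PerfusionMaps",
    "gamma_variate",
    "gamma_variate_integral",
    "signal_to_delta_r2star",
    "fit_gamma_variate",
    "fit_gamma_variate_volume",
    "compute_ucbv",
    "reference_curve",
    "leakage_correct",
    "apply_qc_mask",
    "normalise_to_nawm",
    "quantify_subject",
]


@dataclass
class DSCSeries:
    """A 4-D DSC acquisition: signal S(x, y, z, t) plus timing metadata."""

    signal: np.ndarray
    t: np.ndarray
    TE_s: float
    baseline_window: tuple[int, int] = (0, 5)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("DSC signal must be 4-D (x, y, z, t)")
        if self.signal.shape[-1] != self.t.size:
            raise ValueError("time grid length does not match signal")
        if self.t.size < 10:
            raise ValueError("DSC series needs at least 10 timepoints")
        if self.TE_s <= 0:
            raise ValueError("TE must be positive")
        lo, hi = self.baseline_window
        if not (0 <= lo < hi <= self.t.size):
            raise ValueError(f"invalid baseline window {self.baseline_window}")


@dataclass
class GammaVariateFit:
    """Per-voxel bolus-fit result."""

    A: float = 0.0
    alpha: float = np.nan
    beta: float = np.nan
    t0: float = np.nan
    rmse: float = np.inf
    converged: bool = False


@dataclass
class PerfusionMaps:
    """UCBV / K2 / CCBV volumes with QC bookkeeping.

    ``ucbv`` and ``ccbv`` are in mL/100g/min before normalisation and in
    NAWM-relative units afterwards; ``qc_mask`` flags voxels surviving the
    RMSE and CBV-ceiling masking.
    """

    ucbv: np.ndarray
    k2: np.ndarray
    ccbv: np.ndarray
    qc_mask: np.ndarray
    rmse: np.ndarray | None = None
    normalised: bool = False
    nawm_reference: dict = field(default_factory=dict)


def gamma_variate(t, A, alpha, beta, t0):
    """Gamma-variate bolus curve A*(t-t0)^alpha * exp(-(t-t0)/beta), 0 before t0."""
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - t0, 0.0, None)
    with np.errstate(invalid="ignore"):
        c = A * dt**alpha * np.exp(-dt / beta)
    return np.where(t > t0, c, 0.0)


def gamma_variate_integral(A: float, alpha: float, beta: float) -> float:
    """Closed-form integral of the gamma-variate over [t0, inf):
    ``A * beta**(alpha+1) * Gamma(alpha+1)``."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    return A * beta ** (alpha + 1.0) * gamma_fn(alpha + 1.0)


def signal_to_delta_r2star(
    series: DSCSeries, brain_mask: np.ndarray | None = None
) -> np.ndarray:
    """Convert signal to dR2*(t) = -(1/TE) ln(S(t)/S_baseline) per voxel.

    Voxels whose baseline mean or signal is non-positive (inside the mask)
    cannot be log-transformed; they are returned as NaN curves and should be
    excluded from the QC mask by the caller.
    """
    lo, hi = series.baseline_window
    s0 = series.signal[..., lo:hi].mean(axis=-1, keepdims=True)
    valid = (s0[..., 0] > 0) & (series.signal > 0).all(axis=-1)
    if brain_mask is not None:
        valid &= brain_mask.astype(bool)
    conc = np.full(series.signal.shape, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = series.signal / s0
    conc[valid] = -np.log(ratio[valid]) / series.TE_s
    return conc


def _initial_guess(conc: np.ndarray, t: np.ndarray) -> tuple[float, float, float, float]:
    """Seed (A, alpha, beta, t0) for the nonlinear fit.

    t0 is seeded at the first time the curve reaches 10% of its peak
    (earliest index on ties); alpha at 3; beta from the peak time via the
    mode relation t_peak = t0 + alpha*beta; A from the peak height.
    """
    peak_idx = int(np.argmax(conc))
    peak = conc[peak_idx]
    alpha0 = 3.0
    above = np.nonzero(conc >= 0.1 * peak)[0]
    start = above[0] if above.size else 0
    t0_0 = t[start] - (t[1] - t[0]) if start > 0 else t[0]
    t0_0 = min(t0_0, t[peak_idx] - 1e-3)
    beta0 = max((t[peak_idx] - t0_0) / alpha0, 1e-2)
    mode_height = (alpha0 * beta0) ** alpha0 * np.exp(-alpha0)
    A0 = max(peak / mode_height, 1e-12)
    return A0, alpha0, beta0, t0_0


def fit_gamma_variate(conc: np.ndarray, t: np.ndarray) -> GammaVariateFit:
    """Nonlinear least-squares gamma-variate fit of one voxel curve.

    Returns ``converged=False`` (with the all-zero convention A=0) for flat,
    non-finite or optimiser-failing curves; such voxels contribute nothing
    to CBV and are dropped from the QC mask.
    """
    conc = np.asarray(conc, dtype=float)
    t = np.asarray(t, dtype=float)
    if conc.size < 10:
        raise ValueError("need at least 10 samples to fit a bolus curve")
    if not np.isfinite(conc).all():
        return GammaVariateFit()
    if np.allclose(conc, 0.0) or conc.max() <= 0:
        return GammaVariateFit(A=0.0)

    p0 = _initial_guess(conc, t)
    lower = [0.0, 1e-3, 1e-3, t[0] - (t[-1] - t[0])]
    upper = [np.inf, 50.0, t[-1], t[-1]]
    p0 = tuple(np.clip(p0, lower, upper))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                gamma_variate, t, conc, p0=p0, bounds=(lower, upper), maxfev=2000
            )
    except (RuntimeError, ValueError):
        return GammaVariateFit()
    A, alpha, beta, t0 = popt
    resid = gamma_variate(t, *popt) - conc
    rmse = float(np.sqrt(np.mean(resid**2)))
    ok = alpha > 0 and beta > 0 and np.isfinite(rmse)
    return GammaVariateFit(
        A=float(A), alpha=float(alpha), beta=float(beta), t0=float(t0),
        rmse=rmse, converged=bool(ok),
    )


def fit_gamma_variate_volume(
    conc: np.ndarray, t: np.ndarray, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit every in-mask voxel; returns (raw integral map, rmse map, converged map)."""
    shape = conc.shape[:-1]
    integral = np.zeros(shape)
    rmse = np.full(shape, np.inf)
    converged = np.zeros(shape, dtype=bool)
    for idx in zip(*np.nonzero(mask)):
        fit = fit_gamma_variate(conc[idx], t)
        rmse[idx] = fit.rmse
        converged[idx] = fit.converged
        if fit.converged:
            integral[idx] = gamma_variate_integral(fit.A, fit.alpha, fit.beta)
    return integral, rmse, converged


def compute_ucbv(fit: GammaVariateFit, scale: float = 1.0) -> float:
    """UCBV of one voxel: the analytic gamma-variate integral times the
    mL/100g/min calibration scale.  Non-converged fits are NaN (masked)."""
    if not fit.converged:
        return np.nan
    if fit.A == 0:
        return 0.0
    return scale * gamma_variate_integral(fit.A, fit.alpha, fit.beta)


def reference_curve(
    conc: np.ndarray, t: np.ndarray, reference_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Mean dR2* curve over the non-enhancing reference tissue, its running
    integral, and the double integral over the acquisition window."""
    rbar = np.nanmean(conc[reference_mask.astype(bool)], axis=0)
    rbar_int = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rbar[1:] + rbar[:-1]) * np.diff(t))]
    )
    return rbar, rbar_int, float(np.trapezoid(rbar_int, t))


def leakage_correct(
    conc: np.ndarray,
    t: np.ndarray,
    reference_mask: np.ndarray,
    ucbv_raw: np.ndarray | None = None,
    fit_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Boxerman-style leakage correction.

    Each voxel's dR2*(t) is regressed on the mean curve R(t) over the
    non-enhancing ``reference_mask`` and its running integral:

        dR2*_v(t) ~ K1 * R(t) - K2 * int_0^t R(tau) dtau

    K2 (the negated integral coefficient) measures contrast extravasation
    through a disrupted blood-brain barrier; the corrected blood volume adds
    back the leaked area, ``CCBV = UCBV + K2 * int int R``, so K2 = 0 voxels
    keep CCBV == UCBV exactly.

    Parameters
    ----------
    conc:
        4-D dR2* array (NaN outside the brain).
    ucbv_raw:
        Optional raw (uncalibrated) UCBV map; when given, the corrected map
        ``ccbv_raw`` is returned on the same scale, otherwise the trapezoid
        integral of the observed curves is corrected instead.
    fit_mask:
        Voxels to correct; defaults to all finite curves.

    Returns
    -------
    (k2 map, ccbv_raw map)
    """
    reference_mask = reference_mask.astype(bool)
    if not reference_mask.any():
        raise ValueError("reference mask is empty")
    rbar, rbar_int, rbar_double_int = reference_curve(conc, t, reference_mask)

    if fit_mask is None:
        fit_mask = np.isfinite(conc).all(axis=-1)
    fit_mask = fit_mask.astype(bool)

    k2 = np.full(conc.shape[:-1], np.nan)
    ccbv = np.full(conc.shape[:-1], np.nan)

    X = np.column_stack([rbar, rbar_int])
    # flat reference curve gives degenerate regressors: skip correction
    if np.linalg.matrix_rank(X) < 2 or np.allclose(rbar, rbar[0]):
        warnings.warn(
            "reference curve is degenerate; leakage correction skipped "
            "(CCBV = UCBV)", stacklevel=2,
        )
        k2[fit_mask] = 0.0
        if ucbv_raw is not None:
            ccbv[fit_mask] = ucbv_raw[fit_mask]
        else:
            ccbv[fit_mask] = np.trapezoid(conc[fit_mask], t, axis=-1)
        return k2, ccbv

    Y = conc[fit_mask]  # (n_voxels, n_t)
    coef, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (2, n_voxels)
    k2_vals = -coef[1]
    k2[fit_mask] = k2_vals

    if ucbv_raw is not None:
        base = ucbv_raw[fit_mask]
    else:
        base = np.trapezoid(Y, t, axis=-1)
    ccbv[fit_mask] = base + k2_vals * rbar_double_int
    return k2, ccbv


def apply_qc_mask(
    maps: PerfusionMaps,
    rmse_threshold: float,
    cbv_ceiling: float = 3.0,
) -> PerfusionMaps:
    """Remove voxels with noisy fits or implausible CBV from the QC mask.

    A voxel survives iff its fit RMSE is <= ``rmse_threshold`` AND both
    |UCBV| and |CCBV| are <= ``cbv_ceiling`` (mL/100g/min,
    pre-normalisation).  Values themselves are untouched; masking is pure
    bookkeeping and therefore idempotent.
    """
    if maps.rmse is None:
        raise ValueError("maps carry no rmse volume; fit first")
    keep = maps.qc_mask.astype(bool).copy()
    keep &= maps.rmse <= rmse_threshold
    with np.errstate(invalid="ignore"):
        keep &= np.abs(np.nan_to_num(maps.ucbv, nan=np.inf)) <= cbv_ceiling
        keep &= np.abs(np.nan_to_num(maps.ccbv, nan=np.inf)) <= cbv_ceiling
    if not keep.any():
        warnings.warn("QC mask is empty after thresholding", stacklevel=2)
    return PerfusionMaps(
        ucbv=maps.ucbv, k2=maps.k2, ccbv=maps.ccbv, qc_mask=keep,
        rmse=maps.rmse, normalised=maps.normalised,
        nawm_reference=dict(maps.nawm_reference),
    )


def normalise_to_nawm(
    volume: np.ndarray, nawm_mask: np.ndarray, statistic: str = "mean"
) -> tuple[np.ndarray, float]:
    """Divide a map by its mean (or median) over normal-appearing white
    matter, making NAWM the unit of CBV.  Returns (normalised map, reference
    value used)."""
    nawm_mask = nawm_mask.astype(bool)
    if not nawm_mask.any():
        raise ValueError("NAWM mask is empty")
    vals = volume[nawm_mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("NAWM mask contains no finite values")
    ref = float(np.mean(vals) if statistic == "mean" else np.median(vals))
    if abs(ref) < 1e-12:
        raise ValueError("NAWM reference value is zero; cannot normalise")
    return volume / ref, ref


def _dilate(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    from scipy.ndimage import binary_dilation

    return binary_dilation(mask, iterations=iterations)


def quantify_subject(
    series: DSCSeries,
    brain_mask: np.ndarray,
    roi_mask: np.ndarray,
    nawm_mask: np.ndarray,
    nawm_cbv_reference: float = 0.1,
    rmse_quantile: float = 0.9,
    cbv_ceiling: float = 3.0,
    normalise: bool = True,
    nawm_statistic: str = "mean",
) -> PerfusionMaps:
    """Full per-subject DSC pipeline: dR2* conversion, leakage-rate (K2)
    estimation against non-enhancing tissue (brain minus the dilated tumour
    ROI), voxel-wise gamma-variate fits of the leakage-corrected curves,
    NAWM calibration to ``nawm_cbv_reference`` mL/100g/min, QC masking and
    NAWM normalisation.

    K2 is estimated first because it needs only a linear regression; the
    bolus fit then runs on the corrected curve (pure first-pass shape plus
    noise), so the fit RMSE measures noise rather than extravasation and
    the RMSE threshold — the ``rmse_quantile`` quantile of in-brain RMSE,
    default 90th percentile — rejects noisy voxels without discarding leaky
    tumour tissue.  CCBV is the integral of the corrected fit; UCBV removes
    the add-back again (``UCBV = CCBV - K2 * double-integral``), so the two
    coincide exactly wherever K2 = 0.  The default NAWM reference of
    0.1 mL/100g/min matches the scale on which whole-brain UCBV means of
    ~0.11-0.13 are reported for this acquisition, leaving the 3.0 ceiling to
    catch only implausible fits; downstream features are NAWM-normalised
    and therefore insensitive to the exact reference.
    """
    brain_mask = brain_mask.astype(bool)
    conc = signal_to_delta_r2star(series, brain_mask)
    fit_mask = brain_mask & np.isfinite(conc).all(axis=-1)

    reference_mask = brain_mask & ~_dilate(roi_mask.astype(bool)) & fit_mask
    k2, _ = leakage_correct(conc, series.t, reference_mask, fit_mask=fit_mask)
    _, rbar_int, rbar_double = reference_curve(conc, series.t, reference_mask)

    # corrected curves restore the leaked area: pure bolus shape + noise
    conc_corr = conc + np.nan_to_num(k2)[..., None] * rbar_int
    integral_corr, rmse, converged = fit_gamma_variate_volume(
        conc_corr, series.t, fit_mask
    )

    # calibrate arbitrary units -> mL/100g/min by pinning the NAWM mean
    nawm = nawm_mask.astype(bool) & converged
    if not nawm.any():
        raise ValueError("no converged NAWM voxels; cannot calibrate CBV")
    scale = nawm_cbv_reference / integral_corr[nawm].mean()

    ccbv = np.where(converged, integral_corr * scale, np.nan)
    ucbv = np.where(
        converged, (integral_corr - np.nan_to_num(k2) * rbar_double) * scale,
        np.nan,
    )

    maps = PerfusionMaps(
        ucbv=ucbv, k2=k2, ccbv=ccbv, qc_mask=converged, rmse=rmse,
        nawm_reference={"calibration_scale": float(scale)},
    )
    finite_rmse = rmse[fit_mask & np.isfinite(rmse)]
    thr = float(np.quantile(finite_rmse, rmse_quantile)) if finite_rmse.size else np.inf
    maps = apply_qc_mask(maps, rmse_threshold=thr, cbv_ceiling=cbv_ceiling)

    if normalise:
        ucbv_n, ref_u = normalise_to_nawm(maps.ucbv, nawm, statistic=nawm_statistic)
        ccbv_n, ref_c = normalise_to_nawm(maps.ccbv, nawm, statistic=nawm_statistic)
        maps = PerfusionMaps(
            ucbv=ucbv_n, k2=maps.k2, ccbv=ccbv_n, qc_mask=maps.qc_mask,
            rmse=maps.rmse, normalised=True,
            nawm_reference={
                **maps.nawm_reference,
                "ucbv_reference": ref_u,
                "ccbv_reference": ref_c,
                "statistic": nawm_statistic,
            },
        )
    return maps
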
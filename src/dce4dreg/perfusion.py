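"""Extended Tofts pharmacokinetic modeling of DCE enhancement curves.

The extended Tofts model describes tissue contrast-agent concentration as

    C_t(t) = v_p * C_p(t) + Ktrans * int_0^t C_p(tau) exp(-k_ep (t - tau)) dtau

with k_ep = Ktrans / v_e, where C_p is the arterial input function (AIF),
Ktrans the volume transfer constant (min^-1), v_e the extravascular-
extracellular and v_p the plasma volume fraction.  Voxel-wise bounded
nonlinear least squares yields parameter maps and a per-voxel RMSE
("residual error") that serves as an objective, physiology-aware surrogate
for motion: misaligned voxels mix tissue types across timepoints and fit
the model poorly.

The fitted quantity is relative enhancement (S(t) - S(t0)) / S(t0) of the
postcontrast frames, treated as proportional to concentration; without a T1
map the proportionality constant is absorbed into the AIF units, so
clinical Ktrans values are in population-AIF-normalized units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = ["Aif", "ToftsParams", "ToftsFitResult", "ExtendedToftsModel",
           "aif_value", "tofts_concentration", "fit_voxel", "fit_roi",
           "residual_percentiles", "DEFAULT_BOUNDS"]

# Weinmann-type population AIF constants: dose in mmol per kg body weight,
# amplitudes in kg/L, rates in 1/min; C_p comes out in mM.
WEINMANN_D = 0.1
WEINMANN_A = (3.99, 4.78)
WEINMANN_M = (0.144, 0.0111)

#: (lower, upper) fitting bounds: Ktrans [min^-1], v_e, v_p (fractions).
DEFAULT_BOUNDS = ((0.0, 0.01, 0.0), (5.0, 1.0, 0.5))


@dataclass
class Aif:
    """Arterial input function C_p(t), mM.

    ``form="biexponential"`` uses D*(a1*exp(-m1*t') + a2*exp(-m2*t')) with
    t' in minutes (Weinmann-type population constants by default);
    ``form="user_sampled"`` linearly interpolates measured (time_s,
    concentration_mM) pairs, 0 before the first sample.
    """

    form: str = "biexponential"
    dose: float = WEINMANN_D
    a1: float = WEINMANN_A[0]
    a2: float = WEINMANN_A[1]
    m1: float = WEINMANN_M[0]
    m2: float = WEINMANN_M[1]
    samples: np.ndarray | None = None  # (n, 2): time_s, conc_mM

    def __post_init__(self) -> None:
        if self.form not in ("biexponential", "user_sampled"):
            raise ValueError(f"unknown AIF form: {self.form}")
        if self.form == "user_sampled":
            self.samples = np.asarray(self.samples, dtype=float)
            if self.samples.ndim != 2 or self.samples.shape[1] != 2:
                raise ValueError("user_sampled AIF needs (n, 2) samples")

    def __call__(self, t_seconds) -> np.ndarray:
        return aif_value(self, t_seconds)


def aif_value(aif: Aif, t_seconds) -> np.ndarray:
    """Plasma concentration (mM) at time(s) ``t_seconds`` (>= 0)."""
    t = np.asarray(t_seconds, dtype=float)
    if np.any(t < 0):
        raise ValueError("AIF is undefined for negative times")
    if aif.form == "biexponential":
        tm = t / 60.0
        out = aif.dose * (aif.a1 * np.exp(-aif.m1 * tm)
                          + aif.a2 * np.exp(-aif.m2 * tm))
    else:
        ts, cs = aif.samples[:, 0], aif.samples[:, 1]
        out = np.interp(t, ts, cs, left=0.0, right=float(cs[-1]))
    return out if out.ndim else float(out)


@dataclass
class ToftsParams:
    """Extended Tofts parameters: Ktrans (min^-1), v_e, v_p (fractions)."""

    ktrans: float
    ve: float
    vp: float

    def __post_init__(self) -> None:
        if self.ktrans < 0:
            raise ValueError("Ktrans must be >= 0")
        if not (0 < self.ve <= 1):
            raise ValueError("ve must lie in (0, 1]")
        if not (0 <= self.vp < 1):
            raise ValueError("vp must lie in [0, 1)")


def _biexp_convolution(t_min: np.ndarray, kep: float, aif: Aif) -> np.ndarray:
    """Closed form of int_0^t C_p(tau) exp(-kep (t - tau)) dtau, t in minutes.

    For each AIF exponential a*exp(-m t): a*(exp(-m t) - exp(-kep t))/(kep - m),
    degenerating to a*t*exp(-m t) when kep == m.
    """
    out = np.zeros_like(t_min)
    for a, m in ((aif.a1, aif.m1), (aif.a2, aif.m2)):
        if abs(kep - m) < 1e-9:
            out += a * t_min * np.exp(-m * t_min)
        else:
            out += a * (np.exp(-m * t_min) - np.exp(-kep * t_min)) / (kep - m)
    return aif.dose * out


def _sampled_convolution(t_s: np.ndarray, kep_per_min: float, aif: Aif,
                         dt_s: float = 0.1) -> np.ndarray:
    """Trapezoid convolution on a fine uniform grid (any AIF form).

    Uses the numerically stable recursion
    conv[i+1] = conv[i]*exp(-kep dt) + trapezoid increment, so large k_ep
    values cannot overflow.  Result is in mM*min.
    """
    if np.ndim(t_s) == 0:
        t_s = np.asarray([t_s], dtype=float)
    t_s = np.asarray(t_s, dtype=float)
    if t_s.size == 0:
        return t_s.copy()
    tmax = float(np.max(t_s))
    grid = np.arange(0.0, tmax + dt_s, dt_s)
    cp = np.asarray(aif_value(aif, grid), dtype=float)
    dt_min = dt_s / 60.0
    decay = np.exp(-kep_per_min * dt_min)
    conv = np.empty_like(grid)
    conv[0] = 0.0
    for i in range(grid.size - 1):
        conv[i + 1] = conv[i] * decay + 0.5 * dt_min * (cp[i + 1]
                                                        + cp[i] * decay)
    return np.interp(t_s, grid, conv)


def tofts_concentration(times_s, params: ToftsParams, aif: Aif) -> np.ndarray:
    """Tissue concentration (mM) at the given times (seconds, increasing)."""
    t = np.asarray(times_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if params.ktrans > 0 and params.ve <= 0:
        raise ValueError("ve = 0 with Ktrans > 0: k_ep undefined")
    cp = np.asarray(aif_value(aif, t), dtype=float)
    out = params.vp * cp
    if params.ktrans > 0:
        kep = params.ktrans / params.ve
        if aif.form == "biexponential":
            out = out + params.ktrans * _biexp_convolution(t / 60.0, kep, aif)
        else:
            out = out + params.ktrans * _sampled_convolution(t, kep, aif)
    return out


@dataclass
class ToftsFitResult:
    """Voxel-wise extended Tofts fit: parameter maps plus residual errors.

    ``ktrans``, ``ve``, ``vp`` and ``residual`` are 3D maps (NaN outside the
    fitted ROI); ``residual`` is the per-voxel RMSE of the model fit over
    the fitted timepoints — the objective motion surrogate.
    """

    ktrans: np.ndarray
    ve: np.ndarray
    vp: np.ndarray
    residual: np.ndarray
    n_timepoints: int
    roi_mask: np.ndarray | None = None
    percentile_grid: np.ndarray = field(
        default_factory=lambda: np.arange(10, 91, 10))

    def roi_values(self, name: str) -> np.ndarray:
        arr = getattr(self, name)
        if self.roi_mask is not None:
            return arr[self.roi_mask]
        return arr[np.isfinite(arr)]

    @property
    def ktrans_mean(self) -> float:
        return float(np.mean(self.roi_values("ktrans")))

    @property
    def ktrans_sd(self) -> float:
        return float(np.std(self.roi_values("ktrans"), ddof=1))

    def residual_percentiles(self, percentiles=None) -> np.ndarray:
        pct = self.percentile_grid if percentiles is None else percentiles
        return residual_percentiles(self.residual, self.roi_mask, pct)

    def summary(self) -> str:
        n = int(self.roi_mask.sum()) if self.roi_mask is not None else \
            int(np.isfinite(self.ktrans).sum())
        pct = self.residual_percentiles()
        lines = [
            "Extended Tofts ROI fit",
            "=" * 46,
            f"voxels fitted        {n}",
            f"timepoints used      {self.n_timepoints}",
            f"Ktrans mean (SD)     {self.ktrans_mean:.4f} ({self.ktrans_sd:.4f}) 1/min",
            f"ve mean              {np.mean(self.roi_values('ve')):.4f}",
            f"vp mean              {np.mean(self.roi_values('vp')):.4f}",
            "residual percentiles (RMSE of enhancement fit):",
        ]
        for p, v in zip(np.atleast_1d(self.percentile_grid), pct):
            lines.append(f"  p{int(p):02d}  {v:.5f}")
        return "\n".join(lines)


def _start_grid(bounds) -> np.ndarray:
    """Deterministic 3x3x2 multistart grid inside the bounds (no RNG)."""
    lo, hi = np.asarray(bounds[0], float), np.asarray(bounds[1], float)
    kt = np.array([0.02, 0.15, 0.8])
    ve = np.array([0.1, 0.3, 0.7])
    vp = np.array([0.01, 0.1])
    kt = np.clip(kt, lo[0] + 1e-6, hi[0] - 1e-6)
    ve = np.clip(ve, lo[1] + 1e-6, hi[1] - 1e-6)
    vp = np.clip(vp, lo[2] + 1e-6, hi[2] - 1e-6)
    grid = np.array(np.meshgrid(kt, ve, vp, indexing="ij")).reshape(3, -1).T
    return grid


def fit_voxel(curve, times_s, aif: Aif, bounds=DEFAULT_BOUNDS,
              multistart: int = 3) -> tuple[ToftsParams, float]:
    """Fit one enhancement curve; returns (params, RMSE residual).

    Bounded trust-region least squares over (Ktrans, ve, vp).  Starts are a
    deterministic 3x3x2 grid; the ``multistart`` best by initial cost are
    refined and the lowest final cost wins, dodging local minima without
    randomness.
    """
    y = np.asarray(curve, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if y.size != t.size:
        raise ValueError("curve and times lengths differ")
    if t.size < 4:
        raise ValueError("need at least 4 timepoints to fit 3 parameters")
    if np.all(~np.isfinite(y)):
        raise ValueError("all-NaN curve")
    lo = np.asarray(bounds[0], float)
    hi = np.asarray(bounds[1], float)

    cp = np.asarray(aif_value(aif, t), dtype=float)
    tm = t / 60.0

    def model(theta):
        kt, ve, vp = theta
        out = vp * cp
        if kt > 0:
            kep = kt / ve
            if aif.form == "biexponential":
                out = out + kt * _biexp_convolution(tm, kep, aif)
            else:
                out = out + kt * _sampled_convolution(t, kep, aif)
        return out

    def resid(theta):
        return model(theta) - y

    starts = _start_grid(bounds)
    costs = np.array([float(np.sum(resid(s) ** 2)) for s in starts])
    order = np.argsort(costs)[:max(1, int(multistart))]
    best = None
    for k in order:
        sol = least_squares(resid, starts[k], bounds=(lo, hi),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400)
        if best is None or sol.cost < best.cost:
            best = sol
    kt, ve, vp = best.x
    rmse = float(np.sqrt(np.mean(best.fun ** 2)))
    return ToftsParams(ktrans=float(kt), ve=float(ve), vp=float(vp)), rmse


def fit_roi(series, roi, aif: Aif | None = None, enhancement_scale: float = 1.0,
            bounds=DEFAULT_BOUNDS, multistart: int = 3) -> ToftsFitResult:
    """Voxel-wise extended Tofts fit over an ROI of a DCE series.

    Relative enhancement (S(t) - S(t0)) / S(t0) of the postcontrast frames,
    divided by ``enhancement_scale`` (signal change per mM when known, 1 for
    AIF-normalized units), is fitted at every ROI voxel.  Maps are NaN
    outside the ROI.
    """
    if aif is None:
        aif = Aif()
    mask = np.asarray(roi.mask if hasattr(roi, "mask") else roi, dtype=bool)
    if mask.shape != series.voxels.shape[:3]:
        raise ValueError("ROI grid does not match series grid")
    if not mask.any():
        raise ValueError("empty ROI")
    if series.n_timepoints < 4 + 1:
        raise ValueError("series needs >= 4 postcontrast timepoints")

    t_post = series.times[1:]
    s0 = series.voxels[mask, 0]
    s0 = np.where(np.abs(s0) < 1e-12, 1e-12, s0)
    enh = (series.voxels[mask, 1:] - s0[:, None]) / s0[:, None]
    enh = enh / enhancement_scale

    shape = mask.shape
    maps = {k: np.full(shape, np.nan) for k in ("ktrans", "ve", "vp",
                                                "residual")}
    idx = np.argwhere(mask)
    for row, (i, j, k) in enumerate(idx):
        params, rmse = fit_voxel(enh[row], t_post, aif, bounds=bounds,
                                 multistart=multistart)
        maps["ktrans"][i, j, k] = params.ktrans
        maps["ve"][i, j, k] = params.ve
        maps["vp"][i, j, k] = params.vp
        maps["residual"][i, j, k] = rmse
    return ToftsFitResult(ktrans=maps["ktrans"], ve=maps["ve"],
                          vp=maps["vp"], residual=maps["residual"],
                          n_timepoints=t_post.size, roi_mask=mask)


def residual_percentiles(residual_map, roi, percentiles=None) -> np.ndarray:
    """Empirical percentiles (linear interpolation) of residuals over an ROI."""
    if percentiles is None:
        percentiles = np.arange(10, 91, 10)
    res = np.asarray(residual_map, dtype=float)
    if roi is None:
        vals = res[np.isfinite(res)]
    else:
        mask = np.asarray(roi.mask if hasattr(roi, "mask") else roi, dtype=bool)
        vals = res[mask]
    if vals.size == 0:
        raise ValueError("empty ROI")
    return np.percentile(vals, percentiles)


class ExtendedToftsModel:
    """Extended Tofts model bound to a DCE series and ROI.

    Statsmodels-style front end: construct with the data, call :meth:`fit`
    for a :class:`ToftsFitResult` carrying parameter maps, residual maps and
    ROI summaries.

    Examples
    --------
    >>> model = ExtendedToftsModel(series, roi)          # doctest: +SKIP
    >>> result = model.fit()                             # doctest: +SKIP
    >>> print(result.summary())                          # doctest: +SKIP
    """

    def __init__(self, series, roi, aif: Aif | None = None,
                 enhancement_scale: float = 1.0, bounds=DEFAULT_BOUNDS,
                 multistart: int = 3):
        self.series = series
        self.roi = roi
        self.aif = aif if aif is not None else Aif()
        self.enhancement_scale = enhancement_scale
        self.bounds = bounds
        self.multistart = multistart

    def fit(self) -> ToftsFitResult:
        return fit_roi(self.series, self.roi, self.aif,
                       enhancement_scale=self.enhancement_scale,
                       bounds=self.bounds, multistart=self.multistart)

    def predict(self, params: ToftsParams, times_s=None) -> np.ndarray:
        """Forward-model enhancement for given parameters (model units)."""
        t = self.series.times[1:] if times_s is None else np.asarray(times_s)
        return tofts_concentration(t, params, self.aif) * self.enhancement_scale
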
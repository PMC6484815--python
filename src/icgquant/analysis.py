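"""Perfusion-parameter extraction from a fluorescence time-intensity curve.

This is the quantitative core of the package.  From a baseline-then-rise
inflow curve it measures:

==========  =============================================================
F_MIN       baseline fluorescence before dye arrival (AU)
dF          difference between peak and baseline fluorescence (AU);
            the inflow amplitude, often written F_MAX
slope       dF / T_MAX, the mean rate of fluorescence rise (AU/s)
T_MAX       time from first fluorescence increase (onset) to maximum
T_1/2MAX    time from onset to half of the maximum rise
TR          T_1/2MAX / T_MAX, a dimensionless shape descriptor of the
            inflow: values near 1 mean a sluggish early rise
==========  =============================================================

Intensity is in arbitrary units that depend on the camera, light source
and working distance; the time parameters and TR are invariant to affine
intensity transforms, which is why they are the clinically robust factors.

The module exposes both the functional operations (`smooth`,
`detect_onset`, `compute_params`) and a statsmodels-flavoured pair
(`PerfusionModel` -> `PerfusionResults`) wrapping them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .curves import PerfusionCurve, MIN_SAMPLES
from .exceptions import (
    CurveFormatError,
    InternalConsistencyError,
    InvalidSpecificationError,
    NoPerfusionError,
    PeakNotReachedWarning,
)

__all__ = [
    "AnalysisConfig",
    "OnsetEstimate",
    "PerfusionParams",
    "PerfusionModel",
    "PerfusionResults",
    "smooth",
    "detect_onset",
    "detection_series",
    "compute_params",
]

#: Relative noise level (baseline SD over inflow amplitude) below which the
#: curve is treated as effectively noise-free and sample-exact landmark
#: rules replace the noise-robust estimators.
_NOISE_FREE_FRAC = 1e-7


@dataclass(frozen=True)
class AnalysisConfig:
    """Numerical configuration of the curve parameterization.

    Parameters
    ----------
    smooth_window : float
        Width (seconds) of the centered moving average applied before all
        landmark detection.  The raw curve is retained for plotting.
    onset_k : float
        Baseline-SD multiplier of the onset detection threshold.
    onset_sustain : float
        Seconds the exceedance must persist for onset to be declared,
        guarding against isolated noise spikes.
    plateau_epsilon : float
        T_MAX anchors at the first attainment of (1 - epsilon) of the peak
        rise rather than the raw argmax, so a noisy plateau does not
        inflate the time to maximum.
    analysis_window : float
        Seconds after curve start (for onset search) and after onset (for
        peak search) considered; mirrors the intraoperative cap on how
        long absent inflow is awaited.
    min_baseline_frames : int
        Minimum number of pre-rise samples required to estimate baseline
        statistics.
    refine_onset : bool
        Back-extrapolate the early rising edge to the baseline level to
        refine the onset beyond the threshold-crossing sample.  Ignored
        (the crossing is already frame-exact) on noise-free curves.
    slope_method : str
        "ratio" for dF / T_MAX (the definition used throughout); "fit"
        for a least-squares line over the 20-80% rise as a variant.
    onset_sustain_frac : float
        Fraction of samples inside the sustain window that must exceed the
        threshold (tolerates single noise dips).
    """

    smooth_window: float = 0.5
    onset_k: float = 3.0
    onset_sustain: float = 0.5
    plateau_epsilon: float = 0.02
    analysis_window: float = 300.0
    min_baseline_frames: int = 10
    refine_onset: bool = True
    slope_method: str = "ratio"
    onset_sustain_frac: float = 0.8

    def __post_init__(self) -> None:
        for name in (
            "smooth_window",
            "onset_k",
            "onset_sustain",
            "plateau_epsilon",
            "analysis_window",
            "min_baseline_frames",
        ):
            if getattr(self, name) <= 0:
                raise InvalidSpecificationError(f"{name} must be positive")
        if not 0.0 < self.plateau_epsilon < 0.2:
            raise InvalidSpecificationError("plateau_epsilon must lie in (0, 0.2)")
        if self.slope_method not in ("ratio", "fit"):
            raise InvalidSpecificationError("slope_method must be 'ratio' or 'fit'")
        if not 0.0 < self.onset_sustain_frac <= 1.0:
            raise InvalidSpecificationError("onset_sustain_frac must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class OnsetEstimate:
    """Result of bolus-arrival detection.

    `t_onset` is the estimated time of first fluorescence increase;
    `t_detect` the (later) time at which the sustained threshold
    exceedance was declared; `f_min` and `baseline_sd` are the mean and
    SD of the raw samples preceding the onset.
    """

    t_onset: float
    f_min: float
    baseline_sd: float
    t_detect: float
    n_baseline: int


@dataclass(frozen=True)
class PerfusionParams:
    """The six perfusion parameters plus onset time and censoring flag.

    Times are seconds measured from the detected onset; `t_onset` is the
    absolute onset time on the curve's own axis.  `censored` marks curves
    still rising at the end of the analysis window, whose `t_max` is a
    lower bound (classification treats them as slow flow).
    """

    f_min: float
    delta_f: float
    slope: float
    t_onset: float
    t_max: float
    t_half_max: float
    tr: float
    censored: bool = False
    baseline_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_f <= 0:
            raise InternalConsistencyError("delta_f must be positive")
        if not 0.0 < self.t_half_max <= self.t_max:
            raise InternalConsistencyError(
                f"need 0 < t_half_max <= t_max, got "
                f"{self.t_half_max:.4g} vs {self.t_max:.4g}"
            )
        if not 0.0 < self.tr <= 1.0:
            raise InternalConsistencyError("tr must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "f_min": self.f_min,
            "delta_f": self.delta_f,
            "slope_au_per_s": self.slope,
            "t_onset_s": self.t_onset,
            "t_max_s": self.t_max,
            "t_half_max_s": self.t_half_max,
            "tr": self.tr,
            "censored": self.censored,
        }


# ----------------------------------------------------------------------
# functional operations
# ----------------------------------------------------------------------

def smooth(curve: PerfusionCurve, smooth_window: float) -> PerfusionCurve:
    """Centered moving average; endpoints use truncated windows.

    The window is given in seconds and converted to an odd sample count;
    a window shorter than one inter-sample interval is the identity.
    Length is preserved and a ramp passes through unchanged in the
    interior (linear phase).
    """
    if len(curve) < 2:
        return curve
    dt = curve.dt
    half = int(np.floor(smooth_window / 2.0 / dt + 1e-9))
    if half == 0:
        return curve
    k = 2 * half + 1
    kernel = np.ones(k)
    num = np.convolve(curve.intensities, kernel, mode="same")
    den = np.convolve(np.ones(len(curve)), kernel, mode="same")
    return curve.with_intensities(num / den)


def _running_baseline(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Running mean and SD of y[0:i] for each index i (NaN where i < 2)."""
    n = y.size
    idx = np.arange(n, dtype=float)
    cum = np.concatenate([[0.0], np.cumsum(y)])[:-1]
    cum2 = np.concatenate([[0.0], np.cumsum(y * y)])[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = cum / idx
        var = (cum2 - cum * cum / idx) / (idx - 1.0)
    sd = np.sqrt(np.maximum(var, 0.0))
    mean[0] = np.nan
    sd[:2] = np.nan
    return mean, sd


def _robust_peak(values: np.ndarray, floor: float, band: float = 0.1) -> float:
    """Plateau-level estimate: median of values in the top `band` of the range.

    The raw maximum of a noisy plateau overestimates the peak by the
    extreme of the noise; the median over the near-peak band is unbiased
    when at least half the band is plateau.
    """
    top = values.max()
    sel = values >= floor + (1.0 - band) * (top - floor)
    return float(np.median(values[sel])) if sel.any() else float(top)


def detect_onset(
    curve: PerfusionCurve, config: AnalysisConfig | None = None
) -> OnsetEstimate:
    """Locate the first fluorescence increase (bolus arrival).

    Detection: the first sample exceeding the running baseline mean plus
    `onset_k` running SDs, with the exceedance sustained for
    `onset_sustain` seconds (running statistics use all samples before
    the candidate).  On noisy curves the declared crossing necessarily
    sits where the signal has already cleared the noise band, so the
    onset is then refined by fitting a quadratic to the early rising edge
    of the smoothed curve and intersecting it with the baseline level.
    On effectively noise-free curves the raw crossing is already exact to
    one frame and is returned as is.

    Raises
    ------
    NoPerfusionError
        If no sustained exceedance occurs within the analysis window.
    """
    config = config or AnalysisConfig()
    t, y = curve.times, curve.intensities
    n = y.size
    if n < MIN_SAMPLES:
        raise CurveFormatError(
            f"need at least {MIN_SAMPLES} samples for analysis, got {n}"
        )
    if n < config.min_baseline_frames + 2:
        raise CurveFormatError("too few samples to establish a baseline")

    mean_r, sd_r = _running_baseline(y)
    first = max(config.min_baseline_frames, 2)
    atol = 1e-12 * np.maximum(1.0, np.abs(np.nan_to_num(mean_r)))
    thr = mean_r + config.onset_k * sd_r + atol

    eligible = (np.arange(n) >= first) & (t <= config.analysis_window)
    candidates = np.nonzero(eligible & (y > thr))[0]
    if candidates.size:
        # freeze baseline statistics at the first raw exceedance: later
        # running statistics are contaminated by the rise itself
        i0 = int(candidates[0])
        k_star = i0
    else:
        # a slow-starting rise can contaminate the running statistics so
        # thoroughly that the threshold chases the signal and is never
        # exceeded; fall back to the lowest threshold seen so far and
        # freeze the baseline at the index achieving it (cleanest prefix)
        with np.errstate(invalid="ignore"):
            thr_running_min = np.fmin.accumulate(thr)
        candidates = np.nonzero(eligible & (y > thr_running_min))[0]
        if candidates.size == 0:
            raise NoPerfusionError(
                "no fluorescence increase above baseline detected within "
                f"the analysis window ({config.analysis_window:.0f} s)"
            )
        i0 = int(candidates[0])
        k_star = int(np.nanargmin(thr[: i0 + 1]))
    thr_frozen = float(thr[k_star])
    f_min_det = float(mean_r[k_star])
    sd_det = float(sd_r[k_star])

    i_det = None
    for i in range(i0, n):
        if t[i] > config.analysis_window or y[i] <= thr_frozen:
            continue
        hi = np.searchsorted(t, t[i] + config.onset_sustain, side="right")
        seg = y[i:hi]
        # sustained = the window as a whole stays above the threshold: its
        # mean exceeds it and so do at least half the samples (a lone spike
        # fails both; a true rise passes both)
        if (
            seg.size
            and seg.mean() > thr_frozen
            and np.mean(seg > thr_frozen) >= min(0.5, config.onset_sustain_frac)
        ):
            i_det = int(i)
            break
    if i_det is None:
        raise NoPerfusionError(
            "no sustained fluorescence increase detected within the "
            f"analysis window ({config.analysis_window:.0f} s)"
        )
    t_detect = float(t[i_det])
    t_onset = t_detect

    s = smooth(curve, config.smooth_window).intensities
    in_win = t <= min(t[-1], t_detect + config.analysis_window)
    amp_rough = _robust_peak(s[in_win], f_min_det) - f_min_det
    noise_free = amp_rough <= 0 or sd_det <= _NOISE_FREE_FRAC * amp_rough

    if noise_free:
        # without noise the sample before the first exceedance is the last
        # baseline sample: the increase began at (or just after) it
        t_onset = float(t[i_det - 1])
    elif config.refine_onset and amp_rough > 0:
        t_onset = _refine_onset_edge_fit(
            t, y, s, f_min_det, amp_rough, t_detect
        )

    # baseline statistics over raw samples strictly before the onset
    n_base = int(np.searchsorted(t, t_onset, side="left"))
    if n_base >= config.min_baseline_frames:
        f_min = float(np.mean(y[:n_base]))
        baseline_sd = float(np.std(y[:n_base], ddof=1)) if n_base > 1 else 0.0
    else:  # refinement moved onset into the earliest frames; keep detection stats
        n_base = i_det
        f_min, baseline_sd = f_min_det, sd_det
    return OnsetEstimate(
        t_onset=float(t_onset),
        f_min=f_min,
        baseline_sd=baseline_sd,
        t_detect=t_detect,
        n_baseline=n_base,
    )


def _refine_onset_edge_fit(
    t: np.ndarray,
    y: np.ndarray,
    s: np.ndarray,
    f_min: float,
    amplitude: float,
    t_detect: float,
    lo_frac: float = 0.02,
    hi_frac: float = 0.9,
    baseline_lead: float = 12.0,
    gamma_lo: float = 0.2,
    gamma_hi: float = 8.0,
) -> float:
    """Back-extrapolate the rising edge to the baseline by a power-law fit.

    On a noisy curve the sustained threshold crossing necessarily lags the
    true first increase by the time the signal needs to clear the noise
    band.  The standard bolus-arrival remedy is to fit a flexible rising
    edge and intersect it with the baseline: the raw samples from
    `baseline_lead` seconds before the edge up to `hi_frac` of the rise
    amplitude are fitted with

        f(t) = f_min + a * max(t - t0, 0)^gamma,   gamma in [0.2, 8],

    which is flat before t0 (the pre-onset baseline samples anchor the
    break point) and covers concave through convex inflow fronts after
    it.  The baseline f is itself a free parameter: the running mean at
    detection time is contaminated by the sub-threshold start of the
    rise, and anchoring the fit to it would bias the onset late.  The
    break point makes the objective non-smooth in t0 and t0/gamma
    strongly coupled, so the fit is a coarse profile grid over
    (t0, gamma) with the closed-form (f, a) pair, polished by bounded
    least squares; the raw detection time is the fallback if everything
    fails.
    """
    from scipy.optimize import curve_fit

    hi_level = f_min + hi_frac * amplitude
    lo_level = f_min + lo_frac * amplitude
    above_hi = np.nonzero(s >= hi_level)[0]
    i_hi = int(above_hi[0]) if above_hi.size else s.size - 1
    below_lo = np.nonzero(s[: i_hi + 1] <= lo_level)[0]
    t_edge = float(t[int(below_lo[-1])]) if below_lo.size else float(t[0])
    i_lo = int(np.searchsorted(t, t_edge - baseline_lead, side="left"))
    if i_hi - i_lo < 4:
        i_lo = max(0, i_hi - 4)
    tt, yy = t[i_lo : i_hi + 1], y[i_lo : i_hi + 1]
    if tt.size < 5:
        return t_detect
    n_pts = float(tt.size)
    sy = float(yy.sum())
    syy = float(yy @ yy)

    # coarse profile grid: for each (t0, gamma) the baseline and the
    # amplitude are the closed-form linear least-squares pair
    t0_lo = float(tt[0])
    t0_hi = float(min(t_detect, t_edge + 0.3 * (tt[-1] - tt[0])))
    if t0_hi <= t0_lo:
        t0_hi = float(t_detect)
    n_t0 = max(int((t0_hi - t0_lo) / 0.1) + 2, 8)
    t0s = np.linspace(t0_lo, t0_hi, n_t0)
    dt_grid = np.clip(tt[None, :] - t0s[:, None], 0.0, None)
    best_sse, best = np.inf, None
    for g in np.geomspace(gamma_lo, gamma_hi, 17):
        basis = dt_grid**g
        sb = basis.sum(axis=1)
        sbb = np.einsum("ij,ij->i", basis, basis)
        sby = basis @ yy
        det = n_pts * sbb - sb * sb
        with np.errstate(divide="ignore", invalid="ignore"):
            a_g = np.where(det > 0, (n_pts * sby - sb * sy) / det, 0.0)
        a_g = np.maximum(a_g, 0.0)
        f_g = (sy - a_g * sb) / n_pts
        sse = (
            syy
            - 2.0 * (f_g * sy + a_g * sby)
            + f_g**2 * n_pts
            + 2.0 * f_g * a_g * sb
            + a_g**2 * sbb
        )
        k = int(np.argmin(sse))
        if sse[k] < best_sse:
            best_sse = float(sse[k])
            best = (float(t0s[k]), float(f_g[k]), float(a_g[k]), float(g))
    if best is None:
        return t_detect
    t0g, fg, ag, gg = best

    f_span = 0.2 * amplitude

    def edge(ts, t0, f0, loga, gamma):
        dt = np.maximum(ts - t0, 0.0)
        return f0 + np.exp(loga) * dt**gamma

    t_onset = t0g
    try:
        popt, _ = curve_fit(
            edge,
            tt,
            yy,
            p0=(
                t0g,
                float(np.clip(fg, f_min - f_span + 1e-9, f_min + f_span - 1e-9)),
                float(np.log(max(ag, 1e-9))),
                gg,
            ),
            bounds=(
                [t0_lo, f_min - f_span, -20.0, gamma_lo],
                [t_detect, f_min + f_span, 20.0, gamma_hi],
            ),
            maxfev=1000,
        )
        if float(np.sum((edge(tt, *popt) - yy) ** 2)) <= best_sse:
            t_onset = float(popt[0])
    except (RuntimeError, ValueError):
        pass
    return float(min(max(t_onset, t[0]), t_detect))


def detection_series(
    curve: PerfusionCurve,
    config: AnalysisConfig | None = None,
    onset: OnsetEstimate | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """The monotone landmark trace on which level crossings are located.

    Isotonic (non-decreasing least squares) regression of the smoothed
    curve over the analysis window after onset: for a monotone inflow
    plus noise this is the canonical monotonicity-restoring fit, and
    first crossings of it are far more stable than first crossings of
    the raw noisy trace.  On a noise-free curve it is the identity over
    the rise.  Returns (times, values) inside the window.
    """
    from sklearn.isotonic import IsotonicRegression

    config = config or AnalysisConfig()
    onset = onset or detect_onset(curve, config)
    t = curve.times
    s = smooth(curve, config.smooth_window).intensities
    t_end = min(t[-1], onset.t_onset + config.analysis_window)
    iw = np.nonzero((t > onset.t_onset) & (t <= t_end))[0]
    if iw.size == 0:
        raise NoPerfusionError("no samples after the detected onset")
    iso = IsotonicRegression(increasing=True).fit_transform(t[iw], s[iw])
    return t[iw], np.asarray(iso, dtype=float)


def _first_crossing(tw: np.ndarray, vw: np.ndarray, level: float) -> float | None:
    """First linearly interpolated crossing of `level` on (tw, vw)."""
    above = np.nonzero(vw >= level)[0]
    if above.size == 0:
        return None
    j = int(above[0])
    if j == 0 or vw[j] == vw[j - 1]:
        return float(tw[j])
    frac = (level - vw[j - 1]) / (vw[j] - vw[j - 1])
    return float(tw[j - 1] + min(max(frac, 0.0), 1.0) * (tw[j] - tw[j - 1]))


def compute_params(
    curve: PerfusionCurve, config: AnalysisConfig | None = None
) -> PerfusionParams:
    """Measure the perfusion parameters of an inflow curve.

    The peak level is the robust maximum of the smoothed curve within the
    analysis window after onset; `t_max` is the time of first attainment
    of (1 - plateau_epsilon) of the peak rise, refined by tangent
    extrapolation to the full peak level (sample-exact on noise-free
    curves); `t_half_max` is the first crossing of half the rise on the
    monotone landmark trace (see :func:`detection_series`), linearly
    interpolated between bracketing samples.  All times are reported
    relative to the detected onset.

    A curve still rising at the window end triggers a
    :class:`PeakNotReachedWarning` and is returned with `t_max` censored
    at the window end.
    """
    config = config or AnalysisConfig()
    onset = detect_onset(curve, config)
    t, y = curve.times, curve.intensities
    s = smooth(curve, config.smooth_window).intensities

    f_min = onset.f_min
    t_end = min(t[-1], onset.t_onset + config.analysis_window)
    win = (t > onset.t_onset) & (t <= t_end)
    if not win.any():
        raise NoPerfusionError("no samples after the detected onset")
    iw = np.nonzero(win)[0]

    amp_rough = float(np.max(s[iw])) - f_min
    if amp_rough <= 0:
        raise InternalConsistencyError("curve does not rise above baseline")
    noise_free = onset.baseline_sd <= _NOISE_FREE_FRAC * amp_rough

    if noise_free:
        f_peak = float(np.max(y[iw]))
    else:
        f_peak = _robust_peak(s[iw], f_min)
    delta_f = f_peak - f_min
    if delta_f <= 0:
        raise InternalConsistencyError("peak does not exceed baseline")
    if not noise_free and delta_f < 4.0 * onset.baseline_sd:
        # a rise this small cannot be told apart from the baseline noise;
        # clinically this is inadequate inflow, not a measurable bolus
        raise NoPerfusionError(
            "inflow amplitude indistinguishable from baseline noise "
            f"(delta_f {delta_f:.3g} AU vs baseline SD {onset.baseline_sd:.3g} AU)"
        )

    tw, vw = detection_series(curve, config, onset)

    # ---- T_1/2MAX: first interpolated crossing of half the rise --------
    half_level = f_min + 0.5 * delta_f
    t_half_abs = _first_crossing(tw, vw, half_level)
    if t_half_abs is None:
        # the monotone trace pools peaks downward; the smoothed trace
        # itself always reaches the half level by construction
        t_half_abs = _first_crossing(t[iw], s[iw], half_level)
    if t_half_abs is None:
        raise InternalConsistencyError("half-maximum level never reached")
    t_half_abs = max(t_half_abs, onset.t_onset)
    if t_half_abs <= onset.t_onset:
        raise InternalConsistencyError("half-maximum crossing precedes onset")

    # ---- T_MAX: first attainment of (1 - eps) of the peak --------------
    censored = False
    if noise_free:
        atol = 1e-9 * delta_f
        j_peak = int(iw[np.nonzero(y[iw] >= f_peak - atol)[0][0]])
        t_peak_abs = float(t[j_peak])
        # still rising at the very end of the window?
        if j_peak >= iw[-1] - 1 and y[iw[-1]] > y[iw[-2]]:
            censored = True
    else:
        thr_level = f_min + (1.0 - config.plateau_epsilon) * delta_f
        censored = _rising_at_end(t, y, iw, delta_f, config.smooth_window)
        if censored:
            t_peak_abs = t_end
        else:
            t_cross = _first_crossing(tw, vw, thr_level)
            if t_cross is None:
                # the monotone trace can pool a decaying tail below the
                # threshold; fall back to the smoothed trace
                t_cross = _first_crossing(t[iw], s[iw], thr_level)
            if t_cross is None:
                t_cross = float(tw[int(np.argmax(vw))])
            t_peak_abs = _tangent_extrapolate(
                t, s, t_cross, thr_level, f_peak, t_end
            )
    if censored:
        t_peak_abs = t_end
        warnings.warn(
            "curve still rising at the end of the analysis window; "
            "T_MAX censored at the window end",
            PeakNotReachedWarning,
            stacklevel=2,
        )

    t_max = t_peak_abs - onset.t_onset
    t_half = t_half_abs - onset.t_onset
    if t_half > t_max:  # can only arise through censoring pathologies
        t_max = t_half
    slope = delta_f / t_max
    if config.slope_method == "fit":
        slope = _fitted_slope(t, s, f_min, delta_f, onset.t_onset, t_end, slope)
    return PerfusionParams(
        f_min=f_min,
        delta_f=delta_f,
        slope=slope,
        t_onset=onset.t_onset,
        t_max=t_max,
        t_half_max=t_half,
        tr=min(t_half / t_max, 1.0),
        censored=censored,
        baseline_sd=onset.baseline_sd,
    )


def _rising_at_end(
    t: np.ndarray,
    y: np.ndarray,
    iw: np.ndarray,
    delta_f: float,
    smooth_window: float,
) -> bool:
    """Is the curve still climbing at the end of the analysis window?

    Least-squares slope of the *raw* samples (independent noise, so the
    usual standard error is honest -- smoothed samples are autocorrelated
    and would wildly overstate significance) over the final stretch
    (at least 8 s); "still rising" requires the slope to be both
    statistically positive (> 3 standard errors) and practically
    meaningful (a projected rise of > 2% of the amplitude across the
    stretch), so neither plateau noise nor a microscopic drift censors
    the curve.
    """
    t_end = t[iw[-1]]
    span = max(8.0, 6.0 * smooth_window)
    sel = iw[t[iw] >= t_end - span]
    if sel.size < 5:
        sel = iw[-5:] if iw.size >= 5 else iw
    if sel.size < 3:
        return False
    tt, ss = t[sel], y[sel]
    tc = tt - tt.mean()
    denom = float(tc @ tc)
    if denom <= 0:
        return False
    b = float(tc @ ss) / denom
    resid = ss - ss.mean() - b * tc
    dof = max(sel.size - 2, 1)
    se_b = float(np.sqrt((resid @ resid) / dof / denom))
    span_eff = float(tt[-1] - tt[0])
    return b > 3.0 * se_b and b * span_eff > 0.02 * delta_f


def _tangent_extrapolate(
    t: np.ndarray,
    s: np.ndarray,
    t_cross: float,
    thr_level: float,
    f_peak: float,
    t_end: float,
    fit_window: float = 1.0,
) -> float:
    """Extend the (1 - eps) crossing to the full peak level along the local tangent.

    The local slope is estimated by least squares over `fit_window` seconds
    ending at the crossing; extrapolating the remaining eps of the rise
    along it removes the systematic early bias of the thresholded crossing
    (second-order accurate in eps for smooth rise shapes).
    """
    sel = (t >= t_cross - fit_window) & (t <= t_cross + 1e-12)
    if sel.sum() < 3:
        j = int(np.searchsorted(t, t_cross))
        sel = np.zeros_like(sel)
        sel[max(0, j - 3) : j + 1] = True
    tt, ss = t[sel], s[sel]
    if tt.size < 2:
        return min(t_cross, t_end)
    slope = float(np.polyfit(tt - tt.mean(), ss, deg=1)[0])
    if slope <= 0:
        return min(t_cross, t_end)
    return float(min(t_cross + (f_peak - thr_level) / slope, t_end))


def _fitted_slope(
    t: np.ndarray,
    s: np.ndarray,
    f_min: float,
    delta_f: float,
    t_onset: float,
    t_end: float,
    fallback: float,
) -> float:
    """Least-squares line over the 20-80% portion of the rise (variant slope)."""
    lo, hi = f_min + 0.2 * delta_f, f_min + 0.8 * delta_f
    sel = (t > t_onset) & (t <= t_end) & (s >= lo) & (s <= hi)
    if sel.sum() < 2:
        return fallback
    return float(np.polyfit(t[sel], s[sel], deg=1)[0])


# ----------------------------------------------------------------------
# model / results objects
# ----------------------------------------------------------------------

class PerfusionModel:
    """Quantification model for a single fluorescence inflow curve.

    Examples
    --------
    >>> model = PerfusionModel.from_csv("curve.csv")      # doctest: +SKIP
    >>> res = model.fit()                                 # doctest: +SKIP
    >>> print(res.summary())                              # doctest: +SKIP
    """

    def __init__(
        self, curve: PerfusionCurve, config: AnalysisConfig | None = None
    ) -> None:
        if len(curve) < MIN_SAMPLES:
            raise CurveFormatError(
                f"need at least {MIN_SAMPLES} samples, got {len(curve)}"
            )
        self.curve = curve
        self.config = config or AnalysisConfig()

    @classmethod
    def from_arrays(
        cls, times, intensities, config: AnalysisConfig | None = None, **kw
    ) -> "PerfusionModel":
        return cls(PerfusionCurve(np.asarray(times), np.asarray(intensities), **kw),
                   config)

    @classmethod
    def from_dataframe(cls, frame, config=None, frame_rate=None) -> "PerfusionModel":
        return cls(PerfusionCurve.from_dataframe(frame, frame_rate), config)

    @classmethod
    def from_csv(cls, path, config=None, frame_rate=None) -> "PerfusionModel":
        return cls(PerfusionCurve.from_csv(path, frame_rate), config)

    def fit(self) -> "PerfusionResults":
        """Run onset detection and parameter extraction."""
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", PeakNotReachedWarning)
            params = compute_params(self.curve, self.config)
        notes = [str(w.message) for w in caught
                 if issubclass(w.category, PeakNotReachedWarning)]
        return PerfusionResults(self, params, notes)


@dataclass
class PerfusionResults:
    """Fitted perfusion parameters with diagnostics and reporting helpers."""

    model: PerfusionModel
    params: PerfusionParams
    notes: list[str] = field(default_factory=list)

    @property
    def censored(self) -> bool:
        return self.params.censored

    @property
    def smoothed(self) -> PerfusionCurve:
        return smooth(self.model.curve, self.model.config.smooth_window)

    def classify(self, config=None):
        """Perfusion status (fast/moderate/slow per factor + risk zone)."""
        from .classify import classify_params

        return classify_params(self.params, config)

    def to_dict(self) -> dict:
        out = self.params.to_dict()
        out["config_echo"] = self.model.config.to_dict()
        return out

    def summary(self) -> str:
        p = self.params
        rows = [
            ("F_MIN (baseline, AU)", f"{p.f_min:.2f}"),
            ("dF (peak - baseline, AU)", f"{p.delta_f:.2f}"),
            ("slope (AU/s)", f"{p.slope:.3f}"),
            ("t_onset (s)", f"{p.t_onset:.2f}"),
            ("T_MAX (s, from onset)", f"{p.t_max:.2f}" + (" [censored]" if p.censored else "")),
            ("T_1/2MAX (s, from onset)", f"{p.t_half_max:.2f}"),
            ("TR = T_1/2MAX / T_MAX", f"{p.tr:.3f}"),
        ]
        width = max(len(r[0]) for r in rows)
        lines = ["Perfusion curve quantification", "=" * (width + 12)]
        lines += [f"{k:<{width}}  {v}" for k, v in rows]
        if self.notes:
            lines += ["-" * (width + 12)] + [f"note: {n}" for n in self.notes]
        return "\n".join(lines)

    def plot(self, ax=None, annotate: bool = True):
        """Plot the raw and smoothed curve with annotated landmarks."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        c, p = self.model.curve, self.params
        ax.plot(c.times, c.intensities, lw=0.7, alpha=0.5, label="raw")
        ax.plot(self.smoothed.times, self.smoothed.intensities, lw=1.5,
                label="smoothed")
        if annotate:
            ax.axhline(p.f_min, ls=":", c="gray", lw=0.8)
            ax.axvline(p.t_onset, ls="--", c="tab:green", lw=0.8, label="onset")
            ax.axvline(p.t_onset + p.t_half_max, ls="--", c="tab:orange",
                       lw=0.8, label="T_1/2MAX")
            ax.axvline(p.t_onset + p.t_max, ls="--", c="tab:red", lw=0.8,
                       label="T_MAX")
            ax.plot(
                [p.t_onset, p.t_onset + p.t_max],
                [p.f_min, p.f_min + p.delta_f],
                c="crimson", lw=1.2, label=f"slope {p.slope:.2f} AU/s",
            )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("fluorescence (AU)")
        ax.legend(fontsize=8)
        return ax
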
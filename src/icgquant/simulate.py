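"""Synthetic fluorescence inflow curves, frame stacks and two-group cohorts.

No surgical videos ship with this package; every downstream stage is
instead exercised on generated data with known ground truth.  The kinetic
model is a baseline-then-power-law-rise-then-plateau (optionally decaying)
trajectory:

    I(t) = F0                                           t < t0
    I(t) = F0 + A * ((t - t0) / R) ** gamma             t0 <= t <= t0 + R
    I(t) = F0 + A * exp(-w * (t - t0 - R))              t > t0 + R

with additive white Gaussian noise per sample.  The power-law rise makes
the perfusion landmarks analytic:

    T_MAX      = R
    T_1/2MAX   = R * 0.5 ** (1 / gamma)
    TR         = 0.5 ** (1 / gamma)        (in (0, 1) for any gamma > 0)
    slope      = A / R

so recovery by the analysis pipeline can be checked against exact truth.
A shallow-early-rise (sluggish inflow) curve corresponds to gamma > 1 and
TR above 0.5; gamma = log 0.5 / log 0.6 ~ 1.357 gives the TR = 0.6
boundary that separates slow from moderate perfusion.

Two-group cohorts are calibrated by default to the published group means
of the 86-patient colorectal cohort (see :mod:`icgquant.reference`);
published dispersions are standard errors and are converted to SDs via
SD = SE * sqrt(n).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .curves import PerfusionCurve
from .exceptions import InvalidSpecificationError
from . import reference

__all__ = [
    "KineticTruth",
    "FrameStackSpec",
    "CohortSpec",
    "CohortMember",
    "Cohort",
    "generate_curve",
    "generate_frame_stack",
    "generate_cohort",
    "gamma_for_tr",
]


def gamma_for_tr(tr: float) -> float:
    """Shape exponent gamma such that the analytic TR equals `tr`.

    Inverts TR = 0.5 ** (1 / gamma): gamma = log 0.5 / log tr.
    """
    if not 0.0 < tr < 1.0:
        raise InvalidSpecificationError("tr must lie strictly in (0, 1)")
    return math.log(0.5) / math.log(tr)


@dataclass(frozen=True)
class KineticTruth:
    """Ground-truth generative parameters of one synthetic inflow curve.

    Parameters
    ----------
    baseline_f0 : float
        Pre-arrival fluorescence level (AU).
    amplitude_a : float
        Inflow amplitude A = peak minus baseline (AU), > 0.
    onset_t0 : float
        Time of first fluorescence increase (s), >= 0.
    rise_duration : float
        Duration R of the rise, equal to the analytic T_MAX (s), > 0.
    shape_gamma : float
        Power-law exponent of the rise; TR = 0.5 ** (1 / gamma).
    washout_rate : float
        Exponential decay rate after the peak (1/s); 0 keeps a plateau.
    noise_sd : float
        SD of the additive Gaussian sample noise (AU).
    """

    baseline_f0: float = 10.0
    amplitude_a: float = 60.0
    onset_t0: float = 10.0
    rise_duration: float = 30.0
    shape_gamma: float = 1.0
    washout_rate: float = 0.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_a < 0:
            raise InvalidSpecificationError("amplitude_a must be >= 0")
        if self.onset_t0 < 0:
            raise InvalidSpecificationError("onset_t0 must be >= 0")
        if self.rise_duration <= 0:
            raise InvalidSpecificationError("rise_duration must be > 0")
        if self.shape_gamma <= 0:
            raise InvalidSpecificationError("shape_gamma must be > 0")
        if self.washout_rate < 0 or self.noise_sd < 0:
            raise InvalidSpecificationError(
                "washout_rate and noise_sd must be >= 0"
            )

    # -- analytic landmarks ---------------------------------------------

    @property
    def t_max(self) -> float:
        """Analytic T_MAX (time from onset to maximum) = rise_duration."""
        return self.rise_duration

    @property
    def tr(self) -> float:
        """Analytic TR = 0.5 ** (1 / gamma), in (0, 1)."""
        return 0.5 ** (1.0 / self.shape_gamma)

    @property
    def t_half_max(self) -> float:
        """Analytic T_1/2MAX = rise_duration * TR."""
        return self.rise_duration * self.tr

    @property
    def slope(self) -> float:
        """Analytic slope = amplitude / rise_duration (AU/s)."""
        return self.amplitude_a / self.rise_duration

    def expected_params(self) -> dict:
        """Analytic values of every measured perfusion parameter."""
        return {
            "f_min": self.baseline_f0,
            "delta_f": self.amplitude_a,
            "slope": self.slope,
            "t_onset": self.onset_t0,
            "t_max": self.t_max,
            "t_half_max": self.t_half_max,
            "tr": self.tr,
        }

    def value(self, t) -> np.ndarray:
        """Noiseless trajectory evaluated at times `t` (vectorized)."""
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.baseline_f0, dtype=float)
        rise = (t >= self.onset_t0) & (t <= self.onset_t0 + self.rise_duration)
        x = (t[rise] - self.onset_t0) / self.rise_duration
        out[rise] += self.amplitude_a * np.power(x, self.shape_gamma)
        after = t > self.onset_t0 + self.rise_duration
        dt = t[after] - self.onset_t0 - self.rise_duration
        out[after] += self.amplitude_a * np.exp(-self.washout_rate * dt)
        return out


def generate_curve(
    truth: KineticTruth,
    frame_rate: float,
    duration: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> PerfusionCurve:
    """Sample one noisy inflow curve at `frame_rate` for `duration` seconds.

    Sample times are i / frame_rate for frame index i starting at 0;
    Gaussian noise of SD `truth.noise_sd` is added independently per
    sample.
    """
    if frame_rate <= 0:
        raise InvalidSpecificationError("frame_rate must be positive")
    if duration <= truth.onset_t0 + truth.rise_duration:
        raise InvalidSpecificationError(
            "duration must exceed onset_t0 + rise_duration "
            f"({truth.onset_t0 + truth.rise_duration:.1f} s)"
        )
    n = int(np.floor(duration * frame_rate)) + 1
    times = np.arange(n) / frame_rate
    y = truth.value(times)
    if truth.noise_sd > 0:
        rng = rng or np.random.default_rng(seed)
        y = y + rng.normal(0.0, truth.noise_sd, size=n)
    return PerfusionCurve(times=times, intensities=y, frame_rate=frame_rate)


# ----------------------------------------------------------------------
# frame stacks
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class FrameStackSpec:
    """Geometry and noise of a synthetic fluorescence video.

    Stands in for the laparoscopic recording: pixels inside `roi_mask`
    follow the kinetic trajectory, pixels outside stay at
    `background_level`; both get independent per-pixel Gaussian noise.
    Intensities are stored as floating-point AU; optional 8-bit
    quantization emulates an integer camera pipeline and is off by
    default.
    """

    height: int = 64
    width: int = 64
    frame_rate: float = 10.0
    duration: float = 60.0
    roi_mask: np.ndarray | None = None
    background_level: float = 5.0
    pixel_noise_sd: float = 0.0
    quantize_8bit: bool = False

    def __post_init__(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise InvalidSpecificationError("frame dimensions must be positive")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise InvalidSpecificationError(
                "frame_rate and duration must be positive"
            )
        mask = self.roi_mask
        if mask is None:
            mask = np.zeros((self.height, self.width), dtype=bool)
            h0, h1 = self.height // 4, 3 * self.height // 4
            w0, w1 = self.width // 4, 3 * self.width // 4
            mask[h0:h1, w0:w1] = True
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.height, self.width):
            raise InvalidSpecificationError(
                f"roi_mask shape {mask.shape} does not match "
                f"({self.height}, {self.width})"
            )
        if not mask.any():
            raise InvalidSpecificationError("roi_mask needs at least 1 true pixel")
        mask.setflags(write=False)
        object.__setattr__(self, "roi_mask", mask)


def generate_frame_stack(
    truth: KineticTruth,
    spec: FrameStackSpec,
    path,
    seed: int | None = None,
) -> Path:
    """Write a synthetic fluorescence video to disk with sidecar metadata.

    `path` ending in .tif/.tiff produces a single-channel multi-page TIFF
    (float32, or uint8 when `spec.quantize_8bit`); any other path is
    treated as a directory of zero-padded grayscale PNG frames (written
    as uint8 after clipping to [0, 255] -- PNG cannot carry floats, so
    the directory flavour is inherently quantized).  A sidecar JSON file
    records the frame rate and the generative truth.

    Returns the path of the stack (TIFF file or frame directory).
    """
    if spec.duration <= truth.onset_t0 + truth.rise_duration:
        raise InvalidSpecificationError(
            "duration must exceed onset_t0 + rise_duration"
        )
    path = Path(path)
    rng = np.random.default_rng(seed)
    n = int(np.floor(spec.duration * spec.frame_rate)) + 1
    times = np.arange(n) / spec.frame_rate
    traj = truth.value(times)

    frames = np.empty((n, spec.height, spec.width), dtype=np.float32)
    frames[:] = spec.background_level
    frames[:, spec.roi_mask] = traj[:, None]
    if spec.pixel_noise_sd > 0:
        frames += rng.normal(0.0, spec.pixel_noise_sd, size=frames.shape).astype(
            np.float32
        )

    meta = {
        "frame_rate_fps": spec.frame_rate,
        "n_frames": n,
        "truth": asdict(truth),
        "background_level": spec.background_level,
        "pixel_noise_sd": spec.pixel_noise_sd,
    }

    as_tiff = path.suffix.lower() in (".tif", ".tiff")
    if as_tiff:
        import tifffile

        path.parent.mkdir(parents=True, exist_ok=True)
        data = (
            np.clip(np.round(frames), 0, 255).astype(np.uint8)
            if spec.quantize_8bit
            else frames
        )
        tifffile.imwrite(path, data, photometric="minisblack")
        sidecar = path.with_suffix(".json")
    else:
        import imageio.v3 as iio

        path.mkdir(parents=True, exist_ok=True)
        data = np.clip(np.round(frames), 0, 255).astype(np.uint8)
        pad = max(5, len(str(n)))
        for i in range(n):
            iio.imwrite(path / f"frame_{i:0{pad}d}.png", data[i])
        sidecar = path / "metadata.json"
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)
    return path


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------

def _se_to_sd(se: float, n: int) -> float:
    return se * math.sqrt(n)


def _default_group_params() -> dict:
    """Per-group sampling distributions calibrated to the published cohort.

    Published values are mean +/- SE; SD = SE * sqrt(n).  The published
    TR standard errors round to 0.0, so TR dispersion defaults to 0.05
    (a configurable assumption, not a published value).
    """
    out = {}
    for group, n in (
        ("no_complication", reference.N_NO_COMPLICATION),
        ("complication", reference.N_COMPLICATION),
    ):
        summ = reference.GROUP_SUMMARIES[group]
        out[group] = {
            "slope": (summ["slope"][0], _se_to_sd(summ["slope"][1], n)),
            "t_max": (summ["t_max"][0], _se_to_sd(summ["t_max"][1], n)),
            "tr": (summ["tr"][0], 0.05),
            "f_min": (summ["f_min"][0], _se_to_sd(summ["f_min"][1], n)),
        }
    return out


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a two-group synthetic cohort.

    Each member's kinetic truth is assembled from independently sampled
    slope, T_MAX and TR (truncated normals per group); the amplitude is
    slope * T_MAX and the shape exponent gamma = log 0.5 / log TR, so
    group TR means are matched by construction.  Outcome label 1 marks
    the complication group.
    """

    n_complication: int = reference.N_COMPLICATION
    n_no_complication: int = reference.N_NO_COMPLICATION
    group_params: dict = field(default_factory=_default_group_params)
    tr_bounds: tuple[float, float] = (0.05, 0.95)
    time_bounds: tuple[float, float] = (1.0, 240.0)
    slope_bounds: tuple[float, float] = (0.05, np.inf)
    f_min_bounds: tuple[float, float] = (0.5, np.inf)
    onset_t0: float = 10.0
    frame_rate: float = 10.0
    noise_sd: float = 1.5
    washout_rate: float = 0.0
    random_seed: int = 0
    generate_curves: bool = True

    def __post_init__(self) -> None:
        if self.n_complication < 0 or self.n_no_complication < 0:
            raise InvalidSpecificationError("group sizes must be >= 0")
        if self.n_complication + self.n_no_complication < 1:
            raise InvalidSpecificationError("cohort must have at least 1 member")
        for name in ("tr_bounds", "time_bounds", "slope_bounds", "f_min_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise InvalidSpecificationError(
                    f"infeasible truncation bounds for {name}: ({lo}, {hi})"
                )


@dataclass(frozen=True)
class CohortMember:
    """One synthetic patient: generative truth, optional curve, outcome."""

    truth: KineticTruth
    outcome: int
    curve: PerfusionCurve | None = None
    group: str = ""


class Cohort(list):
    """A list of :class:`CohortMember` with a tabular view."""

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, m in enumerate(self):
            row = {"patient": i, "group": m.group, "outcome": m.outcome}
            row.update({f"true_{k}": v for k, v in m.truth.expected_params().items()})
            rows.append(row)
        return pd.DataFrame(rows)

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([m.outcome for m in self], dtype=int)


def _sample_truncnorm(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    bounds: tuple[float, float],
    size: int,
) -> np.ndarray:
    if sd <= 0:
        vals = np.full(size, mean)
        if np.any((vals <= bounds[0]) | (vals >= bounds[1])):
            raise InvalidSpecificationError(
                f"degenerate mean {mean} outside truncation bounds {bounds}"
            )
        return vals
    a = (bounds[0] - mean) / sd
    b = (bounds[1] - mean) / sd
    if a >= b:
        raise InvalidSpecificationError(f"infeasible truncation bounds {bounds}")
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: CohortSpec | None = None) -> Cohort:
    """Draw a two-group cohort of kinetic truths (and optionally curves).

    Deterministic under a fixed `spec.random_seed`: the same spec yields
    byte-identical cohorts.
    """
    spec = spec or CohortSpec()
    ss = np.random.SeedSequence(spec.random_seed)
    param_rng = np.random.default_rng(ss.spawn(1)[0])
    curve_seeds = np.random.SeedSequence(spec.random_seed + 1)

    cohort = Cohort()
    plan = [
        ("no_complication", 0, spec.n_no_complication),
        ("complication", 1, spec.n_complication),
    ]
    child_iter = iter(
        curve_seeds.spawn(spec.n_no_complication + spec.n_complication)
    )
    for group, outcome, size in plan:
        if size == 0:
            continue
        gp = spec.group_params[group]
        slopes = _sample_truncnorm(param_rng, *gp["slope"], spec.slope_bounds, size)
        t_maxes = _sample_truncnorm(param_rng, *gp["t_max"], spec.time_bounds, size)
        trs = _sample_truncnorm(param_rng, *gp["tr"], spec.tr_bounds, size)
        f_mins = _sample_truncnorm(param_rng, *gp["f_min"], spec.f_min_bounds, size)
        for slope_i, tmax_i, tr_i, fmin_i in zip(slopes, t_maxes, trs, f_mins):
            truth = KineticTruth(
                baseline_f0=float(fmin_i),
                amplitude_a=float(slope_i * tmax_i),
                onset_t0=spec.onset_t0,
                rise_duration=float(tmax_i),
                shape_gamma=gamma_for_tr(float(tr_i)),
                washout_rate=spec.washout_rate,
                noise_sd=spec.noise_sd,
            )
            curve = None
            child = next(child_iter)
            if spec.generate_curves:
                duration = spec.onset_t0 + tmax_i + max(10.0, 0.35 * tmax_i)
                curve = generate_curve(
                    truth,
                    frame_rate=spec.frame_rate,
                    duration=float(duration),
                    rng=np.random.default_rng(child),
                )
            cohort.append(
                CohortMember(truth=truth, outcome=outcome, curve=curve, group=group)
            )
    return cohort
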
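import math

import numpy as np
import pytest

from icgquant import AnalysisConfig, KineticTruth, generate_curve

#: Shape exponents spanning concave (fast-start) through convex
#: (sluggish-start) inflow fronts; 1.357 ~ log 0.5 / log 0.6 puts the
#: analytic TR exactly at the 0.6 slow-perfusion boundary.
GAMMA_GRID = (0.5, math.log(0.5) / math.log(0.4), 1.0,
              math.log(0.5) / math.log(0.6), 2.0)


@pytest.fixture
def default_config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def linear_truth() -> KineticTruth:
    """Linear rise: 60 AU over 30 s from t = 10 s; TR exactly 0.5."""
    return KineticTruth(
        baseline_f0=10.0, amplitude_a=60.0, onset_t0=10.0,
        rise_duration=30.0, shape_gamma=1.0,
    )


@pytest.fixture
def linear_curve(linear_truth) -> "PerfusionCurve":
    return generate_curve(linear_truth, frame_rate=10.0, duration=70.0)


def noisy_curve(gamma: float, noise_frac: float, seed: int,
                frame_rate: float = 10.0):
    """One noisy synthetic curve with known analytic landmarks."""
    truth = KineticTruth(
        baseline_f0=10.0, amplitude_a=60.0, onset_t0=10.0,
        rise_duration=30.0, shape_gamma=gamma,
        noise_sd=noise_frac * 60.0,
    )
    return truth, generate_curve(truth, frame_rate, 70.0, seed=seed)


def brute_force_roi_mean(frames: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Explicit per-pixel loop over the listed ROI pixels (oracle)."""
    coords = [(r, c) for r in range(mask.shape[0])
              for c in range(mask.shape[1]) if mask[r, c]]
    out = np.empty(frames.shape[0])
    for i in range(frames.shape[0]):
        out[i] = sum(frames[i, r, c] for r, c in coords) / len(coords)
    return out
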
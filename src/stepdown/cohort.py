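"""Synthetic cohorts of virtual stepping-down participants.

Each virtual participant carries a latent critical switching height per
threat condition (bivariate normal across the cohort, correlated within
participant), a psychometric slope, an electrodermal tonic level, imposed
walking speeds, and first-block fear ratings.  Defaults mirror the study
conditions the analysis targets: cohort of 24 older adults, mean switching
height 0.043 m with 0.018 m between-subject SD in the low-threat condition,
a -0.010 m shift under high threat, tonic EDA 16.8 +/- 10.0 uS with a
+1.8 uS threat shift, 7/24 fear responders, and a 1.1 m/s imposed speed.

The generator is a pure function of its seed: identical parameters and seed
reproduce the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.special import expit

__all__ = [
    "CohortParameters",
    "Participant",
    "EDATrace",
    "generate_cohort",
    "respond",
    "generate_eda",
    "generate_fear_ratings",
    "HCRIT_TRUNCATION",
]

#: physical truncation of latent switching heights (the grid spans
#: 0.025-0.150 m; values outside (0.005, 0.20) m are non-physical)
HCRIT_TRUNCATION = (0.005, 0.20)

_CONDITIONS = ("low", "high")


@dataclass(frozen=True)
class CohortParameters:
    """Generative truth for a synthetic study."""

    n_participants: int = 24
    mu_hcrit_low: float = 0.043  # m
    sd_hcrit_between: float = 0.018  # m
    threat_shift: float = -0.010  # m, added to h_crit under high threat
    within_correlation: float = 0.8
    slope_mean: float = 150.0  # 1/m
    slope_sd: float = 50.0  # 1/m
    eda_mu_low: float = 16.8  # uS
    eda_sd_between: float = 10.0  # uS
    eda_threat_shift: float = 1.8  # uS
    fear_responder_fraction: float = 7.0 / 24.0
    speed_target: float = 1.1  # m/s
    speed_threat_shift: float = -0.04  # m/s
    trajectory_noise_sd: float = 0.2  # degrees of cluster orientation jitter
    seed: int = 0
    order_scheme: Literal["alternating", "realized_14_10"] = "alternating"

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be at least 1")
        if self.slope_mean <= 0:
            raise ValueError("slope_mean must be positive")
        for name in ("sd_hcrit_between", "slope_sd", "eda_sd_between",
                     "trajectory_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.within_correlation <= 1.0:
            raise ValueError("within_correlation must lie in [0, 1]")
        if not 0.0 <= self.fear_responder_fraction <= 1.0:
            raise ValueError("fear_responder_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class Participant:
    """One virtual participant with latent truth and descriptives."""

    id: str
    condition_order: tuple[str, str]
    true_hcrit_low: float  # m
    true_hcrit_high: float  # m
    true_slope: float  # 1/m
    fear_responder: bool
    eda_tonic_uS: float
    speed_low: float  # m/s
    speed_high: float  # m/s
    fear_first_low: float  # first-block rating, low threat
    fear_first_high: float
    metadata: dict = field(default_factory=dict, compare=False)


@dataclass(frozen=True)
class EDATrace:
    """Electrodermal activity signal for one condition."""

    fs: float  # samples per second
    signal: np.ndarray  # uS
    condition: str

    def duration(self) -> float:
        return self.signal.size / self.fs


def _truncated_bivariate(
    rng: np.random.Generator, n: int, params: CohortParameters
) -> np.ndarray:
    mean = np.array(
        [params.mu_hcrit_low, params.mu_hcrit_low + params.threat_shift]
    )
    s2 = params.sd_hcrit_between**2
    cov = np.array(
        [[s2, params.within_correlation * s2],
         [params.within_correlation * s2, s2]]
    )
    lo, hi = HCRIT_TRUNCATION
    if params.sd_hcrit_between == 0.0:
        if not np.all((mean > lo) & (mean < hi)):
            raise ValueError("degenerate cohort mean outside physical bounds")
        return np.tile(mean, (n, 1))
    out = np.empty((n, 2))
    remaining = np.arange(n)
    for _ in range(1000):
        draw = rng.multivariate_normal(mean, cov, size=remaining.size)
        out[remaining] = draw
        bad = ~np.all((out[remaining] > lo) & (out[remaining] < hi), axis=1)
        remaining = remaining[bad]
        if remaining.size == 0:
            return out
    raise RuntimeError("truncation rejection sampling failed to converge")


def _half_point(x: np.ndarray | float) -> np.ndarray | float:
    """Round to the questionnaire's half-point resolution, clip to [1, 10]."""
    return np.clip(np.round(np.asarray(x) * 2.0) / 2.0, 1.0, 10.0)


def generate_cohort(params: CohortParameters) -> list[Participant]:
    """Draw a cohort of virtual participants from the generative model.

    Latent switching heights are bivariate normal across conditions,
    truncated to physical bounds by rejection; slopes are log-normal with
    the stated mean and SD; condition order alternates (balanced within
    one) unless the realized 14/10 split of the study is requested.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_participants
    hcrit = _truncated_bivariate(rng, n, params)

    if params.slope_sd == 0:
        slopes = np.full(n, params.slope_mean)
    else:
        cv2 = (params.slope_sd / params.slope_mean) ** 2
        sigma2 = np.log1p(cv2)
        mu = np.log(params.slope_mean) - sigma2 / 2.0
        slopes = rng.lognormal(mu, np.sqrt(sigma2), size=n)

    n_resp = int(round(params.fear_responder_fraction * n))
    responder = np.zeros(n, dtype=bool)
    responder[rng.permutation(n)[:n_resp]] = True

    tonic = np.clip(rng.normal(params.eda_mu_low, params.eda_sd_between, n), 0.5, None)
    speed_low = rng.normal(params.speed_target, 0.12, n)
    speed_high = speed_low + params.speed_threat_shift + rng.normal(0, 0.08, n)

    fear_low = _half_point(1.0 + rng.choice([0.0, 0.5, 1.0, 1.5, 2.0], size=n))
    incr = rng.choice([0.5, 1.0, 1.0, 1.5], size=n)  # responders: median +1
    nonresp_shift = rng.choice([0.0, 0.0, -0.5], size=n)
    fear_high = _half_point(fear_low + np.where(responder, incr, nonresp_shift))
    # a non-responder whose low rating was 1 cannot rate lower; keep equal
    fear_high = np.where(responder, np.maximum(fear_high, fear_low + 0.5), fear_high)

    if params.order_scheme == "alternating":
        orders = [("low", "high") if i % 2 == 0 else ("high", "low")
                  for i in range(n)]
    else:  # the study's realized split: 14 low-first of 24, scaled to n
        n_low_first = int(round(n * 14.0 / 24.0))
        flags = np.zeros(n, dtype=bool)
        flags[rng.permutation(n)[:n_low_first]] = True
        orders = [("low", "high") if f else ("high", "low") for f in flags]

    ages = rng.integers(65, 86, size=n)
    participants = []
    for i in range(n):
        participants.append(
            Participant(
                id=f"p{i:03d}",
                condition_order=orders[i],
                true_hcrit_low=float(hcrit[i, 0]),
                true_hcrit_high=float(hcrit[i, 1]),
                true_slope=float(slopes[i]),
                fear_responder=bool(responder[i]),
                eda_tonic_uS=float(tonic[i]),
                speed_low=float(speed_low[i]),
                speed_high=float(speed_high[i]),
                fear_first_low=float(fear_low[i]),
                fear_first_high=float(fear_high[i]),
                metadata={"age": int(ages[i])},
            )
        )
    return participants


def true_hcrit(participant: Participant, condition: str) -> float:
    if condition not in _CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    return (participant.true_hcrit_low if condition == "low"
            else participant.true_hcrit_high)


def respond(
    participant: Participant,
    condition: str,
    step_height: float,
    rng: np.random.Generator,
) -> str:
    """One Bernoulli landing-strategy draw from the latent psychometric curve.

    ``P(heel) = 1 / (1 + exp(b * (h - h_crit)))`` with the participant's
    latent slope and condition-specific switching height.
    """
    if step_height <= 0:
        raise ValueError("step height must be positive")
    h_crit = true_hcrit(participant, condition)
    p_heel = expit(participant.true_slope * (h_crit - step_height))
    return "heel" if rng.random() < p_heel else "toe"


def generate_eda(
    participant: Participant,
    condition: str,
    duration: float,
    rng: np.random.Generator,
    fs: float = 1000.0,
    threat_shift: float = 1.8,
    session_sd: float = 1.5,
    drift_amplitude: float = 0.5,
    noise_sd: float = 0.05,
) -> EDATrace:
    """Synthetic electrodermal trace: tonic level + threat shift + slow
    drift + noise, sampled at 1000 per second.

    ``threat_shift`` (uS, added under high threat only) is shared across
    the cohort: the threat response is a within-participant effect.
    ``session_sd`` is session-to-session tonic variability (electrode
    placement, skin state) drawn once per trace; with ``session_sd =
    drift_amplitude = noise_sd = 0`` the condition mean equals the tonic
    level plus the shift exactly.
    """
    if condition not in _CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    level = participant.eda_tonic_uS + (threat_shift if condition == "high" else 0.0)
    if session_sd > 0:
        level = level + rng.normal(0.0, session_sd)
    # integer number of drift cycles over the trace, so the slow drift
    # averages to (numerically) zero over the full condition
    drift = drift_amplitude * np.sin(2.0 * np.pi * 2.0 * t / duration)
    noise = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0
    return EDATrace(fs, level + drift + noise, condition)


def generate_fear_ratings(
    participant: Participant, condition: str, n_blocks: int = 4
) -> list[float]:
    """Perceived-fear ratings (1-10, half-point steps) per height block.

    The first-block ratings are the participant's latent values: the
    high-threat first block exceeds the low-threat one iff the participant
    is a fear responder.  Later blocks habituate deterministically by half
    a point per block, floored at 1.
    """
    if condition not in _CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    first = (participant.fear_first_low if condition == "low"
             else participant.fear_first_high)
    return [float(_half_point(max(1.0, first - 0.5 * b))) for b in range(n_blocks)]
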
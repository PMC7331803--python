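"""End-to-end study orchestration and parameter-recovery experiments.

``run_study`` executes the full analysis chain on a synthetic cohort:
adaptive protocol -> psychometric switching-height fits -> sequential and
fixed-n JZS tests -> electrodermal / fear summaries -> fear-group
interaction and regression -> kinematic outcomes and trajectory SPM, and
bundles everything in a reproducible :class:`StudyReport` (same config and
seed -> identical report).

All randomness derives from the cohort seed through fixed named
sub-streams, so each stage can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import bayes, physio, spm
from .cohort import (CohortParameters, Participant, generate_cohort,
                     generate_eda, generate_fear_ratings, respond)
from .kinematics import analyze_trial
from .markers import synthesize_markers
from .protocol import TrialRecord, run_protocol
from .psychometric import PsychometricFit, fit_psychometric

__all__ = [
    "StudyConfig",
    "StudyReport",
    "run_study",
    "parameter_recovery",
    "study_operating_characteristics",
    "simulate_hcrit_study",
]

log = logging.getLogger("stepdown.pipeline")

_STREAMS = {"trials": 1, "eda": 2, "markers": 3, "signed_rank": 4}


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one simulated study."""

    cohort: CohortParameters = field(default_factory=CohortParameters)
    hcrit_prior_scale: float = 1.0  # pre-registered one-sided tests
    exploratory_prior_scale: float = 1.0  # two-sided step-length tests
    robustness_scales: tuple = (0.5, 0.707, 1.0)
    bf_threshold: float = 10.0
    n_min: int = 20
    n_max: int = 50
    interaction_prior_scale: float = 0.5
    regression_scale: float = 0.354
    spm_prior_scale: float = 0.707
    spm_threshold: float = 10.0
    eda_duration_s: float = 60.0
    n_fear_blocks: int = 4
    include_kinematics: bool = True
    curve_shape_sd_deg: float = 2.0  # participant-level curve variability
    use_signed_rank: bool = False  # rank-based fear/speed tests (slower)


@dataclass
class StudyReport:
    """Everything the analysis computed, with provenance."""

    table: pd.DataFrame
    results: dict  # named BayesResult / RegressionBayesResult objects
    sequential: bayes.SequentialState
    robustness: list
    fits: list  # (participant_id, condition, PsychometricFit)
    trials: list  # TrialRecord
    summaries: list  # physio.ConditionSummary
    spm_results: dict
    kinematic_rows: pd.DataFrame | None
    provenance: dict


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STREAMS[stream]])


def _config_hash(config: StudyConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _collect_hcrit(
    participants: list[Participant], rng: np.random.Generator
) -> tuple[list[TrialRecord], list, np.ndarray, np.ndarray]:
    """Protocol + psychometric fit for every participant x condition."""
    trials: list[TrialRecord] = []
    fits = []
    h = {"low": [], "high": []}
    for p in participants:
        for cond in p.condition_order:
            recs = run_protocol(
                lambda height: respond(p, cond, height, rng),
                participant_id=p.id, condition=cond,
            )
            trials.extend(recs)
            fit = fit_psychometric(
                [r.step_height_m for r in recs], [r.strategy for r in recs]
            )
            fits.append((p.id, cond, fit))
            h[cond].append(fit.h_crit)
    return trials, fits, np.array(h["low"]), np.array(h["high"])


def simulate_hcrit_study(
    params: CohortParameters, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray, list]:
    """Fast path: cohort -> protocol -> fits -> per-condition h_crit arrays.

    Used by operating-characteristic simulations that do not need the
    physiological or kinematic stages.
    """
    if seed is not None:
        params = replace(params, seed=seed)
    participants = generate_cohort(params)
    _, fits, h_low, h_high = _collect_hcrit(participants, _rng(params.seed, "trials"))
    return h_low, h_high, fits


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    return float(np.mean(x)), float(np.std(x, ddof=1))


def run_study(config: StudyConfig = StudyConfig()) -> StudyReport:
    """Execute the full study pipeline on one synthetic cohort."""
    seed = config.cohort.seed
    log.info("study start: seed=%s hash=%s", seed, _config_hash(config))
    participants = generate_cohort(config.cohort)
    n = len(participants)

    # --- strategy selection: protocol + psychometric fits
    trials, fits, h_low, h_high = _collect_hcrit(
        participants, _rng(seed, "trials")
    )
    diffs = h_high - h_low
    neg_prior = bayes.PriorSpec(scale=config.hcrit_prior_scale, side="negative")
    log.info("h_crit fits done: mean low=%.4f high=%.4f", h_low.mean(), h_high.mean())
    results: dict = {}
    results["hcrit"] = bayes.jzs_paired_bf_from_data(h_high, h_low, neg_prior)
    sequential = bayes.sequential_run(
        diffs, neg_prior, bf_threshold=config.bf_threshold,
        n_min=min(config.n_min, n), n_max=config.n_max,
    )
    robustness = bayes.bf_robustness(
        results["hcrit"].t_statistic, n, side="negative",
        scales=config.robustness_scales,
    )

    # --- physiological arousal and perceived fear
    rng_eda = _rng(seed, "eda")
    summaries = []
    for p in participants:
        traces = {
            cond: generate_eda(
                p, cond, config.eda_duration_s, rng_eda,
                threat_shift=config.cohort.eda_threat_shift,
            )
            for cond in p.condition_order
        }
        summaries.append(
            physio.summarize_participant(
                p.id, traces["low"], traces["high"],
                generate_fear_ratings(p, "low", config.n_fear_blocks),
                generate_fear_ratings(p, "high", config.n_fear_blocks),
            )
        )
    eda_low = np.array([s.eda_low_uS for s in summaries])
    eda_high = np.array([s.eda_high_uS for s in summaries])
    fear_low = np.array([s.fear_first_low for s in summaries])
    fear_high = np.array([s.fear_first_high for s in summaries])
    pos_prior = bayes.PriorSpec(scale=config.hcrit_prior_scale, side="positive")
    results["eda"] = bayes.jzs_paired_bf_from_data(eda_high, eda_low, pos_prior)
    sr_seed = int(_rng(seed, "signed_rank").integers(2**31 - 1))
    try:
        if config.use_signed_rank:
            results["fear"] = bayes.signed_rank_bf(
                fear_high, fear_low, pos_prior, seed=sr_seed
            )
        else:
            results["fear"] = bayes.jzs_paired_bf_from_data(
                fear_high, fear_low, pos_prior
            )
    except ValueError as exc:  # e.g. all first-block ratings tied
        log.warning("fear contrast skipped: %s", exc)
        results["fear"] = None

    # --- fear-group interaction and arousal regression
    labels = [s.fear_group for s in summaries]
    try:
        results["interaction"] = bayes.group_interaction_bf(
            diffs, labels,
            bayes.PriorSpec(scale=config.interaction_prior_scale, side="two"),
        )
    except ValueError as exc:
        log.warning("interaction contrast skipped: %s", exc)
        results["interaction"] = None
    delta_eda_arr = np.array([s.delta_eda_uS for s in summaries])
    results["regression"] = bayes.jzs_regression_bf(
        h_high, np.column_stack([delta_eda_arr, h_low]),
        scale=config.regression_scale,
    )

    # --- kinematics: walking speed / all-trials step length at the 0.05 m
    # reference height; heel-landing curve comparisons at 0.025 m, where
    # heel landings remain likely under both threat conditions
    kin_rows = None
    spm_results: dict = {}
    if config.include_kinematics:
        rng_mk = _rng(seed, "markers")
        rows = []
        curves: dict = {}
        for p in participants:
            for cond in p.condition_order:
                for height in (0.050, 0.025):
                    strategy = respond(p, cond, height, rng_mk)
                    trial = synthesize_markers(
                        p, cond, height, strategy, rng_mk,
                        noise_sd_deg=config.cohort.trajectory_noise_sd,
                        shape_sd_deg=config.curve_shape_sd_deg,
                    )
                    kin = analyze_trial(trial.markers, trial.geometry, trial.fs)
                    rows.append(
                        {
                            "participant_id": p.id, "condition": cond,
                            "step_height_m": height, "strategy": strategy,
                            "step_length_m": kin.step_length_m,
                            "walking_speed_mps": kin.walking_speed_mps,
                        }
                    )
                    curves[(p.id, cond, height)] = kin.curves
        kin_rows = pd.DataFrame(rows)
        ref = kin_rows[kin_rows.step_height_m == 0.050].pivot(
            index="participant_id", columns="condition"
        )
        speed_l = ref[("walking_speed_mps", "low")].to_numpy()
        speed_h = ref[("walking_speed_mps", "high")].to_numpy()
        step_l = ref[("step_length_m", "low")].to_numpy()
        step_h = ref[("step_length_m", "high")].to_numpy()
        results["speed"] = bayes.jzs_paired_bf_from_data(speed_h, speed_l, neg_prior)
        two_prior = bayes.PriorSpec(scale=config.exploratory_prior_scale, side="two")
        results["step_length"] = bayes.jzs_paired_bf_from_data(step_h, step_l, two_prior)

        low25 = kin_rows[(kin_rows.step_height_m == 0.025)].pivot(
            index="participant_id", columns="condition"
        )
        heel_both = [
            pid for pid in low25.index
            if (low25[("strategy", "low")][pid] == "heel"
                and low25[("strategy", "high")][pid] == "heel")
        ]
        log.info("heel-landing subset: n=%d", len(heel_both))
        if len(heel_both) >= 5:
            hl = low25.loc[heel_both]
            results["step_length_heel"] = bayes.jzs_paired_bf_from_data(
                hl[("step_length_m", "high")].to_numpy(),
                hl[("step_length_m", "low")].to_numpy(), two_prior,
            )
            spm_prior = bayes.PriorSpec(scale=config.spm_prior_scale, side="two")
            for key in ("ankle_deg", "ankle_degps", "knee_deg", "knee_degps"):
                A = np.array([curves[(pid, "high", 0.025)][key] for pid in heel_both])
                B = np.array([curves[(pid, "low", 0.025)][key] for pid in heel_both])
                spm_results[key] = spm.spm_compare(
                    A, B, spm_prior, threshold=config.spm_threshold
                )
        else:
            results["step_length_heel"] = None

    # --- report table
    def row(name, unit, low, high, res):
        lm, ls = _mean_sd(low)
        hm, hs = _mean_sd(high)
        return {
            "variable": name, "unit": unit,
            "low_mean": lm, "low_sd": ls, "high_mean": hm, "high_sd": hs,
            "t": res.t_statistic if res else np.nan,
            "bf10": res.bf10 if res else np.nan,
            "delta_median": res.delta_median if res else np.nan,
            "delta_ci_low": res.delta_ci[0] if res else np.nan,
            "delta_ci_high": res.delta_ci[1] if res else np.nan,
        }

    table_rows = [
        row("h_crit", "m", h_low, h_high, results["hcrit"]),
        row("eda", "uS", eda_low, eda_high, results["eda"]),
        row("fear_first_block", "points", fear_low, fear_high, results["fear"]),
    ]
    if kin_rows is not None:
        table_rows.append(row("walking_speed", "m/s", speed_l, speed_h,
                              results["speed"]))
        table_rows.append(row("step_length", "m", step_l, step_h,
                              results["step_length"]))
    table = pd.DataFrame(table_rows)

    provenance = {
        "seed": seed,
        "config_hash": _config_hash(config),
        "n_participants": n,
        "package": "stepdown",
    }
    return StudyReport(
        table=table, results=results, sequential=sequential,
        robustness=robustness, fits=fits, trials=trials,
        summaries=summaries, spm_results=spm_results,
        kinematic_rows=kin_rows, provenance=provenance,
    )


def parameter_recovery(
    config: StudyConfig = StudyConfig(), n_replicates: int = 500,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """True versus estimated switching heights over simulated participants.

    Each replicate draws one participant from the generative model, runs
    the adaptive protocol in both conditions and fits the psychometric
    curve.  Returns the per-replicate table and a summary with bias,
    median absolute error, and the fraction of clamped/separated fits.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    base = config.cohort
    master = base.seed if seed is None else seed
    rows = []
    for rep in range(n_replicates):
        params = replace(base, n_participants=1,
                         seed=int(np.random.default_rng([master, 7, rep])
                                  .integers(2**31 - 1)))
        p = generate_cohort(params)[0]
        rng = _rng(params.seed, "trials")
        rec = {"replicate": rep}
        for cond in ("low", "high"):
            recs = run_protocol(lambda hh: respond(p, cond, hh, rng),
                                participant_id=p.id, condition=cond)
            fit = fit_psychometric([r.step_height_m for r in recs],
                                   [r.strategy for r in recs])
            rec[f"true_{cond}"] = (p.true_hcrit_low if cond == "low"
                                   else p.true_hcrit_high)
            rec[f"est_{cond}"] = fit.h_crit
            rec[f"status_{cond}"] = fit.status
            rec[f"n_trials_{cond}"] = fit.n_trials
        rows.append(rec)
    df = pd.DataFrame(rows)
    err = np.concatenate(
        [(df["est_low"] - df["true_low"]).to_numpy(),
         (df["est_high"] - df["true_high"]).to_numpy()]
    )
    summary = {
        "median_abs_error_m": float(np.median(np.abs(err))),
        "bias_m": float(np.mean(err)),
        "fraction_interior": float(
            np.mean((df["status_low"] == "interior")
                    & (df["status_high"] == "interior"))
        ),
    }
    return df, summary


def study_operating_characteristics(
    config: StudyConfig = StudyConfig(), n_studies: int = 100,
    seed: int | None = None,
) -> pd.DataFrame:
    """Replicate whole studies; report BF, effect sign, and stopping data.

    One row per simulated study: the fixed-n Bayes factor of the h_crit
    contrast, the estimated effect direction, and the sequential design's
    stopping sample size and reason.
    """
    base = config.cohort
    master = base.seed if seed is None else seed
    prior = bayes.PriorSpec(scale=config.hcrit_prior_scale, side="negative")
    rows = []
    for s in range(n_studies):
        sub = int(np.random.default_rng([master, 11, s]).integers(2**31 - 1))
        h_low, h_high, _ = simulate_hcrit_study(base, seed=sub)
        res = bayes.jzs_paired_bf_from_data(h_high, h_low, prior)
        seq = bayes.sequential_run(
            h_high - h_low, prior, bf_threshold=config.bf_threshold,
            n_min=min(config.n_min, h_low.size), n_max=config.n_max,
        )
        rows.append(
            {
                "study": s, "bf10": res.bf10, "t": res.t_statistic,
                "delta_median": res.delta_median,
                "mean_diff_m": float(np.mean(h_high - h_low)),
                "stop_n": seq.n_current, "stop_reason": seq.stop_reason,
            }
        )
    return pd.DataFrame(rows)
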
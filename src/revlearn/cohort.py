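"""Synthetic participant cohorts for the reversal learning task.

Generates three groups — healthy controls (HC), pathological gamblers
(PG) and cocaine dependent individuals (CDI) — with interview-style
exposure composites (intensity = amount x frequency, severity =
amount x frequency x duration), reinforcement-learning agents that play
the task, and decision-latency models.

Exposure enters agent parameters through within-group rank scores:
severity raises the lapse rate (suppressing the learning asymptote) and
intensity lowers both feedback learning rates (raising reversal cost)
and slows decisions.  With all effect slopes at zero the three groups
are statistically exchangeable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .task import OPTIONS, Schedule, TrialState, play_trial

__all__ = [
    "ExposureRecord",
    "AgentParams",
    "ParticipantProfile",
    "CohortConfig",
    "compute_exposure",
    "make_cohort",
    "choice_policy",
    "update_values",
    "sample_latency",
    "simulate_participant",
    "cohort_manifest",
]

log = logging.getLogger(__name__)

GROUPS = ("HC", "PG", "CDI")


@dataclass(frozen=True)
class ExposureRecord:
    """Interview exposure triple and its two composites."""

    amount: float = 0.0       # grams or units per episode
    frequency: float = 0.0    # episodes per month
    duration: float = 0.0     # months of use

    def __post_init__(self):
        for name in ("amount", "frequency", "duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def intensity(self) -> float:
        """Monthly exposure: amount x frequency."""
        return self.amount * self.frequency

    @property
    def severity(self) -> float:
        """Lifetime exposure: amount x frequency x duration."""
        return self.amount * self.frequency * self.duration


def compute_exposure(amount: float, frequency: float, duration: float) -> ExposureRecord:
    """Build an :class:`ExposureRecord`; raises on negative inputs."""
    return ExposureRecord(amount=amount, frequency=frequency, duration=duration)


@dataclass(frozen=True)
class AgentParams:
    """Parameters of the valence-asymmetric delta-rule agent and its
    latency model."""

    alpha_gain: float = 0.70
    alpha_loss: float = 0.73
    beta: float = 12.0
    lapse: float = 0.01
    stickiness: float = 0.0
    latency_base_ms: float = 800.0
    latency_conflict_gain_ms: float = 400.0
    latency_intensity_gain_ms: float = 0.0
    latency_sd_log: float = 0.25

    def __post_init__(self):
        if not (0.0 <= self.alpha_gain <= 1.0 and 0.0 <= self.alpha_loss <= 1.0):
            raise ValueError("learning rates must lie in [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not (0.0 <= self.lapse <= 0.5):
            raise ValueError("lapse must lie in [0, 0.5]")
        if self.latency_base_ms <= 0:
            raise ValueError("latency_base_ms must be positive")


@dataclass
class ParticipantProfile:
    id: str
    group: str
    exposure: ExposureRecord
    agent: AgentParams
    erp_effect: dict
    intensity_rank01: float = 0.0   # within-group (rank - 0.5)/n
    severity_rank01: float = 0.0
    contingency_order: str = "easy-late"


@dataclass(frozen=True)
class CohortConfig:
    """Cohort sizes, exposure distributions and effect maps.

    Effect slopes are expressed per unit of the within-group normalized
    rank score ``(rank - 0.5)/n`` of the relevant exposure composite.
    """

    group_sizes: dict = field(default_factory=lambda: {"HC": 23, "PG": 21, "CDI": 20})
    base: AgentParams = field(default_factory=AgentParams)
    # exposure log-normal parameters: (log-mean, log-sd) per variable
    amount_log: tuple = (0.4, 0.6)
    frequency_log: tuple = (2.3, 0.6)
    duration_log: tuple = (3.6, 2.0)
    # effect maps: intensity slows feedback learning (both valences)
    # and decisions; severity raises the lapse rate
    lapse_severity_slope: float = 0.30
    alpha_loss_intensity_slope: float = -0.70
    alpha_gain_intensity_slope: float = -0.67
    latency_intensity_gain_ms: float = 600.0
    # incidental participant heterogeneity
    alpha_jitter_sd: float = 0.015
    beta_jitter_sd_log: float = 0.08
    latency_base_jitter_sd_log: float = 0.10
    # feedback-ERP effect parameters consumed by the EEG generator:
    # group-mean differential FRN (uV at FCz) and between-subject sd
    frn_differential_means: dict = field(
        default_factory=lambda: {"HC": 3.0, "PG": 1.0, "CDI": 2.0})
    frn_differential_sd: float = 0.6

    def __post_init__(self):
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g} must have at least 2 participants")
        for s in (self.lapse_severity_slope, self.alpha_loss_intensity_slope,
                  self.alpha_gain_intensity_slope,
                  self.latency_intensity_gain_ms):
            if not np.isfinite(s):
                raise ValueError("effect slopes must be finite")


def _rank01(values: np.ndarray) -> np.ndarray:
    """Within-sample normalized rank score in (0, 1), ties averaged."""
    n = len(values)
    return (rankdata(values) - 0.5) / n


def _clip_param(value: float, lo: float, hi: float, name: str) -> float:
    if value < lo or value > hi:
        log.warning("clipping %s=%.3f into [%s, %s]", name, value, lo, hi)
        return float(np.clip(value, lo, hi))
    return float(value)


def make_cohort(config: CohortConfig, seed) -> list[ParticipantProfile]:
    """Draw a full cohort of participant profiles, deterministic in ``seed``.

    Contingency order alternates within each group (balanced factor).
    """
    rng = np.random.default_rng(seed)
    profiles: list[ParticipantProfile] = []
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        if n == 0:
            continue
        if group == "HC":
            exposures = [ExposureRecord()] * n
            int01 = np.zeros(n)
            sev01 = np.zeros(n)
        else:
            amount = rng.lognormal(*config.amount_log, size=n)
            freq = rng.lognormal(*config.frequency_log, size=n)
            dur = rng.lognormal(*config.duration_log, size=n)
            exposures = [compute_exposure(a, f, d)
                         for a, f, d in zip(amount, freq, dur)]
            int01 = _rank01(np.array([e.intensity for e in exposures]))
            sev01 = _rank01(np.array([e.severity for e in exposures]))
        for i in range(n):
            base = config.base
            alpha_gain_raw = base.alpha_gain + rng.normal(0, config.alpha_jitter_sd)
            alpha_loss_raw = base.alpha_loss + rng.normal(0, config.alpha_jitter_sd)
            lapse_raw = base.lapse + rng.normal(0, 0.01)
            lat_gain = 0.0
            if group != "HC":
                alpha_gain_raw += config.alpha_gain_intensity_slope * int01[i]
                alpha_loss_raw += config.alpha_loss_intensity_slope * int01[i]
                lapse_raw += config.lapse_severity_slope * sev01[i]
                lat_gain = config.latency_intensity_gain_ms
            agent = AgentParams(
                alpha_gain=_clip_param(alpha_gain_raw, 0.01, 1.0, "alpha_gain"),
                alpha_loss=_clip_param(alpha_loss_raw, 0.01, 1.0, "alpha_loss"),
                beta=base.beta * float(np.exp(rng.normal(0, config.beta_jitter_sd_log))),
                lapse=_clip_param(lapse_raw, 0.0, 0.5, "lapse"),
                stickiness=base.stickiness,
                latency_base_ms=base.latency_base_ms
                * float(np.exp(rng.normal(0, config.latency_base_jitter_sd_log))),
                latency_conflict_gain_ms=base.latency_conflict_gain_ms,
                latency_intensity_gain_ms=lat_gain,
                latency_sd_log=base.latency_sd_log,
            )
            erp_effect = {
                "frn_differential": float(
                    config.frn_differential_means[group]
                    + rng.normal(0, config.frn_differential_sd)),
            }
            profiles.append(ParticipantProfile(
                id=f"{group}{i + 1:02d}",
                group=group,
                exposure=exposures[i],
                agent=agent,
                erp_effect=erp_effect,
                intensity_rank01=float(int01[i]),
                severity_rank01=float(sev01[i]),
                contingency_order="easy-late" if i % 2 == 0 else "easy-early",
            ))
    return profiles


def choice_policy(values, previous_choice, params: AgentParams) -> float:
    """Probability of choosing option 0 (softmax + stickiness + lapse).

    ``P = (1 - lapse) * sigmoid(beta * (V0' - V1')) + lapse/2`` where
    ``V'`` adds ``stickiness`` to the previously chosen option.
    """
    v0 = values[0] + (params.stickiness if previous_choice == 0 else 0.0)
    v1 = values[1] + (params.stickiness if previous_choice == 1 else 0.0)
    z = params.beta * (v0 - v1)
    p = 1.0 / (1.0 + np.exp(-z))
    return float((1.0 - params.lapse) * p + params.lapse / 2.0)


def update_values(values, chosen: int, reward: float, params: AgentParams):
    """Delta-rule update of the chosen option's value (reward in {+1, -1});
    the unchosen value is untouched."""
    if reward not in (1, -1, 1.0, -1.0):
        raise ValueError("reward must be normalized to +1 or -1")
    alpha = params.alpha_gain if reward > 0 else params.alpha_loss
    out = list(values)
    out[chosen] = out[chosen] + alpha * (reward - out[chosen])
    return out


def sample_latency(params: AgentParams, value_gap: float,
                   intensity_rank: float, rng) -> float:
    """Log-normal decision latency.

    ``(base + conflict_gain*(1 - gap) + intensity_gain*rank) * exp(eps)``
    with ``eps ~ N(0, sd_log)``; strictly positive.
    """
    if value_gap < 0:
        raise ValueError("value_gap must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mu = (params.latency_base_ms
          + params.latency_conflict_gain_ms * (1.0 - value_gap)
          + params.latency_intensity_gain_ms * intensity_rank)
    return float(mu * np.exp(rng.normal(0.0, params.latency_sd_log)))


def simulate_participant(profile: ParticipantProfile, schedule: Schedule,
                         seed) -> pd.DataFrame:
    """Run one agent through a schedule; returns the trial log.

    Option values start at zero and are never reset at reversals — the
    agent must relearn, which is what produces reversal cost.
    """
    rng = np.random.default_rng(seed)
    params = profile.agent
    cfg = schedule.config
    values = [0.0, 0.0]
    prev = -1
    state = TrialState()
    rows = []
    for i in range(schedule.n_trials):
        gap = abs(values[0] - values[1])
        latency = sample_latency(params, min(gap, 1.0),
                                 profile.intensity_rank01, rng)
        p0 = choice_policy(values, prev, params)
        choice = 0 if rng.random() < p0 else 1
        feedback, state = play_trial(schedule, state, choice)
        values = update_values(values, choice, 1.0 if feedback > 0 else -1.0,
                               params)
        rows.append({
            "participant_id": profile.id,
            "phase": int(schedule.phase[i]),
            "trial": i % cfg.trials_per_phase + 1,
            "block": schedule.block(i),
            "correct_option": OPTIONS[schedule.correct[i]],
            "chosen_option": OPTIONS[choice],
            "accurate": bool(choice == schedule.correct[i]),
            "veridical": bool(schedule.veridical[i]),
            "feedback_points": int(feedback),
            "cumulative_points": int(state.cumulative_points),
            "latency_ms": latency,
        })
        prev = choice
    return pd.DataFrame(rows)


def cohort_manifest(profiles: list[ParticipantProfile]) -> pd.DataFrame:
    """Tidy per-participant table of exposure and agent parameters."""
    rows = []
    for p in profiles:
        rows.append({
            "participant_id": p.id,
            "group": p.group,
            "amount": p.exposure.amount,
            "frequency": p.exposure.frequency,
            "duration": p.exposure.duration,
            "intensity": p.exposure.intensity,
            "severity": p.exposure.severity,
            "intensity_rank01": p.intensity_rank01,
            "severity_rank01": p.severity_rank01,
            "contingency_order": p.contingency_order,
            "alpha_gain": p.agent.alpha_gain,
            "alpha_loss": p.agent.alpha_loss,
            "beta": p.agent.beta,
            "lapse": p.agent.lapse,
            "stickiness": p.agent.stickiness,
            "latency_base_ms": p.agent.latency_base_ms,
            "latency_conflict_gain_ms": p.agent.latency_conflict_gain_ms,
            "latency_intensity_gain_ms": p.agent.latency_intensity_gain_ms,
            "latency_sd_log": p.agent.latency_sd_log,
            "frn_differential": p.erp_effect["frn_differential"],
        })
    return pd.DataFrame(rows)
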
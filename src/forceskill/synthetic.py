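"""Seeded generator of expert/novice force-trace cohorts.

The generative model emulates the qualitative morphology of tool-tissue
force recordings from a microsurgical dissection task: a resting grip force,
intermittent grasp/dissection bursts, and high-frequency tremor, all within
the 0-10 N range of the piezoresistive sensor.  Novices press harder and
more erratically than experts — higher and more variable burst amplitudes,
more tremor, less smoothing — which is what makes skill recoverable from
the trace.

The model is: trace = clip_[0,10]( smooth( base + sum of triangular bursts
+ i.i.d. Gaussian tremor ) ), with burst onsets a Poisson process, burst
peaks Normal(burst_amp_mean, burst_amp_sd), burst widths Uniform(5, 25)
steps, and `smooth` a centered moving average of half-width `smoothness`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .force_data import Cohort, ForceTrace, TrialRecord, EXPERT, NOVICE

FORCE_CEILING_N = 10.0  # sensor range upper bound
BURST_WIDTH_RANGE = (5, 25)  # steps


@dataclass(frozen=True)
class SkillProfile:
    """Parameters of the per-class trace generator (forces in newtons)."""

    base_force: float
    burst_rate: float  # expected bursts per 100 steps
    burst_amp_mean: float
    burst_amp_sd: float
    smoothness: int  # moving-average half-width, steps
    tremor_sd: float

    def __post_init__(self):
        for name in ("base_force", "burst_rate", "burst_amp_mean",
                     "burst_amp_sd", "tremor_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.smoothness < 0:
            raise ValueError("smoothness must be non-negative")


@dataclass(frozen=True)
class CohortSpec:
    """Shape of a simulated cohort (defaults mirror the study: 13 surgeons,
    up to 20 trials each, trial lengths of a few hundred steps)."""

    n_experts: int = 7
    n_novices: int = 6
    trials_per_surgeon: tuple[int, int] = (16, 20)
    length_range: tuple[int, int] = (100, 600)
    seed: int = 0
    surgeon_amp_jitter: float = 0.15  # sd of per-surgeon log-amplitude offset

    def __post_init__(self):
        if self.n_experts < 1 or self.n_novices < 1:
            raise ValueError("surgeon counts must be >= 1")
        if self.trials_per_surgeon[0] < 1 or self.length_range[0] < 1:
            raise ValueError("trial counts and lengths must be >= 1")


def default_profiles() -> tuple[SkillProfile, SkillProfile]:
    """(expert, novice) generator defaults.

    Experts: light, steady grip with few moderate bursts and strong
    smoothing.  Novices: heavier grip, frequent large erratic bursts,
    pronounced tremor, little smoothing.
    """
    expert = SkillProfile(base_force=1.0, burst_rate=1.5,
                          burst_amp_mean=1.5, burst_amp_sd=0.5,
                          smoothness=4, tremor_sd=0.15)
    novice = SkillProfile(base_force=2.0, burst_rate=3.0,
                          burst_amp_mean=4.0, burst_amp_sd=1.5,
                          smoothness=1, tremor_sd=0.5)
    return expert, novice


def _moving_average(x: np.ndarray, half_width: int) -> np.ndarray:
    if half_width <= 0:
        return x
    w = 2 * half_width + 1
    xp = np.pad(x, half_width, mode="edge")
    kernel = np.full(w, 1.0 / w)
    return np.convolve(xp, kernel, mode="valid")


def generate_trial(profile: SkillProfile, length: int,
                   rng: np.random.Generator) -> ForceTrace:
    """Simulate one trial of `length` steps from a skill profile."""
    if length < 1:
        raise ValueError("length must be >= 1")
    signal = np.full(length, profile.base_force, dtype=np.float64)
    n_bursts = rng.poisson(profile.burst_rate * length / 100.0)
    for _ in range(n_bursts):
        onset = int(rng.integers(0, length))
        peak = max(0.0, rng.normal(profile.burst_amp_mean, profile.burst_amp_sd))
        width = int(rng.integers(BURST_WIDTH_RANGE[0], BURST_WIDTH_RANGE[1] + 1))
        half = width / 2.0
        t0 = max(0, onset - int(half))
        t1 = min(length, onset + int(half) + 1)
        t = np.arange(t0, t1)
        pulse = peak * np.maximum(0.0, 1.0 - np.abs(t - onset) / half)
        signal[t0:t1] += pulse
    if profile.tremor_sd > 0:
        signal = signal + rng.normal(0.0, profile.tremor_sd, size=length)
    signal = _moving_average(signal, profile.smoothness)
    return ForceTrace(np.clip(signal, 0.0, FORCE_CEILING_N))


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a full cohort; fully reproducible from `spec.seed`.

    Each surgeon receives a multiplicative offset on the class burst
    amplitude (drawn once per surgeon), so surgeons differ systematically —
    this is what makes leave-one-user-out splits genuinely harder than
    random splits.
    """
    rng = np.random.default_rng(spec.seed)
    expert, novice = default_profiles()
    records: list[TrialRecord] = []
    surgeons = ([(f"E{i+1}", EXPERT, expert) for i in range(spec.n_experts)]
                + [(f"N{i+1}", NOVICE, novice) for i in range(spec.n_novices)])
    lo_t, hi_t = spec.trials_per_surgeon
    lo_l, hi_l = spec.length_range
    for sid, skill, profile in surgeons:
        amp_factor = float(np.exp(rng.normal(0.0, spec.surgeon_amp_jitter)))
        surgeon_profile = SkillProfile(
            base_force=profile.base_force,
            burst_rate=profile.burst_rate,
            burst_amp_mean=profile.burst_amp_mean * amp_factor,
            burst_amp_sd=profile.burst_amp_sd,
            smoothness=profile.smoothness,
            tremor_sd=profile.tremor_sd,
        )
        n_trials = int(rng.integers(lo_t, hi_t + 1))
        for k in range(n_trials):
            length = int(rng.integers(lo_l, hi_l + 1))
            trace = generate_trial(surgeon_profile, length, rng)
            records.append(TrialRecord(trace=trace, surgeon_id=sid,
                                       skill=skill, trial_index=k + 1))
    return Cohort(records=records)
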
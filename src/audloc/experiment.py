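"""Synthetic audio-visual localisation study generator.

Emulates a two-day psychophysics experiment on localisation of sounds
and lights presented along a frontal semi-circular ring of speakers and
LEDs.  Twenty-four participants localise stimuli at azimuths
{0, 2, 6, 9, 13} degrees (right of straight ahead) under two auditory
reliability levels (A1 more reliable, A2 less reliable; manipulated via
background noise) and two visual reliability levels (V1: 45 LEDs lit,
V2: 5 LEDs).  Phases: a *before* phase with auditory and visual
localisation tasks, a *training* phase in which A2 localisation is
followed by visual feedback centred on the true source (half the
participants get reliable feedback VF1, half unreliable VF2), and an
*after* phase repeating the auditory task.

Responses are produced by a configurable Bayesian observer (sensory
noise per condition, optional Gaussian spatial prior, motor noise,
lapses) with response azimuth capped at +/-30 degrees.  Training-phase
learning is modelled phenomenologically: per-phase multiplicative
retention factors shrink the prior weight and the sensory noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .observer import GaussianPrior, prior_weight

__all__ = [
    "ApparatusConfig",
    "DesignConfig",
    "ObserverParams",
    "ObserverPopulation",
    "PHASES",
    "sample_visual_stimulus",
    "simulate_response",
    "simulate_eye_trace",
    "simulate_study",
    "speaker_set_stats",
]

PHASES = ("before", "training", "after")

#: number of LEDs lit per visual reliability level
LEDS_PER_CONDITION = {"V1": 45, "V2": 5, "VF1": 45, "VF2": 5}


@dataclass(frozen=True)
class ApparatusConfig:
    """Geometry of the stimulus ring and response range.

    LED positions are integer LED units; two adjacent LEDs span 1 degree,
    i.e. 0.5 degree per LED.  Visual stimuli are drawn from 51 positions
    spanning +/-25 LED units around the stimulus centre with truncated-
    normal selection probabilities (sd 12 LED units).
    """

    target_azimuths: tuple[float, ...] = (0.0, 2.0, 6.0, 9.0, 13.0)
    background_speaker_azimuths: tuple[float, ...] = (
        -35.0, 0.0, 1.0, 2.0, 3.0, 4.0, 6.0, 9.0, 13.0, 18.0)
    led_spacing: float = 0.5
    led_sample_halfwidth: int = 25
    led_sample_sd: float = 12.0
    response_max: float = 30.0
    fixation_azimuth: float = 0.0

    def __post_init__(self) -> None:
        if not self.led_sample_sd > 0:
            raise ValueError("led_sample_sd must be > 0")
        if not self.response_max > max(self.target_azimuths):
            raise ValueError("response_max must exceed the largest target azimuth")

    @property
    def n_led_positions(self) -> int:
        return 2 * self.led_sample_halfwidth + 1


@dataclass(frozen=True)
class DesignConfig:
    """Study design: participants, phases, blocks and feedback groups."""

    n_participants: int = 24
    phases: tuple[str, ...] = PHASES
    blocks_per_task: int = 4
    trials_per_block: int = 50
    feedback_split: tuple[int, int] = (12, 12)
    include_visual: bool = True
    eye_exceed_probability: float = 0.01

    def __post_init__(self) -> None:
        if sum(self.feedback_split) != self.n_participants:
            raise ValueError("feedback groups must partition participants")
        unknown = set(self.phases) - set(PHASES)
        if unknown:
            raise ValueError(f"unknown phases: {sorted(unknown)}")

    def validate_against(self, app: ApparatusConfig) -> None:
        n_loc = len(app.target_azimuths)
        if self.trials_per_block % n_loc:
            raise ValueError(
                f"trials_per_block={self.trials_per_block} not divisible by "
                f"{n_loc} target locations")


def _default_bias_retention() -> dict[str, float]:
    return {"before": 1.0, "training": 0.6, "after": 0.7}


def _default_sd_retention() -> dict[str, float]:
    return {"before": 1.0, "training": 0.85, "after": 0.85}


@dataclass(frozen=True)
class ObserverParams:
    """Generative observer for one participant.

    ``sensory_sd`` maps condition labels (A1, A2, V1, V2) to sensory
    noise in degrees; the A2 noise must exceed A1 and V2 exceed V1 for
    the reliability manipulation to be meaningful.  ``bias_retention``
    and ``sd_retention`` scale the prior weight and the sensory sd in
    the training/after phases (1.0 = no learning).
    """

    sensory_sd: Mapping[str, float] = field(
        default_factory=lambda: {"A1": 3.0, "A2": 5.5, "V1": 1.2, "V2": 2.2})
    prior: GaussianPrior = field(default_factory=lambda: GaussianPrior(20.0, 6.0))
    motor_sd: float = 1.0
    lapse_rate: float = 0.0
    likelihood_bias_slope: float = 0.0
    bias_retention: Mapping[str, float] = field(default_factory=_default_bias_retention)
    sd_retention: Mapping[str, float] = field(default_factory=_default_sd_retention)

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.sensory_sd.values()) or self.motor_sd < 0:
            raise ValueError("sds must be >= 0")
        if not 0 <= self.lapse_rate <= 1:
            raise ValueError("lapse_rate must lie in [0, 1]")
        for factors in (self.bias_retention, self.sd_retention):
            if any(not 0 < f <= 1 for f in factors.values()):
                raise ValueError("retention factors must lie in (0, 1]")

    def phase_weight(self, condition_sd: float, phase: str) -> float:
        """Effective prior weight in a phase (retention-scaled)."""
        w = prior_weight(condition_sd, self.prior.sd)
        return w * self.bias_retention.get(phase, 1.0)

    def phase_sd(self, condition: str, phase: str) -> float:
        return self.sensory_sd[condition] * self.sd_retention.get(phase, 1.0)


@dataclass(frozen=True)
class ObserverPopulation:
    """Distribution over participants' observer parameters.

    Sensory sds get multiplicative log-normal jitter, the prior azimuth
    gets additive normal jitter; all other fields are shared.
    """

    mean: ObserverParams = field(default_factory=ObserverParams)
    sensory_sd_log_jitter: float = 0.15
    prior_mean_jitter_sd: float = 2.0

    def sample(self, rng: np.random.Generator) -> ObserverParams:
        sds = {
            cond: sd * math.exp(rng.normal(0.0, self.sensory_sd_log_jitter))
            for cond, sd in self.mean.sensory_sd.items()
        }
        prior = self.mean.prior
        if not prior.is_flat:
            prior = GaussianPrior(
                prior.mean_azimuth + rng.normal(0.0, self.prior_mean_jitter_sd),
                prior.sd)
        return replace(self.mean, sensory_sd=sds, prior=prior)


def sample_visual_stimulus(
    n_leds: int,
    app: ApparatusConfig,
    center_azimuth: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample the azimuths of the LEDs lit on one visual trial.

    ``n_leds`` distinct positions are drawn without replacement from the
    integer LED grid spanning +/-``led_sample_halfwidth`` units, with
    probabilities proportional to a normal density (sd
    ``led_sample_sd`` LED units) truncated at the grid edges; positions
    are converted to degrees at ``led_spacing`` deg/LED and shifted so
    the distribution centre sits at ``center_azimuth``.
    """
    positions = np.arange(-app.led_sample_halfwidth, app.led_sample_halfwidth + 1)
    if n_leds > positions.size:
        raise ValueError(
            f"cannot draw {n_leds} LEDs from {positions.size} positions")
    probs = norm.pdf(positions, loc=0.0, scale=app.led_sample_sd)
    probs /= probs.sum()
    chosen = rng.choice(positions, size=n_leds, replace=False, p=probs)
    return center_azimuth + chosen * app.led_spacing


def simulate_response(
    true_azimuth,
    obs: ObserverParams,
    condition: str,
    app: ApparatusConfig,
    rng: np.random.Generator,
    phase: str = "before",
):
    """Simulate the response azimuth(s) for one or more trials.

    sensed = true + slope*true + N(0, sd); the Bayesian estimate shrinks
    sensed toward the prior azimuth by the (retention-scaled) prior
    weight; motor noise is added and the response is clipped to the
    +/-response_max dial range.  With probability ``lapse_rate`` the
    response is instead uniform over the dial range.  Scalar in, scalar
    out; array in, array out.
    """
    stimulus = condition.split("+")[0]
    if stimulus not in obs.sensory_sd:
        raise ValueError(f"no sensory sd defined for condition {condition!r}")
    a = np.asarray(true_azimuth, dtype=float)
    scalar = a.ndim == 0
    a = np.atleast_1d(a)

    sd = obs.phase_sd(stimulus, phase)
    sensed = a + obs.likelihood_bias_slope * a + rng.normal(0.0, sd, size=a.shape)
    if obs.prior.is_flat:
        estimate = sensed
    else:
        w = obs.phase_weight(sd, phase)
        estimate = (1.0 - w) * sensed + w * obs.prior.mean_azimuth
    resp = estimate + rng.normal(0.0, obs.motor_sd, size=a.shape)
    if obs.lapse_rate > 0:
        lapse = rng.random(a.shape) < obs.lapse_rate
        resp = np.where(
            lapse, rng.uniform(-app.response_max, app.response_max, size=a.shape), resp)
    resp = np.clip(resp, -app.response_max, app.response_max)
    return float(resp[0]) if scalar else resp


def simulate_eye_trace(
    rng: np.random.Generator, exceed_probability: float, n: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Summaries (mean deviation, sd of deviation) of fixation traces.

    With probability ``exceed_probability`` a trial violates fixation:
    at least one of the two summaries exceeds the 2 degree exclusion
    threshold.  Compliant trials keep both summaries below threshold.
    """
    if not 0 <= exceed_probability <= 1:
        raise ValueError("exceed_probability must lie in [0, 1]")
    mean_dev = rng.uniform(0.0, 1.5, size=n)
    sd_dev = rng.uniform(0.0, 1.5, size=n)
    bad = rng.random(n) < exceed_probability
    which = rng.random(n) < 0.5  # which summary blows the threshold
    excess = rng.uniform(2.2, 4.0, size=n)
    mean_dev = np.where(bad & which, excess, mean_dev)
    sd_dev = np.where(bad & ~which, excess, sd_dev)
    return mean_dev, sd_dev


def speaker_set_stats(app: ApparatusConfig) -> tuple[float, float]:
    """Mean background-speaker azimuth, with and without the -35 degree one.

    Both means are rounded to the nearest degree.  If no speaker sits at
    -35 degrees the second mean equals the first (documented convention
    for degenerate speaker sets).
    """
    speakers = np.asarray(app.background_speaker_azimuths, dtype=float)
    if speakers.size == 0:
        raise ValueError("background speaker set is empty")
    mean_all = round(float(speakers.mean()))
    kept = speakers[speakers != -35.0]
    mean_excl = round(float(kept.mean())) if kept.size else mean_all
    return float(mean_all), float(mean_excl)


def _block_schedule(conditions: Sequence[str], n_blocks: int,
                    rng: np.random.Generator) -> list[str]:
    """Block-to-condition assignment: equal split, random order."""
    if n_blocks % len(conditions):
        raise ValueError("blocks_per_task must be divisible by number of conditions")
    sched = list(conditions) * (n_blocks // len(conditions))
    rng.shuffle(sched)
    return sched


def _phase_tasks(design: DesignConfig, feedback: str) -> list[tuple[str, str, list[str]]]:
    """(phase, task, block conditions template) triples for one participant."""
    tasks = []
    if "before" in design.phases:
        tasks.append(("before", "auditory", ["A1", "A2"]))
        if design.include_visual:
            tasks.append(("before", "visual", ["V1", "V2"]))
    if "training" in design.phases:
        tasks.append(("training", "auditory_feedback", [f"A2+{feedback}"]))
    if "after" in design.phases:
        tasks.append(("after", "auditory", ["A1", "A2"]))
    return tasks


def simulate_study(
    design: DesignConfig,
    app: ApparatusConfig,
    population: ObserverPopulation,
    rng_seed: int,
) -> pd.DataFrame:
    """Simulate the complete study; one row per trial.

    Deterministic for a fixed seed: participants get independent
    substreams spawned from the master seed.  Training-phase trials
    carry the azimuth at which feedback was shown (the mean of the
    sampled feedback LEDs, centred on the true azimuth); all other
    trials have missing feedback.
    """
    design.validate_against(app)
    master = np.random.SeedSequence(rng_seed)
    participant_seeds = master.spawn(design.n_participants)
    n_vf1 = design.feedback_split[0]

    records = []
    for pid in range(design.n_participants):
        rng = np.random.default_rng(participant_seeds[pid])
        obs = population.sample(rng)
        feedback = "VF1" if pid < n_vf1 else "VF2"
        per_loc = design.trials_per_block // len(app.target_azimuths)

        for phase, task, conds in _phase_tasks(design, feedback):
            for block, cond in enumerate(
                    _block_schedule(conds, design.blocks_per_task, rng)):
                locs = np.repeat(app.target_azimuths, per_loc).astype(float)
                rng.shuffle(locs)
                resp = simulate_response(locs, obs, cond, app, rng, phase=phase)
                emean, esd = simulate_eye_trace(
                    rng, design.eye_exceed_probability, n=locs.size)
                if phase == "training":
                    n_leds = LEDS_PER_CONDITION[feedback]
                    fb = np.array([
                        sample_visual_stimulus(n_leds, app, loc, rng).mean()
                        for loc in locs])
                else:
                    fb = np.full(locs.size, np.nan)
                for t in range(locs.size):
                    records.append((
                        pid, phase, task, cond, feedback, block, t,
                        locs[t], resp[t], emean[t], esd[t], fb[t]))

    return pd.DataFrame.from_records(records, columns=[
        "participant_id", "phase", "task", "condition", "feedback_group",
        "block", "trial", "true_azimuth", "response_azimuth",
        "eye_mean_dev", "eye_sd_dev", "feedback_shown_azimuth"])
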
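"""Matching-task paradigm: stimulus domains, scale mapping and trial schedules.

The task asks a participant to reproduce a stimulus feature (tone frequency,
amplitude-modulation rate, colour hue or flash rate) by clicking on a
horizontal on-screen scale.  The feature's parameter range is mapped linearly
onto the central, usable portion of the scale; the extreme 10% of pixels at
each end are excluded because matching at the boundaries is skewed.  In the
working-memory condition the match is made after a masker and a 2-4 s delay;
in the perception condition the target is replayed immediately after each
match attempt.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusDomain",
    "ScaleMapping",
    "TrialSpec",
    "DEFAULT_DOMAINS",
    "WORKING_MEMORY",
    "PERCEPTION",
    "EXPERIMENT_CONDITIONS",
    "make_trial_schedule",
    "param_to_scale",
    "scale_to_param",
    "schedule_to_frame",
]

WORKING_MEMORY = "working_memory"
PERCEPTION = "perception"

DELAY_RANGE_S = (2.0, 4.0)


@dataclass(frozen=True)
class StimulusDomain:
    """A matchable stimulus feature with its parameter range.

    ``error_mode`` controls how matching errors are normalised downstream:
    ``"relative"`` divides the raw error by the target parameter (appropriate
    for frequency-like features whose perceptual distance shrinks as the
    parameter grows), ``"absolute"`` keeps raw units (colour hue).
    """

    name: str
    modality: str  # "auditory" | "visual"
    param_min: float
    param_max: float
    error_mode: str  # "relative" | "absolute"

    def __post_init__(self) -> None:
        if self.param_min >= self.param_max:
            raise ValueError(
                f"domain {self.name!r}: param_min ({self.param_min}) must be "
                f"< param_max ({self.param_max})"
            )
        if self.error_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown error_mode {self.error_mode!r}")
        if self.modality not in ("auditory", "visual"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def param_range(self) -> float:
        return self.param_max - self.param_min


#: Default domain registry: pure tones 440-880 Hz, sinusoidally amplitude
#: modulated noise 5-20 Hz, colour hue 0-300, flashing box 5-20 Hz.
DEFAULT_DOMAINS: Mapping[str, StimulusDomain] = {
    "tone_frequency": StimulusDomain("tone_frequency", "auditory", 440.0, 880.0, "relative"),
    "am_rate": StimulusDomain("am_rate", "auditory", 5.0, 20.0, "relative"),
    "colour_hue": StimulusDomain("colour_hue", "visual", 0.0, 300.0, "absolute"),
    "flash_rate": StimulusDomain("flash_rate", "visual", 5.0, 20.0, "relative"),
}

#: (domain, condition) cells per experiment.  Experiment 1 tests working
#: memory in all four domains; experiment 2 tests the two auditory domains in
#: both working-memory and perception conditions.
EXPERIMENT_CONDITIONS: Mapping[str, tuple[tuple[str, str], ...]] = {
    "exp1": (
        ("tone_frequency", WORKING_MEMORY),
        ("am_rate", WORKING_MEMORY),
        ("colour_hue", WORKING_MEMORY),
        ("flash_rate", WORKING_MEMORY),
    ),
    "exp2": (
        ("tone_frequency", WORKING_MEMORY),
        ("am_rate", WORKING_MEMORY),
        ("tone_frequency", PERCEPTION),
        ("am_rate", PERCEPTION),
    ),
}


@dataclass(frozen=True)
class ScaleMapping:
    """Affine map between a domain's parameter range and scale pixels.

    The full parameter range is mapped onto the central ``usable_fraction``
    of the ``pixel_width`` scale, leaving symmetric excluded margins of
    ``(1 - usable_fraction) / 2`` at each end.
    """

    domain: StimulusDomain
    pixel_width: int = 800
    usable_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.usable_fraction <= 1.0):
            raise ValueError("usable_fraction must be in (0, 1]")
        if self.pixel_width <= 0:
            raise ValueError("pixel_width must be positive")

    @property
    def margin_px(self) -> float:
        return self.pixel_width * (1.0 - self.usable_fraction) / 2.0

    @property
    def usable_band_px(self) -> tuple[float, float]:
        return (self.margin_px, self.pixel_width - self.margin_px)


def param_to_scale(param: float, mapping: ScaleMapping) -> float:
    """Map a stimulus parameter to its pixel position on the scale."""
    d = mapping.domain
    if not (d.param_min <= param <= d.param_max):
        raise ValueError(
            f"param {param} outside [{d.param_min}, {d.param_max}] for domain {d.name!r}"
        )
    lo, hi = mapping.usable_band_px
    frac = (param - d.param_min) / d.param_range
    return lo + frac * (hi - lo)


def scale_to_param(pixel: float, mapping: ScaleMapping) -> float:
    """Inverse of :func:`param_to_scale`; errors on pixels in the margins."""
    lo, hi = mapping.usable_band_px
    if not (lo <= pixel <= hi):
        raise ValueError(
            f"pixel {pixel} lies in an excluded margin (usable band [{lo}, {hi}])"
        )
    d = mapping.domain
    frac = (pixel - lo) / (hi - lo)
    return d.param_min + frac * d.param_range


@dataclass(frozen=True)
class TrialSpec:
    """One matching trial: a target to reproduce and an initial probe."""

    trial_index: int
    participant_id: str
    domain: str
    condition: str  # working_memory | perception
    target_param: float
    probe_param: float
    delay_s: float | None = None  # working-memory trials only

    def __post_init__(self) -> None:
        if self.condition not in (WORKING_MEMORY, PERCEPTION):
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition == WORKING_MEMORY:
            if self.delay_s is None or not (DELAY_RANGE_S[0] <= self.delay_s <= DELAY_RANGE_S[1]):
                raise ValueError(
                    f"working-memory trial needs delay_s in {DELAY_RANGE_S}, got {self.delay_s}"
                )


def make_trial_schedule(
    experiment: str,
    trials_per_condition: int = 14,
    seed: int = 0,
    participant_id: str = "P000",
    domains: Mapping[str, StimulusDomain] = DEFAULT_DOMAINS,
) -> list[TrialSpec]:
    """Build a randomised trial schedule for one participant.

    Experiment 1 runs ``trials_per_condition`` working-memory trials in each
    of the four domains (default 14, i.e. 56 trials); experiment 2 crosses
    the two auditory domains with working-memory and perception conditions.
    Targets and probes are drawn uniformly from each domain's parameter
    range; working-memory delays are uniform on [2, 4] s.  Fully reproducible
    from ``seed``.
    """
    if experiment not in EXPERIMENT_CONDITIONS:
        raise ValueError(
            f"unknown experiment {experiment!r}; expected one of {sorted(EXPERIMENT_CONDITIONS)}"
        )
    if trials_per_condition < 1:
        raise ValueError("trials_per_condition must be >= 1")

    rng = np.random.default_rng(seed)
    cells = EXPERIMENT_CONDITIONS[experiment]
    trials: list[dict] = []
    for domain_name, condition in cells:
        dom = domains[domain_name]
        targets = rng.uniform(dom.param_min, dom.param_max, trials_per_condition)
        probes = rng.uniform(dom.param_min, dom.param_max, trials_per_condition)
        delays = (
            rng.uniform(*DELAY_RANGE_S, trials_per_condition)
            if condition == WORKING_MEMORY
            else [None] * trials_per_condition
        )
        for t, p, dly in zip(targets, probes, delays):
            trials.append(
                dict(
                    participant_id=participant_id,
                    domain=domain_name,
                    condition=condition,
                    target_param=float(t),
                    probe_param=float(p),
                    delay_s=None if dly is None else float(dly),
                )
            )
    order = rng.permutation(len(trials))
    return [
        TrialSpec(trial_index=i, **trials[j]) for i, j in enumerate(order)
    ]


def schedule_to_frame(schedule: Sequence[TrialSpec] | Iterable[TrialSpec]) -> pd.DataFrame:
    """Tabulate a schedule with the canonical column order."""
    rows = [
        (t.trial_index, t.participant_id, t.domain, t.condition, t.target_param, t.probe_param, t.delay_s)
        for t in schedule
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "trial_index",
            "participant_id",
            "domain",
            "condition",
            "target_param",
            "probe_param",
            "delay_s",
        ],
    )
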
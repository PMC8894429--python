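"""Synthetic cohort generator.

Emulates the statistical structure the precision/association pipeline
assumes: each participant carries a latent musical-sophistication trait
(standard normal), per-(domain, condition) error scales whose logs correlate
with that trait at configurable strength, an 18-item 7-point musical
sophistication questionnaire whose total is a noisy monotone transform of
the trait, and age / non-verbal-reasoning covariates with small links to the
trait.  Per-trial matching errors are Gaussian on the normalised error scale
(relative for frequency-like domains, absolute for colour hue), so the
precision estimator downstream recovers 1 / latent sigma.

The construction makes the configured ``rho`` exact in population:

    log sigma = log(sigma_mean) + s * (-rho * trait + sqrt(1 - rho^2) * xi)

with ``s`` the between-participant spread of log sigma, hence
corr(trait, -log sigma) = rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .paradigm import (
    DEFAULT_DOMAINS,
    EXPERIMENT_CONDITIONS,
    PERCEPTION,
    WORKING_MEMORY,
    StimulusDomain,
    TrialSpec,
    schedule_to_frame,
)

__all__ = [
    "GenerativeConfig",
    "Participant",
    "ResponseRecord",
    "generate_cohort",
    "generate_responses",
    "simulate_experiment",
    "participants_to_frame",
    "MSI_N_ITEMS",
    "MSI_TRAINING_ITEMS",
]

MSI_N_ITEMS = 18
#: Indices (0-based) of the items forming the 7-item musical-training
#: subsection (subtotal range 7-49).
MSI_TRAINING_ITEMS = tuple(range(7))

#: Thresholds cutting the latent item score into the 7 response categories.
_MSI_CUTS = np.linspace(-1.25, 1.25, 6)


def _default_rhos() -> dict[tuple[str, str], float]:
    # Strong link only for frequency working memory; weak or null elsewhere.
    return {
        ("tone_frequency", WORKING_MEMORY): 0.5,
        ("am_rate", WORKING_MEMORY): 0.1,
        ("colour_hue", WORKING_MEMORY): 0.0,
        ("flash_rate", WORKING_MEMORY): 0.0,
        ("tone_frequency", PERCEPTION): 0.1,
        ("am_rate", PERCEPTION): 0.1,
    }


@dataclass
class GenerativeConfig:
    """Parameters of the synthetic cohort.

    sigma_wm_mean / sigma_perc_mean are typical relative-error SDs for the
    working-memory and perception conditions (perception is narrower);
    sigma_hue_wm_mean is the absolute-mode analogue in hue units.
    ``between_participant_spread`` is the SD of log sigma across
    participants.  ``age_effect`` / ``matrix_effect`` are standardised
    coefficients linking the covariates to the sophistication trait.
    """

    n_participants: int = 50
    seed: int = 0
    rho_by_condition: dict[tuple[str, str], float] = field(default_factory=_default_rhos)
    age_range: tuple[float, float] = (18.0, 80.0)
    sigma_wm_mean: float = 0.15
    sigma_perc_mean: float = 0.05
    sigma_hue_wm_mean: float = 30.0
    between_participant_spread: float = 0.4
    age_effect: float = 0.1
    matrix_effect: float = 0.1
    msi_item_noise_sd: float = 0.4

    def __post_init__(self) -> None:
        if self.n_participants < 4:
            raise ValueError("n_participants must be >= 4")
        for key, rho in self.rho_by_condition.items():
            if abs(rho) > 1.0:
                raise ValueError(f"|rho| > 1 for {key}: {rho}")
        if not self.sigma_perc_mean < self.sigma_wm_mean:
            raise ValueError("sigma_perc_mean must be < sigma_wm_mean")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("invalid age_range")
        if self.between_participant_spread <= 0:
            raise ValueError("between_participant_spread must be positive")

    def sigma_mean_for(self, domain: StimulusDomain, condition: str) -> float:
        """Typical error-scale SD for one (domain, condition) cell."""
        if domain.error_mode == "absolute":
            base = self.sigma_hue_wm_mean
            if condition == PERCEPTION:
                base *= self.sigma_perc_mean / self.sigma_wm_mean
            return base
        return self.sigma_perc_mean if condition == PERCEPTION else self.sigma_wm_mean


@dataclass
class Participant:
    id: str
    age: float
    matrix_score: int
    msi_items: tuple[int, ...]
    msi_total: int
    msi_training_total: int
    latent_sigma: dict[tuple[str, str], float]
    sophistication: float  # latent trait; synthetic bookkeeping only

    def __post_init__(self) -> None:
        if len(self.msi_items) != MSI_N_ITEMS:
            raise ValueError(f"expected {MSI_N_ITEMS} questionnaire items")
        if self.msi_total != sum(self.msi_items):
            raise ValueError("msi_total must equal sum of items")
        if not (0 <= self.matrix_score <= 12):
            raise ValueError("matrix_score must be in [0, 12]")
        for key, s in self.latent_sigma.items():
            if s <= 0:
                raise ValueError(f"latent_sigma must be positive; {key} -> {s}")


@dataclass(frozen=True)
class ResponseRecord:
    """A participant's final match on one trial."""

    participant_id: str
    trial_index: int
    domain: str
    condition: str
    target_param: float
    matched_param: float


def _msi_items_from_trait(trait: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    """Graded threshold model: latent trait + item noise cut into 1..7."""
    n = trait.size
    u = trait[:, None] + noise_sd * rng.standard_normal((n, MSI_N_ITEMS))
    return 1 + (u[:, :, None] > _MSI_CUTS[None, None, :]).sum(axis=2)


def generate_cohort(
    config: GenerativeConfig,
    domains: Mapping[str, StimulusDomain] = DEFAULT_DOMAINS,
    conditions: Sequence[tuple[str, str]] | None = None,
) -> list[Participant]:
    """Draw a synthetic cohort with the configured correlation structure.

    ``conditions`` defaults to every (domain, condition) key in
    ``config.rho_by_condition`` whose domain is registered.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants

    if conditions is None:
        conditions = [k for k in cfg.rho_by_condition if k[0] in domains]

    lo, hi = cfg.age_range
    age = rng.uniform(lo, hi, n)
    z_age = (age - (lo + hi) / 2.0) / ((hi - lo) / np.sqrt(12.0))

    ability = rng.standard_normal(n)
    matrix_score = np.clip(np.round(6.5 + 2.5 * ability), 0, 12).astype(int)

    resid_var = 1.0 - cfg.age_effect**2 - cfg.matrix_effect**2
    if resid_var <= 0:
        raise ValueError("covariate effects too large; trait variance non-positive")
    trait = (
        cfg.age_effect * z_age
        + cfg.matrix_effect * ability
        + np.sqrt(resid_var) * rng.standard_normal(n)
    )

    items = _msi_items_from_trait(trait, cfg.msi_item_noise_sd, rng)
    totals = items.sum(axis=1)
    training_totals = items[:, list(MSI_TRAINING_ITEMS)].sum(axis=1)

    log_sigma: dict[tuple[str, str], np.ndarray] = {}
    for key in conditions:
        domain_name, condition = key
        rho = cfg.rho_by_condition.get(key, 0.0)
        mean_sigma = cfg.sigma_mean_for(domains[domain_name], condition)
        xi = rng.standard_normal(n)
        log_sigma[key] = np.log(mean_sigma) + cfg.between_participant_spread * (
            -rho * trait + np.sqrt(1.0 - rho**2) * xi
        )

    width = max(3, len(str(n - 1)))
    participants = []
    for i in range(n):
        participants.append(
            Participant(
                id=f"P{i:0{width}d}",
                age=float(age[i]),
                matrix_score=int(matrix_score[i]),
                msi_items=tuple(int(v) for v in items[i]),
                msi_total=int(totals[i]),
                msi_training_total=int(training_totals[i]),
                latent_sigma={k: float(np.exp(v[i])) for k, v in log_sigma.items()},
                sophistication=float(trait[i]),
            )
        )
    return participants


def participants_to_frame(participants: Sequence[Participant]) -> pd.DataFrame:
    """Flat participant table (one msi_item_k column per questionnaire item)."""
    rows = []
    for p in participants:
        row = {
            "participant_id": p.id,
            "age": p.age,
            "matrix_score": p.matrix_score,
            **{f"msi_item_{k + 1}": v for k, v in enumerate(p.msi_items)},
            "msi_total": p.msi_total,
            "msi_training_total": p.msi_training_total,
        }
        rows.append(row)
    return pd.DataFrame(rows)


def _sigma_lookup(participants: Sequence[Participant]) -> dict[tuple[str, str, str], float]:
    return {
        (p.id, dom, cond): s
        for p in participants
        for (dom, cond), s in p.latent_sigma.items()
    }


def generate_responses(
    participants: Sequence[Participant],
    schedule: Sequence[TrialSpec] | pd.DataFrame,
    seed: int = 0,
    domains: Mapping[str, StimulusDomain] = DEFAULT_DOMAINS,
    clamp: bool = False,
) -> pd.DataFrame:
    """Simulate final matches for every scheduled trial.

    Errors are drawn Normal(0, sigma^2) on the domain's normalised error
    scale: relative-mode domains get matched = target * (1 + e), absolute
    mode gets matched = target + e.  ``clamp`` optionally clips matches to
    the parameter range (off by default; clamping induces boundary skew).
    """
    frame = schedule if isinstance(schedule, pd.DataFrame) else schedule_to_frame(schedule)
    frame = frame.reset_index(drop=True)

    for d in frame["domain"].unique():
        if d not in domains:
            raise KeyError(f"unregistered domain {d!r}")

    lookup = _sigma_lookup(participants)
    try:
        sigma = np.array(
            [
                lookup[(pid, dom, cond)]
                for pid, dom, cond in zip(frame["participant_id"], frame["domain"], frame["condition"])
            ]
        )
    except KeyError as exc:
        raise KeyError(f"no latent_sigma for scheduled cell {exc.args[0]}") from None

    rng = np.random.default_rng(seed)
    e = rng.standard_normal(len(frame)) * sigma
    target = frame["target_param"].to_numpy(dtype=float)
    relative = np.array([domains[d].error_mode == "relative" for d in frame["domain"]])
    matched = np.where(relative, target * (1.0 + e), target + e)
    if clamp:
        p_min = np.array([domains[d].param_min for d in frame["domain"]])
        p_max = np.array([domains[d].param_max for d in frame["domain"]])
        matched = np.clip(matched, p_min, p_max)

    return pd.DataFrame(
        {
            "participant_id": frame["participant_id"],
            "trial_index": frame["trial_index"],
            "domain": frame["domain"],
            "condition": frame["condition"],
            "target_param": target,
            "matched_param": matched,
        }
    )


def simulate_experiment(
    config: GenerativeConfig,
    experiment: str = "exp1",
    trials_per_condition: int = 14,
    domains: Mapping[str, StimulusDomain] = DEFAULT_DOMAINS,
) -> tuple[list[Participant], pd.DataFrame, pd.DataFrame]:
    """Cohort + schedule + responses for one experiment, fully seeded.

    Builds a balanced per-participant schedule (targets uniform on each
    domain's range, working-memory delays uniform on [2, 4] s) vectorised
    across the cohort, then simulates responses.  Returns (participants,
    responses, participants_frame).
    """
    if experiment not in EXPERIMENT_CONDITIONS:
        raise ValueError(f"unknown experiment {experiment!r}")
    cells = EXPERIMENT_CONDITIONS[experiment]
    participants = generate_cohort(config, domains=domains, conditions=list(cells))

    ss = np.random.SeedSequence(config.seed)
    sched_seed, resp_seed = (int(s) % (2**31) for s in ss.generate_state(2))
    rng = np.random.default_rng(sched_seed)

    n = len(participants)
    ids = np.array([p.id for p in participants])
    blocks = []
    for domain_name, condition in cells:
        dom = domains[domain_name]
        targets = rng.uniform(dom.param_min, dom.param_max, (n, trials_per_condition))
        probes = rng.uniform(dom.param_min, dom.param_max, (n, trials_per_condition))
        blocks.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(ids, trials_per_condition),
                    "domain": domain_name,
                    "condition": condition,
                    "target_param": targets.ravel(),
                    "probe_param": probes.ravel(),
                    "delay_s": (
                        rng.uniform(2.0, 4.0, n * trials_per_condition)
                        if condition == WORKING_MEMORY
                        else np.nan
                    ),
                }
            )
        )
    schedule = pd.concat(blocks, ignore_index=True)
    schedule = schedule.sort_values("participant_id", kind="stable").reset_index(drop=True)
    schedule["trial_index"] = schedule.groupby("participant_id").cumcount()

    responses = generate_responses(participants, schedule, seed=resp_seed, domains=domains)
    return participants, responses, participants_to_frame(participants)
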
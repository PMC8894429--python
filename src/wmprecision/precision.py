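"""The precision measurement model: errors, inverse-SD precision, z-scores.

For each trial the raw error is matched - target.  For frequency-like
domains (tone frequency, AM rate, flash rate) the error is divided by the
target parameter first, because a fixed parameter difference is perceived as
smaller at higher parameter values; colour hue keeps absolute units.
Precision for one participant, domain and condition is the inverse of the
standard deviation of these normalised errors, and precisions are z-scored
across participants within each domain x condition cell for
interpretability.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .paradigm import DEFAULT_DOMAINS, StimulusDomain

__all__ = [
    "DegenerateDataError",
    "compute_errors",
    "estimate_precision",
    "zscore_precisions",
    "normality_check",
]

_GROUP_KEYS = ["participant_id", "domain", "condition"]


class DegenerateDataError(ValueError):
    """Raised when a participant's errors have zero spread."""


def compute_errors(
    responses: pd.DataFrame,
    domains: Mapping[str, StimulusDomain] = DEFAULT_DOMAINS,
) -> pd.DataFrame:
    """Per-trial raw and normalised errors.

    Input needs columns participant_id, domain, condition, target_param,
    matched_param.  Relative-mode domains require nonzero targets.
    """
    required = {"participant_id", "domain", "condition", "target_param", "matched_param"}
    missing = required - set(responses.columns)
    if missing:
        raise KeyError(f"responses table missing column(s): {sorted(missing)}")

    for d in pd.unique(responses["domain"]):
        if d not in domains:
            raise KeyError(f"unregistered domain {d!r}")

    target = responses["target_param"].to_numpy(dtype=float)
    matched = responses["matched_param"].to_numpy(dtype=float)
    raw = matched - target
    relative = np.array([domains[d].error_mode == "relative" for d in responses["domain"]])
    if np.any(relative & (target == 0.0)):
        raise ValueError("relative-mode trial with target_param = 0")
    normalized = np.where(relative, raw / np.where(target == 0, 1.0, target), raw)

    out = responses[_GROUP_KEYS].copy()
    out["raw_error"] = raw
    out["normalized_error"] = normalized
    return out


def estimate_precision(errors: pd.DataFrame, min_trials: int = 2) -> pd.DataFrame:
    """Inverse-SD precision per participant x domain x condition.

    sd_error is the sample SD (n-1 denominator) of the normalised errors in
    the group; precision = 1 / sd_error.  Groups with fewer than
    ``min_trials`` records are kept but flagged missing (NaN estimates), not
    fabricated.  A zero SD raises :class:`DegenerateDataError` naming the
    participant.
    """
    if min_trials < 2:
        raise ValueError("min_trials must be >= 2 (SD needs at least 2 trials)")
    grouped = errors.groupby(_GROUP_KEYS, sort=True)["normalized_error"]
    table = grouped.agg(n_trials="size", sd_error=lambda v: v.std(ddof=1)).reset_index()

    small = table["n_trials"] < min_trials
    zero = (~small) & (table["sd_error"] == 0.0)
    if zero.any():
        bad = table.loc[zero, _GROUP_KEYS].iloc[0]
        raise DegenerateDataError(
            f"zero error SD for participant {bad['participant_id']!r} "
            f"({bad['domain']}, {bad['condition']}): all matches identical"
        )
    table.loc[small, "sd_error"] = np.nan
    table["precision"] = 1.0 / table["sd_error"]
    return table


def zscore_precisions(estimates: pd.DataFrame) -> pd.DataFrame:
    """Standardise precision across participants within domain x condition.

    Uses mean and sample SD (n-1) over non-missing estimates; requires at
    least two per cell and nonzero spread.
    """
    out = estimates.copy()
    out["z_precision"] = np.nan
    for (dom, cond), idx in out.groupby(["domain", "condition"]).groups.items():
        vals = out.loc[idx, "precision"]
        ok = vals.notna()
        if ok.sum() < 2:
            raise ValueError(f"fewer than 2 precision estimates in cell ({dom}, {cond})")
        sd = vals[ok].std(ddof=1)
        if sd == 0:
            raise DegenerateDataError(f"zero cross-participant spread in cell ({dom}, {cond})")
        out.loc[idx, "z_precision"] = (vals - vals[ok].mean()) / sd
    return out


def normality_check(errors: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Shapiro-Wilk test of the error distribution per group.

    Reported per participant x domain x condition; never used to exclude
    data automatically.  Groups smaller than ``min_n`` raise.
    """
    rows = []
    for key, vals in errors.groupby(_GROUP_KEYS, sort=True)["normalized_error"]:
        if len(vals) < min_n:
            raise ValueError(f"group {key} has fewer than {min_n} trials")
        w, p = stats.shapiro(vals.to_numpy())
        rows.append((*key, len(vals), float(w), float(p)))
    return pd.DataFrame(rows, columns=[*_GROUP_KEYS, "n_trials", "shapiro_w", "p_value"])
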
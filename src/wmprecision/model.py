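"""Model/Results interface tying precision estimates to sophistication.

`PrecisionAssociationModel` joins a per-participant precision table with a
participant covariate table, residualizes the musical-sophistication score
on the nuisance covariates (age, non-verbal reasoning), and on `fit()`
returns a `PrecisionAssociationResults` carrying every covariate-adjusted
association, the Holm-adjusted family, and the bootstrap comparisons of the
dependent correlations (frequency-WM vs AM-WM, and frequency-WM vs
frequency-perception when a perception condition is present).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .association import (
    AssociationResult,
    CorrelationComparison,
    adjusted_association,
    compare_dependent_correlations,
    holm_bonferroni,
    residualize,
)
from .paradigm import PERCEPTION, WORKING_MEMORY

__all__ = ["PrecisionAssociationModel", "PrecisionAssociationResults", "run_full_analysis"]

_DEFAULT_COVARIATES = ("age", "matrix_score")


def _cell_label(domain: str, condition: str) -> str:
    return f"{domain}:{condition}"


class PrecisionAssociationModel:
    """Covariate-adjusted association analysis of precision measures.

    Parameters
    ----------
    precision : DataFrame
        Output of the precision stage: one row per participant x domain x
        condition with a ``z_precision`` column.
    participants : DataFrame
        Covariate table with ``participant_id``, the outcome column
        (default ``msi_total``) and the nuisance covariates.
    adjustment_mode : str
        ``residualize_x_only`` (default: residualize the sophistication
        score on the covariates, correlate with raw precision) or
        ``residualize_both`` (full partial correlation).
    family : sequence of (domain, condition), optional
        The Holm family; defaults to every cell present in the precision
        table.
    comparisons : bool
        Whether to run the bootstrap comparisons of dependent correlations.
    partial_perception : bool
        Additionally report the frequency-WM association with frequency
        perceptual precision partialled out (only meaningful when a
        perception condition is present).
    """

    def __init__(
        self,
        precision: pd.DataFrame,
        participants: pd.DataFrame,
        *,
        outcome: str = "msi_total",
        covariates: Sequence[str] = _DEFAULT_COVARIATES,
        adjustment_mode: str = "residualize_x_only",
        alpha: float = 0.05,
        n_resamples: int = 5000,
        family: Sequence[tuple[str, str]] | None = None,
        comparisons: bool = True,
        partial_perception: bool | None = None,
        measure: str = "z_precision",
    ) -> None:
        for col in ("participant_id", "domain", "condition", measure):
            if col not in precision.columns:
                raise KeyError(f"precision table missing column {col!r}")
        for col in ("participant_id", outcome, *covariates):
            if col not in participants.columns:
                raise KeyError(f"participant table missing column {col!r}")

        self.outcome = outcome
        self.covariates = tuple(covariates)
        self.adjustment_mode = adjustment_mode
        self.alpha = alpha
        self.n_resamples = n_resamples
        self.comparisons = comparisons
        self.measure = measure

        wide = precision.pivot_table(
            index="participant_id", columns=["domain", "condition"], values=measure
        )
        wide.columns = [_cell_label(d, c) for d, c in wide.columns]
        self.cells = (
            [tuple(f) for f in family]
            if family is not None
            else sorted(
                {(d, c) for d, c in zip(precision["domain"], precision["condition"])}
            )
        )
        for d, c in self.cells:
            if _cell_label(d, c) not in wide.columns:
                raise KeyError(f"family cell ({d}, {c}) absent from precision table")

        joined = participants.set_index("participant_id").join(wide, how="inner")
        cols = [outcome, *covariates] + [_cell_label(d, c) for d, c in self.cells]
        complete = joined[cols].dropna()
        self.n_dropped = len(joined) - len(complete)
        if len(complete) < 5:
            raise ValueError("fewer than 5 complete cases after joining tables")
        self.data = complete

        has_perception = any(c == PERCEPTION for _, c in self.cells)
        self.partial_perception = (
            has_perception if partial_perception is None else partial_perception
        )

    @classmethod
    def from_responses(
        cls,
        responses: pd.DataFrame,
        participants: pd.DataFrame,
        domains=None,
        min_trials: int = 2,
        **kwargs,
    ) -> "PrecisionAssociationModel":
        """Build directly from a per-trial response table."""
        from .paradigm import DEFAULT_DOMAINS
        from .precision import compute_errors, estimate_precision, zscore_precisions

        domains = DEFAULT_DOMAINS if domains is None else domains
        errors = compute_errors(responses, domains)
        estimates = zscore_precisions(estimate_precision(errors, min_trials=min_trials))
        return cls(estimates, participants, **kwargs)

    def fit(self, seed: int = 0) -> "PrecisionAssociationResults":
        """Run the association family, Holm correction and comparisons."""
        data = self.data
        X = data[list(self.covariates)].to_numpy() if self.covariates else None
        x_raw = data[self.outcome].to_numpy(dtype=float)
        x_adj = residualize(x_raw, X) if self.covariates else x_raw - x_raw.mean()

        associations: list[AssociationResult] = []
        for d, c in self.cells:
            y = data[_cell_label(d, c)].to_numpy(dtype=float)
            associations.append(
                adjusted_association(
                    x_raw,
                    y,
                    covariates=X,
                    mode=self.adjustment_mode,
                    variable_x=self.outcome,
                    variable_y=_cell_label(d, c),
                    covariate_names=self.covariates,
                )
            )
        reject, p_adj = holm_bonferroni([a.p for a in associations], alpha=self.alpha)

        extra: list[AssociationResult] = []
        freq_wm = _cell_label("tone_frequency", WORKING_MEMORY)
        freq_perc = _cell_label("tone_frequency", PERCEPTION)
        if self.partial_perception and freq_perc in data.columns and freq_wm in data.columns:
            X_plus = np.column_stack(
                [data[list(self.covariates)].to_numpy(), data[freq_perc].to_numpy()]
            )
            extra.append(
                adjusted_association(
                    x_raw,
                    data[freq_wm].to_numpy(dtype=float),
                    covariates=X_plus,
                    mode="residualize_both",
                    variable_x=self.outcome,
                    variable_y=freq_wm,
                    covariate_names=(*self.covariates, freq_perc),
                )
            )

        comparisons: dict[str, CorrelationComparison] = {}
        if self.comparisons:
            ss = np.random.SeedSequence(seed)
            comp_seeds = [int(s) % (2**31) for s in ss.generate_state(2)]
            am_wm = _cell_label("am_rate", WORKING_MEMORY)
            if freq_wm in data.columns and am_wm in data.columns:
                comparisons["freq_wm_vs_am_wm"] = compare_dependent_correlations(
                    x_adj,
                    data[freq_wm].to_numpy(dtype=float),
                    data[am_wm].to_numpy(dtype=float),
                    n_resamples=self.n_resamples,
                    seed=comp_seeds[0],
                )
            if freq_wm in data.columns and freq_perc in data.columns:
                comparisons["freq_wm_vs_freq_perception"] = compare_dependent_correlations(
                    x_adj,
                    data[freq_wm].to_numpy(dtype=float),
                    data[freq_perc].to_numpy(dtype=float),
                    n_resamples=self.n_resamples,
                    seed=comp_seeds[1],
                )

        return PrecisionAssociationResults(
            model=self,
            associations=associations,
            holm_reject=np.asarray(reject, dtype=bool),
            holm_adjusted_p=np.asarray(p_adj, dtype=float),
            extra_associations=extra,
            comparisons=comparisons,
            seed=seed,
        )


@dataclass
class PrecisionAssociationResults:
    """Fitted associations, Holm family and bootstrap comparisons."""

    model: PrecisionAssociationModel
    associations: list[AssociationResult]
    holm_reject: np.ndarray
    holm_adjusted_p: np.ndarray
    extra_associations: list[AssociationResult]
    comparisons: dict[str, CorrelationComparison]
    seed: int

    @property
    def associations_frame(self) -> pd.DataFrame:
        rows = [a.as_dict() for a in self.associations]
        out = pd.DataFrame(rows)
        out["p_holm"] = self.holm_adjusted_p
        out["reject_holm"] = self.holm_reject
        if self.extra_associations:
            extra = pd.DataFrame([a.as_dict() for a in self.extra_associations])
            extra["p_holm"] = np.nan
            extra["reject_holm"] = pd.NA
            out = pd.concat([out, extra], ignore_index=True)
        out["covariates"] = out["covariates"].map(lambda v: "+".join(v))
        return out

    def to_report(self) -> dict:
        """JSON-able structured report (stable key order)."""
        m = self.model
        return {
            "config": {
                "outcome": m.outcome,
                "covariates": list(m.covariates),
                "adjustment_mode": m.adjustment_mode,
                "alpha": m.alpha,
                "n_resamples": m.n_resamples,
                "family": [list(c) for c in m.cells],
                "measure": m.measure,
                "partial_perception": m.partial_perception,
            },
            "n_complete_cases": int(len(m.data)),
            "n_dropped_incomplete": int(m.n_dropped),
            "seed": self.seed,
            "associations": [
                {**a.as_dict(), "p_holm": float(ph), "reject_holm": bool(rj)}
                for a, ph, rj in zip(self.associations, self.holm_adjusted_p, self.holm_reject)
            ],
            "extra_associations": [a.as_dict() for a in self.extra_associations],
            "comparisons": {k: v.as_dict() for k, v in self.comparisons.items()},
        }

    def to_json(self, **kwargs) -> str:
        kwargs.setdefault("sort_keys", True)
        kwargs.setdefault("indent", 2)
        return json.dumps(self.to_report(), **kwargs)

    def summary(self) -> str:
        """Human-readable summary table."""
        m = self.model
        lines = [
            "Precision-association analysis",
            "=" * 78,
            f"outcome: {m.outcome}   covariates: {', '.join(m.covariates) or 'none'}"
            f"   adjustment: {m.adjustment_mode}",
            f"n = {len(m.data)} complete cases ({m.n_dropped} dropped)   alpha = {m.alpha}",
            "-" * 78,
            f"{'measure':<38}{'r':>8}{'df':>6}{'p':>10}{'p_holm':>10}{'sig':>5}",
        ]
        for a, ph, rj in zip(self.associations, self.holm_adjusted_p, self.holm_reject):
            lines.append(
                f"{a.variable_y:<38}{a.r:>8.3f}{a.df:>6d}{a.p:>10.4f}{ph:>10.4f}"
                f"{'  *' if rj else '':>5}"
            )
        for a in self.extra_associations:
            lines.append(
                f"{a.variable_y + ' | ' + a.covariates[-1]:<38}{a.r:>8.3f}{a.df:>6d}"
                f"{a.p:>10.4f}{'':>10}{'':>5}"
            )
        if self.comparisons:
            lines.append("-" * 78)
            lines.append("dependent-correlation comparisons (bootstrap, resampled with replacement)")
            for name, c in self.comparisons.items():
                lines.append(
                    f"  {name}: r1={c.r1:.3f} r2={c.r2:.3f} "
                    f"t={c.t_stat:.2f} p_t={c.p_t:.3g} p_percentile={c.p_percentile:.3g}"
                )
        lines.append("=" * 78)
        return "\n".join(lines)

    def plot_associations(self, ax=None):
        """Scatter of adjusted sophistication vs each precision measure."""
        import matplotlib.pyplot as plt

        m = self.model
        n = len(m.cells)
        if ax is None:
            _, axes = plt.subplots(1, n, figsize=(4 * n, 3.5), squeeze=False)
            axes = axes[0]
        else:
            axes = [ax]
        X = m.data[list(m.covariates)].to_numpy() if m.covariates else None
        x_adj = residualize(m.data[m.outcome].to_numpy(dtype=float), X)
        for axis, (d, c), a in zip(axes, m.cells, self.associations):
            y = m.data[_cell_label(d, c)]
            axis.scatter(x_adj, y, s=12, alpha=0.7)
            axis.set_title(f"{d} / {c}\nr={a.r:.2f}")
            axis.set_xlabel(f"adjusted {m.outcome}")
            axis.set_ylabel(m.measure)
        return axes


def run_full_analysis(
    precision: pd.DataFrame,
    participants: pd.DataFrame,
    config: Mapping | None = None,
    seed: int = 0,
) -> PrecisionAssociationResults:
    """One-call orchestration: build the model from tables and fit it.

    ``config`` keys mirror the model constructor keywords (alpha,
    n_resamples, adjustment_mode, family, ...).
    """
    cfg = dict(config or {})
    model = PrecisionAssociationModel(precision, participants, **cfg)
    return model.fit(seed=seed)
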
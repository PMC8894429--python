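"""Inferential pipeline: residualization, adjusted correlations, bootstrap
comparison of dependent correlations, Holm-Bonferroni, and power.

The headline analysis residualizes the musical-sophistication score on age
and non-verbal reasoning (variables of no interest) and correlates the
residuals with each precision measure.  Two dependent correlations sharing
the adjusted score are compared by resampling participants with replacement
(5000 samples by default), testing the resampled correlation differences
against zero with a one-sample t test and, as a companion, a percentile
p-value.  Family-wise error over the association family is controlled with
the Holm-Bonferroni step-down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AssociationResult",
    "CorrelationComparison",
    "residualize",
    "adjusted_association",
    "compare_dependent_correlations",
    "holm_bonferroni",
    "required_sample_size",
]

ADJUSTMENT_MODES = ("none", "residualize_x_only", "residualize_both")


@dataclass(frozen=True)
class AssociationResult:
    variable_x: str
    variable_y: str
    n: int
    r: float
    df: int
    p: float
    covariates: tuple[str, ...] = ()
    adjustment_mode: str = "none"

    def as_dict(self) -> dict:
        return {
            "variable_x": self.variable_x,
            "variable_y": self.variable_y,
            "n": self.n,
            "r": self.r,
            "df": self.df,
            "p": self.p,
            "covariates": list(self.covariates),
            "adjustment_mode": self.adjustment_mode,
        }


@dataclass
class CorrelationComparison:
    """Bootstrap comparison of two correlations sharing variable x."""

    r1: float
    r2: float
    n: int
    n_resamples: int
    seed: int
    t_stat: float
    p_t: float
    p_percentile: float
    diff_mean: float
    diff_sd: float
    diff_ci95: tuple[float, float]
    n_redraws: int = 0
    diffs: np.ndarray | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        return {
            "r1": self.r1,
            "r2": self.r2,
            "n": self.n,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "t_stat": self.t_stat,
            "p_t": self.p_t,
            "p_percentile": self.p_percentile,
            "diff_mean": self.diff_mean,
            "diff_sd": self.diff_sd,
            "diff_ci95": list(self.diff_ci95),
            "n_redraws": self.n_redraws,
        }


def _as_matrix(covariates) -> np.ndarray:
    if covariates is None:
        return np.empty((0, 0))
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def residualize(y, covariates) -> np.ndarray:
    """Least-squares residuals of y on [intercept, covariates].

    With no covariates this is plain centering.  Raises on rank-deficient
    design or insufficient n.
    """
    y = np.asarray(y, dtype=float)
    X = _as_matrix(covariates)
    if X.size == 0:
        return y - y.mean()
    if X.shape[0] != y.shape[0]:
        raise ValueError("y and covariates have mismatched lengths")
    design = np.column_stack([np.ones(len(y)), X])
    if len(y) <= design.shape[1] + 1:
        raise ValueError(
            f"need n > {design.shape[1] + 1} observations for {X.shape[1]} covariate(s)"
        )
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient (collinear columns)")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def _r_to_p(r: float, df: int) -> float:
    if df <= 0:
        raise ValueError("non-positive degrees of freedom")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df))


def adjusted_association(
    x,
    y,
    covariates=None,
    mode: str = "residualize_x_only",
    variable_x: str = "x",
    variable_y: str = "y",
    covariate_names: tuple[str, ...] = (),
) -> AssociationResult:
    """Covariate-adjusted Pearson correlation.

    ``residualize_x_only`` (the default analysis) correlates the residuals
    of x on the covariates with raw y; ``residualize_both`` residualizes
    both sides, which equals the closed-form higher-order partial
    correlation.  Two-sided p from the t transform of r with df = n - 2
    (minus the number of covariates for ``residualize_both``).
    """
    if mode not in ADJUSTMENT_MODES:
        raise ValueError(f"unknown adjustment mode {mode!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y have mismatched lengths")
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 complete cases")
    X = _as_matrix(covariates)
    k = X.shape[1] if X.size else 0

    if mode == "none" or k == 0:
        xr, yr = x, y
        df = n - 2
    elif mode == "residualize_x_only":
        xr, yr = residualize(x, X), y
        df = n - 2
    else:
        xr, yr = residualize(x, X), residualize(y, X)
        df = n - 2 - k
    r = _pearson(xr, yr)
    return AssociationResult(
        variable_x=variable_x,
        variable_y=variable_y,
        n=n,
        r=r,
        df=df,
        p=_r_to_p(r, df),
        covariates=tuple(covariate_names) if k else (),
        adjustment_mode=mode if k else "none",
    )


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson r of each row of A with the matching row of B."""
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    denom = np.sqrt((A * A).sum(axis=1) * (B * B).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (A * B).sum(axis=1) / denom


def compare_dependent_correlations(
    x,
    y1,
    y2,
    n_resamples: int = 5000,
    seed: int = 0,
    keep_diffs: bool = False,
) -> CorrelationComparison:
    """Bootstrap comparison of r(x, y1) vs r(x, y2) on shared rows.

    Participants (rows) are resampled with replacement ``n_resamples``
    times; each resample yields r(x, y1) - r(x, y2).  The resampled
    differences are tested against zero with a one-sample t test and a
    two-sided percentile p-value 2 * min(frac <= 0, frac >= 0).  Degenerate
    resamples (zero variance in any variable) are redrawn with a logged
    count; more than 10% redraws is an error.
    """
    x = np.asarray(x, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    if not (len(x) == len(y1) == len(y2)):
        raise ValueError("x, y1, y2 must be aligned")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 complete cases for the bootstrap")
    if n_resamples < 100:
        raise ValueError("n_resamples must be >= 100")

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_resamples, n))
    r1s = _rowwise_pearson(x[idx], y1[idx])
    r2s = _rowwise_pearson(x[idx], y2[idx])

    n_redraws = 0
    bad = ~(np.isfinite(r1s) & np.isfinite(r2s))
    while bad.any():
        n_redraws += int(bad.sum())
        if n_redraws > 0.1 * n_resamples:
            raise ValueError("more than 10% of bootstrap resamples were degenerate")
        ridx = rng.integers(0, n, size=(int(bad.sum()), n))
        r1s[bad] = _rowwise_pearson(x[ridx], y1[ridx])
        r2s[bad] = _rowwise_pearson(x[ridx], y2[ridx])
        bad = ~(np.isfinite(r1s) & np.isfinite(r2s))

    diffs = r1s - r2s
    if np.allclose(diffs, 0.0):
        t_stat, p_t = 0.0, 1.0
    else:
        t_stat, p_t = stats.ttest_1samp(diffs, 0.0)
    p_perc = min(1.0, 2.0 * min(np.mean(diffs <= 0.0), np.mean(diffs >= 0.0)))

    lo, hi = np.percentile(diffs, [2.5, 97.5])
    return CorrelationComparison(
        r1=_pearson(x, y1),
        r2=_pearson(x, y2),
        n=n,
        n_resamples=n_resamples,
        seed=seed,
        t_stat=float(t_stat),
        p_t=float(p_t),
        p_percentile=float(p_perc),
        diff_mean=float(diffs.mean()),
        diff_sd=float(diffs.std(ddof=1)),
        diff_ci95=(float(lo), float(hi)),
        n_redraws=n_redraws,
        diffs=diffs if keep_diffs else None,
    )


def holm_bonferroni(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down: (reject flags, adjusted p-values).

    Adjusted p(i) = max over j <= i (in ascending order) of (m - j + 1) *
    p(j), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, p_adj


def required_sample_size(r: float, alpha: float = 0.05, power: float = 0.80) -> int:
    """Sample size for detecting a Pearson correlation via Fisher z.

    n = ceil(((z_{1-alpha/2} + z_power) / atanh(r))^2 + 3).  For r = 0.40,
    alpha = 0.05 two-tailed and power 0.80 this gives 47.
    """
    if not (0.0 < r < 1.0):
        raise ValueError("r must be in (0, 1)")
    if not (0.0 < alpha < 1.0 and 0.0 < power < 1.0):
        raise ValueError("alpha and power must be in (0, 1)")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(power)
    return max(4, ceil(((z_a + z_b) / np.arctanh(r)) ** 2 + 3))
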
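"""Precision and reliability metrics for AUC estimation equations.

Precision is summarised by the root-mean-square error (RMSE), the squared
correlation R^2 of the least-squares line of estimated on measured AUC, and
Spearman's rank correlation.  Reliability is the cross-validated
determination coefficient q^2 = 1 - PRESS / SS_total from leave-one-out
refitting, which penalises overfitting: q^2 <= R^2 for these linear fits.
Per-profile agreement is the absolute difference |estimated - measured|
("delta AUC").  Group contrasts use the nonparametric tests of the source
analysis: Wilcoxon signed-rank for paired comparisons, Kruskal-Wallis plus
pairwise rank tests with Holm step-down adjustment for independent groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    UndefinedTestError,
)
from .lss import LssEquation, SamplingScheme, fit_ols, predict
from .nca import trapezoidal_auc
from .profiles import ConcentrationTimeProfile

__all__ = [
    "rmse",
    "r2_and_fit_line",
    "loocv",
    "LoocvResult",
    "delta_auc",
    "wilcoxon_matched_pairs",
    "group_comparison",
    "GroupComparison",
    "ValidationReport",
    "validate_equation",
]


def _paired(estimated, measured) -> tuple[np.ndarray, np.ndarray]:
    est = np.asarray(estimated, dtype=float)
    mea = np.asarray(measured, dtype=float)
    if est.shape != mea.shape or est.ndim != 1:
        raise ValueError(
            f"estimated and measured must be equal-length vectors, "
            f"got shapes {est.shape} and {mea.shape}"
        )
    if est.size == 0:
        raise ValueError("empty input vectors")
    return est, mea


def rmse(estimated, measured) -> float:
    """Root-mean-square error, in ug.h/mL."""
    est, mea = _paired(estimated, measured)
    return float(np.sqrt(np.mean((est - mea) ** 2)))


def r2_and_fit_line(estimated, measured) -> tuple[float, float, float]:
    """(R^2, slope, intercept) of the least-squares line estimated ~ measured.

    R^2 is the squared Pearson correlation, so it is blind to the sign of
    the slope.  Requires n >= 3 and nonzero variance in ``measured``.
    """
    est, mea = _paired(estimated, measured)
    if est.size < 3:
        raise InsufficientDataError("need at least 3 pairs for a regression line")
    if np.var(mea) == 0:
        raise DegenerateInputError("measured values have zero variance")
    slope, intercept = np.polyfit(mea, est, 1)
    if np.var(est) == 0:
        return 0.0, float(slope), float(intercept)
    r = np.corrcoef(mea, est)[0, 1]
    return float(r * r), float(slope), float(intercept)


@dataclass
class LoocvResult:
    """Leave-one-out cross-validation summary for one scheme."""

    q2: float
    press: float                      # (ug.h/mL)^2
    predictions: np.ndarray = field(repr=False)


def loocv(profiles: Sequence[ConcentrationTimeProfile],
          scheme: SamplingScheme) -> LoocvResult:
    """Leave-one-out cross-validation of an OLS equation on one scheme.

    For each profile the equation is literally refitted on the other n - 1
    profiles and used to predict the held-out measured AUC;
    PRESS = sum of squared held-out errors and q^2 = 1 - PRESS / SS_total.
    The refit loop is the definition; any algebraic shortcut must reproduce
    it exactly.
    """
    k = len(scheme)
    n = len(profiles)
    if n < k + 3:
        raise InsufficientDataError(
            f"LOOCV of a {k}-point scheme needs n >= {k + 3}, got {n}"
        )
    measured = np.array([trapezoidal_auc(p) for p in profiles])
    preds = np.empty(n)
    for i in range(n):
        rest = [p for j, p in enumerate(profiles) if j != i]
        try:
            fit = fit_ols(rest, scheme)
        except Exception as exc:  # noqa: BLE001 - annotate the fold
            raise type(exc)(f"LOOCV fold {i} (leaving out "
                            f"{profiles[i].patient_id!r}): {exc}") from exc
        preds[i] = predict(fit.equation, [profiles[i]])[0]
    press = float(np.sum((measured - preds) ** 2))
    ss_tot = float(np.sum((measured - measured.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateInputError("measured AUCs have zero variance")
    return LoocvResult(q2=1.0 - press / ss_tot, press=press, predictions=preds)


def delta_auc(estimated, measured) -> np.ndarray:
    """Per-profile |estimated - measured| AUC, in ug.h/mL."""
    est, mea = _paired(estimated, measured)
    return np.abs(est - mea)


def wilcoxon_matched_pairs(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped first (Wilcoxon's original convention).
    The exact null distribution is used for n <= 25 without ties in the
    absolute differences; otherwise the normal approximation with tie and
    continuity correction.  Returns (statistic, p).
    """
    x_arr, y_arr = _paired(x, y)
    diffs = x_arr - y_arr
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        raise UndefinedTestError(
            "signed-rank test undefined: all paired differences are zero"
        )
    if nonzero.size < 6:
        raise InsufficientDataError(
            f"need >= 6 nonzero paired differences, got {nonzero.size}"
        )
    has_ties = np.unique(np.abs(nonzero)).size < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not has_ties) else "approx"
    res = scipy.stats.wilcoxon(
        nonzero, zero_method="wilcox", correction=(method == "approx"),
        alternative="two-sided", method=method,
    )
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparison:
    """Kruskal-Wallis omnibus plus Holm-adjusted pairwise rank tests."""

    h_statistic: float
    omnibus_p: float
    groups: tuple[str, ...]
    pairwise: dict[tuple[str, str], dict[str, float]]  # raw_p, adj_p

    def adjusted_p(self, a: str, b: str) -> float:
        key = (a, b) if (a, b) in self.pairwise else (b, a)
        return self.pairwise[key]["adj_p"]


def group_comparison(values_by_group: Mapping[str, Sequence[float]]
                     ) -> GroupComparison:
    """Compare an outcome across >= 2 independent groups.

    Omnibus: Kruskal-Wallis H with tie correction.  Pairwise: two-sided
    Mann-Whitney rank-sum tests with Holm step-down adjustment.  (Groups of
    unequal size cannot be paired, so rank-sum is the applicable pairwise
    rank test even where a matched design would use signed ranks.)  All
    values identical is reported as H = 0, p = 1 rather than an error.
    """
    groups = {str(g): np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g, v in groups.items():
        if v.size < 3:
            raise InsufficientDataError(f"group {g!r} has fewer than 3 values")
    labels = tuple(sorted(groups))
    pooled = np.concatenate([groups[g] for g in labels])
    degenerate = np.all(pooled == pooled[0])
    if degenerate:
        h_stat, omni_p = 0.0, 1.0
    else:
        h_stat, omni_p = scipy.stats.kruskal(*[groups[g] for g in labels])
    pairs = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    raw = []
    for a, b in pairs:
        if np.all(groups[a] == groups[a][0]) and np.all(groups[b] == groups[b][0]) \
                and groups[a][0] == groups[b][0]:
            raw.append(1.0)
        else:
            raw.append(float(scipy.stats.mannwhitneyu(
                groups[a], groups[b], alternative="two-sided").pvalue))
    adj = multipletests(raw, method="holm")[1] if raw else []
    pairwise = {
        pair: {"raw_p": float(rp), "adj_p": float(ap)}
        for pair, rp, ap in zip(pairs, raw, adj)
    }
    return GroupComparison(
        h_statistic=float(h_stat), omnibus_p=float(omni_p),
        groups=labels, pairwise=pairwise,
    )


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, never below the raw p)."""
    return multipletests(list(pvalues), method="holm")[1]


@dataclass
class ValidationReport:
    """Precision/reliability summary of one equation on one dataset."""

    stratum: str
    provenance: str
    n: int
    rmse: float
    r2: float
    spearman_rho: float
    spearman_p: float
    fit_slope: float
    fit_intercept: float
    delta_median: float
    delta_min: float
    delta_max: float
    q2: Optional[float] = None
    press: Optional[float] = None
    n_negative_estimates: int = 0
    estimated: np.ndarray = field(default=None, repr=False)
    measured: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        out = {
            "stratum": self.stratum,
            "provenance": self.provenance,
            "n": self.n,
            "rmse": self.rmse,
            "r2": self.r2,
            "spearman_rho": self.spearman_rho,
            "spearman_p": self.spearman_p,
            "fit_slope": self.fit_slope,
            "fit_intercept": self.fit_intercept,
            "delta_auc_median": self.delta_median,
            "delta_auc_min": self.delta_min,
            "delta_auc_max": self.delta_max,
            "q2": self.q2,
            "press": self.press,
            "n_negative_estimates": self.n_negative_estimates,
        }
        return out


def validate_equation(profiles: Sequence[ConcentrationTimeProfile],
                      equation: LssEquation,
                      with_loocv: bool = False) -> ValidationReport:
    """Validate one equation against measured (trapezoidal) AUCs.

    ``with_loocv=True`` additionally runs leave-one-out refitting of the
    equation's scheme within ``profiles`` (meaningful for fitted equations;
    published equations are fixed, so their q^2 is not defined here).
    """
    measured = np.array([trapezoidal_auc(p) for p in profiles])
    estimated = predict(equation, profiles)
    r2, slope, intercept = r2_and_fit_line(estimated, measured)
    rho, rho_p = scipy.stats.spearmanr(measured, estimated)
    deltas = delta_auc(estimated, measured)
    q2 = press = None
    if with_loocv:
        cv = loocv(profiles, equation.scheme)
        q2, press = cv.q2, cv.press
    return ValidationReport(
        stratum=equation.stratum,
        provenance=equation.provenance,
        n=len(profiles),
        rmse=rmse(estimated, measured),
        r2=r2,
        spearman_rho=float(rho),
        spearman_p=float(rho_p),
        fit_slope=slope,
        fit_intercept=intercept,
        delta_median=float(np.median(deltas)),
        delta_min=float(deltas.min()),
        delta_max=float(deltas.max()),
        q2=q2,
        press=press,
        n_negative_estimates=int(np.sum(estimated < 0)),
        estimated=estimated,
        measured=measured,
    )
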
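"""Limited sampling schemes and AUC-estimation equations.

A *limited sampling strategy* (LSS) estimates the full AUC(0-12) from a
small set of early concentrations via an affine equation

    AUC_est = b0 + sum_j b_j * C(t_j),

with the sampling times t_j restricted to the first 6 h after dosing (four
points by default) so patients need not stay 12 h.  Equations are fitted by
ordinary least squares of the measured (trapezoidal) AUC on the scheme's
concentrations.  With seven candidate times there are only C(7,4) = 35
schemes, so the default search is exhaustive — the exact optimum of what a
stepwise procedure approximates; a classical forward-stepwise search with
backward checks is provided for comparison.

The three published equations (pooled "Method A" and the POD < 31 /
POD >= 31 strata of "Method B") are exposed as a registry so they can be
applied as fixed estimators to new data.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import scipy.stats

from .exceptions import (
    CollinearityError,
    InsufficientDataError,
    MpalssError,
)
from .nca import trapezoidal_auc
from .profiles import ConcentrationTimeProfile, profiles_to_arrays

logger = logging.getLogger(__name__)

#: Candidate sampling times: the measured grid restricted to <= 6 h post-dose.
CANDIDATE_TIMES: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0)

#: Default number of sampling points in a scheme.
DEFAULT_K = 4

_RANK_TOL = 1e-8


@dataclass(frozen=True)
class SamplingScheme:
    """An ordered set of post-dose sampling times (hours) defining an LSS."""

    times_h: tuple[float, ...]

    def __post_init__(self):
        times = tuple(sorted(float(t) for t in self.times_h))
        object.__setattr__(self, "times_h", times)
        if len(set(times)) != len(times):
            raise ValueError(f"duplicate sampling times in scheme {times}")
        if not times:
            raise ValueError("a sampling scheme needs at least one time")
        if times[-1] > 6.0 or times[0] < 0.0:
            raise ValueError(f"scheme times must lie within [0, 6] h, got {times}")

    def __len__(self) -> int:
        return len(self.times_h)

    def __iter__(self):
        return iter(self.times_h)


@dataclass(frozen=True)
class LssEquation:
    """Affine AUC(0-12) estimator: intercept + per-time concentration weights.

    ``coefficients`` maps sampling time (h) to weight (ug.h/mL per ug/mL);
    ``stratum`` names the population the equation was built for ("all" or a
    POD group label); ``provenance`` is "published" or "fitted".
    """

    intercept: float
    coefficients: dict[float, float]
    stratum: str = "all"
    provenance: str = "fitted"

    def __post_init__(self):
        coeffs = {float(t): float(b) for t, b in sorted(self.coefficients.items())}
        object.__setattr__(self, "coefficients", coeffs)
        if not np.isfinite(self.intercept) or not all(
            np.isfinite(b) for b in coeffs.values()
        ):
            raise ValueError("equation has non-finite parameters")

    @property
    def scheme(self) -> SamplingScheme:
        return SamplingScheme(tuple(self.coefficients))

    def __str__(self) -> str:
        terms = " + ".join(
            f"{b:.3g} x C{t:g}h" for t, b in self.coefficients.items()
        )
        return f"AUC ~ {self.intercept:.3g} + {terms}  [{self.stratum}, {self.provenance}]"


@dataclass
class LssFit:
    """A fitted equation together with its resubstitution diagnostics."""

    equation: LssEquation
    r2: float
    n: int
    residuals: np.ndarray = field(repr=False)
    fitted: np.ndarray = field(repr=False)
    press: Optional[float] = None  # populated when a search used LOOCV

    @property
    def scheme(self) -> SamplingScheme:
        return self.equation.scheme


def enumerate_schemes(candidate_times: Sequence[float] = CANDIDATE_TIMES,
                      k: int = DEFAULT_K) -> list[SamplingScheme]:
    """All k-subsets of the candidate times, in lexicographic order."""
    candidates = sorted(float(t) for t in candidate_times)
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} candidate times")
    if k < 1:
        raise ValueError("k must be >= 1")
    return [SamplingScheme(c) for c in itertools.combinations(candidates, k)]


def _design_matrix(profiles: Sequence[ConcentrationTimeProfile],
                   scheme: SamplingScheme) -> tuple[np.ndarray, np.ndarray]:
    X = profiles_to_arrays(profiles, scheme.times_h)
    y = np.array([trapezoidal_auc(p) for p in profiles])
    return X, y


def _check_collinearity(X: np.ndarray, scheme: SamplingScheme) -> None:
    """Raise CollinearityError naming the first dependent concentration column."""
    n = X.shape[0]
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design, tol=_RANK_TOL * max(1.0, np.abs(design).max())) == design.shape[1]:
        return
    scale = max(1.0, float(np.abs(X).max()))
    for j, t in enumerate(scheme.times_h):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-7 * scale * np.sqrt(n):
            raise CollinearityError(
                f"concentration at {t:g} h is collinear with the other predictors",
                column=t,
            )
    raise CollinearityError("design matrix is rank deficient")


def fit_ols(profiles: Sequence[ConcentrationTimeProfile],
            scheme: SamplingScheme,
            stratum: str = "all") -> LssFit:
    """Least-squares fit of measured AUC(0-12) on a scheme's concentrations.

    Solved via SVD-based least squares (``numpy.linalg.lstsq``), never by
    inverting the normal equations.  Requires full-grid profiles (so the
    measured AUC exists) and ``n >= k + 2``.
    """
    k = len(scheme)
    if len(profiles) < k + 2:
        raise InsufficientDataError(
            f"need at least {k + 2} profiles to fit a {k}-point scheme, "
            f"got {len(profiles)}"
        )
    X, y = _design_matrix(profiles, scheme)
    _check_collinearity(X, scheme)
    design = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 1.0
    eq = LssEquation(
        intercept=float(beta[0]),
        coefficients={t: float(b) for t, b in zip(scheme.times_h, beta[1:])},
        stratum=stratum,
        provenance="fitted",
    )
    return LssFit(equation=eq, r2=r2, n=len(y), residuals=resid, fitted=fitted)


@dataclass
class SearchResult:
    """Best fit plus the full per-scheme ranking of a scheme search."""

    best: LssFit
    ranking: list[dict]  # one entry per scheme: times, r2, press, rank

    @property
    def equation(self) -> LssEquation:
        return self.best.equation


def exhaustive_search(profiles: Sequence[ConcentrationTimeProfile],
                      candidate_times: Sequence[float] = CANDIDATE_TIMES,
                      k: int = DEFAULT_K,
                      criterion: str = "max_r2",
                      stratum: str = "all") -> SearchResult:
    """Fit every k-subset of the candidate times and return the best.

    ``criterion`` is ``max_r2`` (resubstitution R^2) or ``min_press``
    (leave-one-out predicted residual sum of squares).  Ties break to the
    lexicographically earliest scheme, so results are platform independent.
    Schemes that fail to fit are skipped with a warning; it is an error only
    if every scheme fails.
    """
    from .metrics import loocv  # local import to avoid a module cycle

    if criterion not in ("max_r2", "min_press"):
        raise ValueError(f"unknown criterion {criterion!r}")
    rows = []
    errors = []
    for scheme in enumerate_schemes(candidate_times, k):
        try:
            fit = fit_ols(profiles, scheme, stratum=stratum)
            press = None
            if criterion == "min_press":
                cv = loocv(profiles, scheme)
                press = cv.press
                fit.press = press
        except MpalssError as exc:
            logger.warning("scheme %s failed to fit: %s", scheme.times_h, exc)
            errors.append((scheme, exc))
            continue
        rows.append((scheme, fit, press))
    if not rows:
        raise InsufficientDataError(
            f"no scheme could be fitted ({len(errors)} failures); "
            f"first error: {errors[0][1]}"
        )
    if criterion == "max_r2":
        rows.sort(key=lambda r: (-r[1].r2, r[0].times_h))
    else:
        rows.sort(key=lambda r: (r[2], r[0].times_h))
    ranking = [
        {
            "times_h": s.times_h,
            "r2": fit.r2,
            "press": press,
            "rank": i + 1,
        }
        for i, (s, fit, press) in enumerate(rows)
    ]
    logger.info("scheme search (%s, k=%d): best %s", criterion, k, ranking[0])
    return SearchResult(best=rows[0][1], ranking=ranking)


def _partial_f_pvalues(X: np.ndarray, y: np.ndarray, included: list[int],
                       candidates: Iterable[int]) -> dict[int, float]:
    """p-value of the partial F test for adding each candidate column."""
    n = len(y)
    base = np.column_stack([np.ones(n)] + [X[:, j] for j in included])
    sse_base = float(np.sum((y - base @ np.linalg.lstsq(base, y, rcond=None)[0]) ** 2))
    out = {}
    for j in candidates:
        full = np.column_stack([base, X[:, j]])
        p_full = full.shape[1]
        if n - p_full <= 0:
            out[j] = 1.0
            continue
        sse_full = float(np.sum((y - full @ np.linalg.lstsq(full, y, rcond=None)[0]) ** 2))
        df_resid = n - p_full
        if sse_full <= 0:
            out[j] = 0.0
            continue
        f_stat = (sse_base - sse_full) / (sse_full / df_resid)
        out[j] = float(scipy.stats.f.sf(max(f_stat, 0.0), 1, df_resid))
    return out


def stepwise_search(profiles: Sequence[ConcentrationTimeProfile],
                    candidate_times: Sequence[float] = CANDIDATE_TIMES,
                    k: int = DEFAULT_K,
                    p_enter: float = 0.05,
                    p_remove: float = 0.10,
                    stratum: str = "all") -> LssFit:
    """Forward-stepwise selection with backward checks, forced to k terms.

    Classical partial-F stepwise regression: at each step the candidate with
    the smallest entry p-value joins if p <= ``p_enter``; included terms
    whose removal p-value exceeds ``p_remove`` are dropped.  If fewer than
    ``k`` predictors enter by threshold, the next-best candidates are added
    to reach exactly ``k`` (logged), mirroring a fixed-size design.
    """
    if p_enter > p_remove:
        raise ValueError(f"p_enter ({p_enter}) must be <= p_remove ({p_remove})")
    candidates = sorted(float(t) for t in candidate_times)
    if len(profiles) < k + 2:
        raise InsufficientDataError(
            f"need at least {k + 2} profiles for a {k}-term stepwise fit"
        )
    X, y = _design_matrix(profiles, SamplingScheme(tuple(candidates)))
    included: list[int] = []
    forced = False
    for _ in range(10 * len(candidates)):  # guard against cycling
        changed = False
        # Forward step.
        if len(included) < k:
            pool = [j for j in range(len(candidates)) if j not in included]
            pvals = _partial_f_pvalues(X, y, included, pool)
            j_best = min(pool, key=lambda j: (pvals[j], j))
            if pvals[j_best] <= p_enter:
                included.append(j_best)
                changed = True
        # Backward step: drop terms that no longer earn their place.
        if included:
            drop_p = {}
            for j in list(included):
                rest = [i for i in included if i != j]
                drop_p[j] = _partial_f_pvalues(X, y, rest, [j])[j]
            j_worst = max(included, key=lambda j: (drop_p[j], j))
            if drop_p[j_worst] > p_remove:
                included.remove(j_worst)
                changed = True
        if not changed:
            break
    while len(included) < k:
        pool = [j for j in range(len(candidates)) if j not in included]
        pvals = _partial_f_pvalues(X, y, included, pool)
        j_best = min(pool, key=lambda j: (pvals[j], j))
        included.append(j_best)
        forced = True
    if forced:
        logger.info(
            "stepwise: fewer than k=%d terms met p_enter=%g; filled up with "
            "next-best predictors", k, p_enter,
        )
    scheme = SamplingScheme(tuple(candidates[j] for j in sorted(included)))
    return fit_ols(profiles, scheme, stratum=stratum)


def equation_registry() -> dict[str, LssEquation]:
    """The three published AUC(0-12) estimation equations.

    ``method_a`` is the pooled equation; ``method_b_lt31`` and
    ``method_b_ge31`` are the POD-stratified pair.  Coefficients are in
    ug.h/mL per ug/mL; intercepts in ug.h/mL.
    """
    return {
        "method_a": LssEquation(
            intercept=7.4,
            coefficients={0.0: 2.3, 1.0: 1.2, 3.0: 2.3, 6.0: 4.4},
            stratum="all",
            provenance="published",
        ),
        "method_b_lt31": LssEquation(
            intercept=10.6,
            coefficients={1.0: 1.1, 2.0: 1.1, 4.0: 2.0, 6.0: 3.9},
            stratum="LT31",
            provenance="published",
        ),
        "method_b_ge31": LssEquation(
            intercept=3.8,
            coefficients={0.0: 3.5, 1.0: 1.2, 3.0: 1.9, 6.0: 5.4},
            stratum="GE31",
            provenance="published",
        ),
    }


def apply_equation(eq: LssEquation, profile: ConcentrationTimeProfile) -> float:
    """Estimated AUC(0-12) for one profile.

    Negative estimates are returned as-is (and flagged downstream), never
    clamped: clamping would bias the validation metrics.  Raises
    :class:`MissingSampleError` if the profile lacks a required time.
    """
    total = eq.intercept
    for t, b in eq.coefficients.items():
        total += b * profile.conc_at(t)
    return float(total)


def predict(eq: LssEquation,
            profiles: Sequence[ConcentrationTimeProfile]) -> np.ndarray:
    """Vector of estimated AUCs for many profiles."""
    return np.array([apply_equation(eq, p) for p in profiles])
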
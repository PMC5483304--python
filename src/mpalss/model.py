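"""Model/Results interface for limited-sampling AUC estimation.

:class:`LimitedSamplingModel` is built from a set of full-grid
concentration-time profiles (optionally POD-stratified); ``fit()`` runs the
scheme search and OLS estimation and returns
:class:`LimitedSamplingResults`, which carries the per-stratum equations,
their validation metrics (RMSE, R^2, Spearman, LOOCV q^2, delta-AUC
summaries), prediction, a ``summary()`` table and a diagnostic plot.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import InsufficientDataError
from .io import read_profiles
from .lss import (
    CANDIDATE_TIMES,
    DEFAULT_K,
    LssEquation,
    LssFit,
    SearchResult,
    apply_equation,
    exhaustive_search,
    stepwise_search,
)
from .metrics import ValidationReport, validate_equation
from .profiles import ConcentrationTimeProfile, classify_pod

_POOLED = "all"

_STRATIFY_SCHEMES = {None: None, "none": None, "pod31": "binary31", "pod91": "binary91"}


class LimitedSamplingModel:
    """Limited-sampling-strategy model for a cohort of profiles.

    Parameters
    ----------
    profiles : sequence of ConcentrationTimeProfile
        Full-grid profiles (measured AUC must be computable).
    candidate_times : sequence of float
        Candidate sampling times, all within 6 h post-dose.
    k : int
        Number of sampling points per scheme (four in the source design).
    stratify : {None, "pod31", "pod91"}
        ``None`` fits one pooled equation; otherwise one equation per POD
        stratum of the chosen binary split.
    """

    def __init__(self, profiles: Sequence[ConcentrationTimeProfile],
                 candidate_times: Sequence[float] = CANDIDATE_TIMES,
                 k: int = DEFAULT_K,
                 stratify: Optional[str] = None):
        if stratify not in _STRATIFY_SCHEMES:
            raise ValueError(f"stratify must be one of {sorted(map(str, _STRATIFY_SCHEMES))}")
        profiles = list(profiles)
        not_full = [p for p in profiles if not p.is_full_grid]
        if not_full:
            raise InsufficientDataError(
                f"{len(not_full)} profile(s) are not on the full nine-point "
                f"grid (first: {not_full[0].patient_id!r}); measured AUC "
                f"requires the full grid"
            )
        self.profiles = profiles
        self.candidate_times = tuple(float(t) for t in candidate_times)
        self.k = int(k)
        self.stratify = None if stratify == "none" else stratify

    @classmethod
    def from_csv(cls, path, **kwargs) -> "LimitedSamplingModel":
        return cls(read_profiles(path), **kwargs)

    @property
    def strata(self) -> dict[str, list[ConcentrationTimeProfile]]:
        """Profiles grouped by stratum ('all' when unstratified)."""
        scheme = _STRATIFY_SCHEMES[self.stratify]
        if scheme is None:
            return {_POOLED: list(self.profiles)}
        out: dict[str, list[ConcentrationTimeProfile]] = {}
        for p in self.profiles:
            out.setdefault(classify_pod(p.pod, scheme), []).append(p)
        return dict(sorted(out.items()))

    def fit(self, method: str = "exhaustive", criterion: str = "max_r2",
            p_enter: float = 0.05, p_remove: float = 0.10,
            ) -> "LimitedSamplingResults":
        """Search for the best scheme per stratum and fit its equation.

        ``method`` is ``exhaustive`` (exact optimum over all k-subsets, the
        default) or ``stepwise`` (classical partial-F forward selection with
        backward checks).  ``criterion`` applies to the exhaustive search:
        ``max_r2`` or ``min_press``.
        """
        fits: dict[str, LssFit] = {}
        rankings: dict[str, list[dict]] = {}
        for stratum, members in self.strata.items():
            if method == "exhaustive":
                res: SearchResult = exhaustive_search(
                    members, self.candidate_times, self.k,
                    criterion=criterion, stratum=stratum)
                fits[stratum] = res.best
                rankings[stratum] = res.ranking
            elif method == "stepwise":
                fits[stratum] = stepwise_search(
                    members, self.candidate_times, self.k,
                    p_enter=p_enter, p_remove=p_remove, stratum=stratum)
                rankings[stratum] = []
            else:
                raise ValueError(f"unknown method {method!r}")
        return LimitedSamplingResults(self, fits, rankings,
                                      method=method, criterion=criterion)

    def evaluate(self, equations: dict[str, LssEquation]
                 ) -> "LimitedSamplingResults":
        """Wrap externally supplied (e.g. published) equations as results.

        ``equations`` maps stratum label to equation; strata must cover the
        model's strata exactly.
        """
        missing = set(self.strata) - set(equations)
        if missing:
            raise ValueError(f"no equation supplied for strata: {sorted(missing)}")
        fits = {}
        for stratum in self.strata:
            eq = equations[stratum]
            fits[stratum] = LssFit(equation=eq, r2=np.nan, n=len(self.strata[stratum]),
                                   residuals=np.array([]), fitted=np.array([]))
        return LimitedSamplingResults(self, fits, {s: [] for s in fits},
                                      method="fixed", criterion="none")


class LimitedSamplingResults:
    """Fitted (or fixed) equations per stratum, with validation machinery."""

    def __init__(self, model: LimitedSamplingModel, fits: dict[str, LssFit],
                 rankings: dict[str, list[dict]], method: str, criterion: str):
        self.model = model
        self.fits = fits
        self.rankings = rankings
        self.method = method
        self.criterion = criterion
        self._reports: Optional[dict[str, ValidationReport]] = None

    @property
    def equations(self) -> dict[str, LssEquation]:
        return {s: f.equation for s, f in self.fits.items()}

    def _stratum_of(self, profile: ConcentrationTimeProfile) -> str:
        scheme = _STRATIFY_SCHEMES[self.model.stratify]
        if scheme is None:
            return _POOLED
        return classify_pod(profile.pod, scheme)

    def predict(self, profiles: Optional[Sequence[ConcentrationTimeProfile]] = None
                ) -> np.ndarray:
        """Estimated AUC(0-12), routing each profile to its stratum equation."""
        profiles = self.model.profiles if profiles is None else list(profiles)
        out = np.empty(len(profiles))
        for i, p in enumerate(profiles):
            stratum = self._stratum_of(p)
            if stratum not in self.fits:
                raise KeyError(
                    f"profile {p.patient_id!r} falls in stratum {stratum!r} "
                    f"with no fitted equation"
                )
            out[i] = apply_equation(self.fits[stratum].equation, p)
        return out

    def validation(self, with_loocv: bool = True) -> dict[str, ValidationReport]:
        """Per-stratum validation reports (cached).

        LOOCV refits the selected scheme within the stratum's own profiles;
        it is skipped for fixed (published) equations, whose q^2 under
        refitting would not describe the fixed coefficients.
        """
        if self._reports is None:
            do_cv = with_loocv and self.method != "fixed"
            self._reports = {
                stratum: validate_equation(
                    self.model.strata[stratum], fit.equation, with_loocv=do_cv)
                for stratum, fit in self.fits.items()
            }
        return self._reports

    def summary(self) -> str:
        """Human-readable per-stratum table of equations and metrics."""
        rows = []
        for stratum, report in self.validation().items():
            eq = self.fits[stratum].equation
            rows.append({
                "stratum": stratum,
                "n": report.n,
                "times_h": "{" + ", ".join(f"{t:g}" for t in eq.coefficients) + "}",
                "equation": _format_equation(eq),
                "RMSE": round(report.rmse, 2),
                "R2": round(report.r2, 3),
                "q2": None if report.q2 is None else round(report.q2, 3),
                "median dAUC": round(report.delta_median, 2),
            })
        frame = pd.DataFrame(rows).set_index("stratum")
        header = (f"Limited sampling strategy fit "
                  f"(method={self.method}, criterion={self.criterion}, "
                  f"k={self.model.k}, stratify={self.model.stratify or 'none'})")
        return header + "\n" + frame.to_string()

    def plot_fit(self, ax=None):
        """Estimated-vs-measured scatter with the identity and fit lines."""
        from .plots import plot_estimated_vs_measured

        return plot_estimated_vs_measured(self.validation(), ax=ax)


def _format_equation(eq: LssEquation) -> str:
    terms = " + ".join(f"{b:.2f}*C{t:g}h" for t, b in eq.coefficients.items())
    return f"{eq.intercept:.2f} + {terms}"
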
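"""Concentration-time profiles and postoperative-day (POD) grouping.

A *profile* is one patient-occasion's sparse sampled mycophenolic acid (MPA)
curve over a single 12-hour dosing interval at steady state, together with
the mycophenolate mofetil (MMF) dose and the postoperative day on which it
was measured.  The full monitoring grid has nine sampling times:
pre-dose (0 h) and 0.5, 1, 2, 3, 4, 6, 8 and 12 h after administration.

Units are fixed package-wide: concentrations in ug/mL, times in hours,
doses in mg, AUC in ug.h/mL, clearance in L/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .exceptions import InvalidProfileError, MissingSampleError

#: The nine-point monitoring grid (hours post-dose).
FULL_GRID: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0)

# POD group labels.
POD7 = "POD7"
POD14 = "POD14"
POD21_28 = "POD21_28"
POD_GE31 = "POD_GE31"
LT31 = "LT31"
GE31 = "GE31"
LT91 = "LT91"
GE91 = "GE91"
UNCLASSIFIED = "UNCLASSIFIED"

FOUR_GROUP_LABELS = (POD7, POD14, POD21_28, POD_GE31)

# Measurement windows for the four-group scheme.  Monitoring nominally happens
# on POD 7, 14, 21-28 and >= 31, but real sampling days drift, so each nominal
# day carries a symmetric window; PODs falling between windows are flagged
# UNCLASSIFIED rather than raising.
_FOUR_GROUP_WINDOWS = (
    (5, 10, POD7),
    (11, 18, POD14),
    (19, 30, POD21_28),
)


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One patient-occasion's sampled MPA concentration-time curve.

    Parameters
    ----------
    patient_id : str
        Opaque identifier of the patient.
    pod : int
        Postoperative day (days since transplant), >= 0.
    dose_mg : float
        Administered MMF dose in mg, > 0.
    times_h : array-like of float
        Strictly increasing sampling times in hours, each in [0, 12].
    concs_ug_ml : array-like of float
        Serum MPA concentrations in ug/mL, same length as ``times_h``,
        each >= 0.  Values reported as 0 (below quantification) are kept
        as-is.
    true_auc : float, optional
        Simulator-known noise-free AUC(0-12); absent for real data.
    """

    patient_id: str
    pod: int
    dose_mg: float
    times_h: tuple[float, ...]
    concs_ug_ml: tuple[float, ...]
    true_auc: Optional[float] = None

    def __post_init__(self):
        times = tuple(float(t) for t in self.times_h)
        concs = tuple(float(c) for c in self.concs_ug_ml)
        object.__setattr__(self, "times_h", times)
        object.__setattr__(self, "concs_ug_ml", concs)
        if int(self.pod) != self.pod or self.pod < 0:
            raise InvalidProfileError(f"pod must be a non-negative integer, got {self.pod}")
        object.__setattr__(self, "pod", int(self.pod))
        if not self.dose_mg > 0:
            raise InvalidProfileError(f"dose_mg must be positive, got {self.dose_mg}")
        if len(times) < 2:
            raise InvalidProfileError("a profile needs at least 2 sampling points")
        if len(concs) != len(times):
            raise InvalidProfileError(
                f"times_h and concs_ug_ml differ in length ({len(times)} vs {len(concs)})"
            )
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise InvalidProfileError(f"times_h must be strictly increasing, got {times}")
        if times[0] < 0 or times[-1] > 12:
            raise InvalidProfileError(f"sampling times must lie in [0, 12] h, got {times}")
        if any(c < 0 for c in concs):
            raise InvalidProfileError("concentrations must be >= 0")

    @property
    def is_full_grid(self) -> bool:
        """True when the profile was sampled on the exact nine-point grid."""
        return self.times_h == FULL_GRID

    def conc_at(self, time_h: float) -> float:
        """Concentration at an exact sampling time.

        Raises
        ------
        MissingSampleError
            If the profile has no sample at ``time_h``.
        """
        for t, c in zip(self.times_h, self.concs_ug_ml):
            if t == float(time_h):
                return c
        raise MissingSampleError(
            f"profile {self.patient_id!r} (POD {self.pod}) has no sample at {time_h} h",
            time_h=float(time_h),
        )

    @property
    def key(self) -> tuple[str, int]:
        return (self.patient_id, self.pod)


def classify_pod(pod: int, scheme: str = "binary31") -> str:
    """Map a postoperative day to its POD group label.

    Parameters
    ----------
    pod : int
        Postoperative day, >= 0.
    scheme : {"four_group", "binary31", "binary91"}
        * ``binary31`` -- LT31 for pod < 31, else GE31 (the stratification
          behind the POD-stratified estimation method).
        * ``binary91`` -- LT91 for pod < 91, else GE91 (alternative split).
        * ``four_group`` -- monitoring windows POD7 [5, 10], POD14 [11, 18],
          POD21_28 [19, 30] and POD_GE31 (>= 31); PODs outside every window
          return ``UNCLASSIFIED``.
    """
    if pod < 0:
        raise InvalidProfileError(f"pod must be >= 0, got {pod}")
    if scheme == "binary31":
        return LT31 if pod < 31 else GE31
    if scheme == "binary91":
        return LT91 if pod < 91 else GE91
    if scheme == "four_group":
        if pod >= 31:
            return POD_GE31
        for lo, hi, label in _FOUR_GROUP_WINDOWS:
            if lo <= pod <= hi:
                return label
        return UNCLASSIFIED
    raise ValueError(f"unknown POD scheme {scheme!r}")


def profiles_to_arrays(profiles: Iterable[ConcentrationTimeProfile], times: Iterable[float]):
    """Stack concentrations at the given sampling times into an (n, k) array.

    Raises :class:`MissingSampleError` if any profile lacks one of the times.
    """
    times = list(times)
    rows = [[p.conc_at(t) for t in times] for p in profiles]
    return np.asarray(rows, dtype=float)
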
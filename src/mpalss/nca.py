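"""Non-compartmental analysis: trapezoidal AUC and apparent oral clearance."""

from __future__ import annotations

import numpy as np

from .exceptions import DomainError, IncompleteIntervalError, InvalidProfileError
from .profiles import ConcentrationTimeProfile


def trapezoidal_auc(profile: ConcentrationTimeProfile) -> float:
    """AUC(0-12) by the linear trapezoidal rule, in ug.h/mL.

    The profile must actually span the dosing interval: its first sample at
    0 h and its last at 12 h.  Missing endpoints are an error -- no
    extrapolation or imputation is performed, because silently filling in
    endpoints would corrupt downstream validation metrics.

    The rule is exact for piecewise-linear curves and non-negative for
    non-negative concentrations.
    """
    times = np.asarray(profile.times_h, dtype=float)
    concs = np.asarray(profile.concs_ug_ml, dtype=float)
    if times.size < 2:
        raise InvalidProfileError("AUC needs at least 2 sampling points")
    if times[0] != 0.0 or times[-1] != 12.0:
        raise IncompleteIntervalError(
            f"AUC(0-12) requires samples at 0 and 12 h; profile spans "
            f"[{times[0]}, {times[-1]}] h"
        )
    return float(np.trapezoid(concs, times))


def oral_clearance(dose_mg: float, auc: float) -> float:
    """Apparent oral clearance CL/F = dose / AUC(0-12), in L/h.

    mg per (ug.h/mL) is dimensionally L/h, so no unit factor is needed.
    """
    if not dose_mg > 0:
        raise DomainError(f"dose_mg must be positive, got {dose_mg}")
    if not auc > 0:
        raise DomainError(f"auc must be positive, got {auc}")
    return float(dose_mg) / float(auc)
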
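"""Reading and writing long-format concentration-time CSV files.

Format: one row per sample, UTF-8, '.' decimal separator, required header
``patient_id,pod,dose_mg,time_h,conc_ug_ml`` with an optional ``true_auc``
column.  A profile is the set of rows sharing ``(patient_id, pod)``.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ProfileIOError
from .profiles import ConcentrationTimeProfile

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("patient_id", "pod", "dose_mg", "time_h", "conc_ug_ml")


def read_profiles(path) -> list[ConcentrationTimeProfile]:
    """Read profiles from a long-format CSV.

    Malformed rows are reported with their 1-based line number in the file
    (header is line 1).  An empty file yields an empty list with a logged
    warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        logger.warning("profile file %s is empty; returning no profiles", path)
        return []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileIOError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df.empty:
        logger.warning("profile file %s has a header but no rows", path)
        return []

    # Line number in the file for each row (header is line 1).
    lines = df.index.to_numpy() + 2

    for col in ("pod", "dose_mg", "time_h", "conc_ug_ml"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            where = ", ".join(str(n) for n in lines[bad.to_numpy()][:5])
            raise ProfileIOError(f"{path}: non-numeric {col!r} on line(s) {where}")
        if numeric.isna().any():
            where = ", ".join(str(n) for n in lines[numeric.isna().to_numpy()][:5])
            raise ProfileIOError(f"{path}: missing {col!r} on line(s) {where}")
        df[col] = numeric

    dup = df.duplicated(subset=["patient_id", "pod", "time_h"], keep=False)
    if dup.any():
        where = ", ".join(str(n) for n in lines[dup.to_numpy()][:8])
        raise ProfileIOError(
            f"{path}: duplicate (patient_id, pod, time_h) rows on line(s) {where}"
        )

    has_true_auc = "true_auc" in df.columns
    profiles = []
    for (pid, pod), grp in df.groupby(["patient_id", "pod"], sort=True):
        grp = grp.sort_values("time_h")
        doses = grp["dose_mg"].unique()
        if len(doses) > 1:
            where = ", ".join(str(n) for n in (grp.index.to_numpy() + 2)[:5])
            raise ProfileIOError(
                f"{path}: inconsistent dose_mg within profile ({pid!r}, POD {pod}) "
                f"on line(s) {where}"
            )
        true_auc = None
        if has_true_auc:
            vals = grp["true_auc"].dropna().unique()
            if len(vals) == 1:
                true_auc = float(vals[0])
        profiles.append(
            ConcentrationTimeProfile(
                patient_id=str(pid),
                pod=int(pod),
                dose_mg=float(doses[0]),
                times_h=tuple(grp["time_h"]),
                concs_ug_ml=tuple(grp["conc_ug_ml"]),
                true_auc=true_auc,
            )
        )
    return profiles


def profiles_to_frame(profiles: Sequence[ConcentrationTimeProfile]) -> pd.DataFrame:
    """Long-format DataFrame representation of a list of profiles."""
    rows = []
    for p in profiles:
        for t, c in zip(p.times_h, p.concs_ug_ml):
            row = {
                "patient_id": p.patient_id,
                "pod": p.pod,
                "dose_mg": p.dose_mg,
                "time_h": t,
                "conc_ug_ml": c,
            }
            if p.true_auc is not None:
                row["true_auc"] = p.true_auc
            rows.append(row)
    df = pd.DataFrame(rows)
    if "true_auc" in df.columns:
        df = df[[*REQUIRED_COLUMNS, "true_auc"]]
    else:
        df = df[list(REQUIRED_COLUMNS)]
    return df


def write_profiles(profiles: Iterable[ConcentrationTimeProfile], path) -> None:
    """Write profiles to a long-format CSV (lossless round-trip)."""
    df = profiles_to_frame(list(profiles))
    # repr-based float formatting keeps the round-trip exact and the file
    # byte-identical for identical inputs.
    df.to_csv(path, index=False, float_format=None)
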
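"""Non-compartmental analysis and the prediction-error validation harness.

AUC uses the linear-up/log-down trapezoidal rule.  The terminal rate
constant is selected by log-linear regression over candidate terminal
windows of at least three points strictly after Tmax, maximizing the
adjusted R-squared (ties favour fewer points).  The prediction error of a
simulated parameter against an observed one is ``100 * |pred - obs| / obs``;
a model passes the accuracy gate when every Cmax and AUC error is at most
20% (Tmax is reported but excluded from the gate).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NcaResult",
    "ValidationRecord",
    "run_nca",
    "pe_percent",
    "pe_table",
    "validate_against_observed",
    "cl_per_kg_from_iv",
    "load_observed_clinical",
    "PE_GATE_PERCENT",
]

PE_GATE_PERCENT = 20.0
GATED_PARAMETERS = ("cmax", "auc0t", "auc0inf")


@dataclass(frozen=True)
class NcaResult:
    c_max: float
    t_max: float
    auc_0_t: float
    auc_0_inf: float
    lambda_z: float
    half_life: float
    mrt_last: float
    lambda_z_points: int
    lambda_z_r2adj: float

    @property
    def has_terminal_phase(self) -> bool:
        return math.isfinite(self.lambda_z)


@dataclass(frozen=True)
class ValidationRecord:
    regimen: str
    parameter: str
    observed: float
    predicted: float
    pe_percent: float


def _segment_auc(t1, t2, c1, c2):
    """(AUC, AUMC) for one interval: linear-up, log-down."""
    dt = t2 - t1
    if c1 > 0 and c2 > 0 and c2 < c1:
        k = math.log(c1 / c2) / dt
        auc = (c1 - c2) / k
        aumc = (t1 * c1 - t2 * c2) / k + (c1 - c2) / k**2
    else:
        auc = dt * (c1 + c2) / 2.0
        aumc = dt * (t1 * c1 + t2 * c2) / 2.0
    return auc, aumc


def _terminal_slope(times, concs, tmax_idx):
    """Best log-linear terminal window (>=3 pts, strictly after Tmax)."""
    mask = concs > 0
    idx = np.arange(times.size)[mask & (np.arange(times.size) > tmax_idx)]
    best = None  # (r2adj, -npts, lambda_z)
    for start in range(len(idx) - 2):
        sel = idx[start:]
        if len(sel) < 3:
            break
        x, y = times[sel], np.log(concs[sel])
        n = len(sel)
        slope, intercept = np.polyfit(x, y, 1)
        yhat = slope * x + intercept
        ss_res = float(np.sum((y - yhat) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else -np.inf
        r2adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        cand = (round(r2adj, 6), -n, -slope)
        # maximize adjusted R2; on ties (rounded) prefer fewer points
        if best is None or cand[0] > best[0] or (cand[0] == best[0] and cand[1] > best[1]):
            best = cand
    if best is None or best[2] <= 0:
        return math.nan, 0, math.nan
    return best[2], -best[1], best[0]


def run_nca(
    profile: Sequence[tuple[float, float]] | np.ndarray,
    dose_mg: float | None = None,
) -> NcaResult:
    """Model-free PK metrics from a ``(time h, concentration ug/mL)`` profile.

    Non-positive concentrations are retained for Cmax/AUC bookkeeping but
    excluded from log-scale operations.  If no terminal decline exists the
    lambda-z-dependent fields are NaN rather than raising.
    """
    arr = np.asarray(profile, dtype=float)
    times, concs = arr[:, 0], arr[:, 1]
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if np.count_nonzero(concs > 0) < 3:
        raise ValueError("need at least 3 positive concentrations")

    tmax_idx = int(np.argmax(concs))
    c_max = float(concs[tmax_idx])
    t_max = float(times[tmax_idx])
    auc = aumc = 0.0
    for i in range(times.size - 1):
        a, m = _segment_auc(times[i], times[i + 1], concs[i], concs[i + 1])
        auc += a
        aumc += m
    lam, npts, r2adj = _terminal_slope(times, concs, tmax_idx)
    pos = concs > 0
    c_last = float(concs[pos][-1])
    auc_inf = auc + c_last / lam if math.isfinite(lam) else math.nan
    return NcaResult(
        c_max=c_max,
        t_max=t_max,
        auc_0_t=auc,
        auc_0_inf=auc_inf,
        lambda_z=lam,
        half_life=math.log(2) / lam if math.isfinite(lam) else math.nan,
        mrt_last=aumc / auc,
        lambda_z_points=npts,
        lambda_z_r2adj=r2adj,
    )


def pe_percent(predicted: float, observed: float) -> float:
    """Absolute prediction error, percent: ``100 |pred - obs| / obs``."""
    if observed == 0:
        raise ZeroDivisionError("prediction error undefined for observed == 0")
    return 100.0 * abs(predicted - observed) / abs(observed)


def pe_table(observed_predicted: pd.DataFrame) -> pd.DataFrame:
    """Append a ``pe_percent`` column to a regimen/parameter table.

    Expects columns ``regimen, parameter, observed, predicted``.
    """
    df = observed_predicted.copy()
    df["pe_percent"] = [
        pe_percent(p, o) for p, o in zip(df["predicted"], df["observed"])
    ]
    return df


def validate_against_observed(
    simulations: Mapping[str, "SimProfile"],
    observed_params: pd.DataFrame,
) -> tuple[list[ValidationRecord], bool]:
    """Compare simulated profiles with observed PK parameters.

    ``observed_params`` holds one row per regimen/parameter pair (parameters
    among cmax, auc0t, auc0inf, tmax).  Returns the record list and the
    overall pass flag: every Cmax and AUC error <= 20% (Tmax not gated).
    """
    missing = set(observed_params["regimen"]) - set(simulations)
    if missing:
        raise ValueError(f"regimen(s) not simulated: {sorted(missing)}")
    records = []
    for regimen, group in observed_params.groupby("regimen", sort=False):
        prof = simulations[regimen]
        nca = run_nca(np.column_stack([prof.times_h, prof.plasma_ug_ml]))
        predicted = {
            "cmax": nca.c_max,
            "auc0t": nca.auc_0_t,
            "auc0inf": nca.auc_0_inf,
            "tmax": nca.t_max,
        }
        for _, row in group.iterrows():
            param = row["parameter"]
            if param not in predicted or not math.isfinite(predicted[param]):
                warnings.warn(f"{regimen}: no predicted {param}; skipped", stacklevel=2)
                continue
            records.append(
                ValidationRecord(
                    regimen=regimen,
                    parameter=param,
                    observed=float(row["observed"]),
                    predicted=float(predicted[param]),
                    pe_percent=pe_percent(predicted[param], float(row["observed"])),
                )
            )
    gate = all(
        r.pe_percent <= PE_GATE_PERCENT
        for r in records
        if r.parameter in GATED_PARAMETERS
    )
    return records, gate


def cl_per_kg_from_iv(dose_mg: float, auc_0_inf: float, weight_kg: float) -> float:
    """Plasma clearance (L/h/kg) from an IV dose and its AUC(0-inf).

    mg divided by ug.h/mL gives L/h directly (1 mg/(ug/mL) = 1 L).
    """
    if dose_mg <= 0 or auc_0_inf <= 0 or weight_kg <= 0:
        raise ValueError("dose, AUC and weight must all be positive")
    return dose_mg / auc_0_inf / weight_kg


def load_observed_clinical(path=None) -> pd.DataFrame:
    """Packaged observed clinical PK table (regimens, cohorts, parameters)."""
    src = (
        path
        if path is not None
        else resources.files("levpbpk.data").joinpath("observed_clinical.csv")
    )
    return pd.read_csv(src, comment="#")
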
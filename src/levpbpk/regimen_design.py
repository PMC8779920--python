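"""Multi-dose regimen simulation against a therapeutic window.

Supports loading/maintenance titration against the pediatric levetiracetam
window (5-19 ug/mL), deterministic grid search for the smallest regimen that
keeps the steady-state trough above the floor and the peak below the
ceiling, and the missed-dose remediation protocol: after a skipped dose the
remedial amount must return the profile into the reference steady-state
envelope by the next trough without overshooting the reference peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .acat_absorption import DissolutionModel
from .pbpk_disposition import DoseEvent, PbpkModel, SimProfile, simulate

__all__ = [
    "Regimen",
    "WindowMetrics",
    "RegimenSearchResult",
    "RemediationCandidate",
    "RemediationResult",
    "THERAPEUTIC_WINDOW_UG_ML",
    "simulate_regimen",
    "find_regimen",
    "missed_dose_remediation",
]

#: pediatric levetiracetam monotherapy reference range, ug/mL
THERAPEUTIC_WINDOW_UG_ML = (5.0, 19.0)

#: numerical tolerance on "never exceeds the reference peak"
PEAK_TOL = 0.02
#: adherence band: post-remediation profile must stay within +/-10% of the
#: reference profile once dosing resumes
ADHERENCE_BAND = 0.10

GRID_STEPS_PER_INTERVAL = 24


@dataclass(frozen=True)
class Regimen:
    loading_dose_mg: float
    maintenance_dose_mg: float
    interval_h: float = 12.0
    duration_days: float = 7.0
    miss_times_h: tuple[float, ...] = ()
    remediation: tuple[float, float] | None = None  # (time h, dose mg)

    def __post_init__(self):
        if self.loading_dose_mg < 0 or self.maintenance_dose_mg < 0:
            raise ValueError("doses must be >= 0")
        if self.interval_h <= 0:
            raise ValueError("interval must be > 0")
        if self.remediation is not None and self.miss_times_h:
            if self.remediation[0] <= max(self.miss_times_h):
                raise ValueError("remediation must come after the missed dose")

    def schedule_times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_days * 24.0 - 1e-9, self.interval_h)

    def dose_events(self) -> list[DoseEvent]:
        events = []
        remed_time = self.remediation[0] if self.remediation else None
        for t in self.schedule_times():
            if any(abs(t - m) < 1e-9 for m in self.miss_times_h):
                continue
            if remed_time is not None and abs(t - remed_time) < 1e-9:
                continue  # replaced by the remedial dose below
            amount = (
                self.loading_dose_mg
                if t == 0 and self.loading_dose_mg > 0
                else self.maintenance_dose_mg
            )
            if amount > 0:
                events.append(DoseEvent("oral", amount, float(t)))
        if self.remediation is not None and self.remediation[1] > 0:
            events.append(DoseEvent("oral", self.remediation[1], self.remediation[0]))
        return sorted(events, key=lambda d: d.time_h)


@dataclass(frozen=True)
class WindowMetrics:
    c_trough_ss: float
    c_peak_ss: float
    fraction_of_interval_in_window: float
    window: tuple[float, float]
    steady: bool

    def __post_init__(self):
        if self.c_trough_ss > self.c_peak_ss + 1e-12:
            raise ValueError("trough must not exceed peak")

    @property
    def within_window(self) -> bool:
        lo, hi = self.window
        return self.c_trough_ss >= lo and self.c_peak_ss <= hi


def _grid(regimen: Regimen) -> np.ndarray:
    t_end = regimen.duration_days * 24.0
    step = regimen.interval_h / GRID_STEPS_PER_INTERVAL
    pts = set(np.round(np.arange(0.0, t_end + step / 2, step), 9))
    for ev in regimen.dose_events():
        pts.add(round(ev.time_h, 9))
    return np.array(sorted(pts))


def simulate_regimen(
    model: PbpkModel,
    regimen: Regimen,
    dissolution: DissolutionModel,
    window: tuple[float, float] = THERAPEUTIC_WINDOW_UG_ML,
) -> tuple[SimProfile, WindowMetrics]:
    """Simulate a repeated oral regimen; metrics from the final interval."""
    events = regimen.dose_events()
    grid = _grid(regimen)
    profile = simulate(model, events, dissolution, grid)
    t, c = profile.times_h, profile.plasma_ug_ml
    t_last = events[-1].time_h if events else 0.0
    # final complete dosing interval (the last scheduled dose onward)
    sched = regimen.schedule_times()
    t0 = sched[-1] if len(sched) else t_last
    t1 = min(t0 + regimen.interval_h, t[-1])
    sel = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
    c_int, t_int = c[sel], t[sel]
    trough = float(c_int[-1])
    peak = float(c_int.max())
    lo, hi = window
    inside = (c_int >= lo) & (c_int <= hi)
    frac = float(np.trapezoid(inside.astype(float), t_int) / (t_int[-1] - t_int[0]))
    # steady-state check: previous-interval trough within 1%
    prev_t = t0 - regimen.interval_h
    steady = False
    if prev_t >= 0:
        c_prev = float(np.interp(t0, t, c))
        steady = abs(trough - c_prev) <= 0.01 * max(trough, 1e-12)
    metrics = WindowMetrics(
        c_trough_ss=trough,
        c_peak_ss=peak,
        fraction_of_interval_in_window=frac,
        window=window,
        steady=steady,
    )
    return profile, metrics


@dataclass(frozen=True)
class RegimenSearchResult:
    regimen: Regimen | None
    feasible: bool
    best_candidate: Regimen
    best_metrics: WindowMetrics


def find_regimen(
    model: PbpkModel,
    window: tuple[float, float],
    loading_grid_mg: Sequence[float],
    maintenance_grid_mg: Sequence[float],
    dissolution: DissolutionModel,
    interval_h: float = 12.0,
    duration_days: float = 7.0,
) -> RegimenSearchResult:
    """Deterministic grid search for the smallest acceptable regimen.

    Candidates are scanned by ascending maintenance dose (the chronic
    exposure) and then ascending loading dose; the first candidate whose
    steady-state trough >= floor and peak <= ceiling wins.  With no feasible
    pair, the result carries the least-violating candidate instead.
    """
    if not loading_grid_mg or not maintenance_grid_mg:
        raise ValueError("dose grids must be non-empty")
    lo, hi = window
    best = None  # (violation, regimen, metrics)
    for maint in sorted(maintenance_grid_mg):
        for load in sorted(loading_grid_mg):
            regimen = Regimen(load, maint, interval_h, duration_days)
            _, metrics = simulate_regimen(model, regimen, dissolution, window)
            violation = max(lo - metrics.c_trough_ss, 0.0) + max(
                metrics.c_peak_ss - hi, 0.0
            )
            if violation == 0.0:
                return RegimenSearchResult(regimen, True, regimen, metrics)
            if best is None or violation < best[0]:
                best = (violation, regimen, metrics)
    return RegimenSearchResult(None, False, best[1], best[2])


@dataclass(frozen=True)
class RemediationCandidate:
    dose_mg: float
    status: str            # ok | low | high
    deviation_ug_h_ml: float
    trough_after: float
    peak_after: float


@dataclass(frozen=True)
class RemediationResult:
    candidates: tuple[RemediationCandidate, ...]
    chosen_dose_mg: float | None
    reference_metrics: WindowMetrics


def missed_dose_remediation(
    model: PbpkModel,
    regimen: Regimen,
    dissolution: DissolutionModel,
    candidates_mg: Sequence[float],
    miss_time_h: float = 60.0,
    remed_time_h: float = 72.0,
    resume_time_h: float = 84.0,
) -> RemediationResult:
    """Rank remedial doses after a missed maintenance dose.

    A candidate is acceptable when the post-remediation curve returns into
    the reference steady-state envelope without exceeding the reference
    peak (2% numerical tolerance) and is back within the +/-10% adherence
    band around the reference profile by the next scheduled dose.  Among the
    acceptable candidates, the one minimizing the integrated absolute
    deviation from the reference profile after remediation is chosen.
    """
    if not candidates_mg:
        raise ValueError("no remediation candidates supplied")
    if regimen.miss_times_h and not (
        min(regimen.miss_times_h) < remed_time_h < resume_time_h
    ):
        raise ValueError("need miss_time < remediation_time < resume_time")

    reference = replace(regimen, miss_times_h=(), remediation=None)
    ref_profile, ref_metrics = simulate_regimen(model, reference, dissolution)
    trough_ss, peak_ss = ref_metrics.c_trough_ss, ref_metrics.c_peak_ss

    evaluated = []
    best = None
    for dose in candidates_mg:
        trial = replace(
            regimen,
            miss_times_h=(miss_time_h,) if miss_time_h is not None else (),
            remediation=(remed_time_h, float(dose)),
        )
        profile, _ = simulate_regimen(model, trial, dissolution)
        t, c = profile.times_h, profile.plasma_ug_ml
        after = t >= remed_time_h - 1e-9
        peak_after = float(c[after].max())
        trough_after = float(np.interp(resume_time_h, t, c))
        high = peak_after > peak_ss * (1.0 + PEAK_TOL)
        low = trough_after < trough_ss * (1.0 - ADHERENCE_BAND)
        status = "high" if high else ("low" if low else "ok")
        ref_c = np.interp(t[after], ref_profile.times_h, ref_profile.plasma_ug_ml)
        dev = float(np.trapezoid(np.abs(c[after] - ref_c), t[after]))
        cand = RemediationCandidate(float(dose), status, dev, trough_after, peak_after)
        evaluated.append(cand)
        if status == "ok" and (best is None or dev < best.deviation_ug_h_ml):
            best = cand
    return RemediationResult(
        candidates=tuple(evaluated),
        chosen_dose_mg=None if best is None else best.dose_mg,
        reference_metrics=ref_metrics,
    )
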
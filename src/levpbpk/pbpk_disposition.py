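"""Whole-body perfusion-limited PBPK disposition with IV and oral input.

Every tissue is a single well-stirred compartment::

    dA_t/dt = Q_t * (C_art - C_t * Rbp / Kp_t)

with the lung in series between the venous and arterial pools, gut and
spleen draining through the portal vein into the liver, renal elimination
(66% of total clearance) driven by the arterial plasma concentration at the
kidney, and the remainder eliminated at the liver inlet (negligible
first-pass for a low-extraction compound).  Oral doses pass through the
compartmental gut model of :mod:`levpbpk.acat_absorption`; absorbed drug
enters the portal stream.

Amounts are in mg, volumes in L, times in h; 1 mg/L of plasma equals
1 ug/mL.  Reported plasma concentration is venous blood / Rbp.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .acat_absorption import DissolutionModel, GIModel
from .compound_physiology import CompoundParams, Physiology
from .partitioning import ConfigurationError, KpSet

__all__ = ["PbpkModel", "DoseEvent", "SimProfile", "assemble_model", "simulate"]

#: tissues whose venous outflow passes through the portal vein to the liver
PORTAL_TISSUES = ("gut", "spleen")

DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


@dataclass(frozen=True)
class PbpkModel:
    physiology: Physiology
    compound: CompoundParams
    kps: KpSet
    clearance_total_l_h: float
    clearance_renal_l_h: float
    clearance_remainder_l_h: float

    def __post_init__(self):
        expected = self.clearance_renal_l_h + self.clearance_remainder_l_h
        if abs(expected - self.clearance_total_l_h) > 1e-9 * self.clearance_total_l_h:
            raise ValueError("renal + remainder clearance must equal total")


@dataclass(frozen=True)
class DoseEvent:
    route: str            # iv_bolus | iv_infusion | oral
    amount_mg: float
    time_h: float = 0.0
    duration_h: float = 0.0

    def __post_init__(self):
        if self.route not in ("iv_bolus", "iv_infusion", "oral"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.amount_mg <= 0:
            raise ValueError("dose amount must be positive")
        if self.time_h < 0:
            raise ValueError("dose time must be >= 0")
        if self.route == "iv_infusion" and self.duration_h <= 0:
            raise ValueError("infusion needs a positive duration")


@dataclass(frozen=True)
class SimProfile:
    times_h: np.ndarray
    plasma_ug_ml: np.ndarray
    tissue_ug_ml: dict[str, np.ndarray]
    eliminated_mg: np.ndarray
    absorbed_mg: np.ndarray       # cumulative gut-wall absorption (oral only)
    gut_lumen_mg: np.ndarray      # drug still in the gut lumen
    gut_exited_mg: np.ndarray     # drug passed out distally, unabsorbed
    dose_total_mg: float

    @property
    def fraction_absorbed(self) -> float:
        return float(self.absorbed_mg[-1] / self.dose_total_mg)


def assemble_model(
    compound: CompoundParams,
    phys: Physiology,
    kps: KpSet,
    population: str = "adult",
) -> PbpkModel:
    """Attach clearances to a subject; renal share 66%, remainder hepatic."""
    missing = [t for t in phys.tissues if t not in kps.kp]
    if missing:
        raise ConfigurationError(f"physiology tissues without Kp: {missing}")
    per_kg = {
        "adult": compound.clearance_plasma_l_h_kg,
        "child": compound.clearance_plasma_child_l_h_kg,
    }[population]
    total = per_kg * phys.body_weight_kg
    renal = compound.renal_fraction * total
    return PbpkModel(
        physiology=phys,
        compound=compound,
        kps=kps,
        clearance_total_l_h=total,
        clearance_renal_l_h=renal,
        clearance_remainder_l_h=total - renal,
    )


class _System:
    """State layout: [GI (28) | venous | arterial | tissues... | el_renal | el_hep]."""

    def __init__(self, model: PbpkModel, dissolution: DissolutionModel | None):
        phys = model.physiology
        self.model = model
        self.gi = GIModel(
            model.compound,
            phys,
            dissolution if dissolution is not None else DissolutionModel(form="immediate"),
        )
        self.ngi = self.gi.NSTATES
        self.tissues = list(phys.tissues)
        self.i_ven = self.ngi
        self.i_art = self.ngi + 1
        self.i_tis = self.ngi + 2
        self.i_elr = self.i_tis + len(self.tissues)
        self.i_elh = self.i_elr + 1
        self.nstates = self.i_elh + 1

        self.v_t = np.array([phys.tissue_volumes_l[t] for t in self.tissues])
        self.q_t = np.array([phys.tissue_blood_flows_l_h[t] for t in self.tissues])
        self.kp = np.array([model.kps[t] for t in self.tissues])
        self.rbp = model.compound.blood_plasma_ratio
        self.idx = {t: k for k, t in enumerate(self.tissues)}
        self.i_lung = self.idx["lung"]
        self.i_liver = self.idx["liver"]
        self.i_kidney = self.idx["kidney"]
        self.i_portal = [self.idx[t] for t in PORTAL_TISSUES]
        self.q_liver_total = self.q_t[self.i_liver] + sum(
            self.q_t[i] for i in self.i_portal
        )
        # tissues returning blood directly to the venous pool
        self.direct = [
            k
            for k, t in enumerate(self.tissues)
            if t != "lung" and t != "liver" and t not in PORTAL_TISSUES
        ]
        self.co = phys.cardiac_output_l_h
        self.v_ven = phys.venous_blood_l
        self.v_art = phys.arterial_blood_l
        self.cl_r = model.clearance_renal_l_h
        self.cl_h = model.clearance_remainder_l_h
        self.oral_clock = 0.0       # time of most recent oral dose
        self.infusion_rate = 0.0    # mg/h, set per integration span

    def rhs(self, t, y):
        dy = np.zeros_like(y)
        gi_y = y[: self.ngi]
        dy[: self.ngi] = self.gi.rhs(t - self.oral_clock, gi_y)
        r_abs = self.gi.portal_rate(gi_y)

        c_ven = y[self.i_ven] / self.v_ven
        c_art = y[self.i_art] / self.v_art
        a_t = y[self.i_tis : self.i_tis + len(self.tissues)]
        c_out = (a_t / self.v_t) * (self.rbp / self.kp)

        d_t = np.zeros(len(self.tissues))
        # lung in series: venous return -> lung -> arterial pool
        d_t[self.i_lung] = self.co * (c_ven - c_out[self.i_lung])
        dy[self.i_art] = self.co * c_out[self.i_lung] - self.co * c_art

        for k in self.direct + list(self.i_portal):
            d_t[k] = self.q_t[k] * (c_art - c_out[k])
        # renal elimination, driven by the arterial plasma concentration
        el_r = self.cl_r * c_art / self.rbp
        d_t[self.i_kidney] -= el_r

        inflow_liv = (
            self.q_t[self.i_liver] * c_art
            + sum(self.q_t[i] * c_out[i] for i in self.i_portal)
            + r_abs
        )
        c_liv_in = inflow_liv / self.q_liver_total
        el_h = self.cl_h * c_liv_in / self.rbp
        d_t[self.i_liver] = inflow_liv - self.q_liver_total * c_out[self.i_liver] - el_h

        dy[self.i_ven] = (
            sum(self.q_t[k] * c_out[k] for k in self.direct)
            + self.q_liver_total * c_out[self.i_liver]
            - self.co * c_ven
            + self.infusion_rate
        )
        dy[self.i_tis : self.i_tis + len(self.tissues)] = d_t
        dy[self.i_elr] = el_r
        dy[self.i_elh] = el_h
        return dy


def simulate(
    model: PbpkModel,
    doses: Sequence[DoseEvent],
    dissolution: DissolutionModel | None,
    t_grid: Sequence[float],
    *,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> SimProfile:
    """Integrate the coupled gut + whole-body system over ``t_grid``.

    Dose events split the integration span (integrator restarts at every
    bolus/oral administration and at infusion starts and ends).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    doses = sorted(doses, key=lambda d: d.time_h)
    if doses and (doses[0].time_h < t_grid[0] or doses[-1].time_h > t_grid[-1]):
        raise ValueError("t_grid must cover all dose times")
    if any(d.route == "oral" for d in doses) and dissolution is None:
        raise ValueError("oral dosing requires a dissolution model")

    sys_ = _System(model, dissolution)
    breaks = {t_grid[0], t_grid[-1]}
    for d in doses:
        breaks.add(d.time_h)
        if d.route == "iv_infusion":
            breaks.add(min(d.time_h + d.duration_h, t_grid[-1]))
    breaks = sorted(breaks)

    y = np.zeros(sys_.nstates)
    out = np.empty((sys_.nstates, t_grid.size))
    filled = np.zeros(t_grid.size, dtype=bool)

    def record(tval, yval):
        j = np.searchsorted(t_grid, tval)
        for jj in (j - 1, j, j + 1):
            if 0 <= jj < t_grid.size and not filled[jj] and abs(t_grid[jj] - tval) < 1e-12:
                out[:, jj] = yval
                filled[jj] = True

    scale = max(1.0, sum(d.amount_mg for d in doses))
    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        for d in doses:
            if abs(d.time_h - t0) < 1e-12:
                if d.route == "iv_bolus":
                    y[sys_.i_ven] += d.amount_mg
                elif d.route == "oral":
                    sys_.gi.add_dose(y[: sys_.ngi], d.amount_mg)
                    sys_.oral_clock = t0
        sys_.infusion_rate = sum(
            d.amount_mg / d.duration_h
            for d in doses
            if d.route == "iv_infusion" and d.time_h - 1e-12 <= t0 < d.time_h + d.duration_h
        )
        record(t0, y)
        inside = t_grid[(t_grid > t0 + 1e-12) & (t_grid < t1 - 1e-12)]
        t_eval = np.unique(np.concatenate([inside, [t1]]))
        sol = solve_ivp(
            sys_.rhs, (t0, t1), y, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol
        )
        if not sol.success:
            raise RuntimeError(
                f"PBPK integration failed on [{t0}, {t1}]: {sol.message}; "
                f"state head={y[:8]}"
            )
        if sol.y.min() < -1e-9 * scale:
            raise RuntimeError(
                f"negative state excursion {sol.y.min():.3e} mg on [{t0}, {t1}]"
            )
        for tv, col in zip(sol.t, sol.y.T):
            record(tv, col)
        y = sol.y[:, -1].copy()
    record(breaks[-1], y)
    if not filled.all():  # pragma: no cover
        raise RuntimeError("internal error: simulation grid not fully populated")

    n = sys_.gi.N
    plasma = out[sys_.i_ven] / sys_.v_ven / sys_.rbp
    tissue_conc = {
        t: out[sys_.i_tis + k] / sys_.v_t[k] for k, t in enumerate(sys_.tissues)
    }
    tissue_conc["venous_blood"] = out[sys_.i_ven] / sys_.v_ven
    tissue_conc["arterial_blood"] = out[sys_.i_art] / sys_.v_art
    return SimProfile(
        times_h=t_grid,
        plasma_ug_ml=np.maximum(plasma, 0.0),
        tissue_ug_ml=tissue_conc,
        eliminated_mg=out[sys_.i_elr] + out[sys_.i_elh],
        absorbed_mg=out[2 * n : 3 * n].sum(axis=0),
        gut_lumen_mg=out[: 2 * n].sum(axis=0),
        gut_exited_mg=out[3 * n],
        dose_total_mg=sum(d.amount_mg for d in doses) if doses else 0.0,
    )
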
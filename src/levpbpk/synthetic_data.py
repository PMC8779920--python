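"""Seed-deterministic generators for every fixture the pipeline needs.

Three families:

* in vitro dissolution profiles of instant-dissolving tablets (fast Weibull
  release, >85% at 2.5 min, complete at 5 min) and deliberately slowed
  variants;
* parallel-group dog PK datasets — per-animal one-compartment oral profiles
  whose group truths are back-calculated from the reported group means
  (ke from the half-life, V/F from dose/AUC/ke, ka fitted so the model peak
  matches the reported Cmax) with lognormal between-subject variability;
* clinical-like adult profiles (mono-exponential IV, Bateman oral) whose
  non-compartmental parameters reproduce the observed Cmax/AUC values.

None of these use the PBPK machinery, so they double as independent
round-trip oracles for the NCA module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .nca import load_observed_clinical

__all__ = [
    "DOG_GROUPS",
    "DogStudySpec",
    "gen_dissolution",
    "gen_dog_dataset",
    "gen_clinical_profile",
    "dog_group_truth",
    "clinical_truth",
]

#: reported dog study group means (n=3 beagles per parallel group):
#: label -> (dose mg, terminal half-life h, Tmax h, Cmax ug/mL,
#:           AUC0-t ug.h/mL, AUC0-inf ug.h/mL, MRT_last h)
DOG_GROUPS = {
    "LEV-IDTs-250": (250.0, 3.54, 1.00, 32.01, 176.16, 177.82, 4.68),
    "LEV-IDTs-500": (500.0, 3.36, 1.00, 55.54, 304.95, 307.17, 4.58),
    "LEV-IDTs-750": (750.0, 3.30, 1.67, 82.81, 510.01, 513.44, 4.81),
    "LEV-IDTs-1000": (1000.0, 3.14, 0.83, 118.89, 718.05, 722.43, 5.02),
    "Spritam-1000": (1000.0, 3.13, 0.28, 127.85, 717.68, 721.98, 4.52),
}

#: dog blood-sampling schedule, hours (pre-dose sample then 15 min to 48 h)
DOG_SAMPLING_H = (0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0)

#: in vitro dissolution sampling times, minutes
DISSOLUTION_TIMES_MIN = (2.5, 5.0, 10.0, 15.0, 20.0, 30.0)

#: adult clinical sampling schedule, hours
CLINICAL_SAMPLING_H = (
    0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 16.0, 24.0, 36.0, 48.0
)

_FAST_TD_MIN = 1.3
_FAST_B = 1.2


@dataclass(frozen=True)
class DogStudySpec:
    groups: tuple[str, ...] = tuple(DOG_GROUPS)
    n_per_group: int = 3
    bsv_cv: float = 0.10
    sampling_times_h: tuple[float, ...] = DOG_SAMPLING_H
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.bsv_cv < 0:
            raise ValueError("bsv_cv must be >= 0")
        if any(t2 <= t1 for t1, t2 in zip(self.sampling_times_h, self.sampling_times_h[1:])):
            raise ValueError("sampling times must be strictly increasing")
        unknown = set(self.groups) - set(DOG_GROUPS)
        if unknown:
            raise ValueError(f"unknown dog groups {sorted(unknown)}")


def _bateman(t, dose, v, ka, ke):
    t = np.asarray(t, float)
    return (dose / v) * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))


def _solve_ka(dose, v, ke, cmax_target, t_dense):
    """ka such that the (dense-grid) Bateman peak equals the target Cmax."""

    def gap(ka):
        return _bateman(t_dense, dose, v, ka, ke).max() - cmax_target

    return float(brentq(gap, ke * 1.001, 500.0, xtol=1e-10))


def dog_group_truth(label: str) -> dict[str, float]:
    """One-compartment truth for a dog group, back-calculated from means.

    ke from the reported half-life, apparent clearance from dose/AUC(0-inf),
    V/F = CL/ke, ka fitted so the model peak matches the reported Cmax (the
    reported Tmax values are not simultaneously satisfiable in a
    one-compartment model and are left free).
    """
    dose, hl, _tmax, cmax, _auct, aucinf, _mrt = DOG_GROUPS[label]
    ke = math.log(2.0) / hl
    cl = dose / aucinf
    v = cl / ke
    ka = _solve_ka(dose, v, ke, cmax, np.asarray(DOG_SAMPLING_H[1:]))
    return {"dose_mg": dose, "ke": ke, "v_f_l": v, "ka": ka, "cl_f_l_h": cl}


def gen_dissolution(
    kind: str = "fast_idt",
    seed: int = 0,
    noise: float = 0.02,
    slow_factor: float = 50.0,
) -> list[tuple[float, float]]:
    """Tabulated ``(minutes, percent)`` dissolution profile.

    ``fast_idt`` draws around a Weibull with td 1.3 min, shape 1.2
    (multiplicative uniform noise, at most ``noise``); points where the true
    curve is essentially complete (>= 99%) are reported as 100%.  ``slowed``
    stretches the time scale by ``slow_factor``.
    """
    if kind not in ("fast_idt", "slowed"):
        raise ValueError(f"unknown dissolution kind {kind!r}")
    td = _FAST_TD_MIN * (slow_factor if kind == "slowed" else 1.0)
    rng = np.random.default_rng(seed)
    out = []
    for t in DISSOLUTION_TIMES_MIN:
        frac = -math.expm1(-((t / td) ** _FAST_B))
        if frac >= 0.99:
            pct = 100.0
        else:
            pct = 100.0 * frac * (1.0 + rng.uniform(-noise, noise))
        out.append((t, min(pct, 100.0)))
    # enforce a physically non-decreasing cumulative profile
    for i in range(1, len(out)):
        if out[i][1] < out[i - 1][1]:
            out[i] = (out[i][0], out[i - 1][1])
    return out


def gen_dog_dataset(spec: DogStudySpec = DogStudySpec()) -> pd.DataFrame:
    """Per-animal dog concentration-time data, long format.

    Columns: ``formulation, dose_mg, animal, time_h, conc_ug_ml``.  Animal
    parameters (CL/F, V/F, ka) are lognormal around the group truth with CV
    ``bsv_cv`` (mean-preserving), so CV 0 collapses to identical animals.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log(1.0 + spec.bsv_cv**2))
    times = np.asarray(spec.sampling_times_h)
    rows = []
    for label in spec.groups:
        truth = dog_group_truth(label)
        for animal in range(spec.n_per_group):
            factors = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=3))
            cl = truth["cl_f_l_h"] * factors[0]
            v = truth["v_f_l"] * factors[1]
            ka = truth["ka"] * factors[2]
            ke = cl / v
            conc = _bateman(times, truth["dose_mg"], v, ka, ke)
            for t, c in zip(times, conc):
                rows.append(
                    {
                        "formulation": label,
                        "dose_mg": truth["dose_mg"],
                        "animal": animal,
                        "time_h": t,
                        "conc_ug_ml": float(c),
                    }
                )
    return pd.DataFrame(rows)


def clinical_truth(regimen: str) -> dict[str, float]:
    """Closed-form truth reproducing one observed adult regimen.

    IV: mono-exponential anchored at the first sampling time with
    ``ke = Cmax/AUC(0-inf)``.  Oral: Bateman with apparent clearance
    dose/AUC(0-inf), ``ke = 1.35 * Cmax/AUC`` (margin so the peak is
    attainable) and ka fitted to the observed Cmax on the sampling grid.
    """
    obs = load_observed_clinical()
    sub = obs[obs.regimen == regimen].set_index("parameter")["observed"]
    if sub.empty:
        raise ValueError(f"unknown regimen {regimen!r}")
    cmax, aucinf = float(sub["cmax"]), float(sub["auc0inf"])
    dose = float(regimen.split("-")[1])
    if regimen.startswith("iv"):
        ke = cmax / aucinf
        return {"route": 0.0, "dose_mg": dose, "ke": ke, "cmax": cmax}
    ke = 1.35 * cmax / aucinf
    cl = dose / aucinf
    v = cl / ke
    ka = _solve_ka(dose, v, ke, cmax, np.asarray(CLINICAL_SAMPLING_H))
    return {"route": 1.0, "dose_mg": dose, "ke": ke, "v_l": v, "ka": ka}


def gen_clinical_profile(
    regimen: str,
    dose_scale: float = 1.0,
    times_h: tuple[float, ...] = CLINICAL_SAMPLING_H,
) -> np.ndarray:
    """Noise-free clinical-like profile as an ``(n, 2)`` time/conc array."""
    truth = clinical_truth(regimen)
    t = np.asarray(times_h, float)
    if truth["route"] == 0.0:
        c = truth["cmax"] * np.exp(-truth["ke"] * (t - t[0]))
    else:
        c = _bateman(t, truth["dose_mg"], truth["v_l"], truth["ka"], truth["ke"])
    return np.column_stack([t, c * dose_scale])
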
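"""Compound parameters, subject physiologies and virtual populations.

A :class:`Physiology` couples a whole-body tissue map (volumes and blood
flows for a perfusion-limited disposition model) to a nine-segment
gastro-intestinal tract (for the compartmental absorption/transit model).
Adult physiologies are scaled from a 70-kg reference-man table: volumes
linearly with body weight, blood flows with weight^0.75.  Pediatric
physiologies additionally carry an age-dependent body-water uplift that the
partitioning module applies to tissue water fractions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GI_SEGMENT_ORDER",
    "GICompartment",
    "CompoundParams",
    "Physiology",
    "PopulationSpec",
    "load_compound_profile",
    "load_reference_physiology",
    "build_adult_physiology",
    "build_child_physiology",
    "sample_population",
    "body_water_fraction",
    "default_child_bmi",
]

#: canonical gut segment order (stomach followed by six small-intestinal
#: segments, then caecum and colon)
GI_SEGMENT_ORDER = (
    "stomach",
    "duodenum",
    "jejunum1",
    "jejunum2",
    "ileum1",
    "ileum2",
    "ileum3",
    "caecum",
    "colon",
)

# reference whole-blood volume and haematocrit
BLOOD_FRACTION_L_PER_KG = 0.07
HEMATOCRIT = 0.45
#: cardiac output of the 70-kg reference adult, L blood / h
CARDIAC_OUTPUT_REF_L_H = 390.0
REFERENCE_WEIGHT_KG = 70.0
FLOW_ALLOMETRIC_EXPONENT = 0.75

# fasted-state gut defaults: (radius cm, transit h, luminal volume L, pH).
# Stomach emptying 0.25 h; the six small-intestinal segments split a 3.3-h
# total transit; caecum + colon together 13 h. pH ascends 1.3 -> 7.4 through
# the small intestine and falls again in the colon.
_GI_DEFAULTS = {
    "stomach": (10.0, 0.25, 0.046, 1.3),
    "duodenum": (1.60, 0.26, 0.042, 6.0),
    "jejunum1": (1.50, 0.95, 0.154, 6.2),
    "jejunum2": (1.34, 0.76, 0.122, 6.4),
    "ileum1": (1.18, 0.59, 0.094, 6.6),
    "ileum2": (1.08, 0.43, 0.071, 6.9),
    "ileum3": (1.00, 0.31, 0.049, 7.4),
    "caecum": (3.39, 4.50, 0.050, 6.4),
    "colon": (2.41, 8.50, 0.100, 6.8),
}


class InvalidInputError(ValueError):
    """Raised for physically impossible anthropometric or spec inputs."""


@dataclass(frozen=True)
class GICompartment:
    name: str
    radius_cm: float
    transit_time_h: float
    volume_luminal_l: float
    ph: float

    def __post_init__(self):
        if self.name not in GI_SEGMENT_ORDER:
            raise InvalidInputError(f"unknown GI segment {self.name!r}")
        if self.transit_time_h <= 0:
            raise InvalidInputError(f"{self.name}: transit time must be > 0")


@dataclass(frozen=True)
class CompoundParams:
    """Physicochemical / biopharmaceutic parameter set for one compound."""

    name: str
    molecular_weight: float          # g/mol
    log_p: float
    pka: float
    log_d: float
    blood_plasma_ratio: float        # Rbp
    fraction_unbound_plasma: float   # fup, 0-1
    aqueous_solubility_mg_ml: float
    effective_permeability_cm_s: float   # in vitro (Caco-2 type) Peff
    permeability_log_scale: float        # calibrated in vitro -> in vivo log10 shift
    clearance_plasma_l_h_kg: float       # adult plasma clearance
    clearance_plasma_child_l_h_kg: float
    clearance_plasma_literature_l_h_kg: float
    renal_fraction: float
    vd_reference_range_l_kg: tuple[float, float]

    def __post_init__(self):
        positives = {
            "molecular_weight": self.molecular_weight,
            "blood_plasma_ratio": self.blood_plasma_ratio,
            "fraction_unbound_plasma": self.fraction_unbound_plasma,
            "aqueous_solubility_mg_ml": self.aqueous_solubility_mg_ml,
            "effective_permeability_cm_s": self.effective_permeability_cm_s,
            "clearance_plasma_l_h_kg": self.clearance_plasma_l_h_kg,
            "renal_fraction": self.renal_fraction,
        }
        for key, value in positives.items():
            if not value > 0:
                raise InvalidInputError(f"{key} must be > 0, got {value}")
        if self.fraction_unbound_plasma > 1:
            raise InvalidInputError("fraction_unbound_plasma must be <= 1")
        if self.renal_fraction > 1:
            raise InvalidInputError("renal_fraction must be <= 1")
        lo, hi = self.vd_reference_range_l_kg
        if not lo < hi:
            raise InvalidInputError("vd_reference_range must satisfy low < high")

    @property
    def effective_permeability_in_vivo_cm_s(self) -> float:
        """In vitro permeability mapped onto the human effective scale."""
        return 10.0 ** (
            math.log10(self.effective_permeability_cm_s) + self.permeability_log_scale
        )


@dataclass(frozen=True)
class Physiology:
    """One subject: whole-body tissue map plus GI tract."""

    age_years: float
    sex: str                               # "M" or "F"
    body_weight_kg: float
    height_m: float
    tissue_volumes_l: dict[str, float]     # perfusion-limited tissues
    tissue_blood_flows_l_h: dict[str, float]
    gi_compartments: tuple[GICompartment, ...]
    venous_blood_l: float
    arterial_blood_l: float
    plasma_volume_l: float
    cardiac_output_l_h: float
    body_water_uplift: float = 1.0         # >1 for young children

    def __post_init__(self):
        for tissue, v in self.tissue_volumes_l.items():
            if v <= 0:
                raise InvalidInputError(f"volume of {tissue} must be > 0")
        for tissue, q in self.tissue_blood_flows_l_h.items():
            if q <= 0:
                raise InvalidInputError(f"flow of {tissue} must be > 0")
        names = tuple(c.name for c in self.gi_compartments)
        if names != GI_SEGMENT_ORDER:
            raise InvalidInputError(
                f"GI compartments must be exactly {GI_SEGMENT_ORDER}, got {names}"
            )

    @property
    def bmi(self) -> float:
        return self.body_weight_kg / self.height_m**2

    @property
    def tissues(self) -> tuple[str, ...]:
        return tuple(self.tissue_volumes_l)


@dataclass(frozen=True)
class PopulationSpec:
    n: int
    age_range_years: tuple[float, float]
    sex_ratio_male: float
    weight_range_kg: tuple[float, float]
    bmi_range: tuple[float, float]
    seed: int = 0

    def __post_init__(self):
        if self.n < 0:
            raise InvalidInputError("n must be >= 0")
        if not 0 <= self.sex_ratio_male <= 1:
            raise InvalidInputError("sex_ratio_male must be in [0, 1]")
        for label, (lo, hi) in (
            ("age_range_years", self.age_range_years),
            ("weight_range_kg", self.weight_range_kg),
            ("bmi_range", self.bmi_range),
        ):
            if not (lo > 0 and hi >= lo):
                raise InvalidInputError(f"{label} must be a non-empty positive range")


def _data_path(name: str):
    return resources.files("levpbpk.data").joinpath(name)


def load_reference_physiology(path=None) -> pd.DataFrame:
    """Reference-man tissue table: volume and blood-flow fractions.

    Columns: ``tissue``, ``volume_frac_bw`` (fraction of body weight,
    density 1 kg/L) and ``flow_frac_co`` (fraction of cardiac output).
    """
    src = path if path is not None else _data_path("reference_physiology.csv")
    df = pd.read_csv(src, comment="#")
    return df.set_index("tissue")


def load_compound_profile(name_or_path: str = "levetiracetam") -> CompoundParams:
    """Load a packaged compound profile (or a YAML file by path)."""
    p = _data_path(f"{name_or_path}.yaml")
    try:
        exists = p.is_file()
    except AttributeError:  # pragma: no cover
        exists = False
    if not exists:
        import os

        if not os.path.exists(name_or_path):
            raise FileNotFoundError(f"no compound profile {name_or_path!r}")
        p = name_or_path
    with open(str(p)) as fh:
        raw = yaml.safe_load(fh)["compound"]
    raw["vd_reference_range_l_kg"] = tuple(raw["vd_reference_range_l_kg"])
    return CompoundParams(**raw)


def _build_gi(weight_kg: float) -> tuple[GICompartment, ...]:
    # luminal volumes scale linearly, radii with the cube root of weight;
    # transit times are kept at the fasted adult defaults.
    s = weight_kg / REFERENCE_WEIGHT_KG
    comps = []
    for name in GI_SEGMENT_ORDER:
        r, t, v, ph = _GI_DEFAULTS[name]
        comps.append(
            GICompartment(
                name=name,
                radius_cm=r * s ** (1 / 3),
                transit_time_h=t,
                volume_luminal_l=v * s,
                ph=ph,
            )
        )
    return tuple(comps)


def _scaled_physiology(
    weight: float, height: float, age: float, sex: str, water_uplift: float = 1.0
) -> Physiology:
    ref = load_reference_physiology()
    s_v = weight / REFERENCE_WEIGHT_KG
    s_q = s_v**FLOW_ALLOMETRIC_EXPONENT
    volumes = (ref["volume_frac_bw"] * weight).to_dict()
    if sex == "F":
        # the reference table describes the adult male; females carry
        # relatively more adipose and less muscle
        volumes["adipose"] *= 1.10
        volumes["muscle"] *= 0.90
    co = CARDIAC_OUTPUT_REF_L_H * s_q
    flows = (ref["flow_frac_co"] * co).to_dict()
    blood = BLOOD_FRACTION_L_PER_KG * weight
    return Physiology(
        age_years=age,
        sex=sex,
        body_weight_kg=weight,
        height_m=height,
        tissue_volumes_l=volumes,
        tissue_blood_flows_l_h=flows,
        gi_compartments=_build_gi(weight),
        venous_blood_l=blood * 2 / 3,
        arterial_blood_l=blood / 3,
        plasma_volume_l=blood * (1 - HEMATOCRIT),
        cardiac_output_l_h=co,
        body_water_uplift=water_uplift,
    )


def build_adult_physiology(
    weight_kg: float, height_m: float, age_years: float, sex: str
) -> Physiology:
    """Adult subject scaled from the 70-kg reference table."""
    if weight_kg <= 0 or height_m <= 0 or age_years <= 0:
        raise InvalidInputError("anthropometrics must be positive")
    if sex not in ("M", "F"):
        raise InvalidInputError("sex must be 'M' or 'F'")
    if age_years < 18:
        raise InvalidInputError("adult model requires age >= 18 years")
    return _scaled_physiology(weight_kg, height_m, age_years, sex)


def body_water_fraction(age_years: float) -> float:
    """Total-body-water fraction: 0.75 at birth, adult 0.60 from age 12."""
    if age_years >= 12:
        return 0.60
    return 0.75 - (0.15 / 12.0) * age_years


def default_child_bmi(age_years: float) -> float:
    """Reference BMI-for-age (piecewise linear through typical medians)."""
    knots = [(0.5, 17.0), (2.0, 16.2), (5.0, 15.5), (10.0, 16.6), (15.0, 19.0)]
    ages = [a for a, _ in knots]
    vals = [b for _, b in knots]
    return float(np.interp(age_years, ages, vals))


def build_child_physiology(
    age_years: float, weight_kg: float, bmi: float | None = None, sex: str = "M"
) -> Physiology:
    """Pediatric subject; height derived from weight and BMI.

    Volumes scale linearly with weight, flows with weight^0.75, and tissue
    water fractions are uplifted for age < 12 (linear from 0.75 at birth to
    the adult 0.60 by age 12).  Ages outside 0.5-15 y raise an extrapolation
    warning, not an error.
    """
    if weight_kg <= 0:
        raise InvalidInputError("weight must be positive")
    if not 0.5 <= age_years <= 15:
        warnings.warn(
            f"age {age_years} y outside the supported 0.5-15 y span; extrapolating",
            stacklevel=2,
        )
    if bmi is None:
        bmi = default_child_bmi(age_years)
    height = math.sqrt(weight_kg / bmi)
    uplift = body_water_fraction(age_years) / 0.60
    return _scaled_physiology(weight_kg, height, age_years, sex, water_uplift=uplift)


def sample_population(spec: PopulationSpec) -> list[Physiology]:
    """Draw a virtual adult population, uniform within the stated ranges.

    The male count is exactly ``round(n * sex_ratio_male)`` and identical
    seeds reproduce identical subject lists.
    """
    if spec.n == 0:
        return []
    rng = np.random.default_rng(spec.seed)
    n_male = int(round(spec.n * spec.sex_ratio_male))
    sexes = np.array(["M"] * n_male + ["F"] * (spec.n - n_male))
    ages = rng.uniform(*spec.age_range_years, size=spec.n)
    weights = rng.uniform(*spec.weight_range_kg, size=spec.n)
    bmis = rng.uniform(*spec.bmi_range, size=spec.n)
    subjects = []
    for age, w, bmi, sex in zip(ages, weights, bmis, sexes):
        height = math.sqrt(w / bmi)
        subjects.append(_scaled_physiology(float(w), height, float(age), str(sex)))
    return subjects
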
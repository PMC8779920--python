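"""Tissue-to-plasma partition coefficients and steady-state volume.

Kp values follow the Berezhkovskiy tissue-composition approach: the drug
distributes between tissue water, neutral lipid and phospholipid, with the
unbound-fraction correction applied between plasma and tissue.  For the
neutral-lipid phase the default partition coefficient is the vegetable
oil:water value from the Leo correlation ``log Pvo:w = 1.115 logP - 1.35``
(applied to every tissue); the plain octanol:water coefficient for lean
tissues is available via ``neutral_lipid_reference="octanol"``.

Levetiracetam (pKa 16.1) is un-ionized at any physiological pH, so only the
neutral-species equations are implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .compound_physiology import CompoundParams, Physiology

__all__ = [
    "TissueComposition",
    "KpSet",
    "load_tissue_composition",
    "kp_berezhkovskiy",
    "kp_for_physiology",
    "vss_from_kp",
    "ConfigurationError",
]


class ConfigurationError(KeyError):
    pass


@dataclass(frozen=True)
class TissueComposition:
    """Fractional water / neutral-lipid / phospholipid content per tissue."""

    fractions: dict[str, tuple[float, float, float]]  # tissue -> (fw, fnl, fph)
    plasma: tuple[float, float, float]

    def __post_init__(self):
        for tissue, fracs in list(self.fractions.items()) + [("plasma", self.plasma)]:
            if any(not 0 <= f <= 1 for f in fracs):
                raise ValueError(f"{tissue}: fractions must lie in [0, 1]")
            if sum(fracs) > 1 + 1e-9:
                raise ValueError(f"{tissue}: fractions sum to more than 1")

    def with_water_uplift(self, uplift: float) -> "TissueComposition":
        """Scale tissue water fractions (pediatric body-water adjustment).

        Plasma composition is left unchanged; per-tissue water is capped so
        the fractions still sum to at most 1.
        """
        if uplift == 1.0:
            return self
        scaled = {}
        for tissue, (fw, fnl, fph) in self.fractions.items():
            scaled[tissue] = (min(fw * uplift, 1.0 - fnl - fph), fnl, fph)
        return TissueComposition(fractions=scaled, plasma=self.plasma)


@dataclass(frozen=True)
class KpSet:
    kp: dict[str, float]

    def __post_init__(self):
        for tissue, value in self.kp.items():
            if not value > 0:
                raise ValueError(f"Kp[{tissue}] must be > 0")

    def __getitem__(self, tissue: str) -> float:
        return self.kp[tissue]

    def __iter__(self):
        return iter(self.kp)


def load_tissue_composition(path=None) -> TissueComposition:
    src = (
        path
        if path is not None
        else resources.files("levpbpk.data").joinpath("tissue_composition.csv")
    )
    df = pd.read_csv(src, comment="#").set_index("tissue")
    fractions = {
        t: (row.f_water, row.f_neutral_lipid, row.f_phospholipid)
        for t, row in df.iterrows()
        if t != "plasma"
    }
    plasma = tuple(df.loc["plasma", ["f_water", "f_neutral_lipid", "f_phospholipid"]])
    return TissueComposition(fractions=fractions, plasma=plasma)


def _neutral_lipid_partition(log_p: float, reference: str) -> float:
    if reference == "vegetable_oil":
        return 10.0 ** (1.115 * log_p - 1.35)
    if reference == "octanol":
        return 10.0**log_p
    raise ValueError(f"unknown neutral_lipid_reference {reference!r}")


def kp_berezhkovskiy(
    compound: CompoundParams,
    comp: TissueComposition,
    *,
    tissues: tuple[str, ...] | None = None,
    lipophilicity: str = "logp",
    neutral_lipid_reference: str = "vegetable_oil",
) -> KpSet:
    """Tissue:plasma partition coefficients from tissue composition.

    For each tissue::

        Kp = [P*f_nl + (0.3*P + 0.7)*f_ph + f_w]_tissue
             ---------------------------------------- * fup / fut
             [P*f_nl + (0.3*P + 0.7)*f_ph + f_w]_plasma

    with ``fut = 1 / (1 + 0.5*(1 - fup)/fup)`` (interstitial binding proteins
    at half their plasma concentration).  ``lipophilicity`` selects logP
    (default) or logD as the input descriptor.
    """
    log_lipo = {"logp": compound.log_p, "logd": compound.log_d}[lipophilicity]
    p = _neutral_lipid_partition(log_lipo, neutral_lipid_reference)
    fup = compound.fraction_unbound_plasma
    fut = 1.0 / (1.0 + 0.5 * (1.0 - fup) / fup)

    def phase_sum(fracs):
        fw, fnl, fph = fracs
        return p * fnl + (0.3 * p + 0.7) * fph + fw

    denom = phase_sum(comp.plasma)
    wanted = tissues if tissues is not None else tuple(comp.fractions)
    kp = {}
    for tissue in wanted:
        if tissue not in comp.fractions:
            raise ConfigurationError(
                f"no tissue composition available for {tissue!r}"
            )
        kp[tissue] = phase_sum(comp.fractions[tissue]) / denom * (fup / fut)
    return KpSet(kp=kp)


def kp_for_physiology(
    compound: CompoundParams,
    phys: Physiology,
    comp: TissueComposition | None = None,
    **kwargs,
) -> KpSet:
    """Kp set for a subject, applying the pediatric body-water uplift."""
    if comp is None:
        comp = load_tissue_composition()
    comp = comp.with_water_uplift(phys.body_water_uplift)
    return kp_berezhkovskiy(compound, comp, tissues=phys.tissues, **kwargs)


def vss_from_kp(kps: KpSet, phys: Physiology) -> float:
    """Steady-state volume of distribution, L/kg.

    ``Vss = (V_plasma + sum_t Kp_t * V_t) / BW``; every perfused tissue of
    the physiology must have a Kp (plasma is excluded).
    """
    total = phys.plasma_volume_l
    for tissue, volume in phys.tissue_volumes_l.items():
        try:
            total += kps[tissue] * volume
        except KeyError:
            raise ConfigurationError(f"missing Kp for tissue {tissue!r}") from None
    return total / phys.body_weight_kg
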
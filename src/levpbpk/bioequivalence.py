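"""Bioequivalence statistics and the virtual crossover trial engine.

Average bioequivalence on log-transformed parameters: the two one-sided
tests procedure is applied through the 90% confidence interval of the
test/reference geometric mean ratio (GMR), which must lie within the
regulatory limits (80-125% standard; 85-120% for the virtual trial here).
Parallel designs use the pooled two-sample interval; 2x2 crossover designs
use the period-difference estimator, which removes period effects and
estimates within-subject variance from the sequence-stratified differences.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .acat_absorption import DissolutionModel
from .compound_physiology import CompoundParams, Physiology
from .nca import run_nca
from .partitioning import kp_for_physiology
from .pbpk_disposition import DoseEvent, assemble_model, simulate

__all__ = [
    "BeDataset",
    "BeParameterResult",
    "BeReport",
    "tost_be",
    "virtual_be_trial",
    "BE_SAMPLING_GRID_H",
]

#: clinical-style sampling grid used for the virtual trial arms
BE_SAMPLING_GRID_H = np.array(
    [0.0, 0.25, 0.5, 0.75, 1, 1.25, 1.5, 2, 2.5, 3, 4, 6, 8, 12, 16, 24, 36]
)

_DEGENERATE_SE = 1e-10


@dataclass(frozen=True)
class BeDataset:
    """Per-subject PK parameters for a BE analysis.

    ``data`` columns: ``subject, formulation`` (test/reference), parameter
    columns, plus ``sequence`` (``TR``/``RT``) and ``period`` for crossover.
    """

    design: str  # parallel | crossover_2x2
    data: pd.DataFrame

    def __post_init__(self):
        if self.design not in ("parallel", "crossover_2x2"):
            raise ValueError(f"unknown design {self.design!r}")
        need = {"subject", "formulation"}
        if self.design == "crossover_2x2":
            need |= {"sequence", "period"}
        missing = need - set(self.data.columns)
        if missing:
            raise ValueError(f"dataset lacks columns {sorted(missing)}")

    def parameters(self) -> list[str]:
        reserved = {"subject", "formulation", "sequence", "period"}
        return [c for c in self.data.columns if c not in reserved]


@dataclass(frozen=True)
class BeParameterResult:
    parameter: str
    gmr_percent: float
    ci_lower_percent: float
    ci_upper_percent: float
    limits_percent: tuple[float, float]
    passed: bool
    anova_p: float
    degenerate: bool = False


@dataclass(frozen=True)
class BeReport:
    design: str
    n_subjects: int
    results: dict[str, BeParameterResult]

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.results.values())


def _interval(est, se, df, alpha):
    """(1 - 2*alpha) CI for the log-scale difference."""
    if se < _DEGENERATE_SE:
        return est, est, True
    tcrit = stats.t.ppf(1.0 - alpha, df)
    return est - tcrit * se, est + tcrit * se, False


def _crossover_estimate(df: pd.DataFrame, param: str):
    wide = df.pivot_table(
        index=["subject", "sequence"], columns="formulation", values=param
    )
    if wide.isna().any().any():
        raise ValueError("crossover dataset incomplete (missing test or reference)")
    d = np.log(wide["test"]) - np.log(wide["reference"])
    by_seq = d.groupby("sequence")
    means = by_seq.mean()
    ns = by_seq.size()
    if len(means) != 2 or (ns < 2).any():
        raise ValueError("crossover analysis needs >= 2 subjects per sequence")
    # equal-weight mean of the two sequence means removes any period effect
    est = float(means.mean())
    pooled = float(((by_seq.var(ddof=1) * (ns - 1)).sum()) / (ns.sum() - 2))
    se = math.sqrt(pooled / 4.0 * (1.0 / ns.iloc[0] + 1.0 / ns.iloc[1]))
    return est, se, int(ns.sum() - 2)


def tost_be(
    data: BeDataset,
    alpha: float = 0.05,
    limits: tuple[float, float] = (80.0, 125.0),
    parameters: Sequence[str] | None = None,
) -> BeReport:
    """TOST / 90% CI bioequivalence assessment of a BE dataset.

    Each parameter is log-transformed; the report carries the GMR, the
    ``(1 - 2*alpha)`` CI, the pass flag (CI within limits) and a two-sided
    ANOVA-type p-value for the formulation effect.  Zero within-design
    variance degenerates the CI to the exact ratio with a warning.
    """
    params = list(parameters) if parameters is not None else data.parameters()
    df = data.data
    results = {}
    for param in params:
        if (df[param] <= 0).any():
            raise ValueError(f"{param}: values must be positive (log scale)")
        if data.design == "parallel":
            t = np.log(df.loc[df.formulation == "test", param].to_numpy())
            r = np.log(df.loc[df.formulation == "reference", param].to_numpy())
            if len(t) < 2 or len(r) < 2:
                raise ValueError("parallel analysis needs >= 2 subjects per arm")
            est = float(t.mean() - r.mean())
            dfree = len(t) + len(r) - 2
            pooled = ((len(t) - 1) * t.var(ddof=1) + (len(r) - 1) * r.var(ddof=1)) / dfree
            se = math.sqrt(pooled * (1.0 / len(t) + 1.0 / len(r)))
            n_subj = len(t) + len(r)
        else:
            est, se, dfree = _crossover_estimate(df, param)
            n_subj = df.subject.nunique()
        lo, hi, degenerate = _interval(est, se, dfree, alpha)
        if degenerate:
            warnings.warn(
                f"{param}: zero variance; confidence interval degenerates to the "
                "exact geometric mean ratio",
                stacklevel=2,
            )
            anova_p = 1.0 if abs(est) < 1e-15 else 0.0
        else:
            tstat = est / se
            anova_p = float(2.0 * stats.t.sf(abs(tstat), dfree))
        ci_lo, ci_hi = 100.0 * math.exp(lo), 100.0 * math.exp(hi)
        results[param] = BeParameterResult(
            parameter=param,
            gmr_percent=100.0 * math.exp(est),
            ci_lower_percent=ci_lo,
            ci_upper_percent=ci_hi,
            limits_percent=tuple(limits),
            passed=bool(limits[0] <= ci_lo and ci_hi <= limits[1]),
            anova_p=anova_p,
            degenerate=degenerate,
        )
    return BeReport(design=data.design, n_subjects=n_subj, results=results)


def virtual_be_trial(
    population: Sequence[Physiology],
    compound: CompoundParams,
    test_dissolution: DissolutionModel,
    ref_dissolution: DissolutionModel,
    dose_mg: float = 1000.0,
    limits: tuple[float, float] = (85.0, 120.0),
    parameters: Sequence[str] = ("cmax", "auc0t"),
    t_grid: np.ndarray | None = None,
) -> tuple[BeReport, BeDataset]:
    """Virtual 2x2 crossover trial: same subjects receive both products.

    Each subject's test and reference arms differ only in the dissolution
    input; between-subject variability comes solely from the sampled
    physiologies.  Deterministic given the population.
    """
    if not population:
        raise ValueError("population must be non-empty")
    grid = BE_SAMPLING_GRID_H if t_grid is None else np.asarray(t_grid, float)
    rows = []
    for i, phys in enumerate(population):
        try:
            kps = kp_for_physiology(compound, phys)
            model = assemble_model(compound, phys, kps, "adult")
            arms = {}
            for label, dissolution in (
                ("test", test_dissolution),
                ("reference", ref_dissolution),
            ):
                prof = simulate(
                    model, [DoseEvent("oral", dose_mg, 0.0)], dissolution, grid
                )
                arms[label] = run_nca(np.column_stack([grid, prof.plasma_ug_ml]))
        except Exception as exc:
            raise RuntimeError(f"simulation failed for subject {i}: {exc}") from exc
        sequence = "TR" if i % 2 == 0 else "RT"
        for label, nca in arms.items():
            first = (sequence == "TR") == (label == "test")
            rows.append(
                {
                    "subject": i,
                    "sequence": sequence,
                    "period": 1 if first else 2,
                    "formulation": label,
                    "cmax": nca.c_max,
                    "auc0t": nca.auc_0_t,
                    "auc0inf": nca.auc_0_inf,
                    "tmax": nca.t_max,
                }
            )
    data = BeDataset(design="crossover_2x2", data=pd.DataFrame(rows))
    report = tost_be(data, limits=limits, parameters=list(parameters))
    return report, data
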
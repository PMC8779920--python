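import math

import numpy as np
import pandas as pd
import pytest

from levpbpk.nca import (
    cl_per_kg_from_iv,
    pe_percent,
    pe_table,
    run_nca,
    validate_against_observed,
)
from levpbpk.pbpk_disposition import SimProfile


def _profile_from(times, concs):
    times = np.asarray(times, float)
    concs = np.asarray(concs, float)
    zeros = np.zeros_like(times)
    return SimProfile(
        times_h=times,
        plasma_ug_ml=concs,
        tissue_ug_ml={},
        eliminated_mg=zeros,
        absorbed_mg=zeros,
        gut_lumen_mg=zeros,
        gut_exited_mg=zeros,
        dose_total_mg=1.0,
    )


class TestRunNca:
    def test_mono_exponential_closed_form(self):
        t = np.linspace(0, 72, 289)
        c = 10.0 * np.exp(-0.1 * t)
        res = run_nca(np.column_stack([t, c]))
        # log-linear regression recovers the rate exactly on noise-free data
        assert res.lambda_z == pytest.approx(0.1, rel=1e-6)
        assert res.auc_0_inf == pytest.approx(100.0, rel=1e-6)
        assert res.half_life == pytest.approx(math.log(2) / 0.1, rel=1e-6)

    def test_oral_tmax_against_closed_form(self):
        ka, ke = 2.0, 0.2165  # terminal half-life about 3.2 h
        step = 0.25
        t = np.arange(step, 24 + step, step)
        c = (ka / (ka - ke)) * (np.exp(-ke * t) - np.exp(-ka * t))
        res = run_nca(np.column_stack([t, c]))
        tmax_true = math.log(ka / ke) / (ka - ke)
        assert abs(res.t_max - tmax_true) <= step

    def test_scaling_homogeneity(self):
        t = np.arange(0.5, 36, 0.5)
        c = 5.0 * (np.exp(-0.2 * t) - np.exp(-2.0 * t))
        base = run_nca(np.column_stack([t, c]))
        scaled = run_nca(np.column_stack([t, 2.0 * c]))
        assert scaled.c_max == pytest.approx(2 * base.c_max)
        assert scaled.auc_0_t == pytest.approx(2 * base.auc_0_t)
        assert scaled.auc_0_inf == pytest.approx(2 * base.auc_0_inf)
        assert scaled.t_max == base.t_max
        assert scaled.lambda_z == pytest.approx(base.lambda_z)
        assert scaled.mrt_last == pytest.approx(base.mrt_last)

    def test_auc_additivity_over_subintervals(self):
        t = np.arange(0.0, 24.5, 0.5)
        c = 8.0 * np.exp(-0.15 * t) + 0.3
        full = run_nca(np.column_stack([t, c])).auc_0_t
        split = 10.0
        left = run_nca(np.column_stack([t[t <= split], c[t <= split]])).auc_0_t
        right = run_nca(np.column_stack([t[t >= split], c[t >= split]])).auc_0_t
        assert left + right == pytest.approx(full, rel=1e-12)

    def test_no_terminal_decline_flags_missing(self):
        t = np.arange(1.0, 10.0)
        c = np.linspace(1.0, 5.0, len(t))  # monotone rise, no decline
        res = run_nca(np.column_stack([t, c]))
        assert not res.has_terminal_phase
        assert math.isnan(res.auc_0_inf) and math.isnan(res.half_life)
        assert math.isfinite(res.auc_0_t)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            run_nca([(0, 1.0), (0, 2.0), (1, 1.5)])
        with pytest.raises(ValueError):
            run_nca([(0, 1.0), (1, 0.0), (2, 0.0)])


# printed observed/predicted pairs for the six adult regimens
_TABLE5 = pd.DataFrame(
    [
        # regimen, parameter, observed, predicted, printed PE
        ("iv-1500", "cmax", 50.80, 54.83, 7.93),
        ("oral-250", "cmax", 5.51, 6.268, 13.76),
        ("oral-500", "cmax", 12.50, 12.54, 0.32),
        ("oral-750", "cmax", 17.00, 18.80, 10.59),
        ("oral-1000", "cmax", 24.10, 25.90, 7.47),
        ("oral-1500", "cmax", 35.30, 35.43, 0.37),
        ("iv-1500", "auc0t", 367.20, 357.40, 2.67),
        ("oral-250", "auc0t", 62.56, 58.96, 5.75),
        ("oral-500", "auc0t", 138.50, 117.90, 14.87),
        ("oral-750", "auc0t", 189.80, 176.90, 6.80),
        ("oral-1000", "auc0t", 222.80, 236.60, 6.19),
        ("oral-1500", "auc0t", 402.30, 354.70, 11.83),
        ("iv-1500", "auc0inf", 370.70, 358.90, 3.18),
        ("oral-250", "auc0inf", 72.56, 59.75, 17.65),
        ("oral-500", "auc0inf", 145.40, 119.50, 17.81),
        ("oral-750", "auc0inf", 196.10, 179.30, 8.57),
        ("oral-1000", "auc0inf", 226.40, 239.40, 5.74),
        ("oral-1500", "auc0inf", 408.30, 356.30, 12.74),
        ("iv-1500", "tmax", 0.711, 0.75, 5.49),
        ("oral-250", "tmax", 1.67, 1.32, 20.96),
        ("oral-500", "tmax", 0.80, 1.32, 65.00),
        ("oral-750", "tmax", 3.16, 1.32, 58.23),
        ("oral-1000", "tmax", 1.45, 1.30, 10.34),
        ("oral-1500", "tmax", 0.646, 1.38, 113.62),
    ],
    columns=["regimen", "parameter", "observed", "predicted", "pe_printed"],
)


class TestPredictionError:
    def test_pe_examples(self):
        assert pe_percent(54.83, 50.80) == pytest.approx(7.93, abs=0.005)
        assert pe_percent(1.38, 0.646) == pytest.approx(113.62, abs=0.005)
        assert pe_percent(3.7, 3.7) == 0.0
        assert pe_percent(2.0, 2.5) == pytest.approx(20.0)

    def test_pe_invariant_to_common_rescaling(self):
        assert pe_percent(54.83, 50.80) == pytest.approx(
            pe_percent(5.483, 5.080), rel=1e-12
        )

    def test_pe_undefined_for_zero_observed(self):
        with pytest.raises(ZeroDivisionError):
            pe_percent(1.0, 0.0)

    def test_reproduces_every_printed_pe_cell(self):
        out = pe_table(_TABLE5)
        for _, row in out.iterrows():
            assert round(row.pe_percent, 2) == pytest.approx(
                row.pe_printed, abs=0.011
            ), f"{row.regimen} {row.parameter}"


class TestValidationHarness:
    def _sims(self, factor=1.0):
        t = np.arange(0.25, 36.25, 0.25)
        sims = {}
        for regimen in ["a", "b"]:
            c = factor * 10.0 * (np.exp(-0.1 * t) - np.exp(-2.0 * t))
            sims[regimen] = _profile_from(t, c)
        return sims

    def _observed_from(self, sims):
        rows = []
        for regimen, prof in sims.items():
            nca = run_nca(np.column_stack([prof.times_h, prof.plasma_ug_ml]))
            for param, val in (
                ("cmax", nca.c_max),
                ("auc0t", nca.auc_0_t),
                ("auc0inf", nca.auc_0_inf),
            ):
                rows.append({"regimen": regimen, "parameter": param, "observed": val})
        return pd.DataFrame(rows)

    def test_identical_observed_and_predicted_pass_with_zero_pe(self):
        sims = self._sims()
        records, gate = validate_against_observed(sims, self._observed_from(sims))
        assert gate
        assert all(r.pe_percent == pytest.approx(0.0, abs=1e-9) for r in records)

    def test_25_percent_deviation_fails_gate(self):
        sims = self._sims()
        observed = self._observed_from(sims)
        inflated = self._sims(factor=1.25)
        records, gate = validate_against_observed(inflated, observed)
        assert not gate
        assert any(r.pe_percent == pytest.approx(25.0, rel=1e-6) for r in records)

    def test_missing_regimen_raises(self):
        sims = self._sims()
        observed = self._observed_from(sims)
        with pytest.raises(ValueError, match="b"):
            validate_against_observed({"a": sims["a"]}, observed)


class TestClearanceDerivation:
    def test_adult_iv_derivation(self):
        assert cl_per_kg_from_iv(1500, 370.70, 64.19) == pytest.approx(0.063, abs=5e-4)

    def test_unit_identity(self):
        assert cl_per_kg_from_iv(37.0, 37.0, 1.0) == pytest.approx(1.0)

    def test_oral_1000_cohort_apparent_clearance(self):
        assert cl_per_kg_from_iv(1000, 226.40, 57.4) == pytest.approx(0.077, abs=5e-4)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            cl_per_kg_from_iv(0, 370.7, 64.19)
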
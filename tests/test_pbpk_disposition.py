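import dataclasses

import numpy as np
import pytest
from scipy.linalg import expm

from levpbpk.acat_absorption import DissolutionModel
from levpbpk.nca import run_nca
from levpbpk.partitioning import ConfigurationError, KpSet, kp_for_physiology
from levpbpk.pbpk_disposition import DoseEvent, assemble_model, simulate


class TestAssembly:
    def test_adult_clearance_from_weight(self, adult_model):
        assert adult_model.clearance_total_l_h == pytest.approx(0.063 * 64.19)
        assert adult_model.clearance_renal_l_h == pytest.approx(
            0.66 * adult_model.clearance_total_l_h
        )

    def test_child_clearance_from_weight(self, child6_model):
        assert child6_model.clearance_total_l_h == pytest.approx(1.18, abs=0.005)

    def test_fully_renal_compound_has_no_remainder(self, compound, adult_phys):
        fully_renal = dataclasses.replace(compound, renal_fraction=1.0)
        model = assemble_model(
            fully_renal, adult_phys, kp_for_physiology(fully_renal, adult_phys), "adult"
        )
        assert model.clearance_remainder_l_h == pytest.approx(0.0, abs=1e-12)

    def test_tissue_mismatch_raises(self, compound, adult_phys):
        with pytest.raises(ConfigurationError):
            assemble_model(compound, adult_phys, KpSet(kp={"muscle": 0.8}), "adult")


def _body_amount(profile, phys):
    total = (
        profile.tissue_ug_ml["venous_blood"] * phys.venous_blood_l
        + profile.tissue_ug_ml["arterial_blood"] * phys.arterial_blood_l
    )
    for tissue, volume in phys.tissue_volumes_l.items():
        total = total + profile.tissue_ug_ml[tissue] * volume
    return total


class TestDisposition:
    def test_mass_conservation_without_clearance(self, compound, adult_phys):
        inert = dataclasses.replace(
            compound, clearance_plasma_l_h_kg=1e-12, renal_fraction=1e-12
        )
        model = assemble_model(inert, adult_phys, kp_for_physiology(inert, adult_phys), "adult")
        prof = simulate(model, [DoseEvent("iv_bolus", 1500.0)], None, np.linspace(0, 48, 49))
        amounts = _body_amount(prof, adult_phys)
        np.testing.assert_allclose(amounts, 1500.0, rtol=1e-6)

    def test_matches_matrix_exponential_oracle(self, compound, adult_phys, adult_model):
        """IV bolus against an independently constructed linear-system solution."""
        phys, kps = adult_phys, adult_model.kps
        tissues = list(phys.tissues)
        rbp = compound.blood_plasma_ratio
        co = phys.cardiac_output_l_h
        q = {t: phys.tissue_blood_flows_l_h[t] for t in tissues}
        v = {t: phys.tissue_volumes_l[t] for t in tissues}
        out = {t: (rbp / kps[t]) / v[t] for t in tissues}  # outflow conc per amount
        i = {t: 2 + k for k, t in enumerate(tissues)}
        n = 2 + len(tissues)
        cl_r, cl_h = adult_model.clearance_renal_l_h, adult_model.clearance_remainder_l_h
        q_liv = q["liver"] + q["gut"] + q["spleen"]
        a = np.zeros((n, n))
        # venous pool (0) and arterial pool (1)
        a[i["lung"], 0] += co / phys.venous_blood_l
        a[0, 0] -= co / phys.venous_blood_l
        a[1, i["lung"]] += co * out["lung"]
        a[i["lung"], i["lung"]] -= co * out["lung"]
        a[1, 1] -= co / phys.arterial_blood_l
        for t in tissues:
            if t in ("lung", "liver"):
                continue
            a[i[t], 1] += q[t] / phys.arterial_blood_l
            a[i[t], i[t]] -= q[t] * out[t]
            if t in ("gut", "spleen"):
                a[i["liver"], i[t]] += q[t] * out[t] * (1 - cl_h / (rbp * q_liv))
            else:
                a[0, i[t]] += q[t] * out[t]
        # liver: hepatic-artery inflow with inlet extraction, outflow to venous
        a[i["liver"], 1] += (q["liver"] / phys.arterial_blood_l) * (
            1 - cl_h / (rbp * q_liv)
        )
        a[i["liver"], i["liver"]] -= q_liv * out["liver"]
        a[0, i["liver"]] += q_liv * out["liver"]
        # renal elimination driven by arterial plasma, removed from kidney
        a[i["kidney"], 1] -= cl_r / (rbp * phys.arterial_blood_l)

        y0 = np.zeros(n)
        y0[0] = 1500.0
        times = np.array([0.25, 1.0, 3.0, 8.0, 24.0])
        oracle = np.array([(expm(a * t) @ y0)[0] for t in times])
        oracle_plasma = oracle / phys.venous_blood_l / rbp

        prof = simulate(
            adult_model,
            [DoseEvent("iv_bolus", 1500.0)],
            None,
            np.concatenate([[0.0], times]),
            rtol=1e-10,
            atol=1e-12,
        )
        np.testing.assert_allclose(prof.plasma_ug_ml[1:], oracle_plasma, rtol=1e-3)

    def test_iv_auc_equals_dose_over_clearance(self, adult_model):
        # dense early grid resolves the mixing spike after the bolus
        grid = np.unique(
            np.concatenate(
                [np.linspace(0, 0.5, 201), np.linspace(0.5, 12, 93), np.linspace(12, 240, 200)]
            )
        )
        prof = simulate(adult_model, [DoseEvent("iv_bolus", 1500.0)], None, grid)
        nca = run_nca(np.column_stack([grid, prof.plasma_ug_ml]))
        assert nca.auc_0_inf == pytest.approx(
            1500.0 / adult_model.clearance_total_l_h, rel=5e-3
        )

    def test_superposition_of_multiple_doses(self, adult_model):
        # constant-hazard release makes the coupled system exactly linear
        dm = DissolutionModel(form="weibull", td_min=1.2, b=1.0)
        grid = np.linspace(0.0, 48.0, 193)
        both = simulate(
            adult_model,
            [DoseEvent("oral", 500.0, 0.0), DoseEvent("oral", 500.0, 12.0)],
            dm,
            grid,
        )
        single = simulate(adult_model, [DoseEvent("oral", 500.0, 0.0)], dm, grid)
        shifted = np.interp(grid - 12.0, grid, single.plasma_ug_ml, left=0.0)
        combined = single.plasma_ug_ml + shifted
        scale = combined.max()
        np.testing.assert_allclose(both.plasma_ug_ml / scale, combined / scale, atol=1e-3)

    def test_dose_linearity(self, adult_model, fast_dissolution):
        grid = np.linspace(0.0, 36.0, 145)
        lo = simulate(adult_model, [DoseEvent("oral", 500.0)], fast_dissolution, grid)
        hi = simulate(adult_model, [DoseEvent("oral", 1500.0)], fast_dissolution, grid)
        assert hi.plasma_ug_ml.max() == pytest.approx(
            3.0 * lo.plasma_ug_ml.max(), rel=1e-3
        )

    def test_grid_must_cover_doses(self, adult_model):
        with pytest.raises(ValueError):
            simulate(
                adult_model,
                [DoseEvent("iv_bolus", 100.0, 50.0)],
                None,
                np.linspace(0, 24, 25),
            )

    def test_infusion_profile_peaks_at_end_of_infusion(self, adult_model):
        grid = np.array([0, 0.25, 0.5, 0.75, 1.0, 1.5, 2, 4, 8, 12, 24])
        prof = simulate(
            adult_model, [DoseEvent("iv_infusion", 1500.0, 0.0, 0.75)], None, grid
        )
        assert grid[np.argmax(prof.plasma_ug_ml)] == pytest.approx(0.75)
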
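"""Respirometry analysis: windows, fluxes, normalizations, control ratios."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import mitoflux as mf
from mitoflux.events import Event
from mitoflux.respirometry import (
    FluxFit,
    SUIT_STATE_ORDER,
    compute_state_flux,
    state_spans,
)


def ramp_trace(slope_um_per_s=0.1, c0=200.0, n=200, dt=1.0):
    t = np.arange(n) * dt
    return mf.RespirometryTrace(
        time_s=t, o2_um=c0 - slope_um_per_s * t, events=[],
        chamber_volume_ml=2.0, sample_mass_mg=2.0,
    )


class TestWindowMarking:
    def test_full_schedule_yields_six_windows_in_suit_order(self, air_trace_noiseless):
        tr, _ = air_trace_noiseless
        windows = mf.mark_state_windows(tr)
        assert [w.label for w in windows] == list(SUIT_STATE_ORDER)
        for a, b in zip(windows[:-1], windows[1:]):
            assert a.end_s <= b.start_s  # non-overlapping, ordered

    def test_missing_antimycin_makes_rox_unmarkable(self, air_trace_noiseless):
        tr, _ = air_trace_noiseless
        stripped = mf.RespirometryTrace(
            time_s=tr.time_s, o2_um=tr.o2_um,
            events=[e for e in tr.events if e.substance != "Ama"],
            chamber_volume_ml=2.0, sample_mass_mg=2.0, state_label=tr.state_label,
        )
        with pytest.raises(ValueError, match="ROX"):
            mf.mark_state_windows(stripped)

    def test_windows_end_before_next_injection(self, air_trace_noiseless):
        tr, _ = air_trace_noiseless
        policy = mf.WindowPolicy()
        injections = [e.time_s for e in tr.events if e.substance != "reoxygenation"]
        for w in mf.mark_state_windows(tr):
            nxt = [t for t in injections if t > w.start_s]
            if nxt:
                assert min(nxt) - w.end_s >= policy.pre_event_gap_s - 1e-9

    def test_windows_exclude_injection_transients(self, air_trace_noiseless):
        tr, _ = air_trace_noiseless
        for w in mf.mark_state_windows(tr):
            for e in tr.events:
                assert not (w.start_s < e.time_s + 10.0 and e.time_s < w.start_s)


class TestVolumeFlux:
    def test_constant_concentration_gives_zero_flux(self):
        fit = mf.compute_volume_flux(ramp_trace(0.0), (20.0, 150.0))
        assert fit.j_v == pytest.approx(0.0, abs=1e-9)

    def test_unit_conversion_on_exact_ramp(self):
        # c(t) = 200 - 0.1 t uM -> J_V = 100 pmol s^-1 mL^-1
        fit = mf.compute_volume_flux(ramp_trace(0.1), (10.0, 180.0))
        assert fit.j_v == pytest.approx(100.0, rel=1e-12)
        assert fit.se == pytest.approx(0.0, abs=1e-5)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            mf.compute_volume_flux(ramp_trace(), (0.0, 5.0))

    def test_noisy_estimate_within_three_standard_errors(self):
        rng = np.random.default_rng(42)
        t = np.arange(0, 180.0, 2.0)
        c = 180.0 - 0.05 * t + rng.normal(0, 0.5, t.size)
        tr = mf.RespirometryTrace(
            time_s=t, o2_um=c, events=[], chamber_volume_ml=2.0, sample_mass_mg=2.0
        )
        fit = mf.compute_volume_flux(tr, (0.0, 180.0))
        assert abs(fit.j_v - 50.0) <= 3 * fit.se

    def test_pooled_fit_matches_single_window_on_clean_plateau(self):
        tr = ramp_trace(0.08, n=200)
        single = mf.compute_volume_flux(tr, (10.0, 169.0))
        pooled = compute_state_flux(tr, (0.0, 199.0), end_is_event=False)
        assert pooled.j_v == pytest.approx(single.j_v, rel=1e-9)

    def test_pooled_fit_bridges_reoxygenation_jump(self):
        # same slope on both sides of a level jump; pooled fit recovers it
        t = np.arange(0, 300.0, 2.0)
        c = 40.0 - 0.05 * t
        c[t > 150.0] += 30.0
        ev = [Event(150.0, "reoxygenation")]
        tr = mf.RespirometryTrace(
            time_s=t, o2_um=c, events=ev, chamber_volume_ml=2.0, sample_mass_mg=2.0
        )
        fit = compute_state_flux(tr, (0.0, 299.0), end_is_event=False)
        assert fit.j_v == pytest.approx(50.0, rel=1e-9)


class TestNormalization:
    def test_mass_and_cs_normalizations(self):
        table = mf.normalize_fluxes(
            {"N_P": 100.0}, chamber_volume_ml=2.0, sample_mass_mg=2.0, cs_units_iu=0.2
        )
        assert table.data.loc["N_P", "j_mass"] == pytest.approx(100.0)
        assert table.data.loc["N_P", "j_cs"] == pytest.approx(1000.0)

    def test_volume_equal_mass_leaves_flux_unchanged(self):
        table = mf.normalize_fluxes(
            {"N_L": 37.5}, chamber_volume_ml=1.7, sample_mass_mg=1.7
        )
        assert table.data.loc["N_L", "j_mass"] == pytest.approx(37.5)

    def test_non_positive_denominators_rejected(self):
        with pytest.raises(ValueError):
            mf.normalize_fluxes({"N_L": 1.0}, chamber_volume_ml=0.0, sample_mass_mg=2.0)
        with pytest.raises(ValueError):
            mf.normalize_fluxes(
                {"N_L": 1.0}, chamber_volume_ml=2.0, sample_mass_mg=2.0, cs_units_iu=-1.0
            )


class TestRoxCorrection:
    def table(self, **j):
        return mf.FluxTable.from_mass_fluxes(j)

    def test_baseline_subtracted_everywhere_and_rox_zeroed(self):
        out = mf.rox_correct(self.table(N_L=10.0, ROX=2.0))
        assert out.data.loc["N_L", "j_mass"] == pytest.approx(8.0)
        assert out.data.loc["ROX", "j_mass"] == 0.0
        assert out.rox_corrected

    def test_states_below_rox_kept_negative_and_flagged(self):
        out = mf.rox_correct(self.table(N_L=1.0, ROX=2.0))
        assert out.data.loc["N_L", "j_mass"] == pytest.approx(-1.0)
        assert out.negative_states == ("N_L",)

    def test_idempotent(self):
        once = mf.rox_correct(self.table(N_L=10.0, N_P=50.0, ROX=2.0))
        twice = mf.rox_correct(once)
        assert np.allclose(
            once.data["j_mass"].to_numpy(), twice.data["j_mass"].to_numpy()
        )

    def test_missing_rox_state_rejected(self):
        with pytest.raises(ValueError, match="ROX"):
            mf.rox_correct(self.table(N_L=10.0))

    def test_correction_commutes_with_normalization(self):
        fits = {"N_L": 20.0, "NS_E": 120.0, "ROX": 4.0}
        norm_then_correct = mf.rox_correct(
            mf.normalize_fluxes(fits, chamber_volume_ml=2.0, sample_mass_mg=1.6)
        )
        corrected_jv = {s: v - fits["ROX"] for s, v in fits.items()}
        correct_then_norm = mf.normalize_fluxes(
            corrected_jv, chamber_volume_ml=2.0, sample_mass_mg=1.6
        )
        assert np.allclose(
            norm_then_correct.data["j_mass"].to_numpy(),
            correct_then_norm.data["j_mass"].to_numpy(),
        )


class TestControlRatios:
    def corrected(self, **j):
        return mf.FluxTable.from_mass_fluxes(j, rox_corrected=True)

    def test_fcr_of_reference_state_is_exactly_one(self):
        t = self.corrected(N_L=10.0, N_P=60.0, NS_P=90.0, NS_E=110.0, S_E=60.0)
        assert mf.flux_control_ratios(t).fcr["NS_E"] == 1.0

    def test_fcr_example(self):
        t = self.corrected(N_L=10.0, N_P=60.0, NS_P=90.0, NS_E=100.0, S_E=60.0)
        assert mf.flux_control_ratios(t).fcr["N_L"] == pytest.approx(0.1)

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_fcr_and_efficiencies_invariant_under_rescaling(self, scale):
        base = {"N_L": 10.0, "N_P": 60.0, "NS_P": 90.0, "NS_E": 110.0, "S_E": 60.0}
        r0 = mf.flux_control_ratios(self.corrected(**base))
        r1 = mf.flux_control_ratios(
            self.corrected(**{k: v * scale for k, v in base.items()})
        )
        for s in base:
            assert r1.fcr[s] == pytest.approx(r0.fcr[s], rel=1e-9)
        assert r1.e_p_efficiency == pytest.approx(r0.e_p_efficiency, rel=1e-9)
        assert r1.p_l_efficiency == pytest.approx(r0.p_l_efficiency, rel=1e-9)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError, match="NS_E"):
            mf.flux_control_ratios(
                self.corrected(N_L=1.0, N_P=2.0, NS_P=3.0, NS_E=0.0, S_E=1.0)
            )

    @pytest.mark.parametrize(
        "fluxes, e_p, p_l",
        [
            # P = E: phosphorylation system not limiting
            (dict(N_L=10.0, N_P=50.0, NS_P=100.0, NS_E=100.0), 0.0, 0.8),
            # zero LEAK: fully coupled
            (dict(N_L=0.0, N_P=100.0, NS_P=100.0, NS_E=120.0), 1 / 6, 1.0),
            # LEAK = OXPHOS: no coupling
            (dict(N_L=50.0, N_P=50.0, NS_P=80.0, NS_E=100.0), 0.2, 0.0),
        ],
    )
    def test_efficiency_endpoints(self, fluxes, e_p, p_l):
        eff = mf.control_efficiencies(self.corrected(**fluxes))
        assert eff.e_p == pytest.approx(e_p)
        assert eff.p_l == pytest.approx(p_l)

    def test_efficiencies_never_exceed_one_for_positive_tables(self):
        eff = mf.control_efficiencies(
            self.corrected(N_L=5.0, N_P=50.0, NS_P=80.0, NS_E=100.0)
        )
        assert eff.e_p <= 1.0 and eff.p_l <= 1.0


class TestUncouplerAndCytochromeC:
    def test_optimum_is_maximal_step(self):
        opt = mf.uncoupler_optimum([80.0, 95.0, 90.0])
        assert (opt.step_index, opt.flux) == (2, 95.0)
        assert not opt.under_titration

    def test_tie_breaks_toward_lower_concentration(self):
        assert mf.uncoupler_optimum([95.0, 95.0, 90.0]).step_index == 1

    def test_single_step_is_returned(self):
        opt = mf.uncoupler_optimum([70.0])
        assert opt.step_index == 1 and not opt.under_titration

    def test_monotone_rising_flags_under_titration(self):
        assert mf.uncoupler_optimum([80.0, 90.0, 100.0]).under_titration

    @pytest.mark.parametrize(
        "before, after, increase, intact",
        [(100.0, 100.0, 0.0, True), (100.0, 130.0, 0.3, False), (100.0, 90.0, -0.1, True)],
    )
    def test_cytochrome_c_integrity(self, before, after, increase, intact):
        res = mf.cytochrome_c_test(before, after)
        assert res.relative_increase == pytest.approx(increase)
        assert res.intact == intact

    def test_cytochrome_c_requires_positive_before_flux(self):
        with pytest.raises(ValueError):
            mf.cytochrome_c_test(0.0, 10.0)


class TestPipeline:
    def test_noiseless_pipeline_recovers_truth_exactly(self, air_trace_noiseless):
        tr, truth = air_trace_noiseless
        res = mf.analyze_trace(tr, cs_units_iu=0.2)
        for s, j in truth.j_o2_mass.items():
            assert res.corrected.mass_flux(s) == pytest.approx(j, abs=1e-9)
        assert res.corrected.data.loc["ROX", "j_mass"] == 0.0
        assert res.ratios.fcr["NS_E"] == 1.0
        # J_mass = J_V * V/m and J_CS = J_V * V/IU for every state
        d = res.corrected.data
        assert np.allclose(d["j_mass"], d["j_v"] * 2.0 / 2.0)
        assert np.allclose(d["j_cs"], d["j_v"] * 2.0 / 0.2)

    def test_pipeline_reports_cytochrome_c_effect(self, air_trace_noiseless):
        tr, truth = air_trace_noiseless
        res = mf.analyze_trace(tr)
        assert res.cytochrome_c is not None
        # generator applies cytc_effect to the mitochondrial (not Rox) part
        n_p = truth.j_o2_mass["N_P"]
        expected = (n_p * (1 + truth.cytc_effect) + truth.j_rox_mass) / (
            n_p + truth.j_rox_mass
        ) - 1.0
        assert res.cytochrome_c.relative_increase == pytest.approx(expected, abs=1e-6)
        assert res.cytochrome_c.intact

    def test_uncoupler_selection_matches_truth_profile(self, air_trace_noiseless):
        tr, truth = air_trace_noiseless
        res = mf.analyze_trace(tr)
        assert res.uncoupler.step_index == int(np.argmax(truth.uncoupler_profile)) + 1
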
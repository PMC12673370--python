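"""Generator-side properties of the simulated respirometry traces."""

import numpy as np
import pytest

import mitoflux as mf
from mitoflux.events import Event, validate_events, run_end_time
from mitoflux.trace import TRANSIENT_LABEL


def clean(trace):
    return trace.state_label != TRANSIENT_LABEL


class TestEvents:
    def test_schedule_is_strictly_ordered_and_complete(self):
        sched = mf.build_suit028_schedule()
        times = [e.time_s for e in sched]
        assert times == sorted(times)
        subs = [e.substance for e in sched]
        for s in ("sample", "P", "M", "G", "D", "c", "S", "U", "Rot", "Ama"):
            assert s in subs

    def test_duplicate_event_times_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            validate_events([Event(10, "D"), Event(10, "S")])

    def test_yaml_round_trip(self, tmp_path):
        sched = mf.build_suit028_schedule(pre_sample_titrations=(40.0, 100.0))
        path = tmp_path / "events.yaml"
        mf.events_to_yaml(sched, path)
        assert mf.events_from_yaml(path) == sched

    def test_trailing_h2o2_titration_only_slightly_extends_run_end(self):
        sched = mf.build_suit028_schedule(h2o2_titration_interval_s=1200.0)
        ama = max(e.time_s for e in sched if e.substance == "Ama")
        last_h2o2 = max(e.time_s for e in sched if e.substance == "H2O2")
        assert ama < last_h2o2 < run_end_time(sched)
        assert run_end_time(sched) <= ama + 330.0

    def test_regime_band_validation(self):
        with pytest.raises(ValueError):
            mf.O2Regime("bad", ceiling_um=30.0, floor_um=40.0)


class TestTraceSimulation:
    def test_zero_flux_gives_constant_concentration(self, flat_flux_truth):
        sched = mf.build_suit028_schedule()
        tr = mf.simulate_respirometry_trace(sched, flat_flux_truth, o2_regime="air")
        o2 = tr.o2_um[clean(tr)]
        assert np.allclose(o2, o2[0])

    def test_flux_to_slope_unit_conversion(self):
        # J_mass = 100 pmol/s/mg, V = 2 mL, m = 2 mg -> slope exactly -0.1 uM/s
        truth = mf.TraceGroundTruth(
            j_o2_mass={"N_L": 100.0, "N_P": 100.0, "NS_P": 100.0, "NS_E": 100.0, "S_E": 100.0},
            j_rox_mass=0.0, j_endogenous_mass=0.0, cytc_effect=0.0,
            uncoupler_profile=(1.0,), seed=0,
        ).noiseless()
        sched = mf.build_suit028_schedule(n_uncoupler_steps=1)
        tr = mf.simulate_respirometry_trace(
            sched, truth, o2_regime="air", chamber_volume_ml=2.0, sample_mass_mg=2.0,
            auto_reoxygenate=False,
        )
        m = (tr.state_label == "N_L")
        dt = np.diff(tr.time_s[m])
        dc = np.diff(tr.o2_um[m])
        assert np.allclose(dc / dt, -0.1)

    def test_fixed_seed_reproduces_trace_exactly(self):
        sched = mf.build_suit028_schedule(pre_sample_titrations=(40.0, 100.0))
        out = []
        for _ in range(2):
            truth = mf.TraceGroundTruth(seed=42)
            tr = mf.simulate_respirometry_trace(sched, truth, o2_regime="normoxic")
            tr = mf.simulate_amr_channel(tr, truth)
            out.append(tr)
        assert np.array_equal(out[0].o2_um, out[1].o2_um)
        assert np.array_equal(out[0].fluo_v, out[1].fluo_v)
        assert out[0].events == out[1].events

    def test_o2_conservation_between_reoxygenations(self, air_trace_noiseless):
        """Total O2 removed between reoxygenations equals the flux integral."""
        tr, truth = air_trace_noiseless
        mass_per_vol = tr.sample_mass_mg / tr.chamber_volume_ml
        reox = [e.time_s for e in tr.events if e.substance == "reoxygenation"]
        assert reox, "air run at default fluxes should need at least one reoxygenation"
        bounds = [tr.time_s[0]] + reox + [tr.time_s[-1]]
        seg_rate = {
            s: (j + (truth.j_rox_mass if s != "pre" else 0.0)) * mass_per_vol / 1000.0
            for s, j in {
                "pre": 0.0, "endogenous": truth.j_endogenous_mass,
                "N_L": truth.j_o2_mass["N_L"], "N_P": truth.j_o2_mass["N_P"],
                "N_P_c": truth.j_o2_mass["N_P"] * (1 + truth.cytc_effect),
                "NS_P": truth.j_o2_mass["NS_P"],
                "NS_E_step1": truth.j_o2_mass["NS_E"] * truth.uncoupler_profile[0],
                "NS_E_step2": truth.j_o2_mass["NS_E"] * truth.uncoupler_profile[1],
                "NS_E_step3": truth.j_o2_mass["NS_E"] * truth.uncoupler_profile[2],
                "S_E": truth.j_o2_mass["S_E"], "ROX": 0.0,
            }.items()
        }
        seg_rate["ROX"] = truth.j_rox_mass * mass_per_vol / 1000.0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            integral = sum(
                seg_rate[s] * (min(hi, t1) - max(lo, t0))
                for s, t0, t1 in tr.segments
                if min(hi, t1) > max(lo, t0)
            )
            # grid samples strictly inside (lo, hi), outside transients
            m = (tr.time_s > lo) & (tr.time_s <= hi) & clean(tr)
            t_first, t_last = tr.time_s[m][0], tr.time_s[m][-1]
            drop = tr.o2_um[m][0] - tr.o2_um[m][-1]
            expected = sum(
                seg_rate[s] * (min(t_last, t1) - max(t_first, t0))
                for s, t0, t1 in tr.segments
                if min(t_last, t1) > max(t_first, t0)
            )
            assert drop == pytest.approx(expected, rel=1e-6, abs=1e-9)
            assert integral >= drop - 1e-6

    def test_overdriven_flux_names_offending_state(self):
        truth = mf.TraceGroundTruth(
            j_o2_mass=dict(mf.TraceGroundTruth().j_o2_mass, NS_P=5000.0)
        ).noiseless()
        sched = mf.build_suit028_schedule()
        with pytest.raises(ValueError, match="NS_P"):
            mf.simulate_respirometry_trace(
                sched, truth, o2_regime="air", auto_reoxygenate=False
            )

    def test_short_plateau_rejected(self):
        sched = mf.build_suit028_schedule(plateau_s=60.0)
        with pytest.raises(ValueError, match=">= 120 s"):
            mf.simulate_respirometry_trace(sched, mf.TraceGroundTruth(), o2_regime="air")

    def test_every_sample_carries_a_state_label(self, air_trace_noiseless):
        tr, _ = air_trace_noiseless
        assert all(lbl for lbl in tr.state_label)

    def test_normoxic_run_stays_inside_regime_band(self):
        truth = mf.TraceGroundTruth(seed=5)
        tr = mf.simulate_respirometry_trace(
            mf.build_suit028_schedule(), truth, o2_regime="normoxic"
        )
        o2 = tr.o2_um[clean(tr)]
        band = mf.NORMOXIC_REGIME
        slack = 4 * truth.o2_noise_um
        assert o2.min() > band.floor_um - slack - 1.0
        assert o2.max() < band.ceiling_um + slack

    def test_csv_round_trip(self, tmp_path, air_trace_noiseless):
        tr, _ = air_trace_noiseless
        tr.to_csv(tmp_path / "t.csv", tmp_path / "e.yaml")
        back = mf.RespirometryTrace.from_csv(
            tmp_path / "t.csv", tmp_path / "e.yaml",
            chamber_volume_ml=tr.chamber_volume_ml, sample_mass_mg=tr.sample_mass_mg,
        )
        assert np.allclose(back.o2_um, tr.o2_um)
        assert back.events == tr.events
        assert list(back.state_label) == list(tr.state_label)


class TestAmrChannelGeneration:
    def test_flat_fluorescence_without_flux_background_or_decay(self, flat_flux_truth):
        truth = flat_flux_truth
        truth.background_slope_v_per_s = 0.0
        truth.sensitivity_decay_per_h = 0.0
        sched = mf.build_suit028_schedule(pre_sample_titrations=(60.0, 140.0))
        tr = mf.simulate_respirometry_trace(sched, truth, o2_regime="normoxic")
        tr = mf.simulate_amr_channel(tr, truth)
        f = tr.fluo_v[clean(tr) & (tr.time_s > 150.0)]
        assert np.allclose(f, f[0])  # flat after the last titration

    def test_step_height_ratio_follows_decay_law(self):
        """10 %/h decay: titrations one hour apart have step ratio 0.9."""
        truth = mf.TraceGroundTruth(
            sensitivity_decay_per_h=0.10, background_slope_v_per_s=0.0, seed=0
        ).noiseless()
        events = [Event(60.0, "H2O2", 0.1, "uM"), Event(3660.0, "H2O2", 0.1, "uM")]
        tr = mf.simulate_respirometry_trace(
            events, truth, o2_regime="air", end_time_s=3800.0
        )
        tr = mf.simulate_amr_channel(tr, truth)

        def step(te):
            before = tr.fluo_v[(tr.time_s >= te - 6) & (tr.time_s < te)].mean()
            after = tr.fluo_v[
                (tr.time_s > te + 12) & (tr.time_s <= te + 18)
            ].mean()
            return after - before

        assert step(3660.0) / step(60.0) == pytest.approx(0.9, abs=1e-3)

    def test_negative_sensitivity_rejected(self):
        with pytest.raises(ValueError, match="sensitivity"):
            mf.TraceGroundTruth(sensitivity_v_per_um=-1.0)
        with pytest.raises(ValueError, match="decay"):
            mf.TraceGroundTruth(sensitivity_decay_per_h=1.5)
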
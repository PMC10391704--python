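"""Synthetic stream generator: forward model, pulses, arrivals, assays."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ampcyt as ac
from ampcyt.synth import (
    PC_DOSE_BACTERIA,
    accumulation_fraction,
    bipolar_pulse,
    freq_key,
)


class TestEventAmplitude:
    def test_volume_scaling(self):
        small = ac.Bead(diameter_um=2.0)
        large = ac.Bead(diameter_um=4.0)
        a1 = ac.event_amplitude(small, 0.5e6)
        a2 = ac.event_amplitude(large, 0.5e6)
        assert abs(a2) == pytest.approx(8 * abs(a1), rel=1e-12)

    def test_bead_phase_nearly_frequency_independent(self):
        phases = [np.angle(ac.event_amplitude(ac.POLYSTYRENE_BEAD, f)) for f in (0.5e6, 11e6, 20e6)]
        assert max(phases) - min(phases) < 0.01

    def test_damaged_rbc_phase_below_healthy_at_high_frequency(self):
        """The L subpopulation sits at lower bead-referenced phase than H."""
        for f in (11e6, 20e6):
            bead = ac.event_amplitude(ac.POLYSTYRENE_BEAD, f)
            a_h = ac.event_amplitude(ac.RBC_HEALTHY, f)
            a_l = ac.event_amplitude(ac.RBC_DAMAGED, f)
            ph_h = np.angle(a_h / bead)
            ph_l = np.angle(a_l / bead)
            assert ph_l < ph_h < 0

    def test_dead_bacterium_phase_closer_to_bead_reference(self):
        for f in (11e6, 20e6):
            bead = ac.event_amplitude(ac.POLYSTYRENE_BEAD, f)
            live = np.angle(ac.event_amplitude(ac.BACTERIUM_LIVE, f) / bead)
            dead = np.angle(ac.event_amplitude(ac.BACTERIUM_DEAD, f) / bead)
            assert abs(dead) < abs(live)

    def test_accepts_population_spec(self):
        pop = ac.PopulationSpec("bead", ac.POLYSTYRENE_BEAD, 1e5)
        assert ac.event_amplitude(pop, 0.5e6) == ac.event_amplitude(ac.POLYSTYRENE_BEAD, 0.5e6)


class TestBipolarPulse:
    def test_zero_amplitude_gives_zero_waveform(self, acq):
        w = bipolar_pulse(0j, 5e-3, acq.mean_velocity, acq, 10e-3)
        assert not np.any(w)

    def test_antisymmetric_lobes_sum_to_zero(self, acq):
        w = bipolar_pulse(3 - 4j, 5e-3, acq.mean_velocity, acq, 10e-3)
        assert abs(w.sum()) < 1e-6 * np.abs(w).sum()

    def test_peak_magnitude_matches_amplitude(self, acq):
        amp = 7.5 * np.exp(1j * 1.1)
        w = bipolar_pulse(amp, 5e-3, acq.mean_velocity, acq, 10e-3)
        # the opposite lobe depresses the peak by exp(-sep^2 / (2 sigma^2));
        # on top of that the sample grid may miss the exact lobe maximum
        overlap = np.exp(-0.5 * (acq.lobe_separation_s / acq.lobe_sigma_s) ** 2)
        expected = abs(amp) * (1.0 - overlap)
        assert np.abs(w).max() == pytest.approx(expected, rel=0.01)

    def test_lobe_separation_matches_kinematics(self, acq):
        # hand calculation: v = Q/A = (10 uL/min) / (40x20 um^2) ~ 0.2083 m/s;
        # separation = 40 um / v ~ 0.192 ms
        v = (10e-9 / 60) / (40e-6 * 20e-6)
        assert acq.mean_velocity == pytest.approx(v, rel=1e-12)
        expected_sep = 40e-6 / v
        assert acq.lobe_separation_s == pytest.approx(expected_sep, rel=1e-12)
        assert expected_sep == pytest.approx(1.92e-4, rel=1e-2)
        w = bipolar_pulse(1.0 + 0j, 5e-3, acq.mean_velocity, acq, 10e-3)
        t = np.arange(len(w)) / acq.sampling_rate
        t_pos = t[np.argmax(w.real)]
        t_neg = t[np.argmin(w.real)]
        assert t_neg - t_pos == pytest.approx(expected_sep, abs=2 / acq.sampling_rate)

    def test_nonpositive_velocity_rejected(self, acq):
        with pytest.raises(ac.InvalidArgumentError):
            bipolar_pulse(1 + 0j, 5e-3, 0.0, acq, 10e-3)


class TestDoseFractions:
    def test_zero_dose_gives_zero_fractions(self):
        assert ac.dose_population_fractions(0.0, ac.DoseModel()) == (0.0, 0.0)

    def test_half_effect_at_k(self):
        model = ac.DoseModel()
        dead, _ = ac.dose_population_fractions(model.k_kill_um, model)
        _, lysed = ac.dose_population_fractions(model.k_lysis_um, model)
        assert dead == pytest.approx(0.5, rel=1e-12)
        assert lysed == pytest.approx(0.5, rel=1e-12)

    def test_saturation(self):
        dead, lysed = ac.dose_population_fractions(np.inf, ac.DoseModel())
        assert (dead, lysed) == (1.0, 1.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ac.InvalidArgumentError):
            ac.dose_population_fractions(-0.1, ac.DoseModel())

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=10))
    def test_hill_fractions_monotone_in_dose(self, doses):
        model = ac.DoseModel()
        doses = sorted(doses)
        fracs = [ac.dose_population_fractions(d, model) for d in doses]
        for (d1, l1), (d2, l2) in zip(fracs, fracs[1:]):
            assert d2 >= d1 and l2 >= l1

    def test_accumulation_fraction_disabled_and_monotone(self):
        off = ac.DoseModel(accumulation_slope=0.0)
        assert accumulation_fraction(0.5, off) == 1.0
        on = ac.DoseModel(accumulation_slope=0.25)
        doses = [0.01, 0.034, 0.1, 0.5, 2.0]
        s = [accumulation_fraction(d, on) for d in doses]
        assert s == sorted(s)
        assert accumulation_fraction(on.k_kill_um, on) == pytest.approx(0.5)


class TestGenerateStream:
    def test_zero_concentration_gives_no_events(self, acq):
        pops = [ac.PopulationSpec("bead", ac.POLYSTYRENE_BEAD, 0.0)]
        stream = ac.generate_stream(pops, 0.0, ac.DoseModel(), acq, 1.0, seed=0)
        assert len(stream.ground_truth) == 0

    def test_same_seed_reproduces_bit_identical_bundle(self, acq):
        pops = ac.default_populations()
        s1 = ac.generate_stream(pops, 0.1, ac.DoseModel(), acq, 0.5, seed=11)
        s2 = ac.generate_stream(pops, 0.1, ac.DoseModel(), acq, 0.5, seed=11)
        for f in s1.frequencies:
            assert np.array_equal(s1.data[f], s2.data[f])
        pd.testing.assert_frame_equal(s1.ground_truth, s2.ground_truth)

    def test_event_rate_matches_concentration_times_flow(self, acq):
        # 9e5 particles/mL x 10 uL/min = 150 events/s
        pops = ac.default_populations()
        expected_rate = sum(p.concentration_per_ml for p in pops) * 10e-3 / 60
        assert expected_rate == pytest.approx(150.0)
        total, expected = 0, 0.0
        for seed in range(10):
            stream = ac.generate_stream(pops, 0.0, ac.DoseModel(), acq, 1.0, seed=seed)
            total += len(stream.ground_truth)
            expected += expected_rate
        assert abs(total - expected) < 3 * np.sqrt(expected)

    def test_empty_population_list_rejected(self, acq):
        with pytest.raises(ac.InvalidArgumentError):
            ac.generate_stream([], 0.0, ac.DoseModel(), acq, 1.0, seed=0)

    def test_channels_equal_length_and_times_in_range(self, mixed_stream):
        n = {len(v) for v in mixed_stream.data.values()}
        assert len(n) == 1
        gt = mixed_stream.ground_truth
        assert (gt["arrival_time"] >= 0).all()
        assert (gt["arrival_time"] <= mixed_stream.duration).all()

    def test_dose_shifts_labels(self, acq):
        pops = ac.default_populations()
        stream = ac.generate_stream(pops, 100.0, ac.DoseModel(), acq, 1.0, seed=3)
        labels = set(stream.ground_truth["label"])
        assert "bacterium_dead" in labels and "rbc_L" in labels
        assert "bacterium_live" not in labels and "rbc_H" not in labels

    def test_save_load_roundtrip(self, acq, tmp_path):
        pops = ac.default_populations()
        stream = ac.generate_stream(pops, 0.0, ac.DoseModel(), acq, 0.3, seed=5)
        stream.save(tmp_path / "sample")
        back = ac.StreamBundle.load(tmp_path / "sample", acq)
        for f in stream.frequencies:
            assert np.array_equal(stream.data[f], back.data[f])
        assert len(back.ground_truth) == len(stream.ground_truth)


class TestReferenceAssays:
    def test_controls_anchor_the_assay(self):
        table = ac.generate_reference_assays(
            ac.DEFAULT_DOSE_GRID, ac.DoseModel(), cfu_nc=100000, seed=1
        )
        nc = table[table["role"] == "NC"].iloc[0]
        pc = table[table["role"] == "PC"].iloc[0]
        assert nc["cfu"] == pytest.approx(100000, abs=3 * np.sqrt(100000))
        assert nc["absorbance"] == pytest.approx(0.05, abs=0.05)
        # PC: saturating peptide -> survival ~ (K/2)^n tail, near-total kill
        assert pc["cfu"] < 0.01 * 100000
        assert pc["absorbance"] == pytest.approx(1.0, abs=0.05)

    def test_killing_curve_passes_half_at_k_kill(self):
        """With the default kill parameters the generated CFU curve crosses
        50% survival at K = 0.034 uM."""
        model = ac.DoseModel()
        table = ac.generate_reference_assays(
            [model.k_kill_um], model, cfu_nc=100000, seed=2
        )
        at_k = table[table["role"] == "dose"].iloc[0]
        assert at_k["cfu"] == pytest.approx(50000, abs=4 * np.sqrt(50000))

    def test_invalid_cfu_nc_rejected(self):
        with pytest.raises(ac.InvalidArgumentError):
            ac.generate_reference_assays([0.1], ac.DoseModel(), cfu_nc=0, seed=0)
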
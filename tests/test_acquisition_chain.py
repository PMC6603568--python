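"""Differential loading, interference conversion, noise, ADC, bench staging."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegbench.acquisition_chain import (
    OPENBCI,
    AmplifierSpec,
    ChannelConfig,
    InterferenceSpec,
    Stage,
    adc_quantize,
    add_amplifier_noise,
    apply_interference,
    attenuation_percent,
    differential_input_voltage,
    run_bench,
    simulate_channel,
)
from eegbench.electrode_models import ElectrodeModel, get_preset
from eegbench.errors import ConfigError, ParameterError
from eegbench.quality_metrics import pearson_r, snr_db, zscore_rescale
from eegbench.synthetic_eeg import EEGEpoch, scale_to_microvolt


def constant_electrode(re_ohm: float) -> ElectrodeModel:
    return ElectrodeModel(
        freqs=np.array([31.0]),
        re_table=np.array([re_ohm]),
        ce_table=np.array([1e-6]),
        extrapolate=True,
    )


class TestDifferentialLoading:
    def test_matched_5k_gain(self):
        v1, v2 = 1.0, -1.0
        out = differential_input_voltage(v1, v2, 5e3, 5e3, 1e9)
        assert out == pytest.approx((v1 - v2) * 0.999995, rel=1e-15)

    def test_matched_100k_gain(self):
        out = differential_input_voltage(2.0, 0.5, 100e3, 100e3, 1e9)
        assert out == pytest.approx(1.5 * 0.9999, rel=1e-15)

    def test_zero_impedance_ideal_source(self):
        v = np.linspace(-1, 1, 11)
        out = differential_input_voltage(v, -v, 0.0, 0.0, 1e9)
        assert np.allclose(out, 2 * v, rtol=0, atol=0)

    def test_common_mode_conversion_by_mismatch(self):
        c = 0.7
        out = differential_input_voltage(c, c, 5e3, 100e3, 1e9)
        assert out == pytest.approx(c * (5e3 - 100e3) / 1e9, rel=1e-12)
        assert out == pytest.approx(-9.5e-5 * c, rel=1e-12)

    def test_nonpositive_zin_rejected(self):
        with pytest.raises(ParameterError):
            differential_input_voltage(1.0, 0.0, 1.0, 1.0, 0.0)

    @given(
        a=st.floats(-2, 2),
        b=st.floats(-2, 2),
        lam=st.floats(-3, 3),
    )
    @settings(derandomize=True, max_examples=40)
    def test_linearity_in_inputs(self, a, b, lam):
        z1, z2, zin = 7e3, 90e3, 1e9
        lhs = differential_input_voltage(lam * a, lam * b, z1, z2, zin)
        rhs = lam * differential_input_voltage(a, b, z1, z2, zin)
        assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-15)

    @given(c=st.floats(-5, 5), z=st.floats(0, 1e6), zin=st.floats(1e3, 1e12))
    @settings(derandomize=True, max_examples=40)
    def test_zero_mismatch_nulls_common_mode(self, c, z, zin):
        # pure common-mode input with matched impedances leaves no residue
        # beyond the (zero) differential term
        assert differential_input_voltage(c, c, z, z, zin) == pytest.approx(
            0.0, abs=1e-12 * max(1.0, abs(c))
        )


class TestAttenuation:
    def test_worked_examples(self):
        assert attenuation_percent(5e3, 5e3, 1e9) == pytest.approx(0.0005, rel=1e-15)
        assert attenuation_percent(100e3, 100e3, 1e9) == pytest.approx(0.01, rel=1e-15)
        assert attenuation_percent(0.0, 0.0, 1e9) == 0.0


class TestInterference:
    def test_balanced_infinite_cmrr_identity(self, short_epoch):
        cfg = ChannelConfig(Stage.RESISTOR, source_resistance=5e3)
        amp = AmplifierSpec(cmrr_db=math.inf)
        out = apply_interference(short_epoch, cfg, amp, InterferenceSpec(cm_amp_v=0.01))
        assert np.array_equal(out.samples, short_epoch.samples)

    def test_zero_amplitude_identity(self, short_epoch):
        cfg = ChannelConfig(
            Stage.GTEC_F, electrode=constant_electrode(198.2e3)
        )
        out = apply_interference(short_epoch, cfg, OPENBCI, InterferenceSpec(cm_amp_v=0.0))
        assert np.array_equal(out.samples, short_epoch.samples)

    def test_mismatch_converted_amplitude(self):
        # 10 mV common mode, z1 = 198.2k + 50, z2 = 5k, ZIN = 1G
        e = EEGEpoch(np.zeros(7500), 250.0)
        cfg = ChannelConfig(
            Stage.GTEC_F,
            electrode=constant_electrode(198.2e3),
            source_resistance=0.0,
        )
        amp = AmplifierSpec(cmrr_db=math.inf)
        out = apply_interference(e, cfg, amp, InterferenceSpec(cm_amp_v=0.01))
        expected = 0.01 * abs(198.2e3 - 5e3) / 1e9
        from eegbench.quality_metrics import powerline_amplitude

        assert powerline_amplitude(out, 50.0) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1.932e-6, rel=1e-3)


class TestNoise:
    def test_zero_noise_identity(self, short_epoch):
        out = add_amplifier_noise(short_epoch, AmplifierSpec(noise_uvpp=0.0), 1)
        assert np.array_equal(out.samples, short_epoch.samples)

    def test_peak_to_peak_sigma_convention(self):
        e = EEGEpoch(np.zeros(10**6), 250.0)
        out = add_amplifier_noise(e, AmplifierSpec(noise_uvpp=1.0), 123)
        assert np.std(out.samples) == pytest.approx(1e-6 / 6.6, rel=0.01)

    def test_seed_reproducible(self, short_epoch):
        a = add_amplifier_noise(short_epoch, OPENBCI, 9)
        b = add_amplifier_noise(short_epoch, OPENBCI, 9)
        assert np.array_equal(a.samples, b.samples)


class TestADC:
    def test_step_size_and_roundtrip_error(self, short_epoch):
        amp = AmplifierSpec(resolution_bits=24, full_scale_v=0.187)
        step = 2 * 0.187 / 2**24
        assert step == pytest.approx(2.23e-8, rel=0.01)
        out = adc_quantize(short_epoch, amp)
        assert np.max(np.abs(out.samples - short_epoch.samples)) <= step / 2 + 1e-18

    def test_on_level_sample_unchanged(self):
        amp = AmplifierSpec(resolution_bits=16, full_scale_v=1.0)
        step = 2.0 / 2**16
        e = EEGEpoch(np.array([0.0, step, -5 * step, 100 * step]), 250.0)
        out = adc_quantize(e, amp)
        assert np.array_equal(out.samples, e.samples)

    def test_fewer_bits_lower_snr(self, short_epoch):
        hi = adc_quantize(short_epoch, AmplifierSpec(resolution_bits=24, full_scale_v=0.187))
        lo = adc_quantize(short_epoch, AmplifierSpec(resolution_bits=12, full_scale_v=0.187))
        x = short_epoch.samples
        assert snr_db(x, lo.samples) < snr_db(x, hi.samples)

    def test_clipping_warns(self):
        e = EEGEpoch(np.array([0.0, 0.5, 2.0]), 250.0)
        with pytest.warns(UserWarning, match="clipped"):
            out = adc_quantize(e, AmplifierSpec(full_scale_v=1.0))
        assert out.peak_v <= 1.0


class TestSimulateChannel:
    def test_transparent_chain(self, reference_epochs):
        src = scale_to_microvolt(reference_epochs[0])
        cfg = ChannelConfig(Stage.WET_F, electrode=constant_electrode(8.1e3))
        amp = AmplifierSpec(
            zin_ohm=1e15,
            cmrr_db=math.inf,
            noise_uvpp=0.0,
            resolution_bits=32,
            full_scale_v=1.0,
        )
        out = simulate_channel(src, cfg, amp, InterferenceSpec(cm_amp_v=0.0), seed=0)
        assert pearson_r(src.samples, out.samples) > 0.999999

    def test_balanced_stages_differ_only_by_gain(self, short_epoch):
        intf = InterferenceSpec(cm_amp_v=0.0)
        amp = AmplifierSpec(noise_uvpp=0.0, resolution_bits=24, full_scale_v=0.187)
        a = simulate_channel(
            short_epoch, ChannelConfig(Stage.RESISTOR, source_resistance=1e3), amp, intf
        )
        b = simulate_channel(
            short_epoch, ChannelConfig(Stage.CLOTH, source_resistance=1e6), amp, intf
        )
        ga = 1 - 2 * 1e3 / (2 * amp.zin_ohm)
        gb = 1 - 2 * 1e6 / (2 * amp.zin_ohm)
        # up to quantization (one step each way), the outputs are the same
        # signal scaled
        step = 2 * amp.full_scale_v / 2**amp.resolution_bits
        assert np.allclose(a.samples / ga, b.samples / gb, atol=1.1 * step)

    def test_wet_beats_gtec_unfiltered_snr(self, short_epoch):
        intf = InterferenceSpec(cm_amp_v=0.01)
        outs = {}
        for name, re_ohm in [("wet", 8.1e3), ("gtec", 198.2e3)]:
            stage = Stage.WET_F if name == "wet" else Stage.GTEC_F
            cfg = ChannelConfig(stage, electrode=constant_electrode(re_ohm))
            rec = simulate_channel(short_epoch, cfg, OPENBCI, intf, seed=5)
            outs[name] = snr_db(
                short_epoch.samples, zscore_rescale(rec.samples, short_epoch.samples)
            )
        assert outs["wet"] > outs["gtec"]


class TestChannelConfig:
    def test_electrode_required_for_electrode_stage(self):
        with pytest.raises(ConfigError):
            ChannelConfig(Stage.MICRO_O)

    def test_electrode_forbidden_for_passive_stage(self):
        with pytest.raises(ConfigError):
            ChannelConfig(Stage.RESISTOR, electrode=constant_electrode(1e4))

    def test_source_impedances_include_cloth(self):
        cfg = ChannelConfig(Stage.WET_F, electrode=constant_electrode(8.1e3))
        z1, z2 = cfg.source_impedances(31.0, cloth_ohm=2.0)
        assert z1 == pytest.approx(8.1e3 + 50.0 + 2.0)
        assert z2 == 5e3


class TestRunBench:
    def test_nine_by_fifteen_recordings(self, bench_run):
        _, recordings, _ = bench_run
        assert len(recordings) == 9
        assert all(len(v) == 15 for v in recordings.values())

    def test_empty_epoch_list_rejected(self):
        with pytest.raises(ParameterError):
            run_bench([])

    def test_seed_reproducibility(self, reference_epochs):
        a = run_bench(reference_epochs[:2], seed=3)
        b = run_bench(reference_epochs[:2], seed=3)
        for stage in a:
            for ea, eb in zip(a[stage], b[stage]):
                assert np.array_equal(ea.samples, eb.samples)

    def test_missing_electrode_model_rejected(self):
        from eegbench.acquisition_chain import default_stages
        from eegbench.electrode_models import preset_models

        models = preset_models()
        models.pop("wet_frontal")
        with pytest.raises(ConfigError):
            default_stages(models)
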
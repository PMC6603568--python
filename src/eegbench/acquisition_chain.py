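"""Electrode-to-digital signal path of the simulated acquisition bench.

A differential amplifier with finite input impedance ``ZIN`` loads the two
source impedances ``Z1``/``Z2`` feeding its inputs.  The received
differential voltage is

    VA - VB = (V1 - V2)/2 * (2 - (Z1 + Z2)/ZIN)
            + (V1 + V2)/2 * (Z1 - Z2)/ZIN

The first term is a small differential-gain loss; the second converts
common-mode voltage (mains pickup, DC bias) into a spurious differential
signal whenever the source impedances are mismatched — the dominant quality
loss for high-impedance dry electrodes.  On top of this the chain models
intrinsic common-mode leakage through finite CMRR, input-referred amplifier
noise, and ADC sampling/quantization.

Source impedances are taken as the real interface resistance ``Re`` (the
in-band low-frequency approximation of the skin-electrode circuit),
evaluated at the 31 Hz impedance-check frequency for signal loading and at
the interference frequency for common-mode conversion.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .electrode_models import ElectrodeModel, preset_models
from .errors import ConfigError, ParameterError
from .synthetic_eeg import (
    CLOTH_RESISTANCE_KEY,
    EEGEpoch,
    cloth_stage,
    scale_to_microvolt,
)

__all__ = [
    "AmplifierSpec",
    "InterferenceSpec",
    "ChannelConfig",
    "Stage",
    "OPENBCI",
    "SCOPE_RECORDER",
    "differential_input_voltage",
    "attenuation_percent",
    "apply_interference",
    "add_amplifier_noise",
    "adc_quantize",
    "simulate_channel",
    "run_bench",
    "default_stages",
]

IN_BAND_CHECK_HZ = 31.0


class Stage(str, Enum):
    """The nine recording stages of the bench."""

    GENERATOR = "generator"
    RESISTOR = "resistor"
    CLOTH = "cloth"
    WET_F = "wet_frontal"
    WET_O = "wet_occipital"
    GTEC_F = "gtec_frontal"
    GTEC_O = "gtec_occipital"
    MICRO_F = "micro_frontal"
    MICRO_O = "micro_occipital"


ELECTRODE_STAGES = (
    Stage.WET_F,
    Stage.WET_O,
    Stage.GTEC_F,
    Stage.GTEC_O,
    Stage.MICRO_F,
    Stage.MICRO_O,
)


@dataclass
class AmplifierSpec:
    """Differential acquisition front-end contract."""

    zin_ohm: float = 1e9
    cmrr_db: float = 120.0
    noise_uvpp: float = 1.0  # input-referred, peak-to-peak
    fs: float = 250.0
    resolution_bits: int = 24
    full_scale_v: float = 0.187

    def __post_init__(self) -> None:
        if self.zin_ohm <= 0 or self.fs <= 0 or self.full_scale_v <= 0:
            raise ParameterError("ZIN, fs and full scale must be positive")
        if self.resolution_bits < 12:
            raise ParameterError("resolution must be >= 12 bits")
        if self.noise_uvpp < 0:
            raise ParameterError("noise must be >= 0")

    def to_dict(self) -> dict:
        return {
            "zin_ohm": self.zin_ohm,
            "cmrr_db": self.cmrr_db,
            "noise_uvpp": self.noise_uvpp,
            "fs": self.fs,
            "resolution_bits": self.resolution_bits,
            "full_scale_v": self.full_scale_v,
        }


#: low-cost wireless EEG board front end (1 GOhm input impedance, 120 dB
#: CMRR, 1 uVpp noise, 24-bit ADC at 250 Hz)
OPENBCI = AmplifierSpec()

#: wide-range recorder used for the +/-0.5 V waveform-generator stage, which
#: would clip the EEG board's ADC range
SCOPE_RECORDER = AmplifierSpec(
    zin_ohm=1e6,
    cmrr_db=100.0,
    noise_uvpp=50.0,
    fs=250.0,
    resolution_bits=16,
    full_scale_v=1.0,
)


@dataclass
class InterferenceSpec:
    """Common-mode mains interference present at both amplifier inputs."""

    cm_amp_v: float = 0.01
    cm_freq: float = 50.0
    cm_phase: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cm_amp_v < 0:
            raise ParameterError("common-mode amplitude must be >= 0")
        if self.cm_freq <= 0:
            raise ParameterError("common-mode frequency must be positive")

    def to_dict(self) -> dict:
        return {
            "cm_amp_v": self.cm_amp_v,
            "cm_freq": self.cm_freq,
            "cm_phase": self.cm_phase,
            "seed": self.seed,
        }


@dataclass
class ChannelConfig:
    """One recording stage: which electrode model (if any) feeds the input.

    ``source_resistance`` is the non-electrode series source resistance
    (waveform generator output, divider output, conductive cloth).
    ``reference_impedance_ohm`` is the impedance of the shared reference
    path; the bench default is a 5 kOhm prepared wet reference.
    """

    stage: Stage
    electrode: ElectrodeModel | None = None
    source_resistance: float = 50.0
    reference_impedance_ohm: float = 5e3

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        is_electrode = self.stage in ELECTRODE_STAGES
        if is_electrode and self.electrode is None:
            raise ConfigError(f"stage {self.stage.value} requires an electrode model")
        if not is_electrode and self.electrode is not None:
            raise ConfigError(
                f"stage {self.stage.value} must not carry an electrode model"
            )
        if self.source_resistance < 0:
            raise ParameterError("source resistance must be >= 0")

    def source_impedances(self, f: float, cloth_ohm: float = 0.0) -> tuple[float, float]:
        """(z1, z2) seen by the amplifier at frequency ``f``.

        Electrode stages: z1 = electrode Re(f) + series source resistance
        (+ cloth); non-electrode stages: both inputs see the source
        resistance (balanced).
        """
        if self.electrode is not None:
            z1 = self.electrode.re_at(f) + self.source_resistance + cloth_ohm
            return z1, self.reference_impedance_ohm
        return self.source_resistance, self.source_resistance


def differential_input_voltage(v1, v2, z1: float, z2: float, zin: float):
    """Voltage received at the amplifier inputs under source loading.

    Applies sample-wise when ``v1``/``v2`` are arrays.
    """
    if zin <= 0:
        raise ParameterError("input impedance must be positive")
    if z1 < 0 or z2 < 0:
        raise ParameterError("source impedances must be >= 0")
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    out = ((v1 - v2) / 2.0) * (2.0 - (z1 + z2) / zin) + ((v1 + v2) / 2.0) * (
        (z1 - z2) / zin
    )
    return out if out.ndim else float(out)


def attenuation_percent(z1: float, z2: float, zin: float) -> float:
    """Differential-gain loss of the loading formula, in percent.

    ``100 * (z1 + z2) / (2 * zin)`` — e.g. 0.0005% for two matched 5 kOhm
    sources into a 1 GOhm input.
    """
    if zin <= 0:
        raise ParameterError("input impedance must be positive")
    if z1 < 0 or z2 < 0:
        raise ParameterError("source impedances must be >= 0")
    return 100.0 * (z1 + z2) / (2.0 * zin)


def differential_gain(z1: float, z2: float, zin: float) -> float:
    """Scalar multiplying (V1 - V2) under matched-source loading."""
    return 1.0 - attenuation_percent(z1, z2, zin) / 100.0


def apply_interference(
    epoch: EEGEpoch,
    cfg: ChannelConfig,
    amp: AmplifierSpec,
    intf: InterferenceSpec,
) -> EEGEpoch:
    """Add the differential residue of common-mode mains interference.

    Two leakage paths: impedance-mismatch conversion
    (``cm_amp * |z1 - z2| / ZIN``) and intrinsic finite-CMRR leakage
    (``cm_amp * 10^(-CMRR/20)``).
    """
    if intf.cm_freq >= epoch.fs / 2:
        raise ParameterError("interference frequency must be below Nyquist")
    if intf.cm_amp_v == 0:
        return epoch.with_samples(epoch.samples)
    cloth = float(epoch.metadata.get(CLOTH_RESISTANCE_KEY, 0.0))
    z1, z2 = cfg.source_impedances(intf.cm_freq, cloth_ohm=cloth)
    mismatch_amp = intf.cm_amp_v * abs(z1 - z2) / amp.zin_ohm
    leakage_amp = (
        intf.cm_amp_v * 10.0 ** (-amp.cmrr_db / 20.0)
        if math.isfinite(amp.cmrr_db)
        else 0.0
    )
    amp_50 = mismatch_amp + leakage_amp
    if amp_50 == 0:
        return epoch.with_samples(epoch.samples)
    t = np.arange(epoch.n_samples) / epoch.fs
    y = epoch.samples + amp_50 * np.sin(2 * np.pi * intf.cm_freq * t + intf.cm_phase)
    return epoch.with_samples(y)


def add_amplifier_noise(
    epoch: EEGEpoch, amp: AmplifierSpec, seed: int | np.random.SeedSequence | None = 0
) -> EEGEpoch:
    """Add input-referred Gaussian amplifier noise.

    The peak-to-peak rating maps to a standard deviation via the 6.6 sigma
    convention (99.9% of samples within the stated peak-to-peak range).
    """
    if amp.noise_uvpp == 0:
        return epoch.with_samples(epoch.samples)
    sigma = amp.noise_uvpp * 1e-6 / 6.6
    rng = np.random.default_rng(seed)
    return epoch.with_samples(epoch.samples + rng.normal(0.0, sigma, epoch.n_samples))


def adc_quantize(epoch: EEGEpoch, amp: AmplifierSpec) -> EEGEpoch:
    """Mid-tread uniform quantization over +/- full scale, with resampling.

    Samples beyond full scale are clipped with a warning.  If the epoch
    sampling rate differs from the converter rate the signal is resampled
    first (polyphase).
    """
    out = epoch
    if out.fs != amp.fs:
        from scipy.signal import resample_poly

        frac = Fraction(amp.fs / out.fs).limit_denominator(1000)
        out = out.with_samples(
            resample_poly(out.samples, frac.numerator, frac.denominator), fs=amp.fs
        )
    x = out.samples
    if np.any(np.abs(x) > amp.full_scale_v):
        warnings.warn(
            f"{int(np.sum(np.abs(x) > amp.full_scale_v))} samples exceed the "
            f"+/-{amp.full_scale_v} V full scale and were clipped",
            stacklevel=2,
        )
        x = np.clip(x, -amp.full_scale_v, amp.full_scale_v)
    step = 2.0 * amp.full_scale_v / 2.0**amp.resolution_bits
    return out.with_samples(np.round(x / step) * step)


def simulate_channel(
    source: EEGEpoch,
    cfg: ChannelConfig,
    amp: AmplifierSpec = OPENBCI,
    intf: InterferenceSpec = InterferenceSpec(),
    seed: int | np.random.SeedSequence | None = 0,
) -> EEGEpoch:
    """Propagate one epoch through loading, interference, noise and ADC.

    The source is treated as a symmetric differential signal (+s/2, -s/2),
    so the loading step reduces to the differential gain factor; a DC
    half-cell offset (electrode ``Ehc``) is added before the amplifier.
    """
    cloth = float(source.metadata.get(CLOTH_RESISTANCE_KEY, 0.0))
    z1, z2 = cfg.source_impedances(IN_BAND_CHECK_HZ, cloth_ohm=cloth)
    s = source.samples
    if cfg.electrode is not None and cfg.electrode.ehc:
        s = s + cfg.electrode.ehc
    loaded = differential_input_voltage(s / 2.0, -s / 2.0, z1, z2, amp.zin_ohm)
    out = source.with_samples(loaded, label=cfg.stage.value)
    out = apply_interference(out, cfg, amp, intf)
    out = add_amplifier_noise(out, amp, seed)
    out = adc_quantize(out, amp)
    return out


def default_stages(
    electrodes: Mapping[str, ElectrodeModel] | None = None,
    *,
    generator_resistance: float = 50.0,
    divider_resistance: float = 50.0,
    reference_impedance_ohm: float = 5e3,
) -> list[ChannelConfig]:
    """The nine bench stages with the measured electrode presets."""
    if electrodes is None:
        electrodes = preset_models()
    stages = [
        ChannelConfig(Stage.GENERATOR, source_resistance=generator_resistance),
        ChannelConfig(Stage.RESISTOR, source_resistance=divider_resistance),
        ChannelConfig(Stage.CLOTH, source_resistance=divider_resistance),
    ]
    for st in ELECTRODE_STAGES:
        if st.value not in electrodes:
            raise ConfigError(f"missing electrode model for stage {st.value}")
        stages.append(
            ChannelConfig(
                st,
                electrode=electrodes[st.value],
                source_resistance=divider_resistance,
                reference_impedance_ohm=reference_impedance_ohm,
            )
        )
    return stages


def run_bench(
    epochs: Sequence[EEGEpoch],
    stages: Sequence[ChannelConfig] | None = None,
    amp: AmplifierSpec = OPENBCI,
    intf: InterferenceSpec = InterferenceSpec(),
    *,
    scope_amp: AmplifierSpec = SCOPE_RECORDER,
    divider_ratio: float = 5000.0,
    cloth_resistance_ohm: float = 2.0,
    seed: int = 0,
) -> dict[str, list[EEGEpoch]]:
    """Simulate every bench stage for every epoch.

    Stage handling mirrors the physical bench: the waveform-generator output
    (+/-0.5 V) is captured by a wide-range recorder; all later stages first
    pass through the resistor divider back to the +/-100 uV EEG range; the
    cloth and electrode stages additionally carry the conductive-cloth
    series resistance.  Returns ``{stage label: [epoch, ...]}`` with one
    recording per input epoch, deterministic in ``seed``.
    """
    epochs = list(epochs)
    if not epochs:
        raise ParameterError("need at least one epoch")
    if stages is None:
        stages = default_stages()
    labels = [cfg.stage.value for cfg in stages]
    if len(set(labels)) != len(labels):
        raise ConfigError("stage labels must be unique")
    out: dict[str, list[EEGEpoch]] = {lab: [] for lab in labels}
    for si, cfg in enumerate(stages):
        stage_amp = scope_amp if cfg.stage is Stage.GENERATOR else amp
        for ei, epoch in enumerate(epochs):
            if cfg.stage is Stage.GENERATOR:
                src = epoch
            else:
                src = scale_to_microvolt(epoch, divider_ratio)
                if cfg.stage is not Stage.RESISTOR:
                    src = cloth_stage(src, cloth_resistance_ohm)
            rec = simulate_channel(
                src,
                cfg,
                stage_amp,
                intf,
                seed=np.random.SeedSequence([seed, si, ei]),
            )
            rec.epoch_index = ei
            out[cfg.stage.value].append(rec)
    return out
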
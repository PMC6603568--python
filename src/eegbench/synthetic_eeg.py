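"""Synthetic neonatal EEG generation, preprocessing stages, and signal I/O.

This module emulates the preprocessed clinical recordings that feed the
simulated acquisition bench: 30-second epochs sampled at 250 Hz, band-limited
to 0.5-100 Hz, peak-normalised to +/-0.5 V (the waveform-generator playback
scale), later divided back down to the physiological +/-100 uV range.

Neonatal background EEG is low-frequency dominant; the generator therefore
synthesises a 1/f ("pink") random background directly in the frequency domain,
which makes the band limits exact.  "Non-healthy" epochs additionally carry a
slow rhythmic discharge (0.5-3 Hz), the dominant morphology of neonatal
seizures.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

__all__ = [
    "EEGEpoch",
    "GeneratorParams",
    "generate_epochs",
    "preprocess_database_epoch",
    "scale_to_microvolt",
    "cloth_stage",
    "read_signals",
    "write_signals",
]

#: metadata key under which the conductive-cloth series resistance is recorded
CLOTH_RESISTANCE_KEY = "cloth_resistance_ohm"

_SPECTRAL_PROFILES = ("pink", "white", "mixed")


@dataclass
class EEGEpoch:
    """A uniformly sampled voltage time series.

    Parameters
    ----------
    samples
        Voltage samples in volts.
    fs
        Sampling rate in Hz (> 0).
    label
        Stage/channel identifier (e.g. ``"generator"``, ``"gtec_frontal"``).
    epoch_index
        Position of this epoch within its batch.
    seed
        Seed used to generate the epoch, if any.
    metadata
        Free-form annotations carried through the processing chain.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    epoch_index: int = 0
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ParameterError("epoch samples must be one-dimensional")
        if not self.fs > 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ParameterError("epoch samples must be finite")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def peak_v(self) -> float:
        """Largest absolute sample value, in volts."""
        return float(np.max(np.abs(self.samples))) if self.n_samples else 0.0

    def with_samples(self, samples: np.ndarray, **changes) -> "EEGEpoch":
        """Copy of this epoch with new samples (metadata is deep-copied)."""
        out = replace(self, samples=np.asarray(samples, dtype=float), **changes)
        out.metadata = dict(self.metadata)
        return out


@dataclass
class GeneratorParams:
    """Parameters of the synthetic neonatal EEG generator.

    Defaults reproduce the bench's reference conditions: 15 epochs of 30 s
    at 250 Hz, band-limited 0.5-100 Hz, peak-normalised to +/-0.5 V.
    """

    n_epochs: int = 15
    duration_s: float = 30.0
    fs: float = 250.0
    band: tuple[float, float] = (0.5, 100.0)
    amplitude_v: float = 0.5
    spectral_profile: str = "pink"
    #: fraction of epochs carrying a rhythmic 0.5-3 Hz discharge
    seizure_fraction: float = 0.4
    #: residual 50 Hz mains amplitude (V); the source database is notch
    #: filtered, so the default is zero
    powerline_amp_v: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        low, high = self.band
        if not (0 < low < high < self.fs / 2):
            raise ParameterError(
                f"band must satisfy 0 < low < high < fs/2, got {self.band} at fs={self.fs}"
            )
        if self.n_epochs < 1:
            raise ParameterError("n_epochs must be >= 1")
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if not 0 <= self.seizure_fraction <= 1:
            raise ParameterError("seizure_fraction must lie in [0, 1]")
        if self.amplitude_v <= 0:
            raise ParameterError("amplitude_v must be positive")
        if self.powerline_amp_v < 0:
            raise ParameterError("powerline_amp_v must be >= 0")
        if self.spectral_profile not in _SPECTRAL_PROFILES:
            raise ParameterError(
                f"spectral_profile must be one of {_SPECTRAL_PROFILES}"
            )

    def to_dict(self) -> dict:
        return {
            "n_epochs": self.n_epochs,
            "duration_s": self.duration_s,
            "fs": self.fs,
            "band": list(self.band),
            "amplitude_v": self.amplitude_v,
            "spectral_profile": self.spectral_profile,
            "seizure_fraction": self.seizure_fraction,
            "powerline_amp_v": self.powerline_amp_v,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        params = cls(**d)
        params.validate()
        return params


def _epoch_rng(master_seed: int, epoch_index: int) -> np.random.Generator:
    # per-epoch seeds derived by counter so generation is reproducible and
    # order-independent
    return np.random.default_rng(np.random.SeedSequence([master_seed, epoch_index]))


def _band_limited_background(
    rng: np.random.Generator,
    n: int,
    fs: float,
    band: tuple[float, float],
    profile: str,
) -> np.ndarray:
    """Random background synthesised in the frequency domain.

    Out-of-band Fourier coefficients are exactly zero, so the band limit is
    exact (no filter transition band).
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    # the emulated database is mains-notch-filtered; keep the synthetic
    # background free of 50 Hz content so that any measured 50 Hz component
    # is attributable to the acquisition chain
    in_band &= ~((freqs >= 48.0) & (freqs <= 52.0))
    mag = np.zeros_like(freqs)
    fpos = freqs[in_band]
    if profile == "pink":
        mag[in_band] = 1.0 / np.sqrt(fpos)  # power ~ 1/f
    elif profile == "white":
        mag[in_band] = 1.0
    else:  # mixed-rhythm: pink background plus delta and theta bumps
        base = 1.0 / np.sqrt(fpos)
        bumps = 0.5 * np.exp(-0.5 * ((fpos - 1.5) / 0.5) ** 2)
        bumps += 0.25 * np.exp(-0.5 * ((fpos - 5.0) / 1.0) ** 2)
        mag[in_band] = base * (1.0 + bumps)
    phases = rng.uniform(0, 2 * np.pi, size=freqs.size)
    spec = mag * np.exp(1j * phases)
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def _rhythmic_discharge(
    rng: np.random.Generator, n: int, fs: float, background_rms: float
) -> np.ndarray:
    """Slow rhythmic discharge emulating neonatal seizure activity.

    A Hann-enveloped sinusoid with slight frequency wander inside 0.5-3 Hz;
    amplitude three times the background RMS so the discharge dominates the
    low band.
    """
    t = np.arange(n) / fs
    f0 = rng.uniform(1.0, 2.5)
    # slow frequency wander, bounded so the instantaneous rate stays in band
    wander = 0.3 * np.sin(2 * np.pi * rng.uniform(0.02, 0.05) * t + rng.uniform(0, 2 * np.pi))
    phase = 2 * np.pi * np.cumsum(f0 + wander) / fs
    envelope = np.hanning(n)
    return 3.0 * background_rms * np.sqrt(2.0) * envelope * np.sin(phase)


def generate_epochs(params: GeneratorParams) -> list[EEGEpoch]:
    """Generate ``params.n_epochs`` synthetic neonatal EEG epochs.

    Each epoch is band-limited to ``params.band`` and peak-normalised so that
    ``max |x|`` equals ``params.amplitude_v`` exactly.  Epochs with index
    ``< round(seizure_fraction * n_epochs)`` carry a rhythmic 0.5-3 Hz
    discharge on top of the background.  Output is a pure function of
    ``params`` (including the seed).
    """
    params.validate()
    n = int(round(params.duration_s * params.fs))
    n_seizure = int(round(params.seizure_fraction * params.n_epochs))
    epochs: list[EEGEpoch] = []
    for i in range(params.n_epochs):
        rng = _epoch_rng(params.seed, i)
        x = _band_limited_background(rng, n, params.fs, params.band, params.spectral_profile)
        is_seizure = i < n_seizure
        if is_seizure:
            x = x + _rhythmic_discharge(rng, n, params.fs, np.sqrt(np.mean(x**2)))
        if params.powerline_amp_v > 0:
            t = np.arange(n) / params.fs
            x = x + (params.powerline_amp_v / params.amplitude_v) * np.sin(
                2 * np.pi * 50.0 * t
            )
        peak = np.max(np.abs(x))
        x = x * (params.amplitude_v / peak)
        epochs.append(
            EEGEpoch(
                samples=x,
                fs=params.fs,
                label="generator",
                epoch_index=i,
                seed=params.seed,
                metadata={"seizure": bool(is_seizure)},
            )
        )
    return epochs


def preprocess_database_epoch(
    e: EEGEpoch,
    notch_hz: float = 50.0,
    *,
    fs_out: float = 250.0,
    band: tuple[float, float] = (0.5, 100.0),
    amplitude_v: float = 0.5,
) -> EEGEpoch:
    """Emulate the database preprocessing applied to raw clinical recordings.

    Band-limits to ``band``, resamples to ``fs_out``, notch-filters the mains
    component at ``notch_hz`` and rescales the peak to ``amplitude_v``.
    """
    from . import quality_metrics as qm  # local import: avoids module cycle

    if notch_hz >= e.fs / 2:
        raise ParameterError(
            f"notch frequency {notch_hz} Hz is not below Nyquist ({e.fs / 2} Hz)"
        )
    out = e
    if out.fs != fs_out:
        from scipy.signal import resample_poly
        from fractions import Fraction

        frac = Fraction(fs_out / out.fs).limit_denominator(1000)
        y = resample_poly(out.samples, frac.numerator, frac.denominator)
        out = out.with_samples(y, fs=fs_out)
    out = qm.bandpass_fir(out, band[0], band[1])
    out = qm.notch_fir(out, notch_hz)
    peak = out.peak_v
    # skip the rescale when nothing in-band survived (e.g. a DC-only input,
    # which only leaves stop-band leakage); amplifying that residue to
    # +/-0.5 V would be meaningless
    if peak > 1e-3 * max(e.peak_v, 1e-30):
        out = out.with_samples(out.samples * (amplitude_v / peak))
    return out


def scale_to_microvolt(e: EEGEpoch, divider_ratio: float = 5000.0) -> EEGEpoch:
    """Divide the epoch by a resistor-divider ratio.

    The default ratio 5000 maps the +/-0.5 V playback amplitude back to the
    physiological +/-100 uV EEG range.
    """
    if not divider_ratio > 1:
        raise ParameterError(f"divider_ratio must exceed 1, got {divider_ratio}")
    return e.with_samples(e.samples / divider_ratio)


def cloth_stage(e: EEGEpoch, series_resistance_ohm: float = 2.0) -> EEGEpoch:
    """Record the conductive-cloth series resistance in epoch metadata.

    The silver-plated cloth strip behaves as a small resistance in series
    with each downstream electrode's source impedance; the waveform itself is
    unchanged at this stage (the loading effect is applied by the acquisition
    chain, where the amplifier input impedance is known).
    """
    if series_resistance_ohm < 0:
        raise ParameterError("series resistance must be >= 0")
    out = e.with_samples(e.samples)
    out.metadata[CLOTH_RESISTANCE_KEY] = float(series_resistance_ohm)
    return out


# ---------------------------------------------------------------------------
# signal I/O


def write_signals(
    epochs: Sequence[EEGEpoch], path: str | Path, format: str = "csv"
) -> Path:
    """Write epochs to CSV (full precision) or EDF (16-bit integer scaled).

    Each epoch becomes one channel; all epochs must share sampling rate and
    length.  CSV layout: ``time_s`` column followed by one column per channel
    label.
    """
    path = Path(path)
    epochs = list(epochs)
    if not epochs:
        raise ParameterError("no epochs to write")
    fs = epochs[0].fs
    n = epochs[0].n_samples
    for e in epochs:
        if e.fs != fs or e.n_samples != n:
            raise ParameterError(
                "all epochs in one file must share sampling rate and length"
            )
    labels = _unique_labels(epochs)
    fmt = format.lower()
    if fmt == "csv":
        df = pd.DataFrame({"time_s": np.arange(n) / fs})
        for lab, e in zip(labels, epochs):
            df[lab] = e.samples
        df.to_csv(path, index=False, float_format="%.17g")
    elif fmt == "edf":
        from ._edf import write_edf

        write_edf(path, [e.samples for e in epochs], fs, labels)
    else:
        raise ParameterError(f"unsupported format {format!r}")
    return path


def read_signals(path: str | Path, format: str | None = None) -> list[EEGEpoch]:
    """Read a CSV or EDF signal file back into a list of epochs."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "edf":
        return _read_edf(path)
    raise ParameterError(f"unsupported format {fmt!r}")


def _unique_labels(epochs: Iterable[EEGEpoch]) -> list[str]:
    labels = []
    seen: dict[str, int] = {}
    for e in epochs:
        base = e.label or "ch"
        k = seen.get(base, 0)
        labels.append(base if k == 0 else f"{base}_{k}")
        seen[base] = k + 1
    return labels


def _read_csv(path: Path) -> list[EEGEpoch]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse CSV {path}: {exc}") from exc
    if df.shape[1] < 2 or df.columns[0] != "time_s":
        raise FormatError(
            f"{path}: expected a 'time_s' column followed by channel columns, "
            f"got columns {list(df.columns)}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError(f"{path}: need at least two samples")
    dt = np.diff(t)
    if np.ptp(dt) > 1e-9 * np.median(dt) + 1e-15:
        raise FormatError(
            f"{path}: non-uniform sampling detected (time steps vary between "
            f"{dt.min():.3g} and {dt.max():.3g} s)"
        )
    fs = 1.0 / float(np.median(dt))
    # snap away the float jitter of a time-column roundtrip
    fs = float(np.round(fs, 6))
    return [
        EEGEpoch(
            samples=df[col].to_numpy(dtype=float), fs=fs, label=str(col), epoch_index=i
        )
        for i, col in enumerate(df.columns[1:])
    ]


def _read_edf(path: Path) -> list[EEGEpoch]:
    import mne

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"could not parse EDF {path}: {exc}") from exc
    fs = float(raw.info["sfreq"])
    data = raw.get_data()  # volts
    return [
        EEGEpoch(samples=data[i], fs=fs, label=str(name), epoch_index=i)
        for i, name in enumerate(raw.ch_names)
    ]


def save_params(params: GeneratorParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.to_dict(), indent=2))


def load_params(path: str | Path) -> GeneratorParams:
    return GeneratorParams.from_dict(json.loads(Path(path).read_text()))
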
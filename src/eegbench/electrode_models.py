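"""Skin-electrode interface impedance: equivalent circuit, sweep fitting, presets.

The skin-electrode (SE) junction is modelled by the standard equivalent
circuit: a half-cell DC potential ``Ehc`` in series with the electrode
material resistance ``Rm`` and a parallel ``Re || Ce`` pair representing the
interface itself.  At EEG frequencies (< 50 Hz) the capacitive branch is
nearly open and ``Rm`` is negligible, so the interface reduces to the real
resistance ``Re`` — the approximation the acquisition-chain simulator uses.

Measured sweeps tabulate resistance and (signed, capacitive) reactance over
frequency; ``fit_sweep`` converts them into per-frequency ``Re``/``Ce``
tables rather than forcing a single parametric RC pair, because real SE
impedance is strongly frequency dependent.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ExtrapolationError, FormatError, ParameterError

__all__ = [
    "ImpedanceSweep",
    "ElectrodeModel",
    "MeterSpec",
    "SweepSummary",
    "impedance_magnitude",
    "capacitance_from_reactance",
    "fit_sweep",
    "summarize_sweeps",
    "preset_models",
    "get_preset",
    "model_impedance_at",
    "meter_total_tolerance",
    "read_sweeps_csv",
    "write_sweeps_csv",
    "TABLE_PRESET_VALUES",
]

LOCATIONS = ("frontal", "occipital")

#: Measured mean SE |Z| and resistance (ohms) at the 31 Hz impedance-check
#: frequency for the six electrode/location combinations (wet Ag/AgCl,
#: g.tec-g.SAHARA dry pins, MicroTIP microneedles; frontal and occipital).
TABLE_PRESET_VALUES: dict[tuple[str, str], dict[str, float]] = {
    ("wet", "frontal"): {"z": 8.2e3, "re": 8.1e3},
    ("wet", "occipital"): {"z": 19.9e3, "re": 17.6e3},
    ("gtec", "frontal"): {"z": 226.5e3, "re": 198.2e3},
    ("gtec", "occipital"): {"z": 77.9e3, "re": 70.7e3},
    ("micro", "frontal"): {"z": 36.7e3, "re": 24.0e3},
    ("micro", "occipital"): {"z": 214.9e3, "re": 135.8e3},
}

PRESET_FREQ_HZ = 31.0


@dataclass
class ImpedanceSweep:
    """One frequency sweep of SE resistance and reactance.

    ``reactance`` is signed; a capacitive interface gives negative values.
    A sweep containing positive reactance is accepted with a warning (the
    magnitude is used wherever capacitance is derived).
    """

    frequencies: np.ndarray
    resistance: np.ndarray
    reactance: np.ndarray
    electrode_label: str = ""
    location: str = "frontal"
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.resistance = np.asarray(self.resistance, dtype=float)
        self.reactance = np.asarray(self.reactance, dtype=float)
        if not (
            self.frequencies.shape == self.resistance.shape == self.reactance.shape
        ):
            raise ParameterError("sweep arrays must have equal length")
        if self.frequencies.size < 2:
            raise ParameterError("a sweep needs at least two frequency points")
        if np.any(self.frequencies <= 0):
            raise ParameterError("sweep frequencies must be positive")
        if np.any(np.diff(self.frequencies) <= 0):
            raise ParameterError("sweep frequencies must be strictly ascending")
        if self.location not in LOCATIONS:
            raise ParameterError(f"location must be one of {LOCATIONS}")
        if np.any(self.reactance > 0):
            warnings.warn(
                "sweep contains positive (inductive) reactance; magnitudes will "
                "be used when deriving capacitance",
                stacklevel=2,
            )


@dataclass
class ElectrodeModel:
    """Tabulated SE equivalent-circuit model.

    ``re_table``/``ce_table`` hold ``Re(f)`` and ``Ce(f)`` at ``freqs``;
    evaluation interpolates log-linearly in frequency.  ``rm`` (electrode
    material resistance) and ``ehc`` (half-cell DC offset) default to zero:
    both are negligible in the EEG band for the electrodes modelled here.
    """

    freqs: np.ndarray
    re_table: np.ndarray
    ce_table: np.ndarray
    rm: float = 0.0
    ehc: float = 0.0
    label: str = ""
    location: str = "frontal"
    #: clamp to the nearest tabulated value outside the measured range
    extrapolate: bool = False

    def __post_init__(self) -> None:
        self.freqs = np.atleast_1d(np.asarray(self.freqs, dtype=float))
        self.re_table = np.atleast_1d(np.asarray(self.re_table, dtype=float))
        self.ce_table = np.atleast_1d(np.asarray(self.ce_table, dtype=float))
        if np.any(self.freqs <= 0):
            raise ParameterError("model frequencies must be positive")
        if np.any(self.re_table <= 0) or np.any(self.ce_table <= 0):
            raise ParameterError("Re and Ce tables must be positive everywhere")
        if self.rm < 0:
            raise ParameterError("Rm must be >= 0")

    def _interp(self, table: np.ndarray, f: float) -> float:
        if f <= 0:
            raise ParameterError("frequency must be positive")
        fmin, fmax = self.freqs[0], self.freqs[-1]
        if (f < fmin or f > fmax) and not self.extrapolate:
            raise ExtrapolationError(
                f"{f} Hz outside tabulated range [{fmin}, {fmax}] Hz "
                "(set extrapolate=True to clamp)"
            )
        if self.freqs.size == 1:
            return float(table[0])
        f = min(max(f, fmin), fmax)
        return float(np.interp(np.log(f), np.log(self.freqs), table))

    def re_at(self, f: float) -> float:
        """Interface resistance Re (ohms) at ``f`` Hz."""
        return self._interp(self.re_table, f)

    def ce_at(self, f: float) -> float:
        """Interface capacitance Ce (farads) at ``f`` Hz."""
        return self._interp(self.ce_table, f)

    def to_dict(self) -> dict:
        return {
            "freqs_hz": self.freqs.tolist(),
            "re_ohm": self.re_table.tolist(),
            "ce_farad": self.ce_table.tolist(),
            "rm_ohm": self.rm,
            "ehc_v": self.ehc,
            "label": self.label,
            "location": self.location,
            "extrapolate": self.extrapolate,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ElectrodeModel":
        return cls(
            freqs=np.asarray(d["freqs_hz"], dtype=float),
            re_table=np.asarray(d["re_ohm"], dtype=float),
            ce_table=np.asarray(d["ce_farad"], dtype=float),
            rm=float(d.get("rm_ohm", 0.0)),
            ehc=float(d.get("ehc_v", 0.0)),
            label=str(d.get("label", "")),
            location=str(d.get("location", "frontal")),
            extrapolate=bool(d.get("extrapolate", False)),
        )


@dataclass
class MeterSpec:
    """LCR-meter accuracy specification."""

    tb_percent: float = 0.3  # basic tolerance from the datasheet
    lc_m: float = 4.0  # test cable length
    fm_hz: float = 31.0  # measurement frequency

    def __post_init__(self) -> None:
        if self.tb_percent < 0 or self.lc_m < 0 or self.fm_hz <= 0:
            raise ParameterError("MeterSpec requires TB >= 0, LC >= 0, FM > 0")


def impedance_magnitude(re: float, x: float) -> float:
    """|Z| = sqrt(Re^2 + X^2) for a series resistance/reactance reading."""
    return float(np.hypot(re, x))


def capacitance_from_reactance(f: float, x: float) -> float:
    """Capacitance implied by a (capacitive) reactance at frequency ``f``.

    Ce = 1 / (2 pi f |X|).
    """
    if f <= 0:
        raise ParameterError("frequency must be positive")
    if x == 0:
        raise ParameterError("zero reactance has no finite equivalent capacitance")
    return 1.0 / (2.0 * math.pi * f * abs(x))


def fit_sweep(sweep: ImpedanceSweep) -> ElectrodeModel:
    """Convert a measured sweep into a tabulated electrode model.

    ``Re(f)`` is the measured resistance; ``Ce(f)`` follows point-wise from
    the reactance; ``Rm`` is estimated as the high-frequency asymptote of the
    resistance (mean over the top decile of sweep frequencies).
    """
    ce = np.array(
        [
            capacitance_from_reactance(f, x)
            for f, x in zip(sweep.frequencies, sweep.reactance)
        ]
    )
    n_top = max(1, sweep.frequencies.size // 10)
    rm = float(np.mean(sweep.resistance[-n_top:]))
    return ElectrodeModel(
        freqs=sweep.frequencies.copy(),
        re_table=sweep.resistance.copy(),
        ce_table=ce,
        rm=rm,
        label=sweep.electrode_label,
        location=sweep.location,
    )


@dataclass
class SweepSummary:
    """Mean and 95% CI of |Z| and Re across replicates, at one frequency."""

    electrode_label: str
    location: str
    at_f: float
    n: int
    z_mean: float
    z_ci95: float
    re_mean: float
    re_ci95: float


def _t_ci95(values: np.ndarray) -> float:
    n = values.size
    if n < 2:
        return float("nan")
    sd = float(np.std(values, ddof=1))
    return float(stats.t.ppf(0.975, n - 1) * sd / math.sqrt(n))


def summarize_sweeps(
    sweeps: Sequence[ImpedanceSweep], at_f: float = PRESET_FREQ_HZ
) -> list[SweepSummary]:
    """Replicate summary (mean +/- 95% t-interval) of |Z| and Re at ``at_f``.

    Sweeps are grouped by (electrode_label, location); each group needs at
    least two replicates.
    """
    groups: dict[tuple[str, str], list[ImpedanceSweep]] = {}
    for s in sweeps:
        groups.setdefault((s.electrode_label, s.location), []).append(s)
    out = []
    for (label, location), reps in sorted(groups.items()):
        if len(reps) < 2:
            raise ParameterError(
                f"need >= 2 replicates for ({label}, {location}), got {len(reps)}"
            )
        z_vals, re_vals = [], []
        for s in reps:
            if not (s.frequencies[0] <= at_f <= s.frequencies[-1]):
                raise ExtrapolationError(
                    f"{at_f} Hz outside sweep range "
                    f"[{s.frequencies[0]}, {s.frequencies[-1]}] Hz"
                )
            logf = np.log(s.frequencies)
            re_i = float(np.interp(np.log(at_f), logf, s.resistance))
            x_i = float(np.interp(np.log(at_f), logf, s.reactance))
            re_vals.append(re_i)
            z_vals.append(impedance_magnitude(re_i, x_i))
        z_vals = np.asarray(z_vals)
        re_vals = np.asarray(re_vals)
        out.append(
            SweepSummary(
                electrode_label=label,
                location=location,
                at_f=at_f,
                n=len(reps),
                z_mean=float(np.mean(z_vals)),
                z_ci95=_t_ci95(z_vals),
                re_mean=float(np.mean(re_vals)),
                re_ci95=_t_ci95(re_vals),
            )
        )
    return out


def preset_models() -> dict[str, ElectrodeModel]:
    """Single-frequency (31 Hz) electrode models from the measured SE study.

    Returns six models keyed ``"<electrode>_<location>"`` for
    wet/gtec/micro x frontal/occipital.  ``Re`` comes from the measured
    resistance; ``Ce`` is recovered from the reactance magnitude implied by
    the measured |Z| (``|X| = sqrt(|Z|^2 - Re^2)``).  ``Rm`` and ``Ehc`` are
    zero (negligible at EEG frequencies).  Models clamp outside 31 Hz.
    """
    models = {}
    for (electrode, location), v in TABLE_PRESET_VALUES.items():
        x = math.sqrt(v["z"] ** 2 - v["re"] ** 2)
        ce = capacitance_from_reactance(PRESET_FREQ_HZ, -x)
        models[f"{electrode}_{location}"] = ElectrodeModel(
            freqs=np.array([PRESET_FREQ_HZ]),
            re_table=np.array([v["re"]]),
            ce_table=np.array([ce]),
            rm=0.0,
            ehc=0.0,
            label=electrode,
            location=location,
            extrapolate=True,
        )
    return models


def get_preset(electrode: str, location: str) -> ElectrodeModel:
    """Convenience lookup, e.g. ``get_preset("gtec", "frontal")``."""
    key = (electrode.lower(), location.lower())
    if key not in TABLE_PRESET_VALUES:
        raise ParameterError(
            f"no preset for {key}; available: {sorted(TABLE_PRESET_VALUES)}"
        )
    return preset_models()[f"{key[0]}_{key[1]}"]


def model_impedance_at(
    m: ElectrodeModel, f: float, *, low_freq_approx: bool = False
) -> complex:
    """Complex SE impedance at ``f`` Hz.

    Full circuit: ``Rm + (Re(f) || 1/(j 2 pi f Ce(f)))``.  With
    ``low_freq_approx=True`` (and ``Rm`` ignored) the interface reduces to
    the real resistance ``Re(f)``, the in-band approximation used by the
    acquisition chain.
    """
    re = m.re_at(f)
    if low_freq_approx:
        return complex(re, 0.0)
    ce = m.ce_at(f)
    zc = 1.0 / (1j * 2.0 * math.pi * f * ce)
    return m.rm + (re * zc) / (re + zc)


def meter_total_tolerance(spec: MeterSpec) -> float:
    """Total LCR-meter tolerance (percent): TB + 0.015% (FM/1 MHz)^2 LC^2.

    The cable-length correction is negligible at EEG impedance-check
    frequencies.
    """
    return spec.tb_percent + 0.015 * (spec.fm_hz / 1e6) ** 2 * spec.lc_m**2


# ---------------------------------------------------------------------------
# sweep I/O

_SWEEP_COLUMNS = [
    "frequency_hz",
    "resistance_ohm",
    "reactance_ohm",
    "electrode",
    "location",
    "replicate",
]


def write_sweeps_csv(sweeps: Iterable[ImpedanceSweep], path: str | Path) -> Path:
    rows = []
    for s in sweeps:
        for f, r, x in zip(s.frequencies, s.resistance, s.reactance):
            rows.append((f, r, x, s.electrode_label, s.location, s.replicate_id))
    pd.DataFrame(rows, columns=_SWEEP_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_sweeps_csv(path: str | Path) -> list[ImpedanceSweep]:
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"could not parse sweep CSV {path}: {exc}") from exc
    missing = [c for c in _SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing sweep columns {missing}")
    if df.empty:
        raise FormatError(f"{path}: empty sweep file")
    sweeps = []
    for (electrode, location, rep), g in df.groupby(
        ["electrode", "location", "replicate"], sort=True
    ):
        g = g.sort_values("frequency_hz")
        sweeps.append(
            ImpedanceSweep(
                frequencies=g["frequency_hz"].to_numpy(),
                resistance=g["resistance_ohm"].to_numpy(),
                reactance=g["reactance_ohm"].to_numpy(),
                electrode_label=str(electrode),
                location=str(location),
                replicate_id=int(rep),
            )
        )
    return sweeps
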
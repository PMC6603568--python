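# Methods

This note records the modelling assumptions, parameter defaults, and open
design choices behind `eegbench`, in the spirit of a simulator's model
documentation. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Synthetic neonatal EEG

The clinical database the bench concept is built around is anonymized and
not publicly deposited, so the generator emulates its *stated* properties
rather than any patient's morphology: 30 s epochs, 250 Hz sampling,
0.5–100 Hz bandwidth, peak amplitude ±0.5 V on the playback scale
(±100 µV after the divider), 15 epochs per run, a mix of background and
abnormal activity.

- **Background**: synthesised directly in the frequency domain with a
  1/f ("pink") power profile and uniform random phases. Neonatal EEG is
  strongly low-frequency dominant, which pink noise captures to first
  order. Frequency-domain synthesis makes the band limits *exact* (out-of-
  band Fourier coefficients are zero), so spectral-compliance tests are not
  at the mercy of a filter transition band. `white` and `mixed` (pink plus
  delta/theta spectral bumps) profiles are available.
- **Mains-free band**: coefficients in 48–52 Hz are zeroed, emulating the
  50 Hz notch applied to the source database during its preprocessing.
  Consequence: any 50 Hz energy measured downstream is attributable to the
  simulated acquisition chain, not to the signal.
- **Abnormal ("non-healthy") epochs**: a Hann-enveloped sinusoid with slow
  frequency wander inside 0.5–3 Hz at three times the background RMS — the
  slow rhythmic discharge morphology typical of neonatal seizures. The
  fraction of such epochs is a parameter (`seizure_fraction`, default 0.4,
  i.e. 6 of 15 epochs) because the original epoch mix is described only as
  "healthy and non-healthy". No seizure-detection realism is intended.
- **Amplitude convention**: the ±0.5 V figure is treated as a *peak*
  bound; each epoch is rescaled so max |x| equals `amplitude_v` exactly.
- **Determinism**: one master seed; per-epoch generators derived via
  `SeedSequence([master, epoch_index])`, so generation is reproducible and
  independent of evaluation order.

What passing tests on this generator do **not** show: robustness to real
artefact content (movement, sweat, electrode pop), inter-patient
variability, or non-stationary background — none of which the generator
emulates.

## Skin-electrode models

The SE interface is the standard `Ehc + Rm + (Re ∥ Ce)` circuit. Measured
sweeps are stored as per-frequency `Re`/`Ce` tables (log-linear
interpolation in frequency) rather than being collapsed to a single RC
pair, because real SE impedance falls steeply with frequency. `Rm` is
estimated as the high-frequency asymptote of the measured resistance (mean
over the top decile of sweep frequencies); `Rm` and `Ehc` default to zero,
as both are negligible against `Re` in the EEG band for the electrodes
modelled. In the band below 50 Hz the simulator uses the real-valued
`Re(f)` approximation; the full complex parallel circuit is available via
`model_impedance_at`.

The six presets are single-frequency (31 Hz — the standard impedance-check
frequency) models built from measured mean |Z| and resistance: Re from the
resistance row, Ce from `|X| = sqrt(|Z|² − Re²)` via `Ce = 1/(2πf|X|)`.
They clamp (constant extrapolation) outside 31 Hz, which is consistent
with the in-band `Re` approximation over the 31–50 Hz span where they are
evaluated. Replicate summaries use Student-t 95% intervals (df = n − 1),
appropriate for the small replicate counts (5–10) of impedance studies.

## Acquisition chain

- **Loading**: the source is treated as a symmetric differential pair
  (+s/2, −s/2), so the loading formula reduces exactly to the
  differential-gain factor `1 − (Z1+Z2)/(2·ZIN)`. Loading impedances are
  evaluated at 31 Hz (in-band representative value); interference
  conversion uses the electrode impedance at the mains frequency. The
  per-frequency spectral convolution was deliberately not made the default:
  with single-frequency presets it would be indistinguishable, and the
  in-band real-resistance approximation is the model the presets were
  built under.
- **Interference**: a common-mode mains sinusoid (default 10 mV, 50 Hz)
  leaks into the differential path through two mechanisms that add in
  phase: impedance-mismatch conversion `cm_amp·|Z1−Z2|/ZIN` and intrinsic
  finite-CMRR leakage `cm_amp·10^(−CMRR/20)`. The 10 mV default is a
  calibration knob chosen so the wet-electrode stages land in the
  sub-microvolt mains range typical of a well-behaved bench; it is not a
  measurement of any physical environment, and absolute SNRs scale with
  it. The reference path impedance `Z2` defaults to 5 kΩ (a prepared wet
  reference electrode), configurable.
- **Noise**: input-referred Gaussian, with the peak-to-peak rating mapped
  to σ via the 6.6 σ convention (99.9 % coverage).
- **ADC**: mid-tread uniform quantizer over ±full-scale (default
  ±0.187 V, a typical high-gain EEG front-end range; configurable), with
  clipping warnings and polyphase resampling when rates differ. Default
  front end: 1 GΩ input impedance, 120 dB CMRR, 1 µVpp noise, 24-bit,
  250 Hz.
- **Stage I recorder**: the ±0.5 V generator stage is captured by a
  wide-range recorder spec (±1 V, 16-bit, 50 µVpp noise, 1 MΩ), standing
  in for the oscilloscope role of a hardware bench; the EEG front end's
  ±0.187 V range would clip it.
- **Seeding**: per-(stage, epoch) noise streams derived as
  `SeedSequence([master, stage_index, epoch_index])`.

## Quality metrics

- **SNR** is the scalar RMS-ratio form `20·log10(rms(X)/rms(X−Y))`
  (log base 10); a per-sample ratio would be undefined at zero crossings.
  A zero residual is capped at 200 dB. `snr_db` itself performs no
  alignment; `summarize` z-score-rescales first, matching the scoring
  pipeline order. No time-lag search is performed — the simulator's
  filters are zero-phase, so it introduces none; imported real recordings
  should be aligned before scoring.
- **Filters** are linear-phase FIR (Kaiser design, 80 dB target) applied
  forward–backward, hence zero net phase. The mains notch stop band is
  49–51 Hz with ±1 Hz transitions, so the whole affected band lies inside
  the generator's mains-free 48–52 Hz band and the notch can only remove
  chain-added contamination.
- **Filtered metrics** apply the same notch to recording *and* reference.
  The reference is mains-free, so this removes only contamination from the
  recording while cancelling the filter's own edge transients in the
  comparison; filtering the recording alone was tried and injects an
  edge-transient floor of up to a few dB that has nothing to do with
  signal quality.
- **50 Hz noise** is measured before any filtering, on the recording
  aligned (z-score) to a microvolt-scale copy of the reference
  (peak 100 µV), so all nine stages — including the ±0.5 V generator
  stage — report mains contamination on the same physiological microvolt
  scale. The rectangular-window FFT over the full 30 s epoch puts 50 Hz
  exactly on bin 1500, so an on-bin sinusoid of amplitude A reads back
  exactly A.
- **Confidence intervals**: Student-t, two-sided 95 %, df = n_epochs − 1;
  with a single epoch the CI is undefined and flagged (`ci_defined`).

## Numerical choices and degenerate inputs

- Correlation uses the 1/(N−1) sample convention and is clipped to
  [−1, 1] against rounding.
- Reactance→capacitance uses |X|; a sweep with positive (inductive)
  reactance warns rather than fails.
- FIR tap counts are capped so forward–backward padding fits the epoch.
- Preprocessing skips the final peak rescale when the filtered output has
  collapsed below 10⁻³ of the input peak (e.g. a DC-only input): blowing
  stop-band leakage back up to ±0.5 V would be meaningless.
- EDF output quantizes against the ASCII-truncated physical range actually
  stored in the header, so the write→read error is bounded by one digital
  step of the stored range. EDF reading goes through `mne`; CSV holds full
  float precision (`round_trip` parsing).

## Problem sizes

The default bench — 15 epochs × 30 s × 250 Hz through nine stages plus
scoring — runs in well under a minute on one core, and the test suite uses
those full reference conditions; a few unit tests use shorter epochs where
only per-sample algebra is exercised.

## Known limitations

- No motion artefacts, electrode-pop transients, drift beyond a constant
  `Ehc` offset, or multi-channel spatial structure.
- Absolute SNR/correlation/noise levels depend on the configured
  interference amplitude, noise, and recorder specs; only orderings and
  trends across electrode models are meaningful bench outputs.
- Impedance presets derive from adult measurements; neonatal SE impedances
  are generally lower, so dry-electrode degradation here is a worst case.
- The in-vivo scoring mode (1–100 Hz band-pass plus notch before
  correlation) is implemented as library functions but no human-subject
  data ships with the package.
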
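"""Synthetic wing-beat signal generator.

Emulates what the optoelectronic sensor records when a fruit fly crosses the
infrared light curtain: a short harmonic burst (fundamental wing-beat
frequency plus components near its integer multiples, with decaying
magnitudes) shaped by a smooth envelope, embedded in background noise with
optional 60 Hz mains hum and slow luminosity drift.  Species presets follow
the characterized wing-beat statistics of *Anastrepha fraterculus*
(~114 Hz fundamental) and *Ceratitis capitata* (~161 Hz).

The generator provides ground-truth labels (species, true fundamental,
event bounds, per-component frequencies/amplitudes) so detection, feature
extraction, characterization and classification can all be validated
without recorded field data.

The analog sensor front end (6th-order Butterworth high-pass at 70 Hz and
low-pass at 5 kHz, unit passband gain) is emulated digitally by
:func:`sensor_chain`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .signal_io import SignalTrack

__all__ = [
    "SpeciesSynthParams",
    "SynthConfig",
    "EventTruth",
    "GroundTruth",
    "afraterculus_params",
    "ccapitata_params",
    "generate_event",
    "generate_track",
    "sensor_chain",
]


@dataclass
class SpeciesSynthParams:
    """Generative parameters for one species' wing-beat events.

    ``f0_mean``/``f0_sd`` give the population distribution of the
    fundamental wing-beat frequency (Hz).  ``mag_ratio_mean`` is the mean
    ratio of the fundamental's amplitude to the 2nd component's (M0/M1);
    components beyond the 2nd decay geometrically by ``mag_decay``.
    ``inharmonicity_sd`` jitters component centers away from exact integer
    multiples of the fundamental.
    """

    species: str
    f0_mean: float
    f0_sd: float
    n_components: int = 5
    mag_ratio_mean: float = 2.26
    mag_ratio_sd: float = 0.0
    mag_decay: float = 0.55
    inharmonicity_sd: float = 1.5
    duration_range: tuple[float, float] = (0.15, 0.45)
    taper_fraction: float = 0.25
    peak_amplitude: float = 0.5

    def __post_init__(self) -> None:
        if not self.f0_sd >= 0:
            raise ValueError("f0_sd must be non-negative")
        if self.mag_ratio_mean < 1:
            raise ValueError("mag_ratio_mean must be >= 1 (fundamental dominates)")
        if self.duration_range[0] < 0.05:
            raise ValueError("minimum event duration must be >= 0.05 s")
        if not 0 < self.peak_amplitude <= 1:
            raise ValueError("peak_amplitude must lie in (0, 1]")


def afraterculus_params(**overrides) -> SpeciesSynthParams:
    """*A. fraterculus* preset: F0 ~ Normal(113.75, 7.97) Hz, M0/M1 = 2.26."""
    return replace(
        SpeciesSynthParams("A. fraterculus", f0_mean=113.75, f0_sd=7.97,
                           mag_ratio_mean=2.26),
        **overrides,
    )


def ccapitata_params(**overrides) -> SpeciesSynthParams:
    """*C. capitata* preset: F0 ~ Normal(160.81, 10.71) Hz, M0/M1 = 2.05."""
    return replace(
        SpeciesSynthParams("C. capitata", f0_mean=160.81, f0_sd=10.71,
                           mag_ratio_mean=2.05),
        **overrides,
    )


@dataclass
class SynthConfig:
    """Track-level generation parameters.

    ``noise_sd`` is the standard deviation of the white background noise;
    ``hum_amplitude`` the 60 Hz mains pickup; ``drift_amplitude`` /
    ``drift_period_s`` a slow sinusoidal baseline wander standing in for
    ambient luminosity fluctuation.  The same seed always yields the same
    track.
    """

    fs: float = 19200.0
    noise_sd: float = 0.003
    hum_amplitude: float = 0.002
    drift_amplitude: float = 0.01
    drift_period_s: float = 7.0
    event_rate_per_min: float = 12.0
    min_gap_s: float = 0.3
    seed: int = 0
    sensor_chain_enabled: bool = False

    def __post_init__(self) -> None:
        if self.fs < 4000:
            raise ValueError("fs must be at least 4 kHz")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class EventTruth:
    """Ground-truth record for one generated event."""

    species: str
    f0: float
    start_s: float
    end_s: float
    component_freqs: np.ndarray
    component_amps: np.ndarray


@dataclass
class GroundTruth:
    """Per-track ground truth: all generated events, in time order."""

    events: list[EventTruth] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)


def _cosine_taper(n: int, taper_fraction: float) -> np.ndarray:
    # Tukey window: flat top with raised-cosine rise/fall lobes
    return sps.windows.tukey(n, alpha=min(1.0, 2.0 * taper_fraction), sym=True)


def generate_event(
    params: SpeciesSynthParams, fs: float, rng: np.random.Generator
) -> tuple[np.ndarray, EventTruth]:
    """Generate one passage event waveform with its ground truth.

    The waveform is a sum of ``n_components`` sinusoids: the fundamental at
    F0 drawn from the species' normal distribution (truncated at zero by
    redrawing), higher components near k*F0 with Gaussian center jitter,
    amplitudes following the configured M0/M1 ratio and geometric decay,
    random phases, all shaped by a cosine-tapered envelope and scaled to
    the configured peak amplitude.  Times in the returned truth are
    relative to the event start.
    """
    f0 = float(rng.normal(params.f0_mean, params.f0_sd)) if params.f0_sd > 0 else params.f0_mean
    while f0 <= 0:
        f0 = float(rng.normal(params.f0_mean, params.f0_sd))

    k = np.arange(1, params.n_components + 1)
    freqs = k * f0
    if params.inharmonicity_sd > 0:
        jitter = rng.normal(0.0, params.inharmonicity_sd, size=len(k))
        jitter[0] = 0.0  # fundamental is exact
        freqs = freqs + jitter

    ratio = params.mag_ratio_mean
    if params.mag_ratio_sd > 0:
        ratio = max(1.0, float(rng.normal(params.mag_ratio_mean, params.mag_ratio_sd)))
    amps = np.empty(len(k))
    amps[0] = 1.0
    if len(k) > 1:
        amps[1] = 1.0 / ratio
        for i in range(2, len(k)):
            amps[i] = amps[i - 1] * params.mag_decay

    lo, hi = params.duration_range
    duration = float(rng.uniform(lo, hi))
    n = max(2, int(round(duration * fs)))
    t = np.arange(n) / fs
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(k))
    wave = np.zeros(n)
    for a, f, ph in zip(amps, freqs, phases):
        wave += a * np.sin(2.0 * np.pi * f * t + ph)
    wave *= _cosine_taper(n, params.taper_fraction)
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave *= params.peak_amplitude / peak

    truth = EventTruth(
        species=params.species,
        f0=f0,
        start_s=0.0,
        end_s=n / fs,
        component_freqs=freqs,
        component_amps=amps * (params.peak_amplitude / peak if peak > 0 else 1.0),
    )
    return wave, truth


def _background(config: SynthConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / config.fs
    bg = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else np.zeros(n)
    if config.hum_amplitude > 0:
        bg += config.hum_amplitude * np.sin(2.0 * np.pi * 60.0 * t)
    if config.drift_amplitude > 0:
        bg += config.drift_amplitude * np.sin(
            2.0 * np.pi * t / config.drift_period_s + rng.uniform(0, 2 * np.pi)
        )
    return bg


def generate_track(
    config: SynthConfig,
    species_mix: list[tuple[SpeciesSynthParams, float]],
    length_s: float,
) -> tuple[SignalTrack, GroundTruth]:
    """Generate a full sensor track with labeled, non-overlapping events.

    Events are placed at uniformly random non-overlapping times (separated
    by at least ``min_gap_s``) at the configured rate, on top of white
    noise, 60 Hz hum and slow drift.  Species are drawn from ``species_mix``
    (weights must sum to 1).  The track is clipped to [-1, 1].

    Raises
    ------
    ValueError
        If the event rate is too high for non-overlapping placement.
    """
    weights = np.array([w for _, w in species_mix], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("species mix weights must sum to 1")
    rng = np.random.default_rng(config.seed)
    n_total = int(round(length_s * config.fs))
    n_events = int(round(config.event_rate_per_min * length_s / 60.0))

    track = _background(config, n_total, rng)
    truth = GroundTruth()

    if n_events > 0:
        choices = rng.choice(len(species_mix), size=n_events, p=weights)
        waves, truths = [], []
        for c in choices:
            w, tr = generate_event(species_mix[c][0], config.fs, rng)
            waves.append(w)
            truths.append(tr)
        gap = int(round(config.min_gap_s * config.fs))
        total_need = sum(len(w) for w in waves) + gap * (n_events + 1)
        if total_need > n_total:
            raise ValueError(
                f"cannot place {n_events} events without overlap in {length_s:g} s"
            )
        # distribute the slack uniformly: random gaps via sorted uniform draws
        slack = n_total - total_need
        cuts = np.sort(rng.integers(0, slack + 1, size=n_events))
        pos = gap
        prev_cut = 0
        for w, tr, cut in zip(waves, truths, cuts):
            pos += int(cut) - prev_cut
            prev_cut = int(cut)
            track[pos : pos + len(w)] += w
            truth.events.append(
                replace(tr, start_s=pos / config.fs, end_s=(pos + len(w)) / config.fs)
            )
            pos += len(w) + gap

    track = np.clip(track, -1.0, 1.0)
    out = SignalTrack(track, config.fs, origin=f"synthetic[seed={config.seed}]")
    if config.sensor_chain_enabled:
        out = sensor_chain(out)
    return out, truth


def sensor_chain(track: SignalTrack) -> SignalTrack:
    """Digitally emulate the analog sensor front end.

    Applies a 6th-order Butterworth high-pass at 70 Hz (removes the DC
    level of the base infrared light and most mains pickup) and, when the
    sampling rate permits, a 6th-order Butterworth low-pass at 5 kHz
    (anti-alias stage), both with unit passband gain, then clips to [-1, 1].
    The filters are causal, matching the analog realization.
    """
    out = track.samples
    sos_hp = sps.butter(6, 70.0, btype="highpass", fs=track.fs, output="sos")
    out = sps.sosfilt(sos_hp, out)
    if track.fs > 10000.0:
        sos_lp = sps.butter(6, 5000.0, btype="lowpass", fs=track.fs, output="sos")
        out = sps.sosfilt(sos_lp, out)
    out = np.clip(out, -1.0, 1.0)
    return SignalTrack(out, track.fs, origin=f"{track.origin}[sensor-chain]")
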
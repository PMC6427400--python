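"""Characteristic extraction (CAEA) for passage-event waveforms.

Two parallel estimates of the wing-beat fundamental are produced from each
event:

* **autocorrelation method** — the event is Blackman–Harris windowed and
  its autocorrelation r_xx(l) = sum_i x(i+l) x(i) is scanned over lags in a
  physiological band; the lag of the largest peak is the fundamental period
  T0 and F0 = 1/T0;
* **FFT method** — the windowed event is zero-padded to a whole second
  (1 Hz bin spacing), and in the magnitude spectrum the largest in-band
  peak is taken as the fundamental F0, after which the four largest local
  maxima above it become components F1..F4 with magnitudes M1..M4.

Derived features (F1 - F0, M0/M1, ...) feed species characterization and
classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detection import EventRecord

__all__ = [
    "WindowSpec",
    "ComponentSet",
    "FeatureVector",
    "ExtractionConfig",
    "blackman_harris",
    "apply_window",
    "zero_pad_to_resolution",
    "autocorr_f0",
    "fft_spectrum",
    "pick_components",
    "extract_features",
]


@dataclass
class WindowSpec:
    """4-term Blackman–Harris window coefficients."""

    a0: float = 0.35875
    a1: float = 0.48829
    a2: float = 0.14128
    a3: float = 0.01168


def blackman_harris(n: int, spec: WindowSpec | None = None) -> np.ndarray:
    """Evaluate the 4-term Blackman–Harris window of length ``n``.

    w(k) = a0 - a1 cos(2 pi k/(n-1)) + a2 cos(4 pi k/(n-1)) - a3 cos(6 pi k/(n-1))

    Symmetric; near-zero at the edges (a0 - a1 + a2 - a3 = 6e-5 with the
    default coefficients) and exactly a0 + a1 + a2 + a3 at the center of an
    odd-length window.
    """
    if n < 2:
        raise ValueError("window length must be at least 2")
    spec = spec or WindowSpec()
    k = np.arange(n)
    x = 2.0 * np.pi * k / (n - 1)
    return spec.a0 - spec.a1 * np.cos(x) + spec.a2 * np.cos(2 * x) - spec.a3 * np.cos(3 * x)


def apply_window(waveform: np.ndarray, spec: WindowSpec | None = None) -> np.ndarray:
    """Multiply a waveform elementwise by the Blackman–Harris window."""
    waveform = np.asarray(waveform, dtype=np.float64)
    return waveform * blackman_harris(len(waveform), spec)


def zero_pad_to_resolution(waveform: np.ndarray, fs: float) -> np.ndarray:
    """Append zeros until the length is a whole number of seconds.

    Events of up to one second are padded to exactly ``fs`` samples, giving
    1 Hz FFT bin spacing; longer events are padded to the next whole second
    (a finer resolution).
    """
    n = len(waveform)
    target = int(math.ceil(n / fs)) * int(round(fs))
    target = max(target, int(round(fs)))
    out = np.zeros(target, dtype=np.float64)
    out[:n] = waveform
    return out


def autocorr_f0(
    waveform: np.ndarray, fs: float, search_band: tuple[float, float] = (70.0, 500.0)
) -> tuple[float, float]:
    """Estimate the fundamental period and frequency by autocorrelation.

    Computes the raw (biased, un-normalized) autocorrelation
    r_xx(l) = sum_i x(i+l) x(i) for positive lags and returns the lag of
    maximal r_xx within [1/f_hi, 1/f_lo] seconds as (T0, F0 = 1/T0).  The
    band restriction excludes the zero-lag main lobe, which would otherwise
    always win.
    """
    waveform = np.asarray(waveform, dtype=np.float64)
    f_lo, f_hi = search_band
    if not 0 < f_lo < f_hi:
        raise ValueError("search band must satisfy 0 < f_lo < f_hi")
    lag_min = int(math.ceil(fs / f_hi))
    lag_max = int(math.floor(fs / f_lo))
    lag_max = min(lag_max, len(waveform) - 1)
    if lag_min > lag_max:
        raise ValueError(
            f"empty lag range for band {search_band} at fs={fs:g} "
            f"and length {len(waveform)}"
        )
    # full autocorrelation via FFT (equivalent to the direct lag sum)
    nfft = 1 << int(np.ceil(np.log2(2 * len(waveform) - 1)))
    spec = np.fft.rfft(waveform, nfft)
    acf = np.fft.irfft(spec * np.conj(spec), nfft)[: len(waveform)]
    lag = lag_min + int(np.argmax(acf[lag_min : lag_max + 1]))
    t0 = lag / fs
    return t0, 1.0 / t0


def fft_spectrum(padded: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Magnitude spectrum of a zero-padded waveform.

    Returns (frequencies, magnitudes) for the non-negative frequency bins;
    with a whole-second padded length the bin spacing is an integer
    fraction of 1 Hz.
    """
    mags = np.abs(np.fft.rfft(padded))
    freqs = np.fft.rfftfreq(len(padded), d=1.0 / fs)
    return freqs, mags


@dataclass
class ComponentSet:
    """CAEA output for one event.

    ``f0_aut``/``t0_aut`` come from the autocorrelation method; ``f0_fft``
    and components ``f1..f4`` (ascending) with magnitudes ``m0..m4`` from
    the FFT method.  ``valid`` flags mark which FFT components were found.
    """

    t0_aut: float
    f0_aut: float
    f0_fft: float
    m0: float
    freqs: np.ndarray  # f1..f4, NaN where invalid
    mags: np.ndarray  # m1..m4, NaN where invalid
    valid: np.ndarray  # bool, per component f1..f4

    @property
    def f1(self) -> float:
        return float(self.freqs[0])

    @property
    def m1(self) -> float:
        return float(self.mags[0])


@dataclass
class FeatureVector:
    """Classification features derived from a ComponentSet.

    ``f1_minus_f0`` is the spacing between the 2nd component and the
    fundamental (another estimate of the wing-beat frequency);
    ``mag_ratio_01`` = M0/M1.  Higher-order differences/ratios are kept for
    diagnostics but are not used for species discrimination.
    """

    f0_aut: float
    f0_fft: float
    f1_minus_f0: float  # NaN when f1 invalid
    mag_ratio_01: float  # NaN when m1 invalid
    fk_minus_f0: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))
    mag_ratio_0k: np.ndarray = field(default_factory=lambda: np.full(3, np.nan))


@dataclass
class ExtractionConfig:
    """CAEA parameters: spectral analysis band, peak separation, lag band."""

    analysis_band: tuple[float, float] = (70.0, 1000.0)
    min_separation_hz: float = 10.0
    min_rel_magnitude: float = 0.01
    autocorr_band: tuple[float, float] = (70.0, 500.0)
    window: WindowSpec = field(default_factory=WindowSpec)
    n_components: int = 5


def pick_components(
    freqs: np.ndarray,
    mags: np.ndarray,
    analysis_band: tuple[float, float] = (70.0, 1000.0),
    min_separation_hz: float = 10.0,
    n_components: int = 5,
    min_rel_magnitude: float = 0.01,
) -> ComponentSet:
    """Locate the fundamental and higher components in a magnitude spectrum.

    The fundamental is the globally largest magnitude inside the analysis
    band.  Among strict local maxima at frequencies above the fundamental
    (and inside the band), the ``n_components - 1`` of greatest magnitude
    that keep at least ``min_separation_hz`` from the fundamental and from
    each other become F1..F(n-1), reported in ascending frequency.  Maxima
    below ``min_rel_magnitude`` times the fundamental's magnitude are
    ignored (window sidelobes and the noise floor, not wing-beat
    components).  Missing components are flagged invalid (NaN).
    Autocorrelation fields are NaN; use :func:`extract_features` for the
    full set.
    """
    f_lo, f_hi = analysis_band
    band = (freqs >= f_lo) & (freqs <= f_hi)
    if not band.any():
        raise ValueError(f"analysis band {analysis_band} contains no FFT bins")
    bidx = np.flatnonzero(band)
    i0 = bidx[np.argmax(mags[bidx])]
    f0, m0 = float(freqs[i0]), float(mags[i0])

    # strict local maxima above the fundamental, inside the band
    interior = np.flatnonzero(
        (mags[1:-1] > mags[:-2]) & (mags[1:-1] > mags[2:])
    ) + 1
    cand = interior[
        (freqs[interior] > f0)
        & (freqs[interior] <= f_hi)
        & (mags[interior] >= min_rel_magnitude * m0)
    ]
    cand = cand[np.argsort(mags[cand])[::-1]]  # by magnitude, descending

    picked: list[int] = []
    n_extra = n_components - 1
    for i in cand:
        if len(picked) == n_extra:
            break
        f = freqs[i]
        if abs(f - f0) < min_separation_hz:
            continue
        if any(abs(f - freqs[j]) < min_separation_hz for j in picked):
            continue
        picked.append(i)
    picked.sort(key=lambda i: freqs[i])

    out_f = np.full(n_extra, np.nan)
    out_m = np.full(n_extra, np.nan)
    valid = np.zeros(n_extra, dtype=bool)
    for k, i in enumerate(picked):
        out_f[k] = freqs[i]
        out_m[k] = mags[i]
        valid[k] = True
    return ComponentSet(
        t0_aut=np.nan, f0_aut=np.nan, f0_fft=f0, m0=m0,
        freqs=out_f, mags=out_m, valid=valid,
    )


def extract_features(
    event: EventRecord | np.ndarray,
    fs: float | None = None,
    config: ExtractionConfig | None = None,
) -> tuple[ComponentSet, FeatureVector]:
    """Run the full CAEA pipeline on one event.

    Accepts an :class:`EventRecord` (its padded waveform and rate are used)
    or a bare waveform with ``fs``.  The windowed signal feeds the
    autocorrelation path directly and, after zero-padding to a whole
    second, the FFT path.
    """
    config = config or ExtractionConfig()
    if isinstance(event, EventRecord):
        waveform, fs = event.waveform, event.fs
    else:
        waveform = np.asarray(event, dtype=np.float64)
        if fs is None:
            raise ValueError("fs is required when passing a bare waveform")
    if len(waveform) == 0:
        raise ValueError("empty event waveform")

    windowed = apply_window(waveform, config.window)
    t0, f0_aut = autocorr_f0(windowed, fs, config.autocorr_band)
    padded = zero_pad_to_resolution(windowed, fs)
    freqs, mags = fft_spectrum(padded, fs)
    # the fundamental's windowed mainlobe spans ~8/T Hz; peaks inside it are
    # skirt ripple, not separate components
    mainlobe_hz = 8.0 * fs / len(waveform)
    comp = pick_components(
        freqs, mags, config.analysis_band,
        max(config.min_separation_hz, mainlobe_hz),
        config.n_components, config.min_rel_magnitude,
    )
    comp.t0_aut, comp.f0_aut = t0, f0_aut

    f1_minus_f0 = comp.f1 - comp.f0_fft if comp.valid[0] else float("nan")
    mag_ratio_01 = comp.m0 / comp.m1 if comp.valid[0] else float("nan")
    n_extra = len(comp.freqs)
    fk = np.full(max(0, n_extra - 1), np.nan)
    rk = np.full(max(0, n_extra - 1), np.nan)
    for k in range(1, n_extra):
        if comp.valid[k]:
            fk[k - 1] = comp.freqs[k] - comp.f0_fft
            rk[k - 1] = comp.m0 / comp.mags[k]
    vec = FeatureVector(
        f0_aut=f0_aut, f0_fft=comp.f0_fft,
        f1_minus_f0=f1_minus_f0, mag_ratio_01=mag_ratio_01,
        fk_minus_f0=fk, mag_ratio_0k=rk,
    )
    return comp, vec
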
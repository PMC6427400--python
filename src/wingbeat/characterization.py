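"""Statistical species characterization.

Turns per-event features into a per-species profile of normal models.  The
protocol, per feature: remove physiologically impossible values (octave
errors: a spectral peak picked at twice the true fundamental, or an
autocorrelation peak at half of it), remove boxplot-fence outliers, gate on
Shapiro–Wilk normality (warn, do not abort), then summarize with
descriptive measures and a Student-t confidence interval for the
population mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "DescriptiveMeasures",
    "NormalModel",
    "SpeciesProfile",
    "describe",
    "boxplot_outliers",
    "octave_gate",
    "shapiro_wilk",
    "t_confidence_interval",
    "build_profile",
    "DEFAULT_GATES",
]

#: Per-species physiological validity gates (Hz) for FFT-derived features.
#: Values outside are octave/peak-location errors, not biological variation:
#: the lighter species' spectral features above 200 Hz, and the heavier
#: species' outside 70-280 Hz, correspond to mislocated peaks.
DEFAULT_GATES: dict[str, dict[str, tuple[float, float]]] = {
    "A. fraterculus": {
        "f0_fft": (-math.inf, 200.0),
        "f1_minus_f0": (-math.inf, 200.0),
    },
    "C. capitata": {
        "f0_fft": (70.0, 280.0),
        "f1_minus_f0": (70.0, 280.0),
    },
}


@dataclass
class DescriptiveMeasures:
    """Descriptive statistics of one feature sample."""

    mean: float
    std_error: float
    std_dev: float
    kurtosis: float  # excess, bias-corrected (normal -> 0)
    skewness: float  # bias-corrected
    range: float
    min: float
    max: float
    n: int


@dataclass
class NormalModel:
    """Normal population model for one feature: mean, SD, n and t-based CI."""

    mu: float
    sigma: float
    n: int
    ci_half_width: float
    confidence: float = 0.95
    shapiro_p: float | None = None
    normal_ok: bool = True


@dataclass
class SpeciesProfile:
    """Per-species characterization result.

    ``models`` maps feature name -> NormalModel; ``counts`` records, per
    feature, how many events went in and how many each cleaning step
    removed.
    """

    species: str
    models: dict[str, NormalModel] = field(default_factory=dict)
    gates: dict[str, tuple[float, float]] = field(default_factory=dict)
    counts: dict[str, dict[str, int]] = field(default_factory=dict)


def describe(sample) -> DescriptiveMeasures:
    """Descriptive measures: mean, SE, sample SD, excess kurtosis, skewness,
    range, min, max.  SD uses the n-1 denominator; kurtosis and skewness are
    bias-corrected, so a normal population gives values near zero."""
    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    s = float(np.std(x, ddof=1))
    if x.size > 3 and s > 0:
        kurt = float(stats.kurtosis(x, fisher=True, bias=False))
        skew = float(stats.skew(x, bias=False))
    else:
        kurt = skew = float("nan")
    return DescriptiveMeasures(
        mean=float(np.mean(x)),
        std_error=s / math.sqrt(x.size),
        std_dev=s,
        kurtosis=kurt,
        skewness=skew,
        range=float(np.max(x) - np.min(x)),
        min=float(np.min(x)),
        max=float(np.max(x)),
        n=int(x.size),
    )


def boxplot_outliers(sample) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Single-pass boxplot-fence outlier removal.

    Fences are Q1 - 1.5 IQR and Q3 + 1.5 IQR with linearly interpolated
    quartiles; values strictly outside either fence are removed.  Returns
    (kept, removed, fences).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for boxplot fences")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    keep = (x >= lo) & (x <= hi)
    return x[keep], x[~keep], (float(lo), float(hi))


def octave_gate(
    sample, gates: tuple[float, float]
) -> tuple[np.ndarray, np.ndarray]:
    """Remove values outside the physiological gate [low, high].

    Removed values are octave / peak-location errors (e.g. a peak picked at
    twice the true fundamental), not statistical outliers.  Returns
    (kept, removed).
    """
    lo, hi = gates
    if not lo < hi:
        raise ValueError("gate low bound must be below high bound")
    x = np.asarray(sample, dtype=float)
    keep = (x >= lo) & (x <= hi)
    return x[keep], x[~keep]


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro–Wilk normality test (Royston's approximation via scipy).

    Returns (W, p); the conventional gate passes when p > 0.05.
    """
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro–Wilk undefined for a constant sample")
    w, p = stats.shapiro(x)
    return float(w), float(p)


def t_confidence_interval(
    mean: float, sd: float, n: int, confidence: float = 0.95
) -> NormalModel:
    """Student-t confidence interval for the population mean.

    half width = t((1+confidence)/2, n-1) * sd / sqrt(n).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not 0 < confidence < 1:
        raise ValueError("confidence must lie in (0, 1)")
    t = stats.t.ppf((1.0 + confidence) / 2.0, n - 1)
    return NormalModel(
        mu=float(mean),
        sigma=float(sd),
        n=int(n),
        ci_half_width=float(t * sd / math.sqrt(n)),
        confidence=confidence,
    )


def build_profile(
    features: dict[str, np.ndarray],
    species: str,
    gates: dict[str, tuple[float, float]] | None = None,
    confidence: float = 0.95,
    min_events: int = 10,
) -> SpeciesProfile:
    """Characterize one species from per-event feature samples.

    ``features`` maps feature name -> array of per-event values (NaNs, i.e.
    events where the feature could not be measured, are dropped first).
    Per feature the cleaning chain is: octave gate -> boxplot fences ->
    Shapiro–Wilk gate (a failing p-value flags the model but does not
    abort) -> descriptive measures -> t confidence interval.  Features with
    no finite values are omitted from the profile.
    """
    if gates is None:
        gates = DEFAULT_GATES.get(species, {})
    n_events = max((np.asarray(v).size for v in features.values()), default=0)
    if n_events < min_events:
        raise ValueError(
            f"need at least {min_events} standard-group events, got {n_events}"
        )
    profile = SpeciesProfile(species=species, gates=dict(gates))
    for name, values in features.items():
        x = np.asarray(values, dtype=float)
        x = x[np.isfinite(x)]
        if x.size == 0:
            continue
        counts = {"events_in": int(x.size)}
        if name in gates:
            x, removed = octave_gate(x, gates[name])
            counts["gated"] = int(removed.size)
        else:
            counts["gated"] = 0
        if x.size >= 4:
            x, removed, _ = boxplot_outliers(x)
            counts["outliers"] = int(removed.size)
        else:
            counts["outliers"] = 0
        if x.size < 2:
            continue
        try:
            _, p = shapiro_wilk(x)
        except ValueError:
            p = float("nan")
        desc = describe(x)
        model = t_confidence_interval(desc.mean, desc.std_dev, desc.n, confidence)
        model.shapiro_p = p
        model.normal_ok = bool(p > 0.05) if np.isfinite(p) else False
        counts["kept"] = desc.n
        profile.models[name] = model
        profile.counts[name] = counts
    return profile
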
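"""Two-species discrimination from wing-beat features.

Each feature carries a normal model per species.  The decision boundary per
feature is the abscissa x* between the two means where the class densities
are equal; the tails of each class density beyond x* give the per-class
misclassification probabilities.  An event is classified by majority vote
over its usable frequency features (fundamental by autocorrelation,
fundamental by FFT, and 2nd-component-minus-fundamental); magnitude-ratio
features overlap too heavily between species and are excluded from voting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .characterization import NormalModel, SpeciesProfile
from .features import FeatureVector

__all__ = [
    "ClassifierModel",
    "gaussian_intersection",
    "misclassification_probs",
    "classify_event",
    "evaluate_classifier",
]

#: frequency features used for voting, in reporting order
VOTING_FEATURES = ("f0_aut", "f0_fft", "f1_minus_f0")


def gaussian_intersection(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Abscissa between the means where two normal densities are equal.

    Equating log-densities gives a quadratic in x; the root strictly
    between the means is returned.  With equal SDs the quadratic
    degenerates to the midpoint.

    Raises
    ------
    ValueError
        If no root lies between the means (pathological SD ratio).
    """
    if mu1 == mu2:
        raise ValueError("means must differ")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if math.isclose(sd1, sd2, rel_tol=1e-12):
        return 0.5 * (mu1 + mu2)
    a = 1.0 / sd1**2 - 1.0 / sd2**2
    b = -2.0 * (mu1 / sd1**2 - mu2 / sd2**2)
    c = mu1**2 / sd1**2 - mu2**2 / sd2**2 - 2.0 * math.log(sd2 / sd1)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        raise ValueError("normal densities do not intersect (negative discriminant)")
    sq = math.sqrt(disc)
    lo, hi = min(mu1, mu2), max(mu1, mu2)
    roots = [(-b - sq) / (2 * a), (-b + sq) / (2 * a)]
    between = [r for r in roots if lo < r < hi]
    if not between:
        raise ValueError(
            f"no density intersection between the means {lo:g} and {hi:g}; "
            f"roots at {roots[0]:g}, {roots[1]:g}"
        )
    return float(between[0])


def misclassification_probs(
    model_low: NormalModel, model_high: NormalModel
) -> tuple[float, float]:
    """Per-class misclassification probabilities at the density intersection.

    ``model_low`` must be the class with the lower mean.  Returns
    (P(low-class event falls above x*), P(high-class event falls below x*)),
    i.e. the probability that an event of each species is identified as the
    other when thresholding at the density intersection x*.
    """
    if model_low.mu == model_high.mu and model_low.sigma == model_high.sigma:
        return 0.5, 0.5  # fully overlapping classes
    if not model_low.mu < model_high.mu:
        raise ValueError("model_low must have the lower mean")
    x = gaussian_intersection(
        model_low.mu, model_low.sigma, model_high.mu, model_high.sigma
    )
    p_low_as_high = float(stats.norm.sf(x, model_low.mu, model_low.sigma))
    p_high_as_low = float(stats.norm.cdf(x, model_high.mu, model_high.sigma))
    return p_low_as_high, p_high_as_low


@dataclass
class ClassifierModel:
    """Two-species classifier over per-feature normal models.

    Boundaries x* are precomputed per feature at construction.  The
    ``likelihood`` combination rule sums per-feature normal log-likelihoods
    instead of majority voting.
    """

    profile_a: SpeciesProfile
    profile_b: SpeciesProfile
    features: tuple[str, ...] = VOTING_FEATURES
    rule: str = "majority"
    boundaries: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rule not in ("majority", "likelihood"):
            raise ValueError(f"unknown combination rule {self.rule!r}")
        for name in self.features:
            ma = self.profile_a.models.get(name)
            mb = self.profile_b.models.get(name)
            if ma is None or mb is None:
                continue
            self.boundaries[name] = gaussian_intersection(
                ma.mu, ma.sigma, mb.mu, mb.sigma
            )

    def _value(self, features: FeatureVector | dict, name: str) -> float:
        if isinstance(features, dict):
            return float(features.get(name, float("nan")))
        return float(getattr(features, name, float("nan")))


def classify_event(
    features: FeatureVector | dict, model: ClassifierModel
) -> tuple[str, dict[str, str], float]:
    """Classify one event from its feature vector.

    Each usable (finite-valued, modeled) feature votes for the species on
    whose side of its density-intersection boundary the value falls; the
    final label is the majority of usable votes.  A tie, a value exactly on
    a lone boundary, or no usable feature yields the label ``"unknown"``.
    Returns (label, per-feature votes, confidence = agreeing fraction).
    """
    a, b = model.profile_a.species, model.profile_b.species
    votes: dict[str, str] = {}
    score_a = score_b = 0.0
    for name in model.features:
        x = model._value(features, name)
        if not np.isfinite(x) or name not in model.boundaries:
            continue
        ma, mb = model.profile_a.models[name], model.profile_b.models[name]
        if model.rule == "likelihood":
            score_a += stats.norm.logpdf(x, ma.mu, ma.sigma)
            score_b += stats.norm.logpdf(x, mb.mu, mb.sigma)
            votes[name] = a if stats.norm.logpdf(x, ma.mu, ma.sigma) > stats.norm.logpdf(x, mb.mu, mb.sigma) else b
            continue
        xstar = model.boundaries[name]
        if x == xstar:
            votes[name] = "tie"
            continue
        lower_is_a = ma.mu < mb.mu
        on_low_side = x < xstar
        votes[name] = (a if on_low_side == lower_is_a else b)

    if model.rule == "likelihood":
        if not votes:
            return "unknown", votes, 0.0
        label = a if score_a > score_b else b if score_b > score_a else "unknown"
        agree = sum(v == label for v in votes.values())
        return label, votes, agree / len(votes)

    n_a = sum(v == a for v in votes.values())
    n_b = sum(v == b for v in votes.values())
    usable = n_a + n_b
    if usable == 0 or n_a == n_b:
        return "unknown", votes, 0.0
    label = a if n_a > n_b else b
    return label, votes, max(n_a, n_b) / usable


def evaluate_classifier(
    model: ClassifierModel,
    labeled_events: list[tuple[str, FeatureVector | dict]],
) -> dict:
    """Score a classifier on labeled events.

    Returns a dict with a confusion matrix ``confusion[true][predicted]``
    (predictions: the two species labels plus "unknown") and per-feature
    empirical error rates (fraction of usable votes on the wrong side of
    the boundary), for comparison against the Gaussian-overlap predictions.
    """
    if not labeled_events:
        raise ValueError("need at least one labeled event")
    a, b = model.profile_a.species, model.profile_b.species
    confusion = {s: {a: 0, b: 0, "unknown": 0} for s in (a, b)}
    feat_err = {name: [0, 0] for name in model.features}  # wrong, usable
    for true_label, feats in labeled_events:
        label, votes, _ = classify_event(feats, model)
        confusion[true_label][label] += 1
        for name, v in votes.items():
            if v == "tie":
                continue
            feat_err[name][1] += 1
            if v != true_label:
                feat_err[name][0] += 1
    rates = {
        name: (wrong / usable if usable else float("nan"))
        for name, (wrong, usable) in feat_err.items()
    }
    return {"confusion": confusion, "feature_error_rates": rates}
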
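"""Closed-form multisensory model predictions.

Implements the building blocks of a non-generative Bayesian
causal-inference account of bimodal distance perception:

* forced fusion of two Gaussian cues by inverse-variance weighting
  (the maximum-likelihood, minimum-variance combination),
* full segregation (each modality keeps its unimodal percept),
* three strategies for resolving an intermediate causal posterior
  (model selection, model averaging, probability matching), and
* three rival models without causal inference (sensory dominance,
  mandatory integration, no interaction).

Everything here is pure computation on small value objects; estimation
of the inputs from trial data lives in :mod:`avcausal.fit`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "VARIANCE_FLOOR",
    "Modality",
    "InvalidProfileError",
    "UnimodalProfile",
    "StimulusPair",
    "CausalPosterior",
    "GaussianEstimate",
    "MixtureEstimate",
    "integrate_common",
    "segregate",
    "resolve_model_selection",
    "resolve_model_averaging",
    "resolve_probability_matching",
    "predict_sensory_dominance",
    "predict_mandatory_integration",
    "predict_no_interaction",
]

Modality = Literal["auditory", "visual"]

#: Lower bound applied to sample variances.  All predictors divide by
#: variances, so a run of identical repeats (sample variance 0) must not
#: produce a degenerate profile.  1e-4 m^2 corresponds to a 1 cm spread,
#: far below the resolution of a hand-moved response slider.
VARIANCE_FLOOR: float = 1e-4


class InvalidProfileError(ValueError):
    """Raised when a sensory profile or estimate has a non-positive variance."""


@dataclass(frozen=True)
class UnimodalProfile:
    """Gaussian belief N(mean, variance) about one stimulus distance.

    Estimated from unimodal reports: ``mean`` is the sample mean of the
    responses to this modality/distance and ``variance`` the unbiased
    sample variance (floored at :data:`VARIANCE_FLOOR`).
    """

    modality: Modality
    stimulus_distance: float
    mean: float
    variance: float
    n_trials: int = 2

    def __post_init__(self) -> None:
        if self.modality not in ("auditory", "visual"):
            raise ValueError(f"unknown modality: {self.modality!r}")
        if not self.variance > 0:
            raise InvalidProfileError(
                f"profile variance must be positive, got {self.variance}"
            )
        if self.n_trials < 2:
            raise InvalidProfileError("a profile needs at least 2 trials")
        if not 0.0 <= self.mean <= 10.0:
            raise InvalidProfileError(
                f"profile mean {self.mean} outside the response range [0, 10]"
            )


@dataclass(frozen=True, order=True)
class StimulusPair:
    """One bimodal stimulus: a visual and an auditory source distance (m)."""

    visual_distance: float
    auditory_distance: float


@dataclass(frozen=True)
class CausalPosterior:
    """Posterior probability that both cues share one physical cause."""

    p_common: float
    n_trials_used: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_common <= 1.0:
            raise ValueError(f"p_common must lie in [0, 1], got {self.p_common}")

    @property
    def p_separate(self) -> float:
        return 1.0 - self.p_common


@dataclass(frozen=True)
class GaussianEstimate:
    """Predicted response distribution N(mean, variance) under one model."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if not self.variance > 0:
            raise InvalidProfileError(
                f"estimate variance must be positive, got {self.variance}"
            )

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class MixtureEstimate:
    """Weighted mixture of Gaussian estimates (probability-matching output)."""

    components: tuple[tuple[float, GaussianEstimate], ...]

    def __post_init__(self) -> None:
        total = sum(w for w, _ in self.components)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"mixture weights sum to {total}, expected 1")
        if any(not 0.0 <= w <= 1.0 for w, _ in self.components):
            raise ValueError("mixture weights must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return sum(w * g.mean for w, g in self.components)

    @property
    def variance(self) -> float:
        m = self.mean
        return sum(w * (g.variance + (g.mean - m) ** 2) for w, g in self.components)


def _profile_estimate(profile: UnimodalProfile) -> GaussianEstimate:
    return GaussianEstimate(mean=profile.mean, variance=profile.variance)


def integrate_common(
    profile_A: UnimodalProfile, profile_V: UnimodalProfile
) -> GaussianEstimate:
    """Fuse the two cues assuming a single cause (C = 1).

    The shared estimate is the inverse-variance-weighted average of the
    two unimodal means,

        s = (x_A / s2_A + x_V / s2_V) / (1 / s2_A + 1 / s2_V),

    and its variance s2_A * s2_V / (s2_A + s2_V) is the minimum attainable
    by any unbiased linear combination of the two cues.  Both modality
    reports receive this single estimate.
    """
    s2a, s2v = profile_A.variance, profile_V.variance
    precision = 1.0 / s2a + 1.0 / s2v
    mean = (profile_A.mean / s2a + profile_V.mean / s2v) / precision
    variance = (s2a * s2v) / (s2a + s2v)
    return GaussianEstimate(mean=mean, variance=variance)


def segregate(profile: UnimodalProfile) -> GaussianEstimate:
    """Predict a report under separate causes (C = 2): the unimodal percept.

    Each modality keeps the mean and variance of its own unimodal
    sensation — the identity mapping from profile to estimate.
    """
    return _profile_estimate(profile)


def resolve_model_selection(
    post: CausalPosterior,
    common: GaussianEstimate,
    separate: GaussianEstimate,
) -> GaussianEstimate:
    """Commit to the more probable causal structure.

    Returns ``common`` when p(C=1) > 0.5 and ``separate`` when
    p(C=1) < 0.5.  The rule is stated with strict inequalities on both
    sides, leaving p = 0.5 undefined; the tie resolves to the
    separate-cause estimate (the conservative, no-interaction default).
    """
    return common if post.p_common > 0.5 else separate


def resolve_model_averaging(
    post: CausalPosterior,
    common: GaussianEstimate,
    separate: GaussianEstimate,
) -> GaussianEstimate:
    """Posterior-weighted linear average of the two structures' estimates.

    Mean and variance are both mixed linearly with weights
    (p(C=1), p(C=2)).  The linear variance rule is a modelling
    hypothesis — it is *not* the variance of the corresponding mixture
    distribution, which also carries the spread between component means.
    """
    p = post.p_common
    q = 1.0 - p
    return GaussianEstimate(
        mean=p * common.mean + q * separate.mean,
        variance=p * common.variance + q * separate.variance,
    )


def resolve_probability_matching(
    post: CausalPosterior,
    common: GaussianEstimate,
    separate: GaussianEstimate,
) -> MixtureEstimate:
    """Expected response distribution under trial-by-trial matching.

    On each trial the observer follows the common-cause estimate with
    probability p(C=1) (a uniform draw zeta < p(C=1)) and the
    separate-cause estimate otherwise.  Over trials the response
    distribution is therefore a two-component Gaussian mixture with
    weights (p(C=1), p(C=2)); this function returns that analytic
    expectation, never a sampled realization.  Zero-weight components
    are dropped.
    """
    p = post.p_common
    components: list[tuple[float, GaussianEstimate]] = []
    if p > 0.0:
        components.append((p, common))
    if p < 1.0:
        components.append((1.0 - p, separate))
    return MixtureEstimate(components=tuple(components))


def predict_sensory_dominance(
    profile_A: UnimodalProfile, profile_V: UnimodalProfile
) -> GaussianEstimate:
    """Winner-takes-all: the more reliable cue captures both reports.

    Returns the profile with the smaller variance, used for both the
    auditory and the visual report.  At exactly equal variances the
    visual cue wins (vision being the more reliable modality for
    distance throughout this setting); the rule itself is silent on
    ties.
    """
    if profile_A.variance < profile_V.variance:
        return _profile_estimate(profile_A)
    return _profile_estimate(profile_V)


def predict_mandatory_integration(
    profile_A: UnimodalProfile, profile_V: UnimodalProfile
) -> GaussianEstimate:
    """Forced fusion on every trial regardless of discrepancy."""
    return integrate_common(profile_A, profile_V)


def predict_no_interaction(profile: UnimodalProfile) -> GaussianEstimate:
    """No crossmodal influence: every report follows its own modality."""
    return segregate(profile)
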
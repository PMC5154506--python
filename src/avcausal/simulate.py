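"""Synthetic observer: simulated response tables with known ground truth.

Real response data for this experiment layout are not redistributable,
so the pipeline is exercised on a simulated observer that enacts the
same statistical assumptions the analysis makes: unimodal reports are
Gaussian draws around the stimulus distance, and on bimodal trials the
observer first samples its two sensations, then decides — via an
explicit generative coupling — whether they share a cause, and answers
accordingly.

The coupling is a Gaussian similarity kernel on the sampled sensations,

    p_c = exp(-(x_V - x_A)^2 / (2 tau^2)),

with kernel width ``tau`` in meters.  This kernel is a simulator
convenience: the analysis pipeline never sees or uses it, it only
receives the response tables.  Its closed-form expectation under the
sensation distributions is available from :func:`ground_truth` for
recovery tests.

Responses are clipped to the slider range [0, 10] m; the resulting
censoring bias at the range edges is part of the simulated data, and
:func:`ground_truth` reports both the raw sensation moments and the
censored (post-clipping) response moments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    CausalPosterior,
    GaussianEstimate,
    StimulusPair,
    UnimodalProfile,
)
from .fit import RESPONSE_COLUMNS
from .weights import weight_surface

__all__ = [
    "Strategy",
    "ObserverConfig",
    "simulate_unimodal",
    "simulate_bimodal",
    "simulate",
    "ground_truth",
    "sample_probability_matching",
    "censored_normal_moments",
]

Strategy = Literal[
    "probability_matching",
    "model_averaging",
    "model_selection",
    "dominance",
    "mandatory",
    "none",
]

SLIDER_LO, SLIDER_HI = 0.0, 10.0


@dataclass(frozen=True)
class ObserverConfig:
    """Parameters of the simulated observer and of the experiment design.

    Defaults reproduce the study layout: visual stimuli at 1, 3, 5, 7,
    9 m, auditory at every meter from 1 to 10 m, all 50 bimodal pairs,
    6 repetitions per stimulus and 6 subjects, slider responses on
    [0, 10] m.

    Sensory noise defaults are calibrated to realistic distance
    localization: visual SD constant at 0.45 m (mean absolute error
    around 0.36 m), auditory SD growing with distance as
    0.6 + 0.2 * d m (mean absolute error around 1.4 m over the grid).
    ``mean_fn_A`` / ``mean_fn_V`` and ``sd_fn_A`` / ``sd_fn_V`` allow
    arbitrary mean and noise functions of distance; by default means
    are the veridical stimulus distances.
    """

    visual_grid: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0, 9.0)
    auditory_grid: tuple[float, ...] = tuple(float(d) for d in range(1, 11))
    repetitions: int = 6
    n_subjects: int = 6
    seed: int = 0
    tau: float = 2.0
    strategy: Strategy = "probability_matching"
    visual_sigma: float = 0.45
    auditory_sigma_base: float = 0.6
    auditory_sigma_slope: float = 0.2
    mean_fn_A: Callable[[float], float] | None = None
    mean_fn_V: Callable[[float], float] | None = None
    sd_fn_A: Callable[[float], float] | None = None
    sd_fn_V: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.repetitions < 0 or self.n_subjects < 1:
            raise ValueError("repetitions must be >= 0 and n_subjects >= 1")
        for d in list(self.visual_grid) + list(self.auditory_grid):
            if self.sd_A(d) <= 0 or self.sd_V(d) <= 0:
                raise ValueError(f"sensory SD must be positive at {d} m")

    def mean_A(self, d: float) -> float:
        return self.mean_fn_A(d) if self.mean_fn_A is not None else d

    def mean_V(self, d: float) -> float:
        return self.mean_fn_V(d) if self.mean_fn_V is not None else d

    def sd_A(self, d: float) -> float:
        if self.sd_fn_A is not None:
            return self.sd_fn_A(d)
        return self.auditory_sigma_base + self.auditory_sigma_slope * d

    def sd_V(self, d: float) -> float:
        return self.sd_fn_V(d) if self.sd_fn_V is not None else self.visual_sigma

    @property
    def subjects(self) -> tuple[str, ...]:
        return tuple(f"s{i + 1}" for i in range(self.n_subjects))

    @property
    def pairs(self) -> tuple[StimulusPair, ...]:
        return tuple(
            StimulusPair(v, a) for a in self.auditory_grid for v in self.visual_grid
        )

    def to_dict(self) -> dict:
        """Serializable numeric parameters (custom callables excluded)."""
        if any(
            f is not None
            for f in (self.mean_fn_A, self.mean_fn_V, self.sd_fn_A, self.sd_fn_V)
        ):
            raise ValueError("configs with custom mean/SD callables cannot be serialized")
        return {
            "visual_grid": list(self.visual_grid),
            "auditory_grid": list(self.auditory_grid),
            "repetitions": self.repetitions,
            "n_subjects": self.n_subjects,
            "seed": self.seed,
            "tau": self.tau,
            "strategy": self.strategy,
            "visual_sigma": self.visual_sigma,
            "auditory_sigma_base": self.auditory_sigma_base,
            "auditory_sigma_slope": self.auditory_sigma_slope,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ObserverConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise KeyError(f"unknown observer-config keys: {sorted(bad)}")
        d = dict(d)
        for key in ("visual_grid", "auditory_grid"):
            if key in d:
                d[key] = tuple(float(x) for x in d[key])
        return cls(**d)


def _subject_rngs(config: ObserverConfig) -> list[tuple[np.random.Generator, np.random.Generator]]:
    """One (unimodal, bimodal) generator pair per subject.

    Subject-level substreams make any subject subset reproducible
    independently of how many subjects are simulated after it.
    """
    children = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    return [tuple(np.random.default_rng(s) for s in c.spawn(2)) for c in children]


def _clip(x: np.ndarray) -> np.ndarray:
    return np.clip(x, SLIDER_LO, SLIDER_HI)


def simulate_unimodal(config: ObserverConfig) -> pd.DataFrame:
    """Unimodal (A and V) response table: Gaussian draws, clipped."""
    reps = np.arange(1, config.repetitions + 1)
    rows = []
    for subject, (rng, _) in zip(config.subjects, _subject_rngs(config)):
        for d in config.auditory_grid:
            resp = _clip(rng.normal(config.mean_A(d), config.sd_A(d), size=reps.size))
            for r, x in zip(reps, resp):
                rows.append((subject, "A", np.nan, d, np.nan, x, int(r)))
        for d in config.visual_grid:
            resp = _clip(rng.normal(config.mean_V(d), config.sd_V(d), size=reps.size))
            for r, x in zip(reps, resp):
                rows.append((subject, "V", d, np.nan, x, np.nan, int(r)))
    return pd.DataFrame(rows, columns=list(RESPONSE_COLUMNS))


def _fused(config: ObserverConfig, pair: StimulusPair, x_a: np.ndarray, x_v: np.ndarray) -> np.ndarray:
    s2a = config.sd_A(pair.auditory_distance) ** 2
    s2v = config.sd_V(pair.visual_distance) ** 2
    return (x_a / s2a + x_v / s2v) / (1.0 / s2a + 1.0 / s2v)


def simulate_bimodal(config: ObserverConfig) -> pd.DataFrame:
    """Bimodal response table under the configured resolution strategy.

    Per trial the observer samples its two sensations, computes the
    kernel coupling p_c from their discrepancy, and answers:

    * ``probability_matching`` — with probability p_c both sliders get
      the inverse-variance fused value (hence matching answers), else
      each slider gets its own sensation;
    * ``model_averaging`` — each slider gets p_c * fused +
      (1 - p_c) * own sensation;
    * ``model_selection`` — fused on both sliders iff p_c > 0.5;
    * ``dominance`` — the lower-variance modality's sensation on both;
    * ``mandatory`` — fused on both, always;
    * ``none`` — own sensation on each, always.
    """
    reps = np.arange(1, config.repetitions + 1)
    rows = []
    for subject, (_, rng) in zip(config.subjects, _subject_rngs(config)):
        for pair in config.pairs:
            a, v = pair.auditory_distance, pair.visual_distance
            x_a = rng.normal(config.mean_A(a), config.sd_A(a), size=reps.size)
            x_v = rng.normal(config.mean_V(v), config.sd_V(v), size=reps.size)
            p_c = np.exp(-((x_v - x_a) ** 2) / (2.0 * config.tau**2))
            fused = _fused(config, pair, x_a, x_v)
            if config.strategy == "probability_matching":
                zeta = rng.uniform(size=reps.size)
                take = zeta < p_c
                resp_a = np.where(take, fused, x_a)
                resp_v = np.where(take, fused, x_v)
            elif config.strategy == "model_averaging":
                resp_a = p_c * fused + (1.0 - p_c) * x_a
                resp_v = p_c * fused + (1.0 - p_c) * x_v
            elif config.strategy == "model_selection":
                take = p_c > 0.5
                resp_a = np.where(take, fused, x_a)
                resp_v = np.where(take, fused, x_v)
            elif config.strategy == "dominance":
                best = x_v if config.sd_V(v) ** 2 <= config.sd_A(a) ** 2 else x_a
                resp_a = resp_v = best
            elif config.strategy == "mandatory":
                resp_a = resp_v = fused
            elif config.strategy == "none":
                resp_a, resp_v = x_a, x_v
            else:
                raise ValueError(f"unknown strategy: {config.strategy!r}")
            resp_a, resp_v = _clip(resp_a), _clip(resp_v)
            for r, ra, rv in zip(reps, resp_a, resp_v):
                rows.append((subject, "AV", v, a, rv, ra, int(r)))
    return pd.DataFrame(rows, columns=list(RESPONSE_COLUMNS))


def simulate(config: ObserverConfig) -> pd.DataFrame:
    """Full experiment: unimodal and bimodal blocks in one table."""
    return pd.concat(
        [simulate_unimodal(config), simulate_bimodal(config)], ignore_index=True
    )


def censored_normal_moments(
    mu: float, sigma: float, lo: float = SLIDER_LO, hi: float = SLIDER_HI
) -> tuple[float, float]:
    """Mean and variance of a N(mu, sigma^2) draw clipped to [lo, hi]."""
    alpha = (lo - mu) / sigma
    beta = (hi - mu) / sigma
    phi_a, phi_b = stats.norm.pdf(alpha), stats.norm.pdf(beta)
    Phi_a, Phi_b = stats.norm.cdf(alpha), stats.norm.cdf(beta)
    mid = Phi_b - Phi_a
    ey = lo * Phi_a + hi * (1.0 - Phi_b) + mu * mid - sigma * (phi_b - phi_a)
    ez1 = phi_a - phi_b
    ez2 = mid + alpha * phi_a - beta * phi_b
    ex2_mid = mu**2 * mid + 2.0 * mu * sigma * ez1 + sigma**2 * ez2
    ey2 = lo**2 * Phi_a + hi**2 * (1.0 - Phi_b) + ex2_mid
    return float(ey), float(ey2 - ey**2)


def _expected_kernel(config: ObserverConfig, pair: StimulusPair) -> float:
    """E[exp(-(x_V - x_A)^2 / 2 tau^2)] under the sensation distributions.

    With x_V - x_A ~ N(delta, s^2), the Gaussian kernel integrates in
    closed form to tau / sqrt(tau^2 + s^2) * exp(-delta^2 / (2 (tau^2 + s^2))).
    """
    a, v = pair.auditory_distance, pair.visual_distance
    delta = config.mean_V(v) - config.mean_A(a)
    s2 = config.sd_A(a) ** 2 + config.sd_V(v) ** 2
    t2 = config.tau**2
    return float(math.sqrt(t2 / (t2 + s2)) * math.exp(-(delta**2) / (2.0 * (t2 + s2))))


def ground_truth(config: ObserverConfig) -> dict:
    """Generative quantities the pipeline should recover from simulations.

    Returns a dict with:

    * ``posteriors`` — per pair, a CausalPosterior whose p_common is the
      closed-form expected kernel value (the expected rate of matching
      answers under probability matching, before slider clipping);
    * ``profiles`` — the configured sensation moments as
      UnimodalProfile objects (raw, pre-clipping);
    * ``response_moments`` — per (modality, distance), the censored
      mean/variance the clipped unimodal *responses* actually follow —
      the right reference for recovery checks at the range edges;
    * ``weights`` — the causal weight surface computed from the truth
      posteriors and raw variances via the analysis code path.
    """
    posteriors = {
        pair: CausalPosterior(p_common=_expected_kernel(config, pair))
        for pair in config.pairs
    }
    profiles: dict[tuple[str, float], UnimodalProfile] = {}
    response_moments: dict[tuple[str, float], tuple[float, float]] = {}
    for d in config.auditory_grid:
        profiles[("auditory", d)] = UnimodalProfile(
            "auditory", d, config.mean_A(d), config.sd_A(d) ** 2, n_trials=2
        )
        response_moments[("auditory", d)] = censored_normal_moments(
            config.mean_A(d), config.sd_A(d)
        )
    for d in config.visual_grid:
        profiles[("visual", d)] = UnimodalProfile(
            "visual", d, config.mean_V(d), config.sd_V(d) ** 2, n_trials=2
        )
        response_moments[("visual", d)] = censored_normal_moments(
            config.mean_V(d), config.sd_V(d)
        )
    weights = weight_surface(
        profiles,
        posteriors,
        target="auditory",
        visual_grid=config.visual_grid,
        auditory_grid=config.auditory_grid,
    )
    return {
        "posteriors": posteriors,
        "profiles": profiles,
        "response_moments": response_moments,
        "weights": weights,
    }


def sample_probability_matching(
    post: CausalPosterior,
    common: GaussianEstimate,
    separate: GaussianEstimate,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n responses by per-trial zeta sampling (no slider clipping).

    Each draw follows the common-cause Gaussian when zeta < p(C=1) and
    the separate-cause Gaussian otherwise — the sampled counterpart of
    the analytic mixture returned by resolve_probability_matching.
    """
    zeta = rng.uniform(size=n)
    take = zeta < post.p_common
    out = np.where(
        take,
        rng.normal(common.mean, common.sd, size=n),
        rng.normal(separate.mean, separate.sd, size=n),
    )
    return out
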
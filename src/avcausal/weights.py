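"""Sensory-weight calculus under causal inference and interaction windows.

The weight of a modality on a multisensory estimate quantifies how much
that cue contributed to it.  Under forced fusion the weights are the
normalized inverse variances; under causal inference the self-weight
gets an extra p(C=2) share because, with separate causes, the estimate
follows its own modality entirely.  Scanning the weights over the whole
stimulus grid yields a weight surface, and the span of concurrent-cue
positions where the *other* modality's weight exceeds 0.5 is the
interaction window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CausalPosterior, InvalidProfileError, Modality, StimulusPair, UnimodalProfile

__all__ = [
    "SensoryWeights",
    "InteractionWindow",
    "mle_weight",
    "causal_weights",
    "weight_surface",
    "interaction_window",
]


@dataclass(frozen=True)
class SensoryWeights:
    """Weights (w_A, w_V) on one estimate; they always sum to 1."""

    target_modality: Modality
    w_A: float
    w_V: float

    def __post_init__(self) -> None:
        if abs(self.w_A + self.w_V - 1.0) > 1e-12:
            raise ValueError(f"weights must sum to 1, got {self.w_A + self.w_V}")
        if not (0.0 <= self.w_A <= 1.0 and 0.0 <= self.w_V <= 1.0):
            raise ValueError("weights must lie in [0, 1]")


@dataclass(frozen=True)
class InteractionWindow:
    """Span of concurrent-cue distances where the cross-modal weight > 0.5."""

    auditory_distance: float
    window_lo: float
    window_hi: float

    def __post_init__(self) -> None:
        if self.window_lo > self.window_hi:
            raise ValueError("window_lo must not exceed window_hi")

    @property
    def width(self) -> float:
        return self.window_hi - self.window_lo

    @property
    def is_empty(self) -> bool:
        return self.window_hi == self.window_lo


def mle_weight(var_A: float, var_V: float) -> float:
    """Auditory weight under forced fusion: normalized inverse variance.

    w_A = (1/s2_A) / (1/s2_A + 1/s2_V) = s2_V / (s2_A + s2_V).
    """
    if not (var_A > 0 and var_V > 0):
        raise InvalidProfileError("variances must be positive")
    return var_V / (var_A + var_V)


def causal_weights(
    post: CausalPosterior,
    var_A: float,
    var_V: float,
    target: Modality = "auditory",
) -> SensoryWeights:
    """Sensory weights on one modality's estimate under causal inference.

    For the auditory estimate: with separate causes the auditory cue
    carries all the weight; with a common cause the weights follow the
    inverse-variance rule.  Averaging over the causal posterior,

        w_A = p(C=2) + p(C=1) * s2_V / (s2_A + s2_V)
        w_V =          p(C=1) * s2_A / (s2_A + s2_V)

    The visual-target case exchanges the roles of the two modalities
    symmetrically.  The self-weight is therefore never below p(C=2).
    """
    if not (var_A > 0 and var_V > 0):
        raise InvalidProfileError("variances must be positive")
    p1 = post.p_common
    p2 = post.p_separate
    fused_self = mle_weight(var_A, var_V) if target == "auditory" else mle_weight(var_V, var_A)
    self_w = p2 + p1 * fused_self
    cross_w = p1 * (1.0 - fused_self)
    # renormalize away float round-off so the invariant holds exactly
    total = self_w + cross_w
    self_w, cross_w = self_w / total, cross_w / total
    if target == "auditory":
        return SensoryWeights(target_modality="auditory", w_A=self_w, w_V=cross_w)
    if target == "visual":
        return SensoryWeights(target_modality="visual", w_A=cross_w, w_V=self_w)
    raise ValueError(f"unknown target modality: {target!r}")


def weight_surface(
    profiles: dict[tuple[Modality, float], UnimodalProfile],
    posteriors: dict[StimulusPair, CausalPosterior],
    target: Modality = "auditory",
    *,
    visual_grid: tuple[float, ...] = (1, 3, 5, 7, 9),
    auditory_grid: tuple[float, ...] = tuple(range(1, 11)),
) -> pd.DataFrame:
    """Weights for every stimulus pair on the (auditory x visual) grid.

    Returns a long-format frame with columns ``auditory_distance``,
    ``visual_distance``, ``w_A``, ``w_V``.  A pair without a posterior
    yields a row with NaN weights — an explicit missing-cell marker, so
    downstream consumers see the hole rather than a silently smaller
    grid.
    """
    rows = []
    for a in auditory_grid:
        prof_a = profiles.get(("auditory", a))
        for v in visual_grid:
            prof_v = profiles.get(("visual", v))
            post = posteriors.get(StimulusPair(visual_distance=v, auditory_distance=a))
            if post is None or prof_a is None or prof_v is None:
                rows.append((a, v, np.nan, np.nan))
                continue
            w = causal_weights(post, prof_a.variance, prof_v.variance, target=target)
            rows.append((a, v, w.w_A, w.w_V))
    return pd.DataFrame(
        rows, columns=["auditory_distance", "visual_distance", "w_A", "w_V"]
    )


def interaction_window(
    surface: pd.DataFrame, auditory_distance: float
) -> InteractionWindow:
    """Window of visual distances where the visual weight exceeds 0.5.

    The weight surface is sampled on a discrete visual grid; the window
    bounds are read off by linear interpolation of w_V between adjacent
    grid points, solving for the crossings of 0.5.  The window is the
    extent from the first up-crossing to the last down-crossing
    (degenerate, width 0, when no grid cell strictly exceeds 0.5).
    Cells exactly at 0.5 lie outside the window.  A window reaching the
    grid edge is truncated there.
    """
    row = surface[surface["auditory_distance"] == auditory_distance]
    if row.empty:
        raise KeyError(f"no surface row for auditory distance {auditory_distance}")
    row = row.sort_values("visual_distance")
    v = row["visual_distance"].to_numpy(dtype=float)
    w = row["w_V"].to_numpy(dtype=float)
    if np.isnan(w).any():
        raise ValueError(
            f"weight surface has missing cells at auditory distance {auditory_distance}"
        )
    above = w > 0.5
    if not above.any():
        return InteractionWindow(auditory_distance, v[0], v[0])

    first = int(np.argmax(above))
    last = len(above) - 1 - int(np.argmax(above[::-1]))

    def cross(i: int, j: int) -> float:
        # linear interpolation of the 0.5 crossing between grid points i, j
        return v[i] + (0.5 - w[i]) / (w[j] - w[i]) * (v[j] - v[i])

    lo = v[first] if first == 0 else cross(first - 1, first)
    hi = v[last] if last == len(v) - 1 else cross(last + 1, last)
    # cross() runs from the below-threshold neighbour toward the cell
    # above threshold in both calls, so lo <= hi always holds
    return InteractionWindow(auditory_distance, lo, hi)
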
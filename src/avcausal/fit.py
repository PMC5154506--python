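"""From trial tables to fitted models: profiles, posteriors, counts, r².

The analysis is deliberately non-generative: nothing is fitted by
maximum likelihood.  Unimodal response profiles give each modality's
sensation distribution, the rate of matching bimodal answers gives the
causal posterior per stimulus pair, and each candidate model then makes
a parameter-free prediction of the response-count histogram for every
pair.  Goodness of fit is the r² of a simple OLS regression of observed
counts on predicted counts over all cells in scope.

A response table is a pandas DataFrame with columns

    subject, condition, vis_dist, aud_dist, resp_vis, resp_aud, rep

where ``condition`` is one of A, V, AV; fields that do not apply to a
condition are left empty (NaN).  Responses live on the slider range
[0, 10] m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core import (
    VARIANCE_FLOOR,
    CausalPosterior,
    GaussianEstimate,
    MixtureEstimate,
    Modality,
    StimulusPair,
    UnimodalProfile,
    integrate_common,
    predict_sensory_dominance,
    resolve_model_averaging,
    resolve_model_selection,
    resolve_probability_matching,
    segregate,
)

__all__ = [
    "MODELS",
    "BIN_CENTERS",
    "RESPONSE_COLUMNS",
    "NoDataError",
    "ModelFit",
    "validate_response_table",
    "bin_of",
    "compute_unimodal_profiles",
    "estimate_p_common",
    "estimate_posteriors",
    "discretize",
    "model_estimate",
    "predict_counts",
    "observed_counts",
    "fit_model",
    "compare_models",
    "summarize_errors",
]

#: The six candidate models, in canonical table order.
MODELS: tuple[str, ...] = (
    "SensoryDominance",
    "MandatoryIntegration",
    "NoInteraction",
    "CausalInferencePM",
    "CausalInferenceMA",
    "CausalInferenceMS",
)

#: Response bins: 1-m bins centered on the integer distances 1..10 m.
BIN_CENTERS: np.ndarray = np.arange(1, 11, dtype=float)

RESPONSE_COLUMNS = ("subject", "condition", "vis_dist", "aud_dist", "resp_vis", "resp_aud", "rep")

VISUAL_GRID: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0, 9.0)
AUDITORY_GRID: tuple[float, ...] = tuple(float(d) for d in range(1, 11))


class NoDataError(ValueError):
    """Raised when an estimate is requested for a condition with no trials."""


@dataclass(frozen=True)
class ModelFit:
    """OLS goodness of fit of one model over one scope of count cells."""

    model: str
    scope: str
    slope: float
    intercept: float
    r_squared: float
    n_points: int
    degenerate: bool = False


def validate_response_table(data: pd.DataFrame) -> pd.DataFrame:
    """Check column layout, condition coding and response ranges.

    Returns the table unchanged; raises ValueError naming the offending
    rows (0-based positions) otherwise.
    """
    missing = [c for c in RESPONSE_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"response table lacks columns: {missing}")
    bad = ~data["condition"].isin(["A", "V", "AV"])
    if bad.any():
        raise ValueError(f"unknown condition at rows {list(np.flatnonzero(bad))[:10]}")
    for col in ("resp_vis", "resp_aud"):
        vals = data[col]
        out = vals.notna() & ((vals < 0) | (vals > 10))
        if out.any():
            raise ValueError(
                f"{col} outside [0, 10] at rows {list(np.flatnonzero(out))[:10]}"
            )
    a = data["condition"] == "A"
    v = data["condition"] == "V"
    av = data["condition"] == "AV"
    checks = [
        (a & (data["aud_dist"].isna() | data["resp_aud"].isna()), "A rows need aud_dist and resp_aud"),
        (v & (data["vis_dist"].isna() | data["resp_vis"].isna()), "V rows need vis_dist and resp_vis"),
        (av & data[["vis_dist", "aud_dist", "resp_vis", "resp_aud"]].isna().any(axis=1),
         "AV rows need all four stimulus/response fields"),
    ]
    for mask, msg in checks:
        if mask.any():
            raise ValueError(f"{msg}; rows {list(np.flatnonzero(mask))[:10]}")
    return data


def bin_of(response: np.ndarray | float) -> np.ndarray | int:
    """Map responses to 1-m bins centered at 1..10 m.

    Bin c covers [c - 0.5, c + 0.5); the extreme bins absorb the tails,
    so a response of exactly 0 lands in bin 1 and 10 in bin 10.
    """
    idx = np.clip(np.floor(np.asarray(response, dtype=float) + 0.5), 1, 10)
    out = idx.astype(int)
    return out if out.ndim else int(out)


def compute_unimodal_profiles(
    data: pd.DataFrame,
    *,
    subject: str | None = None,
    visual_grid: tuple[float, ...] = VISUAL_GRID,
    auditory_grid: tuple[float, ...] = AUDITORY_GRID,
) -> dict[tuple[Modality, float], UnimodalProfile]:
    """Sample mean and unbiased variance of unimodal reports per distance.

    Pools across subjects unless ``subject`` is given.  A zero sample
    variance (all repeats identical) is floored at the global variance
    floor so downstream divisions stay defined.
    """
    if subject is not None:
        data = data[data["subject"] == subject]
    profiles: dict[tuple[Modality, float], UnimodalProfile] = {}
    plan: list[tuple[Modality, str, str, tuple[float, ...]]] = [
        ("auditory", "A", "resp_aud", auditory_grid),
        ("visual", "V", "resp_vis", visual_grid),
    ]
    for modality, cond, resp_col, grid in plan:
        dist_col = "aud_dist" if modality == "auditory" else "vis_dist"
        sub = data[data["condition"] == cond]
        for d in grid:
            resp = sub.loc[sub[dist_col] == d, resp_col].dropna().to_numpy(dtype=float)
            if resp.size < 2:
                raise NoDataError(
                    f"need >= 2 unimodal {modality} trials at {d} m, found {resp.size}"
                )
            var = float(np.var(resp, ddof=1))
            profiles[(modality, d)] = UnimodalProfile(
                modality=modality,
                stimulus_distance=d,
                mean=float(np.mean(resp)),
                variance=max(var, VARIANCE_FLOOR),
                n_trials=int(resp.size),
            )
    return profiles


def _matching(resp_v: np.ndarray, resp_a: np.ndarray, match_rule: str) -> np.ndarray:
    if match_rule == "bin":
        return np.asarray(bin_of(resp_v)) == np.asarray(bin_of(resp_a))
    if match_rule == "exact":
        return resp_v == resp_a
    raise ValueError(f"unknown match rule: {match_rule!r}")


def estimate_p_common(
    data: pd.DataFrame,
    pair: StimulusPair,
    match_rule: str = "bin",
    *,
    subject: str | None = None,
) -> CausalPosterior:
    """Causal posterior for one stimulus pair from the matching-answer rate.

    p(C=1) is the fraction of bimodal trials for this pair whose visual
    and auditory reports match.  The default rule counts two reports as
    matching when they fall into the same 1-m bin, the granularity at
    which responses are analysed; ``match_rule="exact"`` requires float
    equality (observers were instructed to give identical answers under
    a perceived common cause).
    """
    if subject is not None:
        data = data[data["subject"] == subject]
    sub = data[
        (data["condition"] == "AV")
        & (data["vis_dist"] == pair.visual_distance)
        & (data["aud_dist"] == pair.auditory_distance)
    ]
    if sub.empty:
        raise NoDataError(f"no bimodal trials for pair {pair}")
    match = _matching(
        sub["resp_vis"].to_numpy(dtype=float),
        sub["resp_aud"].to_numpy(dtype=float),
        match_rule,
    )
    return CausalPosterior(p_common=float(np.mean(match)), n_trials_used=len(sub))


def estimate_posteriors(
    data: pd.DataFrame,
    match_rule: str = "bin",
    *,
    subject: str | None = None,
) -> dict[StimulusPair, CausalPosterior]:
    """Posterior for every stimulus pair present in the bimodal trials."""
    av = data[data["condition"] == "AV"]
    pairs = {
        StimulusPair(float(v), float(a))
        for v, a in av[["vis_dist", "aud_dist"]].drop_duplicates().to_numpy()
    }
    return {
        p: estimate_p_common(data, p, match_rule, subject=subject) for p in sorted(pairs)
    }


def discretize(
    est: GaussianEstimate | MixtureEstimate,
    bin_centers: np.ndarray = BIN_CENTERS,
) -> np.ndarray:
    """Integrate a predicted density over the response bins.

    Bin probabilities are CDF differences at the bin edges c +/- 0.5;
    the first and last bins absorb the tails below and above the grid,
    so the vector always sums to 1.
    """
    if isinstance(est, MixtureEstimate):
        return sum(
            w * discretize(g, bin_centers) for w, g in est.components
        )  # type: ignore[return-value]
    edges = np.concatenate(([-np.inf], bin_centers[:-1] + 0.5, [np.inf]))
    cdf = stats.norm.cdf(edges, loc=est.mean, scale=est.sd)
    return np.diff(cdf)


def model_estimate(
    model: str,
    pair: StimulusPair,
    profiles: dict[tuple[Modality, float], UnimodalProfile],
    posteriors: dict[StimulusPair, CausalPosterior],
    report_modality: Modality,
) -> GaussianEstimate | MixtureEstimate:
    """Predicted response distribution for one pair, model and report."""
    try:
        prof_a = profiles[("auditory", pair.auditory_distance)]
        prof_v = profiles[("visual", pair.visual_distance)]
    except KeyError as exc:
        raise NoDataError(f"missing unimodal profile for {exc.args[0]}") from None
    own = prof_a if report_modality == "auditory" else prof_v

    if model == "SensoryDominance":
        return predict_sensory_dominance(prof_a, prof_v)
    if model == "MandatoryIntegration":
        return integrate_common(prof_a, prof_v)
    if model == "NoInteraction":
        return segregate(own)

    if pair not in posteriors:
        raise NoDataError(f"missing causal posterior for pair {pair}")
    post = posteriors[pair]
    common = integrate_common(prof_a, prof_v)
    separate = segregate(own)
    if model == "CausalInferencePM":
        return resolve_probability_matching(post, common, separate)
    if model == "CausalInferenceMA":
        return resolve_model_averaging(post, common, separate)
    if model == "CausalInferenceMS":
        return resolve_model_selection(post, common, separate)
    raise ValueError(f"unknown model: {model!r}")


def predict_counts(
    model: str,
    profiles: dict[tuple[Modality, float], UnimodalProfile],
    posteriors: dict[StimulusPair, CausalPosterior],
    design: dict[StimulusPair, int],
) -> pd.DataFrame:
    """Predicted response counts per pair, report modality and bin.

    ``design`` gives the number of bimodal trials per stimulus pair; the
    discretized model probabilities are scaled by it, so each predicted
    vector conserves the pair's total trial mass.  Long format with
    columns vis_dist, aud_dist, modality, bin, count.
    """
    rows = []
    for pair, n_trials in sorted(design.items()):
        for modality in ("auditory", "visual"):
            est = model_estimate(model, pair, profiles, posteriors, modality)
            probs = discretize(est)
            for c, p in zip(BIN_CENTERS, probs):
                rows.append(
                    (pair.visual_distance, pair.auditory_distance, modality, int(c), p * n_trials)
                )
    return pd.DataFrame(
        rows, columns=["vis_dist", "aud_dist", "modality", "bin", "count"]
    )


def observed_counts(data: pd.DataFrame) -> pd.DataFrame:
    """Observed bimodal response counts per subject, pair, modality and bin.

    Every (subject, pair, modality) cell yields all 10 bins, zeros
    included, so observed and predicted tables align cell for cell.
    """
    av = data[data["condition"] == "AV"].copy()
    if av.empty:
        raise NoDataError("response table has no bimodal (AV) trials")
    frames = []
    for modality, col in (("auditory", "resp_aud"), ("visual", "resp_vis")):
        sub = av[["subject", "vis_dist", "aud_dist", col]].copy()
        sub["bin"] = bin_of(sub[col].to_numpy(dtype=float))
        g = (
            sub.groupby(["subject", "vis_dist", "aud_dist", "bin"])
            .size()
            .rename("count")
            .reset_index()
        )
        # reindex onto the full bin grid so empty bins appear as zeros
        full = (
            g.set_index(["subject", "vis_dist", "aud_dist", "bin"])["count"]
            .unstack("bin", fill_value=0)
            .reindex(columns=range(1, 11), fill_value=0)
            .stack()
            .rename("count")
            .reset_index()
        )
        full["modality"] = modality
        frames.append(full)
    out = pd.concat(frames, ignore_index=True)
    return out[["subject", "vis_dist", "aud_dist", "modality", "bin", "count"]]


def fit_model(
    predicted: pd.DataFrame,
    observed: pd.DataFrame,
    scope: str = "All",
) -> ModelFit:
    """Regress observed counts on predicted counts over the scope's cells.

    Scopes: ``All`` (both report modalities), ``All (A)`` / ``All (V)``
    (one modality), or a subject id (both modalities, that subject
    only).  Simple OLS with intercept; the reported statistic is r².  A
    constant predictor has no explanatory power and scores r² = 0 with
    the ``degenerate`` flag set.
    """
    obs = observed
    if scope == "All (A)":
        obs = obs[obs["modality"] == "auditory"]
    elif scope == "All (V)":
        obs = obs[obs["modality"] == "visual"]
    elif scope != "All":
        obs = obs[obs["subject"] == scope]
        if obs.empty:
            raise NoDataError(f"no observed counts for subject {scope!r}")
    merged = obs.merge(
        predicted,
        on=["vis_dist", "aud_dist", "modality", "bin"],
        suffixes=("_obs", "_pred"),
        validate="many_to_one",
    )
    if len(merged) != len(obs):
        raise ValueError("predicted counts do not cover every observed cell")
    x = merged["count_pred"].to_numpy(dtype=float)
    y = merged["count_obs"].to_numpy(dtype=float)
    model_name = predicted.attrs.get("model", "?")
    if np.ptp(x) == 0.0:
        warnings.warn(
            f"constant predictor for model {model_name}; r^2 set to 0", stacklevel=2
        )
        return ModelFit(model_name, scope, 0.0, float(np.mean(y)), 0.0, len(merged), True)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return ModelFit(
        model=model_name,
        scope=scope,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        n_points=len(merged),
    )


def _design_per_subject(av: pd.DataFrame) -> dict[str, dict[StimulusPair, int]]:
    out: dict[str, dict[StimulusPair, int]] = {}
    g = av.groupby(["subject", "vis_dist", "aud_dist"]).size()
    for (s, v, a), n in g.items():
        out.setdefault(s, {})[StimulusPair(float(v), float(a))] = int(n)
    return out


def compare_models(
    data: pd.DataFrame,
    match_rule: str = "bin",
    *,
    models: tuple[str, ...] = MODELS,
    visual_grid: tuple[float, ...] = VISUAL_GRID,
    auditory_grid: tuple[float, ...] = AUDITORY_GRID,
) -> pd.DataFrame:
    """Goodness of fit (r²) of every model over every scope.

    Pooled scopes (All, All (A), All (V)) use profiles and posteriors
    estimated from all subjects together; the prediction for each
    subject's counts is the pooled prediction scaled to that subject's
    trials per pair.  Per-subject columns re-estimate profiles and
    posteriors from that subject alone.  Returns a frame indexed by
    model with one column per scope.
    """
    validate_response_table(data)
    if not (data["condition"] == "AV").any():
        raise NoDataError("model comparison needs bimodal (AV) trials")
    obs = observed_counts(data)
    subjects = sorted(data["subject"].unique())
    per_subject_design = _design_per_subject(data[data["condition"] == "AV"])

    pooled_profiles = compute_unimodal_profiles(
        data, visual_grid=visual_grid, auditory_grid=auditory_grid
    )
    pooled_posteriors = estimate_posteriors(data, match_rule)
    subject_inputs = {
        s: (
            compute_unimodal_profiles(
                data, subject=s, visual_grid=visual_grid, auditory_grid=auditory_grid
            ),
            estimate_posteriors(data, match_rule, subject=s),
        )
        for s in subjects
    }

    scopes = ["All", "All (A)", "All (V)", *subjects]
    table = pd.DataFrame(index=list(models), columns=scopes, dtype=float)
    table.index.name = "model"
    for model in models:
        # one shared per-pair design suffices for the pooled scopes: the
        # prediction is per trial, scaled to each subject's trial count
        pred_frames = []
        for s in subjects:
            pf = predict_counts(
                model, pooled_profiles, pooled_posteriors, per_subject_design[s]
            )
            pf["subject"] = s
            pred_frames.append(pf)
        pooled_pred = pd.concat(pred_frames, ignore_index=True)
        pooled_pred.attrs["model"] = model
        for scope in ("All", "All (A)", "All (V)"):
            fit = _fit_per_subject_pred(pooled_pred, obs, scope, model)
            table.loc[model, scope] = fit.r_squared
        for s in subjects:
            prof_s, post_s = subject_inputs[s]
            pred_s = predict_counts(model, prof_s, post_s, per_subject_design[s])
            pred_s.attrs["model"] = model
            fit = fit_model(pred_s, obs[obs["subject"] == s], scope=s)
            table.loc[model, s] = fit.r_squared
    return table


def _fit_per_subject_pred(
    predicted: pd.DataFrame, observed: pd.DataFrame, scope: str, model: str
) -> ModelFit:
    """fit_model variant whose predicted table is already per subject."""
    obs = observed
    if scope == "All (A)":
        obs = obs[obs["modality"] == "auditory"]
    elif scope == "All (V)":
        obs = obs[obs["modality"] == "visual"]
    merged = obs.merge(
        predicted,
        on=["subject", "vis_dist", "aud_dist", "modality", "bin"],
        suffixes=("_obs", "_pred"),
        validate="one_to_one",
    )
    x = merged["count_pred"].to_numpy(dtype=float)
    y = merged["count_obs"].to_numpy(dtype=float)
    if np.ptp(x) == 0.0:
        warnings.warn(f"constant predictor for model {model}; r^2 set to 0", stacklevel=2)
        return ModelFit(model, scope, 0.0, float(np.mean(y)), 0.0, len(merged), True)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return ModelFit(
        model=model,
        scope=scope,
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        n_points=len(merged),
    )


def summarize_errors(data: pd.DataFrame) -> pd.DataFrame:
    """Mean absolute localization error and its SD per condition/modality.

    The error of a trial is |reported distance - stimulus distance| for
    the given report modality.
    """
    validate_response_table(data)
    rows = []
    plan = [
        ("A", "auditory", "aud_dist", "resp_aud"),
        ("V", "visual", "vis_dist", "resp_vis"),
        ("AV", "auditory", "aud_dist", "resp_aud"),
        ("AV", "visual", "vis_dist", "resp_vis"),
    ]
    for cond, modality, dist_col, resp_col in plan:
        sub = data[data["condition"] == cond]
        if sub.empty:
            continue
        err = (sub[resp_col] - sub[dist_col]).abs().to_numpy(dtype=float)
        rows.append(
            {
                "condition": cond,
                "modality": modality,
                "mean_abs_error": float(np.mean(err)),
                "sd": float(np.std(err, ddof=1)) if err.size > 1 else 0.0,
                "n_trials": int(err.size),
            }
        )
    return pd.DataFrame(rows)
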
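"""Analysis stages for slider datasets: exclusions, normalization,
exhaustivity summaries, factor tests, the k=2 Bayes-consistency check, and
model-data comparison.

The exhaustive state is the singleton state of the mentioned individual,
state index 1 under the canonical encoding (Experiment-2 pooled sliders
carry an explicit "exhaustive" label instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExclusionReport",
    "apply_exclusions",
    "normalize_responses",
    "summarize_exhaustivity",
    "effect_test",
    "k2_consistency_check",
    "compare_model_data",
]

ITEM_KEY = ["participant_id", "probe", "domain_size", "scenario", "prior_type"]

MIN_ITEM_SECONDS = 15.0


@dataclass
class ExclusionReport:
    n_input: int
    n_retained: int
    n_fast: int
    n_allzero: int
    excluded: tuple

    def __post_init__(self) -> None:
        # a participant can trip both rules; counts are per reason
        assert self.n_retained + len(self.excluded) == self.n_input


def apply_exclusions(data: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop participants who rushed or flat-lined.

    A participant is excluded if any of their items took less than 15 s or
    if they assigned the value 0 to every state of at least one item.
    """
    if "response_time_s" not in data.columns:
        raise ValueError("dataset lacks a response_time_s column")
    items = data.groupby(ITEM_KEY, observed=True).agg(
        rt=("response_time_s", "first"), total=("raw_value", "sum")
    )
    by_pid = items.reset_index().groupby("participant_id")
    fast = set(by_pid["rt"].min().pipe(lambda s: s[s < MIN_ITEM_SECONDS]).index)
    zero = set(by_pid["total"].min().pipe(lambda s: s[s == 0.0]).index)
    excluded = fast | zero
    out = data[~data["participant_id"].isin(excluded)].copy()
    report = ExclusionReport(
        n_input=data["participant_id"].nunique(),
        n_retained=out["participant_id"].nunique(),
        n_fast=len(fast),
        n_allzero=len(zero),
        excluded=tuple(sorted(excluded)),
    )
    return out, report


def normalize_responses(data: pd.DataFrame) -> pd.DataFrame:
    """Divide each raw slider value by its item's raw total.

    Adds a ``normalized_value`` column; per-item normalized values sum to
    one, and the operation is idempotent on already-normalized data.
    """
    totals = data.groupby(ITEM_KEY, observed=True)["raw_value"].transform("sum")
    if (totals == 0).any():
        bad = data.loc[totals == 0, "participant_id"].unique()
        raise ValueError(
            f"items with zero raw total (run apply_exclusions first): {list(bad)[:5]}"
        )
    out = data.copy()
    out["normalized_value"] = out["raw_value"] / totals
    return out


def _exhaustive_rows(data: pd.DataFrame) -> pd.DataFrame:
    mask = data["state_index"].eq(1) | data["slider_label"].eq("exhaustive")
    return data[mask.fillna(False)]


def summarize_exhaustivity(data: pd.DataFrame, by=("domain_size", "prior_type")) -> pd.DataFrame:
    """Per-condition exhaustivity summary.

    Means of the normalized and raw exhaustive-state values and of the raw
    per-item slider sums, with retained participant counts.  Conditions
    without data are omitted with a warning.
    """
    if "normalized_value" not in data.columns:
        raise ValueError("run normalize_responses first")
    by = list(by)
    exh = _exhaustive_rows(data)
    if exh.empty:
        warnings.warn("no exhaustive-state responses found; empty summary")
        return pd.DataFrame(
            columns=by + ["mean_normalized_exh", "mean_raw_exh", "mean_raw_sum", "n_participants"]
        )
    sums = (
        data.groupby(ITEM_KEY, observed=True)["raw_value"].sum().reset_index()
        .groupby(by, observed=True)["raw_value"].mean()
    )
    g = exh.groupby(by, observed=True)
    out = pd.DataFrame(
        {
            "mean_normalized_exh": g["normalized_value"].mean(),
            "mean_raw_exh": g["raw_value"].mean(),
            "mean_raw_sum": sums,
            "n_participants": g["participant_id"].nunique(),
        }
    ).reset_index()
    return out


@dataclass
class EffectTestReport:
    factor: str
    response: str
    f_statistic: float
    p_value: float
    level_means: dict
    n_per_level: dict
    significant: bool


def effect_test(
    data: pd.DataFrame, factor: str, response: str = "normalized", alpha: float = 0.05
) -> EffectTestReport:
    """One-way ANOVA of exhaustive-state values across factor levels.

    Each participant contributes one value per level: the mean of their
    exhaustive-state responses at that level (normalized or raw).
    """
    if factor not in ("domain_size", "prior_type", "scenario"):
        raise ValueError(f"unsupported factor {factor!r}")
    col = {"normalized": "normalized_value", "raw": "raw_value"}[response]
    if col not in data.columns:
        raise ValueError(f"dataset lacks {col!r}; normalize first" if col != "raw_value" else "no raw values")
    exh = _exhaustive_rows(data)
    per = exh.groupby(["participant_id", factor], observed=True)[col].mean().reset_index()
    levels = sorted(per[factor].unique())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has a single level; nothing to test")
    groups = [per.loc[per[factor] == lv, col].to_numpy() for lv in levels]
    f_stat, p_val = stats.f_oneway(*groups)
    return EffectTestReport(
        factor=factor,
        response=response,
        f_statistic=float(f_stat),
        p_value=float(p_val),
        level_means={lv: float(g.mean()) for lv, g in zip(levels, groups)},
        n_per_level={lv: int(g.size) for lv, g in zip(levels, groups)},
        significant=bool(p_val < alpha),
    )


@dataclass
class K2ConsistencyReport:
    verdict: str  # consistent | inconsistent | inconclusive
    prior_exh: dict
    posterior_exh: dict
    implied_speaker_prob: dict
    notes: str


def k2_consistency_check(
    prior_summary: pd.DataFrame,
    posterior_summary: pd.DataFrame,
    min_spread: float = 0.05,
) -> K2ConsistencyReport:
    """Test whether k=2 posteriors respond to the priors as Bayes demands.

    With two states, p(exh|foc) = 1 / (1 + s(q) (1-q)/q) where q is the
    prior of the exhaustive state and s the speaker's relative production
    probability in the non-exhaustive state.  Any Bayesian listener with a
    speaker that does not *reward* likelier non-exhaustive states (s
    non-increasing in q) must show strictly increasing posteriors across
    increasing priors.  The verdict is "consistent" when posteriors
    increase with the prior by more than ``min_spread`` overall and the
    implied s values are probabilities, "inconsistent" when they are flat
    or disordered, "inconclusive" when the priors themselves do not vary.
    """
    def exh_by_type(summary):
        sub = summary[summary["domain_size"] == 2]
        return {
            str(r["prior_type"]): float(r["mean_normalized_exh"]) for _, r in sub.iterrows()
        }

    priors, posts = exh_by_type(prior_summary), exh_by_type(posterior_summary)
    common = sorted(set(priors) & set(posts), key=lambda t: priors[t])
    if len(common) < 2:
        raise ValueError("need k=2 summaries for at least two prior types")
    q = np.array([priors[t] for t in common])
    r = np.array([posts[t] for t in common])
    implied = {}
    bayes_ok = True
    for t in common:
        qq, rr = priors[t], posts[t]
        s = (1.0 / rr - 1.0) * qq / (1.0 - qq) if 0 < rr < 1 and qq < 1 else np.nan
        implied[t] = float(s)
        if not (np.isfinite(s) and 0.0 <= s <= 1.0):
            bayes_ok = False

    if q.max() - q.min() < 1e-3:
        return K2ConsistencyReport(
            "inconclusive", priors, posts, implied,
            "priors do not vary; the check has no leverage",
        )
    increasing = bool(np.all(np.diff(r) > 0))
    spread_ok = bool(r.max() - r.min() >= min_spread)
    s_vals = np.array([implied[t] for t in common])
    s_monotone = bool(np.all(np.diff(s_vals) <= 1e-9)) if np.isfinite(s_vals).all() else False
    if increasing and spread_ok and bayes_ok and s_monotone:
        verdict, notes = "consistent", "posteriors increase with the prior as Bayes requires"
    else:
        verdict = "inconsistent"
        notes = (
            "posterior exhaustivity does not track the prior: "
            + ("posteriors not strictly increasing; " if not increasing else "")
            + ("posterior spread below the detectable minimum; " if not spread_ok else "")
            + ("implied speaker probabilities outside [0,1]; " if not bayes_ok else "")
            + ("implied speaker probabilities increase with the prior; " if not s_monotone else "")
        ).rstrip("; ")
    return K2ConsistencyReport(verdict, priors, posts, implied, notes)


def compare_model_data(
    predictions: pd.DataFrame,
    summary: pd.DataFrame,
    hdis: pd.DataFrame,
) -> pd.DataFrame:
    """Per-condition comparison of observed mean normalized exhaustivity
    against model predictions and posterior-predictive HDIs.

    ``predictions`` needs columns (k, exhaustivity); ``hdis`` needs
    (domain_size, state_index, lower, upper) and is matched on the
    exhaustive state.  Raises if a summarized condition has no prediction.
    """
    if predictions.empty:
        raise ValueError("empty prediction table")
    pred_by_k = predictions.set_index("k")["exhaustivity"].to_dict()
    hdi_exh = hdis[hdis["state_index"] == 1].set_index("domain_size")
    rows = []
    missing = []
    for _, r in summary.iterrows():
        k = int(r["domain_size"])
        if k not in pred_by_k or k not in hdi_exh.index:
            missing.append(k)
            continue
        lo, hi = float(hdi_exh.loc[k, "lower"]), float(hdi_exh.loc[k, "upper"])
        obs = float(r["mean_normalized_exh"])
        rows.append(
            {
                "domain_size": k,
                "observed": obs,
                "predicted": float(pred_by_k[k]),
                "hdi_lower": lo,
                "hdi_upper": hi,
                "inside_hdi": bool(lo <= obs <= hi),
            }
        )
    if missing:
        raise ValueError(f"no predictions/HDIs for conditions: {sorted(set(missing))}")
    out = pd.DataFrame(rows)
    out.attrs["n_inside"] = int(out["inside_hdi"].sum())
    out.attrs["n_total"] = int(len(out))
    return out
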
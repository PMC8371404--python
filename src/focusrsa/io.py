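"""Slider-CSV schema, run configuration, prediction curves and figures.

The on-disk slider format is a UTF-8 comma-separated file with a header,
one row per participant x item x slider (schema version 1):

    participant_id, experiment, probe, scenario, domain_size, prior_type,
    state_index, slider_label, raw_value, response_time_s, seed

``state_index`` uses the bitmask encoding (empty for pooled sliders that
do not correspond to a single state); extra columns are preserved.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .rsa import RSAParams, exhaustivity

__all__ = [
    "SCHEMA_VERSION",
    "REQUIRED_COLUMNS",
    "read_slider_csv",
    "write_slider_csv",
    "ModelConfig",
    "McmcSettings",
    "DesignSettings",
    "RunConfig",
    "load_config",
    "predict_curves",
    "preset_curves",
    "plot_curves",
    "FIGURE_PRESETS",
]

SCHEMA_VERSION = 1

REQUIRED_COLUMNS = (
    "participant_id",
    "experiment",
    "probe",
    "scenario",
    "domain_size",
    "prior_type",
    "state_index",
    "slider_label",
    "raw_value",
    "response_time_s",
    "seed",
)


def read_slider_csv(path) -> pd.DataFrame:
    """Read and validate a slider dataset.

    Raises with the offending row number on missing columns, raw values
    outside [0,1], or duplicate (participant, item, slider) keys; an empty
    file yields an empty, correctly-typed frame with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        import warnings

        warnings.warn(f"{path} contains no records")
        return pd.DataFrame(columns=REQUIRED_COLUMNS).astype({"state_index": "Int64"})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df.index[(df["raw_value"] < 0) | (df["raw_value"] > 1)]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(f"{path}: raw_value outside [0,1] at row {bad[0] + 2}")
    key = ["participant_id", "probe", "domain_size", "scenario", "prior_type", "slider_label"]
    dup = df.index[df.duplicated(key)]
    if len(dup):
        raise ValueError(f"{path}: duplicate slider key at row {dup[0] + 2}")
    df["state_index"] = df["state_index"].astype("Int64")
    return df


def write_slider_csv(data: pd.DataFrame, path) -> None:
    """Write a dataset with deterministic formatting (byte-reproducible
    for identical inputs)."""
    cols = [c for c in REQUIRED_COLUMNS if c in data.columns] + [
        c for c in data.columns if c not in REQUIRED_COLUMNS
    ]
    data[cols].to_csv(path, index=False, float_format="%.6f")


# --------------------------------------------------------------------------
# run configuration


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelConfig(_Strict):
    variant: Literal[
        "focus_only",
        "focus_plus_exclusives",
        "collapsed_two_state",
        "collapsed_constant_prior",
    ] = "focus_only"
    p: list[float] = Field(default_factory=lambda: [0.5])
    alpha: list[float] = Field(default_factory=lambda: [3.0])
    cost_per_word: list[float] = Field(default_factory=lambda: [0.0])
    ks: list[int] = Field(default_factory=lambda: [2, 3, 4, 5, 6, 7, 8])
    include_null: bool = True


class McmcSettings(_Strict):
    chains: int = 4
    iterations: int = 2000
    warmup_frac: float = 0.5
    thin: int = 5
    seed: int = 0


class DesignSettings(_Strict):
    experiment: int = 1
    probe: Literal["prior", "posterior"] = "posterior"
    prior_type: Literal["none", "some", "all"] = "some"
    n_participants: Optional[int] = None
    response_mode: Literal[
        "model_normalized", "non_normalizing", "constant_null"
    ] = "model_normalized"


class RunConfig(_Strict):
    """Validated run configuration; unknown keys are rejected."""

    model: ModelConfig = Field(default_factory=ModelConfig)
    mcmc: McmcSettings = Field(default_factory=McmcSettings)
    design: DesignSettings = Field(default_factory=DesignSettings)
    paths: dict = Field(default_factory=dict)


def load_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return RunConfig.model_validate(raw or {})


# --------------------------------------------------------------------------
# prediction curves (the five standard panel configurations)

#: named presets: (variants, p grid, alpha, cost grid, collapsed exclusives)
FIGURE_PRESETS = {
    # effect of the prior: p in {0.1, 0.5, 0.8} at alpha=3, zero cost
    "A": dict(variants=["focus_only"], p=[0.1, 0.5, 0.8], alpha=[3.0], cost=[0.0]),
    # effect of costs per focused word
    "B": dict(variants=["focus_only"], p=[0.5], alpha=[3.0], cost=[0.0, 0.5, 1.0]),
    # with and without exclusive alternatives
    "C": dict(
        variants=["focus_only", "focus_plus_exclusives"], p=[0.5], alpha=[3.0], cost=[0.0]
    ),
    # collapsed two-state / two-alternative space
    "D": dict(
        variants=["collapsed_two_state", "collapsed_two_state+exclusives"],
        p=[0.5], alpha=[3.0], cost=[0.0],
    ),
    # collapsed space with a k-independent constant prior
    "E": dict(
        variants=["collapsed_constant_prior", "collapsed_constant_prior+exclusives"],
        p=[0.5], alpha=[3.0], cost=[0.0],
    ),
}


def predict_curves(
    variants,
    ks,
    p_grid,
    alpha_grid,
    cost_grid=(0.0,),
    include_null: bool = True,
) -> pd.DataFrame:
    """Exhaustivity E(k) over a parameter grid for each model variant.

    Variant names may carry a ``+exclusives`` suffix to add exclusive
    alternatives to a collapsed space.  Returns one row per
    (variant, k, p, alpha, cost_per_word) combination.
    """
    ks = list(ks)
    if not ks or not list(p_grid) or not list(alpha_grid):
        raise ValueError("empty parameter grid")
    rows = []
    for variant in variants:
        base, _, suffix = variant.partition("+")
        collapsed_exclusives = suffix == "exclusives"
        for p in p_grid:
            for alpha in alpha_grid:
                for cost in cost_grid:
                    for k in ks:
                        e = exhaustivity(
                            k,
                            RSAParams(alpha=alpha, p=p, cost_per_word=cost),
                            base,
                            include_null=include_null,
                            collapsed_exclusives=collapsed_exclusives,
                        )
                        rows.append((variant, k, p, alpha, cost, e))
    return pd.DataFrame(
        rows, columns=["variant", "k", "p", "alpha", "cost_per_word", "exhaustivity"]
    )


def preset_curves(panel: str, ks=range(2, 9)) -> pd.DataFrame:
    """Prediction table for one of the named panel presets A-E."""
    if panel not in FIGURE_PRESETS:
        raise ValueError(f"unknown preset {panel!r}; choose from {sorted(FIGURE_PRESETS)}")
    cfg = FIGURE_PRESETS[panel]
    return predict_curves(cfg["variants"], ks, cfg["p"], cfg["alpha"], cfg["cost"])


def plot_curves(table: pd.DataFrame, path=None):
    """Line plot of E(k) against k, one line per (variant, p, cost) cell."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for (variant, p, cost), sub in table.groupby(["variant", "p", "cost_per_word"]):
        label = f"{variant}, p={p}, c={cost}"
        ax.plot(sub["k"], sub["exhaustivity"], marker="o", label=label)
    ax.set_xlabel("domain size k")
    ax.set_ylabel("exhaustivity E(k)")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def predictions_to_json(table: pd.DataFrame, path) -> None:
    records = table.to_dict(orient="records")
    Path(path).write_text(json.dumps({"schema_version": SCHEMA_VERSION, "predictions": records}, indent=2))
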
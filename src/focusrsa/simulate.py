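"""Synthetic slider-experiment generator.

Emulates the statistical structure of two belief-elicitation designs:

* **Experiment 1** — one slider per partial state.  Prior probes show all
  2**k states, posterior probes only the 2**(k-1) states compatible with
  the focus answer.  Each participant rates three items, pairing the three
  scenarios with domain sizes k in {2, 3, 4}.  Default arm sizes are 30
  (prior) and 66 (posterior) retained participants.
* **Experiment 2** — exactly two sliders at every domain size: the
  exhaustive state ("X acted and the others did not") and the pooled
  non-exhaustive description ("X and at least one other acted").  Prior
  probes are elicited knowing that the mentioned individual acted, so the
  state space matches the posterior probes.  Extra "none"/"all" prior-type
  arms manipulate the prior at fixed k=2 with a single item each.

Three response behaviors are available:

* ``model_normalized`` — responses follow the hierarchical generative
  model: beliefs from the population Dirichlet, posterior beliefs through
  the rational-speaker bridge, and a kappa-logit-normal response channel
  applied to each slider's state probability.  Raw sums then hover near 1.
* ``non_normalizing`` — each Experiment-1 slider responds to the
  participant's belief about the *size class* of the state (not divided
  among the C(k,m) interchangeable states), so raw sums grow with the
  number of sliders, emulating participants who do not renormalize.
* ``constant_null`` — the exhaustive slider sits at a constant raw level
  (default 0.9) regardless of domain size and prior, the behavioral null
  against which the Bayesian predictions are compared.

A configurable fraction of too-fast and all-zero participants is appended
so the exclusion stage has something to do; the design's ``n_participants``
is the count that survives exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._names import FIRST_NAMES
from .hier import (
    PosteriorHyperParams,
    PriorHyperParams,
    clip_unit,
    rsa_bridge,
)
from .states import compatible_states, condition_on_focus, expand_size_probs, state_sizes

__all__ = [
    "PRIOR_TYPE_SUCCESS",
    "ExperimentDesign",
    "ResponseBehavior",
    "experiment1_design",
    "experiment2_design",
    "prior_type_hyperparams",
    "default_hyperparams",
    "generate_dataset",
    "generate_constant_null_dataset",
]

SCENARIOS = ("vacation_camping", "halloween_superhero", "movienight_horror")

#: Bernoulli success probability of the size-class prior implied by each
#: prior-type wording; the population-mean exhaustive-state prior on the
#: conditioned k=2 space is (1 - p), i.e. 0.73 / 0.53 / 0.30.
PRIOR_TYPE_SUCCESS = {"none": 0.27, "some": 0.47, "all": 0.70}

RESPONSE_MODES = ("model_normalized", "non_normalizing", "constant_null")


@dataclass(frozen=True)
class ExperimentDesign:
    """One experimental arm: which probe, which domain sizes, how many
    retained participants, and (Experiment 2 only) which prior wording."""

    experiment: int = 1
    probe: str = "posterior"
    domain_sizes: tuple[int, ...] = (2, 3, 4)
    scenarios: tuple[str, ...] = SCENARIOS
    prior_type: str = "some"
    n_participants: int = 66
    items_per_participant: int = 3

    def __post_init__(self) -> None:
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if self.probe not in ("prior", "posterior"):
            raise ValueError("probe must be 'prior' or 'posterior'")
        if self.prior_type not in PRIOR_TYPE_SUCCESS:
            raise ValueError(f"prior_type must be one of {tuple(PRIOR_TYPE_SUCCESS)}")
        if self.experiment == 1 and self.prior_type != "some":
            raise ValueError("Experiment 1 uses the 'some' wording only")
        if self.prior_type in ("none", "all"):
            if self.domain_sizes != (2,) or self.items_per_participant != 1:
                raise ValueError(
                    "'none'/'all' arms are single-item trials at domain size 2"
                )
        if self.items_per_participant != len(self.domain_sizes):
            raise ValueError("one item per domain size: items must equal len(domain_sizes)")
        if len(self.scenarios) < self.items_per_participant:
            raise ValueError("not enough scenarios for the item count")
        if self.n_participants < 1:
            raise ValueError("need at least one participant")


def experiment1_design(probe: str) -> ExperimentDesign:
    """Experiment-1 arm: 30 prior / 66 posterior participants, k in {2,3,4}."""
    return ExperimentDesign(
        experiment=1,
        probe=probe,
        n_participants=30 if probe == "prior" else 66,
    )


def experiment2_design(probe: str, prior_type: str = "some") -> ExperimentDesign:
    """Experiment-2 arm with the published per-arm participant counts."""
    counts = {
        ("none", "prior"): 49, ("none", "posterior"): 82,
        ("some", "prior"): 65, ("some", "posterior"): 60,
        ("all", "prior"): 28, ("all", "posterior"): 63,
    }
    single = prior_type in ("none", "all")
    return ExperimentDesign(
        experiment=2,
        probe=probe,
        prior_type=prior_type,
        domain_sizes=(2,) if single else (2, 3, 4),
        items_per_participant=1 if single else 3,
        n_participants=counts[(prior_type, probe)],
    )


@dataclass(frozen=True)
class ResponseBehavior:
    """How raw slider positions arise from beliefs (see module docstring).

    ``constant_level``/``nonexh_level`` and ``constant_noise`` only apply in
    ``constant_null`` mode.  ``fast_fraction`` and ``allzero_fraction``
    control how many *additional* excludable participants are injected.
    """

    mode: str = "model_normalized"
    constant_level: float = 0.9
    nonexh_level: float = 0.25
    constant_noise: float = 0.05
    fast_fraction: float = 0.07
    allzero_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.mode not in RESPONSE_MODES:
            raise ValueError(f"mode must be one of {RESPONSE_MODES}")
        for name in ("constant_level", "nonexh_level"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        if self.constant_noise < 0:
            raise ValueError("constant_noise must be >= 0")


def prior_type_hyperparams(prior_type: str, k: int) -> PriorHyperParams:
    """Population hyperparameters implied by a prior-type wording.

    The mean size-class vector is binomial with the wording's success
    probability, so the population-mean exhaustive-state prior on the
    conditioned space is (1-p)**(k-1): 0.73, 0.53 and 0.30 at k=2 for
    "none", "some" and "all".  The "some" preset is the default generator
    prior.
    """
    if prior_type not in PRIOR_TYPE_SUCCESS:
        raise ValueError(f"unknown prior type {prior_type!r}")
    if prior_type in ("none", "all") and k != 2:
        raise ValueError(f"the {prior_type!r} wording was only used at k=2")
    p = PRIOR_TYPE_SUCCESS[prior_type]
    mu = np.array([comb(k, m) * p**m * (1 - p) ** (k - m) for m in range(k + 1)])
    return PriorHyperParams(mu={k: mu / mu.sum()})


def default_hyperparams(design: ExperimentDesign) -> PriorHyperParams | PosteriorHyperParams:
    """Generator defaults for one arm: the prior-type size distribution at
    every designed domain size, with kappa=1, w=20, sigma2=0.25 and (for
    posterior probes) mu_alpha=2, sigma2_alpha=1."""
    mu = {
        k: prior_type_hyperparams(design.prior_type, k).mu[k]
        for k in design.domain_sizes
    }
    if design.probe == "prior":
        return PriorHyperParams(mu=mu)
    return PosteriorHyperParams(mu=mu)


def _sample_domain(rng, k: int) -> tuple[str, ...]:
    names = rng.choice(len(FIRST_NAMES), size=k, replace=False)
    return tuple(sorted(FIRST_NAMES[i] for i in names))


def _channel(rng, Q, kappa: float, sigma2: float) -> np.ndarray:
    """Kappa-logit-normal response channel applied per slider.

    State probabilities saturate at the same bounds used when responses are
    mapped back to the logit scale, so the channel is its own inverse: a
    slider cannot express distinctions finer than the response resolution.
    """
    mu = kappa * logit(clip_unit(np.asarray(Q, dtype=float)))
    return expit(mu + np.sqrt(sigma2) * rng.standard_normal(np.shape(Q)))


def generate_dataset(
    design: ExperimentDesign,
    hyper: PriorHyperParams | PosteriorHyperParams | None = None,
    behavior: ResponseBehavior | None = None,
    seed: int = 0,
    return_params: bool = False,
) -> pd.DataFrame:
    """Simulate one experimental arm; same seed => byte-identical output.

    Returns a tidy frame with one row per participant x item x slider and
    columns (participant_id, experiment, probe, scenario, domain_size,
    prior_type, state_index, slider_label, raw_value, response_time_s,
    seed, domain_labels).  ``state_index`` is the bitmask state for
    Experiment-1 sliders and for the Experiment-2 exhaustive slider (always
    1); the pooled non-exhaustive slider has no single state and carries
    a missing state_index.
    """
    behavior = behavior or ResponseBehavior()
    hyper = hyper or default_hyperparams(design)
    if design.probe == "posterior" and behavior.mode != "constant_null":
        if not isinstance(hyper, PosteriorHyperParams):
            raise ValueError("posterior probes need PosteriorHyperParams")
    rng = np.random.default_rng(np.random.SeedSequence([seed, design.experiment,
                                                        0 if design.probe == "prior" else 1]))

    n_fast = round(behavior.fast_fraction * design.n_participants)
    n_zero = round(behavior.allzero_fraction * design.n_participants)
    n_total = design.n_participants + n_fast + n_zero
    # which injected participants get which defect
    defect = ["clean"] * design.n_participants + ["fast"] * n_fast + ["zero"] * n_zero

    arm = f"e{design.experiment}_{design.probe}_{design.prior_type}"
    rows: list[tuple] = []
    latents: dict = {"alpha": {}, "p": {}}
    for j in range(n_total):
        pid = f"{arm}_{j:03d}"
        # pair scenarios with domain sizes (random bijection per participant)
        order = rng.permutation(design.items_per_participant)
        scenarios = [design.scenarios[i] for i in order]
        alpha_j = None
        if design.probe == "posterior" and behavior.mode != "constant_null":
            a, b = hyper.mu_alpha**2 / hyper.sigma2_alpha, hyper.mu_alpha / hyper.sigma2_alpha
            alpha_j = rng.gamma(a, 1.0 / b)
            latents["alpha"][pid] = alpha_j
        bad_item = int(rng.integers(design.items_per_participant)) if defect[j] != "clean" else -1

        for item_ix, (k, scenario) in enumerate(zip(design.domain_sizes, scenarios)):
            labels = _sample_domain(rng, k)
            conc = hyper.w * np.asarray(hyper.mu[k])
            p_jk = rng.dirichlet(conc)
            latents["p"][(pid, k)] = p_jk
            Qfull = expand_size_probs(p_jk, k)

            if design.experiment == 1:
                if design.probe == "prior":
                    states = np.arange(1 << k)
                else:
                    states = compatible_states(k)
                slider_labels = [f"state_{s}" for s in states]
                state_col = [int(s) for s in states]
            else:
                states = None
                slider_labels = ["exhaustive", "nonexhaustive_pooled"]
                state_col = [1, pd.NA]

            if behavior.mode == "constant_null":
                n_sliders = len(slider_labels)
                raw = behavior.nonexh_level + behavior.constant_noise * rng.standard_normal(n_sliders)
                exh_pos = slider_labels.index("exhaustive") if design.experiment == 2 else (
                    int(np.flatnonzero(states == 1)[0])
                )
                raw[exh_pos] = behavior.constant_level + behavior.constant_noise * rng.standard_normal()
                raw = np.clip(raw, 0.0, 1.0)
            else:
                if design.probe == "prior":
                    if design.experiment == 1:
                        if behavior.mode == "non_normalizing":
                            Q = p_jk[state_sizes(k)[states]]  # size-class beliefs
                        else:
                            Q = Qfull[states]
                    else:  # Exp 2: conditioned on one known performer
                        qc = condition_on_focus(Qfull, k)
                        Q = np.array([qc[0], 1.0 - qc[0]])
                else:
                    qc = condition_on_focus(Qfull, k)
                    qpost = rsa_bridge(qc, alpha_j, k)
                    if design.experiment == 1:
                        if behavior.mode == "non_normalizing":
                            # respond to the pooled size-class posterior mass
                            msz = state_sizes(k)[states]
                            Q = np.array([qpost[msz == m].sum() for m in msz])
                        else:
                            Q = qpost
                    else:
                        Q = np.array([qpost[0], 1.0 - qpost[0]])
                raw = _channel(rng, Q, hyper.kappa, hyper.sigma2)

            if defect[j] == "zero" and item_ix == bad_item:
                raw = np.zeros_like(raw)
            rt = float(np.exp(np.log(40.0) + 0.4 * rng.standard_normal()))
            rt = max(rt, 15.5)
            if defect[j] == "fast" and item_ix == bad_item:
                rt = float(rng.uniform(5.0, 14.0))

            for lab, s, v in zip(slider_labels, state_col, raw):
                rows.append(
                    (pid, design.experiment, design.probe, scenario, k,
                     design.prior_type, s, lab, float(v), round(rt, 2), seed,
                     "|".join(labels))
                )

    df = pd.DataFrame(
        rows,
        columns=[
            "participant_id", "experiment", "probe", "scenario", "domain_size",
            "prior_type", "state_index", "slider_label", "raw_value",
            "response_time_s", "seed", "domain_labels",
        ],
    )
    df["state_index"] = df["state_index"].astype("Int64")
    if return_params:
        return df, latents
    return df


def generate_constant_null_dataset(
    design: ExperimentDesign,
    level: float = 0.9,
    noise: float = 0.05,
    seed: int = 0,
    nonexh_level: float = 0.25,
) -> pd.DataFrame:
    """Dataset from the constant-exhaustivity null behavior: the raw
    exhaustive slider is ``level`` plus truncated noise at every domain
    size and prior type; other sliders are drawn independently around
    ``nonexh_level``."""
    behavior = ResponseBehavior(
        mode="constant_null",
        constant_level=level,
        constant_noise=noise,
        nonexh_level=nonexh_level,
    )
    return generate_dataset(design, None, behavior, seed)
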
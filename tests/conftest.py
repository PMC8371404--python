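import dataclasses
import warnings

import pandas as pd
import pytest

from focusrsa import hier, simulate
from focusrsa.calibration import binomial_size_probs


def make_items(records):
    """Build a slider frame from (pid, k, scenario, state, raw, rt) tuples."""
    rows = [
        {
            "participant_id": pid,
            "experiment": 1,
            "probe": "prior",
            "scenario": scenario,
            "domain_size": k,
            "prior_type": "some",
            "state_index": state,
            "slider_label": f"state_{state}",
            "raw_value": raw,
            "response_time_s": rt,
            "seed": 0,
        }
        for pid, k, scenario, state, raw, rt in records
    ]
    df = pd.DataFrame(rows)
    df["state_index"] = df["state_index"].astype("Int64")
    return df


@pytest.fixture(scope="session")
def tiny_prior_data():
    """Prior-probe cohort small enough for quick MCMC smoke tests."""
    gen = hier.PriorHyperParams(
        kappa=1.0, w=20.0, sigma2=0.25,
        mu={k: binomial_size_probs(k, 0.4) for k in (2, 3)},
    )
    design = dataclasses.replace(
        simulate.experiment1_design("prior"),
        domain_sizes=(2, 3), items_per_participant=2, n_participants=10,
    )
    behavior = simulate.ResponseBehavior(fast_fraction=0.0, allzero_fraction=0.0)
    return simulate.generate_dataset(design, gen, behavior, seed=42)


@pytest.fixture(scope="session")
def tiny_prior_fit(tiny_prior_data):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return hier.fit_prior_model(
            tiny_prior_data, hier.McmcConfig(iterations=600, seed=7)
        )


@pytest.fixture(scope="session")
def tiny_posterior_data():
    gen = hier.PosteriorHyperParams(
        mu_alpha=3.0, sigma2_alpha=1.0, kappa=1.0, sigma2=0.25, w=20.0,
        mu={k: binomial_size_probs(k, 0.4) for k in (2, 3)},
    )
    design = dataclasses.replace(
        simulate.experiment1_design("posterior"),
        domain_sizes=(2, 3), items_per_participant=2, n_participants=10,
    )
    behavior = simulate.ResponseBehavior(fast_fraction=0.0, allzero_fraction=0.0)
    return simulate.generate_dataset(design, gen, behavior, seed=43)


@pytest.fixture(scope="session")
def tiny_posterior_fit(tiny_posterior_data):
    fixed = hier.PriorHyperParams(
        kappa=1.0, w=20.0, sigma2=0.25,
        mu={k: binomial_size_probs(k, 0.4) for k in (2, 3)},
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return hier.fit_posterior_model(
            tiny_posterior_data, fixed, hier.McmcConfig(iterations=600, seed=9)
        )
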
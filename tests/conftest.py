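import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tksig.harmonize import harmonize_cohort, select_subgroup
from tksig.pipeline import _survival_for, discover_signature
from tksig.signature import split_cohort
from tksig.simulate import SimulationConfig, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_tn_cohort(seed, n_datasets=4, samples_per_dataset=410, planted="default",
                   censoring_rate=0.4, n_genes_total=150, use_truth_anchors=True,
                   **kwargs):
    """Simulate, harmonize and select the triple-negative analysis set."""
    sim_kwargs = dict(
        seed=seed, n_datasets=n_datasets, samples_per_dataset=samples_per_dataset,
        censoring_rate=censoring_rate, n_genes_total=n_genes_total, **kwargs)
    if planted != "default":
        sim_kwargs["planted_genes"] = planted
    config = SimulationConfig(**sim_kwargs)
    bundle = simulate_cohort(config)
    anchors = (list(bundle.truth.samples.index[bundle.truth.samples["anchor"]])
               if use_truth_anchors else None)
    cohort, _ = harmonize_cohort(bundle.studies, bundle.clinical, anchor_ids=anchors)
    tn = select_subgroup(cohort, "TN", require_survival="dfs")
    return bundle, cohort, tn


def split_and_data(tn, seed, endpoint="dfs"):
    split = split_cohort(tn.matrix.columns, tn.clinical["platform"], seed=seed)
    learn = _survival_for(tn, split.learning_ids, endpoint)
    valid = _survival_for(tn, split.validation_ids, endpoint)
    return split, learn, valid


@pytest.fixture(scope="session")
def planted_run():
    """One default planted cohort with a discovered signature (shared, read-only)."""
    from tksig.genes import TK_PANEL

    bundle, cohort, tn = make_tn_cohort(seed=11)
    split, learn, valid = split_and_data(tn, seed=11)
    model, screen_table = discover_signature(tn, list(TK_PANEL), split)
    return {
        "bundle": bundle, "cohort": cohort, "tn": tn, "split": split,
        "learn": learn, "valid": valid, "model": model,
        "screen_table": screen_table,
    }


def toy_survival(seed=0, n=60, beta=0.7, censor_scale=2.0, k=1):
    """Small generic right-censored dataset with one or more covariates."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, k))
    b = np.zeros(k)
    b[0] = beta
    T = rng.exponential(1.0 / np.exp(X @ b))
    C = rng.exponential(censor_scale, n)
    t = np.minimum(T, C) * 12.0
    e = (T <= C).astype(int)
    return t, e, X
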
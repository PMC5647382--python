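"""Shared fixtures: a small planted cohort and the design pipeline run on it.

The small cohort (4 subgroups × 20 samples, 600 loci, 40 informative loci
per subgroup) keeps unit tests fast; the full-size defaults are exercised in
the acceptance tests.
"""

import numpy as np
import pandas as pd
import pytest

import msmimic as mm


@pytest.fixture(scope="session")
def small_config() -> mm.SyntheticConfig:
    return mm.SyntheticConfig(
        samples_per_subgroup=20,
        n_loci=600,
        informative_per_subgroup=40,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> mm.SyntheticCohort:
    return mm.simulate_cohort(small_config)


@pytest.fixture(scope="session")
def clean_cohort() -> mm.SyntheticCohort:
    """A noiseless, dropout-free cohort for exact-recovery checks."""
    profiles = {"frozen": mm.MaterialProfile(noise_sd=0.0, dropout=0.0)}
    return mm.simulate_cohort(
        mm.SyntheticConfig(
            samples_per_subgroup=15,
            n_loci=400,
            informative_per_subgroup=30,
            material_profiles=profiles,
            material_fractions={"frozen": 1.0},
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def pipeline(small_cohort):
    """Design pipeline on the small cohort, split into train and holdout.

    Returns a dict with the per-subgroup statistics, candidate set, fusion
    ranking, final signature and the two trained models.
    """
    cohort = small_cohort
    labels = cohort.true_labels
    train_ids, holdout_ids = [], []
    for g in mm.SUBGROUPS:
        ids = list(labels.index[labels == g])
        train_ids.extend(ids[:15])
        holdout_ids.extend(ids[15:])
    beta_train = cohort.beta.subset_samples(train_ids)
    y_train = labels.loc[train_ids]

    stats = {g: mm.moderated_t_stats(beta_train, y_train, g) for g in mm.SUBGROUPS}
    candidates = mm.select_candidates(stats, per_group_k=20)
    restricted = beta_train.subset_loci(candidates.pooled)
    ranking = mm.fusion_rank(
        restricted, y_train, seed=7, contrasts=candidates.contrasts
    )
    signature = mm.redundancy_optimize(
        ranking, restricted, y_train, target_size=17, n_iter=10, seed=7
    )
    full_model, sig_model = mm.train_models(
        beta_train, y_train, signature, seed=7, n_top=300
    )
    return {
        "cohort": cohort,
        "train_ids": train_ids,
        "holdout_ids": holdout_ids,
        "labels": labels,
        "stats": stats,
        "candidates": candidates,
        "ranking": ranking,
        "signature": signature,
        "full_model": full_model,
        "sig_model": sig_model,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)


def holdout_beta(pipeline) -> mm.BetaMatrix:
    return pipeline["cohort"].beta.subset_samples(pipeline["holdout_ids"])
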
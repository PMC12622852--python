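"""Shared fixtures: genomes, a planted-contrast cohort, a trained classifier.

The expensive synthetic cohorts are session-scoped so the classifier and
study-level tests share one simulation pass.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from valkit import ScarParams, build_genome, simulate_specimen
from valkit.caller import score_samples, split_train_test, train_model
from valkit.features import feature_matrix
from valkit.genome import GenomeModel
from valkit.simulate import (
    PROFILE_COLUMNS,
    CopyNumberProfile,
    decode_observed_profile,
)

CONTRAST_N_PER_CLASS = 200


@pytest.fixture(scope="session")
def genome() -> GenomeModel:
    return build_genome()


@pytest.fixture(scope="session")
def params() -> ScarParams:
    return ScarParams()


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    return build_genome(
        {"n_chromosomes": 4, "chromosome_length": 20_000_000, "centromere_fraction": 0.4}
    )


def make_random_profile(genome: GenomeModel, rng, max_segments_per_arm: int = 8):
    """A random (not necessarily maximal) tiling profile for oracle tests."""
    rows = []
    for arm in genome.arms:
        k = int(rng.integers(0, max_segments_per_arm))
        cuts = np.sort(rng.choice(np.arange(arm.start + 1, arm.end), size=k, replace=False))
        bounds = [arm.start] + [int(c) for c in cuts] + [arm.end]
        for s, e in zip(bounds[:-1], bounds[1:]):
            t = int(rng.integers(0, 6))
            m = int(rng.integers(0, t // 2 + 1))
            rows.append((arm.chrom, s, e, t, m))
    return CopyNumberProfile(pd.DataFrame(rows, columns=PROFILE_COLUMNS))


@pytest.fixture(scope="session")
def contrast_cohort(genome, params):
    """200 HRD-positive + 200 HRD-negative specimens with observed profiles.

    Observed profiles are decoded at each specimen's native purity, matching
    how replicates are scored in the study pipeline.
    """
    rng = np.random.default_rng(2024)
    truth_profiles, observed, labels, purities = {}, {}, {}, {}
    specimens = {}
    for i in range(2 * CONTRAST_N_PER_CLASS):
        lab = "positive" if i < CONTRAST_N_PER_CLASS else "negative"
        purity = float(rng.uniform(0.2, 0.9))
        sp = simulate_specimen(
            genome, lab, params, purity, int(rng.integers(0, 2**31 - 1)),
            specimen_id=f"C{i + 1}",
        )
        truth_profiles[sp.specimen_id] = sp.profile
        observed[sp.specimen_id] = decode_observed_profile(
            sp.profile, genome, purity, params.noise_sd,
            np.random.default_rng(int(rng.integers(0, 2**31 - 1))),
        )
        labels[sp.specimen_id] = 1 if lab == "positive" else 0
        purities[sp.specimen_id] = purity
        specimens[sp.specimen_id] = sp
    return {
        "truth": truth_profiles,
        "observed": observed,
        "labels": pd.Series(labels),
        "purities": pd.Series(purities),
        "specimens": specimens,
    }


@pytest.fixture(scope="session")
def contrast_features(contrast_cohort, genome) -> pd.DataFrame:
    return feature_matrix(contrast_cohort["observed"], genome)


@pytest.fixture(scope="session")
def trained_split(contrast_features, contrast_cohort):
    """7:3 split, trained ensemble and held-out scores on the contrast cohort."""
    labels = contrast_cohort["labels"]
    train_idx, test_idx = split_train_test(contrast_features, labels, 0.7, seed=11)
    model = train_model(contrast_features.loc[train_idx], labels.loc[train_idx], seed=11)
    test_scores = score_samples(model, contrast_features.loc[test_idx])
    return {
        "model": model,
        "train_idx": train_idx,
        "test_idx": test_idx,
        "test_scores": test_scores,
        "labels": labels,
    }
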
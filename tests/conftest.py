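"""Shared fixtures: small synthetic cohorts and expensive session-scoped runs."""

from __future__ import annotations

import numpy as np
import pytest

from dyadsat import preprocess, prediction
from dyadsat.connectivity import compute_rsfc
from dyadsat.pipeline import satisfaction_table, target_vector
from dyadsat.similarity import build_similarity_matrix
from dyadsat.synthetic import SyntheticConfig, generate_cohort


def small_config(n_pairs=8, n_regions=24, n_timepoints=80, seed=0, **kwargs):
    """A scaled-down cohort configuration for fast unit tests."""
    kwargs.setdefault("signal_pool", min(15, n_regions))
    return SyntheticConfig(
        n_subjects=2 * n_pairs,
        n_pairs=n_pairs,
        n_regions=n_regions,
        n_timepoints=n_timepoints,
        seed=seed,
        **kwargs,
    )


def pipeline_features(cohort, cutoff_hz=0.01):
    """Run cleaning -> RSFC -> dyad similarity; return (X, y_session1)."""
    rsfc = {}
    for subj in cohort.subjects:
        clean = preprocess.clean_timeseries(
            cohort.timeseries[subj],
            cohort.motion[subj],
            cohort.wm[subj],
            cohort.csf[subj],
            tr_seconds=cohort.config.tr_seconds,
            cutoff_hz=cutoff_hz,
        )
        rsfc[subj] = compute_rsfc(clean.data)
    X = build_similarity_matrix(rsfc, cohort.pairs)
    y = target_vector(satisfaction_table(cohort), "pair_mean", 1)
    return X, y


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def null_permutation_pvalues():
    """Permutation-test p-values on 50 independent null cohorts.

    Full pipeline at study scale (58 subjects, 120 regions, 180 volumes)
    with no planted signal; ridge family, 5 repeats, 200 permutations.
    Shared by the calibration acceptance check and the uniformity property.
    """
    spec = prediction.ModelSpec(family="ridge")
    pvals = []
    for seed in range(50):
        cohort = generate_cohort(SyntheticConfig(seed=seed))
        X, y = pipeline_features(cohort)
        res = prediction.permutation_test(
            X, y, spec, k=10, n_repeats=5, n_perm=200, seed=seed
        )
        pvals.append(res.p_value)
    return np.asarray(pvals)
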
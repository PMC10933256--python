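"""Dyadic similarity statistics.

Per-region interpersonal similarity of functional connectomes (the feature
matrix the predictive models consume), Euclidean personality-trait
distances, and the pair-level satisfaction and agreement scores.

For a pair of subjects with RSFC matrices A and B, the similarity for
region j is the Pearson correlation between column j of A and column j of B
after removing the (j, j) diagonal entry from both — N-1 points per
correlation, giving one feature per region and a P-pairs × N-regions
feature matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .connectivity import validate_rsfc

__all__ = [
    "dyad_similarity",
    "build_similarity_matrix",
    "personality_similarity",
    "pair_satisfaction",
    "agreement_score",
    "PairSimilarity",
]


def _column_pearson(a: np.ndarray, b: np.ndarray, j: int) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError(f"zero-variance correlation column for region index {j}")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def dyad_similarity(rsfc_a: np.ndarray, rsfc_b: np.ndarray) -> np.ndarray:
    """Per-region connectome similarity of two subjects.

    Element j is the Pearson correlation over the N-1 off-diagonal entries of
    column j of the two RSFC matrices (the (j, j) entry is excluded from
    both).  Symmetric in its arguments.
    """
    rsfc_a = np.asarray(rsfc_a, dtype=float)
    rsfc_b = np.asarray(rsfc_b, dtype=float)
    if rsfc_a.shape != rsfc_b.shape:
        raise ValueError(
            f"RSFC shape mismatch: {rsfc_a.shape} vs {rsfc_b.shape}"
        )
    validate_rsfc(rsfc_a, atol=1e-9)
    validate_rsfc(rsfc_b, atol=1e-9)
    n = rsfc_a.shape[0]
    keep = ~np.eye(n, dtype=bool)
    out = np.empty(n)
    for j in range(n):
        out[j] = _column_pearson(rsfc_a[keep[:, j], j], rsfc_b[keep[:, j], j], j)
    return out


def build_similarity_matrix(rsfc_by_subject: dict, pair_manifest) -> np.ndarray:
    """Stack per-pair similarity vectors into the P×N feature matrix.

    Parameters
    ----------
    rsfc_by_subject
        Mapping subject id -> N×N RSFC matrix.
    pair_manifest
        Sequence of (subject_a, subject_b) tuples; rows follow this order.
        Subjects must be disjoint across pairs.
    """
    seen: set = set()
    rows = []
    for a, b in pair_manifest:
        for s in (a, b):
            if s in seen:
                raise ValueError(f"subject {s!r} appears in more than one pair")
            if s not in rsfc_by_subject:
                raise ValueError(f"subject {s!r} missing from RSFC collection")
            seen.add(s)
        rows.append(dyad_similarity(rsfc_by_subject[a], rsfc_by_subject[b]))
    if not rows:
        raise ValueError("pair manifest is empty")
    return np.vstack(rows)


def personality_similarity(items_a: np.ndarray, items_b: np.ndarray) -> np.ndarray:
    """Euclidean distance between two subjects' item scores, per trait.

    Inputs are 5 traits × 12 items; element t of the output is the Euclidean
    distance between the two 12-item vectors of trait t (no standardization).
    """
    items_a = np.asarray(items_a, dtype=float)
    items_b = np.asarray(items_b, dtype=float)
    if items_a.shape != items_b.shape or items_a.ndim != 2 or items_a.shape[1] != 12:
        raise ValueError(
            f"expected matching (n_traits x 12) item matrices, got "
            f"{items_a.shape} and {items_b.shape}"
        )
    return np.linalg.norm(items_a - items_b, axis=1)


def _check_items(items: np.ndarray, lo: float = 1.0, hi: float = 8.0) -> np.ndarray:
    items = np.asarray(items, dtype=float).reshape(-1)
    if items.size == 0:
        raise ValueError("empty item vector")
    if np.any(items < lo) or np.any(items > hi):
        raise ValueError(f"item scores must lie in [{lo:g}, {hi:g}]")
    return items


def pair_satisfaction(items_a, items_b) -> float:
    """Pair-level satisfaction: mean of the two subjects' 18-item means."""
    a = _check_items(items_a)
    b = _check_items(items_b)
    return float((a.mean() + b.mean()) / 2.0)


def agreement_score(score_a: float, score_b: float) -> float:
    """Interpersonal agreement: absolute difference of two subject scores."""
    for s in (score_a, score_b):
        if not 1.0 <= s <= 8.0:
            raise ValueError("satisfaction scores must lie in [1, 8]")
    return abs(float(score_a) - float(score_b))


class PairSimilarity(BaseEstimator, TransformerMixin):
    """Transformer mapping stacked RSFC matrices to pair similarity features.

    Parameters
    ----------
    pairs
        Sequence of (index_a, index_b) into the subject axis; subjects must
        be disjoint across pairs.
    """

    def __init__(self, pairs=()):
        self.pairs = pairs

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_subjects, N, N)")
        self.n_regions_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        rsfc_by_subject = {i: X[i] for i in range(X.shape[0])}
        return build_similarity_matrix(rsfc_by_subject, list(self.pairs))
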
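"""Sparse count vectors over the training vocabulary.

The feature space is defined *only* by the keywords found in the training
sets A and B: one dimension per unique term ID across all A and B profiles,
and a coordinate equal to the raw occurrence count of that keyword in the
abstract.  No tf-idf, no normalization.  Query-set (C) profiles are
restricted to this vocabulary — term IDs unseen in training are silently
dropped, which may leave a zero vector; zero vectors are kept and scored
(they receive the model's intercept-only probability).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

from .tagger import KeywordProfile


@dataclass(frozen=True)
class FeatureSpace:
    """Bijection term_id -> dimension (0..V-1), lexicographic on term_id."""

    index: dict[str, int]

    @property
    def n_dims(self) -> int:
        return len(self.index)


@dataclass
class SparseVector:
    pmid: int
    label: str = "unlabeled"  # "A", "B", or "unlabeled"
    entries: dict[int, int] = field(default_factory=dict)

    def total(self) -> int:
        return sum(self.entries.values())


def build_feature_space(profiles_a: Sequence[KeywordProfile],
                        profiles_b: Sequence[KeywordProfile]) -> FeatureSpace:
    """Build the A∪B training vocabulary.

    Dimension order is lexicographic on term_id so the space is reproducible
    across runs regardless of profile order.
    """
    if not profiles_a or not profiles_b:
        raise ValueError("both training sets must contain at least one profile")
    terms: set[str] = set()
    for prof in list(profiles_a) + list(profiles_b):
        terms.update(prof.counts)
    if not terms:
        raise ValueError("untrainable input: no keywords tagged in either training set")
    return FeatureSpace({term: dim for dim, term in enumerate(sorted(terms))})


def vectorize(profile: KeywordProfile, space: FeatureSpace,
              label: str = "unlabeled") -> SparseVector:
    """Project a profile onto the feature space; out-of-vocabulary terms drop."""
    entries = {space.index[t]: c for t, c in profile.counts.items()
               if t in space.index}
    return SparseVector(profile.pmid, label, entries)


def to_csr(vectors: Sequence[SparseVector], n_dims: int) -> sparse.csr_matrix:
    """Stack sparse vectors into a CSR matrix (rows in input order)."""
    data, indices, indptr = [], [], [0]
    for vec in vectors:
        for dim in sorted(vec.entries):
            indices.append(dim)
            data.append(vec.entries[dim])
        indptr.append(len(indices))
    return sparse.csr_matrix(
        (np.asarray(data, dtype=np.float64),
         np.asarray(indices, dtype=np.int32),
         np.asarray(indptr, dtype=np.int32)),
        shape=(len(vectors), n_dims))


def labels_array(vectors: Sequence[SparseVector]) -> np.ndarray:
    """Encode labels as +1 for A, 0 for B (raises on unlabeled)."""
    out = np.empty(len(vectors), dtype=np.int64)
    for i, vec in enumerate(vectors):
        if vec.label not in ("A", "B"):
            raise ValueError(f"vector {vec.pmid} is unlabeled")
        out[i] = 1 if vec.label == "A" else 0
    return out


def export_sparse_text(vectors: Iterable[SparseVector], path) -> None:
    """Write vectors in the conventional ``label dim:count`` text format.

    Labels map to +1 (A) / -1 (B) / 0 (unlabeled); dimensions are written
    1-based ascending, as linear-classifier command-line tools expect.
    """
    label_code = {"A": "+1", "B": "-1", "unlabeled": "0"}
    with open(path, "w") as fh:
        for vec in vectors:
            feats = " ".join(f"{dim + 1}:{vec.entries[dim]}"
                             for dim in sorted(vec.entries))
            fh.write(f"{label_code[vec.label]} {feats}".rstrip() + "\n")
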
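"""Weighted-cosine nearest-neighbor case retrieval.

A query case and every stored case are mapped to weighted vectors
``(x_1 w_1, ..., x_n w_n)`` and compared by the cosine of their angle.
Because all entries are nonnegative, similarities lie in [0, 1]; 1 means
the two cases set exactly the same options.  Retrieval is exhaustive
(nearest-neighbor over the whole base) and returns either the top-k cases
or every case above a similarity threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .case_model import CaseBase
from .weighting import WeightVector

__all__ = [
    "RetrievalError",
    "RetrievalQuery",
    "RetrievalResult",
    "weighted_vector",
    "cosine_similarity",
    "retrieve",
]


class RetrievalError(ValueError):
    """Retrieval precondition violated."""


@dataclass
class RetrievalQuery:
    """Query vector plus retrieval mode (exactly one of top_k / min_similarity)."""

    x: np.ndarray
    top_k: Optional[int] = None
    min_similarity: Optional[float] = None
    feature_subset: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if (self.top_k is None) == (self.min_similarity is None):
            raise RetrievalError("set exactly one of top_k or min_similarity")
        if self.top_k is not None and self.top_k < 1:
            raise RetrievalError("top_k must be >= 1")
        if self.min_similarity is not None and not 0.0 <= self.min_similarity <= 1.0:
            raise RetrievalError("min_similarity must lie in [0, 1]")
        if self.feature_subset is not None:
            self.feature_subset = np.asarray(self.feature_subset, dtype=int)


@dataclass
class RetrievalResult:
    """Ranked (case_id, similarity) pairs, similarities non-increasing."""

    pairs: list[tuple[str, float]]
    query: Optional[RetrievalQuery] = field(default=None, repr=False)

    @property
    def case_ids(self) -> list[str]:
        return [cid for cid, _ in self.pairs]

    @property
    def similarities(self) -> np.ndarray:
        return np.array([s for _, s in self.pairs], dtype=float)

    @property
    def max_similarity(self) -> float:
        """Highest similarity found; 0 for an empty result."""
        return float(self.pairs[0][1]) if self.pairs else 0.0

    def __len__(self) -> int:
        return len(self.pairs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["case_id", "similarity"])

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def weighted_vector(
    x: Sequence[float],
    wv: Union[WeightVector, np.ndarray],
    feature_subset: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Elementwise product ``x_i * w_i`` over the active feature subset."""
    x = np.asarray(x, dtype=float)
    w = wv.weights() if isinstance(wv, WeightVector) else np.asarray(wv, dtype=float)
    if x.shape != w.shape:
        raise RetrievalError(f"dimension mismatch: x has {x.shape}, weights have {w.shape}")
    out = x * w
    if feature_subset is not None:
        mask = np.zeros_like(out, dtype=bool)
        mask[np.asarray(feature_subset, dtype=int)] = True
        out = np.where(mask, out, 0.0)
    return out


def cosine_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """Cosine of the angle between two weighted vectors.

    For nonnegative entries the value lies in [0, 1].  If either vector has
    zero norm the similarity is defined as 0 (an all-absent case matches
    nothing).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise RetrievalError(f"dimension mismatch: {a.shape} vs {b.shape}")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def retrieve(query: RetrievalQuery, cb: CaseBase, wv: WeightVector) -> RetrievalResult:
    """Exhaustive weighted-cosine retrieval over the case base.

    Similarities are sorted descending; ties break by case_id ascending.
    """
    if cb.D == 0:
        raise RetrievalError("case base is empty")
    w = wv.weights()
    if len(w) != cb.schema.n_options:
        raise RetrievalError(
            f"weight dimension {len(w)} != schema dimension {cb.schema.n_options}"
        )
    subset = query.feature_subset
    q = weighted_vector(query.x, w, subset)
    mat = cb.matrix.astype(float) * w  # row-wise weighted vectors
    if subset is not None:
        mask = np.zeros(len(w), dtype=bool)
        mask[subset] = True
        mat = np.where(mask, mat, 0.0)
    norms = np.linalg.norm(mat, axis=1)
    qn = np.linalg.norm(q)
    sims = np.zeros(cb.D, dtype=float)
    ok = norms > 0
    if qn > 0:
        sims[ok] = np.clip(mat[ok] @ q / (norms[ok] * qn), 0.0, 1.0)
    ids = cb.case_ids()
    ranked = sorted(range(cb.D), key=lambda i: (-sims[i], ids[i]))
    if query.top_k is not None:
        ranked = ranked[: query.top_k]
    else:
        ranked = [i for i in ranked if sims[i] >= query.min_similarity]
    return RetrievalResult(pairs=[(ids[i], float(sims[i])) for i in ranked], query=query)
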
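"""Case reuse: similarity-weighted protocol recommendation and retention.

Given the retrieved neighbors of a new case, each treatment protocol j gets
an *adoption rate*

    NewCT_j = sum_i CR_i * CT_ij / sum_i CR_i

— the similarity-weighted fraction of neighbors that used the protocol
(CR_i is neighbor i's similarity, CT_ij its 0/1 indicator for protocol j).
Rates map onto recommendation tiers (necessary / optional / reference /
none) through configurable thresholds, and a retention rule flags the new
case for human review when no stored case is sufficiently similar.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, model_validator

from .case_model import CaseBase
from .retrieval import RetrievalResult

logger = logging.getLogger(__name__)

__all__ = [
    "NoEvidenceError",
    "ReuseConfig",
    "Recommendation",
    "RetentionDecision",
    "adoption_rates",
    "assign_tiers",
    "recommend",
    "retention_decision",
    "append_to_review_queue",
]


class NoEvidenceError(ValueError):
    """No usable retrieved cases to base a recommendation on."""


class ReuseConfig(BaseModel):
    """Tier thresholds and retention threshold, all as fractions.

    Defaults: necessary above 0.95, optional in (0.75, 0.95], reference in
    (0.60, 0.75]; a new case is queued for retention review when its best
    match falls below 0.95.
    """

    necessary_min: float = 0.95
    optional_min: float = 0.75
    reference_min: float = 0.60
    retention_threshold: float = 0.95

    @model_validator(mode="after")
    def _ordered(self) -> "ReuseConfig":
        if not 0.0 <= self.reference_min < self.optional_min < self.necessary_min <= 1.0:
            raise ValueError(
                "thresholds must satisfy 0 <= reference_min < optional_min < necessary_min <= 1"
            )
        if not 0.0 <= self.retention_threshold <= 1.0:
            raise ValueError("retention_threshold must lie in [0, 1]")
        return self

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "ReuseConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(doc)


class RetentionDecision(str, Enum):
    ADD_PENDING_REVIEW = "add_to_base_pending_review"
    DISCARD = "discard"


@dataclass
class Recommendation:
    """Per-protocol adoption rates, tiers and supporting-case counts."""

    protocol_ids: list[str]
    rates: np.ndarray
    tiers: Optional[list[str]] = None
    n_supporting: Optional[np.ndarray] = None
    n_cases_used: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protocol_id": self.protocol_ids,
                "adoption_rate": self.rates,
                "tier": self.tiers if self.tiers is not None else [""] * len(self.protocol_ids),
                "n_supporting_cases": (
                    self.n_supporting.astype(int)
                    if self.n_supporting is not None
                    else [0] * len(self.protocol_ids)
                ),
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)


def adoption_rates(result: RetrievalResult, cb: CaseBase) -> Recommendation:
    """Similarity-weighted adoption rate of every protocol over the
    retrieved set.

    Retrieved cases lacking protocol indicators are excluded with a
    warning.  Raises :class:`NoEvidenceError` when no usable case remains
    or all similarities are zero.
    """
    by_id = {c.case_id: c for c in cb.cases}
    sims: list[float] = []
    prots: list[np.ndarray] = []
    for cid, sim in result.pairs:
        case = by_id.get(cid)
        if case is None:
            raise NoEvidenceError(f"retrieved case {cid!r} not found in case base")
        if case.protocols is None:
            logger.warning("case %s has no protocol indicators; excluded from reuse", cid)
            continue
        sims.append(sim)
        prots.append(case.protocols)
    if not sims:
        raise NoEvidenceError("no retrieved case carries protocol indicators")
    cr = np.array(sims, dtype=float)
    ct = np.vstack(prots).astype(float)
    total = cr.sum()
    if total <= 0.0:
        raise NoEvidenceError("all retrieved similarities are zero: no evidence to reuse")
    rates = (cr @ ct) / total
    return Recommendation(
        protocol_ids=[f"protocol_{j + 1}" for j in range(ct.shape[1])],
        rates=rates,
        n_supporting=ct.sum(axis=0).astype(int),
        n_cases_used=len(cr),
    )


def assign_tiers(rec: Recommendation, cfg: Optional[ReuseConfig] = None) -> Recommendation:
    """Map each adoption rate onto its recommendation tier.

    necessary: rate > necessary_min; optional: (optional_min, necessary_min];
    reference: (reference_min, optional_min]; none otherwise.  Half-open
    bands make the mapping total and non-overlapping.
    """
    cfg = cfg or ReuseConfig()
    tiers = []
    for r in rec.rates:
        if r > cfg.necessary_min:
            tiers.append("necessary")
        elif r > cfg.optional_min:
            tiers.append("optional")
        elif r > cfg.reference_min:
            tiers.append("reference")
        else:
            tiers.append("none")
    rec.tiers = tiers
    return rec


def recommend(
    result: RetrievalResult, cb: CaseBase, cfg: Optional[ReuseConfig] = None
) -> Recommendation:
    """Adoption rates plus tier assignment in one step."""
    return assign_tiers(adoption_rates(result, cb), cfg)


def retention_decision(
    result: RetrievalResult, cfg: Optional[ReuseConfig] = None
) -> RetentionDecision:
    """Decide whether the query case is novel enough to retain.

    If the best match falls below the retention threshold the case is
    queued for review (never auto-committed); an empty retrieval counts as
    maximum similarity 0, i.e. certainly novel.
    """
    cfg = cfg or ReuseConfig()
    if result.max_similarity < cfg.retention_threshold:
        return RetentionDecision.ADD_PENDING_REVIEW
    return RetentionDecision.DISCARD


def append_to_review_queue(
    path: Union[str, Path],
    case_id: str,
    x: np.ndarray,
    rec: Optional[Recommendation] = None,
) -> None:
    """Append a pending case (plus its recommendation) to a JSON-lines
    review queue for manual curation."""
    entry: dict = {"case_id": case_id, "x": np.asarray(x, dtype=int).tolist()}
    if rec is not None:
        entry["recommendation"] = {
            "protocol_ids": rec.protocol_ids,
            "adoption_rates": [float(r) for r in rec.rates],
            "tiers": rec.tiers,
        }
    with open(path, "a") as fh:
        fh.write(json.dumps(entry) + "\n")
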
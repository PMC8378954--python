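"""Attribute weighting: IDF, interclass dispersion, intraclass entropy.

The weight of a Boolean option combines up to three multiplicative factors:

* **IDF** — ``w_i = log2(D / D_i)`` where ``D`` is the total case count and
  ``D_i`` the number of cases with option *i* set.  Rare options are more
  typical of a case and get larger weights.  IDF alone, however,
  over-amplifies incidentally rare options and suppresses common options
  that are genuinely characteristic of a disease class.

* **Interclass dispersion** — a coefficient-of-variation statistic over the
  per-class relative frequencies ``f_k(i)`` of the option: the sample
  standard deviation of ``{f_k(i)}`` divided by their mean.  It is 0 when
  the option occurs with identical frequency in every class (no
  discriminative value) and maximal, ``sqrt(n_classes)``, when the option
  is concentrated in a single class.  We additionally report a normalized
  variant, raw / sqrt(n_classes) clamped to [0, 1], so that the two
  endpoints are 0 and 1 regardless of the number of classes; the
  normalized variant is the default factor in the combined weight.

* **Intraclass entropy** — the Shannon entropy (base-10 by default, the
  conventional reading of "lg") of the option's {0,1} value distribution
  within each class.  A 50/50 split within a class gives the maximum
  lg 2 ~ 0.301; a constant value gives 0.  Per-class entropies are
  aggregated into one per-option factor by a class-size-weighted mean
  (configurable: unweighted mean or max).

Combined modes: ``idf`` (IDF only), ``eq6`` (IDF x dispersion) and the full
``eq8`` (IDF x dispersion x entropy).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, model_validator

from .case_model import CaseBase

logger = logging.getLogger(__name__)

__all__ = [
    "WeightingError",
    "WeightingConfig",
    "ClassFrequencyTable",
    "WeightVector",
    "idf_weights",
    "class_frequencies",
    "interclass_dispersion",
    "intraclass_entropy",
    "combined_weights",
    "select_features",
]


class WeightingError(ValueError):
    """Weighting precondition violated (empty base, missing labels, ...)."""


class WeightingConfig(BaseModel):
    """Tunable knobs of the weighting scheme."""

    mode: Literal["idf", "eq6", "eq8"] = "eq8"
    entropy_log_base: float = 10.0
    dispersion_normalization: Literal["none", "sqrt_n", "clamp"] = "sqrt_n"
    entropy_aggregation: Literal["weighted_mean", "mean", "max"] = "weighted_mean"
    top_n: Optional[int] = None

    @model_validator(mode="after")
    def _check(self) -> "WeightingConfig":
        if self.entropy_log_base <= 1.0:
            raise ValueError("entropy_log_base must exceed 1")
        if self.top_n is not None and self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        return self

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "WeightingConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(doc)


@dataclass
class ClassFrequencyTable:
    """Per-class relative frequencies of each option.

    ``f[k][i]`` is the fraction of class-k cases in which option i is set;
    ``f_bar[i]`` is the unweighted mean of ``f[k][i]`` over classes.
    """

    classes: list[str]
    class_sizes: np.ndarray  # (n_classes,)
    f: np.ndarray  # (n_classes, n_options)
    f_bar: np.ndarray  # (n_options,)

    @property
    def n_classes(self) -> int:
        return len(self.classes)


@dataclass
class WeightVector:
    """Per-option weights with their component breakdown."""

    option_ids: list[str]
    D: int
    D_i: np.ndarray
    idf: np.ndarray
    dispersion_raw: Optional[np.ndarray] = None
    dispersion_norm: Optional[np.ndarray] = None
    entropy: Optional[np.ndarray] = None
    combined: Optional[np.ndarray] = None
    active: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.active is None:
            self.active = self.D_i > 0
        if self.combined is None:
            self.combined = self.idf.copy()

    @property
    def n_options(self) -> int:
        return len(self.option_ids)

    def weights(self) -> np.ndarray:
        """Final per-option weights (0 for inactive options)."""
        w = np.where(self.active, self.combined, 0.0)
        return np.asarray(w, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        def col(a: Optional[np.ndarray]) -> list:
            return [np.nan] * self.n_options if a is None else list(a)

        return pd.DataFrame(
            {
                "option_id": self.option_ids,
                "D_i": self.D_i.astype(int),
                "idf": self.idf,
                "dispersion_raw": col(self.dispersion_raw),
                "dispersion_norm": col(self.dispersion_norm),
                "entropy": col(self.entropy),
                "combined": self.combined,
                "active": self.active.astype(bool),
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path], D: Optional[int] = None) -> "WeightVector":
        df = pd.read_csv(path)
        def arr(name: str) -> Optional[np.ndarray]:
            if name not in df.columns or df[name].isna().all():
                return None
            return df[name].to_numpy(dtype=float)

        return cls(
            option_ids=df["option_id"].astype(str).tolist(),
            D=int(D) if D is not None else int(df["D_i"].max()),
            D_i=df["D_i"].to_numpy(dtype=int),
            idf=df["idf"].to_numpy(dtype=float),
            dispersion_raw=arr("dispersion_raw"),
            dispersion_norm=arr("dispersion_norm"),
            entropy=arr("entropy"),
            combined=df["combined"].to_numpy(dtype=float),
            active=df["active"].to_numpy(dtype=bool),
        )


# --------------------------------------------------------------------------
# the three factors
# --------------------------------------------------------------------------


def idf_weights(cb: CaseBase) -> WeightVector:
    """Inverse-document-frequency weights ``w_i = log2(D / D_i)``.

    Options never observed (``D_i = 0``) are flagged inactive with weight 0
    and are excluded from retrieval.
    """
    if cb.D == 0:
        raise WeightingError("case base is empty")
    d_i = cb.option_counts()
    idf = np.zeros(len(d_i), dtype=float)
    nz = d_i > 0
    idf[nz] = np.log2(cb.D / d_i[nz])
    return WeightVector(
        option_ids=cb.schema.option_ids,
        D=cb.D,
        D_i=d_i,
        idf=idf,
        combined=idf.copy(),
        active=nz,
    )


def class_frequencies(cb: CaseBase) -> ClassFrequencyTable:
    """Relative frequency of every option within every class, plus the
    unweighted across-class mean."""
    classes = cb.class_set
    if not classes:
        raise WeightingError(
            "no labeled cases: class frequencies are undefined; use IDF-only weighting"
        )
    labeled = [c for c in cb.cases if c.class_label is not None]
    sizes = np.array([sum(1 for c in labeled if c.class_label == k) for k in classes])
    mat = cb.matrix
    idx_by_class = {
        k: [i for i, c in enumerate(cb.cases) if c.class_label == k] for k in classes
    }
    f = np.vstack([mat[idx_by_class[k]].mean(axis=0) for k in classes])
    return ClassFrequencyTable(
        classes=classes, class_sizes=sizes, f=f, f_bar=f.mean(axis=0)
    )


def interclass_dispersion(
    freqs: ClassFrequencyTable,
    normalization: Literal["none", "sqrt_n", "clamp"] = "sqrt_n",
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient-of-variation dispersion of per-class frequencies.

    Returns ``(raw, normalized)``.  Raw is the sample standard deviation of
    ``{f_k(i)}`` over classes divided by the mean frequency; it ranges from
    0 (uniform across classes) to ``sqrt(n_classes)`` (all occurrences in
    one class).  The normalized variant rescales onto [0, 1].  Options
    absent everywhere (``f_bar = 0``) get dispersion 0.
    """
    n = freqs.n_classes
    if n < 2:
        raise WeightingError("interclass dispersion needs at least 2 classes")
    sd = freqs.f.std(axis=0, ddof=1)
    # identical frequencies in every class are dispersion 0 by definition;
    # kill the float residue the mean subtraction can leave behind
    sd[np.all(freqs.f == freqs.f[0:1], axis=0)] = 0.0
    raw = np.zeros_like(freqs.f_bar)
    nz = freqs.f_bar > 0
    raw[nz] = sd[nz] / freqs.f_bar[nz]
    if normalization == "none":
        norm = raw.copy()
    elif normalization == "sqrt_n":
        norm = np.clip(raw / np.sqrt(n), 0.0, 1.0)
    elif normalization == "clamp":
        norm = np.clip(raw, 0.0, 1.0)
    else:  # pragma: no cover - guarded by config validation
        raise WeightingError(f"unknown normalization {normalization!r}")
    return raw, norm


def _binary_entropy(p: np.ndarray, base: float) -> np.ndarray:
    """Entropy of a {0,1} distribution with P(1)=p; 0*log 0 := 0."""
    out = np.zeros_like(p, dtype=float)
    for q in (p, 1.0 - p):
        nz = q > 0
        out[nz] -= q[nz] * np.log(q[nz])
    return out / np.log(base)


def intraclass_entropy(
    cb: CaseBase,
    log_base: float = 10.0,
    aggregation: Literal["weighted_mean", "mean", "max"] = "weighted_mean",
) -> np.ndarray:
    """Per-option entropy of the option's value distribution within each
    class, aggregated over classes.

    Within class ``C_k`` the option takes values in {0, 1} with
    probabilities (1-p, p) where p is the within-class relative frequency;
    its entropy is ``-(p lg p + (1-p) lg (1-p))``.  The per-class values
    are combined into one per-option factor (default: class-size-weighted
    mean, least sensitive to tiny classes).
    """
    freqs = class_frequencies(cb)
    per_class = np.vstack([_binary_entropy(freqs.f[k], log_base) for k in range(freqs.n_classes)])
    if aggregation == "weighted_mean":
        w = freqs.class_sizes / freqs.class_sizes.sum()
        return w @ per_class
    if aggregation == "mean":
        return per_class.mean(axis=0)
    if aggregation == "max":
        return per_class.max(axis=0)
    raise WeightingError(f"unknown entropy aggregation {aggregation!r}")


def combined_weights(cb: CaseBase, config: Optional[WeightingConfig] = None) -> WeightVector:
    """Full weight vector under the configured mode.

    ``idf``: IDF only.  ``eq6``: IDF x dispersion.  ``eq8``: IDF x
    dispersion x entropy.  Dispersion uses the normalized variant chosen in
    the config (default raw / sqrt(n_classes), clamped to [0, 1]).
    """
    config = config or WeightingConfig()
    wv = idf_weights(cb)
    if config.mode == "idf":
        return wv
    freqs = class_frequencies(cb)
    if freqs.n_classes < 2:
        raise WeightingError(
            f"mode {config.mode!r} requires at least 2 classes; found {freqs.n_classes}"
        )
    raw, norm = interclass_dispersion(freqs, config.dispersion_normalization)
    wv.dispersion_raw = raw
    wv.dispersion_norm = norm
    disp = norm if config.dispersion_normalization != "none" else raw
    if config.mode == "eq6":
        wv.combined = wv.idf * disp
    else:  # eq8
        wv.entropy = intraclass_entropy(cb, config.entropy_log_base, config.entropy_aggregation)
        wv.combined = wv.idf * disp * wv.entropy
    wv.combined = np.where(wv.active, wv.combined, 0.0)
    return wv


def select_features(wv: WeightVector, n: int) -> np.ndarray:
    """Indices of the N largest combined weights.

    Inactive and zero-weight options are excluded first; ties break toward
    the lower option index.  If fewer than N options remain, all of them
    are returned with a warning.
    """
    if n < 1:
        raise WeightingError("n must be >= 1")
    w = wv.weights()
    eligible = np.flatnonzero(wv.active & (w > 0))
    if n > len(eligible):
        warnings.warn(
            f"requested {n} features but only {len(eligible)} active nonzero options; "
            "returning all of them",
            stacklevel=2,
        )
        n = len(eligible)
    order = sorted(eligible, key=lambda i: (-w[i], i))
    return np.array(sorted(order[:n]), dtype=int)
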
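"""Synthetic case-base generation.

The generator emulates the data a chronic-disease CBR engine is built on:
a case base partitioned into disease classes, Boolean options whose
per-class frequencies are controllable (class-concentrated options are
discriminative, class-uniform ones are not), and treatment-protocol
indicators correlated with class membership.  Every option of case k-class
cases is an independent Bernoulli draw with probability ``p[k][i]``;
protocol j likewise with ``q[k][j]``.  One seeded pseudo-random stream per
generation call makes fixtures bit-reproducible.

:func:`make_toy_base` builds, by exact counting rather than sampling, the
canonical 1000-case base in which the "sex" option is set in 489 cases and
two further options in 200 and 50 cases — the worked IDF examples
(log2(1000/489) ~ 1.03, log2(5) ~ 2.32, log2(20) ~ 4.32).
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml
from pydantic import BaseModel, model_validator

from .case_model import (
    AttributeSchema,
    BooleanCase,
    BooleanRule,
    CaseBase,
    OptionSpec,
    RawCase,
)

__all__ = ["GeneratorSpec", "generate", "concentrated_uniform_spec", "make_toy_base"]


class GeneratorSpec(BaseModel):
    """Full parameterization of a synthetic case base.

    ``p[k][i]`` is the probability that option i is set in a class-k case;
    ``q[k][j]`` the probability that a class-k case adopted protocol j.
    """

    n_classes: int
    cases_per_class: int
    p: list[list[float]]  # (n_classes, n_options)
    q: list[list[float]] = []  # (n_classes, n_protocols); empty = no protocols
    seed: int = 0
    option_ids: Optional[list[str]] = None
    class_labels: Optional[list[str]] = None

    @model_validator(mode="after")
    def _check(self) -> "GeneratorSpec":
        if self.n_classes < 1 or self.cases_per_class < 1:
            raise ValueError("n_classes and cases_per_class must be >= 1")
        if len(self.p) != self.n_classes:
            raise ValueError(f"p must have {self.n_classes} rows")
        n_opt = len(self.p[0])
        for row in self.p:
            if len(row) != n_opt:
                raise ValueError("p rows must have equal length")
        if self.q:
            if len(self.q) != self.n_classes:
                raise ValueError(f"q must have {self.n_classes} rows")
            n_prot = len(self.q[0])
            for row in self.q:
                if len(row) != n_prot:
                    raise ValueError("q rows must have equal length")
        for mat in (self.p, self.q):
            for row in mat:
                for v in row:
                    if not 0.0 <= v <= 1.0:
                        raise ValueError(f"probability {v} outside [0, 1]")
        if self.option_ids is not None and len(self.option_ids) != n_opt:
            raise ValueError("option_ids length must match p columns")
        if self.class_labels is not None and len(self.class_labels) != self.n_classes:
            raise ValueError("class_labels length must match n_classes")
        return self

    @property
    def n_options(self) -> int:
        return len(self.p[0])

    @property
    def n_protocols(self) -> int:
        return len(self.q[0]) if self.q else 0

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "GeneratorSpec":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def _identity_schema(option_ids: Sequence[str]) -> AttributeSchema:
    return AttributeSchema(
        entries=[
            OptionSpec(
                option_id=oid,
                source=oid,
                rule=BooleanRule(true_value=1, false_value=0),
            )
            for oid in option_ids
        ]
    )


def generate(spec: GeneratorSpec) -> tuple[list[RawCase], AttributeSchema]:
    """Draw a synthetic case base; output fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    option_ids = spec.option_ids or [f"opt_{i + 1}" for i in range(spec.n_options)]
    labels = spec.class_labels or [f"class_{k + 1}" for k in range(spec.n_classes)]
    p = np.asarray(spec.p, dtype=float)
    q = np.asarray(spec.q, dtype=float) if spec.q else None
    raws: list[RawCase] = []
    counter = 0
    for k in range(spec.n_classes):
        x = (rng.random((spec.cases_per_class, spec.n_options)) < p[k]).astype(int)
        prot = None
        if q is not None:
            prot = (rng.random((spec.cases_per_class, spec.n_protocols)) < q[k]).astype(int)
        for r in range(spec.cases_per_class):
            counter += 1
            raws.append(
                RawCase(
                    case_id=f"case_{counter:05d}",
                    values={oid: int(x[r, i]) for i, oid in enumerate(option_ids)},
                    class_label=labels[k],
                    protocols=prot[r].tolist() if prot is not None else None,
                )
            )
    return raws, _identity_schema(option_ids)


def concentrated_uniform_spec(
    n_classes: int = 3,
    cases_per_class: int = 500,
    seed: int = 0,
    concentrated_high: float = 0.9,
    concentrated_low: float = 0.1,
    uniform_p: float = 0.5,
) -> GeneratorSpec:
    """Two-option benchmark: one option concentrated in the first class
    (high probability there, low elsewhere) and one with identical
    probability in every class.

    A fully degenerate concentration (1 in one class, 0 elsewhere) would
    zero the intraclass-entropy factor, so the concentrated option keeps a
    small within-class spread by default.  Protocol 1 tracks class 1
    membership; protocol 2 is noise.
    """
    p = [
        [concentrated_high if k == 0 else concentrated_low, uniform_p]
        for k in range(n_classes)
    ]
    q = [[0.9 if k == 0 else 0.1, 0.5] for k in range(n_classes)]
    return GeneratorSpec(
        n_classes=n_classes,
        cases_per_class=cases_per_class,
        p=p,
        q=q,
        seed=seed,
        option_ids=["concentrated", "uniform"],
    )


def make_toy_base() -> CaseBase:
    """Deterministic 1000-case base with exact option counts 489/200/50.

    Constructed combinatorially (the first 489 cases set the sex option,
    the first 200 set the second option, the first 50 the third), so the
    resulting IDF weights are exact, not stochastic, and seed-independent.
    """
    counts = {"sex": 489, "daily_sleep_lt_6h": 200, "fruit_gt_1000g": 50}
    option_ids = list(counts)
    schema = _identity_schema(option_ids)
    cases = []
    for i in range(1000):
        x = np.array([1 if i < counts[oid] else 0 for oid in option_ids], dtype=np.int8)
        cases.append(BooleanCase(case_id=f"case_{i + 1:04d}", x=x))
    return CaseBase(schema=schema, cases=cases)
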
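"""Case data model and schema-driven Boolean encoding.

A *case* is one patient record: raw questionnaire attributes (sex, age,
sleep habits, ...), an optional class label (the diagnosed chronic-disease
category), and optional Boolean treatment-protocol indicators.  Before any
retrieval can happen, every raw attribute is decomposed into mutually
exclusive Boolean *options* (one-hot encoding driven by a declarative
:class:`AttributeSchema`), so that each case becomes an n-dimensional 0/1
feature vector.

Three decomposition rules are supported:

``boolean``
    a two-valued attribute mapped directly onto {0, 1}
    (e.g. sex: male -> 1, female -> 0);
``category_equals``
    option fires when the raw value equals a literal
    (e.g. daily sleep == "less than 6 hours");
``interval``
    option fires when a numeric value falls in a half-open
    interval ``[lower, upper)`` (e.g. age bins).  Intervals from the same
    source attribute must be pairwise disjoint, which guarantees the
    one-hot property.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "EncodingError",
    "CaseBaseError",
    "BooleanRule",
    "CategoryEqualsRule",
    "IntervalRule",
    "OptionSpec",
    "AttributeSchema",
    "RawCase",
    "BooleanCase",
    "CaseBase",
    "load_schema",
    "encode_case",
    "build_case_base",
    "read_raw_cases",
]


class SchemaError(ValueError):
    """The attribute schema is malformed or inconsistent."""


class EncodingError(ValueError):
    """A raw value cannot be encoded under the schema."""


class CaseBaseError(ValueError):
    """The case base violates a structural invariant."""


# --------------------------------------------------------------------------
# schema grammar
# --------------------------------------------------------------------------


class BooleanRule(BaseModel):
    """Two-valued attribute mapped onto {1, 0} via literal matching."""

    type: Literal["boolean"] = "boolean"
    true_value: Union[str, int, float, bool]
    false_value: Union[str, int, float, bool]

    @model_validator(mode="after")
    def _distinct(self) -> "BooleanRule":
        if _canon(self.true_value) == _canon(self.false_value):
            raise ValueError("true_value and false_value must differ")
        return self


class CategoryEqualsRule(BaseModel):
    type: Literal["category_equals"] = "category_equals"
    value: Union[str, int, float, bool]


class IntervalRule(BaseModel):
    """Half-open numeric interval [lower, upper); None = unbounded."""

    type: Literal["interval"] = "interval"
    lower: Optional[float] = None
    upper: Optional[float] = None

    @model_validator(mode="after")
    def _ordered(self) -> "IntervalRule":
        lo = -math.inf if self.lower is None else self.lower
        hi = math.inf if self.upper is None else self.upper
        if not lo < hi:
            raise ValueError(f"empty interval [{lo}, {hi})")
        return self

    def contains(self, value: float) -> bool:
        lo = -math.inf if self.lower is None else self.lower
        hi = math.inf if self.upper is None else self.upper
        return lo <= value < hi

    def overlaps(self, other: "IntervalRule") -> bool:
        lo1 = -math.inf if self.lower is None else self.lower
        hi1 = math.inf if self.upper is None else self.upper
        lo2 = -math.inf if other.lower is None else other.lower
        hi2 = math.inf if other.upper is None else other.upper
        return max(lo1, lo2) < min(hi1, hi2)


Rule = Union[BooleanRule, CategoryEqualsRule, IntervalRule]


def _canon(value: object) -> str:
    """Canonical string form used for literal matching (so 1 == "1")."""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value).strip()


class OptionSpec(BaseModel):
    """One Boolean option: a single dimension of the case vector."""

    option_id: str
    source: str
    rule: Rule = Field(discriminator="type")
    description: str = ""


class AttributeSchema(BaseModel):
    """Ordered list of options; entry order defines the vector index."""

    entries: list[OptionSpec]

    @model_validator(mode="after")
    def _validate(self) -> "AttributeSchema":
        seen: set[str] = set()
        for e in self.entries:
            if e.option_id in seen:
                raise ValueError(f"duplicate option_id {e.option_id!r}")
            seen.add(e.option_id)
        # interval disjointness per source attribute
        by_source: dict[str, list[OptionSpec]] = {}
        for e in self.entries:
            by_source.setdefault(e.source, []).append(e)
        for source, specs in by_source.items():
            ivals = [e for e in specs if isinstance(e.rule, IntervalRule)]
            for a_i in range(len(ivals)):
                for b_i in range(a_i + 1, len(ivals)):
                    a, b = ivals[a_i], ivals[b_i]
                    if a.rule.overlaps(b.rule):  # type: ignore[union-attr]
                        raise ValueError(
                            f"overlapping intervals on {source!r}: "
                            f"{a.option_id!r} and {b.option_id!r}"
                        )
            cats = [e for e in specs if isinstance(e.rule, CategoryEqualsRule)]
            values = [_canon(e.rule.value) for e in cats]  # type: ignore[union-attr]
            if len(values) != len(set(values)):
                raise ValueError(f"duplicate category values on {source!r}")
        return self

    @property
    def n_options(self) -> int:
        return len(self.entries)

    @property
    def option_ids(self) -> list[str]:
        return [e.option_id for e in self.entries]

    def index_of(self, option_id: str) -> int:
        for i, e in enumerate(self.entries):
            if e.option_id == option_id:
                return i
        raise KeyError(option_id)

    @property
    def sources(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.source not in out:
                out.append(e.source)
        return out

    def to_json(self, path: Union[str, Path]) -> None:
        doc = [e.model_dump(mode="json") for e in self.entries]
        Path(path).write_text(json.dumps(doc, indent=2))


def load_schema(path: Union[str, Path]) -> AttributeSchema:
    """Load and validate an attribute schema from a JSON file.

    The document is a top-level list of
    ``{option_id, source, rule: {type, ...}, description}`` objects.
    Raises :class:`SchemaError` naming the offending entry on failure.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: invalid JSON: {exc}") from exc
    if not isinstance(doc, list):
        raise SchemaError(f"{path}: expected a top-level list of options")
    entries = []
    for i, item in enumerate(doc):
        try:
            entries.append(OptionSpec.model_validate(item))
        except ValidationError as exc:
            ident = item.get("option_id", f"#{i}") if isinstance(item, dict) else f"#{i}"
            raise SchemaError(f"{path}: option {ident!r}: {exc}") from exc
    try:
        return AttributeSchema(entries=entries)
    except ValidationError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


# --------------------------------------------------------------------------
# cases
# --------------------------------------------------------------------------


@dataclass
class RawCase:
    """Unencoded case record as it arrives from a questionnaire table."""

    case_id: str
    values: Mapping[str, object]
    class_label: Optional[str] = None
    protocols: Optional[Sequence[int]] = None

    def __post_init__(self) -> None:
        if self.protocols is not None:
            bad = [p for p in self.protocols if p not in (0, 1)]
            if bad:
                raise CaseBaseError(
                    f"case {self.case_id!r}: protocol indicators must be 0/1, got {bad}"
                )


@dataclass
class BooleanCase:
    """Encoded case: an n-dimensional 0/1 feature vector plus metadata."""

    case_id: str
    x: np.ndarray
    class_label: Optional[str] = None
    protocols: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int8)
        if self.protocols is not None:
            self.protocols = np.asarray(self.protocols, dtype=np.int8)


@dataclass
class CaseBase:
    """An encoded case base: the memory a CBR engine retrieves from."""

    schema: AttributeSchema
    cases: list[BooleanCase] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.schema.n_options
        for c in self.cases:
            if c.x.shape != (n,):
                raise CaseBaseError(
                    f"case {c.case_id!r}: vector length {c.x.shape[0]} != schema dimension {n}"
                )
        n_prot = {len(c.protocols) for c in self.cases if c.protocols is not None}
        if len(n_prot) > 1:
            raise CaseBaseError(f"inconsistent protocol vector lengths: {sorted(n_prot)}")

    @property
    def D(self) -> int:
        """Total number of cases in the base."""
        return len(self.cases)

    @property
    def class_set(self) -> list[str]:
        """Distinct observed class labels, sorted for determinism."""
        return sorted({c.class_label for c in self.cases if c.class_label is not None})

    @property
    def n_classes(self) -> int:
        return len(self.class_set)

    @property
    def n_protocols(self) -> int:
        for c in self.cases:
            if c.protocols is not None:
                return len(c.protocols)
        return 0

    @property
    def matrix(self) -> np.ndarray:
        """D x n_options 0/1 matrix in case order."""
        if not self.cases:
            return np.zeros((0, self.schema.n_options), dtype=np.int8)
        return np.vstack([c.x for c in self.cases])

    def option_counts(self) -> np.ndarray:
        """D_i: number of cases in which option i is set."""
        return self.matrix.sum(axis=0).astype(int)

    def case_ids(self) -> list[str]:
        return [c.case_id for c in self.cases]

    # -------------------- persistence (encoded CSV dialect) -------------

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, list] = {"case_id": self.case_ids()}
        mat = self.matrix
        for i, oid in enumerate(self.schema.option_ids):
            cols[oid] = mat[:, i].tolist()
        cols["class"] = [c.class_label if c.class_label is not None else "" for c in self.cases]
        for j in range(self.n_protocols):
            cols[f"protocol_{j + 1}"] = [
                int(c.protocols[j]) if c.protocols is not None else "" for c in self.cases
            ]
        return pd.DataFrame(cols)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path], schema: AttributeSchema) -> "CaseBase":
        df = pd.read_csv(path, dtype={"case_id": str}, keep_default_na=False)
        missing = [oid for oid in schema.option_ids if oid not in df.columns]
        if missing:
            raise CaseBaseError(f"{path}: missing option columns {missing}")
        prot_cols = sorted(
            (c for c in df.columns if c.startswith("protocol_")),
            key=lambda c: int(c.split("_", 1)[1]),
        )
        cases = []
        for _, row in df.iterrows():
            x = np.array([int(row[oid]) for oid in schema.option_ids], dtype=np.int8)
            label = str(row["class"]) if "class" in df.columns and str(row["class"]) else None
            prot = None
            if prot_cols and all(str(row[c]) != "" for c in prot_cols):
                prot = np.array([int(row[c]) for c in prot_cols], dtype=np.int8)
            cases.append(BooleanCase(str(row["case_id"]), x, label, prot))
        return cls(schema=schema, cases=cases)


# --------------------------------------------------------------------------
# encoding
# --------------------------------------------------------------------------


def _is_missing(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False


def encode_case(raw: RawCase, schema: AttributeSchema) -> BooleanCase:
    """Encode a raw case into its Boolean feature vector.

    Missing attributes encode as all-zero for the attribute's options (with
    a warning); numeric values outside every interval of their source
    attribute, or two-valued attributes with an unrecognized literal, raise
    :class:`EncodingError`.
    """
    x = np.zeros(schema.n_options, dtype=np.int8)
    missing_warned: set[str] = set()
    # track, per interval-decomposed source, whether any bin matched
    interval_hit: dict[str, bool] = {}
    interval_value: dict[str, float] = {}

    for i, spec in enumerate(schema.entries):
        value = raw.values.get(spec.source)
        if _is_missing(value):
            if spec.source not in missing_warned:
                logger.warning(
                    "case %s: attribute %r missing; its options encode as 0",
                    raw.case_id,
                    spec.source,
                )
                missing_warned.add(spec.source)
            continue
        rule = spec.rule
        if isinstance(rule, BooleanRule):
            v = _canon(value)
            if v == _canon(rule.true_value):
                x[i] = 1
            elif v == _canon(rule.false_value):
                x[i] = 0
            else:
                raise EncodingError(
                    f"case {raw.case_id!r}: attribute {spec.source!r} value {value!r} "
                    f"matches neither {rule.true_value!r} nor {rule.false_value!r}"
                )
        elif isinstance(rule, CategoryEqualsRule):
            if _canon(value) == _canon(rule.value):
                x[i] = 1
        elif isinstance(rule, IntervalRule):
            try:
                num = float(value)  # type: ignore[arg-type]
            except (TypeError, ValueError) as exc:
                raise EncodingError(
                    f"case {raw.case_id!r}: attribute {spec.source!r} value {value!r} "
                    "is not numeric"
                ) from exc
            interval_value[spec.source] = num
            hit = rule.contains(num)
            interval_hit[spec.source] = interval_hit.get(spec.source, False) or hit
            if hit:
                x[i] = 1

    for source, hit in interval_hit.items():
        if not hit:
            raise EncodingError(
                f"case {raw.case_id!r}: attribute {source!r} value "
                f"{interval_value[source]!r} falls outside every interval"
            )

    protocols = None if raw.protocols is None else np.asarray(raw.protocols, dtype=np.int8)
    return BooleanCase(raw.case_id, x, raw.class_label, protocols)


def build_case_base(raws: Sequence[RawCase], schema: AttributeSchema) -> CaseBase:
    """Encode raw cases in input order into a :class:`CaseBase`."""
    seen: set[str] = set()
    for raw in raws:
        if raw.case_id in seen:
            raise CaseBaseError(f"duplicate case_id {raw.case_id!r}")
        seen.add(raw.case_id)
    return CaseBase(schema=schema, cases=[encode_case(r, schema) for r in raws])


def read_raw_cases(path: Union[str, Path]) -> list[RawCase]:
    """Read a raw-case CSV/TSV: case_id, attribute columns, optional
    ``class`` column and ``protocol_*`` columns."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype={"case_id": str}, keep_default_na=False)
    if "case_id" not in df.columns:
        raise CaseBaseError(f"{path}: missing required column 'case_id'")
    prot_cols = sorted(
        (c for c in df.columns if c.startswith("protocol_")),
        key=lambda c: int(c.split("_", 1)[1]),
    )
    attr_cols = [c for c in df.columns if c not in {"case_id", "class"} and c not in prot_cols]
    raws = []
    for _, row in df.iterrows():
        label = str(row["class"]) if "class" in df.columns and str(row["class"]) != "" else None
        prot = None
        if prot_cols and all(str(row[c]) != "" for c in prot_cols):
            prot = [int(row[c]) for c in prot_cols]
        raws.append(
            RawCase(
                case_id=str(row["case_id"]),
                values={c: row[c] for c in attr_cols},
                class_label=label,
                protocols=prot,
            )
        )
    return raws
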
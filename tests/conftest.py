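import numpy as np
import pytest

from cbrcare.case_model import (
    AttributeSchema,
    BooleanCase,
    BooleanRule,
    CaseBase,
    CategoryEqualsRule,
    IntervalRule,
    OptionSpec,
)


@pytest.fixture
def questionnaire_schema() -> AttributeSchema:
    """Lifestyle-questionnaire schema: sex, age bins, sleep categories,
    weekly fruit intake bins, family diabetes history."""
    return AttributeSchema(
        entries=[
            OptionSpec(
                option_id="sex",
                source="sex",
                rule=BooleanRule(true_value="Male", false_value="Female"),
                description="male 1, female 0",
            ),
            OptionSpec(option_id="child", source="age", rule=IntervalRule(lower=0, upper=12)),
            OptionSpec(option_id="teenager", source="age", rule=IntervalRule(lower=12, upper=18)),
            OptionSpec(option_id="youth", source="age", rule=IntervalRule(lower=18, upper=40)),
            OptionSpec(
                option_id="middle_age", source="age", rule=IntervalRule(lower=40, upper=60)
            ),
            OptionSpec(option_id="old_age", source="age", rule=IntervalRule(lower=60, upper=None)),
            OptionSpec(
                option_id="sleep_lt_6h",
                source="daily_sleep",
                rule=CategoryEqualsRule(value="less than 6 hours"),
            ),
            OptionSpec(
                option_id="sleep_6_7h",
                source="daily_sleep",
                rule=CategoryEqualsRule(value="6-7 hours"),
            ),
            OptionSpec(
                option_id="sleep_7_8h",
                source="daily_sleep",
                rule=CategoryEqualsRule(value="7-8 hours"),
            ),
            OptionSpec(
                option_id="sleep_gt_8h",
                source="daily_sleep",
                rule=CategoryEqualsRule(value="more than 8 hours"),
            ),
            OptionSpec(
                option_id="fruit_lt_250g",
                source="fruit_per_week",
                rule=IntervalRule(lower=0, upper=250),
            ),
            OptionSpec(
                option_id="fruit_250_1000g",
                source="fruit_per_week",
                rule=IntervalRule(lower=250, upper=1000),
            ),
            OptionSpec(
                option_id="fruit_gt_1000g",
                source="fruit_per_week",
                rule=IntervalRule(lower=1000, upper=None),
            ),
            OptionSpec(
                option_id="family_diabetes",
                source="family_diabetes",
                rule=BooleanRule(true_value="Yes", false_value="No"),
            ),
        ]
    )


def identity_schema(n_options: int) -> AttributeSchema:
    return AttributeSchema(
        entries=[
            OptionSpec(
                option_id=f"opt_{i + 1}",
                source=f"opt_{i + 1}",
                rule=BooleanRule(true_value=1, false_value=0),
            )
            for i in range(n_options)
        ]
    )


def base_from_matrix(mat, labels=None, protocols=None) -> CaseBase:
    """Build an encoded CaseBase directly from a 0/1 matrix (test helper)."""
    mat = np.asarray(mat, dtype=np.int8)
    schema = identity_schema(mat.shape[1])
    cases = []
    for i in range(mat.shape[0]):
        cases.append(
            BooleanCase(
                case_id=f"c{i + 1:04d}",
                x=mat[i],
                class_label=None if labels is None else labels[i],
                protocols=None if protocols is None else np.asarray(protocols[i], dtype=np.int8),
            )
        )
    return CaseBase(schema=schema, cases=cases)


def random_base(rng, D, n_options, n_classes=0, with_protocols=0) -> CaseBase:
    """Random dense-ish Boolean base for oracle comparisons."""
    mat = (rng.random((D, n_options)) < rng.uniform(0.1, 0.9, size=n_options)).astype(np.int8)
    labels = None
    if n_classes:
        labels = [f"class_{k + 1}" for k in rng.integers(0, n_classes, size=D)]
    protocols = None
    if with_protocols:
        protocols = (rng.random((D, with_protocols)) < 0.5).astype(np.int8)
    return base_from_matrix(mat, labels, protocols)
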
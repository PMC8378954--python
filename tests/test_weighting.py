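"""Attribute weighting: IDF, dispersion, entropy vs brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cbrcare.weighting import (
    WeightingConfig,
    WeightingError,
    class_frequencies,
    combined_weights,
    idf_weights,
    interclass_dispersion,
    intraclass_entropy,
    select_features,
)

from conftest import base_from_matrix, random_base


# ------------------------- independent oracles ---------------------------


def brute_class_frequencies(cb):
    """Loop-and-count oracle for per-class option frequencies."""
    classes = sorted({c.class_label for c in cb.cases if c.class_label})
    f = {}
    for k in classes:
        members = [c for c in cb.cases if c.class_label == k]
        f[k] = [sum(int(c.x[i]) for c in members) / len(members) for i in range(cb.schema.n_options)]
    return classes, f


def brute_entropy(cb, base=10.0, aggregation="weighted_mean"):
    """Tally-and-sum entropy oracle, all pure-python loops."""
    classes, f = brute_class_frequencies(cb)
    sizes = {k: sum(1 for c in cb.cases if c.class_label == k) for k in classes}
    n_labeled = sum(sizes.values())
    out = []
    for i in range(cb.schema.n_options):
        per_class = []
        for k in classes:
            e = 0.0
            for p in (f[k][i], 1.0 - f[k][i]):
                if p > 0:
                    e -= p * math.log(p, base)
            per_class.append(e)
        if aggregation == "weighted_mean":
            out.append(sum(sizes[k] * e for k, e in zip(classes, per_class)) / n_labeled)
        elif aggregation == "mean":
            out.append(sum(per_class) / len(per_class))
        else:
            out.append(max(per_class))
    return np.array(out)


def brute_dispersion_raw(cb):
    classes, f = brute_class_frequencies(cb)
    n = len(classes)
    out = []
    for i in range(cb.schema.n_options):
        vals = [f[k][i] for k in classes]
        mean = sum(vals) / n
        if mean == 0:
            out.append(0.0)
            continue
        var = sum((v - mean) ** 2 for v in vals) / (n - 1)
        out.append(math.sqrt(var) / mean)
    return np.array(out)


# ------------------------------- IDF --------------------------------------


class TestIdf:
    def test_published_worked_examples(self):
        """1000-case base with option counts 489/200/50 gives weights
        1.03 / 2.32 / 4.32 at two decimals."""
        from cbrcare.synthgen import make_toy_base

        wv = idf_weights(make_toy_base())
        assert [round(v, 2) for v in wv.idf] == [1.03, 2.32, 4.32]

    def test_universal_option_weighs_zero(self):
        cb = base_from_matrix(np.ones((10, 1), dtype=int))
        assert idf_weights(cb).idf[0] == 0.0

    def test_unobserved_option_inactive(self):
        cb = base_from_matrix(np.column_stack([np.ones(5), np.zeros(5)]).astype(int))
        wv = idf_weights(cb)
        assert not wv.active[1]
        assert wv.weights()[1] == 0.0

    def test_empty_base_rejected(self):
        cb = base_from_matrix(np.zeros((0, 3), dtype=int))
        with pytest.raises(WeightingError):
            idf_weights(cb)

    @given(st.data())
    @settings(max_examples=30, deadline=None)
    def test_rarer_option_weighs_more(self, data):
        """Monotonicity: D_i < D_j implies idf_i > idf_j for fixed D."""
        D = data.draw(st.integers(min_value=3, max_value=100))
        d_i = data.draw(st.integers(min_value=1, max_value=D - 1))
        d_j = data.draw(st.integers(min_value=d_i + 1, max_value=D))
        mat = np.zeros((D, 2), dtype=int)
        mat[:d_i, 0] = 1
        mat[:d_j, 1] = 1
        wv = idf_weights(base_from_matrix(mat))
        assert wv.idf[0] > wv.idf[1]


# --------------------------- class frequencies ----------------------------


class TestClassFrequencies:
    def test_direct_count_example(self):
        mat = np.array([[1], [1], [0], [0], [1], [0]])
        labels = ["A"] * 4 + ["B"] * 2
        freqs = class_frequencies(base_from_matrix(mat, labels))
        assert freqs.f[0, 0] == pytest.approx(0.5)
        assert freqs.f[1, 0] == pytest.approx(0.5)
        assert freqs.f_bar[0] == pytest.approx(0.5)

    def test_absent_option_has_zero_mean(self):
        cb = base_from_matrix(np.zeros((6, 1), dtype=int), ["A", "A", "B", "B", "C", "C"])
        assert class_frequencies(cb).f_bar[0] == 0.0

    def test_unlabeled_base_rejected(self):
        with pytest.raises(WeightingError, match="label"):
            class_frequencies(base_from_matrix(np.ones((4, 2), dtype=int)))

    def test_matches_brute_force_on_random_base(self):
        cb = random_base(np.random.default_rng(11), D=150, n_options=8, n_classes=3)
        freqs = class_frequencies(cb)
        classes, f = brute_class_frequencies(cb)
        assert freqs.classes == classes
        for k_idx, k in enumerate(classes):
            np.testing.assert_allclose(freqs.f[k_idx], f[k], rtol=1e-12)
        np.testing.assert_allclose(
            freqs.f_bar, np.mean([f[k] for k in classes], axis=0), rtol=1e-12
        )


# ------------------------------ dispersion ---------------------------------


class TestDispersion:
    def test_uniform_frequencies_give_zero(self):
        """Identical frequency in every class: no class-discriminative
        value, dispersion exactly 0."""
        mat = np.array([[1], [1], [0], [0], [0]] * 3)
        labels = sum([[k] * 5 for k in "ABC"], [])
        raw, norm = interclass_dispersion(class_frequencies(base_from_matrix(mat, labels)))
        assert raw[0] == 0.0
        assert norm[0] == 0.0

    @pytest.mark.parametrize("n_classes", [2, 3, 4, 5, 6])
    def test_single_class_concentration_endpoint(self, n_classes):
        """All occurrences in one class: raw CV = sqrt(n_classes),
        normalized value 1."""
        per = 10
        mat = np.zeros((per * n_classes, 1), dtype=int)
        mat[: per // 2, 0] = 1  # only class 0 has the option
        labels = sum([[f"class_{k}"] * per for k in range(n_classes)], [])
        raw, norm = interclass_dispersion(class_frequencies(base_from_matrix(mat, labels)))
        assert raw[0] == pytest.approx(math.sqrt(n_classes), rel=1e-12)
        assert norm[0] == pytest.approx(1.0, rel=1e-12)

    def test_hand_evaluated_two_class_case(self):
        """f = [0.2, 0.4]: raw CV = stdev([0.2, 0.4]) / 0.3."""
        mat = np.array([[1]] * 2 + [[0]] * 8 + [[1]] * 4 + [[0]] * 6)
        labels = ["A"] * 10 + ["B"] * 10
        raw, _ = interclass_dispersion(class_frequencies(base_from_matrix(mat, labels)))
        expected = np.std([0.2, 0.4], ddof=1) / 0.3
        assert raw[0] == pytest.approx(expected, rel=1e-12)

    def test_single_class_rejected(self):
        cb = base_from_matrix(np.ones((5, 1), dtype=int), ["A"] * 5)
        with pytest.raises(WeightingError, match="2 classes"):
            interclass_dispersion(class_frequencies(cb))

    def test_matches_brute_force_and_stays_in_range(self):
        cb = random_base(np.random.default_rng(5), D=200, n_options=10, n_classes=4)
        raw, norm = interclass_dispersion(class_frequencies(cb))
        np.testing.assert_allclose(raw, brute_dispersion_raw(cb), rtol=1e-12)
        assert np.all((norm >= 0) & (norm <= 1))


# ------------------------------- entropy -----------------------------------


class TestEntropy:
    def test_even_split_gives_lg2(self):
        mat = np.array([[1], [0]] * 5)
        cb = base_from_matrix(mat, ["A"] * 10)
        assert intraclass_entropy(cb)[0] == pytest.approx(math.log10(2), rel=1e-12)

    def test_constant_option_gives_zero(self):
        cb = base_from_matrix(np.ones((8, 1), dtype=int), ["A"] * 4 + ["B"] * 4)
        assert intraclass_entropy(cb)[0] == 0.0

    def test_base2_rescales_but_preserves_order(self):
        cb = random_base(np.random.default_rng(3), D=120, n_options=6, n_classes=3)
        e10 = intraclass_entropy(cb, log_base=10.0)
        e2 = intraclass_entropy(cb, log_base=2.0)
        np.testing.assert_allclose(e2, e10 / math.log10(2), rtol=1e-12)

    @pytest.mark.parametrize("aggregation", ["weighted_mean", "mean", "max"])
    def test_matches_brute_force_oracle(self, aggregation):
        cb = random_base(np.random.default_rng(17), D=180, n_options=9, n_classes=3)
        ours = intraclass_entropy(cb, aggregation=aggregation)
        np.testing.assert_allclose(ours, brute_entropy(cb, 10.0, aggregation), rtol=1e-12)

    def test_entropy_maximal_at_even_split(self):
        """Within one class, a 50/50 option beats any skewed option."""
        mat = np.column_stack([[1, 0] * 5, [1] * 9 + [0]])
        cb = base_from_matrix(mat, ["A"] * 10)
        e = intraclass_entropy(cb)
        assert e[0] > e[1]


# --------------------------- combined weights ------------------------------


class TestCombined:
    def test_modes_agree_with_component_products(self):
        cb = random_base(np.random.default_rng(23), D=150, n_options=7, n_classes=3)
        w_idf = combined_weights(cb, WeightingConfig(mode="idf"))
        w6 = combined_weights(cb, WeightingConfig(mode="eq6"))
        w8 = combined_weights(cb, WeightingConfig(mode="eq8"))
        np.testing.assert_allclose(w_idf.combined, w_idf.idf)
        active = w6.active
        np.testing.assert_allclose(
            w6.combined[active], (w6.idf * w6.dispersion_norm)[active], rtol=1e-12
        )
        np.testing.assert_allclose(
            w8.combined[active],
            (w8.idf * w8.dispersion_norm * w8.entropy)[active],
            rtol=1e-12,
        )

    def test_single_class_base_rejected_for_eq8(self):
        cb = base_from_matrix(np.eye(4, dtype=int), ["A"] * 4)
        with pytest.raises(WeightingError, match="classes"):
            combined_weights(cb, WeightingConfig(mode="eq8"))

    def test_class_uniform_option_gets_zero_combined_weight(self):
        """An option with identical frequency in every class is flagged
        droppable: combined weight 0 under eq6/eq8."""
        mat = np.column_stack([[1, 0] * 6, [1] * 6 + [0] * 6])
        labels = ["A"] * 6 + ["B"] * 6
        w6 = combined_weights(base_from_matrix(mat, labels), WeightingConfig(mode="eq6"))
        assert w6.combined[0] == 0.0  # uniform 0.5 in both classes
        assert w6.combined[1] > 0.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(Exception):
            WeightingConfig(mode="eq99")

    def test_weight_report_roundtrip(self, tmp_path):
        from cbrcare.weighting import WeightVector

        cb = random_base(np.random.default_rng(29), D=80, n_options=5, n_classes=2)
        wv = combined_weights(cb, WeightingConfig(mode="eq8"))
        p = tmp_path / "weights.csv"
        wv.to_csv(p)
        again = WeightVector.from_csv(p, D=cb.D)
        np.testing.assert_allclose(again.weights(), wv.weights(), rtol=1e-12)
        assert again.option_ids == wv.option_ids


# ----------------------------- feature selection ---------------------------


class TestSelectFeatures:
    def _wv(self, combined, active=None):
        from cbrcare.weighting import WeightVector

        combined = np.asarray(combined, dtype=float)
        d_i = np.ones(len(combined), dtype=int)
        if active is not None:
            d_i = np.asarray(active, dtype=int)
        return WeightVector(
            option_ids=[f"o{i}" for i in range(len(combined))],
            D=10,
            D_i=d_i,
            idf=combined.copy(),
            combined=combined.copy(),
        )

    def test_top_n_by_weight(self):
        assert select_features(self._wv([3.0, 1.0, 2.0]), 2).tolist() == [0, 2]

    def test_tie_breaks_to_lower_index(self):
        assert select_features(self._wv([2.0, 2.0, 1.0]), 1).tolist() == [0]

    def test_excess_n_returns_all_active_with_warning(self):
        with pytest.warns(UserWarning, match="returning all"):
            got = select_features(self._wv([1.0, 0.0, 2.0]), 5)
        assert got.tolist() == [0, 2]

    @given(st.lists(st.floats(min_value=0.01, max_value=10), min_size=1, max_size=20),
           st.integers(min_value=1, max_value=20))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_full_sort_oracle(self, weights, n):
        wv = self._wv(weights)
        got = set(select_features(wv, min(n, len(weights))).tolist())
        oracle = sorted(range(len(weights)), key=lambda i: (-weights[i], i))
        assert got == set(oracle[: min(n, len(weights))])
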
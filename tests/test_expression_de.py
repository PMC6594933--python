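"""Fold change, BH FDR, differential calls and category comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from oracle_utils import bh_step_up
from vernalnc import synthetic_data as sd
from vernalnc.expression_de import (
    DEConfig,
    ExpressionMatrix,
    bh_fdr,
    compare_category_expression,
    differential_expression,
    direction_counts,
    log2_fold_change,
)

fpkm = st.floats(min_value=0.0, max_value=1e6, allow_nan=False)


class TestLog2FoldChange:
    def test_identity(self):
        for x in (0.0, 0.37, 12.2, 5000.0):
            assert log2_fold_change(x, x, 0.01) == pytest.approx(0.0)

    @given(a=fpkm, b=fpkm)
    def test_antisymmetry(self, a, b):
        assert log2_fold_change(a, b, 0.01) == pytest.approx(
            -log2_fold_change(b, a, 0.01), abs=1e-9
        )

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change(-1.0, 2.0)


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_hand_step_up_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = rng.uniform(size=int(rng.integers(1, 200)))
            expected = multipletests(p, method="fdr_bh")[1]
            assert bh_fdr(p) == pytest.approx(expected)
            assert bh_fdr(p) == pytest.approx(bh_step_up(list(p)))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_permutation_invariance(self, p):
        p = np.asarray(p)
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(np.sort(bh_fdr(p)), np.sort(bh_fdr(p[perm])))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


def _matrix(nv, v, ids=None):
    nv, v = np.atleast_2d(nv), np.atleast_2d(v)
    frame = pd.DataFrame(
        np.hstack([nv, v]),
        columns=[f"NV_{i+1}" for i in range(nv.shape[1])]
        + [f"V_{i+1}" for i in range(v.shape[1])],
        index=ids or [f"F{i}" for i in range(nv.shape[0])],
    )
    return ExpressionMatrix(frame)


class TestDifferentialExpression:
    def test_identical_conditions_are_all_ns(self):
        vals = np.random.default_rng(0).gamma(2, 10, size=(50, 2))
        de = differential_expression(_matrix(vals, vals))
        assert (de["direction"] == "ns").all()

    def test_planted_sixteen_fold_effect_called_up(self):
        rng = np.random.default_rng(4)
        mean = rng.gamma(2, 10, size=200) + 1
        effect = np.ones(200)
        effect[0] = 16.0  # planted log2 = 4 effect on one feature
        noise = lambda: 2.0 ** rng.normal(0, 0.1, size=(200, 2))
        nv = mean[:, None] * noise()
        v = (mean * effect)[:, None] * noise()
        de = differential_expression(_matrix(nv, v))
        assert de.iloc[0]["direction"] == "up"
        assert de.iloc[0]["log2_ratio"] == pytest.approx(4.0, abs=0.4)

    def test_all_zero_feature_unsupported(self):
        de = differential_expression(_matrix([[0.0, 0.0], [1, 1]], [[0.0, 0.0], [9, 9]]))
        assert not de.iloc[0]["supported"]
        assert de.iloc[0]["direction"] == "ns"

    def test_null_fdr_calibration(self):
        """False-call fraction on 1,000 nulls within 3 binomial s.e. of 5%."""
        matrix, _truth = sd.simulate_planted_effects(0, 1000, rng=7)
        de = differential_expression(matrix)
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert (de["fdr"] < 0.05).mean() <= 0.05 + 3 * se

    def test_power_nondecreasing_in_effect_size(self):
        rng = np.random.default_rng(12)
        powers = []
        for effect in (0.0, 1.0, 2.0, 4.0):
            matrix, truth = sd.simulate_planted_effects(
                150, 300, effect=effect, noise_sd=0.25, rng=rng
            )
            de = differential_expression(matrix)
            called = de.loc[truth[truth != 0].index, "direction"] == "up" if effect else \
                de.loc[truth.index[:150], "direction"] != "ns"
            powers.append(float(np.mean(called)))
        assert all(a <= b + 1e-12 for a, b in zip(powers, powers[1:]))

    def test_direction_counts_partition_supported(self, de_table):
        counts = direction_counts(de_table)
        assert sum(counts.values()) == int(de_table["supported"].sum())
        sig = de_table["direction"] != "ns"
        assert (de_table.loc[sig, "fdr"] < 0.05).all()

    def test_single_replicate_flagged_and_fold_change_only(self):
        de = differential_expression(_matrix([[1.0], [10.0]], [[50.0], [10.0]]))
        assert de.attrs["single_replicate"]
        assert de["p_value"].isna().all()
        assert de.iloc[0]["direction"] == "up"
        assert de.iloc[1]["direction"] == "ns"


class TestCategoryComparison:
    def test_null_categories_not_separated(self):
        rng = np.random.default_rng(21)
        vals = rng.gamma(2, 10, size=(400, 4))
        cats = {f"F{i}": ("a" if i < 200 else "b") for i in range(400)}
        _summary, pairwise = compare_category_expression(
            _matrix(vals[:, :2], vals[:, 2:]), cats
        )
        assert pairwise.iloc[0]["p_adj"] > 0.05

    def test_four_log2_shift_detected(self):
        rng = np.random.default_rng(22)
        base = 2.0 ** rng.normal(4, 1, size=(400, 4))
        base[200:] *= 16.0  # +4 log2 shift for category b
        cats = {f"F{i}": ("a" if i < 200 else "b") for i in range(400)}
        summary, pairwise = compare_category_expression(
            _matrix(base[:, :2], base[:, 2:]), cats
        )
        assert pairwise.iloc[0]["p_adj"] < 0.001
        assert set(summary["category"]) == {"a", "b"}

    def test_single_category_gives_empty_pairwise(self):
        vals = np.ones((10, 4))
        cats = {f"F{i}": "only" for i in range(10)}
        _summary, pairwise = compare_category_expression(
            _matrix(vals[:, :2], vals[:, 2:]), cats
        )
        assert pairwise.empty

    def test_undersized_category_dropped_with_warning(self):
        vals = np.ones((5, 4)) * 3
        cats = {f"F{i}": "big" for i in range(4)} | {"F4": "tiny"}
        with pytest.warns(UserWarning, match="tiny"):
            summary, _ = compare_category_expression(
                _matrix(vals[:, :2], vals[:, 2:]), cats
            )
        assert set(summary["category"]) == {"big"}


class TestExpressionMatrix:
    def test_negative_values_rejected(self):
        frame = pd.DataFrame({"NV_1": [1.0], "V_1": [-2.0]}, index=["F0"])
        with pytest.raises(ValueError):
            ExpressionMatrix(frame)

    def test_condition_inference_and_tsv_roundtrip(self, tmp_path):
        m = _matrix([[1.0, 2.0]], [[3.0, 4.0]])
        assert m.samples_for("NV") == ["NV_1", "NV_2"]
        out = tmp_path / "expr.tsv"
        m.to_tsv(out)
        back = ExpressionMatrix.read_tsv(out)
        pd.testing.assert_frame_equal(back.values, m.values, check_names=False)
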
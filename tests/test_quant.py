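"""Ct quantification chain: parsing, normalization, contrasts, filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qpcrnet.quant import (
    ComparisonResult,
    CtMatrix,
    ExpressionMatrix,
    FilterConfig,
    compare_groups,
    fold_regulation,
    linearize,
    normalize_delta_ct,
    qc_flag,
    read_ct_table,
    significance_filter,
)


def _write(tmp_path, text, name="ct.csv"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadCtTable:
    def test_well_formed(self, tmp_path, tiny_panel):
        path = _write(
            tmp_path,
            "sample_id,group,g1,g2,g3,ref1,ref2\n"
            "a,ctrl,25,30,20,20,22\n"
            "b,test,24,29,21,20,22\n",
        )
        ct = read_ct_table(path, tiny_panel)
        assert ct.values.shape == (2, 5)
        assert ct.values.loc["a", "g1"] == 25.0
        assert ct.groups.loc["b"] == "test"
        assert ct.n_substituted() == 0

    def test_undetermined_ceiled_and_logged(self, tmp_path, tiny_panel):
        path = _write(
            tmp_path,
            "sample_id,group,g1,g2,g3,ref1,ref2\n"
            "a,ctrl,25,Undetermined,20,20,22\n"
            "b,test,24,29,21,20,22\n",
        )
        ct = read_ct_table(path, tiny_panel)
        assert ct.values.loc["a", "g2"] == tiny_panel.ct_ceiling == 35.0
        assert ct.substitutions() == [("a", "g2")]

    def test_missing_reference_column_named(self, tmp_path, tiny_panel):
        path = _write(
            tmp_path,
            "sample_id,group,g1,g2,g3,ref1\na,ctrl,25,30,20,20\n",
        )
        with pytest.raises(ValueError, match="ref2"):
            read_ct_table(path, tiny_panel)

    def test_non_numeric_well_rejected_with_coordinates(self, tmp_path, tiny_panel):
        path = _write(
            tmp_path,
            "sample_id,group,g1,g2,g3,ref1,ref2\n"
            "a,ctrl,25,oops,20,20,22\n",
        )
        with pytest.raises(ValueError, match=r"\('a', 'g2'\)"):
            read_ct_table(path, tiny_panel)


class TestNormalizeAndLinearize:
    def test_delta_ct_arithmetic(self, tiny_ct, tiny_panel):
        expr = normalize_delta_ct(tiny_ct, tiny_panel)
        # reference mean is 21 in every sample
        assert expr.values.loc["s1", "g1"] == pytest.approx(25.0 - 21.0)
        assert set(expr.genes) == {"g1", "g2", "g3"}

    def test_gene_at_reference_mean_gives_zero(self, tiny_panel):
        values = pd.DataFrame(
            {"g1": [21.0], "g2": [25.0], "g3": [26.0],
             "ref1": [20.0], "ref2": [22.0]},
            index=["s"],
        )
        ct = CtMatrix(values=values, groups=pd.Series(["a"], index=["s"]))
        expr = normalize_delta_ct(ct, tiny_panel)
        assert expr.values.loc["s", "g1"] == 0.0

    def test_matches_brute_force_recomputation(self, tiny_panel):
        rng = np.random.default_rng(42)
        values = pd.DataFrame(
            rng.uniform(18, 30, size=(3, 5)),
            index=["s1", "s2", "s3"],
            columns=list(tiny_panel.all_genes),
        )
        ct = CtMatrix(values=values, groups=pd.Series(["a", "a", "b"],
                                                      index=values.index))
        expr = normalize_delta_ct(ct, tiny_panel)
        for s in values.index:
            ref_mean = (values.loc[s, "ref1"] + values.loc[s, "ref2"]) / 2
            for g in ("g1", "g2", "g3"):
                assert expr.values.loc[s, g] == pytest.approx(
                    values.loc[s, g] - ref_mean, rel=1e-12
                )

    @pytest.mark.parametrize(
        "delta, expected", [(0.0, 1.0), (3.0, 0.125), (-2.0, 4.0)]
    )
    def test_linearize_powers_of_two(self, delta, expected):
        expr = ExpressionMatrix(
            values=pd.DataFrame({"g": [delta]}, index=["s"]),
            groups=pd.Series(["a"], index=["s"]),
            scale="delta_ct",
        )
        assert linearize(expr).values.loc["s", "g"] == expected

    def test_linearize_rejects_wrong_scale(self):
        expr = ExpressionMatrix(
            values=pd.DataFrame({"g": [1.0]}, index=["s"]),
            groups=pd.Series(["a"], index=["s"]),
            scale="linear",
        )
        with pytest.raises(ValueError, match="delta_ct"):
            linearize(expr)

    def test_undetermined_reference_well_is_an_error(self, tiny_panel):
        values = pd.DataFrame(
            {"g1": [25.0], "g2": [25.0], "g3": [25.0],
             "ref1": [35.0], "ref2": [22.0]},
            index=["s"],
        )
        missing = values.astype(bool) & False
        missing.loc["s", "ref1"] = True
        ct = CtMatrix(values=values, groups=pd.Series(["a"], index=["s"]),
                      missing=missing)
        with pytest.raises(ValueError, match=r"\('s', 'ref1'\)"):
            normalize_delta_ct(ct, tiny_panel)


class TestQcFlag:
    @pytest.mark.parametrize(
        "test_ct, ctrl_ct, expected",
        [
            (31.2, 24.0, "A"),
            (24.0, 31.2, "A"),
            (31.0, 32.5, "B"),
            (25.0, 26.0, ""),
            (30.0, 25.0, ""),  # exactly at the threshold: neither high nor low
        ],
    )
    def test_flag_rules(self, test_ct, ctrl_ct, expected):
        assert qc_flag(test_ct, ctrl_ct) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            qc_flag(float("nan"), 25.0)


def _expr_from(test_vals, ctrl_vals):
    vals = list(test_vals) + list(ctrl_vals)
    idx = [f"s{i}" for i in range(len(vals))]
    groups = pd.Series(
        ["t"] * len(test_vals) + ["c"] * len(ctrl_vals), index=idx
    )
    expr = ExpressionMatrix(
        values=pd.DataFrame({"g": vals}, index=idx), groups=groups,
        scale="linear",
    )
    # consistent raw Ct so QC flags are computable: Ct = 25 - log2(linear)
    ct = CtMatrix(
        values=pd.DataFrame({"g": 25.0 - np.log2(vals)}, index=idx),
        groups=groups,
    )
    return expr, ct


class TestCompareGroups:
    def test_clear_two_fold_change(self):
        expr, ct = _expr_from([2.0, 2.0, 2.0], [1.0, 1.0001, 0.9999])
        (r,) = compare_groups(expr, ct, "t", "c")
        assert r.fold_change == pytest.approx(2.0, rel=1e-3)
        assert r.fold_regulation == pytest.approx(2.0, rel=1e-3)
        assert r.p_value < 0.05
        # closed-form pooled t-statistic for the same numbers
        x, y = np.array([2.0, 2.0, 2.0]), np.array([1.0, 1.0001, 0.9999])
        sp = np.sqrt(((x.var(ddof=1) * 2 + y.var(ddof=1) * 2) / 4))
        t = (x.mean() - y.mean()) / (sp * np.sqrt(1 / 3 + 1 / 3))
        from scipy import stats

        assert r.p_value == pytest.approx(2 * stats.t.sf(abs(t), df=4), rel=1e-9)

    def test_identical_groups_are_null(self):
        expr, ct = _expr_from([1.5, 1.5, 1.5], [1.5, 1.5, 1.5])
        (r,) = compare_groups(expr, ct, "t", "c")
        assert r.fold_change == 1.0
        assert r.fold_regulation == 1.0
        assert r.p_value == 1.0

    def test_quarter_expression_is_minus_four(self):
        expr, ct = _expr_from([0.25, 0.25, 0.25], [1.0, 1.0, 1.0])
        (r,) = compare_groups(expr, ct, "t", "c")
        assert r.fold_regulation == pytest.approx(-4.0, rel=1e-9)

    def test_singleton_group_rejected(self):
        expr, ct = _expr_from([2.0], [1.0, 1.0])
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(expr, ct, "t", "c")

    def test_swap_inverts_fc_and_negates_fr(self):
        rng = np.random.default_rng(7)
        expr, ct = _expr_from(rng.lognormal(0.5, 0.3, 5), rng.lognormal(0, 0.3, 5))
        (fwd,) = compare_groups(expr, ct, "t", "c")
        (rev,) = compare_groups(expr, ct, "c", "t")
        assert rev.fold_change == pytest.approx(1 / fwd.fold_change, rel=1e-12)
        assert rev.fold_regulation == pytest.approx(-fwd.fold_regulation, rel=1e-12)
        assert rev.p_value == pytest.approx(fwd.p_value, rel=1e-12)

    def test_fc_equals_two_to_minus_ddct(self, tiny_ct, tiny_panel):
        """Ratio definition used must coincide with 2**(-ΔΔCt) on mean ΔCt."""
        expr = linearize(normalize_delta_ct(tiny_ct, tiny_panel))
        results = compare_groups(expr, tiny_ct, "test", "ctrl")
        dct = normalize_delta_ct(tiny_ct, tiny_panel).values
        for r in results:
            ddct = (
                dct.loc[["s3", "s4"], r.gene].mean()
                - dct.loc[["s1", "s2"], r.gene].mean()
            )
            assert r.fold_change == pytest.approx(2.0 ** (-ddct), rel=1e-9)

    def test_mostly_missing_gene_excluded_with_warning(self, tiny_panel):
        values = pd.DataFrame(
            {"g1": [35.0, 35.0, 24.0, 25.0], "g2": [30.0] * 4,
             "g3": [20.0, 20.4, 20.2, 20.1],
             "ref1": [20.0] * 4, "ref2": [22.0] * 4},
            index=["s1", "s2", "s3", "s4"],
        )
        missing = values.astype(bool) & False
        missing.loc[["s1", "s2"], "g1"] = True
        groups = pd.Series(["c", "c", "t", "t"], index=values.index)
        ct = CtMatrix(values=values, groups=groups, missing=missing)
        expr = linearize(normalize_delta_ct(ct, tiny_panel))
        with pytest.warns(UserWarning, match="g1"):
            results = compare_groups(expr, ct, "t", "c")
        assert [r.gene for r in results] == ["g2", "g3"]


class TestFoldRegulation:
    @given(st.floats(min_value=1.0000001, max_value=1e6))
    @settings(max_examples=200, deadline=None)
    def test_odd_on_log_scale(self, x):
        assert fold_regulation(1.0 / x) == pytest.approx(-fold_regulation(x))

    @given(
        st.floats(min_value=1e-6, max_value=1e6),
        st.floats(min_value=1e-6, max_value=1e6),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_and_never_in_unit_gap(self, a, b):
        fa, fb = fold_regulation(a), fold_regulation(b)
        assert abs(fa) >= 1 and abs(fb) >= 1
        assert not (-1 < fa < 1)
        if a < b:
            assert fa <= fb


class TestSignificanceFilter:
    def _rows(self, spec):
        return [
            ComparisonResult(gene=g, p_value=p, fold_change=abs(fr),
                             fold_regulation=fr)
            for g, p, fr in spec
        ]

    def test_strict_inequalities_and_order(self):
        rows = self._rows(
            [
                ("a", 0.01, 2.5),
                ("b", 0.05, 3.0),   # p not < 0.05
                ("c", 0.01, 2.0),   # |FR| not > 2
                ("d", 0.002, -2.7),
                ("e", 0.04, -2.01),
            ]
        )
        res = significance_filter(rows, FilterConfig())
        assert res.up == ["a"]
        assert res.down == ["d", "e"]

    def test_idempotent_and_matches_row_scan(self):
        rng = np.random.default_rng(3)
        rows = self._rows(
            [
                (f"g{i}", float(rng.uniform(0, 0.2)),
                 float(rng.choice([-1, 1]) * rng.uniform(1, 5)))
                for i in range(40)
            ]
        )
        res = significance_filter(rows)
        brute_up = [r.gene for r in rows
                    if r.p_value < 0.05 and r.fold_regulation > 2.0]
        brute_down = [r.gene for r in rows
                      if r.p_value < 0.05 and r.fold_regulation < -2.0]
        assert res.up == brute_up and res.down == brute_down
        kept = [r for r in rows if r.gene in res.up + res.down]
        res2 = significance_filter(kept)
        assert res2.up == res.up and res2.down == res.down

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            significance_filter([])
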
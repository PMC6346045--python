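import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cypscreen import (
    DegenerateInputError,
    ExpressionMatrix,
    TraitTable,
    ValidationError,
    bonferroni_threshold,
    correlation_p,
    pearson_r,
)
from cypscreen.core import gene_of_transcript, pairwise_correlations

from oracles import pearson_oracle


class TestExpressionMatrix:
    def test_roundtrip_preserves_values(self, toy_expr, tmp_path):
        path = tmp_path / "expr.tsv"
        toy_expr.to_tsv(path)
        back = ExpressionMatrix.from_tsv(path)
        assert back.data.shape == (3, 4)
        pd.testing.assert_frame_equal(back.data, toy_expr.data)

    def test_alternative_transcripts_collapse_to_one_gene(self, toy_expr):
        assert toy_expr.gene_of["PgCYP274-1"] == "PgCYP274"
        assert toy_expr.gene_of["PgCYP274-2"] == "PgCYP274"
        assert toy_expr.gene_of["PgCYP100"] == "PgCYP100"
        assert toy_expr.genes == ["PgCYP274", "PgCYP100"]

    @pytest.mark.parametrize(
        "tid,gene",
        [("PgCYP274-1", "PgCYP274"), ("DS_3", "DS"), ("PgCYP414", "PgCYP414"),
         ("CYP716A53v2", "CYP716A53v2")],
    )
    def test_suffix_rule(self, tid, gene):
        assert gene_of_transcript(tid) == gene

    def test_negative_value_names_offending_cell(self):
        df = pd.DataFrame([[1.0, -2.0]], index=["t1"], columns=["s1", "s2"])
        with pytest.raises(ValidationError, match=r"t1.*s2"):
            ExpressionMatrix(df)

    def test_duplicate_transcript_id_rejected(self):
        df = pd.DataFrame([[1.0], [2.0]], index=["t1", "t1"], columns=["s1"])
        with pytest.raises(ValidationError, match="t1"):
            ExpressionMatrix(df)

    def test_missing_value_rejected(self):
        df = pd.DataFrame([[1.0, np.nan]], index=["t1"], columns=["s1", "s2"])
        with pytest.raises(ValidationError, match="missing"):
            ExpressionMatrix(df)


class TestTraitTable:
    def test_total_must_equal_mono_sum(self):
        df = pd.DataFrame(
            {"Rg1": [1.0], "Re": [2.0], "TS": [4.0]}, index=["s1"]
        )
        with pytest.raises(ValidationError, match="sum"):
            TraitTable(df)

    def test_total_computed_when_absent(self, tmp_path):
        df = pd.DataFrame({"Rg1": [1.0, 2.0], "Re": [3.0, 4.0]}, index=["a", "b"])
        tt = TraitTable(df).with_total()
        assert list(tt.data["TS"]) == [4.0, 6.0]
        path = tmp_path / "traits.tsv"
        tt.to_tsv(path)
        back = TraitTable.from_tsv(path)
        pd.testing.assert_frame_equal(back.data, tt.data)


class TestPearson:
    def test_identity_and_antisymmetry(self):
        x = [1.0, 2.0, 4.0, 8.0]
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_matches_first_principles_oracle(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 1.0, 4.0, 3.0]
        assert pearson_r(x, y) == pytest.approx(pearson_oracle(x, y), abs=1e-12)
        assert pearson_r(x, y) == pytest.approx(0.6)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @settings(derandomize=True, max_examples=50)
    @given(
        xs=st.lists(st.floats(-50, 50), min_size=4, max_size=12, unique=True),
        a=st.floats(0.1, 10),
        b=st.floats(-5, 5),
    )
    def test_symmetric_and_affine_invariant(self, xs, a, b):
        n = len(xs)
        ys = [((i * 7919) % n) + 0.5 * i for i in range(n)]  # deterministic partner
        r1 = pearson_r(xs, ys)
        assert pearson_r(ys, xs) == pytest.approx(r1, abs=1e-9)
        assert pearson_r([a * v + b for v in xs], ys) == pytest.approx(r1, abs=1e-7)


class TestCorrelationP:
    def test_null_center(self):
        assert correlation_p(0.0, 42) == 1.0

    def test_critical_r_at_panel_size(self):
        # at n = 42 the two-tailed 5% critical |r| is the t-quantile transform
        tcrit = stats.t.ppf(0.975, 40)
        rcrit = tcrit / np.sqrt(40 + tcrit**2)
        assert rcrit == pytest.approx(0.304, abs=5e-4)
        assert correlation_p(rcrit, 42) == pytest.approx(0.05, abs=1e-10)

    def test_monotone_in_r_and_n(self):
        assert correlation_p(0.5, 42) < correlation_p(0.3, 42)
        assert correlation_p(0.3, 80) < correlation_p(0.3, 42)

    def test_perfect_correlation_hits_floor(self):
        p = correlation_p(1.0, 10)
        assert 0 < p < 1e-300

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            correlation_p(0.5, 2)
        with pytest.raises(ValidationError):
            correlation_p(1.5, 10)

    @settings(derandomize=True, max_examples=40)
    @given(r=st.floats(0.01, 0.95), n=st.integers(4, 200))
    def test_two_tailed_symmetry(self, r, n):
        assert correlation_p(r, n) == pytest.approx(correlation_p(-r, n), rel=1e-12)


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,m,expected",
        [(0.05, 100, 5.0e-4), (0.05, 1, 0.05), (0.01, 4, 0.0025)],
    )
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected, rel=1e-12)

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            bonferroni_threshold(0.05, 0)
        with pytest.raises(ValidationError):
            bonferroni_threshold(1.5, 10)


class TestPairwise:
    def test_matches_scalar_primitives(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(4, 10))
        Y = rng.normal(size=(3, 10))
        r, p = pairwise_correlations(X, Y)
        for i in range(4):
            for j in range(3):
                assert r[i, j] == pytest.approx(pearson_r(X[i], Y[j]), abs=1e-12)
                assert p[i, j] == pytest.approx(correlation_p(r[i, j], 10), rel=1e-9)

    def test_zero_variance_rows_are_nan(self):
        X = np.vstack([np.ones(5), np.arange(5.0)])
        r, _ = pairwise_correlations(X, X)
        assert np.isnan(r[0]).all()
        assert r[1, 1] == pytest.approx(1.0)
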
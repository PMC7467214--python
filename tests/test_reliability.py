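import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import proberel as pr
from proberel.reliability import FLAG_DEGENERATE, FLAG_INSUFFICIENT_N


def anova_ms_oracle(mat):
    """Brute-force two-way ANOVA mean squares, independent of the
    package's vectorized closed form."""
    mat = np.asarray(mat, dtype=float)
    n, k = mat.shape
    grand = mat.mean()
    ssr = k * sum((rm - grand) ** 2 for rm in mat.mean(axis=1))
    ssc = n * sum((cm - grand) ** 2 for cm in mat.mean(axis=0))
    sst = ((mat - grand) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def anova_icc_oracle(mat):
    n = np.asarray(mat).shape[0]
    msr, msc, mse = anova_ms_oracle(mat)
    return (msr - mse) / (msr + (msc - mse) / n)


class TestICC:
    def test_perfect_agreement_is_exactly_one(self):
        icc, comp, flag = pr.icc_absolute_agreement([[1, 1], [2, 2], [3, 3]])
        assert icc == 1.0
        assert comp.mse == 0.0 and comp.msc == 0.0
        assert flag == "ok"

    def test_worked_four_by_two_example(self):
        icc, comp, flag = pr.icc_absolute_agreement([[1, 2], [3, 4], [5, 6], [7, 8]])
        assert comp.msr == pytest.approx(40 / 3)
        assert comp.msc == pytest.approx(2.0)
        assert comp.mse == pytest.approx(0.0, abs=1e-12)
        assert icc == pytest.approx((40 / 3) / (40 / 3 + 2 / 4), abs=1e-12)
        assert icc == pytest.approx(0.964, abs=5e-4)

    def test_constant_offset_lowers_icc_not_pearson(self, rng):
        x = rng.normal(size=30)
        mat = np.column_stack([x, x + 1.5])
        icc, _, _ = pr.icc_absolute_agreement(mat)
        r, _ = pr.compute_pearson(mat)
        assert r == pytest.approx(1.0)
        assert icc < 1.0

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(2024)
        n_defined = 0
        for _ in range(300):
            n = int(rng.integers(3, 51))
            mat = rng.normal(size=(n, 2)) * rng.uniform(0.1, 5)
            icc, comp, flag = pr.icc_absolute_agreement(mat)
            msr, msc, mse = anova_ms_oracle(mat)
            assert comp.msr == pytest.approx(msr, abs=1e-10)
            assert comp.msc == pytest.approx(msc, abs=1e-10)
            assert comp.mse == pytest.approx(mse, abs=1e-10)
            if flag == "ok":
                n_defined += 1
                assert icc == pytest.approx(anova_icc_oracle(mat), abs=1e-10)
        # the coefficient is undefined only for the rare noise-dominated
        # matrices whose ANOVA denominator estimate turns nonpositive
        assert n_defined >= 290

    def test_matches_pingouin_reference(self):
        """Cross-check ICC(A,k) against an independent implementation
        (pingouin's ICC2k, average random raters)."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        for _ in range(5):
            n = int(rng.integers(5, 30))
            mat = rng.normal(size=(n, 2))
            long = pd.DataFrame(
                {
                    "targets": np.repeat(np.arange(n), 2),
                    "raters": np.tile(["a", "b"], n),
                    "scores": mat.ravel(),
                }
            )
            ref = pingouin.intraclass_corr(
                long, targets="targets", raters="raters", ratings="scores"
            )
            icc2k = float(ref.loc[ref["Type"] == "ICC(A,k)", "ICC"].iloc[0])
            icc, _, _ = pr.icc_absolute_agreement(mat)
            assert icc == pytest.approx(icc2k, abs=1e-8)

    def test_insufficient_pairs_flagged(self):
        icc, _, flag = pr.icc_absolute_agreement([[1, 2], [3, 4]])
        assert np.isnan(icc) and flag == FLAG_INSUFFICIENT_N

    def test_zero_variance_flagged_degenerate(self):
        icc, _, flag = pr.icc_absolute_agreement([[0.5, 0.5]] * 5)
        assert np.isnan(icc) and flag == FLAG_DEGENERATE

    def test_missing_cells_use_complete_pairs_only(self):
        full = np.array([[1.0, 1.1], [2.0, 2.2], [3.0, 2.9], [4.0, 4.2]])
        with_nan = np.vstack([full, [[np.nan, 5.0], [6.0, np.nan]]])
        icc_full, _, _ = pr.icc_absolute_agreement(full)
        icc_nan, comp, _ = pr.icc_absolute_agreement(with_nan)
        assert comp.n == 4
        assert icc_nan == pytest.approx(icc_full, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(
            st.tuples(
                st.floats(-10, 10, allow_nan=False),
                st.floats(-10, 10, allow_nan=False),
            ),
            min_size=3,
            max_size=30,
        )
    )
    def test_icc_never_exceeds_one(self, pairs):
        mat = np.array(pairs)
        icc, _, flag = pr.icc_absolute_agreement(mat)
        if flag == "ok":
            assert icc <= 1.0 + 1e-12

    def test_affine_rescaling_invariance(self, rng):
        mat = rng.normal(size=(25, 2))
        icc, _, _ = pr.icc_absolute_agreement(mat)
        icc2, _, _ = pr.icc_absolute_agreement(mat * 3.7 + 0.9)
        assert icc2 == pytest.approx(icc, abs=1e-12)


class TestPearson:
    def test_exact_linearity(self):
        r, _ = pr.compute_pearson(np.array([[1, 2], [2, 4], [3, 6]], dtype=float))
        assert r == pytest.approx(1.0)
        r, _ = pr.compute_pearson(np.array([[1, 3], [2, 2], [3, 1]], dtype=float))
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        mat = rng.normal(size=(50, 2))
        r, _ = pr.compute_pearson(mat)
        x, y = mat[:, 0], mat[:, 1]
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_flagged(self):
        r, flag = pr.compute_pearson(np.array([[1.0, 2.0], [1.0, 3.0], [1.0, 4.0]]))
        assert np.isnan(r) and flag == FLAG_DEGENERATE


class TestReliabilityTable:
    def test_rows_and_summary(self, rng):
        x = rng.random((2, 10))
        probes = ["perfect", "offset"]
        samples = [f"s{i}" for i in range(10)]
        a = pr.BetaMatrix(pd.DataFrame(x, index=probes, columns=samples))
        y = x.copy()
        y[1] = np.clip(x[1] + 0.2, 0, 1)
        b = pr.BetaMatrix(pd.DataFrame(y, index=probes, columns=samples))
        table = pr.reliability_table(pr.pair_matrices(a, b))
        assert table.loc["perfect", "icc"] == pytest.approx(1.0)
        assert table.loc["offset", "icc"] < 1.0
        summary = table.attrs["summary"]
        assert summary["n_probes"] == 2
        assert summary["max_icc"] == pytest.approx(1.0)

    def test_mean_beta_uses_reference_matrix(self, rng):
        x = np.full((1, 5), 0.2)
        y = np.full((1, 5), 0.8)
        a = pr.BetaMatrix(pd.DataFrame(x, index=["p"], columns=list("abcde")))
        b = pr.BetaMatrix(pd.DataFrame(y, index=["p"], columns=list("abcde")))
        table = pr.reliability_table(pr.pair_matrices(a, b))
        assert table.loc["p", "mean_beta"] == pytest.approx(0.2)

    def test_row_shuffle_permutation_invariance(self, paired_panel):
        paired, _ = paired_panel
        table = pr.reliability_table(paired)
        rng = np.random.default_rng(5)
        perm = rng.permutation(len(paired.probe_ids))
        shuffled = pr.PairedBetaMatrix(
            pr.BetaMatrix(paired.first.values.iloc[perm], paired.first.platform_label),
            pr.BetaMatrix(paired.second.values.iloc[perm], paired.second.platform_label),
            sample_pairs=paired.sample_pairs,
        )
        table2 = pr.reliability_table(shuffled)
        pd.testing.assert_frame_equal(table2.sort_index(), table.sort_index())

    def test_degenerate_probe_does_not_abort(self):
        vals = pd.DataFrame(
            [[0.5] * 5, [0.1, 0.3, 0.5, 0.7, 0.9]],
            index=["flat", "varying"],
            columns=[f"s{i}" for i in range(5)],
        )
        a = pr.BetaMatrix(vals)
        table = pr.reliability_table(pr.pair_matrices(a, a))
        assert table.loc["flat", "flags"] == FLAG_DEGENERATE
        assert table.loc["varying", "icc"] == pytest.approx(1.0)

    def test_icc_and_pearson_rank_identically_without_rater_offset(self):
        cfg = pr.GeneratorConfig(n_probes=200, n_samples=80, rater_offset_sd=0.0, seed=3)
        paired, _ = pr.generate_paired(cfg)
        table = pr.reliability_table(paired)
        ok = table["flags"] == "ok"
        icc_rank = table.loc[ok, "icc"].rank()
        r_rank = table.loc[ok, "pearson_r"].rank()
        # with no rater offset MSC is pure noise; rankings agree closely
        assert (icc_rank - r_rank).abs().mean() < 2.0


class TestClassifyAndTransforms:
    @pytest.mark.parametrize(
        "icc,expected",
        [
            (0.3, "poor"),
            (-0.2, "poor"),
            (0.4, "fair"),
            (0.5, "fair"),
            (0.6, "good"),
            (0.75, "good"),
            (0.8, "excellent"),
        ],
    )
    def test_category_boundaries(self, icc, expected):
        assert pr.classify_reliability(icc) == expected

    def test_missing_icc_has_no_category(self):
        assert pr.classify_reliability(float("nan")) is None

    @pytest.mark.parametrize("beta,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_m_value_examples(self, beta, m):
        assert pr.beta_to_m(beta) == pytest.approx(m)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.001, 0.999))
    def test_m_value_antisymmetry(self, b):
        assert pr.beta_to_m(b) == pytest.approx(-pr.beta_to_m(1 - b), abs=1e-9)

    def test_m_value_boundary_epsilon(self):
        assert np.isfinite(pr.beta_to_m(0.0)) and pr.beta_to_m(0.0) < -19
        assert pr.beta_to_m(1.0) == pytest.approx(-pr.beta_to_m(0.0))

    def test_m_value_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            pr.beta_to_m(1.2)

    @pytest.mark.parametrize(
        "alpha,n,expected",
        [(0.05, 1, 0.05), (0.05, 28_000, 1.79e-6)],
    )
    def test_bonferroni(self, alpha, n, expected):
        assert pr.bonferroni_threshold(alpha, n) == pytest.approx(expected, rel=5e-3)
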
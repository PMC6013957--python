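import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.base import clone

from getmm import (
    ExpressionMatrix,
    GeTMMNormalizer,
    RLENormalizer,
    TMMNormalizer,
    TPMNormalizer,
    getmm,
    log2_with_missing,
    rle_factors,
    rpk,
    scaled_expression,
    tmm_factors,
    tpm,
)
from getmm.errors import (
    ContractError,
    DegenerateSampleError,
    EstimationImpossibleError,
    MissingLengthError,
    ValidationError,
)


def _df(rows, samples=None):
    rows = np.atleast_2d(rows)
    return pd.DataFrame(
        rows,
        index=[f"g{i}" for i in range(rows.shape[0])],
        columns=samples or [f"s{j}" for j in range(rows.shape[1])],
    )


class TestRpk:
    @pytest.mark.parametrize(
        "count, length, expected", [(10, 1000, 10.0), (10, 2000, 5.0), (0, 700, 0.0)]
    )
    def test_count_over_kilobases(self, count, length, expected):
        counts = _df([[count]])
        lengths = pd.Series([length], index=["g0"])
        assert rpk(counts, lengths).iloc[0, 0] == pytest.approx(expected)

    def test_missing_length_errors_or_drops(self):
        counts = _df([[1], [2]])
        lengths = pd.Series([1000], index=["g0"])
        with pytest.raises(MissingLengthError, match="g1"):
            rpk(counts, lengths)
        dropped = rpk(counts, lengths, on_missing="drop")
        assert list(dropped.index) == ["g0"]


class TestTpm:
    def test_hand_example(self):
        counts = _df([[10], [20]])
        lengths = pd.Series([1000, 2000], index=["g0", "g1"])  # RPK (10, 10)
        values = tpm(counts, lengths).values
        np.testing.assert_allclose(values.iloc[:, 0], [5e5, 5e5])

    def test_single_expressed_gene_is_point_mass(self):
        counts = _df([[7], [0]])
        lengths = pd.Series([500, 500], index=["g0", "g1"])
        values = tpm(counts, lengths).values
        np.testing.assert_allclose(values.iloc[:, 0], [1e6, 0.0])

    def test_columns_sum_to_one_million(self, small_counts, small_lengths):
        values = tpm(small_counts, small_lengths).values
        np.testing.assert_allclose(values.sum(axis=0), 1e6, rtol=1e-6)

    def test_depth_scaling_of_one_sample_is_absorbed(self, small_counts, small_lengths):
        scaled = small_counts.copy()
        scaled["b"] *= 7
        a = tpm(small_counts, small_lengths).values
        b = tpm(scaled, small_lengths).values
        np.testing.assert_allclose(a["b"], b["b"], rtol=1e-12)

    def test_all_zero_sample_rejected(self):
        counts = _df([[0, 1], [0, 2]])
        lengths = pd.Series([100, 100], index=["g0", "g1"])
        with pytest.raises(DegenerateSampleError):
            tpm(counts, lengths)


class TestRleFactors:
    def test_identical_columns_give_unit_factors(self):
        col = [10, 20, 5, 300]
        nf = rle_factors(_df(np.column_stack([col, col])))
        np.testing.assert_allclose(nf.factors, [1.0, 1.0])

    @pytest.mark.parametrize("c", [2, 3, 10])
    def test_scaled_column_gives_proportional_factors(self, c):
        col = np.array([10, 20, 5, 300])
        nf = rle_factors(_df(np.column_stack([col, c * col])))
        # median of constant ratios: factors proportional to (1, c)
        assert nf.factors.iloc[1] / nf.factors.iloc[0] == pytest.approx(c, rel=1e-12)

    def test_no_all_positive_gene_is_estimation_impossible(self):
        counts = _df([[0, 5], [5, 0]])
        with pytest.raises(EstimationImpossibleError):
            rle_factors(counts)

    def test_fractional_input_rejected(self):
        with pytest.raises(ValidationError, match="integer"):
            rle_factors(_df([[1.5, 2.0], [2.0, 3.0]]))


class TestScaledExpression:
    def test_neutral_factors_give_cpm(self, small_counts):
        nf = tmm_factors(small_counts)
        nf.factors.loc[:] = 1.0
        out = scaled_expression(small_counts, nf).values
        expected = small_counts / small_counts.sum(axis=0) * 1e6
        np.testing.assert_allclose(out, expected)

    def test_rle_factor_divides_counts(self, small_counts):
        nf = rle_factors(small_counts)
        nf.factors.loc[:] = [1.0, 2.0, 1.0]
        out = scaled_expression(small_counts, nf).values
        np.testing.assert_allclose(out["b"], small_counts["b"] / 2.0)

    def test_tmm_column_sums_equal_per_over_factor(self, small_counts):
        nf = tmm_factors(small_counts)
        out = scaled_expression(small_counts, nf, per=1e6).values
        np.testing.assert_allclose(out.sum(axis=0), 1e6 / nf.factors, rtol=1e-12)

    def test_missing_sample_in_factors_is_key_error(self, small_counts):
        nf = tmm_factors(small_counts[["a", "b"]])
        with pytest.raises(KeyError):
            scaled_expression(small_counts, nf)


class TestGetmm:
    def test_equals_tpm_for_identical_rpk_columns(self, small_lengths):
        base = pd.DataFrame(
            {"a": [10, 40, 0, 7, 3, 60, 2, 100], "b": [10, 40, 0, 7, 3, 60, 2, 100]},
            index=small_lengths.index,
        )
        g = getmm(base, small_lengths).values
        t = tpm(base, small_lengths).values
        np.testing.assert_allclose(g, t, rtol=1e-9)

    def test_column_sums_are_per_million_over_factor(self, small_counts, small_lengths):
        nf = tmm_factors(rpk(small_counts, small_lengths))
        values = getmm(small_counts, small_lengths).values
        np.testing.assert_allclose(values.sum(axis=0), 1e6 / nf.factors, rtol=1e-12)

    def test_within_sample_ranking_matches_rpk(self, small_counts, small_lengths):
        r = rpk(small_counts, small_lengths)
        g = getmm(small_counts, small_lengths).values
        for s in g.columns:
            pd.testing.assert_series_equal(
                g[s].rank(), r[s].rank(), check_names=False
            )

    def test_composition_bias_hits_tpm_not_getmm(self):
        # 5% of genes 20-fold up in one sample distorts TPM columns of the
        # unperturbed genes but is absorbed by the trimmed TMM factor
        from getmm import SimConfig, simulate_counts

        cfg = SimConfig(
            n_genes=1000, n_samples=4, composition_bias=(0.05, 20.0, (3,)), seed=13
        )
        counts, lengths, truth = simulate_counts(cfg)
        clean = counts.index.difference(truth.composition_genes)
        g = getmm(counts, lengths).values
        t = tpm(counts, lengths).values
        expressed = (counts.loc[clean] > 5).all(axis=1)
        clean = clean[expressed]
        g_ratio = (g.loc[clean, "S04"] / g.loc[clean, "S01"]).median()
        t_ratio = (t.loc[clean, "S04"] / t.loc[clean, "S01"]).median()
        assert abs(g_ratio - 1) < 0.02
        assert abs(t_ratio - 1) > 0.2


class TestLog2WithMissing:
    def test_values_and_missing_policy(self):
        m = ExpressionMatrix(_df([[8.0, 0.0, 1.0]]), method="tpm")
        out = log2_with_missing(m)
        assert out.scale == "log2"
        row = out.values.iloc[0]
        assert row.iloc[0] == pytest.approx(3.0)
        assert np.isnan(row.iloc[1])
        assert row.iloc[2] == pytest.approx(0.0)

    def test_double_log_is_contract_error(self):
        m = ExpressionMatrix(_df([[8.0]]), method="tpm", scale="log2")
        with pytest.raises(ContractError):
            log2_with_missing(m)


@st.composite
def count_matrices(draw):
    n_genes = draw(st.integers(3, 8))
    n_samples = draw(st.integers(2, 4))
    pool = st.sampled_from([0, 1, 5, 10, 100, 1000])
    rows = draw(
        st.lists(
            st.lists(pool, min_size=n_samples, max_size=n_samples),
            min_size=n_genes,
            max_size=n_genes,
        )
    )
    m = _df(np.array(rows))
    # every column must carry reads and share a positive gene with the others
    if (m.sum(axis=0) == 0).any() or not (m > 0).all(axis=1).any():
        m.iloc[0] = 10
    return m


class TestNormalizationProperties:
    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(count_matrices())
    def test_tmm_factor_geometric_mean_is_one(self, m):
        f = tmm_factors(m).factors.to_numpy()
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(count_matrices())
    def test_permuting_samples_permutes_tmm_factors(self, m):
        # reference pinned explicitly: automatic selection breaks upper-
        # quartile ties by column order, which is not permutation-invariant
        ref = m.columns[0]
        perm = list(m.columns[::-1])
        f = tmm_factors(m, ref_sample=ref).factors
        g = tmm_factors(m[perm], ref_sample=ref).factors
        np.testing.assert_allclose(f.loc[perm], g, rtol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(count_matrices())
    def test_rle_on_proportional_columns_recovers_scales(self, m):
        profile = m.iloc[:, 0].to_numpy() + 1  # strictly positive
        scales = np.arange(1, m.shape[1] + 1)
        prop = _df(np.column_stack([profile * c for c in scales]))
        f = rle_factors(prop).factors.to_numpy()
        np.testing.assert_allclose(f / f[0], scales / scales[0], rtol=1e-9)

    def test_identical_columns_neutral_for_tmm_and_rle(self):
        col = [3, 9, 0, 50, 7]
        m = _df(np.column_stack([col, col]))
        np.testing.assert_allclose(tmm_factors(m).factors, 1.0, atol=1e-12)
        np.testing.assert_allclose(rle_factors(m).factors, 1.0, atol=1e-12)

    def test_pure_depth_change_gives_unit_factors(self):
        col = np.array([3, 9, 1, 50, 7])
        m = _df(np.column_stack([col, 3 * col]))
        np.testing.assert_allclose(tmm_factors(m).factors, 1.0, atol=1e-12)


class TestEstimatorInterface:
    def test_tmm_normalizer_fit_transform(self, small_counts):
        est = TMMNormalizer()
        out = est.fit_transform(small_counts)
        assert est.factors_.shape == (3,)
        assert est.ref_sample_ in small_counts.columns
        np.testing.assert_allclose(
            out, scaled_expression(small_counts, est.norm_factors_).values
        )

    def test_getmm_normalizer_matches_function(self, small_counts, small_lengths):
        est = GeTMMNormalizer(gene_lengths=small_lengths)
        out = est.fit_transform(small_counts)
        np.testing.assert_allclose(out, getmm(small_counts, small_lengths).values)

    def test_tpm_normalizer_log2(self, small_counts, small_lengths):
        est = TPMNormalizer(gene_lengths=small_lengths, log2=True)
        out = est.fit(small_counts).transform(small_counts)
        lin = tpm(small_counts, small_lengths).values
        assert np.isnan(out.to_numpy()[lin.to_numpy() == 0]).all()

    def test_rle_normalizer_per_million(self, small_counts):
        est = RLENormalizer(per_million=True)
        out = est.fit_transform(small_counts)
        eff = est.library_sizes_ / est.factors_
        np.testing.assert_allclose(out.sum(axis=0), small_counts.sum(axis=0) / est.factors_ / (eff / 1e6))

    def test_estimators_clone_and_expose_params(self, small_lengths):
        est = GeTMMNormalizer(gene_lengths=small_lengths, logratio_trim=0.2)
        params = est.get_params()
        assert params["logratio_trim"] == 0.2
        cloned = clone(est)
        assert cloned.get_params()["logratio_trim"] == 0.2
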
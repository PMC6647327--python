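"""Normalization, NB differential expression, PA shifts and Pearson profiles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lincscreen import (
    differential_expression,
    make_count_matrix,
    normalize_counts,
    pearson_profile,
    polysome_shift,
)

LOCI = [f"L{i:04d}" for i in range(50)]
NAMES_AB = [f"condA_total_rep{r}" for r in (1, 2, 3)] + [f"condB_total_rep{r}" for r in (1, 2, 3)]


def _mat(values, names=None, loci=None):
    values = np.asarray(values)
    loci = loci if loci is not None else [f"L{i:04d}" for i in range(values.shape[0])]
    return make_count_matrix(values, loci, names or NAMES_AB)


class TestNormalizeCounts:
    def test_identical_columns_give_unit_size_factors(self, rng):
        col = rng.integers(1, 500, 50)
        norm = _mat(np.tile(col[:, None], (1, 6)))
        out = normalize_counts(norm)
        assert np.allclose(out.size_factors, 1.0)

    def test_doubled_column_gets_doubled_size_factor(self, rng):
        base = rng.integers(1, 500, (50, 6))
        base[:, 1] = base[:, 0] * 2
        out = normalize_counts(_mat(base))
        assert out.size_factors.iloc[1] / out.size_factors.iloc[0] == pytest.approx(2.0)

    def test_matches_direct_median_of_ratios_formula(self, rng):
        raw = rng.integers(1, 1000, (50, 6)).astype(float)
        out = normalize_counts(_mat(raw))
        log_geo = np.log(raw).mean(axis=1, keepdims=True)
        expected = np.exp(np.median(np.log(raw) - log_geo, axis=0))
        assert np.allclose(out.size_factors.to_numpy(), expected, atol=1e-12)
        assert np.allclose(out.data.to_numpy(), raw / expected, atol=1e-9)

    def test_no_all_positive_locus_raises_with_hint(self):
        raw = np.zeros((10, 6), dtype=int)
        raw[:5, :3] = 10  # every locus has a zero somewhere
        with pytest.raises(ValueError, match="pseudo-reference"):
            normalize_counts(_mat(raw))


class TestDifferentialExpression:
    def test_identical_groups_give_unit_fold_change(self, rng):
        half = rng.integers(5, 300, (50, 3))
        de = differential_expression(_mat(np.hstack([half, half])), ("condA", "condB"))
        assert np.allclose(de["fc"], 1.0)
        assert (de["padj"] >= de["p"] - 1e-12).all()

    def test_absent_condition_raises(self, rng):
        with pytest.raises(ValueError, match="absent"):
            differential_expression(_mat(rng.integers(1, 9, (10, 6))), ("condA", "condZ"))

    def test_reverse_contrast_inverts_fold_change(self, rng):
        mat = _mat(rng.integers(5, 500, (50, 6)))
        f = differential_expression(mat, ("condA", "condB"))
        g = differential_expression(mat, ("condB", "condA"))
        assert np.allclose(f["fc"] * g["fc"], 1.0)
        assert np.allclose(f["p"], g["p"])

    def test_null_pvalues_close_to_uniform(self):
        rng = np.random.default_rng(5)
        mu = 10 ** rng.uniform(1.3, 2.7, 2000)
        r = 1 / 0.05
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(2000, 6))
        de = differential_expression(
            _mat(counts, loci=[f"N{i}" for i in range(2000)]), ("condA", "condB")
        )
        assert stats.kstest(de["p"], "uniform").statistic < 0.05

    def test_planted_fourfold_effect_detected_with_power(self):
        rng = np.random.default_rng(7)
        mu = 10 ** rng.uniform(1.3, 2.7, 1000)
        r = 1 / 0.05
        counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(1000, 6))
        counts[:100, :3] = rng.negative_binomial(r, r / (r + 4 * mu[:100, None]), size=(100, 3))
        de = differential_expression(
            _mat(counts, loci=[f"P{i}" for i in range(1000)]), ("condA", "condB")
        )
        planted = de.iloc[:100]
        assert float(((planted["padj"] < 0.1) & (planted["fc"] > 2)).mean()) >= 0.8
        assert 3.0 <= float(planted["fc"].median()) <= 5.3

    def test_type_one_error_controlled_under_global_null(self):
        """FDR sense: fraction of null loci at padj<0.1 stays near or below 0.1."""
        rates = []
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            mu = 10 ** rng.uniform(1.3, 2.7, 400)
            r = 1 / 0.05
            counts = rng.negative_binomial(r, r / (r + mu[:, None]), size=(400, 6))
            de = differential_expression(
                _mat(counts, loci=[f"N{i}" for i in range(400)]), ("condA", "condB")
            )
            rates.append(float((de["padj"] < 0.1).mean()))
        assert np.mean(rates) <= 0.1


class TestPolysomeShift:
    @staticmethod
    def _pair(rng, n=30):
        tot = _mat(rng.integers(10, 400, (n, 6)))
        pol_names = [s.replace("total", "polysomal") for s in NAMES_AB]
        pol = _mat(rng.integers(10, 400, (n, 6)), names=pol_names)
        return tot, pol

    def test_polysomal_equal_to_total_gives_unit_pa_fc(self, rng):
        vals = rng.integers(10, 400, (30, 6))
        tot = _mat(vals)
        pol = _mat(vals, names=[s.replace("total", "polysomal") for s in NAMES_AB])
        res = polysome_shift(tot, pol, ("condA", "condB"))
        assert np.allclose(res["pa_fc"], 1.0)

    def test_swapping_contrast_inverts_pa_fc_same_p(self, rng):
        tot, pol = self._pair(rng)
        f = polysome_shift(tot, pol, ("condA", "condB"))
        g = polysome_shift(tot, pol, ("condB", "condA"))
        assert np.allclose(f["pa_fc"] * g["pa_fc"], 1.0)
        assert np.allclose(f["p"], g["p"])

    def test_mismatched_loci_raise(self, rng):
        tot, pol = self._pair(rng)
        pol.data.index = [f"X{i}" for i in range(len(pol.data))]
        with pytest.raises(ValueError, match="disagree"):
            polysome_shift(tot, pol, ("condA", "condB"))

    def test_missing_fraction_labels_raise(self, rng):
        tot = _mat(rng.integers(10, 400, (10, 6)))
        with pytest.raises(ValueError, match="fraction"):
            polysome_shift(tot, tot, ("condA", "condB"))


class TestPearsonProfile:
    def test_affine_and_reflected_profiles(self, rng):
        x = rng.uniform(1, 100, 12)
        assert pearson_profile(x, 2 * x + 3) == pytest.approx(1.0)
        assert pearson_profile(x, -x) == pytest.approx(-1.0)

    def test_matches_textbook_covariance_formula(self, rng):
        x, y = rng.uniform(0, 50, 12), rng.uniform(0, 50, 12)
        r = pearson_profile(x, y)
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(pearson_profile([1, 1, 1, 1], [1, 2, 3, 4]))


@settings(max_examples=40, deadline=None)
@given(st.lists(st.floats(1e-6, 1.0), min_size=3, max_size=40), st.integers(0, 10_000))
def test_bh_adjustment_is_monotone_and_bounded(pvals, seed):
    """padj is monotone non-decreasing in p-rank and never exceeds 1."""
    rng = np.random.default_rng(seed)
    n = len(pvals)
    counts = rng.integers(1, 50, (n, 6))
    mat = make_count_matrix(counts, [f"L{i}" for i in range(n)], NAMES_AB)
    de = differential_expression(mat, ("condA", "condB"))
    sorted_by_p = de.sort_values("p")
    assert (sorted_by_p["padj"].diff().dropna() >= -1e-12).all()
    assert (de["padj"] <= 1.0 + 1e-12).all()
    assert (de["padj"] >= de["p"] - 1e-12).all()
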
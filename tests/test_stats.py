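import numpy as np
import pytest

from eigendiff import (
    AssayGrouping,
    InsufficientReplicationError,
    ea_group_contributions,
    eg_group_contributions,
    eigenassay_decomposition,
    eigengene_decomposition,
    pooled_sd,
    standardize,
    t_diff,
    t_pooled,
    t_scaled_eg,
)
from conftest import make_matrix


def loop_eg_contributions(z, loadings, j, group):
    """Independent term-by-term oracle for the EG group-mean contribution."""
    m = z.shape[0]
    out = np.zeros(m)
    for i in range(m):
        acc = 0.0
        for k in group:  # 1-based assay indices
            acc += loadings[k - 1, j - 1] * z[i, k - 1]
        out[i] = acc / len(group)
    return out


@pytest.fixture
def fixture_4x4(rng):
    x = make_matrix(rng.normal(5.3, 0.7, size=(4, 4)))
    g = AssayGrouping((1, 2), (3, 4))
    return x, g


class TestContributions:
    def test_eg_matches_loop_oracle(self, rng, grouping_3_3):
        x = make_matrix(rng.normal(5.3, 0.7, size=(12, 6)))
        z = standardize(x)
        d = eigengene_decomposition(z)
        for j in (1, 3):
            c = eg_group_contributions(z, d, j, grouping_3_3)
            np.testing.assert_allclose(
                c.per_gene_group_a,
                loop_eg_contributions(z.z_values, d.loadings, j, grouping_3_3.group_a),
                atol=1e-12,
            )
            np.testing.assert_allclose(
                c.per_gene_group_b,
                loop_eg_contributions(z.z_values, d.loadings, j, grouping_3_3.group_b),
                atol=1e-12,
            )

    def test_eg_singleton_group(self, fixture_4x4):
        x, _ = fixture_4x4
        z = standardize(x)
        d = eigengene_decomposition(z)
        g = AssayGrouping((2,), (3, 4))
        c = eg_group_contributions(z, d, 1, g)
        np.testing.assert_allclose(
            c.per_gene_group_a, d.loadings[1, 0] * z.z_values[:, 1], atol=1e-12
        )

    def test_eg_score_decomposition(self, small_matrix):
        # summing single-assay contributions over all assays recovers the score
        z = standardize(small_matrix)
        d = eigengene_decomposition(z)
        for j in (1, 2, 6):
            total = np.zeros(z.m)
            for k in range(1, z.n + 1):
                g = AssayGrouping((k,), tuple(i for i in range(1, z.n + 1) if i != k))
                total += eg_group_contributions(z, d, j, g).per_gene_group_a
            np.testing.assert_allclose(total, d.scores[:, j - 1], atol=1e-10)

    def test_ea_two_path_identity(self, fixture_4x4):
        # loading times raw group mean must equal the averaged contributions
        x, g = fixture_4x4
        d = eigenassay_decomposition(x)
        c = ea_group_contributions(x, d, 1, g)
        direct = d.loadings[:, 0] * x.values[:, g.a0].mean(axis=1)
        np.testing.assert_allclose(c.per_gene_group_a, direct, atol=1e-12)

    def test_ea_loop_oracle(self, rng):
        x = make_matrix(rng.normal(5.3, 0.7, size=(8, 4)))
        g = AssayGrouping((1, 3), (2, 4))
        d = eigenassay_decomposition(x)
        c = ea_group_contributions(x, d, 2, g)
        for p in range(8):
            acc = sum(d.loadings[p, 1] * x.values[p, i - 1] for i in g.group_b)
            assert c.per_gene_group_b[p] == pytest.approx(acc / g.n_b, abs=1e-12)


class TestTDiff:
    def test_identical_groups_zero(self, fixture_4x4):
        x, _ = fixture_4x4
        z = standardize(x)
        d = eigengene_decomposition(z)
        g = AssayGrouping((1, 2), (3, 4))
        c = eg_group_contributions(z, d, 1, g)
        same = t_diff(c)
        c_rev = eg_group_contributions(z, d, 1, g.swapped())
        np.testing.assert_allclose(same.values, -t_diff(c_rev).values, atol=1e-12)

    def test_antisymmetry_all_statistics(self, small_matrix, grouping_3_3):
        z = standardize(small_matrix)
        d = eigengene_decomposition(z)
        sw = grouping_3_3.swapped()
        td = t_diff(eg_group_contributions(z, d, 1, grouping_3_3)).values
        td_s = t_diff(eg_group_contributions(z, d, 1, sw)).values
        np.testing.assert_allclose(td, -td_s, atol=1e-12)
        ts = t_scaled_eg(z, d, 1, grouping_3_3).values
        ts_s = t_scaled_eg(z, d, 1, sw).values
        np.testing.assert_allclose(ts, -ts_s, atol=1e-12)
        tp = t_pooled(small_matrix, grouping_3_3).values
        tp_s = t_pooled(small_matrix, sw).values
        np.testing.assert_allclose(tp, -tp_s, atol=1e-12)


class TestPooledSd:
    def test_equal_variances(self):
        vals = np.array([[1.0, 3.0, 2.0, 4.0], [0.0, 2.0, 1.0, 3.0]])
        g = AssayGrouping((1, 2), (3, 4))
        np.testing.assert_allclose(pooled_sd(vals, g), [np.sqrt(2)] * 2, atol=1e-12)

    def test_unbalanced_weights(self):
        # n_A=3 with s2_A=1, n_B=2 with s2_B=4: pooled s2 = (2*1 + 1*4)/3 = 2
        a = np.array([0.0, 1.0, 2.0])  # var 1
        b = np.array([0.0, 2.0 * np.sqrt(2)])  # var 4
        vals = np.concatenate([a, b])[None, :].repeat(2, axis=0)
        g = AssayGrouping((1, 2, 3), (4, 5))
        np.testing.assert_allclose(pooled_sd(vals, g), [np.sqrt(2)] * 2, atol=1e-12)

    def test_singleton_group_rejected(self):
        with pytest.raises(InsufficientReplicationError):
            pooled_sd(np.ones((2, 3)), AssayGrouping((1,), (2, 3)))


class TestTScaled:
    def test_unit_variance_equal_loadings_closed_form(self):
        # with equal loadings and balanced groups of size q the statistic
        # reduces to (zbar_A - zbar_B) * sqrt(q/2), independent of the loading
        rng = np.random.default_rng(3)
        z = rng.normal(size=(10, 6))
        g = AssayGrouping((1, 2, 3), (4, 5, 6))
        for ell in (0.3, 1.7):
            loadings = np.full((6, 6), ell)
            from eigendiff.pca import Decomposition, StandardizedMatrix

            zm = StandardizedMatrix(z, np.zeros(6), np.ones(6),
                                    tuple(f"g{i}" for i in range(10)),
                                    tuple(f"a{j}" for j in range(6)))
            d = Decomposition("EG", loadings, z @ loadings, np.ones(6), 6)
            res = t_scaled_eg(zm, d, 1, g, unit_variance=True)
            expected = (z[:, :3].mean(1) - z[:, 3:].mean(1)) * np.sqrt(3 / 2)
            np.testing.assert_allclose(res.values, expected, atol=1e-10)

    def test_scale_equivariance_unit_variance(self, small_matrix, grouping_3_3):
        # multiplying the loading vector by c > 0 leaves the statistic unchanged
        from dataclasses import replace

        z = standardize(small_matrix)
        d = eigengene_decomposition(z)
        base = t_scaled_eg(z, d, 1, grouping_3_3, unit_variance=True).values
        d2 = replace(d, loadings=d.loadings * 3.7)
        scaled = t_scaled_eg(z, d2, 1, grouping_3_3, unit_variance=True).values
        np.testing.assert_allclose(base, scaled, atol=1e-10)

    def test_zero_loadings_flagged_not_infinite(self, small_matrix, grouping_3_3):
        from dataclasses import replace

        z = standardize(small_matrix)
        d = eigengene_decomposition(z)
        d0 = replace(d, loadings=np.zeros_like(d.loadings))
        res = t_scaled_eg(z, d0, 1, grouping_3_3, unit_variance=True)
        assert res.flagged.all()
        assert np.isnan(res.values).all()

    def test_denominator_definition(self, small_matrix, grouping_3_3):
        # spelled-out Eq.: T_diff / (s_pooled_z * sqrt(sum_A l^2/nA^2 + sum_B l^2/nB^2))
        z = standardize(small_matrix)
        d = eigengene_decomposition(z)
        g = grouping_3_3
        ell = d.loadings[:, 0]
        coeff = np.sqrt((ell[g.a0] ** 2).sum() / 9 + (ell[g.b0] ** 2).sum() / 9)
        diff = t_diff(eg_group_contributions(z, d, 1, g)).values
        sp = pooled_sd(z.z_values, g)
        np.testing.assert_allclose(
            t_scaled_eg(z, d, 1, g).values, diff / (sp * coeff), atol=1e-12
        )


class TestTPooled:
    def test_hand_computed_value(self):
        # A=(1,2,3), B=(4,5,6): mean diff -3, pooled s2=1, t = -3/sqrt(2/3)
        vals = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0], [0.0, 1.0, 2.0, 0.0, 1.0, 2.0]])
        g = AssayGrouping((1, 2, 3), (4, 5, 6))
        res = t_pooled(make_matrix(vals), g)
        assert res.values[0] == pytest.approx(-3 / np.sqrt(2 / 3), abs=1e-10)
        assert res.values[1] == pytest.approx(0.0, abs=1e-12)

    def test_equal_means_zero(self):
        vals = np.array([[1.0, 2.0, 1.0, 2.0], [3.0, 5.0, 5.0, 3.0]])
        res = t_pooled(make_matrix(vals), AssayGrouping((1, 2), (3, 4)))
        np.testing.assert_allclose(res.values, 0.0, atol=1e-12)

    def test_matches_scipy(self, small_matrix, grouping_3_3):
        from scipy import stats as sps

        res = t_pooled(small_matrix, grouping_3_3)
        ref = sps.ttest_ind(
            small_matrix.values[:, grouping_3_3.a0],
            small_matrix.values[:, grouping_3_3.b0],
            axis=1,
            equal_var=True,
        ).statistic
        np.testing.assert_allclose(res.values, ref, atol=1e-10)

    def test_affine_invariance_up_to_sign(self, small_matrix, grouping_3_3):
        base = t_pooled(small_matrix, grouping_3_3).values
        for a, b in ((2.5, 1.0), (-1.5, 3.0)):
            x2 = make_matrix(a * small_matrix.values + b)
            other = t_pooled(x2, grouping_3_3).values
            np.testing.assert_allclose(other, np.sign(a) * base, atol=1e-8)

    def test_constant_gene_flagged(self):
        vals = np.array([[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 3.0]])
        res = t_pooled(make_matrix(vals), AssayGrouping((1, 2), (3, 4)))
        assert res.flagged[0] and not res.flagged[1]
        assert np.isnan(res.values[0])


class TestPooledEquivalence:
    def test_ea_scaled_identity_many_fixtures(self):
        """Scaling the EA differential contribution cancels the loading and
        reproduces the pooled two-sample t exactly, on 100 random fixtures."""
        rng = np.random.default_rng(42)
        for trial in range(100):
            m = int(rng.integers(5, 30))
            n_a = int(rng.integers(2, 5))
            n_b = int(rng.integers(2, 5))
            x = make_matrix(rng.normal(5.3, 1.0, size=(m, n_a + n_b)))
            g = AssayGrouping(tuple(range(1, n_a + 1)), tuple(range(n_a + 1, n_a + n_b + 1)))
            d = eigenassay_decomposition(x)
            j = int(rng.integers(1, min(d.n_components, 3) + 1))
            ell = d.loadings[:, j - 1]
            diff = t_diff(ea_group_contributions(x, d, j, g)).values
            denom = np.abs(ell) * pooled_sd(x.values, g) * np.sqrt(1 / g.n_a + 1 / g.n_b)
            ok = denom > 0
            ea_scaled = np.sign(ell[ok]) * diff[ok] / denom[ok]
            pooled = t_pooled(x, g).values[ok]
            np.testing.assert_allclose(ea_scaled, pooled, atol=1e-12)

    def test_ea_tdiff_scales_with_data(self, small_matrix, grouping_3_3):
        # the EA differential contribution is scale-equivariant in the data
        d = eigenassay_decomposition(small_matrix)
        base = t_diff(ea_group_contributions(small_matrix, d, 1, grouping_3_3)).values
        x2 = make_matrix(2.0 * small_matrix.values)
        d2 = eigenassay_decomposition(x2)
        other = t_diff(ea_group_contributions(x2, d2, 1, grouping_3_3)).values
        np.testing.assert_allclose(np.abs(other), 2.0 * np.abs(base), atol=1e-8)
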
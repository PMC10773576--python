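"""TRE computation, noise metrics, stratification, consistency, statistics."""

import numpy as np
import pytest

import liverreg as lr
from liverreg.evaluation import (
    TargetSet,
    compare_methods,
    compute_tre,
    field_consistency,
    fuse_fields,
    noise_group_tests,
    noise_metrics,
    stratify_by_extent,
    stratify_by_segment,
    tre_correlation,
)
from liverreg.fields import DisplacementField
from liverreg.geometry import InvalidInputError


class TestComputeTre:
    def test_zero_when_estimates_exact(self, rng):
        gt = rng.normal(scale=50, size=(30, 3))
        s = compute_tre(TargetSet(gt, gt.copy()))
        assert np.allclose(s.per_target, 0.0)
        assert s.mean == 0.0 and s.median == 0.0

    def test_uniform_offset_345(self, rng):
        gt = rng.normal(scale=50, size=(20, 3))
        s = compute_tre(TargetSet(gt, gt + np.array([3.0, 4.0, 0.0])))
        assert np.allclose(s.per_target, 5.0)

    def test_matches_coordinatewise_recomputation(self, rng):
        gt = rng.normal(scale=50, size=(40, 3))
        est = gt + rng.normal(scale=3, size=gt.shape)
        s = compute_tre(TargetSet(gt, est))
        manual = np.sqrt(((gt - est) ** 2).sum(axis=1))
        assert np.allclose(s.per_target, manual, atol=1e-12)
        assert s.mean == pytest.approx(manual.mean(), rel=1e-12)

    def test_invariant_under_joint_rigid_motion(self, rng):
        gt = rng.normal(scale=50, size=(25, 3))
        est = gt + rng.normal(scale=2, size=gt.shape)
        T = lr.sample_random_rigid(3)
        a = compute_tre(TargetSet(gt, est)).per_target
        b = compute_tre(TargetSet(T.apply(gt), T.apply(est))).per_target
        assert np.allclose(a, b, atol=1e-10)

    def test_count_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            TargetSet(np.zeros((3, 3)), np.zeros((4, 3)))


class TestNoiseMetrics:
    @pytest.mark.parametrize(
        "noisy,clean,expected_dn",
        [
            (3.34, 2.50, 0.42),
            (3.56, 2.56, 0.50),
            (4.80, 4.02, 0.39),
            (7.62, 8.06, -0.22),
            (3.77, 3.77, 0.00),
        ],
    )
    def test_degradation_arithmetic(self, noisy, clean, expected_dn):
        _, dn = noise_metrics(noisy, clean, 2.0)
        assert round(dn, 2) == expected_dn

    def test_trivial_identities(self):
        en, dn = noise_metrics(2.0, 2.0, 2.0)
        assert en == pytest.approx(1.0)
        assert dn == pytest.approx(0.0)

    def test_zero_noisy_mean_flagged(self):
        en, dn = noise_metrics(0.0, 0.0, 2.0)
        assert np.isnan(en)

    def test_bad_amplitude_rejected(self):
        with pytest.raises(InvalidInputError):
            noise_metrics(3.0, 2.0, 0.0)


class TestStratifyByExtent:
    def test_single_middle_bin(self):
        df = stratify_by_extent(np.ones(10), np.full(10, 30.0))
        assert df.loc["[28, 36)", "count"] == 10
        assert df["count"].sum() == 10

    def test_boundary_goes_to_upper_bin(self):
        df = stratify_by_extent(np.ones(1), np.array([28.0]))
        assert df.loc["[28, 36)", "count"] == 1
        assert df.loc["[20, 28)", "count"] == 0

    def test_final_edge_closed(self):
        df = stratify_by_extent(np.ones(1), np.array([44.0]))
        assert df.loc["[36, 44]", "count"] == 1

    def test_counts_conserved_with_outliers(self, rng):
        ext = rng.uniform(15, 50, size=60)
        df = stratify_by_extent(rng.normal(size=60), ext)
        assert df["count"].sum() == 60


class TestStratifyBySegment:
    def test_identical_tre_identical_means(self):
        seg = np.repeat(np.arange(2, 9), 10)
        df = stratify_by_segment(np.full(len(seg), 3.0), seg)
        assert np.allclose(df["mean"], 3.0)

    def test_offset_shifts_only_its_segment(self):
        seg = np.repeat(np.arange(2, 9), 10)
        tre = np.full(len(seg), 3.0)
        tre[seg == 5] += 1.0
        df = stratify_by_segment(tre, seg)
        assert df.loc[5, "mean"] == pytest.approx(4.0)
        assert np.allclose(df.drop(index=5)["mean"], 3.0)

    def test_counts_sum_and_exclusion_flag(self):
        seg = np.array([2] * 10 + [3] * 2)
        df = stratify_by_segment(np.ones(12), seg, min_count=5)
        assert df["count"].sum() == 12
        assert not df.loc[2, "excluded"] and df.loc[3, "excluded"]


class TestFieldConsistency:
    def test_zero_fields(self, cube_tet_mesh):
        z = DisplacementField(np.zeros((cube_tet_mesh.n_nodes, 3)))
        strain, jac = field_consistency(cube_tet_mesh, [z, z])
        assert np.allclose(strain, 0.0)
        assert np.allclose(jac, 1.0)

    def test_single_field_matches_direct_evaluation(self, cube_tet_mesh, rng):
        from liverreg.fields import (
            element_displacement_gradients,
            green_strain_norm,
            jacobian_determinant,
        )

        f = DisplacementField(rng.normal(scale=0.05, size=(cube_tet_mesh.n_nodes, 3)))
        strain, jac = field_consistency(cube_tet_mesh, [f])
        g = element_displacement_gradients(cube_tet_mesh, f)
        assert np.allclose(strain, green_strain_norm(g))
        assert np.allclose(jac, jacobian_determinant(g))

    def test_mean_of_measures_not_measure_of_mean(self, cube_tet_mesh):
        # dilation and contraction: the mean field is zero (|J| = 1), but the
        # mean of per-field |J| is (1.1^3 + 0.9^3) / 2 != 1
        up = DisplacementField(0.1 * cube_tet_mesh.nodes)
        down = DisplacementField(-0.1 * cube_tet_mesh.nodes)
        _, jac = field_consistency(cube_tet_mesh, [up, down])
        expected = 0.5 * (1.1**3 + 0.9**3)
        assert np.allclose(jac, expected, atol=1e-9)
        assert not np.allclose(jac, 1.0)


class TestTreCorrelation:
    def test_self_and_scaled_correlation_unity(self, rng):
        x = rng.normal(size=500) ** 2 + 1
        df = tre_correlation({"a": x, "b": 2.0 * x})
        assert df.loc["a", "a"] == pytest.approx(1.0)
        assert df.loc["a", "b"] == pytest.approx(1.0)

    def test_independent_columns_uncorrelated(self, rng):
        df = tre_correlation(
            {"a": rng.normal(size=1000), "b": rng.normal(size=1000)}
        )
        assert abs(df.loc["a", "b"]) < 0.1

    def test_matrix_symmetric_bounded_psd(self, rng):
        data = {k: rng.normal(size=200) for k in "abcd"}
        df = tre_correlation(data)
        m = df.to_numpy()
        assert np.allclose(m, m.T)
        assert np.all(np.abs(m) <= 1 + 1e-12)
        assert np.linalg.eigvalsh(m).min() > -1e-10

    def test_zero_variance_flagged_nan(self, rng):
        df = tre_correlation({"a": np.ones(50), "b": rng.normal(size=50)})
        assert np.isnan(df.loc["a", "b"])


class TestFuseFields:
    def test_single_field_identity(self, rng):
        f = DisplacementField(rng.normal(size=(10, 3)))
        assert np.allclose(fuse_fields([f]).values, f.values)

    def test_field_and_negation_cancel(self, rng):
        f = DisplacementField(rng.normal(size=(10, 3)))
        g = DisplacementField(-f.values)
        assert np.allclose(fuse_fields([f, g]).values, 0.0)

    def test_complementary_errors_average_out(self, cube_tet_mesh, rng):
        # two registrations erring in opposite directions: fusing their
        # fields beats both individual TREs
        from liverreg.fields import interpolate_displacement

        true_u = np.array([1.0, -0.5, 0.2])
        targets = rng.uniform(0.2, 0.8, size=(25, 3))
        gt = targets + true_u
        bias = np.array([0.6, 0.4, -0.3])
        fa = DisplacementField(np.tile(true_u + bias, (cube_tet_mesh.n_nodes, 1)))
        fb = DisplacementField(np.tile(true_u - bias, (cube_tet_mesh.n_nodes, 1)))
        fused = fuse_fields([fa, fb])

        def mean_tre(field):
            u = interpolate_displacement(cube_tet_mesh, field, targets)
            return np.linalg.norm(targets + u - gt, axis=1).mean()

        assert mean_tre(fused) < mean_tre(fa)
        assert mean_tre(fused) < mean_tre(fb)


class TestCompareMethods:
    def test_identical_methods_not_rejected(self, rng):
        x = rng.normal(size=40) ** 2 + 3
        cmp = compare_methods({"a": x, "b": x.copy(), "c": x.copy()})
        assert cmp.friedman_p == pytest.approx(1.0)
        assert not cmp.any_significant

    def test_uniform_offset_detected(self, rng):
        x = rng.normal(size=40) ** 2 + 3
        cmp = compare_methods({"a": x, "b": x + 5.0})
        assert cmp.any_significant
        assert (cmp.pairwise["p_adjusted"] < 0.05).all()

    def test_bonferroni_adjustment_definition(self, rng):
        vals = {k: rng.normal(size=30) + i * 0.1 for i, k in enumerate("abc")}
        cmp = compare_methods(vals)
        m = 3  # pairwise comparisons among 3 methods
        for _, row in cmp.pairwise.iterrows():
            assert row["p_adjusted"] == pytest.approx(
                min(1.0, m * row["p_raw"])
            )

    def test_noise_group_tests_report(self, rng):
        out = noise_group_tests(rng.normal(size=50) + 3, rng.normal(size=30) + 3)
        assert not out["skipped"]
        assert {"ranksum_p", "brown_forsythe_p", "ks_p"} <= set(out)
        tiny = noise_group_tests(np.ones(1), np.ones(1))
        assert tiny["skipped"]
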
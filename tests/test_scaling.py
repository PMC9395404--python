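"""Population analyses: scaling-line fits, parallel-shift xi^-1 recovery,
condition changes, rank-sum statistics, bead strain and shape descriptors."""

import itertools

import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk, ellipse

from viscocap import (
    PopulationModel,
    SyntheticConfig,
    aggregate_cells,
    binned_scaling_fit,
    normalized_change,
    rank_sum_tests,
    shape_descriptors,
    simulate_bead_field,
    simulate_population,
    strain_from_beads,
    xi_from_parallel_shift,
)


def line_records(n=200, a=0.9, m=0.2, scatter=0.0, seed=0, k_range=(-2.3, -0.7)):
    rng = np.random.default_rng(seed)
    log_k = rng.uniform(*k_range, n)
    beta = a - m * log_k + rng.normal(0, scatter, n)
    return pd.DataFrame({"cell": np.arange(n), "KA0": 10.0**log_k, "beta": beta})


class TestBinnedScalingFit:
    def test_exact_line_recovered(self):
        fit = binned_scaling_fit(line_records(), nbins=8)
        assert fit.slope == pytest.approx(0.2, rel=1e-9)
        assert fit.intercept == pytest.approx(0.9, rel=1e-9)

    def test_2d_mode_on_exact_line(self):
        fit = binned_scaling_fit(line_records(), nbins=6, mode="2d")
        assert fit.slope == pytest.approx(0.2, rel=1e-6)

    def test_noisy_slope_within_15_percent(self):
        fit = binned_scaling_fit(line_records(scatter=0.05, seed=3), nbins=8)
        assert fit.slope == pytest.approx(0.2, rel=0.15)

    def test_degenerate_records_rejected(self):
        df = pd.DataFrame({"cell": range(30), "KA0": [0.05] * 30, "beta": [0.5] * 30})
        with pytest.raises(ValueError, match="occupied bins"):
            binned_scaling_fit(df, nbins=8)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="records"):
            binned_scaling_fit(line_records(n=10), nbins=8)


class TestXiFromParallelShift:
    def test_identical_populations_give_unity(self):
        records = line_records(scatter=0.03, seed=5)
        fit = binned_scaling_fit(records, nbins=8)
        est = xi_from_parallel_shift(fit, fit)
        assert est.xi_inv == pytest.approx(1.0, abs=1e-12)
        assert est.slope_ratio == pytest.approx(1.0)

    def test_constructed_factor_two_shift(self):
        ref = line_records(scatter=0.0, seed=6)
        cond = ref.assign(KA0=ref["KA0"] * 2.0)
        est = xi_from_parallel_shift(
            binned_scaling_fit(ref, nbins=8), binned_scaling_fit(cond, nbins=8)
        )
        assert est.xi_inv == pytest.approx(2.0, rel=1e-9)

    def test_scale_equivariance(self):
        ref = line_records(scatter=0.04, seed=7)
        cond = ref.assign(KA0=ref["KA0"] * 1.7)
        est1 = xi_from_parallel_shift(
            binned_scaling_fit(ref, nbins=8), binned_scaling_fit(cond, nbins=8)
        )
        ref10 = ref.assign(KA0=ref["KA0"] * 10)
        cond10 = cond.assign(KA0=cond["KA0"] * 10)
        est2 = xi_from_parallel_shift(
            binned_scaling_fit(ref10, nbins=8), binned_scaling_fit(cond10, nbins=8)
        )
        assert est1.xi_inv == pytest.approx(est2.xi_inv, rel=1e-9)

    def test_flat_lines_rejected(self):
        ref = line_records(m=0.0, scatter=0.0, seed=8)
        fit = binned_scaling_fit(ref, nbins=8)
        with pytest.raises(ValueError, match="shift undefined"):
            xi_from_parallel_shift(fit, fit)

    def test_recovery_with_scatter(self):
        # shift factor mirroring monolayer stretching, recovered from noisy
        # populations through the shared-slope estimator
        cfg = SyntheticConfig(
            population=PopulationModel(n_cells=200, xi_inv=1.5), seed=42
        )
        records, _ = simulate_population(cfg)
        ref = records[records.condition == "reference"]
        cond = records[records.condition == "condition"]
        est = xi_from_parallel_shift(
            binned_scaling_fit(ref, nbins=8), binned_scaling_fit(cond, nbins=8)
        )
        assert 1.35 <= est.xi_inv <= 1.65


class TestNormalizedChange:
    def test_identical_conditions_zero(self):
        ref = line_records(scatter=0.02, seed=9).assign(sigma0=1e-3)
        table, summary = normalized_change(ref, ref, "KA0")
        assert np.abs(table.change_percent).max() < 1e-12
        assert summary["median"] == 0.0

    def test_doubling_gives_plus_100(self):
        ref = line_records(seed=10).assign(sigma0=1e-3)
        cond = ref.assign(KA0=ref["KA0"] * 2)
        _, summary = normalized_change(cond, ref, "KA0")
        assert summary["median"] == pytest.approx(100.0)

    def test_lognormal_shift_median(self):
        # stiffness up ~60% with 10% lognormal cell noise
        rng = np.random.default_rng(11)
        ref = line_records(seed=11)
        cond = ref.assign(KA0=ref["KA0"] * 1.6 * rng.lognormal(0.0, 0.1, len(ref)))
        _, summary = normalized_change(cond, ref, "KA0")
        assert summary["median"] == pytest.approx(60.0, abs=10.0)

    def test_unmatched_cells_dropped(self):
        ref = line_records(n=50, seed=12)
        cond = line_records(n=50, seed=13)
        cond = cond[cond.cell >= 10]
        table, _ = normalized_change(cond, ref, "KA0")
        assert len(table) == 40


class TestRankSum:
    @staticmethod
    def exact_two_sided_p(a, b):
        """Brute-force enumeration of the two-sided Mann-Whitney null."""
        pooled = np.concatenate([a, b])
        n1 = len(a)

        def u_stat(x, y):
            return sum(1 for xi in x for yi in y if xi > yi) + 0.5 * sum(
                1 for xi in x for yi in y if xi == yi
            )

        u_obs = u_stat(a, b)
        n = len(pooled)
        mu = n1 * (n - n1) / 2
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n1):
            mask = np.zeros(n, bool)
            mask[list(combo)] = True
            u = u_stat(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                count += 1
        return count / total

    def test_small_sample_exact_p(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        assert self.exact_two_sided_p(a, b) == pytest.approx(0.1)
        out = rank_sum_tests({"g1": a, "g2": b})
        assert out.p_raw[0] == pytest.approx(0.1)
        assert out.method[0] == "exact"

    def test_random_case_matches_enumeration(self):
        rng = np.random.default_rng(21)
        a, b = rng.normal(0, 1, 5), rng.normal(0.5, 1, 5)
        out = rank_sum_tests({"g1": a, "g2": b})
        assert out.p_raw[0] == pytest.approx(self.exact_two_sided_p(a, b), abs=1e-12)

    def test_identical_groups_not_significant(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = rank_sum_tests({"g1": a, "g2": a.copy()})
        assert out.p_adjusted[0] == pytest.approx(1.0)
        assert out.code[0] == "ns"

    def test_bonferroni_arithmetic(self):
        # three pairwise comparisons multiply the raw p by three
        rng = np.random.default_rng(22)
        groups = {f"g{i}": rng.normal(i * 0.5, 1, 8) for i in range(3)}
        out = rank_sum_tests(groups)
        assert len(out) == 3
        np.testing.assert_allclose(
            out.p_adjusted, np.minimum(out.p_raw * 3, 1.0), rtol=1e-12
        )

    def test_exact_and_asymptotic_agree(self):
        rng = np.random.default_rng(23)
        a, b = rng.normal(0, 1, 10), rng.normal(0.3, 1, 10)
        p_exact = rank_sum_tests({"a": a, "b": b}).p_raw[0]
        p_asym = rank_sum_tests({"a": a, "b": b}, exact_max_n=0).p_raw[0]
        assert abs(p_exact - p_asym) < 1e-2

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n < 3"):
            rank_sum_tests({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})


class TestStrainFromBeads:
    def test_pure_scaling(self):
        pre, during = simulate_bead_field(0.15, 0.0, n=30, jitter=0.0, seed=1)
        field = strain_from_beads(pre, during, "x")
        assert field.longitudinal == pytest.approx(0.15, abs=1e-12)
        assert field.lateral == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation(self):
        rng = np.random.default_rng(2)
        pre = rng.uniform(0, 100e-6, (20, 2))
        during = pre + np.array([3e-6, -2e-6])
        field = strain_from_beads(pre, during, "x")
        assert field.longitudinal == pytest.approx(0.0, abs=1e-12)
        assert field.lateral == pytest.approx(0.0, abs=1e-12)

    def test_biaxial_with_jitter(self):
        pre, during = simulate_bead_field(0.30, -0.05, n=50, jitter=0.2e-6, seed=3)
        field = strain_from_beads(pre, during, "x")
        assert field.longitudinal == pytest.approx(0.30, abs=0.01)
        assert field.lateral == pytest.approx(-0.05, abs=0.01)

    def test_ambiguous_matching_rejected(self):
        pre = np.array([[0.0, 0.0], [1e-6, 0.0], [50e-6, 50e-6]])
        during = np.array([[0.5e-6, 0.0], [0.5e-6, 0.1e-6], [100e-6, 100e-6]])
        with pytest.raises(ValueError, match="ambiguous"):
            strain_from_beads(pre, during, "x")


class TestShapeDescriptors:
    def test_circle_is_round(self):
        mask = np.zeros((101, 101), bool)
        rr, cc = disk((50, 50), 35)
        mask[rr, cc] = True
        _, ecc, _ = shape_descriptors(mask, "x")
        assert ecc < 0.05

    def test_two_to_one_ellipse_eccentricity(self):
        mask = np.zeros((201, 301), bool)
        rr, cc = ellipse(100, 150, 60, 120)
        mask[rr, cc] = True
        area, ecc, _ = shape_descriptors(mask, "x", pixel_size=0.5)
        assert ecc == pytest.approx(np.sqrt(3) / 2, rel=0.01)
        assert area == pytest.approx(np.pi * 60 * 120 * 0.25, rel=0.01)

    def test_orientation_convention(self):
        mask = np.zeros((201, 301), bool)
        rr, cc = ellipse(100, 150, 40, 120)  # major axis along columns (x)
        mask[rr, cc] = True
        _, _, orient_x = shape_descriptors(mask, "x")
        assert orient_x == pytest.approx(90.0, abs=1.0)
        _, _, orient_y = shape_descriptors(mask, "y")
        assert orient_y == pytest.approx(0.0, abs=1.0)

    def test_translation_and_rotation_invariance(self):
        base = np.zeros((301, 301), bool)
        rr, cc = ellipse(120, 140, 30, 80, rotation=np.deg2rad(25))
        base[rr, cc] = True
        shifted = np.roll(base, (40, -30), axis=(0, 1))
        flipped = base[::-1, ::-1]  # 180 degree rotation
        _, _, o0 = shape_descriptors(base, "x")
        _, _, o1 = shape_descriptors(shifted, "x")
        _, _, o2 = shape_descriptors(flipped, "x")
        assert o1 == pytest.approx(o0, abs=0.5)
        assert o2 == pytest.approx(o0, abs=0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            shape_descriptors(np.zeros((10, 10), bool), "x")


def test_aggregate_cells_averages_indentations():
    fits = pd.DataFrame(
        {"cell": [1, 1, 2], "beta": [0.4, 0.6, 0.3], "KA0": [0.04, 0.06, 0.1],
         "sigma0": [1e-3, 3e-3, 2e-3]}
    )
    agg = aggregate_cells(fits)
    assert len(agg) == 2
    row = agg[agg.cell == 1].iloc[0]
    assert row.beta == pytest.approx(0.5)
    assert row.KA0 == pytest.approx(0.05)
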
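"""Map-comparison and reliability statistics tests."""

import numpy as np
import pytest
from scipy import stats

from motormap import (
    DegenerateMapError,
    css_icms_correlation,
    friedman_test,
    icc,
    interpolate_map,
    make_icms_map,
    make_subject,
    map_area,
    min_mt,
    rank_with_ties,
    session_tests,
    spearman_permutation_test,
)
from motormap.virtual_subject import ICMSMap

NR = np.nan


class TestRanking:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([30, 40, 50], [1, 2, 3]),
            ([30, 30, 50], [1.5, 1.5, 3]),
            ([30, NR, NR], [1, 2.5, 2.5]),  # nonresponsive share the worst rank
        ],
    )
    def test_examples(self, values, expected):
        np.testing.assert_array_equal(rank_with_ties(values), expected)

    def test_all_nonresponsive_rejected(self):
        with pytest.raises(DegenerateMapError):
            rank_with_ties([NR, NR, NR])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=20)
        perm = rng.permutation(20)
        np.testing.assert_array_equal(rank_with_ties(v)[perm], rank_with_ties(v[perm]))


class TestSpearmanPermutation:
    def test_identical_maps(self):
        v = np.arange(32, dtype=float)
        r = spearman_permutation_test(v, v, seed=0)
        assert r.rho == pytest.approx(1.0)
        assert r.significant
        assert r.p_perm >= 1 / (r.n_perm + 1)

    def test_rank_reversal(self):
        v = np.arange(32, dtype=float)
        r = spearman_permutation_test(v, v[::-1].copy(), seed=0)
        assert r.rho == pytest.approx(-1.0)
        assert not r.significant

    def test_matches_scipy_spearman(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=32), rng.normal(size=32)
        r = spearman_permutation_test(a, b, seed=0)
        assert r.rho == pytest.approx(stats.spearmanr(a, b).statistic)

    def test_constant_map_rejected(self):
        with pytest.raises(DegenerateMapError):
            spearman_permutation_test(np.ones(10), np.arange(10.0), seed=0)

    def test_type_one_error_near_one_percent(self):
        """The 99th-percentile criterion on 2,000 resamplings rejects ~1% of
        independent map pairs."""
        rng = np.random.default_rng(2024)
        n_tests = 1000
        hits = 0
        for _ in range(n_tests):
            a = rng.normal(size=32)
            b = rng.normal(size=32)
            hits += spearman_permutation_test(a, b, n_perm=2000, seed=rng).significant
        rate = hits / n_tests
        assert 0.002 <= rate <= 0.022  # 0.01 within ~3.5 binomial s.e.

    def test_exclude_nonresponsive_option(self):
        a = np.array([30.0, 40.0, 50.0, NR, 60.0])
        b = np.array([35.0, 45.0, NR, 55.0, 65.0])
        r = spearman_permutation_test(a, b, seed=0, exclude_nonresponsive=True)
        assert r.n_used == 3 and r.n_excluded == 2


class TestMapParameters:
    def test_uniform_map(self, uniform_subject_factory):
        import motormap as mm

        s = uniform_subject_factory(40.0)
        res = mm.run_mapping(s, "conventional", mm.ScheduleConfig.conventional(seed=0))
        assert min_mt(res.motor_map) == pytest.approx(0.40)
        assert map_area(res.motor_map) == 32

    def test_one_electrode_at_full_output(self):
        # MT of 1.0 mA exceeds the 0.95 mA responsive criterion
        v = np.full(32, NR)
        v[0] = 1.0
        assert map_area(v) == 0
        assert min_mt(v) == pytest.approx(1.0)

    def test_all_nonresponsive(self):
        v = np.full(32, NR)
        assert map_area(v) == 0
        with pytest.raises(DegenerateMapError):
            min_mt(v)

    def test_area_matches_true_thresholds_for_deterministic_subject(self):
        import motormap as mm
        from motormap import GeneratorParams

        params = GeneratorParams(spread_pct=0.0)
        s = make_subject(params=params, seed=6)
        res = mm.run_mapping(s, "novel", mm.ScheduleConfig.novel(seed=6))
        # deterministic novel MT = ceil(theta) - 2.5, so counted iff theta <= 97.5
        expected = int(np.sum(s.thetas_pct <= 97.5))
        assert map_area(res.motor_map) == expected


class TestICC:
    def test_identical_columns(self):
        m = np.column_stack([np.arange(10.0), np.arange(10.0)])
        assert icc(m).icc == pytest.approx(1.0)

    def test_noise_equal_to_signal(self):
        # per-session noise with variance equal to the between-subject
        # variance: ICC = 1/(1+1) = 0.5 when both sessions are noisy, and
        # 1/(1+0.5) = 2/3 when only the retest is (mean error var 0.5)
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, size=4000)
        both = np.column_stack(
            [x + rng.normal(0, 1, size=4000), x + rng.normal(0, 1, size=4000)]
        )
        assert icc(both).icc == pytest.approx(0.5, abs=0.05)
        one_sided = np.column_stack([x, x + rng.normal(0, 1, size=4000)])
        assert icc(one_sided).icc == pytest.approx(2 / 3, abs=0.05)

    def test_offset_degrades_absolute_agreement(self):
        x = np.arange(12.0)
        prev = 1.0
        for c in (1.0, 3.0, 6.0):
            val = icc(np.column_stack([x, x + c])).icc
            assert val < prev
            prev = val

    def test_invariant_to_subject_order(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(12, 2))
        perm = rng.permutation(12)
        assert icc(m).icc == pytest.approx(icc(m[perm]).icc)

    def test_matches_pingouin_reference(self):
        # independent reference implementation of ICC(A,1)
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(9)
        m = rng.normal(size=(12, 3))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "session": np.tile(np.arange(3), 12),
                "value": m.ravel(),
            }
        )
        table = pg.intraclass_corr(df, targets="subject", raters="session", ratings="value")
        ref = float(table.loc[table["Type"].isin(["ICC2", "ICC(A,1)"]), "ICC"].iloc[0])
        assert icc(m).icc == pytest.approx(ref)

    def test_two_by_two_design_supported(self):
        # smallest admissible design: 2 subjects x 2 sessions
        val = icc(np.array([[0.4, 0.41], [0.5, 0.52]])).icc
        assert np.isfinite(val)

    def test_constant_matrix_is_undefined(self):
        assert np.isnan(icc(np.full((12, 2), 32.0)).icc)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            icc(np.ones((1, 2)))


class TestInterpolation:
    def test_reproduces_plane(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 5, size=(20, 2))
        vals = 0.3 + 0.1 * pos[:, 0] - 0.05 * pos[:, 1]
        surf = interpolate_map(pos, vals)
        q = rng.uniform(1.5, 3.5, size=(50, 2))
        np.testing.assert_allclose(
            surf(q[:, 0], q[:, 1]), 0.3 + 0.1 * q[:, 0] - 0.05 * q[:, 1], atol=1e-9
        )

    def test_exact_at_electrodes(self):
        pos = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        vals = np.array([0.4, 0.5, 0.6, 0.7])
        surf = interpolate_map(pos, vals)
        np.testing.assert_allclose(surf(pos[:, 0], pos[:, 1]), vals)

    def test_edge_midpoint_is_mean(self):
        pos = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        vals = np.array([0.4, 0.5, 0.6, 0.7])
        surf = interpolate_map(pos, vals)
        # midpoint of the hull edge (0,0)-(1,0)
        assert surf(0.5, 0.0)[0] == pytest.approx((0.4 + 0.5) / 2)

    def test_outside_hull_flagged(self):
        pos = np.array([[0, 0], [1, 0], [0, 1]], float)
        surf = interpolate_map(pos, np.array([1.0, 2.0, 3.0]))
        assert np.isnan(surf(5.0, 5.0)[0])
        assert not surf.inside_hull(5.0, 5.0)[0]

    def test_collinear_rejected(self):
        pos = np.array([[0, 0], [1, 0], [2, 0]], float)
        with pytest.raises(ValueError):
            interpolate_map(pos, np.array([1.0, 2.0, 3.0]))

    def test_nonresponsive_dropped(self):
        pos = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        vals = np.array([0.4, NR, 0.6, 0.7])
        surf = interpolate_map(pos, vals)
        assert len(surf.values) == 3


class TestCrossModality:
    def _coincident_fixture(self, seed=0):
        rng = np.random.default_rng(seed)
        pos = np.array([[x, y] for x in range(5) for y in range(4)], float)
        css_vals = rng.uniform(0.3, 0.9, size=len(pos))
        surf = interpolate_map(pos, css_vals)
        interior = (
            (pos[:, 0] > 0) & (pos[:, 0] < 4) & (pos[:, 1] > 0) & (pos[:, 1] < 3)
        )
        icms_vals = rng.uniform(10, 50, size=len(pos))
        icms = ICMSMap(pos[:, 0], pos[:, 1], np.where(interior, icms_vals, np.nan))
        return icms, surf, css_vals, interior

    def test_equals_generic_spearman_on_coincident_sites(self):
        """With ICMS sites at the electrode positions the cross-modality
        formula reduces to the ordinary tied-rank Spearman test."""
        icms, surf, css_vals, interior = self._coincident_fixture()
        r = css_icms_correlation(icms, surf, seed=123)
        oracle = spearman_permutation_test(
            icms.mt_ua[interior], css_vals[interior], seed=123
        )
        assert r.rho == pytest.approx(oracle.rho)
        assert r.significant == oracle.significant
        assert r.p_perm == pytest.approx(oracle.p_perm)

    def test_monotone_rescale_of_same_field_gives_rho_one(self):
        from motormap import GeneratorParams

        params = GeneratorParams(jitter_sd_pct=0.0, spread_pct=0.0)
        s = make_subject(params=params, seed=9)
        pos = s.geometry.positions()
        surf = interpolate_map(pos, s.field_pct(pos[:, 0], pos[:, 1]))
        inner = pos[
            (pos[:, 0] > 0.5) & (pos[:, 0] < 4.5) & (pos[:, 1] > 0.3) & (pos[:, 1] < 1.8)
        ]
        icms = make_icms_map(s, seed=0, noise_sd_ua=0.0, max_current_ua=1e9, sites=inner)
        r = css_icms_correlation(icms, surf, seed=0)
        assert r.rho == pytest.approx(1.0)

    def test_shuffled_icms_has_zero_mean_rho(self):
        rng = np.random.default_rng(7)
        icms, surf, _, interior = self._coincident_fixture()
        rhos = []
        base = icms.mt_ua.copy()
        for _ in range(1000):
            shuffled = base.copy()
            vals = shuffled[interior]
            rng.shuffle(vals)
            shuffled[interior] = vals
            m = ICMSMap(icms.x_mm, icms.y_mm, shuffled)
            rhos.append(css_icms_correlation(m, surf, n_perm=20, seed=rng).rho)
        assert abs(np.mean(rhos)) < 0.03

    def test_sites_outside_hull_excluded_and_counted(self):
        icms, surf, _, interior = self._coincident_fixture()
        mt = icms.mt_ua.copy()
        far = np.array([[50.0, 50.0], [60.0, 60.0]])
        m = ICMSMap(
            np.concatenate([icms.x_mm, far[:, 0]]),
            np.concatenate([icms.y_mm, far[:, 1]]),
            np.concatenate([mt, [20.0, 30.0]]),
        )
        r = css_icms_correlation(m, surf, seed=0)
        assert r.n_excluded == 2

    def test_too_few_sites(self):
        pos = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], float)
        surf = interpolate_map(pos, np.array([1.0, 2.0, 3.0, 4.0]))
        icms = ICMSMap(np.array([0.2, 0.3]), np.array([0.2, 0.3]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            css_icms_correlation(icms, surf)


class TestSessionTests:
    def test_identical_conditions(self):
        m = np.tile(np.arange(12.0)[:, None], (1, 4))
        rep = session_tests(m)
        assert rep.friedman_chi2 == 0.0
        assert rep.friedman_p == 1.0
        assert all(not t.significant for t in rep.pairwise)

    def test_friedman_matches_scipy(self):
        rng = np.random.default_rng(5)
        m = rng.normal(size=(15, 4))
        chi2, p = friedman_test(m)
        ref = stats.friedmanchisquare(*(m[:, j] for j in range(4)))
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_two_conditions_agree_with_wilcoxon_decision(self):
        rng = np.random.default_rng(6)
        # strong shift: both reject
        a = rng.normal(0, 1, size=12)
        shifted = np.column_stack([a, a - 5.0])
        rep = session_tests(shifted, alpha=0.05)
        assert rep.friedman_p < 0.05 and rep.pairwise[0].p_raw < 0.05
        # identical: both accept
        same = np.column_stack([a, a])
        rep = session_tests(same, alpha=0.05)
        assert rep.friedman_p == 1.0 and rep.pairwise[0].p_raw == 1.0

    def test_one_fast_condition_drives_all_posthoc_tests(self):
        """12 subjects x 4 conditions with one condition far below the rest:
        omnibus p < 0.001 and all three corrected comparisons against it
        significant at alpha = 0.01."""
        rng = np.random.default_rng(8)
        slow = rng.normal(1500, 60, size=(12, 3))
        fast = rng.normal(100, 10, size=(12, 1))
        m = np.hstack([slow[:, :2], fast, slow[:, 2:]])
        rep = session_tests(m, alpha=0.01)
        assert rep.friedman_p < 0.001
        vs_fast = [t for t in rep.pairwise if 2 in (t.condition_a, t.condition_b)]
        assert len(vs_fast) == 3
        assert all(t.significant for t in vs_fast)

    def test_missing_cells_rejected(self):
        m = np.ones((12, 3))
        m[0, 0] = np.nan
        with pytest.raises(ValueError):
            session_tests(m)
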
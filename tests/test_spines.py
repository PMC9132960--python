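"""Soma-depth geometry, densities, exponential-null statistics, regression."""

import numpy as np
import pytest
from scipy import stats

from corrbridge.skeletons import Branchlet
from corrbridge.spines import (
    DensityRecord,
    Spine,
    SpineAnnotation,
    density_table,
    fit_exponential,
    fit_soma_layer_line,
    inter_spine_distances,
    ks_test_exponential,
    max_gap_vs_length,
    read_annotations_json,
    regress_density_vs_depth,
    soma_depth,
    write_annotations_json,
)
from corrbridge.synthetic import gen_spiny_cells

UM = 1000.0


def make_branchlet(length_um=50.0, cell="c0", bid="b0", dtype="apical_oblique"):
    poly = np.array([[0, 0, 0], [length_um * UM, 0, 0]])
    return Branchlet(cell, bid, poly, dtype)


class TestLayerLine:
    def test_points_on_x_axis(self):
        pts = np.stack([np.linspace(0, 100, 10) * UM, np.zeros(10)], axis=1)
        m = fit_soma_layer_line(pts, deep_hint=np.array([0, 1.0]))
        assert abs(m.direction[1]) < 1e-12
        assert soma_depth(np.array([50 * UM, 0.0]), m) == pytest.approx(0.0)

    def test_rotated_collinear_exact(self):
        th = 0.3
        t = np.linspace(-50, 50, 20) * UM
        pts = np.stack([t * np.cos(th), t * np.sin(th)], axis=1) + [5 * UM, 7 * UM]
        m = fit_soma_layer_line(pts, deep_hint=np.array([-np.sin(th), np.cos(th)]))
        for p in pts:
            assert abs(soma_depth(p, m)) < 1e-6

    def test_noisy_angle_matches_pca_oracle(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(-100, 100, 100) * UM
        th = 0.5
        pts = np.stack([t * np.cos(th), t * np.sin(th)], axis=1)
        pts += rng.normal(scale=2 * UM, size=pts.shape)
        m = fit_soma_layer_line(pts, deep_hint=np.array([-np.sin(th), np.cos(th)]))
        cov = np.cov((pts - pts.mean(axis=0)).T)
        evals, evecs = np.linalg.eigh(cov)
        principal = evecs[:, np.argmax(evals)]
        assert abs(abs(m.direction @ principal) - 1.0) < 1e-9

    def test_all_identical_rejected(self):
        with pytest.raises(ValueError):
            fit_soma_layer_line(np.ones((5, 2)), np.array([0, 1.0]))

    def test_y_on_x_mode(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 100, 50)
        y = 2.0 * x + 3 + rng.normal(scale=0.5, size=50)
        m = fit_soma_layer_line(np.stack([x, y], axis=1), np.array([0, 1.0]),
                                mode="y_on_x")
        slope_ols = stats.linregress(x, y).slope
        assert m.direction[1] / m.direction[0] == pytest.approx(slope_ols)


class TestSomaDepth:
    def line_y0(self):
        pts = np.stack([np.linspace(0, 10, 5) * UM, np.zeros(5)], axis=1)
        return fit_soma_layer_line(pts, deep_hint=np.array([0, 1.0]))

    def test_signed_distance(self):
        m = self.line_y0()
        assert soma_depth(np.array([5 * UM, 3 * UM]), m) == pytest.approx(3 * UM)

    def test_on_line_zero(self):
        m = self.line_y0()
        assert soma_depth(np.array([7 * UM, 0.0]), m) == pytest.approx(0.0)

    def test_sign_flips_with_hint(self):
        pts = np.stack([np.linspace(0, 10, 5) * UM, np.zeros(5)], axis=1)
        up = fit_soma_layer_line(pts, deep_hint=np.array([0, 1.0]))
        down = fit_soma_layer_line(pts, deep_hint=np.array([0, -1.0]))
        soma = np.array([2 * UM, 4 * UM])
        assert soma_depth(soma, up) == pytest.approx(-soma_depth(soma, down))


class TestDensities:
    def test_basic_densities(self):
        spines = [Spine(attachment_arc=a * UM) for a in np.linspace(1, 49, 10)]
        for s in spines[:2]:
            s.has_spine_apparatus = True
        ann = SpineAnnotation("c0", [(make_branchlet(50.0), spines)])
        (rec,) = density_table([ann])
        assert rec.spine_density == pytest.approx(0.2)
        assert rec.sa_density == pytest.approx(0.04)

    def test_branched_spine_counts_once(self):
        s = Spine(attachment_arc=10 * UM, has_spine_apparatus=True,
                  head_positions=np.array([[0, 0, 1e3], [0, 0, 2e3]]))
        ann = SpineAnnotation("c0", [(make_branchlet(10.0), [s])])
        (rec,) = density_table([ann])
        assert rec.n_spines == 1
        assert rec.n_sa == 1

    def test_pooled_over_branchlets(self):
        b1 = make_branchlet(30.0, bid="b1")
        b2 = make_branchlet(20.0, bid="b2")
        sp1 = [Spine(attachment_arc=a * UM) for a in np.linspace(1, 29, 6)]
        sp2 = [Spine(attachment_arc=a * UM) for a in np.linspace(1, 19, 4)]
        (rec,) = density_table([SpineAnnotation("c0", [(b1, sp1), (b2, sp2)])])
        assert rec.spine_density == pytest.approx(10 / 50)

    def test_counting_conservation(self):
        cohort = gen_spiny_cells(n_cells=3, seed=4)
        recs = density_table(cohort.annotations)
        for ann, rec in zip(cohort.annotations, recs):
            assert rec.n_spines == sum(len(sp) for _, sp in ann.branchlets)
            assert rec.n_sa <= rec.n_spines

    def test_depth_attached(self):
        cohort = gen_spiny_cells(n_cells=3, seed=4)
        recs = density_table(cohort.annotations, cohort.depth_model,
                             cohort.somata_xy)
        for rec in recs:
            assert rec.soma_depth == pytest.approx(
                cohort.true_depths_nm[rec.cell_id])


class TestInterSpine:
    def test_gaps(self):
        spines = [Spine(attachment_arc=a * UM) for a in (0, 2, 5)]
        assert np.allclose(inter_spine_distances(spines), [2, 3])

    def test_single_spine_empty(self):
        assert len(inter_spine_distances([Spine(attachment_arc=0)])) == 0

    def test_telescoping(self):
        rng = np.random.default_rng(2)
        arcs = np.sort(rng.uniform(0, 40 * UM, 15))
        spines = [Spine(attachment_arc=a) for a in arcs]
        gaps = inter_spine_distances(spines)
        assert len(gaps) == 14
        assert gaps.sum() == pytest.approx((arcs[-1] - arcs[0]) / UM)


class TestExponentialFit:
    def test_mle_closed_form(self):
        assert fit_exponential(np.array([1.0, 2.0, 3.0])) == pytest.approx(0.5)

    def test_equal_gaps(self):
        assert fit_exponential(np.full(10, 4.0)) == pytest.approx(0.25)

    def test_large_sample_consistency(self):
        rng = np.random.default_rng(13)
        draws = rng.exponential(1 / 0.3, size=10_000)
        lam = fit_exponential(draws)
        assert abs(lam - 0.3) < 3 * 0.3 / np.sqrt(10_000)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential(np.array([1.0, 0.0]))


class TestKSExponential:
    def test_three_point_hand_oracle(self):
        # gaps at the fitted-CDF quantiles i/(n+1): with unit rate,
        # x_i = -ln(1 - i/4); D = max_i max(i/n - c_i, c_i - (i-1)/n) = 1/4
        gaps = -np.log(1 - np.arange(1, 4) / 4.0)
        res = ks_test_exponential(
            np.concatenate([gaps, gaps[:2] + 1e-9]), lambda_hat=1.0)  # pad to n>=5
        # exact oracle on the true 3-point sample
        from corrbridge.spines import _ks_D
        assert _ks_D(gaps, 1.0) == pytest.approx(0.25)

    def test_D_matches_scipy(self):
        rng = np.random.default_rng(3)
        gaps = rng.exponential(2.0, size=50)
        lam = fit_exponential(gaps)
        res = ks_test_exponential(gaps, lam, calibration="naive")
        ref = stats.kstest(gaps, lambda x: 1 - np.exp(-lam * x))
        assert res.ks_D == pytest.approx(ref.statistic)
        assert res.ks_p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_naive_conservative_and_bootstrap_calibrated(self):
        # under the null with estimated rate, naive p-values are biased high
        # (too conservative) while the bootstrap rejection rate is nominal
        rng = np.random.default_rng(77)
        n_reps, n = 400, 100
        naive_rej = boot_rej = 0
        for _ in range(n_reps):
            gaps = rng.exponential(1.7, size=n)
            naive = ks_test_exponential(gaps, calibration="naive")
            boot = ks_test_exponential(gaps, calibration="parametric_bootstrap",
                                       n_boot=199, rng=rng)
            naive_rej += naive.ks_p < 0.05
            boot_rej += boot.ks_p < 0.05
        assert naive_rej / n_reps < 0.02  # conservative
        lo = stats.binom.ppf(0.005, n_reps, 0.05) / n_reps
        hi = stats.binom.ppf(0.995, n_reps, 0.05) / n_reps
        assert lo <= boot_rej / n_reps <= hi

    def test_power_against_regular_spacing(self):
        rng = np.random.default_rng(5)
        gaps = 1.0 + rng.uniform(-0.05, 0.05, size=200)  # jittered lattice
        res = ks_test_exponential(gaps, calibration="parametric_bootstrap",
                                  n_boot=999, rng=1)
        assert res.ks_p < 0.01

    def test_too_few_gaps(self):
        with pytest.raises(ValueError):
            ks_test_exponential(np.array([1.0, 2.0]))


class TestMaxGap:
    def test_simple(self):
        spines = [Spine(attachment_arc=a * UM) for a in (0, 2, 5)]
        ann = SpineAnnotation("c0", [(make_branchlet(10.0), spines)])
        rows = max_gap_vs_length([ann])
        assert rows[0][2] == pytest.approx(10.0)
        assert rows[0][3] == pytest.approx(3.0)

    def test_max_gap_bounded_by_length(self):
        cohort = gen_spiny_cells(n_cells=4, seed=6)
        for _, _, length, gap in max_gap_vs_length(cohort.annotations):
            assert gap <= length + 1e-9

    def test_poisson_expectation_matches_monte_carlo(self):
        # E[max gap] for Poisson spines on a fixed branchlet, estimated two
        # independent ways (generator pipeline vs direct simulation)
        lam, L = 1.5, 30.0
        rng = np.random.default_rng(8)
        direct = []
        for _ in range(2000):
            n = rng.poisson(lam * L)
            if n >= 2:
                arcs = np.sort(rng.uniform(0, L, n))
                direct.append(np.max(np.diff(arcs)))
        cohort = gen_spiny_cells(n_cells=10, branchlets_per_cell=20,
                                 branchlet_length_um=L, spine_rate_per_um=lam,
                                 seed=9)
        via_pkg = [gap for _, _, _, gap in max_gap_vs_length(cohort.annotations)]
        se = np.std(direct) / np.sqrt(len(via_pkg))
        assert abs(np.mean(via_pkg) - np.mean(direct)) < 4 * se


class TestRegression:
    def records(self, x_um, y, dtype="apical_oblique"):
        return [
            DensityRecord("c%d" % i, dtype, 0, 0, 1.0, 0.0, yi, xi * UM)
            for i, (xi, yi) in enumerate(zip(x_um, y))
        ]

    def test_perfect_line(self):
        x = np.arange(7.0)
        res = regress_density_vs_depth(self.records(x, 0.5 * x + 2),
                                       "apical_oblique")
        assert res.slope == pytest.approx(0.5)
        assert res.intercept == pytest.approx(2.0)
        assert res.p_value < 1e-10

    def test_zero_slope_null(self):
        rng = np.random.default_rng(10)
        x = np.linspace(-20, 20, 40)
        y = 1.0 + rng.normal(scale=0.1, size=40)
        res = regress_density_vs_depth(self.records(x, y), "apical_oblique")
        assert abs(res.slope) < 0.01
        assert res.p_value > 0.05

    def test_seven_point_hand_oracle(self):
        x = np.array([-18.0, -11, -4, 1, 6, 12, 19])
        y = np.array([0.10, 0.13, 0.11, 0.16, 0.15, 0.19, 0.21])
        res = regress_density_vs_depth(self.records(x, y), "apical_oblique")
        # normal equations + t CDF, computed independently
        X = np.stack([np.ones(7), x], axis=1)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        s2 = resid @ resid / 5
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        p = 2 * stats.t.sf(abs(beta[1] / se), 5)
        assert res.slope == pytest.approx(beta[1])
        assert res.intercept == pytest.approx(beta[0])
        assert res.p_value == pytest.approx(p)

    def test_ci_band_contains_fit_center(self):
        x = np.arange(10.0)
        rng = np.random.default_rng(3)
        res = regress_density_vs_depth(
            self.records(x, 0.2 * x + rng.normal(scale=0.3, size=10)),
            "apical_oblique")
        lo, hi = res.ci95_band(np.array([4.5]))
        mid = res.intercept + res.slope * 4.5
        assert lo[0] < mid < hi[0]
        # band is symmetric about the fitted line
        assert hi[0] - mid == pytest.approx(mid - lo[0])

    def test_type_filtering_and_min_n(self):
        recs = self.records(np.arange(3.0), np.arange(3.0), dtype="trunk")
        with pytest.raises(ValueError):
            regress_density_vs_depth(recs, "apical_oblique")


class TestAnnotationsIO:
    def test_json_round_trip(self, tmp_path):
        cohort = gen_spiny_cells(n_cells=2, branchlets_per_cell=3, seed=11)
        f = tmp_path / "spines.json"
        write_annotations_json(cohort.annotations, f)
        back = read_annotations_json(f)
        assert len(back) == 2
        for a, b in zip(cohort.annotations, back):
            assert a.cell_id == b.cell_id
            for (br_a, sp_a), (br_b, sp_b) in zip(a.branchlets, b.branchlets):
                assert br_a.dendrite_type == br_b.dendrite_type
                assert np.allclose(br_a.polyline, br_b.polyline)
                assert [s.attachment_arc for s in sp_a] == [
                    s.attachment_arc for s in sp_b]
                assert [s.has_spine_apparatus for s in sp_a] == [
                    s.has_spine_apparatus for s in sp_b]
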
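import numpy as np
import pytest

from pcsm.thresholding import (ThresholdNotFoundError, adaptive_fdr_batch,
                               adaptive_fdr_select, gaussian_intersections,
                               gmm_intersection_threshold, kde_valley_threshold,
                               quartile_bootstrap_thresholds, separation_d)


# ---------------------------------------------------------------------------
# separation and intersections


@pytest.mark.parametrize("m1,s1,m2,s2,expected", [
    (0.0, 1.0, 2.0, 1.0, 2.0),
    (0.0, 1.0, 1.0, 1.0, 1.0),   # the minimum acceptable separation
    (5.0, 2.0, 5.0, 3.0, 0.0),
])
def test_separation_d_hand_values(m1, s1, m2, s2, expected):
    assert separation_d(m1, s1, m2, s2) == pytest.approx(expected)
    with pytest.raises(ValueError):
        separation_d(0, 0.0, 1, 1.0)


def test_symmetric_equal_variance_intersection_is_midpoint():
    roots = gaussian_intersections(0.5, 0.0, 1.0, 0.5, 2.0, 1.0)
    assert len(roots) == 1
    assert roots[0] == pytest.approx(1.0)


def test_unequal_variance_intersection_matches_grid_search():
    w1, m1, s1, w2, m2, s2 = 0.6, 0.0, 0.5, 0.4, 2.0, 1.2
    roots = gaussian_intersections(w1, m1, s1, w2, m2, s2)
    from scipy.stats import norm
    grid = np.linspace(m1, m2, 200001)
    diff = np.abs(w1 * norm.pdf(grid, m1, s1) - w2 * norm.pdf(grid, m2, s2))
    tau_grid = grid[np.argmin(diff)]
    between = roots[(roots > m1) & (roots < m2)]
    assert between[0] == pytest.approx(tau_grid, abs=1e-4)
    # density equality holds exactly at the root
    assert w1 * norm.pdf(between[0], m1, s1) == pytest.approx(
        w2 * norm.pdf(between[0], m2, s2), rel=1e-6)


def test_gmm_threshold_on_well_separated_mixture(rng):
    x = np.concatenate([rng.normal(0.0, 0.5, 3000), rng.normal(3.0, 0.7, 2000)])
    ts = gmm_intersection_threshold(x, seed=0, metric="demo")
    assert ts.method == "gmm_intersection"
    assert 0.5 < ts.taus["single"] < 2.5
    assert ts.separation_d > 1.0
    assert ts.extras["gates_passed"]


def test_gmm_threshold_falls_back_when_gate_fails(rng):
    """A tiny second component (< 20% weight) triggers the KDE fallback."""
    x = np.concatenate([rng.normal(0.5, 0.08, 5000), rng.normal(0.9, 0.02, 200)])
    ts = gmm_intersection_threshold(x, support=(0.0, 1.0), seed=0)
    assert ts.method == "kde_valley"
    assert ts.extras["gates_passed"] is False


# ---------------------------------------------------------------------------
# KDE valley


def test_kde_valley_matches_grid_density_minimum(rng):
    x = np.concatenate([rng.normal(0.3, 0.05, 4000), rng.normal(0.7, 0.05, 4000)])
    x = np.clip(x, 0, 1)
    ts = kde_valley_threshold(x, support=(0.0, 1.0), windows=[(0.35, 0.65)])
    # brute-force grid oracle on a fine Gaussian KDE
    from scipy.stats import gaussian_kde
    grid = np.linspace(0.35, 0.65, 2001)
    dens = gaussian_kde(x)(grid)
    assert ts.taus["single"] == pytest.approx(grid[np.argmin(dens)], abs=0.01)
    assert ts.sensitivity["max_drift"] < 0.05


def test_kde_valley_mirror_symmetry(rng):
    x = np.concatenate([rng.normal(0.25, 0.04, 3000), rng.normal(0.65, 0.06, 3000)])
    x = np.clip(x, 0, 1)
    a = kde_valley_threshold(x, support=(0.0, 1.0), n_bins=512).taus["single"]
    b = kde_valley_threshold(1.0 - x, support=(0.0, 1.0), n_bins=512).taus["single"]
    assert a == pytest.approx(1.0 - b, abs=2.0 / 512)  # bin-resolution mirror


def test_kde_valley_affine_invariance(rng):
    x = np.concatenate([rng.normal(0.3, 0.05, 3000), rng.normal(0.7, 0.05, 3000)])
    bw = 0.02
    a = kde_valley_threshold(x, support=(0.0, 1.0), bandwidth=bw).taus["single"]
    scale, shift = 4.0, -1.0
    b = kde_valley_threshold(scale * x + shift, support=(shift, scale + shift),
                             bandwidth=scale * bw).taus["single"]
    assert b == pytest.approx(scale * a + shift, abs=1e-6)


def test_kde_valley_raises_when_no_minimum(rng):
    x = rng.normal(0.5, 0.05, 2000)
    x = np.clip(x, 0, 1)
    with pytest.raises(ThresholdNotFoundError) as exc:
        kde_valley_threshold(x, support=(0.0, 1.0), windows=[(0.45, 0.55)])
    assert exc.value.density is not None


# ---------------------------------------------------------------------------
# quartile bootstrap


def test_quartile_bootstrap_recovers_normal_quartiles(rng):
    subjects = [rng.normal(size=400) for _ in range(30)]
    ts = quartile_bootstrap_thresholds(subjects, n_boot=300, seed=0)
    assert ts.taus["low"] == pytest.approx(-0.6745, abs=0.05)
    assert ts.taus["high"] == pytest.approx(0.6745, abs=0.05)
    assert ts.ci["low"][0] < ts.taus["low"] < ts.ci["low"][1]
    assert ts.extras["accepted"]


def test_quartile_bootstrap_is_deterministic_under_seed(rng):
    subjects = [rng.normal(size=100) for _ in range(12)]
    a = quartile_bootstrap_thresholds(subjects, n_boot=100, seed=7)
    b = quartile_bootstrap_thresholds(subjects, n_boot=100, seed=7)
    assert a.taus == b.taus and a.ci == b.ci
    with pytest.raises(ValueError):
        quartile_bootstrap_thresholds(subjects[:5])


# ---------------------------------------------------------------------------
# adaptive FDR


def test_adaptive_fdr_hand_example():
    """B = (0.99, 0.95, 0.90, 0.50) at alpha 0.10 keeps exactly 3 nodes."""
    sel, tau, fdr = adaptive_fdr_select(np.asarray([0.99, 0.95, 0.90, 0.50]), 0.10)
    assert sel.tolist() == [0, 1, 2]
    assert tau == pytest.approx(0.90)
    assert fdr == pytest.approx((0.01 + 0.05 + 0.10) / 3, abs=1e-12)


def test_adaptive_fdr_perfect_posteriors_keep_everything():
    sel, tau, fdr = adaptive_fdr_select(np.ones(6), 0.10)
    assert len(sel) == 6 and fdr == 0.0 and tau == 1.0


def test_adaptive_fdr_realized_error_bounded_and_monotone(rng):
    B = rng.uniform(size=(50, 30))
    for alpha in (0.1, 0.2, 0.3):
        counts, taus, fdrs = adaptive_fdr_batch(B, alpha)
        ok = counts > 0
        assert np.all(fdrs[ok] <= alpha + 1e-12)
    counts_by_alpha = [adaptive_fdr_batch(B, a)[0] for a in (0.1, 0.2, 0.3)]
    assert np.all(np.diff(np.asarray(counts_by_alpha), axis=0) >= 0)


def test_adaptive_fdr_bh_mode_agrees_on_easy_cases():
    b = np.asarray([0.999, 0.998, 0.01, 0.02])
    sel_p, _, _ = adaptive_fdr_select(b, 0.05, method="prefix")
    sel_bh, _, _ = adaptive_fdr_select(b, 0.05, method="bh")
    assert sel_p.tolist() == sel_bh.tolist() == [0, 1]
    with pytest.raises(ValueError):
        adaptive_fdr_select(b, 1.5)
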
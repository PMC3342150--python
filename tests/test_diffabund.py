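"""NB differential abundance: folds, dispersion, exact test, GLM-LRT, FDR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from circmir import diffabund, synth
from circmir.diffabund import (
    Dispersion,
    bh_fdr,
    differential_table,
    estimate_common_dispersion,
    group_log2_fold,
    nb_exact_test,
    nb_glm_lrt,
)

# ------------------------------------------------------------- log2 fold


@pytest.mark.parametrize(
    "mean_g1,mean_g2,expected",
    [(32629, 4014, 3.02), (989, 239, 2.05), (454, 89, 2.35), (384, 1235, -1.69)],
)
def test_group_log2_fold_reported_group_means(mean_g1, mean_g2, expected):
    assert round(group_log2_fold(mean_g1, mean_g2), 2) == expected


@given(st.floats(1e-6, 1e6))
def test_group_log2_fold_identity_and_antisymmetry(x):
    assert group_log2_fold(x, x) == 0.0
    assert group_log2_fold(2 * x, x) == pytest.approx(-group_log2_fold(x, 2 * x))


def test_group_log2_fold_degenerate_flags():
    assert group_log2_fold(3.0, 0.0) == np.inf
    assert group_log2_fold(0.0, 3.0) == -np.inf
    assert np.isnan(group_log2_fold(0.0, 0.0))
    with pytest.raises(ValueError):
        group_log2_fold(-1.0, 1.0)


# ------------------------------------------------------------ dispersion


def _sim_matrix(rng, n_genes, n_samples, phi, mean=200):
    mu = rng.lognormal(np.log(mean), 1.0, size=n_genes)
    if phi == 0:
        vals = rng.poisson(mu[:, None], size=(n_genes, n_samples))
    else:
        lam = rng.gamma(1 / phi, mu[:, None] * phi, size=(n_genes, n_samples))
        vals = rng.poisson(lam)
    return pd.DataFrame(vals, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)])


def test_dispersion_poisson_counts_near_zero(rng):
    m = _sim_matrix(rng, 200, 20, phi=0)
    d = estimate_common_dispersion(m, ["a"] * 10 + ["b"] * 10)
    assert d.phi <= 0.05


def test_dispersion_recovers_known_phi(rng):
    m = _sim_matrix(rng, 200, 20, phi=0.3)
    d = estimate_common_dispersion(m, ["a"] * 10 + ["b"] * 10)
    assert 0.2 <= d.phi <= 0.45


def test_dispersion_identical_samples_at_lower_clamp():
    col = [10, 50, 3, 200, 7]
    m = pd.DataFrame({"s1": col, "s2": col})
    d = estimate_common_dispersion(m, ["a", "a"])
    assert d.phi <= 2 * diffabund.PHI_MIN


def test_dispersion_all_zero_matrix_errors():
    m = pd.DataFrame(np.zeros((3, 4), dtype=int))
    with pytest.raises(ValueError):
        estimate_common_dispersion(m, ["a", "a", "b", "b"])


# ------------------------------------------------------------ exact test


def _oracle_exact_p(y1, y2, phi):
    """Brute-force convolution oracle for the conditional NB test."""
    y1, y2 = np.asarray(y1), np.asarray(y2)
    n1, n2 = y1.size, y2.size
    s = int(y1.sum() + y2.sum())
    mu = s / (n1 + n2)
    r = 1.0 / phi
    p_nb = r / (r + mu)
    single = stats.nbinom.pmf(np.arange(s + 1), r, p_nb)

    def group_pmf(n):
        pmf = np.zeros(s + 1)
        pmf[0] = 1.0
        for _ in range(n):
            pmf = np.convolve(pmf, single)[: s + 1]
        return pmf

    f1, f2 = group_pmf(n1), group_pmf(n2)
    cond = f1 * f2[::-1]
    cond = cond / cond.sum()
    obs = int(y1.sum())
    left = cond[: obs + 1].sum()
    right = cond[obs:].sum()
    return min(1.0, 2.0 * min(left, right))


def test_exact_test_balanced_split_is_one():
    assert nb_exact_test([5, 5], [5, 5], 0.1) == pytest.approx(1.0)


def test_exact_test_symmetric_under_label_swap(rng):
    for _ in range(10):
        y1 = rng.integers(0, 50, size=4)
        y2 = rng.integers(0, 50, size=6)
        assert nb_exact_test(y1, y2, 0.2) == pytest.approx(
            nb_exact_test(y2, y1, 0.2), rel=1e-10)


@pytest.mark.parametrize("phi", [0.05, 0.1, 0.5])
def test_exact_test_matches_convolution_oracle(phi, rng):
    for _ in range(15):
        n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 5))
        while True:
            y1 = rng.integers(0, 8, size=n1)
            y2 = rng.integers(0, 8, size=n2)
            if 0 < y1.sum() + y2.sum() <= 30:
                break
        assert nb_exact_test(y1, y2, phi) == pytest.approx(
            _oracle_exact_p(y1, y2, phi), abs=1e-9)


def test_exact_test_tiny_phi_reduces_to_conditional_binomial(rng):
    for _ in range(10):
        y1 = rng.integers(0, 6, size=3)
        y2 = rng.integers(0, 6, size=5)
        s, o = int(y1.sum() + y2.sum()), int(y1.sum())
        if s == 0 or s > 20:
            continue
        w = 3 / 8
        left = stats.binom.cdf(o, s, w)
        right = stats.binom.sf(o - 1, s, w)
        expected = min(1.0, 2 * min(left, right))
        assert nb_exact_test(y1, y2, 1e-8) == pytest.approx(expected, abs=1e-6)


def test_exact_test_rejects_negative_counts():
    with pytest.raises(ValueError):
        nb_exact_test([-1, 2], [3, 4], 0.1)


def test_exact_test_large_totals_windowing_consistent():
    """The windowed large-total path agrees with full enumeration."""
    y1 = np.array([900, 1100, 950])
    y2 = np.array([700, 650, 800])
    p_impl = nb_exact_test(y1, y2, 0.15)
    p_oracle = _oracle_exact_p(y1, y2, 0.15)
    assert p_impl == pytest.approx(p_oracle, rel=1e-6)


# --------------------------------------------------------------- GLM LRT


def test_glm_lrt_null_type_one_error(rng):
    n = 24
    regimen = np.array(["A", "B", "C"] * (n // 3))
    group = np.array(["g1", "g2"] * (n // 2))
    design = pd.get_dummies(pd.Series(regimen), drop_first=True).to_numpy(float)
    phi = 0.15
    rejections = 0
    n_genes = 1000
    for _ in range(n_genes):
        mu = 150.0
        lam = rng.gamma(1 / phi, mu * phi, size=n)
        y = rng.poisson(lam)
        p = nb_glm_lrt(y, group, phi, adjust=design)
        rejections += (p < 0.05)
    assert 0.03 * n_genes <= rejections <= 0.08 * n_genes


def test_glm_lrt_poisson_limit_matches_statsmodels(rng):
    y = np.array([12, 15, 9, 22, 30, 41, 35, 28, 17, 25])
    group = np.array(["g1"] * 5 + ["g2"] * 5)
    offset = np.log(rng.uniform(0.8, 1.2, size=10))
    p_ours = nb_glm_lrt(y, group, 1e-9, offsets=offset)

    X_null = np.ones((10, 1))
    X_full = np.hstack([X_null, (group == "g1").astype(float)[:, None]])
    ll = {}
    for name, X in [("null", X_null), ("full", X_full)]:
        fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        ll[name] = fit.llf
    p_sm = stats.chi2.sf(2 * (ll["full"] - ll["null"]), df=1)
    assert p_ours == pytest.approx(p_sm, abs=1e-6)


def test_glm_lrt_matches_statsmodels_negative_binomial(rng):
    phi = 0.4
    y = np.array([5, 40, 12, 30, 7, 80, 60, 25, 90, 14])
    group = np.array(["g1"] * 5 + ["g2"] * 5)
    p_ours = nb_glm_lrt(y, group, phi)
    X_null = np.ones((10, 1))
    X_full = np.hstack([X_null, (group == "g1").astype(float)[:, None]])
    ll = {}
    for name, X in [("null", X_null), ("full", X_full)]:
        fit = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=phi)).fit()
        ll[name] = fit.llf
    p_sm = stats.chi2.sf(max(0.0, 2 * (ll["full"] - ll["null"])), df=1)
    assert p_ours == pytest.approx(p_sm, abs=1e-5)


def test_glm_lrt_aliased_design_flagged():
    y = np.array([10, 12, 30, 33, 40, 41])
    group = np.array(["g1", "g1", "g2", "g2", "g2", "g2"])
    aliased = (group == "g1").astype(float)[:, None]  # regimen == group
    assert np.isnan(nb_glm_lrt(y, group, 0.1, adjust=aliased))


# ------------------------------------------------------------------- FDR


def test_bh_fdr_hand_examples():
    np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert bh_fdr([0.2]) == pytest.approx([0.2])
    np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0] * 3)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
def test_bh_fdr_matches_definitional_step_up(ps):
    q = bh_fdr(ps)
    m = len(ps)
    order = np.argsort(ps, kind="stable")
    expected = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [m * ps[order[j]] / (j + 1) for j in range(rank_pos, m)]
        expected[idx] = min(1.0, min(candidates))
    np.testing.assert_allclose(q, expected, atol=1e-12)


@given(st.lists(st.floats(0, 1), min_size=2, max_size=40), st.randoms())
def test_bh_fdr_order_invariant_and_monotone(ps, rnd):
    q = bh_fdr(ps)
    shuffled = list(enumerate(ps))
    rnd.shuffle(shuffled)
    idx, vals = zip(*shuffled)
    q_shuffled = bh_fdr(list(vals))
    np.testing.assert_allclose([q[i] for i in idx], q_shuffled, atol=1e-12)
    order = np.argsort(ps, kind="stable")
    assert (np.diff(q[order]) >= -1e-12).all()


def test_bh_fdr_matches_statsmodels():
    rng = np.random.default_rng(0)
    ps = rng.uniform(size=100)
    from statsmodels.stats.multitest import multipletests

    _, q_sm, *_ = multipletests(ps, method="fdr_bh")
    np.testing.assert_allclose(bh_fdr(ps), q_sm, atol=1e-12)


def test_bh_fdr_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_fdr([0.5, 1.5])


# ---------------------------------------------------------------- tables


def test_differential_table_swapped_contrast_negates_folds(cohort):
    counts, meta = cohort
    sub = counts.iloc[:15]
    t12 = differential_table(sub, meta, "relapse", levels=(True, False), phi=0.2)
    t21 = differential_table(sub, meta, "relapse", levels=(False, True), phi=0.2)
    merged = t12.set_index("gene").join(t21.set_index("gene"), rsuffix="_swap")
    np.testing.assert_allclose(merged["log2_fold"], -merged["log2_fold_swap"])
    np.testing.assert_allclose(merged["p_value"], merged["p_value_swap"], rtol=1e-9)


def test_differential_table_sample_order_invariant(cohort):
    counts, meta = cohort
    sub = counts.iloc[:10]
    t1 = differential_table(sub, meta, "relapse", phi=0.2)
    perm = np.random.default_rng(0).permutation(sub.columns)
    t2 = differential_table(sub[perm], meta, "relapse", phi=0.2)
    pd.testing.assert_frame_equal(t1, t2)


def test_differential_table_null_contrast_calibrated(reference):
    cfg = synth.SimulationConfig(
        n_samples=42, planted_effects={}, seed=17, mean_library_size=100_000,
    )
    big_ref = synth.make_reference(
        n_per_class={"miRNA": 500, "tRNA": 0, "rRNA": 0, "scRNA": 0,
                     "snRNA": 0, "snoRNA": 0, "other": 0}, seed=23)
    counts, meta = synth.simulate_cohort(cfg, big_ref)
    table = differential_table(counts, meta, "relapse")
    frac = (table["p_value"] < 0.05).mean()
    assert 0.02 <= frac <= 0.09


def test_differential_table_requires_two_per_level(cohort):
    counts, meta = cohort
    meta2 = meta.copy()
    meta2["relapse"] = [True] + [False] * (len(meta2) - 1)
    with pytest.raises(ValueError, match="at least 2"):
        differential_table(counts.iloc[:5], meta2, "relapse")


def test_differential_table_fdr_consistent_with_bh(cohort):
    counts, meta = cohort
    table = differential_table(counts.iloc[:20], meta, "relapse", phi=0.2)
    np.testing.assert_allclose(
        table["fdr"], bh_fdr(table["p_value"].to_numpy()), atol=1e-12)
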
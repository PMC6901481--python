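import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, special, stats

from pahomics import diffexpr as de
from pahomics.omics_io import IntensityMatrix
from pahomics.synthio import SimConfig, generate_intensity_matrix


def _matrix(values, n_case, n_control, transformed=False, prefix="F"):
    n_case_cols = [f"c{i}" for i in range(n_case)]
    n_ctrl_cols = [f"k{i}" for i in range(n_control)]
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=[f"{prefix}{i}" for i in range(len(values))],
                      columns=n_case_cols + n_ctrl_cols)
    groups = {**{s: "case" for s in n_case_cols},
              **{s: "control" for s in n_ctrl_cols}}
    return IntensityMatrix(values=df, groups=groups, transformed=transformed)


# --------------------------------------------------------------------------
# normalization

def test_glog_reduces_to_log2_at_zero_lambda():
    assert de.glog2(4.0, 0.0) == pytest.approx(2.0)
    x = np.array([0.5, 1.0, 8.0])
    np.testing.assert_allclose(de.glog2(x, 0.0), np.log2(x))


def test_constant_matrix_normalizes_to_constant():
    m = _matrix(np.full((4, 4), 7.0), 2, 2)
    out = de.vsn_normalize(m)
    assert out.transformed
    vals = out.values.to_numpy()
    assert np.allclose(vals, vals[0, 0])


def test_vsn_requires_three_observations_per_sample():
    values = np.full((2, 4), 5.0)
    m = _matrix(values, 2, 2)
    with pytest.raises(de.DiffExprError, match="<3 observed"):
        de.vsn_normalize(m)


def test_glog_stabilizes_low_intensity_variance_vs_log2():
    """With additive background noise, row-SD spread across intensity
    deciles is smaller after glog than after plain log2."""
    cfg = SimConfig(seed=11, n_features=2000, mnar_midpoint=-np.inf,
                    mcar_rate=0.0, mnar_steepness=0.0, frac_de=0.0)
    sim = generate_intensity_matrix(cfg)
    raw = sim.matrix.values.to_numpy()
    raw_pos = np.maximum(raw, 1.0)
    glog = de.vsn_normalize(sim.matrix).values.to_numpy()
    log2 = np.log2(raw_pos)

    def decile_sd_spread(x):
        order = np.argsort(np.nanmean(x, axis=1))
        sds = np.nanstd(x, axis=1, ddof=1)[order]
        deciles = np.array_split(sds, 10)
        return np.var([d.mean() for d in deciles])

    assert decile_sd_spread(glog) < decile_sd_spread(log2)


@given(st.floats(min_value=0.01, max_value=1e6),
       st.floats(min_value=0.01, max_value=1e6))
def test_glog_is_monotone(a, b):
    lo, hi = sorted((a, b))
    assert de.glog2(lo, 100.0) <= de.glog2(hi, 100.0)


# --------------------------------------------------------------------------
# imputation

def test_impute_complete_matrix_unchanged():
    m = _matrix(np.arange(16.0).reshape(4, 4), 2, 2, transformed=True)
    out = de.knn_impute(m, k=2)
    pd.testing.assert_frame_equal(out.values, m.values)


def test_impute_duplicate_row_copies_twin():
    values = np.array([[1.0, 2.0, 3.0, 4.0],
                       [1.0, 2.0, np.nan, 4.0],
                       [10.0, 20.0, 30.0, 40.0]])
    m = _matrix(values, 2, 2, transformed=True)
    out = de.knn_impute(m, k=1)
    assert out.values.iloc[1, 2] == pytest.approx(3.0)


def test_impute_falls_back_to_row_mean():
    # the only potential neighbor shares just one observed sample
    values = np.array([[1.0, np.nan, np.nan, 2.0],
                       [np.nan, 5.0, 6.0, np.nan]])
    m = _matrix(values, 2, 2, transformed=True)
    out = de.knn_impute(m, k=1)
    assert out.values.iloc[0, 1] == pytest.approx(1.5)
    assert out.values.iloc[1, 0] == pytest.approx(5.5)


def test_knn_beats_global_mean_on_mnar_simulation():
    cfg = SimConfig(seed=21, n_features=800)
    sim = generate_intensity_matrix(cfg)
    norm = de.vsn_normalize(sim.matrix)
    missing = sim.matrix.values.isna().to_numpy()
    assert missing.any()
    # reference: the same transform applied to the complete data
    complete_norm = de.vsn_normalize(
        sim.matrix.copy_with(sim.complete)).values.to_numpy()
    imputed = de.knn_impute(norm, k=10).values.to_numpy()
    observed = norm.values.to_numpy()
    global_mean = np.nanmean(observed)
    rmse_knn = np.sqrt(np.mean(
        (imputed[missing] - complete_norm[missing]) ** 2))
    rmse_global = np.sqrt(np.mean(
        (global_mean - complete_norm[missing]) ** 2))
    assert rmse_knn < rmse_global


# --------------------------------------------------------------------------
# moderation

def test_identical_variances_give_infinite_prior():
    values = np.array([[1.0, 2.0, 4.0, 5.0],
                       [11.0, 12.0, 14.0, 15.0],
                       [21.0, 22.0, 24.0, 25.0]])
    m = _matrix(values, 2, 2, transformed=True)
    params = de.fit_moderation(m)
    assert np.isinf(params.d0)
    assert params.s0_sq == pytest.approx(0.5)  # each group's variance


def test_fit_f_dist_two_unequal_variances_brute_force():
    s2 = np.array([1.0, 2.0])
    d0, s0 = de.fit_f_dist(s2, df=np.inf)
    assert 0 < d0 < np.inf
    # independent solution of the moment equations
    z = np.log(s2)
    evar = z.var(ddof=1)
    d0_oracle = 2 * optimize.brentq(
        lambda y: special.polygamma(1, y) - evar, 1e-3, 1e3)
    assert d0 == pytest.approx(d0_oracle, rel=1e-6)
    s0_oracle = np.exp(z.mean() + special.digamma(d0_oracle / 2)
                       - np.log(d0_oracle / 2))
    assert s0 == pytest.approx(s0_oracle, rel=1e-6)


def test_prior_parameter_recovery():
    """Variances drawn from s0^2 * d0 / chi2_d0 recover (d0, s0^2)."""
    rng = np.random.default_rng(31)
    d0_true, s0_true = 4.0, 1.0
    s2 = s0_true * d0_true / rng.chisquare(d0_true, size=20_000)
    d0, s0 = de.fit_f_dist(s2, df=np.inf)
    assert 3.5 <= d0 <= 4.5
    assert 0.9 <= s0 <= 1.1


def test_fit_moderation_needs_three_features():
    m = _matrix(np.ones((2, 4)), 2, 2, transformed=True)
    with pytest.raises(de.DiffExprError, match=">=3 features"):
        de.fit_moderation(m)


# --------------------------------------------------------------------------
# moderated t

def test_identical_group_means_give_null_result():
    values = np.array([[1.0, 2.0, 1.0, 2.0],
                       [5.0, 6.0, 5.0, 6.0],
                       [3.0, 4.0, 3.0, 4.0]])
    m = _matrix(values, 2, 2, transformed=True)
    params = de.ModerationParams(d0=0.0, s0_sq=1.0, residual_df=2)
    res = de.moderated_t_test(m, params)
    np.testing.assert_allclose(res["t_mod"], 0.0)
    np.testing.assert_allclose(res["p"], 1.0)


def test_zero_prior_reproduces_pooled_t_closed_form():
    m = _matrix([[4.0, 5.0, 6.0, 1.0, 2.0, 3.0]] * 3, 3, 3, transformed=True)
    params = de.ModerationParams(d0=0.0, s0_sq=1.0, residual_df=4)
    res = de.moderated_t_test(m, params)
    assert res["t_mod"].iloc[0] == pytest.approx(3.0 / np.sqrt(2.0 / 3.0))
    assert res["p"].iloc[0] == pytest.approx(
        2 * stats.t.sf(3.0 / np.sqrt(2.0 / 3.0), 4))
    assert res["p"].iloc[0] == pytest.approx(0.0213, abs=2e-4)


def test_zero_prior_equals_pooled_t_oracle():
    """d0 = 0 reduces the moderated t to scipy's pooled two-sample t on
    random small matrices."""
    rng = np.random.default_rng(41)
    for _ in range(100):
        n1, n2 = rng.integers(2, 6, size=2)
        nf = rng.integers(1, 8)
        values = rng.normal(size=(nf, n1 + n2))
        m = _matrix(values, n1, n2, transformed=True)
        params = de.ModerationParams(d0=0.0, s0_sq=1.0,
                                     residual_df=n1 + n2 - 2)
        res = de.moderated_t_test(m, params)
        t_ref, p_ref = stats.ttest_ind(values[:, :n1], values[:, n1:],
                                       axis=1, equal_var=True)
        np.testing.assert_allclose(res["t_mod"], t_ref, atol=1e-10)
        np.testing.assert_allclose(res["p"], p_ref, atol=1e-10)


def test_infinite_prior_t_has_unit_null_variance():
    rng = np.random.default_rng(51)
    values = rng.normal(size=(10_000, 9))
    m = _matrix(values, 4, 5, transformed=True)
    params = de.ModerationParams(d0=np.inf, s0_sq=1.0, residual_df=7)
    res = de.moderated_t_test(m, params)
    assert 0.97 <= res["t_mod"].std(ddof=1) <= 1.03


def test_zero_variance_zero_prior_guard():
    values = np.array([[1.0, 1.0, 1.0, 1.0],
                       [2.0, 2.0, 2.0, 2.0],
                       [0.0, 0.0, 5.0, 5.0]])
    m = _matrix(values, 2, 2, transformed=True)
    params = de.ModerationParams(d0=0.0, s0_sq=1.0, residual_df=2)
    with pytest.raises(de.DiffExprError, match="zero variance"):
        de.moderated_t_test(m, params)
    ok = _matrix(values[:2], 2, 2, transformed=True)
    res = de.moderated_t_test(ok, params)
    np.testing.assert_allclose(res["p"], 1.0)


# --------------------------------------------------------------------------
# FDR and classification

def test_bh_single_and_worked_example():
    assert de.bh_fdr([0.05]) == pytest.approx([0.05])
    np.testing.assert_allclose(de.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                               [0.04, 0.04, 0.04, 0.04])


def test_bh_rejects_invalid_p():
    with pytest.raises(de.DiffExprError):
        de.bh_fdr([0.5, 1.2])
    with pytest.raises(de.DiffExprError):
        de.bh_fdr([-0.1])


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                max_size=30))
def test_bh_permutation_invariance_and_dominance(p):
    p = np.asarray(p)
    q = de.bh_fdr(p)
    assert np.all(q >= p - 1e-12)
    assert np.all(q <= 1.0)
    perm = np.random.default_rng(0).permutation(len(p))
    np.testing.assert_allclose(de.bh_fdr(p[perm]), q[perm])


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(61)
    p = rng.random(200)
    _, q_ref, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(de.bh_fdr(p), q_ref)


def test_classify_de_empty_and_all_null():
    counts, _ = de.classify_de(pd.DataFrame(columns=["feature_id", "log2fc",
                                                     "p"]))
    assert (counts.n_sig, counts.n_up, counts.n_down) == (0, 0, 0)
    res = pd.DataFrame({"feature_id": ["a", "b"], "log2fc": [1.0, -1.0],
                        "p": [1.0, 1.0]})
    counts, labeled = de.classify_de(res)
    assert counts.n_sig == 0
    assert (labeled["direction"] == "ns").all()


def test_classify_de_sensitivity_and_fdr_control():
    cfg = SimConfig(seed=71, n_features=1000, frac_de=0.1,
                    effect_log2fc=1.0, n_samples_per_group=(5, 4))
    sim = generate_intensity_matrix(cfg)
    counts, labeled = de.run_de_pipeline(sim.matrix, rule="fdr", alpha=0.05)
    truth = sim.truth.set_index("feature_id")["is_de"]
    called = labeled.loc[labeled["direction"] != "ns", "feature_id"]
    true_de = truth[truth].index
    sens = len(set(called) & set(true_de)) / len(true_de)
    fdr = (len(set(called) - set(true_de)) / max(1, len(called)))
    assert sens > 0.5
    assert fdr <= 0.10  # 2x the nominal 0.05


# --------------------------------------------------------------------------
# phosphosites

def _sites(probs, residues=None):
    residues = residues or ["S"] * len(probs)
    return pd.DataFrame({"peptide_id": [f"pp{i}" for i in range(len(probs))],
                         "residue": residues,
                         "localization_prob": probs,
                         "n_sites_on_peptide": 1})


def test_localization_filter_is_strict():
    kept = de.filter_localized(_sites([0.4, 0.6, 0.51]))
    assert len(kept) == 2
    assert len(de.filter_localized(_sites([0.5]))) == 0  # boundary excluded
    empty = de.filter_localized(_sites([]))
    assert len(empty) == 0


def test_residue_tally_study_counts():
    sites = _sites([1.0] * (6113 + 1065 + 74),
                   ["S"] * 6113 + ["T"] * 1065 + ["Y"] * 74)
    tally = de.tally_residues(sites).set_index("residue")
    assert tally.loc["S", "percent"] == 84.3
    assert tally.loc["T", "percent"] == 14.7
    assert tally.loc["Y", "percent"] == 1.0
    assert tally["count"].sum() == 7252


def test_residue_tally_degenerate():
    tally = de.tally_residues(_sites([0.9], ["S"])).set_index("residue")
    assert tally.loc["S", "percent"] == 100.0
    assert tally.loc["T", "percent"] == 0.0


@given(st.tuples(st.integers(0, 5000), st.integers(0, 5000),
                 st.integers(0, 5000)).filter(lambda t: sum(t) > 0))
def test_residue_percentages_sum_to_100(counts):
    s, t, y = counts
    sites = _sites([1.0] * (s + t + y), ["S"] * s + ["T"] * t + ["Y"] * y)
    tally = de.tally_residues(sites)
    assert tally["percent"].sum() == pytest.approx(100.0, abs=0.15)
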
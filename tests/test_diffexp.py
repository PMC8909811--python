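import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import gammaln

from heterosim import SimulationConfig, simulate_counts
from heterosim.diffexp import ThresholdPolicy, call_de, mpv_test, nb_test
from heterosim.quantify import normalized_counts

from conftest import small_count_matrix


def _nb_world(rng, n_feat, mu, fold, phi, nrep=3):
    r = 1 / phi
    a = rng.negative_binomial(r, r / (r + mu[:, None]), (n_feat, nrep))
    b = rng.negative_binomial(r, r / (r + (mu * fold)[:, None]), (n_feat, nrep))
    return small_count_matrix(np.hstack([a, b]), ["NL"] * nrep + ["AR"] * nrep)


def test_policy_validation():
    with pytest.raises(ValueError):
        ThresholdPolicy(gene_p=1.5)
    with pytest.raises(ValueError):
        ThresholdPolicy(gene_fc=0.5)


def test_swap_groups_negates_log2fc_keeps_p(default_world):
    _, genes, _, _ = default_world
    sub = genes  # full matrix, vectorised anyway
    ab = nb_test(sub, "NL", "AR")
    ba = nb_test(sub, "AR", "NL")
    np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"], atol=1e-12)
    np.testing.assert_allclose(ab["p_value"], ba["p_value"], atol=1e-12)


def test_identical_groups_mean_injection_nothing_significant(injection_world):
    """Under exactly equal group means no feature may be called."""
    _, genes, _, truth = injection_world
    conserved = truth.genes["label"] == "conserved"
    res = call_de(nb_test(genes, "NL", "AR"), ThresholdPolicy(), "gene")
    assert not res.loc[conserved.values, "significant"].any()


def test_all_zero_feature_is_null_call():
    arr = np.array([[0, 0, 0, 0, 0, 0], [5, 6, 7, 5, 6, 7]])
    cm = small_count_matrix(arr, ["NL"] * 3 + ["AR"] * 3)
    res = nb_test(cm, "NL", "AR")
    assert res.iloc[0]["p_value"] == 1.0
    assert res.iloc[0]["log2fc"] == 0.0


def test_missing_group_raises():
    cm = small_count_matrix([[1, 2, 3, 4]], ["NL", "NL", "AR", "AR"])
    with pytest.raises(ValueError, match="absent"):
        nb_test(cm, "NL", "HY")


@pytest.mark.parametrize(
    "feature_type,p,log2fc,expect_sig,expect_dir",
    [
        ("gene", 0.005, np.log2(1.5), False, "ns"),   # FC gate fails
        ("gene", 0.005, np.log2(3.0), True, "up"),    # both thresholds pass
        ("gene", 0.02, np.log2(3.0), False, "ns"),    # p gate fails
        ("gene", 0.005, np.log2(0.4), True, "down"),  # fold < 0.5 counts
        ("mirna", 0.04, np.log2(1.1), True, "up"),    # DEM: p-only threshold
        ("mirna", 0.06, np.log2(5.0), False, "ns"),
    ],
)
def test_threshold_policy_calls(feature_type, p, log2fc, expect_sig, expect_dir):
    """DEG thresholds: p<0.01 plus fold >2 or <0.5; DEM: p<0.05 only."""
    res = pd.DataFrame({"contrast": "HY_vs_NL", "log2fc": [log2fc],
                        "p_value": [p], "adj_p": [p]},
                       index=pd.Index(["f0"], name="feature_id"))
    out = call_de(res, ThresholdPolicy(), feature_type)
    assert bool(out["significant"].iloc[0]) is expect_sig
    assert out["direction"].iloc[0] == expect_dir


def test_wald_matches_likelihood_ratio_oracle():
    """Wald p agrees with an NB likelihood-ratio test sharing the same
    dispersion: within 10% in the body, same order in the far tail, and
    identical significance calls."""
    rng = np.random.default_rng(42)
    n_feat = 50
    mu = rng.uniform(200, 1000, n_feat)
    fold = rng.uniform(1.0, 1.8, n_feat)
    cm = _nb_world(rng, n_feat, mu, fold, phi=0.05)
    res = nb_test(cm, "NL", "AR")

    x = normalized_counts(cm).to_numpy()
    A, B = x[:, :3], x[:, 3:]
    s2 = (A.var(1, ddof=1) * 2 + B.var(1, ddof=1) * 2) / 4
    mub = x.mean(1)
    phi_raw = np.maximum(0, (s2 - mub) / mub ** 2)
    w = 3 / 7
    phis = w * phi_raw + (1 - w) * np.median(phi_raw)

    def nb_ll(y, m, phi_i):
        ri = 1 / phi_i
        return np.sum(gammaln(y + ri) - gammaln(ri) - gammaln(y + 1)
                      + ri * np.log(ri / (ri + m)) + y * np.log(m / (ri + m)))

    p_lrt = np.empty(n_feat)
    for i in range(n_feat):
        ma, mb, m0 = A[i].mean() + 0.5, B[i].mean() + 0.5, x[i].mean() + 0.5
        dev = 2 * (nb_ll(A[i], ma, phis[i]) + nb_ll(B[i], mb, phis[i])
                   - nb_ll(x[i], m0, phis[i]))
        p_lrt[i] = stats.chi2.sf(max(dev, 0.0), 1)

    pw = res["p_value"].to_numpy()
    body = p_lrt >= 1e-3
    assert np.all(np.abs(pw[body] - p_lrt[body]) <= 0.10 * p_lrt[body])
    tail = ~body
    assert np.all((pw[tail] < 2 * p_lrt[tail] + 1e-12) & (pw[tail] > p_lrt[tail] / 2))
    assert np.array_equal(pw < 0.01, p_lrt < 0.01)


def test_power_monotone_in_true_fold():
    """Average detection power never decreases with the true fold change.

    Changed features sit in a 4x larger null backbone so that the
    median-of-ratios normalization keeps its majority-unchanged anchor.
    """
    rng = np.random.default_rng(7)
    n_de, n_null = 800, 3200
    mu = np.full(n_de + n_null, 400.0)
    policy = ThresholdPolicy()
    powers = []
    for fold in (1.0, 1.5, 2.5, 4.0):
        folds = np.concatenate([np.full(n_de, fold), np.ones(n_null)])
        cm = _nb_world(rng, len(mu), mu, folds, phi=0.05)
        called = call_de(nb_test(cm, "NL", "AR"), policy, "gene")
        powers.append(called["significant"].to_numpy()[:n_de].mean())
    assert all(b >= a - 0.01 for a, b in zip(powers, powers[1:]))
    assert powers[-1] > 0.9


def test_mpv_additive_not_flagged_elod_flagged(injection_world):
    """Exact mid-parent hybrids are additive; 4x-beyond-parents hybrids are not."""
    _, genes, _, truth = injection_world
    res = call_de(mpv_test(genes), ThresholdPolicy(), "gene")
    additive = truth.genes["true_group"] == "additive"
    elod_up = truth.genes["true_group"] == "ELOD_up"
    assert not res.loc[additive.values, "significant"].any()
    assert res.loc[elod_up.values, "significant"].all()
    assert (res.loc[elod_up.values, "direction"] == "up").all()


def test_mpv_false_positive_rate_bounded():
    """Noisy but truly additive genes are rarely called non-additive.

    The three-replicate Wald test is mildly anticonservative at the 0.05
    level (realised rate ~2x nominal), so the bound allows 2.5x.
    """
    cfg = SimulationConfig(n_genes=10000, n_mirnas=2, dispersion=0.05, seed=8)
    genes, _, truth = simulate_counts(cfg)
    res = call_de(mpv_test(genes), ThresholdPolicy(), "gene")
    additive = (truth.genes["true_group"] == "additive").to_numpy()
    rate = res.loc[additive, "significant"].mean()
    assert ThresholdPolicy().mpv_p / 2 <= rate <= 2.5 * ThresholdPolicy().mpv_p


def test_mpv_unequal_parent_replicates_warns():
    arr = np.random.default_rng(2).integers(50, 150, size=(30, 8))
    cm = small_count_matrix(arr, ["NL"] * 3 + ["AR"] * 2 + ["HY"] * 3)
    with pytest.warns(UserWarning, match="unequal"):
        mpv_test(cm)


def test_bh_adjustment_monotone(default_gene_calls):
    res = default_gene_calls["NL_vs_AR"]
    order = res["p_value"].sort_values().index
    assert (res.loc[order, "adj_p"].diff().dropna() >= -1e-12).all()
    assert (res["adj_p"] >= res["p_value"] - 1e-12).all()
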
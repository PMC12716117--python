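"""Median polish, moderated t, BH, presence test, and regional trends."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from proformquant.core import SampleDesign
from proformquant.regions import RegionMap
from proformquant.stats import (EBParams, bh_adjust, fit_variance_prior,
                                median_polish, moderated_t, paired_log2fc,
                                presence_test, regional_trend,
                                trigamma_inverse, volcano_classify)


def _design(n=6):
    rows = [{"sample_id": f"D{d}_{c}", "donor_id": f"D{d}", "condition": c}
            for d in range(1, n + 1) for c in ("control", "treated")]
    return SampleDesign(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Median polish


def test_median_polish_exact_additive_matrix():
    m = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]])
    res = median_polish(m)
    assert res.overall == pytest.approx(2.5)
    assert list(res.row_effects) == pytest.approx([-1.0, 1.0])
    assert list(res.col_effects) == pytest.approx([-0.5, 0.5])
    assert np.allclose(res.residuals, 0.0)
    assert np.allclose(res.normalized, m.sub(res.col_effects, axis=1))


def test_median_polish_fixed_point():
    # already median-centered in rows and columns: nothing to remove
    m = pd.DataFrame([[-1.0, 0.0, 1.0], [0.0, 0.0, 0.0], [1.0, 0.0, -1.0]])
    res = median_polish(m)
    assert res.overall == pytest.approx(0.0)
    assert np.allclose(res.row_effects, 0.0)
    assert np.allclose(res.col_effects, 0.0)
    assert np.allclose(res.residuals, m)


def test_median_polish_reconstruction_identity():
    rng = np.random.default_rng(2)
    m = pd.DataFrame(rng.normal(20, 2, (10, 6)))
    res = median_polish(m)
    recon = (res.overall
             + np.add.outer(res.row_effects.to_numpy(),
                            res.col_effects.to_numpy())
             + res.residuals.to_numpy())
    assert np.allclose(recon, m.to_numpy(), atol=1e-9)
    assert np.all(np.abs(np.median(res.residuals, axis=1)) < 1e-6)
    assert np.all(np.abs(np.median(res.residuals, axis=0)) < 1e-6)


def test_median_polish_skips_missing_and_drops_empty():
    m = pd.DataFrame(np.random.default_rng(3).normal(0, 1, (5, 4)))
    m.iloc[0, 0] = np.nan
    m.iloc[2, :] = np.nan  # all-missing row dropped
    res = median_polish(m)
    assert res.residuals.shape == (4, 4)


# ---------------------------------------------------------------------------
# Paired differences


def test_paired_log2fc_difference_and_exclusion():
    design = _design(3)
    m = pd.DataFrame(np.nan, index=["a", "b"], columns=design.sample_ids)
    m.loc["a"] = [10, 12, 11, 13, 9, 12]  # 3 complete pairs
    m.loc["b", "D1_control"] = 10.0
    m.loc["b", "D1_treated"] = 12.0       # one pair only -> excluded
    diffs, n_excluded = paired_log2fc(m, design, min_pairs=2)
    assert list(diffs.index) == ["a"]
    assert list(diffs.loc["a"]) == pytest.approx([2.0, 2.0, 3.0])
    assert n_excluded == 1


def test_paired_log2fc_recovers_injected_effect():
    rng = np.random.default_rng(4)
    design = _design(6)
    true_lfc = 1.5
    rows = {}
    for p in range(50):
        base = rng.normal(20, 2)
        donor = rng.normal(0, 1, 6)
        control = base + donor + rng.normal(0, 0.3, 6)
        treated = base + donor + true_lfc + rng.normal(0, 0.3, 6)
        rows[f"p{p}"] = np.ravel(np.c_[control, treated])
    m = pd.DataFrame.from_dict(rows, orient="index",
                               columns=_design(6).sample_ids)
    diffs, _ = paired_log2fc(m, design)
    assert diffs.mean(axis=1).mean() == pytest.approx(true_lfc, abs=0.4)


# ---------------------------------------------------------------------------
# Moderated t


def test_unmoderated_t_matches_hand_computation():
    diffs = pd.DataFrame([[1.0, 1.2, 0.8, 1.0]], index=["p"])
    _, res = moderated_t(diffs, d0=0.0)
    assert res.loc["p", "t"] == pytest.approx(12.25, abs=0.005)
    assert res.loc["p", "s_sq"] == pytest.approx(0.02667, abs=1e-4)


def test_unmoderated_t_equals_classical_t():
    rng = np.random.default_rng(6)
    x = rng.normal(0.2, 1.0, (1000, 6))
    diffs = pd.DataFrame(x)
    _, res = moderated_t(diffs, d0=0.0)
    t_ref, p_ref = sps.ttest_1samp(x, 0.0, axis=1)
    assert np.allclose(res["t"], t_ref, atol=1e-10)
    assert np.allclose(res["p"], p_ref, atol=1e-12)


def test_infinite_prior_shrinks_to_prior_variance():
    rng = np.random.default_rng(8)
    diffs = pd.DataFrame(rng.normal(0, 1, (20, 6)))
    s0 = 0.25
    _, res = moderated_t(diffs, d0=1e6, s0_sq=s0)
    n = 6
    expected_t = res["log2fc"] / np.sqrt(s0 / n)
    assert np.allclose(res["t"], expected_t, rtol=1e-4)


def test_posterior_variance_between_prior_and_sample():
    eb = EBParams(d0=4.0, s0_sq=0.05)
    for s_sq, d_g in [(0.01, 5.0), (0.2, 5.0)]:
        post = (eb.d0 * eb.s0_sq + d_g * s_sq) / (eb.d0 + d_g)
        assert min(s_sq, eb.s0_sq) <= post <= max(s_sq, eb.s0_sq)


def test_trigamma_inverse_round_trip():
    from scipy.special import polygamma
    for x in (0.1, 1.0, 5.0, 50.0):
        assert trigamma_inverse(float(polygamma(1, x))) == pytest.approx(
            x, rel=1e-6)


def test_eb_prior_recovery_and_type_i_error():
    """2000 null proteoforms with scaled inverse-chi-square variances:
    hyperparameters are recovered and the test is calibrated."""
    rng = np.random.default_rng(10)
    d0_true, s0_true, n = 4.0, 0.05, 6
    n_pf = 2000
    sigma_sq = d0_true * s0_true / rng.chisquare(d0_true, n_pf)
    x = rng.normal(0.0, np.sqrt(sigma_sq)[:, None], (n_pf, n))
    eb, res = moderated_t(pd.DataFrame(x))
    assert 2.0 <= eb.d0 <= 8.0
    assert eb.s0_sq == pytest.approx(s0_true, rel=0.30)
    type_i = float((res["p"] < 0.05).mean())
    assert 0.04 <= type_i <= 0.06


def test_moderated_t_requires_two_pairs():
    diffs = pd.DataFrame([[1.0, np.nan, np.nan], [1.0, 2.0, 3.0]])
    with pytest.raises(ValueError):
        moderated_t(diffs, d0=0.0)


# ---------------------------------------------------------------------------
# BH adjustment


def bh_oracle(p):
    """Direct step-up formula: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    best = np.inf
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        best = min(best, p[i] * m / (rank + 1))
        q[i] = min(best, 1.0)
    return q


def test_bh_examples_and_properties():
    assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
    assert bh_adjust([0.3]) == pytest.approx([0.3])
    rng = np.random.default_rng(12)
    p = rng.uniform(0, 1, 500)
    q = bh_adjust(p)
    assert np.all(q >= p - 1e-12)
    assert np.allclose(q, bh_oracle(p), atol=1e-12)
    # monotone: ranking by q preserves ranking by p after tie grouping
    assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)


# ---------------------------------------------------------------------------
# Volcano classification


@pytest.mark.parametrize("p,lfc,expected", [
    (0.01, 1.5, "increased"),
    (0.01, 0.5, "null"),
    (0.06, -2.0, "null"),   # p boundary is strict
    (0.01, -1.5, "decreased"),
    (0.05, 2.0, "null"),
])
def test_volcano_classification(p, lfc, expected):
    res = pd.DataFrame({"p": [p], "log2fc": [lfc]})
    assert volcano_classify(res).iloc[0] == expected


# ---------------------------------------------------------------------------
# Presence test


def presence_oracle(n_total, n_group, k):
    """Exhaustive enumeration over all k-subsets of N samples."""
    hits = total = 0
    for subset in itertools.combinations(range(n_total), k):
        total += 1
        hits += all(s < n_group for s in subset)
    return hits / total


def test_presence_probability_examples():
    design = _design(6)
    samples = design.sample_ids
    treated = design.samples_in("treated")
    row = pd.Series(False, index=samples)
    row[treated] = True  # all 6 treated samples
    res = presence_test(row, design)
    assert res.probability == pytest.approx(1 / 924)
    assert res.significant
    row2 = pd.Series(False, index=samples)
    row2[treated[:2]] = True
    res2 = presence_test(row2, design)
    assert res2.probability == pytest.approx(15 / 66)
    assert not res2.significant
    row3 = pd.Series(False, index=samples)
    row3[treated[0]] = True
    assert presence_test(row3, design).probability == pytest.approx(0.5)


def test_presence_test_not_applicable_across_groups():
    design = _design(6)
    row = pd.Series(False, index=design.sample_ids)
    row["D1_control"] = True
    row["D1_treated"] = True
    assert presence_test(row, design) is None
    assert presence_test(pd.Series(False, index=design.sample_ids),
                         design) is None


@pytest.mark.parametrize("n_donors,k", [(6, 1), (6, 3), (6, 6), (4, 2),
                                        (5, 4)])
def test_presence_matches_exhaustive_enumeration(n_donors, k):
    design = _design(n_donors)
    group = design.samples_in("control")
    row = pd.Series(False, index=design.sample_ids)
    row[group[:k]] = True
    res = presence_test(row, design)
    assert res.probability == pytest.approx(
        presence_oracle(2 * n_donors, n_donors, k), abs=1e-12)


# ---------------------------------------------------------------------------
# Regional trends


def _toy_results():
    return pd.DataFrame({
        "gene": ["GCG"] * 4, "first_aa": [95, 100, 120, 80],
        "last_aa": [170, 150, 178, 120],
        "log2fc": [0.2, 1.1, -0.3, 2.0],
    }, index=["a", "b", "c", "d"])


def test_regional_trend_counts_contained_only():
    rmap = RegionMap([("GCG", "major proglucagon fragment", 92, 178)])
    tr = regional_trend(_toy_results(), rmap, "GCG",
                        "major proglucagon fragment")
    # proteoform d (80-120) spans the boundary and is excluded
    assert tr["n_total"] == 3
    assert tr["n_up"] == 2
    assert tr["n_down"] == 1
    with pytest.raises(KeyError):
        regional_trend(_toy_results(), rmap, "GCG", "no-such-region")
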
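"""Moderated t, fold change, permutation sampling p, selection, intersection."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _reference import exhaustive_sampling_p, reference_moderated
from conftest import make_ct_table, make_sheet
from mirserum.calibration import filter_expressed
from mirserum.containers import ValidationError
from mirserum.differential import (
    GroupComparison,
    build_diff_table,
    fit_moderated_t,
    fold_change,
    intersect_candidates,
    sampling_p,
    select_candidates,
)
from mirserum.normalization import NormalizedTable
from mirserum.published import screen_candidate_set
from mirserum.stats import moderated_stats, pooled_permutation_p


def frame(rows, samples):
    return pd.DataFrame(rows, columns=samples)


def four_sample_sheet():
    return make_sheet({"m1": "mild", "m2": "mild", "n1": "normal", "n2": "normal"})


def test_zero_prior_df_reproduces_hand_computed_ordinary_t():
    """With d0 = 0 the statistic is the classical pooled t; checked against
    a from-scratch hand computation on one feature."""
    a = np.array([[30.0, 31.0]])
    b = np.array([[28.0, 28.5]])
    res = moderated_stats(a, b, d0=0)
    ma, mb = 30.5, 28.25
    sp2 = ((30.0 - ma) ** 2 + (31.0 - ma) ** 2 + (28.0 - mb) ** 2 + (28.5 - mb) ** 2) / 2
    t_hand = (ma - mb) / math.sqrt(sp2 * (1 / 2 + 1 / 2))
    assert res["t"][0] == pytest.approx(t_hand, abs=1e-12)
    from scipy import stats as st_

    assert res["p"][0] == pytest.approx(2 * st_.t.sf(abs(t_hand), 2), abs=1e-12)


def test_equal_group_means_give_null_result():
    a = np.array([[30.0, 30.0], [25.0, 25.0]])
    res = moderated_stats(a, a)
    assert np.all(res["t"] == 0.0)
    assert np.all(res["p"] == 1.0)


def test_moderated_t_matches_independent_reimplementation():
    """Array implementation vs a straight-line scalar second path (moments
    estimator, trigamma inversion, shrinkage, p) on a 50-feature matrix."""
    rng = np.random.default_rng(13)
    F = 50
    s2true = 0.05 * 4 / rng.chisquare(4, F)
    a = rng.normal(30, np.sqrt(s2true)[:, None], (F, 2))
    b = rng.normal(30, np.sqrt(s2true)[:, None], (F, 2))
    res = moderated_stats(a, b)
    t_ref, p_ref, d0_ref, s0_ref = reference_moderated(a.tolist(), b.tolist())
    assert res["d0"] == pytest.approx(d0_ref, rel=1e-6)
    assert res["s0sq"] == pytest.approx(s0_ref, rel=1e-6)
    np.testing.assert_allclose(res["t"], t_ref, atol=1e-6)
    np.testing.assert_allclose(res["p"], p_ref, atol=1e-6)


def test_posterior_variance_identity():
    rng = np.random.default_rng(3)
    s2true = 0.2 * 3 / rng.chisquare(3, 40)  # heterogeneous true variances
    a = rng.normal(30, np.sqrt(s2true)[:, None], (40, 2))
    b = rng.normal(30, np.sqrt(s2true)[:, None], (40, 2))
    res = moderated_stats(a, b)
    d0, s0, d = res["d0"], res["s0sq"], res["d"]
    assert np.isfinite(d0)
    expect = (d0 * s0 + d * res["s2"]) / (d0 + d)
    np.testing.assert_allclose(res["s2_post"], expect, atol=1e-12)


def test_zero_variance_feature_is_shrunk_not_divided_by_zero():
    a = np.array([[30.0, 30.0], [25.0, 25.4], [27.0, 27.3]])
    b = np.array([[31.0, 31.0], [25.1, 25.2], [27.2, 26.8]])
    res = moderated_stats(a, b)
    assert np.isfinite(res["t"][0]) and res["p"][0] > 0.0


@pytest.mark.parametrize(
    "delta,fc",
    [(0.0, 1.0), (1.0, 0.5), (-1.0, 2.0), (-4.725, 2.0**4.725), (5.236, 2.0**-5.236)],
)
def test_fold_change_formula(delta, fc):
    assert fold_change(delta) == pytest.approx(fc, rel=1e-12)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(delta=st.floats(min_value=-10, max_value=10, allow_nan=False))
def test_fold_change_log_duality(delta):
    assert -math.log2(fold_change(delta)) == pytest.approx(delta, abs=1e-12)


def test_sampling_p_is_one_on_permutation_invariant_data():
    """If every feature carries identical values, no permutation changes
    anything and the sampling p is 1 for all features."""
    vals = np.tile(np.array([[30.0, 31.0, 29.0, 30.5]]), (4, 1))
    p = pooled_permutation_p(vals, np.array([0, 1]), np.array([2, 3]), B=50,
                             rng=np.random.default_rng(0))
    assert np.all(p == 1.0)


def test_sampling_p_requires_seed_and_positive_b():
    vals = frame(np.random.default_rng(0).normal(30, 1, (3, 4)), ["m1", "m2", "n1", "n2"])
    data = NormalizedTable(values=vals, provenance="raw")
    comp = GroupComparison("normal_vs_mild", case="mild", control="normal")
    with pytest.raises(ValidationError, match="seed"):
        sampling_p(data, four_sample_sheet(), comp, B=10)
    with pytest.raises(ValidationError, match="B"):
        sampling_p(data, four_sample_sheet(), comp, B=0, seed=1)


def test_sampling_p_matches_exhaustive_enumeration():
    """Monte-Carlo sampling p at B = 10000 sits within 3 standard errors of
    the exact value from enumerating all 6^4 per-column permutations of a
    3-feature, 2+2-sample fixture."""
    rng = np.random.default_rng(21)
    vals = rng.normal(30, 1.0, (3, 4))
    vals[0, :2] += 2.5  # one shifted feature
    exact, _ = exhaustive_sampling_p(vals.tolist(), [0, 1], [2, 3])
    B = 10_000
    mc = pooled_permutation_p(vals, np.array([0, 1]), np.array([2, 3]), B=B,
                              rng=np.random.default_rng(5))
    for f in range(3):
        se = math.sqrt(max(exact[f] * (1 - exact[f]), 1e-12) / B)
        assert abs(mc[f] - exact[f]) <= 3 * se + 1e-12, (f, mc[f], exact[f], se)


def test_sampling_p_monotone_in_model_p():
    rng = np.random.default_rng(2)
    vals = rng.normal(30, 1.0, (30, 4))
    vals[:5, :2] += rng.uniform(1, 3, size=(5, 1))
    obs_p = moderated_stats(vals[:, :2], vals[:, 2:])["p"]
    sp = pooled_permutation_p(vals, np.array([0, 1]), np.array([2, 3]), B=300,
                              rng=np.random.default_rng(3))
    order = np.argsort(obs_p)
    assert np.all(np.diff(sp[order]) >= -1e-15)


def test_sampling_p_smoothing_avoids_zero():
    rng = np.random.default_rng(8)
    vals = rng.normal(30, 0.3, (20, 4))
    vals[0, :2] += 6.0
    sp = pooled_permutation_p(vals, np.array([0, 1]), np.array([2, 3]), B=100,
                              rng=np.random.default_rng(1), smoothing=True)
    assert np.all(sp > 0)


def test_select_candidates_ordering_and_alpha():
    diff = pd.DataFrame(
        {
            "dCt": [1.0, -2.0, 0.5, 3.0],
            "FC": [0.5, 4.0, 0.707, 0.125],
            "p value": [0.01, 0.002, 0.04, 0.3],
            "sampling p": [0.004, 0.004, 0.03, 0.4],
        },
        index=pd.Index(["hsa-miR-b", "hsa-miR-a", "hsa-miR-c", "hsa-miR-d"],
                       name="MicroRNA Name"),
    )
    cset = select_candidates(diff, alpha=0.05)
    # tie on sampling p broken by model p, then direction from FC
    assert [f for f, _ in cset.members] == ["hsa-miR-a", "hsa-miR-b", "hsa-miR-c"]
    assert cset.direction_of("hsa-miR-a") == "up"
    assert cset.direction_of("hsa-miR-b") == "down"


def test_select_all_null_gives_empty_set():
    diff = pd.DataFrame(
        {"dCt": [0.0], "FC": [1.0], "p value": [1.0], "sampling p": [1.0]},
        index=pd.Index(["hsa-miR-a"], name="MicroRNA Name"),
    )
    assert len(select_candidates(diff)) == 0


def test_intersection_set_algebra():
    from mirserum.differential import CandidateSet

    a = CandidateSet("c", "raw", [("m1", "up"), ("m2", "down"), ("m3", "up")])
    b = CandidateSet("c", "delta", [("m2", "down"), ("m3", "down"), ("m4", "up")])
    ab = intersect_candidates(a, b)
    assert ab.names == {"m2"}  # m3 dropped: direction conflict
    assert intersect_candidates(a, a).members == a.members  # idempotent
    ba = intersect_candidates(b, a)
    assert ab.names == ba.names  # commutative on names
    empty = intersect_candidates(a, CandidateSet("c", "x", []))
    assert len(empty) == 0


def test_published_mild_severe_overlap_is_the_nine_core_mirnas():
    """Intersecting the published 15-candidate mild list with the published
    29-candidate severe list leaves the nine-miRNA core set."""
    mild = screen_candidate_set("mild")
    severe = screen_candidate_set("severe")
    core = intersect_candidates(mild, severe)
    assert core.names == {
        "hsa-miR-589-3p", "hsa-miR-185-3p", "hsa-miR-886-5p", "hsa-miR-520d-5p",
        "hsa-miR-654-5p", "hsa-miR-510-5p", "hsa-miR-143-3p", "hsa-miR-202-3p",
        "hsa-miR-184",
    }
    assert len(core) == 9


def test_spike_recovery_in_both_branches(spiked_experiment):
    """Ten features spiked at |delta| >= 3 cycles are all selected at
    alpha = 0.05 (B = 2000) in the raw and the delta-Ct branch."""
    from mirserum.normalization import delta_ct, make_reference_set

    cfg, table, sheet, truth = spiked_experiment
    filtered = filter_expressed(table, panel_policy="panel_I_only")
    targets = [f for f in filtered.features if filtered.roles[f] == "target"]
    comp = GroupComparison("normal_vs_mild", case="mild", control="normal")

    spiked = set(truth["feature"])
    for branch_data in (
        NormalizedTable(values=filtered.values.loc[targets], provenance="raw"),
        NormalizedTable(
            values=delta_ct(filtered, make_reference_set(filtered)).values.loc[targets],
            provenance="ipc_delta_ct",
        ),
    ):
        fit = fit_moderated_t(branch_data, sheet, comp)
        sp = sampling_p(branch_data, sheet, comp, B=2000, seed=97)
        cset = select_candidates(build_diff_table(fit, sp), alpha=0.05)
        assert spiked <= cset.names, (branch_data.provenance, spiked - cset.names)


def test_fit_requires_two_samples_per_group():
    vals = frame(np.random.default_rng(0).normal(30, 1, (3, 3)), ["m1", "n1", "n2"])
    sheet = make_sheet({"m1": "mild", "n1": "normal", "n2": "normal"})
    comp = GroupComparison("normal_vs_mild", case="mild", control="normal")
    with pytest.raises(ValidationError, match=">= 2 samples"):
        fit_moderated_t(NormalizedTable(values=vals, provenance="raw"), sheet, comp)
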
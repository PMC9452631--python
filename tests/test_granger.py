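import numpy as np
import pandas as pd
import pytest

import ripplesync as rs
from ripplesync.exceptions import DegenerateInputError
from ripplesync.granger import (
    SparseZSeries,
    aggregate,
    bh_fdr,
    decimate_envelope,
    gc_test,
    select_order,
    sparsify,
)
from ripplesync.swr_detect import EnvelopeZ

from oracles import bh_reject_bruteforce

# stable bivariate VAR(3) used in the simulation tests
A1 = np.array([[0.5, 0.1], [0.3, 0.4]])
A3 = np.array([[0.25, 0.1], [0.1, 0.2]])


def _series(values, region="CA1"):
    return SparseZSeries(np.asarray(values, float), fs=100.0, region=region)


def _simulate_var3(n, seed):
    rng = np.random.default_rng(seed)
    X = np.zeros((n, 2))
    for t in range(3, n):
        X[t] = A1 @ X[t - 1] + A3 @ X[t - 3] + rng.standard_normal(2)
    return X


# ---------------------------------------------------------------- sparsify


def test_sparsify_elementwise_rule():
    envz = EnvelopeZ(
        z=np.array([0.1, 6.0, 4.9, 7.2]), fs=2000.0, band=(150, 250), mu=1.0, sigma=2.0
    )
    out = sparsify(envz)
    assert np.allclose(out.values, [0.0, 6.0, 0.0, 7.2])
    assert not out.is_empty


def test_sparsify_all_subthreshold_flagged_empty():
    envz = EnvelopeZ(z=np.full(100, 2.0), fs=2000.0, band=(150, 250), mu=0.0, sigma=1.0)
    assert sparsify(envz).is_empty


def test_decimate_envelope_keeps_band_and_rate():
    envz = EnvelopeZ(
        z=np.sin(np.arange(4000) * 0.01), fs=2000.0, band=(150, 250), mu=1.0, sigma=2.0
    )
    out = decimate_envelope(envz, 20)
    assert out.fs == 100.0
    assert out.z.size == 200
    assert out.band == (150, 250)


# ------------------------------------------------------------ select_order


def test_single_candidate_returns_one():
    X = _simulate_var3(2000, 0)
    assert select_order(_series(X[:, 0]), _series(X[:, 1], "MEC"), max_order=1) == 1


def test_bic_recovers_var3_order():
    hits = 0
    for run in range(20):
        X = _simulate_var3(5000, 1000 + run)
        hits += select_order(_series(X[:, 0]), _series(X[:, 1], "MEC"), "BIC", 10) == 3
    assert hits >= 18


def test_white_noise_selects_short_memory(rng):
    hits = 0
    for _ in range(10):
        x = _series(rng.standard_normal(3000))
        y = _series(rng.standard_normal(3000), "MEC")
        hits += select_order(x, y, "BIC", 10) <= 2
    assert hits >= 9


def test_order_selection_matches_statsmodels():
    from statsmodels.tsa.api import VAR

    for seed in (7, 8, 9):
        X = _simulate_var3(5000, seed)
        sel = VAR(X).select_order(10)
        assert select_order(_series(X[:, 0]), _series(X[:, 1], "MEC"), "AIC", 10) == sel.aic
        assert select_order(_series(X[:, 0]), _series(X[:, 1], "MEC"), "BIC", 10) == sel.bic


def test_all_zero_series_degenerate():
    with pytest.raises(DegenerateInputError):
        select_order(_series(np.zeros(2000)), _series(np.ones(2000), "MEC"), "AIC", 5)


def test_series_too_short_for_order():
    with pytest.raises(ValueError):
        select_order(_series(np.ones(100)), _series(np.ones(100), "MEC"), "AIC", 50)


# ---------------------------------------------------------------- gc_test


def test_directional_coupling_detected(rng):
    hits_fwd = hits_rev = 0
    n_runs = 20
    for _ in range(n_runs):
        n = 5000
        x = np.zeros(n)
        y = np.zeros(n)
        eta = rng.standard_normal(n)
        eps = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = 0.5 * x[t - 1] + eta[t]
            y[t] = 0.8 * x[t - 1] + eps[t]
        fwd, rev = gc_test(_series(x), _series(y, "MEC"), order=2)
        hits_fwd += fwd.p_raw < 0.05
        hits_rev += rev.p_raw < 0.05
    assert hits_fwd == n_runs
    assert hits_rev <= 3


def test_type_one_error_calibrated(rng):
    rejections = 0
    n_runs = 200
    for _ in range(n_runs):
        fwd, rev = gc_test(
            _series(rng.standard_normal(2000)),
            _series(rng.standard_normal(2000), "MEC"),
            order=5,
        )
        rejections += (fwd.p_raw < 0.05) + (rev.p_raw < 0.05)
    rate = rejections / (2 * n_runs)
    assert 0.02 <= rate <= 0.09


def test_f_matches_statsmodels_granger(rng):
    from statsmodels.tsa.stattools import grangercausalitytests

    X = _simulate_var3(3000, 77)
    order = 3
    fwd, _ = gc_test(_series(X[:, 0]), _series(X[:, 1], "MEC"), order=order)
    # statsmodels tests "column 2 causes column 1"
    res = grangercausalitytests(X[:, [1, 0]], maxlag=[order])
    f_sm, p_sm, _, _ = res[order][0]["ssr_ftest"]
    assert fwd.f_stat == pytest.approx(f_sm, rel=1e-6)
    assert fwd.p_raw == pytest.approx(p_sm, rel=1e-6, abs=1e-12)


def test_role_swap_exchanges_directions(rng):
    X = _simulate_var3(2000, 3)
    x, y = _series(X[:, 0], "CA1"), _series(X[:, 1], "MEC")
    fwd, rev = gc_test(x, y, order=4)
    rev2, fwd2 = gc_test(y, x, order=4)
    assert fwd.f_stat == pytest.approx(fwd2.f_stat, rel=1e-9)
    assert rev.f_stat == pytest.approx(rev2.f_stat, rel=1e-9)


def test_f_invariant_to_common_scaling(rng):
    X = _simulate_var3(2000, 4)
    f1, _ = gc_test(_series(X[:, 0]), _series(X[:, 1], "MEC"), order=3)
    f2, _ = gc_test(_series(X[:, 0] * 100), _series(X[:, 1] * 100, "MEC"), order=3)
    assert f1.f_stat == pytest.approx(f2.f_stat, rel=1e-9)


def test_exact_shifted_copy_is_rank_deficient():
    x = np.sin(np.arange(1000) * 0.1)
    y = np.roll(x, 1)
    with pytest.raises(DegenerateInputError, match="direction"):
        gc_test(_series(x), _series(y, "MEC"), order=4)


# ---------------------------------------------------------------- FDR / aggregate


def test_bh_matches_stepup_oracle(rng):
    for _ in range(20):
        p = np.concatenate([rng.uniform(size=10), np.full(10, 1e-6)])
        rng.shuffle(p)
        reject, _ = bh_fdr(p, alpha=0.05)
        assert np.array_equal(reject, bh_reject_bruteforce(p, 0.05))


def test_bh_rejects_the_planted_signals(rng):
    p = np.concatenate([rng.uniform(0.2, 1.0, 10), np.full(10, 1e-6)])
    reject, _ = bh_fdr(p, alpha=0.05)
    assert reject[10:].all()
    assert not reject[:10].any()


def test_aggregate_session_and_pair_means():
    rows = []
    for session, sig_p in zip("abcd", [1e-9, 1e-9, 0.9, 1e-9]):
        rows.append(
            dict(session_id=session, pair_id="p0", direction="MEC->CA1", p_raw=sig_p)
        )
        rows.append(dict(session_id=session, pair_id="p0", direction="CA1->MEC", p_raw=0.5))
    res = aggregate(pd.DataFrame(rows), alpha=0.05)
    per = res.per_pair.set_index("direction")["mean_significance"]
    assert per["MEC->CA1"] == pytest.approx(0.75)
    assert per["CA1->MEC"] == 0.0
    assert res.group_mean["MEC->CA1"] == pytest.approx(0.75)


def test_aggregate_all_null_p_values():
    rows = [
        dict(session_id="s", pair_id=f"p{i}", direction=d, p_raw=0.5)
        for i in range(5)
        for d in ("MEC->CA1", "CA1->MEC")
    ]
    res = aggregate(pd.DataFrame(rows))
    assert all(v == 0.0 for v in res.group_mean.values())


def test_aggregate_empty_grid_is_error():
    with pytest.raises(ValueError):
        aggregate(pd.DataFrame())


# ------------------------------------------------- pipeline-level direction


def test_mec_leads_produces_forward_causality(wt_session):
    lfp_ca1, lfp_mec, track, truth = wt_session
    z_ca1 = sparsify(decimate_envelope(rs.ripple_envelope_z(lfp_ca1)), region="CA1")
    z_mec = sparsify(decimate_envelope(rs.ripple_envelope_z(lfp_mec)), region="MEC")
    order = select_order(z_mec, z_ca1, "AIC", max_order=50)
    fwd, rev = gc_test(z_mec, z_ca1, order)
    assert fwd.direction == "MEC->CA1"
    assert fwd.p_raw < 1e-10
    assert fwd.f_stat > rev.f_stat
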
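import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methmargin.differential import (
    bh_adjust,
    call_dmr,
    fit_dmc,
    fit_dmc_arrays,
    select_markers,
    select_markers_from_scores,
    select_markers_from_sites,
)

from _oracles import brute_bh


def _counts_df(slots, meth, total):
    return pd.DataFrame({
        "contig": "chr1",
        "slot": slots,
        "pos": [100 + 20 * s for s in slots],
        "n_meth": meth,
        "n_total": total,
    })


# ---------------------------------------------------------------------------
# DMC model


def test_identical_groups_give_null_result():
    counts = {f"s{i}": _counts_df([0, 1], [3 + i, 5], [10, 10]) for i in range(4)}
    tc = {k: v for k, v in list(counts.items())[:2]}
    pn = {f"p{k}": v.copy() for k, v in tc.items()}
    dmc = fit_dmc(tc, pn)
    assert np.allclose(dmc["delta_beta"], 0.0)
    assert (dmc["p"] >= 0.99).all()


def test_maximal_separation_direction_and_significance():
    tc = {f"t{i}": _counts_df([0], [30], [30]) for i in range(15)}
    pn = {f"n{i}": _counts_df([0], [0], [30]) for i in range(15)}
    dmc = fit_dmc(tc, pn)
    assert dmc["delta_beta"].iloc[0] == pytest.approx(1.0)
    assert dmc["p"].iloc[0] < 1e-10


def test_group_swap_negates_delta_and_preserves_p_exactly():
    rng = np.random.default_rng(3)
    n = rng.poisson(30, size=(50, 15)).clip(min=1)
    m = rng.binomial(n, 0.4)
    n2 = rng.poisson(30, size=(50, 15)).clip(min=1)
    m2 = rng.binomial(n2, 0.6)
    fwd = fit_dmc_arrays(m, n, m2, n2)
    rev = fit_dmc_arrays(m2, n2, m, n)
    assert np.array_equal(fwd["delta_beta"], -rev["delta_beta"])
    assert np.array_equal(fwd["p"], rev["p"])


def test_one_group_uncovered_site_is_skipped():
    tc = {f"t{i}": _counts_df([0, 1], [5, 5], [10, 10]) for i in range(3)}
    pn = {f"n{i}": _counts_df([0], [5], [10]) for i in range(3)}
    dmc = fit_dmc(tc, pn)
    assert dmc["slot"].tolist() == [0]


def test_null_beta_binomial_type_one_error_calibrated():
    """Empirical size at alpha=0.05 on overdispersed null data (small run;
    the full 2000-site calibration is exercised with the acceptance suite)."""
    rng = np.random.default_rng(21)
    S, n = 600, 15
    a = 0.5 * (1 / 0.1 - 1)
    depth = rng.poisson(30, size=(S, 2 * n)).clip(min=1)
    p = rng.beta(a, a, size=(S, 2 * n))
    m = rng.binomial(depth, p)
    res = fit_dmc_arrays(m[:, :n], depth[:, :n], m[:, n:], depth[:, n:])
    rate = float((res["p"][res["tested"]] < 0.05).mean())
    assert 0.02 < rate < 0.08


# ---------------------------------------------------------------------------
# BH adjustment


def test_bh_worked_examples():
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
    assert bh_adjust([0.5]) == pytest.approx([0.5])
    assert bh_adjust([]).size == 0


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_matches_brute_force_and_inflates(p):
    got = bh_adjust(p)
    assert got == pytest.approx(brute_bh(p), abs=1e-12)
    assert np.all(got >= np.asarray(p) - 1e-15)
    assert np.all(got <= 1.0)


# ---------------------------------------------------------------------------
# DMR merging


def _dmc_frame(pos, p, delta=0.5, cov=300):
    n = len(pos)
    return pd.DataFrame({
        "contig": "chr1",
        "slot": range(n),
        "pos": pos,
        "beta_tc": 0.7,
        "beta_pn": 0.2,
        "delta_beta": [delta] * n,
        "phi": 0.1,
        "wald": 2.0,
        "p": p,
        "q": p,
        "n_total": cov,
    })


def test_dmr_hand_traced_five_cpg_fixture():
    dmc = _dmc_frame([100, 120, 140, 160, 180], [0.01, 0.04, 0.2, 0.03, 0.9])
    dmr = call_dmr(dmc, max_gap_bp=100)
    assert len(dmr) == 1
    assert dmr["n_cpg"].iloc[0] == 5
    assert dmr["frac_sig"].iloc[0] == pytest.approx(0.6)
    assert dmr["mean_delta_beta"].iloc[0] == pytest.approx(0.5)
    assert dmr["start"].iloc[0] == 100 and dmr["end"].iloc[0] == 182


def test_dmr_size_floor_drops_isolated_significant_sites():
    dmc = _dmc_frame([100, 600, 1100], [0.01, 0.01, 0.9])
    assert call_dmr(dmc).empty


def test_dmr_requires_a_significant_seed():
    dmc = _dmc_frame([100, 120, 140], [0.5, 0.5, 0.5])
    assert call_dmr(dmc).empty


def test_dmr_regions_disjoint_and_self_consistent():
    rng = np.random.default_rng(17)
    pos = np.sort(rng.choice(np.arange(100, 20000, 17), size=250, replace=False))
    dmc = _dmc_frame(pos.tolist(), rng.random(250).tolist())
    dmr = call_dmr(dmc)
    prev_end = -1
    for rec in dmr.itertuples():
        assert rec.start > prev_end
        prev_end = rec.end
        assert rec.n_cpg >= 3
        assert rec.frac_sig > 0.1
        members = dmc[(dmc["pos"] >= rec.start) & (dmc["pos"] < rec.end)]
        assert len(members) == rec.n_cpg
        assert (members["p"] < 0.05).sum() == rec.n_sig


# ---------------------------------------------------------------------------
# marker selection


def test_selection_standard_effect_and_fdr():
    dmc = pd.DataFrame({
        "contig": ["chr1"] * 3,
        "pos": [100, 200, 300],
        "beta_tc": [0.8, 0.35, 0.1],
        "beta_pn": [0.2, 0.20, 0.6],
        "delta_beta": [0.6, 0.15, -0.5],
        "p": [0.0001, 0.0001, 0.001],
        "q": [0.001, 0.001, 0.01],
    })
    out = select_markers_from_sites(dmc, feature_type="DMC")
    assert out["marker_id"].tolist() == ["chr1:100", "chr1:300"]
    assert out["direction"].tolist() == ["high", "low"]  # sign rule; 0.15 effect dropped


def test_score_marker_selection_respects_group_support(default_cohort):
    sheet = default_cohort.sample_sheet
    cols = list(sheet.loc[sheet["position"].isin(["TC", "PN"]), "sample_id"])
    is_tc = [s.endswith("_TC") for s in cols]
    row1 = [0.9 if tc else 0.1 for tc in is_tc]
    # keep only 3 informative TC values on the second marker
    seen_tc = 0
    row2 = []
    for tc, v in zip(is_tc, row1):
        if tc:
            seen_tc += 1
            row2.append(v if seen_tc <= 3 else np.nan)
        else:
            row2.append(v)
    scores = pd.DataFrame(
        [row1, row2], index=["AMF|chr1:1:2", "AMF|chr1:3:4"], columns=cols
    )
    out = select_markers_from_scores(scores, default_cohort.sample_sheet)
    # the second marker has only 3 non-missing TC values -> excluded
    assert out["marker_id"].tolist() == ["AMF|chr1:1:2"]
    assert out["direction"].iloc[0] == "high"


def test_select_markers_dispatches_on_columns(default_cohort):
    dmr = pd.DataFrame({
        "contig": ["chr1"],
        "start": [100],
        "end": [300],
        "mean_delta_beta": [0.5],
        "combined_p": [1e-6],
        "q": [1e-5],
    })
    out = select_markers(dmr)
    assert out["feature_type"].tolist() == ["DMR"]
    assert out["marker_id"].tolist() == ["chr1:100:300"]


def test_planted_effect_recovery_sensitivity_and_fdr():
    """Sites planted at delta-beta 0.5 must be found nearly always while BH
    plus the 0.2 effect floor keeps the empirical FDR at or under 10%."""
    rng = np.random.default_rng(31)
    n, reps = 15, 20
    tp = fp = planted_total = found_total = 0
    for _ in range(reps):
        S_null, S_sig = 250, 50
        a_null = 0.4 * (1 / 0.1 - 1)  # beta params: mean 0.4, dispersion 0.1
        b_null = 0.6 * (1 / 0.1 - 1)
        depth = rng.poisson(30, size=(S_null + S_sig, 2 * n)).clip(min=1)
        p_tc = np.concatenate([
            rng.beta(a_null, b_null, size=(S_null, n)),
            rng.beta(0.85 * 9, 0.15 * 9, size=(S_sig, n)),
        ])
        p_pn = np.concatenate([
            rng.beta(a_null, b_null, size=(S_null, n)),
            rng.beta(0.35 * 9, 0.65 * 9, size=(S_sig, n)),
        ])
        m_tc = rng.binomial(depth[:, :n], p_tc)
        m_pn = rng.binomial(depth[:, n:], p_pn)
        res = fit_dmc_arrays(m_tc, depth[:, :n], m_pn, depth[:, n:])
        q = bh_adjust(res["p"])
        selected = (q < 0.05) & (np.abs(res["delta_beta"]) > 0.2)
        is_sig = np.arange(S_null + S_sig) >= S_null
        tp += int((selected & is_sig).sum())
        fp += int((selected & ~is_sig).sum())
        planted_total += S_sig
        found_total += int(selected.sum())
    assert tp / planted_total >= 0.95
    assert fp / max(found_total, 1) <= 0.10
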
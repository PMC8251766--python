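import numpy as np
import pytest

from vpdmeta.effects import EffectEstimate
from vpdmeta.metareg import (DesignSpec, MetaRegression,
                             UnderDeterminedError, build_design,
                             dersimonian_laird_tau2, minimal_adequate_model,
                             reml_tau2, restricted_loglik,
                             single_factor_analysis)
from vpdmeta.pooling import weighted_mean_L

# Two frozen fixtures, with reference values computed independently in R
# with metafor::rma (REML / DL / Knapp-Hartung variants).
FIX1 = dict(
    L=np.array([-0.470682, -0.461981, -0.502734, -0.239683, 0.085789,
                -0.389141, -0.272298, -0.410054, -0.146043, -0.31867,
                0.049328, -0.284036]),
    v=np.array([0.033974, 0.042024, 0.024954, 0.015226, 0.029956, 0.007872,
                0.042243, 0.033425, 0.039114, 0.020954, 0.048681, 0.04519]),
    x=np.array([1.660934, 1.158318, 1.787897, 1.546052, 0.641266, 1.963434,
                1.64171, 1.679096, 0.69217, 1.175579, 1.056197, 1.890147]),
    tau2=0.0, b=(0.1092624636, -0.2726740497),
    se=(0.1680403016, 0.1059482696),
    qm=6.6236882029, qm_p=0.01006312309,
    io_tau2=0.0027946753, io_b=-0.3028704903, io_se=0.0487155575,
)
FIX2 = dict(
    L=np.array([-0.199692, -0.125314, -0.268534, -0.422648, -0.313668,
                -0.447912, -0.184964, 0.135054, -0.323052, -0.355119,
                -0.077539, -0.110778, -0.173646, -0.432617, -0.207313]),
    v=np.array([0.011963, 0.019919, 0.016268, 0.013199, 0.019801, 0.005876,
                0.004884, 0.013026, 0.002791, 0.002642, 0.011268, 0.010392,
                0.018509, 0.013326, 0.011254]),
    x=np.array([0.993747, 0.49503, 0.023588, 0.384804, 1.384064, 0.401213,
                0.739073, 0.007468, 1.660095, 0.308922, 0.535199, 1.760664,
                1.019582, 1.6943, 1.279434]),
    tau2=0.0156969044, b=(-0.2094640165, -0.0395802703),
    se=(0.0738633253, 0.0716131237),
    qm=0.3054726103, qm_p=0.5804717528,
    knha_se1=0.0706687359, knha_p1=0.5849463031,
    dl_tau2=0.0149331392,
)


def _design(fix):
    X = np.column_stack([np.ones(len(fix["L"])), fix["x"]])
    return fix["L"], fix["v"], X


@pytest.mark.parametrize("fix", [FIX1, FIX2], ids=["boundary", "interior"])
def test_reml_fit_matches_independent_reference(fix):
    L, v, X = _design(fix)
    res = MetaRegression(L, v, X, names=["intercept", "x"]).fit()
    assert res.tau2 == pytest.approx(fix["tau2"], abs=2e-6)
    assert res.params == pytest.approx(fix["b"], abs=1e-6)
    assert res.bse == pytest.approx(fix["se"], abs=1e-6)
    assert res.qm == pytest.approx(fix["qm"], abs=1e-4)
    assert res.qm_pvalue == pytest.approx(fix["qm_p"], abs=1e-6)


def test_intercept_only_matches_reference():
    L, v, _ = _design(FIX1)
    res = MetaRegression(L, v, np.ones((len(L), 1)),
                         names=["intercept"]).fit()
    assert res.tau2 == pytest.approx(FIX1["io_tau2"], abs=5e-6)
    assert res.params[0] == pytest.approx(FIX1["io_b"], abs=1e-5)
    assert res.bse[0] == pytest.approx(FIX1["io_se"], abs=1e-5)


def test_knapp_hartung_and_dl_match_reference():
    L, v, X = _design(FIX2)
    assert dersimonian_laird_tau2(L, v, X) == pytest.approx(
        FIX2["dl_tau2"], abs=1e-8)
    res = MetaRegression(L, v, X, names=["intercept", "x"]).fit(
        inference="knha")
    assert res.bse[1] == pytest.approx(FIX2["knha_se1"], abs=1e-6)
    assert res.pvalues[1] == pytest.approx(FIX2["knha_p1"], abs=1e-6)


def test_reml_matches_grid_search_oracle(rng):
    """tau2 from Fisher scoring within 1e-4 of a dense grid maximizer."""
    for _ in range(10):
        k = int(rng.integers(8, 25))
        v = rng.uniform(0.002, 0.05, k)
        x = rng.uniform(0, 2, k)
        L = rng.normal(-0.2 + 0.3 * x, np.sqrt(v + rng.uniform(0, 0.03)))
        X = np.column_stack([np.ones(k), x])
        hat = reml_tau2(L, v, X)
        grid = np.linspace(0.0, 10.0 * np.var(L), 20001)
        ll = [restricted_loglik(t, L, v, X) for t in grid]
        best = grid[int(np.argmax(ll))]
        assert hat == pytest.approx(best, abs=1e-4)
        assert restricted_loglik(hat, L, v, X) >= max(ll) - 1e-8


def test_reml_zero_when_residuals_vanish():
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
    L = 0.2 - 0.4 * x  # exactly linear: no excess dispersion
    v = np.full(6, 0.01)
    X = np.column_stack([np.ones(6), x])
    assert reml_tau2(L, v, X) == 0.0


def test_reml_balanced_closed_form():
    """Equal v, intercept-only: REML tau2 = max(0, s_L^2 - v)."""
    rng = np.random.default_rng(3)
    L = rng.normal(0.1, 0.3, 30)
    v = np.full(30, 0.02)
    X = np.ones((30, 1))
    expected = max(0.0, np.var(L, ddof=1) - 0.02)
    assert reml_tau2(L, v, X) == pytest.approx(expected, rel=1e-6)


def test_increasing_v_never_increases_tau2(rng):
    for _ in range(5):
        k = 20
        v = rng.uniform(0.002, 0.05, k)
        L = rng.normal(0.0, 0.25, k)
        X = np.ones((k, 1))
        t0 = reml_tau2(L, v, X)
        t1 = reml_tau2(L, v + 0.02, X)
        assert t1 <= t0 + 1e-10


def test_moderator_rescaling_rescales_coefficient_only():
    L, v, X = _design(FIX2)
    res = MetaRegression(L, v, X, names=["intercept", "x"]).fit()
    X10 = X.copy()
    X10[:, 1] *= 10.0
    res10 = MetaRegression(L, v, X10, names=["intercept", "x"]).fit()
    assert res10.params[1] == pytest.approx(res.params[1] / 10.0, rel=1e-8)
    assert res10.pvalues[1] == pytest.approx(res.pvalues[1], rel=1e-8)


def test_intercept_only_tau2_zero_equals_pooled_mean():
    L, v, _ = _design(FIX1)
    res = MetaRegression(L, v, np.ones((len(L), 1))).fit(tau2=0.0)
    ests = [EffectEstimate(f"s{i}", float(L[i]), float(v[i]), "reported")
            for i in range(len(L))]
    assert res.params[0] == pytest.approx(weighted_mean_L(ests), abs=1e-12)


# --- design construction -------------------------------------------------


def mk_est(sid, L, v, **mods):
    lvr = mods.pop("log_vpd_ratio", 1.0)
    return EffectEstimate(sid, L, v, "reported", log_vpd_ratio=lvr,
                          species=mods.pop("species", sid),
                          moderators=mods)


def test_build_design_vpd_column():
    ests = [mk_est(f"s{i}", 0.1, 0.01, log_vpd_ratio=0.1 * i)
            for i in range(10)]
    d = build_design(ests, DesignSpec(continuous=("log_vpd_ratio",),
                                      categorical={}))
    assert d.X.shape == (10, 2)
    assert d.names == ["intercept", "log_vpd_ratio"]
    assert d.X[:, 1] == pytest.approx([0.1 * i for i in range(10)])


def test_build_design_dummy_coding_and_reference():
    ests = [mk_est(f"s{i}", 0.1, 0.01,
                   irrigation="hydroponic_or_daily" if i % 2 else
                   "less_than_daily_or_unreported")
            for i in range(10)]
    d = build_design(ests, DesignSpec(
        continuous=(), categorical={"irrigation": "hydroponic_or_daily"}))
    assert d.names == ["intercept",
                       "irrigation[less_than_daily_or_unreported]"]
    assert d.X[:, 1].sum() == 5.0


def test_build_design_drops_and_lists_missing_moderators():
    ests = [mk_est(f"s{i}", 0.1, 0.01, day_temp=20.0 + i) for i in range(9)]
    ests.append(mk_est("s9", 0.1, 0.01, day_temp=None))
    d = build_design(ests, DesignSpec(continuous=("day_temp",),
                                      categorical={}))
    assert d.X.shape[0] == 9
    assert "s9" in d.dropped and "day_temp" in d.dropped["s9"]


def test_build_design_underdetermined():
    ests = [mk_est(f"s{i}", 0.1, 0.01) for i in range(3)]
    with pytest.raises(UnderDeterminedError):
        build_design(ests, DesignSpec(continuous=("log_vpd_ratio",),
                                      categorical={}))


# --- model selection -----------------------------------------------------


def _elimination_data(rng, k=60, strong=0.5):
    mods = {m: rng.uniform(-1, 1, k)
            for m in ("strong", "null_a", "null_b", "null_c")}
    v = rng.uniform(0.005, 0.03, k)
    L = rng.normal(-0.1 + strong * mods["strong"], np.sqrt(v + 0.01))
    return [EffectEstimate(f"s{i:03d}", float(L[i]), float(v[i]), "reported",
                           moderators={m: float(mods[m][i]) for m in mods})
            for i in range(k)]


def test_null_moderator_removed_before_strong_one(rng):
    ests = _elimination_data(rng)
    spec = DesignSpec(continuous=("strong", "null_a", "null_b", "null_c"),
                      categorical={})
    fit, trace = minimal_adequate_model(ests, spec, alpha=0.05)
    assert "strong" in fit.blocks and fit.blocks["strong"]
    removed = [r.removed for r in trace]
    assert "strong" not in removed
    assert all(r.pvalue > 0.05 for r in trace)


def test_elimination_is_deterministic(rng):
    ests = _elimination_data(rng)
    spec = DesignSpec(continuous=("strong", "null_a", "null_b", "null_c"),
                      categorical={})
    _, t1 = minimal_adequate_model(ests, spec)
    _, t2 = minimal_adequate_model(ests, spec)
    assert [r.removed for r in t1] == [r.removed for r in t2]


def test_elimination_gate_requires_enough_studies(rng):
    ests = _elimination_data(rng, k=15)
    with pytest.raises(ValueError, match="requires"):
        minimal_adequate_model(ests, DesignSpec(continuous=("strong",),
                                                categorical={}))


# --- single-factor grouping ----------------------------------------------


def _grouped_data(rng, delta, k_per=30):
    out = []
    for j, (lvl, mu) in enumerate([("woody", delta / 2),
                                   ("forb", -delta / 2)]):
        v = rng.uniform(0.005, 0.02, k_per)
        L = rng.normal(mu, np.sqrt(v + 0.0025))
        out += [EffectEstimate(f"g{j}{i:02d}", float(L[i]), float(v[i]),
                               "reported", species=f"sp{j}{i:02d}",
                               moderators={"growth_habit": lvl})
                for i in range(k_per)]
    return out


def test_single_factor_detects_group_contrast(rng):
    res = single_factor_analysis(_grouped_data(rng, delta=0.6),
                                 "growth_habit")
    assert res.qm_pvalue < 0.05
    assert res.blocks["growth_habit"]


def test_single_factor_one_level_errors(rng):
    ests = [EffectEstimate(f"s{i:02d}", 0.1, 0.01, "reported",
                           species=f"sp{i}",
                           moderators={"growth_habit": "forb"})
            for i in range(30)]
    with pytest.raises(ValueError, match="one level"):
        single_factor_analysis(ests, "growth_habit")


def test_single_factor_species_gate(rng):
    ests = _grouped_data(rng, delta=0.5, k_per=8)  # 16 species < 21
    with pytest.raises(ValueError, match="species"):
        single_factor_analysis(ests, "growth_habit")
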
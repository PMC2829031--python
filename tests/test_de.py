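import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import expression_config
from lncdev.de import (
    FitResult,
    adjust_bh,
    background_correct,
    call_de,
    call_expressed,
    compute_ma,
    estimate_variance_prior,
    fit_reference_design,
    moderate,
    normalize_between_arrays,
    normalize_within_array,
    run_de,
    trigamma_inverse,
)
from lncdev.simulate import simulate_expression, simulate_truth


def _spot_frame(rows):
    return pd.DataFrame(
        rows, columns=["array_id", "stage", "replicate", "probe_id",
                       "fg_ch1", "bg_ch1", "fg_ch2", "bg_ch2"]
    )


# ---------------------------------------------------------------------------
# background correction
# ---------------------------------------------------------------------------

def test_background_subtraction_and_floor():
    spots = _spot_frame([
        ("a1", "OLP", 1, "p1", 1000.0, 200.0, 500.0, 100.0),
        ("a1", "OLP", 1, "p2", 100.0, 150.0, 60.0, 50.0),
        ("a1", "OLP", 1, "p3", 30.0, 20.0, 90.0, 50.0),
    ])
    out = background_correct(spots)
    assert out.corrected_ch1.tolist() == [800.0, 5.0, 10.0]  # min positive 10 -> floor 5
    assert out.at_floor_ch1.tolist() == [False, True, False]


def test_floor_count_monotone_in_background_inflation():
    rng = np.random.default_rng(0)
    fg = rng.uniform(50, 500, 200)
    bg = rng.uniform(10, 200, 200)
    rows = [("a1", "OLP", 1, f"p{i}", fg[i], bg[i], fg[i], bg[i]) for i in range(200)]
    base = background_correct(_spot_frame(rows))
    rows2 = [("a1", "OLP", 1, f"p{i}", fg[i], 2 * bg[i], fg[i], 2 * bg[i]) for i in range(200)]
    inflated = background_correct(_spot_frame(rows2))
    assert inflated.at_floor_ch1.sum() >= base.at_floor_ch1.sum()


def test_all_zero_channel_raises():
    rows = [("a1", "OLP", 1, f"p{i}", 10.0, 20.0, 100.0, 10.0) for i in range(5)]
    with pytest.raises(ValueError, match="a1"):
        background_correct(_spot_frame(rows))


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _ma_frame(a, m, array_id="a1", stage="OLP"):
    return pd.DataFrame({
        "array_id": array_id, "stage": stage,
        "probe_id": [f"p{i}" for i in range(len(a))], "A": a, "M": m,
    })


def test_zero_m_unchanged_by_normalization():
    rng = np.random.default_rng(1)
    ma = _ma_frame(rng.uniform(6, 14, 200), np.zeros(200))
    out = normalize_within_array(ma)
    assert np.allclose(out.M, 0.0, atol=1e-12)


def test_normalization_removes_planted_cubic_bias():
    cfg = expression_config(seed=21, n_probes=1000, pi_de_mrna=0.0, pi_de_ncrna=0.0,
                            dye_bias_amplitude=0.6)
    truth = simulate_truth(cfg)
    spots = simulate_expression(truth, cfg)
    ma = compute_ma(background_correct(spots))
    one = ma[ma.array_id == "OLP_r1"]
    mask = ~one.probe_id.isin(set(truth.probes.probe_id[truth.probes.is_control]))
    out = normalize_within_array(one, fit_mask=mask)
    kept = out[mask.to_numpy()]
    decile_means = kept.groupby(pd.qcut(kept.A, 10), observed=True).M.mean()
    assert decile_means.abs().max() < 0.05


def test_normalization_is_idempotent():
    rng = np.random.default_rng(2)
    a = rng.uniform(6, 14, 300)
    m = 0.4 * (a - 10) ** 3 / 8 + rng.normal(0, 0.2, 300)
    ma = _ma_frame(a, m)
    once = normalize_within_array(ma)
    twice = normalize_within_array(once)
    assert np.max(np.abs(twice.M.to_numpy() - once.M.to_numpy())) < 1e-6


def test_degenerate_constant_a_subtracts_median():
    m = np.r_[np.ones(50), np.zeros(51)]
    ma = _ma_frame(np.full(101, 8.0), m)
    out = normalize_within_array(ma)
    assert np.allclose(out.M, m - np.median(m))


def test_between_array_scaling_closed_form():
    rng = np.random.default_rng(3)
    base = rng.normal(0, 1, 400)
    ma = pd.concat([
        _ma_frame(np.full(400, 8.0), 0.2 * base / np.median(np.abs(base - np.median(base))), "a1"),
        _ma_frame(np.full(400, 8.0), 0.8 * base / np.median(np.abs(base - np.median(base))), "a2"),
    ], ignore_index=True)
    out, scales = normalize_between_arrays(ma)
    assert scales["a1"] == pytest.approx(2.0, rel=1e-9)
    assert scales["a2"] == pytest.approx(0.5, rel=1e-9)
    mads = out.groupby("array_id").M.apply(lambda m: np.median(np.abs(m - np.median(m))))
    assert abs(mads["a1"] - mads["a2"]) < 1e-9


def test_equal_mad_arrays_are_fixed_point():
    rng = np.random.default_rng(4)
    base = rng.normal(0, 0.3, 300)
    ma = pd.concat(
        [_ma_frame(np.full(300, 8.0), base, f"a{i}") for i in range(3)],
        ignore_index=True,
    )
    _, scales = normalize_between_arrays(ma)
    assert np.allclose(scales.to_numpy(), 1.0, atol=1e-9)


# ---------------------------------------------------------------------------
# expressed calls
# ---------------------------------------------------------------------------

def _expression_fixture():
    rows = []
    for stage in ("NOP", "OLP"):
        for rep in (1, 2, 3):
            aid = f"{stage}_r{rep}"
            for i in range(12):
                rows.append((aid, stage, rep, f"ctrl_{i:02d}", 50.0 + i, 10.0, 50.0 + i, 10.0))
            rows.append((aid, stage, rep, "bright", 5000.0, 10.0, 500.0, 10.0))
            rows.append((aid, stage, rep, "dim", 45.0, 10.0, 45.0, 10.0))
    return background_correct(_spot_frame(rows))


def test_expressed_calls():
    corrected = _expression_fixture()
    ctrl = {f"ctrl_{i:02d}" for i in range(12)}
    expressed = call_expressed(corrected, ctrl)
    assert bool(expressed["bright"]) is True
    assert bool(expressed["dim"]) is False
    with pytest.raises(ValueError, match="negative-control"):
        call_expressed(corrected, {"nonexistent"})


# ---------------------------------------------------------------------------
# linear fit and moderation
# ---------------------------------------------------------------------------

def _single_contrast_fit(m_values, n_extra_probes=0, extra_s2=0.05):
    rows = []
    for rep, m in enumerate(m_values, 1):
        rows.append({"array_id": f"OLP_r{rep}", "stage": "OLP",
                     "probe_id": "p0", "M": m, "A": 10.0})
        for j in range(n_extra_probes):
            rows.append({"array_id": f"OLP_r{rep}", "stage": "OLP",
                         "probe_id": f"q{j}", "M": np.sqrt(extra_s2) * (rep - 2), "A": 10.0})
    return fit_reference_design(pd.DataFrame(rows), contrasts=("OLP",))


def test_reference_fit_hand_arithmetic():
    fit = _single_contrast_fit([1.0, 1.2, 0.8])
    assert fit.coefficients.loc["p0", "OLP"] == pytest.approx(1.0)
    assert fit.s2["p0"] == pytest.approx(0.04)
    assert fit.df_residual["p0"] == 2


def test_identical_replicates_zero_variance():
    fit = _single_contrast_fit([0.7, 0.7, 0.7])
    assert fit.s2["p0"] == pytest.approx(0.0)


def test_fit_invariant_to_replicate_order():
    rows = []
    rng = np.random.default_rng(5)
    for rep in (1, 2, 3):
        for i in range(20):
            rows.append({"array_id": f"OLP_r{rep}", "stage": "OLP",
                         "probe_id": f"p{i}", "M": rng.normal(), "A": 10.0})
    df = pd.DataFrame(rows)
    f1 = fit_reference_design(df, contrasts=("OLP",))
    f2 = fit_reference_design(df.sample(frac=1, random_state=0), contrasts=("OLP",))
    pd.testing.assert_frame_equal(f1.coefficients, f2.coefficients)
    pd.testing.assert_series_equal(f1.s2, f2.s2)


def test_ordinary_t_recovered_when_prior_df_zero():
    fit = _single_contrast_fit([1.0, 1.2, 0.8], n_extra_probes=120)
    table, _ = moderate(fit, d0=0)
    t = table[table.probe_id == "p0"].t_mod.iloc[0]
    # ordinary t = 1.0 / (0.2 / sqrt(3)) = 5 * sqrt(3) ~ 8.660
    assert abs(t - 5.0 * np.sqrt(3.0)) < 1e-10


def test_fully_pooled_variance_when_prior_df_infinite():
    fit = _single_contrast_fit([1.0, 1.2, 0.8], n_extra_probes=120)
    table, hyper = moderate(fit, d0=np.inf, s0_sq=0.09)
    # every probe uses s_tilde^2 = s0_sq: t = M / sqrt(0.09 / 3)
    t = table[table.probe_id == "p0"].t_mod.iloc[0]
    assert t == pytest.approx(1.0 / np.sqrt(0.09 / 3.0))
    assert hyper.s0_sq == 0.09


def test_b_statistic_monotone_in_abs_t():
    coefs = np.linspace(-4, 4, 81)
    idx = pd.Index([f"p{i}" for i in range(81)], name="probe_id")
    fit = FitResult(
        coefficients=pd.DataFrame({"OLP": coefs}, index=idx),
        amean=pd.Series(10.0, index=idx),
        s2=pd.Series(0.04, index=idx),
        df_residual=pd.Series(2, index=idx),
        n_per_contrast=pd.DataFrame({"OLP": 3}, index=idx),
    )
    table, _ = moderate(fit, d0=4.0, s0_sq=0.04)
    order = np.argsort(np.abs(table.t_mod.to_numpy()))
    b_sorted = table.B.to_numpy()[order]
    assert (np.diff(b_sorted) > -1e-12).all()


def test_variance_prior_estimator_recovers_truth():
    from scipy import stats
    from scipy.special import polygamma

    rng = np.random.default_rng(6)
    d0, s0, df = 4.0, 0.02, 10
    # s^2 ~ s0^2 F(df, d0) under the scaled inverse-chi-square prior
    s2 = s0 * stats.f(dfn=df, dfd=d0).rvs(5000, random_state=rng)
    d0_hat, s0_hat = estimate_variance_prior(s2, np.full(5000, df))
    assert abs(d0_hat - d0) / d0 < 0.3
    assert abs(s0_hat - s0) / s0 < 0.3
    assert trigamma_inverse(float(polygamma(1, 3.0))) == pytest.approx(3.0, rel=1e-6)


def test_moderation_matches_limma_on_shared_matrix(tmp_path):
    """Independent cross-check: the moderated t, p and variance prior must
    reproduce the reference empirical-Bayes implementation (limma, via R)
    on the same data matrix."""
    rng = np.random.default_rng(7)
    n, reps = 150, 3
    sigma2 = 4.0 * 0.05 / rng.chisquare(4.0, n)
    beta = np.where(rng.random(n) < 0.1, rng.normal(0, 1.5, n), 0.0)
    mat = beta[:, None] + rng.normal(0, 1, (n, reps)) * np.sqrt(sigma2)[:, None]
    mpath = tmp_path / "m.tsv"
    np.savetxt(mpath, mat, delimiter="\t")
    rscript = f"""
    suppressMessages(library(limma))
    M <- as.matrix(read.table('{mpath}'))
    fit <- lmFit(M, design=matrix(1, ncol(M), 1))
    eb <- eBayes(fit, proportion=0.01)
    write.table(data.frame(t=eb$t[,1], p=eb$p.value[,1], d0=eb$df.prior, s0=eb$s2.prior),
                '{tmp_path / "out.tsv"}', sep='\t', row.names=FALSE)
    """
    subprocess.run(["Rscript", "-e", rscript], check=True, capture_output=True)
    ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
    idx = pd.Index([f"p{i}" for i in range(n)], name="probe_id")
    fit = FitResult(
        coefficients=pd.DataFrame({"C": mat.mean(1)}, index=idx),
        amean=pd.Series(10.0, index=idx),
        s2=pd.Series(mat.var(1, ddof=1), index=idx),
        df_residual=pd.Series(reps - 1, index=idx),
        n_per_contrast=pd.DataFrame({"C": reps}, index=idx),
    )
    table, hyper = moderate(fit, p_prior=0.01)
    assert hyper.d0 == pytest.approx(ref.d0.iloc[0], rel=1e-5)
    assert hyper.s0_sq == pytest.approx(ref.s0.iloc[0], rel=1e-5)
    assert np.abs(table.t_mod.to_numpy() - ref.t.to_numpy()).max() < 1e-8
    assert np.abs(table.p_value.to_numpy() - ref.p.to_numpy()).max() < 1e-8


# ---------------------------------------------------------------------------
# multiple testing and calls
# ---------------------------------------------------------------------------

def test_bh_step_up_examples():
    assert np.allclose(adjust_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
    assert np.allclose(adjust_bh([1.0, 1.0, 1.0]), 1.0)
    assert adjust_bh([0.37])[0] == pytest.approx(0.37)
    out = adjust_bh([0.01, np.nan, 0.5])
    assert np.isnan(out[1]) and np.isfinite(out[0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
def test_bh_output_within_unit_interval_and_order_preserving(pvals):
    out = adjust_bh(pvals)
    assert ((out >= 0) & (out <= 1)).all()
    order = np.argsort(pvals)
    assert (np.diff(out[order]) > -1e-12).all()


def test_de_call_strict_boundary():
    table = pd.DataFrame({
        "probe_id": ["a", "b", "c"], "contrast": "OLP",
        "M": [1.0, 1.0, -1.0], "B": [1.5, 1.0, 2.0],
    })
    expressed = pd.Series({"a": True, "b": True, "c": False})
    out = call_de(table, expressed)
    assert out.de_call.tolist() == [True, False, False]  # B = 1 exactly is not DE
    assert out.direction.tolist() == [1, 1, -1]


def test_null_simulation_false_positive_control():
    cfg = expression_config(seed=22, n_probes=600, pi_de_mrna=0.0, pi_de_ncrna=0.0)
    truth = simulate_truth(cfg)
    spots = simulate_expression(truth, cfg)
    table, _, _ = run_de(spots, set(truth.probes.probe_id[truth.probes.is_control]))
    assert (table.B > 1).mean() <= 0.01
    assert table.de_call.mean() <= 0.01


def test_fdr_control_with_planted_effects():
    cfg = expression_config(seed=23, n_probes=2000, pi_de_mrna=0.1, pi_de_ncrna=0.1,
                            lfc_range=(1.0, 2.0))
    truth = simulate_truth(cfg)
    spots = simulate_expression(truth, cfg)
    table, _, _ = run_de(spots, set(truth.probes.probe_id[truth.probes.is_control]))
    truth_de = truth.expected_de().stack()
    truth_de.index.names = ["probe_id", "contrast"]
    merged = table.set_index(["probe_id", "contrast"]).join(truth_de.rename("truth"))
    calls = merged[merged.adj_p < 0.05]
    fdp = (~calls.truth).mean()
    se = np.sqrt(0.05 * 0.95 / len(calls))
    assert fdp <= 0.05 + 2 * se
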
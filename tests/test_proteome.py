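"""Spectrum-count filtering, calibration, trajectories, and temporal fits."""

import numpy as np
import pandas as pd
import pytest

from polystress import (
    SimulationConfig,
    assign_labels,
    calibrate_samples,
    filter_detected,
    fit_temporal,
    fit_temporal_matrix,
    log2_trajectories,
    simulate_spectrum_counts,
)

TIMES6 = np.array([0, 15, 30, 60, 120, 180], dtype=float)


def _matrix(values, samples=None):
    values = np.atleast_2d(values)
    samples = samples or [
        f"stress:{int(t)}:{r}" for t in TIMES6 for r in (1, 2)
    ][: values.shape[1]]
    return pd.DataFrame(
        values, index=[f"prot{i}" for i in range(values.shape[0])], columns=samples
    )


# --- detection filter ---------------------------------------------------

def test_filter_requires_all_samples_and_peptides():
    counts = _matrix(
        [
            [5] * 12,          # kept
            [5] * 11 + [0],    # zero in one sample -> excluded
            [5] * 12,          # only 1 unique peptide -> excluded
        ]
    )
    peptides = pd.Series([3, 3, 1], index=counts.index)
    kept = filter_detected(counts, peptides)
    assert list(kept.index) == ["prot0"]
    lenient = filter_detected(counts, peptides, require_all_samples=False)
    assert list(lenient.index) == ["prot0", "prot1"]


def test_filter_monotone_in_strictness():
    rng = np.random.default_rng(0)
    counts = _matrix(rng.poisson(3, size=(50, 12)))
    peptides = pd.Series(rng.integers(1, 6, size=50), index=counts.index)
    sizes = [
        len(filter_detected(counts, peptides, min_unique_peptides=k))
        for k in (1, 2, 3, 4)
    ]
    assert sizes == sorted(sizes, reverse=True)
    assert len(filter_detected(counts, peptides, require_all_samples=True)) <= len(
        filter_detected(counts, peptides, require_all_samples=False)
    )


def test_filter_empty_matrix_warns():
    with pytest.warns(UserWarning):
        out = filter_detected(_matrix(np.empty((0, 12))), pd.Series(dtype=float))
    assert out.empty


# --- calibration --------------------------------------------------------

def test_calibration_identity_and_closed_form():
    control = np.array([10.0, 20, 30, 40])
    cols = np.column_stack([control] * 11 + [2 * control])
    counts = pd.DataFrame(cols, index=list("abcd"),
                          columns=[f"s:{i}:1" for i in range(12)])
    # every column equals the protein-wise mean except the doubled one
    factors, calibrated = calibrate_samples(counts)
    # closed form: a_s = sum(x*c)/sum(x^2)
    c = counts.to_numpy().mean(axis=1)
    for j, col in enumerate(counts.columns):
        x = counts[col].to_numpy()
        assert factors[col] == pytest.approx((x * c).sum() / (x**2).sum(), abs=1e-12)


def test_calibration_sample_equal_to_control_gets_unit_gain():
    control = np.array([10.0, 20, 30, 40])
    counts = pd.DataFrame(
        np.column_stack([control, control, control]),
        index=list("abcd"), columns=["s:0:1", "s:1:1", "s:2:1"],
    )
    factors, _ = calibrate_samples(counts)
    np.testing.assert_allclose(factors, 1.0)


def test_calibration_scale_equivariance():
    """Multiplying one sample by c divides its fitted gain by c exactly."""
    rng = np.random.default_rng(1)
    counts = _matrix(rng.poisson(50, size=(30, 12)).astype(float))
    f0, _ = calibrate_samples(counts)
    scaled = counts.copy()
    scaled.iloc[:, 3] *= 2.5
    # fix the control vector by comparing against manual closed form
    x = scaled.to_numpy()
    control = x.mean(axis=1)
    a3 = (x[:, 3] * control).sum() / (x[:, 3] ** 2).sum()
    f1, _ = calibrate_samples(scaled)
    assert f1.iloc[3] == pytest.approx(a3, abs=1e-12)
    # equivariance with the control held fixed
    assert ((x[:, 3] / 2.5 * control).sum() / ((x[:, 3] / 2.5) ** 2).sum()
            ) == pytest.approx(a3 * 2.5, abs=1e-9)


def test_calibration_fixed_point():
    """Recalibrating a calibrated matrix yields gains ~ 1."""
    rng = np.random.default_rng(2)
    counts = _matrix(rng.poisson(100, size=(200, 12)).astype(float))
    counts *= rng.uniform(0.5, 2.0, size=12)  # per-sample gains
    _, calibrated = calibrate_samples(counts)
    again, _ = calibrate_samples(calibrated)
    np.testing.assert_allclose(again, 1.0, atol=0.02)


def test_calibration_rejects_zero_column():
    counts = _matrix([[0, 5, 5], [0, 5, 5]], samples=["a:0:1", "a:1:1", "a:2:1"])
    with pytest.raises(ValueError):
        calibrate_samples(counts)


def test_calibration_recovers_planted_scales():
    cfg = SimulationConfig(n_genes=2000, seed=13, planted_fractions={},
                           sample_scale_sd_log=0.2, count_depth=200)
    truth = assign_labels(cfg)
    sc = simulate_spectrum_counts(cfg, truth)
    factors, _ = calibrate_samples(sc.counts.astype(float))
    true = truth.scale_factors.to_numpy()
    est = factors.to_numpy()
    # gains recover the reciprocal planted scales up to one global factor
    ratio = est * true
    ratio /= np.exp(np.log(ratio).mean())
    np.testing.assert_allclose(ratio, 1.0, atol=0.02)


# --- log2 trajectories --------------------------------------------------

def test_trajectories_reference_and_averaging():
    counts = _matrix(
        [[10, 20, 20, 20, 10, 40, 10, 20, 10, 20, 10, 20]],
    )
    traj = log2_trajectories(counts, pseudocount=0)
    assert traj.loc["prot0", 0.0] == 0.0
    # t=15: rep1 20/10 -> 1.0, rep2 20/20 -> 0.0, averaged 0.5
    assert traj.loc["prot0", 15.0] == pytest.approx(0.5)
    # t=30: rep1 10/10 -> 0, rep2 40/20 -> 1, averaged 0.5
    assert traj.loc["prot0", 30.0] == pytest.approx(0.5)


def test_trajectories_constant_protein_is_flat():
    counts = _matrix([[7] * 12])
    traj = log2_trajectories(counts, pseudocount=0.5)
    np.testing.assert_allclose(traj.to_numpy(), 0.0)


def test_trajectories_require_reference():
    counts = _matrix([[5] * 4], samples=["s:15:1", "s:30:1", "s:15:2", "s:30:2"])
    with pytest.raises(ValueError):
        log2_trajectories(counts)


# --- temporal regression ------------------------------------------------

def test_fit_flat_trajectory_unchanged():
    fit = fit_temporal(np.zeros(6), TIMES6)
    assert fit.category == "unchanged"
    assert fit.F == 0.0 and not fit.significant


def test_fit_noiseless_linear_recovers_slope():
    y = 0.01 * TIMES6
    with pytest.warns(UserWarning):
        fit = fit_temporal(y, TIMES6)
    assert fit.category == "linear_up"
    assert fit.beta1 == pytest.approx(0.01, abs=1e-10)
    assert fit.beta2 == pytest.approx(0.0, abs=1e-10)
    assert fit.p == 0.0 and fit.significant


def test_fit_noiseless_quadratic_classified():
    y = 1e-4 * (TIMES6 - 90) ** 2
    with pytest.warns(UserWarning):
        fit = fit_temporal(y, TIMES6)
    assert fit.category == "quadratic_convex"
    assert fit.beta2 == pytest.approx(1e-4, abs=1e-12)
    concave = -(TIMES6 / 180) * (TIMES6 / 180 - 2)  # bump, beta2 < 0
    with pytest.warns(UserWarning):
        fit2 = fit_temporal(concave, TIMES6)
    assert fit2.category == "quadratic_concave"


def test_fit_requires_enough_timepoints():
    with pytest.raises(ValueError):
        fit_temporal(np.zeros(3), TIMES6[:3])


def test_F_matches_statsmodels(rng):
    """Overall F agrees with an independent linear-model routine to 1e-8."""
    sm = pytest.importorskip("statsmodels.api")
    t = TIMES6
    z = (t - t.mean()) / t.std()
    X = sm.add_constant(np.column_stack([z, z**2]))
    Y = rng.normal(size=(300, 6)) + rng.normal(size=(300, 1)) * z
    res = fit_temporal_matrix(Y, t)
    for i in range(0, 300, 11):
        ols = sm.OLS(Y[i], X).fit()
        assert res["F"].iloc[i] == pytest.approx(ols.fvalue, abs=1e-8, rel=1e-8)
        assert res["p"].iloc[i] == pytest.approx(ols.f_pvalue, abs=1e-10)


def test_type_I_error_calibrated(rng):
    """Null Gaussian trajectories are rejected at ~alpha (small-scale check)."""
    n = 2000
    y12 = rng.normal(0, 0.3, size=(n, 12))
    y = 0.5 * (y12[:, ::2] + y12[:, 1::2])  # average duplicates
    res = fit_temporal_matrix(y, TIMES6, alpha=0.05)
    rate = res["significant"].mean()
    mcse = np.sqrt(0.05 * 0.95 / n)
    assert abs(rate - 0.05) < 4 * mcse


def test_category_recovery_on_synthetic_counts():
    """Planted linear/quadratic proteins get their true category back."""
    cfg = SimulationConfig(
        n_genes=1000, seed=21, count_depth=200,
        planted_fractions={
            "protein_linear_up": 0.1, "protein_linear_down": 0.1,
            "protein_convex": 0.1, "protein_concave": 0.1,
        },
    )
    truth = assign_labels(cfg)
    sc = simulate_spectrum_counts(cfg, truth)
    fits, _, _ = __import__("polystress").analyze_counts(
        sc.counts, sc.unique_peptides
    )
    merged = truth.genes.join(fits)
    for label, cat in [
        ("protein_linear_up", "linear_up"),
        ("protein_linear_down", "linear_down"),
        ("protein_convex", "quadratic_convex"),
        ("protein_concave", "quadratic_concave"),
    ]:
        sub = merged[merged["protein_label"] == label]
        assert (sub["category"] == cat).mean() >= 0.9, label
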
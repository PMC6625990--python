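"""Binding kinetics, steady-state binding, one-phase association, melts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flextail.kinetics import (combine_kinetics, fit_association,
                               fit_dissociation, fit_one_phase,
                               fit_steady_state, fold_change, melt_tm,
                               reference_subtract)
from flextail.structio import TraceTable
from flextail.synthetic import NoiseSpec, simulate_bli, simulate_melt

KA, KD_RATE = 1.3e5, 0.031   # reference 1:1 rates (M^-1 s^-1, s^-1)


def _split_phases(tt, col="conc_0"):
    t, y = tt.t, tt.signals[col]
    m = t <= tt.metadata["t_assoc"]
    return (t[m], y[m]), (t[~m], y[~m])


# ---------------------------------------------------------------------------
# reference subtraction


def test_reference_subtract_identity_and_zero():
    t = np.linspace(0, 10, 50)
    sample = TraceTable(t=t, signals={"s": np.sin(t)})
    zero_ref = TraceTable(t=t, signals={"r": np.zeros_like(t)})
    out = reference_subtract(sample, zero_ref)
    np.testing.assert_array_equal(out.signals["s"], np.sin(t))
    self_ref = TraceTable(t=t, signals={"r": np.sin(t)})
    out2 = reference_subtract(sample, self_ref)
    np.testing.assert_allclose(out2.signals["s"], 0.0, atol=1e-15)


def test_reference_subtract_removes_planted_drift():
    noise_sd = 0.01
    tt = simulate_bli(KA, KD_RATE, 1.0, [1e-6],
                      noise=NoiseSpec(trace_sd=noise_sd, seed=4))
    drift = 0.002 * tt.t
    drifted = TraceTable(t=tt.t,
                         signals={"conc_0": tt.signals["conc_0"] + drift},
                         concentrations=dict(tt.concentrations),
                         metadata=dict(tt.metadata))
    ref = TraceTable(t=tt.t, signals={"ref": drift})
    out = reference_subtract(drifted, ref)
    resid = out.signals["conc_0"] - tt.signals["conc_0"]
    assert np.abs(resid).max() < noise_sd


def test_reference_subtract_disjoint_ranges_error():
    a = TraceTable(t=np.linspace(0, 1, 20), signals={"s": np.zeros(20)})
    b = TraceTable(t=np.linspace(5, 6, 20), signals={"r": np.zeros(20)})
    with pytest.raises(ValueError, match="overlap"):
        reference_subtract(a, b)


# ---------------------------------------------------------------------------
# dissociation / association


def test_dissociation_exact_recovery():
    tt = simulate_bli(KA, KD_RATE, 1.0, [1e-6],
                      noise=NoiseSpec(trace_sd=0.0))
    _, dissoc = _split_phases(tt)
    fit = fit_dissociation(dissoc)
    assert fit.k_d == pytest.approx(KD_RATE, abs=1e-6)


def test_dissociation_flat_trace_errors():
    t = np.linspace(0, 10, 30)
    with pytest.raises(ValueError, match="decay"):
        fit_dissociation((t, np.ones_like(t)))


def test_dissociation_noisy_replicates_within_2pct():
    vals = []
    for seed in range(100):
        tt = simulate_bli(KA, KD_RATE, 1.0, [1e-6],
                          noise=NoiseSpec(trace_sd=0.01, seed=seed))
        _, dissoc = _split_phases(tt)
        vals.append(fit_dissociation(dissoc).k_d)
    assert np.mean(vals) == pytest.approx(KD_RATE, rel=0.02)


def test_association_eq1_arithmetic():
    # k_obs = 0.05, k_d = 0.031, C = 1e-7 M -> k_a = 1.9e5
    t = np.linspace(0, 120, 200)
    y = 0.8 * (1 - np.exp(-0.05 * t))
    fit = fit_association((t, y), 1e-7, 0.031)
    assert fit.k_obs == pytest.approx(0.05, rel=1e-4)
    assert fit.k_a == pytest.approx(1.9e5, rel=1e-3)


def test_association_noiseless_recovery():
    tt = simulate_bli(KA, KD_RATE, 1.0, [1e-6],
                      noise=NoiseSpec(trace_sd=0.0))
    assoc, _ = _split_phases(tt)
    fit = fit_association(assoc, 1e-6, KD_RATE)
    assert fit.k_obs == pytest.approx(0.161, rel=0.005)
    assert fit.k_a == pytest.approx(KA, rel=0.005)


def test_association_kobs_below_kd_errors():
    t = np.linspace(0, 120, 200)
    y = 0.8 * (1 - np.exp(-0.01 * t))   # k_obs < k_d: mislabelled phases
    with pytest.raises(ValueError, match="non-physical"):
        fit_association((t, y), 1e-6, 0.031)


def test_kobs_affine_in_concentration():
    """Regression of fitted k_obs on C recovers slope k_a and intercept k_d
    within 2% on noiseless data."""
    concs = np.array([0.25, 0.5, 1.0, 2.0, 4.0]) * 1e-6
    tt = simulate_bli(KA, KD_RATE, 1.0, concs, noise=NoiseSpec(trace_sd=0.0))
    kobs = []
    for ci in range(len(concs)):
        t, y = tt.t, tt.signals[f"conc_{ci}"]
        m = t <= tt.metadata["t_assoc"]
        kobs.append(fit_association((t[m], y[m]), concs[ci], KD_RATE).k_obs)
    slope, intercept = np.polyfit(concs, kobs, 1)
    assert slope == pytest.approx(KA, rel=0.02)
    assert intercept == pytest.approx(KD_RATE, rel=0.02)


def test_full_bli_pipeline_recovers_KD_within_5pct():
    """subtract -> dissociation -> association per concentration ->
    mean-rate aggregation, at the reference rates with 1% noise and four
    concentrations, averaged over replicates."""
    concs = np.array([0.25, 0.5, 1.0, 2.0]) * 1e-6
    KD_true = KD_RATE / KA
    kds = []
    for seed in range(100):
        tt = simulate_bli(KA, KD_RATE, 1.0, concs,
                          noise=NoiseSpec(trace_sd=0.01, seed=seed))
        ref = TraceTable(t=tt.t, signals={"r": np.zeros_like(tt.t)})
        corr = reference_subtract(tt, ref)
        kas, kdvals = [], []
        for ci, C in enumerate(concs):
            t, y = corr.t, corr.signals[f"conc_{ci}"]
            m = t <= tt.metadata["t_assoc"]
            kd_i = fit_dissociation((t[~m], y[~m])).k_d
            ka_i = fit_association((t[m], y[m]), C, kd_i).k_a
            kas.append(ka_i)
            kdvals.append(kd_i)
        kds.append(combine_kinetics(kas, kdvals).K_D)
    assert np.mean(kds) == pytest.approx(KD_true, rel=0.05)


# ---------------------------------------------------------------------------
# aggregation


def test_combine_kinetics_reference_values():
    rc = combine_kinetics([1.3e5], [0.031])
    assert rc.K_D == pytest.approx(2.3846e-7, rel=1e-4)
    assert round(rc.K_D * 1e6, 2) == 0.24


def test_combine_kinetics_passthrough_and_mean():
    rc = combine_kinetics([2e5, 2e5], [0.02, 0.04])
    assert rc.k_a == 2e5 and rc.k_d == pytest.approx(0.03)
    assert rc.k_d_sd is not None and rc.n == 2


def test_combine_kinetics_empty_errors():
    with pytest.raises(ValueError):
        combine_kinetics([], [0.03])


# ---------------------------------------------------------------------------
# steady state


def test_steady_state_exact_recovery():
    KD = 0.27e-6
    C = np.array([0.05, 0.1, 0.27, 0.5, 1.0, 3.0]) * 1e-6
    R = 1.8 * C / (KD + C)
    fit = fit_steady_state(C, R)
    assert fit.K_D == pytest.approx(KD, rel=0.01)
    # fitted curve passes Bmax/2 at C = K_D
    assert fit.Bmax * fit.K_D / (fit.K_D + fit.K_D) == pytest.approx(
        fit.Bmax / 2)


def test_steady_state_noisy_replicates_within_3pct():
    KD = 0.27e-6
    C = np.array([0.05, 0.1, 0.27, 0.5, 1.0, 3.0]) * 1e-6
    R0 = 1.8 * C / (KD + C)
    rng_master = np.random.default_rng(0)
    vals = []
    for _ in range(200):
        R = R0 * (1 + 0.02 * rng_master.standard_normal(len(C)))
        vals.append(fit_steady_state(C, R).K_D)
    assert np.mean(vals) == pytest.approx(KD, rel=0.03)


def test_steady_state_linear_regime_warns():
    C = np.array([1, 2, 3, 4, 5]) * 1e-9   # far below K_D: linear response
    R = 1e6 * C
    with pytest.warns(UserWarning, match="linear"):
        fit = fit_steady_state(C, R)
    assert fit.wide_confidence


# ---------------------------------------------------------------------------
# one-phase association


def test_one_phase_exact():
    t = np.linspace(0, 400, 300)
    y = 3.0 + 1.5 * (1 - np.exp(-0.02 * t))
    fit = fit_one_phase((t, y))
    assert fit.k == pytest.approx(0.02, abs=1e-6)


def test_one_phase_offset_invariance():
    t = np.linspace(0, 400, 300)
    y = 1.5 * (1 - np.exp(-0.02 * t))
    k0 = fit_one_phase((t, y)).k
    k1 = fit_one_phase((t, y + 57.0)).k
    assert k0 == pytest.approx(k1, rel=1e-6)


def test_one_phase_zero_amplitude_errors():
    t = np.linspace(0, 100, 50)
    with pytest.raises(ValueError, match="amplitude"):
        fit_one_phase((t, np.full_like(t, 2.0)))


# ---------------------------------------------------------------------------
# melts


def test_melt_tm_both_methods():
    tt = simulate_melt(52.5, 2.0, 0.0, 1.0, noise=NoiseSpec(trace_sd=0.0))
    fit = melt_tm(tt)
    assert fit.Tm_sigmoid == pytest.approx(52.5, abs=0.2)
    assert fit.Tm_derivative == pytest.approx(52.5, abs=0.2)
    assert fit.Tm == fit.Tm_sigmoid


def test_melt_delta_tm_nine_degrees():
    """Two melts set 9 °C apart (the ligand-stabilization scenario) give a
    ΔTm of 9 ± 0.3 °C."""
    a = melt_tm(simulate_melt(52.5, 2.0, 0.0, 1.0,
                              noise=NoiseSpec(trace_sd=0.01, seed=1))).Tm
    b = melt_tm(simulate_melt(61.5, 2.0, 0.0, 1.0,
                              noise=NoiseSpec(trace_sd=0.01, seed=2))).Tm
    assert b - a == pytest.approx(9.0, abs=0.3)


def test_melt_temperature_shift_equivariance():
    delta = 4.0
    base = simulate_melt(52.5, 2.0, 0.0, 1.0, noise=NoiseSpec(trace_sd=0.0))
    shifted = TraceTable(t=base.t + delta, signals=dict(base.signals))
    f0 = melt_tm(base)
    f1 = melt_tm(shifted)
    assert f1.Tm - f0.Tm == pytest.approx(delta, abs=1e-6)


def test_melt_flat_curve_errors():
    T = np.linspace(30, 60, 31)
    with pytest.raises(ValueError):
        melt_tm((T, np.full(31, 5.0)), method="sigmoid")


# ---------------------------------------------------------------------------
# fold change


def test_fold_change_reference_values():
    # 2.3 µM over 24 nM: printed as about 100-fold
    fc = fold_change(2.3e-6, 24e-9)
    assert fc == pytest.approx(95.83, abs=0.01)


@settings(derandomize=True, max_examples=30)
@given(a=st.floats(1e-9, 1e-3), b=st.floats(1e-9, 1e-3))
def test_fold_change_reciprocal_symmetry(a, b):
    assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)
    assert fold_change(a, a) == 1.0
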
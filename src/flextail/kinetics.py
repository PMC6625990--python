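"""Binding and thermal-stability computations.

Biolayer interferometry (BLI) traces are analysed with the 1:1 Langmuir
model: the dissociation phase gives k_d from R(t) = R0 e^(−k_d t); each
association phase gives k_obs from R(t) = R_eq (1 − e^(−k_obs t)), and
k_a = (k_obs − k_d)/C.  Replicates combine as mean k_a, mean k_d and
K_D = mean k_d / mean k_a.  Steady-state responses fit one-site specific
binding R = Bmax C/(K_D + C).  Nucleotide-exchange fluorescence fits
one-phase association, and thermal melts yield Tm either from a Boltzmann
sigmoid midpoint or from the maximum of the smoothed first derivative.

Fits are unweighted least squares; the association model includes a free
baseline and the dissociation model a free plateau (typical instrument
behaviour the raw traces carry).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .structio import TraceTable

__all__ = [
    "RateConstants",
    "DissocFit",
    "AssocFit",
    "SteadyStateFit",
    "OnePhaseFit",
    "MeltFit",
    "reference_subtract",
    "fit_dissociation",
    "fit_association",
    "combine_kinetics",
    "fit_steady_state",
    "fit_one_phase",
    "melt_tm",
    "fold_change",
]


@dataclass
class RateConstants:
    """1:1 binding rate constants; K_D = k_d / k_a by construction."""

    k_a: float                      # M^-1 s^-1
    k_d: float                      # s^-1
    K_D: float                      # M
    k_a_sd: float | None = None
    k_d_sd: float | None = None
    n: int = 1

    def __post_init__(self):
        if self.k_a <= 0 or self.k_d <= 0 or self.K_D <= 0:
            raise ValueError("rate constants must be positive")
        if abs(self.K_D - self.k_d / self.k_a) / self.K_D > 1e-9:
            raise ValueError("K_D inconsistent with k_d / k_a")


@dataclass
class DissocFit:
    k_d: float
    r0: float
    plateau: float
    residual_norm: float


@dataclass
class AssocFit:
    k_obs: float
    k_a: float
    r_eq: float
    baseline: float
    residual_norm: float

    def __post_init__(self):
        if self.k_obs <= 0:
            raise ValueError("k_obs must be positive")


@dataclass
class SteadyStateFit:
    K_D: float
    Bmax: float
    residual_norm: float
    wide_confidence: bool = False


@dataclass
class OnePhaseFit:
    k: float
    y0: float
    amplitude: float
    residual_norm: float


@dataclass
class MeltFit:
    Tm: float                      # °C, headline (sigmoid unless asked otherwise)
    method: str
    Tm_sigmoid: float | None = None
    Tm_derivative: float | None = None
    slope: float | None = None
    residual_norm: float | None = None


def reference_subtract(sample: TraceTable, reference: TraceTable,
                       reference_column: str | None = None) -> TraceTable:
    """Subtract a reference-sensor trace from every sample column
    (baseline drift / non-specific binding correction).

    The reference is interpolated onto the sample time grid; the grids must
    overlap.
    """
    if reference_column is None:
        reference_column = next(iter(reference.signals))
    ref_t, ref_y = reference.t, reference.signals[reference_column]
    t = sample.t
    if t[-1] < ref_t[0] or t[0] > ref_t[-1]:
        raise ValueError("sample and reference time ranges do not overlap")
    ref_interp = np.interp(t, ref_t, ref_y)
    corrected = {name: y - ref_interp for name, y in sample.signals.items()}
    return TraceTable(t=t.copy(), signals=corrected,
                      concentrations=dict(sample.concentrations),
                      metadata=dict(sample.metadata))


def _trace_xy(trace, column=None):
    if isinstance(trace, TraceTable):
        if column is None:
            column = next(iter(trace.signals))
        return trace.t, trace.signals[column]
    t, y = trace
    return np.asarray(t, dtype=float), np.asarray(y, dtype=float)


def fit_dissociation(trace, column: str | None = None) -> DissocFit:
    """Fit the dissociation phase R(t) = plateau + R0 e^(−k_d t)."""
    t, y = _trace_xy(trace, column)
    if len(t) < 10:
        raise ValueError("need >= 10 points for a dissociation fit")
    t = t - t[0]
    head = y[: max(3, len(y) // 10)].mean()
    tail = y[-max(3, len(y) // 10):].mean()
    if head <= tail + 1e-12 * max(abs(head), 1.0):
        raise ValueError("trace is not decaying; no dissociation phase")

    def model(t, r0, k, c):
        return c + r0 * np.exp(-k * t)

    span = max(head - tail, np.finfo(float).tiny)
    k0 = 1.0 / max(t[-1] / 3.0, np.finfo(float).tiny)
    popt, _ = curve_fit(model, t, y, p0=[span, k0, tail],
                        bounds=([0, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                        maxfev=10000)
    resid = float(np.linalg.norm(y - model(t, *popt)))
    return DissocFit(k_d=float(popt[1]), r0=float(popt[0]),
                     plateau=float(popt[2]), residual_norm=resid)


def fit_association(trace, concentration: float, k_d: float,
                    column: str | None = None) -> AssocFit:
    """Fit the association phase R(t) = baseline + R_eq (1 − e^(−k_obs t)) and
    convert to k_a = (k_obs − k_d)/C (1:1 model)."""
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    t, y = _trace_xy(trace, column)
    if len(t) < 10:
        raise ValueError("need >= 10 points for an association fit")
    t = t - t[0]

    def model(t, req, kobs, b):
        return b + req * (1.0 - np.exp(-kobs * t))

    span = y[-max(3, len(y) // 10):].mean() - y[: max(3, len(y) // 10)].mean()
    k0 = 1.0 / max(t[-1] / 3.0, np.finfo(float).tiny)
    popt, _ = curve_fit(model, t, y, p0=[max(span, 1e-9), k0, y[0]],
                        bounds=([0, 1e-12, -np.inf], [np.inf, np.inf, np.inf]),
                        maxfev=10000)
    k_obs = float(popt[1])
    if k_obs <= k_d:
        raise ValueError(
            f"k_obs ({k_obs:.4g} s^-1) <= k_d ({k_d:.4g} s^-1): non-physical "
            "for a 1:1 model; check concentration/phase labelling"
        )
    k_a = (k_obs - k_d) / concentration
    resid = float(np.linalg.norm(y - model(t, *popt)))
    return AssocFit(k_obs=k_obs, k_a=k_a, r_eq=float(popt[0]),
                    baseline=float(popt[2]), residual_norm=resid)


def combine_kinetics(k_a_values, k_d_values) -> RateConstants:
    """Aggregate replicate rates: mean k_a, mean k_d, K_D = mean k_d / mean k_a
    (the mean-rates convention, not a mean of per-trace K_D values)."""
    ka = np.asarray(list(k_a_values), dtype=float)
    kd = np.asarray(list(k_d_values), dtype=float)
    if len(ka) == 0 or len(kd) == 0:
        raise ValueError("empty rate lists")
    k_a, k_d = float(ka.mean()), float(kd.mean())
    return RateConstants(
        k_a=k_a, k_d=k_d, K_D=k_d / k_a,
        k_a_sd=float(ka.std(ddof=1)) if len(ka) >= 2 else None,
        k_d_sd=float(kd.std(ddof=1)) if len(kd) >= 2 else None,
        n=len(ka),
    )


def fit_steady_state(concentrations, responses) -> SteadyStateFit:
    """One-site specific binding: R = Bmax C / (K_D + C)."""
    C = np.asarray(concentrations, dtype=float)
    R = np.asarray(responses, dtype=float)
    if len(C) < 4:
        raise ValueError("need >= 4 concentrations")

    def model(c, bmax, kd):
        return bmax * c / (kd + c)

    popt, _ = curve_fit(model, C, R, p0=[R.max(), np.median(C)],
                        bounds=([0, 1e-30], [np.inf, np.inf]), maxfev=10000)
    resid = float(np.linalg.norm(R - model(C, *popt)))
    # linearity check: no saturation curvature over the sampled range
    lin = np.polyfit(C, R, 1)
    lin_resid = float(np.linalg.norm(R - np.polyval(lin, C)))
    wide = lin_resid <= 1.05 * resid
    if wide:
        warnings.warn("response is nearly linear in concentration: K_D poorly "
                      "constrained (wide confidence)", stacklevel=2)
    return SteadyStateFit(K_D=float(popt[1]), Bmax=float(popt[0]),
                          residual_norm=resid, wide_confidence=wide)


def fit_one_phase(trace, column: str | None = None) -> OnePhaseFit:
    """One-phase association y = y0 + A (1 − e^(−k t)) (e.g. GTPγS-induced
    tryptophan fluorescence rise)."""
    t, y = _trace_xy(trace, column)
    t = t - t[0]
    span = y[-max(3, len(y) // 10):].mean() - y[: max(3, len(y) // 10)].mean()
    scale = max(abs(y).max(), 1.0)
    if abs(span) < 1e-9 * scale:
        raise ValueError("degenerate trace: zero amplitude")

    def model(t, y0, a, k):
        return y0 + a * (1.0 - np.exp(-k * t))

    k0 = 1.0 / max(t[-1] / 3.0, np.finfo(float).tiny)
    popt, _ = curve_fit(model, t, y, p0=[y[0], span, k0], maxfev=10000)
    k = float(popt[2])
    if k * t[-1] < 1.0:
        warnings.warn("signal far from saturation; rate poorly determined",
                      stacklevel=2)
    resid = float(np.linalg.norm(y - model(t, *popt)))
    return OnePhaseFit(k=k, y0=float(popt[0]), amplitude=float(popt[1]),
                       residual_norm=resid)


def _boltzmann(T, f_low, f_high, tm, slope):
    return f_low + (f_high - f_low) / (1.0 + np.exp((tm - T) / slope))


def melt_tm(curve, method: str = "both", column: str | None = None) -> MeltFit:
    """Extract the melting temperature from a thermal-denaturation curve.

    ``method='sigmoid'`` fits a Boltzmann sigmoid and reports its midpoint;
    ``'derivative'`` takes the argmax of the Savitzky–Golay-smoothed dF/dT
    (window 5); ``'both'`` (default) computes both with the sigmoid midpoint
    as the headline value (more noise-robust).
    """
    T, F = _trace_xy(curve, column)
    if len(T) < 7:
        raise ValueError("need >= 7 temperature points")
    tm_deriv = tm_sig = None
    slope_out = resid = None
    if method in ("derivative", "both"):
        smooth = savgol_filter(F, window_length=5, polyorder=2)
        dF = np.gradient(smooth, T)
        idx = int(np.argmax(dF))
        if idx == 0 or idx == len(T) - 1:
            raise ValueError("no interior inflection in the scanned range")
        # parabolic refinement of the derivative peak (sub-grid precision)
        y0, y1, y2 = dF[idx - 1], dF[idx], dF[idx + 1]
        denom = y0 - 2 * y1 + y2
        shift = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-15 else 0.0
        shift = float(np.clip(shift, -1.0, 1.0))
        dT = 0.5 * (T[idx + 1] - T[idx - 1])
        tm_deriv = float(T[idx] + shift * dT)
    if method in ("sigmoid", "both"):
        span = F.max() - F.min()
        if span <= 0:
            raise ValueError("flat melt curve")
        p0 = [F.min(), F.max(), T[int(np.argmin(np.abs(F - F.mean())))], 2.0]
        popt, _ = curve_fit(_boltzmann, T, F, p0=p0, maxfev=10000)
        tm_sig = float(popt[2])
        slope_out = float(popt[3])
        resid = float(np.linalg.norm(F - _boltzmann(T, *popt)))
        if not (T[0] <= tm_sig <= T[-1]):
            raise ValueError("fitted Tm outside the scanned temperature range")
    headline = tm_sig if tm_sig is not None else tm_deriv
    return MeltFit(Tm=headline, method=method, Tm_sigmoid=tm_sig,
                   Tm_derivative=tm_deriv, slope=slope_out,
                   residual_norm=resid)


def fold_change(K_D_mut: float, K_D_wt: float) -> float:
    """Affinity fold change K_D(mutant) / K_D(reference)."""
    if K_D_mut <= 0 or K_D_wt <= 0:
        raise ValueError("dissociation constants must be positive")
    return K_D_mut / K_D_wt
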
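"""Small-angle X-ray scattering computation and fitting.

Theoretical profiles come from the Debye equation over point scatterers
(residue-level in Cα mode, per-element electron counts on all-atom input);
Guinier analysis estimates Rg from the low-q linear regime (q·Rg < 1.3);
model-vs-experiment agreement is the reduced chi-square with the analytic
least-squares scale; SEC-SAXS frames are reduced by peak/buffer averaging;
small conformational mixtures are fitted by exhaustive subset enumeration
with non-negative weights.

No hydration-shell or excluded-volume modeling is attempted: absolute
chi-square values against beamline data reduced with shell-aware tools are
therefore approximate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls
from scipy.spatial.distance import pdist

from .structio import SAXSCurve, Structure

__all__ = [
    "FormFactorModel",
    "GuinierFit",
    "ChiFit",
    "MultiStateFit",
    "debye_profile",
    "coordinate_rg",
    "guinier",
    "chi_square",
    "reduce_sec_saxs",
    "multistate_fit",
]

# effective electron counts for the common protein elements
_ELECTRONS = {"H": 1.0, "C": 6.0, "N": 7.0, "O": 8.0, "S": 16.0, "P": 15.0}


@dataclass(frozen=True)
class FormFactorModel:
    """Per-site scattering weights.

    In Cα mode every residue site scatters with a constant effective electron
    count (default 60, roughly the mean residue electron count); on all-atom
    input per-element electron counts are used.
    """

    residue_weight: float = 60.0
    mode: str = "calpha"  # "calpha" | "all-atom"

    def __post_init__(self):
        if self.residue_weight <= 0:
            raise ValueError("scattering weights must be positive")
        if self.mode not in ("calpha", "all-atom"):
            raise ValueError("mode must be 'calpha' or 'all-atom'")

    def sites(self, structure: Structure) -> tuple[np.ndarray, np.ndarray]:
        """Return (coordinates, weights) for the scattering sites."""
        if self.mode == "calpha":
            xyz = structure.ca_coords()
            if len(xyz) == 0:  # input without CA naming: use every atom
                xyz = structure.coords()
            w = np.full(len(xyz), self.residue_weight)
        else:
            xyz = structure.coords()
            w = np.array([
                _ELECTRONS.get(a.element.upper(), 6.0) for a in structure.atoms
            ])
        return xyz, w


@dataclass
class GuinierFit:
    """Result of iterative Guinier analysis on the low-q regime."""

    rg: float          # Å
    i0: float
    q_min: float
    q_max: float
    n_points: int
    r_squared: float
    converged: bool


@dataclass
class ChiFit:
    """Analytic-scale chi-square fit of a model profile to an experiment."""

    scale: float
    chi2: float


@dataclass
class MultiStateFit:
    """Best subset of candidate profiles explaining an experimental curve."""

    members: tuple[int, ...]
    weights: np.ndarray      # non-negative, sums to 1
    scale: float
    chi2: float


def debye_profile(
    structure: Structure,
    q_grid: np.ndarray,
    form: FormFactorModel = FormFactorModel(),
) -> np.ndarray:
    """Debye-equation scattering profile of a structure.

    I(q) = sum_i sum_j f_i f_j sin(q d_ij)/(q d_ij), with the q -> 0 and
    d -> 0 limits taken as 1, so I(0) = (sum f_i)^2.
    """
    q = np.asarray(q_grid, dtype=float)
    if q.ndim != 1 or np.any(np.diff(q) <= 0):
        raise ValueError("q_grid must be 1-D ascending")
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    if len(structure) == 0:
        raise ValueError("empty structure")
    xyz, w = form.sites(structure)
    return _debye_from_sites(xyz, w, q)


def _debye_from_sites(xyz: np.ndarray, w: np.ndarray, q: np.ndarray) -> np.ndarray:
    n = len(xyz)
    diag = float(np.sum(w * w))
    if n == 1:
        return np.full(len(q), diag)
    d = pdist(xyz)
    iu = np.triu_indices(n, k=1)
    ww = (w[iu[0]] * w[iu[1]])
    # sin(x)/x via np.sinc (sinc(x) = sin(pi x)/(pi x))
    qd = np.outer(q, d)
    I = diag + 2.0 * (np.sinc(qd / np.pi) @ ww)
    return I


def coordinate_rg(structure: Structure,
                  form: FormFactorModel = FormFactorModel()) -> float:
    """Radius of gyration straight from coordinates (f-weighted second moment)."""
    xyz, w = form.sites(structure)
    com = np.average(xyz, axis=0, weights=w)
    return float(np.sqrt(np.average(np.sum((xyz - com) ** 2, axis=1), weights=w)))


def guinier(curve: SAXSCurve, qrg_max: float = 1.3, max_iter: int = 20) -> GuinierFit:
    """Iterative Guinier fit: ln I vs q² on a window shrunk to q·Rg < qrg_max.

    Starts from the lowest-q 40% of points (at least 5), refits until the
    Rg estimate changes by < 0.1% or ``max_iter`` is reached (warning).
    """
    q, I = curve.q, curve.I
    usable = I > 0
    if np.count_nonzero(usable) < 5:
        raise ValueError("need >= 5 points with positive intensity at low q")
    q, I = q[usable], I[usable]
    n0 = max(5, int(0.4 * len(q)))
    window = np.arange(min(n0, len(q)))
    rg_prev = None
    converged = False
    for _ in range(max_iter):
        qq, ll = q[window] ** 2, np.log(I[window])
        slope, intercept = np.polyfit(qq, ll, 1)
        if slope >= 0:
            raise ValueError("positive Guinier slope: no Guinier region found")
        rg = float(np.sqrt(-3.0 * slope))
        sel = np.flatnonzero(q * rg < qrg_max)
        if len(sel) < 5:
            sel = np.arange(5)
        if rg_prev is not None and abs(rg - rg_prev) / rg < 1e-3:
            converged = True
            window = sel
            break
        rg_prev = rg
        window = sel
    if not converged:
        warnings.warn("Guinier fit did not converge; returning last estimate",
                      stacklevel=2)
    qq, ll = q[window] ** 2, np.log(I[window])
    slope, intercept = np.polyfit(qq, ll, 1)
    rg = float(np.sqrt(-3.0 * slope))
    pred = slope * qq + intercept
    ss_res = float(np.sum((ll - pred) ** 2))
    ss_tot = float(np.sum((ll - ll.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return GuinierFit(
        rg=rg, i0=float(np.exp(intercept)),
        q_min=float(q[window][0]), q_max=float(q[window][-1]),
        n_points=len(window), r_squared=r2, converged=converged,
    )


def chi_square(model_I: np.ndarray, exp_curve: SAXSCurve) -> ChiFit:
    """Reduced chi-square of a model profile against an experimental curve,
    with the analytic least-squares scale:

    c = sum(I_e I_m / σ²) / sum(I_m² / σ²);
    χ² = (1/(N−1)) sum(((I_e − c I_m)/σ)²).
    """
    Im = np.asarray(model_I, dtype=float)
    if len(Im) != len(exp_curve):
        raise ValueError("model profile and experiment have different lengths")
    Ie, sig = exp_curve.I, exp_curve.sigma
    w = 1.0 / sig**2
    c = float(np.sum(Ie * Im * w) / np.sum(Im * Im * w))
    chi2 = float(np.sum(((Ie - c * Im) / sig) ** 2) / (len(Ie) - 1))
    return ChiFit(scale=c, chi2=chi2)


def reduce_sec_saxs(
    frames: list[SAXSCurve],
    peak_ids: list[int],
    buffer_ids: list[int],
) -> SAXSCurve:
    """Reduce SEC-SAXS frames: mean(peak frames) − mean(buffer frames), with
    uncertainties propagated in quadrature of the two standard errors."""
    if not peak_ids or not buffer_ids:
        raise ValueError("both peak and buffer frame sets must be non-empty")
    if set(peak_ids) & set(buffer_ids):
        raise ValueError("peak and buffer frame sets overlap")
    q0 = frames[0].q
    for f in frames:
        if len(f.q) != len(q0) or not np.allclose(f.q, q0):
            raise ValueError("all frames must share one q grid")
    peak = np.array([frames[i].I for i in peak_ids])
    buf = np.array([frames[i].I for i in buffer_ids])
    I = peak.mean(axis=0) - buf.mean(axis=0)
    # standard error of each set mean, propagated from the per-frame
    # uncertainties the frames carry
    sem_p = np.sqrt(np.sum([frames[i].sigma**2 for i in peak_ids], axis=0)) \
        / len(peak_ids)
    sem_b = np.sqrt(np.sum([frames[i].sigma**2 for i in buffer_ids], axis=0)) \
        / len(buffer_ids)
    sigma = np.sqrt(sem_p**2 + sem_b**2)
    sigma = np.where(sigma > 0, sigma, np.finfo(float).tiny)
    return SAXSCurve(q0.copy(), I, sigma)


def multistate_fit(
    candidate_profiles: list[np.ndarray],
    exp_curve: SAXSCurve,
    max_states: int = 3,
) -> MultiStateFit:
    """Best 1..max_states mixture of candidate profiles by exhaustive subset
    enumeration with non-negative weights (the minimal-ensemble idea behind
    rigid-bodies-plus-linker multi-state SAXS fitting).

    Weights are solved per subset by non-negative least squares on the
    sigma-weighted design; the overall scale is folded into c and the weights
    renormalized to the simplex.
    """
    if not candidate_profiles:
        raise ValueError("empty candidate pool")
    if len(candidate_profiles) > 50:
        raise ValueError("candidate pool exceeds the enumeration bound (50)")
    if not (1 <= max_states <= 3):
        raise ValueError("max_states must be in 1..3")
    Ie, sig = exp_curve.I, exp_curve.sigma
    b = Ie / sig
    n = len(Ie)
    best: MultiStateFit | None = None
    for k in range(1, max_states + 1):
        for subset in itertools.combinations(range(len(candidate_profiles)), k):
            A = np.column_stack([
                np.asarray(candidate_profiles[i], dtype=float) / sig
                for i in subset
            ])
            coef, rnorm = nnls(A, b)
            total = coef.sum()
            if total <= 0:
                continue
            chi2 = rnorm**2 / (n - 1)
            if best is None or chi2 < best.chi2 - 1e-12:
                best = MultiStateFit(
                    members=subset,
                    weights=coef / total,
                    scale=float(total),
                    chi2=float(chi2),
                )
    if best is None:
        raise ValueError("no subset produced a non-trivial fit")
    return best
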
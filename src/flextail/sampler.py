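"""Conformational sampling of a flexible tail on a rigid core.

A coarse-grained two-stage protocol for disordered terminal regions: the
chain is a Cα trace with fixed 3.8 Å virtual bonds; moves are pivot
rotations of everything downstream of a random tail residue (which preserve
bond lengths exactly and keep designated helical segments rigid).  Stage 1
makes large pivots under a cooling Metropolis schedule to collapse the tail;
stage 2 refines with small pivots and finishes with greedy line-search
minimization in the pivot-move coordinates.

The energy is a documented coarse-grained surrogate for an all-atom score:
soft-sphere clash repulsion, Debye-screened electrostatics between charged
residues, and flat-harmonic crosslink restraints.  The selection cascade
downstream treats energy as an opaque sortable score, so any monotone
refinement of this surrogate slots in unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numba import njit
from scipy.spatial.distance import pdist, squareform

from .structio import CrosslinkRecord, Structure
from .synthetic import SyntheticSystem, _CHARGE
from .xlms import FlatHarmonicParams, flat_harmonic

__all__ = [
    "ChainModel",
    "EnergyWeights",
    "AnnealSchedule",
    "SampleResult",
    "Restraint",
    "EnergyBreakdown",
    "restraints_from_crosslinks",
    "energy",
    "sample_tail",
    "metropolis_accept",
    "pivot_rotate",
]


@dataclass(frozen=True)
class EnergyWeights:
    w_clash: float = 1.0
    w_elec: float = 1.0
    w_xl: float = 1.0
    clash_dmin: float = 4.0        # Å, soft-sphere contact distance
    screening_length: float = 10.0  # Å, Debye screening length

    def __post_init__(self):
        if min(self.w_clash, self.w_elec, self.w_xl) < 0:
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class AnnealSchedule:
    stage1_steps: int = 2000
    stage2_steps: int = 1000
    T_start: float = 5.0
    T_end: float = 0.2
    stage1_max_angle: float = 60.0  # degrees
    stage2_max_angle: float = 10.0
    minimize_moves: int = 60        # line searches after stage 2

    def __post_init__(self):
        if not (self.T_start >= self.T_end > 0):
            raise ValueError("need T_start >= T_end > 0")


@dataclass(frozen=True)
class Restraint:
    """Flat-harmonic distance restraint between two chain indices."""

    i: int
    j: int
    params: FlatHarmonicParams = FlatHarmonicParams()


@dataclass
class EnergyBreakdown:
    total: float
    clash: float
    elec: float
    xl: float


@dataclass
class ChainModel:
    """Cα chain with a rigid core prefix and a mobile tail."""

    coords: np.ndarray                  # (N, 3)
    charges: np.ndarray                 # (N,), +1/-1/0
    core_n: int
    template: Structure                 # atom metadata for rebuilds
    helix_ranges: tuple[tuple[int, int], ...] = ()  # global index ranges, inclusive

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        if len(self.coords) != len(self.charges):
            raise ValueError("coords/charges length mismatch")
        if not (0 < self.core_n < len(self.coords)):
            raise ValueError("core must be a non-empty strict prefix")

    @property
    def n(self) -> int:
        return len(self.coords)

    @property
    def tail_len(self) -> int:
        return self.n - self.core_n

    @classmethod
    def from_system(cls, system: SyntheticSystem) -> "ChainModel":
        st = system.tail_truth
        coords = st.ca_coords()
        charges = np.array([_CHARGE.get(a.res_name, 0.0) for a in st.ca_atoms()])
        helix = []
        n_core = system.n_core
        for lo, hi in system.truth_params.get("helix_ranges", ()):
            helix.append((n_core + lo - 1, n_core + hi - 1))
        return cls(coords=coords, charges=charges, core_n=n_core,
                   template=st, helix_ranges=tuple(helix))

    def address_index(self, chain_id: str, res_num: int) -> int:
        for idx, a in enumerate(self.template.ca_atoms()):
            if a.chain_id == chain_id and a.res_num == res_num:
                return idx
        raise KeyError(f"residue {chain_id}/{res_num} not in chain model")

    def to_structure(self, coords: np.ndarray | None = None) -> Structure:
        return self.template.with_coords(
            self.coords if coords is None else coords
        )


@dataclass
class SampleResult:
    model_id: int
    structure: Structure
    energy: float
    accepted_moves: int
    seed_used: int


def restraints_from_crosslinks(
    model: ChainModel,
    crosslinks: Sequence[CrosslinkRecord],
    params: FlatHarmonicParams = FlatHarmonicParams(),
) -> list[Restraint]:
    out = []
    for xl in crosslinks:
        try:
            i = model.address_index(xl.chain1, xl.res1)
            j = model.address_index(xl.chain2, xl.res2)
        except KeyError:
            raise KeyError(
                f"restraint references missing residue "
                f"{xl.chain1}/{xl.res1}-{xl.chain2}/{xl.res2}"
            ) from None
        out.append(Restraint(i, j, params))
    return out


# ---------------------------------------------------------------------------
# energy


def energy(
    model: ChainModel,
    restraints: Sequence[Restraint] = (),
    weights: EnergyWeights = EnergyWeights(),
) -> EnergyBreakdown:
    """Total coarse-grained energy with per-term breakdown.

    E = w_clash * sum_{d_ij < dmin, |i-j| > 1} (dmin - d_ij)^2
      + w_elec  * sum_{charged pairs} q_i q_j exp(-d_ij/lambda) / d_ij
      + w_xl    * sum_links f(d)        (flat-harmonic)
    """
    X = model.coords
    n = model.n
    D = squareform(pdist(X))
    iu = np.triu_indices(n, k=1)
    d = D[iu]
    sep = iu[1] - iu[0]
    clash = float(np.sum(np.where((d < weights.clash_dmin) & (sep > 1),
                                  (weights.clash_dmin - d) ** 2, 0.0)))
    qq = model.charges[iu[0]] * model.charges[iu[1]]
    nz = qq != 0
    elec = float(np.sum(qq[nz] * np.exp(-d[nz] / weights.screening_length)
                        / d[nz]))
    xl = 0.0
    for r in restraints:
        if not (0 <= r.i < n and 0 <= r.j < n):
            raise KeyError(f"restraint index ({r.i}, {r.j}) out of range")
        xl += flat_harmonic(float(D[r.i, r.j]), r.params)
    total = (weights.w_clash * clash + weights.w_elec * elec
             + weights.w_xl * xl)
    return EnergyBreakdown(total=total, clash=weights.w_clash * clash,
                           elec=weights.w_elec * elec, xl=weights.w_xl * xl)


@njit(cache=True)
def _tail_pair_energy(X, q, core_n, dmin, lam):  # pragma: no cover - numba
    """Clash + screened-electrostatic terms over pairs touching the tail."""
    n = X.shape[0]
    clash = 0.0
    elec = 0.0
    for i in range(n):
        j0 = core_n if i < core_n else i + 1
        for j in range(j0, n):
            dx = X[i, 0] - X[j, 0]
            dy = X[i, 1] - X[j, 1]
            dz = X[i, 2] - X[j, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d < dmin and j - i > 1:
                clash += (dmin - d) ** 2
            qq = q[i] * q[j]
            if qq != 0.0:
                elec += qq * math.exp(-d / lam) / d
    return clash, elec


@njit(cache=True)
def _tail_energy_nb(X, q, core_n, dmin, lam, wc, we, wx,
                    r_i, r_j, r_lim, r_sig):  # pragma: no cover - numba
    n = X.shape[0]
    clash = 0.0
    elec = 0.0
    for i in range(n):
        j0 = core_n if i < core_n else i + 1
        for j in range(j0, n):
            dx = X[i, 0] - X[j, 0]
            dy = X[i, 1] - X[j, 1]
            dz = X[i, 2] - X[j, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d < dmin and j - i > 1:
                clash += (dmin - d) ** 2
            qq = q[i] * q[j]
            if qq != 0.0:
                elec += qq * math.exp(-d / lam) / d
    xl = 0.0
    for k in range(r_i.shape[0]):
        i, j = r_i[k], r_j[k]
        dx = X[i, 0] - X[j, 0]
        dy = X[i, 1] - X[j, 1]
        dz = X[i, 2] - X[j, 2]
        d = math.sqrt(dx * dx + dy * dy + dz * dz)
        if d > r_lim[k]:
            xl += ((d - r_lim[k]) / r_sig[k]) ** 2
    return wc * clash + we * elec + wx * xl


@njit(cache=True)
def _pivot_inplace(X, pivot, ax, ay, az, angle):  # pragma: no cover - numba
    c = math.cos(angle)
    s = math.sin(angle)
    px, py, pz = X[pivot, 0], X[pivot, 1], X[pivot, 2]
    for k in range(pivot + 1, X.shape[0]):
        vx = X[k, 0] - px
        vy = X[k, 1] - py
        vz = X[k, 2] - pz
        dot = ax * vx + ay * vy + az * vz
        cx = ay * vz - az * vy
        cy = az * vx - ax * vz
        cz = ax * vy - ay * vx
        X[k, 0] = px + vx * c + cx * s + ax * dot * (1 - c)
        X[k, 1] = py + vy * c + cy * s + ay * dot * (1 - c)
        X[k, 2] = pz + vz * c + cz * s + az * dot * (1 - c)


def _restraint_arrays(restraints):
    r_i = np.array([r.i for r in restraints], dtype=np.int64)
    r_j = np.array([r.j for r in restraints], dtype=np.int64)
    r_lim = np.array([r.params.x0 + r.params.tolerance for r in restraints])
    r_sig = np.array([r.params.sigma for r in restraints])
    return r_i, r_j, r_lim, r_sig


def _tail_energy(X, model, restraints, weights) -> float:
    r_i, r_j, r_lim, r_sig = _restraint_arrays(restraints)
    return float(_tail_energy_nb(
        X, model.charges, model.core_n,
        weights.clash_dmin, weights.screening_length,
        weights.w_clash, weights.w_elec, weights.w_xl,
        r_i, r_j, r_lim, r_sig,
    ))


# ---------------------------------------------------------------------------
# moves


def pivot_rotate(coords: np.ndarray, pivot: int, axis: np.ndarray,
                 angle: float) -> np.ndarray:
    """Rotate every residue downstream of ``pivot`` about an axis through
    coords[pivot]; bond lengths are preserved exactly."""
    axis = axis / np.linalg.norm(axis)
    c, s = math.cos(angle), math.sin(angle)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    R = np.eye(3) + s * K + (1 - c) * (K @ K)
    out = coords.copy()
    p = coords[pivot]
    out[pivot + 1:] = (coords[pivot + 1:] - p) @ R.T + p
    return out


def metropolis_accept(delta_e: float, temperature: float,
                      rng: np.random.Generator) -> bool:
    """Standard Metropolis criterion."""
    if delta_e <= 0:
        return True
    return rng.random() < math.exp(-delta_e / temperature)


def _pivot_candidates(model: ChainModel) -> np.ndarray:
    """Pivot indices: core anchor through second-to-last residue, excluding
    positions that would bend a rigid helix segment."""
    cands = []
    for p in range(model.core_n - 1, model.n - 1):
        inside = any(lo <= p + 1 <= hi and p + 1 > lo
                     for lo, hi in model.helix_ranges)
        if not inside:
            cands.append(p)
    return np.array(cands, dtype=int)


def _extended_tail(model: ChainModel, rng: np.random.Generator) -> np.ndarray:
    """Initial conformation: the tail extended away from the core with a
    small random kink per model (mirrors 'attached in a random conformation
    extending away from the core')."""
    X = model.coords.copy()
    core = X[: model.core_n]
    anchor = core[-1]
    out = anchor - core.mean(axis=0)
    out = out / np.linalg.norm(out)
    d = out + 0.15 * rng.standard_normal(3)
    d /= np.linalg.norm(d)
    for k in range(model.core_n, model.n):
        X[k] = X[k - 1] + 3.8 * d
    return X


def sample_tail(
    system: SyntheticSystem | ChainModel,
    restraints: Sequence[Restraint | CrosslinkRecord] = (),
    n_models: int = 200,
    base_seed: int = 0,
    schedule: AnnealSchedule = AnnealSchedule(),
    weights: EnergyWeights = EnergyWeights(),
) -> list[SampleResult]:
    """Sample ``n_models`` independent tail conformations.

    Each model uses seed = base_seed + model_id.  Stage 1: large pivots
    (angle ~ U(-60°, 60°)) under geometrically cooled Metropolis; stage 2:
    small pivots (<= 10°) continuing the cooling, then greedy line-search
    minimization over pivot angles.  Core coordinates never move; helical
    tail segments move only as rigid bodies.
    """
    model = (ChainModel.from_system(system)
             if isinstance(system, SyntheticSystem) else system)
    if model.tail_len < 3:
        raise ValueError("tail too short to sample (need >= 3 residues)")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    rs: list[Restraint] = []
    xls = [r for r in restraints if isinstance(r, CrosslinkRecord)]
    rs.extend(r for r in restraints if isinstance(r, Restraint))
    if xls:
        rs.extend(restraints_from_crosslinks(model, xls))
    cands = _pivot_candidates(model)
    if len(cands) == 0:
        raise ValueError("no pivot positions available")

    # constant core-core contribution, so stored energies match energy()
    e_full0 = energy(model, rs, weights).total
    e_tail0 = _tail_energy(model.coords, model, rs, weights)
    e_core_const = e_full0 - e_tail0

    r_i, r_j, r_lim, r_sig = _restraint_arrays(rs)
    q = model.charges
    core_n = model.core_n

    def _e(X):
        return float(_tail_energy_nb(
            X, q, core_n, weights.clash_dmin, weights.screening_length,
            weights.w_clash, weights.w_elec, weights.w_xl,
            r_i, r_j, r_lim, r_sig,
        ))

    results = []
    for mid in range(n_models):
        seed = base_seed + mid
        rng = np.random.default_rng(seed)
        X = _extended_tail(model, rng)
        e = _e(X)
        accepted = 0
        for stage, (steps, max_ang) in enumerate([
            (schedule.stage1_steps, schedule.stage1_max_angle),
            (schedule.stage2_steps, schedule.stage2_max_angle),
        ]):
            if steps == 0:
                continue
            stage_accepted = 0
            total_steps = schedule.stage1_steps + schedule.stage2_steps
            offset = 0 if stage == 0 else schedule.stage1_steps
            for step in range(steps):
                frac = (offset + step) / max(total_steps - 1, 1)
                T = schedule.T_start * (schedule.T_end / schedule.T_start) ** frac
                p = int(cands[rng.integers(len(cands))])
                ax, ay, az = _rand_unit(rng)
                ang = math.radians(rng.uniform(-max_ang, max_ang))
                Xn = X.copy()
                _pivot_inplace(Xn, p, ax, ay, az, ang)
                en = _e(Xn)
                if metropolis_accept(en - e, T, rng):
                    X, e = Xn, en
                    accepted += 1
                    stage_accepted += 1
            if stage_accepted == 0:
                warnings.warn(
                    f"model {mid}: no moves accepted in stage {stage + 1}",
                    stacklevel=2,
                )
        # greedy line-search minimization over pivot angles
        grid = np.radians(np.linspace(-schedule.stage2_max_angle,
                                      schedule.stage2_max_angle, 7))
        grid = grid[grid != 0.0]
        for _ in range(schedule.minimize_moves):
            p = int(cands[rng.integers(len(cands))])
            ax, ay, az = _rand_unit(rng)
            best_e, best_X = e, None
            for ang in grid:
                Xn = X.copy()
                _pivot_inplace(Xn, p, ax, ay, az, float(ang))
                en = _e(Xn)
                if en < best_e:
                    best_e, best_X = en, Xn
            if best_X is not None:
                X, e = best_X, best_e
                accepted += 1
        results.append(SampleResult(
            model_id=mid,
            structure=model.to_structure(X),
            energy=e + e_core_const,
            accepted_moves=accepted,
            seed_used=seed,
        ))
    return results


def _rand_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)
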
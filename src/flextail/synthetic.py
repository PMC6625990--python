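"""Synthetic-data generators with known ground truth.

Every input class the pipeline consumes can be generated here: a rigid
Cα-only solenoid core built from helical repeats (one short helix packed
against an antiparallel two-helix hairpin, repeats stacked along a
right-handed superhelical path) carrying a basic surface patch; a flexible
charged tail grown onto the core in a known ("truth") conformation with its
acidic stretch docked on the patch; lysine-reactive crosslinks drawn under
the crosslinker's distance geometry; scattering curves from the Debye
profile of the truth coordinates; 1:1 binding traces at several analyte
concentrations; and sigmoidal thermal melts.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .saxs import FormFactorModel, debye_profile
from .structio import Atom, CrosslinkRecord, SAXSCurve, Structure, TraceTable

__all__ = [
    "SyntheticSystem",
    "NoiseSpec",
    "build_core",
    "attach_truth_tail",
    "default_system",
    "simulate_crosslinks",
    "simulate_saxs",
    "simulate_bli",
    "simulate_melt",
]

BOND = 3.8          # Å, Cα virtual bond
CLASH_MIN = 4.0     # Å, minimum allowed non-bonded Cα separation
_RISE = 1.5         # Å per residue along an ideal helix axis
_TWIST = math.radians(100.0)
# helix radius such that the Cα-Cα chord is exactly BOND
_HELIX_R = math.sqrt(BOND**2 - _RISE**2) / (2.0 * math.sin(_TWIST / 2.0))

# default tail: 30 residues, lysine surrogates on the 6-periodic raster,
# acidic stretch (10 x D/E) mid-tail
DEFAULT_TAIL = "GSKGSAGSGKEDEEDDEEDDKSAGSGAKSG"


@dataclass
class NoiseSpec:
    """Noise model for simulated observables."""

    saxs_rel_sigma: float = 0.02   # sigma_i = rel * I_i (multiplicative)
    trace_sd: float = 0.02         # additive Gaussian sd on time series
    seed: int = 0

    def __post_init__(self):
        if self.saxs_rel_sigma < 0 or self.trace_sd < 0:
            raise ValueError("noise levels must be non-negative")


@dataclass
class SyntheticSystem:
    """A rigid core plus flexible tail with a known truth conformation."""

    core: Structure
    tail_truth: Structure          # core + tail, truth coordinates
    basic_patch: list[tuple[str, int]]
    acidic_stretch: list[tuple[str, int]]
    truth_params: dict = field(default_factory=dict)

    @property
    def n_core(self) -> int:
        return len(self.core)

    @property
    def tail_addresses(self) -> list[tuple[str, int]]:
        return self.tail_truth.residue_addresses()[self.n_core:]

    @property
    def core_addresses(self) -> list[tuple[str, int]]:
        return self.tail_truth.residue_addresses()[: self.n_core]


def _ideal_helix(n: int, start: np.ndarray, axis: np.ndarray,
                 ref: np.ndarray, phase: float = 0.0) -> np.ndarray:
    """n Cα positions on an ideal helix whose first residue sits at ``start``.

    The helix axis is ``axis`` (unit); ``ref`` seeds the perpendicular basis.
    Consecutive Cα-Cα distances equal BOND exactly by construction.
    """
    axis = axis / np.linalg.norm(axis)
    u = ref - np.dot(ref, axis) * axis
    nu = np.linalg.norm(u)
    if nu < 1e-8:
        tmp = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = tmp - np.dot(tmp, axis) * axis
        nu = np.linalg.norm(u)
    u /= nu
    v = np.cross(axis, u)
    i = np.arange(n)
    ang = phase + i * _TWIST
    pts = (_RISE * i)[:, None] * axis \
        + _HELIX_R * np.cos(ang)[:, None] * u \
        + _HELIX_R * np.sin(ang)[:, None] * v
    return pts - pts[0] + start


def _rot(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _helix_on_line(n: int, axis_point: np.ndarray, axis: np.ndarray,
                   ref: np.ndarray, phase: float, y0: float) -> np.ndarray:
    """n Cα positions on the ideal helix whose axis is the line
    axis_point + t*axis; the first residue sits at axial offset ``y0`` and
    angular phase ``phase``."""
    axis = axis / np.linalg.norm(axis)
    u = ref - np.dot(ref, axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    i = np.arange(n)
    ang = phase + i * _TWIST
    return (axis_point
            + (y0 + _RISE * i)[:, None] * axis
            + _HELIX_R * np.cos(ang)[:, None] * u
            + _HELIX_R * np.sin(ang)[:, None] * v)


def _connect_helix(
    n: int,
    end_pt: np.ndarray,
    axis_point: np.ndarray,
    axis: np.ndarray,
    ref: np.ndarray,
    existing: np.ndarray,
    end_toward: np.ndarray | None = None,
) -> np.ndarray:
    """Place an ideal helix on a prescribed axis line so that its first
    residue is exactly BOND from ``end_pt``.

    The start phase (and the axial offset it implies) is chosen to maximize
    clearance from ``existing`` points (capped, so ties are broken by how
    well the final residue's radial direction aligns with ``end_toward`` —
    the direction the next chain element must be reachable in).
    Deterministic.
    """
    axis = axis / np.linalg.norm(axis)
    u = ref - np.dot(ref, axis) * axis
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    best = None
    for phase in np.linspace(0.0, 2.0 * math.pi, 241)[:-1]:
        e = math.cos(phase) * u + math.sin(phase) * v
        Q = axis_point + _HELIX_R * e
        w = Q - end_pt
        b = float(np.dot(axis, w))
        c = float(np.dot(w, w)) - BOND**2
        disc = b * b - c
        if disc < 0:
            continue
        for sgn in (1.0, -1.0):
            y0 = -b + sgn * math.sqrt(disc)
            helix = _helix_on_line(n, axis_point, axis, ref, phase, y0)
            d = np.sqrt(((helix[:, None, :] - existing[None, :, :]) ** 2).sum(-1))
            d[0, -1] = np.inf  # bonded junction to the previous residue
            clearance = d.min()
            if clearance < CLASH_MIN:
                continue
            end_ang = phase + (n - 1) * _TWIST
            e_end = math.cos(end_ang) * u + math.sin(end_ang) * v
            align = (float(np.dot(e_end, end_toward))
                     if end_toward is not None else 0.0)
            # clash-freeness is already enforced; among clash-free
            # placements prefer junction-compatible end phases
            score = (round(align, 3), clearance, -abs(y0))
            if best is None or score > best[0]:
                best = (score, helix)
    if best is None:
        raise RuntimeError("could not connect helix without clashes")
    return best[1]


def build_core(n_repeats: int = 8, seed: int = 0) -> Structure:
    """Cα-only solenoid core of helical repeats.

    Each 32-residue repeat is one 8-residue helix (h1) running roughly
    perpendicular to a 12+12-residue antiparallel hairpin (h2, h3); repeats
    stack with a per-repeat rotation about the superhelical axis plus an
    axial rise, tracing a right-handed superhelix.  Consecutive Cα-Cα
    distances are exactly the virtual bond length, including across helix
    junctions.  Deterministic for fixed inputs; every 6th residue is named
    LYS (lysine surrogate raster), the rest ALA.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    theta = math.radians(24.0)          # superhelical twist per repeat
    z = np.array([0.0, 0.0, 1.0])

    def _perp(d: np.ndarray, axis: np.ndarray) -> np.ndarray:
        p = d - np.dot(d, axis) * axis
        return p / np.linalg.norm(p)

    coords: list[np.ndarray] = []
    prev_end: np.ndarray | None = None
    for k in range(n_repeats):
        Rk = _rot(z, k * theta)
        lat = Rk @ np.array([1.0, 0.0, 0.0])
        dep = Rk @ np.array([0.0, 1.0, 0.0])
        # h1 is a near-vertical riser perpendicular to the hairpin plane;
        # successive hairpins stack above one another with a per-repeat
        # rotation, tracing the right-handed superhelix
        a1 = Rk @ np.array([0.2, 0.0, 1.0])
        a1 /= np.linalg.norm(a1)
        a2 = dep
        a3 = Rk @ np.array([0.10, -1.0, 0.04])
        a3 /= np.linalg.norm(a3)
        existing = (np.vstack(coords) if coords
                    else np.full((1, 3), 1e6))
        if prev_end is None:
            h1 = _helix_on_line(8, np.zeros(3), a1, ref=lat, phase=0.0, y0=0.0)
        else:
            # route the new axis just past the previous endpoint so the
            # entry phase is unconstrained
            c1 = prev_end + 1.45 * _perp(-dep, a1)
            h1 = _connect_helix(8, prev_end, c1, a1, ref=lat,
                                existing=existing, end_toward=dep)
        existing = np.vstack([existing, h1])
        c2 = h1[-1] + 1.45 * _perp(lat, a2)
        h2 = _connect_helix(12, h1[-1], c2, a2, ref=z, existing=existing,
                            end_toward=lat)
        existing = np.vstack([existing, h2])
        # antiparallel hairpin partner: axis offset laterally from h2's axis
        # at the height the chain turns
        top = c2 + float(np.dot(a2, h2[-1] - c2)) * a2
        c3 = top + 8.0 * lat
        h3 = _connect_helix(12, h2[-1], c3, a3, ref=z, existing=existing,
                            end_toward=z)
        coords.extend([h1, h2, h3])
        prev_end = h3[-1]
    xyz = np.vstack(coords)
    atoms = [
        Atom(serial=i + 1, name="CA", element="C",
             res_name="LYS" if (i + 1) % 6 == 0 else "ALA",
             chain_id="A", res_num=i + 1,
             x=float(p[0]), y=float(p[1]), z=float(p[2]))
        for i, p in enumerate(xyz)
    ]
    return Structure(atoms, title=f"synthetic {n_repeats}-repeat solenoid core")


_CHARGE = {"ARG": 1.0, "LYS": 1.0, "ASP": -1.0, "GLU": -1.0}
_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def _acidic_run(seq: str) -> tuple[int, int]:
    """(start, end) 0-based half-open indices of the longest D/E run."""
    best = (0, 0)
    i = 0
    while i < len(seq):
        if seq[i] in "DE":
            j = i
            while j < len(seq) and seq[j] in "DE":
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    return best


def attach_truth_tail(
    core: Structure,
    tail_sequence: str = DEFAULT_TAIL,
    helix_ranges: tuple[tuple[int, int], ...] = (),
    seed: int = 0,
    max_restarts: int = 400,
) -> SyntheticSystem:
    """Grow a flexible tail onto the core in a clash-free truth conformation
    whose acidic stretch docks on a basic surface patch of the core.

    ``helix_ranges`` are 1-based inclusive residue ranges within the tail that
    are placed as rigid ideal helices.  The patch is a cluster of residues on
    the outer face of the last repeat's hairpin, renamed ARG.
    """
    seq = tail_sequence.upper()
    for hr in helix_ranges:
        if not (1 <= hr[0] <= hr[1] <= len(seq)):
            raise ValueError(f"helix range {hr} outside tail")
    n_core = len(core)
    core_xyz = core.coords()
    core_centroid = core_xyz.mean(axis=0)

    # basic patch: ten consecutive residues of the last hairpin helix (h3);
    # spatially clustered by construction
    patch_idx = list(range(n_core - 11, n_core - 1))
    patch_centroid = core_xyz[patch_idx].mean(axis=0)
    outward = patch_centroid - core_centroid
    outward /= np.linalg.norm(outward)
    target = patch_centroid + 7.0 * outward

    acid_lo, acid_hi = _acidic_run(seq)  # 0-based half-open
    rng_master = np.random.default_rng(seed)

    def _grow(rng: np.random.Generator) -> np.ndarray | None:
        pts = list(core_xyz)
        anchor = core_xyz[-1]
        prev = anchor
        i = 0
        while i < len(seq):
            hr = next((h for h in helix_ranges if h[0] - 1 == i), None)
            if hr is not None:
                n_h = hr[1] - hr[0] + 1
                placed = None
                for _ in range(60):
                    d = _steer(prev, i, rng)
                    helix = _ideal_helix(n_h, prev + BOND * d, d,
                                         ref=rng.standard_normal(3))
                    if _clash_free_block(helix, pts):
                        placed = helix
                        break
                if placed is None:
                    return None
                pts.extend(placed)
                prev = placed[-1]
                i += n_h
                continue
            ok = False
            for _ in range(150):
                d = _steer(prev, i, rng)
                cand = prev + BOND * d
                if _clash_free(cand, pts):
                    pts.append(cand)
                    prev = cand
                    ok = True
                    break
            if not ok:
                return None
            i += 1
        return np.array(pts[n_core:])

    acid_mid = 0.5 * (acid_lo + acid_hi)

    def _steer(prev: np.ndarray, i: int, rng: np.random.Generator) -> np.ndarray:
        # walk toward the docking target so the chain arrives there as the
        # acidic stretch is laid down, then wander outward
        if i < acid_mid:
            to_target = target - prev
            nt = np.linalg.norm(to_target)
            reach = max((acid_mid - i), 1.0) * BOND * 0.65
            if nt > reach:
                bias = 0.95
            elif nt > 6.0:
                bias = 0.5
            else:
                bias = 0.1
            d = bias * (to_target / max(nt, 1e-9)) \
                + (1 - bias) * _rand_unit(rng)
        elif i < acid_hi:
            # lay the stretch down loosely around the patch
            to_target = target - prev
            nt = np.linalg.norm(to_target)
            bias = 0.6 if nt > 8.0 else 0.05
            d = bias * (to_target / max(nt, 1e-9)) \
                + (1 - bias) * _rand_unit(rng)
        else:
            d = 0.5 * outward + 0.8 * _rand_unit(rng)
        return d / np.linalg.norm(d)

    def _clash_free(p: np.ndarray, pts: list[np.ndarray]) -> bool:
        arr = np.asarray(pts[-len(pts):])
        d2 = np.sum((arr - p) ** 2, axis=1)
        # the immediately preceding residue is bonded at BOND < CLASH_MIN
        d2[-1] = np.inf
        return bool(np.all(d2 >= CLASH_MIN**2))

    def _clash_free_block(block: np.ndarray, pts: list[np.ndarray]) -> bool:
        arr = np.asarray(pts)
        from scipy.spatial.distance import cdist
        d = cdist(block, arr)
        d[0, -1] = np.inf  # bonded junction
        if d.min() < CLASH_MIN:
            return False
        dd = cdist(block, block)
        np.fill_diagonal(dd, np.inf)
        for k in range(len(block) - 1):
            dd[k, k + 1] = dd[k + 1, k] = np.inf
        return bool(dd.min() >= CLASH_MIN)

    tail_xyz = None
    for attempt in range(max_restarts):
        rng = np.random.default_rng(seed * 100003 + attempt)
        cand = _grow(rng)
        if cand is None:
            continue
        acid_centroid = cand[acid_lo:acid_hi].mean(axis=0)
        if np.linalg.norm(acid_centroid - patch_centroid) < 12.0:
            tail_xyz = cand
            break
    if tail_xyz is None:
        raise RuntimeError(
            "tail growth failed after bounded retries; try a different seed"
        )

    atoms = []
    for a in core.atoms:
        res_name = "ARG" if (a.res_num - 1) in patch_idx and a.res_name != "LYS" \
            else a.res_name
        atoms.append(Atom(a.serial, a.name, a.element, res_name, a.chain_id,
                          a.res_num, a.x, a.y, a.z))
    for j, p in enumerate(tail_xyz):
        num = n_core + j + 1
        res = _ONE_TO_THREE.get(seq[j], "ALA")
        atoms.append(Atom(num, "CA", "C", res, "A", num,
                          float(p[0]), float(p[1]), float(p[2])))
    tail_truth = Structure(atoms, title=core.title + " + truth tail")
    return SyntheticSystem(
        core=core,
        tail_truth=tail_truth,
        basic_patch=[("A", i + 1) for i in patch_idx],
        acidic_stretch=[("A", n_core + 1 + j) for j in range(acid_lo, acid_hi)],
        truth_params={
            "seed": seed,
            "tail_sequence": seq,
            "helix_ranges": tuple(helix_ranges),
            "n_core": n_core,
        },
    )


def _rand_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def default_system(seed: int = 0, n_repeats: int = 8,
                   tail_sequence: str = DEFAULT_TAIL) -> SyntheticSystem:
    """The packaged study system: 8-repeat core + 30-residue charged tail."""
    return attach_truth_tail(build_core(n_repeats), tail_sequence, seed=seed)


def simulate_crosslinks(
    system: SyntheticSystem,
    n_true: int = 4,
    n_decoy: int = 0,
    max_true_dist: float = 24.0,
    seed: int = 0,
    span: str = "tail-core",
) -> list[CrosslinkRecord]:
    """Draw crosslink records under the crosslinker's distance geometry.

    True records are sampled among lysine-surrogate pairs (every 6th residue)
    whose truth Cα-Cα distance is <= ``max_true_dist`` (default ~24 Å, the
    geometric crosslinker reach); with ``span='tail-core'`` (default,
    mirroring the study scenario) one side must lie in the tail.  Decoys are
    drawn among pairs with truth distance > 40 Å.  True scores ~ U(20, 40),
    decoy scores ~ U(0, 20): disjoint by default.
    """
    rng = np.random.default_rng(seed)
    st = system.tail_truth
    addrs = st.residue_addresses()
    xyz = st.ca_coords()
    eligible = [i for i, (_, num) in enumerate(addrs) if num % 6 == 0]
    n_core = system.n_core

    def _spans(i, j):
        if span == "any":
            return True
        return (i < n_core) != (j < n_core)

    true_pool, decoy_pool = [], []
    for ii, i in enumerate(eligible):
        for j in eligible[ii + 1:]:
            d = float(np.linalg.norm(xyz[i] - xyz[j]))
            if d <= max_true_dist and _spans(i, j):
                true_pool.append((i, j))
            elif d > 40.0:
                decoy_pool.append((i, j))
    if len(true_pool) < n_true:
        raise ValueError(
            f"only {len(true_pool)} qualifying pairs <= {max_true_dist} Å "
            f"available (need {n_true})"
        )
    if len(decoy_pool) < n_decoy:
        raise ValueError(
            f"only {len(decoy_pool)} pairs > 40 Å available (need {n_decoy})"
        )
    records: list[CrosslinkRecord] = []
    for i, j in _sample(true_pool, n_true, rng):
        records.append(CrosslinkRecord(
            addrs[i][0], addrs[i][1], addrs[j][0], addrs[j][1],
            score=float(rng.uniform(20.0, 40.0)), is_decoy=False,
        ))
    for i, j in _sample(decoy_pool, n_decoy, rng):
        records.append(CrosslinkRecord(
            addrs[i][0], addrs[i][1], addrs[j][0], addrs[j][1],
            score=float(rng.uniform(0.0, 20.0)), is_decoy=True,
        ))
    return records


def _sample(pool, n, rng):
    idx = rng.choice(len(pool), size=n, replace=False) if n else []
    return [pool[i] for i in idx]


def simulate_saxs(
    structure: Structure,
    q_grid: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
    form: FormFactorModel = FormFactorModel(),
    exact: bool = False,
) -> SAXSCurve:
    """Scattering curve of a structure.

    I is the Debye profile; sigma_i = saxs_rel_sigma * I_i (multiplicative
    error model, scale-invariant chi-square); observed intensities are drawn
    Gaussian(I_i, sigma_i) with ``noise.seed``.  ``exact=True`` (or a zero
    saxs_rel_sigma) skips the Gaussian draw and returns the exact profile,
    keeping the stated uncertainty band (with a tiny positive floor so the
    curve container stays valid).
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    if q_grid is None:
        q_grid = np.linspace(0.004, 0.388, 97)
    q_grid = np.asarray(q_grid, dtype=float)
    I = debye_profile(structure, q_grid, form)
    rel = max(noise.saxs_rel_sigma, 1e-6)
    sigma = rel * I
    if noise.saxs_rel_sigma > 0 and not exact:
        rng = np.random.default_rng(noise.seed)
        I_obs = rng.normal(I, sigma)
    else:
        I_obs = I.copy()
    return SAXSCurve(q_grid, I_obs, sigma)


def simulate_sec_saxs_frames(
    structure: Structure,
    n_peak: int = 5,
    n_buffer: int = 5,
    background_level: float = 0.1,
    q_grid: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> tuple[list[SAXSCurve], list[int], list[int]]:
    """SEC-SAXS frame stack: buffer frames carry a smooth background, peak
    frames carry signal + background; all share one q grid."""
    if q_grid is None:
        q_grid = np.linspace(0.004, 0.388, 97)
    q_grid = np.asarray(q_grid, dtype=float)
    I_sig = debye_profile(structure, q_grid)
    bg = background_level * I_sig[0] * np.exp(-q_grid / 0.1)
    rng = np.random.default_rng(noise.seed)
    rel = max(noise.saxs_rel_sigma, 1e-6)
    frames = []
    for _ in range(n_peak):
        mean = I_sig + bg
        sig = rel * mean
        frames.append(SAXSCurve(q_grid, rng.normal(mean, sig), sig))
    for _ in range(n_buffer):
        sig = rel * np.maximum(bg, 1e-12 * I_sig[0])
        frames.append(SAXSCurve(q_grid, rng.normal(bg, sig), sig))
    return frames, list(range(n_peak)), list(range(n_peak, n_peak + n_buffer))


def simulate_bli(
    k_a: float,
    k_d: float,
    Bmax: float,
    concentrations,
    t_assoc: float = 120.0,
    t_dissoc: float = 180.0,
    noise: NoiseSpec = NoiseSpec(),
    dt: float = 0.2,
) -> TraceTable:
    """1:1 binding traces at several analyte concentrations.

    Association: R(t) = R_eq (1 − e^(−k_obs t)) with k_obs = k_a C + k_d and
    R_eq = Bmax C/(C + k_d/k_a); dissociation continues from R(t_assoc) as
    R e^(−k_d (t − t_assoc)).  Gaussian noise of sd ``noise.trace_sd`` is
    added.  ``t_dissoc = 0`` yields an association-only table.
    """
    if k_a <= 0 or k_d <= 0:
        raise ValueError("rate constants must be positive")
    if Bmax <= 0:
        raise ValueError("Bmax must be positive")
    K_D = k_d / k_a
    t = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    t[0] = 0.0
    rng = np.random.default_rng(noise.seed)
    signals: dict[str, np.ndarray] = {}
    conc_map: dict[str, float | None] = {}
    truth = {}
    for ci, C in enumerate(concentrations):
        if C <= 0:
            raise ValueError("concentrations must be positive")
        k_obs = k_a * C + k_d
        r_eq = Bmax * C / (C + K_D)
        R = np.where(
            t <= t_assoc,
            r_eq * (1.0 - np.exp(-k_obs * t)),
            r_eq * (1.0 - np.exp(-k_obs * t_assoc))
            * np.exp(-k_d * (t - t_assoc)),
        )
        if noise.trace_sd > 0:
            R = R + rng.normal(0.0, noise.trace_sd, size=len(R))
        name = f"conc_{ci}"
        signals[name] = R
        conc_map[name] = float(C)
        truth[name] = {"k_obs": k_obs, "r_eq": r_eq}
    # offset time so it is strictly increasing from 0
    return TraceTable(
        t=t, signals=signals, concentrations=conc_map,
        metadata={
            "t_assoc": t_assoc, "t_dissoc": t_dissoc,
            "k_a": k_a, "k_d": k_d, "Bmax": Bmax, "truth": truth,
        },
    )


def simulate_melt(
    Tm: float,
    slope: float,
    F_low: float,
    F_high: float,
    T_grid: np.ndarray | None = None,
    noise: NoiseSpec = NoiseSpec(),
) -> TraceTable:
    """Boltzmann-sigmoid thermal melt
    F(T) = F_low + (F_high − F_low)/(1 + e^((Tm − T)/slope)) plus Gaussian
    noise of sd ``noise.trace_sd``."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    if T_grid is None:
        T_grid = np.arange(25.0, 95.0 + 0.5, 1.0)
    T = np.asarray(T_grid, dtype=float)
    F = F_low + (F_high - F_low) / (1.0 + np.exp((Tm - T) / slope))
    if noise.trace_sd > 0:
        rng = np.random.default_rng(noise.seed)
        F = F + rng.normal(0.0, noise.trace_sd, size=len(F))
    return TraceTable(t=T, signals={"rfu": F},
                      metadata={"Tm": Tm, "slope": slope})
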
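"""Structural measurements: Cα distances, solvent-accessible surface area,
interface burial, and per-residue ensemble fluctuation (RMSF).

SASA uses Shrake–Rupley numerical quadrature (Fibonacci sphere points over a
neighbour tree); interface burial is the standard
(SASA_A + SASA_B − SASA_AB)/2.  RMSF superposes every frame on the first
using a rigid alignment range before measuring per-residue fluctuation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .selection import superpose
from .structio import Structure

__all__ = [
    "SASAParams",
    "RMSFProfile",
    "ca_distance",
    "sasa",
    "interface_area",
    "rmsf",
]

_DEFAULT_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2, "P": 1.8}


@dataclass
class SASAParams:
    probe_radius: float = 1.4        # Å, water probe
    n_sphere_points: int = 960
    radii: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_RADII))
    calpha_radius: float = 3.0       # Å, pseudo-residue sphere in Cα-only mode

    def __post_init__(self):
        if self.probe_radius < 0:
            raise ValueError("probe radius must be non-negative")
        if self.n_sphere_points < 60:
            raise ValueError("need at least 60 quadrature points")


@dataclass
class RMSFProfile:
    addresses: list[tuple[str, int]]
    rmsf: np.ndarray              # Å, per residue
    align_range: list[tuple[str, int]]


def ca_distance(structure: Structure, addr_a: tuple[str, int],
                addr_b: tuple[str, int]) -> float:
    """Euclidean Cα–Cα distance (Å) between two residue addresses."""
    a = structure.get_atom(*addr_a).xyz
    b = structure.get_atom(*addr_b).xyz
    return float(np.linalg.norm(a - b))


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def _atom_radii(structure: Structure, params: SASAParams) -> np.ndarray:
    # Cα-only models get a fat pseudo-residue sphere; all-atom input uses the
    # per-element table.
    if all(a.name == "CA" for a in structure.atoms):
        return np.full(len(structure), params.calpha_radius)
    return np.array([
        params.radii.get(a.element.upper(), 1.7) for a in structure.atoms
    ])


def sasa(structure: Structure,
         params: SASAParams = SASAParams()) -> tuple[np.ndarray, float]:
    """Shrake–Rupley solvent-accessible surface area.

    For each atom, the fraction of quasi-uniform sphere points at radius
    r + probe not buried inside any neighbour's expanded sphere, times
    4π(r + probe)².  Returns (per-atom areas, total area) in Å².
    """
    if len(structure) == 0:
        raise ValueError("empty structure")
    xyz = structure.coords()
    radii = _atom_radii(structure, params) + params.probe_radius
    sphere = _fibonacci_sphere(params.n_sphere_points)
    tree = cKDTree(xyz)
    r_max = radii.max()
    areas = np.empty(len(xyz))
    for i in range(len(xyz)):
        pts = xyz[i] + radii[i] * sphere
        neighbours = tree.query_ball_point(xyz[i], radii[i] + r_max)
        neighbours = [j for j in neighbours if j != i]
        exposed = np.ones(len(pts), dtype=bool)
        for j in neighbours:
            d2 = np.sum((pts - xyz[j]) ** 2, axis=1)
            exposed &= d2 > radii[j] ** 2
        areas[i] = exposed.mean() * 4.0 * np.pi * radii[i] ** 2
    return areas, float(areas.sum())


def interface_area(
    structure: Structure,
    group_a: Iterable[tuple[str, int]] | str,
    group_b: Iterable[tuple[str, int]] | str,
    params: SASAParams = SASAParams(),
) -> float:
    """Buried interface area between two residue groups:
    (SASA(A alone) + SASA(B alone) − SASA(A∪B)) / 2, in Å².

    Groups may be residue-address iterables or single chain ids.
    """
    addr_a = _resolve_group(structure, group_a)
    addr_b = _resolve_group(structure, group_b)
    if not addr_a or not addr_b:
        raise ValueError("both groups must be non-empty")
    if addr_a & addr_b:
        raise ValueError("groups overlap")
    sub_a = structure.select(addr_a)
    sub_b = structure.select(addr_b)
    both = structure.select(addr_a | addr_b)
    _, area_a = sasa(sub_a, params)
    _, area_b = sasa(sub_b, params)
    _, area_ab = sasa(both, params)
    return (area_a + area_b - area_ab) / 2.0


def _resolve_group(structure: Structure, group) -> set[tuple[str, int]]:
    if isinstance(group, str):
        return {a for a in structure.residue_addresses() if a[0] == group}
    return set(group)


def rmsf(
    ensemble: Sequence[Structure],
    align_range: Iterable[tuple[str, int]] | None = None,
    report_selection: Iterable[tuple[str, int]] | None = None,
) -> RMSFProfile:
    """Per-residue root-mean-square fluctuation across an aligned ensemble.

    Every frame is superposed on the first using the Cα atoms of
    ``align_range`` (all shared residues if None); RMSF_i =
    sqrt(mean_t |x_i(t) − <x_i>|²) over ``report_selection``.
    """
    if len(ensemble) < 2:
        raise ValueError("need at least 2 conformations")
    ref = ensemble[0]
    if align_range is None:
        align_range = ref.residue_addresses()
    align_range = list(align_range)
    if report_selection is None:
        report_selection = ref.residue_addresses()
    report_selection = list(report_selection)
    for frame in ensemble[1:]:
        for addr in align_range + report_selection:
            if not frame.has_atom(*addr):
                raise KeyError(f"residue {addr} missing from a frame")
    # iterative mean-structure alignment: converges to a reference that does
    # not depend on frame order (up to a global rigid transform, which RMSF
    # is blind to)
    aligns = np.array([
        [f.get_atom(*a).xyz for a in align_range] for f in ensemble
    ])
    ref_align = aligns.mean(axis=0)
    for _ in range(50):
        moved = np.empty_like(aligns)
        for fi in range(len(ensemble)):
            R, t, _ = superpose(aligns[fi], ref_align)
            moved[fi] = aligns[fi] @ R.T + t
        new_ref = moved.mean(axis=0)
        if np.max(np.abs(new_ref - ref_align)) < 1e-12:
            ref_align = new_ref
            break
        ref_align = new_ref
    stacked = np.empty((len(ensemble), len(report_selection), 3))
    for fi, frame in enumerate(ensemble):
        R, t, _ = superpose(aligns[fi], ref_align)
        sel = np.array([frame.get_atom(*a).xyz for a in report_selection])
        stacked[fi] = sel @ R.T + t
    mean = stacked.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((stacked - mean) ** 2, axis=2), axis=0))
    return RMSFProfile(addresses=report_selection, rmsf=fluct,
                       align_range=align_range)
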
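"""Crosslink restraint mathematics.

DSS (disuccinimidyl suberate) bridges lysine primary amines; the spacer
(11.4 Å) plus two lysine side chains (6.4 Å each) caps the Cα–Cα distance of
a crosslinked pair at ~24 Å, relaxed to a <30 Å working threshold to allow
for protein dynamics.  Restraints use a flat-harmonic penalty: zero inside
the tolerance window, quadratic growth outside.  Crosslink identification
lists are filtered by a decoy-counting false-discovery-rate estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .structio import CrosslinkRecord, Structure

__all__ = [
    "FlatHarmonicParams",
    "LinkerGeometry",
    "LinkReport",
    "SatisfactionReport",
    "flat_harmonic",
    "max_linker_distance",
    "satisfaction",
    "decoy_fdr",
]


@dataclass(frozen=True)
class FlatHarmonicParams:
    """Flat-harmonic restraint parameters: zero penalty for dist <= x0 + tolerance,
    ((dist - x0 - tolerance)/sigma)^2 beyond."""

    x0: float = 15.0          # Å
    tolerance: float = 15.0   # Å
    sigma: float = 1.0        # dimensionless scale of the quadratic wall

    def __post_init__(self):
        if self.x0 < 0 or self.tolerance < 0:
            raise ValueError("x0 and tolerance must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class LinkerGeometry:
    """Distance geometry of a lysine-reactive crosslinker (defaults: DSS)."""

    spacer_length: float = 11.4      # Å, NHS-ester to NHS-ester
    sidechain_length: float = 6.4    # Å, Lys Cα to NZ
    dynamics_allowance: float = 6.0  # Å, slack for conformational dynamics
    threshold: float = 30.0          # Å, working Cα–Cα satisfaction cutoff

    def __post_init__(self):
        if self.threshold < self.spacer_length + 2 * self.sidechain_length:
            raise ValueError(
                "threshold must be at least spacer + 2 x sidechain length"
            )


@dataclass(frozen=True)
class LinkReport:
    chain1: str
    res1: int
    chain2: str
    res2: int
    distance: float
    satisfied: bool


@dataclass
class SatisfactionReport:
    """Per-crosslink Cα distances against a threshold, plus the satisfied fraction."""

    links: list[LinkReport]
    threshold: float

    @property
    def fraction_satisfied(self) -> float:
        if not self.links:
            return float("nan")
        return sum(l.satisfied for l in self.links) / len(self.links)


def flat_harmonic(dist, params: FlatHarmonicParams = FlatHarmonicParams()):
    """Flat-harmonic restraint penalty (vectorized over ``dist``)."""
    d = np.asarray(dist, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    excess = np.maximum(d - params.x0 - params.tolerance, 0.0)
    out = (excess / params.sigma) ** 2
    return float(out) if np.isscalar(dist) else out


def max_linker_distance(geometry: LinkerGeometry = LinkerGeometry()) -> float:
    """Maximal Cα–Cα distance bridgeable by the crosslinker (Å):
    spacer + 2 x side-chain reach (DSS/Lys: 11.4 + 6.4 + 6.4 = 24.2 ≈ 24 Å)."""
    return geometry.spacer_length + 2 * geometry.sidechain_length


def satisfaction(
    structure: Structure,
    crosslinks: Iterable[CrosslinkRecord],
    threshold: float = 30.0,
) -> SatisfactionReport:
    """Measure each crosslink's Cα–Cα distance in ``structure`` and compare to
    ``threshold`` (satisfied means distance < threshold)."""
    links = list(crosslinks)
    bad = [
        xl for xl in links
        if not (structure.has_atom(xl.chain1, xl.res1)
                and structure.has_atom(xl.chain2, xl.res2))
    ]
    if bad:
        addrs = ", ".join(
            f"{xl.chain1}/{xl.res1}-{xl.chain2}/{xl.res2}" for xl in bad
        )
        raise KeyError(f"crosslink residues not resolvable to a CA: {addrs}")
    reports = []
    for xl in links:
        a = structure.get_atom(xl.chain1, xl.res1).xyz
        b = structure.get_atom(xl.chain2, xl.res2).xyz
        d = float(np.linalg.norm(a - b))
        reports.append(LinkReport(xl.chain1, xl.res1, xl.chain2, xl.res2,
                                  d, d < threshold))
    return SatisfactionReport(links=reports, threshold=threshold)


def decoy_fdr(
    matches: Sequence[CrosslinkRecord],
    n_decoy_copies: int = 10,
    fdr_threshold: float = 0.05,
) -> tuple[float, list[CrosslinkRecord]]:
    """Decoy-counting FDR filter for crosslink identifications.

    The decoy database is the target sequence set randomized ``n_decoy_copies``
    times and appended, so decoy counts are divided by the copy number:
    FDR(s) = (decoys with score >= s / n_decoy_copies) / max(targets >= s, 1).
    Returns (FDR at the chosen cutoff, targets kept at the loosest score
    cutoff whose FDR is <= ``fdr_threshold``).
    """
    if n_decoy_copies < 1:
        raise ValueError("n_decoy_copies must be >= 1")
    targets = [m for m in matches if not m.is_decoy]
    decoys = [m for m in matches if m.is_decoy]
    if not targets:
        raise ValueError("no target matches to filter")
    t_scores = np.sort(np.array([m.score for m in targets]))[::-1]
    d_scores = np.array([m.score for m in decoys])

    def fdr_at(s: float) -> float:
        n_t = int(np.sum(t_scores >= s))
        n_d = int(np.sum(d_scores >= s))
        return (n_d / n_decoy_copies) / max(n_t, 1)

    # candidate cutoffs are the observed target scores; scan loosest-first
    best_cut = None
    for s in np.unique(t_scores):  # ascending = loosest first
        if fdr_at(s) <= fdr_threshold:
            best_cut = float(s)
            break
    if best_cut is None:
        return (fdr_at(float(t_scores[0])), [])
    kept = [m for m in targets if m.score >= best_cut]
    return (fdr_at(best_cut), kept)
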
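"""Model-selection cascade and ensemble clustering.

An ensemble of scored conformations is narrowed in three stages — energy
ranking, SAXS chi-square cutoff, held-out crosslink satisfaction — then
partitioned by leader clustering on pairwise RMSD (Kabsch superposition on a
rigid alignment subset, RMSD on the flexible subset).  Minor clusters that
contain none of the top-energy models are rejected; each retained cluster is
represented by its lowest-energy member.

All orderings are fully deterministic: ties break by ascending energy, then
ascending model id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .structio import Structure

__all__ = [
    "EnsembleEntry",
    "CascadeConfig",
    "CascadeResult",
    "ClusterResult",
    "SelectionResult",
    "filter_cascade",
    "superpose",
    "superpose_structures",
    "rmsd_cluster",
    "select_representatives",
]


@dataclass
class EnsembleEntry:
    """One sampled model with the scores the cascade consumes."""

    model_id: int
    structure: Structure
    energy: float
    chi2: float | None = None
    link_distances: dict[tuple, float] = field(default_factory=dict)


@dataclass
class CascadeConfig:
    top_n_energy: int = 500
    chi_cutoff: float = 2.0
    link_threshold: float = 30.0
    rmsd_cutoff: float = 2.5
    min_cluster_size: int = 14
    top_k_energy: int = 10

    def __post_init__(self):
        for name in ("top_n_energy", "chi_cutoff", "link_threshold",
                     "rmsd_cutoff", "min_cluster_size", "top_k_energy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CascadeResult:
    """Survivor id sets after each stage, plus a count log."""

    after_energy: list[int]
    after_chi2: list[int]
    after_heldout: list[int]
    counts: dict[str, int]

    @property
    def final_ids(self) -> list[int]:
        return self.after_heldout


@dataclass
class ClusterResult:
    """Clusters as member-id lists ordered by size (desc), representatives =
    lowest-energy member of each cluster."""

    clusters: list[list[int]]
    representatives: list[int]
    excluded_minor: list[int] = field(default_factory=list)


@dataclass
class SelectionResult:
    retained_clusters: list[list[int]]
    representatives: list[int]
    rejected_ids: list[int]


def _entry_order(e: EnsembleEntry) -> tuple[float, int]:
    return (e.energy, e.model_id)


def filter_cascade(
    entries: Sequence[EnsembleEntry], cfg: CascadeConfig = CascadeConfig()
) -> CascadeResult:
    """Run the three-stage selection cascade.

    Stage A keeps the ``top_n_energy`` lowest-energy entries; stage B keeps
    chi2 < chi_cutoff; stage C keeps entries whose every held-out crosslink
    distance is below ``link_threshold``.
    """
    if not entries:
        raise ValueError("empty ensemble")
    ranked = sorted(entries, key=_entry_order)
    stage_a = ranked[: cfg.top_n_energy]
    if not stage_a:
        raise ValueError("cascade stage 'energy' left no survivors")

    def _chi(e: EnsembleEntry) -> float:
        if e.chi2 is None:
            raise ValueError(f"entry {e.model_id} has no chi2 score")
        return e.chi2

    stage_b = [e for e in stage_a if _chi(e) < cfg.chi_cutoff]
    if not stage_b:
        raise ValueError("cascade stage 'chi2' left no survivors")
    stage_c = [
        e for e in stage_b
        if all(d < cfg.link_threshold for d in e.link_distances.values())
    ]
    if not stage_c:
        raise ValueError("cascade stage 'heldout-crosslink' left no survivors")
    return CascadeResult(
        after_energy=[e.model_id for e in stage_a],
        after_chi2=[e.model_id for e in stage_b],
        after_heldout=[e.model_id for e in stage_c],
        counts={
            "input": len(entries),
            "energy": len(stage_a),
            "chi2": len(stage_b),
            "heldout": len(stage_c),
        },
    )


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Kabsch least-squares superposition of point sets (N, 3).

    Returns (rotation R, translation t, rmsd) such that mobile @ R.T + t best
    fits reference; R is a proper rotation (det = +1).
    """
    X = np.asarray(mobile, dtype=float)
    Y = np.asarray(reference, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("point sets must both be (N, 3)")
    if len(X) < 3:
        raise ValueError("need at least 3 points to superpose")
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    X0, Y0 = X - xc, Y - yc
    H = X0.T @ Y0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9 * max(S[0], 1.0):
        raise ValueError("points are collinear; rotation is ill-defined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = yc - R @ xc
    moved = X @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Y) ** 2, axis=1))))
    return R, t, rmsd


def superpose_structures(
    mobile: Structure,
    reference: Structure,
    atom_subset: Iterable[tuple[str, int]] | None = None,
    atom_name: str = "CA",
) -> tuple[np.ndarray, np.ndarray, float]:
    """Superpose two structures on the CA atoms of ``atom_subset`` residue
    addresses (all shared residues if None)."""
    if atom_subset is None:
        addrs = [a for a in mobile.residue_addresses()
                 if reference.has_atom(*a, atom_name)]
    else:
        addrs = list(atom_subset)
    X = np.array([mobile.get_atom(*a, atom_name).xyz for a in addrs])
    Y = np.array([reference.get_atom(*a, atom_name).xyz for a in addrs])
    return superpose(X, Y)


def _subset_coords(structure: Structure,
                   addrs: Sequence[tuple[str, int]]) -> np.ndarray:
    return np.array([structure.get_atom(*a).xyz for a in addrs])


def rmsd_cluster(
    entries: Sequence[EnsembleEntry],
    cfg: CascadeConfig = CascadeConfig(),
    align_subset: Sequence[tuple[str, int]] | None = None,
    cluster_subset: Sequence[tuple[str, int]] | None = None,
) -> ClusterResult:
    """Leader clustering by RMSD.

    Entries are visited by ascending (energy, model_id); each joins the first
    existing cluster whose leader is within ``cfg.rmsd_cutoff`` (RMSD over
    ``cluster_subset`` after superposition on ``align_subset``), else founds a
    new cluster.  Clusters are then sorted by size (desc, ties by leader
    order).  The representative of a cluster is its lowest-energy member.
    """
    if not entries:
        raise ValueError("no entries to cluster")
    ordered = sorted(entries, key=_entry_order)
    ref = ordered[0].structure
    if align_subset is None:
        align_subset = ref.residue_addresses()
    if cluster_subset is None:
        cluster_subset = ref.residue_addresses()
    align_subset = list(align_subset)
    cluster_subset = list(cluster_subset)

    leaders: list[EnsembleEntry] = []
    members: list[list[EnsembleEntry]] = []
    for e in ordered:
        placed = False
        for li, leader in enumerate(leaders):
            r = _pair_rmsd(e.structure, leader.structure,
                           align_subset, cluster_subset)
            if r < cfg.rmsd_cutoff:
                members[li].append(e)
                placed = True
                break
        if not placed:
            leaders.append(e)
            members.append([e])
    order = sorted(range(len(members)),
                   key=lambda i: (-len(members[i]), i))
    clusters = [[m.model_id for m in members[i]] for i in order]
    reps = [min(members[i], key=_entry_order).model_id for i in order]
    return ClusterResult(clusters=clusters, representatives=reps)


def _pair_rmsd(
    mobile: Structure,
    reference: Structure,
    align_subset: Sequence[tuple[str, int]],
    cluster_subset: Sequence[tuple[str, int]],
) -> float:
    R, t, _ = superpose(
        _subset_coords(mobile, align_subset),
        _subset_coords(reference, align_subset),
    )
    X = _subset_coords(mobile, cluster_subset) @ R.T + t
    Y = _subset_coords(reference, cluster_subset)
    return float(np.sqrt(np.mean(np.sum((X - Y) ** 2, axis=1))))


def select_representatives(
    cluster_result: ClusterResult,
    entries: Sequence[EnsembleEntry],
    cfg: CascadeConfig = CascadeConfig(),
) -> SelectionResult:
    """Reject minor clusters and pick representatives.

    A cluster is rejected iff its size is below ``cfg.min_cluster_size`` AND
    it contains none of the ``cfg.top_k_energy`` lowest-energy models of the
    clustered set; representatives are the lowest-energy member of each
    retained cluster.
    """
    by_id = {e.model_id: e for e in entries}
    clustered_ids = [mid for c in cluster_result.clusters for mid in c]
    top_k = {
        e.model_id
        for e in sorted((by_id[m] for m in clustered_ids), key=_entry_order)
        [: cfg.top_k_energy]
    }
    retained, reps, rejected = [], [], []
    for cluster in cluster_result.clusters:
        minor = len(cluster) < cfg.min_cluster_size
        has_top = any(m in top_k for m in cluster)
        if minor and not has_top:
            rejected.extend(cluster)
        else:
            retained.append(cluster)
            reps.append(min((by_id[m] for m in cluster), key=_entry_order).model_id)
    if not retained:
        raise ValueError("all clusters rejected as minor")
    return SelectionResult(retained_clusters=retained, representatives=reps,
                           rejected_ids=rejected)
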
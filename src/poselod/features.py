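"""Per-pose feature vectors for log-odds rescoring.

For every docked pose the screen evaluates three kinds of features: the
predicted binding affinity (raw and z-normalized across the target's pose
population), the closest heavy-atom distance to the catalytic-site center of
mass, and the size of the spatial cluster the pose belongs to.  These are the
inputs Q_f(X) to the log-odds score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import Atom, GridBox, Pose

__all__ = [
    "TargetSite",
    "PoseFeatures",
    "DEFAULT_SITE_RESIDUES",
    "center_of_mass",
    "geometric_center",
    "resolve_site",
    "distance_to_site",
    "normalize_affinity",
    "compute_pose_features",
]

#: Catalytic residues used by default to define each kinase's target site:
#: the ATP-site lysine and the two catalytic aspartates for VEGFR-2, and the
#: catalytic-loop His/Asp plus the DFG aspartate for c-Met.
DEFAULT_SITE_RESIDUES: dict[str, tuple[int, ...]] = {
    "VEGFR-2": (868, 1028, 1046),   # Lys868, Asp1028, Asp1046
    "c-Met": (1204, 1202, 1222),    # Asp1204, His1202, Asp1222
}


@dataclass
class TargetSite:
    """A receptor's catalytic site: the resolved site atoms, an optional grid
    box, and the derived site center of mass (Å)."""

    target_id: str
    site_atoms: list[Atom]
    box: GridBox | None = None
    use_mass_weighting: bool = True
    site_com: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not self.site_atoms:
            raise ValueError(f"target site {self.target_id!r}: no site atoms resolved")
        self.site_com = (
            center_of_mass(self.site_atoms) if self.use_mass_weighting
            else geometric_center(self.site_atoms)
        )


@dataclass(frozen=True)
class PoseFeatures:
    """The feature vector of one docked pose.

    ``affinity_norm`` is the per-target z-score of the affinity over all poses
    of all drugs; ``dist_to_site`` is the closest heavy-atom distance to the
    site COM (Å); cluster sizes come from the COM-based and adjacency-based
    labelings.
    """

    drug_id: str
    target_id: str
    pose_index: int
    affinity_raw: float
    affinity_norm: float
    dist_to_site: float
    cluster_size_com: int
    cluster_size_adj: int

    def __post_init__(self) -> None:
        if self.dist_to_site < 0:
            raise ValueError("dist_to_site must be >= 0")
        if self.cluster_size_com < 1 or self.cluster_size_adj < 1:
            raise ValueError("cluster sizes must be >= 1")


def center_of_mass(atoms: Sequence[Atom]) -> np.ndarray:
    """Mass-weighted mean position (Å) of an atom list."""
    if not atoms:
        raise ValueError("center_of_mass of an empty atom list")
    coords = np.array([a.coords for a in atoms], dtype=float)
    masses = np.array([a.mass for a in atoms], dtype=float)
    return masses @ coords / masses.sum()


def geometric_center(atoms: Sequence[Atom]) -> np.ndarray:
    """Unweighted centroid (Å); offered as a sensitivity check alongside the
    mass-weighted COM."""
    if not atoms:
        raise ValueError("geometric_center of an empty atom list")
    return np.array([a.coords for a in atoms], dtype=float).mean(axis=0)


def resolve_site(
    target_id: str,
    receptor_atoms: Sequence[Atom],
    selectors: Sequence[tuple[int, str | None]] | None = None,
    box: GridBox | None = None,
) -> TargetSite:
    """Resolve residue/atom selectors against a receptor structure.

    Each selector is ``(residue_number, atom_name-or-None)``; ``None`` takes
    every atom of the residue.  Without explicit selectors the default
    catalytic residues for the target are used (all atoms per residue).
    """
    if selectors is None:
        residues = DEFAULT_SITE_RESIDUES.get(target_id)
        if residues is None:
            raise ValueError(
                f"no default site residues for target {target_id!r}; pass explicit selectors"
            )
        selectors = [(r, None) for r in residues]
    chosen: list[Atom] = []
    for resnum, atom_name in selectors:
        hits = [
            a for a in receptor_atoms
            if a.residue_number == resnum and (atom_name is None or a.name == atom_name)
        ]
        if not hits:
            raise ValueError(f"selector ({resnum}, {atom_name!r}) matched no atoms in {target_id}")
        chosen.extend(hits)
    return TargetSite(target_id=target_id, site_atoms=chosen, box=box)


def distance_to_site(pose: Pose, site: TargetSite, heavy_only: bool = True) -> float:
    """Closest distance (Å) from the pose's atoms to the site center of mass.

    Hydrogens are excluded by default: docking hydrogens are placement
    artifacts and would otherwise dominate the minimum.
    """
    atoms = pose.heavy_atoms() if heavy_only else pose.atoms
    if not atoms:
        atoms = pose.atoms  # all-hydrogen pose: fall back rather than fail
    coords = np.array([a.coords for a in atoms], dtype=float)
    return float(np.min(np.linalg.norm(coords - site.site_com, axis=1)))


def normalize_affinity(affinities: Sequence[float]) -> np.ndarray:
    """Population z-scores of the affinities of all poses for one target.

    A degenerate (constant) population maps to all zeros.  The transform is
    monotone, so pose ordering by affinity is preserved.
    """
    arr = np.asarray(affinities, dtype=float)
    if arr.size == 0:
        raise ValueError("normalize_affinity of an empty list")
    sd = arr.std()  # population SD (ddof=0)
    if sd == 0:
        return np.zeros_like(arr)
    return (arr - arr.mean()) / sd


def compute_pose_features(
    poses: Sequence[Pose],
    site: TargetSite,
    cluster_labels_com: Mapping[tuple[str, int], int] | None = None,
    cluster_labels_adj: Mapping[tuple[str, int], int] | None = None,
    heavy_only: bool = True,
) -> list[PoseFeatures]:
    """Assemble one :class:`PoseFeatures` per pose.

    ``cluster_labels_*`` map ``(drug_id, pose_index)`` to a cluster id within
    the drug; every pose must be labeled (an unlabeled pose raises an error
    naming it).  Missing labelings default every pose to a singleton cluster.
    Poses with absent affinity are rejected.
    """
    for p in poses:
        if p.affinity is None:
            raise ValueError(f"pose {p.drug_id}#{p.pose_index} has no affinity; cannot compute features")
    norm = normalize_affinity([p.affinity for p in poses])

    def _sizes(labels: Mapping[tuple[str, int], int] | None) -> dict[tuple[str, int], int]:
        if labels is None:
            return {(p.drug_id, p.pose_index): 1 for p in poses}
        counts: dict[tuple[str, int], int] = {}
        for key, cid in labels.items():
            counts[(key[0], cid)] = counts.get((key[0], cid), 0) + 1
        sizes = {}
        for p in poses:
            key = (p.drug_id, p.pose_index)
            if key not in labels:
                raise ValueError(f"pose {p.drug_id}#{p.pose_index} missing from cluster labeling")
            sizes[key] = counts[(p.drug_id, labels[key])]
        return sizes

    sizes_com = _sizes(cluster_labels_com)
    sizes_adj = _sizes(cluster_labels_adj)
    out = []
    for p, z in zip(poses, norm):
        key = (p.drug_id, p.pose_index)
        out.append(
            PoseFeatures(
                drug_id=p.drug_id,
                target_id=p.target_id,
                pose_index=p.pose_index,
                affinity_raw=float(p.affinity),
                affinity_norm=float(z),
                dist_to_site=distance_to_site(p, site, heavy_only=heavy_only),
                cluster_size_com=sizes_com[key],
                cluster_size_adj=sizes_adj[key],
            )
        )
    return out
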
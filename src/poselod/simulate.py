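"""Synthetic inputs with known ground truth for every pipeline stage.

The generator is feature-first: it draws each pose's feature values (affinity,
distance to the site, cluster mode) from the binder/decoy laws and then
realizes a small rigid point set whose computed features reproduce the drawn
values exactly.  That gives the tests exact ground truth, which physical
emulation of docking cannot.  What it deliberately does not emulate: real
ligand topology and flexibility, receptor contacts, force-field energetics,
or property-matched decoys.

Stream discipline: every drug and every trajectory draws from its own named
substream (seeded by ``(seed, index)``), so adding a drug or series never
perturbs the others and all outputs are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import Atom, Pose, TrajectoryFrame, element_mass
from .lod import BinderLabel
from .md import DistanceSeries

__all__ = [
    "ScreenSimParams",
    "TrajSimParams",
    "gen_screen_library",
    "gen_distance_series",
    "gen_toy_complex",
]


@dataclass(frozen=True)
class ScreenSimParams:
    """Parameters of a synthetic screening library.

    The defaults emulate the statistical structure a pose-rescoring screen
    assumes: 20 sampled poses per drug; binder affinities around -8.5 kcal/mol
    versus decoys around -6.5 (SD 0.5 each, matching the spread of the
    candidate affinities the screen ranks); binder poses landing ~3 Å from the
    catalytic-site COM versus ~10 Å for decoys; binder poses concentrated on a
    few orientation modes (large clusters) while decoy poses scatter over
    many.
    """

    n_drugs: int = 100
    n_binders: int = 20
    n_poses_per_drug: int = 20
    mu_aff_true: float = -8.5   # kcal/mol
    mu_aff_false: float = -6.5
    sd_aff_true: float = 0.5
    sd_aff_false: float = 0.5
    mu_dist_true: float = 3.0   # Å to site COM
    mu_dist_false: float = 10.0
    sd_dist_true: float = 1.0
    sd_dist_false: float = 3.0
    n_modes_true: int = 2       # orientation modes binder poses concentrate on
    n_modes_false: int = 12
    mode_jitter: float = 0.05   # radians of angular scatter within a mode
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_binders <= self.n_drugs:
            raise ValueError("need 1 <= n_binders <= n_drugs")
        for s in (self.sd_aff_true, self.sd_aff_false, self.sd_dist_true, self.sd_dist_false):
            if not s > 0:
                raise ValueError("all SDs must be positive")


@dataclass(frozen=True)
class TrajSimParams:
    """Parameters of one synthetic interaction-distance trajectory: a
    stationary AR(1) process around ``mu`` Å with marginal SD ``sigma`` and
    lag-1 autocorrelation ``ar1_phi``, sampled every ``frame_interval`` ns
    starting at ``t_start`` (the default places 100 frames over the trailing
    10 ns of a 50 ns production run)."""

    mu: float
    sigma: float
    n_frames: int = 100
    frame_interval: float = 0.1  # ns
    t_start: float = 40.0        # ns
    ar1_phi: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0 <= self.ar1_phi < 1:
            raise ValueError(f"ar1_phi must lie in [0, 1), got {self.ar1_phi}")


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return _unit(v)


def _perturb_direction(u: np.ndarray, jitter: float, rng: np.random.Generator) -> np.ndarray:
    return _unit(u + jitter * rng.normal(size=3))


#: Radial spacing (Å) between the atoms of a generated 3-atom pose.
_POSE_ATOM_SPREAD = 1.0


def gen_screen_library(
    p: ScreenSimParams,
) -> tuple[list[Pose], list[BinderLabel], pd.DataFrame]:
    """Generate a labeled synthetic pose library with the site COM at the
    origin.

    Each pose is three collinear carbon atoms placed radially so that the
    closest atom sits exactly at the drawn site distance; the pose direction
    comes from one of the drug's orientation modes.  Drugs ``B000..`` are
    binders (label T), ``D000..`` decoys (label F).  Returns the poses, the
    binder labels, and a ground-truth table (drug_id, pose_index, affinity,
    dist_true, mode, is_binder).
    """
    poses: list[Pose] = []
    labels: list[BinderLabel] = []
    truth_rows = []
    c_mass = element_mass("C")
    for d in range(p.n_drugs):
        is_binder = d < p.n_binders
        drug_id = f"{'B' if is_binder else 'D'}{d:03d}"
        rng = np.random.default_rng(np.random.SeedSequence([p.seed, d]))
        labels.append(BinderLabel(drug_id, "T" if is_binder else "F"))
        n_modes = p.n_modes_true if is_binder else p.n_modes_false
        modes = [_random_unit(rng) for _ in range(n_modes)]
        mu_a = p.mu_aff_true if is_binder else p.mu_aff_false
        sd_a = p.sd_aff_true if is_binder else p.sd_aff_false
        mu_d = p.mu_dist_true if is_binder else p.mu_dist_false
        sd_d = p.sd_dist_true if is_binder else p.sd_dist_false
        for k in range(1, p.n_poses_per_drug + 1):
            affinity = float(rng.normal(mu_a, sd_a))
            dist = float(abs(rng.normal(mu_d, sd_d)))
            mode_idx = int(rng.integers(n_modes))
            u = _perturb_direction(modes[mode_idx], p.mode_jitter, rng)
            atoms = [
                Atom(name=f"C{j + 1}", element="C",
                     coords=tuple((dist + j * _POSE_ATOM_SPREAD) * u),
                     residue_name="LIG", residue_number=1, mass=c_mass)
                for j in range(3)
            ]
            poses.append(Pose(drug_id=drug_id, target_id="synthetic",
                              pose_index=k, atoms=atoms, affinity=affinity))
            truth_rows.append(
                {"drug_id": drug_id, "pose_index": k, "affinity": affinity,
                 "dist_true": dist, "mode": mode_idx, "is_binder": is_binder}
            )
    return poses, labels, pd.DataFrame(truth_rows)


def gen_distance_series(
    p: TrajSimParams,
    drug_id: str = "",
    target_id: str = "",
    interaction_label: str = "",
) -> DistanceSeries:
    """Simulate a stationary AR(1) distance series, clipped at 0 Å.

    x_0 ~ N(mu, sigma); x_t = mu + phi (x_{t-1} - mu) + eps_t with
    eps_t ~ N(0, sigma * sqrt(1 - phi^2)), so the marginal law is N(mu, sigma)
    at every t and the lag-1 autocorrelation is phi.
    """
    rng = np.random.default_rng(np.random.SeedSequence([p.seed]))
    x = np.empty(p.n_frames)
    x[0] = rng.normal(p.mu, p.sigma)
    innov_sd = p.sigma * np.sqrt(1.0 - p.ar1_phi**2)
    eps = rng.normal(0.0, innov_sd, size=p.n_frames - 1)
    for t in range(1, p.n_frames):
        x[t] = p.mu + p.ar1_phi * (x[t - 1] - p.mu) + eps[t - 1]
    x = np.clip(x, 0.0, None)
    times = p.t_start + p.frame_interval * np.arange(p.n_frames)
    return DistanceSeries(
        drug_id=drug_id, target_id=target_id, interaction_label=interaction_label,
        times=times, distances=x, window=(float(times[0]), float(times[-1])),
    )


def gen_toy_complex(spec: dict) -> tuple[list[Atom], list[Pose], list[TrajectoryFrame]]:
    """Build a small receptor + ligand system from an explicit geometry spec.

    ``spec`` keys:

    * ``receptor``: list of atom dicts (name, element, coords, residue_name,
      residue_number);
    * ``ligand_poses``: list of ``{"affinity": float, "atoms": [atom dicts]}``
      (residue defaults to LIG 1);
    * ``trajectory`` (optional): ``{"n_frames", "frame_interval",
      "translate"}`` — frames hold receptor + first ligand pose, with the
      ligand translated by ``translate`` (Å/frame) each frame.

    Output structures round-trip exactly through the PDBQT/PDB writers.
    """

    def _atom(d: dict, default_res: tuple[str, int] | None = None) -> Atom:
        resname = d.get("residue_name", default_res[0] if default_res else "")
        resnum = d.get("residue_number", default_res[1] if default_res else 0)
        elem = d["element"]
        return Atom(name=d["name"], element=elem, coords=tuple(float(c) for c in d["coords"]),
                    residue_name=resname, residue_number=resnum,
                    chain_id=d.get("chain_id", ""), mass=element_mass(elem))

    receptor = [_atom(d) for d in spec.get("receptor", [])]
    if not receptor:
        raise ValueError("toy complex spec has no receptor atoms")
    pose_specs = spec.get("ligand_poses", [])
    poses = []
    for i, ps in enumerate(pose_specs, start=1):
        atoms = [_atom(d, default_res=("LIG", 1)) for d in ps.get("atoms", [])]
        if not atoms:
            raise ValueError(f"ligand pose {i} has no atoms")
        poses.append(Pose(drug_id=spec.get("drug_id", "toy"), target_id=spec.get("target_id", "toy"),
                          pose_index=i, atoms=atoms, affinity=ps.get("affinity")))
    frames: list[TrajectoryFrame] = []
    traj = spec.get("trajectory")
    if traj:
        if not poses:
            raise ValueError("trajectory spec requires at least one ligand pose")
        shift = np.asarray(traj.get("translate", (0.0, 0.0, 0.0)), dtype=float)
        interval = float(traj.get("frame_interval", 0.1))
        for k in range(int(traj["n_frames"])):
            moved = [
                Atom(name=a.name, element=a.element,
                     coords=tuple(np.asarray(a.coords) + k * shift),
                     residue_name=a.residue_name, residue_number=a.residue_number,
                     chain_id=a.chain_id, mass=a.mass)
                for a in poses[0].atoms
            ]
            frames.append(TrajectoryFrame(time=k * interval, atoms=receptor + moved))
    return receptor, poses, frames
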
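"""Shared fixtures: tiny poses, synthetic AutoDock logs, toy trajectories."""

from __future__ import annotations

import numpy as np
import pytest

from poselod.io import Atom, Pose


def make_pose(coords, drug_id="drug", target_id="t", pose_index=1, affinity=-8.0,
              element="C"):
    """A pose from a bare list of 3-vectors (equal-mass atoms)."""
    atoms = [
        Atom(name=f"{element}{i + 1}", element=element, coords=tuple(map(float, c)),
             residue_name="LIG", residue_number=1, mass=12.011)
        for i, c in enumerate(coords)
    ]
    return Pose(drug_id=drug_id, target_id=target_id, pose_index=pose_index,
                atoms=atoms, affinity=affinity)


def make_dlg_text(energies, truncate_after=None):
    """AutoDock 4-style docking log with one energy record per run.

    ``truncate_after=k`` keeps the first k complete records and then a run
    header whose energy line is missing (a mid-record truncation).
    """
    lines = ["AutoDock 4.2 Release", ""]
    for i, e in enumerate(energies, start=1):
        lines.append(f"Run:   {i} / {len(energies)}")
        if truncate_after is not None and i > truncate_after:
            break
        lines.append("DOCKED: USER")
        lines.append(f"DOCKED: USER    Estimated Free Energy of Binding    =  {e:7.2f} kcal/mol")
        lines.append("")
    return "\n".join(lines) + "\n"


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_poses(rng, n, max_atoms=3, box=15.0):
    """Random small poses for clustering property tests."""
    out = []
    for i in range(1, n + 1):
        k = int(rng.integers(1, max_atoms + 1))
        center = rng.uniform(0, box, size=3)
        coords = center + rng.uniform(-1.5, 1.5, size=(k, 3))
        out.append(make_pose(coords, pose_index=i))
    return out
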
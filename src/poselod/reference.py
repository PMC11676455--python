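"""Bundled reference tables for the c-Met / VEGFR-2 dual-inhibitor screen.

Three small TSVs ship with the package as worked inputs:

* ``candidates.tsv`` — the 11 top-ranked candidate drugs with per-target
  binding affinity (kcal/mol), proximity to the catalytic site (Å), and LOD
  score; crizotinib (c-Met) and cabozantinib (VEGFR-2) are the controls.
* ``interactions_cmet.tsv`` / ``interactions_vegfr2.tsv`` — published
  per-drug mean interaction distances (Å, mean ± dispersion) at key catalytic
  residues, with the printed drug-minus-control differences and significance
  flags (``control`` marks the control drug's own row).

These are summary-level inputs for the ranking and table-arithmetic
operations; the underlying docking poses and MD trajectories are not
recomputable from them (use :mod:`poselod.simulate` for full-pipeline
inputs with ground truth).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .lod import LodResult, rank_drugs, select_dual_candidates

__all__ = [
    "CONTROLS",
    "load_candidate_table",
    "load_interaction_table",
    "candidate_ranking",
    "dual_candidates_from_table",
    "significant_diff_range",
]

#: Control drug per target.
CONTROLS = {"c-Met": "Crizotinib", "VEGFR-2": "Cabozantinib"}

_TARGET_KEY = {"c-Met": "cmet", "VEGFR-2": "vegfr2"}


def _read(name: str) -> pd.DataFrame:
    with resources.files("poselod.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["-"])


def load_candidate_table() -> pd.DataFrame:
    """The 11-candidate comparison table (affinity, proximity, LOD per target)."""
    return _read("candidates.tsv")


def load_interaction_table(target: str) -> pd.DataFrame:
    """Long-format interaction-distance summary for one target.

    Columns: drug, interaction (``Residue:Atom``), mean (Å), dispersion (Å),
    flag (``***``/``NS``/``control``), diff (Å vs the control's mean).
    """
    key = _TARGET_KEY.get(target)
    if key is None:
        raise ValueError(f"unknown target {target!r}; expected one of {sorted(_TARGET_KEY)}")
    return _read(f"interactions_{key}.tsv")


def candidate_ranking(target: str) -> list[LodResult]:
    """Rank the bundled candidates for one target by their LOD column.

    Each table row stands for a drug's best pose, so the drug's best LOD is
    the printed LOD and the tie-break affinity is the printed affinity.
    """
    key = _TARGET_KEY.get(target)
    if key is None:
        raise ValueError(f"unknown target {target!r}; expected one of {sorted(_TARGET_KEY)}")
    df = load_candidate_table()
    results = [
        LodResult(
            drug_id=row["drug"],
            target_id=target,
            pose_lods={1: float(row[f"lod_{key}"])},
            best_lod=float(row[f"lod_{key}"]),
            best_pose_affinity=float(row[f"affinity_{key}"]),
        )
        for _, row in df.iterrows()
    ]
    return rank_drugs(results)


def dual_candidates_from_table(k: int = 3, exclude_controls: bool = True) -> list[str]:
    """Dual-target candidates from the bundled table: non-control drugs in the
    top-k LOD ranking of both targets."""
    controls = tuple(CONTROLS.values()) if exclude_controls else ()
    return select_dual_candidates(
        candidate_ranking("c-Met"), candidate_ranking("VEGFR-2"), k=k, controls=controls
    )


def significant_diff_range(target: str, drug: str) -> tuple[float, float]:
    """(min, max) of a drug's significant mean differences vs the control
    across the interactions of one target (rows flagged NS are excluded)."""
    df = load_interaction_table(target)
    rows = df[(df["drug"] == drug) & (df["flag"].isin(["***", "*"])) & df["diff"].notna()]
    if rows.empty:
        raise ValueError(f"no significant interactions for {drug!r} on {target!r}")
    return float(rows["diff"].min()), float(rows["diff"].max())
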
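"""Interaction-distance statistics over MD trajectory windows.

Given production-run frames (or precomputed per-frame distance tables), this
module extracts ligand-to-residue-atom distance series over a trailing
analysis window (the final 10 ns by default), summarizes each series
(mean ± dispersion), compares each drug with a control drug by a two-sided
Welch t-test with a 95% confidence interval on the mean difference, flags
significance, and renders the drug × interaction summary table.  It also
provides RMSD (after Kabsch superposition) and per-residue RMSF summaries.

Interpretation choices that the inputs leave open are explicit parameters:
the ± dispersion defaults to the standard error of the mean (SD available via
``dispersion="sd"``), frames are treated as independent observations for the
tests (an optional block-averaging correction addresses autocorrelation), and
the significance conventions are ``***`` for p < 1e-4, ``NS`` for p > 0.05,
and ``*`` between.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Atom, TrajectoryFrame

__all__ = [
    "AtomSelector",
    "DistanceSeries",
    "InteractionSummary",
    "extract_distance_series",
    "summarize_series",
    "mean_difference",
    "format_signed",
    "welch_test",
    "significance_flag",
    "compare_to_control",
    "build_interaction_table",
    "rmsd_series",
    "rmsf_per_residue",
    "kabsch_superpose",
]

Dispersion = Literal["sem", "sd"]

P_HIGH = 1e-4   # "***": highly significant
P_NS = 0.05     # "NS": not significant


@dataclass(frozen=True)
class AtomSelector:
    """Selects atoms of a frame by residue name/number and/or atom name.

    ``heavy_only`` drops hydrogens (the default for ligand selections, where
    hydrogen placement is an artifact of system preparation).
    """

    residue_name: str | None = None
    residue_number: int | None = None
    atom_name: str | None = None
    heavy_only: bool = True

    def select(self, atoms: Sequence[Atom]) -> list[Atom]:
        out = [
            a for a in atoms
            if (self.residue_name is None or a.residue_name == self.residue_name)
            and (self.residue_number is None or a.residue_number == self.residue_number)
            and (self.atom_name is None or a.name == self.atom_name)
            and (not self.heavy_only or a.is_heavy)
        ]
        return out

    def label(self) -> str:
        parts = [p for p in (self.residue_name, str(self.residue_number or ""), self.atom_name) if p]
        return ":".join(parts) or "*"


@dataclass
class DistanceSeries:
    """Per-frame minimum ligand-to-residue-atom distances (Å) over a window."""

    drug_id: str
    target_id: str
    interaction_label: str
    times: np.ndarray
    distances: np.ndarray
    window: tuple[float, float]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.shape != self.distances.shape:
            raise ValueError("times and distances must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.distances < 0):
            raise ValueError("distances must be >= 0")


@dataclass
class InteractionSummary:
    """Summary of one drug × interaction cell: mean ± dispersion over the
    window frames, and — when compared against a control — the mean
    difference, Welch p-value, 95% CI, and significance flag."""

    drug_id: str
    interaction_label: str
    mean: float
    dispersion: float
    n_frames: int
    mean_diff_vs_control: float | None = None
    p_value: float | None = None
    ci95: tuple[float, float] | None = None
    flag: str | None = None


def extract_distance_series(
    frames: Sequence[TrajectoryFrame],
    ligand_selector: AtomSelector,
    residue_atom_selector: AtomSelector,
    window: tuple[float, float],
    drug_id: str = "",
    target_id: str = "",
) -> DistanceSeries:
    """Per-frame minimum distance between the selected ligand heavy atoms and
    the named residue atom(s), restricted to frames inside ``window`` (ns,
    inclusive)."""
    start, end = window
    if not end > start:
        raise ValueError(f"empty analysis window {window}")
    times, dists = [], []
    for k, fr in enumerate(frames):
        lig = ligand_selector.select(fr.atoms)
        res = residue_atom_selector.select(fr.atoms)
        if not lig:
            raise ValueError(f"ligand selector {ligand_selector.label()!r} matched no atoms in frame {k + 1}")
        if not res:
            raise ValueError(f"residue selector {residue_atom_selector.label()!r} matched no atoms in frame {k + 1}")
        if not (start <= fr.time <= end):
            continue
        lc = np.array([a.coords for a in lig])
        rc = np.array([a.coords for a in res])
        d = np.linalg.norm(lc[:, None, :] - rc[None, :, :], axis=2).min()
        times.append(fr.time)
        dists.append(float(d))
    if not times:
        raise ValueError(f"no frames fall inside window {window}")
    return DistanceSeries(
        drug_id=drug_id, target_id=target_id,
        interaction_label=residue_atom_selector.label(),
        times=np.array(times), distances=np.array(dists), window=window,
    )


def summarize_series(s: DistanceSeries, dispersion: Dispersion = "sem") -> tuple[float, float, int]:
    """Arithmetic mean, dispersion (SEM by default, SD optional; ddof=1), and
    frame count of a distance series."""
    n = s.distances.size
    if n < 2:
        raise ValueError(f"need >= 2 frames to summarize, got {n}")
    mean = float(s.distances.mean())
    sd = float(s.distances.std(ddof=1))
    disp = sd / math.sqrt(n) if dispersion == "sem" else sd
    return mean, disp, n


def mean_difference(drug_mean: float, control_mean: float) -> float:
    """Drug minus control mean distance (Å), rounded to 2 decimals to match
    the parenthetical convention of published interaction tables."""
    if not (math.isfinite(drug_mean) and math.isfinite(control_mean)):
        raise ValueError("means must be finite")
    return round(drug_mean - control_mean, 2)


def format_signed(diff: float) -> str:
    """Render a mean difference with an explicit sign, e.g. ``+7.60``/``-3.55``."""
    return f"{diff:+.2f}"


def welch_test(a: Sequence[float], b: Sequence[float]) -> tuple[float, float, float, tuple[float, float]]:
    """Two-sided Welch (unequal-variance) t-test of two distance samples.

    Returns ``(t, df, p, ci95)`` where the 95% CI is on mean(a) - mean(b).
    Both samples with zero variance and equal means degenerate to p = 1 with a
    CI collapsed at 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        diff = float(a.mean() - b.mean())
        if diff == 0:
            return 0.0, float(a.size + b.size - 2), 1.0, (0.0, 0.0)
        return math.inf if diff > 0 else -math.inf, float(a.size + b.size - 2), 0.0, (diff, diff)
    res = stats.ttest_ind(a, b, equal_var=False)
    ci = res.confidence_interval(0.95)
    return float(res.statistic), float(res.df), float(res.pvalue), (float(ci.low), float(ci.high))


def significance_flag(p: float) -> str:
    """Flag convention: ``***`` if p < 1e-4, ``NS`` if p > 0.05, ``*`` between."""
    if not (0 <= p <= 1):
        raise ValueError(f"p-value outside [0, 1]: {p}")
    if p < P_HIGH:
        return "***"
    if p > P_NS:
        return "NS"
    return "*"


def block_average(x: np.ndarray, block_length: int) -> np.ndarray:
    """Means of consecutive non-overlapping blocks; a simple correction for
    frame autocorrelation before testing (trailing partial block dropped)."""
    x = np.asarray(x, dtype=float)
    n_blocks = x.size // block_length
    if n_blocks < 2:
        raise ValueError("block length leaves fewer than 2 blocks")
    return x[: n_blocks * block_length].reshape(n_blocks, block_length).mean(axis=1)


def compare_to_control(
    series_by_drug: Mapping[str, DistanceSeries],
    control_drug: str,
    dispersion: Dispersion = "sem",
    block_length: int | None = None,
) -> list[InteractionSummary]:
    """Summarize one interaction across drugs and test each non-control drug
    against the control's series.  ``block_length`` switches the test to block
    means (autocorrelation correction); the default tests raw frames."""
    if control_drug not in series_by_drug:
        raise ValueError(f"control drug {control_drug!r} has no series for this interaction")
    ctrl = series_by_drug[control_drug]
    ctrl_sample = ctrl.distances if block_length is None else block_average(ctrl.distances, block_length)
    out = []
    for drug, s in series_by_drug.items():
        mean, disp, n = summarize_series(s, dispersion=dispersion)
        summ = InteractionSummary(drug, s.interaction_label, mean, disp, n)
        if drug != control_drug:
            sample = s.distances if block_length is None else block_average(s.distances, block_length)
            _, _, p, ci = welch_test(sample, ctrl_sample)
            summ.mean_diff_vs_control = mean_difference(mean, float(ctrl.distances.mean()))
            summ.p_value = p
            summ.ci95 = ci
            summ.flag = significance_flag(p)
        out.append(summ)
    return out


def build_interaction_table(
    summaries: Sequence[InteractionSummary],
    control_drug: str,
    interactions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Render drug × interaction summaries as a wide table of formatted cells.

    Cells read ``mean ± dispersion flag (±diff)``; the control row carries no
    parenthetical; absent drug × interaction pairs render as ``-``.
    """
    if interactions is None:
        seen: list[str] = []
        for s in summaries:
            if s.interaction_label not in seen:
                seen.append(s.interaction_label)
        interactions = seen
    by_cell = {(s.drug_id, s.interaction_label): s for s in summaries}
    drugs = []
    for s in summaries:
        if s.drug_id not in drugs:
            drugs.append(s.drug_id)
    if control_drug not in drugs:
        raise ValueError(f"control drug {control_drug!r} absent from summaries")
    for label in interactions:
        if any((d, label) in by_cell for d in drugs) and (control_drug, label) not in by_cell:
            raise ValueError(f"missing control summary for interaction {label!r}")
    rows = {}
    for d in drugs:
        cells = {}
        for label in interactions:
            s = by_cell.get((d, label))
            if s is None:
                cells[label] = "-"
            elif d == control_drug:
                cells[label] = f"{s.mean:.2f} ± {s.dispersion:.2f}"
            else:
                cells[label] = (
                    f"{s.mean:.2f} ± {s.dispersion:.2f} {s.flag} "
                    f"({format_signed(s.mean_diff_vs_control)})"
                )
        rows[d] = cells
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(interactions))
    df.index.name = "drug"
    return df


# ---------------------------------------------------------------------------
# RMSD / RMSF
# ---------------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimally superpose ``mobile`` onto ``reference`` (least-squares rigid
    fit: centroid shift + Kabsch rotation).  Returns the moved coordinates."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError(f"selection mismatch: {mobile.shape} vs {reference.shape}")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    m0, r0 = mobile - mc, reference - rc
    h = m0.T @ r0
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return (rot @ m0.T).T + rc


def _selection_coords(frames: Sequence[TrajectoryFrame], selection: AtomSelector) -> np.ndarray:
    coords = []
    n0 = None
    for k, fr in enumerate(frames):
        sel = selection.select(fr.atoms)
        if n0 is None:
            n0 = len(sel)
            if n0 == 0:
                raise ValueError(f"selection {selection.label()!r} matched no atoms")
        elif len(sel) != n0:
            raise ValueError(f"selection resolves to {len(sel)} atoms in frame {k + 1}, expected {n0}")
        coords.append([a.coords for a in sel])
    return np.asarray(coords, dtype=float)  # (n_frames, n_atoms, 3)


def rmsd_series(
    frames: Sequence[TrajectoryFrame],
    reference: TrajectoryFrame,
    selection: AtomSelector,
    superpose: bool = True,
) -> np.ndarray:
    """Per-frame RMSD (Å) of the selection to the reference, after optimal
    rigid superposition by default (set ``superpose=False`` for raw RMSD)."""
    traj = _selection_coords(frames, selection)
    ref = _selection_coords([reference], selection)[0]
    out = np.empty(len(frames))
    for k, x in enumerate(traj):
        fitted = kabsch_superpose(x, ref) if superpose else x
        out[k] = np.sqrt(((fitted - ref) ** 2).sum(axis=1).mean())
    return out


def rmsf_per_residue(
    frames: Sequence[TrajectoryFrame],
    selection: AtomSelector,
) -> pd.Series:
    """Per-residue RMSF (Å): frames are superposed onto the first frame's
    selection, and each residue's value is the RMS fluctuation of its atoms
    about their time-averaged positions."""
    traj = _selection_coords(frames, selection)
    sel_atoms = selection.select(frames[0].atoms)
    ref = traj[0]
    fitted = np.stack([kabsch_superpose(x, ref) for x in traj])
    mean_pos = fitted.mean(axis=0)
    per_atom_msf = ((fitted - mean_pos) ** 2).sum(axis=2).mean(axis=0)  # (n_atoms,)
    resnums = np.array([a.residue_number for a in sel_atoms])
    out = {}
    for r in sorted(set(resnums.tolist())):
        out[r] = float(np.sqrt(per_atom_msf[resnums == r].mean()))
    return pd.Series(out, name="rmsf_A").rename_axis("residue")
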
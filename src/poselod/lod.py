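"""Log-odds (LOD) rescoring and ranking of docked poses.

The LOD score of a pose X sums, over features f, the log ratio of the
feature's density under true binders (T) versus decoys (F):

    LOD(X) = sum_f log[ P_f^T(Q_f(X)) / P_f^F(Q_f(X)) ]

where Q_f(X) is the value of feature f for pose X.  Higher scores mean a
pose looks more binder-like.  Densities are estimated from a labeled
calibration set by equal-width histograms with Laplace smoothing, which keeps
scores exactly reproducible; out-of-support values clamp to the edge bins
because screening libraries routinely exceed the calibration range.  Drugs
are ranked by the best LOD among their sampled poses (20 per drug in the
default screen), and dual-target candidates are the non-control drugs in the
top-k of both targets.

The natural logarithm is the default base; any base rescales scores
monotonically and leaves every ranking unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .features import PoseFeatures

__all__ = [
    "BinderLabel",
    "FeatureDistributions",
    "LodResult",
    "DEFAULT_FEATURES",
    "estimate_feature_distributions",
    "lod_score",
    "score_poses",
    "rank_drugs",
    "select_dual_candidates",
]

#: Features entering the score: normalized affinity, closest-atom distance to
#: the site COM, and the COM-cluster size (adjacency-cluster size optional).
DEFAULT_FEATURES = ("affinity_norm", "dist_to_site", "cluster_size_com")


@dataclass(frozen=True)
class BinderLabel:
    """Calibration label for one reference drug: 'T' (true binder) or 'F'
    (decoy / assumed non-binder)."""

    drug_id: str
    label: Literal["T", "F"]

    def __post_init__(self) -> None:
        if self.label not in ("T", "F"):
            raise ValueError(f"label must be 'T' or 'F', got {self.label!r}")


@dataclass
class FeatureDistributions:
    """Binned per-class feature densities.

    For each feature: shared equal-width ``edges`` over the pooled calibration
    range, and smoothed per-bin probabilities ``p_true`` / ``p_false`` that
    each sum to 1 and are strictly positive.
    """

    edges: dict[str, np.ndarray]
    p_true: dict[str, np.ndarray]
    p_false: dict[str, np.ndarray]
    smoothing_alpha: float
    log_base: float = math.e

    def __post_init__(self) -> None:
        for f in self.edges:
            for p in (self.p_true[f], self.p_false[f]):
                if not np.all(p > 0):
                    raise ValueError(f"feature {f!r}: probabilities must be strictly positive")
                if abs(p.sum() - 1.0) > 1e-12:
                    raise ValueError(f"feature {f!r}: probabilities must sum to 1")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.edges)

    def swapped(self) -> "FeatureDistributions":
        """The distributions with T and F classes exchanged (negates every
        LOD score exactly)."""
        return FeatureDistributions(
            edges=self.edges, p_true=self.p_false, p_false=self.p_true,
            smoothing_alpha=self.smoothing_alpha, log_base=self.log_base,
        )


@dataclass
class LodResult:
    """Per-drug scoring outcome for one target: per-pose LOD scores, the best
    score, the affinity of the best-scoring pose, and (after ranking) the rank."""

    drug_id: str
    target_id: str
    pose_lods: dict[int, float]
    best_lod: float
    best_pose_affinity: float
    rank: int | None = None

    def __post_init__(self) -> None:
        if self.pose_lods and abs(self.best_lod - max(self.pose_lods.values())) > 1e-12:
            raise ValueError("best_lod must equal the maximum per-pose LOD")


def _bin_index(value: float, edges: np.ndarray) -> int:
    """Bin index for ``value``, clamping out-of-support values to the edge bins."""
    n_bins = len(edges) - 1
    if value <= edges[0]:
        return 0
    if value >= edges[-1]:
        return n_bins - 1
    return min(int(np.searchsorted(edges, value, side="right")) - 1, n_bins - 1)


def estimate_feature_distributions(
    features: Sequence[PoseFeatures],
    labels: Sequence[BinderLabel],
    n_bins: int = 20,
    alpha: float = 1.0,
    feature_names: Sequence[str] = DEFAULT_FEATURES,
    log_base: float = math.e,
) -> FeatureDistributions:
    """Estimate P_f^T and P_f^F from a labeled calibration pose set.

    Per feature: equal-width bins spanning the pooled (T+F) range, per-class
    counts with a Laplace pseudocount ``alpha`` added to every bin, then
    normalized.  Both classes must contribute at least one pose.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if alpha <= 0:
        raise ValueError(f"smoothing alpha must be positive, got {alpha}")
    label_of = {l.drug_id: l.label for l in labels}
    if len(label_of) != len(labels):
        raise ValueError("duplicate drug_id in calibration labels")
    missing = sorted({f.drug_id for f in features} - set(label_of))
    if missing:
        raise ValueError(f"calibration poses with no binder label: {missing}")
    true_feats = [f for f in features if label_of[f.drug_id] == "T"]
    false_feats = [f for f in features if label_of[f.drug_id] == "F"]
    if not true_feats or not false_feats:
        raise ValueError("both classes (T and F) need at least one calibration pose")

    edges: dict[str, np.ndarray] = {}
    p_true: dict[str, np.ndarray] = {}
    p_false: dict[str, np.ndarray] = {}
    for name in feature_names:
        pooled = np.array([getattr(f, name) for f in features], dtype=float)
        lo, hi = pooled.min(), pooled.max()
        if lo == hi:  # degenerate feature: widen so histogram is well defined
            lo, hi = lo - 0.5, hi + 0.5
        e = np.linspace(lo, hi, n_bins + 1)
        edges[name] = e
        for cls, store in ((true_feats, p_true), (false_feats, p_false)):
            vals = np.array([getattr(f, name) for f in cls], dtype=float)
            counts, _ = np.histogram(vals, bins=e)
            smoothed = counts.astype(float) + alpha
            store[name] = smoothed / smoothed.sum()
    return FeatureDistributions(edges=edges, p_true=p_true, p_false=p_false,
                                smoothing_alpha=alpha, log_base=log_base)


def lod_score(q: PoseFeatures, d: FeatureDistributions) -> float:
    """LOD score of one pose: sum over features of log[P_T(bin)/P_F(bin)]."""
    total = 0.0
    for name in d.features:
        try:
            value = float(getattr(q, name))
        except AttributeError:
            raise ValueError(f"pose features missing feature {name!r} required by distributions") from None
        b = _bin_index(value, d.edges[name])
        total += math.log(d.p_true[name][b] / d.p_false[name][b], d.log_base)
    return total


def score_poses(
    features: Sequence[PoseFeatures],
    d: FeatureDistributions,
) -> list[LodResult]:
    """Score every pose and aggregate per drug by the best (maximum) LOD."""
    by_drug: dict[str, list[PoseFeatures]] = {}
    for f in features:
        by_drug.setdefault(f.drug_id, []).append(f)
    results = []
    for drug_id, feats in by_drug.items():
        lods = {f.pose_index: lod_score(f, d) for f in feats}
        best_idx = max(lods, key=lambda k: (lods[k], -k))  # ties: lowest pose_index
        results.append(
            LodResult(
                drug_id=drug_id,
                target_id=feats[0].target_id,
                pose_lods=lods,
                best_lod=lods[best_idx],
                best_pose_affinity=next(f.affinity_raw for f in feats if f.pose_index == best_idx),
            )
        )
    return results


def rank_drugs(lod_results: Sequence[LodResult]) -> list[LodResult]:
    """Rank drugs for one target by descending best LOD.

    Ties break toward the more negative best-pose affinity, then lexicographic
    drug_id, so the ranking is a deterministic permutation of the input
    regardless of input order.
    """
    seen: set[str] = set()
    for r in lod_results:
        if r.drug_id in seen:
            raise ValueError(f"duplicate drug_id in ranking input: {r.drug_id!r}")
        seen.add(r.drug_id)
    ordered = sorted(
        lod_results,
        key=lambda r: (-r.best_lod, r.best_pose_affinity, r.drug_id),
    )
    out = []
    for i, r in enumerate(ordered, start=1):
        out.append(LodResult(r.drug_id, r.target_id, r.pose_lods, r.best_lod,
                             r.best_pose_affinity, rank=i))
    return out


def select_dual_candidates(
    rank_a: Sequence[LodResult],
    rank_b: Sequence[LodResult],
    k: int,
    controls: Sequence[str] = (),
) -> list[str]:
    """Drugs in the top-k of both targets, controls excluded, ordered by the
    sum of their two ranks (ties lexicographic)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ra = {r.drug_id: r.rank for r in rank_a}
    rb = {r.drug_id: r.rank for r in rank_b}
    if None in ra.values() or None in rb.values():
        raise ValueError("rankings must be produced by rank_drugs (rank field filled)")
    control_set = set(controls)
    common = [
        d for d in ra
        if d in rb and d not in control_set and ra[d] <= k and rb[d] <= k
    ]
    return sorted(common, key=lambda d: (ra[d] + rb[d], d))
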
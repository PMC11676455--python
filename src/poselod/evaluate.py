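"""Self-evaluation utilities: enrichment of the LOD ranking on synthetic
libraries with known labels, and recovery of known interaction-distance
effects by the summary/test machinery.

These drive the package's own validation runs; they are not part of the
screening pipeline proper.
"""

from __future__ import annotations

import numpy as np

from .clustering import adjacency_cluster, com_cluster
from .features import TargetSite, compute_pose_features
from .io import Atom
from .lod import estimate_feature_distributions, rank_drugs, score_poses
from .md import block_average, mean_difference, significance_flag, welch_test
from .simulate import ScreenSimParams, TrajSimParams, gen_distance_series, gen_screen_library

__all__ = ["roc_auc", "run_synthetic_screen", "enrichment_auc",
           "interaction_recovery_trials"]


def roc_auc(scores: np.ndarray, is_positive: np.ndarray) -> float:
    """Rank-statistic ROC-AUC (probability a positive outscores a negative;
    ties count half)."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(is_positive, dtype=bool)
    order = np.argsort(scores)
    ranks = np.empty(scores.size)
    # midranks for ties
    sorted_scores = scores[order]
    i = 0
    while i < scores.size:
        j = i
        while j + 1 < scores.size and sorted_scores[j + 1] == sorted_scores[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1
        i = j + 1
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("need both positives and negatives")
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def run_synthetic_screen(params: ScreenSimParams):
    """Full rescoring pipeline on one synthetic library: cluster each drug's
    poses, build features against the known site (origin), calibrate the LOD
    densities on the labeled library, score, and rank.  Returns the ranked
    results and the drug -> label map."""
    poses, labels, _ = gen_screen_library(params)
    site = TargetSite(target_id="synthetic",
                      site_atoms=[Atom(name="COM", element="C", coords=(0.0, 0.0, 0.0),
                                       mass=12.011)])
    by_drug: dict[str, list] = {}
    for p in poses:
        by_drug.setdefault(p.drug_id, []).append(p)
    labels_com, labels_adj = {}, {}
    for drug, ps in by_drug.items():
        c1 = com_cluster(ps)
        c2 = adjacency_cluster(ps)
        for p in ps:
            labels_com[(drug, p.pose_index)] = c1.labels[p.pose_index]
            labels_adj[(drug, p.pose_index)] = c2.labels[p.pose_index]
    feats = compute_pose_features(poses, site, labels_com, labels_adj)
    dists = estimate_feature_distributions(feats, labels)
    ranked = rank_drugs(score_poses(feats, dists))
    return ranked, {l.drug_id: l.label for l in labels}


def enrichment_auc(params: ScreenSimParams) -> float:
    """ROC-AUC of the best-LOD drug ranking against the known binder labels."""
    ranked, label_of = run_synthetic_screen(params)
    scores = np.array([r.best_lod for r in ranked])
    y = np.array([label_of[r.drug_id] == "T" for r in ranked])
    return roc_auc(scores, y)


#: Drug-minus-control mean shifts (Å) exercised by the recovery trials,
#: spanning the magnitudes seen across lead-drug interaction tables.
_EFFECT_SHIFTS = (-5.38, -3.55, -1.61, -0.94, -0.58, 0.92, 4.75, 7.60)


def interaction_recovery_trials(
    n_trials: int = 200,
    seed: int = 0,
    effect_prob: float = 0.75,
    control_mu: float = 8.09,
    sigma: float = 0.25,
    n_frames: int = 100,
    ar1_phi: float = 0.5,
    block_length: int = 10,
) -> dict:
    """Run seeded drug-vs-control trials with known ground truth.

    Each trial draws a control series and a drug series whose true mean either
    equals the control's (truth: NS) or is shifted by one of the tabulated
    effect sizes (truth: *** with the shift's sign).  The measured triple is
    (rounded mean difference, Welch p on block means, flag).  Returns match
    rate of the measured classification against truth, the fraction of trials
    whose sample mean falls inside the 99.7% sampling band of the true mean,
    and the trial count.
    """
    rng = np.random.default_rng(seed)
    # sampling band for an AR(1) mean: var ~ (sigma^2 / n) (1+phi)/(1-phi)
    band = 3.0 * sigma * np.sqrt((1 + ar1_phi) / (1 - ar1_phi) / n_frames)
    matches = 0
    in_band = 0
    for trial in range(n_trials):
        shift = float(rng.choice(_EFFECT_SHIFTS)) if rng.random() < effect_prob else 0.0
        mu_drug = control_mu + shift
        sc = gen_distance_series(TrajSimParams(
            mu=control_mu, sigma=sigma, n_frames=n_frames, ar1_phi=ar1_phi,
            seed=int(rng.integers(2**31))))
        sd = gen_distance_series(TrajSimParams(
            mu=mu_drug, sigma=sigma, n_frames=n_frames, ar1_phi=ar1_phi,
            seed=int(rng.integers(2**31))))
        if abs(sd.distances.mean() - mu_drug) <= band:
            in_band += 1
        a = block_average(sd.distances, block_length)
        b = block_average(sc.distances, block_length)
        _, _, p, _ = welch_test(a, b)
        diff = mean_difference(float(sd.distances.mean()), float(sc.distances.mean()))
        flag = significance_flag(p)
        if shift == 0.0:
            matches += flag == "NS"
        else:
            matches += flag == "***" and np.sign(diff) == np.sign(shift)
    return {
        "match_rate": matches / n_trials,
        "mean_in_band_rate": in_band / n_trials,
        "n_trials": n_trials,
    }
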
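# Methods

## Scope and model

`poselod` analyzes the output of a dual-target docking screen; it does not
run docking or molecular dynamics. Its core statistic is the log-odds score
of a docked pose X,

    LOD(X) = Σ_f  log_b [ P_f^T(Q_f(X)) / P_f^F(Q_f(X)) ],

a sum of per-feature log likelihood ratios between the true-binder (T) and
decoy (F) classes. The score is a relative-entropy-style discriminator: a
pose whose features look like calibration poses of known binders scores
high. Drugs are ranked by the best LOD among their sampled poses (20 per
drug in the default screen), and dual-target candidates are the non-control
drugs ranked in the top-*k* for both receptors.

The log base *b* defaults to the natural logarithm. Any base rescales all
scores by a positive constant, so rankings, sign identities, and the
label-swap antisymmetry are base-independent; the base is exposed in the
config for presentation only.

## Features

Three features enter the score by default:

* **Normalized affinity** — the per-target population z-score of the
  docking affinity over all poses of all drugs. Z-scoring is monotone (so
  pose ordering is preserved) and makes the density estimate scale-free;
  the raw affinity in kcal/mol is carried alongside.
* **Distance to the site** — the minimum distance from the pose's heavy
  atoms to the center of mass of the catalytic-site residues. The COM is
  mass-weighted (a geometric-centroid switch exists for sensitivity
  checks); hydrogens are excluded because docking hydrogens are placement
  artifacts. Default site residues are the catalytic triads of the two
  bundled kinase targets — Lys868/Asp1028/Asp1046 for VEGFR-2 and
  His1202/Asp1204/Asp1222 for c-Met — and are user-overridable, since a
  screen against other receptors needs its own selectors. A single pooled
  COM over all site residues is the default; per-residue selectors can be
  supplied where a per-residue distance is wanted.
* **Cluster size** — how many of the drug's poses share the pose's spatial
  cluster, a proxy for the entropic favourability of a binding mode. The
  COM-based labeling is the default feature; the adjacency-based size is
  computed alongside and selectable.

## Clustering

Two partitions of each drug's poses, both with a 4 Å default cutoff:

* **COM-based**: single-linkage agglomerative clustering on pairwise
  ligand-COM distances, cut at the cutoff. Single linkage is the unique
  standard linkage for which the cut coincides with connected components of
  the "within cutoff" graph, i.e. the plain reading of a distance cutoff;
  complete and average linkage are available but change the cutoff's
  meaning.
* **Adjacency-based**: connected components of the contact graph joining
  poses whose minimum heavy-atom distance is within the cutoff. "Adjacency"
  is interpreted as inter-pose atomic contact; this is recorded as an
  explicit interpretation since elongated poses can touch while their COMs
  are far apart (the two methods then genuinely disagree, and a test pins
  this).

Cluster ids are canonical — numbered in order of each cluster's smallest
member pose index — so partitions are deterministic and order-invariant.
Both methods are property-tested against a brute-force transitive-closure
oracle on random instances.

## Density estimation and scoring

Class densities are equal-width histograms (20 bins by default) over the
pooled calibration range, with a Laplace pseudocount α = 1 added to every
bin before normalization. Histograms keep scores exactly reproducible and
make the smoothing arithmetic auditable (a two-bin example with class
counts [3, 1] and α = 1 gives exactly [2/3, 1/3]); a KDE could be dropped
in behind the same interface but trades reproducibility for smoothness.
Feature values outside the calibration support clamp to the nearest edge
bin rather than erroring, because screening libraries routinely exceed the
calibration range. Degenerate (constant) features widen their range by
±0.5 so the histogram stays well defined and contributes a flat, zero-LOD
term.

Calibration requires an explicit labeled reference set (known inhibitors as
T, assumed inactives as F), supplied as a TSV of drug/label pairs; the
synthetic generator emits one.

Ranking ties (equal best LOD) break toward the more negative best-pose
affinity, then lexicographic drug id. In the bundled candidate table this
tie-break is load-bearing: two drugs print LOD −0.6 and −0.60 for VEGFR-2,
and the stronger affinity (−8.3 vs −7.5 kcal/mol) decides the order.

## MD interaction-distance statistics

For each drug × interaction (a residue atom such as `Asp1222:OD2`), the
per-frame statistic is the minimum distance from the ligand's heavy atoms
to the named atom, restricted to the analysis window — by default the final
10 ns of a 50 ns production run (100 frames at 0.1 ns), both configurable.

* The printed `±` dispersion is the **SEM** by default. This is an
  interpretation, not a fact of the input tables: the tabulated values
  (e.g. ±0.01–0.6 Å over hundreds of MD frames) are implausibly small as
  frame SDs of a fluctuating distance; SD is available via config.
* Drug-vs-control comparisons use the **Welch** (unequal-variance) t-test,
  two-sided, with the 95% CI on the mean difference. Welch is the safer
  default when variances differ across binding modes; the pooled Student
  test is a config switch.
* Frames are treated as independent observations by default, mirroring how
  such tables are usually produced. Because MD distance series are
  autocorrelated, this anti-conservatively inflates significance; an
  optional block-averaging correction (configurable block length) tests
  block means instead, and the package's own recovery benchmark uses
  blocks of 10 frames.
* Flags: `***` for p < 10⁻⁴, `NS` for p > 0.05, `*` between; thresholds
  configurable. Mean differences are reported rounded to 0.01 Å with an
  explicit sign, matching the parenthetical convention of published
  interaction tables; the control row carries no parenthetical and absent
  cells render as `-`.
* A fully degenerate comparison (both samples zero-variance, equal means)
  returns p = 1 with a CI collapsed at 0 rather than NaN.

RMSD uses least-squares rigid superposition (centroid shift plus Kabsch
rotation with reflection guard) of the selection onto the reference;
disabling superposition gives raw RMSD. RMSF superposes every frame onto
the first, then reports each residue's RMS fluctuation of atom positions
about their time averages.

## Synthetic data

The generator is **feature-first**: it draws each pose's affinity, site
distance, and orientation mode from the class laws, then realizes a 3-atom
collinear rigid pose whose nearest atom sits exactly at the drawn distance
from the site COM (at the origin), so recomputed features equal the drawn
values to 1e-9 Å. Defaults: 100 drugs × 20 poses, 20 binders; binder
affinities N(−8.5, 0.5²) kcal/mol vs decoys N(−6.5, 0.5²); site distances
|N(3, 1²)| Å vs |N(10, 3²)|; binder poses concentrated on 2 orientation
modes (large clusters) vs 12 for decoys. Distance trajectories are
stationary AR(1) processes x_t = μ + φ(x_{t−1} − μ) + ε with marginal
N(μ, σ²), lag-1 autocorrelation φ (default 0.5), clipped at 0 Å.

Every drug and every trajectory uses its own named substream (seeded by
(seed, index)), so adding a drug never perturbs the others and all outputs
are bit-reproducible.

What the generator does **not** emulate — and hence what passing tests do
not show about real screens: real ligand topology and flexibility,
receptor-specific contacts, force-field energetics, property-matched
(DUD-E-style) decoys, or non-Gaussian/multimodal distance dynamics.
Enrichment results on synthetic libraries certify the scoring machinery,
not docking accuracy. Under the default effect sizes the best-LOD ranking
separates binders from decoys completely (ROC-AUC 1.0 across seeds); the
score's correctness is therefore additionally pinned by exact-value
identities (Laplace smoothing arithmetic, ln 4 single-feature score,
additivity, label-swap antisymmetry) rather than by the enrichment margin
alone.

## Problem sizes used in the validation runs

The bundled validation (tests and `scripts/acceptance.py`) uses 20
synthetic libraries of 100 drugs × 20 poses for enrichment, 200 random pose
sets (≤ 25 poses) for clustering-oracle agreement, 200 AR(1) trials of 100
frames for statistics recovery, and 50 random small-sample pairs for the
Welch-vs-textbook comparison — sizes at which every check is exact or
tightly seeded while the whole suite runs in seconds.

## Known limitations

* The bundled candidate and interaction tables are summary-level inputs;
  the underlying docking runs, MD trajectories, and the calibration set
  that produced their LOD values are not recoverable from them, so those
  printed LOD magnitudes are consumed as given (ranking inputs), never
  recomputed.
* PDBQT/PDB parsing is line-based and covers the multi-model dialects the
  pipeline touches (Vina and AutoDock 4 energy remarks); it does not
  perceive chemistry, bonds, or mmCIF, and binary trajectory formats are
  out of scope — convert to multi-model PDB or per-frame distance TSVs.
* Interaction selectors are taken verbatim from user input; the package
  does not second-guess residue/atom labels (e.g. a selector naming an
  atom a residue type cannot have simply matches nothing and errors).
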
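# Methods

This note documents the models and procedures implemented in `topoact`, the
defaults and why they were chosen, what the synthetic cohort generator does
and does not emulate, and the numerical conventions that make runs exactly
reproducible.

## Pipeline

### Cleaning

The resting-state cleaning follows the six-step sequence standard in motion
scrubbing work: (1) nuisance regression, (2) band-pass filtering, (3)
censoring of high-motion frames, (4) interpolation over the censored frames,
(5) re-regression and refiltering of the interpolated series so censoring
artifacts do not blur into kept frames, (6) removal of the censored frames.

* **Framewise displacement** is the sum of absolute frame-to-frame
  differentials of the six realignment parameters, with rotational
  differentials converted to arc displacement on a 50 mm sphere
  (configurable); FD at frame 0 is defined as 0. Frames with FD > 0.3 mm
  are censored, and a participant with fewer than 75 surviving frames is
  excluded (`ParticipantExcludedError`; the caller decides cohort handling).
* **Nuisance design**: `friston24` builds the 24-column motion design
  (parameters at t and t−1 plus their squares; lagged values at frame 0 are
  0). Arbitrary extra regressor columns (global/tissue signals computed
  upstream) are accepted; an intercept is always added; a rank-deficient
  design is an error naming the collinear columns.
* **Filter**: order-2 Butterworth band-pass, 0.009–0.08 Hz, applied
  forward–backward (zero phase) as second-order sections. Only the band is
  part of the analysis contract; at TR = 2 s a 0.04 Hz tone passes with
  amplitude ratio > 0.9 and a 0.2 Hz tone is attenuated below 10% RMS.
* **Interpolation** of censored frames is linear between the nearest kept
  frames, ends held constant. Spectral (Lomb–Scargle style) interpolation
  would be a drop-in alternative and is noted as future work; with the
  band-limited signals used here the linear version recovers censored
  pass-band signal with correlation > 0.95 at up to ~20% censoring.
* Discarding leading scanner-stabilization frames is the caller's
  responsibility; synthetic runs have none.

### Graphs

Edges are Fisher-z transformed Pearson correlations (`z = atanh r`).
Negative edges are removed before any analysis. Density thresholding keeps
the top `round(d · N(N−1)/2)` edges (round half up; ties at the cutoff
broken by lexicographic node-pair order so results are platform-stable);
thresholded graphs stay weighted because the participation coefficient is
defined on weighted connections. Group matrices are means of z (not of r).
Requesting more edges than there are positive entries keeps all positive
edges and records the achieved density.

### Consensus systems

Per age group: resample participants with replacement (default 1000
bootstraps; the recovery benchmarks use 100), average z, threshold at each
density 2–10% (1% steps), detect communities, label them against the
reference partition, and keep each node's modal label per density with its
frequency as an agreement score. Frequency ties go to the lexicographically
smallest label and are recorded.

* **Backend**: community detection minimizes the map equation via igraph's
  Infomap implementation behind a pluggable, seed-deterministic contract
  (isolated nodes become singletons). Five optimization trials per call.
* **Labeling** solves an optimal one-to-one assignment on the
  community-by-system overlap-count matrix (Hungarian algorithm), rather
  than greedy argmax, so labels are permutation-invariant. Communities
  smaller than `min_nodes` (default 5, configurable — the exclusion
  threshold for "too small" systems is a judgment call) or with zero overlap
  are left `unassigned`. Unassigned is an abstention: unassigned nodes are
  excluded from within-system statistics and from partition-agreement
  scores.

### Node topology

`PC_i = 1 − Σ_s (k_i(s)/k_i)²` summed over **all** systems including the
node's own, so a fully within-system node scores 0 — the standard
role-cartography form, which matches the interpretation of PC as
cross-system participation. A literal variant that excludes the node's own
system from the sum (scoring a fully-within node 1) is available as
`variant="literal"` for sensitivity analysis. Edges to unassigned nodes
contribute to neither numerator nor denominator; isolated nodes score 0
with a warning. PCs are computed per density with that density's consensus
assignment and summed over densities 2–10%; classification is a median
split of the summed PC within each system (ties at the median are
non-connectors, so connectors never outnumber non-connectors). Group-level
roles use group-mean matrices; participant-level PCs reuse the group
consensus assignment, chosen for stability since per-participant partitions
at ~140-frame runs are noise-dominated.

The role split is performed on the consensus partition of the density that
assigns the most nodes (ties toward the sparser density); systems are
near-identical across densities, so this only maximizes usable nodes.

### Selectivity

`selectivity = −1 × r(PC_sum, β)` across nodes (Pearson by default;
Spearman available), excluding default-system nodes unless
`include_default_system` is set, since task-evoked deactivation there would
conflate the score. Scope-restricted scores (sensory–motor, association)
require at least 3 nodes; a constant PC or β vector makes the score
undefined (an error at the operation level; the pipeline records it and
continues). Cohort summaries report mean, SD, the Pearson correlation of
score with age, and a descriptive LOESS trend (span 0.75). Group
inferential statistics (ANOVAs, post hocs) are deliberately left to
standard tools on the exported score tables; the package asserts only
sign/direction properties on synthetic data.

## Synthetic cohort generator

The generator plants, per participant: a node correlation matrix with
block (system) structure, connector/non-connector roles, an age-graded
dedifferentiation gradient, a motion trace with censorable spikes, and
per-task β maps with a non-connector activation bonus in task-relevant
system types.

### Factor model

Node *i* in system *s* is
`x_i = λ_i f_s + ν_i g + e_i b_{p(i)} + σ_i ε_i`
with system factors `f_s`, a global factor `g` carrying baseline
between-system coupling, and bridge factors `b_p`, each shared by one
cross-system pair of connectors. All factors and unique noise are unit
Gaussian, communality + σ² = 1, so the covariance is exactly
`L Lᵀ + diag(σ²)`: positive semidefinite by construction, unit diagonal,
and the planted pairwise correlations are closed-form (within-system
same-class pairs hit `ρ_own` exactly, baseline cross pairs `ρ_x`, bridged
pairs `ρ_between + connector_boost`).

Defaults (five 20-node systems: two sensory–motor, two association, one
default — so the default-exclusion rule is always exercised):

| parameter | default | rationale |
| --- | --- | --- |
| `rho_within` | 0.40 | moderate within-system coupling; the strong-signal recovery level |
| `rho_between` | 0.05 | weak baseline cross-system coupling |
| `connector_fraction` | 0.5 | connector status is *defined* by a median split, so any other planted base rate caps recovery accuracy at max(f, 1−f) by construction |
| `connector_within_premium` | 0.10 | connectors are hubs with elevated within-system strength; their within edges are the strongest edge class, anchoring them to their home system at the sparsest densities where only they survive thresholding |
| `connector_boost` | 0.44 | bridge edges (corr 0.49) sit between the connector-anchor class and the mixed within bulk on the empirical z scale, so they enter the retained edge set at ~5–6% density: every connector acquires cross-system weight at moderate densities while 2–4% graphs stay block-pure |
| `dediff_slope_within` | 0.05 | per-unit-age erosion of non-connector within-system coupling |
| `dediff_slope_between` | 0.05 | per-unit-age growth of non-connector between-system coupling |
| `dediff_slope_bridge` | 0.12 | per-unit-age erosion of connector bridges, with per-bridge rates spread deterministically over 0.5–1.5× so dropout from the thresholded graphs is gradual across the lifespan rather than simultaneous |
| `loading_jitter_sd` | 0.05 | node-level heterogeneity of non-connector within loadings; a perfectly homogeneous block model makes thresholding a degenerate step function |
| `cross_jitter_sd` | 0.15 | mean-one lognormal heterogeneity of non-connector cross loadings |
| `n_frames`, `tr_seconds` | 154, 2.0 | one rest run at TR = 2 s |
| `spike_prob`, `spike_fd_mm` | 0.1, 0.6 | ~15 censorable spike frames, leaving ~139 kept frames on average |

Jitter is deterministic given `jitter_seed` (a property of the cohort, not
of a participant), so the planted matrix is a pure function of
(spec, age). The planted matrix at age 0 equals the slope-free baseline
entrywise.

Because edge-density thresholding retains at most 495 of the 950
within-system pairs at these sizes, any cross-system structure that should
survive thresholding must rank with the strongest edges — which is also
what a retained cross-system edge in a real sparse brain graph is. The
edge-class ordering (connector–connector within > bridges > mixed bulk >
baseline cross) is engineered with margins larger than the group-level
sampling noise, so class retention per density is stable across seeds.

### Aging model

Normalized age in [0, 1] maps linearly onto three coupling changes:
non-connector within-coupling erodes, non-connector between-coupling grows,
and connector bridges erode (heterogeneously). On the full (unthresholded)
planted matrix the connector-minus-non-connector PC gap is non-increasing
in age via the non-connector side; through the thresholded pipeline the gap
closure is expressed mainly by the graded dropout of bridges from the
density ladder. This is a known deviation from the empirical aging
pattern, in which the PCs of *both* node types rise with age
(non-connectors faster): the generator reproduces the shrinking contrast
and the selectivity decline, not the absolute PC trajectories. Task β
bonuses attenuate linearly with age (`delta_age_slope`, default 0.6), the
second, activation-side channel of the selectivity decline.

Task defaults follow the reported group cell means: a visual-like task
(sensory–motor base β 1.67, non-connector bonus 1.0, noise SD 0.75) and a
semantic-like task (association base 0.11, bonus 0.45, noise SD 0.5).

### Motion

Baseline motion is a gentle random walk (expected FD ≈ 0.04 mm). Spikes
are persistent step offsets in the three translations only
(`spike_fd_mm`/3 each, random signs), so the FD at a spike frame equals
`spike_fd_mm` analytically and rotations stay clean.

### What the generator does not emulate

No hemodynamic convolution, physiological noise, spatial autocorrelation of
β noise, scanner drift, or volumetric/surface geometry; β noise is i.i.d.
Gaussian per node. Ages sit on a fixed grid (default four equally spaced
groups), not a distribution, so cohort summaries are exactly reproducible.
Passing recovery tests therefore demonstrates that the analysis chain
recovers planted block-and-role structure under realistic sampling noise
and motion censoring — not that it is robust to every artifact of real
fMRI.

## Recovery benchmarks and problem sizes

`topoact.benchmarks` (used by the acceptance tests and
`scripts/acceptance.py`) runs the full pipeline at desk scale:

* consensus recovery: 20 participants × 1000 frames, 100 bootstraps,
  densities 2–10%; agreement = adjusted Rand index against the planted
  partition over consensus-assigned nodes;
* role recovery: the same conditions over 20 independent cohorts;
  accuracy of the median-split classification against planted roles;
* selectivity recovery: one 50-participant young cohort carrying four task
  conditions with bonus δ ∈ {0, 0.25, 0.5, 1.0}; per-participant scores
  from individual z-matrices with the group consensus;
* dedifferentiation: 48 participants over four age groups; the summed-PC
  gap per age group is reported against planted roles (the recovery
  reading; the median-split gap is a selection statistic whose old-age
  floor is churn noise and is reported descriptively);
* permutation null: 1000 role shuffles of group-mean β over the
  task-relevant node set;
* determinism: two end-to-end runs with identical config and seed are
  compared byte for byte (wall-clock `timing.json` is the single documented
  exception).

## Numerical conventions

* All text output is tab-delimited UTF-8 with '.' decimals; floats are
  written at 17 significant digits and read back with the round-trip
  parser, so every writer/reader pair preserves values exactly.
* All randomness flows from one top-level seed through named substreams
  (CRC-keyed `SeedSequence` spawn), so adding a stage never perturbs
  another stage's draws; igraph's RNG is seeded per detection call.
* Frame indexing is 0-based everywhere; `keep_mask` always has one entry
  per original frame.
* The FD threshold is strict (`FD > 0.3` is censored; exactly 0.3 is kept).

## Known limitations

* The linear-in-age dedifferentiation model and the bridge-erosion channel
  are modeling choices; the underlying study reports group contrasts, not a
  generative model.
* Individual-participant PC estimates at realistic run lengths
  (~140 frames) are noise-dominated at these planted coupling levels; the
  selectivity benchmarks therefore use 1000-frame runs, and selectivity on
  154-frame synthetic cohorts should be interpreted at the group level
  only.
* Spectral interpolation of censored frames and negative-edge network
  analysis are out of scope.
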
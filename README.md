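# topoact

Resting-state network topology and task activation selectivity across the
adult lifespan.

`topoact` implements, as a tested pipeline, the analysis chain that relates a
brain area's *connectional topology* at rest to its *task-evoked activity* —
and how both change with age. It is aimed at network-neuroscience
practitioners who extract node-level BOLD time series upstream (no
NIfTI/CIFTI handling here: all inputs are plain tab-delimited text), and it
ships a synthetic lifespan cohort generator that plants known topology and
activation structure so every stage can be verified by parameter recovery.

## The analysis

1. **Cleaning.** Per participant, the node time series (frames × nodes) is
   residualized against nuisance regressors (the 24-parameter motion design
   built from the six realignment parameters, plus any extra columns),
   band-pass filtered (0.009–0.08 Hz, zero-phase), and motion-scrubbed:
   framewise displacement `FD_t = |Δd_x|+|Δd_y|+|Δd_z| + r·(|Δα|+|Δβ|+|Δγ|)`
   (r = 50 mm), frames with FD > 0.3 mm censored, interpolated, the series
   re-cleaned, and the censored frames dropped. Participants with fewer than
   75 surviving frames are excluded.
2. **Graphs.** Pairwise Pearson correlations are Fisher-transformed
   (`z = atanh r`), negative edges removed, and the matrix thresholded at
   edge densities 2–10% (top `round(d·N(N−1)/2)` weighted edges).
3. **Consensus systems.** Per age group, participants are bootstrap-resampled
   (default 1000 times); each bootstrap-mean z-matrix is thresholded per
   density and partitioned with the Infomap map-equation algorithm; detected
   communities are named by optimal overlap assignment against a reference
   system partition; per node and density the modal label is kept.
4. **Node topology.** The weighted participation coefficient
   `PC_i = 1 − Σ_s (k_i(s)/k_i)²` is computed per density and summed across
   densities; within each system, nodes above the system median are
   *connectors*, the rest *non-connectors*.
5. **Activation selectivity.** Per participant and task,
   `selectivity = −1 × r(PC, β)` over non-default-system nodes: positive
   scores mean greater activation at non-connector nodes. Scores are
   summarized by system type (sensory–motor vs association) and against age.

## Worked example

```python
from topoact import PipelineConfig, run_pipeline
from topoact.simulate import strong_signal_spec

spec = strong_signal_spec(n_participants=8, age_grid=(0.0, 1.0))
result = run_pipeline(PipelineConfig(n_boot=50, seed=7), spec=spec)
print(result.summary["pc_gap_by_age"])
print(result.scores.head(6).to_string(index=False))
```

prints

```
{'0.0': 1.054..., '1.0': 0.329...}
participant_id     task         scope     score  n_nodes
       sub-000 semantic     all-nodes  0.075750       78
       sub-000 semantic sensory-motor -0.154733       40
       sub-000 semantic   association  0.318335       38
       sub-000   visual     all-nodes  0.268781       78
       sub-000   visual sensory-motor  0.174046       40
       sub-000   visual   association  0.344460       38
```

The first line is the group-level connector-minus-non-connector summed-PC
gap per age group: the planted topological contrast (≈1.05 in the young
group) erodes to ≈0.33 in the old group — the dedifferentiation gradient the
generator plants. The score table holds one activation-selectivity score per
participant, task, and scope; positive values mean non-connector nodes
activated more. In the same run, selectivity declines with age specifically
in the scope carrying the planted bonus (e.g. `visual|sensory-motor`
r_age ≈ −0.72 while `visual|association` shows no decline).

The same pipeline runs from the shell:

```bash
topoact simulate --out cohort/ --participants 8 --seed 7
topoact run-all --input cohort/ --out results/ --n-boot 100 --seed 7
```

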
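"""End-to-end pipeline: cohort -> cleaning -> graphs -> consensus ->
topology -> selectivity -> cohort summaries.

Every stage writes its artifacts under the output directory; all
randomness flows from the single configured seed through named
substreams, and a run is byte-identical given identical config + seed
(wall-clock timings go to ``timing.json``, which is the one
non-deterministic artifact).
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as tio
from ._seeds import child_seed_ints, substream
from .communities import MIN_NODES, consensus_assignment
from .errors import (
    EmptyCellError,
    InputError,
    ParticipantExcludedError,
    UndefinedCorrelationError,
)
from .graph import DEFAULT_DENSITIES, correlation_zmatrix, mean_zmatrix
from .preprocess import (
    BAND_HZ,
    FD_THRESHOLD_MM,
    MIN_FRAMES,
    ROTATION_RADIUS_MM,
    clean_rsfc,
    compute_fd,
    friston24,
)
from .selectivity import (
    SCOPE_ALL,
    activation_by_node_type,
    cohort_summary,
    default_node_mask,
    selectivity_score,
    system_type_selectivity,
)
from .simulate import Cohort, CohortSpec, generate_cohort
from .topology import ROLE_CONNECTOR, ROLE_NON_CONNECTOR, node_topology_table, summed_pc

log = logging.getLogger("topoact")


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    Defaults match the study parameters: densities 2-10% in 1% steps,
    FD censoring at 0.3 mm, a 75-frame minimum, a 0.009-0.08 Hz band,
    and 1000 bootstrap resamples.
    """

    densities: tuple = DEFAULT_DENSITIES
    fd_threshold: float = FD_THRESHOLD_MM
    min_frames: int = MIN_FRAMES
    band: tuple = BAND_HZ
    n_boot: int = 1000
    min_nodes: int = MIN_NODES
    pc_variant: str = "standard"
    include_default_system: bool = False
    rotation_radius_mm: float = ROTATION_RADIUS_MM
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["densities"] = list(self.densities)
        d["band"] = list(self.band)
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    n_analyzable: int
    excluded: list
    consensus: dict  # age -> ConsensusAssignment
    topology: dict  # age -> per-node DataFrame (group-level)
    scores: pd.DataFrame
    summary: dict
    outdir: Path | None = None
    errors: list = field(default_factory=list)


def _score_rows(scores):
    return pd.DataFrame(
        [
            {
                "participant_id": s.participant_id,
                "task": s.task,
                "scope": s.scope,
                "score": s.score,
                "n_nodes": s.n_nodes,
            }
            for s in scores
        ]
    )


def run_pipeline(
    config: PipelineConfig,
    cohort: Cohort | None = None,
    spec: CohortSpec | None = None,
    input_dir=None,
    outdir=None,
    reference=None,
) -> PipelineResult:
    """Run the full analysis.

    The cohort comes from (in order of precedence) ``cohort``, the
    on-disk contract at ``input_dir``, or simulation from ``spec`` with
    the configured seed. The reference partition defaults to the
    cohort's planted partition.
    """
    t0 = time.perf_counter()
    timings = {}
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        if input_dir is not None:
            cohort = tio.read_cohort(input_dir, spec=spec)
        else:
            cohort = generate_cohort(spec or CohortSpec(), seed=config.seed)
    if reference is None:
        reference = cohort.participants[0].truth.reference_partition()
    tr = cohort.spec.tr_seconds
    timings["ingest_s"] = time.perf_counter() - t0
    log.info("cohort: %d participants, %d nodes", len(cohort.participants),
             reference.n_nodes)

    # -- preprocessing and per-participant z-matrices -------------------
    t1 = time.perf_counter()
    excluded, kept, zmats = [], [], {}
    for p in cohort.participants:
        fd = compute_fd(p.motion, rotation_radius_mm=config.rotation_radius_mm)
        design = friston24(p.motion)
        try:
            clean = clean_rsfc(
                p.timeseries,
                design,
                fd,
                fd_threshold=config.fd_threshold,
                min_frames=config.min_frames,
                tr_seconds=tr,
                low_hz=config.band[0],
                high_hz=config.band[1],
            )
        except ParticipantExcludedError as err:
            excluded.append({"participant_id": p.participant_id, "reason": str(err)})
            log.info("excluded %s: %s", p.participant_id, err)
            continue
        kept.append(p)
        zmats[p.participant_id] = correlation_zmatrix(
            clean, node_ids=list(reference.node_ids)
        )
        if out is not None:
            tio.write_clean_sidecar(
                clean, config.fd_threshold, out / f"{p.participant_id}_clean.json"
            )
    timings["preprocess_s"] = time.perf_counter() - t1

    if not kept:
        summary = {"n_analyzable": 0, "excluded": excluded}
        log.warning("zero analyzable participants after scrubbing")
        result = PipelineResult(
            config=config, n_analyzable=0, excluded=excluded, consensus={},
            topology={}, scores=pd.DataFrame(), summary=summary, outdir=out,
        )
        if out is not None:
            _write_outputs(result, timings, cohort)
        return result

    # -- group consensus and group-level topology ----------------------
    t2 = time.perf_counter()
    groups: dict = {}
    for p in kept:
        groups.setdefault(p.age, []).append(p)
    groups = dict(sorted(groups.items()))
    group_seeds = child_seed_ints(
        substream(config.seed, "consensus-groups"), len(groups)
    )
    consensus, topology = {}, {}
    for gseed, (age, members) in zip(group_seeds, groups.items()):
        group_z = [zmats[p.participant_id] for p in members]
        cons = consensus_assignment(
            group_z,
            reference,
            densities=config.densities,
            n_boot=config.n_boot,
            seed=gseed,
            min_nodes=config.min_nodes,
        )
        consensus[age] = cons
        topology[age] = node_topology_table(
            mean_zmatrix(group_z), cons, config.densities, variant=config.pc_variant
        )
    timings["consensus_s"] = time.perf_counter() - t2

    # -- per-participant topology and selectivity ----------------------
    t3 = time.perf_counter()
    scores, activation_tables, score_errors = [], [], []
    for age, members in groups.items():
        cons = consensus[age]
        group_part = _classification_partition(topology[age], cons, config)
        roles = topology[age]["role"].to_numpy()
        mask = default_node_mask(group_part, config.include_default_system)
        for p in members:
            pc_table = summed_pc(
                zmats[p.participant_id], cons, config.densities,
                variant=config.pc_variant,
            )
            pc_sum = pc_table["pc_sum"].to_numpy()
            for task_name in sorted(p.betas):
                beta = p.betas[task_name]
                try:
                    scores.append(
                        selectivity_score(
                            pc_sum, beta, mask,
                            participant_id=p.participant_id, task=task_name,
                            scope=SCOPE_ALL,
                        )
                    )
                    scores.extend(
                        system_type_selectivity(
                            pc_sum, beta, group_part,
                            participant_id=p.participant_id, task=task_name,
                        ).values()
                    )
                except (UndefinedCorrelationError, InputError) as err:
                    # constant PC within a scope, or a scope left with fewer
                    # than 3 assigned nodes; the score is undefined, not zero
                    score_errors.append(
                        {"participant_id": p.participant_id, "task": task_name,
                         "error": str(err)}
                    )
                try:
                    table = activation_by_node_type(
                        beta, roles, group_part, config.include_default_system
                    )
                except EmptyCellError as err:
                    score_errors.append(
                        {"participant_id": p.participant_id, "task": task_name,
                         "error": str(err)}
                    )
                    continue
                table.insert(0, "participant_id", p.participant_id)
                table.insert(1, "task", task_name)
                table.insert(2, "age", p.age)
                activation_tables.append(table)
    score_frame = _score_rows(scores)
    activation = (
        pd.concat(activation_tables, ignore_index=True)
        if activation_tables
        else pd.DataFrame()
    )
    timings["selectivity_s"] = time.perf_counter() - t3

    # -- cohort summaries ----------------------------------------------
    participant_ages = {p.participant_id: p.age for p in kept}
    summary: dict = {
        "n_analyzable": len(kept),
        "excluded": excluded,
        "score_errors": score_errors,
        "pc_gap_by_age": _pc_gap_by_age(topology),
    }
    ages_per_score = np.array([participant_ages[s.participant_id] for s in scores])
    if len(kept) >= 4 and len(scores) and np.ptp(ages_per_score) > 0:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summ = cohort_summary(scores, ages_per_score)
        summary["selectivity"] = {
            f"{task}|{scope}": stats for (task, scope), stats in summ.items()
        }
    result = PipelineResult(
        config=config,
        n_analyzable=len(kept),
        excluded=excluded,
        consensus=consensus,
        topology=topology,
        scores=score_frame,
        summary=summary,
        outdir=out,
        errors=score_errors,
    )
    if len(activation):
        result.summary["activation_cells"] = (
            activation.groupby(["task", "system_type", "role"], sort=True)["mean_beta"]
            .mean()
            .reset_index()
            .to_dict(orient="records")
        )
    timings["total_s"] = time.perf_counter() - t0
    if out is not None:
        _write_outputs(result, timings, cohort, activation)
    return result


def _classification_partition(topo_table, cons, config):
    """The consensus partition whose density classified the roles."""
    assigned = [
        (int(cons.partition_at(d).assigned_mask().sum()), -d)
        for d in config.densities
    ]
    best = config.densities[
        int(np.argmax([a[0] + 1e-9 * a[1] for a in assigned]))
    ]
    return cons.partition_at(best)


def _pc_gap_by_age(topology: dict) -> dict:
    """Connector minus non-connector mean summed PC, per age group."""
    gaps = {}
    for age, table in topology.items():
        c = table.loc[table["role"] == ROLE_CONNECTOR, "pc_sum"]
        nc = table.loc[table["role"] == ROLE_NON_CONNECTOR, "pc_sum"]
        gaps[str(age)] = float(c.mean() - nc.mean()) if len(c) and len(nc) else float("nan")
    return gaps


def _write_outputs(result, timings, cohort, activation=None) -> None:
    out = result.outdir
    for age, cons in result.consensus.items():
        tag = f"age{age:.3f}".replace(".", "p")
        tio.write_consensus(cons, out / f"consensus_{tag}.tsv")
        result.topology[age].to_csv(
            out / f"topology_{tag}.tsv", sep="\t", float_format="%.17g"
        )
    if len(result.scores):
        result.scores.to_csv(
            out / "selectivity_scores.tsv", sep="\t", index=False,
            float_format="%.17g",
        )
    if activation is not None:
        activation.to_csv(
            out / "activation_by_node_type.tsv", sep="\t", index=False,
            float_format="%.17g",
        )
    tio.write_json(result.summary, out / "summary.json")
    manifest = {
        "config": result.config.to_dict(),
        "seed": result.config.seed,
        "cohort_seed": cohort.seed,
        "n_participants": len(cohort.participants),
        "n_analyzable": result.n_analyzable,
        "stages": ["ingest", "preprocess", "consensus", "selectivity"],
    }
    tio.write_json(manifest, out / "manifest.json")
    tio.write_json(timings, out / "timing.json")  # excluded from byte-identity
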
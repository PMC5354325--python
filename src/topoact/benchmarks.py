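"""Desk-scale parameter-recovery benchmarks.

Each function generates a synthetic cohort under the strong-signal
recovery conditions, runs the full pipeline (cleaning, Fisher-z graphs,
bootstrap consensus, participation coefficients, selectivity), and
scores the result against the planted ground truth. They are the basis
of the acceptance checks and of ``scripts/acceptance.py``.

Problem sizes follow the recovery conditions: 100 nodes (five 20-node
systems), 1000-frame runs, 20 participants per group, 100 bootstrap
resamples across densities 2-10%.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from ._seeds import child_seed_ints, substream
from .communities import consensus_assignment
from .graph import DEFAULT_DENSITIES, correlation_zmatrix, mean_zmatrix
from .pipeline import PipelineConfig, run_pipeline
from .preprocess import clean_rsfc, compute_fd, friston24
from .selectivity import (
    default_node_mask,
    role_permutation_test,
    selectivity_score,
)
from .simulate import (
    CONNECTOR,
    NON_CONNECTOR,
    SENSORY_MOTOR,
    TaskSpec,
    generate_cohort,
    strong_signal_spec,
)
from .topology import node_topology_table, summed_pc

AGE_GRID_4 = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)


def _participant_zmatrices(cohort, reference):
    zmats = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in cohort.participants:
            fd = compute_fd(p.motion)
            clean = clean_rsfc(
                p.timeseries, friston24(p.motion), fd,
                tr_seconds=cohort.spec.tr_seconds,
            )
            zmats.append(
                correlation_zmatrix(clean, node_ids=list(reference.node_ids))
            )
    return zmats


def consensus_recovery(seed: int, n_boot: int = 100) -> dict:
    """Bootstrap-consensus labels vs the planted partition, per density.

    Agreement is the adjusted Rand index over nodes the consensus
    assigns to a named system.
    """
    spec = strong_signal_spec()
    cohort = generate_cohort(spec, seed=seed)
    truth = cohort.participants[0].truth
    reference = truth.reference_partition()
    zmats = _participant_zmatrices(cohort, reference)
    cons = consensus_assignment(
        zmats, reference, densities=DEFAULT_DENSITIES, n_boot=n_boot,
        seed=int(seed) + 1,
    )
    planted = truth.system_array()
    ari, agreement = {}, {}
    for d in DEFAULT_DENSITIES:
        part = cons.partition_at(d)
        assigned = part.assigned_mask()
        ari[d] = float(adjusted_rand_score(planted[assigned], part.system[assigned]))
        agreement[d] = float(cons.agreement[d].mean())
    return {
        "ari_by_density": ari,
        "ari_min": min(ari.values()),
        "agreement_mean": float(np.mean(list(agreement.values()))),
        "n_nodes": spec.n_nodes,
    }


def role_recovery(seed: int, n_seeds: int = 20, n_boot: int = 100) -> dict:
    """Connector classification accuracy vs planted roles over cohorts."""
    seeds = child_seed_ints(substream(seed, "role-recovery"), n_seeds)
    accuracies = []
    for s in seeds:
        spec = strong_signal_spec()
        cohort = generate_cohort(spec, seed=s)
        truth = cohort.participants[0].truth
        reference = truth.reference_partition()
        zmats = _participant_zmatrices(cohort, reference)
        cons = consensus_assignment(
            zmats, reference, densities=DEFAULT_DENSITIES, n_boot=n_boot,
            seed=s + 1,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            topo = node_topology_table(mean_zmatrix(zmats), cons, DEFAULT_DENSITIES)
        classified = topo["role"].to_numpy()
        planted = truth.role_array()
        scored = classified != "excluded"
        accuracies.append(float((classified[scored] == planted[scored]).mean()))
    return {
        "accuracy_by_seed": accuracies,
        "accuracy_mean": float(np.mean(accuracies)),
        "n_seeds": n_seeds,
    }


DELTA_GRID = (0.0, 0.25, 0.5, 1.0)


def selectivity_recovery(seed: int, n_participants: int = 50,
                         n_boot: int = 100) -> dict:
    """Cohort selectivity vs planted non-connector bonus (delta grid).

    One young cohort carries four task conditions differing only in the
    planted bonus; selectivity is computed per participant from the
    individual z-matrix with the group consensus assignment.
    """
    tasks = tuple(
        TaskSpec(
            name=f"delta{delta}",
            relevant_types=frozenset({SENSORY_MOTOR}),
            beta_base={"sensory-motor": 1.67, "association": 0.94, "default": -0.5},
            delta_selectivity=delta,
            beta_noise_sd=0.75,
            delta_age_slope=0.0,
        )
        for delta in DELTA_GRID
    )
    spec = replace(strong_signal_spec(n_participants=n_participants),
                   task_specs=tasks)
    cohort = generate_cohort(spec, seed=seed)
    truth = cohort.participants[0].truth
    reference = truth.reference_partition()
    zmats = _participant_zmatrices(cohort, reference)
    cons = consensus_assignment(
        zmats, reference, densities=DEFAULT_DENSITIES, n_boot=n_boot,
        seed=int(seed) + 1,
    )
    best = max(DEFAULT_DENSITIES, key=lambda d: cons.partition_at(d).assigned_mask().sum())
    mask = default_node_mask(cons.partition_at(best))
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pc_sums = [
            summed_pc(zm, cons, DEFAULT_DENSITIES)["pc_sum"].to_numpy()
            for zm in zmats
        ]
    for delta, task in zip(DELTA_GRID, tasks):
        scores = np.array(
            [
                selectivity_score(pc, p.betas[task.name], mask).score
                for pc, p in zip(pc_sums, cohort.participants)
            ]
        )
        n_pos = int((scores > 0).sum())
        sign_p = stats.binomtest(n_pos, scores.size, 0.5,
                                 alternative="greater").pvalue
        out[delta] = {
            "mean": float(scores.mean()),
            "sd": float(scores.std(ddof=1)),
            "n_positive": n_pos,
            "sign_test_p": float(sign_p),
        }
    return {"by_delta": out, "n_participants": n_participants}


def dedifferentiation(seed: int, n_participants: int = 48,
                      n_boot: int = 100) -> dict:
    """Age-graded dedifferentiation through the full pipeline.

    Returns the connector-minus-non-connector summed-PC gap per age
    group (against planted roles, and against the median-split
    classification), plus the selectivity-age correlations per task and
    scope.
    """
    spec = strong_signal_spec(n_participants=n_participants, age_grid=AGE_GRID_4)
    cohort = generate_cohort(spec, seed=seed)
    truth = cohort.participants[0].truth
    config = PipelineConfig(n_boot=n_boot, seed=int(seed) + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_pipeline(config, cohort=cohort)
    planted = truth.role_array()
    gap_planted, gap_classified = {}, {}
    for age, table in result.topology.items():
        ps = table["pc_sum"].to_numpy()
        cl = table["role"].to_numpy()
        gap_planted[age] = float(
            ps[planted == CONNECTOR].mean() - ps[planted == NON_CONNECTOR].mean()
        )
        gap_classified[age] = float(
            ps[cl == "connector"].mean() - ps[cl == "non-connector"].mean()
        )
    r_age = {
        key: stats_dict["r_age"]
        for key, stats_dict in result.summary.get("selectivity", {}).items()
    }
    return {
        "ages": sorted(gap_planted),
        "gap_planted": gap_planted,
        "gap_classified": gap_classified,
        "r_age": r_age,
        "n_analyzable": result.n_analyzable,
    }


def role_shuffle_null(seed: int, n_perm: int = 1000) -> dict:
    """Permutation null for the non-connector activation advantage.

    Group-mean β maps from a young cohort; roles are the planted ones,
    the mask is the task-relevant (sensory-motor) node set.
    """
    spec = strong_signal_spec(n_participants=50)
    cohort = generate_cohort(spec, seed=seed)
    truth = cohort.participants[0].truth
    roles = truth.role_array()
    types = np.array(
        [truth.system_types[truth.partition[n]] for n in truth.node_ids]
    )
    mask = types == SENSORY_MOTOR
    mean_beta = {
        task: np.mean([p.betas[task] for p in cohort.participants], axis=0)
        for task in cohort.participants[0].betas
    }
    planted = role_permutation_test(
        mean_beta["visual"], roles, mask, n_perm=n_perm, seed=int(seed) + 1
    )
    # the semantic task plants no bonus in sensory-motor systems: a null case
    null = role_permutation_test(
        mean_beta["semantic"], roles, mask, n_perm=n_perm, seed=int(seed) + 2
    )
    return {
        "planted_observed": planted["observed"],
        "planted_ci95": planted["ci95"],
        "planted_p": planted["p_value"],
        "planted_null_mean": float(planted["null"].mean()),
        "null_observed": null["observed"],
        "null_ci95": null["ci95"],
        "null_p": null["p_value"],
        "n_perm": n_perm,
    }


def determinism_check(tmpdir, seed: int) -> dict:
    """Byte-identity of two pipeline runs with identical config + seed."""
    from pathlib import Path

    spec = strong_signal_spec(
        n_participants=6, age_grid=(0.0, 1.0), n_frames=154
    )
    config = PipelineConfig(n_boot=20, seed=seed)
    tmpdir = Path(tmpdir)
    for sub in ("run-a", "run-b"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run_pipeline(config, spec=spec, outdir=tmpdir / sub)
    mismatches = []
    files = sorted((tmpdir / "run-a").iterdir())
    for fa in files:
        if fa.name == "timing.json":  # wall-clock, documented exception
            continue
        fb = tmpdir / "run-b" / fa.name
        if not fb.exists() or fa.read_bytes() != fb.read_bytes():
            mismatches.append(fa.name)
    return {
        "identical": not mismatches,
        "n_files_compared": len(files) - 1,
        "mismatches": mismatches,
    }
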
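"""Readers and writers: tab-delimited UTF-8 text and JSON.

Floats are serialized at 17 significant digits so every writer/reader
pair round-trips exactly. All files use '.' as the decimal separator
regardless of locale.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .communities import ConsensusAssignment, SystemPartition
from .errors import InputError
from .preprocess import CleanTimeSeries
from .simulate import MOTION_COLUMNS, Cohort, CohortSpec, Participant, SyntheticTruth

FLOAT_FMT = "%.17g"


def _write_tsv(frame: pd.DataFrame, path, index=False) -> None:
    frame.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT, encoding="utf-8")


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))


# -- time series, motion, betas ----------------------------------------


def write_timeseries(ts: np.ndarray, node_ids, path) -> None:
    _write_tsv(pd.DataFrame(ts, columns=list(node_ids)), path)


def read_timeseries(path):
    frame = pd.read_csv(path, sep="\t", encoding="utf-8", float_precision="round_trip")
    return frame.to_numpy(dtype=float), list(frame.columns)


def write_motion(motion: np.ndarray, path) -> None:
    _write_tsv(pd.DataFrame(motion, columns=list(MOTION_COLUMNS)), path)


def read_motion(path) -> np.ndarray:
    frame = pd.read_csv(path, sep="\t", encoding="utf-8", float_precision="round_trip")
    if list(frame.columns) != list(MOTION_COLUMNS):
        raise InputError(
            f"{path}: expected motion columns {MOTION_COLUMNS}, got {list(frame.columns)}"
        )
    return frame.to_numpy(dtype=float)


def write_betas(betas: dict, node_ids, path) -> None:
    rows = [
        {"node_id": nid, "task": task, "beta": float(vals[i])}
        for task, vals in sorted(betas.items())
        for i, nid in enumerate(node_ids)
    ]
    _write_tsv(pd.DataFrame(rows), path)


def read_betas(path, node_ids) -> dict:
    frame = pd.read_csv(path, sep="\t", encoding="utf-8", float_precision="round_trip")
    out = {}
    for task, grp in frame.groupby("task", sort=True):
        series = grp.set_index("node_id")["beta"]
        missing = [n for n in node_ids if n not in series.index]
        if missing:
            raise InputError(f"{path}: task {task!r} missing nodes {missing[:3]}...")
        out[task] = series.loc[list(node_ids)].to_numpy(dtype=float)
    return out


# -- matrices and partitions -------------------------------------------


def write_matrix(matrix: np.ndarray, node_ids, path) -> None:
    frame = pd.DataFrame(matrix, index=list(node_ids), columns=list(node_ids))
    frame.index.name = "node_id"
    _write_tsv(frame, path, index=True)


def read_matrix(path):
    frame = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8", float_precision="round_trip")
    return frame.to_numpy(dtype=float), list(frame.columns)


def write_reference_partition(partition: SystemPartition, path) -> None:
    types = partition.type_of_node()
    _write_tsv(
        pd.DataFrame(
            {
                "node_id": partition.node_ids,
                "system_name": partition.system,
                "system_type": types,
            }
        ),
        path,
    )


def read_reference_partition(path) -> SystemPartition:
    frame = pd.read_csv(path, sep="\t", encoding="utf-8", dtype=str)
    required = {"node_id", "system_name", "system_type"}
    if not required.issubset(frame.columns):
        raise InputError(f"{path}: reference partition needs columns {sorted(required)}")
    system_types = {}
    for name, t in zip(frame["system_name"], frame["system_type"]):
        if name == "unassigned":
            continue
        if name in system_types and system_types[name] != t:
            raise InputError(f"{path}: system {name!r} has conflicting types")
        system_types[name] = t
    return SystemPartition(
        node_ids=frame["node_id"].tolist(),
        system=frame["system_name"].to_numpy(dtype=object),
        system_types=system_types,
        provenance=f"read from {Path(path).name}",
    )


def write_consensus(consensus: ConsensusAssignment, path) -> None:
    rows = []
    for d in consensus.densities:
        part = consensus.partitions[d]
        agree = consensus.agreement[d]
        for i, nid in enumerate(part.node_ids):
            rows.append(
                {
                    "node_id": nid,
                    "density": d,
                    "system_name": part.system[i],
                    "agreement": float(agree[i]),
                }
            )
    _write_tsv(pd.DataFrame(rows), path)


def write_clean_sidecar(clean: CleanTimeSeries, fd_threshold: float, path) -> None:
    write_json(
        {
            "fd_threshold_mm": fd_threshold,
            "n_kept": clean.n_kept,
            "dropped_frames": np.flatnonzero(~clean.keep_mask).tolist(),
        },
        path,
    )


# -- synthetic truth and whole cohorts ---------------------------------


def write_truth(truth: SyntheticTruth, path) -> None:
    write_json(
        {
            "age": truth.age,
            "partition": dict(truth.partition),
            "system_types": dict(truth.system_types),
            "roles": dict(truth.roles),
            "planted_selectivity": dict(truth.planted_selectivity),
            "bridges": [list(map(int, b)) for b in truth.bridges],
        },
        path,
    )


def read_truth(path) -> SyntheticTruth:
    obj = read_json(path)
    return SyntheticTruth(
        node_ids=tuple(obj["partition"].keys()),
        partition=obj["partition"],
        system_types=obj["system_types"],
        roles=obj["roles"],
        age=float(obj["age"]),
        planted_selectivity=obj["planted_selectivity"],
        bridges=tuple(tuple(b) for b in obj["bridges"]),
    )


def write_cohort(cohort: Cohort, outdir) -> None:
    """Write a cohort as the on-disk ingestion contract.

    ``cohort.json`` lists participants (id, age, file names); each
    participant gets ``<id>_timeseries.tsv``, ``<id>_motion.tsv``,
    ``<id>_betas.tsv`` and ``<id>_truth.json``; the planted partition is
    written as ``reference_partition.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": cohort.seed, "participants": []}
    node_ids = list(cohort.participants[0].truth.node_ids)
    for p in cohort.participants:
        write_timeseries(p.timeseries, node_ids, outdir / f"{p.participant_id}_timeseries.tsv")
        write_motion(p.motion, outdir / f"{p.participant_id}_motion.tsv")
        write_betas(p.betas, node_ids, outdir / f"{p.participant_id}_betas.tsv")
        write_truth(p.truth, outdir / f"{p.participant_id}_truth.json")
        manifest["participants"].append(
            {"participant_id": p.participant_id, "age": p.age, "seed": p.seed}
        )
    write_reference_partition(
        cohort.participants[0].truth.reference_partition(),
        outdir / "reference_partition.tsv",
    )
    write_json(manifest, outdir / "cohort.json")


def read_cohort(indir, spec: CohortSpec | None = None) -> Cohort:
    indir = Path(indir)
    manifest = read_json(indir / "cohort.json")
    participants = []
    for entry in manifest["participants"]:
        pid = entry["participant_id"]
        ts, node_ids = read_timeseries(indir / f"{pid}_timeseries.tsv")
        motion = read_motion(indir / f"{pid}_motion.tsv")
        betas = read_betas(indir / f"{pid}_betas.tsv", node_ids)
        truth = read_truth(indir / f"{pid}_truth.json")
        participants.append(
            Participant(
                participant_id=pid,
                age=float(entry["age"]),
                timeseries=ts,
                motion=motion,
                betas=betas,
                truth=truth,
                seed=int(entry["seed"]),
            )
        )
    return Cohort(
        spec=spec if spec is not None else CohortSpec(),
        participants=participants,
        seed=int(manifest["seed"]),
    )
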
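"""Activation selectivity: relating node topology to task activation.

The per-participant selectivity score is

    selectivity = -1 * r(PC, beta)

the sign-flipped correlation, across nodes, of participation
coefficient and task activation (β estimate): a positive score means
greater activation at nodes with fewer cross-system connections
(non-connector nodes). Default-system nodes are excluded by default so
task-evoked deactivation does not conflate the score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .communities import UNASSIGNED, SystemPartition
from .errors import EmptyCellError, InputError, UndefinedCorrelationError
from .simulate import ASSOCIATION, DEFAULT, SENSORY_MOTOR
from .topology import ROLE_CONNECTOR, ROLE_NON_CONNECTOR

SCOPE_ALL = "all-nodes"

#: Span of the descriptive LOESS trend (fraction of points per local fit).
LOESS_SPAN = 0.75


@dataclass(frozen=True)
class SelectivityScore:
    participant_id: str
    task: str
    scope: str  # all-nodes | sensory-motor | association
    score: float
    n_nodes: int


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            "correlation undefined: PC or beta is constant over the masked nodes"
        )
    if method == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise InputError(f"unknown correlation method {method!r}")


def default_node_mask(
    partition: SystemPartition, include_default_system: bool = False
) -> np.ndarray:
    """Analysis mask: assigned nodes, minus the default system by default."""
    types = partition.type_of_node()
    mask = partition.system != UNASSIGNED
    if not include_default_system:
        mask &= types != DEFAULT
    return mask


def selectivity_score(
    pc: np.ndarray,
    beta: np.ndarray,
    node_mask: np.ndarray | None = None,
    participant_id: str = "",
    task: str = "",
    scope: str = SCOPE_ALL,
    method: str = "pearson",
) -> SelectivityScore:
    """``-1 * r(PC, beta)`` over the masked nodes (>= 3 required)."""
    pc = np.asarray(pc, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if pc.shape != beta.shape:
        raise InputError("pc and beta must have the same length")
    if not np.isfinite(beta).all():
        raise InputError("beta contains non-finite values")
    mask = np.ones(pc.shape[0], dtype=bool) if node_mask is None else np.asarray(node_mask, bool)
    x, y = pc[mask], beta[mask]
    if x.size < 3:
        raise InputError(f"need at least 3 nodes after masking, got {x.size}")
    return SelectivityScore(
        participant_id=participant_id,
        task=task,
        scope=scope,
        score=-1.0 * _corr(x, y, method),
        n_nodes=int(x.size),
    )


def system_type_selectivity(
    pc: np.ndarray,
    beta: np.ndarray,
    partition: SystemPartition,
    participant_id: str = "",
    task: str = "",
    method: str = "pearson",
) -> dict:
    """Selectivity computed separately over sensory-motor and association nodes."""
    types = partition.type_of_node()
    out = {}
    for scope in (SENSORY_MOTOR, ASSOCIATION):
        mask = (types == scope) & (partition.system != UNASSIGNED)
        out[scope] = selectivity_score(
            pc, beta, mask, participant_id=participant_id, task=task,
            scope=scope, method=method,
        )
    return out


def activation_by_node_type(
    beta: np.ndarray,
    roles: np.ndarray,
    partition: SystemPartition,
    include_default_system: bool = False,
) -> pd.DataFrame:
    """Mean and SE of β per (role x system type) cell.

    Raises :class:`EmptyCellError` when any role-by-type cell is empty.
    """
    beta = np.asarray(beta, dtype=float)
    roles = np.asarray(roles, dtype=object)
    types = partition.type_of_node()
    keep_types = [SENSORY_MOTOR, ASSOCIATION] + (
        [DEFAULT] if include_default_system else []
    )
    rows = []
    for t in keep_types:
        for role in (ROLE_CONNECTOR, ROLE_NON_CONNECTOR):
            cell = (types == t) & (roles == role)
            n = int(cell.sum())
            if n == 0:
                raise EmptyCellError(f"no nodes in cell (role={role}, type={t})")
            vals = beta[cell]
            rows.append(
                {
                    "system_type": t,
                    "role": role,
                    "n_nodes": n,
                    "mean_beta": float(vals.mean()),
                    "se_beta": float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def role_permutation_test(
    beta: np.ndarray,
    roles: np.ndarray,
    node_mask: np.ndarray | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict:
    """Permutation null for the non-connector minus connector β difference.

    Shuffles role labels over the masked nodes; returns the observed
    difference, the null distribution, and the two-sided 95% interval.
    """
    beta = np.asarray(beta, dtype=float)
    roles = np.asarray(roles, dtype=object)
    mask = np.ones(beta.shape[0], bool) if node_mask is None else np.asarray(node_mask, bool)
    b, r = beta[mask], roles[mask]
    nc, c = b[r == ROLE_NON_CONNECTOR], b[r == ROLE_CONNECTOR]
    if nc.size == 0 or c.size == 0:
        raise EmptyCellError("need both connector and non-connector nodes in the mask")
    observed = float(nc.mean() - c.mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    is_nc = r == ROLE_NON_CONNECTOR
    for p in range(n_perm):
        perm = rng.permutation(is_nc)
        null[p] = b[perm].mean() - b[~perm].mean()
    lo, hi = np.quantile(null, [0.025, 0.975])
    p_two = float((np.sum(np.abs(null) >= abs(observed)) + 1) / (n_perm + 1))
    return {
        "observed": observed,
        "null": null,
        "ci95": (float(lo), float(hi)),
        "p_value": p_two,
    }


def cohort_summary(scores: list, ages: np.ndarray) -> dict:
    """Cohort-level summary per (task, scope): mean, SD, age correlation, trend.

    ``scores`` is a flat list of :class:`SelectivityScore` with ``ages``
    aligned entrywise (one age per score). The LOESS-style trend is
    descriptive output only.
    """
    ages = np.asarray(ages, dtype=float)
    if len(scores) != ages.size:
        raise InputError("scores and ages must align entrywise")
    if np.unique(ages).size < 2:
        raise UndefinedCorrelationError("ages are constant; age trend undefined")
    frame = pd.DataFrame(
        [
            {"task": s.task, "scope": s.scope, "participant_id": s.participant_id,
             "score": s.score, "age": age}
            for s, age in zip(scores, ages)
        ]
    )
    if frame["participant_id"].nunique() < 4:
        raise InputError("need at least 4 participants for a cohort summary")
    out = {}
    for (task, scope), grp in frame.groupby(["task", "scope"], sort=True):
        vals = grp["score"].to_numpy()
        grp_ages = grp["age"].to_numpy()
        if np.ptp(vals) == 0:
            raise UndefinedCorrelationError(
                f"scores constant in group (task={task}, scope={scope})"
            )
        r, p = stats.pearsonr(grp_ages, vals)
        trend = lowess(vals, grp_ages, frac=LOESS_SPAN, return_sorted=True)
        out[(task, scope)] = {
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "n": int(vals.size),
            "r_age": float(r),
            "p_age": float(p),
            "trend_age": [float(x) for x in trend[:, 0]],
            "trend_score": [float(x) for x in trend[:, 1]],
        }
    return out
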
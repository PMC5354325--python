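"""Synthetic lifespan cohort generator.

Generates per-participant node time series, head-realignment traces, and
per-node task activation (β) maps with *planted* network structure:

* block-structured node correlation matrices (one block per functional
  system) built from a latent factor model, so positive semidefiniteness
  and the planted pairwise correlations are exact by construction;
* planted connector / non-connector roles — connectors carry strong
  cross-system "bridge" coupling that survives sparse density
  thresholding, non-connectors do not;
* an age-graded dedifferentiation gradient: with increasing (normalized)
  age, non-connector within-system coupling erodes and non-connector
  between-system coupling grows, shrinking the topological contrast
  between the two node classes;
* motion spikes in the realignment trace with analytically known
  framewise displacement; and
* task β maps with a non-connector activation bonus restricted to
  task-relevant system types, attenuating with age.

The factor model
----------------
Node ``i`` in system ``s`` is generated as

    x_i = lam_i * f_s + nu_i * g + e_i * b_{p(i)} + sig_i * eps_i

where ``f_s`` is the system factor, ``g`` a global factor shared by all
nodes (carrying the baseline between-system coupling), ``b_p`` a bridge
factor shared by exactly one cross-system pair of planted connectors,
and ``eps_i`` unique noise. Loadings are chosen so that the expected
correlations hit the planted targets exactly:

* within-system, same role:      rho_own(role, age)
* between-system, no bridge:     rho_x(role_i, age) * rho_x(role_j, age) ** 0.5 each side
  (equal to rho_between for two baseline nodes)
* bridged connector pair:        rho_between + connector_boost

with ``rho_own = rho_within - dediff_slope_within * age`` and
``rho_x = rho_between + dediff_slope_between * age`` for non-connectors,
and age-free values for connectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ._seeds import substream
from .errors import ParameterError

SENSORY_MOTOR = "sensory-motor"
ASSOCIATION = "association"
DEFAULT = "default"
SYSTEM_TYPES = (SENSORY_MOTOR, ASSOCIATION, DEFAULT)

CONNECTOR = "connector"
NON_CONNECTOR = "non-connector"

#: Default age grid: four equally spaced lifespan groups (young, middle
#: early, middle late, old), normalized to [0, 1].
DEFAULT_AGE_GRID = (0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0)


@dataclass(frozen=True)
class TaskSpec:
    """Planted activation structure of one task condition.

    ``beta_base`` maps each system type to its baseline activation;
    ``delta_selectivity`` is the extra activation given to non-connector
    nodes of task-relevant system types at age 0, attenuated linearly by
    ``delta_age_slope`` per unit normalized age.
    """

    name: str
    relevant_types: frozenset = frozenset({SENSORY_MOTOR})
    beta_base: dict = field(
        default_factory=lambda: {SENSORY_MOTOR: 1.67, ASSOCIATION: 0.94, DEFAULT: -0.5}
    )
    delta_selectivity: float = 1.0
    beta_noise_sd: float = 0.75
    delta_age_slope: float = 0.6

    def realized_delta(self, age: float) -> float:
        return self.delta_selectivity * (1.0 - self.delta_age_slope * age)


def default_tasks() -> tuple[TaskSpec, TaskSpec]:
    """A visual-like and a semantic-like task.

    Baseline β levels follow the reported group cell means for the two
    task conditions: the visual-like task drives sensory-motor systems
    hard (base 1.67, non-connector bonus 1.0), the semantic-like task
    drives association systems weakly but selectively (base 0.11,
    bonus 0.45).
    """
    visual = TaskSpec(
        name="visual",
        relevant_types=frozenset({SENSORY_MOTOR}),
        beta_base={SENSORY_MOTOR: 1.67, ASSOCIATION: 0.94, DEFAULT: -0.5},
        delta_selectivity=1.0,
        beta_noise_sd=0.75,
        delta_age_slope=0.6,
    )
    semantic = TaskSpec(
        name="semantic",
        relevant_types=frozenset({ASSOCIATION}),
        beta_base={SENSORY_MOTOR: 0.10, ASSOCIATION: 0.11, DEFAULT: -0.3},
        delta_selectivity=0.45,
        beta_noise_sd=0.5,
        delta_age_slope=0.6,
    )
    return visual, semantic


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of the synthetic cohort.

    Defaults emulate the study conditions: a 154-frame rest run at
    TR = 2 s, five functional systems (two sensory-motor, two
    association, one default) of 20 nodes each, moderate within-system
    coupling (0.4) against weak between-system coupling (0.05), and
    motion spikes frequent enough that scrubbing keeps ~139 frames on
    average.
    """

    n_participants: int = 48
    age_grid: tuple = DEFAULT_AGE_GRID
    n_systems: int = 5
    nodes_per_system: int = 20
    system_types: tuple = (
        SENSORY_MOTOR,
        SENSORY_MOTOR,
        ASSOCIATION,
        ASSOCIATION,
        DEFAULT,
    )
    connector_fraction: float = 0.5
    rho_within: float = 0.4
    rho_between: float = 0.05
    connector_boost: float = 0.44
    connector_within_premium: float = 0.10
    dediff_slope_within: float = 0.05
    dediff_slope_between: float = 0.05
    dediff_slope_bridge: float = 0.12
    n_frames: int = 154
    tr_seconds: float = 2.0
    spike_prob: float = 0.1
    spike_fd_mm: float = 0.6
    task_specs: tuple = field(default_factory=default_tasks)
    loading_jitter_sd: float = 0.05
    cross_jitter_sd: float = 0.15
    jitter_seed: int = 101

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.n_systems * self.nodes_per_system

    @property
    def node_ids(self) -> list:
        return [f"n{i:03d}" for i in range(self.n_nodes)]

    @property
    def system_names(self) -> list:
        counts: dict = {}
        names = []
        for t in self.system_types:
            counts[t] = counts.get(t, 0) + 1
            names.append(f"{t}-{counts[t]}")
        return names

    def validate(self) -> None:
        if self.n_systems < 1 or len(self.system_types) != self.n_systems:
            raise ParameterError("system_types must list one type per system")
        if any(t not in SYSTEM_TYPES for t in self.system_types):
            raise ParameterError(f"system types must be one of {SYSTEM_TYPES}")
        if self.nodes_per_system < 4:
            raise ParameterError("nodes_per_system must be >= 4")
        if not 0.0 < self.connector_fraction < 1.0:
            raise ParameterError("connector_fraction must lie strictly in (0, 1)")
        if not all(0.0 <= a <= 1.0 for a in self.age_grid):
            raise ParameterError("age_grid entries must be normalized ages in [0, 1]")
        for name, val in [
            ("rho_within", self.rho_within),
            ("rho_between", self.rho_between),
        ]:
            if not 0.0 <= val < 1.0:
                raise ParameterError(f"{name}={val} outside [0, 1)")
        if self.connector_boost < 0.0:
            raise ParameterError("connector_boost must be non-negative")
        # dediff slopes must never push a planted correlation outside (-1, 1)
        # (or below the feasibility floor of the factor construction) over the grid
        for age in self.age_grid:
            self._class_targets(age)
        if self.rho_within + self.connector_boost >= 1.0:
            raise ParameterError(
                "rho_within + connector_boost >= 1: bridged connector pairs "
                "would need correlation >= 1"
            )
        if self.spike_prob < 0.0 or self.spike_prob > 1.0:
            raise ParameterError("spike_prob must be a probability")
        if self.n_frames < 2 or self.tr_seconds <= 0:
            raise ParameterError("need n_frames >= 2 and tr_seconds > 0")

    def _class_targets(self, age: float) -> dict:
        """Planted (rho_own, rho_x) per role at ``age``; raises if infeasible."""
        if not 0.0 <= age <= 1.0:
            raise ParameterError(f"age={age} outside [0, 1]")
        out = {}
        for role in (CONNECTOR, NON_CONNECTOR):
            if role == NON_CONNECTOR:
                rho_own = self.rho_within - self.dediff_slope_within * age
                rho_x = self.rho_between + self.dediff_slope_between * age
            else:
                # connectors are hubs: slightly elevated within-system strength
                # keeps them anchored to their home system at sparse densities,
                # and their within-system couplings are age-stable — aging acts
                # on their cross-system bridges and on non-connector couplings
                rho_own = self.rho_within + self.connector_within_premium
                rho_x = self.rho_between
            if not 0.0 < rho_own < 1.0:
                raise ParameterError(
                    f"within-system correlation for {role} nodes is {rho_own:.4f} "
                    f"at age {age:.3f}: outside (0, 1)"
                )
            if not 0.0 <= rho_x < 1.0:
                raise ParameterError(
                    f"between-system correlation for {role} nodes is {rho_x:.4f} "
                    f"at age {age:.3f}: outside [0, 1)"
                )
            if rho_x >= rho_own:
                raise ParameterError(
                    f"between-system correlation ({rho_x:.4f}) reaches the "
                    f"within-system level ({rho_own:.4f}) for {role} nodes at "
                    f"age {age:.3f}: factor loadings infeasible"
                )
            out[role] = (rho_own, rho_x)
        return out


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth planted in one participant (or one planted matrix)."""

    node_ids: tuple
    partition: dict  # node_id -> system name
    system_types: dict  # system name -> system type
    roles: dict  # node_id -> connector | non-connector
    age: float
    planted_selectivity: dict  # task name -> realized non-connector bonus
    bridges: tuple = ()  # pairs of node indices sharing a bridge factor

    def systems(self) -> list:
        seen: dict = {}
        for s in self.partition.values():
            seen.setdefault(s, None)
        return list(seen)

    def role_array(self) -> np.ndarray:
        return np.array([self.roles[n] for n in self.node_ids])

    def system_array(self) -> np.ndarray:
        return np.array([self.partition[n] for n in self.node_ids])

    def reference_partition(self):
        """The planted partition as a reference SystemPartition."""
        from .communities import SystemPartition

        return SystemPartition(
            node_ids=list(self.node_ids),
            system=self.system_array().copy(),
            system_types=dict(self.system_types),
            provenance="planted synthetic partition",
        )


# ----------------------------------------------------------------------
# planted model construction
# ----------------------------------------------------------------------


def _roles_and_bridges(spec: CohortSpec) -> tuple[np.ndarray, np.ndarray, list]:
    """Planted system index and role per node, plus bridged connector pairs.

    Within each system the first ``round(connector_fraction * n)`` nodes
    are connectors. Connectors are interleaved round-robin across systems
    and paired off so each bridge joins two connectors from different
    systems; a leftover connector (odd counts) carries no bridge.
    """
    n = spec.nodes_per_system
    k = int(spec.connector_fraction * n + 0.5)
    sys_idx = np.repeat(np.arange(spec.n_systems), n)
    roles = np.full(spec.n_nodes, NON_CONNECTOR, dtype=object)
    connectors_by_system = []
    for s in range(spec.n_systems):
        ids = np.arange(s * n, s * n + k)
        roles[ids] = CONNECTOR
        connectors_by_system.append(list(ids))
    # round-robin interleave, then pair consecutive cross-system connectors
    interleaved = []
    for j in range(k):
        for s in range(spec.n_systems):
            if j < len(connectors_by_system[s]):
                interleaved.append(connectors_by_system[s][j])
    bridges = []
    pending = None
    for idx in interleaved:
        if pending is None:
            pending = idx
        elif sys_idx[pending] != sys_idx[idx]:
            bridges.append((pending, idx))
            pending = None
        else:  # same system (only one system has connectors left at this level)
            pending = idx  # earlier connector stays unbridged
    return sys_idx, roles, bridges


def _planted_loadings(spec: CohortSpec, age: float):
    """Loading matrix L (nodes x factors) and unique s.d. per node."""
    spec.validate()
    targets = spec._class_targets(age)
    sys_idx, roles, bridges = _roles_and_bridges(spec)
    n_nodes = spec.n_nodes
    n_factors = spec.n_systems + 1 + len(bridges)
    L = np.zeros((n_nodes, n_factors))

    jitter_rng = np.random.default_rng(
        substream(spec.jitter_seed, "loading-jitter")
    )
    # heterogeneity is planted in the non-connector population only: that is
    # the coupling the dedifferentiation gradient reshapes, and connectors are
    # defined by stable, strong anchoring to their home system. Non-connectors
    # get independent jitter on the within-system and global (between-system)
    # loadings, so the upper tail of their cross-system coupling enters the
    # thresholded graphs progressively as the age gradient raises its mean.
    jitter = 1.0 + jitter_rng.normal(0.0, spec.loading_jitter_sd, size=n_nodes)
    # cross-coupling heterogeneity is heavy-tailed (mean-one lognormal): the
    # few non-connectors with the strongest between-system coupling sit just
    # below the edge-retention cutoff when young and cross it progressively as
    # the age gradient raises the mean — the "proto-connector" tail through
    # which dedifferentiation expresses itself in thresholded graphs
    s = spec.cross_jitter_sd
    jitter_x = np.exp(jitter_rng.normal(-0.5 * s * s, s, size=n_nodes))
    jitter[roles == CONNECTOR] = 1.0
    jitter_x[roles == CONNECTOR] = 1.0

    for i in range(n_nodes):
        rho_own, rho_x = targets[roles[i]]
        lam = np.sqrt(rho_own - rho_x) * jitter[i]
        nu = np.sqrt(rho_x) * jitter_x[i]
        # cap so the unit-variance budget survives the lognormal tail
        nu = min(nu, np.sqrt(max(0.90 - lam * lam, 0.0)))
        L[i, sys_idx[i]] = lam
        L[i, spec.n_systems] = nu
    # hub bridges erode with age faster than the within-system bulk: they
    # slide down the density-cutoff ladder, so the connector/non-connector
    # topological contrast closes smoothly over the lifespan. Bridges share
    # one strength when young but erode at (deterministically) spread rates,
    # so the dropout is gradual rather than simultaneous.
    n_bridges = len(bridges)
    rate = np.linspace(0.5, 1.5, n_bridges) if n_bridges > 1 else np.ones(1)
    for b, (i, j) in enumerate(bridges):
        e = np.sqrt(
            max(
                spec.connector_boost
                - spec.dediff_slope_bridge * rate[b] * age,
                0.0,
            )
        )
        L[i, spec.n_systems + 1 + b] = e
        L[j, spec.n_systems + 1 + b] = e

    communality = np.sum(L**2, axis=1)
    bad = np.flatnonzero(communality >= 1.0)
    if bad.size:
        i = int(bad[0])
        raise ParameterError(
            f"node {spec.node_ids[i]} has planted common variance "
            f"{communality[i]:.4f} >= 1 at age {age:.3f}; reduce couplings, "
            f"connector_boost, or loading_jitter_sd"
        )
    sigma = np.sqrt(1.0 - communality)
    return L, sigma, sys_idx, roles, bridges


def _truth(spec: CohortSpec, age: float, sys_idx, roles, bridges) -> SyntheticTruth:
    names = spec.system_names
    node_ids = tuple(spec.node_ids)
    partition = {nid: names[s] for nid, s in zip(node_ids, sys_idx)}
    system_types = dict(zip(names, spec.system_types))
    role_map = dict(zip(node_ids, roles))
    planted = {t.name: t.realized_delta(age) for t in spec.task_specs}
    return SyntheticTruth(
        node_ids=node_ids,
        partition=partition,
        system_types=system_types,
        roles=role_map,
        age=age,
        planted_selectivity=planted,
        bridges=tuple(bridges),
    )


def plant_covariance(spec: CohortSpec, age: float):
    """Planted node-by-node correlation matrix and ground truth at ``age``.

    The matrix is symmetric with unit diagonal and positive semidefinite
    by construction (``L @ L.T + diag(sigma**2)``).
    """
    L, sigma, sys_idx, roles, bridges = _planted_loadings(spec, age)
    C = L @ L.T
    np.fill_diagonal(C, C.diagonal() + sigma**2)
    C = (C + C.T) / 2.0
    return C, _truth(spec, age, sys_idx, roles, bridges)


# ----------------------------------------------------------------------
# participant generation
# ----------------------------------------------------------------------


@dataclass
class Participant:
    participant_id: str
    age: float
    timeseries: np.ndarray  # frames x nodes
    motion: np.ndarray  # frames x 6 (d_x, d_y, d_z mm; alpha, beta, gamma rad)
    betas: dict  # task name -> (nodes,) array
    truth: SyntheticTruth
    seed: int


MOTION_COLUMNS = ("d_x", "d_y", "d_z", "alpha", "beta", "gamma")

# Quiet-breathing baseline motion: gentle random-walk drift far below the
# 0.3 mm censoring threshold (expected baseline FD ~ 0.04 mm at 50 mm radius).
_BASE_TRANS_STEP_SD = 0.010  # mm per frame
_BASE_ROT_STEP_SD = 1e-4  # rad per frame


def _motion_trace(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    F = spec.n_frames
    steps = np.empty((F, 6))
    steps[:, :3] = rng.normal(0.0, _BASE_TRANS_STEP_SD, size=(F, 3))
    steps[:, 3:] = rng.normal(0.0, _BASE_ROT_STEP_SD, size=(F, 3))
    steps[0] = 0.0
    trace = np.cumsum(steps, axis=0)
    # motion spikes: persistent step offsets in the translations only, so the
    # framewise displacement at the spike frame is spike_fd_mm by construction
    spikes = rng.random(F) < spec.spike_prob
    spikes[0] = False
    signs = rng.choice([-1.0, 1.0], size=(F, 3))
    offset = np.zeros(3)
    for t in range(F):
        if spikes[t]:
            offset = offset + signs[t] * (spec.spike_fd_mm / 3.0)
        trace[t, :3] += offset
    return trace


def generate_participant(
    spec: CohortSpec, age: float, seed: int, participant_id: str = "sub-000"
) -> Participant:
    """Sample one participant: time series, motion trace, and task β maps.

    Identical ``(spec, age, seed)`` reproduces bitwise-identical output.
    """
    L, sigma, sys_idx, roles, bridges = _planted_loadings(spec, age)
    if spec.n_frames < 2 * spec.n_nodes:
        warnings.warn(
            f"n_frames={spec.n_frames} < 2 x {spec.n_nodes} nodes: "
            "correlation estimates will be noisy",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    factors = rng.standard_normal((spec.n_frames, L.shape[1]))
    unique = rng.standard_normal((spec.n_frames, spec.n_nodes))
    ts = factors @ L.T + unique * sigma

    motion = _motion_trace(spec, rng)

    truth = _truth(spec, age, sys_idx, roles, bridges)
    types = np.array([truth.system_types[truth.partition[n]] for n in truth.node_ids])
    role_arr = truth.role_array()
    betas = {}
    for task in spec.task_specs:
        base = np.array([task.beta_base[t] for t in types], dtype=float)
        bonus = task.realized_delta(age) * (
            (role_arr == NON_CONNECTOR)
            & np.isin(types, list(task.relevant_types))
        )
        noise = rng.normal(0.0, task.beta_noise_sd, size=spec.n_nodes)
        betas[task.name] = base + bonus + noise
    return Participant(
        participant_id=participant_id,
        age=age,
        timeseries=ts,
        motion=motion,
        betas=betas,
        truth=truth,
        seed=int(seed),
    )


@dataclass
class Cohort:
    spec: CohortSpec
    participants: list
    seed: int

    @property
    def ages(self) -> np.ndarray:
        return np.array([p.age for p in self.participants])

    def by_age_group(self) -> dict:
        groups: dict = {}
        for p in self.participants:
            groups.setdefault(p.age, []).append(p)
        return dict(sorted(groups.items()))


def generate_cohort(spec: CohortSpec, seed: int) -> Cohort:
    """Generate ``spec.n_participants`` participants, cycling the age grid."""
    spec.validate()
    ss = substream(seed, "cohort")
    children = ss.spawn(spec.n_participants)
    participants = []
    for p, child in enumerate(children):
        age = spec.age_grid[p % len(spec.age_grid)]
        pseed = int(child.generate_state(1, dtype=np.uint32)[0] >> np.uint32(1))
        participants.append(
            generate_participant(spec, age, pseed, participant_id=f"sub-{p:03d}")
        )
    return Cohort(spec=spec, participants=participants, seed=int(seed))


def strong_signal_spec(**overrides) -> CohortSpec:
    """Single-age strong-signal recovery conditions (desk-scale benchmark).

    20 participants, 1000 frames, five 20-node systems, within-system
    rho 0.4 against between-system rho 0.05. Used for parameter-recovery
    checks of the full pipeline.
    """
    base = dict(
        n_participants=20,
        age_grid=(0.0,),
        n_frames=1000,
    )
    base.update(overrides)
    return replace(CohortSpec(), **base)
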
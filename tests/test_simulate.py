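"""Synthetic cohort generator: planted correlations, truth, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from topoact.errors import ParameterError
from topoact.simulate import (
    CONNECTOR,
    NON_CONNECTOR,
    CohortSpec,
    TaskSpec,
    generate_cohort,
    generate_participant,
    plant_covariance,
    strong_signal_spec,
)
from topoact.preprocess import compute_fd

from conftest import naive_participation_coefficient


def two_block_spec(**overrides):
    base = dict(
        n_participants=2,
        age_grid=(0.0,),
        n_systems=2,
        nodes_per_system=4,
        system_types=("sensory-motor", "association"),
        connector_fraction=0.1,  # rounds to zero connectors
        rho_within=0.36,
        rho_between=0.0,
        connector_boost=0.0,
        connector_within_premium=0.0,
        dediff_slope_within=0.0,
        dediff_slope_between=0.0,
        dediff_slope_bridge=0.0,
        loading_jitter_sd=0.0,
        cross_jitter_sd=0.0,
        n_frames=64,
    )
    base.update(overrides)
    return replace(CohortSpec(), **base)


class TestPlantCovariance:
    def test_independent_systems_give_block_diagonal(self):
        C, truth = plant_covariance(two_block_spec(), age=0.0)
        sysa = truth.system_array()
        off_block = sysa[:, None] != sysa[None, :]
        assert np.all(C[off_block] == 0.0)

    def test_within_correlation_matches_squared_loading(self):
        # loading 0.6 on the system factor => within correlation 0.36
        C, truth = plant_covariance(two_block_spec(), age=0.0)
        sysa = truth.system_array()
        within = (sysa[:, None] == sysa[None, :]) & ~np.eye(8, dtype=bool)
        assert np.allclose(C[within], 0.36)
        assert np.allclose(np.diag(C), 1.0)

    def test_age_zero_equals_slope_free_baseline(self):
        spec = strong_signal_spec()
        baseline = replace(
            spec,
            dediff_slope_within=0.0,
            dediff_slope_between=0.0,
            dediff_slope_bridge=0.0,
        )
        C_aged, _ = plant_covariance(spec, age=0.0)
        C_base, _ = plant_covariance(baseline, age=0.0)
        np.testing.assert_array_equal(C_aged, C_base)

    @pytest.mark.parametrize("age", [0.0, 0.5, 1.0])
    def test_positive_semidefinite_unit_diagonal(self, age):
        C, _ = plant_covariance(strong_signal_spec(), age=age)
        assert np.allclose(C, C.T)
        assert np.allclose(np.diag(C), 1.0)
        assert np.linalg.eigvalsh(C).min() > -1e-10

    def test_bridged_connector_pairs_carry_the_boost(self):
        spec = strong_signal_spec()
        C, truth = plant_covariance(spec, age=0.0)
        bi, bj = np.array(truth.bridges).T
        expected = spec.rho_between + spec.connector_boost
        assert np.allclose(C[bi, bj], expected)

    def test_infeasible_dediff_slope_raises_naming_role(self):
        spec = replace(strong_signal_spec(), dediff_slope_between=0.5,
                       age_grid=(0.0, 1.0))
        with pytest.raises(ParameterError, match="non-connector"):
            spec.validate()

    def test_planted_role_separation_on_noise_free_matrix(self):
        # on the density-thresholded planted matrix (the graph the pipeline
        # sees), connectors carry the cross-system weight in every system
        from topoact.graph import ZMatrix, threshold_density

        spec = strong_signal_spec()
        C, truth = plant_covariance(spec, age=0.0)
        W = np.where(C > 0, C, 0.0)
        np.fill_diagonal(W, 0.0)
        zm = ZMatrix(node_ids=list(truth.node_ids), z=W)
        g = threshold_density(zm, 0.10)
        pc = naive_participation_coefficient(g.adjacency, truth.system_array())
        roles = truth.role_array()
        sysa = truth.system_array()
        for name in truth.systems():
            members = sysa == name
            c_pc = pc[members & (roles == CONNECTOR)].mean()
            nc_pc = pc[members & (roles == NON_CONNECTOR)].mean()
            assert c_pc > nc_pc

    def test_planted_pc_gap_non_increasing_in_age(self):
        spec = strong_signal_spec()
        gaps = []
        for age in (0.0, 0.25, 0.5, 0.75, 1.0):
            C, truth = plant_covariance(spec, age=age)
            W = np.where(C > 0, C, 0.0)
            np.fill_diagonal(W, 0.0)
            pc = naive_participation_coefficient(W, truth.system_array())
            roles = truth.role_array()
            gaps.append(pc[roles == CONNECTOR].mean() - pc[roles == NON_CONNECTOR].mean())
        assert all(a >= b - 1e-12 for a, b in zip(gaps, gaps[1:]))


class TestSpecValidation:
    @pytest.mark.parametrize(
        "overrides,match",
        [
            (dict(connector_fraction=0.0), "connector_fraction"),
            (dict(connector_fraction=1.0), "connector_fraction"),
            (dict(nodes_per_system=3), "nodes_per_system"),
            (dict(rho_within=1.2), "rho_within"),
            (dict(age_grid=(0.0, 1.5)), "age_grid"),
            (dict(system_types=("cortex",) * 5), "system types"),
        ],
    )
    def test_invalid_parameters_raise(self, overrides, match):
        with pytest.raises(ParameterError, match=match):
            replace(CohortSpec(), **overrides).validate()

    def test_truth_partition_and_roles_cover_every_node(self):
        spec = strong_signal_spec()
        _, truth = plant_covariance(spec, age=0.0)
        assert set(truth.partition) == set(truth.node_ids)
        assert set(truth.roles) == set(truth.node_ids)
        roles = truth.role_array()
        k = int(spec.connector_fraction * spec.nodes_per_system + 0.5)
        sysa = truth.system_array()
        for name in truth.systems():
            assert (roles[sysa == name] == CONNECTOR).sum() == k


class TestGenerateParticipant:
    def test_identical_seed_is_bitwise_identical(self):
        spec = two_block_spec(n_frames=40)
        a = generate_participant(spec, 0.0, seed=9)
        b = generate_participant(spec, 0.0, seed=9)
        np.testing.assert_array_equal(a.timeseries, b.timeseries)
        np.testing.assert_array_equal(a.motion, b.motion)
        for task in a.betas:
            np.testing.assert_array_equal(a.betas[task], b.betas[task])
        c = generate_participant(spec, 0.0, seed=10)
        assert not np.array_equal(a.timeseries, c.timeseries)

    def test_no_spikes_keeps_fd_below_threshold(self):
        spec = replace(strong_signal_spec(), spike_prob=0.0)
        p = generate_participant(spec, 0.0, seed=3)
        assert compute_fd(p.motion).max() < 0.3

    def test_spikes_produce_fd_near_requested_magnitude(self):
        spec = replace(strong_signal_spec(), spike_prob=0.1, spike_fd_mm=0.6)
        p = generate_participant(spec, 0.0, seed=3)
        fd = compute_fd(p.motion)
        spikes = fd > 0.3
        assert spikes.any()
        assert np.allclose(fd[spikes], 0.6, atol=0.1)

    def test_noiseless_null_betas_constant_within_system_type(self):
        tasks = (
            TaskSpec(name="null", delta_selectivity=0.0, beta_noise_sd=0.0),
        )
        spec = replace(strong_signal_spec(), task_specs=tasks)
        p = generate_participant(spec, 0.0, seed=1)
        types = np.array(
            [p.truth.system_types[p.truth.partition[n]] for n in p.truth.node_ids]
        )
        beta = p.betas["null"]
        for t in np.unique(types):
            assert np.ptp(beta[types == t]) == 0.0

    def test_empirical_correlation_converges_to_planted(self):
        spec = two_block_spec(n_frames=10000)
        C, truth = plant_covariance(spec, age=0.0)
        p = generate_participant(spec, 0.0, seed=5)
        emp = np.corrcoef(p.timeseries, rowvar=False)
        sysa = truth.system_array()
        within = (sysa[:, None] == sysa[None, :]) & ~np.eye(8, dtype=bool)
        assert abs(emp[within].mean() - 0.36) < 0.02
        assert np.abs(emp - C).max() < 3.0 / np.sqrt(10000) * 3

    def test_short_run_warns(self):
        spec = two_block_spec(n_frames=10)
        with pytest.warns(UserWarning, match="noisy"):
            generate_participant(spec, 0.0, seed=1)


def test_generate_cohort_cycles_age_grid_deterministically():
    spec = replace(strong_signal_spec(), n_participants=8,
                   age_grid=(0.0, 0.5, 1.0))
    cohort = generate_cohort(spec, seed=4)
    ages = [p.age for p in cohort.participants]
    assert ages == [0.0, 0.5, 1.0, 0.0, 0.5, 1.0, 0.0, 0.5]
    again = generate_cohort(spec, seed=4)
    np.testing.assert_array_equal(
        cohort.participants[3].timeseries, again.participants[3].timeseries
    )
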
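import dataclasses
import io

import numpy as np
import pytest

import metapopnet as mp
from metapopnet.records_io import write_observations
from metapopnet.synthetic_data import (
    ConfigError,
    PopulationSpec,
    SyntheticConfig,
    WithinMoveKernel,
    config_from_yaml,
    config_to_yaml,
    default_study_config,
    generate_observations,
    ground_truth,
    planted_partition_matrix,
    two_cluster_config,
)

from conftest import two_population_config


def one_population_config(seed=7):
    return SyntheticConfig(
        populations=(PopulationSpec("P", 47.0, 2.0, 10_000.0, 30.0),),
        years=(2000, 2008),
        flow_matrix=((1.0,),),
        seed=seed,
        ring_prob=1.0,
        resight_prob=1.0,
        within_move=WithinMoveKernel(p_move=0.0),
        location_sigma_km=0.0,
    )


class TestGenerateObservations:
    def test_determinism_byte_identical(self, tmp_path):
        cfg = two_population_config(3, 0.02, 0.02)
        a, b = generate_observations(cfg), generate_observations(cfg)
        fa, fb = io.StringIO(), io.StringIO()
        write_observations(a, fa)
        write_observations(b, fb)
        assert fa.getvalue() == fb.getvalue()

    def test_no_movement_config_pins_every_bird_to_its_nest(self):
        cfg = one_population_config()
        rec = generate_observations(cfg)
        assert (rec["population"] == "P").all()
        for _, grp in rec.groupby("individual_id"):
            assert grp["lat"].nunique() == 1 and grp["lon"].nunique() == 1
        events = mp.extract_dispersal_events(rec, cfg.to_populations())
        assert len(events) == 0

    def test_forced_switching_alternates_populations(self):
        cfg = dataclasses.replace(
            two_population_config(11, 0.5, 0.5),
            flow_matrix=((0.0, 1.0), (1.0, 0.0)),
            ring_prob=1.0,
            resight_prob=1.0,
            survival=1.0,
            location_sigma_km=0.0,
            within_move=WithinMoveKernel(p_move=0.0),
        )
        rec = generate_observations(cfg)
        resights = rec[rec["event_type"] == "resight"]
        for ind, grp in resights.groupby("individual_id"):
            pops = grp.sort_values("date")["population"].tolist()
            natal = ind.split("-")[0]
            # age-4 first resight: even ages back home, odd ages away
            expected = [natal if i % 2 == 0 else ({"A", "B"} - {natal}).pop() for i in range(4, 4 + len(pops))]
            assert pops == expected
        events = mp.extract_dispersal_events(rec, cfg.to_populations())
        assert len(events) > 0
        assert (events["scope"] == "between").all()

    def test_each_individual_ringed_once_and_resighted_only_as_adult(self):
        cfg = two_population_config(5, 0.02, 0.02)
        rec = generate_observations(cfg)
        rings = rec[rec["event_type"] == "ring"].groupby("individual_id").size()
        assert (rings == 1).all()
        assert set(rings.index) == set(rec["individual_id"])
        ring_year = rec[rec["event_type"] == "ring"].set_index("individual_id")["date"].dt.year
        res = rec[rec["event_type"] == "resight"]
        ages = res["date"].dt.year.to_numpy() - ring_year.reindex(res["individual_id"]).to_numpy()
        assert (ages >= cfg.adult_age).all()
        # at most one resighting per breeding season
        per_season = res.groupby(["individual_id", res["date"].dt.year]).size()
        assert (per_season == 1).all()

    def test_invalid_configs_name_the_offending_field(self):
        good = two_population_config(1, 0.02, 0.02)
        with pytest.raises(ConfigError, match="flow_matrix"):
            dataclasses.replace(good, flow_matrix=((0.9, 0.2), (0.5, 0.5)))
        with pytest.raises(ConfigError, match="flow_matrix"):
            dataclasses.replace(good, flow_matrix=((1.2, -0.2), (0.5, 0.5)))
        with pytest.raises(ConfigError, match="years"):
            dataclasses.replace(good, years=(2010, 2000))
        with pytest.raises(ConfigError, match="area_km2"):
            dataclasses.replace(
                good,
                populations=(PopulationSpec("A", 0.0, 0.0, -5.0, 1.0), good.populations[1]),
            )
        with pytest.raises(ConfigError, match="resight_prob"):
            dataclasses.replace(good, resight_prob=1.5)

    def test_ground_truth_reports_flow_and_pair_trajectories(self):
        cfg = default_study_config(2)
        truth = ground_truth(cfg)
        F = np.array(truth["flow_matrix"])
        assert F.shape == (5, 5)
        assert np.allclose(F.sum(axis=1), 1.0)
        ne = truth["pairs_by_year"]["NE"]
        assert ne["1988"] == pytest.approx(70.0)
        assert ne["1989"] == pytest.approx(70.0 * 1.06)


class TestPlantedPartitionMatrix:
    def test_two_disconnected_dyads_reach_half_modularity(self):
        S = planted_partition_matrix(2, 10.0, 0.0)
        q = mp.modularity(S, [{0, 1}, {2, 3}])
        assert q == pytest.approx(0.5)

    def test_single_block_has_zero_modularity(self):
        S = planted_partition_matrix(1, 5.0, 0.0, block_sizes=[4])
        assert mp.modularity(S, [{0, 1, 2, 3}]) == pytest.approx(0.0)

    def test_uniform_weights_make_the_block_split_worthless(self):
        # with a zero diagonal the uniform matrix gives each dyad
        # e_kk = 2/12 and a_k^2 = 1/4, so the block partition scores
        # Q = 2 (1/6 - 1/4) = -1/6 and the best cut is the single cluster
        S = planted_partition_matrix(2, 1.0, 1.0)
        assert mp.modularity(S, [{0, 1}, {2, 3}]) == pytest.approx(-1 / 6, abs=1e-12)
        d = mp.average_linkage_dendrogram(S)
        _, q_max, _ = mp.max_modularity_partition(d, S)
        assert q_max == pytest.approx(0.0, abs=1e-12)

    def test_invalid_sizes_and_weights_rejected(self):
        with pytest.raises(ValueError):
            planted_partition_matrix(2, 1.0, 0.0, block_sizes=[2, 0])
        with pytest.raises(ValueError):
            planted_partition_matrix(2, 1.0, 2.0)
        with pytest.raises(ValueError):
            planted_partition_matrix(0, 1.0, 0.0)


class TestFlowRecovery:
    """The generator's planted asymmetry must be detectable downstream, and
    symmetric flow must not trigger false alarms beyond the nominal rate."""

    @staticmethod
    def _edge_p(seed, fab, fba):
        cfg = two_population_config(seed, fab, fba)
        rec = generate_observations(cfg)
        pops = cfg.to_populations()
        net = mp.build_network(mp.extract_dispersal_events(rec, pops), pops)
        a, b = int(net.W[0, 1]), int(net.W[1, 0])
        return a, b, mp.edge_asymmetry_test(a, b, n_perm=2000, seed=seed).p_value

    def test_three_to_one_flow_detected(self):
        results = [self._edge_p(s, 0.018, 0.006) for s in range(200)]
        totals = [a + b for a, b, _ in results]
        assert np.mean(totals) >= 30  # enough events on the edge for power
        rejections = np.mean([p <= 0.05 for _, _, p in results])
        assert rejections >= 0.80

    def test_symmetric_flow_rejects_at_nominal_rate(self):
        results = [self._edge_p(1000 + s, 0.012, 0.012) for s in range(200)]
        rejections = np.mean([p <= 0.05 for _, _, p in results])
        assert 0.03 <= rejections <= 0.07


def test_yaml_config_roundtrip(tmp_path):
    cfg = two_cluster_config(9)
    path = tmp_path / "cfg.yaml"
    config_to_yaml(cfg, path)
    back = config_from_yaml(path)
    assert back == cfg
    assert generate_observations(back).equals(generate_observations(cfg))
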
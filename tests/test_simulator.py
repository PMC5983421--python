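"""Run orchestration: seeding, determinism, transect sampling."""

import math

import numpy as np
import pytest

import phonosfe as ph
from phonosfe import (InitialScenario, PhonemeInventory, SimConfig,
                      make_initial_languages, run, scaled_config,
                      two_language_inventories)


class TestInitialLanguages:
    def test_counts_within_scenario_range(self, rng):
        inv = PhonemeInventory.generated(908)
        scen = InitialScenario(n_languages=5, phoneme_range=(35, 40))
        ancs = make_initial_languages(scen, inv, rng)
        assert len(ancs) == 5
        assert all(35 <= a.K <= 40 for a in ancs)
        assert len({a.id for a in ancs}) == 5

    def test_single_fixed_count_language(self, rng):
        inv = PhonemeInventory.generated(908)
        scen = InitialScenario(n_languages=1, phoneme_range=(71, 71))
        (anc,) = make_initial_languages(scen, inv, rng)
        assert anc.K == 71

    def test_full_overlap_gives_identical_masks(self, rng):
        inv = PhonemeInventory.generated(100)
        scen = InitialScenario(n_languages=2, phoneme_range=(40, 40), overlap=1.0)
        a, b = make_initial_languages(scen, inv, rng)
        assert (a.full_mask == b.full_mask).all()

    def test_nested_masks_are_nested(self, rng):
        inv = PhonemeInventory.generated(100)
        scen = InitialScenario(n_languages=3, phoneme_range=(10, 30), overlap="nested")
        ancs = make_initial_languages(scen, inv, rng)
        ancs = sorted(ancs, key=lambda a: a.K)
        for small, big in zip(ancs, ancs[1:]):
            assert not np.any(small.full_mask & ~big.full_mask)

    def test_disjoint_masks_share_nothing(self, rng):
        inv = PhonemeInventory.generated(300)
        scen = InitialScenario(n_languages=3, phoneme_range=(40, 40), overlap="disjoint")
        a, b, c = make_initial_languages(scen, inv, rng)
        assert not np.any(a.full_mask & b.full_mask)
        assert not np.any(b.full_mask & c.full_mask)

    def test_range_exceeding_inventory_rejected(self, rng):
        inv = PhonemeInventory.generated(30)
        scen = InitialScenario(phoneme_range=(35, 40))
        with pytest.raises(ValueError):
            make_initial_languages(scen, inv, rng)

    def test_two_language_pair_overlap(self, rng):
        inv = PhonemeInventory.generated(908)
        a, b = two_language_inventories(inv, rng, k=40, shared=20)
        assert a.K == b.K == 40
        assert int((a.full_mask & b.full_mask).sum()) == 20

    def test_multiplicities_round_robin(self):
        assert InitialScenario(n_tribes=10, n_languages=5).multiplicities() == [2] * 5
        assert InitialScenario(n_tribes=10, n_languages=1).multiplicities() == [10]
        assert InitialScenario(n_tribes=10, n_languages=3).multiplicities() == [4, 3, 3]


class TestRun:
    def test_zero_generations_only_origin_occupied(self):
        cfg = scaled_config(grid_side=21, generations=0, nph=120)
        res = run(cfg)
        assert res.state.total_tribes == 10
        assert (res.records["distance_km"] == 0).all()
        assert len(res.records) == 10

    def test_no_loss_single_language_counts_constant(self):
        scen = InitialScenario(n_languages=1, phoneme_range=(37, 37))
        cfg = scaled_config(loss_time=math.inf, grid_side=21, scenario=scen,
                            generations=400, nph=120)
        res = run(cfg)
        assert (res.records["phoneme_count"] == 37).all()
        assert ph.count_cline_from_run(res).slope == 0.0

    def test_same_seed_reproduces_bit_for_bit(self):
        cfg = scaled_config(loss_time=10, grid_side=21, generations=400, nph=120)
        r1, r2 = run(cfg), run(cfg)
        assert r1.generations_run == r2.generations_run
        assert (r1.state.counts == r2.state.counts).all()
        assert r1.records.equals(r2.records)
        assert (r1.state.pool_bits == r2.state.pool_bits).all()

    def test_distinct_seeds_differ(self):
        cfg1 = scaled_config(loss_time=10, grid_side=21, generations=400, nph=120, seed=1)
        cfg2 = scaled_config(loss_time=10, grid_side=21, generations=400, nph=120, seed=2)
        assert not run(cfg1).records.equals(run(cfg2).records)

    def test_coverage_stop(self):
        cfg = scaled_config(loss_time=10, grid_side=21, generations=4000, nph=120)
        res = run(cfg)
        assert res.covered_at is not None
        assert res.covered_at == res.generations_run < 4000
        assert (res.state.counts >= 1).all()

    def test_saturated_transect_has_200_records_per_1000km(self):
        cfg = scaled_config(loss_time=math.inf, grid_side=41, generations=2000,
                            nph=120, transect_axis="+x")
        res = run(cfg)
        rec = res.records
        first_k = rec[rec["distance_km"] < 1000]
        assert len(first_k) == 20 * 10  # 20 cells x 10 tribes
        assert rec["distance_km"].max() <= (41 // 2) * 50.0

    def test_front_radius_monotone(self):
        cfg = scaled_config(loss_time=math.inf, grid_side=21, generations=300, nph=120)
        cfg.track_front = True
        res = run(cfg)
        fr = res.front_radius
        assert fr is not None and (np.diff(fr) >= 0).all()
        assert (np.diff(res.arrival_generation) > 0).all()  # outward in order

    def test_density_profile_flat_at_saturation(self):
        cfg = scaled_config(loss_time=math.inf, grid_side=21, generations=2000, nph=120)
        res = run(cfg)
        assert (res.density_profile == 10).all()


class TestConfigRoundTrip:
    def test_dict_round_trip(self):
        cfg = scaled_config(loss_time=60, grid_side=31, R0=1.2, seed=9)
        again = SimConfig.from_dict(cfg.to_dict())
        assert again.to_dict() == cfg.to_dict()

    def test_infinite_loss_time_serializes(self):
        cfg = scaled_config(loss_time=math.inf, grid_side=31)
        again = SimConfig.from_dict(cfg.to_dict())
        assert not again.demography.loss_enabled


class TestExpandRows:
    def test_masks_match_counts_and_ancestors(self):
        cfg = scaled_config(loss_time=10, grid_side=21, generations=400, nph=120)
        res = run(cfg)
        rec = res.records
        masks = ph.expand_rows(res.state, rec["language_id"].to_numpy())
        assert masks.shape == (len(rec), 120)
        assert (masks.sum(axis=1) == rec["phoneme_count"].to_numpy()).all()
        # each mask is a subset of its ancestor's mask
        anc_by_id = {a.id: a for a in res.state.ancestors}
        for i in range(0, len(rec), 37):
            anc = anc_by_id[rec["ancestor"].iloc[i]]
            assert not np.any(masks[i] & ~anc.full_mask)
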
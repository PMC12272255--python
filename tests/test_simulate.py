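"""Synthetic-cohort generator: determinism, planted structure, spectra."""

import dataclasses

import numpy as np
import pytest

import alans


class TestDeterminism:
    def test_contrasts_bit_identical(self, small_cohort):
        a = alans.simulate_contrasts(small_cohort)
        b = alans.simulate_contrasts(small_cohort)
        np.testing.assert_array_equal(a.values, b.values)

    def test_rest_bit_identical(self, small_cohort):
        a = alans.simulate_rest_timeseries(small_cohort)
        b = alans.simulate_rest_timeseries(small_cohort)
        np.testing.assert_array_equal(a.data, b.data)

    def test_seed_changes_output(self, small_cohort):
        other = dataclasses.replace(small_cohort, rng_seed=small_cohort.rng_seed + 1)
        a = alans.simulate_contrasts(small_cohort)
        b = alans.simulate_contrasts(other)
        assert not np.array_equal(a.values, b.values)


class TestContrastStructure:
    def test_planted_pairs_carry_effects(self):
        cfg = alans.CohortConfig(
            n_participants=4000, n_pairs=2,
            pair_ids=("planted", "null"),
            planted_pairs={"planted": "Left"},
            activation_effect=1.5, asymmetry_effect=1.0,
            module_spec={"A": ("planted",)}, rng_seed=3,
        )
        table = alans.simulate_contrasts(cfg)
        left, right = table.left(), table.right()
        j = table.pair_ids.index("planted")
        assert left[:, j].mean() == pytest.approx(1.5 + 0.5, abs=0.06)
        assert right[:, j].mean() == pytest.approx(1.5 - 0.5, abs=0.06)
        k = table.pair_ids.index("null")
        assert abs(left[:, k].mean()) < 0.06

    def test_excluded_pairs_masked(self, small_cohort):
        cfg = dataclasses.replace(small_cohort, excluded_pairs=("n1", "n2"))
        table = alans.simulate_contrasts(cfg)
        assert table.n_pairs == small_cohort.n_pairs - 2
        assert "n1" not in table.pair_ids

    def test_invalid_planted_index_rejected(self):
        with pytest.raises(ValueError, match="planted"):
            alans.CohortConfig(n_pairs=3, planted_pairs={"pair009": "Left"})


class TestRestStructure:
    def test_out_of_band_power_negligible(self, small_cohort):
        panel = alans.simulate_rest_timeseries(small_cohort)
        freqs = np.fft.rfftfreq(small_cohort.n_timepoints, d=small_cohort.tr_seconds)
        power = np.abs(np.fft.rfft(panel.data, axis=-1)) ** 2
        lo, hi = small_cohort.band
        out = power[..., (freqs < lo) | (freqs > hi)].sum()
        assert out < 0.05 * power.sum()

    def test_within_exceeds_between_correlation(self, small_cohort):
        panel = alans.simulate_rest_timeseries(small_cohort)
        stack = alans.stack_from_timeseries(
            panel.data, panel.region_ids, panel.participant_ids
        )
        group = alans.fisher_group_average(stack)
        labels = alans.planted_truth(small_cohort).module_labels
        same = np.array([[labels[a] == labels[b] for b in panel.region_ids]
                         for a in panel.region_ids])
        off = ~np.eye(len(panel.region_ids), dtype=bool)
        assert group[same & off].mean() > group[~same].mean() + 0.2

    def test_zero_between_target_gives_near_zero_mean_r(self):
        cfg = alans.CohortConfig(
            n_participants=130, n_pairs=8,
            pair_ids=tuple(f"r{i}" for i in range(8)),
            planted_pairs={f"r{i}": "Right" for i in range(8)},
            module_spec={"A": tuple(f"r{i}" for i in range(4)),
                         "B": tuple(f"r{i}" for i in range(4, 8))},
            between_module_r={},
            n_timepoints=240, rng_seed=9,
        )
        panel = alans.simulate_rest_timeseries(cfg)
        stack = alans.stack_from_timeseries(
            panel.data, panel.region_ids, panel.participant_ids
        )
        vals = alans.participant_pair_mean(
            stack, [f"r{i}" for i in range(4)], [f"r{i}" for i in range(4, 8)]
        )
        assert abs(vals.mean()) < 0.05

    def test_degenerate_single_module_unit_loadings(self):
        cfg = alans.CohortConfig(
            n_participants=2, n_pairs=3,
            pair_ids=("a", "b", "c"),
            planted_pairs={"a": "Left", "b": "Left", "c": "Left"},
            module_spec={"M": ("a", "b", "c")},
            noise_sd=0.0, n_timepoints=64, rng_seed=1,
        )
        panel = alans.simulate_rest_timeseries(cfg)
        r = alans.participant_correlation(panel.data[0])
        np.testing.assert_allclose(r, 1.0, atol=1e-10)

    def test_unreachable_between_target_rejected(self):
        cfg = alans.CohortConfig(
            n_participants=4, n_pairs=4,
            pair_ids=("a", "b", "c", "d"),
            planted_pairs={p: "Left" for p in "abcd"},
            module_spec={"A": ("a", "b"), "B": ("c", "d")},
            between_module_r={("A", "B"): 0.9},  # exceeds within-module r
            rng_seed=0,
        )
        with pytest.raises(ValueError, match="unreachable"):
            alans.simulate_rest_timeseries(cfg)


class TestGroundTruth:
    def test_truth_mirrors_config(self, small_cohort):
        truth = alans.planted_truth(small_cohort)
        assert truth.selected_regions == frozenset(
            small_cohort.planted_pairs.items()
        )
        assert set(truth.module_labels) == set(small_cohort.region_ids)
        assert truth.hub_regions == frozenset({"r00"})

    def test_empty_hub_spec(self, small_cohort):
        cfg = dataclasses.replace(small_cohort, hub_spec={})
        assert alans.planted_truth(cfg).hub_regions == frozenset()

    def test_demo_config_matches_atlas(self, atlas):
        cfg = alans.demo_config(rng_seed=0)
        truth = alans.planted_truth(cfg)
        assert len(truth.selected_regions) == 95
        sizes = sorted(len(v) for v in cfg.module_spec.values())
        assert sizes == [12, 15, 20, 23, 25]
        hemis = dict(truth.selected_regions)
        assert sum(h == "Right" for h in hemis.values()) == 66


def test_panel_roundtrip(tmp_path, small_cohort):
    panel = alans.simulate_rest_timeseries(small_cohort)
    panel.to_dir(tmp_path / "ts")
    back = alans.TimeSeriesPanel.from_dir(tmp_path / "ts")
    assert back.region_ids == panel.region_ids
    np.testing.assert_allclose(back.data, panel.data, rtol=1e-12)
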
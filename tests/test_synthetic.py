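"""Ground-truth fidelity and determinism of the synthetic study generator."""

import numpy as np
import pytest

from senoscope.errors import CapacityError, ScenarioError
from senoscope.image_io import CellMask, image_from_array
from senoscope.profiling import build_profile, detect_peaks
from senoscope.quantify import (mean_density, pixel_densities,
                                projected_area)
from senoscope.scoring import FieldCount, positive_fraction
from senoscope.synthetic import (Component, ScenarioSpec, analytic_fractions,
                                 generate_cell_field, generate_count_tables,
                                 generate_intensity_population,
                                 generate_mito_population,
                                 generate_peak_observations)


class TestScenarioSpec:
    def test_default_spec_is_valid_and_full_factorial(self):
        spec = ScenarioSpec()
        assert len(spec.conditions) == 3 * 6
        assert 95 <= spec.n_cells_per_condition <= 600

    def test_weights_must_sum_to_one(self):
        with pytest.raises(ScenarioError):
            ScenarioSpec(lyso_components=[(1.0, 0.1, 0.4), (2.0, 0.1, 0.4)])

    def test_component_count_capped_at_three(self):
        with pytest.raises(ScenarioError):
            ScenarioSpec(lyso_components=[(k, 0.1, 0.25) for k in range(4)])

    def test_cell_count_outside_study_range_rejected(self):
        with pytest.raises(ScenarioError):
            ScenarioSpec(n_cells_per_condition=50)
        with pytest.raises(ScenarioError):
            ScenarioSpec(n_cells_per_condition=1000)

    def test_json_roundtrip(self, tmp_path, small_spec):
        path = tmp_path / "spec.json"
        small_spec.to_json(path)
        loaded = ScenarioSpec.from_json(path)
        assert loaded == small_spec


class TestIntensityPopulation:
    def test_determinism_identical_spec_and_seed(self, small_spec):
        a, ta = generate_intensity_population(small_spec, "YD", "C10")
        b, tb = generate_intensity_population(small_spec, "YD", "C10")
        assert ta == tb
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca, cb)

    def test_streams_differ_across_conditions(self, small_spec):
        a, _ = generate_intensity_population(small_spec, "YD", "C10")
        b, _ = generate_intensity_population(small_spec, "YD", "Doxo")
        assert not np.array_equal(a[0], b[0])

    def test_zero_variance_components_hit_modes_exactly(self):
        spec = ScenarioSpec(seed=1, lyso_components=[(1.0, 0.0, 0.5),
                                                     (2.5, 0.0, 0.5)],
                            curve_intercept_sd=0.0)
        cells, truth = generate_intensity_population(spec, "YD", "C10")
        observed = np.unique(np.concatenate(cells))
        np.testing.assert_allclose(np.log10(observed), truth.modes)

    def test_truth_modes_ascend_and_carry_all_shifts(self):
        spec = ScenarioSpec(seed=2)
        _, truth = generate_intensity_population(spec, "RS", "Bleo")
        assert truth.modes == tuple(sorted(truth.modes))
        assert truth.shift == pytest.approx(0.5 + 0.4)

    def test_single_component_population_recovered_by_pipeline(self):
        spec = ScenarioSpec(seed=3, lyso_components=[(1.0, 0.15, 1.0)],
                            curve_intercept_sd=0.0)
        cells, truth = generate_intensity_population(spec, "YD", "C10")
        peaks = detect_peaks(build_profile(cells, n_bins=30_000),
                             smooth_window=600)
        assert len(peaks) == 1
        assert peaks.positions[0] == pytest.approx(truth.modes[0], abs=0.05)


class TestPeakObservations:
    def test_observation_table_structure(self, small_spec):
        obs, truth = generate_peak_observations(small_spec, n_curves=20)
        assert set(obs.columns) == {"log10_xpeak", "donor", "inducer",
                                    "peak_id", "curve_id"}
        assert obs["curve_id"].nunique() == 20
        assert obs["peak_id"].between(1, 3).all()
        assert truth["peak_id"] == 0.4

    def test_deterministic_given_seed(self, small_spec):
        a, _ = generate_peak_observations(small_spec, n_curves=10)
        b, _ = generate_peak_observations(small_spec, n_curves=10)
        assert a.equals(b)


class TestCellField:
    def test_quantification_closure_recovers_draws_exactly(self, small_spec):
        field = generate_cell_field(small_spec, "YD", "C10",
                                    image_size=(256, 256), n_cells=4)
        image = image_from_array(field.image,
                                 pixel_size_x=field.pixel_size_um,
                                 pixel_size_y=field.pixel_size_um)
        for mask_arr, draws, area in zip(field.masks, field.cell_values,
                                         field.cell_areas_um2):
            mask = CellMask(mask_arr)
            assert projected_area(mask, field.pixel_size_um) == \
                pytest.approx(area)
            np.testing.assert_allclose(
                np.sort(pixel_densities(image, mask, area)),
                np.sort(draws), rtol=1e-12)
            assert mean_density(image, mask, area) == \
                pytest.approx(draws.sum(), rel=1e-12)

    def test_masks_are_disjoint(self, small_spec):
        field = generate_cell_field(small_spec, "YD", "C10", n_cells=8)
        stacked = np.sum(field.masks, axis=0)
        assert stacked.max() <= 1

    def test_empty_request_rejected(self, small_spec):
        with pytest.raises(ScenarioError):
            generate_cell_field(small_spec, "YD", "C10", n_cells=0)

    def test_overcrowded_field_raises_capacity_error(self, small_spec):
        with pytest.raises(CapacityError):
            generate_cell_field(small_spec, "YD", "C10",
                                image_size=(64, 64), n_cells=50,
                                max_attempts=200)


class TestMitoPopulation:
    def test_requires_two_components(self):
        spec = ScenarioSpec(seed=4, mito_components=[(2.0, 0.3, 1.0)])
        with pytest.raises(ScenarioError):
            generate_mito_population(spec, "YD", "C10")

    def test_weight_swap_mirrors_analytic_fractions(self):
        comps = (Component(1.0, 0.2, 0.3), Component(3.0, 0.2, 0.7))
        swapped = (Component(1.0, 0.2, 0.7), Component(3.0, 0.2, 0.3))
        f = analytic_fractions(comps, 1.0, 3.0)
        g = analytic_fractions(swapped, 1.0, 3.0)
        # mass below the low mode mirrors mass above the high mode
        assert f[0] == pytest.approx(g[2], abs=1e-9)
        assert f[2] == pytest.approx(g[0], abs=1e-9)

    def test_truth_components_carry_condition_shift(self):
        spec = ScenarioSpec(seed=5)
        _, truth = generate_mito_population(spec, "OD", "Doxo")
        assert truth["modes"][0] == pytest.approx(1.0 + 0.3 + 0.35)


class TestCountTables:
    def test_s_percent_recovered_across_replicates(self):
        hits = 0
        for rep in range(100):
            spec = ScenarioSpec(seed=5000 + rep, s_percent_baseline={
                "YD": 2.5, "OD": 9.1, "RS": 16.3})
            counts, _, truth = generate_count_tables(spec, "RS", "C10")
            fields = [FieldCount(r.field_id, r.condition, r.n_positive,
                                 r.n_total)
                      for r in counts.itertuples(index=False)]
            estimate, _ = positive_fraction(fields)
            hits += abs(estimate - truth["s_percent"]) <= 3.0
        assert hits >= 90

    def test_zero_s_percent_gives_all_zero_positives(self):
        spec = ScenarioSpec(seed=6, s_percent_baseline={"YD": 0.0, "OD": 0.0,
                                                        "RS": 0.0})
        counts, _, _ = generate_count_tables(spec, "YD", "C10")
        assert (counts["n_positive"] == 0).all()

    def test_tables_bit_identical_across_calls(self, small_spec):
        a, ea, _ = generate_count_tables(small_spec, "YD", "Doxo")
        b, eb, _ = generate_count_tables(small_spec, "YD", "Doxo")
        assert a.equals(b)
        np.testing.assert_array_equal(ea, eb)

    def test_flow_events_centre_on_condition_mfi(self, small_spec):
        _, events, truth = generate_count_tables(small_spec, "YD", "Doxo")
        assert np.median(events) == pytest.approx(truth["mfi"], rel=0.1)
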
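"""Mixed-model fitting, diagnostics, shape comparison and FDR control."""

import numpy as np
import pandas as pd
import pytest

from senoscope.errors import DomainError, EstimabilityError, SampleSizeError
from senoscope.peakstats import (PSEUDOREPLICATION_NOTE, bh_adjust,
                                 dunn_posthoc, fit_peak_lmm, group_compare,
                                 residual_normality, shape_compare,
                                 variance_homogeneity)
from senoscope.synthetic import ScenarioSpec, generate_peak_observations


def _null_spec(seed):
    return ScenarioSpec(seed=seed,
                        donors={"YD": 0.0, "OD": 0.0, "RS": 0.0},
                        inducers={"C10": 0.0, "C1": 0.0, "Doxo": 0.0,
                                  "Cis": 0.0, "Eto": 0.0, "Bleo": 0.0})


class TestPeakLMM:
    def test_null_effects_estimated_near_zero(self):
        obs, _ = generate_peak_observations(_null_spec(3), n_curves=60,
                                            peak_slope=0.0)
        result = fit_peak_lmm(obs)
        table = result.fixed_effects.set_index("term")
        for term in table.index:
            if term == "Intercept":
                continue
            row = table.loc[term]
            assert abs(row["estimate"]) < 3 * row["se"], term

    def test_known_offsets_recovered_close_to_truth(self):
        spec = ScenarioSpec(seed=8)
        obs, truth = generate_peak_observations(spec, n_curves=60)
        result = fit_peak_lmm(obs)
        table = result.fixed_effects.set_index("term")
        for term in ("donor[OD]", "donor[RS]", "peak_id"):
            row = table.loc[term]
            assert abs(row["estimate"] - truth[term]) < 3 * row["se"], term

    def test_global_shift_moves_only_intercept(self):
        obs, _ = generate_peak_observations(ScenarioSpec(seed=5), n_curves=40)
        shifted = obs.assign(log10_xpeak=obs["log10_xpeak"] + 1.0)
        a = fit_peak_lmm(obs).fixed_effects.set_index("term")
        b = fit_peak_lmm(shifted).fixed_effects.set_index("term")
        assert b.loc["Intercept", "estimate"] - a.loc["Intercept", "estimate"] \
            == pytest.approx(1.0, abs=1e-5)
        others = [t for t in a.index if t != "Intercept"]
        np.testing.assert_allclose(b.loc[others, "estimate"],
                                   a.loc[others, "estimate"], atol=1e-5)

    def test_cis_contain_their_estimates_and_variance_nonnegative(self):
        obs, _ = generate_peak_observations(ScenarioSpec(seed=9), n_curves=30)
        result = fit_peak_lmm(obs)
        t = result.fixed_effects
        assert ((t["ci_low"] <= t["estimate"]) & (t["estimate"] <= t["ci_high"])).all()
        assert result.random_intercept_variance >= 0

    def test_confounded_level_raises_estimability_error(self):
        # donor OD appears only with inducer Doxo and vice versa: aliased dummies
        rows = []
        for c, (donor, inducer) in enumerate([("YD", "C10"), ("OD", "Doxo")] * 3):
            for pid in (1, 2):
                rows.append((1.0 + 0.1 * pid + 0.01 * c, donor, inducer, pid,
                             f"v{c}"))
        obs = pd.DataFrame(rows, columns=["log10_xpeak", "donor", "inducer",
                                          "peak_id", "curve_id"])
        with pytest.raises(EstimabilityError):
            fit_peak_lmm(obs)

    def test_single_curve_rejected(self):
        obs = pd.DataFrame({
            "log10_xpeak": [1.0, 1.4], "donor": ["YD", "YD"],
            "inducer": ["C10", "C10"], "peak_id": [1, 2],
            "curve_id": ["only", "only"]})
        with pytest.raises(SampleSizeError):
            fit_peak_lmm(obs)


class TestDiagnostics:
    def test_shapiro_calibrated_under_normal_null(self):
        rng = np.random.default_rng(0)
        rejections = sum(
            residual_normality(rng.normal(size=40))[1] < 0.05
            for _ in range(500))
        assert 10 <= rejections <= 45  # ~5% of 500, binomial slack

    def test_shapiro_rejects_bimodal_residuals(self):
        rng = np.random.default_rng(1)
        residuals = np.concatenate([
            -1 + 0.01 * rng.normal(size=20), 1 + 0.01 * rng.normal(size=20)])
        assert residual_normality(residuals)[1] < 0.01

    def test_shapiro_sample_size_floor(self):
        with pytest.raises(SampleSizeError):
            residual_normality(np.array([0.1, 0.2]))

    def test_levene_calibrated_under_equal_variances(self):
        rng = np.random.default_rng(2)
        rejections = sum(
            variance_homogeneity({g: rng.normal(size=30)
                                  for g in "abc"})[1] < 0.05
            for _ in range(500))
        assert 10 <= rejections <= 45

    def test_levene_detects_tenfold_variance(self):
        rng = np.random.default_rng(3)
        groups = {"a": rng.normal(scale=1.0, size=30),
                  "b": rng.normal(scale=np.sqrt(10.0), size=30)}
        assert variance_homogeneity(groups)[1] < 0.01

    def test_levene_identical_constant_groups(self):
        f, p = variance_homogeneity({"a": [2.0, 2.0, 2.0],
                                     "b": [2.0, 2.0, 2.0]})
        assert (f, p) == (0.0, 1.0)


class TestShapeCompare:
    def _donor_samples(self, rng, shift=0.0, n=20):
        return {"YD": rng.lognormal(0, 0.4, n),
                "OD": rng.lognormal(0, 0.4, n),
                "RS": rng.lognormal(0, 0.4, n) + shift}

    def test_identical_distributions_not_rejected(self):
        rng = np.random.default_rng(4)
        results = shape_compare({"C1": self._donor_samples(rng)})
        assert results[0].included
        assert results[0].p_raw > 0.05

    def test_shifted_group_detected_in_most_replicates(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(1000 + rep)
            samples = {d: np.log10(v) for d, v in
                       self._donor_samples(rng).items()}
            samples["RS"] = samples["RS"] + 1.0
            result = shape_compare({"Bleo": samples})[0]
            hits += result.p_raw < 0.05
        assert hits >= 90

    def test_min_peaks_rule_excludes_single_peak_group(self):
        groups = {"YD": [1.0, 1.5], "OD": [1.1, 1.6], "RS": [1.2]}
        result = shape_compare({"Doxo": groups})[0]
        assert not result.included
        assert result.exclusion_reason == "min_peaks"
        assert result.statistic is None

    def test_location_shift_of_all_groups_preserves_statistic(self):
        rng = np.random.default_rng(5)
        base = self._donor_samples(rng)
        shifted = {d: v + 17.3 for d, v in base.items()}
        r1 = shape_compare({"x": base})[0]
        r2 = shape_compare({"x": shifted})[0]
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_bh_applied_across_included_inducers(self):
        rng = np.random.default_rng(6)
        mapping = {f"i{k}": self._donor_samples(rng) for k in range(4)}
        results = shape_compare(mapping)
        raw = [r.p_raw for r in results]
        adjusted = [r.p_adjusted for r in results]
        np.testing.assert_allclose(adjusted, bh_adjust(raw))
        assert all(r.note == PSEUDOREPLICATION_NOTE for r in results)


class TestBHAdjust:
    def test_hand_step_up_example(self):
        adjusted = bh_adjust([0.017, 0.075, 0.25, 0.25, 0.25])
        assert adjusted.min() == pytest.approx(0.085)
        assert (adjusted < 0.10).sum() == 1  # significant at FDR 0.10 ...
        assert (adjusted < 0.05).sum() == 0  # ... but not at 0.05

    def test_single_p_unchanged(self):
        assert bh_adjust([0.42])[0] == pytest.approx(0.42)

    def test_all_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 6), 0.2)

    def test_never_decreases_and_dominates_bonferroni(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = rng.random(rng.integers(2, 12))
            adjusted = bh_adjust(p)
            assert np.all(adjusted >= p - 1e-12)
            bonf = np.minimum(p * p.size, 1.0)
            q = 0.1
            assert set(np.flatnonzero(bonf <= q)) <= \
                set(np.flatnonzero(adjusted <= q))

    def test_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.2])


class TestGroupCompare:
    def test_identical_groups_not_rejected(self, rng):
        values = rng.normal(size=30)
        result = group_compare({"a": values, "b": values.copy()})
        assert result.p_value > 0.9
        assert result.design == "two-group"

    def test_separated_groups_rejected_in_most_replicates(self):
        hits = 0
        for rep in range(40):
            rng = np.random.default_rng(2000 + rep)
            result = group_compare({"a": rng.normal(0, 1, 30),
                                    "b": rng.normal(2, 1, 30)})
            hits += result.p_value < 0.001
        assert hits >= 38

    def test_dunn_flags_only_pairs_with_shifted_group(self):
        hits = 0
        for rep in range(40):
            rng = np.random.default_rng(3000 + rep)
            result = group_compare({"a": rng.normal(0, 1, 30),
                                    "b": rng.normal(0, 1, 30),
                                    "c": rng.normal(2, 1, 30)})
            posthoc = result.posthoc.set_index(["group1", "group2"])
            good = (posthoc.loc[("a", "c"), "p_BH"] < 0.05
                    and posthoc.loc[("b", "c"), "p_BH"] < 0.05
                    and posthoc.loc[("a", "b"), "p_BH"] > 0.05)
            hits += good
        assert hits >= 36

    def test_normality_gate_recorded(self, rng):
        result = group_compare({"a": rng.normal(size=20),
                                "b": rng.normal(size=20)})
        assert set(result.normality) == {"a", "b"}
        assert result.all_normal in (True, False)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(SampleSizeError):
            group_compare({"a": [1.0]})

    def test_dunn_tie_correction_consistency(self):
        # heavily tied data still yields finite z and p in [0, 1]
        table = dunn_posthoc({"a": [1, 1, 2, 2], "b": [1, 2, 2, 3],
                              "c": [3, 3, 4, 4]})
        assert np.isfinite(table["z"]).all()
        assert table["p_raw"].between(0, 1).all()
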
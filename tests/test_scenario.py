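"""Pipeline orchestration: expected LE, ranking, equivalence analyses."""

import numpy as np
import pandas as pd
import pytest

from prolonger import DeathRecordSet, PopulationTable, ReductionScenario
from prolonger.scenario import (
    DataBundle,
    compare_individual_vs_aggregate,
    compare_reduction_modes,
    expected_le,
    prepare_pipeline,
    r_squared,
    rank_geounits,
)

from tests.helpers import two_band_schema


class TestRSquared:
    def test_identical_vectors_give_one(self):
        assert r_squared([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_affine_relation_gives_one(self):
        assert r_squared([1, 2, 3, 4], [3, 5, 7, 9]) == pytest.approx(1.0)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0], [1.0, 2.0])


class TestToyGain:
    """Hand-computable 2-band pipeline with smoothing disabled (threshold 0).

    Observed rates (0.010, 0.050) give e0 = 23.9024...; averting 20% of the
    'target' cause within each age band (2 and 4 deaths; single-year window,
    so no attrition) gives rates (0.008, 0.046) and e0 = 25.7886....
    """

    OBSERVED_E0 = 23.902439024390244
    EXPECTED_E0 = 25.788576300085253

    def test_gain_matches_hand_calculation(self, toy_two_band_bundle):
        state = prepare_pipeline(toy_two_band_bundle, "target", threshold=0)
        sc = ReductionScenario("target", 0.20, n_replicates=5, seed=0)
        out = expected_le(toy_two_band_bundle, sc, "A", state=state)
        assert out.observed_e0 == pytest.approx(self.OBSERVED_E0, abs=1e-9)
        assert out.expected_e0 == pytest.approx(self.EXPECTED_E0, abs=1e-9)
        assert out.gain == pytest.approx(self.EXPECTED_E0 - self.OBSERVED_E0, abs=1e-9)
        assert out.median_lives_saved == 6.0

    def test_null_scenario_gain_exactly_zero(self, toy_two_band_bundle):
        state = prepare_pipeline(toy_two_band_bundle, "target", threshold=0)
        sc = ReductionScenario("target", 0.0, n_replicates=5, seed=0)
        out = expected_le(toy_two_band_bundle, sc, "A", state=state)
        assert out.expected_e0 == out.observed_e0
        assert out.gain == 0.0


class TestExpectedLe:
    def test_zero_death_cause_gain_zero(self, small_bundle):
        state = prepare_pipeline(small_bundle, "stroke")
        sc = ReductionScenario("no_such_cause", 0.20, n_replicates=10, seed=1)
        # reuse the stroke smoothing state but simulate a cause absent from records
        out = expected_le(small_bundle, sc, small_bundle.geounits[0], state=state)
        assert out.median_lives_saved == 0.0
        assert out.gain == 0.0

    def test_gains_monotone_over_proportion_menu(self, small_bundle, small_state):
        g = small_bundle.geounits[0]
        gains = []
        for p in (0.05, 0.10, 0.15, 0.20):
            sc = ReductionScenario("heart_disease", p, n_replicates=50, seed=5)
            gains.append(expected_le(small_bundle, sc, g, state=small_state).gain)
        assert gains[0] >= 0
        assert gains == sorted(gains)

    def test_gain_nonnegative_across_geounits(self, small_bundle, small_state):
        sc = ReductionScenario("heart_disease", 0.10, n_replicates=20, seed=8)
        for g in small_bundle.geounits:
            assert expected_le(small_bundle, sc, g, state=small_state).gain >= 0


class TestRankGeounits:
    def test_single_geounit_ranking(self, toy_two_band_bundle):
        state = prepare_pipeline(toy_two_band_bundle, "target", threshold=0)
        sc = ReductionScenario("target", 0.20, n_replicates=5, seed=0)
        rep = rank_geounits(toy_two_band_bundle, sc, state=state)
        assert len(rep.table) == 1
        assert rep.table["geounit"].iloc[0] == "A"

    def test_sorted_descending_with_stable_ties(self, small_bundle, small_state):
        sc = ReductionScenario("heart_disease", 0.20, n_replicates=20, seed=2)
        rep = rank_geounits(small_bundle, sc, state=small_state)
        gains = rep.table["gain"].to_numpy()
        assert (np.diff(gains) <= 1e-12).all()
        assert set(rep.table["geounit"]) == set(small_bundle.geounits)

    def test_input_order_invariance(self, small_city, small_state):
        sc = ReductionScenario("heart_disease", 0.20, n_replicates=20, seed=2)
        from tests.conftest import bundle_from_city

        b1 = bundle_from_city(small_city)
        shuffled = small_city.records.data.sample(frac=1.0, random_state=0).reset_index(drop=True)
        b2 = DataBundle(population=small_city.population, covariates=small_city.covariates,
                        window=small_city.config.window,
                        records=DeathRecordSet(shuffled, small_city.config.schema),
                        schema=small_city.config.schema)
        r1 = rank_geounits(b1, sc, state=small_state).table
        r2 = rank_geounits(b2, sc, state=small_state).table
        assert r1["geounit"].tolist() == r2["geounit"].tolist()
        # LE arithmetic identical; only the within-band selection order differs
        assert r1["observed_le"].to_numpy() == pytest.approx(r2["observed_le"].to_numpy())

    def test_young_deaths_outrank_higher_crude_rate(self):
        """A geounit whose cause deaths are young ranks above one with a
        higher crude cause-mortality rate concentrated at old ages."""
        from prolonger import AgeBandSchema

        schema = AgeBandSchema.default()
        rows = []
        # Y: 20 young target deaths; O: 40 old ones (twice the crude rate)
        rows += [{"year": 2015, "age": 32, "cause": "t", "geounit": "Y"}] * 20
        rows += [{"year": 2015, "age": 82, "cause": "t", "geounit": "O"}] * 40
        # identical background mortality so only the cause age profile differs
        for g in ("Y", "O"):
            rows += [{"year": 2015, "age": 87, "cause": "bg", "geounit": g}] * 100
        records = DeathRecordSet(pd.DataFrame(rows), schema)
        pop = PopulationTable(pd.DataFrame(
            [{"geounit": g, "year": 2015, "age_band": b, "population": 1000.0}
             for g in ("Y", "O") for b in schema.labels]), schema)
        cov = pd.DataFrame({"prop_black": [0.5, 0.5], "prop_white": [0.4, 0.4],
                            "median_income": [4e4, 4e4], "prop_above_hs": [0.5, 0.5]},
                           index=pd.Index(["Y", "O"], name="geounit"))
        bundle = DataBundle(population=pop, covariates=cov, window=(2015, 2015),
                            records=records, schema=schema)
        state = prepare_pipeline(bundle, "t", threshold=0)
        sc = ReductionScenario("t", 0.20, n_replicates=5, seed=0)
        rep = rank_geounits(bundle, sc, state=state)
        assert rep.table["geounit"].iloc[0] == "Y"

    def test_median_iqr_use_linear_interpolation(self, small_bundle, small_state):
        sc = ReductionScenario("heart_disease", 0.20, n_replicates=20, seed=2)
        rep = rank_geounits(small_bundle, sc, state=small_state)
        g = rep.table["gain"].to_numpy()
        assert rep.median_gain == pytest.approx(np.percentile(g, 50))
        assert rep.iqr_gain == pytest.approx(tuple(np.percentile(g, [25, 75])))


class TestComparisons:
    def test_mode_comparison_r2_near_one(self, small_bundle, small_state):
        res = compare_reduction_modes(small_bundle, "heart_disease", 0.20,
                                      seed=4, n_replicates=30, state=small_state)
        assert res["r2_expected_le"] > 0.99
        assert res["r2_expected_deaths"] > 0.99
        t = res["targets"]
        slack = 0.5 * t["n_nonzero_bands"]
        assert ((t["within_total"] - t["overall_total"]).abs() <= slack + 0.5).all()

    def test_individual_vs_aggregate_r2_high(self, small_bundle, small_state):
        sc = ReductionScenario("heart_disease", 0.20, n_replicates=30, seed=4)
        res = compare_individual_vs_aggregate(small_bundle, sc, state=small_state)
        assert res["r2_expected_deaths"] > 0.99
        assert res["r2_expected_le"] > 0.99

    def test_aggregate_arm_shares_observed_band_counts(self, small_bundle):
        from prolonger import aggregate_individual, make_pseudo_individuals

        agg = aggregate_individual(small_bundle.records)
        pseudo = make_pseudo_individuals(agg, 7)
        agg2 = aggregate_individual(pseudo)
        pd.testing.assert_frame_equal(agg.sorted_key(), agg2.sorted_key())

    def test_too_few_geounits_rejected(self, toy_two_band_bundle):
        with pytest.raises(ValueError, match="3 geounits"):
            compare_reduction_modes(toy_two_band_bundle, "target", 0.2)
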
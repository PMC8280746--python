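"""Lives-saved simulation: targeting, follow-up attrition, replication."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prolonger import DeathRecordSet, ReductionScenario, run_lisso, run_replicate, target_averted_counts

from tests.helpers import two_band_schema


class TestScenarioValidation:
    def test_null_proportion_allowed_but_one_rejected(self):
        ReductionScenario("hd", 0.0)
        with pytest.raises(ValueError):
            ReductionScenario("hd", 1.0)

    @pytest.mark.parametrize("kw", [
        {"proportion": -0.1}, {"mode": "sideways"}, {"n_replicates": 0},
        {"attrition": "magic"},
    ])
    def test_invalid_fields_rejected(self, kw):
        with pytest.raises(ValueError):
            ReductionScenario("hd", **{"proportion": 0.2, **kw})


class TestTargetAvertedCounts:
    def test_twenty_percent_of_hundred(self):
        t = target_averted_counts(np.array([100.0]), ReductionScenario("c", 0.20))
        assert t.tolist() == [20]

    def test_overall_symmetric_apportionment(self):
        sc = ReductionScenario("c", 0.20, mode="overall")
        t = target_averted_counts(np.array([50.0, 50.0]), sc)
        assert t.tolist() == [10, 10]

    def test_half_even_rounding(self):
        # 0.5 rounds to nearest even in both modes
        sc = ReductionScenario("c", 0.05)
        assert target_averted_counts(np.array([10.0]), sc).tolist() == [0]
        assert target_averted_counts(np.array([30.0]), sc).tolist() == [2]

    def test_overall_mode_sums_exactly_to_rounded_total(self):
        rng = np.random.default_rng(0)
        sc = ReductionScenario("c", 0.17, mode="overall")
        for _ in range(200):
            d = rng.integers(0, 40, size=6).astype(float)
            t = target_averted_counts(d, sc)
            assert t.sum() == int(np.rint(0.17 * d.sum()))
            assert (t <= d).all() and (t >= 0).all()

    @settings(max_examples=100, deadline=None)
    @given(d=st.lists(st.integers(min_value=0, max_value=200), min_size=2, max_size=18),
           p=st.sampled_from([0.05, 0.10, 0.15, 0.20]))
    def test_mode_totals_agree_up_to_rounding_remainder(self, d, p):
        """Overall and within-age totals differ at most by the accumulated
        half-even rounding slack: 0.5 per nonzero band."""
        d = np.array(d, dtype=float)
        within = target_averted_counts(d, ReductionScenario("c", p)).sum()
        overall = target_averted_counts(d, ReductionScenario("c", p, mode="overall")).sum()
        assert abs(within - overall) <= 0.5 * (d > 0).sum() + 0.5


def toy_records(n0=20, n1=10, schema=None):
    """Cause decedents in a 2-band schema: n0 at age 3 in 2012, n1 at age 4 in 2013."""
    schema = schema or two_band_schema()
    rows = ([{"year": 2012, "age": 3, "cause": "c", "geounit": "A"}] * n0
            + [{"year": 2013, "age": 4, "cause": "c", "geounit": "A"}] * n1)
    return DeathRecordSet(pd.DataFrame(rows), schema)


WINDOW = (2012, 2014)
# peer all-cause rates: band 0-4 -> 0.1/yr, band 5+ -> 0.2/yr
RATES = np.array([[0.1, 0.1, 0.1], [0.2, 0.2, 0.2]])


class TestRunReplicate:
    def test_null_scenario_saves_nobody(self):
        sc = ReductionScenario("c", 0.0)
        rep = run_replicate(toy_records(), RATES, sc, np.random.default_rng(0), WINDOW)
        assert rep.net_total == 0
        assert rep.redeaths.sum() == 0

    def test_zero_peer_rates_mean_no_attrition(self):
        sc = ReductionScenario("c", 0.5)
        rep = run_replicate(toy_records(), np.zeros_like(RATES), sc,
                            np.random.default_rng(1), WINDOW)
        assert rep.net_by_band.tolist() == rep.selected_by_band.tolist() == [15, 0]

    def test_net_bounded_by_target(self):
        sc = ReductionScenario("c", 0.5)
        for seed in range(20):
            rep = run_replicate(toy_records(), RATES, sc, np.random.default_rng(seed), WINDOW)
            assert (rep.net_by_band <= rep.selected_by_band).all()
            assert (rep.net_by_band >= 0).all()

    def test_followup_deaths_reenter_expected_table_at_new_band(self):
        # agents saved at age 4 in 2013 are in band 5+ during 2014
        sc = ReductionScenario("c", 0.5, attrition="deterministic")
        rep = run_replicate(toy_records(n0=0, n1=10), RATES, sc,
                            np.random.default_rng(0), WINDOW)
        # 5 saved; each faces 0.2 in band 5+ in 2014
        assert rep.redeaths[1, 2] == pytest.approx(1.0)
        assert rep.net_by_band[0] == pytest.approx(4.0)

    def test_deterministic_attrition_matches_survival_product(self):
        sc = ReductionScenario("c", 0.5, attrition="deterministic")
        rep = run_replicate(toy_records(), RATES, sc, np.random.default_rng(0), WINDOW)
        # 2012 cohort (10 saved at age 3): 2013 in band 0 (0.9), 2014 in band 1 (0.8)
        # 2013 cohort (5 saved at age 4): 2014 in band 1 (0.8)
        assert rep.net_by_band[0] == pytest.approx(10 * 0.9 * 0.8 + 5 * 0.8)

    def test_stochastic_net_matches_closed_form_expectation(self):
        """Mean net lives saved over replicates vs the survival-product formula."""
        sc = ReductionScenario("c", 0.5, n_replicates=200, seed=12)
        res = run_lisso(toy_records(), RATES, sc, WINDOW)
        totals = res.per_replicate.sum(axis=1)
        expect = 10 * 0.9 * 0.8 + 5 * 0.8
        se = totals.std(ddof=1) / np.sqrt(len(totals))
        assert abs(totals.mean() - expect) < 3 * se


class TestRunLisso:
    def test_single_replicate_equals_that_replicate(self):
        sc = ReductionScenario("c", 0.5, n_replicates=1, seed=4)
        res = run_lisso(toy_records(), RATES, sc, WINDOW)
        rng = np.random.default_rng(np.random.SeedSequence([4, 0]))
        rep = run_replicate(toy_records(), RATES, sc, rng, WINDOW)
        assert res.per_replicate[0].tolist() == rep.net_by_band.tolist()
        assert res.median_by_band.tolist() == rep.net_by_band.tolist()

    def test_same_seed_bit_identical(self):
        sc = ReductionScenario("c", 0.3, n_replicates=25, seed=9)
        a = run_lisso(toy_records(), RATES, sc, WINDOW)
        b = run_lisso(toy_records(), RATES, sc, WINDOW)
        assert (a.per_replicate == b.per_replicate).all()
        assert a.expected_by_band.tolist() == b.expected_by_band.tolist()

    def test_replicate_streams_independent_of_order(self):
        sc1 = ReductionScenario("c", 0.3, n_replicates=10, seed=9)
        sc2 = ReductionScenario("c", 0.3, n_replicates=5, seed=9)
        a = run_lisso(toy_records(), RATES, sc1, WINDOW)
        b = run_lisso(toy_records(), RATES, sc2, WINDOW)
        assert (a.per_replicate[:5] == b.per_replicate).all()

    def test_expected_deaths_nonnegative_and_bounded(self):
        sc = ReductionScenario("c", 0.5, n_replicates=50, seed=2)
        res = run_lisso(toy_records(), RATES, sc, WINDOW)
        assert (res.expected_by_band >= 0).all()
        assert (res.expected_by_band <= res.observed_by_band).all()

    def test_observed_table_matches_records(self):
        res = run_lisso(toy_records(), RATES,
                        ReductionScenario("c", 0.1, n_replicates=1), WINDOW)
        assert res.observed_by_band.tolist() == [30.0, 0.0]

    def test_attrition_strictly_reduces_net_below_target(self):
        sc = ReductionScenario("c", 0.5, n_replicates=100, seed=0)
        res = run_lisso(toy_records(), RATES, sc, WINDOW)
        assert res.median_total < 15  # targets 10 + 5, positive peer rates

    def test_monotone_in_proportion(self):
        medians = []
        for p in (0.05, 0.10, 0.15, 0.20):
            sc = ReductionScenario("c", p, n_replicates=100, seed=3)
            medians.append(run_lisso(toy_records(100, 60), RATES, sc, WINDOW).median_total)
        assert medians == sorted(medians)
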
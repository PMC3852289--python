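"""Shock propagation: elasticity arithmetic, pooled vs stratified models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nutrishock import (
    CutPoint,
    Elasticity,
    PooledShockModel,
    Shock,
    StratifiedPopulation,
    StratifiedShockModel,
    Stratum,
    ValidationError,
    calibrate_cv,
    elasticity_table_report,
    from_mean_cv,
    intake_change,
    run_pooled,
    run_stratified,
)
from nutrishock.datasets import income_elasticity_table
from nutrishock.reporting import round_half_away


class TestIntakeChange:
    @pytest.mark.parametrize(
        "eps,pct,expected",
        [(1.244, 15.0, 18.66), (1.92, -15.0, -28.8), (0.0, 37.0, 0.0), (1.47, -15.0, -22.05)],
    )
    def test_elasticity_times_shock(self, eps, pct, expected):
        e = Elasticity(value=eps, driver="income")
        assert intake_change(e, Shock("income", pct)) == pytest.approx(expected)

    def test_driver_mismatch_rejected(self):
        e = Elasticity(value=1.0, driver="income")
        with pytest.raises(ValidationError, match="income"):
            intake_change(e, Shock("price", 10.0))

    @settings(derandomize=True, max_examples=50)
    @given(eps=st.floats(-3, 3), a=st.floats(-50, 200), scale=st.floats(0.1, 3))
    def test_linear_in_shock_magnitude(self, eps, a, scale):
        """Constant elasticity means the response scales linearly with the shock."""
        e = Elasticity(value=eps, driver="price")
        one = intake_change(e, Shock("price", a))
        scaled = intake_change(e, Shock("price", a * scale)) if a * scale > -100 else None
        if scaled is not None:
            assert scaled == pytest.approx(one * scale, rel=1e-12, abs=1e-12)


class TestPooledModel:
    def test_whole_sample_income_drop(self, ear_cut, income_drop):
        """ε = 1.47 under −15% income: −22.05% intake, rendered −22.1."""
        cv = calibrate_cv(1025.0, ear_cut, 0.095)
        res = run_pooled(
            from_mean_cv(1025.0, cv), ear_cut, Elasticity(1.47, "income"), income_drop
        )
        row = res.aggregate
        assert row.intake_change_pct == pytest.approx(-22.05)
        assert round_half_away(row.intake_change_pct, 1) == -22.1
        assert row.baseline_prevalence == pytest.approx(0.095, abs=1e-8)
        assert row.new_prevalence > row.baseline_prevalence
        assert row.change_pp == pytest.approx(
            (row.new_prevalence - row.baseline_prevalence) * 100, abs=1e-9
        )

    def test_null_shock_changes_nothing(self, ear_cut):
        res = run_pooled(
            from_mean_cv(800.0, 0.4), ear_cut, Elasticity(1.47, "income"), Shock("income", 0.0)
        )
        assert res.aggregate.new_prevalence == res.aggregate.baseline_prevalence
        assert res.aggregate.change_pp == 0.0

    @settings(derandomize=True, max_examples=40)
    @given(eps=st.floats(0.1, 2.5), pct=st.floats(0.5, 40.0))
    def test_sign_coherence(self, eps, pct):
        """Positive elasticity, positive shock: intake up, prevalence down."""
        cut = CutPoint(threshold=500.0)
        res = run_pooled(from_mean_cv(900.0, 0.5), cut, Elasticity(eps, "income"), Shock("income", pct))
        assert res.aggregate.intake_change_pct > 0
        assert res.aggregate.new_prevalence <= res.aggregate.baseline_prevalence


@pytest.fixture(scope="module")
def quartile_population(ear_cut):
    means = (600.0, 800.0, 1200.0, 1500.0)
    targets = (0.457, 0.085, 0.011, 0.001)
    eps = (1.92, 1.79, 1.29, 1.35)
    strata = tuple(
        Stratum(
            stratum_id=f"q{i+1}",
            weight=0.25,
            dist=from_mean_cv(m, calibrate_cv(m, ear_cut, t), nutrient_id="vitamin_a"),
            elasticity=Elasticity(e, "income", nutrient_id="vitamin_a", stratum_id=f"q{i+1}"),
        )
        for i, (m, t, e) in enumerate(zip(means, targets, eps))
    )
    return StratifiedPopulation(strata=strata, cut=ear_cut)


class TestStratifiedModel:
    def test_quartile_intake_changes_and_aggregate(self, quartile_population, income_drop):
        res = run_stratified(quartile_population, income_drop)
        changes = [r.intake_change_pct for r in res.rows]
        assert changes == pytest.approx([-28.8, -26.85, -19.35, -20.25])
        assert res.aggregate.intake_change_pct == pytest.approx(-23.8125)
        assert round_half_away(res.aggregate.intake_change_pct, 1) == -23.8

    def test_aggregate_prevalences_are_weighted_means(self, quartile_population, income_drop):
        res = run_stratified(quartile_population, income_drop)
        w = np.array([r.weight for r in res.rows])
        assert res.aggregate.baseline_prevalence == pytest.approx(
            float(w @ [r.baseline_prevalence for r in res.rows])
        )
        assert res.aggregate.new_prevalence == pytest.approx(
            float(w @ [r.new_prevalence for r in res.rows])
        )
        assert res.aggregate.baseline_prevalence == pytest.approx(0.1385, abs=1e-8)

    def test_equal_weight_mean_of_reported_new_deficiencies(self):
        """The aggregation rule applied to reported quartile outcomes gives 20.0%."""
        agg = float(np.dot([0.25] * 4, [0.610, 0.164, 0.025, 0.002]))
        assert agg == pytest.approx(0.20025)
        assert round_half_away(agg * 100, 1) == 20.0

    def test_identical_strata_collapse_to_pooled(self, ear_cut, income_drop):
        d = from_mean_cv(900.0, 0.45, nutrient_id="vitamin_a")
        e = Elasticity(1.5, "income", nutrient_id="vitamin_a")
        pop = StratifiedPopulation(
            strata=tuple(
                Stratum(stratum_id=f"s{i}", weight=0.25, dist=d, elasticity=e) for i in range(4)
            ),
            cut=ear_cut,
        )
        strat = run_stratified(pop, income_drop)
        pooled = run_pooled(d, ear_cut, e, income_drop)
        for attr in ("baseline_prevalence", "intake_change_pct", "new_prevalence"):
            assert getattr(strat.aggregate, attr) == pytest.approx(
                getattr(pooled.aggregate, attr), abs=1e-12
            )

    def test_stratified_impact_exceeds_pooled_on_quartile_fixture(
        self, quartile_population, ear_cut, income_drop
    ):
        """High elasticities concentrated in low-intake quartiles deepen the hit."""
        strat = run_stratified(quartile_population, income_drop)
        cv = calibrate_cv(1025.0, ear_cut, 0.095)
        pooled = run_pooled(
            from_mean_cv(1025.0, cv), ear_cut, Elasticity(1.47, "income"), income_drop
        )
        assert strat.aggregate.change_pp >= pooled.aggregate.change_pp

    def test_intake_weighted_aggregation_available(self, quartile_population, income_drop):
        res = run_stratified(quartile_population, income_drop, aggregation="intake")
        # richer quartiles eat more and shrink less, so the intake-weighted
        # aggregate drop is milder than the population-weighted one
        assert res.aggregate.intake_change_pct > -23.8125
        with pytest.raises(ValidationError):
            run_stratified(quartile_population, income_drop, aggregation="calorie")

    def test_weights_must_sum_to_one(self, ear_cut):
        d = from_mean_cv(900.0, 0.45)
        e = Elasticity(1.5, "income")
        with pytest.raises(ValidationError, match="sum to 1"):
            StratifiedPopulation(
                strata=(
                    Stratum("a", 0.6, d, e),
                    Stratum("b", 0.6, d, e),
                ),
                cut=ear_cut,
            )


class TestElasticityTableReport:
    def test_published_five_nutrient_table(self):
        report = elasticity_table_report(income_elasticity_table(), Shock("income", 15.0))
        assert list(report["intake_change_rendered"]) == [-0.6, 18.7, 15.6, -5.7, -2.8]

    def test_single_row_rendering(self):
        report = elasticity_table_report(
            [Elasticity(-0.378, "income", nutrient_id="iron")], Shock("income", 15.0)
        )
        assert report.loc[0, "intake_change_pct"] == pytest.approx(-5.67)
        assert report.loc[0, "intake_change_rendered"] == -5.7

    def test_empty_table_gives_empty_report(self):
        assert elasticity_table_report([], Shock("income", 15.0)).empty

    def test_duplicate_nutrient_rejected(self):
        table = [
            Elasticity(1.0, "income", nutrient_id="zinc"),
            Elasticity(0.5, "income", nutrient_id="zinc"),
        ]
        with pytest.raises(ValidationError, match="zinc"):
            elasticity_table_report(table, Shock("income", 15.0))
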
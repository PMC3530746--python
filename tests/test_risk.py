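import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aquarisk as aq
from aquarisk.risk import LOW_RISK_LIMIT
from aquarisk.toxicity import PCB_MIXTURE_ID

GROUP = aq.PopulationGroup("adults", size=8140, bw=70.0, ir=1.4, ed_years=30)


class TestCancerRisk:
    def test_one_hit_matches_published_pcb_adult_cell(self):
        assert aq.cancer_risk(2.518e-6, 2.0, "one_hit") == pytest.approx(5.035e-6, rel=1e-3)

    @pytest.mark.parametrize("model", ["linear", "one_hit", "auto"])
    def test_zero_dose_gives_zero_risk(self, model):
        assert aq.cancer_risk(0.0, 2.0, model) == 0.0

    def test_dose_times_sf_of_ln2_gives_one_half(self):
        assert aq.cancer_risk(math.log(2) / 2.0, 2.0, "one_hit") == pytest.approx(0.5)

    def test_auto_switches_from_linear_to_one_hit(self):
        below = (LOW_RISK_LIMIT * 0.99) / 2.0
        above = (LOW_RISK_LIMIT * 1.01) / 2.0
        assert aq.cancer_risk(below, 2.0, "auto") == aq.cancer_risk(below, 2.0, "linear")
        assert aq.cancer_risk(above, 2.0, "auto") == aq.cancer_risk(above, 2.0, "one_hit")

    def test_linear_risk_caps_at_one(self):
        assert aq.cancer_risk(10.0, 2.0, "linear") == 1.0

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            aq.cancer_risk(-1e-6, 2.0)

    @given(x=st.floats(min_value=0.0, max_value=50.0))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_one_hit_never_exceeds_linear(self, x):
        assert aq.cancer_risk(x, 1.0, "one_hit") <= aq.cancer_risk(x, 1.0, "linear")

    @given(x=st.floats(min_value=1e-8, max_value=0.5))
    @settings(max_examples=80, derandomize=True, deadline=None)
    def test_small_dose_gap_bracketed_by_series_bounds(self, x):
        """linear - one_hit lies in [x^2/2 - x^3/6, x^2/2] for small x."""
        gap = x - (1.0 - math.exp(-x))
        assert x * x / 2 - x**3 / 6 - 1e-15 <= gap <= x * x / 2 + 1e-15

    @given(doses=st.lists(st.floats(min_value=0, max_value=1e-2), min_size=2, max_size=6))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_risk_nondecreasing_in_dose(self, doses):
        risks = [aq.cancer_risk(d, 2.0, "one_hit") for d in sorted(doses)]
        assert risks == sorted(risks)


class TestCumulativeRisk:
    def test_adult_per_analyte_risks_sum_to_published_total(self):
        adult_elcr = [5.035e-6, 6.209e-7, 4.104e-8, 6.678e-8, 9.043e-8]
        assert aq.cumulative_risk(adult_elcr) == pytest.approx(5.855e-6, rel=1e-3)

    def test_single_element_is_itself(self):
        assert aq.cumulative_risk([0.25]) == 0.25

    def test_order_does_not_matter(self):
        risks = [1e-6, 5e-5, 2e-4]
        assert aq.cumulative_risk(risks) == aq.cumulative_risk(risks[::-1])

    def test_out_of_range_risk_rejected(self):
        with pytest.raises(ValueError):
            aq.cumulative_risk([0.5, 1.0])


class TestExtraCancerCases:
    def test_adult_population_burden(self):
        assert aq.extra_cancer_cases(5.855e-6, GROUP) == pytest.approx(4.766e-2, rel=1e-3)

    def test_empty_population_has_no_cases(self):
        empty = aq.PopulationGroup("none", size=0, bw=70.0, ir=1.4, ed_years=30)
        assert aq.extra_cancer_cases(5.855e-6, empty) == 0.0


class TestHazard:
    def test_pcb_hazard_quotient(self):
        assert aq.hazard_quotient(5.875e-6, 2e-5) == pytest.approx(0.2938, rel=1e-3)

    def test_ddt_hazard_quotient(self):
        assert aq.hazard_quotient(1.055e-7, 5e-4) == pytest.approx(2.110e-4, rel=1e-3)

    def test_zero_dose_gives_zero_quotient(self):
        assert aq.hazard_quotient(0.0, 2e-5) == 0.0

    def test_nonpositive_rfd_rejected(self):
        with pytest.raises(ValueError):
            aq.hazard_quotient(1e-6, 0.0)

    def test_children_7_17_hazard_index(self):
        hqs = [3.193e-1, 2.625e-3, 1.735e-5, 9.410e-6, 2.294e-4]
        assert aq.hazard_index(hqs) == pytest.approx(0.3222, rel=1e-3)

    def test_empty_index_is_zero(self):
        assert aq.hazard_index([]) == 0.0

    @given(hqs=st.lists(st.floats(min_value=0, max_value=10), max_size=8))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_index_equals_brute_force_sum(self, hqs):
        assert aq.hazard_index(hqs) == sum(hqs)


class TestClassification:
    @pytest.mark.parametrize(
        "elcr,level",
        [
            (0.0, aq.RiskLevel.NEGLIGIBLE),
            (9.99e-7, aq.RiskLevel.NEGLIGIBLE),
            (1e-6, aq.RiskLevel.ACCEPTABLE_RANGE),
            (5.855e-6, aq.RiskLevel.ACCEPTABLE_RANGE),
            (1e-4, aq.RiskLevel.REMEDIATION_DESIRABLE),
            (1e-3, aq.RiskLevel.PROTECTIVE_MEASURES_REQUIRED),
            (0.5, aq.RiskLevel.PROTECTIVE_MEASURES_REQUIRED),
        ],
    )
    def test_bands_partition_with_inclusive_lower_bounds(self, elcr, level):
        assert aq.classify(elcr) is level


class TestSlopeFactorConfigs:
    def test_as_published_applies_mixture_slope_factor_uniformly(self):
        sfs = aq.slope_factors(aq.default_registry(), "as_published")
        assert set(sfs.values()) == {2.0}
        assert len(sfs) == 5

    def test_per_analyte_uses_per_analyte_values(self):
        sfs = aq.slope_factors(aq.default_registry(), "per_analyte")
        assert sfs[PCB_MIXTURE_ID] == 2.0
        assert sfs["58-89-9"] == 1.10
        assert sfs["50-29-3"] == 0.34


class TestTableAssembly:
    def test_elcr_cells_are_twice_ladd_under_published_config(self, study_assessment):
        """Uniform slope factor 2.0 with one-hit response: every ELCR cell is
        ~2x its LADD (to first order at these dose levels)."""
        from aquarisk import dose_frame

        ladd = dose_frame(study_assessment.doses, "ladd")
        ratio = study_assessment.risks.elcr / ladd
        assert ((ratio - 2.0).abs() < 1e-4).all().all()

    def test_burden_additivity_to_machine_precision(self, study_assessment):
        burden = study_assessment.burden
        assert burden.ecc_gen == pytest.approx(float(burden.ecc.to_numpy().sum()), rel=1e-14)
        for g in burden.ecc_pop.index:
            assert burden.ecc_pop[g] == pytest.approx(float(burden.ecc[g].sum()), rel=1e-14)

    def test_missing_rfd_drops_analyte_from_hazard_with_full_index_kept(self, study_assessment, scenario):
        import dataclasses

        groups, _, registry = scenario
        partial = [
            dataclasses.replace(e, rfd=None) if e.analyte_id == "50-29-3" else e for e in registry
        ]
        table = aq.hazard_table(study_assessment.doses, partial)
        assert "DDT" not in table.hq.index
        assert len(table.hq.index) == 4

    def test_no_hazard_exceedance_for_study(self, study_assessment):
        assert not study_assessment.hazards.exceedances.any()
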
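import datetime
import random

import pytest

import aquarisk as aq
from aquarisk import study
from aquarisk.monitoring import MonitoringFormatError

from study_tables import CROSS_SITE_MEANS

DATE = datetime.date(2010, 3, 1)


def rec(site="w1", value=1.0, below_loq=False, loq=1.0, analyte="58-89-9", date=DATE):
    return aq.ConcentrationRecord(
        site_id=site, sample_date=date, analyte_id=analyte,
        value=value, below_loq=below_loq, loq=loq,
    )


class TestConcentrationRecord:
    def test_accepts_sub_loq_value_with_flag(self):
        r = rec(value=0.5, below_loq=True, loq=1.0)
        assert r.value == 0.5 and r.below_loq

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"value": -0.1},
            {"loq": 0.0},
            {"value": 2.0, "below_loq": True, "loq": 1.0},
        ],
    )
    def test_invariant_violations_raise(self, kwargs):
        with pytest.raises(ValueError):
            rec(**kwargs)


class TestCsvRoundTrip:
    def test_records_survive_write_read(self, tmp_path, study_records):
        path = tmp_path / "mon.csv"
        aq.write_monitoring_csv(study_records, path)
        back = aq.read_monitoring_csv(path)
        assert back == study_records

    def test_missing_column_is_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("site_id,sample_date,analyte_cas\nw1,2010-03-01,58-89-9\n")
        with pytest.raises(MonitoringFormatError, match="value_ng_dm3"):
            aq.read_monitoring_csv(path)

    def test_negative_value_reports_row_number(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text(
            "site_id,sample_date,analyte_cas,analyte_name,value_ng_dm3,below_loq,loq_ng_dm3\n"
            "w1,2010-03-01,58-89-9,gamma-HCH,2.0,0,1.0\n"
            "w1,2010-03-15,58-89-9,gamma-HCH,-2.0,0,1.0\n"
        )
        with pytest.raises(ValueError, match="row 3"):
            aq.read_monitoring_csv(path)

    def test_empty_data_section_gives_empty_collection(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text(
            "site_id,sample_date,analyte_cas,analyte_name,value_ng_dm3,below_loq,loq_ng_dm3\n"
        )
        assert aq.read_monitoring_csv(path) == []


class TestSummarize:
    def test_reproduces_every_study_cross_site_mean(self, study_summaries):
        """Feeding the per-well campaign means reproduces each printed
        'average over wells' value to the 2 printed decimals."""
        by_name = {s.analyte_name: s for s in study_summaries}
        assert set(by_name) == set(CROSS_SITE_MEANS)
        for name, printed in CROSS_SITE_MEANS.items():
            assert by_name[name].cross_site_mean == pytest.approx(printed, abs=0.005)

    def test_cross_site_mean_is_mean_of_per_site_means(self):
        records = [rec(site="a", value=2.44), rec(site="b", value=285.87), rec(site="c", value=131.33)]
        (s,) = aq.summarize(records, {"a", "b", "c"})
        assert s.cross_site_mean == pytest.approx(139.88, abs=5e-3)

    def test_single_site_single_record_identity(self):
        (s,) = aq.summarize([rec(value=7.5)], {"w1"})
        assert s.cross_site_mean == 7.5
        assert s.n_samples == {"w1": 1}

    def test_non_supply_site_excluded_from_cross_site_mean(self):
        records = [rec(site="well", value=10.0), rec(site="river", value=1000.0)]
        (s,) = aq.summarize(records, {"well"})
        assert s.cross_site_mean == 10.0
        assert s.per_site_mean["river"] == 1000.0  # still summarised per site

    def test_analyte_absent_from_supply_sites_means_zero(self):
        (s,) = aq.summarize([rec(site="river", value=5.0)], {"well"})
        assert s.cross_site_mean == 0.0

    def test_permutation_invariance(self, study_records):
        shuffled = study_records.copy()
        random.Random(7).shuffle(shuffled)
        a = aq.summarize(study_records, study.SUPPLY_SITES)
        b = aq.summarize(shuffled, study.SUPPLY_SITES)
        assert {s.analyte_id: s.cross_site_mean for s in a} == {
            s.analyte_id: s.cross_site_mean for s in b
        }

    def test_empty_supply_sites_rejected(self):
        with pytest.raises(ValueError):
            aq.summarize([rec()], set())


class TestCensorPolicies:
    @pytest.fixture()
    def censored_records(self):
        rng = random.Random(0)
        records = []
        for i in range(20):
            v = rng.uniform(1.0, 10.0)
            records.append(rec(value=v, date=DATE + datetime.timedelta(days=i)))
        for i in range(5):
            records.append(
                rec(value=0.4, below_loq=True, date=DATE + datetime.timedelta(days=100 + i))
            )
        return records

    def test_zero_vs_half_loq_differ_by_censored_mass(self, censored_records):
        """mean(half_loq) - mean(zero) must equal (n_censored/n) * loq/2 —
        checked against a brute-force recomputation of both means."""
        (s_zero,) = aq.summarize(censored_records, {"w1"}, censor_policy="zero")
        (s_half,) = aq.summarize(censored_records, {"w1"}, censor_policy="half_loq")
        n = len(censored_records)
        n_cens = sum(r.below_loq for r in censored_records)
        expected_gap = (n_cens / n) * (1.0 / 2)
        assert s_half.cross_site_mean - s_zero.cross_site_mean == pytest.approx(expected_gap)
        # brute force both means directly
        vals_zero = [0.0 if r.below_loq else r.value for r in censored_records]
        assert s_zero.cross_site_mean == pytest.approx(sum(vals_zero) / n)

    def test_policy_ordering(self, censored_records):
        means = {
            p: aq.summarize(censored_records, {"w1"}, censor_policy=p)[0].cross_site_mean
            for p in ("zero", "half_loq", "as_reported")
        }
        assert means["zero"] <= means["half_loq"]
        # reported sub-LOQ values here are below loq/2, so as_reported <= half_loq
        assert means["as_reported"] <= means["half_loq"]

    def test_as_reported_keeps_sub_loq_values(self):
        (s,) = aq.summarize([rec(value=0.5, below_loq=True)], {"w1"})
        assert s.cross_site_mean == 0.5


class TestClassTotals:
    def test_study_class_totals(self, study_summaries):
        assert aq.class_total(study_summaries, "PCB") == pytest.approx(451.95, abs=5e-3)
        assert aq.class_total(study_summaries, "COP") == pytest.approx(73.5167, abs=5e-3)

    def test_total_is_sum_of_members(self, study_summaries):
        total = sum(
            s.cross_site_mean for s in study_summaries if s.analyte_class is aq.AnalyteClass.PCB
        )
        assert aq.class_total(study_summaries, aq.AnalyteClass.PCB) == total

    def test_empty_class_sums_to_zero(self, study_summaries):
        only_pcb = [s for s in study_summaries if s.analyte_class is aq.AnalyteClass.PCB]
        assert aq.class_total(only_pcb, "COP") == 0.0

    def test_unknown_class_lists_valid_ones(self, study_summaries):
        with pytest.raises(ValueError, match="PCB.*COP"):
            aq.class_total(study_summaries, "dioxin")
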
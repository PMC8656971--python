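"""The exposure/risk chain: ADDs, hazard quotients, cancer risk, classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dustrisk as dr
from dustrisk.health_risk import (
    ElementToxicity,
    ParameterError,
    TlcrClass,
    ToxicityTable,
)


class TestAverageDailyDoses:
    def test_ingestion_young_child_unit_concentration(self, exposure):
        # IgR 200 mg/day, BW 15 kg; EF*ED cancels against AT = 365*ED
        assert dr.add_ingestion(1.0, exposure, "young_child") == pytest.approx(
            1.3333e-5, rel=1e-4
        )

    def test_ingestion_carcinogenic_lifetime_averaging(self, exposure):
        # as-stated carcinogenic mode spreads 6 exposure years over 70
        value = dr.add_ingestion(1.0, exposure, "young_child", mode="carc")
        assert value == pytest.approx(1.3333e-5 * 6 / 70, rel=1e-4)
        assert value == pytest.approx(1.1429e-6, rel=1e-4)

    def test_dermal_young_child_unit_concentration(self, exposure):
        # SA 2336 cm2 * AF 0.2 * ABS 0.01 * CF / BW 15
        assert dr.add_dermal(
            1.0, exposure, "young_child", abs_frac=0.01
        ) == pytest.approx(3.1147e-7, rel=1e-4)

    def test_inhalation_young_child_unit_concentration(self, exposure):
        # IhR 20 / (PEF 1.36e9 * BW 15)
        assert dr.add_inhalation(1.0, exposure, "young_child") == pytest.approx(
            9.8039e-10, rel=1e-4
        )

    @pytest.mark.parametrize("cohort", dr.COHORTS)
    @pytest.mark.parametrize("mode", ["noncarc", "carc"])
    def test_zero_concentration_gives_zero_dose(self, exposure, cohort, mode):
        assert dr.add_ingestion(0.0, exposure, cohort, mode) == 0.0
        assert dr.add_dermal(0.0, exposure, cohort, 0.01, mode) == 0.0
        assert dr.add_inhalation(0.0, exposure, cohort, mode) == 0.0

    def test_ingestion_dermal_ratio_is_concentration_free(self, exposure):
        # IgR / (SA * AF * ABS) = 200 / (2336 * 0.2 * 0.01) = 42.81
        for c in (1.0, 17.3, 368.0):
            ratio = dr.add_ingestion(c, exposure, "young_child") / dr.add_dermal(
                c, exposure, "young_child", 0.01
            )
            assert ratio == pytest.approx(42.81, abs=0.01)

    def test_inhalation_ingestion_ratio_constant(self, exposure):
        # (IhR/PEF) / (IgR*CF) = 7.35e-5, independent of element and c
        for c in (2.0, 53.0):
            ratio = dr.add_inhalation(c, exposure, "young_child") / (
                dr.add_ingestion(c, exposure, "young_child")
            )
            assert ratio == pytest.approx(7.353e-5, rel=1e-3)

    def test_noncarc_dose_independent_of_exposure_duration(self, exposure):
        # AT = 365*ED cancels ED: six-year and thirty-year cohorts with
        # otherwise identical parameters get the same non-carcinogenic ADD
        base = exposure.cohort("young_child")
        cohorts = {
            "ed6": base,
            "ed30": dr.health_risk.CohortParameters(
                igr=base.igr, ed=30.0, bw=base.bw, sa=base.sa, af=base.af
            ),
        }
        params = dr.ExposureParameters(cohorts=cohorts)
        assert dr.add_ingestion(5.0, params, "ed6") == pytest.approx(
            dr.add_ingestion(5.0, params, "ed30"), rel=1e-12
        )

    def test_unknown_cohort_refused(self, exposure):
        with pytest.raises(ParameterError, match="toddler"):
            dr.add_ingestion(1.0, exposure, "toddler")

    def test_missing_abs_refused(self, exposure):
        with pytest.raises(dr.ConfigurationError, match="ABS"):
            dr.add_dermal(1.0, exposure, "young_child", abs_frac=None)


class TestHazard:
    def test_hq_is_add_over_rfd(self, exposure, toxicity):
        result = dr.hazard(1.0, "As", exposure, toxicity, "young_child")
        expected = dr.add_ingestion(1.0, exposure, "young_child") / 3.0e-4
        assert result.hq["ingestion"] == pytest.approx(expected, rel=1e-12)

    def test_hi_sums_routes(self, exposure, toxicity):
        result = dr.hazard(38.0, "Pb", exposure, toxicity, "young_child")
        assert result.hi == pytest.approx(sum(result.hq.values()), rel=1e-12)
        assert result.complete

    def test_lead_at_study_mean_below_concern(self, exposure, toxicity):
        result = dr.hazard(38.0, "Pb", exposure, toxicity, "young_child")
        assert result.hi < 1.0
        assert not result.concern

    def test_missing_route_rfd_omitted_and_flagged(self, exposure):
        tox = ToxicityTable({
            "X": ElementToxicity(
                rfd={"ingestion": 1e-3, "dermal": None, "inhalation": None},
                sf={"ingestion": None, "dermal": None, "inhalation": None},
                abs_frac=0.01,
            )
        })
        result = dr.hazard(1.0, "X", exposure, tox, "young_child")
        assert set(result.hq) == {"ingestion"}
        assert not result.complete
        assert result.omitted_routes == ("dermal", "inhalation")

    def test_no_rfd_at_all_refused(self, exposure):
        tox = ToxicityTable({
            "X": ElementToxicity(
                rfd={r: None for r in dr.ROUTES},
                sf={r: None for r in dr.ROUTES},
            )
        })
        with pytest.raises(dr.ConfigurationError, match="reference dose"):
            dr.hazard(1.0, "X", exposure, tox, "young_child")


class TestCancerRisk:
    @pytest.mark.parametrize(
        "routes, expected",
        [
            # published per-county young-child route LCR triples: the TLCR
            # is their plain sum, reported to 3 significant figures
            ((8.59e-5, 2.01e-6, 5.41e-10), 8.79e-5),
            ((4.42e-4, 1.03e-5, 2.78e-9), 4.52e-4),
        ],
    )
    def test_tlcr_is_route_sum(self, routes, expected):
        tlcr = dr.tlcr_from_routes(
            dict(zip(("ingestion", "dermal", "inhalation"), routes))
        )
        assert float(f"{tlcr:.2e}") == pytest.approx(expected, rel=1e-9)

    def test_zero_concentration_very_low(self, exposure, toxicity):
        result = dr.cancer_risk(0.0, "As", exposure, toxicity, "young_child")
        assert result.tlcr == 0.0
        assert result.tlcr_class is TlcrClass.VERY_LOW

    def test_no_slope_factor_refused(self, exposure, toxicity):
        with pytest.raises(dr.ConfigurationError, match="slope factor"):
            dr.cancer_risk(53.0, "Cu", exposure, toxicity, "young_child")

    def test_at_mode_scales_by_ed_over_lifetime(self, exposure, toxicity):
        stated = dr.cancer_risk(
            10.0, "As", exposure, toxicity, "young_child", at_mode="as_stated"
        )
        tabulated = dr.cancer_risk(
            10.0, "As", exposure, toxicity, "young_child", at_mode="as_tabulated"
        )
        assert stated.tlcr == pytest.approx(tabulated.tlcr * 6 / 70, rel=1e-12)


class TestClassifyTlcr:
    @pytest.mark.parametrize(
        "tlcr, expected",
        [
            (0.0, TlcrClass.VERY_LOW),
            (5e-7, TlcrClass.VERY_LOW),
            (1e-6, TlcrClass.VERY_LOW),
            (2e-6, TlcrClass.LOW),
            (1e-4, TlcrClass.LOW),
            (4.52e-4, TlcrClass.MODERATE),
            (1e-3, TlcrClass.HIGH),  # overlapping printed bound -> high
            (5e-2, TlcrClass.HIGH),
            (1e-1, TlcrClass.VERY_HIGH),
            (0.2, TlcrClass.VERY_HIGH),
        ],
    )
    def test_bins(self, tlcr, expected):
        assert dr.classify_tlcr(tlcr) is expected

    def test_negative_refused(self):
        with pytest.raises(ValueError):
            dr.classify_tlcr(-1e-6)

    @given(st.floats(min_value=0, max_value=10))
    @settings(max_examples=300, deadline=None)
    def test_total_partition_and_monotone(self, tlcr):
        order = list(TlcrClass)
        cls = dr.classify_tlcr(tlcr)
        assert cls in order
        # monotone: a strictly larger TLCR never gets a lower class
        bigger = dr.classify_tlcr(tlcr * 2 + 1e-12)
        assert order.index(bigger) >= order.index(cls)

    def test_acceptable_range(self):
        assert not dr.is_acceptable(5e-7)
        assert dr.is_acceptable(1e-6)
        assert dr.is_acceptable(5e-5)
        assert dr.is_acceptable(1e-4)
        assert not dr.is_acceptable(4.52e-4)


class TestLinearity:
    @given(
        c=st.floats(min_value=1e-3, max_value=1e4),
        scale=st.floats(min_value=1e-2, max_value=1e2),
    )
    @settings(max_examples=100, deadline=None)
    def test_homogeneous_degree_one(self, exposure, toxicity, c, scale):
        base = dr.cancer_risk(c, "Cd", exposure, toxicity, "young_child")
        scaled = dr.cancer_risk(
            c * scale, "Cd", exposure, toxicity, "young_child"
        )
        assert scaled.tlcr == pytest.approx(base.tlcr * scale, rel=1e-9)
        hazard_base = dr.hazard(c, "Cd", exposure, toxicity, "young_child")
        hazard_scaled = dr.hazard(
            c * scale, "Cd", exposure, toxicity, "young_child"
        )
        assert hazard_scaled.hi == pytest.approx(
            hazard_base.hi * scale, rel=1e-9
        )


class TestRiskTable:
    def test_shape_and_default_elements(self, study31):
        table = dr.risk_table(study31, scope="county")
        assert set(table["element"]) == set(dr.PRIORITY_METALS)
        assert set(table["cohort"]) == set(dr.COHORTS)
        assert len(table) == 4 * 7 * 3  # counties x elements x cohorts

    def test_county_tlcr_is_linear_in_mean(self, study31, exposure, toxicity):
        table = dr.risk_table(
            study31, scope="county", p=exposure, tox=toxicity
        )
        means = study31.county_mean_concentrations()
        row = table[
            (table.scope == "Harris") & (table.element == "As")
            & (table.cohort == "young_child")
        ].iloc[0]
        direct = dr.cancer_risk(
            float(means.loc["Harris", "As"]), "As", exposure, toxicity,
            "young_child",
        )
        assert row["tlcr"] == pytest.approx(direct.tlcr, rel=1e-12)

    def test_elements_without_slope_factor_have_hazard_only(self, study31):
        table = dr.risk_table(study31, scope="study")
        no_sf = table[table.element.isin(["Cu", "Pb", "Zn"])]
        assert no_sf["tlcr"].isna().all()
        assert no_sf["hi"].notna().all()

    def test_additivity_asserted_on_output(self, study31):
        table = dr.risk_table(study31, scope="county")
        with_sf = table.dropna(subset=["tlcr"])
        lcr_sum = with_sf[
            ["lcr_ingestion", "lcr_dermal", "lcr_inhalation"]
        ].sum(axis=1)
        assert np.allclose(with_sf["tlcr"], lcr_sum, rtol=1e-12)
        hq_sum = with_sf[["hq_ingestion", "hq_dermal", "hq_inhalation"]].sum(
            axis=1
        )
        assert np.allclose(with_sf["hi"], hq_sum, rtol=1e-12)

    def test_empty_scope_refused(self, exposure, toxicity):
        empty = pd.DataFrame(columns=list(dr.PRIORITY_METALS))
        with pytest.raises(ValueError, match="empty"):
            dr.risk_table(empty, p=exposure, tox=toxicity)
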
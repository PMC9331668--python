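"""Adjusted concentrations and daily-dose equations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmrisk.config import ExposureParameters
from pmrisk.exceptions import ValidationError
from pmrisk.exposure import (
    TABLE_VARIANTS,
    VARIANTS,
    adjusted_concentrations,
    add_inh,
    concentration_summary,
    dose_table,
    ladd_inh,
)

PARAMS_CHILD = ExposureParameters(inh_r=10.0, bw=20.0, ed=6.0, ef=350.0)


class TestAdjustedConcentrations:
    def test_zero_deposition_zeroes_df_variants(self):
        cs = adjusted_concentrations(1.0, 0.5, 0.2, 0.0)
        assert cs.c_df == cs.c_alf_df == cs.c_gs_df == 0.0

    def test_full_deposition_is_identity(self):
        cs = adjusted_concentrations(1.0, 0.5, 0.2, 1.0)
        assert cs.c_df == 1.0
        assert cs.variant("ALF+DF") == 0.5

    def test_hand_computed_products(self):
        cs = adjusted_concentrations(10.7e-6, 3.50e-6, 2.13e-6, 0.2)
        assert cs.c_alf_df == pytest.approx(7.0e-7)
        assert cs.c_gs_df == pytest.approx(4.26e-7)

    def test_df_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            adjusted_concentrations(1.0, 0.5, 0.2, 1.5)

    def test_extracts_below_total_keep_variant_order(self):
        cs = adjusted_concentrations(1.0, 0.7, 0.3, 0.25)
        assert 0.0 <= cs.c_gs_df <= cs.c_alf_df <= cs.c_df


class TestDoseEquations:
    def test_zero_concentration_zero_dose(self):
        assert add_inh(0.0, PARAMS_CHILD) == 0.0

    def test_hand_computed_add(self):
        # 1e-3 x 10 x 350 x 6 / (20 x 6 x 365)
        assert add_inh(1e-3, PARAMS_CHILD) == pytest.approx(4.7945e-4, rel=1e-4)

    def test_both_algebraic_forms_agree(self):
        c = 3.2e-6
        long_form = add_inh(c, PARAMS_CHILD)
        short_form = c * PARAMS_CHILD.inh_r * (PARAMS_CHILD.ef / 365.0) / PARAMS_CHILD.bw
        assert long_form == pytest.approx(short_form, rel=1e-12)

    def test_doubling_bw_halves_add(self):
        import dataclasses

        heavy = dataclasses.replace(PARAMS_CHILD, bw=PARAMS_CHILD.bw * 2)
        assert add_inh(1e-3, heavy) == pytest.approx(add_inh(1e-3, PARAMS_CHILD) / 2)

    def test_ladd_is_add_scaled_by_ed_over_70(self):
        c = 1e-3
        assert ladd_inh(c, PARAMS_CHILD) == pytest.approx(
            add_inh(c, PARAMS_CHILD) * 6.0 / 70.0, rel=1e-12
        )

    def test_ladd_table_examples(self):
        # printed case-study cells: ADD 0.427e-6 (ED 6) and 0.115e-6 (ED 26)
        assert 0.427e-6 * 6 / 70 == pytest.approx(0.037e-6, abs=0.0005e-6)
        assert 0.115e-6 * 26 / 70 == pytest.approx(0.043e-6, abs=0.0005e-6)

    def test_ed_70_makes_ladd_equal_add(self):
        import dataclasses

        lifetime = dataclasses.replace(PARAMS_CHILD, ed=70.0)
        assert ladd_inh(1e-3, lifetime) == pytest.approx(add_inh(1e-3, lifetime))

    @settings(deadline=None, max_examples=50)
    @given(
        c=st.floats(1e-9, 1e-3),
        inh_r=st.floats(1.0, 30.0),
        bw=st.floats(5.0, 120.0),
        ed_a=st.floats(1.0, 70.0),
        ed_b=st.floats(1.0, 70.0),
    )
    def test_add_independent_of_ed(self, c, inh_r, bw, ed_a, ed_b):
        pa = ExposureParameters(inh_r=inh_r, bw=bw, ed=ed_a)
        pb = ExposureParameters(inh_r=inh_r, bw=bw, ed=ed_b)
        assert add_inh(c, pa) == pytest.approx(add_inh(c, pb), rel=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(c=st.floats(1e-9, 1e-3), k=st.floats(0.1, 10.0))
    def test_dose_linear_in_concentration(self, c, k):
        assert add_inh(c * k, PARAMS_CHILD) == pytest.approx(
            add_inh(c, PARAMS_CHILD) * k, rel=1e-9
        )


class TestDoseTable:
    def test_table_variant_row_count(self, table1_samples, df_table, config):
        conc = concentration_summary(table1_samples, grouping="site")
        doses = dose_table(conc, df_table, config, variants=TABLE_VARIANTS, site="ALL")
        assert len(doses) == 8 * 2 * 2 * 2  # ages x sexes x metals x variants

    def test_ladd_only_for_carcinogens(self, table1_samples, df_table, config):
        conc = concentration_summary(table1_samples, grouping="site")
        doses = dose_table(conc, df_table, config, site="ALL")
        assert doses[doses.metal == "Pb"].ladd_mgkgday.isna().all()
        assert doses[doses.metal == "Cd"].ladd_mgkgday.notna().all()

    def test_ladd_add_ratio_is_ed_over_70(self, table1_samples, df_table, config):
        conc = concentration_summary(table1_samples, grouping="site")
        doses = dose_table(conc, df_table, config, site="ALL")
        cd = doses[(doses.metal == "Cd") & (doses.add_mgkgday > 0)]
        np.testing.assert_allclose(
            cd.ladd_mgkgday / cd.add_mgkgday, cd.ed_years / 70.0, rtol=1e-12
        )

    def test_alf_gs_dose_ratio_cancels_cohort_parameters(
        self, table1_samples, df_table, config
    ):
        conc = concentration_summary(table1_samples, grouping="site")
        doses = dose_table(conc, df_table, config, site="ALL")
        cd = doses[doses.metal == "Cd"].pivot_table(
            index=["age_group", "sex"], columns="variant", values="add_mgkgday"
        )
        ratio = cd["ALF+DF"] / cd["GS+DF"]
        # identical across cohorts (InhR, BW, DF all cancel) ...
        np.testing.assert_allclose(ratio, ratio.iloc[0], rtol=1e-12)
        # ... and equal to the concentration ratio C_ALF : C_GS
        assert ratio.iloc[0] == pytest.approx(3.50 / 2.13, rel=0.01)

    def test_zero_concentrations_give_zero_doses(self, table1_samples, df_table, config):
        conc = concentration_summary(table1_samples, grouping="site")
        conc[["total_mgm3", "alf_mgm3", "gs_mgm3"]] = 0.0
        doses = dose_table(conc, df_table, config, site="ALL")
        assert (doses.add_mgkgday == 0).all()

    def test_variant_ordering_when_extracts_below_total(
        self, table1_samples, df_table, config
    ):
        conc = concentration_summary(table1_samples, grouping="site")
        doses = dose_table(conc, df_table, config, site="ALL")
        wide = doses.pivot_table(
            index=["age_group", "sex", "metal"], columns="variant",
            values="add_mgkgday",
        )
        assert (wide["ALF+DF"] <= wide["DF"] + 1e-18).all()
        assert (wide["GS+DF"] <= wide["DF"] + 1e-18).all()

    def test_ng_to_mg_conversion_applied_once(self, table1_samples):
        conc = concentration_summary(table1_samples, grouping="site")
        cd = conc[(conc.site == "XP") & (conc.metal == "Cd")]
        assert cd.total_mgm3.iloc[0] == pytest.approx(9.99e-6, rel=1e-9)
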
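"""Regional deposition-fraction engine, scaling rule and override tables."""

import math

import numpy as np
import pandas as pd
import pytest

from pmrisk.cohorts import Cohort
from pmrisk.config import DEFAULT_FRC_COEFFICIENTS, Physiology
from pmrisk.deposition import (
    ParticleSpec,
    RegionalDF,
    cohort_regional_df,
    default_df_table,
    df_lookup,
    frc_estimate,
    icrp_regional_df,
    icrp_total_df,
    load_df_table,
    scale_df,
)
from pmrisk.exceptions import (
    ConfigurationError,
    DepositionLookupError,
    ValidationError,
)

REFERENCE = Physiology(
    height_cm=175.0,
    body_weight_kg=71.0,
    frc_ml=3300.0,
    tidal_volume_ml=620.0,
    breathing_frequency=13.0,
)


class TestClosedForm:
    def test_pm25_reference_adult(self):
        df = icrp_regional_df(ParticleSpec(2.5))
        for part in (df.head, df.tracheobronchial, df.pulmonary):
            assert 0.0 <= part <= 1.0
        assert df.total <= 1.0
        assert df.head > df.pulmonary  # coarse particles impact in the nose

    @pytest.mark.parametrize("d_um", [0.01, 0.1, 0.3, 1.0, 2.5, 5.0, 10.0])
    def test_regional_sum_tracks_independent_total_fit(self, d_um):
        # the separately fitted total-deposition curve is an independent
        # closed form for the same model; the two fits agree to within
        # ~6 percentage points across the accumulation/coarse range
        regional = icrp_regional_df(ParticleSpec(d_um)).total
        fitted = icrp_total_df(ParticleSpec(d_um))
        assert regional == pytest.approx(fitted, abs=0.06)

    def test_u_shaped_total_deposition(self):
        total = lambda d: icrp_regional_df(ParticleSpec(d)).total
        assert total(0.3) < total(0.01)
        assert total(0.3) < total(5.0)

    def test_large_particles_skip_the_alveoli(self):
        assert icrp_regional_df(ParticleSpec(100.0)).pulmonary < 1e-3

    def test_density_raises_aerodynamic_diameter(self):
        light = ParticleSpec(2.5, density_g_cm3=1.0)
        heavy = ParticleSpec(2.5, density_g_cm3=4.0)
        assert heavy.aerodynamic_diameter_um == pytest.approx(5.0)
        assert icrp_regional_df(heavy).head > icrp_regional_df(light).head

    def test_out_of_range_diameter_rejected(self):
        with pytest.raises(ValidationError):
            icrp_regional_df(ParticleSpec(1000.0))

    def test_deterministic(self):
        a = icrp_regional_df(ParticleSpec(2.5))
        b = icrp_regional_df(ParticleSpec(2.5))
        assert a == b


class TestScaleDF:
    def test_identity_at_reference(self):
        base = icrp_regional_df(ParticleSpec(2.5))
        scaled = scale_df(base, REFERENCE, REFERENCE)
        assert scaled.pulmonary == pytest.approx(base.pulmonary)
        assert scaled.tracheobronchial == pytest.approx(base.tracheobronchial)

    def test_halving_frc_does_not_decrease_pulmonary(self):
        base = icrp_regional_df(ParticleSpec(2.5))
        import dataclasses

        small_lung = dataclasses.replace(REFERENCE, frc_ml=REFERENCE.frc_ml / 2)
        scaled = scale_df(base, small_lung, REFERENCE)
        assert scaled.pulmonary >= base.pulmonary

    @pytest.mark.parametrize("vt,frc,bf", [(100, 800, 25), (900, 4000, 10),
                                           (620, 3300, 13), (50, 5000, 40)])
    def test_output_always_a_valid_simplex(self, vt, frc, bf):
        import dataclasses

        base = icrp_regional_df(ParticleSpec(2.5))
        phys = dataclasses.replace(
            REFERENCE, tidal_volume_ml=vt, frc_ml=frc, breathing_frequency=bf
        )
        out = scale_df(base, phys, REFERENCE)
        assert 0.0 <= out.pulmonary <= 1.0
        assert out.total <= 1.0 + 1e-9

    def test_cohort_engine_end_to_end(self, config):
        child = config.physiology[Cohort("2-5", "male")]
        adult = config.physiology[Cohort("23-30", "male")]
        child_df = cohort_regional_df(ParticleSpec(2.5), child, adult)
        adult_df = cohort_regional_df(ParticleSpec(2.5), adult, adult)
        # children's smaller FRC pulls more aerosol into the alveolar region
        assert child_df.pulmonary > adult_df.pulmonary


class TestRegionalDFInvariants:
    def test_component_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            RegionalDF(head=1.2, tracheobronchial=0.0, pulmonary=0.0)

    def test_oversum_rejected(self):
        with pytest.raises(ValidationError):
            RegionalDF(head=0.6, tracheobronchial=0.4, pulmonary=0.2)


class TestOverrideTable:
    def test_lookup_returns_tabulated_value(self, df_table):
        df = df_lookup(df_table, Cohort("2-5", "male"))
        assert df.pulmonary == pytest.approx(0.255)
        assert df.source == "override"

    def test_missing_cohort_names_the_cohort(self, df_table):
        empty = df_table.iloc[0:0]
        with pytest.raises(DepositionLookupError, match="2-5/male"):
            df_lookup(empty, Cohort("2-5", "male"))

    def test_invalid_row_rejected_on_load(self):
        bad = pd.DataFrame(
            [{"age_group": "2-5", "sex": "male", "df_head": 0.8,
              "df_tb": 0.2, "df_pulmonary": 0.2}]
        )
        with pytest.raises(ValidationError):
            load_df_table(bad)

    def test_missing_column_rejected(self, df_table):
        with pytest.raises(ValidationError, match="df_pulmonary"):
            load_df_table(df_table.drop(columns=["df_pulmonary"]))


class TestShippedTableOrderings:
    """The shipped table reproduces the case study's qualitative findings."""

    def _pulm(self, df_table, age_group, sex):
        return df_lookup(df_table, Cohort(age_group, sex)).pulmonary

    def test_pulmonary_decreases_with_age(self, df_table):
        children = ["2-5", "5-7", "7-11", "11-23"]
        adults = ["23-30", "30-40", "40-65", "65-96"]
        for sex in ("male", "female"):
            for groups in (children, adults):
                vals = [self._pulm(df_table, g, sex) for g in groups]
                assert vals == sorted(vals, reverse=True)

    def test_male_at_least_female(self, df_table):
        for age_group in df_table.age_group.unique():
            assert self._pulm(df_table, age_group, "male") >= self._pulm(
                df_table, age_group, "female"
            )

    def test_child_pulmonary_above_adult(self, df_table):
        rep = df_table.copy()
        child = rep[rep.age_group.isin(["2-5", "5-7", "7-11", "11-23"])]
        adult = rep[~rep.age_group.isin(["2-5", "5-7", "7-11", "11-23"])]
        assert child.df_pulmonary.min() > adult.df_pulmonary.max()

    def test_total_adults_above_children_on_average(self, df_table):
        tot = df_table.df_head + df_table.df_tb + df_table.df_pulmonary
        child_mask = df_table.age_group.isin(["2-5", "5-7", "7-11", "11-23"])
        assert tot[~child_mask].mean() > tot[child_mask].mean()

    def test_reported_ranges(self, df_table):
        child_mask = df_table.age_group.isin(["2-5", "5-7", "7-11", "11-23"])
        pulm = df_table.df_pulmonary
        tot = df_table.df_head + df_table.df_tb + df_table.df_pulmonary
        assert round(pulm[child_mask].min(), 2) == 0.15
        assert round(pulm[child_mask].max(), 2) == 0.26
        assert round(pulm[~child_mask].min(), 2) == 0.12
        assert round(pulm[~child_mask].max(), 2) == 0.14
        assert 0.64 <= tot[child_mask].min() and tot[child_mask].max() <= 0.79
        assert 0.72 <= tot[~child_mask].min() and tot[~child_mask].max() <= 0.80


class TestFRC:
    def test_adult_exceeds_child(self):
        child = frc_estimate(8.0, 130.0, "male", DEFAULT_FRC_COEFFICIENTS)
        adult = frc_estimate(30.0, 175.0, "male", DEFAULT_FRC_COEFFICIENTS)
        assert adult > child > 0

    def test_child_formula_uses_height_only(self):
        a = frc_estimate(5.0, 120.0, "male", DEFAULT_FRC_COEFFICIENTS)
        b = frc_estimate(10.0, 120.0, "female", DEFAULT_FRC_COEFFICIENTS)
        assert a == b  # same height, both under 23 years

    def test_adult_formula_uses_age(self):
        young = frc_estimate(25.0, 175.0, "male", DEFAULT_FRC_COEFFICIENTS)
        old = frc_estimate(70.0, 175.0, "male", DEFAULT_FRC_COEFFICIENTS)
        assert young != old

    def test_determinism(self):
        args = (9.0, 140.0, "female", DEFAULT_FRC_COEFFICIENTS)
        assert frc_estimate(*args) == frc_estimate(*args)

    def test_negative_height_rejected(self):
        with pytest.raises(ValidationError):
            frc_estimate(9.0, -1.0, "male", DEFAULT_FRC_COEFFICIENTS)

    def test_missing_coefficients_is_config_error(self):
        with pytest.raises(ConfigurationError):
            frc_estimate(9.0, 140.0, "male", {})
        with pytest.raises(ConfigurationError):
            frc_estimate(9.0, 140.0, "male", {"child": {"a": 0.001}})
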
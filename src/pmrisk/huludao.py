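"""Huludao smelting-district case study: reference data shipped with pmrisk.

Huludao City (Liaoning, northeast China) hosts Asia's largest zinc smelter;
a year of PM₂.₅ filter sampling at two urban sites — Xinqu Park (XP) and
Dongcheng District (DD) — yielded annual mean ± SD concentrations of PM₂.₅
mass and of Cd and Pb (total and dissolved in the two simulated lung
fluids, ALF and GS).  Those published summary statistics, the corresponding
per-cohort dose table, and the reported risk values are transcribed here
and serve three purposes:

* site profiles for the synthetic sample generator,
* a calibration anchor for the shipped deposition-fraction table and
  inhalation-rate registry,
* reference values that the ``reproduce`` workflow compares its recomputed
  results against.

The case study's dose table lists, for each age group and sex, ADD (and Cd
LADD) computed from the bioaccessible concentration *after* applying the
pulmonary deposition fraction — i.e. the ALF+DF and GS+DF variants — in
units of 10⁻⁶ mg·kg⁻¹·day⁻¹.
"""

from __future__ import annotations

import io as _io

import pandas as pd

from .synthetic import MetalProfile, SiteProfile

#: Chinese ambient air-quality standard for annual PM2.5, µg·m⁻³.
NAAQS_PM25 = 35.0

SITES = ("XP", "DD", "ALL")


def site_profiles() -> dict[str, SiteProfile]:
    """Annual mean ± SD profiles for XP, DD, and the pooled study area.

    Extractable-fraction means are the published bioaccessibility
    percentages; their SDs were not published and default to 0.05
    (absolute), a typical between-sample spread for repeated lung-fluid
    extractions.
    """
    fsd = 0.05

    def metal(total_mean, total_sd, alf, gs):
        return MetalProfile(
            total_mean=total_mean,
            total_sd=total_sd,
            alf_fraction_mean=alf,
            alf_fraction_sd=fsd,
            gs_fraction_mean=gs,
            gs_fraction_sd=fsd,
        )

    return {
        "XP": SiteProfile(
            site="XP",
            pm25_mean=74.7,
            pm25_sd=49.2,
            metals={
                "Cd": metal(9.99, 3.46, 0.348, 0.121),
                "Pb": metal(264.0, 109.0, 0.263, 0.124),
            },
        ),
        "DD": SiteProfile(
            site="DD",
            pm25_mean=88.8,
            pm25_sd=55.4,
            metals={
                "Cd": metal(11.4, 3.30, 0.308, 0.267),
                "Pb": metal(452.0, 337.0, 0.362, 0.184),
            },
        ),
        "ALL": SiteProfile(
            site="ALL",
            pm25_mean=81.7,
            pm25_sd=52.9,
            metals={
                "Cd": metal(10.7, 3.46, 0.328, 0.199),
                "Pb": metal(358.0, 268.0, 0.326, 0.162),
            },
        ),
    }


def pseudo_samples(sites: tuple[str, ...] = SITES) -> pd.DataFrame:
    """One exact-mean pseudo-sample per site profile (long format).

    Degenerate samples (SD = 0) whose concentrations equal the published
    annual means; feeding them through the pipeline reproduces the
    summary-level case-study numbers.
    """
    rows = []
    for name in sites:
        p = site_profiles()[name]
        for metal_symbol, m in p.metals.items():
            rows.append(
                {
                    "sample_id": f"{name}-mean",
                    "site": p.site,
                    "date": "",
                    "pm25_ugm3": p.pm25_mean,
                    "metal": metal_symbol,
                    "total_ngm3": m.total_mean,
                    "alf_ngm3": m.total_mean * m.alf_fraction_mean,
                    "gs_ngm3": m.total_mean * m.gs_fraction_mean,
                }
            )
    return pd.DataFrame(rows)


#: Published bioaccessibility percentages.  ``consistent`` marks cells that
#: round-trip from the printed mean concentrations; the others were
#: evidently computed from unrounded means and differ in the last digit.
REPORTED_BIOACCESSIBILITY = pd.DataFrame(
    [
        ("XP", "Cd", "ALF", 34.8, True),
        ("XP", "Cd", "GS", 12.1, True),
        ("XP", "Pb", "ALF", 26.3, True),
        ("XP", "Pb", "GS", 12.4, True),
        ("DD", "Cd", "ALF", 30.8, True),
        ("DD", "Cd", "GS", 26.7, True),
        ("DD", "Pb", "ALF", 36.2, False),
        ("DD", "Pb", "GS", 18.4, True),
        ("ALL", "Cd", "ALF", 32.8, False),
        ("ALL", "Cd", "GS", 19.9, True),
        ("ALL", "Pb", "ALF", 32.6, False),
        ("ALL", "Pb", "GS", 16.2, True),
    ],
    columns=["site", "metal", "fluid", "fraction_pct", "consistent"],
)

#: Published mean PM2.5 (µg·m⁻³) and the reported exceedance ratios over
#: the 35 µg·m⁻³ annual standard.
REPORTED_PM25 = {"XP": 74.7, "DD": 88.8, "ALL": 81.7}
REPORTED_PM25_EXCEEDANCE = {"XP": 2.13, "DD": 2.54, "ALL": 2.33}

_DOSE_CSV = """\
age_group,sex,add_cd_alf_df,add_cd_gs_df,add_pb_alf_df,add_pb_gs_df,ladd_cd_alf_df,ladd_cd_gs_df
2-5,male,0.427,0.260,14.2,7.07,0.037,0.022
2-5,female,0.420,0.255,14.0,6.95,0.036,0.022
5-7,male,0.337,0.205,11.3,5.59,0.029,0.018
5-7,female,0.322,0.196,10.7,5.33,0.028,0.017
7-11,male,0.235,0.143,7.82,3.89,0.020,0.012
7-11,female,0.221,0.135,7.38,3.67,0.019,0.012
11-23,male,0.147,0.090,4.91,2.44,0.013,0.008
11-23,female,0.137,0.083,4.58,2.27,0.012,0.007
23-30,male,0.115,0.070,3.83,1.90,0.043,0.026
23-30,female,0.105,0.064,3.52,1.75,0.039,0.024
30-40,male,0.107,0.065,3.57,1.77,0.040,0.024
30-40,female,0.096,0.058,3.19,1.59,0.036,0.022
40-65,male,0.099,0.060,3.29,1.64,0.037,0.022
40-65,female,0.084,0.051,2.82,1.40,0.031,0.019
65-96,male,0.074,0.045,2.48,1.23,0.028,0.017
65-96,female,0.068,0.041,2.27,1.13,0.025,0.015
"""


def reported_dose_table() -> pd.DataFrame:
    """The case study's per-cohort dose table, 10⁻⁶ mg·kg⁻¹·day⁻¹.

    Columns name metal and concentration variant: e.g. ``add_cd_alf_df`` is
    the Cd ADD under the ALF+DF variant.  LADD columns exist for the
    carcinogen (Cd) only.
    """
    return pd.read_csv(_io.StringIO(_DOSE_CSV))


#: Reported hazard indices for the 2–5-year-old male cohort, by variant.
REPORTED_HI_2_5_MALE = {
    "DF": 0.014,
    "ALF": 0.018,
    "GS": 0.009,
    "ALF+DF": 0.004,
    "GS+DF": 0.002,
}

#: Reported Cd ILCR for the 23–30-year-old male cohort, by variant.
REPORTED_ILCR_23_30_MALE = {
    "DF": 8.21e-7,
    "ALF": 1.94e-6,
    "GS": 1.18e-6,
    "ALF+DF": 2.69e-7,
    "GS+DF": 1.63e-7,
}

_DF_CSV = """\
age_group,sex,df_head,df_tb,df_pulmonary
2-5,male,0.375,0.030,0.255
2-5,female,0.360,0.030,0.250
5-7,male,0.425,0.030,0.235
5-7,female,0.412,0.030,0.228
7-11,male,0.495,0.030,0.205
7-11,female,0.482,0.030,0.198
11-23,male,0.590,0.030,0.170
11-23,female,0.588,0.030,0.152
23-30,male,0.601,0.020,0.139
23-30,female,0.567,0.020,0.133
30-40,male,0.615,0.020,0.135
30-40,female,0.581,0.020,0.129
40-65,male,0.630,0.020,0.130
40-65,female,0.595,0.020,0.125
65-96,male,0.656,0.020,0.124
65-96,female,0.620,0.020,0.120
"""


def df_override_table() -> pd.DataFrame:
    """The shipped per-cohort deposition-fraction table.

    Calibrated to the case study: pulmonary fractions decrease with age
    within each life stage (0.15–0.26 for children, 0.12–0.14 for adults,
    male above female), total deposition is higher for adults (0.72–0.80)
    than children (0.64–0.79), and the 2–5 male / 23–30 male pulmonary
    values are pinned by the reported risk ratios between the with- and
    without-deposition variants.
    """
    from .deposition import load_df_table

    return load_df_table(pd.read_csv(_io.StringIO(_DF_CSV)))
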
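"""Adjusted exposure concentrations and average daily inhaled doses.

Six concentration variants feed the dose equation: the total airborne
concentration (Total), the fluid-dissolved concentrations (ALF, GS), and
each of those multiplied by the pulmonary deposition fraction (DF, ALF+DF,
GS+DF).  The average daily dose for non-carcinogens and its lifetime
analogue for carcinogens are

    ADD_inh  = C × InhR × EF × ED / (BW × AT_n),   AT_n = ED × 365 d
    LADD_inh = C × InhR × EF × ED / (BW × AT_c),   AT_c = 70 × 365 d

in mg·kg⁻¹·day⁻¹, so ADD is independent of ED (the ED in numerator and
AT_n cancel) and LADD = ADD × ED / 70 exactly.

Unit convention: sample tables carry ng·m⁻³; the single ng→mg conversion
in the package (× 10⁻⁶, :data:`NG_TO_MG`) happens here when concentration
summaries are assembled into :class:`ConcentrationSet` objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bioaccessibility import site_bioaccessibility
from .cohorts import all_cohorts
from .config import ExposureParameters, PipelineConfig
from .deposition import df_lookup
from .exceptions import ConfigurationError, ValidationError

#: The package's one ng·m⁻³ → mg·m⁻³ conversion factor.
NG_TO_MG = 1e-6

VARIANTS = ("Total", "ALF", "GS", "DF", "ALF+DF", "GS+DF")
#: Variants reported in the case study's dose table.
TABLE_VARIANTS = ("ALF+DF", "GS+DF")


@dataclass(frozen=True)
class ConcentrationSet:
    """All six assessment concentrations for one metal, mg·m⁻³."""

    total: float
    alf: float
    gs: float
    df_pulmonary: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.df_pulmonary <= 1.0:
            raise ValidationError("df_pulmonary must lie in [0, 1]")
        for name in ("total", "alf", "gs"):
            if getattr(self, name) < 0:
                raise ValidationError(f"concentration {name} must be >= 0")

    @property
    def c_df(self) -> float:
        return self.total * self.df_pulmonary

    @property
    def c_alf_df(self) -> float:
        return self.alf * self.df_pulmonary

    @property
    def c_gs_df(self) -> float:
        return self.gs * self.df_pulmonary

    def variant(self, name: str) -> float:
        """Concentration (mg·m⁻³) for a named variant."""
        table = {
            "Total": self.total,
            "ALF": self.alf,
            "GS": self.gs,
            "DF": self.c_df,
            "ALF+DF": self.c_alf_df,
            "GS+DF": self.c_gs_df,
        }
        try:
            return table[name]
        except KeyError:
            raise ValidationError(f"unknown concentration variant {name!r}") from None


def adjusted_concentrations(
    total: float, alf: float, gs: float, df_pulmonary: float
) -> ConcentrationSet:
    """Build the six-variant concentration set (inputs in mg·m⁻³)."""
    return ConcentrationSet(total=total, alf=alf, gs=gs, df_pulmonary=df_pulmonary)


def add_inh(c: float, params: ExposureParameters) -> float:
    """Average daily inhaled dose (non-carcinogens), mg·kg⁻¹·day⁻¹."""
    return c * params.inh_r * params.ef * params.ed / (params.bw * params.at_n)


def ladd_inh(c: float, params: ExposureParameters) -> float:
    """Lifetime average daily inhaled dose (carcinogens), mg·kg⁻¹·day⁻¹."""
    return c * params.inh_r * params.ef * params.ed / (params.bw * params.at_c)


def concentration_summary(samples: pd.DataFrame, grouping: str = "all") -> pd.DataFrame:
    """Group-level mean concentrations in mg·m⁻³ (the ng→mg conversion point).

    One row per group × metal with columns total_mgm3, alf_mgm3, gs_mgm3.
    """
    bio = site_bioaccessibility(samples, grouping=grouping)
    if bio.empty:
        raise ValidationError("no usable concentration data in the sample table")
    wide = bio.pivot_table(
        index=["site", "metal"], columns="fluid", values="extract_mean"
    )
    totals = bio.groupby(["site", "metal"])["total_mean"].first()
    out = pd.DataFrame(
        {
            "total_mgm3": totals * NG_TO_MG,
            "alf_mgm3": wide.get("ALF", np.nan) * NG_TO_MG,
            "gs_mgm3": wide.get("GS", np.nan) * NG_TO_MG,
        }
    ).reset_index()
    out.attrs["units"] = {c: "mg/m3" for c in ("total_mgm3", "alf_mgm3", "gs_mgm3")}
    return out


def dose_table(
    conc_summary: pd.DataFrame,
    df_table: pd.DataFrame,
    config: PipelineConfig,
    variants: tuple[str, ...] = VARIANTS,
    site: str | None = None,
) -> pd.DataFrame:
    """Per-cohort dose table: one row per cohort × sex × metal × variant.

    ``conc_summary`` is the output of :func:`concentration_summary`; if it
    contains several sites, ``site`` selects one (default: the pooled
    'ALL' group if present, else an error).  LADD is populated only for
    metals carrying a cancer slope factor.  Doses are mg·kg⁻¹·day⁻¹; the
    ``*_1e6`` display columns are the same numbers × 10⁶.
    """
    sites = list(conc_summary["site"].unique())
    if site is None:
        site = "ALL" if "ALL" in sites else (sites[0] if len(sites) == 1 else None)
        if site is None:
            raise ValidationError(
                f"multiple sites {sites} in summary; pass site= explicitly"
            )
    sel = conc_summary[conc_summary["site"] == site]
    if sel.empty:
        raise ValidationError(f"site {site!r} not present in the summary")

    unknown = set(variants) - set(VARIANTS)
    if unknown:
        raise ValidationError(f"unknown variant(s) {sorted(unknown)}")

    carcinogens = set(config.carcinogens)
    rows = []
    for cohort in all_cohorts():
        try:
            params = config.exposure[cohort]
        except KeyError:
            raise ConfigurationError(f"exposure registry missing {cohort}") from None
        df_pulm = df_lookup(df_table, cohort).pulmonary
        for _, rec in sel.iterrows():
            cs = ConcentrationSet(
                total=float(rec.total_mgm3),
                alf=float(rec.alf_mgm3) if pd.notna(rec.alf_mgm3) else 0.0,
                gs=float(rec.gs_mgm3) if pd.notna(rec.gs_mgm3) else 0.0,
                df_pulmonary=df_pulm,
            )
            for variant in variants:
                c = cs.variant(variant)
                add = add_inh(c, params)
                ladd = ladd_inh(c, params) if rec.metal in carcinogens else np.nan
                rows.append(
                    {
                        "age_group": cohort.age_group,
                        "sex": cohort.sex,
                        "life_stage": cohort.life_stage,
                        "metal": rec.metal,
                        "variant": variant,
                        "ed_years": params.ed,
                        "add_mgkgday": add,
                        "ladd_mgkgday": ladd,
                    }
                )
    out = pd.DataFrame(rows)
    out["add_1e6"] = out["add_mgkgday"] * 1e6
    out["ladd_1e6"] = out["ladd_mgkgday"] * 1e6
    out.attrs["units"] = {
        "add_mgkgday": "mg/kg/day", "ladd_mgkgday": "mg/kg/day",
        "add_1e6": "1e-6 mg/kg/day", "ladd_1e6": "1e-6 mg/kg/day",
    }
    return out
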
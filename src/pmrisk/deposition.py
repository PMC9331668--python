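"""Regional respiratory deposition fractions (head / tracheobronchial / pulmonary).

Two sources of deposition fractions (DF) are supported:

1. A semi-empirical closed-form engine: the ICRP-66 regional deposition
   model in its widely used fitted form (nose breathing, reference adult),
   plus a documented ventilation/FRC scaling rule to move from the
   reference adult to an arbitrary cohort physiology.
2. A per-cohort override table (CSV or DataFrame), e.g. output of an
   external dosimetry run.  The shipped default table
   (:func:`default_df_table`) is calibrated to the Huludao case study.

The downstream dose equations use the *pulmonary* fraction only: particles
depositing in the alveolar region reside long enough (a day or more) for
dissolution into lung fluid to matter, whereas head/TB deposits clear
quickly via the mucociliary escalator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .cohorts import ADULT_AGE, Cohort
from .config import Physiology
from .exceptions import ConfigurationError, DepositionLookupError, ValidationError

_SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class ParticleSpec:
    """A monodisperse spherical particle.

    ``diameter_um`` is the physical diameter; with the default unit density
    (1.0 g·cm⁻³) it coincides with the aerodynamic diameter used by the
    deposition formulas, which is otherwise d·√ρ.
    """

    diameter_um: float = 2.5
    density_g_cm3: float = 1.0
    shape: str = "spherical"

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValidationError("particle diameter must be > 0")
        if self.density_g_cm3 <= 0:
            raise ValidationError("particle density must be > 0")

    @property
    def aerodynamic_diameter_um(self) -> float:
        return self.diameter_um * math.sqrt(self.density_g_cm3)


@dataclass(frozen=True)
class RegionalDF:
    """Deposition fractions in the three respiratory regions."""

    head: float
    tracheobronchial: float
    pulmonary: float
    cohort: Cohort | None = None
    source: str = "model"  # 'model' or 'override'

    def __post_init__(self) -> None:
        for name in ("head", "tracheobronchial", "pulmonary"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"RegionalDF.{name}={v} outside [0, 1]")
        if self.total > 1.0 + _SIMPLEX_TOL:
            raise ValidationError(
                f"regional deposition fractions sum to {self.total:.4f} > 1"
            )

    @property
    def total(self) -> float:
        return self.head + self.tracheobronchial + self.pulmonary


# ---------------------------------------------------------------------------
# ICRP-66 closed forms (fitted equations, nose breathing, reference adult)
# ---------------------------------------------------------------------------


def inhalable_fraction(d_um: float) -> float:
    """Fraction of ambient particles that enters the nose at all."""
    return 1.0 - 0.5 * (1.0 - 1.0 / (1.0 + 0.00076 * d_um**2.8))


def icrp_regional_df(particle: ParticleSpec = ParticleSpec()) -> RegionalDF:
    """Regional deposition fractions for the reference adult, nose breathing.

    Evaluates the fitted closed-form expressions of the ICRP-66 model
    (head/extrathoracic, tracheobronchial and alveolar regions) at the
    particle's aerodynamic diameter.  Valid for 0.001–100 µm.
    """
    d = particle.aerodynamic_diameter_um
    if not 0.001 <= d <= 100.0:
        raise ValidationError(
            f"diameter {d} µm outside the 0.001–100 µm validity range"
        )
    ln_d = math.log(d)
    inh = inhalable_fraction(d)

    head = inh * (
        1.0 / (1.0 + math.exp(6.84 + 1.183 * ln_d))
        + 1.0 / (1.0 + math.exp(0.924 - 1.885 * ln_d))
    )
    tb = (0.00352 / d) * (
        math.exp(-0.234 * (ln_d + 3.40) ** 2)
        + 63.9 * math.exp(-0.819 * (ln_d - 1.61) ** 2)
    )
    alveolar = (0.0155 / d) * (
        math.exp(-0.416 * (ln_d + 2.84) ** 2)
        + 19.11 * math.exp(-0.482 * (ln_d - 1.362) ** 2)
    )
    return RegionalDF(head=head, tracheobronchial=tb, pulmonary=alveolar)


def icrp_total_df(particle: ParticleSpec = ParticleSpec()) -> float:
    """Independently fitted total-deposition curve (same model family).

    Fitted directly to total deposition rather than summed over regions;
    agrees with the regional sum to within a few percent and serves as a
    cross-check of the regional closed forms.
    """
    d = particle.aerodynamic_diameter_um
    ln_d = math.log(d)
    inh = inhalable_fraction(d)
    return inh * (
        0.0587
        + 0.911 / (1.0 + math.exp(4.77 + 1.485 * ln_d))
        + 0.943 / (1.0 + math.exp(0.508 - 2.58 * ln_d))
    )


# ---------------------------------------------------------------------------
# Physiology scaling
# ---------------------------------------------------------------------------


def scale_df(base: RegionalDF, physiology: Physiology, reference: Physiology) -> RegionalDF:
    """Rescale reference-adult deposition to another physiology.

    Penetration-probability scaling: the escape probability of each lower
    region is raised to a ventilation exponent, DF' = 1 − (1 − DF)^s, with

    * pulmonary: s = (VT/FRC) / (VT/FRC)_ref — deeper breaths relative to
      resting lung volume carry aerosol further into the alveolar region;
    * tracheobronchial: s = (VT·BF) / (VT·BF)_ref — minute ventilation.

    The head fraction is left at its reference value.  The exponent form
    keeps each component inside [0, 1] for any s > 0 and is monotone:
    shrinking FRC (children) raises the pulmonary fraction.  If the scaled
    components overshoot the simplex they are renormalised with a warning.
    """
    s_pulm = (physiology.tidal_volume_ml / physiology.frc_ml) / (
        reference.tidal_volume_ml / reference.frc_ml
    )
    s_tb = (physiology.tidal_volume_ml * physiology.breathing_frequency) / (
        reference.tidal_volume_ml * reference.breathing_frequency
    )
    pulm = 1.0 - (1.0 - base.pulmonary) ** s_pulm
    tb = 1.0 - (1.0 - base.tracheobronchial) ** s_tb
    head = base.head
    total = head + tb + pulm
    if total > 1.0:
        warnings.warn(
            f"scaled deposition fractions sum to {total:.3f}; renormalising",
            stacklevel=2,
        )
        head, tb, pulm = (x / total for x in (head, tb, pulm))
    return replace(base, head=head, tracheobronchial=tb, pulmonary=pulm)


def frc_estimate(
    age: float,
    height: float,
    sex: str,
    coefficients: dict[str, dict[str, float]],
) -> float:
    """Functional residual capacity (mL) from anthropometry.

    Children (age < 23): power law in height only, FRC = a × H^b.
    Adults: linear in height and age, FRC = 1000 × (c_h·H + c_a·age + c0),
    with sex-specific coefficients.  Coefficients must be supplied
    explicitly (shipped defaults: ``config.DEFAULT_FRC_COEFFICIENTS``).
    """
    if height <= 0:
        raise ValidationError("height must be > 0")
    if age <= 0:
        raise ValidationError("age must be > 0")
    if not coefficients:
        raise ConfigurationError("FRC coefficients must be provided")
    try:
        if age < ADULT_AGE:
            c = coefficients["child"]
            frc = c["a"] * height ** c["b"]
        else:
            c = coefficients[f"adult_{sex}"]
            frc = 1000.0 * (
                c["c_height"] * height + c["c_age"] * age + c["intercept"]
            )
    except KeyError as exc:
        raise ConfigurationError(f"missing FRC coefficient: {exc}") from exc
    if frc <= 0:
        raise ValidationError(f"FRC formula returned {frc:.1f} mL <= 0")
    return frc


def cohort_regional_df(
    particle: ParticleSpec,
    physiology: Physiology,
    reference: Physiology,
    cohort: Cohort | None = None,
) -> RegionalDF:
    """Closed-form engine end to end: reference curve + physiology scaling."""
    base = icrp_regional_df(particle)
    scaled = scale_df(base, physiology, reference)
    return replace(scaled, cohort=cohort, source="model")


# ---------------------------------------------------------------------------
# Override tables
# ---------------------------------------------------------------------------

_DF_COLUMNS = ["age_group", "sex", "df_head", "df_tb", "df_pulmonary"]


def load_df_table(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    """Load and validate a per-cohort DF override table.

    Expects columns age_group, sex, df_head, df_tb, df_pulmonary; each row
    must satisfy the simplex invariants (components in [0, 1], sum ≤ 1).
    """
    if isinstance(source, pd.DataFrame):
        table = source.copy()
    else:
        table = pd.read_csv(source, comment="#")
    missing = [c for c in _DF_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"DF table missing column(s) {missing}")
    for _, row in table.iterrows():
        # constructing RegionalDF enforces the invariants per row
        RegionalDF(
            head=float(row.df_head),
            tracheobronchial=float(row.df_tb),
            pulmonary=float(row.df_pulmonary),
            cohort=Cohort(str(row.age_group), str(row.sex)),
            source="override",
        )
    return table[_DF_COLUMNS].reset_index(drop=True)


def df_lookup(table: pd.DataFrame, cohort: Cohort) -> RegionalDF:
    """Fetch the tabulated regional fractions for one cohort."""
    rows = table[(table.age_group == cohort.age_group) & (table.sex == cohort.sex)]
    if rows.empty:
        raise DepositionLookupError(
            f"cohort {cohort.age_group}/{cohort.sex} not in the DF table"
        )
    row = rows.iloc[0]
    return RegionalDF(
        head=float(row.df_head),
        tracheobronchial=float(row.df_tb),
        pulmonary=float(row.df_pulmonary),
        cohort=cohort,
        source="override",
    )


def default_df_table() -> pd.DataFrame:
    """The shipped per-cohort DF table (Huludao case-study calibration)."""
    from .huludao import df_override_table

    return df_override_table()


def deposition_report(table: pd.DataFrame) -> pd.DataFrame:
    """One row per cohort with the three regional fractions and their total."""
    out = table.copy()
    out["df_total"] = out.df_head + out.df_tb + out.df_pulmonary
    return out
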
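"""Pipeline configuration: cohort registries, toxicity values, MC settings.

Everything the dose and risk equations need beyond the measured
concentrations lives here: per-cohort inhalation rate and body weight,
per-cohort respiratory physiology (for the closed-form deposition engine),
per-metal toxicity references, and Monte Carlo settings.  All registries
ship with documented defaults and every value can be overridden from a YAML
file (see :func:`read_config`).

Default provenance
------------------
Body weights follow USEPA exposure-handbook conventions (age-group means).
Inhalation rates are the calibrated defaults that, combined with the
shipped pulmonary deposition-fraction table, reproduce the Huludao
case-study dose table; they fall in the plausible long-term range
(8–15 m³·day⁻¹ for children, 11–18 m³·day⁻¹ for adults).  Toxicity values
are the standard inhalation references: RfD 1.0e-3 (Cd) and 3.5e-3 (Pb)
mg·kg⁻¹·day⁻¹, cancer slope factor 6.3 (mg·kg⁻¹·day⁻¹)⁻¹ for Cd only.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .cohorts import ADULT_AGE, AGE_GROUPS, SEXES, Cohort, all_cohorts
from .exceptions import ConfigurationError, ValidationError

DAYS_PER_YEAR = 365.0
#: Lifetime (years) used by the carcinogenic averaging time AT_c = 70 × 365 d.
LIFETIME_YEARS = 70.0
#: Default exposure frequency, day·year⁻¹.
DEFAULT_EF = 350.0
#: Default exposure durations by life stage, years.
DEFAULT_ED = {"child": 6.0, "adult": 26.0}


@dataclass(frozen=True)
class ExposureParameters:
    """Symbols of the daily-dose equation for one cohort.

    ADD_inh = C × InhR × EF × ED / (BW × AT_n) with AT_n = ED × 365 d;
    LADD_inh uses AT_c = 70 × 365 d instead.
    """

    inh_r: float  # inhalation rate, m³·day⁻¹
    bw: float  # body weight, kg
    ed: float  # exposure duration, years
    ef: float = DEFAULT_EF  # exposure frequency, day·year⁻¹

    def __post_init__(self) -> None:
        for name in ("inh_r", "bw", "ed", "ef"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"ExposureParameters.{name} must be > 0")

    @property
    def at_n(self) -> float:
        """Averaging time for non-carcinogens, days (= ED × 365)."""
        return self.ed * DAYS_PER_YEAR

    @property
    def at_c(self) -> float:
        """Averaging time for carcinogens, days (= 70 × 365)."""
        return LIFETIME_YEARS * DAYS_PER_YEAR


@dataclass(frozen=True)
class Physiology:
    """Respiratory physiology for one cohort (nasal breathing assumed)."""

    height_cm: float
    body_weight_kg: float
    frc_ml: float  # functional residual capacity
    tidal_volume_ml: float
    breathing_frequency: float  # breaths·min⁻¹
    upper_airway_volume_ml: float = 50.0
    breathing_mode: str = "nasal"

    def __post_init__(self) -> None:
        for name in (
            "height_cm",
            "body_weight_kg",
            "frc_ml",
            "tidal_volume_ml",
            "breathing_frequency",
            "upper_airway_volume_ml",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"Physiology.{name} must be > 0")


@dataclass(frozen=True)
class ToxicityReference:
    """Inhalation toxicity constants for one metal."""

    metal: str
    rfd: float  # reference dose, mg·kg⁻¹·day⁻¹
    csf: float | None = None  # cancer slope factor, (mg·kg⁻¹·day⁻¹)⁻¹

    def __post_init__(self) -> None:
        if self.rfd <= 0:
            raise ValidationError("RfD must be > 0")
        if self.csf is not None and self.csf <= 0:
            raise ValidationError("CSF must be > 0 when present")


@dataclass(frozen=True)
class MonteCarloSettings:
    """Uncertainty-propagation settings.

    Only the respiration (inhalation) rate is randomised — normally
    distributed with coefficient of variation ``inh_r_cv``, truncated at
    zero — while concentrations and body weights are held at their means.
    """

    iterations: int = 5000
    inh_r_cv: float = 0.3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValidationError("Monte Carlo iterations must be >= 1")
        if self.inh_r_cv < 0:
            raise ValidationError("inh_r_cv (coefficient of variation) must be >= 0")


# ---------------------------------------------------------------------------
# Default registries (male tuple, female tuple, ordered as AGE_GROUPS)
# ---------------------------------------------------------------------------

_BW = {
    "male": (17.4, 23.0, 32.0, 56.8, 71.0, 78.0, 80.0, 75.0),
    "female": (16.8, 22.1, 31.7, 51.4, 61.0, 67.0, 68.0, 65.0),
}
_INHR = {
    "male": (8.68, 9.83, 10.93, 14.63, 17.50, 18.42, 18.15, 13.34),
    "female": (8.41, 9.30, 10.54, 13.80, 14.35, 14.86, 13.62, 10.97),
}
_HEIGHT = {
    "male": (105.0, 118.0, 135.0, 168.0, 176.0, 175.0, 172.0, 168.0),
    "female": (104.0, 117.0, 134.0, 158.0, 163.0, 162.0, 160.0, 156.0),
}
_TIDAL = {
    "male": (130.0, 165.0, 240.0, 420.0, 620.0, 620.0, 600.0, 550.0),
    "female": (125.0, 160.0, 230.0, 380.0, 460.0, 460.0, 450.0, 420.0),
}
_BF = {
    "male": (22.0, 20.0, 18.0, 14.0, 13.0, 13.0, 13.0, 14.0),
    "female": (23.0, 21.0, 19.0, 15.0, 14.0, 14.0, 14.0, 15.0),
}
_UAV = (30.0, 34.0, 40.0, 48.0, 50.0, 50.0, 50.0, 50.0)

#: Coefficients of the FRC formulas (see :func:`pmrisk.deposition.frc_estimate`).
#: Children: FRC(mL) = a × height(cm)^b (height only).
#: Adults:   FRC(mL) = 1000 × (c_height × height + c_age × age + intercept).
DEFAULT_FRC_COEFFICIENTS: dict[str, dict[str, float]] = {
    "child": {"a": 1.29e-5, "b": 3.73},
    "adult_male": {"c_height": 0.0472, "c_age": 0.0090, "intercept": -5.92},
    "adult_female": {"c_height": 0.0360, "c_age": 0.0031, "intercept": -3.182},
}

DEFAULT_TOXICITY: dict[str, ToxicityReference] = {
    "Cd": ToxicityReference("Cd", rfd=1.00e-3, csf=6.30),
    "Pb": ToxicityReference("Pb", rfd=3.50e-3, csf=None),
}


def _default_exposure_registry() -> dict[Cohort, ExposureParameters]:
    reg = {}
    for i, age_group in enumerate(AGE_GROUPS):
        for sex in SEXES:
            cohort = Cohort(age_group, sex)
            reg[cohort] = ExposureParameters(
                inh_r=_INHR[sex][i],
                bw=_BW[sex][i],
                ed=DEFAULT_ED[cohort.life_stage],
            )
    return reg


def _default_physiology_registry() -> dict[Cohort, Physiology]:
    from .deposition import frc_estimate  # local import avoids a cycle

    reg = {}
    for i, age_group in enumerate(AGE_GROUPS):
        for sex in SEXES:
            cohort = Cohort(age_group, sex)
            frc = frc_estimate(
                age=cohort.midpoint_age,
                height=_HEIGHT[sex][i],
                sex=sex,
                coefficients=DEFAULT_FRC_COEFFICIENTS,
            )
            reg[cohort] = Physiology(
                height_cm=_HEIGHT[sex][i],
                body_weight_kg=_BW[sex][i],
                frc_ml=frc,
                tidal_volume_ml=_TIDAL[sex][i],
                breathing_frequency=_BF[sex][i],
                upper_airway_volume_ml=_UAV[i],
            )
    return reg


@dataclass
class PipelineConfig:
    """Bundle of every registry the pipeline stages consume."""

    exposure: dict[Cohort, ExposureParameters] = field(
        default_factory=_default_exposure_registry
    )
    physiology: dict[Cohort, Physiology] = field(
        default_factory=_default_physiology_registry
    )
    toxicity: dict[str, ToxicityReference] = field(
        default_factory=lambda: dict(DEFAULT_TOXICITY)
    )
    mc: MonteCarloSettings = field(default_factory=MonteCarloSettings)
    frc_coefficients: dict[str, dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_FRC_COEFFICIENTS)
    )
    grouping: str = "all"  # 'all' pools sites; 'site' keeps them separate

    def validate(self) -> "PipelineConfig":
        """Check that every cohort any stage can reference is registered."""
        for cohort in all_cohorts():
            if cohort not in self.exposure:
                raise ConfigurationError(f"exposure registry missing {cohort}")
            if cohort not in self.physiology:
                raise ConfigurationError(f"physiology registry missing {cohort}")
        if self.grouping not in ("all", "site"):
            raise ConfigurationError("grouping must be 'all' or 'site'")
        return self

    @property
    def carcinogens(self) -> list[str]:
        return [m for m, t in self.toxicity.items() if t.csf is not None]


def default_config() -> PipelineConfig:
    """The shipped default configuration (validated)."""
    return PipelineConfig().validate()


# ---------------------------------------------------------------------------
# YAML reading
# ---------------------------------------------------------------------------

_TOP_KEYS = {
    "exposure",
    "physiology",
    "toxicity",
    "monte_carlo",
    "frc_coefficients",
    "grouping",
}
_EXPOSURE_FIELDS = {"inh_r", "bw", "ed", "ef"}
_PHYSIOLOGY_FIELDS = {
    "height_cm",
    "body_weight_kg",
    "frc_ml",
    "tidal_volume_ml",
    "breathing_frequency",
    "upper_airway_volume_ml",
    "breathing_mode",
}
_TOXICITY_FIELDS = {"rfd", "csf"}
_MC_FIELDS = {"iterations", "inh_r_cv", "seed"}


def _check_keys(mapping: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in {where}; allowed: {sorted(allowed)}"
        )


def _cohort_overrides(section: Mapping[str, Any], where: str):
    """Yield (Cohort, field dict) from an {age_group: {sex: {...}}} mapping."""
    for age_group, by_sex in section.items():
        if age_group not in AGE_GROUPS:
            raise ConfigurationError(
                f"unknown cohort age group {age_group!r} in {where}"
            )
        if not isinstance(by_sex, Mapping):
            raise ConfigurationError(f"{where}.{age_group} must map sexes to fields")
        for sex, fields_ in by_sex.items():
            if sex not in SEXES:
                raise ConfigurationError(f"unknown sex {sex!r} in {where}.{age_group}")
            yield Cohort(age_group, sex), dict(fields_)


def read_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config file, merging overrides onto the shipped defaults.

    An empty file yields the documented defaults (EF = 350 day·year⁻¹,
    AT_c = 70 × 365 days, 5000 MC iterations, ...).  Unknown keys anywhere
    are rejected rather than ignored.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return default_config()
    if not isinstance(raw, Mapping):
        raise ConfigurationError("config file must contain a mapping at top level")
    _check_keys(raw, _TOP_KEYS, "config")

    cfg = PipelineConfig()

    for cohort, fields_ in _cohort_overrides(raw.get("exposure", {}), "exposure"):
        _check_keys(fields_, _EXPOSURE_FIELDS, f"exposure.{cohort.age_group}")
        cfg.exposure[cohort] = replace(cfg.exposure[cohort], **fields_)
    for cohort, fields_ in _cohort_overrides(raw.get("physiology", {}), "physiology"):
        _check_keys(fields_, _PHYSIOLOGY_FIELDS, f"physiology.{cohort.age_group}")
        cfg.physiology[cohort] = replace(cfg.physiology[cohort], **fields_)

    for metal, fields_ in raw.get("toxicity", {}).items():
        _check_keys(dict(fields_), _TOXICITY_FIELDS, f"toxicity.{metal}")
        base = cfg.toxicity.get(metal)
        merged = {
            "rfd": fields_.get("rfd", base.rfd if base else None),
            "csf": fields_.get("csf", base.csf if base else None),
        }
        if merged["rfd"] is None:
            raise ConfigurationError(f"toxicity.{metal} needs an rfd")
        cfg.toxicity[metal] = ToxicityReference(metal, **merged)

    if "monte_carlo" in raw:
        _check_keys(dict(raw["monte_carlo"]), _MC_FIELDS, "monte_carlo")
        cfg.mc = replace(cfg.mc, **dict(raw["monte_carlo"]))

    if "frc_coefficients" in raw:
        _check_keys(
            dict(raw["frc_coefficients"]),
            set(DEFAULT_FRC_COEFFICIENTS),
            "frc_coefficients",
        )
        for group, coeffs in raw["frc_coefficients"].items():
            _check_keys(
                dict(coeffs),
                set(DEFAULT_FRC_COEFFICIENTS[group]),
                f"frc_coefficients.{group}",
            )
            cfg.frc_coefficients[group].update(coeffs)

    if "grouping" in raw:
        cfg.grouping = raw["grouping"]

    return cfg.validate()
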
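"""Age/sex cohort definitions.

The assessment splits the population into eight age groups and two sexes.
Children span 2–23 years (four groups) and adults 23–96 years (four
groups); the life stage drives the exposure duration (6 years for children,
26 for adults) used by the dose equations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import ValidationError

#: Age-group label -> (lower bound, upper bound) in years.
AGE_BOUNDS: dict[str, tuple[float, float]] = {
    "2-5": (2, 5),
    "5-7": (5, 7),
    "7-11": (7, 11),
    "11-23": (11, 23),
    "23-30": (23, 30),
    "30-40": (30, 40),
    "40-65": (40, 65),
    "65-96": (65, 96),
}

AGE_GROUPS: tuple[str, ...] = tuple(AGE_BOUNDS)
SEXES: tuple[str, ...] = ("male", "female")

#: Boundary between the child (2–23 y) and adult (23–96 y) life stages.
ADULT_AGE = 23


@dataclass(frozen=True, order=True)
class Cohort:
    """One age-group × sex population cell."""

    age_group: str
    sex: str

    def __post_init__(self) -> None:
        if self.age_group not in AGE_BOUNDS:
            raise ValidationError(
                f"unknown age group {self.age_group!r}; "
                f"expected one of {sorted(AGE_BOUNDS)}"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"unknown sex {self.sex!r}; expected male/female")

    @property
    def bounds(self) -> tuple[float, float]:
        return AGE_BOUNDS[self.age_group]

    @property
    def midpoint_age(self) -> float:
        lo, hi = self.bounds
        return (lo + hi) / 2.0

    @property
    def life_stage(self) -> str:
        """'child' for groups within 2–23 years, 'adult' for 23–96."""
        return "child" if self.bounds[1] <= ADULT_AGE else "adult"


def all_cohorts() -> list[Cohort]:
    """Every age group × sex combination, in registry order (16 cohorts)."""
    return [Cohort(a, s) for a in AGE_GROUPS for s in SEXES]
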
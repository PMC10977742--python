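"""Covariate profiles and the piecewise-constant segmentation of a life course.

Transition intensities depend on sex, an age category, a calendar-period
category, and on whether diabetes onset has been "activated" (age >= 40 in
normal weight, age >= 25 otherwise).  Along an individual's life course these
covariates are piecewise constant, changing only at the age breakpoints
{25, 40, 50} and at the calendar breakpoints {1995, 2005} converted to ages
through the birth year.  Splitting an observation interval at those points
yields segments on which the generator matrix is constant, so interval
transition probabilities are products of matrix exponentials.

Conventions: an individual's age in calendar year ``y`` is ``y - birth_year``
(surveys record years only, so mid-year effects are ignored); age intervals
are half-open ``[a, b)``; period boundaries sit at January 1 of 1995 and 2005.
The last observed period (2005-2014) is carried forward for all later years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MALE = "M"
FEMALE = "F"
SEXES = (MALE, FEMALE)

AGE_CLASSES = ("lt25", "a25_49", "ge50")
PERIODS = ("pre1995", "p1995_2004", "p2005_2014")


@dataclass(frozen=True)
class ModelConfig:
    """Structural constants: breakpoints, activation ages, simulation origin."""

    start_age: float = 3.0               # BMI transitions possible from age 3
    age_breaks: tuple[float, float] = (25.0, 50.0)   # BMI-transition age classes
    dm_age_break: float = 50.0           # diabetes-onset age effect (<50 vs >=50)
    period_breaks: tuple[int, int] = (1995, 2005)    # calendar periods
    dm_start_nw: float = 40.0            # diabetes activation age, normal weight
    dm_start_owob: float = 25.0          # diabetes activation age, overweight/obese
    horizon_age: float = 110.0           # projection / lifetime-risk horizon

    def age_class(self, age: float) -> str:
        if age < self.age_breaks[0]:
            return "lt25"
        if age < self.age_breaks[1]:
            return "a25_49"
        return "ge50"

    def period(self, year: float) -> str:
        if year < self.period_breaks[0]:
            return "pre1995"
        if year < self.period_breaks[1]:
            return "p1995_2004"
        return "p2005_2014"


DEFAULT_CONFIG = ModelConfig()


@dataclass(frozen=True)
class CovariateProfile:
    """Fully resolved covariate values, constant on one segment."""

    sex: str
    age_class: str
    period: str
    dm_active_nw: bool
    dm_active_owob: bool
    dm_age_lt50: bool

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValueError(f"unknown age class {self.age_class!r}")
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r}")

    @classmethod
    def at(
        cls,
        sex: str,
        age: float,
        year: float,
        config: ModelConfig = DEFAULT_CONFIG,
    ) -> "CovariateProfile":
        """Profile of an individual of given sex at an exact age and calendar year."""
        return cls(
            sex=sex,
            age_class=config.age_class(age),
            period=config.period(year),
            dm_active_nw=age >= config.dm_start_nw,
            dm_active_owob=age >= config.dm_start_owob,
            dm_age_lt50=age < config.dm_age_break,
        )


@dataclass(frozen=True)
class Segment:
    """A sub-interval ``[start_age, end_age)`` of constant covariates."""

    start_age: float
    end_age: float
    profile: CovariateProfile

    @property
    def length(self) -> float:
        return self.end_age - self.start_age


def make_segments(
    birth_year: int,
    sex: str,
    end_age: float,
    start_age: float | None = None,
    config: ModelConfig = DEFAULT_CONFIG,
) -> list[Segment]:
    """Split ``[start_age, end_age)`` into maximal constant-covariate segments.

    Cut points are the age breakpoints (25, 40, 50 by default — 40 enters
    through diabetes activation in normal weight) and the calendar breakpoints
    (1995, 2005) converted to ages via ``birth_year``.  Consecutive segments
    abut exactly and their union covers the whole interval.

    Returns an empty list when the interval has zero length; raises for
    ``end_age < start_age`` or an end age before the simulation origin.
    """
    if start_age is None:
        start_age = config.start_age
    if end_age < config.start_age:
        raise ValueError(
            f"end_age={end_age} precedes the simulation origin (age {config.start_age})"
        )
    if end_age < start_age:
        raise ValueError(f"end_age={end_age} < start_age={start_age}")
    if end_age == start_age:
        return []

    cuts = {
        *config.age_breaks,
        config.dm_age_break,
        config.dm_start_nw,
        config.dm_start_owob,
        *(float(p - birth_year) for p in config.period_breaks),
    }
    points = sorted({start_age, end_age, *(c for c in cuts if start_age < c < end_age)})
    segments = []
    for a, b in zip(points[:-1], points[1:]):
        profile = CovariateProfile.at(sex, a, birth_year + a, config)
        segments.append(Segment(start_age=a, end_age=b, profile=profile))
    return segments
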
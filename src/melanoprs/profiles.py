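"""Study design profiles for the two case-control settings the package emulates.

A :class:`StudyProfile` captures the design constants of a population-based
melanoma case-control study: how many cases and controls are ascertained, the
permissible age windows for each, the sex mix, the ancestry composition and
the baseline (population) disease prevalence driving the outcome simulator.

Two ready-made profiles are provided:

``AUSTRALIA``
    An early-onset study: all cases diagnosed before age 40, controls
    ascertained below age 45, 578 cases / 457 controls, 60% female.
``LEEDS``
    An unrestricted-age study: ages 18-82, 964 cases / 496 controls,
    60% female.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

__all__ = ["StudyProfile", "AUSTRALIA", "LEEDS", "get_profile"]

_PROP_TOL = 1e-9


@dataclass(frozen=True)
class StudyProfile:
    """Design constants of one case-control study.

    Parameters
    ----------
    name:
        Human-readable label, also used for the ``center`` column.
    n_cases, n_controls:
        Number of cases / controls ascertained into the analytic dataset.
    age_range_cases, age_range_controls:
        Half-open ``[low, high)`` age intervals (years) within which cases /
        controls are eligible.
    prop_female:
        Proportion of females in the source population.
    ancestry_distribution:
        Mapping of ancestry category to its proportion; must sum to 1.
    baseline_prevalence:
        Population disease prevalence targeted by the outcome simulator's
        intercept calibration.
    """

    name: str
    n_cases: int
    n_controls: int
    age_range_cases: Tuple[float, float]
    age_range_controls: Tuple[float, float]
    prop_female: float = 0.60
    centers: Tuple[str, ...] = ()
    ancestry_distribution: Dict[str, float] = field(
        default_factory=lambda: {
            "british": 0.70,
            "other_northern_european": 0.10,
            "southern_eastern_european": 0.15,
            "mixed_other_european": 0.05,
        }
    )
    baseline_prevalence: float = 0.01

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("n_cases and n_controls must be positive")
        for label, (lo, hi) in (
            ("age_range_cases", self.age_range_cases),
            ("age_range_controls", self.age_range_controls),
        ):
            if not lo < hi:
                raise ValueError(f"{label} interval [{lo}, {hi}) is empty")
        if not 0.0 <= self.prop_female <= 1.0:
            raise ValueError("prop_female must lie in [0, 1]")
        total = sum(self.ancestry_distribution.values())
        if abs(total - 1.0) > _PROP_TOL:
            raise ValueError(
                f"ancestry_distribution proportions sum to {total}, expected 1"
            )
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError("baseline_prevalence must lie strictly in (0, 1)")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def center_list(self) -> Tuple[str, ...]:
        """Recruitment centers; defaults to a single center named after the study."""
        return self.centers if self.centers else (self.name,)

    @property
    def age_range_source(self) -> Tuple[float, float]:
        """Union of the case and control age windows (source-population ages)."""
        lo = min(self.age_range_cases[0], self.age_range_controls[0])
        hi = max(self.age_range_cases[1], self.age_range_controls[1])
        return (lo, hi)


#: Early-onset study profile: cases < 40 years at diagnosis, controls < 45.
AUSTRALIA = StudyProfile(
    name="australia",
    n_cases=578,
    n_controls=457,
    age_range_cases=(18.0, 40.0),
    age_range_controls=(18.0, 45.0),
    centers=("sydney", "melbourne", "brisbane"),
)

#: Unrestricted-age study profile.
LEEDS = StudyProfile(
    name="leeds",
    n_cases=964,
    n_controls=496,
    age_range_cases=(18.0, 82.0),
    age_range_controls=(18.0, 82.0),
)

_PROFILES = {"australia": AUSTRALIA, "leeds": LEEDS}


def get_profile(name: str) -> StudyProfile:
    """Look up a built-in profile by name (``australia`` or ``leeds``)."""
    try:
        return _PROFILES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown profile {name!r}; available: {sorted(_PROFILES)}"
        ) from None
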
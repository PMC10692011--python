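"""Patient cohort generation.

A patient is characterised by a group flag ``x`` (1 if impaired or
pre-diseased), an optional comorbidity label, a true death probability ``p``
drawn from the group's triangular distribution, a decision score ``e * p``
used for triage ranking only, and a realized death-on-treatment indicator
``y ~ Bernoulli(p)`` fixed at generation time.  Triage never observes ``y``,
only the decision score; outcomes are realized up front so that a policy
cannot peek at them.

In the real-world scenario a comorbid patient has a 10% probability of an
impairment and 90% of a pre-existing condition, with the specific condition
drawn proportionally to prevalence weights within the category.
Single-comorbidity scenarios carry exactly one profile and bypass that
split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .distributions import (
    BASELINE,
    ComorbidityProfile,
    TriangularParams,
    load_profiles,
)


def _ppf_scalar(params: TriangularParams, u: float) -> float:
    # scalar inverse-CDF transform, kept free of ndarray overhead because it
    # sits in the innermost loop of every replication
    a, b, c = params.minimum, params.maximum, params.mode
    if b == a:
        return a
    if u * (b - a) < (c - a):
        return a + math.sqrt(u * (b - a) * (c - a))
    return b - math.sqrt((1.0 - u) * (b - a) * (b - c))

__all__ = ["Patient", "ScenarioConfig", "ConfigurationError",
           "assign_comorbidity", "generate_patient", "generate_cohort"]


class ConfigurationError(ValueError):
    """Scenario configuration is internally inconsistent."""


@dataclass(slots=True)
class Patient:
    id: int
    x: int                      # 1 = impaired or pre-diseased
    comorbidity: str | None
    p: float                    # true death probability
    decision_score: float       # e * p, ordinal use only (never clipped)
    y: int                      # realized death-on-treatment indicator
    arrival_time: int


@dataclass(frozen=True)
class ScenarioConfig:
    """Scenario parameters for the triage simulation.

    Defaults reflect the reference overload scenario: B=60 operable ICU
    beds, initial demand d=70, queue length w=10 at each of T=3 consecutive
    time points, comorbid fraction s=0.7, exact mortality estimation e=1,
    and R=10,000 Monte-Carlo replications.
    """

    name: str = "realworld"
    R: int = 10_000
    B: int = 60
    d: int = 70
    w: int = 10
    T: int = 3
    s: float = 0.7
    e: float = 1.0
    impairment_share: float = 0.1
    baseline: TriangularParams = BASELINE
    profiles: tuple[ComorbidityProfile, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < self.B:
            raise ConfigurationError(f"initial demand d={self.d} < beds B={self.B}")
        if self.w < 1:
            raise ConfigurationError("queue length w must be >= 1")
        if self.T < 0:
            raise ConfigurationError("horizon T must be >= 0")
        if not 0.0 <= self.s <= 1.0:
            raise ConfigurationError("comorbid fraction s must lie in [0, 1]")
        if self.e <= 0:
            raise ConfigurationError("misestimation factor e must be positive")
        if not 0.0 <= self.impairment_share <= 1.0:
            raise ConfigurationError("impairment_share must lie in [0, 1]")
        if not self.profiles:
            object.__setattr__(self, "profiles", tuple(load_profiles()[1]))
        if self.s > 0 and len(self.profiles) > 1:
            cats = {p.category for p in self.profiles}
            if self.impairment_share > 0 and "impairment" not in cats:
                raise ConfigurationError("no impairment profile but impairment_share > 0")
            if self.impairment_share < 1 and "pre-existing" not in cats:
                raise ConfigurationError("no pre-existing profile but impairment_share < 1")

    @classmethod
    def realworld(cls, **overrides) -> "ScenarioConfig":
        """The mixture scenario with all five packaged comorbidities."""
        return cls(name=overrides.pop("name", "realworld"), **overrides)

    @classmethod
    def single_comorbidity(cls, name: str, **overrides) -> "ScenarioConfig":
        """A scenario where every comorbid patient has the one named condition."""
        profiles = overrides.pop("profiles", None)
        if profiles is None:
            profiles = load_profiles()[1]
        matches = [p for p in profiles if p.name == name]
        if not matches:
            raise ConfigurationError(
                f"unknown comorbidity {name!r}; have {[p.name for p in profiles]}"
            )
        return cls(name=name, profiles=(matches[0],), **overrides)

    def with_(self, **overrides) -> "ScenarioConfig":
        return replace(self, **overrides)

    # --- cached lookup tables for assignment (built lazily, not hashed) ---

    def _category_tables(self):
        cached = getattr(self, "_tables", None)
        if cached is not None:
            return cached
        imps = [p for p in self.profiles if p.category == "impairment"]
        pres = [p for p in self.profiles if p.category == "pre-existing"]
        tables = {}
        for cat, members in (("impairment", imps), ("pre-existing", pres)):
            if members:
                w = np.array([p.prevalence_weight for p in members], dtype=float)
                if w.sum() <= 0:
                    raise ConfigurationError(f"prevalence weights in {cat} sum to 0")
                tables[cat] = (members, np.cumsum(w / w.sum()))
        object.__setattr__(self, "_tables", tables)
        return tables


def assign_comorbidity(
    scenario: ScenarioConfig, rng: np.random.Generator
) -> ComorbidityProfile | None:
    """Draw a comorbidity for one patient, or ``None`` for the healthy group.

    With probability ``1 - s`` the patient has no comorbidity.  Otherwise a
    single-profile scenario returns its profile directly; the mixture
    scenario first picks the category (impairment with probability
    ``impairment_share``) and then a member proportional to prevalence
    weight.
    """
    if rng.random() >= scenario.s:
        return None
    if len(scenario.profiles) == 1:
        return scenario.profiles[0]
    tables = scenario._category_tables()
    cat = "impairment" if rng.random() < scenario.impairment_share else "pre-existing"
    members, cum = tables[cat]
    return members[int(np.searchsorted(cum, rng.random(), side="right"))]


def generate_patient(
    scenario: ScenarioConfig,
    t: int,
    rng: np.random.Generator,
    patient_id: int = 0,
) -> Patient:
    """Generate one patient arriving at time ``t``.

    The death probability is an inverse-CDF draw from the distribution of
    the assigned group; the outcome ``y`` is realized from one further
    uniform draw on [0, 1].  The decision score is ``e * p`` and is never
    clipped — it is used only for ranking.
    """
    profile = assign_comorbidity(scenario, rng)
    params = scenario.baseline if profile is None else profile.params
    p = _ppf_scalar(params, rng.random())
    y = int(rng.random() < p)
    return Patient(
        id=patient_id,
        x=0 if profile is None else 1,
        comorbidity=None if profile is None else profile.name,
        p=p,
        decision_score=scenario.e * p,
        y=y,
        arrival_time=t,
    )


def generate_cohort(
    n: int,
    scenario: ScenarioConfig,
    t: int,
    rng: np.random.Generator,
    start_id: int = 0,
) -> list[Patient]:
    """Generate ``n`` independent patients with consecutive ids."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [
        generate_patient(scenario, t, rng, patient_id=start_id + i)
        for i in range(n)
    ]
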
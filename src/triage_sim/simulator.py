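"""Single-replication ICU simulation under a triage policy.

One replication proceeds in discrete time.  At ``t = 0`` an initial demand
of ``d`` patients competes for ``B`` beds and the policy's initial rule
(random, ex ante, or 90/10 mixed) fills the unit.  At each consecutive time
point ``t = 1..T`` a fresh queue of ``w`` patients arrives and the policy's
consecutive rule reallocates capacity: random exchange of 10% of beds, or
ex post triage, in which treated and queued patients are pooled and the
``B`` patients with the lowest decision scores keep (or take) the beds.
After every step the unit is full and the prospective ICU mortality

    m_t = (1/B) * sum of realized death indicators over treated patients

is recorded, overall and within the groups with and without comorbidities
(each group rate uses the group's own treated count as denominator).
Patients who are never admitted, or are discharged, leave the system; they
are logged but excluded from treated-cohort mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .population import (
    ConfigurationError,
    Patient,
    ScenarioConfig,
    generate_cohort,
)

__all__ = [
    "PolicySpec",
    "POLICIES",
    "ICUState",
    "MetricsRow",
    "CohortMetrics",
    "initial_occupancy",
    "consecutive_step",
    "cohort_mortality",
    "run_replication",
]

INITIAL_RULES = ("random", "exante", "mixed_90_10")
CONSECUTIVE_RULES = ("random", "expost")


@dataclass(frozen=True)
class PolicySpec:
    """A control policy: initial-occupancy rule x consecutive-occupancy rule."""

    policy_id: int
    initial_rule: str
    consecutive_rule: str

    def __post_init__(self) -> None:
        if self.initial_rule not in INITIAL_RULES:
            raise ValueError(f"unknown initial rule {self.initial_rule!r}")
        if self.consecutive_rule not in CONSECUTIVE_RULES:
            raise ValueError(f"unknown consecutive rule {self.consecutive_rule!r}")


#: The six control policies.  Policy 0 is the fully random benchmark;
#: policy 4 (90% random / 10% ex ante initial occupancy, random consecutive
#: occupancy) mirrors current German legislation, which excludes already
#: allocated capacity from triage; policies with the "expost" consecutive
#: rule re-triage treated patients against the queue.
POLICIES: dict[int, PolicySpec] = {
    0: PolicySpec(0, "random", "random"),
    1: PolicySpec(1, "random", "expost"),
    2: PolicySpec(2, "exante", "random"),
    3: PolicySpec(3, "exante", "expost"),
    4: PolicySpec(4, "mixed_90_10", "random"),
    5: PolicySpec(5, "mixed_90_10", "expost"),
}


@dataclass
class ICUState:
    """Treated cohort plus an event log.

    ``treated`` holds exactly ``B`` patients once demand has reached the
    bed count (always true under the default scenarios).  Events are
    ``(t, patient, kind)`` with kind in {"admitted", "discharged",
    "turned_away"}.
    """

    treated: list[Patient]
    time: int = 0
    events: list[tuple[int, Patient, str]] = field(default_factory=list)
    log_events: bool = True

    def _log(self, t: int, patients, kind: str) -> None:
        if self.log_events:
            self.events.extend((t, p, kind) for p in patients)


@dataclass(frozen=True)
class MetricsRow:
    """Mortality and flow counts of the treated cohort at one time point."""

    t: int
    m: float                    # overall prospective ICU mortality
    m_none: float | None        # within patients without comorbidities
    m_com: float | None         # within patients with comorbidities
    n_none: int
    n_com: int
    admitted_none: int = 0
    admitted_com: int = 0
    discharged_none: int = 0
    discharged_com: int = 0
    turned_away_none: int = 0
    turned_away_com: int = 0


CohortMetrics = list  # list[MetricsRow] over t = 0..T


def _score_key(p: Patient) -> tuple[float, int]:
    # deterministic tie-break by id; ties have probability zero under
    # continuous draws but must not depend on list order
    return (p.decision_score, p.id)


def _split_groups(patients) -> tuple[list[Patient], list[Patient]]:
    none = [p for p in patients if p.x == 0]
    com = [p for p in patients if p.x == 1]
    return none, com


def initial_occupancy(
    policy: PolicySpec,
    demand: list[Patient],
    B: int,
    rng: np.random.Generator,
    log_events: bool = True,
) -> ICUState:
    """Fill the ICU at t = 0 from the initial demand.

    random
        ``B`` uniformly random patients are admitted.
    exante
        The ``B`` patients with the lowest decision scores are admitted.
    mixed_90_10
        ``floor(0.9 B)`` beds are filled at random; the remaining beds go
        to the lowest-scoring patients among the rest (ex ante triage of
        the residual 10% of capacity).

    Unselected patients are logged as turned away.
    """
    d = len(demand)
    if d < B:
        raise ConfigurationError(f"initial demand {d} below bed count {B}")
    if policy.initial_rule == "random":
        idx = rng.choice(d, size=B, replace=False)
        chosen = [demand[i] for i in idx]
    elif policy.initial_rule == "exante":
        chosen = sorted(demand, key=_score_key)[:B]
    else:  # mixed_90_10
        n_random = int(np.floor(0.9 * B))
        idx = rng.choice(d, size=n_random, replace=False)
        chosen = [demand[i] for i in idx]
        taken = set(idx.tolist())
        rest = [demand[i] for i in range(d) if i not in taken]
        chosen += sorted(rest, key=_score_key)[: B - n_random]
    chosen_ids = {p.id for p in chosen}
    turned_away = [p for p in demand if p.id not in chosen_ids]
    state = ICUState(treated=chosen, time=0, log_events=log_events)
    state._log(0, chosen, "admitted")
    state._log(0, turned_away, "turned_away")
    return state


def consecutive_step(
    state: ICUState,
    queue: list[Patient],
    policy: PolicySpec,
    rng: np.random.Generator,
    t: int | None = None,
) -> ICUState:
    """Reallocate capacity at one consecutive time point.

    random
        ``k = round(0.1 B)`` treated patients (capped at the queue length)
        are discharged uniformly at random and ``k`` queued patients are
        admitted uniformly at random.
    expost
        Treated and queued patients are pooled and the ``B`` lowest
        decision scores retain/receive the beds; everyone else is
        discharged (if previously treated) or turned away (if queued).

    The treated count is ``B`` before and after the step.
    """
    if not queue:
        raise ConfigurationError("consecutive step requires a non-empty queue")
    B = len(state.treated)
    t = state.time + 1 if t is None else t
    if policy.consecutive_rule == "random":
        k = min(int(round(0.1 * B)), len(queue), B)
        out_idx = set(rng.choice(B, size=k, replace=False).tolist())
        in_idx = set(rng.choice(len(queue), size=k, replace=False).tolist())
        discharged = [state.treated[i] for i in out_idx]
        admitted = [queue[i] for i in in_idx]
        kept = [p for i, p in enumerate(state.treated) if i not in out_idx]
        turned_away = [p for i, p in enumerate(queue) if i not in in_idx]
        new_treated = kept + admitted
    else:  # expost
        pool = state.treated + queue
        keep = sorted(pool, key=_score_key)[:B]
        keep_ids = {p.id for p in keep}
        discharged = [p for p in state.treated if p.id not in keep_ids]
        admitted = [p for p in queue if p.id in keep_ids]
        turned_away = [p for p in queue if p.id not in keep_ids]
        new_treated = keep
    new_state = ICUState(
        treated=new_treated,
        time=t,
        events=state.events,
        log_events=state.log_events,
    )
    new_state._log(t, admitted, "admitted")
    new_state._log(t, discharged, "discharged")
    new_state._log(t, turned_away, "turned_away")
    new_state._step_counts = _group_counts(admitted, discharged, turned_away)
    return new_state


def _group_counts(admitted, discharged, turned_away) -> dict[str, int]:
    def pair(patients):
        com = sum(p.x for p in patients)
        return len(patients) - com, com

    an, ac = pair(admitted)
    dn, dc = pair(discharged)
    tn, tc = pair(turned_away)
    return {
        "admitted_none": an, "admitted_com": ac,
        "discharged_none": dn, "discharged_com": dc,
        "turned_away_none": tn, "turned_away_com": tc,
    }


def cohort_mortality(state: ICUState, **flow_counts) -> MetricsRow:
    """Prospective mortality of the treated cohort, overall and per group.

    Group rates use the group's own treated count as denominator and are
    reported as ``None`` when the group is empty (never as 0).
    """
    treated = state.treated
    B = len(treated)
    none, com = _split_groups(treated)
    deaths_none = sum(p.y for p in none)
    deaths_com = sum(p.y for p in com)
    counts = getattr(state, "_step_counts", {})
    return MetricsRow(
        t=state.time,
        m=(deaths_none + deaths_com) / B,
        m_none=deaths_none / len(none) if none else None,
        m_com=deaths_com / len(com) if com else None,
        n_none=len(none),
        n_com=len(com),
        **{**counts, **flow_counts},
    )


def run_replication(
    scenario: ScenarioConfig,
    policy: PolicySpec | int,
    seed: int | np.random.SeedSequence,
    log_events: bool = False,
    return_events: bool = False,
) -> CohortMetrics:
    """Run one replication and return metrics for t = 0..T.

    The seed spawns two independent sub-streams: one for patient
    generation, one for the policy's random selections.  Because every
    policy consumes the generation stream identically (full demand at
    t = 0, a fresh queue per consecutive time point), policies sharing an
    initial rule see the same initial cohort and produce identical t = 0
    metrics for the same seed, and varying only the misestimation factor
    ``e`` leaves every admission decision unchanged.
    """
    if isinstance(policy, int):
        policy = POLICIES[policy]
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    gen_ss, pol_ss = ss.spawn(2)
    rng_gen = np.random.default_rng(gen_ss)
    rng_pol = np.random.default_rng(pol_ss)

    demand = generate_cohort(scenario.d, scenario, 0, rng_gen)
    state = initial_occupancy(policy, demand, scenario.B, rng_pol, log_events=log_events)
    none, com = _split_groups(state.treated)
    metrics: CohortMetrics = [
        cohort_mortality(
            state,
            admitted_none=len(none),
            admitted_com=len(com),
            turned_away_none=sum(1 for p in demand if p.x == 0) - len(none),
            turned_away_com=sum(1 for p in demand if p.x == 1) - len(com),
        )
    ]
    next_id = scenario.d
    for t in range(1, scenario.T + 1):
        queue = generate_cohort(scenario.w, scenario, t, rng_gen, start_id=next_id)
        next_id += scenario.w
        state = consecutive_step(state, queue, policy, rng_pol, t=t)
        metrics.append(cohort_mortality(state))
    if return_events:
        return metrics, state.events
    return metrics
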
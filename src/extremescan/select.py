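"""Case stratification and extreme-group selection.

Instead of modelling the full survival curve, the method compares the
earliest events against the longest survivors: two equal-sized groups taken
from the two ends of the ordered survival spectrum, never defined by
arbitrary time cut-offs. Group membership is purely rank-based, so heavily
right-censored intermediate cases are simply unused, and long-follow-up
censored cases are legitimate members of the survivor extreme (their
observed time is a lower bound on true survival).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import CohortTable

logger = logging.getLogger(__name__)


@dataclass
class SelectionCriteria:
    """Clinical stratification plus extreme-group sizing.

    ``core_size`` (k) is the size of the groups entering the primary
    comparison; ``extended_size`` (m >= k) the size of the ordered pools the
    sliding windows draw from. ``skip_initial_events`` drops the very first
    events before forming the early group (perioperative deaths unlikely to
    reflect tumour progression).
    """

    include_stages: frozenset[str] | None = None
    require_no_adjuvant: bool = False
    subtype_requirements: dict[str, bool] = field(default_factory=dict)
    core_size: int = 20
    extended_size: int = 40
    skip_initial_events: int = 0
    early_group_requires_event: bool = True

    def __post_init__(self) -> None:
        if self.core_size < 1:
            raise ValueError("core_size must be positive")
        if self.extended_size < self.core_size:
            raise ValueError("extended_size must be >= core_size")
        if self.skip_initial_events < 0:
            raise ValueError("skip_initial_events must be non-negative")
        if self.include_stages is not None:
            self.include_stages = frozenset(self.include_stages)


@dataclass
class ExtremeGroups:
    """Ordered extreme-group memberships.

    ``early_*`` lists are in ascending time order (earliest event first),
    ``late_*`` in descending time order (longest follow-up first); the
    ordering is what the window generators slide over. Cores are prefixes of
    the extended groups.
    """

    early_core: list[str]
    late_core: list[str]
    early_extended: list[str]
    late_extended: list[str]
    censoring_summary: dict[str, int]

    def __post_init__(self) -> None:
        k, m = len(self.early_core), len(self.early_extended)
        if len(self.late_core) != k or len(self.late_extended) != m:
            raise ValueError("early/late group sizes differ")
        if self.early_core != self.early_extended[:k]:
            raise ValueError("early_core is not a prefix of early_extended")
        if self.late_core != self.late_extended[:k]:
            raise ValueError("late_core is not a prefix of late_extended")
        if set(self.early_extended) & set(self.late_extended):
            raise ValueError("extreme groups overlap")


def apply_strata(cohort: CohortTable, criteria: SelectionCriteria) -> CohortTable:
    """Drop records failing any clinical criterion; log per-criterion counts."""
    kept = list(cohort.records)
    exclusions: dict[str, int] = {}

    if criteria.include_stages is not None:
        before = len(kept)
        kept = [r for r in kept if r.stage in criteria.include_stages]
        exclusions["stage"] = before - len(kept)
    if criteria.require_no_adjuvant:
        before = len(kept)
        kept = [r for r in kept if r.adjuvant_therapy is False]
        exclusions["adjuvant_therapy"] = before - len(kept)
    for flag, required in criteria.subtype_requirements.items():
        before = len(kept)
        kept = [r for r in kept if r.subtype_flags.get(flag) is required]
        exclusions[f"flag:{flag}"] = before - len(kept)

    logger.info("apply_strata: %d -> %d records, exclusions %s", len(cohort), len(kept), exclusions)
    if not kept:
        raise ValueError(f"no records satisfy criteria (exclusions: {exclusions}); relax them")
    return CohortTable(kept)


def select_extremes(cohort: CohortTable, criteria: SelectionCriteria) -> ExtremeGroups:
    """Pick the ordered early-event and long-survivor extremes.

    Early pool: event cases sorted by ascending time (events before censored
    on ties, then stable input order), after skipping the first
    ``skip_initial_events`` events. Late pool: all cases sorted by descending
    time (censored records eligible — long follow-up censored survivors
    count), ties broken by stable input order. The two extended pools must be
    time-separated and disjoint.
    """
    k, m = criteria.core_size, criteria.extended_size
    records = list(cohort.records)
    order = {r.sample_id: i for i, r in enumerate(records)}

    early_pool = [r for r in records if r.event] if criteria.early_group_requires_event else records
    early_sorted = sorted(early_pool, key=lambda r: (r.time, not r.event, order[r.sample_id]))
    early_sorted = early_sorted[criteria.skip_initial_events:]
    late_sorted = sorted(records, key=lambda r: (-r.time, order[r.sample_id]))

    if len(early_sorted) < m:
        raise ValueError(
            f"only {len(early_sorted)} eligible early cases, need {m} "
            f"(after skipping {criteria.skip_initial_events} events)"
        )
    if len(late_sorted) < m:
        raise ValueError(f"only {len(late_sorted)} cases for the late extreme, need {m}")

    early_ext = early_sorted[:m]
    late_ext = late_sorted[:m]
    overlap = {r.sample_id for r in early_ext} & {r.sample_id for r in late_ext}
    if overlap:
        raise ValueError(
            f"extreme groups overlap ({len(overlap)} cases, e.g. {sorted(overlap)[:3]}); "
            "the cohort is too small for the requested group sizes"
        )
    if max(r.time for r in early_ext) >= min(r.time for r in late_ext):
        raise ValueError(
            "early and late extended groups are not time-separated: "
            f"max early time {max(r.time for r in early_ext)} >= "
            f"min late time {min(r.time for r in late_ext)}"
        )

    groups = ExtremeGroups(
        early_core=[r.sample_id for r in early_ext[:k]],
        late_core=[r.sample_id for r in late_ext[:k]],
        early_extended=[r.sample_id for r in early_ext],
        late_extended=[r.sample_id for r in late_ext],
        censoring_summary={
            "early_core_censored": sum(not r.event for r in early_ext[:k]),
            "early_extended_censored": sum(not r.event for r in early_ext),
            "late_core_censored": sum(not r.event for r in late_ext[:k]),
            "late_extended_censored": sum(not r.event for r in late_ext),
        },
    )
    logger.info(
        "select_extremes: k=%d m=%d, censoring %s", k, m, groups.censoring_summary
    )
    return groups
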
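"""Potential reproductive lifetime output (PRLO) projection.

A female's lifetime output is projected by counting reproductive events from
the age at her first event up to the last possible age, stepping through
inter-event intervals (a fixed cycle, an explicit interval sequence, or a
stochastic biennial/triennial mixture), then multiplying the event count by
the litter size. Comparing a strict biennial schedule with one that mixes in
triennial cycles quantifies the fecundity cost of triennial reproduction.

Default parameters (first event at 20 y, last possible at 54 y, 34 pups per
litter) reproduce the reference projection of 18 biennial events = 612 pups
versus 16 mixed-schedule events = 544 pups, an 11.1% reduction; they are
plain config values, not constants of the method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_AGE_FIRST = 20.0
DEFAULT_AGE_LAST = 54.0
DEFAULT_LITTER_SIZE = 34.0


@dataclass(frozen=True)
class PRLOParams:
    """Reproductive schedule driving a lifetime-output projection.

    ``schedule`` is a fixed interval in years (number), an explicit interval
    sequence (list/tuple), or ``("mixture", p_triennial)`` drawing each
    interval independently as 3 y with probability ``p_triennial`` else 2 y.
    """

    age_first_event: float = DEFAULT_AGE_FIRST
    age_last_possible: float = DEFAULT_AGE_LAST
    litter_size: float = DEFAULT_LITTER_SIZE
    schedule: object = 2

    def __post_init__(self):
        if self.age_first_event > self.age_last_possible:
            raise ValueError(
                f"age_first_event ({self.age_first_event}) exceeds "
                f"age_last_possible ({self.age_last_possible})"
            )
        if self.litter_size <= 0:
            raise ValueError("litter_size must be positive")
        if self.is_mixture and not 0.0 <= self.p_triennial <= 1.0:
            raise ValueError("p_triennial must lie in [0, 1]")

    @property
    def is_mixture(self) -> bool:
        return isinstance(self.schedule, tuple) and len(self.schedule) == 2 and (
            self.schedule[0] == "mixture"
        )

    @property
    def p_triennial(self) -> float:
        if not self.is_mixture:
            raise AttributeError("not a mixture schedule")
        return float(self.schedule[1])


@dataclass(frozen=True)
class PRLOResult:
    n_events: float
    total_pups: float
    schedule_label: str


def reproductive_events(params: PRLOParams) -> int:
    """Count events at ages first, first+i1, first+i1+i2, ... while <= last.

    For a fixed interval k this is ``1 + floor(span / k)``; an explicit
    sequence is walked until it runs out or the last possible age is passed.
    """
    span = params.age_last_possible - params.age_first_event
    if isinstance(params.schedule, (int, float)):
        if params.schedule <= 0:
            raise ValueError("fixed interval must be positive")
        return 1 + int(np.floor(span / float(params.schedule) + 1e-12))
    if params.is_mixture:
        raise ValueError("mixture schedules require expected_prlo_mixture")
    age, n = 0.0, 1
    for interval in params.schedule:
        if interval <= 0:
            raise ValueError("intervals must be positive")
        age += interval
        if age > span:
            break
        n += 1
    return n


def prlo_total(params: PRLOParams) -> PRLOResult:
    """Total projected pups = reproductive events x litter size."""
    n = reproductive_events(params)
    label = (
        f"fixed-{params.schedule}y"
        if isinstance(params.schedule, (int, float))
        else "explicit-sequence"
    )
    return PRLOResult(n_events=n, total_pups=n * params.litter_size,
                      schedule_label=label)


def prlo_reduction(reference: PRLOResult, alternative: PRLOResult) -> float:
    """Percent reduction of the alternative schedule vs the reference.

    Reported to one decimal: (612, 544) -> 11.1.
    """
    if reference.total_pups <= 0:
        raise ValueError("reference projection must have positive output")
    return round(
        100.0 * (reference.total_pups - alternative.total_pups)
        / reference.total_pups,
        1,
    )


def expected_prlo_mixture(
    params: PRLOParams, n_draws: int = 100_000, seed: int | None = None
) -> dict:
    """Monte-Carlo mean lifetime output under a biennial/triennial mixture.

    Each draw samples inter-event intervals independently (3 y with
    probability ``p_triennial``, else 2 y) until the last possible age is
    passed. Degenerate mixtures (p in {0, 1}) collapse exactly to the
    corresponding fixed schedule. The closed-form expected interval,
    ``2 + p_triennial``, is returned as a consistency check.
    """
    p = params.p_triennial
    span = params.age_last_possible - params.age_first_event
    rng = np.random.default_rng(seed)
    max_cycles = int(np.ceil(span / 2.0)) + 1
    if p in (0.0, 1.0):
        fixed = PRLOParams(
            params.age_first_event,
            params.age_last_possible,
            params.litter_size,
            3 if p == 1.0 else 2,
        )
        n = reproductive_events(fixed)
        events = np.full(n_draws, n, dtype=float)
    else:
        intervals = np.where(
            rng.random((n_draws, max_cycles)) < p, 3.0, 2.0
        )
        ages = np.cumsum(intervals, axis=1)
        events = 1.0 + (ages <= span + 1e-12).sum(axis=1)
    pups = events * params.litter_size
    mean_events = float(events.mean())
    se = float(events.std(ddof=1) / np.sqrt(n_draws)) if n_draws > 1 else 0.0
    return {
        "p_triennial": p,
        "mean_events": mean_events,
        "mean_pups": float(pups.mean()),
        "events_ci95": (mean_events - 1.96 * se, mean_events + 1.96 * se),
        "expected_interval_years": 2.0 + p,
        "n_draws": n_draws,
    }
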
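"""Expected-event bookkeeping under stagewise-uniform accrual and exponential survival.

The design calculus is a deterministic "fluid" approximation: patients enter
one arm at a piecewise-constant rate, fail with a constant hazard, and we track
the expected number of events e(t) and the expected number still at risk N(t).
Because the exponential distribution is memoryless, both quantities satisfy
simple stage-by-stage recurrences, and the inverse problem (the calendar time
at which a target number of events is expected) can be solved by
Newton-Raphson using the exact derivative e'(t) = lambda * N(t).

No loss to follow-up is modelled, so N(t) + e(t) equals the number of patients
recruited by time t exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AccrualSchedule",
    "ExponentialSurvival",
    "expected_events_uniform",
    "advance_state",
    "events_at",
    "at_risk_at",
    "time_for_events",
    "total_patients",
]

#: absolute tolerance (in events) for the events -> time inversion
EVENT_TOL = 1e-6
_MAX_NEWTON = 100


@dataclass(frozen=True)
class ExponentialSurvival:
    """Exponential time-to-event distribution with hazard ``lam`` (> 0)."""

    lam: float

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError(f"hazard must be positive, got {self.lam}")

    @classmethod
    def from_median(cls, median: float) -> "ExponentialSurvival":
        return cls(np.log(2.0) / median)

    @property
    def median(self) -> float:
        return np.log(2.0) / self.lam

    def survival(self, t: float) -> float:
        return float(np.exp(-self.lam * t))

    def cdf(self, t: float) -> float:
        return float(-np.expm1(-self.lam * t))


@dataclass(frozen=True)
class AccrualSchedule:
    """Piecewise-constant one-arm accrual.

    Parameters
    ----------
    rates
        Accrual rates (patients per time-unit) for stages 1..k.  The last
        stage is open-ended unless ``recruit_stop`` is set.
    boundaries
        End times of stages 1..k-1 (strictly increasing, starting after 0).
        ``len(boundaries) == len(rates) - 1``.
    recruit_stop
        Optional calendar time t* after which the rate drops to zero.  Must
        lie strictly after the last boundary (i.e. inside the final stage).
    """

    rates: tuple[float, ...]
    boundaries: tuple[float, ...] = field(default=())
    recruit_stop: float | None = None

    def __post_init__(self) -> None:
        rates = tuple(float(r) for r in self.rates)
        bounds = tuple(float(b) for b in self.boundaries)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "boundaries", bounds)
        if len(bounds) != len(rates) - 1:
            raise ValueError(
                f"need len(boundaries) == len(rates) - 1, got {len(bounds)} and {len(rates)}"
            )
        if any(r < 0 for r in rates):
            raise ValueError("accrual rates must be non-negative")
        ts = (0.0,) + bounds
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("stage boundaries must be strictly increasing and positive")
        if self.recruit_stop is not None and bounds and self.recruit_stop <= bounds[-1]:
            raise ValueError(
                "recruit_stop must fall strictly inside the final stage "
                f"(after t={bounds[-1]}); stopping recruitment during an "
                "intermediate stage would make later looks redundant"
            )

    def rate_at(self, t: float) -> float:
        if self.recruit_stop is not None and t >= self.recruit_stop:
            return 0.0
        i = int(np.searchsorted(self.boundaries, t, side="right"))
        return self.rates[i]

    def recruits_by(self, t: float) -> float:
        """Cumulative number of patients entered on (0, t]."""
        if t <= 0:
            return 0.0
        t_eff = t if self.recruit_stop is None else min(t, self.recruit_stop)
        total = 0.0
        start = 0.0
        for i, r in enumerate(self.rates):
            end = self.boundaries[i] if i < len(self.boundaries) else np.inf
            d = min(t_eff, end) - start
            if d <= 0:
                break
            total += r * d
            start = end
        return total


def expected_events_uniform(r: float, lam: float, t: float) -> float:
    """Expected events by time t with uniform entry at rate r on (0, t] and
    exponential failure with hazard lam: ``r*t - (r/lam)*(1 - exp(-lam*t))``."""
    if r < 0 or lam <= 0:
        raise ValueError("rate must be >= 0 and hazard > 0")
    if t < 0:
        raise ValueError(f"negative duration t={t}")
    return r * (t + np.expm1(-lam * t) / lam)


def advance_state(
    n_risk: float, e_cum: float, r: float, lam: float, d: float
) -> tuple[float, float]:
    """Advance (at-risk, cumulative-events) across one stage of duration d.

    Existing at-risk patients decay by the survival fraction S(d); recruits
    entering uniformly at rate r contribute ``r*d`` patients of whom
    ``expected_events_uniform(r, lam, d)`` have failed by the stage end.
    Valid because the exponential distribution is memoryless.
    """
    if d < 0:
        raise ValueError(f"negative stage duration d={d}")
    if d == 0:
        return n_risk, e_cum
    surv = np.exp(-lam * d)
    new_events = expected_events_uniform(r, lam, d)
    e_next = e_cum + n_risk * (1.0 - surv) + new_events
    n_next = n_risk * surv + (r * d - new_events)
    return n_next, e_next


def _state_at(t: float, schedule: AccrualSchedule, lam: float) -> tuple[float, float]:
    """(N(t), e(t)) by chaining advance_state through stages, honouring t*."""
    if t <= 0:
        return 0.0, 0.0
    # breakpoints where the effective rate changes
    cuts = list(schedule.boundaries)
    if schedule.recruit_stop is not None:
        cuts.append(schedule.recruit_stop)
    cuts = sorted(c for c in set(cuts) if c < t)
    n_risk, e_cum = 0.0, 0.0
    start = 0.0
    for c in cuts + [t]:
        r = schedule.rate_at(0.5 * (start + c))
        n_risk, e_cum = advance_state(n_risk, e_cum, r, lam, c - start)
        start = c
    return n_risk, e_cum


def events_at(t: float, schedule: AccrualSchedule, lam: float) -> float:
    """Expected cumulative events at calendar time t.

    Beyond the last boundary the final-stage rate (or zero after t*) applies,
    so the curve extrapolates smoothly; as t -> infinity with recruitment
    stopped, e(t) converges to the number of patients recruited.
    """
    if t < 0:
        raise ValueError(f"negative time t={t}")
    return _state_at(t, schedule, lam)[1]


def at_risk_at(t: float, schedule: AccrualSchedule, lam: float) -> float:
    """Expected number of patients at risk at calendar time t."""
    if t < 0:
        raise ValueError(f"negative time t={t}")
    return _state_at(t, schedule, lam)[0]


def time_for_events(
    e_target: float,
    schedule: AccrualSchedule,
    lam: float,
    t_floor: float = 0.0,
) -> float:
    """Calendar time at which the expected event count reaches ``e_target``.

    Newton-Raphson on g(t) = e(t) - e_target with g'(t) = lam * N(t) (event
    intensity = hazard x number at risk), started at t_floor + half a median;
    any step leaving the bracketing interval falls back to bisection.

    Raises
    ------
    ValueError
        If the target exceeds the asymptotic event total (recruitment stopped
        and everyone recruited would still be too few): the design is
        infeasible.
    """
    if e_target <= 0:
        raise ValueError(f"event target must be positive, got {e_target}")
    if schedule.recruit_stop is not None or schedule.rates[-1] == 0.0:
        # finite asymptote: every recruit eventually fails
        horizon = schedule.recruit_stop if schedule.recruit_stop is not None else np.inf
        asymptote = schedule.recruits_by(min(horizon, 1e12))
        if e_target > asymptote - EVENT_TOL:
            raise ValueError(
                f"design infeasible: event target {e_target} exceeds the "
                f"{asymptote:.1f} patients ever recruited"
            )

    median = np.log(2.0) / lam

    def g(t: float) -> float:
        return events_at(t, schedule, lam) - e_target

    # bracket [lo, hi] with g(lo) <= 0 <= g(hi)
    lo = max(t_floor, 0.0)
    if g(lo) >= 0.0:
        return lo
    hi = lo + median
    for _ in range(200):
        if g(hi) >= 0.0:
            break
        lo = hi
        hi += max(median, 0.5 * (hi - t_floor))
    else:  # pragma: no cover - guarded by feasibility check above
        raise RuntimeError("failed to bracket the event target")

    t = min(max(t_floor + 0.5 * median, lo), hi)
    for _ in range(_MAX_NEWTON):
        gt = g(t)
        if abs(gt) < EVENT_TOL:
            return t
        if gt > 0:
            hi = min(hi, t)
        else:
            lo = max(lo, t)
        deriv = lam * at_risk_at(t, schedule, lam)
        step_ok = deriv > 0 and np.isfinite(deriv)
        t_new = t - gt / deriv if step_ok else np.nan
        if not np.isfinite(t_new) or not (lo < t_new < hi):
            t_new = 0.5 * (lo + hi)  # bisection fallback
        t = t_new
    raise RuntimeError(
        f"event-time inversion did not converge to {EVENT_TOL} events "
        f"within {_MAX_NEWTON} iterations"
    )


def total_patients(schedule: AccrualSchedule, allocation: float, t_stop: float) -> float:
    """Total patients (both arms) recruited by ``t_stop``: (1+A) x control recruits."""
    if allocation <= 0:
        raise ValueError("allocation ratio must be positive")
    return (1.0 + allocation) * schedule.recruits_by(t_stop)
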
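"""Core design solver: per-stage critical hazard ratios and event targets.

A two-arm multi-stage (TAMS) design screens an experimental arm E against a
control arm C for lack of benefit at s - 1 interim looks on an intermediate
time-to-event outcome I, followed by a definitive analysis on outcome D at
stage s.  At stage i the trial stops for lack of benefit if the estimated
hazard ratio exceeds a critical value delta_i chosen so that, under the null
HR Delta0_i, the probability of the estimate falling below delta_i is exactly
the stagewise one-sided significance level alpha_i:

    ln delta_i = ln Delta0_i + Phi^-1(alpha_i) * sigma0_i,

with sigma0_i^2 = (1 + 1/A) / e_i the approximate null variance of the log-HR
at e_i cumulative control-arm events (allocation ratio A).  The event target
e_i is the smallest integer for which the attained marginal power

    Phi((ln delta_i - ln Delta1_i) / sigma1_i),
    sigma1_i^2 = 1/e_i + 1/e*_i,

reaches the nominal power omega_i, where e*_i is the expected number of
experimental-arm events under the alternative by the calendar time t_i at
which the control arm shows e_i events.  Interim analyses are triggered by
control-arm event counts, so the stage times are the same under either
hypothesis.  Stage times assume exponential survival and stagewise-uniform
accrual (see :mod:`tamsdesign.accrual`); the event targets themselves only
require proportional hazards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .accrual import AccrualSchedule, events_at, time_for_events, total_patients

__all__ = [
    "DesignSpec",
    "StagePlan",
    "DesignResult",
    "variance_null",
    "variance_alt",
    "critical_hr",
    "attained_power",
    "initial_events",
    "solve_stage",
    "build_design",
]

_MAX_EVENT_ITER = 10**6


def _as_stage_vector(x, s: int, name: str) -> tuple[float, ...]:
    """Broadcast a scalar to s stages, or validate a length-s sequence."""
    if np.isscalar(x):
        return (float(x),) * s
    vec = tuple(float(v) for v in x)
    if len(vec) != s:
        raise ValueError(f"{name} must have length {s}, got {len(vec)}")
    return vec


@dataclass(frozen=True)
class DesignSpec:
    """User-facing parameter bundle for a TAMS design.

    Parameters
    ----------
    alpha, omega
        Stagewise one-sided significance levels and powers; length s.
        The alpha must be strictly descending, otherwise later stages are
        redundant.
    hr_null, hr_alt
        Null and alternative hazard ratios per stage (scalars broadcast).
        Taking the same alternative HR on I- and D-stages is the conservative
        default; a more optimistic I-stage effect may be supplied per stage.
    allocation
        Experimental-arm patients per control-arm patient (A).
    accrual
        Stagewise accrual rates, patients per time-unit; interpreted on the
        arm given by ``accrual_basis`` ("control": control-arm rate, the
        natural parameter; "total": whole-trial rate, divided by 1 + A).
    hazard_I, hazard_D
        Exponential hazards of the intermediate and definitive outcomes in
        the control arm (alternatively pass ``median_I`` / ``median_D`` to
        :meth:`from_medians`).
    recruit_stop
        Optional calendar time t* at which recruitment halts; must fall in
        the final stage.
    attenuation
        Cross-outcome correlation attenuation factor c in (0, 1] used by the
        operating-characteristics module; 0.6 by default.
    """

    n_stages: int
    alpha: tuple[float, ...]
    omega: tuple[float, ...]
    hr_alt: tuple[float, ...]
    hr_null: tuple[float, ...] = ()
    allocation: float = 1.0
    accrual: tuple[float, ...] = ()
    hazard_I: float = 0.0
    hazard_D: float = 0.0
    recruit_stop: float | None = None
    attenuation: float = 0.6
    accrual_basis: str = "control"

    def __post_init__(self) -> None:
        s = self.n_stages
        if s < 1:
            raise ValueError("need at least one stage")
        object.__setattr__(self, "alpha", _as_stage_vector(self.alpha, s, "alpha"))
        object.__setattr__(self, "omega", _as_stage_vector(self.omega, s, "omega"))
        object.__setattr__(self, "hr_alt", _as_stage_vector(self.hr_alt, s, "hr_alt"))
        hr_null = self.hr_null if (self.hr_null or np.isscalar(self.hr_null)) else 1.0
        object.__setattr__(self, "hr_null", _as_stage_vector(hr_null, s, "hr_null"))
        accrual = self.accrual
        if np.isscalar(accrual) or len(accrual) > 0:
            object.__setattr__(self, "accrual", _as_stage_vector(accrual, s, "accrual"))
        else:
            raise ValueError("accrual rates are required")

        if not all(0 < a < 1 for a in self.alpha):
            raise ValueError("alpha values must lie in (0, 1)")
        if not all(0 < w < 1 for w in self.omega):
            raise ValueError("omega values must lie in (0, 1)")
        if any(b >= a for a, b in zip(self.alpha, self.alpha[1:])):
            raise ValueError(
                "stagewise significance levels must be strictly descending; "
                "non-descending alpha make some stages redundant"
            )
        if any(h <= 0 for h in self.hr_null):
            raise ValueError("null hazard ratios must be positive")
        if any(not 0 < h1 < h0 for h0, h1 in zip(self.hr_null, self.hr_alt)):
            raise ValueError("need 0 < hr_alt < hr_null at every stage")
        if self.allocation <= 0:
            raise ValueError("allocation ratio must be positive")
        if any(r <= 0 for r in self.accrual):
            raise ValueError("accrual rates must be positive")
        if self.hazard_I <= 0 or self.hazard_D <= 0:
            raise ValueError("hazards must be positive")
        if not 0 < self.attenuation <= 1:
            raise ValueError("attenuation factor c must lie in (0, 1]")
        if self.accrual_basis not in ("control", "total"):
            raise ValueError("accrual_basis must be 'control' or 'total'")
        if s > 6:
            warnings.warn(
                f"{s}-stage design requested; more than 6 stages are rarely "
                "of practical value",
                stacklevel=3,
            )
        if self.hazard_I < self.hazard_D:
            warnings.warn(
                "intermediate-outcome hazard is smaller than the definitive "
                "one; I-events should occur at least as often as D-events",
                stacklevel=3,
            )

    @classmethod
    def from_medians(
        cls,
        n_stages: int,
        alpha,
        omega,
        hr_alt,
        median_I: float,
        median_D: float,
        **kwargs,
    ) -> "DesignSpec":
        """Construct a spec from median survival times (hazard = ln 2 / median)."""
        return cls(
            n_stages=n_stages,
            alpha=alpha,
            omega=omega,
            hr_alt=hr_alt,
            hazard_I=math.log(2.0) / median_I,
            hazard_D=math.log(2.0) / median_D,
            **kwargs,
        )

    @property
    def control_accrual(self) -> tuple[float, ...]:
        if self.accrual_basis == "total":
            return tuple(r / (1.0 + self.allocation) for r in self.accrual)
        return self.accrual

    def stage_hazard(self, i: int) -> float:
        """Control-arm hazard of the outcome analysed at stage i (1-based)."""
        return self.hazard_I if i < self.n_stages else self.hazard_D


@dataclass(frozen=True)
class StagePlan:
    """Solved quantities for one stage (1-based ``index``)."""

    index: int
    outcome_kind: str  # "I" for interim looks, "D" for the definitive stage
    alpha: float
    omega: float
    delta: float
    e_control: int
    e_exp_alt: float
    t_end: float
    duration: float
    n_control: float
    n_total: float
    power_marginal: float
    degenerate: bool = False

    @property
    def e_total_alt(self) -> float:
        """Expected total events (both arms) under H1 at the stage end."""
        return self.e_control + self.e_exp_alt


@dataclass(frozen=True)
class DesignResult:
    stages: tuple[StagePlan, ...]
    spec: DesignSpec
    total_patients: float
    degenerate: bool = False
    message: str = ""

    @property
    def e_control(self) -> tuple[int, ...]:
        return tuple(st.e_control for st in self.stages)

    @property
    def deltas(self) -> tuple[float, ...]:
        return tuple(st.delta for st in self.stages)

    @property
    def times(self) -> tuple[float, ...]:
        return tuple(st.t_end for st in self.stages)

    @property
    def attained_powers(self) -> tuple[float, ...]:
        return tuple(st.power_marginal for st in self.stages)

    def to_frame(self):
        """Stage table as a pandas DataFrame (one row per stage)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "stage": [st.index for st in self.stages],
                "outcome": [st.outcome_kind for st in self.stages],
                "alpha": [st.alpha for st in self.stages],
                "omega": [st.omega for st in self.stages],
                "delta": [st.delta for st in self.stages],
                "e_control": [st.e_control for st in self.stages],
                "e_total": [st.e_total_alt for st in self.stages],
                "t_end": [st.t_end for st in self.stages],
                "duration": [st.duration for st in self.stages],
                "n_cumulative": [st.n_total for st in self.stages],
                "power_attained": [st.power_marginal for st in self.stages],
            }
        )


def variance_null(e: float, allocation: float) -> float:
    """Approximate variance of the log-HR under H0: ``(1 + 1/A) / e`` with e
    cumulative control-arm events and A the allocation ratio."""
    if e <= 0 or allocation <= 0:
        raise ValueError("event count and allocation ratio must be positive")
    return (1.0 + 1.0 / allocation) / e


def variance_alt(e_control: float, e_exp: float) -> float:
    """Variance of the log-HR under H1: sum of reciprocal per-arm event counts."""
    if e_control <= 0 or e_exp <= 0:
        raise ValueError("per-arm event counts must be positive")
    return 1.0 / e_control + 1.0 / e_exp


def critical_hr(alpha: float, sigma0: float, hr_null: float = 1.0) -> float:
    """Critical hazard ratio delta with P(estimate < delta | H0) = alpha."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    return float(hr_null * np.exp(norm.ppf(alpha) * sigma0))


def attained_power(delta: float, hr_alt: float, sigma1: float) -> float:
    """Marginal probability under H1 that the estimate falls below delta."""
    if sigma1 <= 0:
        raise ValueError("sigma1 must be positive")
    return float(norm.cdf((np.log(delta) - np.log(hr_alt)) / sigma1))


def initial_events(
    alpha: float, omega: float, hr_null: float, hr_alt: float, allocation: float
) -> int:
    """Closed-form starting value for the control-arm event target.

    ``ceil[(1 + 1/A) (z_omega - z_alpha)^2 / ln(Delta0/Delta1)^2]``, clamped
    to >= 1.  This undershoots slightly (it ignores the smaller experimental
    event count under H1); the power loop then increments to the final target.
    """
    if hr_alt >= hr_null:
        raise ValueError("need hr_alt < hr_null")
    num = (1.0 + 1.0 / allocation) * (norm.ppf(omega) - norm.ppf(alpha)) ** 2
    den = np.log(hr_null / hr_alt) ** 2
    return max(1, int(np.ceil(num / den)))


def solve_stage(
    spec: DesignSpec, i: int, previous: tuple[StagePlan, ...] = ()
) -> StagePlan:
    """Solve stage ``i`` (1-based) given the solved earlier stages.

    Iterates: event target -> critical HR -> stage time (control-arm event
    curve) -> expected experimental events under H1 -> attained power;
    increments the integer event target by one until the nominal power is
    reached, which guarantees the target is minimal.
    """
    if len(previous) != i - 1:
        raise ValueError(f"stage {i} needs exactly {i - 1} previous stage plans")
    s = spec.n_stages
    lam = spec.stage_hazard(i)
    alpha_i, omega_i = spec.alpha[i - 1], spec.omega[i - 1]
    hr0, hr1 = spec.hr_null[i - 1], spec.hr_alt[i - 1]
    A = spec.allocation
    r_ctrl = spec.control_accrual[: i]
    t_prev = previous[-1].t_end if previous else 0.0
    bounds = tuple(st.t_end for st in previous)
    recruit_stop = spec.recruit_stop if i == s else None

    ctrl_sched = AccrualSchedule(r_ctrl, bounds, recruit_stop)
    exp_sched = AccrualSchedule(
        tuple(A * r for r in r_ctrl),
        bounds,
        recruit_stop,
    )

    e = initial_events(alpha_i, omega_i, hr0, hr1, A)
    if i < s:  # cumulative I-event targets must increase look to look
        prev_same = [st.e_control for st in previous if st.outcome_kind == "I"]
        if prev_same:
            e = max(e, prev_same[-1] + 1)

    for _ in range(_MAX_EVENT_ITER):
        sigma0 = math.sqrt(variance_null(e, A))
        delta = critical_hr(alpha_i, sigma0, hr0)
        t_i = time_for_events(e, ctrl_sched, lam, t_floor=t_prev)
        e_star = events_at(t_i, exp_sched, hr1 * lam)
        sigma1 = math.sqrt(variance_alt(e, e_star))
        power = attained_power(delta, hr1, sigma1)
        if power >= omega_i:
            break
        e += 1
    else:
        raise RuntimeError(
            f"stage {i}: event/power iteration failed to converge within "
            f"{_MAX_EVENT_ITER} increments"
        )

    duration = t_i - t_prev
    degenerate = duration <= 1e-9
    n_control = ctrl_sched.recruits_by(t_i)
    return StagePlan(
        index=i,
        outcome_kind="I" if i < s else "D",
        alpha=alpha_i,
        omega=omega_i,
        delta=delta,
        e_control=e,
        e_exp_alt=e_star,
        t_end=t_i,
        duration=duration,
        n_control=n_control,
        n_total=(1.0 + A) * n_control,
        power_marginal=power,
        degenerate=degenerate,
    )


def build_design(spec: DesignSpec) -> DesignResult:
    """Solve all stages of a TAMS design.

    Stages 1..s-1 are interim looks on the intermediate outcome; stage s is
    the definitive analysis.  A single-stage spec reduces to a conventional
    one-look trial.  A stage of non-positive duration (its event target is
    already met when the previous look fires) marks the design degenerate but
    is not fatal, matching the behaviour of the published designs.
    """
    stages: list[StagePlan] = []
    for i in range(1, spec.n_stages + 1):
        stages.append(solve_stage(spec, i, tuple(stages)))

    sched = AccrualSchedule(
        spec.control_accrual,
        tuple(st.t_end for st in stages[:-1]),
        spec.recruit_stop,
    )
    n_total = total_patients(sched, spec.allocation, stages[-1].t_end)
    degenerate = any(st.degenerate for st in stages)
    msg = ""
    if degenerate:
        bad = [st.index for st in stages if st.degenerate]
        msg = (
            f"degenerate design: stage(s) {bad} have zero length; the event "
            "target is reached before the previous look"
        )
    return DesignResult(
        stages=tuple(stages),
        spec=spec,
        total_patients=n_total,
        degenerate=degenerate,
        message=msg,
    )
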
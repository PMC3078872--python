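"""Monte-Carlo validation engine: whole-trial simulation of multi-stage designs.

Each replicate recruits patients at the design's stagewise rates, assigns
correlated intermediate/definitive outcome times, and applies the stopping
rule look by look.  Looks are event-driven: look i fires at the calendar
time when the control arm shows its e_i-th triggering-outcome event (the
intermediate outcome for i < s, the definitive outcome at i = s); the
planned stage times t_i are planning quantities only and play no role.
At each look the log hazard ratio is estimated by Cox partial likelihood on
the data visible at that time, and the trial continues iff the estimated HR
does not exceed the stage's critical value.

Summaries over replicates give empirical stagewise conditional pass
probabilities, overall significance level / power, cross-stage correlations
of the log-HR estimates (and hence the attenuation factor c), and the
information fraction at stopping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .coxfit import fit_cox_binary
from .design import DesignResult, variance_alt, variance_null
from .outcomes import OutcomeModel, apply_treatment, calibrate_model

__all__ = [
    "SimulatedTrial",
    "SimSummary",
    "simulate_trial",
    "estimate_loghr",
    "run_study",
    "estimate_cross_correlation",
    "diagnostics_bias",
]


# ---------------------------------------------------------------------------
# arrivals

def _uniform_arrivals(rates, boundaries, t_end: float) -> np.ndarray:
    """Deterministic-uniform entry times matching the fluid accrual calculus."""
    times = []
    start = 0.0
    carry = 0.0  # fractional patient carried across stage boundaries
    for i, r in enumerate(rates):
        end = boundaries[i] if i < len(boundaries) else t_end
        end = min(end, t_end)
        d = end - start
        if d <= 0:
            break
        m = r * d + carry
        k = int(np.floor(m))
        if k > 0:
            # entries at the times where cumulative accrual crosses j - 0.5
            j = np.arange(k) + 0.5 - carry
            times.append(start + j / r)
        carry = m - k
        start = end
        if end >= t_end:
            break
    return np.concatenate(times) if times else np.empty(0)


def _poisson_arrivals(rates, boundaries, t_end: float, rng: np.random.Generator) -> np.ndarray:
    times = []
    start = 0.0
    for i, r in enumerate(rates):
        end = min(boundaries[i] if i < len(boundaries) else t_end, t_end)
        d = end - start
        if d <= 0:
            break
        k = rng.poisson(r * d)
        if k:
            times.append(np.sort(rng.uniform(start, end, k)))
        start = end
        if end >= t_end:
            break
    return np.concatenate(times) if times else np.empty(0)


def _arrivals(design: DesignResult, allocation_side: float, mode: str,
              rng: np.random.Generator) -> np.ndarray:
    spec = design.spec
    rates = [allocation_side * r for r in spec.control_accrual]
    boundaries = [st.t_end for st in design.stages[:-1]]
    t_end = design.stages[-1].t_end
    if spec.recruit_stop is not None:
        t_end = min(t_end, spec.recruit_stop)
    if mode == "uniform":
        return _uniform_arrivals(rates, boundaries, t_end)
    if mode == "poisson":
        return _poisson_arrivals(rates, boundaries, t_end, rng)
    raise ValueError(f"unknown arrivals mode {mode!r}")


# ---------------------------------------------------------------------------
# single trial

@dataclass(frozen=True)
class LookRecord:
    stage: int
    outcome_kind: str
    look_time: float
    e_control: int
    e_experimental: int
    loghr: float
    se: float
    passed: bool


@dataclass(frozen=True)
class SimulatedTrial:
    looks: tuple[LookRecord, ...]
    stop_stage: int  # stage at which the trial stopped (s = reached the end)
    passed_all: bool
    information_fraction: float  # control D-events at stopping / designed e_s


def estimate_loghr(
    entry: np.ndarray,
    event_time: np.ndarray,
    is_experimental: np.ndarray,
    look_time: float,
) -> tuple[float, float]:
    """Cox log-HR estimate at a calendar look, censoring at the look time.

    Patients not yet entered are excluded; everyone else contributes
    follow-up from entry to min(event, look).  Breslow tie handling.  With
    zero events in one arm the estimate is +-infinity (the decision rule
    then resolves by sign).
    """
    visible = entry < look_time
    dur = np.minimum(event_time[visible], look_time - entry[visible])
    ev = event_time[visible] <= (look_time - entry[visible])
    return fit_cox_binary(dur, ev, is_experimental[visible])


def _kth_event_time(entry: np.ndarray, times: np.ndarray, k: int) -> float:
    cal = entry + times
    if k > len(cal):
        raise ValueError("replicate cannot reach the required event count")
    return float(np.partition(cal, k - 1)[k - 1])


def simulate_trial(
    design: DesignResult,
    control_model: OutcomeModel,
    experimental_model: OutcomeModel,
    rng: np.random.Generator,
    arrivals: str = "uniform",
) -> SimulatedTrial:
    """One replicate of a multi-stage trial under the given outcome models.

    Follow-up extends for as long as needed to reach each event target
    (event-driven looks), so slow replicates simply take longer in calendar
    time rather than failing.
    """
    trial = _simulate_arrays(design, control_model, experimental_model, rng, arrivals)
    return trial


def _simulate_arrays(
    design: DesignResult,
    control_model: OutcomeModel,
    experimental_model: OutcomeModel,
    rng: np.random.Generator,
    arrivals: str,
    stop_early: bool = True,
) -> SimulatedTrial:
    spec = design.spec
    s = spec.n_stages
    A = spec.allocation

    entry_c = _arrivals(design, 1.0, arrivals, rng)
    entry_e = _arrivals(design, A, arrivals, rng)
    zc, yc = control_model.sample(len(entry_c), rng)
    ze, ye = experimental_model.sample(len(entry_e), rng)

    entry = np.concatenate([entry_c, entry_e])
    z = np.concatenate([zc, ze])
    y = np.concatenate([yc, ye])
    arm = np.concatenate(
        [np.zeros(len(entry_c), dtype=bool), np.ones(len(entry_e), dtype=bool)]
    )

    looks: list[LookRecord] = []
    stop_stage = s
    passed_all = True
    stop_time = None
    for i, st in enumerate(design.stages, start=1):
        trig_c = zc if st.outcome_kind == "I" else yc
        trig = z if st.outcome_kind == "I" else y
        tau = _kth_event_time(entry_c, trig_c, st.e_control)
        beta, se = estimate_loghr(entry, trig, arm, tau)
        passed = bool(np.exp(beta) <= st.delta) if np.isfinite(beta) else beta < 0
        visible_e = (entry < tau) & arm
        e_exp = int(np.count_nonzero(trig[visible_e] <= tau - entry[visible_e]))
        looks.append(
            LookRecord(
                stage=i,
                outcome_kind=st.outcome_kind,
                look_time=tau,
                e_control=st.e_control,
                e_experimental=e_exp,
                loghr=beta,
                se=se,
                passed=passed,
            )
        )
        if not passed:
            passed_all = False
            stop_stage = i
            stop_time = tau
            if stop_early:
                break
    if stop_time is None:
        stop_time = looks[-1].look_time

    d_events = int(np.count_nonzero((entry_c < stop_time) & (entry_c + yc <= stop_time)))
    info_frac = min(1.0, d_events / design.stages[-1].e_control)
    if passed_all or stop_stage == s:
        info_frac = 1.0
    return SimulatedTrial(
        looks=tuple(looks),
        stop_stage=stop_stage,
        passed_all=passed_all,
        information_fraction=info_frac,
    )


# ---------------------------------------------------------------------------
# replicated studies

@dataclass(frozen=True)
class SimSummary:
    """Empirical operating characteristics over replicates."""

    n_reps: int
    seed: int
    truth: tuple[float, float]  # (hr_I, hr_D) generating the data
    pass_marginal: tuple[float, ...]  # fraction passing stages 1..i jointly
    pass_conditional: tuple[float, ...]  # among those passing stage i-1
    pass_conditional_se: tuple[float, ...]
    overall: float
    overall_se: float
    mean_information_fraction: float
    n_at_stage: tuple[int, ...]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "stage": np.arange(1, len(self.pass_conditional) + 1),
                "pass_conditional": self.pass_conditional,
                "mc_se": self.pass_conditional_se,
                "n_conditioning": self.n_at_stage,
            }
        )


def _study_models(
    design: DesignResult,
    hr_I: float,
    hr_D: float,
    rho: float,
    rng: np.random.Generator,
    n_ref: int,
) -> tuple[OutcomeModel, OutcomeModel]:
    spec = design.spec
    if spec.hazard_I == spec.hazard_D:
        # single-outcome design: Z' is Y itself (identical outcomes)
        control = _identical_outcome_model(spec.hazard_D, n_ref)
    else:
        control = calibrate_model(spec.hazard_D, spec.hazard_I, rho, rng=rng, n_ref=n_ref)
    experimental = apply_treatment(control, hr_I, hr_D, rng=rng)
    return control, experimental


class _IdenticalOutcomeModel(OutcomeModel):
    """I = D: one exponential time serves both outcomes."""

    def sample(self, n: int, rng: np.random.Generator):  # noqa: D102
        y = rng.exponential(1.0 / self.lambda_D, n)
        return y, y


def _identical_outcome_model(lam: float, n_ref: int) -> OutcomeModel:
    p = (np.arange(n_ref) + 0.5) / n_ref
    ref = -np.log1p(-p)
    ref.setflags(write=False)
    return _IdenticalOutcomeModel(
        lambda_D=lam, lambda_I=lam, rho=0.0, lambda_X=lam, reference=ref
    )


def run_study(
    design: DesignResult,
    truth: str | tuple[float, float],
    n_reps: int,
    seed: int = 0,
    rho: float = 0.6,
    arrivals: str = "uniform",
    n_ref: int = 500_000,
) -> SimSummary:
    """Replicate whole trials and summarise empirical operating characteristics.

    ``truth`` is "h0" (all hazard ratios 1), "h1" (the design's alternative),
    or an explicit (hr_I, hr_D) pair.  Conditional pass probabilities at
    stage i are computed among replicates that passed stages 1..i-1, with
    binomial Monte-Carlo standard errors on that conditioning count.  The
    information fraction at stopping (control-arm definitive events at the
    stopping look over the design's final target, final-stage replicates
    counting 1.0) is averaged over all replicates.
    """
    if n_reps < 100:
        raise ValueError("need at least 100 replicates")
    spec = design.spec
    if truth == "h0":
        hr_I = hr_D = 1.0
    elif truth == "h1":
        hr_I, hr_D = spec.hr_alt[0], spec.hr_alt[-1]
    else:
        hr_I, hr_D = truth

    master = np.random.default_rng(seed)
    control, experimental = _study_models(design, hr_I, hr_D, rho, master, n_ref)

    s = spec.n_stages
    reach = np.zeros(s, dtype=int)  # replicates reaching (conditioning on) stage i
    joint = np.zeros(s, dtype=int)  # replicates passing stages 1..i
    info = 0.0
    seeds = master.integers(0, 2**63 - 1, size=n_reps)
    for k in range(n_reps):
        rng = np.random.default_rng(seeds[k])
        trial = _simulate_arrays(design, control, experimental, rng, arrivals)
        for look in trial.looks:
            reach[look.stage - 1] += 1
            if look.passed:
                joint[look.stage - 1] += 1
            else:
                break
        info += trial.information_fraction

    cond = joint / np.maximum(reach, 1)
    cond_se = np.sqrt(cond * (1 - cond) / np.maximum(reach, 1))
    overall = joint[-1] / n_reps
    return SimSummary(
        n_reps=n_reps,
        seed=seed,
        truth=(hr_I, hr_D),
        pass_marginal=tuple(joint / n_reps),
        pass_conditional=tuple(cond),
        pass_conditional_se=tuple(cond_se),
        overall=float(overall),
        overall_se=float(np.sqrt(overall * (1 - overall) / n_reps)),
        mean_information_fraction=float(info / n_reps),
        n_at_stage=tuple(reach),
    )


def estimate_cross_correlation(
    design: DesignResult,
    n_reps: int,
    truth: str | tuple[float, float] = "h0",
    seed: int = 0,
    rho: float = 0.6,
    arrivals: str = "uniform",
    estimator: str = "cox",
    n_ref: int = 500_000,
):
    """Empirical correlation matrix of stagewise log-HR estimates.

    Runs replicates *without* stopping so every look is observed, then
    returns ``(R_hat, c_hat, rho_ID_hat)`` where ``c_hat[i]`` is the
    cross-outcome attenuation estimate R_hat[i, s-1] / sqrt(e_i / e_s) for
    each intermediate stage and ``rho_ID_hat[i]`` is the correlation between
    the I- and D-outcome log-HRs evaluated at the same (stage-i) look time.

    ``estimator`` chooses the log-HR estimate at each look: "cox" (partial
    likelihood) or "events" (the event-count ratio O_i / (A e_i), the
    quantity whose cross-stage correlation the sqrt(e_i/e_j) rule describes).
    """
    spec = design.spec
    s = spec.n_stages
    A = spec.allocation
    if truth == "h0":
        hr_I = hr_D = 1.0
    elif truth == "h1":
        hr_I, hr_D = spec.hr_alt[0], spec.hr_alt[-1]
    else:
        hr_I, hr_D = truth

    master = np.random.default_rng(seed)
    control, experimental = _study_models(design, hr_I, hr_D, rho, master, n_ref)

    loghr = np.empty((n_reps, s))
    loghr_d_at_look = np.empty((n_reps, s))  # D-outcome estimate at each look time
    seeds = master.integers(0, 2**63 - 1, size=n_reps)
    for k in range(n_reps):
        rng = np.random.default_rng(seeds[k])
        entry_c = _arrivals(design, 1.0, arrivals, rng)
        entry_e = _arrivals(design, A, arrivals, rng)
        zc, yc = control.sample(len(entry_c), rng)
        ze, ye = experimental.sample(len(entry_e), rng)
        entry = np.concatenate([entry_c, entry_e])
        z = np.concatenate([zc, ze])
        y = np.concatenate([yc, ye])
        arm = np.concatenate(
            [np.zeros(len(entry_c), dtype=bool), np.ones(len(entry_e), dtype=bool)]
        )
        for i, st in enumerate(design.stages, start=1):
            trig_c = zc if st.outcome_kind == "I" else yc
            trig = z if st.outcome_kind == "I" else y
            tau = _kth_event_time(entry_c, trig_c, st.e_control)
            if estimator == "cox":
                beta, _ = estimate_loghr(entry, trig, arm, tau)
            elif estimator == "events":
                vis = (entry < tau) & arm
                o = np.count_nonzero(trig[vis] <= tau - entry[vis])
                beta = np.log(max(o, 0.5) / (A * st.e_control))
            else:
                raise ValueError(f"unknown estimator {estimator!r}")
            loghr[k, i - 1] = beta
            bd, _ = estimate_loghr(entry, y, arm, tau)
            loghr_d_at_look[k, i - 1] = bd

    finite = np.all(np.isfinite(loghr), axis=1) & np.all(
        np.isfinite(loghr_d_at_look), axis=1
    )
    loghr = loghr[finite]
    loghr_d_at_look = loghr_d_at_look[finite]
    R_hat = np.corrcoef(loghr, rowvar=False)
    e = design.e_control
    c_hat = tuple(
        float(R_hat[i, s - 1] / np.sqrt(e[i] / e[s - 1])) for i in range(s - 1)
    )
    rho_id = tuple(
        float(np.corrcoef(loghr[:, i], loghr_d_at_look[:, i])[0, 1])
        for i in range(s)
    )
    return R_hat, c_hat, rho_id


def diagnostics_bias(
    design_factory,
    alphas,
    omegas,
    n_reps: int,
    seed: int = 0,
    arrivals: str = "uniform",
):
    """Bias diagnostics for the normal approximation in single-stage designs.

    For each (alpha, omega) cell, builds a single-stage design via
    ``design_factory(alpha, omega)``, simulates the standardized statistics

        A1 = z_alpha + ln(HR_hat) / sigma0      (under H0)
        B1 = z_omega + (ln HR_hat - ln HR_alt) / sigma1   (under H1)

    and reports their means and SDs: both should be (z, 1) if the design
    variance formulas were exact.  The expected empirical pattern is SDs a
    little above 1 under H0 and a little below 1 under H1.
    """
    import pandas as pd

    rows = []
    master = np.random.default_rng(seed)
    for a in alphas:
        for w in omegas:
            design: DesignResult = design_factory(a, w)
            st = design.stages[0]
            spec = design.spec
            sigma0 = np.sqrt(variance_null(st.e_control, spec.allocation))
            sigma1 = np.sqrt(variance_alt(st.e_control, st.e_exp_alt))
            lam = spec.hazard_D
            out = {}
            for label, hr in (("H0", 1.0), ("H1", spec.hr_alt[-1])):
                control = _identical_outcome_model(lam, 10_000)
                experimental = apply_treatment(control, hr, hr)
                vals = np.empty(n_reps)
                seeds = master.integers(0, 2**63 - 1, size=n_reps)
                for k in range(n_reps):
                    rng = np.random.default_rng(seeds[k])
                    trial = _simulate_arrays(design, control, experimental, rng, arrivals)
                    vals[k] = trial.looks[0].loghr
                if label == "H0":
                    stat = norm.ppf(a) + vals / sigma0
                else:
                    stat = norm.ppf(w) + (vals - np.log(spec.hr_alt[-1])) / sigma1
                out[f"mean_{label}"] = float(np.mean(stat))
                out[f"sd_{label}"] = float(np.std(stat, ddof=1))
            rows.append(
                {
                    "alpha": a,
                    "omega": w,
                    "z_alpha": float(norm.ppf(a)),
                    "z_omega": float(norm.ppf(w)),
                    **out,
                }
            )
    return pd.DataFrame(rows)
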
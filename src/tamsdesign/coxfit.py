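"""Fast Cox proportional-hazards fit for a single binary treatment covariate.

Interim looks in the trial simulator need tens of thousands of Cox fits, so
the partial likelihood is maximised directly with a vectorised Newton
iteration instead of going through a general-purpose survival package.  Ties
are handled with the Breslow approximation.  For one binary covariate the
score and information reduce to sums over event times of simple functions of
the numbers at risk per arm, all computable from one sort and cumulative
sums.
"""

from __future__ import annotations

import numpy as np

__all__ = ["fit_cox_binary"]

_MAX_ITER = 60
_TOL = 1e-9
_BETA_CAP = 50.0


def fit_cox_binary(
    time: np.ndarray, event: np.ndarray, group: np.ndarray
) -> tuple[float, float]:
    """Maximum partial-likelihood log hazard ratio for group 1 vs group 0.

    Parameters
    ----------
    time
        Follow-up durations (entry to event or censoring).
    event
        1/True where an event occurred, 0/False where censored.
    group
        1/True for the experimental arm, 0/False for control.

    Returns
    -------
    (beta, se)
        The estimated log hazard ratio and its standard error (inverse
        square-root observed information).  If one arm has no events the
        estimate diverges: ``+inf`` (no control events) or ``-inf`` (no
        experimental events) is returned with ``se = inf``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    group = np.asarray(group, dtype=bool)
    if not (time.shape == event.shape == group.shape):
        raise ValueError("time, event and group must have identical shapes")

    d1_total = int(np.count_nonzero(event & group))
    d_total = int(np.count_nonzero(event))
    d0_total = d_total - d1_total
    if d_total == 0:
        raise ValueError("no events: log-HR is undefined")
    if d1_total == 0:
        return -np.inf, np.inf
    if d0_total == 0:
        return np.inf, np.inf

    order = np.argsort(time, kind="stable")
    t = time[order]
    ev = event[order]
    g1 = group[order].astype(float)

    # risk-set sizes just before each index position (risk set = suffix)
    n = len(t)
    n1_after = np.cumsum(g1[::-1])[::-1]  # number in group 1 with index >= k
    n_after = n - np.arange(n)

    # Breslow: group tied event times; the risk set is everyone with t >= t_k,
    # i.e. the suffix starting at the first index of the tied block
    ev_idx = np.flatnonzero(ev)
    t_ev = t[ev_idx]
    block_start = np.searchsorted(t, t_ev, side="left")
    uniq_start, first_pos = np.unique(block_start, return_index=True)
    # events (total / group-1) per tied block
    d_block = np.diff(np.append(first_pos, len(ev_idx)))
    g_ev = g1[ev_idx]
    d1_block = np.add.reduceat(g_ev, first_pos)
    r1 = n1_after[uniq_start]  # group-1 members at risk at each event time
    r_all = n_after[uniq_start].astype(float)
    r0 = r_all - r1

    beta = 0.0
    for _ in range(_MAX_ITER):
        eb = np.exp(beta)
        s1 = eb * r1
        s0 = r0 + s1
        frac = s1 / s0
        score = float(np.sum(d1_block) - np.sum(d_block * frac))
        info = float(np.sum(d_block * frac * (1.0 - frac)))
        if info <= 0:
            break
        step = score / info
        beta += np.clip(step, -2.0, 2.0)
        if abs(step) < _TOL:
            break
        if abs(beta) > _BETA_CAP:  # separation: estimate diverges
            return (np.inf if beta > 0 else -np.inf), np.inf

    eb = np.exp(beta)
    frac = eb * r1 / (r0 + eb * r1)
    info = float(np.sum(d_block * frac * (1.0 - frac)))
    se = 1.0 / np.sqrt(info) if info > 0 else np.inf
    return float(beta), float(se)
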
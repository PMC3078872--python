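"""Overall and stagewise operating characteristics via multivariate normal integrals.

The stagewise log hazard-ratio estimates of a multi-stage design are treated
as jointly normal with a correlation matrix R built from cumulative event
counts: between two looks on the same outcome, R_ij = sqrt(e_i / e_j) for
e_i <= e_j; between an intermediate-outcome look and the definitive analysis
the correlation is attenuated by a constant factor c in (0, 1],
R_is = c * sqrt(e_i / e_s).  Overall significance level and power are then
lower-orthant probabilities of the s-variate standard normal at the
stagewise quantiles, and conditional (stagewise) quantities are ratios of
successive joint probabilities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import multivariate_normal, norm

__all__ = [
    "CorrelationModel",
    "OCResult",
    "corr_pair",
    "build_R",
    "mvn_lower_orthant",
    "overall_oc",
    "sensitivity_over_c",
    "c_from_rho",
]

#: fixed QMC stream so repeated orthant evaluations are reproducible
_MVN_SEED = 20110318
_MVN_MAXPTS_PER_DIM = 200_000


def corr_pair(e_i: float, e_j: float) -> float:
    """Correlation sqrt(e_i / e_j) between log-HR estimates at two looks on
    the same outcome with cumulative control-arm events e_i <= e_j."""
    if e_i <= 0:
        raise ValueError("event counts must be positive")
    if e_i > e_j:
        raise ValueError(f"need e_i <= e_j, got {e_i} > {e_j}")
    return float(np.sqrt(e_i / e_j))


def _nearest_psd(R: np.ndarray) -> np.ndarray:
    """Eigenvalue-clip projection to the nearest PSD matrix with unit diagonal."""
    vals, vecs = np.linalg.eigh(R)
    vals = np.clip(vals, 0.0, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


@dataclass(frozen=True)
class CorrelationModel:
    """Correlation matrix of stagewise log-HR estimates plus its provenance."""

    R: np.ndarray
    events: tuple[float, ...]
    c: float
    source: str = "analytic"  # analytic | supplied | empirical

    @property
    def n_stages(self) -> int:
        return self.R.shape[0]

    def with_c(self, c: float) -> "CorrelationModel":
        """Analytic rebuild at a different attenuation factor (drops overrides)."""
        return build_R(self.events, c)


def build_R(
    e,
    c: float = 0.6,
    cross_overrides: dict[int, float] | None = None,
    source: str = "analytic",
) -> CorrelationModel:
    """Build the s x s correlation matrix from cumulative control-arm events.

    Parameters
    ----------
    e
        Cumulative control-arm event targets per stage: intermediate-outcome
        counts for stages 1..s-1 (ascending), the definitive-outcome count
        for stage s.
    c
        Attenuation factor applied to correlations between an I-stage and
        the final D-stage.  ``c=1`` recovers the identical-outcome case.
    cross_overrides
        Optional replacement values for the final column, keyed by 1-based
        stage index: e.g. ``{1: 0.367, 2: 0.504}`` substitutes empirically
        estimated R_1s, R_2s for the analytic ``c * sqrt(e_i/e_s)``.

    The assembled matrix is checked for positive semi-definiteness and, if an
    eigenvalue falls below -1e-8 (possible with supplied overrides), projected
    to the nearest PSD matrix with a warning.
    """
    e = tuple(float(v) for v in e)
    s = len(e)
    if any(v <= 0 for v in e):
        raise ValueError("event counts must be positive")
    if any(a >= b for a, b in zip(e[: s - 1], e[1 : s - 1])):
        raise ValueError("intermediate-stage event counts must be ascending")
    if not 0 <= c <= 1:
        raise ValueError("attenuation factor c must lie in [0, 1]")

    R = np.eye(s)
    for i in range(s):
        for j in range(i + 1, s):
            factor = c if (j == s - 1 and s > 1 and i < s - 1) else 1.0
            # the D-stage count may be smaller than a late I-stage count;
            # the event-ratio rule uses the smaller count over the larger
            R[i, j] = R[j, i] = factor * corr_pair(min(e[i], e[j]), max(e[i], e[j]))
    if cross_overrides:
        for idx, val in cross_overrides.items():
            if not 1 <= idx <= s - 1:
                raise ValueError(
                    f"override index {idx} outside intermediate stages 1..{s - 1}"
                )
            R[idx - 1, s - 1] = R[s - 1, idx - 1] = float(val)
        source = "supplied"

    min_eig = float(np.linalg.eigvalsh(R).min())
    if min_eig < -1e-8:
        warnings.warn(
            f"correlation matrix not PSD (min eigenvalue {min_eig:.2e}); "
            "projecting to the nearest PSD matrix",
            stacklevel=2,
        )
        R = _nearest_psd(R)
    R.setflags(write=False)
    return CorrelationModel(R=R, events=e, c=c, source=source)


def mvn_lower_orthant(thresholds, R) -> float:
    """P(Z_1 <= u_1, ..., Z_s <= u_s) for standard MVN with correlation R.

    Deterministic: the quasi-Monte-Carlo integrator runs with a fixed seed
    and a generous point budget (absolute accuracy well below 1e-5 for the
    dimensions used here, s <= 10).
    """
    u = np.atleast_1d(np.asarray(thresholds, dtype=float))
    R = np.asarray(R, dtype=float)
    s = u.shape[0]
    if R.shape != (s, s):
        raise ValueError(f"correlation matrix shape {R.shape} does not match {s} thresholds")
    if s == 1:
        return float(norm.cdf(u[0]))
    min_eig = float(np.linalg.eigvalsh(R).min())
    if min_eig < -1e-8:
        raise ValueError("correlation matrix is not positive semi-definite")
    val = multivariate_normal.cdf(
        u,
        mean=np.zeros(s),
        cov=R,
        allow_singular=True,
        maxpts=_MVN_MAXPTS_PER_DIM * s,
        abseps=1e-7,
        releps=0.0,
        rng=np.random.default_rng(_MVN_SEED),
    )
    return float(min(1.0, max(0.0, val)))


@dataclass(frozen=True)
class OCResult:
    """Overall, intermediate-only, conditional and bounding significance/power."""

    alpha_overall: float
    omega_overall: float
    alpha_I: float
    omega_I: float
    alpha_conditional: tuple[float, ...]
    omega_conditional: tuple[float, ...]
    alpha_bounds: tuple[float, float]  # (min at c=0: independence, max at c=1)
    omega_bounds: tuple[float, float]
    alphas: tuple[float, ...] = field(default=())
    powers: tuple[float, ...] = field(default=())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "stage": np.arange(1, len(self.alpha_conditional) + 1),
                "alpha_marginal": self.alphas,
                "power_marginal": self.powers,
                "alpha_conditional": self.alpha_conditional,
                "omega_conditional": self.omega_conditional,
            }
        )


def _joint_chain(levels: tuple[float, ...], R: np.ndarray) -> list[float]:
    """Joint lower-orthant probabilities for leading sub-vectors 1..s."""
    u = norm.ppf(levels)
    return [mvn_lower_orthant(u[: i + 1], R[: i + 1, : i + 1]) for i in range(len(u))]


def overall_oc(alphas, marginal_powers, model: CorrelationModel) -> OCResult:
    """Operating characteristics of a design under a correlation model.

    ``marginal_powers`` should be the attained stagewise powers from the
    solved design (slightly above nominal at integer event targets); using
    nominal powers understates the overall and conditional power.

    Bounds: with no knowledge of the cross-outcome correlations, Slepian's
    inequality makes the joint pass probability monotone in c, so the
    overall significance level and power are smallest when the I- and
    D-outcome estimates are independent (c = 0, where the orthant
    probability factorises into alpha_I * alpha_s) and largest at c = 1
    (the full same-outcome event-ratio matrix, which stays positive
    semi-definite); there the overall level approaches its ceiling alpha_s.
    """
    alphas = tuple(float(a) for a in alphas)
    powers = tuple(float(w) for w in marginal_powers)
    s = model.n_stages
    if len(alphas) != s or len(powers) != s:
        raise ValueError(f"need {s} stagewise levels and powers")

    joint_a = _joint_chain(alphas, model.R)
    joint_w = _joint_chain(powers, model.R)
    cond_a = tuple(
        joint_a[i] / joint_a[i - 1] if i else joint_a[0] for i in range(s)
    )
    cond_w = tuple(
        joint_w[i] / joint_w[i - 1] if i else joint_w[0] for i in range(s)
    )
    alpha_I = joint_a[s - 2] if s > 1 else 1.0
    omega_I = joint_w[s - 2] if s > 1 else 1.0

    if s > 1:
        alpha_min = alpha_I * alphas[-1]
        omega_min = omega_I * powers[-1]
        R_max = build_R(model.events, 1.0)
        alpha_max = _joint_chain(alphas, R_max.R)[-1]
        omega_max = _joint_chain(powers, R_max.R)[-1]
    else:
        alpha_min = alpha_max = joint_a[-1]
        omega_min = omega_max = joint_w[-1]

    return OCResult(
        alpha_overall=joint_a[-1],
        omega_overall=joint_w[-1],
        alpha_I=alpha_I,
        omega_I=omega_I,
        alpha_conditional=cond_a,
        omega_conditional=cond_w,
        alpha_bounds=(alpha_min, alpha_max),
        omega_bounds=(omega_min, omega_max),
        alphas=alphas,
        powers=powers,
    )


def sensitivity_over_c(e, alphas, marginal_powers, c_grid):
    """Overall (alpha, omega) on a grid of attenuation factors, analytic R only."""
    import pandas as pd

    rows = []
    for c in c_grid:
        if not 0 < c <= 1:
            raise ValueError("c grid values must lie in (0, 1]")
        oc = overall_oc(alphas, marginal_powers, build_R(e, c))
        rows.append({"c": c, "alpha": oc.alpha_overall, "omega": oc.omega_overall})
    return pd.DataFrame(rows)


def c_from_rho(rho_id: float) -> float:
    """Heuristic attenuation factor from the fixed-time I/D log-HR correlation.

    Rule of thumb c ~= 1.1 * rho, clamped to 1; treat the result as a
    starting point for a sensitivity analysis, not a precise estimate.
    """
    if not 0 < rho_id <= 0.9:
        raise ValueError("rho must lie in (0, 0.9]")
    return min(1.0, 1.1 * rho_id)
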
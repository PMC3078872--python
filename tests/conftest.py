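import numpy as np
import pytest

from tamsdesign import DesignSpec, build_design
from tamsdesign.outcomes import calibrate_model


@pytest.fixture(scope="session")
def table4a_design():
    """3-stage GOG182/ICON5-style design: I median 1 yr, D median 2 yr,
    control accrual 125/yr, alpha=(0.5, 0.25, 0.025)."""
    spec = DesignSpec(
        3,
        (0.5, 0.25, 0.025),
        (0.95, 0.95, 0.9),
        0.75,
        accrual=125,
        hazard_I=0.693,
        hazard_D=0.347,
    )
    return build_design(spec)


@pytest.fixture(scope="session")
def table8_design():
    """4-stage single-outcome design (median 1 yr, control accrual 125/yr)."""
    spec = DesignSpec(
        4,
        (0.5, 0.25, 0.1, 0.025),
        (0.95, 0.95, 0.95, 0.9),
        0.75,
        accrual=125,
        hazard_I=np.log(2.0),
        hazard_D=np.log(2.0),
    )
    return build_design(spec)


@pytest.fixture(scope="session")
def power_at_events():
    """Callable recomputing the attained power of a solved stage at an
    arbitrary event count (for minimality checks)."""
    import math

    from tamsdesign import (
        AccrualSchedule,
        attained_power,
        critical_hr,
        events_at,
        time_for_events,
        variance_alt,
        variance_null,
    )

    def _power(design, i, e):
        spec = design.spec
        prev = design.stages[: i - 1]
        lam = spec.stage_hazard(i)
        bounds = tuple(st.t_end for st in prev)
        rates = spec.control_accrual[:i]
        ctrl = AccrualSchedule(rates, bounds)
        exp_s = AccrualSchedule(tuple(spec.allocation * r for r in rates), bounds)
        sigma0 = math.sqrt(variance_null(e, spec.allocation))
        delta = critical_hr(spec.alpha[i - 1], sigma0, spec.hr_null[i - 1])
        t_i = time_for_events(e, ctrl, lam, t_floor=prev[-1].t_end if prev else 0.0)
        e_star = events_at(t_i, exp_s, spec.hr_alt[i - 1] * lam)
        return attained_power(delta, spec.hr_alt[i - 1], math.sqrt(variance_alt(e, e_star)))

    return _power


@pytest.fixture(scope="session")
def calibrated_model():
    """Correlated outcome model at the simulation-study hazards and rho=0.6."""
    return calibrate_model(
        0.347, 0.693, 0.6, rng=np.random.default_rng(20110318), n_cal=150_000, n_ref=400_000
    )
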
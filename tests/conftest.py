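import logging

import numpy as np
import pytest

import vancoforecast as vf

# the two-point fitter logs a (by-design) steady-state caution on short
# histories; keep test output readable
logging.getLogger("vancoforecast.sawchuk").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def prior():
    return vf.default_prior()


@pytest.fixture(scope="session")
def flat_prior():
    """Covariate-free prior with CL 2.5 L/h, V 6.36 L."""
    return vf.PopPrior(model="constant", theta={"cl": 2.5, "v": 6.36})


@pytest.fixture
def cov():
    return vf.PatientCovariates(age_months=24.0, weight_kg=10.0, scr=0.34)


def q6h_schedule(n_doses: int, amount: float = 150.0, duration: float = 1.0):
    return [
        vf.DosingEvent(i * 6.0, amount, duration, interval_hint=6.0)
        for i in range(n_doses)
    ]


@pytest.fixture
def q6h():
    return q6h_schedule


def ode_concentration(cl, v, doses, times, rtol=1e-10):
    """Independent oracle: adaptive ODE integration of dC/dt = R(t)/V - ke*C."""
    from scipy.integrate import solve_ivp

    ke = cl / v
    breaks = sorted({0.0} | {d.start_time for d in doses} | {d.end_time for d in doses})

    def rate(t):
        return sum(d.rate for d in doses if d.start_time < t <= d.end_time)

    scalar = np.ndim(times) == 0
    times = np.atleast_1d(np.asarray(times, dtype=float))
    out = np.empty_like(times)
    c0, t0 = 0.0, 0.0
    for i in np.argsort(times):
        t = times[i]
        # integrate piecewise between infusion breakpoints so the stepper
        # never straddles a rate discontinuity
        segs = [b for b in breaks if t0 < b < t] + [t]
        for b in segs:
            if b <= t0:
                continue
            r = rate(0.5 * (t0 + b))
            sol = solve_ivp(
                lambda tt, y, r=r: [r / v - ke * y[0]],
                (t0, b),
                [c0],
                rtol=rtol,
                atol=1e-12,
            )
            c0, t0 = float(sol.y[0, -1]), b
        out[i] = c0
    return float(out[0]) if scalar else out


@pytest.fixture(scope="session")
def ode_oracle():
    return ode_concentration
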
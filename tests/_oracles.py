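"""Shared independent oracles for the test suite."""

import warnings

import numpy as np
from scipy.integrate import solve_ivp

from socturn.radiocarbon import LAMBDA_14C


def ode_delta14c(k, curve, end_year=2014.5, lam=LAMBDA_14C):
    """High-accuracy integration of the continuous one-pool model
    dF/dt = k·F_atm(t) − (k+λ)·F from the same spin-up state the monthly
    recursion uses; the independent oracle for the forward model."""
    pre = np.linspace(max(curve.start, 1920.0), 1950.0, 121)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_pre = np.mean(curve.value_at(pre)) / 1000.0 + 1.0

        def rhs(t, f):
            return k * (curve.value_at(t) / 1000.0 + 1.0) - (k + lam) * f

        sol = solve_ivp(
            rhs,
            (1950.0, end_year),
            [k * f_pre / (k + lam)],
            rtol=1e-10,
            atol=1e-12,
            max_step=1 / 24,
        )
    return 1000.0 * (sol.y[0, -1] - 1.0)
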
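"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed-form code paths in :mod:`ctpta.pkpd` and
the algebraic Wilson formula in :mod:`ctpta.trial_stats`: the PK oracle
integrates the compartment ODEs to periodic steady state with an adaptive
stiff solver, and the interval oracle root-finds the score equation.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq
from scipy.stats import norm


def ode_profile_ss(params, regimen, times, driven_by="total", max_intervals=800):
    """Plasma and ELF steady-state concentrations by repeated-dose ODE integration.

    Integrates interval by interval from drug-free initial conditions until
    the state at interval start is periodic to ~1e-12 relative (at least 20
    intervals), then evaluates the final interval on ``times``.
    """
    k10 = params.cl / params.v1
    k12 = params.q / params.v1 if params.q else 0.0
    k21 = params.q / params.v2 if params.q else 0.0
    drive = params.fu_plasma if driven_by == "free" else 1.0

    def rhs(t, y, r0):
        a1, a2, ce = y
        return [
            r0 - (k10 + k12) * a1 + k21 * a2,
            k12 * a1 - k21 * a2,
            params.k_in * drive * a1 / params.v1 - params.k_out * ce,
        ]

    opts = dict(rtol=1e-11, atol=1e-13, method="LSODA")
    tinf, tau = regimen.infusion_duration, regimen.interval
    y = np.zeros(3)
    for i in range(max_intervals):
        y0 = y.copy()
        y = solve_ivp(rhs, (0, tinf), y, args=(regimen.rate,), **opts).y[:, -1]
        y = solve_ivp(rhs, (tinf, tau), y, args=(0.0,), **opts).y[:, -1]
        if i >= 19 and np.all(np.abs(y - y0) <= 1e-12 * np.maximum(np.abs(y), 1e-30) + 1e-14):
            break
    t1 = times[times <= tinf]
    t2 = times[times > tinf]
    s1 = solve_ivp(rhs, (0, tinf), y, args=(regimen.rate,), t_eval=t1, **opts)
    s2 = solve_ivp(rhs, (tinf, tau), s1.y[:, -1] if t1.size else y, args=(0.0,), t_eval=t2, **opts)
    plasma = np.concatenate([s1.y[0] if t1.size else [], s2.y[0] if t2.size else []]) / params.v1
    elf = np.concatenate([s1.y[2] if t1.size else [], s2.y[2] if t2.size else []])
    return plasma, elf


def wilson_by_root_finding(x, n, alpha=0.05):
    """Wilson endpoints as the roots of the score equation (p̂−p)² = z²p(1−p)/n."""
    z = norm.ppf(1 - alpha / 2)
    phat = x / n

    def score(p):
        return (phat - p) ** 2 - z * z * p * (1 - p) / n

    # score is zero at p = p̂ itself, so bracket strictly inside (0, p̂) / (p̂, 1)
    lo = 0.0 if x == 0 else brentq(score, 1e-15, phat - 1e-13, xtol=1e-15)
    hi = 1.0 if x == n else brentq(score, phat + 1e-13, 1 - 1e-15, xtol=1e-15)
    return lo, hi


def time_above_dense(params, regimen, threshold, matrix, fu, factor=10):
    """Brute-force fT>threshold on a grid ``factor``× denser than the default."""
    from ctpta.pkpd import default_time_grid, elf_profile_ss, DEFAULT_DT

    times = default_time_grid(regimen, dt=DEFAULT_DT / factor)
    prof = elf_profile_ss(params, regimen, times)
    conc = prof.concentration(matrix=matrix, free=fu)
    above = conc > threshold
    mids = 0.5 * (above[:-1].astype(float) + above[1:].astype(float))
    return float((mids * np.diff(times)).sum() / (times[-1] - times[0]))
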
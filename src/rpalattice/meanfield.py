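"""Deterministic mean-field surrogate of the two-mode binding kinetics.

Writing ``rho20``/``rho30`` for bound-molecule densities (per nt), total
density ``rho = rho20 + rho30`` and free fraction
``f = 1 - 20*rho20 - 30*rho30``, the availability of a free 20-nt window per
site under a random (equilibrium) arrangement of the bound footprints is the
finite-ligand McGhee-von Hippel factor

    w20 = f * (f / (f + rho))**19,

and the chance that the 10 nt on the 3' side of a given 20-nt-mode molecule
are free is ``e10 = (f / (f + rho))**10`` (geometric gap closure).  The rate
equations are

    d rho20/dt = fold*k_bind*w20 - k_off20*rho20 - k_ext*e10*rho20 + k_retr*rho30
    d rho30/dt =                                   k_ext*e10*rho20 - k_retr*rho30

(k_bind here is per free window per second, as in the stochastic model).  The
closure is exact in the low-coverage limit and for the reversible 20-mer-only
system at equilibrium, where the stationary coverage solves the classical
McGhee-von Hippel isotherm; away from those limits it is an approximation
used for fast pre-fitting, not a substitute for the stochastic simulation.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .lattice import Protocol, RateSet

__all__ = ["meanfield_trajectory", "mcghee_von_hippel_isotherm"]


def _rhs(t, y, rates: RateSet, fold: float):
    rho20, rho30 = y
    rho20 = max(rho20, 0.0)
    rho30 = max(rho30, 0.0)
    rho = rho20 + rho30
    f = max(1.0 - 20.0 * rho20 - 30.0 * rho30, 0.0)
    if rho > 0 and f + rho > 0:
        cond = f / (f + rho)
    else:
        cond = 1.0
    w20 = f * cond**19
    e10 = cond**10
    ext = rates.k_ext * e10 * rho20
    retr = rates.k_retr * rho30
    d20 = fold * rates.k_bind * w20 - rates.k_off20 * rho20 - ext + retr
    d30 = ext - retr
    return [d20, d30]


def meanfield_trajectory(
    rates: RateSet | dict[str, RateSet],
    fold: float | None,
    protocol: Protocol,
    L: int,
    sample_dt: float = 5.0,
    rtol: float = 1e-7,
    atol: float = 1e-10,
):
    """Integrate the mean-field equations over the protocol phases.

    ``rates`` may be a single :class:`RateSet` (applied to every phase, with
    ``fold`` overriding the phase folds when given) or a label->RateSet map
    resolved per phase.  Returns ``(times, N20, N30)`` with counts on the
    ``L``-nt lattice.  Raises ``RuntimeError`` with solver diagnostics on
    integration failure.
    """
    total = protocol.total_duration
    times = np.arange(0.0, total + 0.5 * sample_dt, sample_dt)
    times[-1] = min(times[-1], total)
    y = np.array([0.0, 0.0])
    out20 = np.empty_like(times)
    out30 = np.empty_like(times)
    t0 = 0.0
    ti = 0
    for phase in protocol.phases:
        t1 = t0 + phase.duration
        rs = rates[phase.rate_label] if isinstance(rates, dict) else rates
        ph_fold = phase.fold if fold is None else fold
        in_phase = [t for t in times[ti:] if t < t1 - 1e-9]
        t_eval = in_phase + [t1]
        sol = solve_ivp(
            _rhs,
            (t0, t1),
            y,
            args=(rs, ph_fold),
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            method="LSODA",
        )
        if not sol.success:
            raise RuntimeError(f"mean-field integration failed: {sol.message}")
        for k in range(len(in_phase)):
            out20[ti + k] = sol.y[0][k]
            out30[ti + k] = sol.y[1][k]
        ti += len(in_phase)
        y = sol.y[:, -1]
        t0 = t1
    # remaining sample points are at (or numerically past) the final boundary
    while ti < len(times):
        out20[ti], out30[ti] = y
        ti += 1
    return times, out20 * L, out30 * L


def mcghee_von_hippel_isotherm(Ka: float, n: int = 20) -> float:
    """Stationary bound density ``rho`` (molecules per site) solving the
    McGhee-von Hippel isotherm ``Ka * f * (f/(f+rho))**(n-1) = rho`` with
    ``f = 1 - n*rho``; ``Ka = fold*k_bind/k_off20`` per window."""
    from scipy.optimize import brentq

    def g(rho):
        f = 1.0 - n * rho
        if f <= 0:
            return -rho
        return Ka * f * (f / (f + rho)) ** (n - 1) - rho

    hi = 1.0 / n - 1e-12
    return brentq(g, 0.0, hi, xtol=1e-14)
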
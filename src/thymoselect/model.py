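"""Steady states, stability, analytic solutions and RK4 integration.

Both models are linear cascades

.. math::

    dn_1/dt &= \\phi - (\\varphi_1+\\mu_1)\\,n_1 \\\\
    dn_2/dt &= \\varphi_1 n_1 - (\\varphi_2+\\mu_2)\\,n_2 \\\\
    dn_3/dt &= \\varphi_2 n_2 - (\\varphi_3+\\mu_3-\\lambda_3)\\,n_3

(with the third compartment split into parallel CD4/CD8 branches fed by
``phi4``/``phi8`` in the lineage model).  The Jacobian is lower triangular, so
the eigenvalues are minus the per-compartment net decay rates and the exact
solution from arbitrary initial conditions is a sum of exponentials whose
coefficients follow from the cascade structure.  The closed form implemented
here is re-derived from the ODEs and is validated against the RK4 integrator
in the test-suite; it requires a non-degenerate spectrum (pairwise distinct
decay rates) and raises :class:`~thymoselect.params.DegenerateSpectrumError`
otherwise.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .params import (CompartmentState, DegenerateSpectrumError, LineageRates,
                     NoSteadyStateError, PooledRates, StabilityReport)

Rates = PooledRates | LineageRates

#: default RK4 step, days (>= 100 steps per fastest timescale of ~1/1.49 d)
DEFAULT_DT = 0.01

_DEGENERACY_RTOL = 1e-9


def steady_state(rates: Rates) -> CompartmentState:
    """Unique steady state of either model.

    Raises
    ------
    NoSteadyStateError
        If a net SP decay rate ``phi3+mu3-lam3`` (pooled) or
        ``xi+mu-lam`` (per lineage) is not strictly positive: proliferation
        then balances or outruns removal and no stable steady state exists.
    """
    if isinstance(rates, PooledRates):
        d1, d2, d3 = rates.decay_rates
        _require_positive_decay({"SP (n3)": d3})
        n1 = rates.phi / d1
        n2 = n1 * rates.phi1 / d2
        n3 = n2 * rates.phi2 / d3
        return CompartmentState.pooled(t=np.inf, n1=n1, n2=n2, n3=n3)
    d1, d2, d4, d8 = rates.decay_rates
    _require_positive_decay({"CD4 SP (n4)": d4, "CD8 SP (n8)": d8})
    n1 = rates.phi / d1
    n2 = n1 * rates.phi1 / d2
    n4 = n2 * rates.phi4 / d4
    n8 = n2 * rates.phi8 / d8
    return CompartmentState.split(t=np.inf, n1=n1, n2=n2, n4=n4, n8=n8)


def _require_positive_decay(named: dict[str, float]) -> None:
    bad = [name for name, d in named.items() if d <= 0]
    if bad:
        raise NoSteadyStateError(
            "no stable steady state: net decay rate (egress + death - "
            f"proliferation) is <= 0 in compartment(s) {', '.join(bad)}")


def stability(rates: Rates) -> StabilityReport:
    """Closed-form Jacobian eigenvalues and the stability condition.

    The Jacobian is triangular, so the eigenvalues are minus the per-compartment
    net decay rates; the steady state exists and is stable iff all are negative.
    """
    return StabilityReport.from_eigenvalues([-d for d in rates.decay_rates])


def jacobian(rates: Rates) -> np.ndarray:
    """Assembled Jacobian matrix of the linear system (for cross-checks)."""
    if isinstance(rates, PooledRates):
        d1, d2, d3 = rates.decay_rates
        return np.array([[-d1, 0.0, 0.0],
                         [rates.phi1, -d2, 0.0],
                         [0.0, rates.phi2, -d3]])
    d1, d2, d4, d8 = rates.decay_rates
    return np.array([[-d1, 0.0, 0.0, 0.0],
                     [rates.phi1, -d2, 0.0, 0.0],
                     [0.0, rates.phi4, -d4, 0.0],
                     [0.0, rates.phi8, 0.0, -d8]])


def _check_spectrum(decays) -> None:
    d = np.asarray(decays, dtype=float)
    scale = max(d.max(), 1e-300)
    for i in range(len(d)):
        for j in range(i + 1, len(d)):
            if abs(d[i] - d[j]) <= _DEGENERACY_RTOL * scale:
                raise DegenerateSpectrumError(
                    f"decay rates {d[i]:.6g} and {d[j]:.6g} coincide; the cascade "
                    "closed form is singular — use rk4_simulate instead")


def _cascade_coefficients(rates: Rates, init: CompartmentState):
    """Exponential-mode coefficients of the exact solution from ``init``.

    Returns ``(nstar, decays, C)`` with ``n_i(t) = nstar_i + sum_k C[i, k]
    exp(-decays[k] t)``.  ``C`` is lower triangular in mode order because each
    compartment only inherits modes of its upstream feeders.
    """
    star = steady_state(rates)
    decays = rates.decay_rates
    _check_spectrum(decays)
    dev = np.asarray(init.counts(), dtype=float) - np.asarray(star.counts(), dtype=float)
    k = len(decays)
    C = np.zeros((k, k))
    # compartment 1: pure decay of its own deviation
    C[0, 0] = dev[0]
    # compartment 2 is fed by phi1 * n1
    d = decays
    C[1, 0] = rates.phi1 * C[0, 0] / (d[1] - d[0])
    C[1, 1] = dev[1] - C[1, 0]
    if isinstance(rates, PooledRates):
        feeders = [(2, rates.phi2)]
    else:
        feeders = [(2, rates.phi4), (3, rates.phi8)]
    for i, feed in feeders:
        C[i, 0] = feed * C[1, 0] / (d[i] - d[0])
        C[i, 1] = feed * C[1, 1] / (d[i] - d[1])
        C[i, i] = dev[i] - C[i, 0] - C[i, 1]
    return star, np.asarray(d), C


def analytic_solution(rates: Rates, init: CompartmentState, t) -> CompartmentState:
    """Exact solution of the linear ODEs at time ``t`` (days).

    ``init`` must match the model family of ``rates`` (pooled 3-compartment
    state for :class:`PooledRates`, split 4-compartment state for
    :class:`LineageRates`).  Requires a stable spectrum (the closed form is
    organized around the steady state); use :func:`rk4_simulate` to follow the
    unbounded growth of an unstable parameter set.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if init.is_split != isinstance(rates, LineageRates):
        raise ValueError("initial state does not match the model family")
    star, decays, C = _cascade_coefficients(rates, init)
    n = _eval_modes(star, decays, C, float(t))
    if isinstance(rates, PooledRates):
        return CompartmentState.pooled(t, *n)
    return CompartmentState.split(t, *n)


def _eval_modes(star, decays, C, t: float) -> np.ndarray:
    nstar = np.asarray(star.counts(), dtype=float)
    n = nstar + C @ np.exp(-decays * t)
    # linear-cascade counts are nonnegative for nonnegative inits; clip the
    # closed form's rounding dust so downstream validation never trips
    return np.clip(n, 0.0, None)


def solution_at_times(rates: Rates, init: CompartmentState, times) -> np.ndarray:
    """Vectorized closed-form trajectory; rows are times, columns compartments."""
    star, decays, C = _cascade_coefficients(rates, init)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    out = np.asarray(star.counts(), dtype=float)[None, :] + np.exp(
        -times[:, None] * decays[None, :]) @ C.T
    return np.clip(out, 0.0, None)


def _deriv(rates: Rates, n: np.ndarray) -> np.ndarray:
    if isinstance(rates, PooledRates):
        d1, d2, d3 = rates.decay_rates
        return np.array([rates.phi - d1 * n[0],
                         rates.phi1 * n[0] - d2 * n[1],
                         rates.phi2 * n[1] - d3 * n[2]])
    d1, d2, d4, d8 = rates.decay_rates
    return np.array([rates.phi - d1 * n[0],
                     rates.phi1 * n[0] - d2 * n[1],
                     rates.phi4 * n[1] - d4 * n[2],
                     rates.phi8 * n[1] - d8 * n[3]])


def rk4_simulate(rates: Rates, init: CompartmentState, t_end: float,
                 dt: float = DEFAULT_DT) -> pd.DataFrame:
    """Classical fourth-order Runge–Kutta trajectory on a fixed grid.

    Parameters
    ----------
    t_end : float
        End time, days (>= 0).
    dt : float
        Step, days.  A warning (not an error) is raised when ``dt`` exceeds
        half the fastest model timescale, where accuracy degrades.

    Returns
    -------
    pandas.DataFrame
        Columns ``t, n1, n2, n3`` (pooled) or ``t, n1, n2, n3, n4, n8``
        (lineage; ``n3`` is the ``n4 + n8`` view).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    if init.is_split != isinstance(rates, LineageRates):
        raise ValueError("initial state does not match the model family")
    fastest = max(rates.decay_rates)
    if fastest > 0 and dt >= 0.5 / fastest:
        warnings.warn(
            f"dt = {dt:g} d is >= half the fastest timescale ({1 / fastest:.3g} d); "
            "accuracy of the RK4 trajectory may suffer", stacklevel=2)
    n_steps = int(round(t_end / dt))
    n = np.asarray(init.counts(), dtype=float)
    out = np.empty((n_steps + 1, n.size))
    out[0] = n
    for k in range(n_steps):
        k1 = _deriv(rates, n)
        k2 = _deriv(rates, n + 0.5 * dt * k1)
        k3 = _deriv(rates, n + 0.5 * dt * k2)
        k4 = _deriv(rates, n + dt * k3)
        n = n + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[k + 1] = n
    t = np.arange(n_steps + 1) * dt
    if isinstance(rates, PooledRates):
        return pd.DataFrame({"t": t, "n1": out[:, 0], "n2": out[:, 1], "n3": out[:, 2]})
    return pd.DataFrame({"t": t, "n1": out[:, 0], "n2": out[:, 1],
                         "n3": out[:, 2] + out[:, 3], "n4": out[:, 2], "n8": out[:, 3]})


def lineage_to_pooled(rates: LineageRates, state: CompartmentState) -> PooledRates:
    """Count-weighted effective pooled-SP rates of a lineage-resolved model.

    The two model families agree when ``phi2 = phi4 + phi8`` and the pooled SP
    egress/death/proliferation fluxes match the summed lineage fluxes, i.e.
    ``phi3 n3 = xi4 n4 + xi8 n8`` (and likewise for ``mu3``, ``lam3``), which
    fixes the pooled rates as ``n4/n8``-weighted averages at the given state.
    """
    if not state.is_split:
        raise ValueError("a lineage-resolved (n4, n8) state is required")
    n3 = state.n3
    if n3 <= 0:
        raise ValueError("count-weighted pooled rates are undefined at n3 = n4 + n8 = 0")
    w4, w8 = state.n4 / n3, state.n8 / n3
    return PooledRates(
        phi=rates.phi, phi1=rates.phi1, mu1=rates.mu1,
        phi2=rates.phi4 + rates.phi8, mu2=rates.mu2,
        phi3=w4 * rates.xi4 + w8 * rates.xi8,
        mu3=w4 * rates.mu4 + w8 * rates.mu8,
        lam3=w4 * rates.lam4 + w8 * rates.lam8,
    )


def write_trajectory_csv(traj: pd.DataFrame, path) -> None:
    traj.to_csv(path, index=False)
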
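"""Steady-state computation and trajectory simulation.

All simulations start from the pre-stimulation steady state (ligand at its
basal level); the HGF input is applied as a constant, non-depleting species
concentration from t = 0.  Units are molecules/cell and minutes throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import _integrate
from .network import ReactionNetwork, build_hgf_network, conserved_moieties
from .params import ParameterSet, basal_steady_state, reaction_rate_constants

__all__ = ["TrajectorySet", "steady_state", "simulate", "integrate_network",
           "SteadyStateError", "IntegrationError"]

RTOL = 1e-8
ATOL = 1e-10


class SteadyStateError(RuntimeError):
    pass


class IntegrationError(RuntimeError):
    pass


@dataclass
class TrajectorySet:
    """Species x time trajectory matrix for one experimental condition."""

    times: np.ndarray
    states: np.ndarray  # (n_species, n_times)
    species_names: list[str]
    condition: str = ""
    dose: float = 0.0

    def state(self, name: str) -> np.ndarray:
        return self.states[self.species_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states.T, columns=self.species_names)
        df.insert(0, "time", self.times)
        return df


def _rate_jacobian(net: ReactionNetwork, k: np.ndarray, x: np.ndarray,
                   E: np.ndarray) -> np.ndarray:
    """d(rates)/d(x) for mass-action monomial rates (dense, reactions x species)."""
    n_r, n_s = E.shape
    J = np.zeros((n_r, n_s))
    for r in range(n_r):
        nz = np.nonzero(E[r])[0]
        for s in nz:
            prod = k[r]
            for q in nz:
                e = E[r, q]
                if q == s:
                    e -= 1
                    prod *= e + 1  # power rule coefficient
                prod *= max(x[q], 0.0) ** e
            J[r, s] = prod
    return J


def integrate_network(net: ReactionNetwork, k: np.ndarray, x0: np.ndarray,
                      times: np.ndarray, rtol: float = RTOL, atol: float = ATOL,
                      packed: dict | None = None, max_steps: int = 2_000_000,
                      fallback: bool = True) -> np.ndarray:
    """Integrate the mass-action ODEs, returning states (n_species, n_times).

    Uses the compiled adaptive Runge-Kutta loop; falls back to scipy's LSODA
    if the step budget is exhausted (stiff regimes).  With ``fallback=False``
    a step-budget overrun raises immediately (used inside optimization, where
    a pathological parameter corner should fail fast instead of stalling).
    """
    packed = packed if packed is not None else _integrate.pack_network(net)
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    prepend = t[0] != 0.0
    t_eval = np.concatenate([[0.0], t]) if prepend else t
    out, status = _integrate.integrate(x0, t_eval, k, packed, rtol, atol,
                                       max_steps=max_steps)
    if status != 0 and not fallback:
        raise IntegrationError("step budget exhausted")
    if status != 0:
        sol = solve_ivp(
            lambda _, x: _integrate.rhs(x, k, packed), (t_eval[0], t_eval[-1]),
            x0, t_eval=t_eval, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(f"integration failed: {sol.message}")
        out = sol.y.T
    states = out[1:] if prepend else out
    if np.min(states) < -1e-6 * max(1.0, np.max(np.abs(states))):
        raise IntegrationError("negative state beyond tolerance")
    return states.T


def steady_state(net: ReactionNetwork, params, x0: np.ndarray | None = None,
                 tol: float = 1e-9, max_equilibration: float = 1e6):
    """Pre-stimulation steady state of a network.

    For the reference build with a parameter dict/:class:`ParameterSet`, the
    analytical steady-state expressions are evaluated and Newton-verified.  For
    a generic network, ``params`` is the per-reaction rate-constant vector and
    ``x0`` supplies the conserved totals and the Newton starting point; rows of
    the singular steady-state system are replaced by the conservation relations
    (Newton on the reduced system), with numeric pre-equilibration as fallback.

    Returns the state vector; raises :class:`SteadyStateError` on
    non-convergence.
    """
    if isinstance(params, (dict, ParameterSet)):
        p = params.native() if isinstance(params, ParameterSet) else params
        ss = basal_steady_state(p)
        return np.array([ss[s.name] for s in net.species])

    k = np.asarray(params, dtype=float)
    if x0 is None:
        raise ValueError("generic steady_state needs x0 for conserved totals")
    x0 = np.asarray(x0, dtype=float)
    packed = _integrate.pack_network(net)
    E = net.rate_exponents()
    S = net.stoichiometry_matrix.astype(float)
    moieties = conserved_moieties(net)

    # pick one dependent species per moiety whose ODE row is replaced
    replaced: list[int] = []
    L_rows: list[np.ndarray] = []
    for v in moieties:
        nz = [i for i in np.nonzero(v)[0] if i not in replaced]
        if not nz:
            continue
        replaced.append(nz[-1])
        L_rows.append(v.astype(float))
    totals = [v @ x0 for v in L_rows]

    def fun(x):
        f = _integrate.rhs(x, k, packed)
        for row, (i, v, tot) in enumerate(zip(replaced, L_rows, totals)):
            f[i] = v @ x - tot
        return f

    def jac(x):
        J = S @ _rate_jacobian(net, k, x, E)
        for i, v in zip(replaced, L_rows):
            J[i, :] = v
        return J

    guess = x0.copy()
    for attempt in range(2):
        sol = root(fun, guess, jac=jac, method="hybr", tol=1e-12)
        x = sol.x
        dx = _integrate.rhs(x, k, packed)
        scale = np.maximum(np.abs(x), 1.0)
        if sol.success and np.all(x > -1e-9) and np.max(np.abs(dx) / scale) < tol:
            return np.maximum(x, 0.0)
        # numeric pre-equilibration fallback, then retry Newton
        t_eval = np.array([0.0, max_equilibration])
        states = integrate_network(net, k, np.maximum(guess, 0.0), t_eval)
        guess = states[:, -1]
    dx = _integrate.rhs(guess, k, packed)
    if np.max(np.abs(dx) / np.maximum(np.abs(guess), 1.0)) < tol:
        return np.maximum(guess, 0.0)
    raise SteadyStateError("steady state did not converge within iteration budget")


def simulate(net: ReactionNetwork, params, dose: float, times,
             condition: str = "", rtol: float = RTOL, atol: float = ATOL,
             packed: dict | None = None, x0: np.ndarray | None = None,
             max_steps: int = 2_000_000, fallback: bool = True) -> TrajectorySet:
    """Simulate the HGF response of the reference network.

    ``params`` is a native-scale parameter dict or :class:`ParameterSet`.
    The trajectory is initialized at the pre-stimulation steady state and the
    ligand input (``hgf_scale`` x dose, plus basal ligand) is applied from t=0.
    """
    p = params.native() if isinstance(params, ParameterSet) else dict(params)
    t = np.asarray(times, dtype=float)
    if t[0] != 0.0:
        raise ValueError("times must start at 0 (stimulation time)")
    k = reaction_rate_constants(net, p)
    if x0 is None:
        x0 = steady_state(net, p)
    x0 = np.array(x0, dtype=float)
    x0[net.species_index["HGF"]] = p["hgf_scale"] * (dose + p["hgf_basal"])
    states = integrate_network(net, k, x0, t, rtol=rtol, atol=atol,
                               packed=packed, max_steps=max_steps,
                               fallback=fallback)
    return TrajectorySet(times=t, states=states, species_names=net.species_names,
                         condition=condition, dose=float(dose))


_REFERENCE_CACHE: dict = {}


def reference_network_packed() -> tuple[ReactionNetwork, dict]:
    """Cached reference network and its packed sparse encoding."""
    if "net" not in _REFERENCE_CACHE:
        net = build_hgf_network()
        _REFERENCE_CACHE["net"] = net
        _REFERENCE_CACHE["packed"] = _integrate.pack_network(net)
    return _REFERENCE_CACHE["net"], _REFERENCE_CACHE["packed"]
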
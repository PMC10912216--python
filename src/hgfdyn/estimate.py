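"""Maximum-likelihood calibration, profile-likelihood identifiability and BIC.

The objective is the standard -2 log-likelihood of independent Gaussian
observations, sum_i ((y_model,i - y_data,i) / sigma_i)^2 up to an additive
constant.  Optimization runs on the log10-parameter scale with a deterministic
multi-start scheme: Latin-hypercube starting points drawn from the bounds with
a fixed seed, each start refined by a trust-region least-squares optimizer,
results sorted into a waterfall.  Identifiability is assessed by the profile
likelihood: one parameter fixed along an adaptive grid, all others
re-optimized; the 95% confidence interval collects grid values whose profile
lies within the chi-square(1 dof) threshold of the optimum.  Hypotheses about
which parameters are condition-specific are compared with the Bayesian
information criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import chi2, qmc

from .observe import ObservationModel, default_observation_model
from .simulate import IntegrationError, reference_network_packed, simulate

__all__ = ["FitProblem", "FitResult", "Profile", "negloglik", "multistart_fit",
           "profile_likelihood", "bic", "compare_hypotheses", "free_parameter_ids"]

CHI2_95_1DOF = float(chi2.ppf(0.95, 1))   # 3.84
CONVERGENCE_TOL = 0.01                    # objective gap counted as "same optimum"


def free_parameter_ids(shared: list[str], specific: list[str],
                       conditions: list[str]) -> list[str]:
    """Parameter ids of a hypothesis: shared names plus 'name@condition'."""
    ids = list(shared)
    for name in specific:
        ids += [f"{name}@{c}" for c in conditions]
    return ids


@dataclass
class FitProblem:
    """Model + data + hypothesis: everything the objective needs.

    ``data`` is an aligned long-format table (target, condition, dose, time,
    value, sigma) whose targets are observables of ``om``.  ``free`` lists the
    free parameter ids: a bare model-parameter name is shared across
    conditions, ``name@condition`` is condition-specific, ``scale_<target>``
    (or ``offset_<target>``) is a free observation parameter.  Everything else
    is fixed at ``base``.  ``abundance`` optionally adds log2-scale Gaussian
    observations of abundance parameters (columns: parameter, condition,
    log2_value, sd).
    """

    data: pd.DataFrame
    base: dict[str, float]
    free: list[str]
    bounds: dict[str, tuple[float, float]]          # log10 bounds per free id
    conditions: dict[str, float]                    # label -> HGF dose (ng/ml)
    om: ObservationModel = field(default_factory=default_observation_model)
    abundance: pd.DataFrame | None = None
    log_residuals: bool = False                     # residuals on log10 signal

    def __post_init__(self):
        need = {"target", "condition", "dose", "time", "value", "sigma"}
        if not need <= set(self.data.columns):
            raise ValueError(f"data table needs columns {sorted(need)}")
        unknown = set(self.data["condition"]) - set(self.conditions)
        if unknown:
            raise ValueError(f"data conditions not in the condition map: {unknown}")
        for pid in self.free:
            if pid not in self.bounds:
                raise ValueError(f"free parameter {pid!r} has no bounds")
            lo, hi = self.bounds[pid]
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"free parameter {pid!r}: bounds must be finite")
        self._index = self._build_index()

    def _build_index(self):
        """Pre-group data rows per (condition, dose) with their time grids."""
        groups = []
        pos = 0
        for (cond, dose), sub in self.data.groupby(["condition", "dose"], sort=False):
            times = np.unique(np.concatenate([[0.0], sub["time"].to_numpy()]))
            t_idx = {t: i for i, t in enumerate(times)}
            per_target = []
            for target, tsub in sub.groupby("target", sort=False):
                per_target.append((
                    target,
                    tsub["time"].map(t_idx).to_numpy(dtype=int),
                    tsub["value"].to_numpy(dtype=float),
                    tsub["sigma"].to_numpy(dtype=float),
                ))
            n_rows = len(sub)
            groups.append((cond, float(dose), times, per_target, n_rows))
            pos += n_rows
        return groups

    # -- parameter plumbing -----------------------------------------------

    def start_point(self) -> np.ndarray:
        """Mid-bounds default start (log10)."""
        return np.array([np.mean(self.bounds[p]) for p in self.free])

    def split(self, theta: np.ndarray) -> tuple[dict, dict, dict]:
        """theta (log10) -> (shared model params, per-condition overrides,
        observation overrides)."""
        shared, per_cond, obs = {}, {c: {} for c in self.conditions}, {}
        for pid, v in zip(self.free, 10.0 ** np.asarray(theta, dtype=float)):
            if pid.startswith(("scale_", "offset_")):
                obs[pid] = v
            elif "@" in pid:
                name, cond = pid.split("@", 1)
                per_cond[cond][name] = v
            else:
                shared[pid] = v
        return shared, per_cond, obs

    def condition_params(self, theta: np.ndarray) -> dict[str, dict[str, float]]:
        shared, per_cond, _ = self.split(theta)
        out = {}
        for cond in self.conditions:
            p = dict(self.base)
            p.update(shared)
            p.update(per_cond[cond])
            out[cond] = p
        return out

    def _observation(self, theta: np.ndarray) -> tuple[dict, dict]:
        _, _, obs = self.split(theta)
        scales = dict(self.om.scales)
        offsets = dict(self.om.offsets)
        for pid, v in obs.items():
            kind, target = pid.split("_", 1)
            (scales if kind == "scale" else offsets)[target] = v
        return scales, offsets

    # -- objective --------------------------------------------------------

    def residuals(self, theta: np.ndarray) -> np.ndarray:
        net, packed = reference_network_packed()
        params = self.condition_params(theta)
        scales, offsets = self._observation(theta)
        out = []
        for cond, dose, times, per_target, n_rows in self._index:
            p = params[cond]
            try:
                traj = simulate(net, p, dose, times, packed=packed,
                                rtol=1e-7, atol=1e-9, max_steps=30_000,
                                fallback=False)
            except (IntegrationError, ValueError, FloatingPointError):
                out.append(np.full(n_rows, 1e6))
                continue
            for target, row_t, values, sigmas in per_target:
                tot = sum(traj.state(s) for s in self.om.mapping[target])
                model = (scales[target] * tot + offsets[target])[row_t]
                if self.log_residuals:
                    res = (np.log10(np.clip(model, 1e-12, None))
                           - np.log10(values)) / sigmas
                else:
                    res = (model - values) / sigmas
                out.append(res)
        if self.abundance is not None:
            ab = self.abundance
            pred = np.array([np.log2(params[c][p])
                             for p, c in zip(ab["parameter"], ab["condition"])])
            out.append((pred - ab["log2_value"].to_numpy()) / ab["sd"].to_numpy())
        return np.concatenate(out)

    @property
    def n_data(self) -> int:
        n = len(self.data)
        if self.abundance is not None:
            n += len(self.abundance)
        return n


def negloglik(problem: FitProblem, theta: np.ndarray) -> float:
    """-2 log-likelihood (Gaussian, up to constants) at log10 parameters."""
    theta = np.asarray(theta, dtype=float)
    lo = np.array([problem.bounds[p][0] for p in problem.free])
    hi = np.array([problem.bounds[p][1] for p in problem.free])
    if np.any(theta < lo - 1e-9) or np.any(theta > hi + 1e-9):
        raise ValueError("parameters outside bounds")
    r = problem.residuals(theta)
    return float(r @ r)


@dataclass
class FitResult:
    """Multi-start optimization outcome."""

    waterfall: np.ndarray          # sorted objectives, one per start
    start_params: np.ndarray       # (n_starts, n_free), sorted like waterfall
    best_params: np.ndarray        # log10
    best_objective: float
    free: list[str]
    convergence_fraction: float
    n_starts: int
    seed: int

    def params_native(self) -> dict[str, float]:
        return {p: 10.0 ** v for p, v in zip(self.free, self.best_params)}


def _optimize(problem: FitProblem, x0: np.ndarray, max_nfev: int | None,
              xtol: float = 1e-10, ftol: float = 1e-10):
    lo = np.array([problem.bounds[p][0] for p in problem.free])
    hi = np.array([problem.bounds[p][1] for p in problem.free])
    return least_squares(problem.residuals, np.clip(x0, lo, hi),
                         bounds=(lo, hi), method="trf", x_scale="jac",
                         xtol=xtol, ftol=ftol, gtol=1e-10, max_nfev=max_nfev)


def multistart_fit(problem: FitProblem, n_starts: int = 50, seed: int = 0,
                   max_nfev: int | None = 60, n_polish: int = 3,
                   extra_starts: np.ndarray | None = None) -> FitResult:
    """Deterministic multi-start trust-region fit.

    Starting points are a seeded Latin hypercube over the bounds; every start
    is optimized to local convergence (iteration-capped), the best few are
    polished to tight tolerance, and the waterfall is the sorted list of final
    objectives.  Identical seeds give identical results.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    lo = np.array([problem.bounds[p][0] for p in problem.free])
    hi = np.array([problem.bounds[p][1] for p in problem.free])
    sampler = qmc.LatinHypercube(d=len(problem.free), seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)
    if extra_starts is not None:
        starts = np.vstack([np.atleast_2d(extra_starts), starts])
        n_starts = len(starts)

    objectives = np.full(n_starts, np.inf)
    finals = np.full((n_starts, len(problem.free)), np.nan)
    failures = []
    for i in range(n_starts):
        try:
            sol = _optimize(problem, starts[i], max_nfev)
            objectives[i] = 2 * sol.cost
            finals[i] = sol.x
        except Exception as err:  # noqa: BLE001 - collected and reported
            failures.append(f"start {i}: {err}")
    if not np.isfinite(objectives).any():
        raise RuntimeError("all optimization starts failed: " + "; ".join(failures))

    # polish the leading starts to tight convergence
    for i in np.argsort(objectives)[:n_polish]:
        if not np.isfinite(objectives[i]):
            continue
        sol = _optimize(problem, finals[i], max_nfev=400)
        if 2 * sol.cost < objectives[i]:
            objectives[i] = 2 * sol.cost
            finals[i] = sol.x

    order = np.argsort(objectives)
    objectives, finals = objectives[order], finals[order]
    best = objectives[0]
    conv = float(np.mean(objectives <= best + CONVERGENCE_TOL))
    return FitResult(waterfall=objectives, start_params=finals,
                     best_params=finals[0].copy(), best_objective=float(best),
                     free=list(problem.free), convergence_fraction=conv,
                     n_starts=n_starts, seed=seed)


@dataclass
class Profile:
    """Profile-likelihood curve of one parameter."""

    parameter: str
    grid: np.ndarray               # log10 values (sorted)
    objective: np.ndarray          # re-optimized objective per grid value
    best_value: float              # log10 at the optimum
    best_objective: float
    threshold: float
    ci: tuple[float, float]        # log10; +-inf when open
    lower_open: bool
    upper_open: bool

    @property
    def identifiable(self) -> bool:
        return not (self.lower_open or self.upper_open)

    def ci_native(self) -> tuple[float, float]:
        return tuple(10.0 ** np.asarray(self.ci))


def profile_likelihood(problem: FitProblem, fit: FitResult, parameter: str,
                       level: float = 0.95, init_step: float = 0.02,
                       target_increment: float = 0.7, max_points: int = 30,
                       max_step: float = 0.75, max_nfev: int = 60) -> Profile:
    """Profile one parameter of a converged fit.

    The parameter is fixed along an adaptively stepped log10 grid (step grows
    where the profile is flat, shrinks where it climbs); all remaining
    parameters are re-optimized warm-started from the neighboring grid point.
    The CI at ``level`` collects the grid region within the chi2(1) quantile of
    the optimum; a side that reaches its bound without crossing is "open"
    (non-identifiable direction).
    """
    if parameter not in fit.free:
        raise KeyError(f"{parameter!r} is not a free parameter of the fit")
    j = fit.free.index(parameter)
    threshold = float(chi2.ppf(level, 1))
    lo, hi = problem.bounds[parameter]

    others = [p for p in fit.free if p != parameter]
    other_idx = np.array([i for i in range(len(fit.free)) if i != j], dtype=int)
    lo_o = np.array([problem.bounds[p][0] for p in others])
    hi_o = np.array([problem.bounds[p][1] for p in others])

    def objective_at(value: float, warm: np.ndarray) -> tuple[float, np.ndarray]:
        """Re-optimize the non-profiled parameters with ``parameter`` frozen."""
        if len(others) == 0:
            r = problem.residuals(np.array([value]))
            return float(r @ r), warm
        full = np.empty(len(fit.free))
        full[j] = value

        def residuals(x):
            full[other_idx] = x
            return problem.residuals(full)

        sol = least_squares(residuals, np.clip(warm, lo_o, hi_o),
                            bounds=(lo_o, hi_o), method="trf", x_scale="jac",
                            xtol=1e-9, ftol=1e-9, max_nfev=max_nfev)
        return float(2 * sol.cost), sol.x

    base_warm = np.delete(fit.best_params, j)
    grid = [fit.best_params[j]]
    objs = [fit.best_objective]
    open_side = {}
    for direction in (+1, -1):
        value = fit.best_params[j]
        warm = base_warm.copy()
        h = init_step
        last_obj = fit.best_objective
        open_side[direction] = True
        for _ in range(max_points):
            value_next = value + direction * h
            bounded = False
            if value_next <= lo:
                value_next, bounded = lo, True
            elif value_next >= hi:
                value_next, bounded = hi, True
            obj, warm = objective_at(value_next, warm)
            grid.append(value_next)
            objs.append(obj)
            dinc = obj - last_obj
            value, last_obj = value_next, obj
            if obj > fit.best_objective + threshold + 0.25:
                open_side[direction] = False
                break
            if bounded:
                break
            # adapt the grid step toward ~target_increment objective increments
            if dinc < 0.3 * target_increment:
                h = min(h * 2.0, max_step)
            elif dinc > 1.5 * target_increment:
                h = max(h * 0.4, 1e-4)

    order = np.argsort(grid)
    grid = np.asarray(grid)[order]
    objs = np.asarray(objs)[order]

    cut = fit.best_objective + threshold

    def crossing(side: int) -> float:
        idx = np.nonzero(objs <= cut)[0]
        edge = idx[0] if side < 0 else idx[-1]
        nxt = edge - 1 if side < 0 else edge + 1
        if nxt < 0 or nxt >= len(grid):
            return -np.inf if side < 0 else np.inf
        x0, x1 = grid[edge], grid[nxt]
        y0, y1 = objs[edge], objs[nxt]
        if y1 <= cut or y1 == y0:
            return -np.inf if side < 0 else np.inf
        return float(x0 + (cut - y0) * (x1 - x0) / (y1 - y0))

    lo_ci = crossing(-1) if not open_side[-1] else -np.inf
    hi_ci = crossing(+1) if not open_side[+1] else np.inf
    return Profile(parameter=parameter, grid=grid, objective=objs,
                   best_value=float(fit.best_params[j]),
                   best_objective=fit.best_objective, threshold=threshold,
                   ci=(lo_ci, hi_ci),
                   lower_open=not np.isfinite(lo_ci),
                   upper_open=not np.isfinite(hi_ci))


def bic(fit_or_objective, n_data: int, k_params: int | None = None) -> float:
    """Bayesian information criterion: objective + k ln(n); lower is better."""
    if n_data <= 0:
        raise ValueError("n_data must be positive")
    if isinstance(fit_or_objective, FitResult):
        objective = fit_or_objective.best_objective
        k = len(fit_or_objective.free) if k_params is None else k_params
    else:
        objective = float(fit_or_objective)
        if k_params is None:
            raise ValueError("k_params required with a bare objective")
        k = k_params
    return float(objective + k * np.log(n_data))


def compare_hypotheses(problems: dict[str, FitProblem], n_starts: int = 10,
                       seed: int = 0, max_nfev: int | None = 60) -> pd.DataFrame:
    """Fit competing condition-specificity hypotheses and rank them by BIC.

    All problems must share the same data (same likelihood denominator).
    Returns a table (hypothesis, objective, k, n, bic) sorted ascending by BIC.
    """
    items = list(problems.items())
    ref = items[0][1]
    for name, prob in items[1:]:
        same = prob.data.reset_index(drop=True).equals(ref.data.reset_index(drop=True))
        if prob.abundance is not None or ref.abundance is not None:
            same = same and prob.abundance is not None and ref.abundance is not None \
                and prob.abundance.reset_index(drop=True).equals(
                    ref.abundance.reset_index(drop=True))
        if not same:
            raise ValueError(f"hypothesis {name!r} does not share the data")
    rows = []
    for name, prob in items:
        fit = multistart_fit(prob, n_starts=n_starts, seed=seed, max_nfev=max_nfev)
        rows.append({"hypothesis": name, "objective": fit.best_objective,
                     "k": len(prob.free), "n": prob.n_data,
                     "bic": bic(fit, prob.n_data)})
    return pd.DataFrame(rows).sort_values("bic", ignore_index=True)
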
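"""Patient-adapted model fits and outcome correlation.

The calibrated mouse model is carried over to patient-derived primary human
hepatocytes: all mouse parameters stay fixed except a patient-specific subset
(basal MET phosphorylation rate and protein abundances) and two human-shared
kinetic parameters (the HGF-induced MET phosphorylation rate and the pMET
degradation rate), which are re-estimated by maximum likelihood on log-scale
residuals.  Model-derived per-patient features (k_basal, AUC of ppAKT, MET
abundance and their ratios) are then correlated with clinical covariates using
Spearman's rank correlation with AS 89 p-values (Best & Roberts 1975) and, for
the outcome block, partial Spearman correlations correcting for age, BMI,
fibrosis and the Charlson comorbidity index.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, t as t_dist

from .estimate import FitProblem, FitResult, multistart_fit
from .observe import default_observation_model
from .perturb import extract_features
from .simulate import reference_network_packed, simulate
from .synth import PatientDataset

__all__ = ["spearman_test", "partial_spearman", "significance_stars",
           "adapt_to_patients", "PatientFit", "patient_features",
           "rank_patients", "correlation_table"]

# ---------------------------------------------------------------------------
# Spearman correlation with AS 89 p-values

_AS89_C = (0.2274, 0.2531, 0.1745, 0.0758, 0.1033, 0.3932, 0.0879, 0.0151,
           0.0072, 0.0831, 0.0267, 0.04567)
_EXACT_MAX_N = 9
_null_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _null_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of S = sum(d^2): unique values and counts."""
    if n not in _null_cache:
        base = np.arange(1, n + 1)
        perms = np.array(list(itertools.permutations(base)), dtype=np.int64)
        S = ((perms - base) ** 2).sum(axis=1)
        vals, counts = np.unique(S, return_counts=True)
        _null_cache[n] = (vals, counts)
    return _null_cache[n]


def _edgeworth_upper(n: int, S: float) -> float:
    """AS 89 Edgeworth-series upper tail P(S_null >= S)."""
    c = _AS89_C
    b = 1.0 / n
    x = (6.0 * (S - 1.0) * b / (n * n - 1.0) - 1.0) * np.sqrt(1.0 / b - 1.0)
    y = x * x
    u = x * b * (c[0] + b * (c[1] + c[2] * b)
                 + y * (-c[3] + b * (c[4] + c[5] * b)
                 - y * b * (c[6] + c[7] * b
                 - y * (c[8] - c[9] * b
                 + y * b * (c[10] - c[11] * y)))))
    return float(np.clip(u / np.exp(y / 2.0) + norm.sf(x), 0.0, 1.0))


def _prho_upper(n: int, S: float) -> float:
    """AS 89 upper tail P(S_null >= S): exact for small n, Edgeworth beyond."""
    if n <= _EXACT_MAX_N:
        vals, counts = _null_distribution(n)
        total = counts.sum()
        return float(counts[vals >= S - 1e-9].sum() / total)
    return _edgeworth_upper(n, S)


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    stat = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * t_dist.sf(abs(stat), n - 2))


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided AS 89 p-value.

    For tie-free samples the p-value follows Best & Roberts' algorithm AS 89
    (exact small-sample null distribution, Edgeworth series for larger n);
    with ties it falls back to the t approximation, as the reference
    implementations do.  Constant input is flagged with a ValueError.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    rx, ry = rankdata(x), rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    has_ties = (len(np.unique(rx)) < n) or (len(np.unique(ry)) < n)
    if has_ties:
        return rho, _t_approx_p(rho, n)
    S = float(np.sum((rx - ry) ** 2))
    s_max = n * (n * n - 1) / 3.0          # reflection of S around its mean
    p = 2.0 * min(_prho_upper(n, S), _prho_upper(n, s_max - S))
    return rho, float(min(p, 1.0))


def partial_spearman(x, y, confounders) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given confounders.

    Rank-transforms every variable, removes the linear effect of the
    confounder ranks from both x and y, and correlates the residuals; the
    p-value uses the t approximation with n - 2 - k degrees of freedom.
    With no confounders this reduces to :func:`spearman_test`'s coefficient
    with a t-based p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Z = np.atleast_2d(np.asarray(confounders, dtype=float))
    if Z.size == 0:
        Z = np.empty((len(x), 0))
    elif Z.shape[0] != len(x):
        Z = Z.T
    n, k = len(x), Z.shape[1]
    if n <= k + 2:
        raise ValueError("need n > k + 2 observations")
    rx, ry = rankdata(x), rankdata(y)
    RZ = np.column_stack([np.ones(n)] + [rankdata(Z[:, i]) for i in range(k)])
    if np.linalg.matrix_rank(RZ) < RZ.shape[1]:
        raise ValueError("singular confounder matrix")
    beta_x, *_ = np.linalg.lstsq(RZ, rx, rcond=None)
    beta_y, *_ = np.linalg.lstsq(RZ, ry, rcond=None)
    ex, ey = rx - RZ @ beta_x, ry - RZ @ beta_y
    denom = np.sqrt((ex @ ex) * (ey @ ey))
    if denom == 0:
        raise ValueError("degenerate residuals in partial correlation")
    rho = float((ex @ ey) / denom)
    dof = n - 2 - k
    if abs(rho) >= 1.0:
        return rho, 0.0
    stat = rho * np.sqrt(dof / (1.0 - rho * rho))
    return rho, float(2.0 * t_dist.sf(abs(stat), dof))


def significance_stars(p: float) -> str:
    """Star annotation: *** p<0.001, ** p<0.01, * p<0.05."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Patient adaptation

#: human-shared kinetic parameters re-estimated when porting the mouse model
HUMAN_SHARED = ["k_act_MET", "k_deg_pMET"]
#: patient-specific subset (a patient analog of the diet-dysregulated set)
PATIENT_SPECIFIC = ["k_basal_MET", "k_total_MET", "k_total_AKT"]

PATIENT_TIMES = np.array([0.0, 1.0, 5.0, 15.0, 30.0, 60.0, 120.0])
PATIENT_AUC_WINDOW = (0.0, 120.0)


@dataclass
class PatientFit:
    """Per-patient and human-shared estimates on top of the fixed mouse fit."""

    fit: FitResult
    patients: list[str]
    mouse_params: dict[str, float]

    def patient_params(self, patient: str) -> dict[str, float]:
        est = self.fit.params_native()
        p = dict(self.mouse_params)
        for name in HUMAN_SHARED:
            if name in est:
                p[name] = est[name]
        for name in PATIENT_SPECIFIC:
            key = f"{name}@{patient}"
            if key in est:
                p[name] = est[key]
        return p


def adapt_to_patients(mouse_params: dict[str, float], data: PatientDataset,
                      seed: int = 0, n_starts: int = 6,
                      free_specific: list[str] | None = None,
                      max_nfev: int | None = 150) -> PatientFit:
    """Re-estimate the patient-specific and human-shared parameter subset.

    All other parameters stay fixed at the mouse estimates.  Residuals are
    computed on log10 signals (patient immunoblot data are analyzed on log
    scale).  Patients lacking any basal (dose 0) measurement are reported: for
    them k_basal is flagged as non-identifiable.
    """
    free_specific = free_specific if free_specific is not None else PATIENT_SPECIFIC
    tc = data.timecourses.copy()
    patients = sorted(tc["patient"].unique())
    no_basal = [p for p in patients
                if not ((tc["patient"] == p) & (tc["dose"] == 0)).any()]
    if no_basal:
        raise ValueError(
            f"patients without basal measurements (k_basal non-identifiable): {no_basal}")

    # long table in FitProblem layout; sigma converted to log10 scale
    tc["condition"] = tc["patient"]
    tc["sigma"] = tc["sigma"] / tc["value"] / np.log(10.0)
    table = tc[["target", "condition", "dose", "time", "value", "sigma"]]

    free = list(HUMAN_SHARED)
    bounds = {}
    for name in HUMAN_SHARED:
        c = np.log10(mouse_params[name])
        bounds[name] = (c - 1.5, c + 1.5)
    for name in free_specific:
        c = np.log10(mouse_params[name])
        for pid in patients:
            key = f"{name}@{pid}"
            free.append(key)
            bounds[key] = (c - 1.5, c + 1.5)

    problem = FitProblem(
        data=table, base=dict(mouse_params), free=free, bounds=bounds,
        conditions={pid: 40.0 for pid in patients},
        om=default_observation_model(), log_residuals=True)
    if not free:
        # empty free subset: the mouse fit is returned unchanged
        empty = FitResult(waterfall=np.array([0.0]),
                          start_params=np.zeros((1, 0)),
                          best_params=np.zeros(0), best_objective=0.0,
                          free=[], convergence_fraction=1.0, n_starts=0,
                          seed=seed)
        return PatientFit(fit=empty, patients=patients,
                          mouse_params=dict(mouse_params))
    fit = multistart_fit(problem, n_starts=n_starts, seed=seed,
                         max_nfev=max_nfev)
    return PatientFit(fit=fit, patients=patients,
                      mouse_params=dict(mouse_params))


def patient_features(pfit: PatientFit, dose: float = 40.0) -> pd.DataFrame:
    """Model-derived per-patient characteristics and their ratios.

    Returns one row per patient: k_basal, auc_ppakt, k_total_met and the
    ratios k_basal/auc_ppakt and k_basal/k_total_met.
    """
    net, packed = reference_network_packed()
    om = default_observation_model()
    rows = []
    for pid in pfit.patients:
        p = pfit.patient_params(pid)
        traj = simulate(net, p, dose, PATIENT_TIMES, packed=packed)
        feats = extract_features(traj, om, window=PATIENT_AUC_WINDOW)
        if feats.auc_ppAKT == 0 or p["k_total_MET"] == 0:
            raise ZeroDivisionError(f"patient {pid}: zero denominator in ratios")
        rows.append({
            "patient": pid,
            "k_basal": p["k_basal_MET"],
            "auc_ppakt": feats.auc_ppAKT,
            "k_total_met": p["k_total_MET"],
            "k_basal_over_auc_ppakt": p["k_basal_MET"] / feats.auc_ppAKT,
            "k_basal_over_k_total_met": p["k_basal_MET"] / p["k_total_MET"],
        })
    return pd.DataFrame(rows)


def rank_patients(features: pd.DataFrame, by: str = "k_basal",
                  ascending: bool = False) -> list[str]:
    """Patients ordered by a feature (default: descending basal MET rate).

    Ties are broken deterministically by patient id.
    """
    if by not in features.columns:
        raise KeyError(f"feature {by!r} missing")
    if features[by].isna().any():
        raise ValueError(f"feature {by!r} missing for some patients")
    ordered = features.sort_values([by, "patient"],
                                   ascending=[ascending, True], kind="mergesort")
    return ordered["patient"].tolist()


def correlation_table(features: pd.DataFrame, clinical: pd.DataFrame,
                      feature_cols: list[str] | None = None,
                      clinical_cols: list[str] | None = None,
                      outcome_cols: list[str] | None = None,
                      confounder_cols: tuple[str, ...] = ("age", "bmi",
                                                          "fibrosis", "cci")
                      ) -> pd.DataFrame:
    """Spearman correlation of model features with clinical variables.

    One row per (feature, clinical variable) with rho, p and significance
    stars; for outcome columns an additional partial-Spearman block corrects
    for the confounders (age, BMI, fibrosis, CCI).
    """
    merged = features.merge(clinical, on="patient")
    feature_cols = feature_cols or [c for c in features.columns if c != "patient"]
    clinical_cols = clinical_cols or [c for c in clinical.columns if c != "patient"]
    outcome_cols = outcome_cols or []
    Z = merged[list(confounder_cols)].to_numpy() if confounder_cols else None
    rows = []
    for f in feature_cols:
        for c in clinical_cols:
            rho, p = spearman_test(merged[f], merged[c])
            row = {"feature": f, "variable": c, "rho": rho, "p": p,
                   "stars": significance_stars(p)}
            if c in outcome_cols and Z is not None and len(merged) > Z.shape[1] + 2:
                prho, pp = partial_spearman(merged[f], merged[c], Z)
                row.update({"partial_rho": prho, "partial_p": pp,
                            "partial_stars": significance_stars(pp)})
            rows.append(row)
    return pd.DataFrame(rows)
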
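"""Observables, multi-gel immunoblot alignment, and abundance anchoring.

Quantitative immunoblot signals are only relative: each gel/experiment has its
own unknown multiplicative scale.  The alignment model assumes every raw
measurement ``Y_ij`` of biological effect ``i`` on gel ``j`` follows

    Y_ij ~ y_i / s_j,        sigma_ij ~ e_rel * y_i / s_j,

i.e. a shared latent effect ``y_i`` divided by a per-gel scaling factor ``s_j``
with a relative error of size ``e_rel``.  On the log scale this is an additive
two-way Gaussian model and the maximum-likelihood solution is a linear least
squares problem; the gauge freedom (multiplying all ``s_j`` and ``y_i``
together) is fixed by setting the geometric mean of the scaling factors of each
target to one.

Protein abundances measured as label-free (LFQ) intensities are likewise only
relative; a single absolute anchor (AKT molecules/cell from quantitative
immunoblotting) converts them all to molecules/cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .simulate import TrajectorySet

__all__ = [
    "ObservationModel",
    "default_observation_model",
    "observe",
    "align_replicates",
    "AlignedDataset",
    "lfq_to_molecules",
    "DisconnectedDesignError",
]

#: columns identifying one biological effect in a raw measurement table
EFFECT_COLS = ["target", "condition", "dose", "time"]
#: columns identifying one scaling group (gel x target)
SCALE_COLS = ["target", "experiment"]


class DisconnectedDesignError(ValueError):
    """Scaling factors are not identifiable: the gel/effect design splits into
    disconnected blocks (listed in ``blocks``)."""

    def __init__(self, target: str, blocks: list[list[str]]):
        self.target = target
        self.blocks = blocks
        super().__init__(
            f"target {target!r}: scaling design is disconnected; "
            f"blocks of experiments: {blocks}")


@dataclass
class ObservationModel:
    """Linear observation functions: observable = scale * sum(states) + offset."""

    mapping: dict[str, list[str]]
    scales: dict[str, float] = field(default_factory=dict)
    offsets: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for obs, states in self.mapping.items():
            if not states:
                raise ValueError(f"observable {obs!r} maps to no model state")
            if self.scales.setdefault(obs, 1.0) <= 0:
                raise ValueError(f"observable {obs!r}: scale must be positive")
            self.offsets.setdefault(obs, 0.0)

    def observables(self) -> list[str]:
        return list(self.mapping)


def default_observation_model() -> ObservationModel:
    """Antibody mapping of the reference immunoblot panel.

    The Ser473 antibody detects exclusively the doubly phosphorylated AKT;
    the Thr308 antibody detects Thr308 phosphorylation regardless of Ser473
    (pAKT + ppAKT); total-protein antibodies sum all forms.
    """
    return ObservationModel({
        "pMET": ["pMET"],
        "pMEK": ["pMEK"],
        "pERK": ["pERK"],
        "pAKT_T308": ["pAKT", "ppAKT"],
        "ppAKT_S473": ["ppAKT"],
        "pS6K": ["pS6K"],
        "pS6": ["pS6"],
        "tMET": ["MET", "pMET"],
        "tERK": ["ERK", "pERK"],
        "tAKT": ["AKT", "pAKT", "ppAKT"],
        "tS6": ["S6", "pS6"],
    })


def observe(traj: TrajectorySet, om: ObservationModel,
            observables: list[str] | None = None) -> pd.DataFrame:
    """Apply the observation functions to a trajectory.

    Returns a tidy frame (time, observable, value) in arbitrary units.
    """
    rows = []
    for obs in observables or om.observables():
        states = om.mapping[obs]
        missing = [s for s in states if s not in traj.species_names]
        if missing:
            raise KeyError(f"observable {obs!r}: missing model states {missing}")
        total = sum(traj.state(s) for s in states)
        vals = om.scales[obs] * total + om.offsets[obs]
        rows.append(pd.DataFrame({"time": traj.times, "observable": obs,
                                  "value": vals}))
    return pd.concat(rows, ignore_index=True)


@dataclass
class AlignedDataset:
    """Replicate-aligned measurements with 1-sigma uncertainties."""

    data: pd.DataFrame          # EFFECT_COLS + value (y_i) + sigma
    scaling: pd.DataFrame       # SCALE_COLS + scale (s_j)
    e_rel: dict[str, float]     # per-target relative error parameter


def _check_connected(sub: pd.DataFrame, target: str) -> None:
    effs = {e: i for i, e in enumerate(sub["_effect"].unique())}
    exps = {e: i for i, e in enumerate(sub["experiment"].unique())}
    n_i, n_j = len(effs), len(exps)
    rows = sub["_effect"].map(effs).to_numpy()
    cols = sub["experiment"].map(exps).to_numpy() + n_i
    n = n_i + n_j
    adj = coo_matrix((np.ones(len(sub) * 2),
                      (np.r_[rows, cols], np.r_[cols, rows])), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        inv = {v + n_i: k for k, v in exps.items()}
        blocks = [[inv[i] for i in np.nonzero(labels == c)[0] if i >= n_i]
                  for c in range(n_comp)]
        raise DisconnectedDesignError(target, [b for b in blocks if b])


def align_replicates(raw: pd.DataFrame, min_sigma_rel: float = 1e-6) -> AlignedDataset:
    """Maximum-likelihood alignment of multi-gel measurements.

    ``raw`` is a long-format table with columns target, condition, dose, time,
    experiment, value (all values > 0).  Per target, log-scale least squares
    estimates the aligned effects ``y_i``, scaling factors ``s_j`` (geometric
    mean fixed to 1) and the relative error ``e_rel``; per-effect 1-sigma
    intervals follow from the linear-model covariance.
    """
    required = set(EFFECT_COLS + ["experiment", "value"])
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"raw table is missing columns {sorted(missing)}")
    if not (raw["value"] > 0).all():
        raise ValueError("raw measurements must be strictly positive")

    out_rows, scale_rows, e_rel = [], [], {}
    for target, sub in raw.groupby("target", sort=False):
        sub = sub.copy()
        sub["_effect"] = list(zip(sub["condition"], sub["dose"], sub["time"]))
        _check_connected(sub, target)
        effects = list(dict.fromkeys(sub["_effect"]))
        exps = list(dict.fromkeys(sub["experiment"]))
        n_i, n_j, n = len(effects), len(exps), len(sub)
        ei = sub["_effect"].map({e: i for i, e in enumerate(effects)}).to_numpy()
        xj = sub["experiment"].map({e: i for i, e in enumerate(exps)}).to_numpy()

        # log Y = log y_i - log s_j ; gauge: sum_j log s_j = 0
        A = np.zeros((n + 1, n_i + n_j))
        A[np.arange(n), ei] = 1.0
        A[np.arange(n), n_i + xj] = -1.0
        A[n, n_i:] = 1.0
        b = np.concatenate([np.log(sub["value"].to_numpy()), [0.0]])
        beta, *_ = np.linalg.lstsq(A, b, rcond=None)
        resid = A[:n] @ beta - b[:n]
        dof = max(n - (n_i + n_j - 1), 1)
        sigma_log = float(np.sqrt(resid @ resid / dof))
        sigma_log = max(sigma_log, min_sigma_rel)
        e_rel[target] = sigma_log

        # per-effect uncertainty from the linear-model covariance
        cov = np.linalg.pinv(A.T @ A) * sigma_log**2
        se_log = np.sqrt(np.maximum(np.diag(cov)[:n_i], 0.0))
        y = np.exp(beta[:n_i])
        for (cond, dose, time), yv, se in zip(effects, y, se_log):
            out_rows.append({"target": target, "condition": cond, "dose": dose,
                             "time": time, "value": yv,
                             "sigma": yv * max(se, min_sigma_rel)})
        for exp, ls in zip(exps, beta[n_i:]):
            scale_rows.append({"target": target, "experiment": exp,
                               "scale": float(np.exp(ls))})
    return AlignedDataset(pd.DataFrame(out_rows), pd.DataFrame(scale_rows), e_rel)


def lfq_to_molecules(lfq: pd.DataFrame, akt_molecules: float,
                     anchor: str = "AKT", value_col: str = "log2_intensity") -> pd.Series:
    """Convert relative LFQ intensities to absolute molecules/cell.

    ``lfq`` holds one row per protein (index or column 'protein') with log2
    intensities; the AKT anchor (molecules/cell from quantitative
    immunoblotting) fixes the shared conversion factor.  Replicate rows per
    protein are averaged on the log2 scale first.
    """
    if akt_molecules <= 0:
        raise ValueError("AKT anchor must be positive")
    df = lfq.reset_index() if "protein" not in lfq.columns else lfq
    mean_log2 = df.groupby("protein")[value_col].mean()
    if anchor not in mean_log2.index:
        raise KeyError(f"anchor protein {anchor!r} missing from LFQ table")
    intensity = np.exp2(mean_log2)
    factor = akt_molecules / intensity[anchor]
    return intensity * factor
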
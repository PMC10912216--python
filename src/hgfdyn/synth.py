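"""Synthetic-data generators with known ground truth.

Every stage of the analysis can be exercised without any external download:
the generators emulate (a) multi-gel quantitative immunoblot time courses and
dose responses with per-experiment multiplicative scaling and relative noise,
(b) DIA/LFQ-style log2 protein-abundance tables with one absolute anchor (AKT
molecules/cell), (c) a small surgical cohort whose outcomes are statistically
linked to a ground-truth basal MET phosphorylation rate, and (d) FUCCI
two-channel intensity traces with a known number of cell-cycle entries.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fucci import FucciTrace
from .network import DYSREGULATED_PARAMETERS
from .observe import ObservationModel, default_observation_model, observe
from .params import ParameterSet, reference_parameters
from .simulate import reference_network_packed, simulate

__all__ = [
    "GroundTruth",
    "default_ground_truth",
    "BlotDesign",
    "gen_blot_dataset",
    "gen_abundance_dataset",
    "PatientDataset",
    "gen_patient_cohort",
    "gen_fucci_traces",
]

#: protein labels of the LFQ table mapped to abundance parameters
PROTEIN_TO_PARAM = {
    "MET": "k_total_MET", "MEK": "k_total_MEK", "ERK": "k_total_ERK",
    "PI3K": "k_total_PI3K", "AKT": "k_total_AKT", "TSC": "k_total_TSC",
    "mTORC1": "k_total_mTORC1", "S6K": "k_total_S6K", "S6": "k_total_S6",
    "SIN1": "k_total_mTORC2", "IRS1": "k_total_IRS1",
}


@dataclass
class GroundTruth:
    """True SD and WD parameterizations of the synthetic study.

    SD and WD differ in exactly the twelve dysregulated parameters: the basal
    MET phosphorylation rate (default 5-fold higher under Western diet) and the
    eleven protein abundances (default shifts: MET, SIN1/mTORC2 and S6 reduced,
    TSC increased, matching the measured directionality; the remaining
    abundances diet-specific but numerically equal).
    """

    base: ParameterSet = field(default_factory=reference_parameters)
    kbasal_fold: float = 5.0
    abundance_shifts: dict[str, float] = field(default_factory=lambda: {
        "k_total_MET": 0.6, "k_total_mTORC2": 0.7,
        "k_total_S6": 0.7, "k_total_TSC": 1.4})
    e_rel: float = 0.1
    scale_spread: float = 0.3     # lognormal sigma of the gel scaling factors
    lfq_log2_sd: float = 0.25     # replicate spread of log2 LFQ intensities
    lfq_factor: float = 1e-4      # arbitrary LFQ intensity units per molecule

    def sd_params(self) -> ParameterSet:
        return self.base

    def wd_params(self) -> ParameterSet:
        p = self.base.native()
        p["k_basal_MET"] *= self.kbasal_fold
        for name, fold in self.abundance_shifts.items():
            p[name] *= fold
        return ParameterSet(p)

    def params(self, diet: str) -> ParameterSet:
        if diet == "SD":
            return self.sd_params()
        if diet == "WD":
            return self.wd_params()
        raise KeyError(f"unknown diet {diet!r}")

    def dysregulated(self, diet: str) -> dict[str, float]:
        p = self.params(diet).native()
        return {name: p[name] for name in DYSREGULATED_PARAMETERS}


def default_ground_truth() -> GroundTruth:
    return GroundTruth()


@dataclass
class BlotDesign:
    """Doses x times x replicate-experiments design of a blot study."""

    doses: tuple[float, ...] = (0.0, 40.0)
    times: tuple[float, ...] = (0.0, 5.0, 10.0, 20.0, 30.0, 45.0, 60.0, 90.0,
                                120.0, 180.0, 240.0)
    n_experiments: int = 3
    targets: tuple[str, ...] = ("pMET", "pERK", "pAKT_T308", "ppAKT_S473",
                                "pS6K", "pS6", "tMET", "tERK", "tAKT", "tS6")
    diets: tuple[str, ...] = ("SD", "WD")


def _simulate_observables(params: ParameterSet, dose: float, times: np.ndarray,
                          om: ObservationModel, targets) -> pd.DataFrame:
    net, packed = reference_network_packed()
    traj = simulate(net, params, dose, times, packed=packed)
    obs = observe(traj, om, observables=list(targets))
    return obs


def gen_blot_dataset(truth: GroundTruth, design: BlotDesign | None = None,
                     seed: int = 0, om: ObservationModel | None = None) -> pd.DataFrame:
    """Generate raw multi-gel immunoblot measurements.

    Each experiment (gel) j divides the true aligned signal by its own
    lognormal scaling factor s_j and multiplies by relative Gaussian noise of
    size ``e_rel``.  Returns the long-format raw table consumed by
    :func:`hgfdyn.observe.align_replicates`.
    """
    design = design or BlotDesign()
    if not design.doses or not design.times or design.n_experiments < 1:
        raise ValueError("invalid design: needs doses, times and >=1 experiment")
    om = om or default_observation_model()
    rng = np.random.default_rng(seed)
    times = np.asarray(sorted(set(design.times) | {0.0}))

    rows = []
    for diet in design.diets:
        params = truth.params(diet)
        for dose in design.doses:
            obs = _simulate_observables(params, dose, times, om, design.targets)
            obs = obs[obs["time"].isin(design.times)]
            for _, r in obs.iterrows():
                rows.append((r["observable"], diet, dose, r["time"], r["value"]))
    base = pd.DataFrame(rows, columns=["target", "condition", "dose", "time",
                                       "y_true"])

    out = []
    for j in range(design.n_experiments):
        exp = f"exp{j + 1}"
        block = base.copy()
        block["experiment"] = exp
        # one scaling factor per (gel, target)
        for target in design.targets:
            s_j = float(np.exp(rng.normal(0.0, truth.scale_spread)))
            m = block["target"] == target
            noise = 1.0 + truth.e_rel * rng.standard_normal(int(m.sum()))
            block.loc[m, "value"] = (block.loc[m, "y_true"] / s_j
                                     * np.clip(noise, 0.05, None))
        out.append(block)
    raw = pd.concat(out, ignore_index=True)
    return raw[["target", "condition", "dose", "time", "experiment", "value"]]


def gen_abundance_dataset(truth: GroundTruth, n_mice: int = 9, seed: int = 0
                          ) -> tuple[pd.DataFrame, float]:
    """Generate an LFQ-normalized log2 abundance table plus the AKT anchor.

    Returns ``(table, akt_molecules)``: one row per (protein, diet, mouse) with
    log2 intensity = log2(molecules x global factor) + Gaussian noise, and the
    absolute AKT molecules/cell measured by quantitative immunoblotting.
    """
    if n_mice < 2:
        raise ValueError("need at least two mice per diet")
    rng = np.random.default_rng(seed)
    rows = []
    for diet in ("SD", "WD"):
        p = truth.params(diet).native()
        for protein, param in PROTEIN_TO_PARAM.items():
            mu = np.log2(p[param] * truth.lfq_factor)
            vals = mu + truth.lfq_log2_sd * rng.standard_normal(n_mice)
            for m, v in enumerate(vals):
                rows.append({"protein": protein, "diet": diet,
                             "mouse": f"{diet}{m + 1}", "log2_intensity": v})
    akt_molecules = truth.sd_params()["k_total_AKT"]
    return pd.DataFrame(rows), float(akt_molecules)


@dataclass
class PatientDataset:
    """Synthetic surgical cohort with model-ready time courses and clinical data."""

    timecourses: pd.DataFrame   # patient, target, dose, time, value, sigma
    clinical: pd.DataFrame      # one row per patient, covariates + outcomes
    truth: pd.DataFrame         # per-patient generating parameters
    human_shared: dict[str, float]   # true human-specific shared parameters


def gen_patient_cohort(n_patients: int = 7, seed: int = 0,
                       truth: GroundTruth | None = None,
                       e_rel: float = 0.1,
                       outcome_noise: float = 0.25) -> PatientDataset:
    """Generate a patient cohort linked to ground-truth basal MET activity.

    Per-patient basal MET phosphorylation rates are drawn log-uniformly over a
    10-fold range; hepatocyte time courses (1-120 min, 40 ng/ml HGF, plus the
    unstimulated control) follow from the patient-specific model with
    human-shared MET kinetics; outcomes are monotone functions of
    log(k_basal) plus noise; confounders are drawn independently; the PDGF
    blood metric is generated anti-correlated with k_basal.
    """
    if n_patients < 3:
        raise ValueError("cohort needs at least 3 patients")
    truth = truth or default_ground_truth()
    rng = np.random.default_rng(seed)
    om = default_observation_model()
    base = truth.base.native()
    # human-shared kinetics differ from mouse (ligand affinity, pMET turnover)
    human_shared = {"k_act_MET": base["k_act_MET"] * 0.5,
                    "k_deg_pMET": base["k_deg_pMET"] * 1.5}

    kb_lo = base["k_basal_MET"]
    log_kb = rng.uniform(np.log(kb_lo), np.log(10 * kb_lo), size=n_patients)
    times = np.array([0.0, 1.0, 5.0, 15.0, 30.0, 60.0, 120.0])
    targets = ["pMET", "pERK", "ppAKT_S473", "pS6K", "tMET", "tAKT"]

    tc_rows, truth_rows = [], []
    for i in range(n_patients):
        pid = f"P{i + 1:02d}"
        p = dict(base, **human_shared)
        p["k_basal_MET"] = float(np.exp(log_kb[i]))
        # mild biological abundance variability between patients
        for name in ("k_total_MET", "k_total_AKT", "k_total_mTORC2"):
            p[name] *= float(np.exp(rng.normal(0.0, 0.15)))
        pset = ParameterSet(p)
        for dose in (0.0, 40.0):
            obs = _simulate_observables(pset, dose, times, om, targets)
            noise = 1.0 + e_rel * rng.standard_normal(len(obs))
            vals = obs["value"].to_numpy() * np.clip(noise, 0.05, None)
            for (_, r), v in zip(obs.iterrows(), vals):
                tc_rows.append({"patient": pid, "target": r["observable"],
                                "dose": dose, "time": r["time"], "value": v,
                                "sigma": e_rel * max(v, 1e-12)})
        truth_rows.append({"patient": pid, "k_basal_MET": p["k_basal_MET"],
                           "k_total_MET": p["k_total_MET"]})

    z = (log_kb - log_kb.mean()) / max(log_kb.std(), 1e-12)
    noise = lambda: outcome_noise * rng.standard_normal(n_patients)  # noqa: E731
    clinical = pd.DataFrame({
        "patient": [f"P{i + 1:02d}" for i in range(n_patients)],
        "age": rng.uniform(40, 75, n_patients).round(),
        "bmi": rng.uniform(20, 35, n_patients).round(1),
        "fibrosis": rng.integers(0, 5, n_patients),
        "cci": rng.integers(0, 10, n_patients),
        # outcome block: monotone in log k_basal plus noise
        "clavien_dindo": np.clip(np.round(2 + 1.2 * z + noise()), 0, 5),
        "complication_index": 30 + 15 * z + 10 * noise(),
        "icu_days": np.clip(np.round(2 + 1.5 * z + 2 * noise()), 0, None),
        "hospitalization_days": np.clip(np.round(12 + 5 * z + 4 * noise()), 1, None),
        "proliferation_fc": np.exp(0.4 * z + noise()),
    })
    for metric in ("hgf", "il6", "il8", "pdgf"):
        for tp in ("preop", "d1", "d3", "d7"):
            if metric == "pdgf":
                vals = np.exp(-0.8 * z + noise())
            else:
                vals = np.exp(rng.normal(0.0, 0.5, n_patients))
            clinical[f"{metric}_{tp}"] = vals

    return PatientDataset(pd.DataFrame(tc_rows), clinical,
                          pd.DataFrame(truth_rows), human_shared)


def gen_fucci_traces(n_cells: int | None = None,
                     entries_per_cell: list[int] | None = None, seed: int = 0,
                     dt_min: float = 15.0, t_max_h: float = 65.0,
                     rfp_thr: float = 100.0, yfp_thr: float = 100.0,
                     noise: float = 0.1) -> tuple[list[FucciTrace], list[np.ndarray]]:
    """Generate FUCCI reporter traces with a known number of cell-cycle entries.

    ``entries_per_cell`` requests the exact number of S->G2 transitions per
    cell (default: drawn 0-3).  Returns the traces and the generating phase
    sequences (codes G1/S/G2/M).  Channel intensities are placed in the
    quadrant of the generating phase with multiplicative noise small enough
    never to cross the thresholds.
    """
    rng = np.random.default_rng(seed)
    if entries_per_cell is None:
        if n_cells is None:
            raise ValueError("give n_cells or entries_per_cell")
        entries_per_cell = rng.integers(0, 4, n_cells).tolist()
    n_frames = int(t_max_h * 60 / dt_min) + 1
    times = np.arange(n_frames) * dt_min / 60.0  # hours

    # intensity levels per phase quadrant (low, high) x (rfp, yfp)
    lo_r, hi_r = 0.4 * rfp_thr, 2.0 * rfp_thr
    lo_y, hi_y = 0.4 * yfp_thr, 2.0 * yfp_thr
    level = {"G1": (hi_r, lo_y), "S": (hi_r, hi_y),
             "G2": (lo_r, hi_y), "M": (lo_r, lo_y)}

    traces, phase_seqs = [], []
    for n_entries in entries_per_cell:
        # a full cycle G1->S->G2->M uses >=8 frames; check feasibility
        if 8 * n_entries + 1 > n_frames:
            raise ValueError(f"{n_entries} entries infeasible in {n_frames} frames")
        segments = []
        for _ in range(n_entries):
            segments += [("G1", int(rng.integers(6, 30))), ("S", int(rng.integers(4, 20))),
                         ("G2", int(rng.integers(3, 12))), ("M", int(rng.integers(2, 6)))]
        # shrink random durations if they would truncate later cycles
        while sum(d for _, d in segments) > n_frames - 1:
            segments = [(name, max(d - 1, 2 if name in ("G1", "S") else 1))
                        for name, d in segments]
            if all(d <= 2 for _, d in segments):
                break
        segments.append(("G1", n_frames))  # pad out the tail
        phases = []
        for name, length in segments:
            phases += [name] * int(length)
            if len(phases) >= n_frames:
                break
        phases = np.array(phases[:n_frames])
        rfp = np.empty(n_frames)
        yfp = np.empty(n_frames)
        for i, ph in enumerate(phases):
            r, y = level[ph]
            rfp[i] = r * (1 + noise * (rng.random() - 0.5))
            yfp[i] = y * (1 + noise * (rng.random() - 0.5))
        traces.append(FucciTrace(times=times, rfp=rfp, yfp=yfp,
                                 thresholds=(rfp_thr, yfp_thr)))
        phase_seqs.append(phases)
    return traces, phase_seqs


def swap_test_truth(truth: GroundTruth | None = None) -> GroundTruth:
    """Ground truth with the WD shifts switched off (SD == WD)."""
    truth = truth or default_ground_truth()
    return replace(truth, kbasal_fold=1.0, abundance_shifts={})
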
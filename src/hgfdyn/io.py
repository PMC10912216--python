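"""Table and configuration IO: long CSVs, PEtab-convention TSVs, YAML configs.

The measurement/parameter/condition tables follow the PEtab column
conventions (observableId, simulationConditionId, time, measurement,
noiseParameters; parameterId, parameterScale, bounds, nominalValue) so the
fitting setup is portable to PEtab-aware tools.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimate import FitProblem, FitResult, Profile

__all__ = ["write_petab_tables", "write_fit_result", "write_profile",
           "load_config", "save_config"]


def write_petab_tables(problem: FitProblem, out_dir: str | Path) -> dict[str, Path]:
    """Write measurement, condition and parameter tables (PEtab conventions)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meas = pd.DataFrame({
        "observableId": problem.data["target"],
        "simulationConditionId": problem.data["condition"].astype(str)
        + "__dose" + problem.data["dose"].astype(str),
        "time": problem.data["time"],
        "measurement": problem.data["value"],
        "noiseParameters": problem.data["sigma"],
    })
    conds = (problem.data[["condition", "dose"]].drop_duplicates()
             .reset_index(drop=True))
    cond_tab = pd.DataFrame({
        "conditionId": conds["condition"].astype(str) + "__dose"
        + conds["dose"].astype(str),
        "HGF_dose_ng_ml": conds["dose"],
    })
    rows = []
    for pid in problem.free:
        lo, hi = problem.bounds[pid]
        rows.append({"parameterId": pid, "parameterScale": "log10",
                     "lowerBound": 10.0 ** lo, "upperBound": 10.0 ** hi,
                     "nominalValue": 10.0 ** np.mean([lo, hi]), "estimate": 1})
    for name, value in problem.base.items():
        rows.append({"parameterId": name, "parameterScale": "log10",
                     "lowerBound": value, "upperBound": value,
                     "nominalValue": value, "estimate": 0})
    par_tab = pd.DataFrame(rows)
    paths = {}
    for name, df in [("measurements", meas), ("conditions", cond_tab),
                     ("parameters", par_tab)]:
        paths[name] = out / f"{name}.tsv"
        df.to_csv(paths[name], sep="\t", index=False)
    return paths


def write_fit_result(fit: FitResult, out_dir: str | Path,
                     manifest_extra: dict | None = None) -> None:
    """Serialize a fit: waterfall CSV, best parameters CSV, JSON run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"start_rank": np.arange(len(fit.waterfall)),
                  "objective": fit.waterfall}).to_csv(
        out / "waterfall.csv", index=False)
    pd.DataFrame({"parameter": fit.free, "log10_value": fit.best_params,
                  "value": 10.0 ** fit.best_params}).to_csv(
        out / "best_parameters.csv", index=False)
    manifest = {"n_starts": fit.n_starts, "seed": fit.seed,
                "best_objective": fit.best_objective,
                "convergence_fraction": fit.convergence_fraction}
    manifest.update(manifest_extra or {})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def write_profile(profile: Profile, path: str | Path) -> None:
    df = pd.DataFrame({"log10_value": profile.grid,
                       "objective": profile.objective})
    df.attrs["parameter"] = profile.parameter
    df.to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """YAML run configuration: hypothesis, doses, time grids."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
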
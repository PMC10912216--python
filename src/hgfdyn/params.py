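"""Parameter sets, condition maps and the reference parameterization.

Parameters are stored on natural-log scale to guarantee positivity; the native
scale is recovered with :meth:`ParameterSet.native`.  A :class:`ConditionMap`
declares, per parameter, whether its value is shared across experimental
conditions (diets, patients) or condition-specific, and carries the
experimental input (HGF dose in ng/ml) per condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import (
    ABUNDANCE_PARAMETERS,
    DYNAMIC_PARAMETERS,
    DYSREGULATED_PARAMETERS,
    INPUT_PARAMETERS,
    ReactionNetwork,
)

__all__ = [
    "ParameterSet",
    "ConditionMap",
    "resolve_parameters",
    "reference_parameters",
    "reaction_rate_constants",
    "basal_steady_state",
]

MODEL_PARAMETERS = DYNAMIC_PARAMETERS + INPUT_PARAMETERS + ABUNDANCE_PARAMETERS

#: S6K occupancy at which the active IRS1 pool equals its abundance parameter;
#: part of the steady-state reparameterization of the IRS1 synthesis flux.
S6K_REFERENCE_FRACTION = 0.06


class ParameterSet:
    """Log-scale parameter store (all native values strictly positive)."""

    def __init__(self, values: dict[str, float], log: bool = False):
        if log:
            self._log = dict(values)
        else:
            bad = [k for k, v in values.items() if not v > 0]
            if bad:
                raise ValueError(f"parameters must be strictly positive: {bad}")
            self._log = {k: float(np.log(v)) for k, v in values.items()}

    def native(self) -> dict[str, float]:
        return {k: float(np.exp(v)) for k, v in self._log.items()}

    def log(self) -> dict[str, float]:
        return dict(self._log)

    def __getitem__(self, key: str) -> float:
        return float(np.exp(self._log[key]))

    def __contains__(self, key: str) -> bool:
        return key in self._log

    def names(self) -> list[str]:
        return list(self._log)

    def updated(self, **native_values: float) -> "ParameterSet":
        out = self.native()
        out.update(native_values)
        return ParameterSet(out)


@dataclass
class ConditionMap:
    """Shared/condition-specific resolution rules plus experimental inputs.

    ``specific`` lists the parameters that take condition-specific values; for
    those, the per-condition override dict supplies the value.  ``conditions``
    maps each label to its experimental input: HGF dose (ng/ml) and stimulation
    start time (minutes).
    """

    specific: list[str] = field(default_factory=list)
    conditions: dict[str, dict] = field(default_factory=dict)
    overrides: dict[str, dict[str, float]] = field(default_factory=dict)

    def add_condition(self, label: str, dose: float = 0.0, t_start: float = 0.0,
                      overrides: dict[str, float] | None = None) -> None:
        self.conditions[label] = {"dose": float(dose), "t_start": float(t_start)}
        self.overrides[label] = dict(overrides or {})

    def dose(self, label: str) -> float:
        return self.conditions[label]["dose"]


def resolve_parameters(params: ParameterSet, cmap: ConditionMap, condition: str,
                       order: list[str] | None = None) -> np.ndarray:
    """Resolve one numeric (native-scale) value per model parameter.

    Shared parameters take the base value from ``params``; parameters declared
    condition-specific take the per-condition override (falling back to the base
    value when no override is given, e.g. the reference condition itself).
    """
    if condition not in cmap.conditions:
        raise KeyError(f"unknown condition {condition!r}; registered: {list(cmap.conditions)}")
    order = order or MODEL_PARAMETERS
    base = params.native()
    over = cmap.overrides.get(condition, {})
    unknown = set(over) - set(cmap.specific)
    if unknown:
        raise ValueError(f"overrides for non-condition-specific parameters: {sorted(unknown)}")
    out = np.empty(len(order))
    for i, name in enumerate(order):
        if name in over:
            out[i] = over[name]
        elif name in base:
            out[i] = base[name]
        else:
            raise KeyError(f"parameter {name!r} unresolved for condition {condition!r}")
    return out


def reference_parameters() -> ParameterSet:
    """Synthetic default parameterization of the reference network.

    Order-of-magnitude plausible rates (1/min; bimolecular rates per
    molecules/cell per min) and abundances (molecules/cell) chosen so that the
    simulated dynamics show the qualitative hallmarks of HGF-stimulated
    hepatocytes: a pMET peak near 10 min with partial adaptation by 240 min, an
    early AKT response, and low basal phosphorylation of all species.  These are
    synthetic defaults, not fitted estimates.
    """
    return ParameterSet({
        # MET module
        "k_deg_MET": 5e-3, "k_basal_MET": 2e-3, "k_act_MET": 1.25e-3,
        "k_deg_pMET": 0.3,
        # MAPK
        "k_act_MEK": 3e-5, "k_deact_MEK": 1.0,
        "k_act_ERK": 1e-5, "k_deact_ERK": 1.0,
        # PI3K (rate per pMET per IRS1_active molecule)
        "k_act_PI3K": 1.6e-10, "k_deact_PI3K": 0.2,
        # AKT cycle
        "k_act_AKT_T308": 6e-6, "k_act_AKT_S473": 1e-5, "k_deact_AKT": 0.5,
        # TSC / mTORC1
        "k_inact_TSC": 7.5e-6, "k_react_TSC": 0.1,
        "k_act_mTORC1": 0.05, "k_inact_mTORC1": 2e-5,
        # S6K / S6
        "k_act_S6K": 1.2e-6, "k_deact_S6K": 0.3,
        "k_act_S6": 2e-6, "k_deact_S6": 0.1,
        # mTORC2 and IRS1 feedback targets
        "k_act_mTORC2": 4e-5, "k_inact_mTORC2": 8e-5,
        "k_deg_IRS1": 4e-11,
        # ligand input: effective intracellular stimulus units per ng/ml, and
        # the residual autocrine ligand level before stimulation
        "hgf_scale": 1.0, "hgf_basal": 1e-6,
        # protein abundances, molecules/cell
        "k_total_MET": 1e5, "k_total_MEK": 3e5, "k_total_ERK": 6e5,
        "k_total_PI3K": 5e4, "k_total_AKT": 2e5, "k_total_TSC": 5e4,
        "k_total_mTORC1": 1e5, "k_total_S6K": 2e5, "k_total_S6": 1e6,
        "k_total_mTORC2": 5e4, "k_total_IRS1": 1e5,
    })


def _frac(a: float, d: float) -> float:
    return a / (a + d)


def basal_steady_state(p: dict[str, float]) -> dict[str, float]:
    """Closed-form pre-stimulation steady state of the reference network.

    With the ERK-carried TSC crosstalk the basal network is triangular: every
    steady-state pool follows in closed form from the ones upstream, which is
    what makes analytical steady-state expressions possible.  The MET pool is
    pinned to its abundance parameter by construction, and the IRS1 pool to its
    abundance parameter at the reference S6K activity (the synthesis fluxes are
    the derived quantities, see :func:`reaction_rate_constants`).
    """
    H0 = p["hgf_basal"] * p["hgf_scale"]
    phi = p["k_basal_MET"] + p["k_act_MET"] * H0
    met = p["k_total_MET"] / (1.0 + phi / p["k_deg_pMET"])
    pmet = phi * met / p["k_deg_pMET"]

    pmek = p["k_total_MEK"] * _frac(p["k_act_MEK"] * pmet, p["k_deact_MEK"])
    perk = p["k_total_ERK"] * _frac(p["k_act_ERK"] * pmek, p["k_deact_ERK"])

    tsci = p["k_total_TSC"] * _frac(p["k_inact_TSC"] * perk, p["k_react_TSC"])
    tsc = p["k_total_TSC"] - tsci
    mtorc1a = p["k_total_mTORC1"] * _frac(p["k_act_mTORC1"], p["k_inact_mTORC1"] * tsc)
    ps6k = p["k_total_S6K"] * _frac(p["k_act_S6K"] * mtorc1a, p["k_deact_S6K"])
    ps6 = p["k_total_S6"] * _frac(p["k_act_S6"] * ps6k, p["k_deact_S6"])

    # IRS1 pool: abundance parameter normalized at the reference S6K activity
    # (S6K_REFERENCE_FRACTION of the S6K pool phosphorylated); pS6K above that
    # reference depletes active IRS1 — the basal arm of the S6K->IRS1 feedback.
    s6k_ref = S6K_REFERENCE_FRACTION * p["k_total_S6K"]
    irs1 = p["k_total_IRS1"] * (s6k_ref / ps6k) ** 2
    pi3ka = p["k_total_PI3K"] * _frac(p["k_act_PI3K"] * pmet * irs1, p["k_deact_PI3K"])
    mtorc2a = p["k_total_mTORC2"] * _frac(
        p["k_act_mTORC2"] * pi3ka, p["k_inact_mTORC2"] * ps6k)

    # AKT cycle: equal fluxes through the three conversions
    a1 = p["k_act_AKT_T308"] * pi3ka
    a2 = p["k_act_AKT_S473"] * mtorc2a
    a3 = p["k_deact_AKT"]
    inv = 1.0 / a1 + 1.0 / a2 + 1.0 / a3
    flux = p["k_total_AKT"] / inv
    akt, pakt, ppakt = flux / a1, flux / a2, flux / a3

    return {
        "HGF": H0,
        "MET": met, "pMET": pmet,
        "MEK": p["k_total_MEK"] - pmek, "pMEK": pmek,
        "ERK": p["k_total_ERK"] - perk, "pERK": perk,
        "PI3K": p["k_total_PI3K"] - pi3ka, "PI3K_active": pi3ka,
        "AKT": akt, "pAKT": pakt, "ppAKT": ppakt,
        "TSC": tsc, "TSC_inactive": tsci,
        "mTORC1": p["k_total_mTORC1"] - mtorc1a, "mTORC1_active": mtorc1a,
        "S6K": p["k_total_S6K"] - ps6k, "pS6K": ps6k,
        "S6": p["k_total_S6"] - ps6, "pS6": ps6,
        "mTORC2": p["k_total_mTORC2"] - mtorc2a, "mTORC2_active": mtorc2a,
        "IRS1_active": irs1,
    }


def reaction_rate_constants(net: ReactionNetwork, p: dict[str, float]) -> np.ndarray:
    """One rate constant per reaction, with the two synthesis fluxes derived.

    The MET and IRS1 synthesis rates are eliminated by the steady-state
    reparameterization: they are computed so that the pre-stimulation pools
    equal ``k_total_MET`` and ``k_total_IRS1``.
    """
    p = dict(p)
    H0 = p["hgf_basal"] * p["hgf_scale"]
    phi = p["k_basal_MET"] + p["k_act_MET"] * H0
    met_ss = p["k_total_MET"] / (1.0 + phi / p["k_deg_pMET"])
    p["k_synth_MET"] = (p["k_deg_MET"] + phi) * met_ss

    ss = basal_steady_state(p)
    p["k_synth_IRS1"] = p["k_deg_IRS1"] * ss["IRS1_active"] * ss["pS6K"] ** 2

    return np.array([p[r.rate_parameter] for r in net.reactions])
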
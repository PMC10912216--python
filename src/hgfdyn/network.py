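"""Mass-action reaction network of HGF-induced signal transduction.

The reference network describes ligand-induced activation of the MET receptor
tyrosine kinase in primary hepatocytes and its propagation through two branches,
the MAPK cascade (MEK/ERK) and the PI3K/AKT axis, coupled to mTOR signaling:
AKT phosphorylated on Thr308 arises downstream of PI3K, the second AKT
phosphorylation (Ser473) requires active mTORC2, active mTORC1 drives
S6K -> S6, and two negative feedbacks emanate from phosphorylated S6K
(inhibition of mTORC2 complex formation and inactivation of IRS1, which gates
PI3K activation).  MET itself turns over: it is produced and degraded, with the
phosphorylated receptor degraded at a distinct rate, and is phosphorylated both
ligand-independently (the basal rate ``k_basal_MET``) and in response to HGF.

All rate laws are mass action: the rate of a reaction is its rate constant
multiplied by the concentrations of its reactants and modifiers.  Modifiers
(catalysts) appear in the rate but are not consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import sympy

__all__ = [
    "Species",
    "Reaction",
    "ReactionNetwork",
    "build_hgf_network",
    "conserved_moieties",
    "DYNAMIC_PARAMETERS",
    "INPUT_PARAMETERS",
    "ABUNDANCE_PARAMETERS",
    "DYSREGULATED_PARAMETERS",
    "parameter_bookkeeping",
]


@dataclass(frozen=True)
class Species:
    """A chemical species of the network.

    ``initial_source`` is either ``"abundance"`` (the pre-ligand pool is set by a
    free protein-abundance parameter) or ``"derived"`` (zero or steady-state
    derived at the pre-ligand reference, e.g. phosphorylated forms).
    """

    name: str
    role: str  # ligand | receptor | kinase | complex | substrate
    initial_source: str = "derived"


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction.

    ``reactants``/``products`` map species names to positive integer
    stoichiometric coefficients; ``modifiers`` map species names to the power
    with which they enter the rate without being consumed.
    """

    name: str
    reactants: dict[str, int]
    products: dict[str, int]
    rate_parameter: str
    modifiers: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for coeff in list(self.reactants.values()) + list(self.products.values()):
            if not (isinstance(coeff, int) and coeff > 0):
                raise ValueError(f"{self.name}: stoichiometric coefficients must be positive integers")


class ReactionNetwork:
    """An ordered collection of species and mass-action reactions."""

    def __init__(self, species: list[Species], reactions: list[Reaction]):
        names = [s.name for s in species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")
        known = set(names)
        for r in reactions:
            for n in list(r.reactants) + list(r.products) + list(r.modifiers):
                if n not in known:
                    raise ValueError(f"reaction {r.name} references unknown species {n!r}")
        self.species = list(species)
        self.reactions = list(reactions)
        self.species_index = {s.name: i for i, s in enumerate(species)}

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def parameter_names(self) -> list[str]:
        return [r.rate_parameter for r in self.reactions]

    @property
    def stoichiometry_matrix(self) -> np.ndarray:
        """Integer species x reactions stoichiometry matrix (net change)."""
        S = np.zeros((self.n_species, self.n_reactions), dtype=int)
        for j, r in enumerate(self.reactions):
            for name, c in r.reactants.items():
                S[self.species_index[name], j] -= c
            for name, c in r.products.items():
                S[self.species_index[name], j] += c
        return S

    def rate_exponents(self) -> np.ndarray:
        """Reactions x species exponent matrix of the mass-action rate monomials."""
        E = np.zeros((self.n_reactions, self.n_species), dtype=int)
        for j, r in enumerate(self.reactions):
            for name, c in r.reactants.items():
                E[j, self.species_index[name]] += c
            for name, p in r.modifiers.items():
                E[j, self.species_index[name]] += p
        return E


def conserved_moieties(net: ReactionNetwork) -> list[np.ndarray]:
    """Integer basis of the left null space of the stoichiometry matrix.

    Each returned vector ``v`` satisfies ``v @ S == 0`` exactly and defines a
    conserved total (e.g. ERK + pERK) along any trajectory.
    """
    S = sympy.Matrix(net.stoichiometry_matrix.tolist())
    basis = S.T.nullspace()
    out = []
    for vec in basis:
        fracs = [Fraction(sympy.Rational(x).p, sympy.Rational(x).q) for x in vec]
        denom = np.lcm.reduce([f.denominator for f in fracs]) if fracs else 1
        ints = np.array([int(f * denom) for f in fracs], dtype=int)
        g = np.gcd.reduce(np.abs(ints[ints != 0])) if np.any(ints) else 1
        ints = ints // g
        if ints.sum() < 0:
            ints = -ints
        out.append(ints)
    return out


# --- reference build -----------------------------------------------------------

#: Proteins whose abundance is a free (diet- or patient-specific) parameter.
ABUNDANCE_PARAMETERS = [
    "k_total_MET",
    "k_total_MEK",
    "k_total_ERK",
    "k_total_PI3K",
    "k_total_AKT",
    "k_total_TSC",
    "k_total_mTORC1",
    "k_total_S6K",
    "k_total_S6",
    "k_total_mTORC2",
    "k_total_IRS1",
]

#: Free kinetic rate constants (shared across diets except ``k_basal_MET``).
DYNAMIC_PARAMETERS = [
    "k_deg_MET",
    "k_basal_MET",
    "k_act_MET",
    "k_deg_pMET",
    "k_act_MEK",
    "k_deact_MEK",
    "k_act_ERK",
    "k_deact_ERK",
    "k_act_PI3K",
    "k_deact_PI3K",
    "k_act_AKT_T308",
    "k_act_AKT_S473",
    "k_deact_AKT",
    "k_inact_TSC",
    "k_react_TSC",
    "k_act_mTORC1",
    "k_inact_mTORC1",
    "k_act_S6K",
    "k_deact_S6K",
    "k_act_S6",
    "k_deact_S6",
    "k_act_mTORC2",
    "k_inact_mTORC2",
    "k_deg_IRS1",
]

#: Ligand-input parameters (dose-to-intracellular-units conversion and the
#: residual autocrine ligand level at the pre-stimulation reference).
INPUT_PARAMETERS = ["hgf_scale", "hgf_basal"]

#: The reference two-diet hypothesis: one kinetic rate plus eleven abundances.
DYSREGULATED_PARAMETERS = ["k_basal_MET"] + ABUNDANCE_PARAMETERS

#: Synthesis rates eliminated by the steady-state reparameterization: the MET
#: and IRS1 production fluxes are derived from the abundance parameters so that
#: the pre-ligand pools equal ``k_total_MET`` and ``k_total_IRS1``.
DERIVED_PARAMETERS = ["k_synth_MET", "k_synth_IRS1"]


def build_hgf_network() -> ReactionNetwork:
    """Build the reference HGF signal-transduction network.

    Returns the 23-species / 26-reaction mass-action network with both the MAPK
    and PI3K branches, mTORC1/2, and the two S6K feedbacks.
    """
    species = [
        Species("HGF", "ligand"),
        Species("MET", "receptor", "abundance"),
        Species("pMET", "receptor"),
        Species("MEK", "kinase", "abundance"),
        Species("pMEK", "kinase"),
        Species("ERK", "kinase", "abundance"),
        Species("pERK", "kinase"),
        Species("PI3K", "kinase", "abundance"),
        Species("PI3K_active", "kinase"),
        Species("AKT", "kinase", "abundance"),
        Species("pAKT", "kinase"),
        Species("ppAKT", "kinase"),
        Species("TSC", "complex", "abundance"),
        Species("TSC_inactive", "complex"),
        Species("mTORC1", "complex", "abundance"),
        Species("mTORC1_active", "complex"),
        Species("S6K", "kinase", "abundance"),
        Species("pS6K", "kinase"),
        Species("S6", "substrate", "abundance"),
        Species("pS6", "substrate"),
        Species("mTORC2", "complex", "abundance"),
        Species("mTORC2_active", "complex"),
        Species("IRS1_active", "substrate", "abundance"),
    ]
    R = Reaction
    reactions = [
        # MET receptor turnover and activation
        R("synth_MET", {}, {"MET": 1}, "k_synth_MET"),
        R("deg_MET", {"MET": 1}, {}, "k_deg_MET"),
        R("basal_phos_MET", {"MET": 1}, {"pMET": 1}, "k_basal_MET"),
        R("hgf_phos_MET", {"MET": 1}, {"pMET": 1}, "k_act_MET", {"HGF": 1}),
        R("deg_pMET", {"pMET": 1}, {}, "k_deg_pMET"),
        # MAPK cascade
        R("act_MEK", {"MEK": 1}, {"pMEK": 1}, "k_act_MEK", {"pMET": 1}),
        R("deact_MEK", {"pMEK": 1}, {"MEK": 1}, "k_deact_MEK"),
        R("act_ERK", {"ERK": 1}, {"pERK": 1}, "k_act_ERK", {"pMEK": 1}),
        R("deact_ERK", {"pERK": 1}, {"ERK": 1}, "k_deact_ERK"),
        # PI3K recruitment (gated by active IRS1)
        R("act_PI3K", {"PI3K": 1}, {"PI3K_active": 1}, "k_act_PI3K",
          {"pMET": 1, "IRS1_active": 1}),
        R("deact_PI3K", {"PI3K_active": 1}, {"PI3K": 1}, "k_deact_PI3K"),
        # AKT two-site phosphorylation cycle
        R("phos_AKT_T308", {"AKT": 1}, {"pAKT": 1}, "k_act_AKT_T308",
          {"PI3K_active": 1}),
        R("phos_AKT_S473", {"pAKT": 1}, {"ppAKT": 1}, "k_act_AKT_S473",
          {"mTORC2_active": 1}),
        R("dephos_AKT", {"ppAKT": 1}, {"AKT": 1}, "k_deact_AKT"),
        # TSC complex inactivation (MAPK -> mTOR crosstalk) and recovery
        R("inact_TSC", {"TSC": 1}, {"TSC_inactive": 1}, "k_inact_TSC", {"pERK": 1}),
        R("react_TSC", {"TSC_inactive": 1}, {"TSC": 1}, "k_react_TSC"),
        # mTORC1 activation, suppressed by active TSC
        R("act_mTORC1", {"mTORC1": 1}, {"mTORC1_active": 1}, "k_act_mTORC1"),
        R("inact_mTORC1", {"mTORC1_active": 1}, {"mTORC1": 1}, "k_inact_mTORC1",
          {"TSC": 1}),
        # S6K / S6
        R("act_S6K", {"S6K": 1}, {"pS6K": 1}, "k_act_S6K", {"mTORC1_active": 1}),
        R("deact_S6K", {"pS6K": 1}, {"S6K": 1}, "k_deact_S6K"),
        R("phos_S6", {"S6": 1}, {"pS6": 1}, "k_act_S6", {"pS6K": 1}),
        R("dephos_S6", {"pS6": 1}, {"S6": 1}, "k_deact_S6"),
        # mTORC2 formation driven by active PI3K, feedback-inhibited by pS6K
        R("act_mTORC2", {"mTORC2": 1}, {"mTORC2_active": 1}, "k_act_mTORC2",
          {"PI3K_active": 1}),
        R("inact_mTORC2", {"mTORC2_active": 1}, {"mTORC2": 1}, "k_inact_mTORC2",
          {"pS6K": 1}),
        # IRS1 turnover; pS6K-driven loss implements the second feedback.  The
        # quadratic pS6K dependence condenses multi-site inhibitory serine
        # phosphorylation of IRS1 into a single cooperative step.
        R("synth_IRS1", {}, {"IRS1_active": 1}, "k_synth_IRS1"),
        R("deg_IRS1", {"IRS1_active": 1}, {}, "k_deg_IRS1", {"pS6K": 2}),
    ]
    return ReactionNetwork(species, reactions)


def parameter_bookkeeping() -> dict[str, int]:
    """Count the parameter classes of the two-diet reference model.

    Diet-specific parameters are counted once per diet (the convention used for
    reporting "initial protein concentration" and "dynamical" parameter totals);
    the reference hypothesis marks ``k_basal_MET`` and the eleven abundances as
    diet-specific, everything else shared.
    """
    n_shared_kinetic = len(DYNAMIC_PARAMETERS) - 1  # all but k_basal_MET
    return {
        "species": len(build_hgf_network().species),
        "reactions": len(build_hgf_network().reactions),
        "diet_specific": len(DYSREGULATED_PARAMETERS),
        "initial_concentration_values": 2 * len(ABUNDANCE_PARAMETERS),
        "dynamical_values": n_shared_kinetic + 2 + len(INPUT_PARAMETERS),
    }
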
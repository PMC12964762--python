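"""Connect extracellular substrates to the core network; extract substrate fates.

The same MILP machinery as BBB subnetwork enumeration is used, but the
forcing is a fixed unit uptake of the substrate's exchange reaction on top
of the medium: the enumeration then finds the smallest sets of non-core
reactions that integrate the substrate into the (free) core at steady
state. The substrate's secretion is blocked so a trivial in-and-out route
cannot satisfy the balance.

Fates are read from exchange fluxes only: co-substrates are the species
taken up alongside the substrate, byproducts the species secreted, across
the union of enumerated subnetworks. Freely available inorganics (water,
protons, the medium's mineral background) are suppressed from co-substrate
sets; CO2 is reported as a byproduct.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import cobra
import pandas as pd

from gemreduce.core import CoreNetwork
from gemreduce.gem_io import (
    FLUX_TOL,
    Medium,
    apply_medium,
    base_id,
    biomass_reaction_id,
    exchange_reactions,
    is_exchange,
)
from gemreduce.subnetworks import (
    Subnetwork,
    SubnetworkSet,
    free_core_metabolites,
    non_core_reactions,
    run_enumeration,
)

logger = logging.getLogger("gemreduce")

#: base ids never reported as co-substrates (free background); byproduct
#: reporting suppresses only water and protons, so CO2 secretion is visible.
DEFAULT_CO_SUBSTRATE_IGNORE = frozenset({"h2o", "h"})
DEFAULT_BYPRODUCT_IGNORE = frozenset({"h2o", "h"})


@dataclass(frozen=True)
class SubstrateFate:
    """Exchange-level summary of how a substrate is catabolized."""

    substrate: str  # base id
    co_substrates: frozenset[str]
    byproducts: frozenset[str]
    subnetworks: tuple[Subnetwork, ...] = field(compare=False, default=())

    def __post_init__(self):
        if self.substrate in self.byproducts:
            raise ValueError(
                f"substrate {self.substrate} cannot be its own byproduct"
            )


def _find_exchange(g: cobra.Model, substrate: str) -> cobra.Reaction | None:
    """Exchange reaction of an extracellular metabolite id (or base id)."""
    for rxn in exchange_reactions(g):
        met = next(iter(rxn.metabolites))
        if met.id == substrate or base_id(met) == substrate:
            return rxn
    return None


def _has_transporter(g: cobra.Model, met_id: str) -> bool:
    met = g.metabolites.get_by_id(met_id)
    return any(not is_exchange(r) for r in met.reactions)


def connect_extracellular(
    g: cobra.Model,
    core: CoreNetwork,
    substrate: str,
    medium: Medium,
    k_relax: int = 0,
    cap: int = 5000,
) -> SubnetworkSet:
    """Minimal balanced subnetworks integrating one unit of substrate uptake.

    ``substrate`` names the extracellular metabolite (compartmented id or
    base id); its exchange is fixed at unit uptake and its secretion is
    blocked. An empty result carries a diagnostic distinguishing a missing
    exchange, a missing transporter, and the absence of any balanced route.
    """
    ex = _find_exchange(g, substrate)
    label = substrate
    if ex is None:
        return SubnetworkSet(
            target=label,
            diagnostic=f"{label}: no exchange reaction in the model",
        )
    ex_met = next(iter(ex.metabolites))
    m = g.copy()
    m.biomass_reaction_id = biomass_reaction_id(g)
    apply_medium(m, medium)
    bid = biomass_reaction_id(m)
    if bid is not None:
        m.reactions.get_by_id(bid).bounds = (0.0, 0.0)
    m.reactions.get_by_id(ex.id).bounds = (-1.0, -1.0)  # forced unit uptake
    free_core_metabolites(m, core)
    candidates = non_core_reactions(m, core)
    result = run_enumeration(m, candidates, label, k_relax=k_relax, cap=cap)
    if not result.subnetworks and not result.diagnostic.startswith(label + ": no"):
        if not _has_transporter(g, ex_met.id):
            result.diagnostic = f"{label}: no transporter for {ex_met.id}"
        else:
            result.diagnostic = f"{label}: no balanced route into the core"
    return result


def substrate_fate(
    subnets: SubnetworkSet | Sequence[Subnetwork],
    g: cobra.Model,
    co_substrate_ignore: Iterable[str] = DEFAULT_CO_SUBSTRATE_IGNORE,
    byproduct_ignore: Iterable[str] = DEFAULT_BYPRODUCT_IGNORE,
    medium_inorganics: Iterable[str] = (),
) -> SubstrateFate:
    """Union of uptaken co-substrates and secreted byproducts over subnetworks.

    Only non-zero exchange fluxes of the solutions are read, so fates are
    invariant to internal route relabeling. ``medium_inorganics`` adds
    further base ids (the medium's mineral background) to the co-substrate
    suppression list.
    """
    if isinstance(subnets, SubnetworkSet):
        substrate = subnets.target
        members = list(subnets.subnetworks)
    else:
        members = list(subnets)
        if not members:
            raise ValueError("substrate_fate needs >= 1 subnetwork")
        substrate = members[0].target
    substrate_base = (
        base_id(g.metabolites.get_by_id(substrate))
        if substrate in g.metabolites else substrate
    )
    ignore_up = set(co_substrate_ignore) | set(medium_inorganics)
    ignore_down = set(byproduct_ignore)
    ex_by_id = {r.id: r for r in exchange_reactions(g)}
    co: set[str] = set()
    by: set[str] = set()
    for sn in members:
        for rid, flux in sn.fluxes.items():
            if rid not in ex_by_id or abs(flux) <= FLUX_TOL:
                continue
            species = base_id(next(iter(ex_by_id[rid].metabolites)))
            if flux < 0 and species != substrate_base and species not in ignore_up:
                co.add(species)
            elif flux > 0 and species != substrate_base and species not in ignore_down:
                by.add(species)
    return SubstrateFate(
        substrate=substrate_base,
        co_substrates=frozenset(co),
        byproducts=frozenset(by),
        subnetworks=tuple(members),
    )


def _can_secrete(g: cobra.Model, substrate: str, medium: Medium) -> bool:
    ex = _find_exchange(g, substrate)
    if ex is None:
        return False
    with g as m:
        apply_medium(m, medium)
        rxn = m.reactions.get_by_id(ex.id)
        rxn.lower_bound = min(rxn.lower_bound, 0.0)
        m.objective = m.problem.Objective(rxn.flux_expression, direction="max")
        vmax = m.slim_optimize(error_value=0.0)
    return vmax is not None and vmax > FLUX_TOL


def exchange_capability_matrix(
    gems: Sequence[tuple[str, cobra.Model, CoreNetwork]],
    substrates: Sequence[str],
    shared_medium: Medium,
    k_relax: int = 0,
    cap: int = 50,
) -> pd.DataFrame:
    """Per (organism, substrate) capability: uptake / secrete / both / neither.

    Uptake capability means connect_extracellular finds >= 1 balanced
    subnetwork under the shared medium; secretion capability means the
    substrate's exchange can carry positive flux under the shared medium.
    """
    rows = {}
    for label, g, core in gems:
        row = {}
        for substrate in substrates:
            uptake = bool(
                connect_extracellular(
                    g, core, substrate, shared_medium, k_relax=k_relax, cap=cap
                ).subnetworks
            )
            secrete = _can_secrete(g, substrate, shared_medium)
            row[substrate] = (
                "both" if uptake and secrete
                else "uptake" if uptake
                else "secrete" if secrete
                else "neither"
            )
        rows[label] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(substrates))
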
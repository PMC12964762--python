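"""Minimal balanced subnetwork enumeration and reaction lumping.

For a target metabolite (a biomass building block, or an extracellular
substrate routed in by :mod:`gemreduce.exchange`), the MILP couples a
binary use-indicator to the flux of every non-core reaction and minimizes
the number of active non-core reactions subject to steady state, the medium
uptake limits, and unit production of the target. Metabolites of the core
network are treated as free boundary species (no steady-state constraint):
the core supplies precursors and energy/redox carriers and absorbs
byproducts, which is what makes the resulting net "lumped" reaction a
conversion between core species.

All alternative optima of size <= S_min + k_relax are enumerated with
integer cuts on the flux support of each solution; a cut excludes every
superset of a found support, so the enumeration yields exactly the
support-minimal active sets, in nondecreasing size order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import cobra

from gemreduce.core import CoreNetwork
from gemreduce.gem_io import (
    FLUX_TOL,
    Medium,
    apply_medium,
    base_id,
    biomass_reaction_id,
    is_exchange,
)

logger = logging.getLogger("gemreduce")

BIG_M_DEFAULT = 1000.0
INTEGRALITY_TOL = 1e-6
COEFF_DROP_TOL = 1e-9


@dataclass(frozen=True)
class Subnetwork:
    """A minimal balanced active set of non-core reactions producing one target.

    ``fluxes`` holds every non-zero flux of the solution (active non-core
    reactions, core reactions, exchanges) at unit target production
    (1 mmol gDW^-1 h^-1). ``active_reactions`` may be empty when the target
    is itself a core metabolite and needs no non-core step.
    """

    target: str
    active_reactions: frozenset[str]
    fluxes: dict[str, float] = field(compare=False, default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.active_reactions)


@dataclass
class SubnetworkSet(Sequence):
    """Enumeration result: the subnetworks plus truncation/diagnostic flags."""

    target: str
    subnetworks: list[Subnetwork] = field(default_factory=list)
    truncated: bool = False
    diagnostic: str = ""

    def __len__(self) -> int:
        return len(self.subnetworks)

    def __getitem__(self, i):
        return self.subnetworks[i]

    def __iter__(self) -> Iterator[Subnetwork]:
        return iter(self.subnetworks)

    @property
    def active_sets(self) -> set[frozenset[str]]:
        return {sn.active_reactions for sn in self.subnetworks}

    @property
    def reaction_union(self) -> set[str]:
        return {r for sn in self.subnetworks for r in sn.active_reactions}


# ---------------------------------------------------------------------------
# MILP machinery


def free_core_metabolites(m: cobra.Model, core: CoreNetwork) -> None:
    """Drop the steady-state constraint of every core metabolite (free boundary)."""
    for met_id in core.metabolites:
        if met_id in m.metabolites:
            cons = m.constraints[met_id]
            cons.lb = None
            cons.ub = None


def non_core_reactions(m: cobra.Model, core: CoreNetwork,
                       skip: Iterable[str] = ()) -> list[str]:
    """Candidate reactions for use-indicators: everything outside the core
    except exchanges and the biomass reaction (the medium governs exchanges;
    biomass is blocked during enumeration)."""
    biomass_id = biomass_reaction_id(m)
    skip = set(skip)
    return sorted(
        r.id
        for r in m.reactions
        if r.id not in core.reactions
        and r.id != biomass_id
        and r.id not in skip
        and not is_exchange(r)
    )


def _big_m(rxn: cobra.Reaction) -> float:
    m = max(abs(rxn.lower_bound), abs(rxn.upper_bound))
    if m == 0 or m == float("inf"):
        return BIG_M_DEFAULT
    return m


def run_enumeration(
    m: cobra.Model,
    candidates: list[str],
    target_label: str,
    k_relax: int = 0,
    cap: int = 5000,
) -> SubnetworkSet:
    """Enumerate support-minimal active sets on a fully prepared model.

    ``m`` must already carry the medium, the unit-production forcing
    (target drain or fixed substrate uptake), freed core metabolites and a
    blocked biomass reaction. Binary indicators are added here.
    """
    interface = m.problem
    indicators = {}
    to_add = []
    for rid in candidates:
        rxn = m.reactions.get_by_id(rid)
        z = interface.Variable(f"use_{rid}", type="binary")
        big_m = _big_m(rxn)
        upper = interface.Constraint(
            rxn.flux_expression - big_m * z, ub=0.0, name=f"use_ub_{rid}"
        )
        lower = interface.Constraint(
            rxn.flux_expression + big_m * z, lb=0.0, name=f"use_lb_{rid}"
        )
        indicators[rid] = z
        to_add.extend([z, upper, lower])
    m.solver.add(to_add)
    m.objective = interface.Objective(sum(indicators.values()), direction="min")
    try:
        m.solver.configuration.tolerances.integrality = INTEGRALITY_TOL
    except (AttributeError, ValueError):
        pass  # solver interface without an adjustable integrality tolerance

    result = SubnetworkSet(target=target_label)
    s_min: int | None = None
    n_cuts = 0
    while True:
        m.solver.optimize()
        if m.solver.status != "optimal":
            if s_min is None:
                result.diagnostic = (
                    f"{target_label}: unproducible on this medium (MILP infeasible)"
                )
            break
        support = sorted(
            rid for rid in candidates
            if abs(m.reactions.get_by_id(rid).flux) > FLUX_TOL
        )
        if s_min is None:
            s_min = len(support)
        if len(support) > s_min + k_relax:
            break
        fluxes = {
            r.id: r.flux for r in m.reactions if abs(r.flux) > FLUX_TOL
        }
        result.subnetworks.append(
            Subnetwork(
                target=target_label,
                active_reactions=frozenset(support),
                fluxes=fluxes,
            )
        )
        if len(result.subnetworks) >= cap:
            result.truncated = True
            logger.warning("%s: enumeration cap %d reached", target_label, cap)
            break
        if not support:
            break  # the empty support has no proper alternatives
        n_cuts += 1
        cut = interface.Constraint(
            sum(indicators[rid] for rid in support),
            ub=len(support) - 1,
            name=f"cut_{n_cuts}",
        )
        m.solver.add(cut)
    return result


def _drain_id(target: str) -> str:
    return f"DM__{target}"


def prepare_bbb_model(
    g: cobra.Model,
    core: CoreNetwork,
    target: str,
    medium: Medium,
) -> tuple[cobra.Model, list[str]]:
    """Copy + prepare a model for BBB subnetwork enumeration."""
    if target not in g.metabolites:
        raise KeyError(f"target metabolite {target!r} not in model")
    m = g.copy()
    m.biomass_reaction_id = biomass_reaction_id(g)
    apply_medium(m, medium)
    bid = biomass_reaction_id(m)
    if bid is not None:
        m.reactions.get_by_id(bid).bounds = (0.0, 0.0)
    drain = cobra.Reaction(_drain_id(target))
    drain.add_metabolites({m.metabolites.get_by_id(target): -1.0})
    drain.bounds = (1.0, 1.0)
    m.add_reactions([drain])
    free_core_metabolites(m, core)
    candidates = non_core_reactions(m, core, skip={drain.id})
    return m, candidates


def enumerate_min_subnetworks(
    g: cobra.Model,
    core: CoreNetwork,
    target: str,
    medium: Medium,
    k_relax: int = 0,
    cap: int = 5000,
) -> SubnetworkSet:
    """All minimal balanced subnetworks producing ``target`` from the core.

    A temporary drain fixes target production to 1 mmol gDW^-1 h^-1; the
    biomass reaction is blocked; core reactions carry no indicator (free).
    A target that is available in the medium yields a transport-only
    subnetwork; a target that is itself a core metabolite yields one empty
    subnetwork (drawn directly from the core).
    """
    m, candidates = prepare_bbb_model(g, core, target, medium)
    result = run_enumeration(m, candidates, target, k_relax=k_relax, cap=cap)
    logger.info(
        "%s: %d subnetwork(s)%s", target, len(result),
        " [truncated]" if result.truncated else "",
    )
    return result


# ---------------------------------------------------------------------------
# replay / minimality checks


def subnetwork_feasible(
    g: cobra.Model,
    core: CoreNetwork,
    sn: Subnetwork,
    medium: Medium,
    active: frozenset[str] | None = None,
) -> bool:
    """Linear solve: can exactly this active set sustain unit target production?"""
    if active is None:
        active = sn.active_reactions
    m, candidates = prepare_bbb_model(g, core, sn.target, medium)
    for rid in candidates:
        if rid not in active:
            m.reactions.get_by_id(rid).bounds = (0.0, 0.0)
    m.objective = m.problem.Objective(0, direction="min")
    m.solver.optimize()
    return m.solver.status == "optimal"


def subnetwork_minimal(
    g: cobra.Model, core: CoreNetwork, sn: Subnetwork, medium: Medium
) -> bool:
    """Removing any single active reaction must make the system infeasible."""
    for rid in sorted(sn.active_reactions):
        if subnetwork_feasible(
            g, core, sn, medium, active=sn.active_reactions - {rid}
        ):
            return False
    return True


# ---------------------------------------------------------------------------
# lumping


@dataclass
class LumpedReaction:
    """Net stoichiometry of a subnetwork, normalized to +1 of its target.

    Keys of ``net_stoich`` are compartmented metabolite ids; ``base_stoich``
    aggregates the coefficients by compartment-free id. An empty-support
    subnetwork (target already in the core) lumps to the bare ``{target: +1}``
    with ``core_supplied`` set.
    """

    target: str
    net_stoich: dict[str, float]
    base_stoich: dict[str, float] = field(default_factory=dict)
    source_subnetworks: list[Subnetwork] = field(default_factory=list)
    core_supplied: bool = False
    target_base: str = ""

    def equation(self) -> str:
        """Human-readable net reaction string with BiGG-style arrow."""
        lhs = [
            f"{-c:g} {m}" for m, c in sorted(self.net_stoich.items()) if c < 0
        ]
        rhs = [
            f"{c:g} {m}" for m, c in sorted(self.net_stoich.items()) if c > 0
        ]
        return " + ".join(lhs) + " --> " + " + ".join(rhs)


def lump(sn: Subnetwork, g: cobra.Model) -> LumpedReaction:
    """Condense a subnetwork into a single net reaction.

    The net stoichiometry is the flux-weighted sum of the active (non-core)
    reactions; species balanced inside the subnetwork cancel, and the
    core-boundary species remain by construction. Coefficients are
    normalized so the target has +1 and near-zero coefficients are dropped.
    Elementally unbalanced member reactions trigger a warning naming the
    imbalance.
    """
    net: dict[str, float] = {}
    for rid in sn.active_reactions:
        rxn = g.reactions.get_by_id(rid)
        imbalance = rxn.check_mass_balance()
        if imbalance:
            logger.warning(
                "lump(%s): member reaction %s is unbalanced: %s",
                sn.target, rid, imbalance,
            )
        v = sn.fluxes.get(rid, 0.0)
        for met, coef in rxn.metabolites.items():
            net[met.id] = net.get(met.id, 0.0) + v * coef
    tbase = (
        base_id(g.metabolites.get_by_id(sn.target))
        if sn.target in g.metabolites else sn.target
    )
    if not sn.active_reactions:
        result = LumpedReaction(
            target=sn.target,
            net_stoich={sn.target: 1.0},
            source_subnetworks=[sn],
            core_supplied=True,
            target_base=tbase,
        )
    else:
        tc = net.get(sn.target, 0.0)
        if tc <= FLUX_TOL:
            raise ValueError(
                f"lump({sn.target}): subnetwork does not net-produce its target "
                f"(coefficient {tc:g})"
            )
        net = {m: c / tc for m, c in net.items() if abs(c / tc) > COEFF_DROP_TOL}
        net[sn.target] = 1.0
        result = LumpedReaction(
            target=sn.target, net_stoich=net, source_subnetworks=[sn],
            target_base=tbase,
        )
    result.base_stoich = _aggregate_bases(result.net_stoich, g)
    return result


def _aggregate_bases(net: dict[str, float], g: cobra.Model) -> dict[str, float]:
    agg: dict[str, float] = {}
    for met_id, coef in net.items():
        b = base_id(g.metabolites.get_by_id(met_id)) if met_id in g.metabolites else met_id
        agg[b] = agg.get(b, 0.0) + coef
    return {b: c for b, c in agg.items() if abs(c) > COEFF_DROP_TOL}


def lump_element_residual(lr: LumpedReaction, g: cobra.Model) -> dict[str, float]:
    """Net elemental balance of a lumped reaction (zero for balanced members)."""
    residual: dict[str, float] = {}
    for met_id, coef in lr.net_stoich.items():
        met = g.metabolites.get_by_id(met_id)
        for element, count in (met.elements or {}).items():
            residual[element] = residual.get(element, 0.0) + coef * count
        if met.charge is not None:
            residual["charge"] = residual.get("charge", 0.0) + coef * met.charge
    return {e: r for e, r in residual.items() if abs(r) > 1e-6}


def unique_lumps(
    lumps: Iterable[LumpedReaction], tol: float = 1e-6
) -> list[LumpedReaction]:
    """Deduplicate lumped reactions: identical metabolite support, coefficients
    equal within ``tol`` after normalization. Representatives accumulate all
    source subnetworks."""
    reps: list[LumpedReaction] = []
    for lr in lumps:
        merged = False
        for rep in reps:
            if rep.target != lr.target:
                continue
            if set(rep.net_stoich) != set(lr.net_stoich):
                continue
            if all(
                abs(rep.net_stoich[m] - lr.net_stoich[m]) <= tol
                for m in rep.net_stoich
            ):
                rep.source_subnetworks.extend(lr.source_subnetworks)
                merged = True
                break
        if not merged:
            reps.append(
                LumpedReaction(
                    target=lr.target,
                    net_stoich=dict(lr.net_stoich),
                    base_stoich=dict(lr.base_stoich),
                    source_subnetworks=list(lr.source_subnetworks),
                    core_supplied=lr.core_supplied,
                    target_base=lr.target_base,
                )
            )
    return reps
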
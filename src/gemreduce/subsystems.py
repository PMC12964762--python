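"""Assign reactions to metabolic subsystems from curated metabolite lists.

A subsystem is defined by a curated list of compartment-free metabolite
identifiers (typically derived from KEGG modules and mapped to the model's
namespace). A reaction belongs to a subsystem when *all* of its reactants
and products — after removing inorganic compounds and cofactor pairs that
turn over across the reaction — are members of the list. Oxidative
phosphorylation is the exception: it is defined as every reaction touching
an electron carrier (quinones/quinols, cytochromes).

The curated rule, not the source model's annotation, decides membership;
annotation disagreements are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import cobra
import pandas as pd
import yaml

from gemreduce.gem_io import base_id, biomass_reaction_id, is_exchange

logger = logging.getLogger("gemreduce")

OXPHOS_MODE = "electron_carriers"


@dataclass(frozen=True)
class SubsystemDefinition:
    """A named subsystem given by its curated, compartment-free metabolite list.

    ``mode`` is ``"metabolite_list"`` for ordinary subsystems and
    ``"electron_carriers"`` for oxidative phosphorylation, whose content is
    every reaction touching a configured electron carrier.
    """

    name: str
    metabolite_list: frozenset[str] = frozenset()
    source_modules: tuple[str, ...] = ()
    mode: str = "metabolite_list"

    def __post_init__(self):
        object.__setattr__(self, "metabolite_list", frozenset(self.metabolite_list))
        object.__setattr__(self, "source_modules", tuple(self.source_modules))
        if self.mode == "metabolite_list" and not self.metabolite_list:
            raise ValueError(f"subsystem {self.name!r}: empty metabolite list")
        tagged = {m for m in self.metabolite_list if m.endswith(("_c", "_e", "_m", "_p"))}
        if tagged:
            logger.warning(
                "subsystem %s: identifiers %s look compartment-tagged; lists "
                "must use base identifiers", self.name, sorted(tagged)[:5],
            )


@dataclass(frozen=True)
class ExclusionConfig:
    """Global exclusion lists applied during subsystem assignment and graph search."""

    inorganics: frozenset[str] = frozenset()
    cofactor_pairs: frozenset[frozenset[str]] = frozenset()
    electron_carriers: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "inorganics", frozenset(self.inorganics))
        object.__setattr__(
            self,
            "cofactor_pairs",
            frozenset(frozenset(p) for p in self.cofactor_pairs),
        )
        object.__setattr__(self, "electron_carriers", frozenset(self.electron_carriers))
        for pair in self.cofactor_pairs:
            if len(pair) != 2:
                raise ValueError(f"cofactor pair {set(pair)} must have exactly 2 members")
            overlap = pair & self.inorganics
            if overlap:
                logger.warning(
                    "cofactor pair %s overlaps the inorganic list (%s); "
                    "the pair rule takes precedence", set(pair), set(overlap),
                )

    @property
    def pair_members(self) -> frozenset[str]:
        members: set[str] = set()
        for pair in self.cofactor_pairs:
            members |= pair
        return frozenset(members)

    @property
    def traversal_excluded(self) -> frozenset[str]:
        """Base ids unusable as graph-search intermediates: inorganics and pair members."""
        return self.inorganics | self.pair_members

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExclusionConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            inorganics=frozenset(raw.get("inorganics", [])),
            cofactor_pairs=frozenset(
                frozenset(p) for p in raw.get("cofactor_pairs", [])
            ),
            electron_carriers=frozenset(raw.get("electron_carriers", [])),
        )


def load_subsystems(path: str | Path) -> list[SubsystemDefinition]:
    """Read subsystem definitions from a YAML mapping name -> {metabolites, modules, mode}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    defs = []
    for name, entry in raw.items():
        defs.append(
            SubsystemDefinition(
                name=name,
                metabolite_list=frozenset(entry.get("metabolites", [])),
                source_modules=tuple(entry.get("modules", [])),
                mode=entry.get("mode", "metabolite_list"),
            )
        )
    return defs


# ---------------------------------------------------------------------------
# the inclusion rule


def effective_members(rxn: cobra.Reaction, x: ExclusionConfig) -> set[str]:
    """Base ids of a reaction's participants after the exclusion rules.

    Inorganics are always removed. A cofactor pair is removed only when its
    two members appear on opposite sides of the reaction (donor/acceptor
    turnover); a lone pair member is an ordinary metabolite.
    """
    reactants = {base_id(m) for m, c in rxn.metabolites.items() if c < 0}
    products = {base_id(m) for m, c in rxn.metabolites.items() if c > 0}
    removed: set[str] = set(x.inorganics)
    for pair in x.cofactor_pairs:
        a, b = sorted(pair)
        if (a in reactants and b in products) or (b in reactants and a in products):
            removed |= {a, b}
    return (reactants | products) - removed


def _assignable(rxn: cobra.Reaction, biomass_id: str | None) -> bool:
    return not is_exchange(rxn) and rxn.id != biomass_id


def assign_reactions(
    g: cobra.Model, s: SubsystemDefinition, x: ExclusionConfig
) -> set[str]:
    """Reaction ids of ``g`` whose effective members all lie in the subsystem list.

    Compartment tags are ignored for membership. Exchange reactions, the
    biomass reaction, and reactions whose effective member set is empty
    (pure cofactor/inorganic interconversions, which would otherwise join
    every subsystem vacuously) are never assigned.
    """
    if s.mode == OXPHOS_MODE:
        return assign_oxphos(g, x)
    if not s.metabolite_list:
        raise ValueError(f"subsystem {s.name!r}: empty metabolite list")
    biomass_id = biomass_reaction_id(g)
    assigned: set[str] = set()
    for rxn in g.reactions:
        if not _assignable(rxn, biomass_id):
            continue
        members = effective_members(rxn, x)
        if members and members <= s.metabolite_list:
            assigned.add(rxn.id)
    _log_annotation_disagreements(g, s, assigned)
    return assigned


def _log_annotation_disagreements(
    g: cobra.Model, s: SubsystemDefinition, assigned: set[str]
) -> None:
    for rxn in g.reactions:
        annotated = rxn.subsystem or ""
        if s.name.lower() in annotated.lower() and rxn.id not in assigned:
            logger.info(
                "reaction %s annotated to %r in the source model but fails "
                "the metabolite-list rule; excluded", rxn.id, s.name,
            )


def assign_oxphos(g: cobra.Model, x: ExclusionConfig) -> set[str]:
    """Reactions touching >= 1 electron carrier (quinone/quinol, cytochrome) base id."""
    if not x.electron_carriers:
        raise ValueError("electron_carriers list is empty")
    biomass_id = biomass_reaction_id(g)
    return {
        rxn.id
        for rxn in g.reactions
        if _assignable(rxn, biomass_id)
        and any(base_id(m) in x.electron_carriers for m in rxn.metabolites)
    }


def subsystem_report(
    g: cobra.Model,
    defs: Iterable[SubsystemDefinition],
    x: ExclusionConfig,
) -> pd.DataFrame:
    """Per-subsystem reaction count, compartmented metabolite count, unique metabolite count."""
    rows = []
    for s in defs:
        rids = assign_reactions(g, s, x)
        mets = {
            m.id
            for rid in rids
            for m in g.reactions.get_by_id(rid).metabolites
        }
        rows.append(
            {
                "subsystem": s.name,
                "reactions": len(rids),
                "metabolites_compartmentalized": len(mets),
                "metabolites_unique": len(
                    {base_id(g.metabolites.get_by_id(m)) for m in mets}
                ),
            }
        )
    return pd.DataFrame(rows, columns=[
        "subsystem", "reactions", "metabolites_compartmentalized", "metabolites_unique",
    ])


def subsystem_metabolite_instances(
    g: cobra.Model, s: SubsystemDefinition, x: ExclusionConfig
) -> set[str]:
    """Compartmented metabolite ids of ``g`` that instantiate the subsystem's members.

    For an electron-carrier subsystem the members are the non-excluded
    species touched by its reactions.
    """
    if s.mode == OXPHOS_MODE:
        members: set[str] = set()
        for rid in assign_oxphos(g, x):
            for m in g.reactions.get_by_id(rid).metabolites:
                if base_id(m) in x.electron_carriers:
                    members.add(base_id(m))
    else:
        members = set(s.metabolite_list)
    return {m.id for m in g.metabolites if base_id(m) in members}


def subsystem_base_members(
    g: cobra.Model, s: SubsystemDefinition, x: ExclusionConfig
) -> set[str]:
    """Base-id member set of a subsystem (the carrier set for oxphos-mode)."""
    if s.mode == OXPHOS_MODE:
        return {
            base_id(m)
            for rid in assign_oxphos(g, x)
            for m in g.reactions.get_by_id(rid).metabolites
            if base_id(m) in x.electron_carriers
        }
    return set(s.metabolite_list)
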
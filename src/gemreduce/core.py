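"""Core-network extraction: subsystem cores and degree-D graph expansion.

The D0 core of a model is the union of the reactions assigned to the chosen
subsystems, enriched with every further reaction whose non-excluded
participants all lie inside the union of the subsystem metabolite lists.
The degree-D core adds, for every unordered subsystem pair and every path
length d <= D, all directed paths of exactly d reactions that lead from a
metabolite of one subsystem to a metabolite of the other over the bipartite
metabolite-reaction digraph. Reversible reactions contribute both
directions; inorganics and cofactor-pair members are unusable as path
intermediates, as are metabolites of either endpoint subsystem.

Path endpoints are the compartmented instances of subsystem member
metabolites that appear in the D0 core, so e.g. an extracellular copy of a
glycolytic species that the core never touches is not an endpoint.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import cobra
import networkx as nx

from gemreduce.gem_io import base_id, biomass_reaction_id, is_exchange
from gemreduce.subsystems import (
    ExclusionConfig,
    SubsystemDefinition,
    assign_reactions,
    effective_members,
    subsystem_base_members,
)

logger = logging.getLogger("gemreduce")


@dataclass(frozen=True)
class PathRecord:
    """A directed inter-subsystem path: alternating metabolites and reactions."""

    pair: frozenset[str]
    length: int
    mets: tuple[str, ...]   # length + 1 metabolite ids, source first
    rxns: tuple[str, ...]   # length reaction ids

    def canonical(self) -> tuple:
        """Orientation-free key: a reversible chain traversed both ways is one connection."""
        fwd = (self.mets, self.rxns)
        rev = (tuple(reversed(self.mets)), tuple(reversed(self.rxns)))
        return min(fwd, rev)


@dataclass(frozen=True)
class PairDistance:
    """Minimum inherent distance between two subsystems and its path multiplicity."""

    subsystem_pair: frozenset[str]
    min_distance: int | None
    n_min_paths: int
    d_max: int

    @property
    def connected(self) -> bool:
        return self.min_distance is not None


@dataclass(frozen=True)
class CoreNetwork:
    """A degree-annotated reaction/metabolite subset of a GEM with provenance.

    ``provenance`` maps each reaction id to the records that brought it in:
    ``("subsystem", name)``, ``("enrichment",)``, or
    ``("path", pair_key, d, index)``. ``met_base`` caches compartment
    stripping so cores can be compared without the parent model.
    """

    degree: int
    reactions: frozenset[str]
    metabolites: frozenset[str]
    provenance: dict[str, tuple] = field(default_factory=dict, compare=False)
    subsystem_reactions: dict[str, frozenset[str]] = field(
        default_factory=dict, compare=False
    )
    subsystem_bases: dict[str, frozenset[str]] = field(
        default_factory=dict, compare=False
    )
    met_base: dict[str, str] = field(default_factory=dict, compare=False)
    paths: tuple[PathRecord, ...] = field(default=(), compare=False)

    @property
    def base_metabolites(self) -> frozenset[str]:
        return frozenset(self.met_base.get(m, m) for m in self.metabolites)


# ---------------------------------------------------------------------------
# D0


def _touched(g: cobra.Model, rids: Iterable[str]) -> frozenset[str]:
    return frozenset(
        m.id for rid in rids for m in g.reactions.get_by_id(rid).metabolites
    )


def build_d0(
    g: cobra.Model,
    defs: Sequence[SubsystemDefinition],
    x: ExclusionConfig,
) -> CoreNetwork:
    """Build the degree-0 core: subsystem-assigned reactions plus enrichment.

    Enrichment adds every unassigned reaction (exchanges and biomass
    excepted) whose non-empty effective member set lies inside the union of
    all subsystem member lists.
    """
    if not defs:
        raise ValueError("no subsystem definitions given")
    provenance: dict[str, list] = defaultdict(list)
    subsystem_reactions: dict[str, frozenset[str]] = {}
    subsystem_bases: dict[str, frozenset[str]] = {}
    union_members: set[str] = set()
    for s in defs:
        rids = assign_reactions(g, s, x)
        subsystem_reactions[s.name] = frozenset(rids)
        bases = frozenset(subsystem_base_members(g, s, x))
        subsystem_bases[s.name] = bases
        union_members |= bases
        for rid in rids:
            provenance[rid].append(("subsystem", s.name))
    if not union_members:
        raise ValueError("union of subsystem metabolite lists is empty")
    assigned = set(provenance)
    biomass_id = biomass_reaction_id(g)
    for rxn in g.reactions:
        if rxn.id in assigned or is_exchange(rxn) or rxn.id == biomass_id:
            continue
        members = effective_members(rxn, x)
        if members and members <= union_members:
            provenance[rxn.id].append(("enrichment",))
            logger.info("D0 enrichment: %s (members %s)", rxn.id, sorted(members))
    reactions = frozenset(provenance)
    metabolites = _touched(g, reactions)
    return CoreNetwork(
        degree=0,
        reactions=reactions,
        metabolites=metabolites,
        provenance={r: tuple(v) for r, v in provenance.items()},
        subsystem_reactions=subsystem_reactions,
        subsystem_bases=subsystem_bases,
        met_base={m: base_id(g.metabolites.get_by_id(m)) for m in metabolites},
    )


# ---------------------------------------------------------------------------
# bipartite digraph and path search


def reaction_digraph(g: cobra.Model, x: ExclusionConfig) -> nx.DiGraph:
    """Bipartite directed graph: metabolite -> reaction when consumed, reaction
    -> metabolite when produced; reversible reactions expanded to both
    directions; excluded metabolites (inorganics, cofactor-pair members)
    removed as nodes. Reaction nodes are ``(reaction_id, direction)``.
    """
    excluded = x.traversal_excluded
    graph = nx.DiGraph()
    biomass_id = biomass_reaction_id(g)
    for rxn in g.reactions:
        if is_exchange(rxn) or rxn.id == biomass_id:
            continue
        directions = []
        if rxn.upper_bound > 0:
            directions.append(1)
        if rxn.lower_bound < 0:
            directions.append(-1)
        for d in directions:
            rnode = (rxn.id, d)
            for met, coef in rxn.metabolites.items():
                if base_id(met) in excluded:
                    continue
                if coef * d < 0:
                    graph.add_edge(met.id, rnode)
                else:
                    graph.add_edge(rnode, met.id)
    return graph


def _adjacency(graph: nx.DiGraph):
    """met -> [(rxn_id, [produced met ids]), ...] adjacency for the DFS."""
    adj: dict[str, list] = defaultdict(list)
    for node in graph.nodes:
        if isinstance(node, tuple):
            rid, _ = node
            consumed = list(graph.predecessors(node))
            produced = list(graph.successors(node))
            for met in consumed:
                adj[met].append((rid, produced))
    return adj


def _search_paths(
    adj,
    sources: set[str],
    targets: set[str],
    d_max: int,
    forbidden_bases: set[str],
    met_base: dict[str, str],
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """All simple directed paths of 1..d_max reactions from sources to targets.

    Intermediate metabolites may not carry a base id in ``forbidden_bases``
    (the two endpoint subsystems); a path never reuses a reaction or
    revisits a metabolite. The search stops at the first target metabolite
    reached (extending through a target would make it a forbidden
    intermediate).
    """
    out: list[tuple[tuple[str, ...], tuple[str, ...]]] = []

    def rec(met: str, mets: list[str], rxns: list[str]):
        depth = len(rxns)
        if depth > 0 and met in targets:
            out.append((tuple(mets), tuple(rxns)))
            return
        if depth > 0 and met_base.get(met, met) in forbidden_bases:
            return
        if depth == d_max:
            return
        for rid, produced in adj.get(met, ()):
            if rid in rxns:
                continue
            for met2 in produced:
                if met2 in mets:
                    continue
                mets.append(met2)
                rxns.append(rid)
                rec(met2, mets, rxns)
                mets.pop()
                rxns.pop()

    for src in sorted(sources):
        rec(src, [src], [])
    return out


def _pair_endpoints(
    g: cobra.Model, d0: CoreNetwork, name: str
) -> set[str]:
    bases = d0.subsystem_bases[name]
    return {m for m in d0.metabolites if d0.met_base.get(m) in bases}


def _pair_paths(
    g: cobra.Model,
    d0: CoreNetwork,
    x: ExclusionConfig,
    d_max: int,
    adj=None,
) -> dict[frozenset[str], list[PathRecord]]:
    if adj is None:
        adj = _adjacency(reaction_digraph(g, x))
    met_base = {m.id: base_id(m) for m in g.metabolites}
    found: dict[frozenset[str], list[PathRecord]] = {}
    names = sorted(d0.subsystem_bases)
    for a, b in combinations(names, 2):
        pair = frozenset((a, b))
        sources = _pair_endpoints(g, d0, a)
        targets = _pair_endpoints(g, d0, b)
        forbidden = set(d0.subsystem_bases[a]) | set(d0.subsystem_bases[b])
        raw = _search_paths(adj, sources, targets, d_max, forbidden, met_base)
        raw += _search_paths(adj, targets, sources, d_max, forbidden, met_base)
        seen: dict[tuple, PathRecord] = {}
        for mets, rxns in raw:
            rec = PathRecord(pair=pair, length=len(rxns), mets=mets, rxns=rxns)
            seen.setdefault(rec.canonical(), rec)
        found[pair] = sorted(
            seen.values(), key=lambda p: (p.length, p.mets, p.rxns)
        )
    return found


def expand_to_degree(
    g: cobra.Model,
    d0: CoreNetwork,
    D: int,
    x: ExclusionConfig,
) -> CoreNetwork:
    """Expand a D0 core to degree D (cumulative over all path lengths d <= D)."""
    if D < 0:
        raise ValueError("D must be >= 0")
    if D == 0:
        return d0
    per_pair = _pair_paths(g, d0, x, D)
    provenance = {r: list(v) for r, v in d0.provenance.items()}
    paths: list[PathRecord] = list(d0.paths)
    for pair in sorted(per_pair, key=lambda p: tuple(sorted(p))):
        for idx, rec in enumerate(per_pair[pair]):
            paths.append(rec)
            pair_key = "|".join(sorted(pair))
            for rid in rec.rxns:
                provenance.setdefault(rid, []).append(
                    ("path", pair_key, rec.length, idx)
                )
    reactions = frozenset(provenance)
    metabolites = _touched(g, reactions)
    return CoreNetwork(
        degree=D,
        reactions=reactions,
        metabolites=metabolites,
        provenance={r: tuple(v) for r, v in provenance.items()},
        subsystem_reactions=d0.subsystem_reactions,
        subsystem_bases=d0.subsystem_bases,
        met_base={m: base_id(g.metabolites.get_by_id(m)) for m in metabolites},
        paths=tuple(paths),
    )


def pairwise_distances(
    g: cobra.Model,
    d0: CoreNetwork,
    x: ExclusionConfig,
    d_max: int,
) -> list[PairDistance]:
    """Minimum inherent distance per subsystem pair, with minimal-path counts.

    A pair with no valid path of length <= d_max is reported unconnected.
    """
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    per_pair = _pair_paths(g, d0, x, d_max)
    out = []
    for pair in sorted(per_pair, key=lambda p: tuple(sorted(p))):
        recs = per_pair[pair]
        if not recs:
            out.append(PairDistance(pair, None, 0, d_max))
            continue
        dmin = min(r.length for r in recs)
        n_min = sum(1 for r in recs if r.length == dmin)
        out.append(PairDistance(pair, dmin, n_min, d_max))
    return out


def replay_path(g: cobra.Model, x: ExclusionConfig, rec: PathRecord) -> bool:
    """Check a recorded path against the digraph: connected, directed, right length."""
    graph = reaction_digraph(g, x)
    if len(rec.mets) != rec.length + 1 or len(rec.rxns) != rec.length:
        return False
    for i, rid in enumerate(rec.rxns):
        src, dst = rec.mets[i], rec.mets[i + 1]
        ok = False
        for d in (1, -1):
            node = (rid, d)
            if graph.has_edge(src, node) and graph.has_edge(node, dst):
                ok = True
        if not ok:
            return False
    return True


def export_graphml(g: cobra.Model, x: ExclusionConfig, path: str) -> None:
    """Write the bipartite digraph as GraphML (reaction nodes flattened to strings)."""
    graph = reaction_digraph(g, x)
    flat = nx.DiGraph()
    for u, v in graph.edges:
        fu = u if isinstance(u, str) else f"{u[0]}@{'fwd' if u[1] > 0 else 'rev'}"
        fv = v if isinstance(v, str) else f"{v[0]}@{'fwd' if v[1] > 0 else 'rev'}"
        flat.add_edge(fu, fv)
    for node in flat.nodes:
        flat.nodes[node]["kind"] = "reaction" if "@" in node else "metabolite"
    nx.write_graphml(flat, path)
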
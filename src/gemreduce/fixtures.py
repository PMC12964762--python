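"""Deterministic toy GEMs with fully known ground truth, plus brute-force oracles.

The generator emulates the structure the reduction workflow consumes:

* ``n_subsystems`` isomerization chains of elementally identical species
  (one curated metabolite list each), with cofactor side-reactions
  (ATP-activation, NAD-reduction) that pull the energy/redox carriers into
  the core, and optional shortcut reactions the source model leaves
  unannotated but the metabolite-list rule recovers;
* planted inter-subsystem bridges of known length and multiplicity — the
  only connections between subsystems, so pairwise distances are known by
  construction;
* planted biosynthetic routes from a core anchor metabolite to each biomass
  building block, each step drawn from {isomerize, aminate, ATP-activate,
  NAD-reduce}, so the minimal subnetwork, its lumped net reaction and its
  cost vector are known by construction;
* an exchange layer (glucose, ammonia, phosphate, oxygen, water) with
  transporters, optional alternative carbon source, optional
  medium-supplied building block, and an optional extracellular substrate
  with a unique 3-reaction catabolic route secreting a byproduct;
* dead-end distractor chains that enlarge the search space without
  touching the ground truth.

Every non-boundary reaction is elementally balanced; the build validates
this and refuses a spec that plants an unbalanced reaction.

The oracles are exhaustive enumerations (depth-bounded DFS over the raw
stoichiometry; subset search with an LP feasibility check) guarded to small
problems; they exist to certify the graph search and the MILP enumeration
on fixtures and are independent of both implementations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import cobra
import numpy as np

from gemreduce.core import CoreNetwork, PathRecord
from gemreduce.gem_io import Medium, base_id, biomass_reaction_id
from gemreduce.subnetworks import non_core_reactions, prepare_bbb_model
from gemreduce.subsystems import ExclusionConfig, SubsystemDefinition

logger = logging.getLogger("gemreduce")


class ToySpecError(ValueError):
    """The fixture spec is internally inconsistent."""


class OracleGuardError(RuntimeError):
    """The oracle was asked for a problem beyond its tractability guard."""


# elemental formulas (all species neutral); the shared skeleton of every
# isomer is C6H12O6, cofactors carry their real compositions
_F = {
    "skel": {"C": 6, "H": 12, "O": 6},
    "atp": {"C": 10, "H": 16, "N": 5, "O": 13, "P": 3},
    "adp": {"C": 10, "H": 15, "N": 5, "O": 10, "P": 2},
    "pi": {"H": 3, "O": 4, "P": 1},
    "nad": {"C": 21, "H": 27, "N": 7, "O": 14, "P": 2},
    "nadh": {"C": 21, "H": 29, "N": 7, "O": 14, "P": 2},
    "nh3": {"H": 3, "N": 1},
    "h2o": {"H": 2, "O": 1},
    "o2": {"O": 2},
    "q": {"C": 9, "H": 10, "O": 2},
    "qh2": {"C": 9, "H": 12, "O": 2},
    "byp": {"C": 3, "H": 6, "O": 3},
}

_STEP_DELTA = {
    "iso": {},
    "aminate": {"H": 3, "N": 1},
    "phos": {"H": 1, "O": 3, "P": 1},
    "redox": {"H": -2},
}

STEP_KINDS = tuple(_STEP_DELTA)


def _formula_str(counts: dict[str, int]) -> str:
    order = ["C", "H"] + sorted(k for k in counts if k not in ("C", "H"))
    return "".join(f"{el}{counts[el]}" for el in order if counts.get(el))


def _add(a: dict, b: dict, sign: int = 1) -> dict:
    out = dict(a)
    for el, n in b.items():
        out[el] = out.get(el, 0) + sign * n
    return {el: n for el, n in out.items() if n}


@dataclass(frozen=True)
class Bridge:
    """A planted inter-subsystem connection of known length and multiplicity."""

    pair: tuple[int, int]
    length: int = 2
    multiplicity: int = 1


@dataclass(frozen=True)
class Route:
    """A planted biosynthesis route from a core anchor to a building block."""

    target: str
    subsystem: int = 0
    anchor: int = 1
    kinds: tuple[str, ...] = ("aminate",)
    n_alternatives: int = 1
    extra_step_alternative: bool = False  # one alt route one step longer


@dataclass(frozen=True)
class ToyGemSpec:
    """Blueprint of a toy GEM; deterministic for a fixed seed."""

    n_subsystems: int = 3
    metabolites_per_subsystem: int = 4
    planted_bridges: tuple[Bridge, ...] = (Bridge((0, 1), 2),)
    planted_bbb_routes: tuple[Route, ...] = (Route("bbb0"),)
    n_unannotated: int = 1
    n_distractors: int = 2
    include_oxphos: bool = False
    alt_carbon: bool = False
    bbb_in_medium: bool = False
    substrate_route: bool = False
    unbalanced_reaction: bool = False
    seed: int = 0

    def validate(self) -> None:
        p = self.metabolites_per_subsystem
        if self.n_subsystems < 1 or p < 2:
            raise ToySpecError("need >= 1 subsystem with >= 2 metabolites each")
        for br in self.planted_bridges:
            a, b = br.pair
            if not (0 <= a < self.n_subsystems and 0 <= b < self.n_subsystems) or a == b:
                raise ToySpecError(f"bridge endpoints {br.pair} do not exist")
            if br.length < 1 or br.multiplicity < 1:
                raise ToySpecError(f"bridge {br.pair}: bad length/multiplicity")
        for rt in self.planted_bbb_routes:
            if not (0 <= rt.subsystem < self.n_subsystems):
                raise ToySpecError(f"route {rt.target}: subsystem out of range")
            if not (0 <= rt.anchor < p):
                raise ToySpecError(f"route {rt.target}: anchor out of range")
            bad = set(rt.kinds) - set(STEP_KINDS)
            if bad or not rt.kinds:
                raise ToySpecError(f"route {rt.target}: bad step kinds {bad}")
        if self.unbalanced_reaction:
            raise ToySpecError(
                "spec plants an elementally unbalanced reaction; refusing to build"
            )


@dataclass
class GroundTruth:
    """Everything the workflow should recover from the generated model."""

    assignments: dict[str, set[str]] = field(default_factory=dict)
    enrichment: set[str] = field(default_factory=set)
    d0_reactions: set[str] = field(default_factory=set)
    bridges: dict[frozenset[str], dict] = field(default_factory=dict)
    bbbs: set[str] = field(default_factory=set)
    minimal_subnetworks: dict[str, list[frozenset[str]]] = field(default_factory=dict)
    expected_lumps: dict[str, dict[str, float]] = field(default_factory=dict)
    minimal_media: list[frozenset[str]] = field(default_factory=list)
    medium_candidates: list[str] = field(default_factory=list)
    substrate: str | None = None
    substrate_subnetwork: frozenset[str] | None = None
    substrate_byproducts: frozenset[str] = frozenset()


@dataclass
class ToyGem:
    """Generated model plus its ground truth and workflow configuration."""

    model: cobra.Model
    truth: GroundTruth
    subsystem_defs: list[SubsystemDefinition]
    exclusions: ExclusionConfig
    medium: Medium


def _met(mid: str, formula: dict, comp: str = "c") -> cobra.Metabolite:
    m = cobra.Metabolite(
        f"{mid}_{comp}", formula=_formula_str(formula), compartment=comp, charge=0
    )
    return m


def make_toy_gem(spec: ToyGemSpec) -> ToyGem:
    """Build a toy GEM from a spec; deterministic for a fixed seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    model = cobra.Model(f"toy_seed{spec.seed}")
    truth = GroundTruth()
    mets: dict[str, cobra.Metabolite] = {}
    reactions: list[cobra.Reaction] = []

    def met(mid: str, formula: dict, comp: str = "c") -> cobra.Metabolite:
        key = f"{mid}_{comp}"
        if key not in mets:
            mets[key] = _met(mid, formula, comp)
        return mets[key]

    def rxn(rid: str, stoich: dict[cobra.Metabolite, float],
            lb: float, ub: float, subsystem: str = "") -> cobra.Reaction:
        r = cobra.Reaction(rid)
        r.add_metabolites(stoich)
        r.bounds = (lb, ub)
        if subsystem:
            r.subsystem = subsystem
        reactions.append(r)
        return r

    p = spec.metabolites_per_subsystem
    names = [f"SS{k}" for k in range(spec.n_subsystems)]
    atp, adp = met("atp", _F["atp"]), met("adp", _F["adp"])
    nad, nadh = met("nad", _F["nad"]), met("nadh", _F["nadh"])
    nh3 = met("nh3", _F["nh3"])

    # --- subsystem chains + cofactor side reactions -----------------------
    lists: dict[str, set[str]] = {}
    for k, name in enumerate(names):
        chain = [met(f"m{k}_{i}", _F["skel"]) for i in range(p)]
        members = {base_id(m) for m in chain}
        for i in range(p - 1):
            r = rxn(f"R_{name}_{i}", {chain[i]: -1, chain[i + 1]: 1},
                    -10, 10, subsystem=name)
            truth.assignments.setdefault(name, set()).add(r.id)
        if k == 0:
            # activation / reduction side branches put atp, adp, nad, nadh
            # (hence the carriers the routes rely on) into the core
            act = met(f"m{k}_act", _add(_F["skel"], _STEP_DELTA["phos"]))
            red = met(f"m{k}_red", _add(_F["skel"], _STEP_DELTA["redox"]))
            members |= {base_id(act), base_id(red)}
            r1 = rxn(f"R_{name}_act", {chain[0]: -1, atp: -1, act: 1, adp: 1},
                     -10, 10, subsystem=name)
            r2 = rxn(f"R_{name}_red", {chain[1]: -1, nad: -1, red: 1, nadh: 1},
                     -10, 10, subsystem=name)
            truth.assignments[name] |= {r1.id, r2.id}
        lists[name] = members

    # --- unannotated shortcuts inside a subsystem: the metabolite-list rule
    # recovers these although the source model carries no subsystem label
    for j in range(spec.n_unannotated):
        k = int(rng.integers(0, spec.n_subsystems))
        i = int(rng.integers(0, p - 2)) if p > 2 else 0
        hop = min(i + 2, p - 1)
        if hop == i:
            continue
        r = rxn(f"R_unannot{j}", {mets[f"m{k}_{i}_c"]: -1, mets[f"m{k}_{hop}_c"]: 1},
                -10, 10)
        truth.assignments.setdefault(names[k], set()).add(r.id)

    # --- bridges ----------------------------------------------------------
    for bi, br in enumerate(spec.planted_bridges):
        a, b = br.pair
        src, dst = mets[f"m{a}_{p - 1}_c"], mets[f"m{b}_0_c"]
        pair_key = frozenset((names[a], names[b]))
        entry = truth.bridges.setdefault(
            pair_key, {"length": br.length, "multiplicity": 0, "paths": []}
        )
        for alt in range(br.multiplicity):
            nodes = [src]
            nodes += [
                met(f"x{bi}_{alt}_{s}", _F["skel"])
                for s in range(br.length - 1)
            ]
            nodes.append(dst)
            rids = []
            for s in range(br.length):
                r = rxn(f"BR{bi}_{alt}_{s}", {nodes[s]: -1, nodes[s + 1]: 1}, 0, 10)
                rids.append(r.id)
            entry["multiplicity"] += 1
            entry["paths"].append(rids)
            if br.length == 1:
                # a one-reaction bridge is recovered by D0 enrichment, not search
                truth.enrichment.add(rids[0])

    # --- exchange layer ---------------------------------------------------
    def boundary(species: str, formula: dict, reversible_transport: bool = True,
                 uptake: bool = True):
        ce = met(species, formula, comp="e")
        cc = met(species, formula, comp="c")
        rxn(f"EX_{species}_e", {ce: -1}, -10 if uptake else 0, 10)
        lb = -10 if reversible_transport else 0
        rxn(f"T_{species}", {ce: -1, cc: 1}, lb, 10)
        return cc

    glc_c = boundary("glc", _F["skel"], reversible_transport=False)
    rxn("T_glc_entry", {glc_c: -1, mets["m0_0_c"]: 1}, 0, 10)
    nh3_c_in = boundary("nh3", _F["nh3"], reversible_transport=False)
    assert nh3_c_in is nh3
    pi_c = boundary("pi", _F["pi"], reversible_transport=False)
    o2_c = boundary("o2", _F["o2"], reversible_transport=False)
    h2o_c = met("h2o", _F["h2o"])
    boundary("h2o", _F["h2o"], reversible_transport=True)
    q, qh2 = met("q", _F["q"]), met("qh2", _F["qh2"])
    rxn("NADHQ", {nadh: -1, q: -1, nad: 1, qh2: 1}, 0, 10)
    rxn("QO", {qh2: -1, o2_c: -0.5, q: 1, h2o_c: 1}, 0, 10)
    rxn("ATPS", {adp: -1, pi_c: -1, atp: 1, h2o_c: 1}, 0, 10)

    medium_uptakes = {"EX_glc_e": 10.0, "EX_nh3_e": 10.0, "EX_pi_e": 10.0,
                      "EX_o2_e": 10.0, "EX_h2o_e": 10.0}
    if spec.alt_carbon:
        fru_c = boundary("fru", _F["skel"], reversible_transport=False)
        rxn("T_fru_entry", {fru_c: -1, mets["m0_0_c"]: 1}, 0, 10)
        medium_uptakes["EX_fru_e"] = 10.0

    # --- planted biosynthesis routes --------------------------------------
    biomass_demand: dict[cobra.Metabolite, float] = {}
    needs_n = needs_atp = needs_redox = False
    for rt in spec.planted_bbb_routes:
        anchor = mets[f"m{rt.subsystem}_{rt.anchor}_c"]
        delta: dict[str, int] = {}
        for kind in rt.kinds:
            delta = _add(delta, _STEP_DELTA[kind])
        target = met(rt.target, _add(_F["skel"], delta))
        truth.bbbs.add(target.id)
        biomass_demand[target] = biomass_demand.get(target, 0) - 1
        n_amin = rt.kinds.count("aminate")
        n_phos = rt.kinds.count("phos")
        n_red = rt.kinds.count("redox")
        needs_n |= n_amin > 0
        needs_atp |= n_phos > 0
        needs_redox |= n_red > 0
        alt_orders = [tuple(rt.kinds)]
        for _ in range(rt.n_alternatives - 1):
            order = list(rt.kinds)
            rng.shuffle(order)
            alt_orders.append(tuple(order))
        if rt.extra_step_alternative:
            alt_orders.append(tuple(rt.kinds) + ("iso",))
        supports = []
        for ai, order in enumerate(alt_orders):
            current = anchor
            acc: dict[str, int] = {}
            rids = []
            for si, kind in enumerate(order):
                acc = _add(acc, _STEP_DELTA[kind])
                nxt = (
                    target if si == len(order) - 1
                    else met(f"z_{rt.target}_{ai}_{si}", _add(_F["skel"], acc))
                )
                stoich: dict[cobra.Metabolite, float] = {current: -1, nxt: 1}
                if kind == "aminate":
                    stoich[nh3] = -1
                elif kind == "phos":
                    stoich[atp] = -1
                    stoich[adp] = 1
                elif kind == "redox":
                    stoich[nad] = -1
                    stoich[nadh] = 1
                r = rxn(f"RT_{rt.target}_{ai}_{si}", stoich, 0, 10)
                rids.append(r.id)
                current = nxt
            support = frozenset(rids) | ({"T_nh3"} if "aminate" in order else frozenset())
            supports.append(support)
        truth.minimal_subnetworks[target.id] = supports
        truth.expected_lumps[target.id] = {
            base_id(anchor): -1.0,
            base_id(target): 1.0,
            **({"nh3": -float(n_amin)} if n_amin else {}),
            **({"atp": -float(n_phos), "adp": float(n_phos)} if n_phos else {}),
            **({"nad": -float(n_red), "nadh": float(n_red)} if n_red else {}),
        }

    if spec.bbb_in_medium:
        vit_c = boundary("vit", _add(_F["skel"], {"N": 2, "H": 4}),
                         reversible_transport=False)
        truth.bbbs.add(vit_c.id)
        biomass_demand[vit_c] = -1
        truth.minimal_subnetworks[vit_c.id] = [frozenset({"T_vit"})]
        # pure translocation: the compartment-stripped net stoichiometry cancels
        truth.expected_lumps[vit_c.id] = {}
        medium_uptakes["EX_vit_e"] = 10.0

    # --- extracellular substrate with a unique 3-reaction catabolic route --
    if spec.substrate_route:
        sub_f = _add(_F["skel"], _F["byp"])
        sub_e = met("sub", sub_f, comp="e")
        sub_c = met("sub", sub_f, comp="c")
        byp_c = met("byp", _F["byp"], comp="c")
        byp_e = met("byp", _F["byp"], comp="e")
        rxn("EX_sub_e", {sub_e: -1}, 0, 10)
        rxn("T_sub", {sub_e: -1, sub_c: 1}, 0, 10)
        rxn("SUBCAT", {sub_c: -1, mets["m0_1_c"]: 1, byp_c: 1}, 0, 10)
        rxn("T_byp", {byp_c: -1, byp_e: 1}, 0, 10)
        rxn("EX_byp_e", {byp_e: -1}, 0, 10)
        truth.substrate = "sub_e"
        truth.substrate_subnetwork = frozenset({"T_sub", "SUBCAT", "T_byp"})
        truth.substrate_byproducts = frozenset({"byp"})

    # --- distractor dead ends ---------------------------------------------
    for j in range(spec.n_distractors):
        k = int(rng.integers(0, spec.n_subsystems))
        i = int(rng.integers(0, p))
        w1 = met(f"w{j}_1", _F["skel"])
        w2 = met(f"w{j}_2", _F["skel"])
        rxn(f"DIST{j}_a", {mets[f"m{k}_{i}_c"]: -1, w1: 1}, 0, 10)
        rxn(f"DIST{j}_b", {w1: -1, w2: 1}, 0, 10)

    # --- biomass ----------------------------------------------------------
    biomass = cobra.Reaction("BIOMASS")
    biomass.add_metabolites(biomass_demand)
    biomass.bounds = (0, 10)
    reactions.append(biomass)

    order = rng.permutation(len(reactions))
    model.add_metabolites(sorted(mets.values(), key=lambda m: m.id))
    model.add_reactions([reactions[i] for i in order])
    model.objective = "BIOMASS"
    model.biomass_reaction_id = "BIOMASS"
    # subsystem annotations as SBML groups so both dialects round-trip them
    groups = []
    for name in names:
        members = [
            model.reactions.get_by_id(r.id) for r in model.reactions
            if r.subsystem == name
        ]
        groups.append(cobra.core.Group(id=name, name=name, members=members))
    model.add_groups(groups)

    _validate_balance(model)

    # --- configs and remaining truth --------------------------------------
    exclusions = ExclusionConfig(
        inorganics=frozenset({"h2o", "o2", "pi", "nh3", "co2", "h"}),
        cofactor_pairs=frozenset({
            frozenset({"atp", "adp"}), frozenset({"nad", "nadh"}),
        }),
        electron_carriers=frozenset({"q", "qh2"}),
    )
    defs = [
        SubsystemDefinition(name=name, metabolite_list=frozenset(lists[name]))
        for name in names
    ]
    if spec.include_oxphos:
        defs.append(SubsystemDefinition(name="OXPHOS", mode="electron_carriers"))
        truth.assignments["OXPHOS"] = {"NADHQ", "QO"}
    truth.d0_reactions = (
        set().union(*truth.assignments.values()) | truth.enrichment
    )
    medium = Medium(uptakes=medium_uptakes, label="toy_medium")

    carbon = ["EX_glc_e"] + (["EX_fru_e"] if spec.alt_carbon else [])
    minimal: set[str] = set()
    if needs_n:
        minimal.add("EX_nh3_e")
    if needs_atp:
        minimal |= {"EX_pi_e", "EX_o2_e"} if needs_redox else {"EX_pi_e"}
    if needs_redox:
        minimal.add("EX_o2_e")
    if spec.bbb_in_medium:
        minimal.add("EX_vit_e")
    truth.minimal_media = [frozenset(minimal | {c}) for c in carbon]
    truth.medium_candidates = sorted(medium_uptakes)

    return ToyGem(model=model, truth=truth, subsystem_defs=defs,
                  exclusions=exclusions, medium=medium)


_ROUTE_KIND_MENU = (
    ("iso",), ("aminate",), ("redox",), ("aminate", "iso"),
    ("aminate", "phos"), ("phos", "redox"), ("iso", "redox"),
)


def variant_spec(seed: int, lean: bool = False) -> ToyGemSpec:
    """A varied, seed-determined blueprint for property-testing batteries.

    Rotates subsystem counts, bridge geometries, route chemistries and the
    optional structural flags. ``lean`` keeps the non-core reaction count
    small enough for the exhaustive subnetwork oracle to stay fast.
    """
    rng = np.random.default_rng(seed)
    n_sub = int(rng.integers(2, 4))
    p = int(rng.integers(3, 5))
    bridges = [Bridge((0, 1), int(rng.integers(1, 4)),
                      1 if lean else int(rng.integers(1, 3)))]
    if n_sub == 3 and rng.random() < 0.6:
        bridges.append(Bridge((1, 2), int(rng.integers(1, 3))))
    kinds = _ROUTE_KIND_MENU[int(rng.integers(0, len(_ROUTE_KIND_MENU)))]
    routes = [Route("bbb0", subsystem=0, anchor=int(rng.integers(0, p)),
                    kinds=kinds, n_alternatives=int(rng.integers(1, 3)))]
    return ToyGemSpec(
        n_subsystems=n_sub,
        metabolites_per_subsystem=p,
        planted_bridges=tuple(bridges),
        planted_bbb_routes=tuple(routes),
        n_unannotated=int(rng.integers(0, 2)),
        n_distractors=1 if lean else int(rng.integers(1, 4)),
        include_oxphos=not lean and seed % 4 == 0,
        alt_carbon=not lean and seed % 5 == 0,
        bbb_in_medium=seed % 3 == 1,
        substrate_route=not lean and seed % 3 == 0,
        seed=seed,
    )


def _validate_balance(model: cobra.Model) -> None:
    bad = {}
    for r in model.reactions:
        if r.id == "BIOMASS" or r.id.startswith("EX_"):
            continue
        imbalance = r.check_mass_balance()
        if imbalance:
            bad[r.id] = imbalance
    if bad:
        raise ToySpecError(f"unbalanced planted reactions: {bad}")


def write_toy(model: cobra.Model, out_dir: str | Path) -> dict[str, Path]:
    """Write a toy model in both dialects so I/O round-trips share one truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "sbml": out_dir / f"{model.id}.xml",
        "json": out_dir / f"{model.id}.json",
    }
    cobra.io.write_sbml_model(model, str(paths["sbml"]))
    cobra.io.save_json_model(model, str(paths["json"]))
    return paths


# ---------------------------------------------------------------------------
# oracles


def oracle_paths(
    g: cobra.Model,
    sources: Iterable[str],
    targets: Iterable[str],
    d_max: int,
    excluded_bases: Iterable[str] = (),
    forbidden_intermediate_bases: Iterable[str] = (),
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Exhaustively enumerate directed paths of <= d_max reactions.

    Semantics match the core graph search: reversible reactions usable in
    both directions, excluded metabolites unusable as nodes, intermediates
    outside the forbidden base-id sets, simple paths (no reaction reuse, no
    metabolite revisits), recording stops at the first target. Guarded to
    d_max <= 4 and <= 60 reactions.
    """
    if d_max > 4 or len(g.reactions) > 60:
        raise OracleGuardError(
            f"oracle_paths guard: d_max <= 4 and <= 60 reactions "
            f"(got {d_max}, {len(g.reactions)})"
        )
    excluded = set(excluded_bases)
    forbidden = set(forbidden_intermediate_bases)
    sources, targets = set(sources), set(targets)
    biomass_id = biomass_reaction_id(g)
    bases = {m.id: base_id(m) for m in g.metabolites}

    steps = []  # (rxn_id, consumed met ids, produced met ids)
    for r in g.reactions:
        if r.id == biomass_id or len(r.metabolites) == 1:
            continue
        fwd_in = [m.id for m, c in r.metabolites.items() if c < 0]
        fwd_out = [m.id for m, c in r.metabolites.items() if c > 0]
        if r.upper_bound > 0:
            steps.append((r.id, fwd_in, fwd_out))
        if r.lower_bound < 0:
            steps.append((r.id, fwd_out, fwd_in))

    found = []

    def rec(met, mets, rxns):
        if len(rxns) > 0 and met in targets:
            found.append((tuple(mets), tuple(rxns)))
            return
        if len(rxns) > 0 and bases[met] in forbidden:
            return
        if len(rxns) == d_max:
            return
        for rid, consumed, produced in steps:
            if rid in rxns or met not in consumed:
                continue
            for nxt in produced:
                if nxt in mets or bases[nxt] in excluded:
                    continue
                rec(nxt, mets + [nxt], rxns + [rid])

    for src in sorted(sources):
        if bases[src] in excluded:
            continue
        rec(src, [src], [])
    return found


def oracle_pair_paths(
    g: cobra.Model,
    d0: CoreNetwork,
    x: ExclusionConfig,
    d_max: int,
) -> dict[frozenset[str], set[tuple]]:
    """Canonical path keys per subsystem pair, from the exhaustive oracle."""
    out: dict[frozenset[str], set[tuple]] = {}
    for a, b in combinations(sorted(d0.subsystem_bases), 2):
        pair = frozenset((a, b))
        src = {m for m in d0.metabolites if d0.met_base.get(m) in d0.subsystem_bases[a]}
        dst = {m for m in d0.metabolites if d0.met_base.get(m) in d0.subsystem_bases[b]}
        forbidden = set(d0.subsystem_bases[a]) | set(d0.subsystem_bases[b])
        raw = oracle_paths(g, src, dst, d_max, x.traversal_excluded, forbidden)
        raw += oracle_paths(g, dst, src, d_max, x.traversal_excluded, forbidden)
        keys = set()
        for mets, rxns in raw:
            rec = PathRecord(pair=pair, length=len(rxns), mets=mets, rxns=rxns)
            keys.add(rec.canonical())
        out[pair] = keys
    return out


def oracle_subnetworks(
    g: cobra.Model,
    core: CoreNetwork,
    target: str,
    medium: Medium,
    max_size: int = 4,
) -> list[frozenset[str]]:
    """All support-minimal feasible non-core reaction subsets, by subset search.

    A subset is feasible when, with every other non-core reaction shut and
    core metabolites free, a flux distribution produces one unit of the
    target under the medium (checked by a linear solve). Guarded to <= 25
    non-core reactions.
    """
    m, candidates = prepare_bbb_model(g, core, target, medium)
    if len(candidates) > 25:
        raise OracleGuardError(
            f"oracle_subnetworks guard: <= 25 non-core reactions (got {len(candidates)})"
        )
    originals = {rid: m.reactions.get_by_id(rid).bounds for rid in candidates}
    m.objective = m.problem.Objective(0, direction="min")

    def feasible(subset: frozenset[str]) -> bool:
        for rid in candidates:
            m.reactions.get_by_id(rid).bounds = (
                originals[rid] if rid in subset else (0.0, 0.0)
            )
        m.solver.optimize()
        return m.solver.status == "optimal"

    minimal: list[frozenset[str]] = []
    for size in range(0, max_size + 1):
        for combo in combinations(candidates, size):
            subset = frozenset(combo)
            if any(found <= subset for found in minimal):
                continue
            if feasible(subset):
                minimal.append(subset)
    return minimal
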
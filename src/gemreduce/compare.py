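"""Jaccard similarity at every level of the workflow, and biosynthetic costs.

The Jaccard index J(A, B) = |A n B| / |A u B| is applied to reaction or
metabolite sets of core networks, to the unions of alternative biosynthetic
subnetworks per biomass building block, and to co-substrate/byproduct sets.
Costs are read off lumped reactions: moles of each of the twelve canonical
biosynthetic precursor metabolites, plus net ATP / NADH / NADPH turnover,
per mole of target, averaged across alternative lumps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from gemreduce.core import CoreNetwork
from gemreduce.subnetworks import LumpedReaction, Subnetwork, SubnetworkSet

logger = logging.getLogger("gemreduce")


def jaccard(a: Iterable, b: Iterable) -> float:
    """|A n B| / |A u B|. Two empty sets are defined as identical (1, logged)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        logger.warning("jaccard of two empty sets: defined as 1 by convention")
        return 1.0
    return len(a & b) / len(union)


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise Jaccard matrix with its comparison metadata."""

    values: pd.DataFrame
    level: str = "reaction"           # reaction | metabolite
    compartments: str = "kept"        # kept | stripped

    @property
    def labels(self) -> list[str]:
        return list(self.values.index)

    def __getitem__(self, pair):
        a, b = pair
        return self.values.loc[a, b]


def _item_set(net, level: str, compartments: str) -> set:
    if isinstance(net, CoreNetwork):
        if level == "reaction":
            return set(net.reactions)
        if compartments == "stripped":
            return set(net.base_metabolites)
        return set(net.metabolites)
    return set(net)


def compare_networks(
    nets: Sequence[tuple[str, object]],
    level: str = "reaction",
    compartments: str = "kept",
) -> SimilarityMatrix:
    """Pairwise Jaccard over labeled networks (CoreNetwork or plain sets).

    For CoreNetwork inputs the item sets are taken at the requested level;
    plain sets are compared as given (strip them first for a
    compartment-free comparison).
    """
    if len(nets) < 2:
        raise ValueError("need >= 2 networks to compare")
    labels = [label for label, _ in nets]
    sets = {label: _item_set(net, level, compartments) for label, net in nets}
    mat = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    for a, b in combinations(labels, 2):
        v = jaccard(sets[a], sets[b])
        mat.loc[a, b] = v
        mat.loc[b, a] = v
    for label in labels:
        mat.loc[label, label] = jaccard(sets[label], sets[label])
    return SimilarityMatrix(values=mat, level=level, compartments=compartments)


def _union_reactions(
    subnets: SubnetworkSet | Sequence[Subnetwork],
    harmonization: Mapping[str, str] | None,
) -> set[str]:
    members = subnets.subnetworks if isinstance(subnets, SubnetworkSet) else subnets
    union = {r for sn in members for r in sn.active_reactions}
    if harmonization:
        union = {harmonization.get(r, r) for r in union}
    return union


def compare_subnetwork_unions(
    per_target: Mapping[str, Mapping[str, SubnetworkSet | Sequence[Subnetwork]]],
    harmonization: Mapping[str, Mapping[str, str]] | None = None,
) -> dict[str, SimilarityMatrix]:
    """Per-BBB Jaccard of the unions of alternative subnetwork reaction sets.

    ``per_target`` maps organism label -> (BBB base id -> subnetworks);
    ``harmonization`` optionally maps each organism's reaction ids into a
    common namespace. A BBB absent in an organism (or with an empty
    enumeration) is flagged missing (NaN), never scored 0.
    """
    organisms = sorted(per_target)
    if len(organisms) < 2:
        raise ValueError("need >= 2 organisms")
    bbbs = sorted({b for org in organisms for b in per_target[org]})
    out: dict[str, SimilarityMatrix] = {}
    for bbb in bbbs:
        mat = pd.DataFrame(
            np.full((len(organisms),) * 2, np.nan),
            index=organisms, columns=organisms,
        )
        sets = {}
        for org in organisms:
            subnets = per_target[org].get(bbb)
            if subnets is None or len(subnets) == 0:
                continue  # missing: leave NaN
            hmap = (harmonization or {}).get(org)
            sets[org] = _union_reactions(subnets, hmap)
        for org in sets:
            mat.loc[org, org] = 1.0
        for a, b in combinations(sorted(sets), 2):
            v = jaccard(sets[a], sets[b])
            mat.loc[a, b] = v
            mat.loc[b, a] = v
        out[bbb] = SimilarityMatrix(values=mat, level="reaction",
                                    compartments="stripped")
    return out


def category_average(
    per_bbb: Mapping[str, SimilarityMatrix],
    categories: Mapping[str, str],
) -> dict[str, pd.DataFrame]:
    """Arithmetic mean of per-BBB Jaccard matrices within each category.

    Missing-flagged (NaN) entries are excluded from the mean; the exclusion
    count per pair is reported alongside as the ``..._n_excluded`` frame.
    Every BBB must be categorized; empty categories are omitted with a
    warning.
    """
    uncategorized = set(per_bbb) - set(categories)
    if uncategorized:
        raise ValueError(f"uncategorized BBBs: {sorted(uncategorized)}")
    out: dict[str, pd.DataFrame] = {}
    by_cat: dict[str, list[str]] = {}
    for bbb in per_bbb:
        by_cat.setdefault(categories[bbb], []).append(bbb)
    for cat in sorted(set(categories.values())):
        members = by_cat.get(cat, [])
        if not members:
            logger.warning("category %r has no BBBs; omitted", cat)
            continue
        stack = np.stack([per_bbb[b].values.to_numpy() for b in members])
        labels = per_bbb[members[0]].labels
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(stack, axis=0)
        out[cat] = pd.DataFrame(mean, index=labels, columns=labels)
        out[f"{cat}_n_excluded"] = pd.DataFrame(
            np.isnan(stack).sum(axis=0), index=labels, columns=labels
        )
    return out


# ---------------------------------------------------------------------------
# biosynthetic cost


#: the twelve canonical biosynthetic precursor metabolites (BiGG base ids):
#: glucose-6-P, fructose-6-P, ribose-5-P, erythrose-4-P, triose-P,
#: 3-phosphoglycerate, phosphoenolpyruvate, pyruvate, acetyl-CoA,
#: oxaloacetate, 2-oxoglutarate, succinyl-CoA
DEFAULT_PRECURSORS = (
    "g6p", "f6p", "r5p", "e4p", "g3p", "3pg", "pep", "pyr",
    "accoa", "oaa", "akg", "succoa",
)

#: energy/redox carrier accounting: ATP cost counts ADP produced plus twice
#: AMP produced; NADH/NADPH costs are net consumption (negative = produced).
DEFAULT_CARRIERS = {
    "atp": {"adp": 1.0, "amp": 2.0},
    "nadh": {"nadh": -1.0},
    "nadph": {"nadph": -1.0},
}


@dataclass
class CostVector:
    """Moles of precursors and carriers per mole of one biomass building block."""

    target: str
    precursor_moles: dict[str, float] = field(default_factory=dict)
    atp: float = 0.0
    nadh: float = 0.0
    nadph: float = 0.0
    other: dict[str, float] = field(default_factory=dict)
    n_lumps: int = 1

    def as_series(self, precursors: Sequence[str] = DEFAULT_PRECURSORS) -> pd.Series:
        data = {p: self.precursor_moles.get(p, 0.0) for p in precursors}
        data.update(atp=self.atp, nadh=self.nadh, nadph=self.nadph)
        for k, v in sorted(self.other.items()):
            data[k] = v
        return pd.Series(data, name=self.target)


def _cost_of_lump(
    lr: LumpedReaction,
    precursors: Sequence[str],
    carriers: Mapping[str, Mapping[str, float]],
    inorganics: Iterable[str],
) -> CostVector:
    base = dict(lr.base_stoich)
    target_base = lr.target_base or lr.target
    if lr.core_supplied:
        # the target is drawn straight from the core: one mole of itself
        return CostVector(target=lr.target,
                          precursor_moles={target_base: 1.0})
    if base.get(target_base, 0.0) < 0.5:
        # transport-only lump: compartment copies cancel. The building block
        # is supplied by the environment (auxotrophy); its cost is one mole
        # of the medium species, no precursors or carriers.
        return CostVector(target=lr.target, other={target_base: 1.0})
    carrier_species = {s for spec in carriers.values() for s in spec}
    carrier_partners = set()
    for spec in carriers.values():
        carrier_partners |= set(spec)
    # paired oxidized/reduced and nucleotide forms never show up in `other`
    paired = carrier_partners | {"atp", "adp", "amp", "nad", "nadp", "pi", "ppi"}
    cost = CostVector(target=lr.target)
    for p in precursors:
        consumed = -base.get(p, 0.0)
        cost.precursor_moles[p] = consumed if consumed > 1e-9 else 0.0
    totals = {}
    for name, spec in carriers.items():
        totals[name] = sum(w * base.get(s, 0.0) for s, w in spec.items())
    cost.atp = totals.get("atp", 0.0)
    cost.nadh = totals.get("nadh", 0.0)
    cost.nadph = totals.get("nadph", 0.0)
    skip = set(precursors) | paired | set(inorganics) | {target_base}
    for b, c in base.items():
        if b in skip or c >= -1e-9:
            continue
        cost.other[b] = -c
    return cost


def biosynthetic_cost(
    lumps: Sequence[LumpedReaction],
    precursors: Sequence[str] = DEFAULT_PRECURSORS,
    carriers: Mapping[str, Mapping[str, float]] = DEFAULT_CARRIERS,
    inorganics: Iterable[str] = (),
    allowed_species: Iterable[str] | None = None,
) -> CostVector:
    """Average cost vector across (unique) lumped reactions of one target.

    Consumption is positive; carriers are net and signed (negative =
    produced). Non-precursor, non-carrier consumed species (medium species
    an auxotroph depends on) land in ``other``. When ``allowed_species``
    is given (core + medium base ids), a lump consuming anything outside it
    raises, flagging incomplete lumping upstream.
    """
    lumps = list(lumps)
    if not lumps:
        raise ValueError("biosynthetic_cost needs >= 1 lump")
    targets = {lr.target for lr in lumps}
    if len(targets) > 1:
        raise ValueError(f"lumps span several targets: {sorted(targets)}")
    if allowed_species is not None:
        allowed = set(allowed_species) | set(precursors)
        for spec in carriers.values():
            allowed |= set(spec)
        for lr in lumps:
            stray = {
                b for b, c in lr.base_stoich.items()
                if c < -1e-9 and b not in allowed
            }
            if stray:
                raise ValueError(
                    f"lump for {lr.target} consumes species outside "
                    f"core/medium: {sorted(stray)} (incomplete lumping?)"
                )
    per = [_cost_of_lump(lr, precursors, carriers, inorganics) for lr in lumps]
    n = len(per)
    mean = CostVector(target=per[0].target, n_lumps=n)
    for p in precursors:
        mean.precursor_moles[p] = sum(c.precursor_moles.get(p, 0.0) for c in per) / n
    mean.atp = sum(c.atp for c in per) / n
    mean.nadh = sum(c.nadh for c in per) / n
    mean.nadph = sum(c.nadph for c in per) / n
    others = {k for c in per for k in c.other}
    for k in sorted(others):
        mean.other[k] = sum(c.other.get(k, 0.0) for c in per) / n
    return mean
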
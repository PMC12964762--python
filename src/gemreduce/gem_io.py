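"""Read, harmonize and interrogate genome-scale metabolic models.

Models are held as :class:`cobra.Model` objects; this module adds the
operations the reduction workflow needs on top of cobrapy: compartment
stripping to a shared base-identifier namespace, biomass building-block
(BBB) identification, in-silico minimal-media analysis by mixed-integer
optimization, and media algebra.

Sign conventions
----------------
Uptake through an exchange reaction is a negative flux; all user-facing
medium bounds are magnitudes (``Medium.uptakes`` maps exchange-reaction id
to a maximal uptake rate in mmol·gDW⁻¹·h⁻¹, always >= 0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import cobra

logger = logging.getLogger("gemreduce")

#: numerical tolerance for "a flux is non-zero"
FLUX_TOL = 1e-6

DEFAULT_UPTAKE_BOUND = 10.0


class GEMError(Exception):
    """Base class for model-level errors."""


class GEMParseError(GEMError):
    """A model file could not be parsed; the message names the offending element."""


class NoGrowthError(GEMError):
    """The model cannot reach the growth threshold even with all candidate uptakes open."""


@dataclass(frozen=True)
class Medium:
    """An extracellular environment: maximal uptake magnitudes per exchange reaction."""

    uptakes: Mapping[str, float] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self):
        bad = {e: b for e, b in self.uptakes.items() if b < 0}
        if bad:
            raise ValueError(f"medium bounds must be magnitudes >= 0, got {bad}")

    def __eq__(self, other):
        if not isinstance(other, Medium):
            return NotImplemented
        return dict(self.uptakes) == dict(other.uptakes)

    def __hash__(self):
        return hash(frozenset(self.uptakes.items()))


# ---------------------------------------------------------------------------
# reading


def read_gem(path: str | Path, dialect: str | None = None) -> cobra.Model:
    """Read a GEM from SBML (Level 3 + FBC) or BiGG-style JSON.

    The dialect is inferred from the file extension when not given
    (``.xml``/``.sbml`` -> sbml, ``.json`` -> json). Subsystem annotations
    are preserved verbatim (cobrapy keeps them on ``Reaction.subsystem``,
    including multi-subsystem strings). The detected biomass reaction id is
    attached to the returned model as ``model.biomass_reaction_id`` (None,
    with a warning, when no biomass reaction is found).
    """
    path = Path(path)
    if dialect is None:
        suffix = path.suffix.lower()
        if suffix in (".xml", ".sbml"):
            dialect = "sbml"
        elif suffix == ".json":
            dialect = "json"
        else:
            raise GEMParseError(f"cannot infer dialect from extension {suffix!r}")
    if dialect not in ("sbml", "json"):
        raise GEMParseError(f"unknown dialect {dialect!r}")
    try:
        if dialect == "sbml":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = cobra.io.read_sbml_model(str(path))
        else:
            model = cobra.io.load_json_model(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise GEMParseError(f"failed to parse {path.name} as {dialect}: {exc}") from exc
    _validate(model, path.name)
    model.biomass_reaction_id = find_biomass(model)
    if model.biomass_reaction_id is None:
        warnings.warn(f"no biomass reaction detected in {path.name}", stacklevel=2)
    return model


def _validate(model: cobra.Model, name: str) -> None:
    for rxn in model.reactions:
        if len(rxn.metabolites) == 0:
            raise GEMParseError(f"{name}: reaction {rxn.id!r} has empty stoichiometry")
        for met in rxn.metabolites:
            if met.id not in model.metabolites:
                raise GEMParseError(
                    f"{name}: reaction {rxn.id!r} references undeclared metabolite {met.id!r}"
                )


def find_biomass(model: cobra.Model) -> str | None:
    """Return the biomass reaction id: the linear objective if set, else by name."""
    try:
        objective = cobra.util.solver.linear_reaction_coefficients(model)
    except Exception:  # pragma: no cover - defensive, optlang quirk on empty models
        objective = {}
    for rxn in objective:
        if objective[rxn] > 0:
            return rxn.id
    for rxn in model.reactions:
        text = (rxn.id + " " + (rxn.name or "")).lower()
        if "biomass" in text:
            return rxn.id
    return None


def biomass_reaction_id(model: cobra.Model) -> str | None:
    """Biomass reaction id of a model, whether or not it went through read_gem."""
    return getattr(model, "biomass_reaction_id", None) or find_biomass(model)


# ---------------------------------------------------------------------------
# identifiers and compartments


def base_id(met: cobra.Metabolite) -> str:
    """Identifier of a metabolite with its compartment tag removed.

    The tag is resolved from the metabolite's declared ``compartment``
    attribute (``atp_c`` -> ``atp``, ``atp[c]`` -> ``atp``); identifiers
    without a matching declared tag pass through unchanged.
    """
    comp = met.compartment
    if comp:
        for pattern in (f"_{comp}", f"[{comp}]", f"({comp})"):
            if met.id.endswith(pattern):
                return met.id[: -len(pattern)]
    return met.id


def strip_compartment(x, model: cobra.Model | None = None):
    """Strip compartment tags from a metabolite or a set of metabolite ids.

    For a single :class:`cobra.Metabolite` the base id is returned; for an
    iterable of metabolite ids a ``model`` is required to resolve declared
    compartments and a set of base ids is returned. Idempotent; never
    increases cardinality.
    """
    if isinstance(x, cobra.Metabolite):
        return base_id(x)
    if isinstance(x, str):
        if model is not None and x in model.metabolites:
            return base_id(model.metabolites.get_by_id(x))
        return x
    return {strip_compartment(i, model) for i in x}


def harmonize(ids: Iterable[str], mapping: Mapping[str, str]) -> set[str]:
    """Map base identifiers into a common namespace via a user-supplied lookup table."""
    return {mapping.get(i, i) for i in ids}


# ---------------------------------------------------------------------------
# exchanges and media


def exchange_reactions(model: cobra.Model) -> list[cobra.Reaction]:
    """Boundary exchange reactions: single-metabolite reactions crossing the model boundary.

    Both the BiGG ``EX_`` prefix and cobrapy's boundary detection (SBML
    boundaryCondition / outermost compartment) are honoured.
    """
    found = {r.id: r for r in model.exchanges}
    for rxn in model.reactions:
        if rxn.id.startswith("EX_") and len(rxn.metabolites) == 1:
            found[rxn.id] = rxn
    return [found[i] for i in sorted(found)]


def is_exchange(rxn: cobra.Reaction) -> bool:
    if len(rxn.metabolites) != 1:
        return False
    return rxn.id.startswith("EX_") or rxn.boundary


def apply_medium(model: cobra.Model, medium: Medium) -> None:
    """Constrain the model's exchange uptakes to a medium, in place.

    All exchange uptake bounds are closed, then each medium entry is opened
    at ``lower_bound = -magnitude``. Secretion bounds are left untouched.
    """
    for rxn in exchange_reactions(model):
        if rxn.id in medium.uptakes:
            rxn.lower_bound = -abs(medium.uptakes[rxn.id])
        else:
            rxn.lower_bound = 0.0


def union_media(media: Iterable[Medium], label: str = "union") -> Medium:
    """Union of media: union of uptakes, per-exchange bound the maximum across inputs."""
    uptakes: dict[str, float] = {}
    for m in media:
        for ex, bound in m.uptakes.items():
            uptakes[ex] = max(uptakes.get(ex, 0.0), bound)
    return Medium(uptakes=uptakes, label=label)


# ---------------------------------------------------------------------------
# biomass building blocks


def identify_bbbs(
    model: cobra.Model, inorganics: Iterable[str] = ()
) -> dict[str, bool]:
    """Biomass building blocks: species consumed by the biomass reaction.

    Returns a mapping metabolite-id -> inorganic flag (True when the
    compartment-stripped id is in the configured inorganic list). Species on
    the produced side of the biomass reaction (e.g. ADP, Pi) are never
    counted.
    """
    bid = biomass_reaction_id(model)
    if bid is None:
        raise GEMError("model has no biomass reaction; cannot identify BBBs")
    biomass = model.reactions.get_by_id(bid)
    inorganic_set = set(inorganics)
    return {
        met.id: base_id(met) in inorganic_set
        for met, coef in biomass.metabolites.items()
        if coef < 0
    }


def shared_bbbs(
    g1: cobra.Model, g2: cobra.Model, inorganics: Iterable[str] = ()
) -> tuple[set[str], set[str]]:
    """Intersection of the two models' BBB sets on base identifiers.

    Returns ``(shared, inorganic_shared)``; both models must already be
    harmonized to a common namespace.
    """
    b1 = {strip_compartment(m, g1) for m in identify_bbbs(g1, inorganics)}
    b2 = {strip_compartment(m, g2) for m in identify_bbbs(g2, inorganics)}
    shared = b1 & b2
    inorganic_shared = shared & set(inorganics)
    return shared, inorganic_shared


# ---------------------------------------------------------------------------
# minimal media


def minimal_media(
    model: cobra.Model,
    candidates: Iterable[str],
    growth_fraction: float = 0.1,
    max_alternatives: int = 16,
    uptake_bound: float = DEFAULT_UPTAKE_BOUND,
) -> list[Medium]:
    """Enumerate minimal-cardinality media supporting growth.

    A binary indicator gates the uptake of each candidate exchange; the MILP
    minimizes the number of open uptakes subject to biomass flux >=
    ``growth_fraction`` x the maximal biomass flux with all candidates open.
    Alternative minima of the same cardinality are enumerated with integer
    cuts, up to ``max_alternatives``.
    """
    candidates = sorted(set(candidates))
    bid = biomass_reaction_id(model)
    if bid is None:
        raise GEMError("model has no biomass reaction; cannot run minimal media")
    media: list[Medium] = []
    # work on a copy: the indicator variables and cuts added below live in
    # the solver object and would leak into the caller's model otherwise
    m = model.copy()
    biomass = m.reactions.get_by_id(bid)
    for rxn in exchange_reactions(m):
        # only candidate uptakes are open; everything else secretion-only
        rxn.lower_bound = -abs(uptake_bound) if rxn.id in candidates else 0.0
    m.objective = bid
    vmax = m.slim_optimize(error_value=0.0)
    if vmax is None or vmax <= FLUX_TOL:
        raise NoGrowthError(
            "no growth even with all candidate uptakes open "
            f"(max biomass {vmax})"
        )
    threshold = growth_fraction * vmax
    interface = m.problem
    indicators = {}
    to_add = []
    for ex in candidates:
        rxn = m.reactions.get_by_id(ex)
        u = interface.Variable(f"medium_use_{ex}", type="binary")
        # uptake only when the indicator is on: v_ex >= -bound * u
        gate = interface.Constraint(
            rxn.flux_expression + abs(uptake_bound) * u,
            lb=0.0,
            name=f"medium_gate_{ex}",
        )
        indicators[ex] = u
        to_add.extend([u, gate])
    growth = interface.Constraint(
        biomass.flux_expression, lb=threshold, name="medium_growth"
    )
    to_add.append(growth)
    m.solver.add(to_add)
    m.objective = interface.Objective(
        sum(indicators.values()), direction="min"
    )
    best: int | None = None
    while len(media) < max_alternatives:
        m.solver.optimize()
        if m.solver.status != "optimal":
            break
        size = round(m.objective.value)
        if best is None:
            best = size
        if size > best:
            break
        selected = sorted(
            ex for ex, u in indicators.items() if u.primal > 0.5
        )
        media.append(
            Medium(
                uptakes={ex: abs(uptake_bound) for ex in selected},
                label=f"minimal_{len(media)}",
            )
        )
        if not selected:
            break  # the empty medium has no proper alternatives
        cut = interface.Constraint(
            sum(indicators[ex] for ex in selected),
            ub=len(selected) - 1,
            name=f"medium_cut_{len(media)}",
        )
        m.solver.add(cut)
    logger.info(
        "minimal_media: %d alternative minima of size %s (growth_fraction=%g)",
        len(media), best, growth_fraction,
    )
    return media


def supports_growth(
    model: cobra.Model,
    medium: Medium,
    growth_threshold: float,
) -> bool:
    """Flux-balance check that a medium supports biomass above a threshold."""
    bid = biomass_reaction_id(model)
    with model as m:
        apply_medium(m, medium)
        m.objective = bid
        vmax = m.slim_optimize(error_value=0.0)
    return vmax is not None and vmax >= growth_threshold - FLUX_TOL
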
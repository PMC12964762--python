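"""Drive the reduction workflow end to end from a YAML run configuration.

Every stage writes plain-text tables prefixed with a provenance header that
records the exact parameters and solver used, so a rerun with the same
configuration reproduces the files bit for bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import cobra
import optlang
import pandas as pd
import yaml

from gemreduce import compare as cmp
from gemreduce.core import build_d0, expand_to_degree, pairwise_distances
from gemreduce.exchange import (
    connect_extracellular,
    exchange_capability_matrix,
    substrate_fate,
)
from gemreduce.gem_io import Medium, identify_bbbs, read_gem, strip_compartment
from gemreduce.subnetworks import enumerate_min_subnetworks, lump, unique_lumps
from gemreduce.subsystems import ExclusionConfig, load_subsystems

logger = logging.getLogger("gemreduce")


def _data_path(name: str):
    return resources.files("gemreduce.data").joinpath(name)


def default_subsystems():
    with resources.as_file(_data_path("subsystems_bigg.yaml")) as p:
        return load_subsystems(p)


def default_exclusions() -> ExclusionConfig:
    with resources.as_file(_data_path("exclusions_bigg.yaml")) as p:
        return ExclusionConfig.from_yaml(p)


def default_precursor_config() -> dict:
    with resources.as_file(_data_path("precursors_bigg.yaml")) as p:
        with open(p) as fh:
            return yaml.safe_load(fh)


@dataclass
class RunConfig:
    """Validated run configuration; mirrors the YAML file."""

    models: dict[str, str]
    out_dir: str = "gemreduce_out"
    subsystems: str | None = None       # path; None = shipped BiGG defaults
    exclusions: str | None = None
    media: dict[str, object] = field(default_factory=dict)  # label -> path or dict
    D: int = 2
    d_max: int = 3
    k_relax: int = 0
    cap: int = 5000
    growth_fraction: float = 0.1
    lump_tol: float = 1e-6
    substrate_pool: list[str] = field(default_factory=list)
    categories: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        missing = [p for p in cfg.models.values() if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"model files not found: {missing}")
        if cfg.D < 0 or cfg.d_max < 1 or cfg.k_relax < 0 or cfg.cap < 1:
            raise ValueError("D >= 0, d_max >= 1, k_relax >= 0, cap >= 1 required")
        if not (0 < cfg.growth_fraction <= 1):
            raise ValueError("growth_fraction must be in (0, 1]")
        return cfg

    def load_models(self) -> dict[str, cobra.Model]:
        return {label: read_gem(path) for label, path in sorted(self.models.items())}

    def load_subsystems(self):
        if self.subsystems:
            return load_subsystems(self.subsystems)
        return default_subsystems()

    def load_exclusions(self) -> ExclusionConfig:
        if self.exclusions:
            return ExclusionConfig.from_yaml(self.exclusions)
        return default_exclusions()

    def load_medium(self, label: str) -> Medium:
        entry = self.media.get(label, {})
        if isinstance(entry, Mapping):
            return Medium(uptakes=dict(entry), label=label)
        table = pd.read_csv(entry, sep="\t", comment="#",
                            names=["exchange_id", "max_uptake"], header=None)
        return Medium(
            uptakes=dict(zip(table.exchange_id, table.max_uptake.astype(float))),
            label=label,
        )


def provenance_header(cfg: RunConfig, stage: str) -> str:
    solver = f"optlang-{optlang.__version__}/glpk"
    lines = [
        f"# stage: {stage}",
        f"# solver: {solver}",
        f"# D: {cfg.D}", f"# d_max: {cfg.d_max}", f"# k_relax: {cfg.k_relax}",
        f"# cap: {cfg.cap}", f"# growth_fraction: {cfg.growth_fraction}",
        f"# lump_tol: {cfg.lump_tol}", f"# seed: {cfg.seed}",
    ]
    return "\n".join(lines) + "\n"


def _write_table(df: pd.DataFrame, path: Path, header: str,
                 index_label: str | None = None) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t", index=index_label is not None,
                  index_label=index_label)


def _degree_added(provenance: tuple) -> int:
    degrees = []
    for rec in provenance:
        if rec[0] in ("subsystem", "enrichment"):
            degrees.append(0)
        elif rec[0] == "path":
            degrees.append(rec[2])
    return min(degrees) if degrees else 0


def run_core(cfg: RunConfig) -> dict:
    """Core extraction stage: D0 + degree-D cores, pair distances, comparisons."""
    out = Path(cfg.out_dir)
    header = provenance_header(cfg, "core")
    defs = cfg.load_subsystems()
    x = cfg.load_exclusions()
    models = cfg.load_models()
    cores, d0s = {}, {}
    for label, g in models.items():
        d0 = build_d0(g, defs, x)
        core = expand_to_degree(g, d0, cfg.D, x)
        d0s[label], cores[label] = d0, core
        rows = [
            {
                "reaction_id": rid,
                "degree_added": _degree_added(core.provenance[rid]),
                "provenance": ";".join(
                    ":".join(str(v) for v in rec) for rec in core.provenance[rid]
                ),
            }
            for rid in sorted(core.reactions)
        ]
        _write_table(pd.DataFrame(rows), out / f"core_{label}.tsv", header)
        dist = pairwise_distances(g, d0, x, cfg.d_max)
        drows = [
            {
                "subsystem_pair": "|".join(sorted(d.subsystem_pair)),
                "min_distance": d.min_distance if d.connected else "unconnected",
                "n_min_paths": d.n_min_paths,
                "d_max": d.d_max,
            }
            for d in dist
        ]
        _write_table(pd.DataFrame(drows), out / f"distances_{label}.tsv", header)
    if len(cores) >= 2:
        for level, comp in (("reaction", "kept"), ("metabolite", "kept"),
                            ("metabolite", "stripped")):
            sim = cmp.compare_networks(sorted(cores.items()), level=level,
                                       compartments=comp)
            _write_table(sim.values, out / f"core_similarity_{level}_{comp}.tsv",
                         header, index_label="label")
    return {"cores": cores, "d0": d0s, "defs": defs, "exclusions": x,
            "models": models}


def run_lump(cfg: RunConfig, core_state: dict | None = None) -> dict:
    """BBB subnetworks, lumped reactions and cost vectors per organism."""
    out = Path(cfg.out_dir)
    header = provenance_header(cfg, "lump")
    state = core_state or run_core(cfg)
    x = state["exclusions"]
    pconf = default_precursor_config()
    precursors = pconf["precursors"]
    carriers = pconf["carriers"]
    per_org: dict[str, dict] = {}
    for label, g in state["models"].items():
        medium = cfg.load_medium(label)
        d0 = state["d0"][label]
        bbbs = identify_bbbs(g, x.inorganics)
        subnet_rows, lump_rows, cost_rows = [], [], []
        per_target = {}
        for target in sorted(bbbs):
            result = enumerate_min_subnetworks(
                g, d0, target, medium, k_relax=cfg.k_relax, cap=cfg.cap
            )
            per_target[strip_compartment(target, g)] = result
            for i, sn in enumerate(result):
                for rid in sorted(sn.active_reactions):
                    subnet_rows.append({
                        "target": target, "subnetwork_index": i,
                        "reaction_id": rid,
                        "flux": round(sn.fluxes.get(rid, 0.0), 9),
                    })
            lumps = [lump(sn, g) for sn in result]
            uniq = unique_lumps(lumps, tol=cfg.lump_tol)
            for lr in uniq:
                lump_rows.append({
                    "target": target,
                    "equation": lr.equation(),
                    "n_subnetworks": len(lr.source_subnetworks),
                    "truncated": result.truncated,
                })
            if uniq:
                cost = cmp.biosynthetic_cost(
                    uniq, precursors=precursors, carriers=carriers,
                    inorganics=x.inorganics,
                )
                row = {"target": target, "n_lumps": cost.n_lumps}
                row.update(cost.as_series(precursors).to_dict())
                cost_rows.append(row)
        per_org[label] = per_target
        _write_table(pd.DataFrame(subnet_rows), out / f"subnetworks_{label}.tsv",
                     header)
        _write_table(pd.DataFrame(lump_rows), out / f"lumps_{label}.tsv", header)
        _write_table(pd.DataFrame(cost_rows), out / f"costs_{label}.tsv", header)
    state["bbb_subnetworks"] = per_org
    return state


def run_connect(cfg: RunConfig, core_state: dict | None = None) -> dict:
    """Extracellular connection stage: substrate subnetworks, fates, capability."""
    out = Path(cfg.out_dir)
    header = provenance_header(cfg, "connect")
    state = core_state or run_core(cfg)
    x = state["exclusions"]
    pool = cfg.substrate_pool or default_precursor_config()["substrate_pool"]
    media = {label: cfg.load_medium(label) for label in state["models"]}
    fates = {}
    for label, g in state["models"].items():
        d0 = state["d0"][label]
        for substrate in pool:
            result = connect_extracellular(
                g, d0, substrate, media[label], k_relax=cfg.k_relax, cap=cfg.cap
            )
            if result.subnetworks:
                fate = substrate_fate(result, g, medium_inorganics=x.inorganics)
                fates[(label, substrate)] = {
                    "co_substrates": sorted(fate.co_substrates),
                    "byproducts": sorted(fate.byproducts),
                    "n_subnetworks": len(result),
                }
            else:
                fates[(label, substrate)] = {"diagnostic": result.diagnostic}
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "substrate_fates.json", "w") as fh:
        json.dump(
            {f"{label}::{sub}": v for (label, sub), v in sorted(fates.items())},
            fh, indent=2, sort_keys=True,
        )
    gems = [
        (label, g, state["d0"][label])
        for label, g in sorted(state["models"].items())
    ]
    shared = Medium(
        uptakes={
            e: b for m in media.values() for e, b in m.uptakes.items()
        },
        label="shared",
    )
    matrix = exchange_capability_matrix(gems, pool, shared,
                                        k_relax=cfg.k_relax, cap=50)
    _write_table(matrix, out / "capability_matrix.tsv", header,
                 index_label="organism")
    state["fates"] = fates
    return state


def run_compare(cfg: RunConfig, state: dict | None = None) -> dict:
    """Cross-organism comparison of BBB subnetwork unions, with categories."""
    out = Path(cfg.out_dir)
    header = provenance_header(cfg, "compare")
    state = state or run_lump(cfg)
    if "bbb_subnetworks" not in state:
        state = run_lump(cfg, state)
    per_bbb = cmp.compare_subnetwork_unions(state["bbb_subnetworks"])
    rows = []
    for bbb, sim in sorted(per_bbb.items()):
        labels = sim.labels
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                rows.append({"bbb": bbb, "pair": f"{a}|{b}",
                             "jaccard": sim.values.loc[a, b]})
    _write_table(pd.DataFrame(rows), out / "bbb_similarity.tsv", header)
    if cfg.categories:
        cats = cmp.category_average(
            {b: s for b, s in per_bbb.items() if b in cfg.categories},
            cfg.categories,
        )
        for name, frame in sorted(cats.items()):
            _write_table(frame, out / f"category_{name}.tsv", header,
                         index_label="label")
    state["bbb_similarity"] = per_bbb
    return state


def run_all(cfg: RunConfig) -> dict:
    state = run_core(cfg)
    state = run_lump(cfg, state)
    state = run_connect(cfg, state)
    state = run_compare(cfg, state)
    return state
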
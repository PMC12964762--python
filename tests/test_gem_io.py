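"""Model reading, compartment stripping, BBB identification, media algebra."""

import itertools

import cobra
import pytest

import gemreduce as gr
from gemreduce.fixtures import write_toy
from gemreduce.gem_io import (
    GEMError,
    GEMParseError,
    NoGrowthError,
    exchange_reactions,
    supports_growth,
)


@pytest.fixture(scope="module", params=["sbml", "json"])
def roundtripped(request, tmp_path_factory, default_toy):
    paths = write_toy(default_toy.model, tmp_path_factory.mktemp("models"))
    return gr.read_gem(paths[request.param])


class TestReadGem:
    def test_reaction_count_preserved(self, roundtripped, default_toy):
        assert len(roundtripped.reactions) == len(default_toy.model.reactions)
        assert len(roundtripped.metabolites) == len(default_toy.model.metabolites)

    def test_biomass_detected(self, roundtripped):
        assert roundtripped.biomass_reaction_id == "BIOMASS"

    def test_bounds_and_formulas_survive(self, roundtripped, default_toy):
        for rxn in default_toy.model.reactions:
            assert roundtripped.reactions.get_by_id(rxn.id).bounds == rxn.bounds
        assert roundtripped.metabolites.get_by_id("atp_c").formula == "C10H16N5O13P3"

    def test_undeclared_metabolite_is_a_parse_error(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text(
            '{"metabolites": [], "reactions": '
            '[{"id": "R1", "metabolites": {"ghost_c": -1}}]}'
        )
        with pytest.raises(GEMParseError):
            gr.read_gem(bad)

    def test_unknown_extension_rejected(self, tmp_path):
        f = tmp_path / "model.txt"
        f.write_text("")
        with pytest.raises(GEMParseError):
            gr.read_gem(f)


class TestStripCompartment:
    def test_collapses_compartment_copies(self):
        m = cobra.Model("t")
        ids = []
        for base, comps in [("atp", "cme"), ("adp", "cm"), ("pyr", "cmp"),
                            ("glc", "ce"), ("h2o", "cme"), ("nad", "c"),
                            ("nadh", "c")]:
            for comp in comps:
                met = cobra.Metabolite(f"{base}_{comp}", compartment=comp)
                m.add_metabolites([met])
                ids.append(met.id)
        # 15 compartmented species over 7 base species
        assert len(ids) == 15
        stripped = gr.strip_compartment(ids, m)
        assert stripped == {"atp", "adp", "pyr", "glc", "h2o", "nad", "nadh"}

    def test_idempotent_and_never_growing(self, default_toy):
        ids = {m.id for m in default_toy.model.metabolites}
        once = gr.strip_compartment(ids, default_toy.model)
        assert len(once) <= len(ids)
        assert gr.strip_compartment(once, default_toy.model) == once

    def test_single_compartment_size_unchanged(self):
        m = cobra.Model("t")
        m.add_metabolites([
            cobra.Metabolite(f"x{i}_c", compartment="c") for i in range(5)
        ])
        assert len(gr.strip_compartment({x.id for x in m.metabolites}, m)) == 5

    def test_untagged_identifier_passes_through(self):
        met = cobra.Metabolite("weird-id", compartment="c")
        assert gr.base_id(met) == "weird-id"


class TestBBBs:
    def test_consumed_side_only(self):
        m = cobra.Model("t")
        ala = cobra.Metabolite("ala_c", compartment="c")
        atp = cobra.Metabolite("atp_c", compartment="c")
        h2o = cobra.Metabolite("h2o_c", compartment="c")
        adp = cobra.Metabolite("adp_c", compartment="c")
        pi = cobra.Metabolite("pi_c", compartment="c")
        bm = cobra.Reaction("BIOMASS_x")
        bm.add_metabolites({ala: -2, atp: -1, h2o: -1, adp: 1, pi: 1})
        m.add_reactions([bm])
        m.objective = "BIOMASS_x"
        bbbs = gr.identify_bbbs(m, inorganics={"h2o", "pi"})
        assert set(bbbs) == {"ala_c", "atp_c", "h2o_c"}
        assert bbbs["h2o_c"] is True and bbbs["ala_c"] is False

    def test_toy_bbbs_match_truth(self, default_toy):
        bbbs = gr.identify_bbbs(default_toy.model, default_toy.exclusions.inorganics)
        assert set(bbbs) == default_toy.truth.bbbs

    def test_no_biomass_is_an_error(self):
        m = cobra.Model("empty")
        with pytest.raises(GEMError):
            gr.identify_bbbs(m)

    def test_shared_bbbs_identity_and_disjoint(self, default_toy, rich_toy):
        g = default_toy.model
        shared, inorg = gr.shared_bbbs(g, g, default_toy.exclusions.inorganics)
        assert shared == gr.strip_compartment(default_toy.truth.bbbs, g)
        assert inorg == set()
        # rich toy's vit BBB is absent from the default toy
        shared2, _ = gr.shared_bbbs(default_toy.model, rich_toy.model)
        assert "vit" not in shared2


class TestMedia:
    def test_union_media_max_bound_and_idempotence(self):
        a = gr.Medium({"EX_a": 5.0, "EX_b": 1.0}, label="a")
        b = gr.Medium({"EX_b": 3.0, "EX_c": 2.0}, label="b")
        u = gr.union_media([a, b])
        assert u.uptakes == {"EX_a": 5.0, "EX_b": 3.0, "EX_c": 2.0}
        assert gr.union_media([a, a]) == a

    def test_negative_bound_rejected(self):
        with pytest.raises(ValueError):
            gr.Medium({"EX_a": -1.0})


def _exhaustive_minimal_media(model, candidates, growth_fraction):
    """Independent subset-search oracle for minimal media (<= 8 candidates)."""
    assert len(candidates) <= 8
    with model as m:
        for r in exchange_reactions(m):
            r.lower_bound = -10.0 if r.id in candidates else min(r.lower_bound, 0)
        m.objective = "BIOMASS"
        vmax = m.slim_optimize(error_value=0.0)
    threshold = growth_fraction * vmax
    feasible = []
    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(sorted(candidates), size):
            if any(set(f) <= set(combo) for f in feasible):
                continue
            medium = gr.Medium({e: 10.0 for e in combo})
            if supports_growth(model, medium, threshold):
                feasible.append(combo)
        if feasible:
            break
    return {frozenset(f) for f in feasible}


class TestMinimalMedia:
    def test_matches_exhaustive_search(self, rich_toy):
        truth = rich_toy.truth
        found = gr.minimal_media(rich_toy.model, truth.medium_candidates)
        found_sets = {frozenset(m.uptakes) for m in found}
        oracle = _exhaustive_minimal_media(
            rich_toy.model, truth.medium_candidates, 0.1
        )
        assert found_sets == oracle
        assert found_sets == set(truth.minimal_media)

    def test_alternative_carbon_sources_enumerated(self, rich_toy):
        found = gr.minimal_media(rich_toy.model, rich_toy.truth.medium_candidates)
        carbons = {
            next(iter({"EX_glc_e", "EX_fru_e"} & set(m.uptakes))) for m in found
        }
        assert carbons == {"EX_glc_e", "EX_fru_e"}
        assert len({len(m.uptakes) for m in found}) == 1  # equal cardinality

    def test_each_medium_minimal_by_single_removal(self, default_toy):
        model = default_toy.model
        candidates = default_toy.truth.medium_candidates
        with model as m:
            for r in exchange_reactions(m):
                r.lower_bound = -10.0 if r.id in candidates else 0.0
            m.objective = "BIOMASS"
            vmax = m.slim_optimize()
        threshold = 0.1 * vmax
        for medium in gr.minimal_media(model, candidates):
            assert supports_growth(model, medium, threshold)
            for ex in medium.uptakes:
                sub = gr.Medium({e: b for e, b in medium.uptakes.items() if e != ex})
                assert not supports_growth(model, sub, threshold)

    def test_growth_without_uptakes_gives_empty_medium(self):
        m = cobra.Model("auto")
        a = cobra.Metabolite("a_c", compartment="c")
        src = cobra.Reaction("SRC")
        src.add_metabolites({a: 1})
        src.bounds = (0, 10)
        bm = cobra.Reaction("BIOMASS_auto")
        bm.add_metabolites({a: -1})
        bm.bounds = (0, 10)
        ex = cobra.Reaction("EX_b_e")
        b = cobra.Metabolite("b_e", compartment="e")
        ex.add_metabolites({b: -1})
        m.add_reactions([src, bm, ex])
        m.objective = "BIOMASS_auto"
        media = gr.minimal_media(m, ["EX_b_e"])
        assert len(media) == 1 and media[0].uptakes == {}

    def test_no_growth_raises(self, default_toy):
        with pytest.raises(NoGrowthError):
            gr.minimal_media(default_toy.model, ["EX_h2o_e"])
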
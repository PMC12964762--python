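"""Jaccard similarity, subnetwork-union comparison, category averages, costs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gemreduce as gr
from gemreduce.compare import DEFAULT_PRECURSORS
from gemreduce.subnetworks import LumpedReaction, Subnetwork, SubnetworkSet

sets = st.frozensets(st.integers(min_value=0, max_value=30), max_size=12)


class TestJaccard:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({1, 2, 3}, {1, 2, 3}, 1.0),
            ({1, 2}, {3, 4}, 0.0),
            ({1, 2, 3}, {2, 3, 4}, 0.5),  # |intersection| 2, |union| 4
            (set(), {1}, 0.0),
            (set(), set(), 1.0),  # convention, logged
        ],
    )
    def test_examples(self, a, b, expected):
        assert gr.jaccard(a, b) == pytest.approx(expected)

    @settings(max_examples=200, derandomize=True)
    @given(a=sets, b=sets)
    def test_axioms(self, a, b):
        j = gr.jaccard(a, b)
        assert 0.0 <= j <= 1.0
        assert j == gr.jaccard(b, a)
        assert gr.jaccard(a, a) == 1.0
        if a | b:
            assert j == pytest.approx(len(a & b) / len(a | b))

    @settings(max_examples=100, derandomize=True)
    @given(a=sets, b=sets, extra=st.integers(min_value=31, max_value=40))
    def test_monotone_under_intersection_growth_at_fixed_union(self, a, b, extra):
        # moving one element of the symmetric difference into both sets
        # keeps the union and cannot decrease similarity
        sym = sorted((a | b) - (a & b))
        if not sym:
            return
        x = sym[0]
        assert gr.jaccard(a | {x}, b | {x}) >= gr.jaccard(a, b)


class TestCompareNetworks:
    def test_engineered_overlap(self):
        a = {f"r{i}" for i in range(6)}
        b = {f"r{i}" for i in range(3)} | {"s1", "s2", "s3"}
        sim = gr.compare_networks([("a", a), ("b", b)])
        assert sim[("a", "b")] == pytest.approx(3 / 9)

    def test_stripping_separates_compartment_effects(self):
        # same chemistry, different localization: identical when stripped,
        # different when compartments are kept
        kept_a = {"fum_c", "mal_c", "oaa_c"}
        kept_b = {"fum_m", "mal_m", "oaa_m"}
        sim_kept = gr.compare_networks(
            [("a", kept_a), ("b", kept_b)], level="metabolite"
        )
        stripped = gr.compare_networks(
            [("a", {"fum", "mal", "oaa"}), ("b", {"fum", "mal", "oaa"})],
            level="metabolite", compartments="stripped",
        )
        assert sim_kept[("a", "b")] == 0.0
        assert stripped[("a", "b")] == 1.0

    def test_symmetric_with_unit_diagonal(self, default_d0, rich_d0):
        sim = gr.compare_networks([("a", default_d0), ("b", rich_d0)])
        v = sim.values.to_numpy()
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)

    def test_needs_two_networks(self, default_d0):
        with pytest.raises(ValueError):
            gr.compare_networks([("a", default_d0)])


def _subnets(target, *reaction_sets):
    return SubnetworkSet(
        target=target,
        subnetworks=[
            Subnetwork(target=target, active_reactions=frozenset(s))
            for s in reaction_sets
        ],
    )


class TestSubnetworkUnions:
    def test_identical_organisms_all_one(self):
        per = {
            "orgA": {"ser": _subnets("ser", {"r1", "r2"})},
            "orgB": {"ser": _subnets("ser", {"r1", "r2"})},
        }
        sim = gr.compare_subnetwork_unions(per)
        assert sim["ser"][("orgA", "orgB")] == 1.0

    def test_disjoint_routes_zero(self):
        per = {
            "orgA": {"ser": _subnets("ser", {"r1", "r2"})},
            "orgB": {"ser": _subnets("ser", {"q1", "q2"})},
        }
        assert gr.compare_subnetwork_unions(per)["ser"][("orgA", "orgB")] == 0.0

    def test_partial_overlap_of_unions(self):
        per = {
            "orgA": {"ser": _subnets("ser", {"r1", "r2", "r3"}, {"r4", "r5"})},
            "orgB": {"ser": _subnets("ser", {"r1", "r2", "r3", "r4"})},
        }
        # unions: {r1..r5} vs {r1..r4} -> 4/5
        assert gr.compare_subnetwork_unions(per)["ser"][("orgA", "orgB")] == \
            pytest.approx(4 / 5)

    def test_missing_bbb_flagged_not_zero(self):
        per = {
            "orgA": {"ser": _subnets("ser", {"r1"}), "cys": _subnets("cys", {"r9"})},
            "orgB": {"ser": _subnets("ser", {"r1"})},
        }
        sim = gr.compare_subnetwork_unions(per)
        assert np.isnan(sim["cys"][("orgA", "orgB")])
        assert sim["ser"][("orgA", "orgB")] == 1.0

    def test_harmonization_map_applied(self):
        per = {
            "orgA": {"ser": _subnets("ser", {"FUM"})},
            "orgB": {"ser": _subnets("ser", {"FUMm"})},
        }
        raw = gr.compare_subnetwork_unions(per)
        mapped = gr.compare_subnetwork_unions(
            per, harmonization={"orgB": {"FUMm": "FUM"}}
        )
        assert raw["ser"][("orgA", "orgB")] == 0.0
        assert mapped["ser"][("orgA", "orgB")] == 1.0


class TestCategoryAverage:
    def _sim(self, value):
        import pandas as pd
        frame = pd.DataFrame(
            [[1.0, value], [value, 1.0]],
            index=["orgA", "orgB"], columns=["orgA", "orgB"],
        )
        return gr.SimilarityMatrix(values=frame)

    def test_single_member_category_is_identity(self):
        out = gr.category_average({"ser": self._sim(0.4)}, {"ser": "amino acid"})
        assert out["amino acid"].loc["orgA", "orgB"] == pytest.approx(0.4)

    def test_two_members_average(self):
        out = gr.category_average(
            {"ser": self._sim(0.4), "gly": self._sim(0.6)},
            {"ser": "amino acid", "gly": "amino acid"},
        )
        assert out["amino acid"].loc["orgA", "orgB"] == pytest.approx(0.5)

    def test_missing_entries_excluded_and_counted(self):
        import pandas as pd
        nanframe = pd.DataFrame(
            [[1.0, np.nan], [np.nan, 1.0]],
            index=["orgA", "orgB"], columns=["orgA", "orgB"],
        )
        out = gr.category_average(
            {"ser": self._sim(0.4), "cys": gr.SimilarityMatrix(values=nanframe)},
            {"ser": "aa", "cys": "aa"},
        )
        assert out["aa"].loc["orgA", "orgB"] == pytest.approx(0.4)
        assert out["aa_n_excluded"].loc["orgA", "orgB"] == 1

    def test_uncategorized_bbb_rejected(self):
        with pytest.raises(ValueError):
            gr.category_average({"ser": self._sim(0.5)}, {})


def _lump(stoich, target="ser_c", target_base="ser", core_supplied=False):
    return LumpedReaction(
        target=target, net_stoich=dict(stoich), base_stoich=dict(stoich),
        target_base=target_base, core_supplied=core_supplied,
        source_subnetworks=[object()],
    )


class TestBiosyntheticCost:
    def test_precursor_bbb_costs_one_of_itself(self):
        lr = _lump({"pyr_c": 1.0}, target="pyr_c", target_base="pyr",
                   core_supplied=True)
        cost = gr.biosynthetic_cost([lr])
        assert cost.precursor_moles["pyr"] == 1.0
        assert cost.atp == cost.nadh == cost.nadph == 0.0

    def test_averaging_across_lumps(self):
        a = _lump({"3pg": -1.0, "ser": 1.0})
        b = _lump({"3pg": -2.0, "ser": 1.0})
        cost = gr.biosynthetic_cost([a, b])
        assert cost.precursor_moles["3pg"] == pytest.approx(1.5)
        assert cost.n_lumps == 2

    def test_serine_style_route_vector(self):
        # 3pg + glu + nad -> ser + akg + nadh + pi
        lr = _lump({
            "3pg": -1.0, "glu__L": -1.0, "nad": -1.0,
            "ser": 1.0, "akg": 1.0, "nadh": 1.0, "pi": 1.0,
        })
        cost = gr.biosynthetic_cost([lr], inorganics={"pi", "h2o", "h"})
        assert cost.precursor_moles["3pg"] == pytest.approx(1.0)
        assert cost.nadh == pytest.approx(-1.0)  # net produced
        assert cost.other == {"glu__L": 1.0}  # nitrogen donor consumed
        assert cost.precursor_moles["akg"] == 0.0  # produced, not consumed

    def test_atp_accounting_counts_amp_twice(self):
        lr = _lump({"pyr": -1.0, "atp": -2.0, "adp": 1.0, "amp": 1.0, "ser": 1.0})
        cost = gr.biosynthetic_cost([lr])
        assert cost.atp == pytest.approx(1.0 + 2.0)

    def test_recomputation_from_stored_lumps_is_exact(self, rich_toy, rich_d0):
        g = rich_toy.model
        target = "bbb0_c"
        result = gr.enumerate_min_subnetworks(g, rich_d0, target, rich_toy.medium)
        uniq = gr.unique_lumps([gr.lump(sn, g) for sn in result])
        c1 = gr.biosynthetic_cost(uniq, inorganics=rich_toy.exclusions.inorganics)
        c2 = gr.biosynthetic_cost(uniq, inorganics=rich_toy.exclusions.inorganics)
        assert c1.precursor_moles == c2.precursor_moles
        assert (c1.atp, c1.nadh, c1.nadph, c1.other) == \
            (c2.atp, c2.nadh, c2.nadph, c2.other)

    def test_toy_route_cost_matches_construction(self, rich_toy, rich_d0):
        # route: anchor + NH3 + ATP -> bbb0 + ADP (aminate + phosphorylate)
        g = rich_toy.model
        result = gr.enumerate_min_subnetworks(g, rich_d0, "bbb0_c", rich_toy.medium)
        uniq = gr.unique_lumps([gr.lump(sn, g) for sn in result])
        cost = gr.biosynthetic_cost(
            uniq, precursors=("m0_1",), inorganics=rich_toy.exclusions.inorganics,
        )
        assert cost.precursor_moles["m0_1"] == pytest.approx(1.0)
        assert cost.atp == pytest.approx(1.0)
        assert cost.nadh == pytest.approx(0.0)

    def test_medium_supplied_bbb_costs_one_environmental_mole(self, rich_toy,
                                                              rich_d0):
        g = rich_toy.model
        result = gr.enumerate_min_subnetworks(g, rich_d0, "vit_c", rich_toy.medium)
        uniq = gr.unique_lumps([gr.lump(sn, g) for sn in result])
        cost = gr.biosynthetic_cost(uniq, inorganics=rich_toy.exclusions.inorganics)
        assert cost.other == {"vit": 1.0}
        assert cost.atp == cost.nadh == cost.nadph == 0.0
        assert all(v == 0.0 for v in cost.precursor_moles.values())

    def test_stray_species_rejected_when_allowlist_given(self):
        lr = _lump({"mystery": -1.0, "ser": 1.0})
        with pytest.raises(ValueError, match="outside"):
            gr.biosynthetic_cost([lr], allowed_species={"3pg"})

    def test_mixed_targets_rejected(self):
        with pytest.raises(ValueError):
            gr.biosynthetic_cost([
                _lump({"3pg": -1, "ser": 1}),
                _lump({"3pg": -1, "gly": 1}, target="gly_c", target_base="gly"),
            ])

    def test_default_precursor_list_has_twelve_entries(self):
        assert len(DEFAULT_PRECURSORS) == 12
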
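"""MILP subnetwork enumeration vs the exhaustive oracle; lumping; uniqueness."""

import cobra
import pytest

import gemreduce as gr
from gemreduce.fixtures import oracle_subnetworks
from gemreduce.subnetworks import (
    LumpedReaction,
    Subnetwork,
    lump_element_residual,
    subnetwork_feasible,
    subnetwork_minimal,
)


class TestEnumeration:
    def test_planted_routes_recovered(self, rich_toy, rich_d0):
        truth = rich_toy.truth
        for target, supports in truth.minimal_subnetworks.items():
            result = gr.enumerate_min_subnetworks(
                rich_toy.model, rich_d0, target, rich_toy.medium
            )
            assert result.active_sets == set(supports), target

    def test_matches_exhaustive_subset_search(self, rich_toy, rich_d0):
        target = "bbb0_c"
        oracle = oracle_subnetworks(
            rich_toy.model, rich_d0, target, rich_toy.medium, max_size=4
        )
        s_min = min(len(s) for s in oracle)
        for k in (0, 1):
            result = gr.enumerate_min_subnetworks(
                rich_toy.model, rich_d0, target, rich_toy.medium, k_relax=k
            )
            expected = {s for s in oracle if len(s) <= s_min + k}
            assert result.active_sets == expected

    def test_transport_only_for_medium_supplied_bbb(self, rich_toy, rich_d0):
        result = gr.enumerate_min_subnetworks(
            rich_toy.model, rich_d0, "vit_c", rich_toy.medium
        )
        assert result.active_sets == {frozenset({"T_vit"})}

    def test_core_metabolite_target_needs_no_reaction(self, rich_toy, rich_d0):
        anchor = next(iter(rich_d0.metabolites & {"m0_1_c"}))
        result = gr.enumerate_min_subnetworks(
            rich_toy.model, rich_d0, anchor, rich_toy.medium
        )
        assert result.active_sets == {frozenset()}

    def test_unproducible_target_diagnosed(self, rich_toy, rich_d0):
        # remove ammonia from the medium: the aminated BBB becomes unreachable
        no_n = gr.Medium(
            {e: b for e, b in rich_toy.medium.uptakes.items() if e != "EX_nh3_e"}
        )
        result = gr.enumerate_min_subnetworks(
            rich_toy.model, rich_d0, "bbb0_c", no_n
        )
        assert len(result) == 0 and "unproducible" in result.diagnostic

    def test_cap_truncates_with_flag(self, rich_toy, rich_d0):
        result = gr.enumerate_min_subnetworks(
            rich_toy.model, rich_d0, "bbb0_c", rich_toy.medium, cap=1
        )
        assert len(result) == 1 and result.truncated

    def test_solutions_feasible_and_minimal(self, rich_toy, rich_d0):
        for target in sorted(rich_toy.truth.bbbs):
            for sn in gr.enumerate_min_subnetworks(
                rich_toy.model, rich_d0, target, rich_toy.medium
            ):
                assert subnetwork_feasible(rich_toy.model, rich_d0, sn, rich_toy.medium)
                assert subnetwork_minimal(rich_toy.model, rich_d0, sn, rich_toy.medium)

    def test_repeated_runs_identical(self, rich_toy, rich_d0):
        runs = [
            gr.enumerate_min_subnetworks(
                rich_toy.model, rich_d0, "bbb0_c", rich_toy.medium, k_relax=1
            ).active_sets
            for _ in range(2)
        ]
        assert runs[0] == runs[1]


class TestLump:
    def test_telescoping_chain(self):
        m = cobra.Model("chain")
        a = cobra.Metabolite("a_c", formula="C2H4O2", compartment="c", charge=0)
        b = cobra.Metabolite("b_c", formula="C2H4O2", compartment="c", charge=0)
        c = cobra.Metabolite("c_c", formula="C2H4O2", compartment="c", charge=0)
        r1 = cobra.Reaction("R1"); r1.add_metabolites({a: -1, b: 1}); r1.bounds = (0, 10)
        r2 = cobra.Reaction("R2"); r2.add_metabolites({b: -1, c: 1}); r2.bounds = (0, 10)
        m.add_reactions([r1, r2])
        sn = Subnetwork(
            target="c_c", active_reactions=frozenset({"R1", "R2"}),
            fluxes={"R1": 1.0, "R2": 1.0},
        )
        lr = gr.lump(sn, m)
        assert lr.net_stoich == {"a_c": -1.0, "c_c": 1.0}
        assert lump_element_residual(lr, m) == {}

    def test_planted_route_lumps_match_truth(self, rich_toy, rich_d0):
        g, truth = rich_toy.model, rich_toy.truth
        for target, expected in truth.expected_lumps.items():
            result = gr.enumerate_min_subnetworks(g, rich_d0, target, rich_toy.medium)
            lumps = [gr.lump(sn, g) for sn in result]
            uniq = gr.unique_lumps(lumps)
            assert len(uniq) == 1
            got = uniq[0].base_stoich
            assert set(got) == set(expected)
            for species, coef in expected.items():
                assert got[species] == pytest.approx(coef, abs=1e-6)
            if expected:  # a pure translocation lump cancels when stripped
                assert got[uniq[0].target_base] == pytest.approx(1.0)

    def test_element_conservation_on_balanced_fixture(self, rich_toy, rich_d0):
        g = rich_toy.model
        for target in sorted(rich_toy.truth.bbbs):
            for sn in gr.enumerate_min_subnetworks(g, rich_d0, target, rich_toy.medium):
                lr = gr.lump(sn, g)
                if not lr.core_supplied:
                    assert lump_element_residual(lr, g) == {}

    def test_unbalanced_member_warns(self, caplog):
        m = cobra.Model("bad")
        a = cobra.Metabolite("a_c", formula="C2H4O2", compartment="c", charge=0)
        b = cobra.Metabolite("b_c", formula="C3H6O3", compartment="c", charge=0)
        r = cobra.Reaction("RBAD"); r.add_metabolites({a: -1, b: 1}); r.bounds = (0, 10)
        m.add_reactions([r])
        sn = Subnetwork(target="b_c", active_reactions=frozenset({"RBAD"}),
                        fluxes={"RBAD": 1.0})
        with caplog.at_level("WARNING", logger="gemreduce"):
            gr.lump(sn, m)
        assert any("unbalanced" in rec.message for rec in caplog.records)


class TestUniqueLumps:
    def _lr(self, stoich, target="t_c"):
        return LumpedReaction(target=target, net_stoich=dict(stoich),
                              base_stoich=dict(stoich), target_base="t",
                              source_subnetworks=[object()])

    def test_identical_lumps_collapse(self):
        a = self._lr({"x_c": -1.0, "t_c": 1.0})
        b = self._lr({"x_c": -1.0, "t_c": 1.0})
        uniq = gr.unique_lumps([a, b])
        assert len(uniq) == 1
        assert len(uniq[0].source_subnetworks) == 2

    def test_tolerance_boundary(self):
        tol = 1e-6
        a = self._lr({"x_c": -1.0, "t_c": 1.0})
        within = self._lr({"x_c": -1.0 + 0.5 * tol, "t_c": 1.0})
        beyond = self._lr({"x_c": -1.0 + 2 * tol, "t_c": 1.0})
        assert len(gr.unique_lumps([a, within], tol=tol)) == 1
        assert len(gr.unique_lumps([a, beyond], tol=tol)) == 2

    def test_different_support_never_merged(self):
        a = self._lr({"x_c": -1.0, "t_c": 1.0})
        b = self._lr({"y_c": -1.0, "t_c": 1.0})
        assert len(gr.unique_lumps([a, b])) == 2
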
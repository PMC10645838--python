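"""Residue-tree model: census, topology, canonical assembly, extension."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fructans.linkages import LinkageClass as L
from fructans.simulate import MixtureParams, generate_structure
from fructans.structures import (
    FructanStructure,
    InfeasibleCensusError,
    StructureError,
    assemble_core,
    extend_to_target_dp,
    required_terminals,
)


def nonzero(census):
    return {k: v for k, v in census.items() if v}


class TestCensus:
    @pytest.mark.parametrize(
        "counts,mode,expected_dp",
        [
            ({L.T_FRUF: 1, L.T_GLCP: 1}, "terminal", 2),  # sucrose
            ({L.T_FRUF: 1, L.B21_FRUF: 1, L.T_GLCP: 1}, "terminal", 3),  # 1-kestose
            ({L.T_FRUF: 1, L.B21_FRUF: 2, L.T_GLCP: 1}, "terminal", 4),  # 1-nystose
            ({L.T_FRUF: 2, L.I_GLCP: 1}, "internal", 3),  # neokestose
        ],
    )
    def test_small_molecules_round_trip(self, counts, mode, expected_dp):
        s = assemble_core(counts, mode)
        assert s.dp() == expected_dp
        assert nonzero(s.census()) == counts

    def test_branched_core_census(self, graminan_core):
        """One glucose, a 2-1 backbone, a branch residue and its levan chain
        give the measured per-molecule composition at DP 7."""
        assert graminan_core.dp() == 7
        assert nonzero(graminan_core.census()) == {
            L.T_FRUF: 2,
            L.B21_FRUF: 2,
            L.B26_FRUF: 1,
            L.DI_FRUF: 1,
            L.T_GLCP: 1,
        }
        assert sum(graminan_core.census().values()) == graminan_core.dp()

    def test_two_glucoses_rejected(self):
        with pytest.raises(StructureError, match="one glucose"):
            FructanStructure(
                [("G1", "glucose"), ("G2", "glucose"), ("F1", "fructose")],
                [("G1", "F1", "C2"), ("G2", "F1", "C1")],
            )

    def test_cycle_rejected(self):
        with pytest.raises(StructureError, match="tree"):
            FructanStructure(
                [("F1", "fructose"), ("F2", "fructose")],
                [("F1", "F2", "C1"), ("F2", "F1", "C6")],
            )

    def test_bad_position_names_residue(self):
        with pytest.raises(StructureError, match="F1"):
            FructanStructure(
                [("F1", "fructose"), ("F2", "fructose")],
                [("F2", "F1", "C3")],
            )

    def test_glucose_cannot_accept_at_c1(self):
        with pytest.raises(StructureError, match="glucose"):
            FructanStructure(
                [("G", "glucose"), ("F1", "fructose"), ("F2", "fructose")],
                [("G", "F1", "C2"), ("F2", "G", "C1")],
            )


class TestTopology:
    def test_linear_chain_with_terminal_glucose_is_inulin(self):
        s = assemble_core({L.T_FRUF: 1, L.B21_FRUF: 3, L.T_GLCP: 1}, "terminal")
        assert s.classify_topology() == "inulin"

    def test_levan_dominant_linear_chain(self):
        s = assemble_core({L.T_FRUF: 1, L.B26_FRUF: 3, L.T_GLCP: 1}, "terminal")
        assert s.classify_topology() == "levan"

    def test_branched_terminal_glucose_is_graminan(self, graminan_core):
        assert graminan_core.classify_topology() == "graminan"

    def test_branched_internal_glucose_is_agavin(self):
        s = assemble_core(
            {L.T_FRUF: 3, L.B21_FRUF: 1, L.B26_FRUF: 1, L.DI_FRUF: 1, L.I_GLCP: 1},
            "internal",
        )
        assert s.classify_topology() == "agavin"

    def test_no_glucose_is_f_series(self):
        s = FructanStructure(
            [("F1", "fructose"), ("F2", "fructose")], [("F2", "F1", "C1")]
        )
        assert s.classify_topology() == "F-series"

    def test_internal_unbranched_is_neo_series(self):
        s = assemble_core({L.T_FRUF: 2, L.B21_FRUF: 2, L.I_GLCP: 1}, "internal")
        assert s.classify_topology() == "inulin-neo-series"


class TestAssembly:
    def test_infeasible_terminal_count_raises(self):
        # a tree with one branch residue must expose exactly two terminals
        with pytest.raises(InfeasibleCensusError, match="terminal fructoses"):
            assemble_core(
                {L.T_FRUF: 3, L.B21_FRUF: 1, L.DI_FRUF: 1, L.T_GLCP: 1}, "terminal"
            )

    def test_spec_dp8_internal_census_is_unrealizable(self):
        # internal glucose adds an arm, so it needs one more terminal cap
        with pytest.raises(InfeasibleCensusError):
            assemble_core(
                {L.T_FRUF: 2, L.B21_FRUF: 3, L.B26_FRUF: 1, L.DI_FRUF: 1, L.I_GLCP: 1},
                "internal",
            )

    def test_levan_run_without_branch_residue(self):
        # G-F(2-6)-F is a tree even with no branch residue
        s = assemble_core({L.T_FRUF: 1, L.B26_FRUF: 1, L.T_GLCP: 1}, "terminal")
        assert nonzero(s.census()) == {L.T_FRUF: 1, L.B26_FRUF: 1, L.T_GLCP: 1}

    def test_multiple_branch_residues_round_trip(self):
        counts = {L.T_FRUF: 4, L.B21_FRUF: 5, L.B26_FRUF: 3, L.DI_FRUF: 3, L.T_GLCP: 1}
        s = assemble_core(counts, "terminal")
        assert nonzero(s.census()) == counts
        assert len(s.edges) == s.dp() - 1

    def test_glucose_mode_overrides_census_class(self):
        s = assemble_core(
            {L.T_FRUF: 2, L.B21_FRUF: 1, L.T_GLCP: 1}, "internal"
        )
        c = s.census()
        assert c[L.I_GLCP] == 1 and c[L.T_GLCP] == 0


class TestExtension:
    def test_identity_extension(self, graminan_core):
        same = extend_to_target_dp(graminan_core, graminan_core.dp(), "backbone")
        assert same.census() == graminan_core.census()

    def test_backbone_extension_adds_only_inulin_units(self, graminan_core):
        ext = extend_to_target_dp(graminan_core, 20, "backbone")
        assert ext.dp() == 20
        diff = {
            k: ext.census()[k] - graminan_core.census()[k] for k in L
        }
        assert diff == {L.B21_FRUF: 13, **{k: 0 for k in L if k != L.B21_FRUF}}
        assert ext.classify_topology() == "graminan"

    def test_backbone_extension_of_sucrose(self):
        suc = assemble_core({L.T_FRUF: 1, L.T_GLCP: 1}, "terminal")
        ext = extend_to_target_dp(suc, 4, "backbone")
        assert nonzero(ext.census()) == {L.T_FRUF: 1, L.B21_FRUF: 2, L.T_GLCP: 1}

    def test_proportional_extension_round_trips(self, graminan_core):
        # factor 20/7 scales each fructose count, rounds, then the terminal
        # count is canonicalised to the tree identity (DP conserved)
        ext = extend_to_target_dp(graminan_core, 20, "proportional")
        c = ext.census()
        assert c[L.DI_FRUF] == 3  # 1 * 20/7 = 2.857 -> 3
        assert c[L.B26_FRUF] == 3
        assert c[L.T_FRUF] == required_terminals(3, internal_glucose=False)
        # 2 * 20/7 -> 6 rounded for both t and 2-1; surplus terminals move
        # into the backbone: 6 + (6 - 4) = 8
        assert c[L.B21_FRUF] == 8
        assert ext.dp() == 6 + 6 + 3 + 3 + 1

    def test_target_below_core_dp_raises(self, graminan_core):
        with pytest.raises(StructureError, match="below"):
            extend_to_target_dp(graminan_core, 5, "backbone")


class TestSerialization:
    def test_json_round_trip(self, graminan_core):
        clone = FructanStructure.from_json(graminan_core.to_json())
        assert clone.census() == graminan_core.census()
        assert sorted(clone.edges) == sorted(graminan_core.edges)

    def test_schema_version_checked(self):
        with pytest.raises(StructureError, match="schema"):
            FructanStructure.from_dict({"schema": "bogus", "residues": [], "edges": []})


@st.composite
def realizable_census(draw):
    """Censuses satisfying the tree identity t-Fruf == di + 1 + internal."""
    nd = draw(st.integers(0, 4))
    internal = draw(st.booleans())
    n1 = draw(st.integers(0, 8))
    n6 = draw(st.integers(0, 6))
    counts = {
        L.T_FRUF: required_terminals(nd, internal),
        L.B21_FRUF: n1,
        L.B26_FRUF: n6,
        L.DI_FRUF: nd,
        (L.I_GLCP if internal else L.T_GLCP): 1,
    }
    return counts, "internal" if internal else "terminal"


@given(realizable_census())
@settings(max_examples=60, deadline=None, derandomize=True)
def test_assembly_census_round_trip_property(case):
    counts, mode = case
    s = assemble_core(counts, mode)
    assert nonzero(s.census()) == {k: v for k, v in counts.items() if v}
    assert len(s.edges) == s.dp() - 1
    assert sum(s.census().values()) == s.dp()


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_generated_structures_valid_and_conserved(seed):
    rng = np.random.default_rng(seed)
    s = generate_structure(MixtureParams(seed=seed), rng)
    s.validate()
    c = s.census()
    assert sum(c.values()) == s.dp()
    assert c[L.T_GLCP] + c[L.I_GLCP] == 1
    assert c[L.T_FRUF] == required_terminals(
        c[L.DI_FRUF], internal_glucose=bool(c[L.I_GLCP])
    )
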
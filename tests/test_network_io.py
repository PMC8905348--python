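"""Network structure, SBML round-trip, reversible splitting, boundary blocking."""

import numpy as np
import pytest

import deltaflux as df
from deltaflux.network_io import NetworkError, SBMLFormatError, write_split_tsv


def toy_net(reversible=False):
    mets = [df.Metabolite("A", compartment="c"), df.Metabolite("B", compartment="c")]
    rxns = [
        df.Reaction(
            "r1", (("A", 1.0),), (("B", 1.0),), reversible=reversible,
            upper_bound=10.0, reverse_upper_bound=5.0 if reversible else None,
        )
    ]
    return df.MetabolicNetwork(mets, rxns)


class TestNetworkStructure:
    def test_matrix_signs(self):
        net = toy_net()
        S = net.S.toarray()
        assert S.shape == (2, 1)
        assert S[net.met_index["A"], 0] == -1.0
        assert S[net.met_index["B"], 0] == 1.0

    @pytest.mark.parametrize(
        "bad",
        [
            lambda: df.Reaction("r", (("A", 1.0),), (("A", 1.0),)),  # overlap
            lambda: df.Reaction("r", (("A", -1.0),), (("B", 1.0),)),  # coeff <= 0
            lambda: df.Reaction("r", (("A", 1.0),), (("B", 1.0),), upper_bound=-1),
            lambda: df.Metabolite(""),
        ],
    )
    def test_invalid_components_rejected(self, bad):
        with pytest.raises(NetworkError):
            bad()

    def test_duplicate_ids_rejected(self):
        mets = [df.Metabolite("A"), df.Metabolite("A")]
        with pytest.raises(NetworkError, match="duplicate"):
            df.MetabolicNetwork(mets, [])


class TestSplitReversible:
    def test_pair_columns_are_negations(self):
        sn = df.split_reversible(toy_net(reversible=True))
        assert len(sn.pair_map) == 1
        j, jb = sn.pair_map[0]
        S = sn.S.toarray()
        np.testing.assert_array_equal(S[:, j], -S[:, jb])
        assert sn.reactions[jb].id == "r1_R"
        assert sn.origin("r1_R") == ("r1", "reverse")

    def test_split_bounds_from_lb_ub(self):
        sn = df.split_reversible(toy_net(reversible=True))
        j, jb = sn.pair_map[0]
        assert sn.reactions[j].upper_bound == 10.0
        assert sn.reactions[jb].upper_bound == 5.0

    def test_irreversible_pass_through(self):
        net = toy_net(reversible=False)
        sn = df.split_reversible(net)
        assert sn.pair_map == []
        assert [r.id for r in sn.reactions] == ["r1"]
        np.testing.assert_array_equal(sn.S.toarray(), net.S.toarray())

    def test_counts_mixed_network(self):
        # 3 reversible + 2 irreversible -> 8 columns, 3 pairs
        mets = [df.Metabolite(f"M{i}") for i in range(6)]
        rxns = [
            df.Reaction(f"v{i}", ((mets[i].id, 1.0),), ((mets[i + 1].id, 1.0),),
                        reversible=(i < 3))
            for i in range(5)
        ]
        sn = df.split_reversible(df.MetabolicNetwork(mets, rxns))
        assert sn.n_reactions == 8
        assert len(sn.pair_map) == 3

    def test_id_collision_refused(self):
        mets = [df.Metabolite("A"), df.Metabolite("B")]
        rxns = [
            df.Reaction("r1", (("A", 1.0),), (("B", 1.0),), reversible=True),
            df.Reaction("r1_R", (("B", 1.0),), (("A", 1.0),)),
        ]
        with pytest.raises(NetworkError, match="r1_R"):
            df.split_reversible(df.MetabolicNetwork(mets, rxns))


class TestBoundary:
    def _net_with_sink(self):
        mets = [df.Metabolite("A"), df.Metabolite("B"), df.Metabolite("X_b", is_boundary=True)]
        rxns = [
            df.Reaction("r1", (("A", 1.0),), (("B", 1.0),)),
            df.Reaction("EX_B", (("B", 1.0),), ()),           # sink: empty products
            df.Reaction("SRC", (), (("A", 1.0),)),            # source: empty substrates
            df.Reaction("rb", (("X_b", 1.0),), (("A", 1.0),)),  # boundary-species rule
        ]
        return df.split_reversible(df.MetabolicNetwork(mets, rxns))

    def test_find_boundary(self):
        sn = self._net_with_sink()
        assert set(df.find_boundary_reactions(sn)) == {"EX_B", "SRC", "rb"}

    def test_block_all(self):
        sn, blocked = df.block_boundary(self._net_with_sink(), [])
        assert set(blocked) == {"EX_B", "SRC", "rb"}
        for rid in blocked:
            assert sn.reactions[sn.rxn_index[rid]].upper_bound == 0.0
        # internal reaction untouched
        assert sn.reactions[sn.rxn_index["r1"]].upper_bound > 0

    def test_exempt_keeps_bound(self):
        sn, blocked = df.block_boundary(self._net_with_sink(), ["EX_B"])
        assert "EX_B" not in blocked
        assert sn.reactions[sn.rxn_index["EX_B"]].upper_bound > 0

    def test_exempt_all_is_noop(self):
        orig = self._net_with_sink()
        sn, blocked = df.block_boundary(orig, ["EX_B", "SRC", "rb"])
        assert blocked == []
        assert [r.upper_bound for r in sn.reactions] == [
            r.upper_bound for r in orig.reactions
        ]

    def test_unknown_exempt_named(self):
        with pytest.raises(NetworkError, match="nope"):
            df.block_boundary(self._net_with_sink(), ["nope"])


class TestSBML:
    def test_round_trip_minimal(self, tmp_path):
        net = toy_net(reversible=True)
        path = tmp_path / "model.xml"
        df.write_sbml(net, str(path))
        loaded = df.load_sbml(str(path))
        assert [m.id for m in loaded.metabolites] == ["A", "B"]
        assert loaded.reactions[0].reversible
        np.testing.assert_array_equal(loaded.S.toarray(), [[-1.0], [1.0]])

    def test_round_trip_matches_cobra(self, tmp_path):
        """Independent reader cross-check: cobra parses the same stoichiometry."""
        cobra = pytest.importorskip("cobra")
        net = df.make_toy_network("branch", 4).base
        path = tmp_path / "branch.xml"
        df.write_sbml(net, str(path))
        model = cobra.io.read_sbml_model(str(path))
        ours = df.load_sbml(str(path))
        assert {r.id for r in model.reactions} == {r.id for r in ours.reactions}
        for rxn in model.reactions:
            mine = ours.reactions[ours.rxn_index[rxn.id]]
            theirs = {m.id: c for m, c in rxn.metabolites.items()}
            mine_coeffs = {m: -c for m, c in mine.substrates}
            mine_coeffs.update(dict(mine.products))
            assert mine_coeffs == theirs

    def test_boundary_condition_flag(self, tmp_path):
        mets = [df.Metabolite("A"), df.Metabolite("E", is_boundary=True)]
        rxns = [df.Reaction("r", (("A", 1.0),), (("E", 1.0),))]
        path = tmp_path / "b.xml"
        df.write_sbml(df.MetabolicNetwork(mets, rxns), str(path))
        loaded = df.load_sbml(str(path))
        assert loaded.metabolites[loaded.met_index["E"]].is_boundary

    def test_parse_failure_raises(self, tmp_path):
        bad = tmp_path / "bad.xml"
        bad.write_text("<sbml><model></sbml>")
        with pytest.raises(SBMLFormatError):
            df.load_sbml(str(bad))

    def test_zero_reaction_model_rejected(self, tmp_path):
        mets = [df.Metabolite("A")]
        path = tmp_path / "empty.xml"
        df.write_sbml(df.MetabolicNetwork(mets, []), str(path))
        with pytest.raises(NetworkError, match="zero reactions"):
            df.load_sbml(str(path))


def test_split_tsv_dump(tmp_path):
    sn = df.split_reversible(toy_net(reversible=True))
    path = tmp_path / "split.tsv"
    write_split_tsv(sn, str(path))
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "reaction_id\torigin_id\tdirection\tupper_bound"
    assert "r1_R\tr1\treverse\t5" in lines[2]
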
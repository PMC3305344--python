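"""Reaction parsing, pair extraction, net changes, trajectories, modules."""

import numpy as np
import pandas as pd
import pytest

from metachem.descriptors import compute_descriptors, descriptor_table
from metachem.reactions import (
    extract_pairs,
    module_profile,
    net_changes,
    parse_reactions,
    pathway_trajectory,
)

from conftest import met


def write_rxns(tmp_path, text):
    f = tmp_path / "rxns.txt"
    f.write_text(text)
    return f


class TestParsing:
    def test_irreversible(self, tmp_path):
        rxns, rej = parse_reactions(write_rxns(tmp_path, "R1: A + B => C\n"))
        assert not rej
        (r,) = rxns
        assert not r.reversible
        assert r.reactant_ids == ["A", "B"]
        assert r.product_ids == ["C"]

    def test_reversible_and_flags(self, tmp_path):
        rxns, _ = parse_reactions(write_rxns(tmp_path, "R2: A <=> B\nR3: S + O2 => P | o2\n"))
        assert rxns[0].reversible
        assert not rxns[1].reversible and rxns[1].oxygen_dependent

    def test_stoichiometry(self, tmp_path):
        rxns, _ = parse_reactions(write_rxns(tmp_path, "R1: 2 A + B => 3 C\n"))
        assert rxns[0].reactants == [("A", 2.0), ("B", 1.0)]
        assert rxns[0].products == [("C", 3.0)]

    def test_identity_overlap_flagged(self, tmp_path):
        rxns, _ = parse_reactions(write_rxns(tmp_path, "R3: 2 A => A\n"))
        assert any(f.startswith("identity_overlap") for f in rxns[0].flags)

    def test_malformed_line_rejected_not_dropped(self, tmp_path):
        rxns, rej = parse_reactions(write_rxns(tmp_path, "R1: A => B\ngarbage line\n"))
        assert len(rxns) == 1 and len(rej) == 1

    def test_species_names_with_plus_sign(self, tmp_path):
        rxns, rej = parse_reactions(write_rxns(tmp_path, "R1: A + NADH => B + NAD+\n"))
        assert not rej
        assert rxns[0].product_ids == ["B", "NAD+"]


MW = {"A": 100.0, "B": 120.0, "C": 140.0, "D": 160.0, "H2O": 18.0, "X": 300.0}


class TestExtractPairs:
    def test_cofactors_discarded(self, tmp_path):
        rxns, _ = parse_reactions(write_rxns(tmp_path, "R1: A + ATP => B + ADP\n"))
        pairs = extract_pairs(rxns, MW, cofactors={"ATP", "ADP"})
        assert [(p.substrate_id, p.product_id) for p in pairs] == [("A", "B")]

    def test_low_mw_discarded(self, tmp_path):
        rxns, _ = parse_reactions(write_rxns(tmp_path, "R1: A => H2O + B\n"))
        pairs = extract_pairs(rxns, MW, cofactors=set())
        assert [(p.substrate_id, p.product_id) for p in pairs] == [("A", "B")]

    def test_cartesian_product(self, tmp_path):
        rxns, _ = parse_reactions(write_rxns(tmp_path, "R1: A + B => C + D\n"))
        pairs = extract_pairs(rxns, MW, cofactors=set())
        assert len(pairs) == 4
        assert {(p.substrate_id, p.product_id) for p in pairs} == {
            ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")
        }

    def test_main_pair_mode(self, tmp_path):
        rxns, _ = parse_reactions(write_rxns(tmp_path, "R1: A + B => C + D\n"))
        pairs = extract_pairs(rxns, MW, cofactors=set(), mode="main")
        assert [(p.substrate_id, p.product_id) for p in pairs] == [("B", "D")]

    def test_reversible_excluded(self, tmp_path):
        rxns, _ = parse_reactions(write_rxns(tmp_path, "R1: A <=> B\n"))
        assert extract_pairs(rxns, MW, cofactors=set()) == []

    def test_no_survivors_contributes_zero(self, tmp_path):
        rxns, _ = parse_reactions(write_rxns(tmp_path, "R1: ATP => ADP\n"))
        assert extract_pairs(rxns, MW, cofactors={"ATP", "ADP"}) == []

    def test_unresolvable_id_errors(self, tmp_path):
        rxns, _ = parse_reactions(write_rxns(tmp_path, "R1: A => Unknown\n"))
        with pytest.raises(KeyError, match="Unknown"):
            extract_pairs(rxns, MW, cofactors=set())

    def test_pair_count_bookkeeping(self, tmp_path):
        text = "R1: A + B => C + D\nR2: A => B\nR3: X <=> A\nR4: A + H2O => C\n"
        rxns, _ = parse_reactions(write_rxns(tmp_path, text))
        pairs = extract_pairs(rxns, MW, cofactors=set())
        expected = 0
        for r in rxns:
            if r.reversible:
                continue
            s = [m for m in r.reactant_ids if MW[m] >= 70]
            p = [m for m in r.product_ids if MW[m] >= 70]
            expected += len(s) * len(p)
        assert len(pairs) == expected


class TestNetChanges:
    def setup_method(self):
        mets = [met("c1ccccc1", "benzene"), met("Oc1ccccc1", "phenol")]
        self.desc = descriptor_table(mets, embed=False)

    def test_identity_pair_all_zero(self, tmp_path):
        rxns, _ = parse_reactions(write_rxns(tmp_path, "R1: benzene => benzene2\n"))
        desc = self.desc.rename(index={"phenol": "benzene2"})
        desc.loc["benzene2"] = desc.loc["benzene"]
        pairs = extract_pairs(rxns, desc["MW"].to_dict(), cofactors=set())
        nc = net_changes(pairs, desc)
        assert (nc.deltas == 0).all()

    def test_benzene_to_phenol_signs(self, tmp_path):
        rxns, _ = parse_reactions(write_rxns(tmp_path, "R1: benzene => phenol\n"))
        pairs = extract_pairs(rxns, self.desc["MW"].to_dict(), cofactors=set())
        nc = net_changes(pairs, self.desc)
        assert nc.deltas["Donor"] == 1
        assert nc.deltas["Acceptor"] == 1
        assert nc.deltas["PSA"] > 0
        assert nc.deltas["AlogP98"] < 0

    def test_known_mean_recovered_exactly(self):
        """Pairs planted with an exact mean delta are recovered to 1e-9."""
        from metachem.reactions import ReactionPair

        desc = pd.DataFrame(
            {"PSA": [100.0, 90.0, 70.0, 40.0], "AlogP98": [0.0, 1.0, 2.0, 3.0]},
            index=["a", "b", "c", "d"],
        )
        pairs = [ReactionPair("a", "b", "r1"), ReactionPair("c", "d", "r2")]
        nc = net_changes(pairs, desc, columns=["PSA", "AlogP98"])
        assert nc.deltas["PSA"] == pytest.approx((-10 + -30) / 2, abs=1e-9)

    def test_linearity_under_duplication(self):
        from metachem.reactions import ReactionPair

        desc = pd.DataFrame({"PSA": [10.0, 25.0]}, index=["a", "b"])
        pairs = [ReactionPair("a", "b", "r1")]
        once = net_changes(pairs, desc, columns=["PSA"])
        twice = net_changes(pairs * 2, desc, columns=["PSA"])
        assert once.deltas["PSA"] == twice.deltas["PSA"]
        assert twice.n_pairs == 2 * once.n_pairs

    def test_empty_pairs_error(self):
        with pytest.raises(ValueError):
            net_changes([], self.desc)


class TestTrajectory:
    def setup_method(self):
        mets = [met("Oc1ccccc1", "p0"), met("Cc1ccccc1", "p1"), met("CCc1ccccc1", "p2")]
        self.desc = descriptor_table(mets, embed=False)

    def test_hydrophobizing_chain_monotone(self):
        df = pathway_trajectory(["p0", "p1", "p2"], self.desc)
        vals = df["AlogP98"].to_list()
        assert vals == sorted(vals)
        assert df.attrs["fraction_increasing"] == 1.0

    def test_constant_chain_flat(self):
        df = pathway_trajectory(["p1", "p1", "p1"], self.desc)
        assert df["AlogP98"].nunique() == 1
        assert df.attrs["fraction_increasing"] == 0.0

    def test_reversed_path_reverses_series(self):
        fwd = pathway_trajectory(["p0", "p1", "p2"], self.desc)["AlogP98"].to_list()
        rev = pathway_trajectory(["p2", "p1", "p0"], self.desc)["AlogP98"].to_list()
        assert rev == fwd[::-1]

    def test_unresolvable_id_named(self):
        with pytest.raises(KeyError, match="ghost"):
            pathway_trajectory(["p0", "ghost"], self.desc)

    def test_too_short(self):
        with pytest.raises(ValueError):
            pathway_trajectory(["p0"], self.desc)


class TestModuleProfile:
    def test_linear_chain(self, tmp_path):
        f = tmp_path / "r.txt"
        f.write_text("r1: A => B\nr2: B => C\n")
        rxns, _ = parse_reactions(f)
        prof = module_profile(rxns, ["A", "B", "C"], core=["C"])
        assert prof.initial_reactants == ["A"]
        assert prof.mean_participation == 1
        assert prof.distances["A"] == 2.0

    def test_single_reaction_undirected_distance(self, tmp_path):
        f = tmp_path / "r.txt"
        f.write_text("r1: A => B\n")
        rxns, _ = parse_reactions(f)
        prof = module_profile(rxns, ["A", "B"], core=["A"])
        assert prof.distances["B"] == 1.0

    def test_empty_reactions_error(self):
        with pytest.raises(ValueError):
            module_profile([], ["A"])

    def test_unreachable_excluded_with_count(self, tmp_path):
        f = tmp_path / "r.txt"
        f.write_text("r1: A => B\nr2: X => Y\n")
        rxns, _ = parse_reactions(f)
        prof = module_profile(rxns, ["A", "B", "X", "Y"], core=["B"])
        assert prof.n_unreachable == 1      # X cannot reach B
        assert prof.distances["A"] == 1.0
        assert "X" not in prof.distances

    def test_participation_counts_consuming_reactions(self, tmp_path):
        f = tmp_path / "r.txt"
        f.write_text("r1: A => B\nr2: A => C\nr3: A + B => D\n")
        rxns, _ = parse_reactions(f)
        prof = module_profile(rxns, ["A", "B", "C", "D"], core=["D"])
        assert prof.participation["A"] == 3
        assert prof.mean_participation == 3
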
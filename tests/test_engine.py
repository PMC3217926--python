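"""Site-graph engine: canonical labels, matching, rule application, network
generation against exhaustive oracles."""

import random

import pytest

from integrinsim import bngl
from integrinsim.engine import (
    BOUND,
    FREE,
    MoleculeDef,
    NetworkExplosionError,
    Pattern,
    PatternMol,
    SiteDef,
    StructuralError,
    _Graph,
    generate_network,
    make_species,
    match,
)

DEFS = {
    "A": MoleculeDef("A", (SiteDef("b"), SiteDef("s", ("u", "p"))), frozenset({"CP"})),
    "B": MoleculeDef("B", (SiteDef("a"),), frozenset({"CP"})),
    "P": MoleculeDef(
        "P",
        (SiteDef("t1"), SiteDef("t2"), SiteDef("x")),
        frozenset({"CP"}),
        symmetric=(frozenset({"t1", "t2"}),),
    ),
}


def dimer(state_a="u"):
    return make_species(
        DEFS,
        [("A", {"s": state_a}), ("B", {})],
        [(0, "b", 1, "a")],
        "CP",
    )


class TestCanonicalLabel:
    def test_ordering_invariance(self):
        """Two build orders of the same A-B dimer give identical labels."""
        s1 = make_species(DEFS, [("A", {"s": "u"}), ("B", {})], [(0, "b", 1, "a")], "CP")
        s2 = make_species(DEFS, [("B", {}), ("A", {"s": "u"})], [(1, "b", 0, "a")], "CP")
        assert s1.label == s2.label

    def test_dimer_differs_from_monomers(self):
        bound = make_species(DEFS, [("A", {}), ("A", {})], [(0, "b", 1, "b")], "CP")
        free = make_species(DEFS, [("A", {})], [], "CP")
        assert bound.label != free.label

    def test_state_matters(self):
        assert dimer("u").label != dimer("p").label

    def test_symmetric_sites_merge(self):
        """Binding via either arm of a symmetric scaffold is one species."""
        via1 = make_species(DEFS, [("P", {}), ("A", {})], [(0, "t1", 1, "b")], "CP")
        via2 = make_species(DEFS, [("P", {}), ("A", {})], [(0, "t2", 1, "b")], "CP")
        assert via1.label == via2.label

    def test_random_permutations_one_label(self):
        """500 random instance orderings of a 4-molecule complex: 1 label."""
        rng = random.Random(42)
        mols = [("P", {}), ("A", {"s": "u"}), ("A", {"s": "p"}), ("B", {})]
        bonds = [(0, "t1", 1, "b"), (0, "t2", 2, "b"), (0, "x", 3, "a")]
        labels = set()
        for _ in range(500):
            perm = list(range(4))
            rng.shuffle(perm)
            inv = {old: new for new, old in enumerate(perm)}
            pm = [mols[old] for old in perm]
            pb = [(inv[i], si, inv[j], sj) for i, si, j, sj in bonds]
            labels.add(make_species(DEFS, pm, pb, "CP").label)
        assert len(labels) == 1

    def test_asymmetric_states_on_symmetric_arms_distinct(self):
        """u- and p-arm assignments around the scaffold are isomorphic."""
        a = make_species(
            DEFS,
            [("P", {}), ("A", {"s": "u"}), ("A", {"s": "p"})],
            [(0, "t1", 1, "b"), (0, "t2", 2, "b")],
            "CP",
        )
        b = make_species(
            DEFS,
            [("P", {}), ("A", {"s": "p"}), ("A", {"s": "u"})],
            [(0, "t1", 1, "b"), (0, "t2", 2, "b")],
            "CP",
        )
        assert a.label == b.label

    def test_malformed_bond_rejected(self):
        g = _Graph(DEFS, "CP")
        g.add_molecule("A", {"s": "u"})
        g.add_molecule("B", {})
        g.bonds[0]["b"] = (1, "a")  # one-sided bond
        with pytest.raises(StructuralError):
            g.canonical()

    def test_disconnected_rejected(self):
        g = _Graph(DEFS, "CP")
        g.add_molecule("A", {"s": "u"})
        g.add_molecule("B", {})
        with pytest.raises(StructuralError):
            g.canonical()


class TestMatch:
    def test_free_site_matches_free_monomer(self):
        pat = Pattern((PatternMol("A", (("b", (None, FREE)),)),))
        free = make_species(DEFS, [("A", {})], [], "CP")
        assert len(match(pat, free, DEFS)) == 1

    def test_free_site_rejects_bound(self):
        pat = Pattern((PatternMol("A", (("b", (None, FREE)),)),))
        aa = make_species(DEFS, [("A", {}), ("A", {})], [(0, "b", 1, "b")], "CP")
        assert match(pat, aa, DEFS) == []

    def test_bound_wildcard_counts_automorphisms(self):
        """A(b!+) embeds twice into the symmetric A-A dimer."""
        pat = Pattern((PatternMol("A", (("b", (None, BOUND)),)),))
        aa = make_species(DEFS, [("A", {}), ("A", {})], [(0, "b", 1, "b")], "CP")
        assert len(match(pat, aa, DEFS)) == 2

    def test_symmetric_site_embeddings(self):
        """P(t1) matches either free arm: two embeddings on free P."""
        pat = Pattern((PatternMol("P", (("t1", (None, FREE)),)),))
        p = make_species(DEFS, [("P", {})], [], "CP")
        assert len(match(pat, p, DEFS)) == 2
        # with one arm taken there is exactly one embedding
        pa = make_species(DEFS, [("P", {}), ("A", {})], [(0, "t1", 1, "b")], "CP")
        assert len(match(pat, pa, DEFS)) == 1

    def test_compartment_constraint(self):
        pat = Pattern((PatternMol("A", ()),), compartment="PM")
        free = make_species(DEFS, [("A", {})], [], "CP")
        assert match(pat, free, DEFS) == []


class TestNetworkGeneration:
    def test_toy_fixture_matches_oracle(self, toy):
        """Species and reaction sets equal the enumerated oracle exactly."""
        fx, _parsed, net = toy
        assert {sp.label for sp in net.species} == fx.species
        assert len(net.reactions) == fx.n_reactions

    def test_molecule_conservation(self, toy):
        _fx, _parsed, net = toy
        net.check_molecule_conservation()

    def test_idempotence(self, toy):
        """Re-running generation from the full species set adds nothing."""
        _fx, parsed, net = toy
        net2 = generate_network(parsed.molecules, parsed.rules, net.species)
        assert {s.label for s in net2.species} == {s.label for s in net.species}
        assert len(net2.reactions) == len(net.reactions)

    def test_deterministic_tables(self, toy):
        fx, parsed, net = toy
        net2 = generate_network(
            parsed.molecules, parsed.rules, [s.species for s in parsed.seeds]
        )
        assert net.species_table() == net2.species_table()
        assert net.reaction_table() == net2.reaction_table()

    def test_symmetric_dimer_rate_convention(self):
        """A+A association carries the 1/2 factor; AA dissociation counts
        its one bond once despite the two automorphic embeddings."""
        fx = __import__("integrinsim.fixtures", fromlist=["x"]).generate_toy_fixture(
            "symmetric-dimer"
        )
        parsed = bngl.parse_model(fx.model_text)
        net = generate_network(
            parsed.molecules, parsed.rules, [s.species for s in parsed.seeds]
        )
        by_rule = {r.rule_id: r for r in net.reactions}
        assert by_rule["S1"].sym_factor == 0.5
        assert by_rule["S1"].multiplicity == 1
        assert by_rule["S1_r"].sym_factor == 1.0
        assert by_rule["S1_r"].multiplicity == 1

    def test_max_species_explosion_error(self):
        fx = __import__("integrinsim.fixtures", fromlist=["x"]).generate_toy_fixture(
            "dimer"
        )
        parsed = bngl.parse_model(fx.model_text)
        with pytest.raises(NetworkExplosionError) as err:
            generate_network(
                parsed.molecules, parsed.rules,
                [s.species for s in parsed.seeds], max_species=2,
            )
        assert err.value.last_rule


class TestParser:
    def test_rejects_unknown_block(self):
        with pytest.raises(bngl.ParseError, match="line 1"):
            bngl.parse_model("begin nonsense\nend nonsense\n")

    def test_rejects_two_transformations(self):
        text = """
begin molecule types
  A(x~u~p,y~u~p) @CP
end molecule types
begin reaction rules
  R1: A(x~u,y~u) -> A(x~p,y~p)  k
end reaction rules
"""
        with pytest.raises(bngl.ParseError, match="exactly one transformation"):
            bngl.parse_model(text)

    def test_rejects_dangling_bond(self):
        text = """
begin molecule types
  A(x) @CP
end molecule types
begin reaction rules
  R1: A(x) -> A(x!1)  k
end reaction rules
"""
        with pytest.raises(bngl.ParseError):
            bngl.parse_model(text)

    def test_seed_requires_full_state(self):
        text = """
begin molecule types
  A(x~u~p) @CP
end molecule types
begin seed species
  A(x)@CP  1.0
end seed species
"""
        with pytest.raises(bngl.ParseError, match="state"):
            bngl.parse_model(text)
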
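import itertools
from fractions import Fraction

import pytest

from qcfnet.cfengine import cf_table, quartet_cf
from qcfnet.fixtures import NamedNetworkSpec, make_named, random_params
from qcfnet.netmodel import (
    CFTable,
    CFVector,
    Edge,
    Network,
    NetworkError,
    add_pseudotaxa,
    defining_quartets,
    find_cycles,
    induced_network,
    induced_quartet_network,
    parse_network,
    quartet_key,
    replace_two_cycles,
    to_semidirected,
    write_network,
)

from conftest import tables_equal


class TestParseWrite:
    def test_parse_simple_tree(self):
        net = parse_network("((a:1.0,b:1.0):0.5,c:2.0);")
        assert net.rooted
        assert net.taxa == ["a", "b", "c"]
        assert len(net.edges) == 4
        assert not net.hybrid_nodes()

    def test_parse_hybrid_gamma_pair(self):
        s = "((a:1,(b:1)#H1:0.5::0.3):1,(#H1:0.6::0.7,c:1):1);"
        net = parse_network(s)
        hybs = net.hybrid_nodes()
        assert len(hybs) == 1
        gammas = sorted(e.gamma for e in net.hybrid_parent_edges(hybs[0]))
        assert gammas == [Fraction(3, 10), Fraction(7, 10)]

    def test_gamma_inferred_from_one_edge(self):
        s = "((a:1,(b:1)#H1:0.5::0.3):1,(#H1:0.6,c:1):1);"
        net = parse_network(s)
        hybs = net.hybrid_nodes()
        gammas = sorted(e.gamma for e in net.hybrid_parent_edges(hybs[0]))
        assert gammas == [Fraction(3, 10), Fraction(7, 10)]

    def test_gamma_pair_not_summing_errors(self):
        s = "((a:1,(b:1)#H1:0.5::0.3):1,(#H1:0.6::0.6,c:1):1);"
        with pytest.raises(NetworkError, match="gamma pair"):
            parse_network(s)

    def test_malformed_raises(self):
        with pytest.raises(NetworkError):
            parse_network("((a,b)")
        with pytest.raises(NetworkError):
            parse_network("((a,b),a);")  # duplicate taxon

    def test_round_trip_tree(self):
        net = parse_network("((a:1.0,b:1.0):0.5,c:2.0);")
        again = parse_network(write_network(net))
        assert again.taxa == net.taxa
        assert sorted(float(e.length) for e in again.edges if e.length is not None) == sorted(
            float(e.length) for e in net.edges if e.length is not None
        )

    def test_round_trip_network_preserves_gamma(self):
        net = make_named(random_params("Ns", seed=3))
        again = parse_network(write_network(net))
        assert sorted(again.leaves()) == sorted(net.leaves())
        g1 = sorted(float(e.gamma) for e in net.edges if e.kind == "hybrid")
        g2 = sorted(float(e.gamma) for e in again.edges if e.kind == "hybrid")
        assert g1 == pytest.approx(g2)
        assert [c.m for c in find_cycles(again)] == [4]

    def test_round_trip_two_cycle_not_simplified(self):
        edges = [
            Edge("r", "u"),
            Edge("r", "c"),
            Edge("u", "v", kind="hybrid", gamma=Fraction(1, 3), prob=Fraction(1, 2)),
            Edge("u", "v", kind="hybrid", gamma=Fraction(2, 3), prob=Fraction(3, 4)),
            Edge("v", "w"),
            Edge("w", "a"),
            Edge("w", "b"),
        ]
        net = Network(edges, rooted=True, root="r")
        again = parse_network(write_network(net))
        assert [c.m for c in find_cycles(again)] == [2]


class TestSemidirected:
    def test_tree_root_suppressed(self):
        net = parse_network("((a:1.0,b:1.0):0.5,c:2.0);")
        sd = to_semidirected(net)
        assert not sd.rooted
        # the two root-incident lengths merge: 0.5 + 2.0
        lengths = sorted(float(e.length) for e in sd.edges if e.length is not None)
        assert lengths[-1] == pytest.approx(2.5)

    def test_idempotent(self):
        net = make_named(random_params("Na", seed=5))
        sd = to_semidirected(net)
        sd2 = to_semidirected(sd)
        assert len(sd2.edges) == len(sd.edges)

    def test_structure_above_lsa_removed_cf_unchanged(self):
        # a chain and an extra dangling subdivision above the LSA
        spec = random_params("T5", seed=1)
        base = make_named(spec)
        t_base = cf_table(base)
        # re-root higher: new root with an extra edge above the old root
        edges = [e.copy() for e in base.edges]
        edges.append(Edge("_top", "_R", prob=Fraction(1, 2)))
        lifted = Network(edges, rooted=True, root="_top", validate=False)
        sd = to_semidirected(lifted)
        assert tables_equal(cf_table(sd), t_base)


class TestFindCycles:
    def test_tree_has_none(self):
        net = make_named(random_params("T6", seed=0))
        assert find_cycles(net) == []

    def test_ns_four_cycle_blocks(self):
        net = make_named(random_params("Ns", seed=0))
        recs = find_cycles(net)
        assert len(recs) == 1
        rec = recs[0]
        assert rec.m == 4
        assert rec.k == 2
        assert rec.hybrid_block == frozenset({"a1", "a2"})
        assert sorted(rec.block_sizes()) == [1, 1, 1, 2]

    def test_shared_node_not_level_one(self):
        # two triangles sharing node u
        g = Fraction(1, 2)
        edges = [
            Edge("r", "u"),
            Edge("r", "c"),
            Edge("u", "p1"),
            Edge("u", "p2"),
            Edge("p1", "h1", kind="hybrid", gamma=g),
            Edge("p2", "h1", kind="hybrid", gamma=1 - g),
            Edge("p1", "p2"),
            Edge("h1", "a"),
        ]
        # build a second cycle through u itself: p3/p4 both children of u
        edges += [
            Edge("u", "h2", kind="hybrid", gamma=g),
            Edge("p1", "h2", kind="hybrid", gamma=1 - g),
            Edge("h2", "b"),
        ]
        net = Network(edges, rooted=True, root="r", validate=False)
        with pytest.raises(NetworkError, match="level-1"):
            find_cycles(net)


class TestInducedNetworks:
    def test_tree_internal_length_sums(self):
        net = parse_network("(((a:1,b:1):1,(c:1,d:1):2):1,(e:1,f:1):1);")
        sub = induced_quartet_network(net, ("a", "c", "e", "f"))
        assert sorted(sub.leaves()) == ["a", "c", "e", "f"]
        vec = quartet_cf(sub)
        # split ac|ef has internal path of length 2 (1 + 1 up the spine)
        import math

        assert float(vec.cf("e", "f")) == pytest.approx(1 - 2 * math.exp(-2.0) / 3)

    def test_restriction_cf_consistency_na(self, na_net, na_table):
        q = ("a1", "a2", "b1", "c1")
        sub = induced_quartet_network(na_net, q)
        assert quartet_cf(sub) == na_table.get(q)
        assert [c.m for c in find_cycles(sub)] == [3]

    def test_ns_restriction_keeps_four_cycle(self, ns_net):
        sub = induced_network(ns_net, ("a1", "b", "c", "d"))
        recs = find_cycles(sub)
        assert [c.m for c in recs] == [4]
        assert recs[0].k == 1
        full = cf_table(ns_net)
        assert quartet_cf(sub) == full.get(("a1", "b", "c", "d"))


class TestReplaceTwoCycles:
    def _with_two_cycle(self, g, h1, h2):
        edges = [
            Edge("r", "u", prob=Fraction(1, 2)),
            Edge("r", "c"),
            Edge("u", "v", kind="hybrid", gamma=g, prob=h1),
            Edge("u", "v", kind="hybrid", gamma=1 - g, prob=h2),
            Edge("v", "w", prob=Fraction(2, 3)),
            Edge("w", "a"),
            Edge("w", "b"),
        ]
        return Network(edges, rooted=True, root="r")

    def test_half_and_half(self):
        net = self._with_two_cycle(Fraction(1, 2), Fraction(1, 3), Fraction(1, 3))
        out = replace_two_cycles(net)
        assert not [c for c in find_cycles(out) if c.m == 2]
        # 1 - l = (1-h)/2 with h = 1/3 -> l = 2/3; merged with neighbors 1/2, 2/3
        probs = [e.prob for e in out.edges if e.prob is not None]
        assert Fraction(1, 2) * Fraction(2, 3) * Fraction(2, 3) in probs

    def test_zero_length_pair_gives_identity_edge(self):
        net = self._with_two_cycle(Fraction(1, 4), 1, 1)
        out = replace_two_cycles(net)
        probs = [e.prob for e in out.edges if e.prob is not None]
        assert Fraction(1, 2) * Fraction(2, 3) in probs

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cf_table_preserved(self, seed):
        import random

        rng = random.Random(seed)

        def r():
            return Fraction(rng.randrange(1, 64), 64)

        g, h1, h2 = r(), r(), r()
        # embed the 2-cycle inside a 5-taxon tree so there are >= 4 taxa
        edges = [
            Edge("r", "u", prob=r()),
            Edge("r", "q"),
            Edge("q", "c"),
            Edge("q", "e"),
            Edge("u", "v", kind="hybrid", gamma=g, prob=h1),
            Edge("u", "v", kind="hybrid", gamma=1 - g, prob=h2),
            Edge("v", "w", prob=r()),
            Edge("w", "a"),
            Edge("w", "x"),
            Edge("x", "b"),
            Edge("x", "d"),
        ]
        for e in edges:
            if e.u == "x":
                pass
        net = Network(edges, rooted=True, root="r", validate=False)
        out = replace_two_cycles(net)
        assert tables_equal(cf_table(net), cf_table(out))


class TestPseudotaxa:
    def test_cherry_attached(self):
        net = make_named(random_params("T5", seed=0))
        out = add_pseudotaxa(net, "c", 2)
        assert "c.1" in out.leaves() and "c.2" in out.leaves()
        assert "c" not in out.leaves()

    def test_k1_identity(self):
        net = make_named(random_params("T5", seed=0))
        out = add_pseudotaxa(net, "c", 1)
        assert sorted(out.leaves()) == sorted(net.leaves())

    def test_triple_gives_uniform_cfs(self):
        net = make_named(random_params("T5", seed=0))
        table = cf_table(net, samples={"c": 3})
        third = Fraction(1, 3)
        for other in ("a1", "a2", "b1", "b2"):
            vec = table.get(("c.1", "c.2", "c.3", other))
            assert tuple(vec.values) == (third, third, third)

    def test_unknown_taxon(self):
        net = make_named(random_params("T5", seed=0))
        with pytest.raises(NetworkError):
            add_pseudotaxa(net, "zz", 2)


class TestDefiningQuartets:
    def test_tree_internal_edges_defined(self):
        net = parse_network("(((a:1,b:1):1,(c:1,d:1):1):1,(e:1,f:1):1);")
        internal = [e for e in net.edges if not net.is_pendant(e)]
        for e in internal:
            if e.u == net.root or e.v == net.root:
                continue
            dq = defining_quartets(net, e, first_only=True)
            assert dq, f"edge {e.u}->{e.v} should be defined by some quartet"

    def test_hybrid_edges_not_defined(self, ns_net):
        for e in ns_net.edges:
            if e.kind == "hybrid":
                dq = defining_quartets(ns_net, e)
                assert dq == []

    def test_sunlet_five_matches_characterization(self):
        """An internal edge is defined by a quartet iff it is neither hybrid
        nor adjacent to a hybrid edge (checked exhaustively)."""
        net = make_named(random_params("sunlet(5)", seed=1))
        sd = to_semidirected(net)
        for e in sd.edges:
            if sd.is_pendant(e):
                continue
            adjacent_hybrid = e.kind == "hybrid" or any(
                x.kind == "hybrid"
                for n in e.nodes()
                for x in sd.incident(n)
                if x.eid != e.eid
            )
            dq = defining_quartets(sd, e)
            if adjacent_hybrid:
                assert dq == []
            else:
                assert dq

    def test_pendant_errors(self, ns_net):
        pend = next(e for e in ns_net.edges if ns_net.is_pendant(e))
        with pytest.raises(NetworkError):
            defining_quartets(ns_net, pend)


class TestCFTableContainers:
    def test_quartet_key_validation(self):
        with pytest.raises(NetworkError):
            quartet_key(("a", "a", "b", "c"))

    def test_cfvector_lookup(self):
        vec = CFVector(("d", "a", "c", "b"), (Fraction(1, 2), Fraction(1, 4), Fraction(1, 4)))
        assert vec.taxa == ("a", "b", "c", "d")
        assert vec.cf("a", "b") == Fraction(1, 2)
        assert vec.cf("c", "d") == Fraction(1, 2)
        assert vec.cf("a", "d") == Fraction(1, 4)

    def test_csv_round_trip_exact(self, tmp_path, na_table):
        path = tmp_path / "cf.csv"
        na_table.to_csv(path, exact=True)
        again = CFTable.from_csv(path)
        assert tables_equal(na_table, again)

    def test_csv_reorders_noncanonical_rows(self, tmp_path):
        path = tmp_path / "cf.csv"
        path.write_text(
            "taxon1,taxon2,taxon3,taxon4,CF12_34,CF13_24,CF14_23\n"
            "d,c,b,a,1/2,1/4,1/4\n"
        )
        table = CFTable.from_csv(path)
        vec = table.get(("a", "b", "c", "d"))
        # pair (d,c) in original = pair (c,d) canonical -> split ab|cd
        assert vec.cf("c", "d") == Fraction(1, 2)
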
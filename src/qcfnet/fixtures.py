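"""Generators for the named study networks and random parameter draws.

Every generator returns a rooted :class:`~qcfnet.netmodel.Network` whose
edges carry exact edge *probabilities* (``l = exp(-t)``) so that downstream
CF computations are exact for rational or symbolic inputs.  The returned
network has a ``roles`` attribute mapping each named numerical parameter to
the edge id carrying it, so recovery tests can match estimates to truth.

Pendant edges (and hybrid edges that can never carry two lineages) get no
metric annotation, mirroring the convention that parameters which cannot
appear in CF formulas are left unlabeled.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Any, Dict, List, Optional, Sequence, Tuple

from .netmodel import Edge, Network, NetworkError

__all__ = [
    "NamedNetworkSpec",
    "NETWORK_CATALOG",
    "make_named",
    "random_params",
    "example_4cherry_pair",
    "three_cycle_block_fragment",
    "three_cycle_template",
    "four_cycle_template",
]


@dataclass
class NamedNetworkSpec:
    """A catalog network name plus its parameter map."""

    name: str
    params: Dict[str, Any] = field(default_factory=dict)


def _net(edges: List[Edge], root, roles: Dict[str, int]) -> Network:
    net = Network(edges, rooted=True, root=root, validate=True)
    net.roles = roles  # type: ignore[attr-defined]
    return net


def _caterpillar(anchor, prefix, n, p, roles, cut_role) -> List[Edge]:
    """Attach taxa prefix1..prefixN below ``anchor`` as a caterpillar.

    The cut edge (anchor to block) takes probability ``p[cut_role]`` if
    present; internal caterpillar edges take ``p[f"{cut_role}_{i}"]``.
    """
    if n == 1:
        return [Edge(anchor, f"{prefix}1")]
    edges: List[Edge] = []
    top = Edge(anchor, f"_{prefix}x0", prob=p.get(cut_role))
    if cut_role in p:
        roles[cut_role] = top.eid
    edges.append(top)
    cur = f"_{prefix}x0"
    for i in range(1, n - 1):
        edges.append(Edge(cur, f"{prefix}{i}"))
        nxt = f"_{prefix}x{i}"
        key = f"{cut_role}_{i + 1}"
        inner = Edge(cur, nxt, prob=p.get(key))
        if key in p:
            roles[key] = inner.eid
        edges.append(inner)
        cur = nxt
    edges.append(Edge(cur, f"{prefix}{n - 1}"))
    edges.append(Edge(cur, f"{prefix}{n}"))
    return edges


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def _make_t5(p):
    roles: Dict[str, int] = {}
    edges = [Edge("_R", "c"), Edge("_R", "_z")]
    e1 = Edge("_z", "_u", prob=p["l1"])
    e2 = Edge("_z", "_v", prob=p["l2"])
    roles["l1"], roles["l2"] = e1.eid, e2.eid
    edges += [e1, e2]
    edges += [Edge("_u", "a1"), Edge("_u", "a2"), Edge("_v", "b1"), Edge("_v", "b2")]
    return _net(edges, "_R", roles)


def _make_t6(p):
    roles: Dict[str, int] = {}
    edges = [Edge("_R", "_w"), Edge("_R", "_z")]
    e3 = edges[0]
    e3.prob = p["l3"]
    roles["l3"] = e3.eid
    e1 = Edge("_z", "_u", prob=p["l1"])
    e2 = Edge("_z", "_v", prob=p["l2"])
    roles["l1"], roles["l2"] = e1.eid, e2.eid
    edges += [e1, e2]
    for node, pre in (("_u", "a"), ("_v", "b"), ("_w", "c")):
        edges += [Edge(node, f"{pre}1"), Edge(node, f"{pre}2")]
    return _net(edges, "_R", roles)


# ---------------------------------------------------------------------------
# 5-taxon 3-cycle networks
# ---------------------------------------------------------------------------

def _make_n5_31(p):
    roles: Dict[str, int] = {}
    # root on the cut edge toward the a cherry, keeping the 3-cycle intact
    e1 = Edge("_Z", "_u", prob=p["l1"])
    roles["l1"] = e1.eid
    edges = [e1, Edge("_Z", "_PA", prob=1)]
    ex = Edge("_PA", "_PB", prob=p["x"])
    roles["x"] = ex.eid
    h1 = Edge("_PA", "_H", kind="hybrid", gamma=p["gamma"])
    h2 = Edge("_PB", "_H", kind="hybrid", gamma=1 - p["gamma"])
    roles["gamma"] = h1.eid
    edges += [ex, h1, h2, Edge("_H", "c")]
    e2 = Edge("_PB", "_v", prob=p["l2"])
    roles["l2"] = e2.eid
    edges += [e2]
    edges += [Edge("_u", "a1"), Edge("_u", "a2"), Edge("_v", "b1"), Edge("_v", "b2")]
    return _net(edges, "_Z", roles)


def _make_n5_32(p, swap_ab: bool = False):
    roles: Dict[str, int] = {}
    # root on the cut edge toward the b cherry, keeping the 3-cycle intact
    e2 = Edge("_Z", "_v", prob=p["l2"])
    roles["l2"] = e2.eid
    edges = [e2, Edge("_Z", "_PB", prob=1)]
    ex = Edge("_PB", "_PC", prob=p["x"])
    roles["x"] = ex.eid
    h1 = Edge("_PB", "_H", kind="hybrid", gamma=p["gamma"], prob=p["h1"])
    h2 = Edge("_PC", "_H", kind="hybrid", gamma=1 - p["gamma"], prob=p["h2"])
    roles["gamma"], roles["h1"], roles["h2"] = h1.eid, h1.eid, h2.eid
    edges += [ex, h1, h2]
    e1 = Edge("_H", "_u", prob=p["l1"])
    roles["l1"] = e1.eid
    edges += [e1, Edge("_PC", "c")]
    apre, bpre = ("b", "a") if swap_ab else ("a", "b")
    edges += [Edge("_u", f"{apre}1"), Edge("_u", f"{apre}2"), Edge("_v", f"{bpre}1"), Edge("_v", f"{bpre}2")]
    return _net(edges, "_Z", roles)


# ---------------------------------------------------------------------------
# 6-taxon 3-cycle networks (three cherries)
# ---------------------------------------------------------------------------

def _make_na(p, rotation: int = 0):
    """The 3-cycle with three cherries; rotation moves the hybrid block."""
    roles: Dict[str, int] = {}
    # root sits on the cut edge toward the c cherry
    e3 = Edge("_Z", "_w", prob=p["l3"])
    roles["l3"] = e3.eid
    edges = [e3, Edge("_Z", "_PC", prob=1)]
    ex = Edge("_PB", "_PC", prob=p["x"])
    roles["x"] = ex.eid
    # orientation: _PC -> _PB around the cycle
    ex.u, ex.v = "_PC", "_PB"
    h1 = Edge("_PB", "_H", kind="hybrid", gamma=p["gamma"], prob=p["h1"])
    h2 = Edge("_PC", "_H", kind="hybrid", gamma=1 - p["gamma"], prob=p["h2"])
    roles["gamma"], roles["h1"], roles["h2"] = h1.eid, h1.eid, h2.eid
    edges += [ex, h1, h2]
    e1 = Edge("_H", "_u", prob=p["l1"])
    e2 = Edge("_PB", "_v", prob=p["l2"])
    roles["l1"], roles["l2"] = e1.eid, e2.eid
    edges += [e1, e2]
    pres = ["a", "b", "c"]
    rot = {pres[i]: pres[(i + rotation) % 3] for i in range(3)}
    for node, pre in (("_u", rot["a"]), ("_v", rot["b"]), ("_w", rot["c"])):
        edges += [Edge(node, f"{pre}1"), Edge(node, f"{pre}2")]
    return _net(edges, "_Z", roles)


# ---------------------------------------------------------------------------
# 5- and 6-taxon 4-cycle networks
# ---------------------------------------------------------------------------

def _four_cycle_core(p, with_h: bool):
    """Cycle S(hybrid), W, N, E rooted above N; returns (edges, roles)."""
    roles: Dict[str, int] = {}
    x1 = Edge("_N", "_W", prob=p["x1"])
    x2 = Edge("_N", "_E", prob=p["x2"])
    roles["x1"], roles["x2"] = x1.eid, x2.eid
    h1 = Edge("_W", "_S", kind="hybrid", gamma=p["gamma"], prob=p.get("h1"))
    h2 = Edge("_E", "_S", kind="hybrid", gamma=1 - p["gamma"], prob=p.get("h2"))
    roles["gamma"] = h1.eid
    if with_h:
        roles["h1"], roles["h2"] = h1.eid, h2.eid
    return [x1, x2, h1, h2], roles


def _make_ns(p):
    edges, roles = _four_cycle_core(p, with_h=True)
    el = Edge("_S", "_u", prob=p["l"])
    roles["l"] = el.eid
    edges += [el, Edge("_u", "a1"), Edge("_u", "a2")]
    edges += [Edge("_W", "b"), Edge("_E", "d")]
    edges += [Edge("_R", "c"), Edge("_R", "_N")]
    return _net(edges, "_R", roles)


def _make_nw(p):
    edges, roles = _four_cycle_core(p, with_h=False)
    el = Edge("_W", "_u", prob=p["l"])
    roles["l"] = el.eid
    edges += [el, Edge("_u", "a1"), Edge("_u", "a2")]
    edges += [Edge("_S", "b"), Edge("_E", "d")]
    edges += [Edge("_R", "c"), Edge("_R", "_N")]
    return _net(edges, "_R", roles)


def _make_nn(p):
    # cherry opposite the hybrid node; rooted on the W pendant edge, so the
    # cycle tree edges run W->N and N->E
    roles: Dict[str, int] = {}
    x1 = Edge("_W", "_N", prob=p["x1"])
    x2 = Edge("_N", "_E", prob=p["x2"])
    roles["x1"], roles["x2"] = x1.eid, x2.eid
    h1 = Edge("_W", "_S", kind="hybrid", gamma=p["gamma"])
    h2 = Edge("_E", "_S", kind="hybrid", gamma=1 - p["gamma"])
    roles["gamma"] = h1.eid
    el = Edge("_N", "_u", prob=p["l"])
    roles["l"] = el.eid
    edges = [x1, x2, h1, h2, el, Edge("_u", "a1"), Edge("_u", "a2")]
    edges += [Edge("_S", "b"), Edge("_E", "d")]
    edges += [Edge("_R", "c"), Edge("_R", "_W")]
    return _net(edges, "_R", roles)


def _make_nsw(p):
    edges, roles = _four_cycle_core(p, with_h=True)
    e1 = Edge("_S", "_u", prob=p["l1"])
    e2 = Edge("_W", "_v", prob=p["l2"])
    roles["l1"], roles["l2"] = e1.eid, e2.eid
    edges += [e1, e2]
    edges += [Edge("_u", "a1"), Edge("_u", "a2"), Edge("_v", "b1"), Edge("_v", "b2")]
    edges += [Edge("_E", "d"), Edge("_R", "c"), Edge("_R", "_N")]
    return _net(edges, "_R", roles)


def _make_nsn(p):
    edges, roles = _four_cycle_core(p, with_h=True)
    e1 = Edge("_S", "_u", prob=p["l1"])
    roles["l1"] = e1.eid
    edges += [e1, Edge("_u", "a1"), Edge("_u", "a2")]
    # cherry above the cycle: root on the N cut edge, cherry beyond it
    e2 = Edge("_R", "_v", prob=p["l2"])
    roles["l2"] = e2.eid
    edges += [e2, Edge("_v", "b1"), Edge("_v", "b2")]
    edges += [Edge("_W", "c"), Edge("_E", "d"), Edge("_R", "_N")]
    return _net(edges, "_R", roles)


def _make_sunlet(k: int):
    def build(p):
        roles: Dict[str, int] = {}
        names = [chr(ord("a") + i) for i in range(k)]
        cyc = [f"_n{i}" for i in range(k)]
        edges: List[Edge] = []
        h1 = Edge(cyc[1], cyc[0], kind="hybrid", gamma=p["gamma"], prob=p.get("h1"))
        h2 = Edge(cyc[k - 1], cyc[0], kind="hybrid", gamma=1 - p["gamma"], prob=p.get("h2"))
        roles["gamma"] = h1.eid
        if "h1" in p:
            roles["h1"], roles["h2"] = h1.eid, h2.eid
        edges += [h1, h2]
        for i in range(1, k - 1):
            # orient away from the root, which sits above cycle node 2
            if i + 1 <= 2:
                e = Edge(cyc[i + 1], cyc[i], prob=p[f"x{i}"])
            else:
                e = Edge(cyc[i], cyc[i + 1], prob=p[f"x{i}"])
            roles[f"x{i}"] = e.eid
            edges.append(e)
        edges.append(Edge(cyc[0], names[0]))
        for i in range(1, k):
            if i == 2:
                continue
            edges.append(Edge(cyc[i], names[i]))
        # root on the pendant edge of the taxon at cycle node 2
        edges += [Edge("_R", names[2]), Edge("_R", cyc[2])]
        return _net(edges, "_R", roles)

    return build


def _make_twin_l(p):
    roles: Dict[str, int] = {}
    em = Edge("_Z", "_PL1", prob=p["l"])
    roles["l"] = em.eid
    edges = [em, Edge("_Z", "_PR1", prob=1)]
    for side, (hx, tx1, tx2, hybname, blocks) in {
        "L": ("_HL", "_PL2", "_PL3", "gl", ("a", "b", "f")),
        "R": ("_HR", "_PR2", "_PR3", "gr", ("d", "c", "e")),
    }.items():
        p1 = f"_P{side}1"
        g = p[hybname]
        h1 = Edge(p1, hx, kind="hybrid", gamma=g)
        h2 = Edge(tx2, hx, kind="hybrid", gamma=1 - g)
        roles[hybname] = h1.eid
        xa = Edge(p1, tx1, prob=p[f"x{side.lower()}1"])
        xb = Edge(tx1, tx2, prob=p[f"x{side.lower()}2"])
        roles[f"x{side.lower()}1"], roles[f"x{side.lower()}2"] = xa.eid, xb.eid
        hybt, opp, third = blocks
        edges += [h1, h2, xa, xb, Edge(hx, hybt), Edge(tx1, opp), Edge(tx2, third)]
    return _net(edges, "_Z", roles)


def _make_twin_r(p, mirror: bool = False):
    roles: Dict[str, int] = {}
    # left 4-cycle rooted above PL2; its hybrid's child edge q leads into the
    # right 4-cycle at the node PR1 adjacent to the right hybrid edge.
    edges = [Edge("_R", "c"), Edge("_R", "_PL2")]
    xl1 = Edge("_PL2", "_PL1", prob=p["xl1"])
    xl2 = Edge("_PL2", "_PL3", prob=p["xl2"])
    roles["xl1"], roles["xl2"] = xl1.eid, xl2.eid
    hl1 = Edge("_PL1", "_HL", kind="hybrid", gamma=p["gl"], prob=p["hl1"])
    hl2 = Edge("_PL3", "_HL", kind="hybrid", gamma=1 - p["gl"], prob=p["hl2"])
    roles["gl"], roles["hl1"], roles["hl2"] = hl1.eid, hl1.eid, hl2.eid
    q = Edge("_HL", "_PR1", prob=p["l"])
    roles["l"] = q.eid
    edges += [xl1, xl2, hl1, hl2, q, Edge("_PL1", "b"), Edge("_PL3", "f")]
    xr1 = Edge("_PR1", "_PR2", prob=p["xr1"])
    xr2 = Edge("_PR2", "_PR3", prob=p["xr2"])
    roles["xr1"], roles["xr2"] = xr1.eid, xr2.eid
    hr1 = Edge("_PR1", "_HR", kind="hybrid", gamma=p["gr"])
    hr2 = Edge("_PR3", "_HR", kind="hybrid", gamma=1 - p["gr"])
    roles["gr"] = hr1.eid
    edges += [xr1, xr2, hr1, hr2, Edge("_HR", "a"), Edge("_PR2", "d"), Edge("_PR3", "e")]
    net = _net(edges, "_R", roles)
    if mirror:
        net = _relabel(net, {"a": "f", "f": "a", "b": "e", "e": "b", "c": "d", "d": "c"})
        net.roles = roles  # type: ignore[attr-defined]
    return net


def _relabel(net: Network, mapping: Dict[str, str]) -> Network:
    edges = []
    for e in net.edges:
        edges.append(e.copy(u=mapping.get(e.u, e.u), v=mapping.get(e.v, e.v)))
    out = Network(edges, rooted=net.rooted, root=net.root, validate=False)
    return out


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

def four_cycle_template(sizes: Tuple[int, int, int, int], p: Dict[str, Any]) -> Network:
    """A 4-cycle with caterpillar blocks of the given sizes (A = hybrid)."""
    nA, nB, nC, nD = sizes
    roles: Dict[str, int] = {}
    x1 = Edge("_N", "_W", prob=p["x1"])
    x2 = Edge("_N", "_E", prob=p["x2"])
    roles["x1"], roles["x2"] = x1.eid, x2.eid
    h1 = Edge("_W", "_S", kind="hybrid", gamma=p["gamma"], prob=p.get("h1"))
    h2 = Edge("_E", "_S", kind="hybrid", gamma=1 - p["gamma"], prob=p.get("h2"))
    roles["gamma"] = h1.eid
    if "h1" in p:
        roles["h1"], roles["h2"] = h1.eid, h2.eid
    edges = [x1, x2, h1, h2]
    edges += _caterpillar("_S", "a", nA, p, roles, "l")
    edges += _caterpillar("_W", "b", nB, p, roles, "lB")
    edges += _caterpillar("_E", "d", nD, p, roles, "lD")
    # root within block C, above the top cycle node
    edges.append(Edge("_R", "_N"))
    edges += _caterpillar("_R", "c", nC, p, roles, "lC")
    return _net(edges, "_R", roles)


def three_cycle_template(sizes: Tuple[int, int, int], p: Dict[str, Any]) -> Network:
    """A 3-cycle with caterpillar blocks (A = hybrid block, root in C)."""
    nA, nB, nC = sizes
    roles: Dict[str, int] = {}
    ex = Edge("_PC", "_PB", prob=p["x"])
    roles["x"] = ex.eid
    h1 = Edge("_PB", "_H", kind="hybrid", gamma=p["gamma"], prob=p.get("h1"))
    h2 = Edge("_PC", "_H", kind="hybrid", gamma=1 - p["gamma"], prob=p.get("h2"))
    roles["gamma"] = h1.eid
    if "h1" in p:
        roles["h1"], roles["h2"] = h1.eid, h2.eid
    edges = [ex, h1, h2]
    edges += _caterpillar("_H", "a", nA, p, roles, "l1")
    edges += _caterpillar("_PB", "b", nB, p, roles, "l2")
    # block C hangs above the root; the exit cut edge carries l3
    e3 = Edge("_Z", "_PC", prob=p.get("l3"))
    if "l3" in p:
        roles["l3"] = e3.eid
    edges.append(e3)
    edges += _caterpillar("_Z", "c", nC, p, roles, "lC")
    return _net(edges, "_Z", roles)


def three_cycle_block_fragment(gamma, l1, l2, l3, h1, h2, x) -> Network:
    """The isolated 3-cycle block D with ports 'a', 'b' and exit at its root.

    Matches the role conventions of :func:`qcfnet.cfengine.p_vector`.
    """
    ex = Edge("_PC", "_PB", prob=x)
    e1 = Edge("_H", "a", prob=l1)
    e2 = Edge("_PB", "b", prob=l2)
    e3 = Edge("_X", "_PC", prob=l3)
    hb = Edge("_PB", "_H", kind="hybrid", gamma=gamma, prob=h1)
    hc = Edge("_PC", "_H", kind="hybrid", gamma=1 - gamma, prob=h2)
    return Network([ex, e1, e2, e3, hb, hc], rooted=True, root="_X", validate=False)


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

NETWORK_CATALOG: Dict[str, Tuple[Tuple[str, ...], Any]] = {
    "T5": (("l1", "l2"), _make_t5),
    "N5-31": (("gamma", "x", "l1", "l2"), _make_n5_31),
    "N5-32": (("gamma", "h1", "h2", "x", "l1", "l2"), _make_n5_32),
    "N5-32p": (("gamma", "h1", "h2", "x", "l1", "l2"), lambda p: _make_n5_32(p, swap_ab=True)),
    "T6": (("l1", "l2", "l3"), _make_t6),
    "Na": (("gamma", "h1", "h2", "x", "l1", "l2", "l3"), _make_na),
    "Nb": (("gamma", "h1", "h2", "x", "l1", "l2", "l3"), lambda p: _make_na(p, rotation=1)),
    "Nc": (("gamma", "h1", "h2", "x", "l1", "l2", "l3"), lambda p: _make_na(p, rotation=2)),
    "N6-32": (("gamma", "h1", "h2", "x", "l1", "l2", "l3"), _make_na),
    "Ns": (("gamma", "h1", "h2", "x1", "x2", "l"), _make_ns),
    "Nw": (("gamma", "x1", "x2", "l"), _make_nw),
    "Nn": (("gamma", "x1", "x2", "l"), _make_nn),
    "Nsw": (("gamma", "h1", "h2", "x1", "x2", "l1", "l2"), _make_nsw),
    "Nsn": (("gamma", "h1", "h2", "x1", "x2", "l1", "l2"), _make_nsn),
    "twin4cycles-L": (("gl", "xl1", "xl2", "gr", "xr1", "xr2", "l"), _make_twin_l),
    "twin4cycles-R": (("gl", "hl1", "hl2", "xl1", "xl2", "gr", "xr1", "xr2", "l"), _make_twin_r),
    "twin4cycles-C": (
        ("gl", "hl1", "hl2", "xl1", "xl2", "gr", "xr1", "xr2", "l"),
        lambda p: _make_twin_r(p, mirror=True),
    ),
}
for _k in (5, 6, 7, 8):
    NETWORK_CATALOG[f"sunlet({_k})"] = (
        ("gamma",) + tuple(f"x{i}" for i in range(1, _k - 1)),
        _make_sunlet(_k),
    )


def make_named(spec: NamedNetworkSpec) -> Network:
    """Instantiate a catalog network; parameter keys must match exactly."""
    if spec.name == "fig14-template":
        raise NetworkError("use four_cycle_template(sizes, params) directly")
    if spec.name not in NETWORK_CATALOG:
        raise NetworkError(f"unknown network name {spec.name!r}")
    keys, builder = NETWORK_CATALOG[spec.name]
    got = set(spec.params)
    want = set(keys)
    optional = {"h1", "h2"} if spec.name.startswith("sunlet") else set()
    if got - want - optional or want - got:
        raise NetworkError(
            f"{spec.name}: expected parameters {sorted(want)}, got {sorted(got)}"
        )
    return builder(spec.params)


def random_params(name: str, seed: int, bounds: Tuple[Any, Any] = (Fraction(1, 10), Fraction(9, 10))) -> NamedNetworkSpec:
    """Seeded uniform dyadic-rational parameters for a catalog network."""
    if name not in NETWORK_CATALOG:
        raise NetworkError(f"unknown network name {name!r}")
    lo, hi = Fraction(bounds[0]), Fraction(bounds[1])
    rng = random.Random(seed)
    denom = 2 ** 12
    lo_n = int(lo * denom) + 1
    hi_n = int(hi * denom)
    keys, _ = NETWORK_CATALOG[name]
    params = {k: Fraction(rng.randrange(lo_n, hi_n + 1), denom) for k in keys}
    return NamedNetworkSpec(name, params)


# ---------------------------------------------------------------------------
# The indistinguishable cherry-rotation pair
# ---------------------------------------------------------------------------

def example_4cherry_pair() -> Tuple[Network, Network]:
    """Two 6-taxon 3-cycle networks with different hybrid cherries but
    identical CF tables.

    The first carries the reference rational parameters; the second's
    parameters are solved exactly from the six block probabilities with its
    ``l2`` pinned to 1/2, realizing the infinite-to-one fiber of the block
    parameterization.
    """
    from .cfengine import p_vector

    pa = {
        "gamma": Fraction(28, 100),
        "h1": Fraction(83, 100),
        "h2": Fraction(78, 100),
        "x": Fraction(98, 100),
        "l1": Fraction(88, 100),
        "l2": Fraction(61, 100),
        "l3": Fraction(50, 100),
    }
    na = make_named(NamedNetworkSpec("Na", pa))
    p = p_vector(pa["gamma"], pa["l1"], pa["l2"], pa["l3"], pa["h1"], pa["h2"], pa["x"])
    p1, p2, p3, p4, p5, p6 = p
    # target block probabilities for the rotated network (hybrid cherry = b):
    # its six observable CFs must equal those of the reference network.
    q1 = 1 - 3 * p5
    q2 = 1 - 3 * p6
    q3 = p2
    q4 = (1 - p1) / 3
    q5 = p4
    q6 = (1 - p3) / 3
    l2b = Fraction(1, 2)
    A = 3 * q4 / l2b          # gamma + (1-gamma) x
    B = 1 - q1                # l3 (1 - gamma + gamma x)
    C = (1 - q3) / l2b        # x l3
    xb = C * (1 - A) / (B - C)
    gb = (A - xb) / (1 - xb)
    l3b = C / xb
    # linear system in u = l1 h1, w = l1, v = l1 h2
    g1, g2 = gb, 1 - gb
    rows = [
        (g1 * g1, g1 * g2 * (3 - xb), g2 * g2, 3 * q5),
        (g1 * g1 * l2b, 2 * g1 * g2 * l2b, g2 * g2 * xb * l2b, 3 * q6),
        (g1 * g1 * xb * l3b, 2 * g1 * g2 * l3b, g2 * g2 * l3b, 1 - q2),
    ]
    u, w, v = _solve3(rows)
    pb = {
        "gamma": gb,
        "h1": u / w,
        "h2": v / w,
        "x": xb,
        "l1": w,
        "l2": l2b,
        "l3": l3b,
    }
    nb = make_named(NamedNetworkSpec("Nb", pb))
    return na, nb


def _solve3(rows):
    """Solve a 3x3 rational linear system given as rows (a, b, c, rhs)."""
    m = [[Fraction(x) for x in r] for r in rows]

    def det3(a):
        return (
            a[0][0] * (a[1][1] * a[2][2] - a[1][2] * a[2][1])
            - a[0][1] * (a[1][0] * a[2][2] - a[1][2] * a[2][0])
            + a[0][2] * (a[1][0] * a[2][1] - a[1][1] * a[2][0])
        )

    base = [[m[i][j] for j in range(3)] for i in range(3)]
    d = det3(base)
    sols = []
    for j in range(3):
        mat = [[m[i][k] if k != j else m[i][3] for k in range(3)] for i in range(3)]
        sols.append(det3(mat) / d)
    return tuple(sols)
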
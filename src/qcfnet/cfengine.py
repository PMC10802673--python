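"""Exact quartet concordance factors under the coalescent on level-1 networks.

The computation is a dynamic program over a rooted realization of the
network, tracing the four sampled lineages backward in time.  Two facts
drive it: the first coalescent event among the four lineages determines the
gene quartet, and once three or more of them reach a common point without a
prior coalescence each quartet topology has conditional probability 1/3 by
exchangeability.  Consequently an *unresolved* state always consists of the
four original lineages, each at some node of the network, with at most two
per node; an edge is traversed by at most two lineages at a time, which
either coalesce on it (probability ``1 - l``) or both survive it
(probability ``l = exp(-t)``).

All arithmetic is generic: rational inputs give exact rational CFs,
symbolic inputs give polynomial CFs in the edge probabilities and
inheritance parameters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Any, Dict, FrozenSet, Iterable, List, Optional, Tuple

from .netmodel import (
    CFTable,
    CFVector,
    CycleRecord,
    Edge,
    Network,
    NetworkError,
    expand_samples,
    find_cycles,
    induced_quartet_network,
    quartet_key,
    rooted_version,
)

Pair = FrozenSet[str]


# ---------------------------------------------------------------------------
# Lineage configurations and resolution outcomes
# ---------------------------------------------------------------------------

@dataclass
class LineageConfig:
    """Placement of sampled lineages at network nodes (all unresolved)."""

    placement: Tuple[Tuple[str, Any], ...]  # sorted (sample, node) pairs

    @classmethod
    def at(cls, mapping: Dict[str, Any]) -> "LineageConfig":
        return cls(tuple(sorted(mapping.items(), key=lambda kv: kv[0])))

    def samples_at(self, node: Any) -> List[str]:
        return [s for s, n in self.placement if n == node]

    def move(self, moves: Dict[str, Any]) -> "LineageConfig":
        return LineageConfig(
            tuple(sorted(((s, moves.get(s, n)) for s, n in self.placement), key=lambda kv: kv[0]))
        )

    def __hash__(self):
        return hash(self.placement)

    def __eq__(self, other):
        return isinstance(other, LineageConfig) and self.placement == other.placement


@dataclass
class ResolutionProbs:
    """Outcome distribution of a network fragment, conditioned on distinct entry.

    ``coal_first[{x,y}]`` is the probability that the first coalescence in
    the fragment joins samples x and y (which then determines the quartet
    ``xy|zw``).  ``uniform`` is the probability that three or more lineages
    reach a common node first, after which each quartet has probability 1/3.
    ``undetermined`` is the mass exiting the fragment with no event.
    """

    coal_first: Dict[Pair, Any] = field(default_factory=dict)
    uniform: Any = 0
    undetermined: Any = 0

    def resolve(self, x: str, y: str, z: str, w: str) -> Any:
        """P(the fragment ensures the quartet xy|zw forms)."""
        return (
            self.coal_first.get(frozenset((x, y)), 0)
            + self.coal_first.get(frozenset((z, w)), 0)
            + self.uniform * Fraction(1, 3)
        )

    def total(self) -> Any:
        return sum(self.coal_first.values()) + self.uniform + self.undetermined


# ---------------------------------------------------------------------------
# The core dynamic program
# ---------------------------------------------------------------------------

def _topo_nodes(net: Network) -> List[Any]:
    """Nodes ordered children-before-parents (leaves first, root last)."""
    indeg = {n: len(net.parent_edges(n)) for n in net.nodes}
    outdeg = {n: len(net.children_edges(n)) for n in net.nodes}
    order = []
    ready = sorted((n for n in net.nodes if outdeg[n] == 0), key=str)
    remaining_children = dict(outdeg)
    while ready:
        n = ready.pop()
        order.append(n)
        for e in net.parent_edges(n):
            remaining_children[e.u] -= 1
            if remaining_children[e.u] == 0:
                ready.append(e.u)
    if len(order) != len(net.nodes):
        raise NetworkError("network is not acyclic as directed")
    return order


def _lineage_dp(net: Network, initial: Dict[str, Any], exit_is_boundary: bool) -> ResolutionProbs:
    """Trace lineages bottom-up; see module docstring for the state logic.

    ``initial`` maps sample labels to starting nodes.  If
    ``exit_is_boundary`` is true, lineages surviving to the root exit
    undetermined; otherwise the root is an ancestral population in which
    any remaining lineages meet (the whole-network case).
    """
    res = ResolutionProbs()
    third = Fraction(1, 3)
    states: Dict[LineageConfig, Any] = {LineageConfig.at(initial): Fraction(1)}
    for v in _topo_nodes(net):
        if not states:
            break
        parents = net.parent_edges(v)
        at_root = not parents
        new_states: Dict[LineageConfig, Any] = {}

        def put(cfg: LineageConfig, mass: Any) -> None:
            new_states[cfg] = new_states.get(cfg, 0) + mass

        for cfg, mass in states.items():
            here = cfg.samples_at(v)
            if len(here) >= 3:
                res.uniform += mass
                continue
            if at_root:
                if not here:
                    put(cfg, mass)
                    continue
                if exit_is_boundary:
                    put(cfg, mass)  # survivors exit; resolved at the very end
                    continue
                # ancestral population above the root: lineages elsewhere are
                # impossible in a whole-network run, so <=2 here means <=2 alive
                if len(here) == 2:
                    res.coal_first[frozenset(here)] = (
                        res.coal_first.get(frozenset(here), 0) + mass
                    )
                else:
                    res.undetermined += mass
                continue
            if not here:
                put(cfg, mass)
                continue
            if len(parents) == 1:
                e = parents[0]
                ell = e.edge_prob()
                if len(here) == 2:
                    pair = frozenset(here)
                    res.coal_first[pair] = res.coal_first.get(pair, 0) + mass * (1 - ell)
                    put(cfg.move({s: e.u for s in here}), mass * ell)
                else:
                    put(cfg.move({here[0]: e.u}), mass)
            else:  # hybrid node
                e1, e2 = parents
                g1, g2 = e1.gamma, e2.gamma
                if len(here) == 1:
                    s = here[0]
                    put(cfg.move({s: e1.u}), mass * g1)
                    put(cfg.move({s: e2.u}), mass * g2)
                else:
                    s1, s2 = here
                    pair = frozenset(here)
                    for ea, eb, w in ((e1, e1, g1 * g1), (e2, e2, g2 * g2), (e1, e2, g1 * g2), (e2, e1, g1 * g2)):
                        if ea is eb:
                            h = ea.edge_prob()
                            res.coal_first[pair] = res.coal_first.get(pair, 0) + mass * w * (1 - h)
                            put(cfg.move({s1: ea.u, s2: ea.u}), mass * w * h)
                        else:
                            put(cfg.move({s1: ea.u, s2: eb.u}), mass * w)
        states = new_states
    for cfg, mass in states.items():
        res.undetermined += mass
    # keep exit configurations for chaining
    res._exit_states = states  # type: ignore[attr-defined]
    return res


def conditional_resolution(fragment: Network, entry: Dict[Any, List[str]]) -> ResolutionProbs:
    """Resolution probabilities of a fragment for lineages entering at its
    leaf ports, conditioned on their entering distinctly."""
    initial: Dict[str, Any] = {}
    for node, samples in entry.items():
        if node not in fragment.nodes:
            raise NetworkError(f"entry point {node!r} not in fragment")
        for s in samples:
            if s in initial:
                raise NetworkError(f"duplicate sample {s!r}")
            initial[s] = node
    if len(initial) > 4:
        raise NetworkError("at most 4 entering lineages are supported")
    frag = fragment if fragment.rooted else rooted_version(fragment)
    return _lineage_dp(frag, initial, exit_is_boundary=True)


# ---------------------------------------------------------------------------
# Quartet CFs and CF tables
# ---------------------------------------------------------------------------

def quartet_cf(net: Network, expand: bool = False) -> CFVector:
    """The exact CF vector of a 4-taxon level-1 network."""
    taxa = net.leaves()
    if len(taxa) != 4:
        raise NetworkError(f"need exactly 4 taxa, got {len(taxa)}")
    rnet = net if net.rooted else rooted_version(net)
    res = _lineage_dp(rnet, {t: t for t in taxa}, exit_is_boundary=False)
    a, b, c, d = quartet_key(taxa)
    third = Fraction(1, 3)
    vals = [
        res.coal_first.get(frozenset((a, b)), 0) + res.coal_first.get(frozenset((c, d)), 0),
        res.coal_first.get(frozenset((a, c)), 0) + res.coal_first.get(frozenset((b, d)), 0),
        res.coal_first.get(frozenset((a, d)), 0) + res.coal_first.get(frozenset((b, c)), 0),
    ]
    vals = [v + res.uniform * third for v in vals]
    if expand:
        import sympy

        vals = [sympy.expand(v) for v in vals]
    return CFVector(taxa, vals)


def cf_table(net: Network, samples: Optional[Dict[str, int]] = None, expand: bool = False) -> CFTable:
    """CF vectors for every 4-subset of taxa, via induced quartet networks."""
    work = expand_samples(net, samples)
    taxa = work.leaves()
    if len(taxa) < 4:
        raise NetworkError("need at least 4 taxa")
    rwork = work if work.rooted else rooted_version(work)
    table = CFTable(taxa)
    for q in itertools.combinations(taxa, 4):
        sub = induced_quartet_network(rwork, q)
        table.set(quartet_cf(sub, expand=expand))
    return table


# ---------------------------------------------------------------------------
# Within-edge transition distribution
# ---------------------------------------------------------------------------

_Q_CACHE: Dict[Tuple[int, int], Any] = {}


def _merge_seq_prob(j: int, r: int):
    """P(one specific ordered sequence of r pair-merges among j lineages
    within an edge, and no further merge), as a polynomial in ``l``."""
    import sympy

    key = (j, r)
    if key in _Q_CACHE:
        return _Q_CACHE[key]
    t, s, ell = sympy.symbols("t s ell", positive=True)

    def q(k: int, rr: int, tt):
        rate = sympy.Rational(k * (k - 1), 2)
        if rr == 0:
            return sympy.exp(-rate * tt)
        inner = q(k - 1, rr - 1, tt - s)
        return sympy.integrate(sympy.exp(-rate * s) * inner, (s, 0, tt))

    expr = q(j, r, t)
    expr = sympy.expand(expr.rewrite(sympy.exp))
    expr = expr.subs(t, -sympy.log(ell))
    expr = sympy.expand(sympy.powsimp(sympy.expand(expr), force=True))
    poly = sympy.Poly(expr, ell)
    _Q_CACHE[key] = (poly, ell)
    return _Q_CACHE[key]


def edge_transition(j: int, ell: Any) -> Dict[Tuple[Pair, ...], Any]:
    """Distribution over ordered labeled merge sequences within an edge.

    Lineages are labeled by frozensets over ``range(j)``; each outcome key
    is the tuple of merged label-pairs in time order (empty tuple: no
    coalescence).  Values are exact polynomials in ``ell`` evaluated at the
    given value (numeric or symbolic).
    """
    if not 1 <= j <= 4:
        raise NetworkError("1 <= j <= 4 required")
    import sympy

    out: Dict[Tuple[Pair, ...], Any] = {}

    def eval_q(r: int) -> Any:
        poly, sym = _merge_seq_prob(j, r)
        expr = poly.as_expr().subs(sym, sympy.sympify(ell))
        if isinstance(ell, (int, Fraction)):
            return Fraction(sympy.Rational(expr))
        if isinstance(ell, float):
            return float(expr)
        return sympy.expand(expr)

    probs = {r: eval_q(r) for r in range(j)}

    def walk(lineages: Tuple[FrozenSet[int], ...], seq: Tuple, r: int):
        out[seq] = probs[r]
        if len(lineages) == 1:
            return
        for pair in itertools.combinations(lineages, 2):
            merged = tuple(x for x in lineages if x not in pair) + (pair[0] | pair[1],)
            walk(tuple(sorted(merged, key=sorted)), seq + (frozenset(pair),), r + 1)

    start = tuple(frozenset([i]) for i in range(j))
    walk(start, (), 0)
    return out


# ---------------------------------------------------------------------------
# The six 3-cycle block probabilities and the decomposition
# ---------------------------------------------------------------------------

def p_vector(gamma, l1, l2, l3, h1, h2, x) -> Tuple[Any, Any, Any, Any, Any, Any]:
    """The six conditional resolution probabilities of a 3-cycle block.

    Roles: the hybrid node's cut edge has probability ``l1`` (toward taxa a),
    ``l2`` leads to taxa b, ``l3`` exits toward the root, ``x`` is the cycle
    tree edge, ``h1``/``h2`` the hybrid edge probabilities on the b-/root-
    side, and ``gamma`` the inheritance probability of the b-side edge.
    """
    g = gamma
    third = Fraction(1, 3)
    p1 = 1 - l3 * (1 - g + g * x)
    p2 = 1 - l1 * l3 * (g * g * h1 * x + 2 * g * (1 - g) + (1 - g) * (1 - g) * h2)
    p3 = 1 - x * l2 * l3
    p4 = l2 * (g + (1 - g) * x) * third
    p5 = l1 * (g * g * h1 + g * (1 - g) * (3 - x) + (1 - g) * (1 - g) * h2) * third
    p6 = l1 * l2 * (g * g * h1 + 2 * g * (1 - g) + (1 - g) * (1 - g) * h2 * x) * third
    return (p1, p2, p3, p4, p5, p6)


@dataclass
class ThreeCycleDecomposition:
    """The A/B/C/D pieces of a network cut at a 3-cycle (root in C)."""

    fragment_a: Optional[Network]
    fragment_b: Optional[Network]
    fragment_c: Network
    fragment_d: Network
    port_a: Any  # node where A meets D (bottom of the hybrid's cut edge)
    port_b: Any
    port_c: Any  # node where D meets C (top of the exit cut edge)
    taxa_a: FrozenSet[str]
    taxa_b: FrozenSet[str]
    taxa_c: FrozenSet[str]


def decompose_three_cycle(net: Network, cycle: Optional[CycleRecord] = None) -> ThreeCycleDecomposition:
    rnet = net if net.rooted else rooted_version(net)
    if cycle is None:
        threes = [c for c in find_cycles(rnet) if c.m == 3]
        if not threes:
            raise NetworkError("network has no 3-cycle")
        cycle = threes[0]
    else:
        # refresh against the rooted copy
        threes = [c for c in find_cycles(rnet) if c.m == 3 and c.blocks[0] == cycle.blocks[0]]
        cycle = threes[0]
    hyb = cycle.hybrid_node
    cyc_ids = {e.eid for e in cycle.edges}
    cut: Dict[Any, Edge] = {}
    for n in cycle.nodes:
        cands = [e for e in rnet.incident(n) if e.eid not in cyc_ids]
        if len(cands) != 1:
            raise NetworkError("cycle node without a unique cut edge")
        cut[n] = cands[0]
    exit_node = None
    for n in cycle.nodes:
        if cut[n].v == n:  # cut edge points into the cycle: root side
            exit_node = n
    if exit_node is None:
        raise NetworkError("no root-side cut edge on the 3-cycle")
    b_node = next(n for n in cycle.nodes if n not in (hyb, exit_node))
    d_edges = [e.copy() for e in cycle.edges] + [cut[n].copy() for n in cycle.nodes]
    port_a, port_b, port_c = cut[hyb].v, cut[b_node].v, cut[exit_node].u

    def component(start: Any, blocked: set) -> List[Edge]:
        seen = {start}
        stack = [start]
        out: List[Edge] = []
        d_ids = {e.eid for e in d_edges}
        while stack:
            n = stack.pop()
            for e in rnet.incident(n):
                if e.eid in d_ids:
                    continue
                o = e.other(n)
                out.append(e.copy())
                if o not in seen:
                    seen.add(o)
                    stack.append(o)
        uniq = {e.eid: e for e in out}
        return list(uniq.values())

    a_edges = component(port_a, set())
    b_edges = component(port_b, set())
    c_edges = component(port_c, set())
    frag_a = Network(a_edges, rooted=True, root=port_a, validate=False) if a_edges else None
    frag_b = Network(b_edges, rooted=True, root=port_b, validate=False) if b_edges else None
    frag_c = Network(c_edges, rooted=True, root=rnet.root, validate=False)
    frag_d = Network(d_edges, rooted=True, root=port_c, validate=False)
    leaves = set(rnet.leaves())
    taxa_a = frozenset(n for n in (frag_a.nodes if frag_a else {port_a}) if n in leaves) or frozenset([port_a])
    taxa_b = frozenset(n for n in (frag_b.nodes if frag_b else {port_b}) if n in leaves) or frozenset([port_b])
    taxa_c = frozenset(n for n in frag_c.nodes if n in leaves)
    return ThreeCycleDecomposition(
        frag_a, frag_b, frag_c, frag_d, port_a, port_b, port_c, taxa_a, taxa_b, taxa_c
    )


def _fragment_pass(frag: Optional[Network], entry: Dict[Any, List[str]], boundary: bool):
    """Run the DP on a fragment; returns (ResolutionProbs, exit sample list)."""
    samples = [s for ss in entry.values() for s in ss]
    if frag is None or not samples:
        rp = ResolutionProbs(undetermined=Fraction(1))
        rp._exit_states = {LineageConfig.at({s: None for s in samples}): Fraction(1)}  # type: ignore
        return rp
    initial = {}
    for node, ss in entry.items():
        for s in ss:
            initial[s] = node
    return _lineage_dp(frag, initial, exit_is_boundary=boundary)


def cf_via_decomposition(net: Network, cycle: Optional[CycleRecord] = None) -> CFTable:
    """CF table assembled from the A/B/C/D factorization at a 3-cycle.

    Produces the same table as :func:`cf_table`; exercised as an independent
    route through the factored parameterization.
    """
    dec = decompose_three_cycle(net, cycle)
    rnet = net if net.rooted else rooted_version(net)
    taxa = rnet.leaves()
    table = CFTable(taxa)
    third = Fraction(1, 3)
    for q in itertools.combinations(taxa, 4):
        a, b, c, d = quartet_key(q)
        coal: Dict[Pair, Any] = {}
        uniform = Fraction(0)

        qa = [t for t in q if t in dec.taxa_a]
        qb = [t for t in q if t in dec.taxa_b]
        qc = [t for t in q if t in dec.taxa_c]

        def add_coal(pair: Pair, mass: Any) -> None:
            coal[pair] = coal.get(pair, 0) + mass

        # stage A and B independently, then D, then C.  A and B run on
        # disjoint subnetworks, so their events are independent; when both
        # could resolve (a 2+2 quartet) the overlapping both-coalesce event
        # yields the same split either way, and is attributed to A by
        # scaling B's events with A's survival probability.
        res_a = _fragment_pass(dec.fragment_a, {t: [t] for t in qa}, True) if qa else None
        res_b = _fragment_pass(dec.fragment_b, {t: [t] for t in qb}, True) if qb else None

        pa_und = res_a.undetermined if res_a else Fraction(1)
        pb_und = res_b.undetermined if res_b else Fraction(1)
        if res_a is not None:
            for pair, m in res_a.coal_first.items():
                add_coal(pair, m)
            uniform += res_a.uniform
        if res_b is not None:
            for pair, m in res_b.coal_first.items():
                add_coal(pair, pa_und * m)
            uniform += pa_und * res_b.uniform
        mass_through = pa_und * pb_und
        entry_d = {}
        if qa:
            entry_d[dec.port_a] = qa
        if qb:
            entry_d[dec.port_b] = qb
        if entry_d:
            res_d = _fragment_pass(dec.fragment_d, entry_d, True)
            for pair, m in res_d.coal_first.items():
                add_coal(pair, mass_through * m)
            uniform += mass_through * res_d.uniform
            mass_c = mass_through * res_d.undetermined
        else:
            mass_c = mass_through
        survivors = qa + qb
        entry_c = {dec.port_c: survivors} if survivors else {}
        entry_c = dict(entry_c)
        for t in qc:
            entry_c.setdefault(t, []).append(t)
        res_c = _fragment_pass(dec.fragment_c, entry_c, False)
        for pair, m in res_c.coal_first.items():
            add_coal(pair, mass_c * m)
        uniform += mass_c * res_c.uniform

        vals = [
            coal.get(frozenset((a, b)), 0) + coal.get(frozenset((c, d)), 0) + uniform * third,
            coal.get(frozenset((a, c)), 0) + coal.get(frozenset((b, d)), 0) + uniform * third,
            coal.get(frozenset((a, d)), 0) + coal.get(frozenset((b, c)), 0) + uniform * third,
        ]
        table.set(CFVector(q, vals))
    return table
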
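"""Recovery of numerical parameters from CF tables and identifiability audits.

The audit labels every edge length and inheritance probability of a level-1
network as identified/identifiable, not-identifiable, or inert (pendant
edges, and hybrid edges that can never carry two lineages).  Recovery uses
closed-form identities where they exist (the quartet formula ``l = 3 CF`` for
edges defined by four taxa, and the large-cycle difference formulas for
inheritance probabilities and cycle edges adjacent to hybrid edges), and
otherwise exact polynomial solving of the CF equations of small induced
subnetworks, with one unknown symbol per original edge so that suppressed
chains factor transparently.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Any, Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .netmodel import (
    CFTable,
    CycleRecord,
    Edge,
    Network,
    NetworkError,
    defining_quartets,
    descendant_leaves,
    find_cycles,
    induced_network,
    quartet_key,
    rooted_version,
)

__all__ = [
    "ParamEstimate",
    "IdentifiabilityReport",
    "edge_length_from_quartet",
    "sunlet_cycle_params",
    "four_cycle_case",
    "identifiability_audit",
    "recover_parameters",
    "effective_cherry_z",
]


@dataclass
class ParamEstimate:
    """One recovered (or labeled) numerical parameter."""

    role: str  # "edge" or "gamma"
    edge: Optional[int]  # edge id in the input topology
    value: Any = None  # edge probability l, or gamma
    status: str = "identified"  # identified | not-identifiable | inert | locally-identified
    provenance: str = ""

    @property
    def length(self) -> Optional[float]:
        if self.role == "edge" and self.value is not None:
            v = float(self.value)
            return -math.log(v) if v > 0 else math.inf
        return None


@dataclass
class IdentifiabilityReport:
    cycles: List[Dict[str, Any]] = field(default_factory=list)
    edge_status: Dict[int, Tuple[str, str]] = field(default_factory=dict)  # eid -> (status, why)
    gamma_status: Dict[Any, Tuple[str, str]] = field(default_factory=dict)  # hybrid node -> (status, why)
    multi_sample: bool = False

    def status_of(self, eid: int) -> str:
        return self.edge_status.get(eid, ("unknown", ""))[0]


# ---------------------------------------------------------------------------
# Closed-form recoveries
# ---------------------------------------------------------------------------

def edge_length_from_quartet(table: CFTable, quartet: Sequence[str], split: Tuple[Sequence[str], Sequence[str]],
                             extended: bool = False, tol: float = 0.0) -> ParamEstimate:
    """Edge probability/length from the defining quartet: ``l = 3 CF_disc``.

    ``split`` gives the two taxon pairs separated by the edge; the
    discordant CF pairs one taxon of each side.
    """
    (x, y), (z, w) = (tuple(split[0]), tuple(split[1]))
    cf = table.cf(x, z, y, w)
    ell = 3 * cf
    if float(cf) <= 0:
        raise NetworkError("discordant CF must be positive")
    if float(cf) >= Fraction(1, 3) + tol and float(ell) != 1.0:
        if float(ell) > 1 and not extended:
            raise NetworkError("discordant CF above 1/3: no nonnegative length (use extended mode)")
    return ParamEstimate(role="edge", edge=None, value=ell, status="identified", provenance="quartet-defined edge")


def sunlet_cycle_params(table: CFTable, cycle: CycleRecord, representatives: Optional[Sequence[str]] = None) -> List[ParamEstimate]:
    """Inheritance probability and hybrid-adjacent cycle edges of a k-cycle,
    k >= 5, via the difference identities on a 5-taxon sunlet reduction.

    ``representatives`` (optional) lists one taxon per block in cyclic order
    starting with the hybrid block.  Hybrid edge lengths are labeled inert
    when the hybrid block is a singleton (no coalescence can occur on them).
    """
    k = cycle.m
    if k < 5:
        raise NetworkError("needs a cycle of size >= 5")
    if representatives is None:
        representatives = [sorted(b)[0] for b in cycle.blocks]
    reps = list(representatives)
    a, b, c, d = reps[0], reps[1], reps[2], reps[3]
    e = reps[-1]
    # y: the cycle edge between blocks 2 and 3 of the reduction, which the
    # quartet {b, c, d, e} defines
    y = 3 * table.cf(b, d, c, e)
    if float(y) >= 1 and float(y) != 1.0:
        raise NetworkError("degenerate reduction: opposite cycle edge probability >= 1")
    denom = 1 - y
    if denom == 0:
        raise NetworkError("y = 1: the inheritance probability is not recoverable from this reduction")
    gamma = (table.cf(a, c, d, e) - table.cf(a, d, c, e)) / denom
    out = [ParamEstimate("gamma", None, gamma, "identified", "k-cycle difference formula")]
    if not (0 < float(gamma) < 1):
        out[0].status = "out-of-range"
    x1 = 1 - (table.cf(a, b, c, d) - table.cf(a, c, b, d)) / gamma
    out.append(ParamEstimate("edge", None, x1, "identified", "hybrid-adjacent cycle edge (b side)"))
    # mirror reduction for the other hybrid-adjacent edge
    am, bm, cm, dm = a, reps[-1], reps[-2], reps[-3]
    em = reps[1]
    ym = 3 * table.cf(bm, dm, cm, em)
    gm = (table.cf(am, cm, dm, em) - table.cf(am, dm, cm, em)) / (1 - ym)
    x2 = 1 - (table.cf(am, bm, cm, dm) - table.cf(am, cm, bm, dm)) / gm
    out.append(ParamEstimate("edge", None, x2, "identified", "hybrid-adjacent cycle edge (far side)"))
    if cycle.k < 2:
        out.append(ParamEstimate("edge", None, None, "inert", "hybrid edges carry one lineage"))
    return out


def effective_cherry_z(gamma, h1, h2, x) -> Tuple[Any, bool]:
    """Effective cherry-edge probability of a contracted boundary 3-cycle,
    and whether it exceeds 1 (the anomalous, hence detectable, regime)."""
    g = gamma
    z = g * g * h1 + (1 - g) * (1 - g) * h2 + g * (1 - g) * (3 - x)
    return z, float(z) > 1


# ---------------------------------------------------------------------------
# 4-cycle case analysis
# ---------------------------------------------------------------------------

def _child_of_hybrid_cut_edge(net: Network, cycle: CycleRecord) -> Optional[Edge]:
    hyb = cycle.hybrid_node
    cyc_ids = {e.eid for e in cycle.edges}
    for e in net.incident(hyb):
        if e.eid not in cyc_ids and e.u == hyb:
            return e
    return None


def _node_in_three_cycle(net: Network, node) -> bool:
    for c in find_cycles(net):
        if c.m == 3 and node in c.nodes:
            return True
    return False


def four_cycle_case(net: Network, cycle: CycleRecord) -> Tuple[str, List[str]]:
    """The identifiability case of a 4-cycle and its identifiable parameters.

    Cases: "a" (all non-hybrid blocks singletons) -> none; "b.i" (hybrid and
    both adjacent blocks singletons) -> none; "b.ii" (hybrid singleton, an
    adjacent block of size >= 2) -> gamma and the two hybrid-adjacent cycle
    edges; "c.i"/"c.ii" (hybrid block >= 2): everything, except the hybrid
    child edge when its child node sits in a 3-cycle.
    """
    if cycle.m != 4:
        raise NetworkError("not a 4-cycle")
    nA = len(cycle.blocks[0])
    nB = len(cycle.blocks[1])
    nC = len(cycle.blocks[2])
    nD = len(cycle.blocks[3])
    if nB == 1 and nC == 1 and nD == 1:
        return "a", []
    if nA == 1 and nB == 1 and nD == 1:
        return "b.i", []
    if nA == 1:
        return "b.ii", ["x1", "x2", "gamma"]
    # nA >= 2 and some other block >= 2
    child_edge = _child_of_hybrid_cut_edge(net, cycle)
    in3 = child_edge is not None and _node_in_three_cycle(net, child_edge.v)
    if in3:
        return "c.ii", ["x1", "x2", "h1", "h2", "gamma"]
    return "c.i", ["x1", "x2", "h1", "h2", "gamma", "l"]


# ---------------------------------------------------------------------------
# The audit
# ---------------------------------------------------------------------------

def _cycle_of_edge(cycles: List[CycleRecord], eid: int) -> Optional[CycleRecord]:
    for c in cycles:
        if any(e.eid == eid for e in c.edges):
            return c
    return None


def _adjacent_hybrid_edges(net: Network, e: Edge) -> List[Edge]:
    out = []
    for n in e.nodes():
        for x in net.incident(n):
            if x.eid != e.eid and x.kind == "hybrid":
                out.append(x)
    return out


def _effective_block_size(size: int, multi: bool) -> int:
    return max(size, 2) if multi else size


def identifiability_audit(net: Network, samples_per_taxon: int = 1) -> IdentifiabilityReport:
    """Label every numerical parameter of the network per the topological
    and numerical identifiability results; with two or more samples per
    taxon, pendant-edge and block-size exceptions lift."""
    rnet = net
    multi = samples_per_taxon >= 2
    rep = IdentifiabilityReport(multi_sample=multi)
    cycles = find_cycles(rnet)
    twos = [c for c in cycles if c.m == 2]
    n = len(rnet.leaves())

    for c in cycles:
        entry: Dict[str, Any] = {"m": c.m, "k": c.k, "blocks": [sorted(b) for b in c.blocks]}
        sizes = [_effective_block_size(len(b), multi) for b in c.blocks]
        if c.m == 2:
            entry["topology"] = "never identifiable; replaced by an effective edge"
        elif c.m == 3:
            raw = sorted(len(b) for b in c.blocks)
            if raw[0] == 1 and raw[1] == 1 and not multi:
                if c.k == 1:
                    entry["topology"] = (
                        "indistinguishable from the contracted node and from the "
                        "network with the singleton blocks swapped"
                    )
                else:
                    entry["topology"] = "parameter-dependent: identifiable on one positive-measure regime, not on another"
            elif raw[0] == 1 and not multi:
                entry["topology"] = "undirected 3-cycle identifiable; hybrid node parameter-dependent"
            else:
                entry["topology"] = (
                    "undirected 3-cycle identifiable; one non-hybrid block determinable; "
                    "hybrid node parameter-dependent"
                )
        elif c.m == 4:
            entry["topology"] = "orientation (hybrid edge directions) generically identifiable" if n >= 5 else "see 4-taxon analysis"
            case, idents = four_cycle_case(rnet, c)
            if multi and case in ("a", "b.i", "b.ii"):
                # with pseudotaxa every block behaves as size >= 2
                case, idents = ("c.i", ["x1", "x2", "h1", "h2", "gamma", "l"]) if c.k >= 1 else (case, idents)
            entry["case"] = case
            entry["identifiable"] = idents
        else:
            entry["topology"] = "cycle identifiable"
        rep.cycles.append(entry)

    three_cycle_zone: Set[int] = set()
    for c in cycles:
        if c.m == 3:
            for e in c.edges:
                three_cycle_zone.add(e.eid)
            for node in c.nodes:
                for e in rnet.incident(node):
                    three_cycle_zone.add(e.eid)

    cache: Dict = {}
    for e in rnet.edges:
        if rnet.is_pendant(e) and not multi:
            rep.edge_status[e.eid] = ("inert", "pendant edge: no coalescence with one sample per taxon")
            continue
        if e.eid in three_cycle_zone:
            rep.edge_status[e.eid] = ("not-identifiable", "edge in or adjacent to a 3-cycle")
            continue
        cyc = _cycle_of_edge(cycles, e.eid)
        if cyc is not None:
            if cyc.m == 2:
                rep.edge_status[e.eid] = ("not-identifiable", "2-cycle edge")
                continue
            sizes = [_effective_block_size(len(b), multi) for b in cyc.blocks]
            if e.kind == "hybrid":
                if cyc.m == 4:
                    case = [x for x in rep.cycles if x["m"] == 4 and x["blocks"] == [sorted(b) for b in cyc.blocks]][0].get("case")
                    if case in ("c.i", "c.ii"):
                        rep.edge_status[e.eid] = ("identifiable", f"4-cycle case {case}")
                    elif sizes[0] >= 2:
                        rep.edge_status[e.eid] = ("not-identifiable", f"4-cycle case {case}")
                    else:
                        rep.edge_status[e.eid] = ("inert", "hybrid edge with a single descendant taxon")
                else:
                    if sizes[0] >= 2:
                        rep.edge_status[e.eid] = ("identifiable", "hybrid edges of a large cycle with 2+ hybrid descendants")
                    else:
                        rep.edge_status[e.eid] = ("inert", "hybrid edge with a single descendant taxon")
                continue
            # cycle tree edge
            if cyc.m == 4:
                case = [x for x in rep.cycles if x["m"] == 4 and x["blocks"] == [sorted(b) for b in cyc.blocks]][0].get("case")
                if case in ("b.ii", "c.i", "c.ii"):
                    rep.edge_status[e.eid] = ("identifiable", f"4-cycle case {case}")
                else:
                    rep.edge_status[e.eid] = ("not-identifiable", f"4-cycle case {case}")
            else:
                adj = _adjacent_hybrid_edges(rnet, e)
                why = "hybrid-adjacent cycle edge (difference formula)" if adj else "cycle edge defined by four taxa"
                rep.edge_status[e.eid] = ("identifiable", why)
            continue
        # cut edges
        adj = _adjacent_hybrid_edges(rnet, e)
        if not adj:
            rep.edge_status[e.eid] = ("identifiable", "internal edge defined by four taxa")
            continue
        hyb_children = {x.v for x in adj}
        if e.u in hyb_children:
            # child edge of a hybrid node
            cyc = _cycle_of_edge(cycles, adj[0].eid)
            k = _effective_block_size(cyc.k, multi) if cyc else 1
            if cyc and cyc.m == 4:
                case = [x for x in rep.cycles if x["m"] == 4 and x["blocks"] == [sorted(b) for b in cyc.blocks]][0].get("case")
                if case == "c.i":
                    rep.edge_status[e.eid] = ("identifiable", "4-cycle case c.i hybrid child edge")
                else:
                    rep.edge_status[e.eid] = ("not-identifiable", f"4-cycle case {case} hybrid child edge")
            elif k >= 2 and not _node_in_three_cycle(rnet, e.v):
                rep.edge_status[e.eid] = ("identifiable", "hybrid child edge of a large cycle")
            elif k >= 2:
                rep.edge_status[e.eid] = ("not-identifiable", "hybrid child edge into a 3-cycle")
            else:
                rep.edge_status[e.eid] = ("inert", "below a hybrid with a single descendant taxon")
            continue
        # cut edge adjacent to hybrid edges at its top/side
        cyc_sizes = {(_cycle_of_edge(cycles, x.eid).m if _cycle_of_edge(cycles, x.eid) else 0) for x in adj}
        if all(m >= 4 for m in cyc_sizes):
            rep.edge_status[e.eid] = ("identifiable", "cut edge adjacent to hybrid edges of cycles of size >= 4")
        else:
            rep.edge_status[e.eid] = ("not-identifiable", "adjacent to a small cycle")

    for c in cycles:
        hyb = c.hybrid_node
        sizes = [_effective_block_size(len(b), multi) for b in c.blocks]
        if c.m == 2:
            rep.gamma_status[hyb] = ("not-identifiable", "2-cycle")
        elif c.m == 3:
            rep.gamma_status[hyb] = ("not-identifiable", "3-cycle parameters are not identifiable")
        elif c.m == 4:
            case = [x for x in rep.cycles if x["m"] == 4 and x["blocks"] == [sorted(b) for b in c.blocks]][0].get("case")
            if case in ("b.ii", "c.i", "c.ii"):
                rep.gamma_status[hyb] = ("identifiable", f"4-cycle case {case}")
            else:
                rep.gamma_status[hyb] = ("not-identifiable", f"4-cycle case {case}")
        else:
            rep.gamma_status[hyb] = ("identifiable", "large-cycle difference formula")
    return rep


# ---------------------------------------------------------------------------
# Exact solving on induced subnetworks
# ---------------------------------------------------------------------------

def _skey(e: Edge) -> Tuple[int, ...]:
    """Identity of a semidirected edge: the sorted original edge ids."""
    return tuple(sorted(e.src)) if e.src else (e.eid,)


def _symbolized_copy(net: Network, known: Dict[Tuple[int, ...], Any], gamma_known: Dict[Any, Any]):
    """Rooted copy of the (semidirected) network with known probabilities
    substituted and a fresh sympy symbol per remaining relevant parameter.

    Artificial root-half edges (empty ``src``) are fixed at probability 1 so
    each semidirected edge owns exactly one symbol.
    """
    import sympy

    rnet = net if net.rooted else rooted_version(net)
    cache: Dict = {}
    symbols: Dict[str, Tuple[str, Any]] = {}  # name -> ("edge", skey) | ("gamma", node)
    edges = []
    for e in rnet.edges:
        new = e.copy()
        new.length = None
        if not e.src:
            new.prob = 1
        elif _skey(e) in known:
            new.prob = known[_skey(e)]
        elif rnet.is_pendant(e):
            new.prob = None
        elif e.kind == "hybrid" and len(descendant_leaves(rnet, e.v, cache)) <= 1:
            new.prob = None
        else:
            s = sympy.Symbol("u_" + "_".join(str(i) for i in _skey(e)), positive=True)
            symbols[s.name] = ("edge", _skey(e))
            new.prob = s
        edges.append(new)
    by_hybrid: Dict[Any, List[Edge]] = {}
    for e in edges:
        if e.kind == "hybrid":
            by_hybrid.setdefault(e.v, []).append(e)
    for node, pair in by_hybrid.items():
        if node in gamma_known:
            g = gamma_known[node]
        else:
            g = sympy.Symbol(f"g_{node}".replace("-", "_"), positive=True)
            symbols[g.name] = ("gamma", node)
        pair[0].gamma = g
        pair[1].gamma = 1 - g
    out = Network(edges, rooted=True, root=rnet.root, validate=False)
    return out, symbols


def _contract_boundary_three_cycles(sub: Network, wanted: Set[str]):
    """Replace induced 3-cycles with (1,1,rest) blocks whose parameters are
    not identifiable by their effective-parameter equivalents.

    Case hybrid-singleton: the structure is CF-equivalent to a tree node
    with an extra pass-through probability on the edge toward the large
    block.  Case hybrid-large: equivalent to a cherry over the two
    singletons with an effective (possibly > 1) cherry-edge probability.
    Returns (network, names of fresh nuisance symbols) or None if an
    offending 3-cycle cannot be contracted.
    """
    import sympy

    nuisance: List[str] = []
    work = sub
    for _ in range(4):
        bad = None
        for c in find_cycles(work):
            if c.m != 3:
                continue
            names: Set[str] = set()
            for e in c.edges:
                for attr in (e.prob, e.gamma):
                    if hasattr(attr, "free_symbols"):
                        names |= {s.name for s in attr.free_symbols}
            if names & wanted:
                return None  # a wanted parameter sits on a 3-cycle: hopeless
            bad = c
            break
        if bad is None:
            return work, nuisance
        sizes = sorted(len(b) for b in bad.blocks)
        if sizes[0] != 1 or sizes[1] != 1:
            return None
        big_idx = max(range(3), key=lambda i: len(bad.blocks[i]))
        cyc_ids = {e.eid for e in bad.edges}
        star = f"_c3_{len(nuisance)}"
        fresh = sympy.Symbol(f"z{len(nuisance)}_eff", positive=True)
        nuisance.append(fresh.name)
        edges = []
        singles = []
        big_edge = None
        for e in work.edges:
            if e.eid in cyc_ids:
                continue
            new = e.copy()
            for i, node in enumerate(bad.nodes):
                if new.u == node:
                    new.u = star
                if new.v == node:
                    new.v = star
            edges.append(new)
            if star in new.nodes():
                if _block_taxa_of(work, e, bad) == bad.blocks[big_idx]:
                    big_edge = new
                else:
                    singles.append(new)
        if big_edge is None or len(singles) != 2:
            return None
        if bad.k >= 2:
            # hybrid block is the large one: effective cherry over singletons
            w = star + "w"
            for e in singles:
                if e.u == star:
                    e.u = w
                else:
                    e.v = w
            edges.append(Edge(star, w, prob=fresh))
        else:
            # hybrid is a singleton: pass-through probability toward the rest
            big_edge.prob = (big_edge.prob if big_edge.prob is not None else 1) * fresh
        from .netmodel import _suppress_degree_two

        deg: Dict[Any, int] = {}
        for e in edges:
            deg[e.u] = deg.get(e.u, 0) + 1
            deg[e.v] = deg.get(e.v, 0) + 1
        leaves = {n for n, d in deg.items() if d == 1}
        edges = _suppress_degree_two(edges, keep=leaves)
        work = Network(edges, rooted=False, root=None, validate=False)
    return None


def _block_taxa_of(net: Network, cut_edge: Edge, cycle: CycleRecord):
    for i, node in enumerate(cycle.nodes):
        if node in cut_edge.nodes():
            return cycle.blocks[i]
    return frozenset()


def _solve_projection(sym_net: Network, symbols: Dict[str, Tuple[str, Any]], table: CFTable,
                      subtaxa: Sequence[str], wanted: Optional[Set[str]] = None) -> Dict[str, Any]:
    """Exactly solve the CF equations of the induced network on ``subtaxa``.

    Merged chains appear as monomials in the per-edge symbols; each is
    lumped into one unknown, solved for, and returned as a product equation
    under the key ``("product", (factor names...))``.  Non-identifiable
    3-cycles met along the way are contracted to effective parameters.
    Returns symbol-name -> exact value (plus product equations) for a
    uniquely determined, exactly verified solution; {} otherwise.
    """
    import sympy

    from .cfengine import cf_table as _cf_table

    wanted = set(wanted or ())
    sub = induced_network(sym_net, subtaxa)
    contracted = _contract_boundary_three_cycles(sub, wanted)
    if contracted is None:
        return {}
    sub, nuisance = contracted
    # lump merged-chain monomials into single unknowns
    lumps: Dict[Any, Any] = {}  # fresh symbol -> tuple of factor names
    edges = []
    for e in sub.edges:
        new = e.copy()
        if hasattr(new.prob, "free_symbols") and len(new.prob.free_symbols) > 1:
            factors = tuple(sorted(s.name for s in new.prob.free_symbols))
            key = sympy.Symbol("M_" + "__".join(factors), positive=True)
            lumps[key] = factors
            new.prob = key
        edges.append(new)
    sub = Network(edges, rooted=sub.rooted, root=sub.root, validate=False)
    bare: Set[str] = set()
    for e in sub.edges:
        for attr in (e.prob, e.gamma):
            if hasattr(attr, "free_symbols"):
                bare |= {s.name for s in attr.free_symbols}
    bare -= {k.name for k in lumps}
    bare -= set(nuisance)
    if wanted and bare - wanted:
        return {}  # an unresolvable parameter appears unlumped
    stab = _cf_table(sub, expand=True)
    eqs = []
    unknowns: Set[Any] = set()
    for q in stab.quartets():
        for i in range(2):  # third entry is 1 - the others
            expr = stab.data[q].values[i]
            free = expr.free_symbols if hasattr(expr, "free_symbols") else set()
            if not free:
                continue
            obs = sympy.Rational(Fraction(table.data[q].values[i]))
            eqs.append(sympy.expand(expr - obs))
            unknowns |= free
    if not unknowns:
        return {}
    unknowns = sorted(unknowns, key=lambda s: s.name)
    soft: Set[str] = set(nuisance)
    for sym, factors in lumps.items():
        if any(f in nuisance or (wanted and f not in wanted) for f in factors):
            soft.add(sym.name)
    upper = [3.0 if s.name in soft else 1.0 for s in unknowns]
    solved = _solve_equations_exactly(eqs, unknowns, upper, soft)
    if not solved:
        return {}
    out: Dict[Any, Any] = {}
    for name, value in solved.items():
        if name in nuisance:
            continue
        sym = sympy.Symbol(name, positive=True)
        if sym in lumps:
            out[("product", lumps[sym])] = value
        else:
            out[name] = value
    return out


def _solve_equations_exactly(eqs, unknowns, upper: Optional[Sequence[float]] = None,
                             soft: Optional[Set[str]] = None) -> Dict[str, Any]:
    """Solve polynomial equations numerically, rationalize, and certify the
    solution by exact substitution.

    Underdetermined systems (numeric Jacobian rank below the number of
    unknowns) are rejected, since no unique solution exists.
    """
    import numpy as np
    import sympy
    from scipy.optimize import least_squares

    n = len(unknowns)
    if len(eqs) < n:
        return {}
    hi = np.asarray(upper if upper is not None else [1.0] * n, dtype=float)
    vec = sympy.Matrix(eqs)
    jac = vec.jacobian(sympy.Matrix(unknowns))
    f = sympy.lambdify(unknowns, eqs, "numpy")
    jf = sympy.lambdify(unknowns, jac, "numpy")
    rng = np.random.default_rng(20240111)
    probe = rng.uniform(0.2, 0.8, size=n)
    if np.linalg.matrix_rank(np.asarray(jf(*probe), dtype=float), tol=1e-9) < n:
        return {}

    def resid(theta):
        return np.asarray(f(*theta), dtype=float)

    def dresid(theta):
        return np.asarray(jf(*theta), dtype=float)

    best = None
    for _ in range(20):
        theta0 = rng.uniform(0.03, 0.97, size=n) * hi
        try:
            sol = least_squares(resid, theta0, jac=dresid, bounds=(1e-9, hi),
                                xtol=1e-15, ftol=1e-15, gtol=1e-15)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
        if best.cost < 1e-24:
            break
    if best is None or best.cost > 1e-18:
        return {}
    soft = soft or set()
    out: Dict[str, Any] = {}
    subs = {}
    soft_syms = []
    for s, v in zip(unknowns, best.x):
        if s.name in soft:
            soft_syms.append((s, float(v)))
            continue
        fr = _snap_rational(float(v))
        out[s.name] = fr
        subs[s] = sympy.Rational(fr)
    residual = [sympy.expand(eq.subs(subs)) for eq in eqs]
    if not soft_syms:
        if any(sympy.Rational(r) != 0 for r in residual):
            return {}
        return out
    # certify the core values: the remaining system in the soft unknowns
    # must be exactly consistent
    active = [r for r in residual if r.free_symbols]
    if any(sympy.Rational(r) != 0 for r in residual if not r.free_symbols):
        return {}
    try:
        sols = sympy.solve(active, [s for s, _ in soft_syms], dict=True)
    except Exception:
        return {}
    ok = False
    for sol in sols:
        if all(v.is_real is not False for v in sol.values()):
            ok = True
            break
    if not ok:
        return {}
    return out


def _snap_rational(x: float) -> Fraction:
    """Best small-denominator rational within float tolerance of ``x``."""
    for cap in (1 << 12, 1 << 16, 1 << 20, 1 << 28, 1 << 40):
        fr = Fraction(x).limit_denominator(cap)
        if abs(float(fr) - x) < 1e-10:
            return fr
    return Fraction(x).limit_denominator(1 << 48)


# ---------------------------------------------------------------------------
# Full recovery
# ---------------------------------------------------------------------------

def recover_parameters(net: Network, table: CFTable) -> List[ParamEstimate]:
    """Recover all identifiable numerical parameters of a (2-cycle-free)
    level-1 topology from an exact CF table.

    Estimates refer to semidirected edges; ``ParamEstimate.edge`` holds the
    tuple of input edge ids making up that edge (a single id in the common
    case).  Inheritance-probability estimates carry the hybrid node and are
    oriented toward the cycle's second block (the neighbor listed first in
    the cycle record).
    """
    from .netmodel import to_semidirected

    sd = to_semidirected(net) if net.rooted else net.copy()
    cycles = find_cycles(sd)
    if any(c.m == 2 for c in cycles):
        raise NetworkError("replace 2-cycles before recovery (their parameters are never identifiable)")
    audit = identifiability_audit(sd)
    known: Dict[Tuple[int, ...], Any] = {}
    gamma_known: Dict[Any, Any] = {}
    estimates: List[ParamEstimate] = []

    # pass 1: edges defined by four taxa
    for e in sd.edges:
        if sd.is_pendant(e) or e.kind == "hybrid":
            continue
        if _adjacent_hybrid_edges(sd, e):
            continue
        dq = defining_quartets(sd, e, first_only=True)
        if not dq:
            continue
        est = edge_length_from_quartet(table, dq[0].taxa, dq[0].split)
        est.edge = _skey(e)
        known[_skey(e)] = est.value
        estimates.append(est)

    # pass 2: large-cycle closed forms
    for c in cycles:
        if c.m < 5:
            continue
        ests = sunlet_cycle_params(table, c)
        gamma_known[c.hybrid_node] = ests[0].value
        ests[0].edge = c.hybrid_node
        ests[0].provenance += " (of the hybrid edge toward the second block)"
        estimates.append(ests[0])
        # the recovered cycle edges are the unique tree cycle edges incident
        # to the hybrid-edge parent nodes on each side
        for est, idx in ((ests[1], 1), (ests[2], len(c.nodes) - 1)):
            node = c.nodes[idx]
            tree_cyc = [e for e in c.edges if e.kind == "tree" and node in e.nodes()]
            if len(tree_cyc) == 1 and _skey(tree_cyc[0]) not in known:
                est.edge = _skey(tree_cyc[0])
                known[_skey(tree_cyc[0])] = est.value
                estimates.append(est)

    # pass 3: exact solving on projections, with product bookkeeping
    products: List[Tuple[Tuple[str, ...], Any]] = []
    skey_by_name: Dict[str, Tuple[str, Any]] = {}

    def absorb(name_or_key, value, symbols) -> bool:
        if isinstance(name_or_key, tuple) and name_or_key[0] == "product":
            products.append((name_or_key[1], value))
            return False
        kind, target = symbols[name_or_key]
        if kind == "edge":
            if target in known:
                return False
            known[target] = value
            estimates.append(ParamEstimate("edge", target, value, "identified", "exact subnetwork solve"))
        else:
            if target in gamma_known:
                return False
            gamma_known[target] = value
            estimates.append(ParamEstimate("gamma", target, value, "identified", "exact subnetwork solve"))
        return True

    def resolve_products(symbols) -> bool:
        moved = False
        for factors, value in list(products):
            vals = []
            missing = []
            for name in factors:
                if name not in symbols:
                    vals.append(None)
                    continue
                kind, target = symbols[name]
                if kind == "edge" and target in known:
                    vals.append(known[target])
                else:
                    missing.append(name)
            if len(missing) == 1 and all(v is not None for v in vals):
                rest = Fraction(1)
                for v in vals:
                    rest *= Fraction(v)
                if rest != 0:
                    moved |= absorb(missing[0], Fraction(value) / rest, symbols)
        return moved

    status_by_skey = {_skey(e): audit.edge_status.get(e.eid, ("", ""))[0] for e in sd.edges}
    guard = 0
    progress = True
    while progress and guard < 8:
        guard += 1
        progress = False
        sym_net, symbols = _symbolized_copy(sd, known, gamma_known)
        skey_by_name.update(symbols)
        remaining = {name for name, tgt in symbols.items() if _is_wanted(tgt, audit, status_by_skey)}
        if not remaining:
            break
        for sub in _projection_plan(sd, cycles, audit):
            solved = _solve_projection(sym_net, symbols, table, sub, wanted=remaining)
            for key, value in solved.items():
                progress |= absorb(key, value, symbols)
            progress |= resolve_products(symbols)
            if progress:
                break

    # label everything not recovered
    recovered_edges = {e.edge for e in estimates if e.role == "edge"}
    for e in sd.edges:
        if _skey(e) in recovered_edges:
            continue
        status, why = audit.edge_status.get(e.eid, ("unknown", ""))
        if status == "identifiable":
            status = "unrecovered"
        estimates.append(ParamEstimate("edge", _skey(e), None, status, why))
    for c in cycles:
        if c.hybrid_node in gamma_known:
            continue
        status, why = audit.gamma_status.get(c.hybrid_node, ("unknown", ""))
        estimates.append(ParamEstimate("gamma", c.hybrid_node, None, status, why))
    for est in estimates:
        if est.role == "gamma" and est.edge is None and est.value is not None:
            for node, v in gamma_known.items():
                if v == est.value:
                    est.edge = node
    return estimates


def _block_of(net: Network, node, cycle: CycleRecord) -> FrozenSet[str]:
    idx = cycle.nodes.index(node)
    return cycle.blocks[idx]


def _is_wanted(target, audit: IdentifiabilityReport, status_by_skey: Dict[Tuple[int, ...], str]) -> bool:
    kind, obj = target
    if kind == "edge":
        return status_by_skey.get(obj, "identifiable") == "identifiable"
    return audit.gamma_status.get(obj, ("", ""))[0] == "identifiable"


def _projection_plan(net: Network, cycles: List[CycleRecord], audit: IdentifiabilityReport) -> List[List[str]]:
    """Small taxon subsets on which to solve, following the reduction
    strategy of the identifiability proofs: for each cycle, first a
    projection with a pair in a non-hybrid block (placing the hybrid
    adjacent to the cherry), then one with a pair in the hybrid block; and
    finally the full taxon set for anything left (e.g. edges joining two
    cycles)."""
    plans: List[List[str]] = []
    taxa = net.leaves()
    for c in cycles:
        if c.m < 4:
            continue
        blocks = [sorted(b) for b in c.blocks]
        singles = [b[0] for b in blocks]
        # a pair in a non-hybrid block of size >= 2 (hybrid lands adjacent
        # to or opposite the cherry); try a few pairs since a block may
        # contain further cycles that a good pair avoids
        for i in range(1, len(blocks)):
            if len(blocks[i]) >= 2:
                for second in blocks[i][1:3]:
                    sub = list(singles)
                    sub.append(second)
                    plans.append(sub)
        if len(blocks[0]) >= 2:
            for second in blocks[0][1:3]:
                sub = list(singles)
                sub.append(second)
                plans.append(sub)
    plans.append(list(taxa))
    return plans
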
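"""Algebraic and semialgebraic statistics on CF tables.

Implements the 3-cycle detection statistics (the bilinear forms on
pairwise-pair quartet CFs and the cherry statistics on 2+2+1 blocks), the
sign-based classification of 3-cycle hybrid locations, exact Jacobian-rank
dimension checks of CF parameterizations, and 4-cycle hybrid-placement
calls by model fitting against the exact engine.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Any, Dict, List, Optional, Sequence, Tuple

from .netmodel import CFTable, NetworkError, quartet_key

__all__ = [
    "BlockAssignment",
    "ThreeCycleCall",
    "FourCycleCall",
    "cf_pattern",
    "f_statistic",
    "g_statistics",
    "f_tilde_statistic",
    "classify_three_cycle",
    "orient_four_cycle",
    "variety_dimension",
    "symbolic_cf_coords",
]


# ---------------------------------------------------------------------------
# Block assignments and pattern extraction
# ---------------------------------------------------------------------------

@dataclass
class BlockAssignment:
    """Designated taxon blocks a/b/c for the detection statistics."""

    a: Tuple[str, ...]
    b: Tuple[str, ...]
    c: Tuple[str, ...]

    def __post_init__(self):
        self.a, self.b, self.c = tuple(self.a), tuple(self.b), tuple(self.c)
        all_ = self.a + self.b + self.c
        if len(set(all_)) != len(all_):
            raise NetworkError("blocks must be disjoint")

    def roles(self) -> Dict[str, Tuple[str, ...]]:
        return {"a": self.a, "b": self.b, "c": self.c}


def cf_pattern(table: CFTable, pattern: str, roles: Dict[str, Sequence[str]]) -> Any:
    """Average CF of a subscript pattern like ``"ab|ac"`` over all valid
    assignments of block members to the letter occurrences.

    Exchangeability makes every assignment equal on exact tables; on
    empirical tables the average reduces variance.
    """
    left, right = pattern.split("|")
    letters = list(left) + list(right)
    # assign distinct members per letter
    per_letter: Dict[str, List[str]] = {}
    for ch in letters:
        per_letter.setdefault(ch, [])
    choices: List[List[Tuple[str, ...]]] = []
    keys = sorted(per_letter)
    for ch in keys:
        n = letters.count(ch)
        members = list(roles[ch])
        if len(members) < n:
            raise NetworkError(f"block {ch!r} needs {n} members, has {len(members)}")
        choices.append(list(itertools.permutations(members, n)))
    vals = []
    for combo in itertools.product(*choices):
        picks = {ch: list(c) for ch, c in zip(keys, combo)}
        occs = {ch: 0 for ch in keys}

        def take(ch: str) -> str:
            v = picks[ch][occs[ch]]
            occs[ch] += 1
            return v

        lx, ly = (take(c) for c in left)
        rx, ry = (take(c) for c in right)
        vals.append(table.cf(lx, ly, rx, ry))
    total = vals[0]
    for v in vals[1:]:
        total = total + v
    n = len(vals)
    if isinstance(total, float):
        return total / n
    return total * Fraction(1, n)


# ---------------------------------------------------------------------------
# The detection statistics
# ---------------------------------------------------------------------------

def f_statistic(table: CFTable, blocks: BlockAssignment) -> Any:
    """``3 CF_ab|ac CF_ab|bc - CF_ab|ab`` for pair blocks a, b and singleton c.

    Vanishes identically on the 5-taxon tree; positive on the 3-cycle with
    the singleton below the hybrid node; either sign when a pair block is
    hybrid.
    """
    r = blocks.roles()
    return 3 * cf_pattern(table, "ab|ac", r) * cf_pattern(table, "ab|bc", r) - cf_pattern(table, "ab|ab", r)


def f_tilde_statistic(table: CFTable, blocks: BlockAssignment) -> Any:
    """``f_abc - CF_ab|ab / 2``; strictly negative when a pair block is the
    hybrid block, but admits positive values when the singleton is."""
    r = blocks.roles()
    half = Fraction(1, 2)
    return f_statistic(table, blocks) - cf_pattern(table, "ab|ab", r) * half


def g_statistics(table: CFTable, blocks: BlockAssignment) -> Tuple[Any, Any, Any]:
    """The three bilinear forms (G_abc, G_cab, G_bca) on pairwise-pair CFs.

    They satisfy G_abc + G_cab + G_bca = 0 identically; all vanish on the
    three-cherry tree, and G_xyz > 0 on the 3-cycle with hybrid block x.
    """
    r = blocks.roles()
    X = cf_pattern(table, "ac|ac", r) * cf_pattern(table, "ab|bc", r)
    Y = cf_pattern(table, "bc|bc", r) * cf_pattern(table, "ab|ac", r)
    Z = cf_pattern(table, "ab|ab", r) * cf_pattern(table, "ac|bc", r)
    g_abc = X - 2 * Y + Z
    g_cab = Y - 2 * Z + X
    g_bca = Z - 2 * X + Y
    return (g_abc, g_cab, g_bca)


# ---------------------------------------------------------------------------
# 3-cycle classification
# ---------------------------------------------------------------------------

@dataclass
class ThreeCycleCall:
    verdict: str  # "tree-node" | "hybrid:<x>" | "hybrid-ambiguous:<x,y>" | "excluded:<x>" | "no-exclusion" | "inconclusive"
    candidates: Tuple[str, ...]
    evidence: Dict[str, Any] = field(default_factory=dict)


def _sign(value: Any, tol: float) -> int:
    v = float(value)
    if v > tol:
        return 1
    if v < -tol:
        return -1
    return 0


def classify_three_cycle(table: CFTable, blocks: BlockAssignment, tolerance: float = 0.0) -> ThreeCycleCall:
    """Sign-pattern classification of a candidate 3-cycle location.

    With three pair blocks the three bilinear forms are used; with a
    singleton c block the cherry statistics are.  ``tolerance`` is the
    numeric threshold below which a statistic counts as zero (0 for exact
    tables).
    """
    if len(blocks.c) >= 2 and len(blocks.a) >= 2 and len(blocks.b) >= 2:
        gs = g_statistics(table, blocks)
        names = ("a", "c", "b")  # G_abc, G_cab, G_bca point at blocks a, c, b
        signs = tuple(_sign(g, tolerance) for g in gs)
        ev = {"G_abc": gs[0], "G_cab": gs[1], "G_bca": gs[2], "signs": signs}
        pos = [names[i] for i, s in enumerate(signs) if s > 0]
        if all(s == 0 for s in signs):
            return ThreeCycleCall("tree-node", (), ev)
        if len(pos) == 1:
            return ThreeCycleCall(f"hybrid:{pos[0]}", tuple(pos), ev)
        if len(pos) == 2:
            return ThreeCycleCall(f"hybrid-ambiguous:{','.join(sorted(pos))}", tuple(sorted(pos)), ev)
        return ThreeCycleCall("inconclusive", (), ev)
    if len(blocks.c) != 1 or len(blocks.a) < 2 or len(blocks.b) < 2:
        raise NetworkError("blocks must be 2+2+2 or 2+2+1 (c the singleton)")
    f = f_statistic(table, blocks)
    ft = f_tilde_statistic(table, blocks)
    ev = {"f_abc": f, "f_tilde": ft}
    sf = _sign(f, tolerance)
    if sf == 0:
        return ThreeCycleCall("tree-node", (), ev)
    if sf < 0:
        return ThreeCycleCall("excluded:c", ("a", "b"), ev)
    if _sign(ft, tolerance) > 0:
        return ThreeCycleCall("hybrid:c", ("c",), ev)
    return ThreeCycleCall("no-exclusion", ("a", "b", "c"), ev)


# ---------------------------------------------------------------------------
# Symbolic CF coordinates and Jacobian ranks
# ---------------------------------------------------------------------------

_COORD_CACHE: Dict[str, Tuple[Tuple[str, ...], list, list]] = {}


def symbolic_cf_coords(family: str):
    """(parameter names, sympy symbols, CF coordinate polynomials) for a
    catalog network family, cached."""
    import sympy

    from .cfengine import cf_table
    from .fixtures import NETWORK_CATALOG, NamedNetworkSpec, make_named

    if family in _COORD_CACHE:
        return _COORD_CACHE[family]
    keys, _ = NETWORK_CATALOG[family]
    syms = sympy.symbols([f"p_{k}" for k in keys], positive=True)
    params = dict(zip(keys, syms))
    net = make_named(NamedNetworkSpec(family, params))
    table = cf_table(net, expand=True)
    coords = []
    for q in table.quartets():
        coords.extend(table.data[q].values)
    _COORD_CACHE[family] = (keys, list(syms), coords)
    return _COORD_CACHE[family]


def _pvector_coords():
    import sympy

    from .cfengine import p_vector

    keys = ("gamma", "l1", "l2", "l3", "h1", "h2", "x")
    syms = sympy.symbols([f"p_{k}" for k in keys], positive=True)
    g, l1, l2, l3, h1, h2, x = syms
    coords = [sympy.expand(e) for e in p_vector(g, l1, l2, l3, h1, h2, x)]
    return keys, list(syms), coords


def variety_dimension(family: str, point: Dict[str, Any], confirm: bool = True) -> int:
    """Exact rank of the Jacobian of the CF parameterization at a point.

    ``family`` is a catalog network name, or ``"pvector"`` for the map from
    the seven 3-cycle block parameters to the six block probabilities.
    With ``confirm``, the rank is re-evaluated at a second pseudo-random
    rational point and a genericity warning is raised on mismatch.
    """
    import sympy

    if family == "pvector":
        keys, syms, coords = _pvector_coords()
    else:
        keys, syms, coords = symbolic_cf_coords(family)
    J = sympy.Matrix(coords).jacobian(sympy.Matrix(syms))

    def rank_at(vals: Dict[str, Any]) -> int:
        subs = {s: sympy.Rational(Fraction(vals[k])) for s, k in zip(syms, keys)}
        return J.subs(subs).rank()

    r = rank_at(point)
    if confirm:
        primes = [101, 103, 107, 109, 113, 127, 131, 137]
        alt = {k: Fraction(p, 211) for k, p in zip(keys, primes)}
        r2 = rank_at(alt)
        if r2 != r:
            warnings.warn(
                f"rank {r} at the given point differs from rank {r2} at a "
                "second point; the point may be non-generic"
            )
    return r


# ---------------------------------------------------------------------------
# 4-cycle hybrid placement by model fitting
# ---------------------------------------------------------------------------

@dataclass
class FourCycleCall:
    verdict: Tuple[str, ...]  # subset of ("s", "w", "n")
    residuals: Dict[str, float]
    best_position: Optional[int]
    generator_values: Dict[str, Tuple[float, ...]] = field(default_factory=dict)
    inconclusive: bool = False


_FIT_CACHE: Dict[int, Any] = {}


def _candidate_cf_map(position: int):
    """Lambdified CF map (and Jacobian) of a 5-taxon 4-cycle network with a
    cherry at cyclic block 0 and the hybrid node at cyclic ``position``."""
    import sympy

    from .cfengine import cf_table
    from .netmodel import Edge, Network

    if position in _FIT_CACHE:
        return _FIT_CACHE[position]
    g = sympy.Symbol("g", positive=True)
    x1, x2, ell = sympy.symbols("x1 x2 ell", positive=True)
    if position == 0:
        h1, h2 = sympy.symbols("h1 h2", positive=True)
        syms = [g, h1, h2, x1, x2, ell]
    else:
        syms = [g, x1, x2, ell]
    # cycle nodes n0..n3 carry blocks 0..3; hybrid at n{position}
    nodes = [f"_n{i}" for i in range(4)]
    hyb = nodes[position]
    neighbors = [nodes[(position - 1) % 4], nodes[(position + 1) % 4]]
    opposite = nodes[(position + 2) % 4]
    edges = []
    hprob = (h1, h2) if position == 0 else (None, None)
    edges.append(Edge(neighbors[0], hyb, kind="hybrid", gamma=g, prob=hprob[0]))
    edges.append(Edge(neighbors[1], hyb, kind="hybrid", gamma=1 - g, prob=hprob[1]))
    edges.append(Edge(opposite, neighbors[0], prob=x1))
    edges.append(Edge(opposite, neighbors[1], prob=x2))
    # blocks: 0 = cherry (p1, p2); 1..3 singletons q1..q3
    edges.append(Edge(nodes[0], "_ch", prob=ell))
    edges += [Edge("_ch", "p1"), Edge("_ch", "p2")]
    for i in (1, 2, 3):
        if nodes[i] == opposite:
            continue
        edges.append(Edge(nodes[i], f"q{i}"))
    # root above the node opposite the hybrid
    opp_block = (position + 2) % 4
    if opp_block == 0:
        # hybrid opposite the cherry: root on the cherry cut edge
        edges = [e for e in edges if not (e.u == nodes[0] and e.v == "_ch")]
        edges.append(Edge("_R", "_ch", prob=ell))
        edges.append(Edge("_R", nodes[0]))
        # nodes[0] is 'opposite' here, so re-orient the two x edges
        for e in edges:
            if e.prob is x1 and e.u != nodes[0]:
                e.u, e.v = nodes[0], neighbors[0]
            if e.prob is x2 and e.u != nodes[0]:
                e.u, e.v = nodes[0], neighbors[1]
        root = "_R"
    else:
        edges.append(Edge("_R", f"q{opp_block}"))
        edges.append(Edge("_R", opposite))
        root = "_R"
    net = Network(edges, rooted=True, root=root, validate=True)
    table = cf_table(net, expand=True)
    coords = []
    for q in table.quartets():
        coords.extend(table.data[q].values)
    quartet_order = table.quartets()
    vec = sympy.Matrix(coords)
    jac = vec.jacobian(sympy.Matrix(syms))
    import numpy as np

    f = sympy.lambdify(syms, coords, "numpy")
    jf = sympy.lambdify(syms, jac, "numpy")
    _FIT_CACHE[position] = (len(syms), f, jf, quartet_order)
    return _FIT_CACHE[position]


def _observed_vector(table: CFTable, labels: Dict[str, str], quartet_order):
    """Observed CFs mapped into the candidate's canonical label space."""
    inv = labels  # canonical -> actual
    out = []
    for q in quartet_order:
        actual = [inv[t] for t in q]
        a, b, c, d = q
        out.append(float(table.cf(inv[a], inv[b], inv[c], inv[d])))
        out.append(float(table.cf(inv[a], inv[c], inv[b], inv[d])))
        out.append(float(table.cf(inv[a], inv[d], inv[b], inv[c])))
    import numpy as np

    return np.array(out)


def orient_four_cycle(
    table: CFTable,
    blocks: Sequence[Sequence[str]],
    pair_block: int = 0,
    seed: int = 0,
    n_starts: int = 8,
    residual_tol: float = 1e-8,
) -> FourCycleCall:
    """Place the hybrid node of a known undirected 4-cycle from CFs.

    ``blocks`` lists the four taxon blocks in cyclic order around the cycle;
    one block (``pair_block``) must have two or more taxa, providing the
    cherry pair of representatives.  Each hybrid position (at the pair
    block: "s"; adjacent: "w"; opposite: "n") is fit to the observed CFs by
    bounded least squares against the exact CF map; a position is accepted
    when its residual is below ``residual_tol``.  Since the s-variety
    contains the other two, the verdict is the set of most specific
    positions that fit.
    """
    import numpy as np
    from scipy.optimize import least_squares

    blocks = [tuple(b) for b in blocks]
    if len(blocks) != 4:
        raise NetworkError("need 4 blocks in cyclic order")
    blocks = blocks[pair_block:] + blocks[:pair_block]
    if len(blocks[0]) < 2:
        raise NetworkError("the pair block needs at least 2 taxa")
    labels = {
        "p1": blocks[0][0],
        "p2": blocks[0][1],
        "q1": blocks[1][0],
        "q2": blocks[2][0],
        "q3": blocks[3][0],
    }
    rng = np.random.default_rng(seed)
    residuals: Dict[str, float] = {}
    fits: Dict[int, float] = {}
    for position in range(4):
        nparams, f, jf, quartet_order = _candidate_cf_map(position)
        y = _observed_vector(table, labels, quartet_order)
        if np.allclose(y, 1.0 / 3, atol=1e-12):
            return FourCycleCall((), {}, None, inconclusive=True)

        def resid(theta):
            return np.asarray(f(*theta), dtype=float) - y

        def jac(theta):
            return np.asarray(jf(*theta), dtype=float)

        best = math.inf
        for s in range(n_starts):
            theta0 = rng.uniform(0.05, 0.95, size=nparams)
            try:
                sol = least_squares(resid, theta0, jac=jac, bounds=(1e-9, 1.0), xtol=1e-14, ftol=1e-14, gtol=1e-14)
            except Exception:
                continue
            best = min(best, 2 * sol.cost)
            if best < residual_tol ** 2:
                break
        fits[position] = best
    pos_name = {0: "s", 1: "w", 2: "n", 3: "w"}
    for position, r in fits.items():
        key = f"{pos_name[position]}@{position}"
        residuals[key] = math.sqrt(max(r, 0.0))
    accepted = {p for p, r in fits.items() if math.sqrt(max(r, 0.0)) < residual_tol}
    specific = {pos_name[p] for p in accepted if p != 0}
    if specific:
        verdict = tuple(sorted(specific))
        best_pos = min((p for p in accepted if p != 0), key=lambda p: fits[p])
    elif 0 in accepted:
        verdict = ("s",)
        best_pos = 0
    else:
        verdict = ()
        best_pos = None
    gens = _generator_evidence(table, labels)
    return FourCycleCall(verdict, residuals, best_pos, gens, inconclusive=not verdict)


def _generator_evidence(table: CFTable, labels: Dict[str, str]) -> Dict[str, Tuple[float, ...]]:
    """Values of the printed extra generators of the three components of the
    intersection of the adjacent- and opposite-placement varieties."""
    roles = {"a": (labels["p1"], labels["p2"]), "b": (labels["q1"],), "c": (labels["q2"],), "d": (labels["q3"],)}

    def p(pat):
        return float(cf_pattern(table, pat, roles))

    v1 = (p("ab|cd") - p("ac|bd"), p("ab|ad") - p("ac|ad"), 3 * p("ac|ad") * p("ac|bd") - p("ab|ac"))
    v2 = (p("ab|cd") + 2 * p("ac|bd") - 1, p("ab|ad") - p("ab|ac"), 3 * p("ab|ac") * p("ac|bd") - p("ac|ad"))
    v3 = (p("ac|ad"), p("ab|ac"), p("ab|ad"))
    return {"V1": v1, "V2": v2, "V3": v3}
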
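"""Data model and graph operations for binary level-1 phylogenetic networks.

A :class:`Network` stores a rooted or semidirected metric network.  Edges are
directed parent-to-child; for a semidirected network the stored orientation of
tree edges is an arbitrary valid one and carries no meaning, while hybrid
edges are always meaningfully directed into their hybrid node and carry an
inheritance probability ``gamma``.

Edge "lengths" are in coalescent units.  The derived *edge probability*
``l = exp(-t)`` (the chance that two lineages entering the edge fail to
coalesce on it) may instead be stored directly as an exact rational or a
symbolic expression; this is what makes exact-rational CF computation
possible.  An edge with neither a length nor a probability is treated as
zero-length (probability 1, i.e. no coalescence is possible on it).
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field, replace as _dc_replace
from fractions import Fraction
from typing import Any, Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple


class NetworkError(ValueError):
    """Raised for malformed networks or invalid operations on them."""


# ---------------------------------------------------------------------------
# Edges and networks
# ---------------------------------------------------------------------------

_EDGE_COUNTER = itertools.count()


@dataclass
class Edge:
    """A network edge from ``u`` (parent side) to ``v`` (child side).

    ``kind`` is ``"tree"`` or ``"hybrid"``; hybrid edges point into a hybrid
    node and carry ``gamma``.  ``length`` is in coalescent units; ``prob``
    optionally stores the edge probability exp(-length) directly (exact or
    symbolic).  ``src`` records the ids of original edges a merged edge was
    built from, so induced networks can be mapped back.
    """

    u: Any
    v: Any
    kind: str = "tree"
    length: Any = None
    prob: Any = None
    gamma: Any = None
    eid: int = field(default_factory=lambda: next(_EDGE_COUNTER))
    src: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("tree", "hybrid"):
            raise NetworkError(f"unknown edge kind {self.kind!r}")
        if not self.src:
            self.src = (self.eid,)

    def edge_prob(self) -> Any:
        """Edge probability exp(-t); missing lengths count as zero length."""
        if self.prob is not None:
            return self.prob
        if self.length is not None:
            try:
                return math.exp(-float(self.length))
            except TypeError:  # symbolic length
                import sympy

                return sympy.exp(-self.length)
        return 1

    def has_metric(self) -> bool:
        return self.prob is not None or self.length is not None

    def nodes(self) -> Tuple[Any, Any]:
        return (self.u, self.v)

    def other(self, n: Any) -> Any:
        if n == self.u:
            return self.v
        if n == self.v:
            return self.u
        raise KeyError(n)

    def copy(self, **kw) -> "Edge":
        e = _dc_replace(self, **kw)
        e.src = kw.get("src", self.src)
        return e


@dataclass
class CycleRecord:
    """An undirected cycle of a level-1 network with its taxon blocks.

    ``blocks`` is ordered around the cycle starting at the hybrid node, so
    ``blocks[0]`` is the hybrid block and ``k == len(blocks[0])``.
    ``nodes`` follows the same circular order.
    """

    edges: List[Edge]
    hybrid_node: Any
    m: int
    k: int
    blocks: List[FrozenSet[str]]
    nodes: List[Any]

    @property
    def hybrid_block(self) -> FrozenSet[str]:
        return self.blocks[0]

    def block_sizes(self) -> Tuple[int, ...]:
        return tuple(len(b) for b in self.blocks)


def quartet_key(taxa: Iterable[str]) -> Tuple[str, str, str, str]:
    """Canonical (lexicographic) key for an unordered quartet of taxa."""
    t = tuple(sorted(taxa))
    if len(t) != 4 or len(set(t)) != 4:
        raise NetworkError(f"a quartet needs 4 distinct taxa, got {t}")
    return t


class CFVector:
    """The three concordance factors of one quartet, in canonical order.

    For sorted taxa ``(a, b, c, d)`` the entries are the probabilities of the
    splits ``ab|cd``, ``ac|bd`` and ``ad|bc``.
    """

    __slots__ = ("taxa", "values")

    def __init__(self, taxa: Iterable[str], values: Sequence[Any]):
        self.taxa = quartet_key(taxa)
        vals = tuple(values)
        if len(vals) != 3:
            raise NetworkError("a CF vector has exactly 3 entries")
        self.values = vals

    def cf(self, x: str, y: str) -> Any:
        """CF of the split pairing taxa ``x`` and ``y`` (against the rest)."""
        a, b, c, d = self.taxa
        pair = frozenset((x, y))
        if pair == frozenset((a, b)) or pair == frozenset((c, d)):
            return self.values[0]
        if pair == frozenset((a, c)) or pair == frozenset((b, d)):
            return self.values[1]
        if pair == frozenset((a, d)) or pair == frozenset((b, c)):
            return self.values[2]
        raise KeyError((x, y))

    def __iter__(self):
        return iter(self.values)

    def __repr__(self) -> str:
        return f"CFVector({self.taxa}, {self.values})"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CFVector)
            and self.taxa == other.taxa
            and all(a == b for a, b in zip(self.values, other.values))
        )


class CFTable:
    """Concordance factors for every 4-subset of a taxon set."""

    def __init__(self, taxa: Iterable[str]):
        self.taxa = sorted(taxa)
        self.data: Dict[Tuple[str, str, str, str], CFVector] = {}
        self.ngenes: Dict[Tuple[str, str, str, str], int] = {}

    def set(self, vec: CFVector, ngenes: Optional[int] = None) -> None:
        self.data[vec.taxa] = vec
        if ngenes is not None:
            self.ngenes[vec.taxa] = ngenes

    def get(self, taxa: Iterable[str]) -> CFVector:
        return self.data[quartet_key(taxa)]

    def cf(self, x: str, y: str, z: str, w: str) -> Any:
        """CF of the labelled split ``xy|zw``."""
        return self.get((x, y, z, w)).cf(x, y)

    def quartets(self) -> List[Tuple[str, str, str, str]]:
        return sorted(self.data)

    def is_complete(self) -> bool:
        return all(quartet_key(q) in self.data for q in itertools.combinations(self.taxa, 4))

    # -- CSV interface ------------------------------------------------------
    CSV_HEADER = ["taxon1", "taxon2", "taxon3", "taxon4", "CF12_34", "CF13_24", "CF14_23"]

    def to_csv(self, path, exact: bool = False) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            header = list(self.CSV_HEADER)
            if self.ngenes:
                header.append("ngenes")
            w.writerow(header)
            for key in self.quartets():
                vec = self.data[key]
                if exact:
                    vals = [str(Fraction(v)) for v in vec.values]
                else:
                    vals = [repr(float(v)) for v in vec.values]
                row = list(key) + vals
                if self.ngenes:
                    row.append(self.ngenes.get(key, ""))
                w.writerow(row)

    @classmethod
    def from_csv(cls, path) -> "CFTable":
        import csv

        taxa = set()
        rows = []
        with open(path) as fh:
            reader = csv.DictReader(fh)
            for row in reader:
                rows.append(row)
                taxa.update(row[f"taxon{i}"] for i in range(1, 5))
        table = cls(taxa)
        for row in rows:
            q = [row[f"taxon{i}"] for i in range(1, 5)]
            vals = [_parse_number(row[c]) for c in ("CF12_34", "CF13_24", "CF14_23")]
            key = quartet_key(q)
            if tuple(q) != key:
                # reorder the three entries to the canonical taxon order
                pairs = {frozenset((q[0], q[1])): vals[0], frozenset((q[0], q[2])): vals[1], frozenset((q[0], q[3])): vals[2]}
                a, b, c, d = key
                vals = [_lookup_split(pairs, a, b, c, d), _lookup_split(pairs, a, c, b, d), _lookup_split(pairs, a, d, b, c)]
            vec = CFVector(key, vals)
            ng = row.get("ngenes")
            table.set(vec, int(ng) if ng else None)
        return table


def _lookup_split(pairs, x, y, z, w):
    key = frozenset((x, y))
    if key in pairs:
        return pairs[key]
    return pairs[frozenset((z, w))]


def _parse_number(s: str):
    s = s.strip()
    if "/" in s:
        return Fraction(s)
    f = float(s)
    return f


class Network:
    """A binary rooted or semidirected metric phylogenetic network."""

    def __init__(self, edges: Iterable[Edge], rooted: bool, root: Any = None, validate: bool = True):
        self.edges: List[Edge] = list(edges)
        self.rooted = rooted
        self.root = root
        self.nodes = set()
        for e in self.edges:
            self.nodes.add(e.u)
            self.nodes.add(e.v)
        if rooted and root is None:
            raise NetworkError("rooted network needs a root")
        if rooted and root not in self.nodes and self.edges:
            raise NetworkError("root is not a node of the network")
        self._adj: Dict[Any, List[Edge]] = {n: [] for n in self.nodes}
        for e in self.edges:
            self._adj[e.u].append(e)
            self._adj[e.v].append(e)
        if validate:
            self.validate()

    # -- basic accessors ----------------------------------------------------
    def incident(self, n: Any) -> List[Edge]:
        return self._adj[n]

    def degree(self, n: Any) -> int:
        return len(self._adj[n])

    def children_edges(self, n: Any) -> List[Edge]:
        return [e for e in self._adj[n] if e.u == n]

    def parent_edges(self, n: Any) -> List[Edge]:
        return [e for e in self._adj[n] if e.v == n]

    def leaves(self) -> List[Any]:
        return sorted(n for n in self.nodes if self.degree(n) == 1)

    @property
    def taxa(self) -> List[str]:
        return self.leaves()

    def hybrid_nodes(self) -> List[Any]:
        seen = {}
        for e in self.edges:
            if e.kind == "hybrid":
                seen.setdefault(e.v, []).append(e)
        return sorted(seen, key=str)

    def hybrid_parent_edges(self, n: Any) -> List[Edge]:
        return [e for e in self._adj[n] if e.kind == "hybrid" and e.v == n]

    def is_pendant(self, e: Edge) -> bool:
        return self.degree(e.u) == 1 or self.degree(e.v) == 1

    def edge_by_id(self, eid: int) -> Edge:
        for e in self.edges:
            if e.eid == eid:
                return e
        raise KeyError(eid)

    def copy(self) -> "Network":
        return Network([e.copy() for e in self.edges], self.rooted, self.root, validate=False)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        if not self.edges:
            raise NetworkError("empty network")
        leaves = [n for n in self.nodes if self.degree(n) == 1]
        if len(set(leaves)) != len(leaves):
            raise NetworkError("duplicate taxon labels")
        for n in self.nodes:
            hyb_in = self.hybrid_parent_edges(n)
            deg = self.degree(n)
            if hyb_in:
                if len(hyb_in) != 2:
                    raise NetworkError(f"hybrid node {n} has {len(hyb_in)} hybrid parent edges")
                if deg != 3:
                    raise NetworkError(f"hybrid node {n} is not binary")
                g1, g2 = (e.gamma for e in hyb_in)
                if g1 is None or g2 is None:
                    raise NetworkError(f"hybrid edges into {n} are missing gamma")
                if not _sums_to_one(g1, g2):
                    raise NetworkError("gamma pair does not sum to 1")
            elif self.rooted and n == self.root:
                if len(self.parent_edges(n)) != 0:
                    raise NetworkError("root has a parent edge")
                if len(self.children_edges(n)) != 2 and deg != 1:
                    raise NetworkError("root must have outdegree 2")
            else:
                if deg not in (1, 3) and not (not self.rooted and deg == 2):
                    raise NetworkError(f"non-binary node {n} (degree {deg})")
                if self.rooted and deg == 3 and len(self.parent_edges(n)) != 1:
                    raise NetworkError(f"tree node {n} must have indegree 1")
        find_cycles(self)  # raises on level-1 violations

    # -- convenience --------------------------------------------------------
    def __repr__(self) -> str:
        kind = "rooted" if self.rooted else "semidirected"
        return f"<Network {kind}, {len(self.taxa)} taxa, {len(self.edges)} edges>"


def _sums_to_one(g1, g2) -> bool:
    try:
        s = g1 + g2
    except TypeError:
        return True
    try:
        import sympy

        if isinstance(s, sympy.Basic):
            return sympy.simplify(s - 1) == 0
    except ImportError:  # pragma: no cover
        pass
    if isinstance(s, float) or isinstance(g1, float) or isinstance(g2, float):
        return abs(float(s) - 1.0) < 1e-9
    return s == 1


# ---------------------------------------------------------------------------
# Extended Newick I/O
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|,|;|[^(),;:]+|:")


def parse_network(text: str) -> Network:
    """Parse an extended-Newick string into a rooted :class:`Network`.

    Hybrid nodes are tagged ``#H<k>``; the annotation convention is
    ``name:length:support:gamma``.  A gamma missing from one of a hybrid
    pair's edges is inferred as ``1 - gamma`` of the other.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NetworkError("Newick string must end with ';'")
    pos = 0
    s = text[:-1]
    counter = itertools.count()
    edges: List[Edge] = []
    hybrids: Dict[str, Any] = {}
    hybrid_edges: Dict[str, List[Edge]] = {}

    def new_node() -> str:
        return f"_n{next(counter)}"

    def parse_clade(parent: Optional[Any]):
        nonlocal pos
        children: List[Any] = []
        if pos < len(s) and s[pos] == "(":
            pos += 1
            node = new_node()
            while True:
                parse_clade(node)
                if pos >= len(s):
                    raise NetworkError("unbalanced parentheses")
                if s[pos] == ",":
                    pos += 1
                    continue
                if s[pos] == ")":
                    pos += 1
                    break
                raise NetworkError(f"unexpected character {s[pos]!r}")
        else:
            node = None
        # label and annotations
        m = re.match(r"[^(),:;]*", s[pos:])
        label = m.group(0) if m else ""
        pos += len(label)
        fields = []
        while pos < len(s) and s[pos] == ":":
            pos += 1
            m = re.match(r"[^(),:;]*", s[pos:])
            tok = m.group(0)
            pos += len(tok)
            fields.append(tok)
        length = _num_or_none(fields[0]) if len(fields) >= 1 else None
        gamma = _num_or_none(fields[2]) if len(fields) >= 3 else None

        hybrid_tag = None
        hm = re.search(r"#\w+", label)
        if hm:
            hybrid_tag = hm.group(0)
            label = label[: hm.start()]

        if hybrid_tag is not None:
            if hybrid_tag in hybrids:
                node_id = hybrids[hybrid_tag]
            else:
                node_id = node if node is not None else (label or new_node())
                hybrids[hybrid_tag] = node_id
            if node is not None and node != node_id:
                # merge: re-point edges created under the placeholder id
                for e in edges:
                    if e.u == node:
                        e.u = node_id
                    if e.v == node:
                        e.v = node_id
            if parent is None:
                raise NetworkError("hybrid tag at the network root")
            e = Edge(parent, node_id, kind="hybrid", length=length, gamma=gamma)
            edges.append(e)
            hybrid_edges.setdefault(hybrid_tag, []).append(e)
            return node_id
        if node is None:
            if not label:
                raise NetworkError("leaf without a label")
            node = label
        if parent is not None:
            edges.append(Edge(parent, node, kind="tree", length=length))
        return node

    root = parse_clade(None)
    if pos != len(s):
        raise NetworkError(f"trailing characters: {s[pos:]!r}")
    for tag, pair in hybrid_edges.items():
        if len(pair) != 2:
            raise NetworkError(f"hybrid tag {tag} appears {len(pair)} times, need 2")
        g1, g2 = pair[0].gamma, pair[1].gamma
        if g1 is None and g2 is None:
            raise NetworkError(f"no gamma given for hybrid {tag}")
        if g1 is None:
            pair[0].gamma = 1 - g2
        if g2 is None:
            pair[1].gamma = 1 - g1
    return Network(edges, rooted=True, root=root)


def _num_or_none(tok: str):
    tok = tok.strip()
    if not tok:
        return None
    if "/" in tok:
        return Fraction(tok)
    try:
        return Fraction(tok)  # exact for decimal strings
    except ValueError:
        return float(tok)


def write_network(net: Network) -> str:
    """Serialize a network to extended Newick (rooting one if needed)."""
    if not net.rooted:
        net = rooted_version(net)
    hybrid_tags: Dict[Any, str] = {}
    for i, h in enumerate(net.hybrid_nodes(), start=1):
        hybrid_tags[h] = f"#H{i}"
    written = set()

    def annot(e: Edge) -> str:
        out = ""
        if e.length is not None or e.gamma is not None or e.prob is not None:
            ln = e.length
            if ln is None and e.prob is not None:
                try:
                    ln = -math.log(float(e.prob))
                except (TypeError, ValueError):
                    ln = None
            out += ":" + (_fmt_num(ln) if ln is not None else "")
        if e.gamma is not None:
            out += "::" + _fmt_num(e.gamma)
        return out

    def subtree(node: Any, in_edge: Optional[Edge]) -> str:
        tag = hybrid_tags.get(node, "")
        if tag and node in written:
            return tag + (annot(in_edge) if in_edge is not None else "")
        written.add(node)
        kids = net.children_edges(node)
        if not kids:
            return str(node) + (annot(in_edge) if in_edge is not None else "")
        inner = ",".join(subtree(e.v, e) for e in kids)
        lbl = tag
        return f"({inner}){lbl}" + (annot(in_edge) if in_edge is not None else "")

    return subtree(net.root, None) + ";"


def _fmt_num(x) -> str:
    if isinstance(x, Fraction):
        return str(x)
    return repr(float(x))


# ---------------------------------------------------------------------------
# Rooting and semidirecting
# ---------------------------------------------------------------------------

def _orient_from(net: Network, root: Any) -> Optional[List[Edge]]:
    """Orient all edges away from ``root``; None if no valid orientation."""
    oriented: Dict[int, Tuple[Any, Any]] = {}
    for e in net.edges:
        if e.kind == "hybrid":
            oriented[e.eid] = (e.u, e.v)
    visited = {root}
    frontier = [root]
    while frontier:
        n = frontier.pop()
        for e in net.incident(n):
            if e.eid in oriented:
                u, v = oriented[e.eid]
                if u == n and v not in visited:
                    visited.add(v)
                    frontier.append(v)
                continue
            other = e.other(n)
            oriented[e.eid] = (n, other)
            if other not in visited:
                visited.add(other)
                frontier.append(other)
    if len(oriented) != len(net.edges) or visited != net.nodes:
        return None
    indeg: Dict[Any, int] = {n: 0 for n in net.nodes}
    for u, v in oriented.values():
        indeg[v] += 1
    hybrids = set(net.hybrid_nodes())
    for n in net.nodes:
        want = 0 if n == root else (2 if n in hybrids else 1)
        if indeg[n] != want:
            return None
    out = []
    for e in net.edges:
        u, v = oriented[e.eid]
        out.append(e.copy(u=u, v=v))
    return out


def valid_rootings(net: Network) -> List[Edge]:
    """Tree edges of a semidirected network on which a root may be placed."""
    out = []
    for e in net.edges:
        if e.kind == "hybrid":
            continue
        test = _root_on_edge(net, e)
        if test is not None:
            out.append(e)
    return out


def _root_on_edge(net: Network, e: Edge) -> Optional[Network]:
    rootname = "_root"
    others = [x for x in net.edges if x.eid != e.eid]
    half1 = Edge(rootname, e.u, kind="tree", length=e.length, prob=e.prob, src=e.src)
    half2 = Edge(rootname, e.v, kind="tree", length=0, prob=1, src=())
    half2.src = ()
    cand = Network(others + [half1, half2], rooted=False, root=None, validate=False)
    oriented = _orient_from(cand, rootname)
    if oriented is None:
        return None
    return Network(oriented, rooted=True, root=rootname, validate=False)


def rooted_version(net: Network) -> Network:
    """A valid rooted realization of a semidirected network.

    CF computations are invariant to the choice (Lemma-style rooting
    invariance), so the lexicographically first valid rooting edge is used.
    """
    if net.rooted:
        return net
    candidates = sorted(
        (e for e in net.edges if e.kind != "hybrid"),
        key=lambda e: (str(min(e.u, e.v, key=str)), str(max(e.u, e.v, key=str)), e.eid),
    )
    for e in candidates:
        r = _root_on_edge(net, e)
        if r is not None:
            return r
    raise NetworkError("semidirected network admits no valid rooting")


def all_rootings(net: Network) -> List[Network]:
    if net.rooted:
        net = to_semidirected(net)
    out = []
    for e in net.edges:
        if e.kind == "hybrid":
            continue
        r = _root_on_edge(net, e)
        if r is not None:
            out.append(r)
    return out


def _merge_chain(e1: Edge, e2: Edge) -> Edge:
    """Merge two edges around a suppressed degree-2 node; lengths sum."""
    if e1.length is None and e2.length is None:
        length = None
    else:
        length = (e1.length or 0) + (e2.length or 0)
    if e1.prob is None and e2.prob is None:
        prob = None
    else:
        p1 = 1 if e1.prob is None and e1.length is None else e1.edge_prob()
        p2 = 1 if e2.prob is None and e2.length is None else e2.edge_prob()
        prob = p1 * p2
    hybrid = e2.kind == "hybrid"
    return Edge(
        e1.u,
        e2.v,
        kind="hybrid" if hybrid else "tree",
        length=length,
        prob=prob,
        gamma=e2.gamma if hybrid else None,
        src=tuple(e1.src) + tuple(e2.src),
    )


def _suppress_degree_two(edges: List[Edge], keep: Iterable[Any] = ()) -> List[Edge]:
    keep = set(keep)
    edges = list(edges)
    changed = True
    while changed:
        changed = False
        incid: Dict[Any, List[Edge]] = {}
        for e in edges:
            incid.setdefault(e.u, []).append(e)
            incid.setdefault(e.v, []).append(e)
        for n, es in incid.items():
            if n in keep or len(es) != 2:
                continue
            e1, e2 = es
            if e1.v == n and e2.u == n:
                merged = _merge_chain(e1, e2)
            elif e2.v == n and e1.u == n:
                merged = _merge_chain(e2, e1)
            else:
                # both in or both out: not an in/out chain (e.g. a root)
                if e1.u == n and e2.u == n:
                    # suppressed root: undirect by flipping one side
                    flip = e1.copy(u=e1.v, v=e1.u)
                    merged = _merge_chain(flip, e2)
                else:
                    continue
            edges = [x for x in edges if x.eid not in (e1.eid, e2.eid)]
            edges.append(merged)
            changed = True
            break
    return edges


def descendant_leaves(net: Network, node: Any, cache: Optional[Dict] = None) -> FrozenSet[str]:
    if cache is not None and node in cache:
        return cache[node]
    kids = net.children_edges(node)
    if not kids:
        out = frozenset([node])
    else:
        acc = set()
        for e in kids:
            acc |= descendant_leaves(net, e.v, cache)
        out = frozenset(acc)
    if cache is not None:
        cache[node] = out
    return out


def least_stable_ancestor(net: Network) -> Any:
    """The lowest node through which every root-to-leaf path passes."""
    if not net.rooted:
        raise NetworkError("LSA requires a rooted network")
    leaves = set(net.leaves())
    dominators = []
    for n in net.nodes:
        if n in leaves and len(leaves) > 1:
            continue
        reach = _reachable_leaves_avoiding(net, n)
        if not reach:
            dominators.append(n)
    cache: Dict = {}
    depth = {net.root: 0}
    frontier = [net.root]
    while frontier:
        n = frontier.pop()
        for e in net.children_edges(n):
            d = depth[n] + 1
            if e.v not in depth or d > depth[e.v]:
                depth[e.v] = d
                frontier.append(e.v)
    dominators.sort(key=lambda n: (len(descendant_leaves(net, n, cache)), -depth.get(n, 0)))
    return dominators[0]


def _reachable_leaves_avoiding(net: Network, avoid: Any) -> set:
    if net.root == avoid:
        return set()
    seen = {net.root}
    stack = [net.root]
    leaves = set()
    while stack:
        n = stack.pop()
        for e in net.children_edges(n):
            v = e.v
            if v == avoid or v in seen:
                continue
            seen.add(v)
            if net.degree(v) == 1:
                leaves.add(v)
            stack.append(v)
    return leaves


def to_semidirected(net: Network) -> Network:
    """Drop structure above the LSA, suppress it, and unroot."""
    if not net.rooted:
        return net.copy()
    if len(net.leaves()) < 2:
        raise NetworkError("need at least 2 taxa")
    lsa = least_stable_ancestor(net)
    below = {lsa}
    stack = [lsa]
    while stack:
        n = stack.pop()
        for e in net.children_edges(n):
            if e.v not in below:
                below.add(e.v)
                stack.append(e.v)
    edges = [e.copy() for e in net.edges if e.u in below and e.v in below]
    leaves = set(net.leaves())
    edges = _suppress_degree_two(edges, keep=leaves)
    return Network(edges, rooted=False, root=None, validate=False)


# ---------------------------------------------------------------------------
# Cycles and level-1 validation
# ---------------------------------------------------------------------------

def _is_bridge(edges: List[Edge], e: Edge) -> bool:
    adj: Dict[Any, List[Edge]] = {}
    for x in edges:
        if x.eid == e.eid:
            continue
        adj.setdefault(x.u, []).append(x)
        adj.setdefault(x.v, []).append(x)
    seen = {e.u}
    stack = [e.u]
    while stack:
        n = stack.pop()
        for x in adj.get(n, ()):  # undirected walk
            o = x.other(n)
            if o not in seen:
                seen.add(o)
                stack.append(o)
    return e.v not in seen


def find_cycles(net: Network) -> List[CycleRecord]:
    """All undirected cycles; raises NetworkError if the network is not level-1."""
    cyc_edges = [e for e in net.edges if not _is_bridge(net.edges, e)]
    # connected components of the cycle edges
    comps: List[List[Edge]] = []
    remaining = list(cyc_edges)
    while remaining:
        comp = [remaining.pop()]
        nodes = set(comp[0].nodes())
        grew = True
        while grew:
            grew = False
            for e in list(remaining):
                if e.u in nodes or e.v in nodes:
                    comp.append(e)
                    nodes |= set(e.nodes())
                    remaining.remove(e)
                    grew = True
        comps.append(comp)
    records = []
    for comp in comps:
        count: Dict[Any, int] = {}
        for e in comp:
            count[e.u] = count.get(e.u, 0) + 1
            count[e.v] = count.get(e.v, 0) + 1
        if any(c != 2 for c in count.values()):
            raise NetworkError("not level-1: two cycles share a node")
        hybrids = [n for n in count if len([e for e in comp if e.kind == "hybrid" and e.v == n]) == 2]
        if len(hybrids) != 1:
            raise NetworkError("cycle without a unique hybrid node")
        hyb = hybrids[0]
        # order nodes around the cycle starting at the hybrid node
        order = [hyb]
        used = set()
        while len(order) < len(count):
            cur = order[-1]
            nxt = None
            for e in comp:
                if e.eid in used:
                    continue
                if cur in e.nodes():
                    nxt = e.other(cur)
                    used.add(e.eid)
                    break
            order.append(nxt)
        blocks = []
        cyc_ids = {e.eid for e in comp}
        for n in order:
            blocks.append(_block_taxa(net, n, cyc_ids))
        records.append(
            CycleRecord(
                edges=comp,
                hybrid_node=hyb,
                m=len(comp),
                k=len(blocks[0]),
                blocks=blocks,
                nodes=order,
            )
        )
    records.sort(key=lambda r: (r.m, str(r.hybrid_node)))
    return records


def _block_taxa(net: Network, node: Any, cycle_edge_ids: set) -> FrozenSet[str]:
    leaves = set(net.leaves())
    seen = {node}
    stack = [node]
    taxa = set()
    if node in leaves:
        taxa.add(node)
    while stack:
        n = stack.pop()
        for e in net.incident(n):
            if e.eid in cycle_edge_ids:
                continue
            o = e.other(n)
            if o in seen:
                continue
            seen.add(o)
            if o in leaves:
                taxa.add(o)
            stack.append(o)
    return frozenset(taxa)


# ---------------------------------------------------------------------------
# Restriction, 2-cycle removal, pseudotaxa
# ---------------------------------------------------------------------------

def induced_network(net: Network, taxa: Iterable[str], suppress: bool = True) -> Network:
    """The induced (semidirected) network on a subset of the taxa."""
    taxa = set(taxa)
    missing = taxa - set(net.leaves())
    if missing:
        raise NetworkError(f"taxa not in network: {sorted(missing)}")
    rnet = net if net.rooted else rooted_version(net)
    cache: Dict = {}
    keep_nodes = {n for n in rnet.nodes if descendant_leaves(rnet, n, cache) & taxa}
    edges = [e.copy() for e in rnet.edges if e.u in keep_nodes and e.v in keep_nodes]
    sub = Network(edges, rooted=True, root=rnet.root, validate=False)
    # trim above the new LSA, then optionally suppress degree-2 chains
    lsa = least_stable_ancestor(sub)
    below = {lsa}
    stack = [lsa]
    while stack:
        n = stack.pop()
        for e in sub.children_edges(n):
            if e.v not in below:
                below.add(e.v)
                stack.append(e.v)
    edges = [e for e in edges if e.u in below and e.v in below]
    if suppress:
        edges = _suppress_degree_two(edges, keep=taxa)
    return Network(edges, rooted=False, root=None, validate=False)


def induced_quartet_network(net: Network, quartet: Iterable[str]) -> Network:
    q = quartet_key(quartet)
    return induced_network(net, q)


def replace_two_cycles(net: Network) -> Network:
    """Replace every 2-cycle by a single tree edge with the matching
    edge probability ``1 - l = g^2 (1-h1) + (1-g)^2 (1-h2)``."""
    out = net.copy()
    while True:
        twos = [c for c in find_cycles(out) if c.m == 2]
        if not twos:
            return out
        cyc = twos[0]
        e1, e2 = cyc.edges
        g = e1.gamma
        h1 = e1.edge_prob()
        h2 = e2.edge_prob()
        ell = 1 - (g * g * (1 - h1) + (1 - g) * (1 - g) * (1 - h2))
        u, v = e1.u, e1.v  # parallel edges share endpoints; v is hybrid
        edges = [e.copy() for e in out.edges if e.eid not in (e1.eid, e2.eid)]
        edges.append(Edge(u, v, kind="tree", prob=ell))
        leaves = set(out.leaves())
        edges = _suppress_degree_two(edges, keep=leaves | ({out.root} if out.rooted else set()))
        out = Network(edges, rooted=out.rooted, root=out.root, validate=False)


def add_pseudotaxa(net: Network, taxon: str, count: int) -> Network:
    """Replace leaf ``taxon`` by a caterpillar of ``count`` pseudotaxa.

    New edges carry no length (no coalescence on them).  If the former
    pendant edge has no metric annotation, it stays metric-free, i.e. it is
    treated as zero-length in downstream computations.
    """
    if count < 1:
        raise NetworkError("count must be >= 1")
    if taxon not in set(net.leaves()):
        raise NetworkError(f"unknown taxon {taxon!r}")
    if count == 1:
        return net.copy()
    edges = [e.copy() for e in net.edges]
    attach = taxon  # the old leaf node becomes the cherry root
    new_edges = []
    labels = [f"{taxon}.{i}" for i in range(1, count + 1)]
    cur = attach
    for i in range(count - 2):
        nxt = f"_{taxon}_ps{i}"
        new_edges.append(Edge(cur, labels[i], kind="tree", prob=1))
        new_edges.append(Edge(cur, nxt, kind="tree", prob=1))
        cur = nxt
    new_edges.append(Edge(cur, labels[count - 2], kind="tree", prob=1))
    new_edges.append(Edge(cur, labels[count - 1], kind="tree", prob=1))
    return Network(edges + new_edges, rooted=net.rooted, root=net.root, validate=False)


def expand_samples(net: Network, samples: Optional[Dict[str, int]]) -> Network:
    if not samples:
        return net
    out = net
    for taxon, k in sorted(samples.items()):
        out = add_pseudotaxa(out, taxon, k)
    return out


# ---------------------------------------------------------------------------
# Edges defined by 4 taxa
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DefiningQuartet:
    taxa: Tuple[str, str, str, str]
    split: Tuple[FrozenSet[str], FrozenSet[str]]  # the split induced by the edge


def _restricted_unsuppressed(rnet: Network, taxa: set) -> Optional[Network]:
    cache: Dict = {}
    keep = {n for n in rnet.nodes if descendant_leaves(rnet, n, cache) & taxa}
    edges = [e for e in rnet.edges if e.u in keep and e.v in keep]
    if not edges:
        return None
    sub = Network(edges, rooted=True, root=rnet.root, validate=False)
    lsa = least_stable_ancestor(sub)
    below = {lsa}
    stack = [lsa]
    while stack:
        n = stack.pop()
        for e in sub.children_edges(n):
            if e.v not in below:
                below.add(e.v)
                stack.append(e.v)
    edges = [e for e in edges if e.u in below and e.v in below]
    return Network(edges, rooted=True, root=lsa, validate=False)


def _cut_separation(edges: List[Edge], e: Edge, taxa: set) -> Optional[Tuple[set, set]]:
    """If removing e splits its graph, taxa on (u side, v side); else None."""
    if not _is_bridge(edges, e):
        return None
    adj: Dict[Any, List[Edge]] = {}
    for x in edges:
        if x.eid == e.eid:
            continue
        adj.setdefault(x.u, []).append(x)
        adj.setdefault(x.v, []).append(x)
    seen = {e.u}
    stack = [e.u]
    while stack:
        n = stack.pop()
        for x in adj.get(n, ()):
            o = x.other(n)
            if o not in seen:
                seen.add(o)
                stack.append(o)
    side_u = taxa & seen
    return side_u, taxa - side_u


def defining_quartets(net: Network, edge: Edge, first_only: bool = False) -> List[DefiningQuartet]:
    """All 4-taxon sets defining ``edge`` (empty iff the edge is hybrid or
    adjacent to a hybrid edge, for internal edges of a binary level-1 net)."""
    if net.is_pendant(edge):
        raise NetworkError("pendant edges are not defined by any quartet")

    def locate(rn: Network) -> Optional[Edge]:
        for e in rn.edges:
            if e.eid == edge.eid or set(e.src) == set(edge.src):
                return e
        return None

    if net.rooted:
        rnet, target = net, locate(net)
    else:
        rnet, target = None, None
        for cand in all_rootings(net):
            target = locate(cand)
            if target is not None:
                rnet = cand
                break
    if target is None or rnet is None:
        raise NetworkError("edge not found in network (or split by every rooting)")
    out: List[DefiningQuartet] = []
    taxa_all = rnet.leaves()
    for q in itertools.combinations(taxa_all, 4):
        qset = set(q)
        sub = _restricted_unsuppressed(rnet, qset)
        if sub is None:
            continue
        sedges = sub.edges
        present = [e for e in sedges if e.eid == target.eid]
        if not present:
            continue
        e = present[0]
        sep = _cut_separation(sedges, e, qset)
        if sep is None or len(sep[0]) != 2 or len(sep[1]) != 2:
            continue
        # the 4 adjacent edges must be cut edges isolating one taxon each
        adjacent = [x for x in sedges if x.eid != e.eid and (set(x.nodes()) & set(e.nodes()))]
        if len(adjacent) != 4:
            continue
        singles = set()
        ok = True
        for x in adjacent:
            s = _cut_separation(sedges, x, qset)
            if s is None:
                ok = False
                break
            small = min(s, key=len)
            if len(small) != 1:
                ok = False
                break
            singles |= small
        if not ok or singles != qset:
            continue
        out.append(DefiningQuartet(quartet_key(q), (frozenset(sep[0]), frozenset(sep[1]))))
        if first_only:
            return out
    return out
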
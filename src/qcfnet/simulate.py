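"""Gene-tree simulation under the coalescent on a rooted metric network.

Lineages are traced backward in time through the edge populations; within an
edge each pair coalesces at rate 1 per coalescent unit, at a hybrid node
each lineage independently follows a parent edge with its inheritance
probability, and above the root remaining lineages are merged by uniform
random pairing (which gives the same topology distribution as exponential
racing).  Sampled topologies are summarized as empirical CF tables for
cross-validation of the exact engine.
"""

from __future__ import annotations

import itertools
import math
import random
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Any, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .netmodel import (
    CFTable,
    CFVector,
    Network,
    NetworkError,
    expand_samples,
    quartet_key,
    rooted_version,
)

__all__ = ["GeneTreeSample", "EmpiricalCFTable", "sample_gene_tree", "empirical_cf_table", "displayed_quartet"]


@dataclass
class GeneTreeSample:
    """One sampled gene tree, as a chronological list of merge events.

    Each sample taxon owns one bit in a mask; ``merges[i] = (A, B)`` records
    the i-th coalescence joining lineage groups with bitmasks A and B.
    ``hybrid_choices`` logs, per traversal of a hybrid node, which parent
    edge ids were taken.
    """

    taxa: Tuple[str, ...]
    merges: List[Tuple[int, int]]
    hybrid_choices: List[Tuple[Any, int]] = field(default_factory=list)
    seed: Optional[int] = None

    def bit(self, taxon: str) -> int:
        return 1 << self.taxa.index(taxon)

    def newick(self) -> str:
        """Topology-only Newick string of the sampled gene tree."""
        clades: Dict[int, str] = {1 << i: t for i, t in enumerate(self.taxa)}
        mask_all = (1 << len(self.taxa)) - 1
        for a, b in self.merges:
            clades[a | b] = f"({clades.pop(a)},{clades.pop(b)})"
        rest = sorted(clades)
        while len(rest) > 1:  # should not happen: merges end with one group
            a, b = rest[0], rest[1]
            clades[a | b] = f"({clades.pop(a)},{clades.pop(b)})"
            rest = sorted(clades)
        return clades[mask_all] + ";"

    def quartet_split(self, quartet: Sequence[str]) -> Tuple[str, str, str, str]:
        """The displayed quartet, as (x, y, z, w) meaning xy|zw."""
        q = quartet_key(quartet)
        qmask = 0
        bits = {}
        for t in q:
            b = self.bit(t)
            bits[b] = t
            qmask |= b
        for a, b in self.merges:
            ia, ib = a & qmask, b & qmask
            if ia and ib:
                # the first merge uniting two of the four samples decides
                x, y = bits[ia], bits[ib]
                z, w = sorted(set(q) - {x, y})
                return (x, y, z, w)
        raise RuntimeError("gene tree did not resolve the quartet")


def displayed_quartet(sample: GeneTreeSample, quartet: Sequence[str]) -> int:
    """Index (0/1/2, canonical order) of the quartet displayed by the tree."""
    x, y, z, w = sample.quartet_split(quartet)
    a, b, c, d = quartet_key(quartet)
    pair = frozenset((x, y))
    if pair in (frozenset((a, b)), frozenset((c, d))):
        return 0
    if pair in (frozenset((a, c)), frozenset((b, d))):
        return 1
    return 2


class EmpiricalCFTable(CFTable):
    """A CF table of displayed-quartet frequencies with multinomial SEs."""

    def __init__(self, taxa, reps: int):
        super().__init__(taxa)
        self.reps = reps

    def se(self, taxa) -> Tuple[float, float, float]:
        vec = self.get(taxa)
        return tuple(math.sqrt(float(v) * (1 - float(v)) / self.reps) for v in vec.values)


def _edge_time(e) -> float:
    if e.length is not None:
        return float(e.length)
    if e.prob is not None:
        p = float(e.prob)
        if p <= 0:
            return math.inf
        return -math.log(p)
    return 0.0


def sample_gene_tree(net: Network, samples: Optional[Dict[str, int]] = None, seed: Optional[int] = None,
                     rng: Optional[random.Random] = None) -> GeneTreeSample:
    """Draw one gene tree from the coalescent on a rooted metric network."""
    work = expand_samples(net, samples)
    if not work.rooted:
        work = rooted_version(work)
    taxa = tuple(work.leaves())
    if rng is None:
        rng = random.Random(seed)
    # children-before-parents order
    order = []
    remaining = {n: len(work.children_edges(n)) for n in work.nodes}
    ready = [n for n in work.nodes if remaining[n] == 0]
    while ready:
        n = ready.pop()
        order.append(n)
        for e in work.parent_edges(n):
            remaining[e.u] -= 1
            if remaining[e.u] == 0:
                ready.append(e.u)
    merges: List[Tuple[int, int]] = []
    choices: List[Tuple[Any, int]] = []
    # lineages waiting at the top of each edge, keyed by edge id
    at_node: Dict[Any, List[int]] = {t: [1 << i] for i, t in enumerate(taxa)}

    def coalesce_in_edge(lineages: List[int], t: float) -> List[int]:
        lineages = list(lineages)
        elapsed = 0.0
        while len(lineages) > 1:
            k = len(lineages)
            rate = k * (k - 1) / 2.0
            elapsed += rng.expovariate(rate)
            if elapsed > t:
                break
            i, j = rng.sample(range(k), 2)
            a, b = lineages[i], lineages[j]
            merges.append((a, b))
            lineages = [x for x in lineages if x not in (a, b)] + [a | b]
        return lineages

    for v in order:
        lineages = at_node.get(v, [])
        parents = work.parent_edges(v)
        if not parents:
            # ancestral population above the root: merge to completion
            while len(lineages) > 1:
                i, j = rng.sample(range(len(lineages)), 2)
                a, b = lineages[i], lineages[j]
                merges.append((a, b))
                lineages = [x for x in lineages if x not in (a, b)] + [a | b]
            continue
        if len(parents) == 1:
            e = parents[0]
            # metric-free edges count as zero-length (no coalescence),
            # matching the exact engine's convention
            out = coalesce_in_edge(lineages, _edge_time(e)) if len(lineages) > 1 else lineages
            at_node.setdefault(e.u, []).extend(out)
        else:
            buckets = {parents[0].eid: [], parents[1].eid: []}
            g1 = float(parents[0].gamma)
            for lin in lineages:
                pick = parents[0] if rng.random() < g1 else parents[1]
                choices.append((v, pick.eid))
                buckets[pick.eid].append(lin)
            for e in parents:
                lin = buckets[e.eid]
                out = coalesce_in_edge(lin, _edge_time(e)) if len(lin) > 1 else lin
                at_node.setdefault(e.u, []).extend(out)
    return GeneTreeSample(taxa=taxa, merges=merges, hybrid_choices=choices, seed=seed)


def empirical_cf_table(net: Network, samples: Optional[Dict[str, int]] = None, reps: int = 1000,
                       seed: int = 0) -> EmpiricalCFTable:
    """Displayed-quartet frequencies over ``reps`` independent gene trees.

    Per-tree RNG streams are spawned from the master seed, so results are
    reproducible and independent of execution order.
    """
    if reps < 1:
        raise NetworkError("reps must be >= 1")
    work = expand_samples(net, samples)
    if not work.rooted:
        work = rooted_version(work)
    taxa = tuple(work.leaves())
    quartets = list(itertools.combinations(range(len(taxa)), 4))
    counts = np.zeros((len(quartets), 3), dtype=np.int64)
    child_seeds = np.random.SeedSequence(seed).generate_state(reps, dtype=np.uint64)
    qmasks = []
    for q in quartets:
        qmask = 0
        for i in q:
            qmask |= 1 << i
        qmasks.append(qmask)
    for r in range(reps):
        rng = random.Random(int(child_seeds[r]))
        gt = sample_gene_tree(work, None, rng=rng)
        for qi, q in enumerate(quartets):
            qmask = qmasks[qi]
            for a, b in gt.merges:
                ia, ib = a & qmask, b & qmask
                if ia and ib:
                    # canonical order: indices ascending within the quartet
                    i0 = q[0]
                    b0 = 1 << i0
                    if ia & b0 or ib & b0:
                        other = ib if ia & b0 else ia
                        if other == 1 << q[1]:
                            counts[qi, 0] += 1
                        elif other == 1 << q[2]:
                            counts[qi, 1] += 1
                        else:
                            counts[qi, 2] += 1
                    else:
                        rest = ia | ib
                        if rest == (1 << q[2]) | (1 << q[3]):
                            counts[qi, 0] += 1
                        elif rest == (1 << q[1]) | (1 << q[3]):
                            counts[qi, 1] += 1
                        else:
                            counts[qi, 2] += 1
                    break
    table = EmpiricalCFTable(taxa, reps)
    for qi, q in enumerate(quartets):
        names = [taxa[i] for i in q]
        vals = [Fraction(int(c), reps) for c in counts[qi]]
        table.set(CFVector(names, vals), ngenes=reps)
    return table
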
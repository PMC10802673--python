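# qcfnet

Exact quartet concordance factors (CFs) and identifiability analysis for
binary level-1 phylogenetic networks under the network multispecies
coalescent.

The package provides:

- **`qcfnet.netmodel`** — the network data model (rooted and semidirected
  metric networks with inheritance probabilities), extended-Newick I/O,
  level-1 validation, cycle/block records, induced subnetworks, 2-cycle
  replacement, pseudotaxon expansion for multi-sample data, and detection of
  edges defined by four taxa.
- **`qcfnet.cfengine`** — exact computation of quartet CFs by a lineage
  dynamic program (rational in, rational out; symbolic in, polynomial out),
  conditional resolution probabilities of network fragments, the six
  3-cycle block probabilities, and the CF factorization through a 3-cycle
  decomposition.
- **`qcfnet.simulate`** — a coalescent gene-tree sampler on rooted metric
  networks and empirical CF tables with multinomial standard errors, for
  Monte-Carlo cross-validation of the exact engine.
- **`qcfnet.invariants`** — the algebraic/semialgebraic detection
  statistics on CF tables (the cherry statistics `f`, `f~` and the three
  bilinear forms `G`), sign-based classification of 3-cycle hybrid
  placements, exact Jacobian-rank dimension checks of CF
  parameterizations, and 4-cycle hybrid placement by model fitting.
- **`qcfnet.identify`** — identifiability audits of every edge length and
  inheritance probability, and exact recovery of all identifiable
  parameters from CF tables (closed forms where they exist, otherwise
  exact polynomial solving on induced subnetworks).
- **`qcfnet.fixtures`** — generators for the named study networks
  (5/6-taxon trees, 3-cycle and 4-cycle networks, sunlets, joined 4-cycle
  pairs, block templates), seeded random rational parameters, and the
  indistinguishable cherry-rotation pair with exactly equal CF tables.

## CLI

The console script `qcfnet` exposes the main operations:

```bash
qcfnet fixture --name Ns --seed 1 --out ns.enewick       # a catalog network
qcfnet cftable --network ns.enewick --out cf.csv --exact # exact CF table
qcfnet simulate --network ns.enewick --reps 10000 --seed 7 --out emp.csv
qcfnet invariants --cf cf.csv --blocks a1,a2/b1,b2/c1,c2
qcfnet classify3  --cf cf.csv --blocks a1,a2/b1,b2/c1,c2
qcfnet orient4    --cf cf.csv --cycle a1,a2/b/c/d --pair-block 0
qcfnet identify   --topology ns.enewick --cf cf.csv --out params.json
qcfnet audit      --network ns.enewick [--samples 2]
```

CF tables are CSV with columns
`taxon1,taxon2,taxon3,taxon4,CF12_34,CF13_24,CF14_23[,ngenes]`; with
`--exact`, entries are serialized as fraction strings.

Extended Newick uses the `name:length:support:gamma` convention with hybrid
nodes tagged `#H<k>`; a gamma omitted on one edge of a hybrid pair is
inferred as one minus the other.

## Conventions

- Edge lengths are in coalescent units; computations use the edge
  probability `l = exp(-t)`, which may be stored directly as an exact
  rational or symbol. An edge with no metric annotation is treated as
  zero-length (`l = 1`, no coalescence) — this covers pendant edges and
  pseudotaxon cherries, where no coalescence is possible anyway.
- CF vectors are indexed against the lexicographic order of their four
  taxa: `(ab|cd, ac|bd, ad|bc)`.
- Semidirected networks store an arbitrary valid orientation for tree
  edges; all CF computations are invariant to the rooting choice.
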
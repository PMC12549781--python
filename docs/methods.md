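# Methods

## Scope and model

`qdnet` operates on binary semi-directed phylogenetic networks: mixed
multigraphs obtained from a rooted binary network by suppressing the root
and undirecting all non-hybrid edges. Validity is defined operationally —
a network is accepted iff some placement of a root on an undirected edge
orients every undirected edge into a rooted DAG with the correct degree
profile, all nodes reachable from the root, and the root equal to the
least stable ancestor (LSA) of the taxa. The search over root edges is
brute force with forced-orientation propagation (undirected edges at a
hybrid node must point away from it; a tree node with a parent sends its
remaining undirected edges outward). This avoids re-deriving orientability
theory and is cheap at the instance sizes the package targets (tens of
nodes).

The classes of interest are networks whose blobs (2-edge-connected
components) are outer-labeled planar, galled, and carry at most two hybrid
nodes. Galledness is checked directly from its cycle definition: for each
hybrid, a cycle through both its hybrid edges avoiding all other hybrid
edges. Outer-labeled planarity uses the standard apex reduction: the
network plus one vertex adjacent to every leaf must be planar. Every
strictly level-2 galled planar bloblet is two undirected cycles (galls)
sharing a single edge `{s, t}` — sharing a longer path would trap pendant
leaves inside the embedding, and binarity forbids bare degree-2 nodes —
with one hybrid per gall; the pendant leaves split into the canonical
partition blocks `A1, A2` (on the `s` side), `B1, B2` (on the `t` side)
and the hybrid leaves `C1, C2`. This shape is the basis of the
constructors, of the enumeration, and of the closed-form error term.

## Metrics

All distances are exact `fractions.Fraction` values; equality tests in the
package and its suite are exact, with no epsilon anywhere. The quartet
metric of a tree is computed by counting, for each pair `{x, y}`, the
pairs `{z, w}` falling in a common component off the `x`–`y` path (these
are exactly the quartets in which `x, y` form a cherry); the literal
restrict-every-4-subset sum is kept as a test oracle, and the equivalent
quartet metrization (block-size products on edges) as an independent
route. Network metrics follow the definitions: every 4-subset's quarnet is
built as the union of up-down paths (a DFS with an up/down phase flag
enumerates exactly the admissible simple paths; a brute-force
enumerate-and-filter oracle cross-checks the edge unions in the tests),
then its displayed quartet topologies are enumerated by hybrid-edge
deletion. The displayed quartet metric additionally recomputes itself as
the multiplicity-weighted average of the displayed trees' quartet metrics
and asserts exact agreement (`check=True` by default), so every call
exercises the central identity of the construction.

For strictly level-2 bloblets the error term `eps = d_N - d~_N` is also
evaluated in closed form from the canonical partition (per-pair values in
`{0, ±1/2, ±|.|/2, ...}` depending on block membership); the direct and
closed-form routes are asserted equal.

## Circular decomposition

Split weights use the Chepoi–Fichet formula
`alpha_ij = d(x_i,x_j) + d(x_{i+1},x_{j+1}) - d(x_i,x_{j+1}) - d(x_{i+1},x_j)`
over a circular order; a metric is decomposed iff all `alpha_ij >= 0`,
with weights `alpha_ij/2` and support `{alpha_ij > 0}`. The reconstruction
identity holds for any symmetric zero-diagonal table, which the suite
checks on non-Kalmanson inputs as well. Circular orders are canonicalized
up to rotation and reversal; induced orders of a network are assembled
from the per-blob cyclic order of attachments (read from a planar
embedding of the blob plus apex) with both traversal directions explored
at every blob, which covers all outer-labeled planar embeddings at the
multi-blob sizes used here. Bloblets have a unique order, asserted where
relied upon.

## Canonical form

The eight reductions are applied in their fixed order, recomputing blobs
between stages: contract 2- and 3-blobs; replace 4-blobs and
split-symmetric 5-blobs by undirected representative cycles in the
induced attachment order; contract 3-cycles (>= 5 articulation nodes);
suppress dts-undetectable 4-cycles (a 4-cycle through one hybrid and a
parent of the other: delete the hybrid edge from the articulation parent,
undirect its partner, suppress the two degree-2 nodes); contract
dts-undetectable frontier edges (>= 6 articulation nodes; the resulting
degree-4 node is deliberately *not* suppressed, canonical forms may be
non-binary); undirect remaining 4-cycles. The split-symmetric 5-blob is
recognized by isomorphism against a stored template (block sizes
1,1,1,0); its defining property — displayed splits invariant under
cyclically permuting the leaves — is verified in the tests. For
dts-undetectable edges, type 2 ("one endpoint a hybrid parent, the other
on a 4-cycle") excludes edges lying on the 4-cycle itself; otherwise an
edge of the 4-cycle would qualify and the at-most-one-per-blob invariant
(enforced as a runtime assertion) would fail. In a blob with at least five
articulation nodes at most one gall can be a 4-cycle, so at most one
dts-undetectable 4-cycle can exist per blob and suppression order is moot;
blob processing order is shuffleable via `blob_order_seed` and the result
asserted order-invariant in the tests.

Mixed-graph isomorphism (labeled, or up to relabeling) is delegated to a
VF2 matcher on a directed encoding (undirected edge = arc pair, hybrid
edge = single attributed arc), preserving parallel-edge multiplicity and
leaf labels; a witness mapping is available.

## Generators and fixtures

The enumeration of small bloblets is template-based: the level-1 cycle
plus every block-size composition of the two-gall shape, deduplicated by
the size-orbit under the `A<->B` / gall-swap symmetry and cross-checked by
pairwise graph isomorphism at run time. Completeness rests on the
structural argument above (every member of the class has the template
shape); reproducing the catalogue counts 4 (5 leaves) and 9 (6 leaves) and
their 2 and 5 canonical classes is the external check. Output order is
deterministic (descending size compositions after the cycle).

The random generator draws a seeded random binary tree and expands random
connected sets of internal nodes into cycle blobs or two-gall blobs with
random block compositions and rotations; the draw is retried until the
requested class (including at least one strictly level-2 blob when level 2
is asked for) validates. It emulates topology only: there are no branch
lengths, no inheritance probabilities, and no data-level noise, so passing
property suites certify the combinatorial identities, not statistical
behavior on estimated quartet frequencies.

The 5- and 6-leaf figure fixtures are template instances; the 6-leaf
labelings were pinned by requiring `nanuq_metric` to reproduce the five
published 6x6 distance tables exactly, which also fixes which members
carry dts-undetectable 4-cycles (N2, N3) and dts-undetectable edges of
type 1 (N7, N8) and type 2 (N9). The 10-leaf multi-blob example `fig2b`
is a synthetic stand-in constructed to satisfy the properties stated for
the published example (strictly level-2, galled, outer-labeled planar,
not a bloblet, inducing the circular order `x1..x10`); its exact published
topology is not recoverable from text.

## Problem sizes and limitations

The test and acceptance workloads use 200 random level-2 networks with
4–10 leaves, 100 random bloblets with 4–8 leaves, and 500 random trees
with 4–12 leaves; the whole suite runs in well under a minute on one CPU.
All algorithms are exponential-in-principle (path enumeration, 2^r
displayed trees, VF2) but the galled planar structure keeps them fast for
networks with tens of nodes; the package makes no attempt at genome-scale
inputs. Estimation of these distances from data (concordance factors,
sequences), Neighbor-Net fitting, tree-of-blobs inference from data, and
splits-graph drawing are out of scope. Canonical forms are defined only
for the outer-labeled planar galled level-2 class; inputs outside it are
rejected rather than approximated. Whether the NANUQ metric of an
arbitrary (non-bloblet) member of the class is always a true metric is
only tested, not assumed: `DistanceTable.is_metric()` checks the triangle
inequality explicitly where the suite relies on it.
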
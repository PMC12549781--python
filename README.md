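# qdnet

Quartet distances, circular split decomposition, and canonical forms for
**semi-directed level-2 phylogenetic networks**.

## The problem

Hybridization and gene flow make the history of many groups of organisms a
network rather than a tree. Statistically consistent network inference has
long been restricted to *level-1* networks, whose reticulation cycles are
disjoint. `qdnet` implements the combinatorial machinery for the next step
up: semi-directed networks that are **outer-labeled planar** (drawable with
all taxa on the outside), **galled** (each reticulation sits on its own
cycle), and **level-2** (at most two reticulations per blob). It is aimed
at researchers studying identifiability of phylogenetic networks and at
developers of quartet-based inference tools in the NANUQ family.

A semi-directed network `N` keeps direction only on the two *hybrid edges*
entering each reticulation node; everything else, including the root, is
forgotten. The package answers two questions about this class:

1. **Which inter-taxon distances derived from quartets are well behaved?**
   Deleting one hybrid edge per hybrid node in every way yields the
   *displayed trees* `T(N)` with multiplicities `mu(T, N)`,
   `sum_T mu(T, N) = 2^r`. For a 4-taxon subnetwork (a *quarnet*)
   `N|xyzw`, let `rho_xy = 0/1` indicate whether `x, y` form a cherry.
   Averaging `rho` over the displayed quartet trees — weighted by
   multiplicity (`rho~`) or unweighted over distinct topologies (`rho-`) —
   and summing over quartets gives two exact-rational metrics

       d~_N(x,y) = sum_{z,w} 2 rho~_xy(N|xyzw) + 2n - 4     (displayed quartet metric)
       d_N(x,y)  = sum_{z,w} 2 rho-_xy(N|xyzw) + 2n - 4     (NANUQ metric)

   Both generalize Rhodes' quartet metric of a tree, which equals the path
   distance under the *quartet metrization* (internal edge: `w(e) =
   |X1||X2| + |X3||X4|` over the four leaf blocks; pendant edge:
   `w(e) = |X1||X2|`). For single-blob networks (*bloblets*) in the class,
   `d_N` is **circular decomposable** (Kalmanson): it is a nonnegative
   combination of split metrics over one circular split system whose
   support is exactly the splits of the displayed trees — so a splits
   graph of `d_N` faithfully depicts what the quartets can see.

2. **Which networks can quartets distinguish at all?** Two networks in the
   class display the same quartets exactly when they share a **canonical
   form**: the mixed graph left after eight blob-local reductions that
   erase quartet-invisible features (small blobs become undirected cycles;
   3-cycles are contracted; *dts-undetectable* 4-cycles and frontier edges
   — structures no displayed-tree split can see — are suppressed or
   contracted). The canonical form is the most refined structure
   identifiable from displayed quartets, under any model in which quartet
   topologies are identifiable.

## Worked example

Build the 6-taxon bloblet `N5` from the bundled catalogue (two galls
sharing an edge, hybrids above `c` and `d`) and print its NANUQ distances:

```
$ python -c "from qdnet.generate import figure_fixtures;
from qdnet.network import write_edgelist;
open('N5.net','w').write(write_edgelist(figure_fixtures()['fig9_N5']))"
$ qdnet dist N5.net --metric nanuq
6
a  0 11 16 18 18 17
b  11 0 13 19 19 18
c  16 13 0 14 19 18
d  18 19 14 0 13 16
e  18 19 19 13 0 11
f  17 18 18 16 11 0
```

This is the published distance table for this network, entry for entry.
Small entries (`d(a,b) = 11`) mark pairs that are cherries in most
displayed quartets; the table is circular decomposable along the circular
order `(a, b, c, d, e, f)` induced by the planar embedding, and
`qdnet splits N5.net` writes the corresponding weighted split system as a
SplitsTree-readable NEXUS file. `qdnet compare A.net B.net` reports
whether two networks are distinguishable by canonical form, displayed
quartets, displayed splits, and (for bloblets) the NANUQ metric — the four
verdicts provably agree. `qdnet enumerate --n 6` lists all nine
3-cycle-free 6-leaf bloblets of the class up to relabeling; they fall into
five canonical classes.

Networks are read either as edge lists (`u -- v` undirected, `u -> v`
hybrid, `leaf u LABEL`) or as the rooted partner in extended Newick
(`--dialect enewick`, e.g. `((a,(b)h#H1),(h#H1,c));`).

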
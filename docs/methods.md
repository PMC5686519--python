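# Methods

This note documents the models, conventions and design choices behind
`bgclust`, in the spirit of a methods appendix: what each stage computes,
which knobs matter, what the synthetic data does and does not emulate, and
where genuinely open choices were resolved.

## Pairwise syntenic similarity

Gene-cluster comparison tools score a pair of clusters by combining protein
homology with gene-order conservation.  The exact internals of the
established tools are not published as a formula, so `bgclust` defines its
score explicitly and tests it as such:

    S(a, b) = h + w·s

* **h** — the number of reciprocal-best-hit (RBH) gene pairs.  Every gene
  of *a* is globally aligned against every gene of *b* (edlib,
  Needleman–Wunsch).  Identity is matched columns divided by total
  alignment columns, i.e. match = 1, mismatch = 0, and gap columns counted
  in the length.  A pair is a *hit* when identity ≥ `min_identity`
  (default 0.30) and the length ratio len(shorter)/len(longer) ≥
  `min_coverage` (default 0.25).  Coverage is a length-compatibility gate:
  a global alignment always spans both sequences, so "fraction of the
  shorter protein covered" can only be meaningfully enforced through the
  length ratio.  Best hits break ties toward the lowest gene index in the
  partner cluster, making the computation deterministic; the score is
  symmetric under argument swap whenever identities are distinct.
* **s** — the number of unordered RBH pairs whose genes are adjacent in
  both clusters: conserved local adjacencies, the testable core of
  "synteny".  `synteny_weight` *w* defaults to 0.5, weighting gene content
  above gene order without ignoring it.

Self-comparison yields S(a, a) = n + w(n − 1) for an n-gene cluster, the
maximum achievable against any partner — which is what makes the
column-normalized self-similarity equal 1.

### Matrix transforms

Directional scores (query vs subject) are averaged, (M + Mᵀ)/2.  Each
column of the averaged matrix is divided by its column maximum (all-zero
columns stay zero) and the result is re-symmetrized by averaging mirror
entries; normalizing the full symmetric matrix rather than a
lower-triangular layout keeps the result independent of row ordering, and
the distance matrix DBSCAN consumes must be symmetric anyway.  Distance is
1 − v.  Two readings of "inverting" the normalized values exist — 1 − v
and a reciprocal — and 1 − v is used because it is bounded, defined at
zero, and maps self-similarity 1 to distance 0.  Distance matrices are
symmetric, zero-diagonal and confined to [0, 1] by construction; these
invariants are property-tested.

## Density-based clustering

DBSCAN is implemented directly on the precomputed distance matrix: a point
is *core* when at least MinPts points (itself included) lie within EPS;
clusters are density-connected components of core points; a non-core point
within EPS of a core point is a *border* point and joins the cluster of its
lowest-index core neighbor (the textbook definition leaves border
assignment order-dependent; fixing the tie makes output reproducible and
permutation-equivariant up to relabeling).  Everything else is noise.
Cluster ids are renumbered contiguously by lowest member index.  The
implementation is verified against an independent brute-force
density-connectivity oracle on hundreds of random matrices.

Each BGC class is clustered independently on its distance submatrix, and
every combination of EPS ∈ {0.01, 0.02, …, 0.98} and MinPts ∈ {2, …, 15} is
evaluated — 1,372 parameterizations per class, always emitted as a TSV so a
user can replicate a manual, alignment-guided parameter choice.

### Silhouette and automatic selection

The silhouette coefficient of a sample is s = (b − a)/max(a, b) with *a*
the mean distance to own-cluster co-members and *b* the smallest mean
distance to another cluster.  Reported silhouettes follow the standard
conventions: noise excluded, size-1 clusters score 0, and with fewer than
two clusters the mean is an explicit NaN sentinel rather than an exception.

Automatic selection maximizes a *noise-penalized* mean silhouette — the sum
of per-sample silhouettes divided by the total number of points, so each
noise point contributes 0 — subject to at least two clusters and a noise
fraction at most `noise_cap` (default 0.5), with ties broken toward smaller
EPS then smaller MinPts.  The penalty is load-bearing: because h + w·s is
integer-quantized, unmutated family instances sit at distance exactly 0,
and a tiny EPS can collect only those while discarding every gene-loss or
rearrangement variant as noise, achieving a perfect noise-excluded
silhouette on a badly fragmented solution.  Weighting by clustered mass
restores the intended optimum (the full families) and leaves genuinely
unclusterable points as noise.  On the default benchmark this selection
recovers the planted families with adjusted Rand index ≥ 0.9 (exactly 1 at
divergence 0).

Singletons are noise points plus members of size-1 clusters, matching the
survey notion of a BGC that "clusters with nothing".

## HGT annotation

Horizontally acquired DNA often retains donor nucleotide composition.  The
detector is a fixed-order compositional scan — deliberately simpler than
interpolated variable-order genomic-island models, and documented as such:
per window (default 5 kb, step 2.5 kb) the Kullback–Leibler divergence of
k-mer frequencies (k = 6, pseudocount 0.5) from the whole-genome background
is computed; windows above mean + z·sd (z = 2) are alien and merged into
maximal intervals.  Under a homogeneous null this flags only the upper tail
(≲ 3% of windows empirically); a 10 kb insert at strongly shifted GC is
recovered as a single merged region.

Each BGC's overlap fraction is |union(alien) ∩ BGC| / |BGC| on 0-based
half-open intervals (regions merged first, so the fraction is invariant to
region order and pre-merging, and monotone as regions are added).  The HGT
score is the overlap on a 0–100 scale and the flag threshold is **75,
boundary inclusive** — "above a score of 75" and "a 75% cutoff" conflict at
the boundary, and the inclusive reading is adopted and tested.

## Synthetic collections and what they show

The generator emulates the gross structure of a large single-genus survey:

* conserved families, each derived from a random ancestor (3–12 genes,
  120–250 aa proteins, uniform 20-letter alphabet) by per-site amino-acid
  substitution at the family's divergence rate, per-gene loss with
  probability divergence/4, and an adjacent-gene swap with probability
  divergence/4;
* singletons as fresh random gene sets (Poisson per genome, default rate
  0.3), with classes drawn from the run's class list;
* species-group metadata (group fractions, species names, public vs
  proprietary collection);
* HGT families embedded, with 1 kb flanks, in sequence synthesized at
  `gc_alien` (default 0.60) while the rest of the genome uses
  `gc_background` (default 0.35).  Reverse translation draws synonymous
  codons with weights (p^G (1−p)^{A+T})³ per codon; the cubed sharpening is
  needed because amino-acid composition caps how far coding sequence can
  drift from GC 0.5, and with it realized CDS GC tracks the target closely
  enough that alien spans differ from background by well over half the
  configured contrast.

The default benchmark is 10 genomes × 6 families at prevalence 1.0 (60
family BGCs, divergence 0.05–0.15), two families per class so each
per-class submatrix poses a real discrimination problem, one family of 10
flagged as HGT, and one family seeded into the reference library as a
characterized compound.  All randomness flows through a single seeded
generator; fixed seed means byte-identical FASTA/GenBank/TSV output.

What the generator does **not** emulate: realistic phylogenetic sequence
evolution (no substitution matrices, no codon models, no tree), assembly
artifacts, operon structure, paralogy within a cluster, or antiSMASH's
boundary-calling behavior.  Passing recovery tests therefore demonstrates
the pipeline's correctness and discriminative machinery on data with the
survey's *structure*, not performance on real genomes, where within-family
divergence is phylogenetically correlated and class labels are noisier.

## Bookkeeping conventions

* Internal coordinates are 0-based half-open everywhere; GenBank's 1-based
  inclusive convention exists only inside files, with Biopython handling
  the conversion.
* Class vocabulary is fixed (NRPS, PKS-I/II/III, hybrid, lanthipeptide
  I–IV, thiopeptide, bacteriocin, terpene, ectoine, phosphonate,
  siderophore, other); trans-AT PKS maps to type I, a product string naming
  both NRPS and PKS machinery is a hybrid, and unknown strings degrade to
  "other" with a warning rather than failing ingestion.
* Reference ids get a `REF_` prefix on merge; a DBSCAN cluster is *known*
  iff it contains at least one reference record, and compound names are
  aggregated per cluster.
* Prevalence counts strains by presence/absence, never BGC multiplicity;
  percentages round half-up at the table's precision (one decimal for
  strain percentages, integer for percent-unknown) so every printed number
  is exactly reproducible from its numerator and denominator.
* The network edge threshold (default 0.75 on the distance scale) affects
  display only, never statistics; isolated nodes are retained because
  unconnected rare families are themselves a result.

## Pipeline determinism

Each stage writes its artifacts plus a manifest entry hashing its
configuration and upstream outputs; reruns skip stages whose keys and
outputs are unchanged, a cutoff change therefore recomputes only the HGT
stage and whatever downstream tables actually change, and two fresh runs
with the same seed produce byte-identical text outputs (TSV floats are
formatted explicitly; graph exports are insertion-ordered).

## Problem sizes

Tests and the acceptance script run the full benchmark (≈ 63 predicted
BGCs + 1 reference, 10 × 100 kb genomes, full 1,372-point sweeps per class)
plus hundreds of randomized oracle comparisons; the complete suite and the
acceptance script each finish in well under a minute on a single core.

## Known limitations

* The similarity score is a documented surrogate for unpublished tool
  internals; absolute score values are not comparable to MultiGeneBlast
  output, only the derived distances are meaningful.
* The compositional HGT scan cannot see ameliorated (old) transfers or
  transfers between hosts of similar composition, and the z-threshold is
  calibrated per genome, so a genome consisting mostly of alien DNA would
  mask its own signal.
* Silhouette-based selection assumes families are tighter than
  between-family gaps; classes whose families overlap heavily in distance
  may still be over- or under-split, which is why the full sweep table is
  always emitted.
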
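# Methods

## Fragmentation

A genome is a linear string over {A,C,G,T} of length *N* (non-ACGT symbols
are kept but excluded from all counting). Windows of length *L* start at
positions 1, 1+*R*, 1+2*R*, …; only full windows are taken, so the count is
⌊(N−L)/R⌋+1. *L* must be odd and divisible by 3 (integer central
nucleotide, whole-triplet tiling) and *R* must not be divisible by 3
(consecutive windows sample all three frame offsets). Defaults L=603,
R=11 give ~10⁴ windows on a plastome-sized genome; both are configurable
(e.g. L=1005/R=202 or L=30003/R=601 for long-window bacterial surveys).
Circular records are read but tiled linearly; windows never wrap the
origin, and origin-spanning annotated features are split into two regions.

## Triplet frequency space

Each fragment is tiled into M = L/3 non-overlapping triplets starting at
its first position; triplets containing an ambiguous symbol are skipped and
M reduced, keeping Σ<sub>ω</sub> f<sub>ω</sub> = 1. Since frequencies sum
to one, one coordinate is redundant; per genome we drop the triplet whose
frequency has the least **population** standard deviation (ddof = 0) over
that genome's fragment ensemble — the coordinate least able to distinguish
fragments. Ties go to the lexicographically smallest triplet; each column
is put in a canonical sorted order before the SD summation so the choice is
bit-identical under permutation of the ensemble. The exclusion is
per-genome (it is known to differ between genomes). Distances are plain
Euclidean; dropping a coordinate whose value is determined by the rest
changes no analysis conclusion, and the full 64-vector is recoverable
exactly (1 − row sum).

## Phase labeling

Only the annotation decides the label; "coding" is taken widely (protein
genes, tRNA, rRNA, other RNA kinds). With ceil(L/2) = 302 at L = 603:

1. **JUNK** if ≥ ceil(L/2) window positions are covered by no region.
2. else **TAIL** if ≥ ceil(L/2) positions are covered by tRNA/rRNA/other-RNA
   regions — an operational stand-in for the emergent GC-rich RNA-block
   cluster that does not require clustering first; the emergent-cluster
   reading stays checkable through the K-means verification.
3. else the region containing the central nucleotide assigns
   F<sub>(c−start) mod 3</sub> (forward) or B<sub>(end−c) mod 3</sub>
   (backward — a backward gene's biological start is the annotated end).

Deterministic tie-breaks where annotation is messy: if the center lies in
several overlapping regions, the region with the largest overlap with the
window wins (then forward strand, then smaller start); if the center falls
in a short annotation gap but the window is mostly coding, the
largest-overlap region's phase is used, so every fragment gets exactly one
label. The expected number of border windows labeled junk is L/(2R) per
region border, i.e. L/(2R)·n·2 for n regions on both strands.

### Frame arithmetic

The tiling always starts at the window's first position while the label is
defined at the center. For L odd and divisible by 3, L = 3m with m odd, so
(L−1)/2 = 3(m−1)/2 + 1 ≡ 1 (mod 3) for **every** valid L: a fragment
labeled phase *j* tiles its gene at codon-frame shift (j−1) mod 3. Phase-1
fragments, not phase-0 ones, read genes in frame. All analytic oracles and
the pairing derivation below use this mapping.

## Embedding and geometry

PCA (top three components of the column-centered 63-dim matrix, full SVD)
with a deterministic sign convention: each component is flipped so its
largest-magnitude loading is positive. Cluster verification uses K-means
(default K=4, 10 restarts, seeded) on the 63-dim points, classes renumbered
by ascending centroid norm so runs are comparable.

Geometry diagnostics, computed on per-phase centroids in PC coordinates
(the circuit notion lives in projections):

* **circuit areas** — signed area of (F0,F1,F2) and of (B0,B1,B2) in a
  chosen PC plane (default PC1–PC2; configurable). Opposite signs =
  counter-directed circuits = **mirror**; same signs = **rotational**.
* **orientation** — U when the pooled F2∪B2 centroid exceeds the pooled
  F0∪F1∪B0∪B1 centroid on PC3 in the sign-canonicalized embedding, else D.
  This is an operational proxy for the visual up/down of the merged F2–B2
  cluster in the (PC2,PC3) view; matching an external plotting convention
  may need the global `orientation_flip` switch, since only the two-class
  split, not its naming, is intrinsic.
* **abundances** — counts per label, the population SD of the six coding
  counts, and the strand biases |F0|−|B0|, |F1|−|B1|, |F2|−|B2|.

The plane choice for circuit areas is a declared default, not an inherited
convention; results carry both signed areas so any plane can be inspected.

## GC statistics

Per-fragment GC = (G+C)/(A+C+G+T) with ambiguous symbols excluded; ensemble
means over the coding (six phases pooled), junk and tail fragments plus the
whole-genome value. A genome without tail fragments reports that mean as
absent. Across a corpus, Pearson (optionally Spearman) correlations of the
four ensemble means, with pairwise exclusion of genomes lacking an
ensemble. With R ≪ L the fragment-mean GC tracks whole-genome GC to ~0.01
(positions are covered near-uniformly), which is tested.

## Synthetic genomes

The generator emulates exactly the statistical structure the analysis
assumes: forward genes are i.i.d. codon strings from a 64-codon usage;
backward genes are codon strings reverse-complemented onto the forward
strand; intergenic stretches are i.i.d. bases at a neutral GC; a single
dense block of short RNA genes (annotated tRNA/rRNA alternately) at GC 0.62
with short spacers of the same composition provides the tail. Stop codons
are not modelled — only triplet composition matters here. Features are
placed left-to-right in a seed-determined order with multinomially split
gaps; one seeded generator drives every draw, so a seed fully determines
the genome, its annotation, and the per-position ground truth (stratum +
mRNA-sense codon offset).

Default sizes are plastome-like: N = 120 000 with 30 forward + 30 backward
genes of 900–1500 nt (~60 % coding; ~10⁴ fragments at L=603/R=11),
intergenic GC 0.37, gaps averaging ~700 nt so the junk cluster is well
populated, and a 30-gene RNA block. Larger gene totals at this N would
leave no room for junk windows at all (a window must be ≥ half intergenic
to be junk).

### Default codon usage and the pairing

The default usage is a product of position compositions
π₀ = (A .36, C .22, G .12, T .30), π₁ = complement(π₀), π₂ = (.22, .28,
.28, .22) (self-complementary). Writing E(p,σ) for the exact triplet
distribution of tiling an i.i.d. codon stream at frame shift σ (computed by
enumeration over all 64² two-codon pairs), the frame arithmetic gives
centroids F<sub>j</sub> = E(p,(j−1) mod 3) and B<sub>j</sub> =
RC(E(p,(j−1) mod 3)), RC being the reverse-complement permutation of
triplet space. Under the two structural properties above, RC maps the
shift triangle onto itself with vertices 0 and 1 swapped — so the backward
circuit visits (nearly) the same three locations in transposed order:
exactly the F0–B1 / F1–B0 / F2–B2 pairing and the counter-directed
(mirror) circuits seen in plastomes. The analytic distributions double as
convergence oracles: empirical phase centroids from long-gene genomes
(~1.5×10⁵ codons per phase) match them to L1 < 0.02; at plastome-scale
defaults the sampling bound is ~0.05, which is why the convergence test
uses the long-gene specification.

### Bacteria-like control

RC is a fixed-point-free involution of triplet space, so when both strands
are equally represented every between-cluster principal component is
either symmetric or antisymmetric under RC, and the backward triangle
projects with one sign per component. Mirror geometry arises when exactly
one of the two leading components is antisymmetric. The control usage is a
fixed, strongly Chargaff-asymmetric 64-vector (stored as integer per-mille
weights) whose reading-frame asymmetry makes **both** leading components
antisymmetric: the backward triangle then projects as the point reflection
of the forward one — same circuit direction, i.e. the rotational
arrangement of bacterial genomes. Backward-only usage overrides of the
plastome-like default were found to remain mirror (the symmetry class is a
property of the joint geometry, not of strand asymmetry alone), so the
control sets both per-strand usage fields; each remains independently
overridable.

## Numerical choices

* Population SD everywhere a spread over an ensemble is ranked or
  reported; sorted-column summation for the exclusion argmin.
* PCA: `svd_solver="full"`; sign canonicalization as above; a matrix of
  centered rank < 3 raises a degenerate-embedding error carrying the rank.
* K-means: Euclidean inertia, best of 10 restarts, fixed seed 0 by
  default; assignments are reported after canonical relabeling. On the
  default synthetic genome, assignments under different seeds agree on
  ≥ 95 % of fragments (tested).
* Ambiguous bases: never counted — triplets containing them are skipped
  (M reduced), GC denominators exclude them.
* All tabular output is TSV with a header; the frequency-matrix file
  carries `excluded_triplet`, `fragment_length` and `step` in a leading
  comment line so any stage can be re-run from files alone.

## What the synthetic tests do and do not show

Passing on synthetic genomes shows the pipeline recovers by construction
known structure: frame phases, the mirror/rotational distinction, the
tail's GC pinning, and the abundance bookkeeping. Real plastomes have
structure the generator deliberately omits — inverted repeats, introns and
trans-splicing, codon correlations beyond i.i.d. usage, pseudogenes,
partial or erroneous annotation — so agreement with published per-accession
numbers is checked separately against the real EMBL records (fetched by
`scripts/fetch_accessions.py`; not redistributable within this package's
size budget). Those checks are sensitive to the declared labeling
tie-breaks; any residual discrepancy should be traced to a specific
declared decision above. U/D orientation is internally consistent but its
absolute naming against any external figure requires the one-time
`orientation_flip` calibration.
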
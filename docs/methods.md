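# Methods

This note documents the statistical model, the synthetic-data generator,
the numerical and design choices, and the known limitations of
`cphotspot`.

## Window statistics

The scan operates on **alignment coordinates** (columns of the gapped
multiple alignment), the only coordinate system shared by all sequences of
a genus.  Windows of length W start at 1, 1+s, 1+2s, …; the last start is
the largest with the full window inside the alignment, and a trailing
stretch shorter than W is skipped (a shrunken window would have an
incomparable S) with the skipped length logged.  Defaults W = 600 bp
(typical barcode read length) and s = 50 bp (fine positioning).

*Segregating sites* S counts analyzed columns with ≥ 2 distinct residue
states among non-missing characters.  *Nucleotide diversity*
π = 2/(n(n−1)) Σ_{i<j} d_ij/L_ij averages the per-pair mismatch proportion
over pairs.  Two site-deletion policies are exposed, because sliding-window
software differs here and the choice is part of the analysis definition:

- `complete` (default): a column enters the analysis only if **no**
  sequence carries a gap or IUPAC-ambiguity character there; all pairs
  then share one retained-column set, and for n = 2, π·L_retained = S
  exactly.
- `pairwise`: every column is retained; each pair is compared over the
  columns where both members have unambiguous residues.

Ambiguity codes (N, R, Y, …) are always treated as missing data, never as
polymorphism.  A window in which no pair has a single comparable column
reports π as *undefined* (None/NA), never 0 — a zero would fake
conservation.  Profile summaries are S_max, the arithmetic mean of S, and
the sample (n−1) standard deviation (0 for a single window); the sample
estimator is conventional, the choice is isolated in `summarize_profile`.

An *indel event* is a maximal gap run in one sequence; runs with identical
coordinates in several sequences collapse into one event (one historical
indel inherited by several lineages).  An event is assigned to the window
containing its first gap column, so each event is counted exactly once
across a tiling profile.  Declared inversions are separated
(reverse-complemented in place, gap positions untouched) before scanning;
the separation count feeds the per-window/per-locus inversion indicator.
Separation is an involution, so re-applying a declaration restores the
input.

## Hotspot loci

Windows with S **strictly greater than** mean + k·stdev (k = 2) qualify.
Qualifying windows are merged when they overlap or are separated by at
most one step (max_gap = s): one step bridges staircase artifacts while
keeping well-separated sub-loci distinct (the two-loci-in-one-gene
situation that motivates the `-a`/`-b` naming).  Raising k never adds
loci.

Naming maps the locus to ungapped reference coordinates through the
reference row's gap structure, then applies majority (≥ 50%) rules in
order: exons of one gene → *coding* (named by the gene); one gene's intron
→ *intron* ("gene intron"); the spacer between two genes →
*intergenic_spacer* ("left-right" in genome order).  Otherwise the locus
is *mixed* and named by the dominant feature, where gene dominance is
judged by whole-gene-span overlap — a locus straddling a split
(exon/intron) gene is still named for that gene instead of flipping
between its flanking spacers, which keeps names comparable across genera.
tRNA names get an anticodon suffix (trnS^UGA^) only when paralogs make the
bare name ambiguous.  Genes without annotated exon structure count as
entirely exonic; genes with exons but no explicit introns get the
inter-exon gaps as introns.

Per locus the report carries S (maximum window S inside), π recomputed
over the full span, the indel + inversion indicator I, and the threshold
used.  User-supplied control intervals (e.g. proposed barcodes rbcL, rpoB,
rpoC1, atpF-atpH) are appended with S recomputed over their span, since
controls have no window-selection history.

## Cross-genus intersection

Plastome coordinates are not comparable between genera, so locus identity
is the annotation-derived **name** (anticodon-aware; exact match).  Loci
present in fewer than m = 3 genera are dropped; the cumulative count of
loci shared by ≥ m genera is reported for every m.  Retained loci are
ranked by (genus count descending, mean π descending, name) — breadth
before variability, deterministically.  Homology-aware matching of
differently annotated loci is out of scope; a locus variable in one genus
but annotated under another name elsewhere will not intersect.

## Primer design

Primer-binding sites are maximal flank runs in which **every** supplied
sequence carries the same unambiguous residue — universality is by
construction and re-verifiable by string comparison against each ungapped
input sequence.  Defaults: flank span 400 bp; length 18–27 nt; GC fraction
0.30–0.75; Tm 50–65 °C from the basic GC-count formula
Tm = 64.9 + 41·(nGC − 16.4)/L (adequate for primers > 13 nt, parameter
free, and isolated in one swappable function — nearest-neighbor
thermodynamics is a non-goal); homopolymers ≤ 4 nt; the 3′ G/C clamp is a
soft preference (flagged, not dropped).  The length and GC bounds are
calibrated so that published universal chloroplast primer sets for these
locus classes — which run 19–27 nt and up to ~74% GC — fall inside them.
Pairs must bracket the entire locus with a product of 300–2500 bp and a
Tm difference ≤ 5 °C, ranked by (Tm difference, product length).  Because
nearly invariant flanks yield thousands of interchangeable candidates,
only the 150 candidates nearest the locus on each side (the ones
minimizing product length, the secondary key) enter the quadratic pairing
step; the cap is a constraint field.

## Tree evaluation

Characters are nucleotides; gaps and ambiguity are **missing** (wildcard
states) in both parsimony and distances.  Fitch small parsimony is
computed bottom-up on state-set masks; the score is invariant to the
rooting, and the implementation is checked against an exhaustive
internal-labeling oracle in the tests.  Unrooted topologies are enumerated
exactly — (2n−5)!! trees, feasible to 9 taxa; the intended scale is the
7-taxon case design (six ingroup species plus outgroup, 945 trees) —
and heuristic search is deliberately out of scope.

Neighbor joining uses uncorrected p-distances with pairwise deletion
(divergences at this scale make model correction immaterial).  Ties in the
Q criterion are broken deterministically in lexicographic order of the
clusters' smallest taxon labels; identical sequences therefore give an
arbitrary but reproducible resolution of the zero-length star.

Bootstrap resamples columns with replacement; per replicate the tree is
rebuilt by NJ or by exhaustive MP, where co-optimal MP trees contribute
1/#ties to each of their bipartitions (deterministic, unbiased).  Site
patterns are collapsed once and per-tree pattern scores precomputed, so an
MP replicate is a single matrix-vector product.  The majority-rule
consensus keeps bipartitions with support strictly above 50%.  The
resolution metric is (internal edges present, n−3, fully-resolved);
"solving" six ingroup species under a 7-taxon design means 4 of 4 edges.

## Synthetic congener genomes

The generator emulates what the discovery procedure consumes: a pair (or
star-shaped set) of congeneric plastome-like sequences whose variation is
concentrated in a few hotspots.

Model: ancestral sequence uniform over {A,C,G,T}, length 30 000 bp
(a plastome-scale segment that keeps scans fast); each taxon evolves
independently (star phylogeny — congener sets are small and tree shape is
irrelevant to window statistics) under Jukes–Cantor with branch length
t_b = 0.002 substitutions/site outside hotspots and f·t_b (f = 10) inside.
Per site the change probability is (3/4)(1 − e^{−4t/3}) with the new base
uniform over the other three — exactly the JC transition kernel, so two
taxa diverge by the closed form at total path 2·t_b ≈ 0.004, the
recently-diverged-congener regime.  Six hotspots of 800 bp alternate
between genic and intergenic contexts.  Host features are sized to contain
their hotspot — a genic hotspot sits in a long two-unit gene, an
intergenic one in a widened spacer — mirroring real plastome hotspots
(kb-scale ycf1/ndhF; wide rpl32-trnL-like spacers) and giving loci stable
annotation names across genera.

Indels are lineage-specific **deletions** from the ancestral state
(Poisson rate 2×10⁻⁴ events/site/branch, geometric length, mean 4 bp,
non-overlapping by redraw), so the emitted alignment is the true alignment
in ancestral coordinates and no realignment step is needed.
Microsatellites are (AT)₁₀ tracts whose repeat number drops by 0–4 units
per non-reference taxon (stutter as unit-sized deletions).  One 30 bp
inversion is applied to the second taxon and also emitted as a declaration
table, exercising the separation step.  The reference taxon receives
substitutions but no indels/inversions, so annotation (reference)
coordinates coincide with ancestral coordinates.  Everything derives from
one seed; identical configuration gives byte-identical output.

For multi-genus studies all genera share one genome layout — hence one set
of named shared hotspots — plus optional genus-private hotspots assigned
round-robin from well-separated, deterministically chosen slots, so
private loci are disjoint and differently named across genera.

What the generator does **not** emulate: quadripartite (IR/LSC/SSC)
structure, realistic gene content, codon structure and selection,
insertions creating novel columns, rate heterogeneity beyond the
hotspot/background dichotomy, and alignment error.  Passing tests
demonstrate the pipeline's correctness and its detection behavior under
this idealized model, not performance on real plastomes — in particular
real data add alignment uncertainty at exactly the indel-rich loci the
method favors.

### Detection behavior under the default conditions

With six 800 bp hotspots in 30 kb, 16% of the genome is hotspot-derived,
so the adaptive cutoff mean + 2·stdev sits close beneath the
fully-inside-hotspot window signal (S ≈ 24 vs cutoff ≈ 20): planted-hotspot
recall measured over 20 replicates is ≈ 0.87–0.95 depending on the seed
stream, while precision is ≈ 1 (background windows essentially never cross
the cutoff).  The 3-genus demonstration study instead uses four hotspots
with f = 30: its purpose is the cross-genus set logic (shared loci
retained at m = 3, private loci dropped), which requires locus
presence/absence to reflect the planted design rather than borderline
detection; detection power itself is measured by the single-genus recovery
experiment.

## Numerical choices and degenerate inputs

- π is accumulated as Σ(d_ij/L_ij) in double precision; the n = 2 identity
  π·L = S holds to float round-off.
- Profile TSVs store floats at full precision (`%.17g`, round-trip parse),
  so write → read → write is byte-stable and pipeline reruns are
  checksum-identical; no timestamps are written anywhere.
- Gap-only columns are removed at load (count logged): they carry no
  information and would distort window coordinates.
- An interval lying entirely inside a reference gap maps to the zero-width
  reference position after the preceding residue.
- Empty feature table: loci are named `region_<start>_<end>` (category
  mixed) with a warning.
- `summarize_profile` of a single window reports stdev 0.

## Limitations

- Exact-name cross-genus matching cannot join loci annotated under
  synonymous gene names.
- Exhaustive MP refuses > 9 taxa by design.
- The Tm formula ignores salt and oligo concentration; reported Tm values
  are comparative, not predictive — consistent with protocols that anneal
  at a fixed temperature regardless of computed Tm.
- Primer design emits no degenerate bases; a locus without perfectly
  conserved flanks in the supplied sequence panel simply gets no primers.
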
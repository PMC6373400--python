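# Methods

This note documents the models, conventions and numerical choices behind
`markereval`, and what its synthetic benchmark does and does not show about
real data.

## Coordinates and alphabets

All coordinates are 1-based and inclusive: alignment columns, ungapped
fragment positions, full-gene positions, codon indices.  The only gap
character is `-` (`.` is rejected); `U` is normalized to `T` and case to
upper on input, so every downstream scan works over one canonical alphabet
(A, C, G, T, the eleven IUPAC ambiguity codes, and `-`).  FASTA output is
uppercase, wrapped at 60 columns, so golden files diff cleanly.

A `CoordinateMap` carries three user-supplied integers: the reference
strain, `gene_offset` (full-gene bases upstream of the fragment's first
ungapped base) and `frame_start` (full-gene position of the first codon
base, default 1).  The column → gene map adds `gene_offset` to the count of
non-gap reference characters up to the column; it is strictly increasing
over mappable columns and refuses columns where the reference is gapped.
The codon map is pure arithmetic: with `p = gene_position − frame_start + 1`,
codon index `⌈p/3⌉` and codon position `((p−1) mod 3) + 1`; e.g. gene
position 561 in frame 1 is the third position of codon 187.  The offset is
deliberately configuration, not a built-in constant: for a sequenced
fragment whose first base is gene position 337, the user passes 336.

## Variable sites

A column is variable iff at least two distinct concrete bases occur in it.
Gaps and ambiguity codes are ignored — a column reading A/A/-/N is
invariant.  This is the conservative convention of standard alignment
viewers: an N is an uncertain read, not evidence of polymorphism.  Reports
always carry both the variable count and the column denominator (the full
trimmed alignment length, gap columns included) so the printed fraction is
interpretable whatever the trimming was.

## Percent identity and the barcoding gap

Pairwise identity uses pairwise deletion: columns where either sequence has
a gap *or an ambiguity code* are excluded, and identity is
100 × matches / comparable.  Pairs with zero comparable columns are flagged
undefined and excluded from ranges rather than silently contributing a 0 or
100.  Because different published identity tools treat ambiguity codes
differently, the rule is a switch (`ambiguity="exclude"` default;
`"overlap"` counts a pair of characters as matching when their IUPAC
expansions intersect) and the rule in effect is stamped into every matrix
header.

Off-diagonal identities of labeled strains split into intraspecific and
interspecific pools (strains labeled `unassigned` are excluded; every other
pair falls in exactly one pool).  The barcoding-gap statistic is
`gap = min(intra) − max(inter)`, positive exactly when every conspecific
pair is more similar than every heterospecific pair.  Displayed values are
rounded half-up to one decimal, matching how identity tables are
conventionally printed; JSON artifacts keep full precision.

## Diagnostic SNPs

For a target species, a column is diagnostic when (i) every target strain
carries the same concrete base *s* — a gapped or ambiguous target cell
disqualifies the column, since a diagnostic claim needs positive evidence
and a deletion is not a SNP — and (ii) no labeled background strain carries
*s*, where an ambiguity code carries *s* whenever its expansion includes
*s* (an N might be the diagnostic base, so it counts against the site).
Relaxed mode admits up to `max_exceptions` background carriers and reports
the count; strict mode is relaxed(0), and relaxed(k) results are supersets
of relaxed(k−1).

Annotation enriches a site without altering it: gene position via the
coordinate map; codon index/position via the frame; the reference codon
read from a supplied full-gene sequence, or from the reference strain's
ungapped fragment when the codon lies wholly inside it ("codon incomplete"
error otherwise).  Synonymy is judged against the codons obtained by
substituting each *observed* background base — not all three alternatives —
because the claim of interest concerns the substitutions actually present
in the data.  Translation is the standard genetic code (Biopython).

Query classification against a saved panel is per species: *present* if the
query matches the diagnostic state at every panel site, *absent* if it
carries a different concrete base at every site, *inconclusive* for gaps,
ambiguity codes or mixed evidence.

## Distances, neighbor-joining, bootstrap

Distances use the same pairwise-deletion rule.  Available corrections:
p-distance, JC69 `−¾·ln(1−4p/3)`, and K2P
`−½·ln((1−2P−Q)·√(1−2Q))` with P and Q the transition
(purine↔purine/pyrimidine↔pyrimidine) and transversion proportions.
Saturated pairs (non-positive log argument) are flagged undefined, never
clamped; tree building refuses matrices containing undefined pairs and
names them.

Neighbor-joining is the classic Q-criterion algorithm with the standard
branch-length and reduction formulas.  Two numerical policies make it
deterministic and safe: Q-matrix ties are resolved toward the
lexicographically smallest active index pair (input order, then creation
order), and negative branch lengths are clamped to zero with a warning.
On additive matrices the algorithm recovers the generating topology; the
test suite certifies this against an exhaustive least-squares topology
oracle for up to 6 taxa and against zero-residual fits up to 8.

Bootstrap resamples alignment *columns* with replacement (same length),
re-derives the distance matrix per replicate from a precomputed per-pair
per-column classification (match / transition / transversion /
incomparable), and re-joins.  Support of an internal edge of the
point-estimate tree is the percentage of successful replicates whose tree
contains the same bipartition; replicates with undefined distances are
skipped and counted, and more than 50 % skipped is an error.  Supports are
stored as internal node labels so they survive Newick round trips.  The
replicate count defaults to 100 and the display threshold (supports below
which are blanked in the display tree) to 70 — the threshold is a report
option, not part of the computation.  Clamp warnings are suppressed inside
replicates, where tiny negative branches are routine.

This distance/NJ machinery is a deliberately lightweight clustering
surrogate for likelihood tree inference: reports state that comparisons
with published ML trees are qualitative (cluster membership), not
branch-for-branch, and bootstrap values are not comparable across methods.

## Monophyly and outliers

A species with ≥ 2 strains is monophyletic when some edge bipartition
separates exactly its strains from all other *labeled* strains (unassigned
leaves may fall on either side).  For non-monophyletic species the report
lists outliers: members outside the species' largest single-edge pure core.
When two pure cores tie in size, the core containing the species' type
strain wins — clusters are anchored at nomenclatural reference strains, as
in taxonomic practice; without a type strain the tie is broken by traversal
order.  Outliers are the computational counterpart of "misnamed" database
strains.

## Synthetic data and calibration

The generator emulates a single-gene genus survey under a star phylogeny:
a uniform-random root, one ancestor per species, strains sampled around
each ancestor.  Each branch of length *t* substitutes each site with
probability `¾·(1−e^(−4t/3))` — exactly the JC transition probability, so
branch lengths compose additively and realized divergences match their
expectations in closed form, which keeps calibration exact without
continuous-time simulation.  The replacement base is the transition partner
with weight κ (default 2.0, a typical transition bias for bacterial
protein-coding genes) against weight 1 per transversion; κ ≠ 1 perturbs
additivity only at the level of coincident double substitutions, far below
the calibration tolerances used anywhere.

`intra_divergence` and `inter_divergence` are *pairwise* expectations
(substitutions/site between two strains of the same vs different species);
internally the root→ancestor branch is `(inter−intra)/2` and the
ancestor→strain branch `intra/2`, so both pair classes hit their targets.
`calibrate_to_identity` inverts the JC expectation
`p = ¾·(1−e^(−4d/3))` at the midpoints of requested identity intervals;
the defaults are calibrated to ≈ 98.6 % within and ≈ 88.7 % between
species, the midpoints of the 97–100 % / 80–97.4 % ranges typical of a
single-genus housekeeping-gene survey.  Scale defaults: 733 columns, 69
strains in 28 species (one focal species with 22 strains, twenty species
with 2, seven singletons), gap fraction 0.005 per cell, one planted
diagnostic site (focal species, column 225, G).

Planted sites are applied after strain generation and excluded from every
random process (mutation and gap injection); each non-target species
receives one resampled non-diagnostic base shared by its strains, so
planting neither creates within-species variation nor can be destroyed by
it — diagnostic-scan recovery of planted sites is exact by construction,
not probabilistic.  Outlier strains are *relabeled*, not resequenced
(emulating misnamed accessions), and never involve species named in
planted sites, which would otherwise break the planted-site guarantee.
A single RNG stream (NumPy PCG64 from `seed`) is consumed in fixed order —
root, ancestors, strains, planted resampling, gaps, outliers — so output is
bit-reproducible.

What the generator does *not* emulate: nested species trees (between-species
identities concentrate near their expectation instead of spanning a wide
range), indel evolution (gaps are uniform noise), rate variation across
sites, and recombination.  Passing recovery tests on this benchmark
therefore demonstrates correctness of the *algorithms*, not robustness to
every pattern in real survey data — in particular, real alignments show far
lower variable-site fractions than the star-phylogeny benchmark, and real
identity pools usually overlap (negative barcoding gap).

## In-silico PCR

Primer–template matching is positional over IUPAC expansions: characters
match when their expansions intersect (primer Y matches template C or T but
not A or G; degeneracy on either side is honored).  The reverse primer is
given 5′→3′ on the reverse strand, as in wet-lab convention, and is matched
as its reverse complement on the supplied strand.  A product spans the
first base of a forward site through the last base of a downstream,
non-overlapping reverse site; all products are reported sorted by
coordinates, with an optional per-site mismatch tolerance (default 0).
Thermodynamics (melting temperature, dimers) are out of scope.

## Pipeline determinism

The `run` pipeline writes one artifact per stage plus `summary.json` and
`summary.txt`.  Determinism is a contract: no timestamps, sorted JSON keys,
deterministic NJ and seeded bootstrap — reruns with the same inputs and
seed are byte-identical.  Degenerate inputs degrade gracefully with logged
reasons: a single-species table skips diagnostics (no background), fewer
than three strains skips tree building.  Stage failures propagate with the
stage name attached.

## Problem sizes used in the checks

The bundled acceptance checks run at the survey scale above (69 × 733, 20
seeded replicates for recovery statistics, 100 bootstrap replicates for the
reported tree), with randomized-oracle comparisons on 200 alignments up to
12 × 60 and NJ recovery on 50 random additive matrices of 4–8 taxa; the
whole suite completes in a few seconds on one core.
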
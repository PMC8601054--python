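# Methods

## The domain model

A RING domain is modelled as an octuple of metal-ligand (ml) positions in a
protein sequence. The scanner's unit of work, an *arrangement*, is eight
strictly increasing 1-based positions whose residues fall in the per-slot
residue sets and whose seven inter-residue spacers g12…g78 fall in the
per-gap windows. A spacer counts residues strictly between two consecutive
ml residues: "C x2 C" means positions p and p+3. This convention is the only
one consistent with the canonical 40–60 residue domain length given the
consensus windows.

The default constraints are the union over the eight per-type consensus
rows:

| slot | residues | gap | window |
|------|----------|-----|--------|
| ml1  | C        | g12 | {2} |
| ml2  | C, S, T  | g23 | [8, 33] |
| ml3  | C        | g34 | [1, 4] |
| ml4  | H, C     | g45 | [2, 7] |
| ml5  | H, C, D, G | g56 | [1, 2] |
| ml6  | C, S, T  | g67 | [1, 64] |
| ml7  | C        | g78 | {1, 2, 3, 4, 10} |
| ml8  | C        |     | |

Two deliberately conservative choices live here. First, T is accepted at
ml2/ml6 alongside S (the substitution type is named S/T even though every
reported flax domain carries S); `SpacingConstraints.strict()` removes T for
surveys that want the narrower reading. Second, g78 is the discrete set
{1,2,3,4,10} — the isolated 10 comes from the RING-v consensus ("C x2,10 C")
and intermediate values 5–9, never observed, are excluded by default. Both
are constructor parameters, not constants. The unknown residue X never fills
an ml slot but is legal inside spacers.

### Search and overlap resolution

Enumeration is depth-first over anchor positions with window pruning. It is
exhaustive by construction: the only skipped branches are those that violate
a residue set or gap window. Worst-case cost is bounded by the product of
window widths and is negligible at proteome scale (the test suite compares
against a brute-force nested-loop enumerator on hundreds of random
sequences).

Overlapping candidates are resolved deterministically: prefer arrangements
whose assigned type's own consensus windows are fully satisfied, then
earliest ml1, then smallest span, then lexicographically smallest position
tuple; accept greedily in that order, skipping overlaps. This favours
canonical domains and reproduces the observed "up to three domains per
protein" structure without heuristics.

## Type assignment

Types are decided by residue identity alone, with the single documented
exception of the HCa/HCb split on g78. The tree branches on (ml4, ml5):
(H,H)→RING-H2, (C,H)→RING-v, (C,C)→RING-C2, (H,D)→RING-D, (H,G)→RING-G.
For (H,C): an S or T at ml2 or ml6 makes RING-S/T — the substitution check
precedes the C-terminal spacing split, since S/T is its own type regardless
of g78 — otherwise g78∈{1,2}→RING-HCa, g78∈{3,4}→RING-HCb. An (H,C) domain
with g78=10 (legal under the union window via the RING-v row) is reported
*unclassified* rather than forced into a subgroup defined only for g78 ≤ 4.
Unclassified calls are carried through every report in their own row,
excluded from the eight-type percentage base, and never dropped.

Census percentages use two decimals with round-half-up, matching the
precision convention of published family surveys (49.74%, 34.75%, …).

## Spacing and flanking statistics

Spacer histograms are exact counts per ml pair, overall and per type;
per-type histograms stack bin-wise to the overall histogram (asserted in
tests). Flanking-residue frequencies are anchored on ml positions in
ungapped protein coordinates with a fixed offset glossary: "ahead of" = −1,
"next to" = +1, "second site after" = +2, "fourth site after" = +4. An
anchored position falling on another ml site is counted normally (logos
include inter-ml columns); one falling outside the protein is skipped and
the skip count reported, so each frequency vector sums to 1 over the domains
where the position exists.

## Architecture grouping

Proteins are keyed by the multiset of their non-RING domain names,
normalised case-insensitively; any name containing the token "RING" is
treated as the RING domain itself (InterProScan/SMART emit heterogeneous
labels such as zf-RING_2), and {TM, TMhelix, transmembrane} map to the
reserved token TM. Group 1 is the empty signature, group 2 is {TM} with
multiplicity collapsed ("one or more transmembrane domains"); a protein with
TM plus anything else belongs to its full signature group. Other domains
keep multiplicity (ANK×3 ≠ ANK×1). Remaining groups are numbered by
decreasing size, ties by lexicographic signature, making the grouping
invariant to input row order.

## Ka/Ks and duplication dating

Codon alignments are built by threading each CDS (terminal stop trimmed)
onto its protein alignment row, one residue → one codon, one gap → "---";
translation is verified site by site under the standard code before any
counting.

The estimator is Nei–Gojobori (1986). Each codon contributes a synonymous
site count s = (number of the nine single-nucleotide changes that are
synonymous)/3, averaged over the two sequences of a column, with the
nonsynonymous count its complement to 3, so N + S = 3 × (ungapped codon
columns) exactly. Changes to stop codons count as nonsynonymous sites.
Codons differing at several positions are averaged with equal weight over
all orderings of the single steps, excluding pathways through stop codons;
in the rare corner where every pathway is blocked, the average is taken over
all pathways rather than discarding the column. Columns containing a gap or
an N in either codon are dropped pairwise. Proportions are Jukes–Cantor
corrected, d = −(3/4)·ln(1 − (4/3)p), with p ≥ 3/4 flagged as saturated;
Ka/Ks is reported only when Ks > 0 and unsaturated.

Dating uses T = Ks/(2λ) with λ = 1.5×10⁻⁸ synonymous substitutions per site
per year (the flax rate) as an explicit parameter. Age binning is likewise
parameterised: pairs with T ≤ 15 MYA are *recent*, pairs above the boundary
with Ks ≤ 3 are *ancient*, the rest *excluded*. The 15 MYA default sits
between the flax mesopolyploidy (3.7–9 MYA) and palaeopolyploidy (20–44 MYA)
windows; the Ks ≤ 3 cutoff drops saturated pairs whose JC correction is
unreliable. A helper accepts externally supplied Ks values so dating and
binning can run on published duplication tables without re-estimating rates.

## Neighbor joining and clades

Distances are uncorrected p-distances with pairwise deletion of columns
containing a gap or X — chosen over corrected models for exact testability;
a pair with no comparable column is an error, not a silent zero. NJ is the
classic Q-criterion algorithm with rate-corrected branch lengths; negative
lengths are clamped to zero with the deficit moved to the sister edge so the
pair distance is preserved; ties in Q are broken by the lexicographically
smallest taxon-id pair (internal clusters inherit their smallest leaf id),
making the topology a pure function of the matrix. On additive matrices the
generating topology and branch lengths are recovered exactly (tested against
an independent NJ implementation and a brute-force split check).

Bootstrap support resamples alignment columns with replacement per
replicate and scores each internal bipartition of the full-data tree by the
percentage of replicate trees containing it; the resampling stream is seeded
and rows are processed in id order, so supports are reproducible and
invariant to leaf order.

Clade extraction is algorithmic, because published clade boundaries are
typically drawn by inspection: root at the midpoint of the longest
leaf-to-leaf path, then greedily cut edges — internal edges before leaf
edges, longest first — rejecting any cut that would strand a leafless
component, until k leaf-bearing components exist. Exact leaf-level agreement
with a published figure is not claimed (the published tree's distance model
is not recoverable); only qualitative composition (majority type per clade)
is checked, on synthetic families with planted structure.

## Synthetic data: what it emulates and what it does not

`plant_domains` builds proteins around consensus-conformant domains with
spacers drawn uniformly from the assigned type's own windows. In *clean*
mode the background and spacer alphabet excludes every ml-capable residue
(C,H,S,T,D,G) and planted spans are separated by ≥ 70 residues — more than
the widest spacer window — so each planted octuple is provably the unique
satisfying arrangement; this is what makes exact recall/census tests
possible. In *full-alphabet* mode decoys may arise and only recall is
guaranteed. `evolve_codon_pair` plants at most one substitution per codon,
split into synonymous/nonsynonymous classes measured against the ancestor's
NG86 site counts, never creating stops. `make_family_alignment` derives
family ancestors from a common root at a between-family per-site
substitution probability and members at a smaller within-family one.

None of this emulates real evolutionary sequence structure: no indels, no
rate heterogeneity, no codon-usage bias, no empirical spacer-length
distribution (real families concentrate on a few spacer values; the
generator is uniform within windows). Passing tests therefore demonstrate
correctness of the algorithms under their stated models — exhaustiveness,
exact counting, estimator consistency — not field performance on divergent
or degenerate real sequences. Reproduction of the published flax census
requires the real published domain set, consumed through the same pipeline
when present under `data/flax/`.

## Numerical choices and degenerate inputs

- Percentages: two decimals, round-half-up (decimal arithmetic, not float).
- Fraction/percentage invariants asserted at 1e-9; p-distance symmetry at
  1e-12; newick round-trip lengths at 1e-9.
- Empty scan results are valid (empty list); empty call sets are an error
  for statistics (nothing to summarise).
- A protein with zero domains still appears in the census histogram at 0.
- Identical sequences give Ka = Ks = 0, T = 0, ratio undefined; a pair with
  no synonymous sites gives Ks undefined rather than a division error.
- Acceptance-script problem sizes: 587 planted domains (the published
  family size), 200 codon-pair replicates at 500 codons, 200 additive
  matrices on 4–8 taxa, 100 bootstrap replicates.

## Known limitations

- The scanner assumes degapped, validated sequences; it does not rescue
  incomplete domains missing an ml residue (by design — degenerate domains
  are excluded, not repaired).
- NG86 is a counting method; it will disagree in detail with
  maximum-likelihood estimators on real data, and published Ka/Ks tables
  computed with unknown software are matched only approximately.
- Bootstrap on alignments with many gap columns can produce replicates with
  no comparable columns for a pair; this surfaces as an error rather than a
  silently biased support.
- The clade cutter guarantees k leaf-bearing components, not balanced or
  "natural" clades; on star-like trees the cuts follow edge length and the
  deterministic tie-break only.
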
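# Methods

This note records the models, conventions and numerical choices behind
`mgbssr`, in the order the pipeline runs.

## Coordinates and sequence handling

All in-memory coordinates are 0-based half-open; exported locus tables and
GFF3 use 1-based inclusive positions and say so in a header line. Sequences
are stored uppercase; IUPAC ambiguity letters are collapsed to N on input,
anything else is rejected. N is legal in a genome but never inside a
reported SSR core.

## SSR detection

A reported locus is a **maximal perfect tandem run of a primitive motif**
(3–6 nt by default): the run cannot be extended by one whole motif copy on
either side, partial trailing copies are excluded (maximality is in whole
units), and motifs that are repetitions of a shorter motif (e.g. ATAT) are
never reported — a dinucleotide tract is invisible to a 3–6-mer scan.
Runs containing N are split at the N.

A long run always contains shorter runs of the motif's cyclic rotations
starting 1..k−1 bases in, so "report every maximal run exactly once" needs
a tie-break. The published contract is: enumerate all left-maximal runs
above threshold, then select greedily by (leftmost start, longest run,
shortest motif). Consequences: reported loci never overlap, and detection
is shift-equivariant. The test oracle re-implements this contract with an
exhaustive O(n·k) window scan.

**min_repeats defaults to 4** for every motif length. The protocol this
package follows states its repeat-count bound in an internally inconsistent
form; 4 is the smallest count among the validated markers of the published
panel, and the threshold is one flag away for other readings. Compound and
interrupted repeats are out of scope (none of the published markers is
compound). Loci carry the motif as spelled in the genome; a canonical
rotation/reverse-complement key is available for optional grouping, since
the screen compares loci by position, not motif class.

## Genome search (seed and extend)

The screen's matching contract is "find the orthologous flank block", not
any particular aligner. `search_genome` collects exact 15-mer seed matches
(step 5 for long queries, every position for primers), clusters them by
diagonal (band 25), and refines each candidate window with an infix gapped
alignment (edlib), reading identity = matches / aligned columns off the
alignment path. Both strands are searched; minus-strand hits are reported
in forward target coordinates with strand `-`. The infix mode consumes the
whole query, so diverged ends depress identity rather than coverage; with
15% substitutions a 300 bp flank falls to ≈0.85 identity and is cleanly
rejected by the 0.90 floor, while 5% divergence passes. Near-co-optimal
secondary hits (identity within 0.05 of the best) are treated as evidence
of repetitive context; a weak secondary hit is not.

## The five-stage screen

Identity ("consistency") is computed **over flank columns only, with the
SSR core excised before alignment** — otherwise repeat-count differences
would depress identity and conflate the conservation filter with the
polymorphism test. Flank matching searches the left and right flank
separately and pairs placements on the same sequence and strand with a
0–400 bp gap; combined identity is the length-weighted mean of the two
flank identities.

Stages, in order, with the status each assigns:

1. *Self-uniqueness*: the anchor locus's flank block must place exactly
   once in the anchor genome (`dropped_nonunique`). Because identity is
   flank-only, a duplicated flank block scores ≈1 regardless of how long
   the core is.
2. *Cross-genome matching*: no qualifying placement in some genome →
   `dropped_low_identity`; ambiguous near-equal placements →
   `dropped_nonunique`.
3. *Repeat-count comparison*: the target's count is **recomputed by running
   the detector on the matched core window ± one motif length** (threshold
   2 for robustness), never inferred from alignment lengths; rotations of
   the anchor motif count, and minus-strand counts are taken on the reverse
   complement. All counts equal → `dropped_monomorphic`.
4. *Flank-mutation filter*: the 50 bp windows immediately adjacent to the
   core (the likely primer sites) must align edit-free against every
   matched genome (`dropped_flank_mutation`); window size and edit
   tolerance are parameters, zero edits being the default because the
   underlying protocol names no threshold.
5. *Full polymorphism*: counts differing between only two genomes →
   `dropped_two_way_only`; retained loci have pairwise-distinct counts in
   every genome. With exactly two genomes this stage is a documented no-op.

The funnel counts (detected → self-unique → cross-matched → polymorphic →
clean-flanks → retained) are logged and are non-increasing by construction.
Raising the identity floor or adding a genome can only shrink the retained
set.

## Primer evaluation

Six independent booleans per pair; `overall` is their conjunction.
Tm is nearest-neighbor with SantaLucia-1998 unified parameters at 50 mM
monovalent salt and 250 nM primer (ΔTm tolerance 5 °C — "similar annealing
temperatures" quantified as a default, not a claim). Dimer screening fails
a pair on a perfect inter-primer duplex run ≥ 8 nt anywhere or ≥ 5 nt
anchored at either 3′ end. Specificity counts convergent
forward/reverse-site pairs within 2 kb per genome and requires exactly one.
The M13(−21) universal tail (TGTAAAACGACGGCCAGT) is the default 18 nt
fluorescent-linker sequence and is configurable. Primer *design* is
deliberately out of scope: the module scores externally designed pairs, so
the criteria apply regardless of the designer used.

Panel packing is deterministic greedy by descending amplicon length onto
the least-loaded feasible dye (≥ 20 bp same-dye separation, ties by dye
order). Best-fit rather than first-fit is used because tightly clustered
amplicon sizes — the published panel has five within 24 bp — are packable
only if the cluster is spread across dyes early. Dye names are opaque
labels ("TAME" is accepted as an alias of TAMRA).

## Diversity statistics

Frequencies count allele copies as recorded per cell (a triploid cell
contributes three copies; a single recorded allele contributes one — the
table format writes homozygotes with full multiplicity). He is Nei's gene
diversity without small-sample correction by default; the 2n/(2n−1)
unbiased variant is a flag, because upstream software reports both and
published tables rarely say which was used. Ho is the fraction of typed
samples carrying ≥ 2 distinct alleles, which extends naturally to
triploids; a `diploid_only` flag gives strict diploid statistics.
PIC uses the Botstein closed form. Fragment-size binning from capillary
traces is out of scope: tables hold integer sizes already.

Note for users of published tables: printed Ne/He pairs are not always
mutually consistent under a single correction convention; such rows are
treated as data, not re-derived.

## ID cards

Patterns (sorted allele-size tuples) per marker are coded "01".."99" in
ascending lexicographic order of the tuple — the sort the underlying
protocol leaves unspecified; frequency-rank ordering would also be
deterministic but lexicographic makes codes independent of cohort
composition, so adding samples with known patterns never changes existing
codes or IDs. "00" is reserved for missing. Capacity is 99 patterns per
marker by construction of the 2-digit code. Coding is per genotype
pattern, not per allele: that is the only reading that yields exactly two
digits per marker and hence a 24-digit ID for a 12-marker panel.

## Trees and ordination

The 0/1 matrix scores allele presence (not dosage), columns ordered by
marker then allele size; a missing cell is all-zero in its marker's
columns. Jaccard distance is the default for such dominant-band matrices
(Dice and simple matching are available); two all-band-free samples are
defined to be at distance 0, and an all-zero sample at distance 1 from any
banded one.

Neighbor joining is implemented in-package because the required
negative-branch policy — clamp to zero and move the deficit to the adjacent
branch of the joined pair, preserving their summed length — is not what the
available library implementations do (they only zero the branch). On
additive distances the implementation reproduces generating-tree path
lengths to machine precision and agrees with scikit-bio's NJ, which serves
as an independent cross-check in the tests. Q-matrix ties break toward the
lowest taxon indices; newick serialization uses 6 significant digits, while
the returned tree object keeps exact lengths.

PCoA delegates to scikit-bio's classical scaling (Gower centering of
−d²/2). Negative eigenvalues — routine for Jaccard-type distances — are
reported but their axes are never returned as coordinates; requesting more
axes than positive eigenvalues warns and truncates. Axis signs are
canonicalized (largest-magnitude loading positive) so runs are
deterministic and relabeling-equivariant. Tree "group cutting" (removing
the k−1 longest internal edges) is a presentation utility with no
analytical claims attached.

## Synthetic data

`generate_genomes` plants one block per locus — left flank, motif run,
right flank — separated by repeat-suppressed random spacers
(rejection-sampled so no chance 3–6-mer run reaches threshold−1 copies,
the one-copy slack guarding junctions). Flank characters adjacent to the
core are forced to differ from the motif's terminal characters so the
planted run is exactly maximal. Six locus classes map one-to-one onto
screen outcomes; per-class conditions are: identical flanks with
pairwise-distinct counts (retained), counts differing in only one genome,
identical counts, flank block duplicated (without core) elsewhere in the
anchor, ~15% flank substitutions in one genome, and 2 substitutions inside
one 50 bp primer window. Defaults — 10 loci per class, 300 bp flanks, 3–4 nt
motifs, 4–12 copies, ~100 kb genomes — are the study conditions the screen
is validated under. Every assembled genome is verified by running the
detector: the planted cores must be the only detections, else the build
re-rolls (seeded). Generation is byte-reproducible per seed.

`generate_genotypes` samples allele copies i.i.d. from the given
frequencies (Hardy–Weinberg), with a per-sample ploidy plan (e.g. 26
diploids + 4 triploids, the mixed-panel design) and an optional missing
rate. What the generators do **not** emulate: indel divergence between
genomes, compound repeats, assembly gaps, sequencing error, genotyping
error, linkage and population structure. Passing the planted-truth tests
therefore demonstrates correctness of the screen's logic under its stated
assumptions, not robustness to assembly artifacts.

## Problem sizes and tolerances

The validation suite runs the screen on three ~100 kb genomes with 60
planted loci, detector-oracle equivalence on 200 random 5 kb sequences, NJ
consistency on 50 random trees of ≤ 12 taxa (path error < 1e-9), PCoA
round-trips on Euclidean configurations (< 1e-8), and frequency recovery
at n = 500 within three binomial standard errors — sizes chosen so the
whole suite completes in well under a minute while every code path,
including all six screen outcomes, is exercised with exact expected
results.
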
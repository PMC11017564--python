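# Methods

This note records the models, conventions and design choices behind
`pgatype`, in the order the pipeline runs them.

## Genome model and coordinates

Genomes are held as a `GenomeRecord`: id, length, nucleotide sequence
and an ordered list of CDS features. All internal coordinates are
0-based half-open; GenBank's 1-based inclusive convention is converted
exactly once, at the I/O boundary (Biopython does the parsing and
serialisation). `complement()` locations map to strand `−`. Only CDS
features are retained — the analyses work on proteins. A CDS without a
`/translation` qualifier is translated with NCBI table 11 (the
*Bacillus* standard) and the terminal stop is stripped. Origin-spanning
CDS are rejected with a clear error: circular topology is modelled, but
cluster-spanning-origin layouts are normalised away by the generator
and never produced. Written files carry a fixed LOCUS date so output is
byte-stable.

## Pairwise alignment

The aligner is a three-state Gotoh dynamic program (match, gap-in-a,
gap-in-b) with an affine gap model: the first gapped residue of a run
costs `gap_open`, each further residue `gap_extend`, and switching gap
direction opens a new run. Defaults are BLOSUM62 with −11/−1, global
mode; local (Smith–Waterman) mode is available for detection. `X`
scores 0 against everything. Traceback is deterministic with the fixed
preference diagonal > up > left, so alignments are reproducible
bit-for-bit. The implementation is vectorised row-wise; the in-row
dependency of the left-gap state is resolved with a running cumulative
maximum, which is exact for this recurrence.

**Identity** is identical columns divided by *all* alignment columns
(gap columns count in the denominator, never the numerator). Published
identity ranges for these proteins are not recomputable from their
methods sections, so the denominator convention is stated explicitly
and an `ungapped_columns` alternative is provided.

## Gene detection

Each of the eleven panel genes is searched against every translated
CDS. Candidates shorter than `min_coverage` times the reference length
are skipped; exact copies short-circuit the DP. A hit requires identity
≥ 0.30 and reference coverage (residue–residue columns / reference
length) ≥ 0.50. No homology cutoff is published for this gene set; 0.30
separates the phage-derived hydrolase paralogs — which share only
~27–37% identity with the PghP-family reference — from random matches,
and both thresholds are configurable. Each CDS may serve at most one
gene (greedy by score, ties by genome position). The cluster's small
fourth ORF is labelled both *ywtC* and *pgsE* in the literature; the
panel treats the two names as one slot.

## Architecture and spacing

Architecture records gene order, per-gene strand, lengths, and
spacings. The spacing convention is the end-to-start gap between
genome-ordered genes (negative when they overlap); a start-to-start
alternative exists for sensitivity analysis. Gap distance is the
convention consistent with using a ~1.7 kb *pgdS*–*ywtC* figure as a
cluster-internal discriminator, which is how the genotype-3 rule uses
it.

## Genotyping rules

The packaged table (`bacillus-g7-v1`) encodes a seven-genotype scheme:

| genotype | gene content |
|---|---|
| G1 | all 11 genes |
| G2 | all except *pghZ* |
| G3 | G2 content, *pgdS*–*ywtC* gap in an unusual window |
| G4 | no *pghB*, no *pghZ* |
| G5 | no *pghC*, *pghL*, *pghZ*, *ggt* |
| G6 | all except *pghL*, *pghZ* |
| G7 | G6 minus *ywtC* |

Evaluation is ordered with first match wins; G3 is listed before G2
because it is the more specific rule (same content, distinguished only
by spacing), so the order is G1, G3, G2, G4, G5, G6, G7. "The G2 genome
contains the other enzyme genes in addition to *pghZ*" is grammatically
ambiguous in the source narrative; the G1-vs-G2 contrast supports "all
except *pghZ*", which the table encodes — flagged here rather than
silently resolved. Genotype rules check presence/absence plus any
spacing clause; subtype rules add order templates, strand templates
(`*` = wildcard, flagged in the evidence trail) and spacing windows.
Spacing windows are ±10% around the observed values (1720 bp and
58,256 bp): printed distances are strain observations, not thresholds,
and a tolerance makes the rules usable on new genomes. A genome
matching a genotype but no subtype is "unassigned", not an error
(G4 and G5 have a single member each); a genome matching nothing is
"untyped".

The narrative behind this scheme fixes only some subtype
discriminators (e.g. the G2 *pghB/pghC/pghL/ggt* genes antisense to the
synthetase cluster and *racE* except in SG2.3/SG2.5/SG2.8; the
SG1.6-vs-SG1.3 *racE* orientation flip; the SG6.1/6.8, SG6.2/6.9 and
SG6.4/6.10 *ggt* flips). The remaining discriminators are completed
with distinct synthetic layouts so that the 32 packaged subtypes are
pairwise distinguishable and every subtype has a concrete, generatable
template — a requirement for closure testing. Those completions are
design choices of this package, not published observations.

## Variation catalogs

Substitutions are called from a global alignment of each strain protein
against the reference and reported as `ref`–`1-based position`–`alt`
(e.g. D74N), anchored on the reference: columns where the reference is
gapped (insertions) shift no positions, which is what makes notations
aggregatable across strains. Insertions and deletions are catalogued in
a separate indel list; applying substitutions plus indels to the
reference reconstructs the query exactly (a tested invariant).
Frequency = carrier count / panel size; strains missing a protein are
excluded from that protein's panel size. Text output formats
percentages with two decimals; machine output keeps raw fractions, and
count and percentage are always computed from each other, never
reported independently. Identical strain sequences share one memoised
alignment, so large panels of few haplotypes stay cheap.

## Trees

Multiple alignments are progressive: pairwise identities → average-
linkage (UPGMA) guide tree → profile–profile merges using the same
affine recurrence, with column scores summed over cross-profile residue
pairs and gap penalties scaled by the cross-profile pair count so the
DP objective tracks the sum-of-pairs score. Progressive alignment is a
heuristic; it is not guaranteed to beat other heuristics on arbitrary
unrelated strings, and the test suite asserts its sum-of-pairs
advantage only on homologous inputs, which is the domain use case.

Distances are pairwise-deletion p-distances (mismatches over columns
where neither row is gapped) — robust when one divergent sequence
introduces many gap columns, unlike complete deletion. Trees are
Saitou–Nei neighbor joining with deterministic first-minimum tie-breaks
in stable node order; NJ is exact on additive matrices (tested to
1e−9). Negative branch estimates are clamped to zero with the raw value
retained. Bootstrap resamples alignment columns with replacement
(seeded NumPy generator); support is the percentage of replicate trees
containing each internal split of the full-data tree, stored as
internal node labels so Newick round-trips preserve them. Distance-NJ
replaces likelihood inference deliberately: it is desk-scale,
dependency-free and sufficient for the diversity summaries this
package reports; ML/Bayesian inference is out of scope. "Evolutionary
branch" counts quoted for these enzymes elsewhere have no stated
operational definition; `count_variants` (distinct haplotypes) is the
documented proxy.

## Assay arithmetic

The standard curve is ordinary least squares of A₅₇₀ on glutamate
concentration; R² = 1 − SSres/SStot. Back-calculation inverts the
line; negative concentrations (response below the blank) are returned
and flagged rather than clipped. For content, the published equation,
its inline percent form and the published result table are mutually
inconsistent, so two variants are shipped: the default `mass_ratio`
form, content = glutamate × W / G (a sample's glutamate converts
through the standard's G µg glutamate per W g polymer — dimensionally
coherent and self-consistent: the standard reconstructs its own mass),
and the `literal` percent form, content = glutamate / ((G/W)·100),
kept for fidelity. The published per-strain content values are not
reproducible from G = 1600 µg and any stated W with either variant; an
unstated dilution factor is likely, so a free `conversion_factor` is
exposed and the provenance string records variant and factor for every
number. W's unit must be declared by the caller. OD600 is carried
through reports but enters no formula. Only the content → yield step
(yield = content / volume) reproduces published numbers directly, and
the yield·volume = content invariant is enforced.

## Synthetic data

The generator is the ground-truth source for all tests. Reference
proteins are random sequences with *B. subtilis*-like residue
composition starting with M; default lengths approximate the real
enzymes (pgsC 149 aa smallest … ggt 587 aa largest) but are
configuration values, not biology claims. Back-translation uses one
fixed preferred codon per residue plus a TAA stop (codon usage is
cosmetic here); filler sequence is random at 43% GC (Bacillus-like,
configurable). Genomes realise an `ArchitectureSpec` (order, strands,
n−1 gaps, flanks) exactly, with default gaps of 30 bp inside the
synthetase cluster, 100 bp for *ywtC*–*pgdS* (overridden to 1720 or
58,256 bp in G3 templates) and 200 bp elsewhere; decoy CDS with random
proteins are planted in the flanks. Strain panels plant a fixed event
set into ⌈carrier_fraction·n⌉ strains (ceiling, so small panels have
exact frequencies), carriers chosen by a seeded permutation. Every
generator is a pure function of (spec, seed).

What the generator does **not** emulate: indels between strains,
recombination, codon-model evolution, pseudo-genes, fragmented
assemblies or annotation errors. Passing closure tests therefore shows
that the pipeline's logic is internally consistent on clean inputs —
it does not certify recall on messy real annotations, where the
configurable thresholds matter.

## Problem sizes and numerical choices

The test and acceptance runs use desk-scale sizes chosen to exercise
every code path: all 34 packaged templates for closure, 64 single-gene
deletions for perturbation, ≥1000 short pairs against the exhaustive
alignment oracle, 10×200-strain panels for substitution recovery,
50–100 random 4–8-leaf additive trees for NJ, 1000 bootstrap
replicates, and 50 round-trip fixtures. Headline strain counts from
multi-hundred-genome surveys require the underlying GenBank corpus and
are out of scope as numeric targets; the package reproduces the
procedures, not those datasets. Score comparisons in the DP are exact
(integer-valued float64); NJ assertions use 1e−9; the distance-matrix
symmetry tolerance is 1e−9.

## Known limitations

- Detection is full-protein alignment only: no k-mer seeding, E-values,
  HMMs or nucleotide search; runtime is O(nm) per pair.
- Rule matching compares genome-order templates directly; a genome
  archived in the opposite assembly orientation would need its rules
  mirrored (or the record reverse-complemented) first.
- The literal assay formula is preserved but cannot reproduce published
  content values without an unstated dilution factor.
- Fuzzy GenBank locations (`<`, `>`), joined/compound CDS and GFF3
  input are unsupported by design.
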
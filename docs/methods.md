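# Methods

## The model system

The pipeline models a promoter-scale insertion polymorphism: a short
retroposon of fixed architecture present at one or two defined loci in some
lineages of a species panel and absent in others, with short palindromic
entrance sites whose base-pairing state co-varies with element presence.
The element model is a dimer — monomer 1 (116 nt), linker (27 nt),
monomer 2 (117 nt), terminator [AGC]×4 — 272 nt in total.  Monomers are
homologous and are distinguished by *diagnostic sites*: positions at which
the two monomers always differ.  The diagnostic positions used by the
generator are synthetic defaults (a property of the generated element
model, flagged as such in output); for real data they are user-overridable,
since the true positions come from the repeat-family literature, not from
promoter data.

## The synthetic panel: what it emulates, and what it does not

`palinsert.panel` generates a 14-species panel of ~1.6 kb promoters
(1,088 nt non-coding region + 450 nt downstream-gene exon portion +
50 nt margin; TSS at offset 1,538):

- **PALI1**, the first entrance palindrome, at TSS−518..TSS−500: the pinned
  18-mer `TCAGAAAGTGATTGCTGA`.  Its first 12 nt are the duplicated
  target-site 12-mer; position 14 is a G paired in the wild-type structure;
  the "cow" allele (G14→A, carried by cow and zebu) breaks exactly that
  pair.  Under the detector's symmetric folding the wild type spans 18 nt
  with one intrinsic A·G contact; under the template's recorded (bulged)
  pairing map the wild type pairs perfectly.  The 18 nt of the published
  palindrome exist only as a figure image, so the sequence is built from
  the stated constraints; the pairing map is recorded explicitly in the
  template rather than guessed from the image.
- **PALI2**, 39 bp downstream: a pinned 20-mer whose central 14 nt form the
  base palindrome in all species; the "eland" allele (A16→C plus loss of
  the last 4 nt) creates one extra terminal pair, extending the span to 16.
- **Insertions.**  Seven antelope-lineage species carry one
  reverse-orientation element immediately downstream of PALI1, followed by
  the duplicated, 5′-truncated PALI1 copy (`AGTGATTGCTGA`, 12 nt — the
  last 12 nt of PALI1, so the duplication the TSD search recovers is
  exact).  The eland carries the 16 nt extended PALI2 followed by
  element + truncated PALI2 copy + element + truncated PALI2 copy, i.e.
  two sequential forward insertions whose internal truncated copy is the
  evidence separating two tandem elements from one fused double-length
  element.  The four wild-type PALI2 nucleotides displaced by the eland
  allele are retained downstream of the insertion rather than erased: the
  source text itself leaves open whether those 4 nt were lost before or
  during insertion, and this choice keeps the eland-vs-reference alignment
  a pure one-substitution + one-insertion event with exactly recoverable
  truth.  The tandem tract length that results (566 nt) is an emergent
  value recorded in truth; the generator does not target a particular
  printed total, whose composition is not derivable from the text.
- **Relic.**  The addax element carries a 12 nt poly-A run followed by the
  first 8 nt of PALI1 between terminator triplets 3 and 4 (the poly-A bound
  is strict: > 10 nt).
- **Lineage-specific element variants** (transition substitutions at fixed
  consensus positions): four shared by all antelope-lineage elements; two
  more shared by goat and ibex (identical sets); two shared by sheep and
  wildebeest; gazelle carries the goat monomer-1 variant plus three private
  monomer-2 variants; the eland's private variants sit in its second
  (downstream) copy.
- **Motif words** for the element-unique-motif analysis: a STAT-like word
  in the linker, an NFκB-like word in monomer 2, an Sp1-like word planted
  once in the shared promoter background.

Background sequence is uniform random DNA, rejection-validated so that the
planted palindromes are the locally maximal ones at their loci at exactly
the designed spans, the planted motif words occur nowhere else on either
strand, the duplicated target copy is the unique longest repeat shared by
the insertion flanks, and no sequence context lets a called insertion
slide past its 3′-normalized anchor.  Validation failures redraw only the
random context (never the pinned templates); the generator raises rather
than silently relaxing a constraint.  Same seed + config ⇒ byte-identical
panel.

What the generator does **not** emulate: real LINE-derived flanking
sequence (the background is i.i.d. uniform), indel mutation processes
(background noise is substitution-only at a configurable rate, default 0),
sequencing error, CpG-island base composition, and the literal nucleotide
content of the published figure panels.  Passing tests therefore
demonstrate correct recovery of planted structure under clean and mildly
noisy conditions — not performance on diverged real promoters, where
alignment quality and TSD decay would dominate.

## Insertion calling

Global affine-gap alignment (Gotoh), match +2, mismatch −3, gap open −6,
gap extend −1 (a gap of length L costs −6 − L).  The open penalty is −6
rather than a more conventional −5 because with −5 the match−mismatch
difference exactly equals the opening cost, which makes "one mismatch
column" and "a match mined out of the insertion plus an extra gap" exactly
co-optimal and floods the traceback with ties at every insertion boundary.

A target-site duplication makes an insertion's placement ambiguous by
exactly the duplicated-copy length.  Ties are resolved by **3′-normalizing
gaps** (rightmost placement, kept contiguous): the call then lands at the
biological entrance site downstream of the retained target copy, and the
inter-locus distance reported by locus clustering equals the distance
between entrance sites.  Calls are query-only gap runs ≥ 50 nt (the
objects of interest are 272/566 nt; 50 excludes background indel noise),
clustered into loci by single-linkage at ±5 nt.

The aligner is numba-compiled; promoter-scale pairs (~1.6 kb × ~1.9 kb)
align in tens of milliseconds, so the whole panel aligns in ~1 s.

## Element decomposition

Orientation is the argmax of the local-alignment score of the insert
against the consensus and its reverse complement; both scores below 40% of
the maximum attainable is reported as "not a recognizable element"
(an outcome, not an error).  Components are located by mapping consensus
component boundaries through a global alignment of the oriented insert;
the terminator repeat count is the maximal run of exact `AGC` units from
the terminator's aligned start, so a relic interrupts the count (addax:
3).  Copy number is counted by iterated best local alignment with masking
of previous hits (floor: 40% of a perfect single-copy score); masking uses
`N`, which never matches.  Monomer identity is a majority vote over
diagnostic sites; ties are reported as "ambiguous", never resolved
arbitrarily.  Variant calls are reported on consensus coordinates on the
consensus strand regardless of insertion orientation; query-only runs
touching the insert boundaries are flanking target-site remnants, not
variants.

## Palindromes and hairpin energetics

A near-palindrome is scored over its **full genomic span** (loop included):
"span 18" means the structure occupies 18 nt.  This convention is a
documented choice — the source text never states whether its printed
lengths count the loop — and is used everywhere lengths are reported.
Detection enumerates loop placements (0–4 nt) and extends arms outward
under a mismatch budget (default 1); arms may not begin or end on a
mismatch; a candidate is dropped when a strictly longer candidate overlaps
it, and equal-length co-maximal spans are all reported (this selection
rule, unlike a leftmost tie-break, is symmetric under reverse complement —
an invariant the tests check).  The mismatch tolerance of 1 is what lets
the cow allele still be detected as a (disrupted) palindrome so its broken
position can be reported.

Hairpin free energy is a deliberately simple nearest-neighbor sum at
37 °C: Watson–Crick stack terms (unified DNA parameter set, shipped as
package data with provenance notes) + hairpin-loop initiation (tabulated
for 3–30 nt, monotone extrapolation at +0.1 kcal/mol/nt beyond, loops
shorter than 3 nt charged as a strained 3-loop) + 1.0 kcal/mol per internal
mismatch (1×1 internal loop) + 3.5 kcal/mol per bulge run.  A pairing with
no Watson–Crick pair is "no stable hairpin" (ΔG = +∞).  Exact agreement
with full secondary-structure prediction is a non-goal; the quantities the
analysis relies on are orderings (mutant vs wild type), which are robust to
the simplifications.  Allele comparison evaluates each allele under its
recorded structural hypothesis (the wild-type map, or an allele-specific
map when the mutation creates a new pair) and classifies the change as
stabilizing/destabilizing/neutral beyond a 0.1 kcal/mol tolerance.

When a pairing profile is computed against a template, a broken pair is
localized to the member whose base deviates from the template wild type —
this is how the cow allele's mismatch is reported at position 14 rather
than at its partner.

## TSDs and relics

The TSD search takes 30 nt windows adjacent to the element boundaries (the
5′ window ends at the call start; the 3′ window starts at the element end,
so the duplicated copy retained inside the 3′-normalized call is visible
to the search) and finds the longest shared substring with at most one
internal mismatch — the match may not begin or end on a mismatch, and `N`
never matches.  Truncation sidedness comes from aligning the observed copy
to the full template: flags record whether the alignment reaches the
template's first/last position; copies retaining < 50% are declared
unrecognizable rather than classified.  Relic detection requires a poly-A
run > 10 nt followed within ≤ 3 nt (the text says "followed by" without a
distance; the 3 nt bound is documented in output) by a ≥ 6 nt prefix or
suffix of an entrance-palindrome template, positioned between terminator
repeats.

## Characters and parsimony

Four binary characters per species: element presence at each locus (from
insertion calls), first-palindrome intactness (zero mismatches in the
template pairing profile), second-palindrome extension (detected span
≥ 16).  Unassayed species get `?` and are excluded per character.  Fitch
parsimony runs on a user newick tree (a schematic tribe-level 14-species
tree ships as package data); ancestral ties prefer absence, since
insertions are gains — a reporting convention, not biological truth.
A presence/absence character needing more than one change is flagged
homoplastic, the package's operationalization of "a single insertion event
is an unreliable marker when entrance-site mutations can mimic or erase
it".  The consistency report flags intact-palindrome/absent-element
species (insertion-capable but empty — the buffalo pattern) and
disrupted-palindrome/present-element conflicts.

## Motif classification

PWMs are log-odds in bits from JASPAR counts (pseudocount 0.5, uniform
background); the hit threshold defaults to 80% of each motif's maximum
attainable score (the proprietary matrices and scoring of the original
analysis are not reproducible, so the threshold is a documented,
configurable choice).  Scanning covers both strands; windows containing
`N` are skipped.  The analyzed region runs from a user-declared CpG-island
start (CpG detection itself is out of scope) through TSS+50.  A motif is
element-unique iff ≥ 1 hit lies entirely inside an element interval and
none lie elsewhere in the region; the classification
(element-unique/shared/background-only/absent) is a partition, and counts
are reported so enrichment (e.g. 2:1 inside:outside) is visible even for
"shared" motifs.

## Numerical and testing choices

Problem sizes were chosen so the full test suite and the acceptance script
each run in a few minutes on one core: promoters ~1.6 kb, oracle suites of
500 (palindrome detection), 200 (parsimony), and tens of cases for
alignment and PWM scanning, and 20 replicates for the variant-sensitivity
check at 2% substitution density.  All randomness flows from explicit
integer seeds through `numpy` generators; every oracle in the test suite
(exhaustive enumeration, textbook dynamic programming) is implemented
independently of the code it checks.

## Known limitations

- The alignment model is global with affine gaps; highly diverged or
  rearranged promoters are out of scope (no local chaining, no inversions).
- Hairpin energetics ignore dangling ends, terminal-mismatch stabilization,
  coaxial stacking and the loop-sequence dependence of loop penalties.
- Fitch parsimony treats polytomies by left-to-right folding, which is
  exact for binary trees (the property the oracle suite checks) and a
  standard approximation on polytomies.
- The TSD search is bounded to 30 nt windows by design; distant or heavily
  decayed duplications are not found.
- Real diagnostic sites and real motif matrices must be supplied by the
  user; the synthetic defaults exist to make the pipeline testable
  end-to-end.
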
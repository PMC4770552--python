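# Methods

This note documents the models, parameter choices and numerical decisions
behind `nirktools`, and what the synthetic-data tests do and do not show
about real data.

## Reference-anchored coordinates instead of a progressive MSA

Every per-sequence feature — conserved residues, active-site motifs,
clade-diagnostic indels, terminal extensions — is defined in the residue
numbering of a full-length 375-aa reference NirK (numbering origin 1).
Each candidate is pairwise-aligned to the reference and the alignment is
reduced to a map classifying every candidate residue as (a) matched to a
reference position, (b) inserted between reference positions, or (c) part
of an N- or C-terminal overhang. A multiple alignment for phylogeny is
produced by stacking these reference-anchored rows (a star alignment),
padding insertion columns. This removes the dependence on an external
progressive aligner while preserving reference-coordinate semantics; the
cost is that insertions relative to the reference are aligned only
against the reference, not against each other — acceptable here because
distances are computed under complete deletion, which discards those
columns anyway.

The true reference protein is not bundled; the package ships a
deterministic 375-aa **surrogate** (generated from a fixed seed with the
conserved residues and Clade I motif pinned at their canonical positions)
and accepts a user-supplied real reference FASTA via config. Everything
downstream is expressed in reference coordinates, so swapping in a real
reference changes no code paths.

### Alignment scoring

Affine-gap Needleman–Wunsch with BLOSUM62, gap open 11, gap extend 1
(total penalty `open + extend × (L−1)`), all config-overridable. The DP is
exact and deterministic: backtrace ties resolve match/mismatch first, then
gap-in-reference, then gap-in-target. The forward pass is vectorised per
row; the within-row gap recursion is computed as a running maximum, which
is algebraically identical to the elementwise recurrence. Scores are
validated against exhaustive enumeration of all alignments for sequences
up to 8 aa.

## Residue rules, motifs, indels, extensions

* **Rules.** Seven copper-ligand positions (His59, His64, His99, Cys100,
  His110, Met115, His298) and two active-site positions (Asp62, His237).
  A sequence is accepted as NirK only if all nine pass; a deleted position
  or an `X` placeholder counts as a failure. The T1Cu/T2Cu partition of
  the ligands is metadata only; validation treats all seven equally.
* **Motifs.** His237 motif window [−3, +1] (the printed motif types TRPHL
  and SSFHV place the His fourth of five); Asp62 window [−2, +2], a
  symmetric default. Windows touching deleted positions yield a flagged,
  undefined motif rather than a shortened string. Motifs are reported but
  deliberately not used for clade typing — motif variability within clades
  makes them weak discriminators; the indels are the robust signal.
* **Indels.** The linker (190–196) and tower (258–264) deletion regions
  and the Bacillus extra-loop insertion point (after position 300, 6 aa)
  are configuration values in surrogate coordinates, shared between the
  feature caller and the generator — they are pipeline parameters, not
  facts about the reference protein, since the loops are only defined
  structurally. A deletion region is called present when a majority of its
  interval (≥ ceil(L/2)+1 positions) is deleted; exact-length matching is
  brittle when point indels shift alignment edges by a residue. Insertions
  use the same threshold on the inserted-residue count between the
  region's flanks.
* **Clade call.** Both deletions → Clade II; neither → Clade I; exactly
  one → `unclassified`. There is no principled tie-break for a
  single-deletion sequence short of a full phylogenetic placement, so the
  package refuses to guess.
* **Extensions.** The c-type heme pattern C-X2-C-H-X50-M is searched only
  in the C-terminal overhang, the cupredoxin pattern C-X4-H-X4-M only in
  the N-terminal overhang; spacers are matched exactly by default
  (`spacer_tolerance 0`, configurable) because the patterns are defined
  with exact counts. Restricting the scan to overhangs guarantees the
  patterns can never fire inside the mapped catalytic core.

## Phylogeny

Distances: amino-acid "number of differences" (count of differing
columns) or p-distance, under complete deletion (every column with ≥ 1
gap removed before any counting, so all pairs share one column set) or
pairwise deletion. Neighbour joining is the standard Q-criterion
agglomeration with a lowest-index tie-break, making output deterministic;
on additive matrices it recovers the generating topology and branch
lengths exactly (property-tested to 1e-9). Negative branch estimates are
clamped to zero with the deficit transferred to the sibling edge, the
usual display convention. Bootstrap resamples original alignment columns
with replacement and re-applies the deletion policy per replicate (the
alternative — resampling the post-deletion columns — would never let a
replicate explore columns that deletion removed); replicates that lose
every gap-free column are skipped and support is computed over completed
replicates. Support of an edge is the percentage of replicate trees
containing its bipartition. Default 1000 replicates; the analysis drivers
use 200 to keep runs interactive.

Note an interaction worth knowing: complete deletion removes exactly the
columns where Clade II carries its diagnostic deletions, so the
clade-separating signal in the distance matrix comes from substitution
differences (e.g. the motif columns), not from the indels themselves.
With substitution noise at 8 % the clade split is recovered but with
moderate bootstrap support; with no noise it is near-100 %.

## Primer analysis

A primer position mismatches a template position iff their IUPAC base
sets are disjoint (so R matches A, S does not). The best binding site is
the leftmost minimal-mismatch offset; reverse primers are scanned against
the reverse complement so mismatch vectors always read primer 5′→3′. The
3′ window is 3 positions by default (configurable). Mismatch profiles
report, per clade and primer position, the fraction of sequences
mismatching at their best site; the combined panel is the count-weighted
mean of the clade panels (an exact identity, tested). Sequence logos
report per-column base frequencies and information content
`log2(4) − H` in bits, without small-sample correction — at the cohort
sizes involved the correction is negligible and it would break the
closed-form column checks. In-silico PCR reports every forward/reverse
site pair within the mismatch budget with the reverse site strictly
downstream, with an option to reject sites carrying any 3′-window
mismatch. Primer sequences are always configuration inputs; the bundled
example primer is a synthetic stand-in.

Both evaluation modes — per-sequence best site and anchored
(alignment-fixed) site — are available; the mismatch profiles reported by
the pipeline use the best-site mode, which is the conservative choice for
coverage claims (a primer is only called mismatching if no better site
exists anywhere on the gene).

## Pathway inventories and co-occurrence

A genome enters the cohort only with a nitrite reductase (nirK copies ≥ 1
or nirS) — the *sensu stricto* criterion. Denitrification category follows
from (nor, nosZ): both → complete; nosZ only → −nor; nor only → −nos;
neither → −nor/−nos. DNRA labels pair each of nrfA/nirB with every
nitrate reductase present (napA → nap_*, narG → nar_*, neither → *_only)
and are **non-exclusive**: a genome with nrfA and nirB contributes to both
branches. This is the only reading under which per-label percentages can
sum above the combined denitrification+DNRA percentage, as published
summary tables do. nirV is carried and summarised but plays no part in
classification. Percentages are reported to one decimal, rounding half
away from zero, and the Total row is always computed from raw calls,
never from rounded per-phylum values.

Co-occurrence of two presence/absence vectors uses the exact
hypergeometric (probabilistic co-occurrence) model: with marginals N1, N2
of N, `P(j) = C(N1,j)·C(N−N1,N2−j)/C(N,N2)`; `p_lt` and `p_gt` are the
inclusive lower and upper tails (they overlap at the observed count, so
their sum is ≥ 1). The phi coefficient is the Pearson correlation of the
binary vectors, flagged undefined for constant vectors. The all-pairs
screen combines the two tails into a two-sided p (2·min, capped at 1) and
applies Benjamini–Hochberg across pairs. The one-sided exact test is
slightly conservative on a discrete lattice; at N = 250 with balanced
margins its null rejection rate at α = 0.05 measures ≈ 0.04–0.065.

## Synthetic-data generator

The generator is a pure function of (config, seed) and emulates the
structural and statistical features the analysis assumes:

* sequence counts default to 10 per clade; substitution noise is i.i.d.
  uniform over the 19 alternative residues, applied outside protected
  positions (the nine rule positions, both motif windows, indel flanks);
* Clade II sequences carry the SSFHV motif (one member of the SSFHV/I/P
  family; others via config) and both 7-aa deletions; a configurable
  number additionally carry the 6-aa Bacillus-type insertion;
* terminal extensions are appended with the exact heme/cupredoxin spacing
  (fractions 0.15 + 0.15 by default, emulating a cohort where ~30 % of
  sequences carry an extension, and never both on one sequence);
* 5 % of genomes carry a second gene copy;
* back-translation draws uniform synonymous codons (translation is an
  exact inverse); primer sites are embedded at random offsets with
  per-clade per-position mismatch probabilities;
* genome inventories sample genes per phylum from marginal frequencies
  (defaults loosely matching the published cohort's prevalences: nor 0.71,
  nosZ 0.40, napA 0.45, narG 0.27, nrfA 0.20, nirB 0.60, nirS 0.05,
  nirV 0.61, over the fifteen published phylum sizes summing to 249
  genomes), with specified gene pairs drawn from the exact 2×2 joint
  distribution matching their odds ratio. Association pairs must form a
  forest, so the joint factorises along trees and sampling stays exact;
  the default plants the narG–nrfA avoidance at odds ratio 0.2, which at
  those margins corresponds to phi ≈ −0.21.

What passing the synthetic tests shows: the callers invert the
generator's planted structure exactly at zero noise and robustly at 10 %
substitution noise, and the statistics recover planted effect sizes at
their Monte-Carlo tolerances. What it does not show: performance under
real evolutionary heterogeneity — the generator has no site-rate
variation, no tree-structured substitution process, no codon-usage bias,
and its sequences share a single backbone, so real-data divergence
(within-clade identity down to ~16 %) is far harsher than anything tested
here. Published dataset-level statistics that depend on the real
sequence cohort are therefore not reproduced by this package, by design.

## Problem sizes

Default test and driver sizes were chosen to keep every run interactive:
20–60 sequences per set, 100–200 bootstrap replicates in drivers and
tests (1000 remains the pipeline default), 200 Monte-Carlo seeds for
calibration and planted-effect checks, and exhaustive hypergeometric
verification up to N = 60.

## Known limitations

* Star alignment degrades when a candidate is mostly unalignable to the
  reference; such sequences should be inspected via their alignment score.
* Clade typing of sequences with exactly one diagnostic deletion is
  refused rather than resolved phylogenetically.
* The cohort reconstructor inverts printed percentage tables only for the
  category and combined columns; full non-exclusive DNRA label spectra
  are not identifiable from rounded, overlapping columns.
* Maximum-likelihood phylogeny, signal-peptide prediction, homology
  searches to build inventories, and de-novo primer design are out of
  scope.
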
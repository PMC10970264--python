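# Methods

## Problem setting

Maize chloroplast genomes (plastomes) are circular, quadripartite
(LSC–IRa–SSC–IRb, with IRb the exact reverse complement of IRa),
effectively haploid, and maternally inherited. Within the species they
are highly conserved — on the order of a hundred variant loci across a
~140 kb genome — but the variants that do exist partition cultivars
into a small number of chloroplast groups, each associated with
characteristic cytoplasms (including the C-, S- and T-type male-sterile
cytoplasms). A small panel of group-diagnostic markers therefore
supports tasks nuclear markers handle poorly: tracing the maternal
parent of a hybrid, telling reciprocal crosses apart, and recognising
CMS cytoplasm types.

`plastotype` implements the full desk-side pipeline: variant discovery
from an aligned plastome panel, marker filtering, group-specificity
assignment by one-vs-rest F_st, discriminating-panel selection, KASP
(Kompetitive Allele Specific PCR) primer construction, and maternal
lineage validation. Alignment construction, genome assembly and
annotation are upstream of the package: it consumes an aligned
multi-FASTA, a sample sheet, and a gene map.

## Variant discovery

Because the input is a gap-aware multiple alignment of haploid
sequences, exhaustive pairwise comparison reduces to a column scan.

* **SNPs** — one locus per gap-free column with at least two distinct
  unambiguous bases. `N` is missing data: it never creates an allele,
  and a column polymorphic only because of `N` is not a locus.
* **InDels** — maximal runs of adjacent gap-containing columns whose
  per-sample gap pattern is identical are merged into a single event;
  adjacent runs with different carrier sets split into separate loci.
  Alleles are the gap-stripped subsequences (the deletion allele is the
  empty string). Merging by pattern identity, not mere adjacency, is
  what keeps one multi-column biological event from surfacing as two
  markers.

Annotation maps alignment columns into the ungapped coordinate frame of
a designated reference sample (the first, by default; the choice is
configurable because alignments carry no privileged reference). A locus
is genic iff its reference-frame interval intersects a gene interval;
intergenic loci record the bracketing gene pair. Variant density is
reported as mean ungapped genome length divided by locus count.

Flanks of width 60 bp (the KASP design window; configurable) are read
from the columns adjacent to each locus. A locus is design-eligible
only if both flanks are full-width, identical in every sample, and free
of gaps and Ns.

## Group specificity: one-vs-rest Weir–Cockerham F_st

For each locus and each chloroplast group, the package computes the
Weir & Cockerham (1984) ratio-of-averages F_st estimator between the
focal group and all remaining samples pooled. Chloroplast calls are
haploid and homozygous, so each call is encoded as one homozygous
diploid individual: every heterozygosity term (h̄, and the c component)
vanishes, which reproduces the semantics of running `vcftools
--weir-fst-pop` on homozygous diploid genotype tables. Multi-allelic
loci are collapsed to the focal-group-enriched allele versus all others
before estimation. Properties relied on by the pipeline, and enforced
by tests against an independently coded direct-formula oracle:

* a fixed difference scores exactly 1.0 for any sample sizes;
* equal frequencies score ≤ 0 (negative estimates are reported as
  computed, never clamped);
* agreement with the direct formula to better than 1e-10 across 1,000
  random two-population configurations.

A locus is assigned to a group iff **exactly one** group's F_st exceeds
the threshold (default 0.9). Multi-hit loci get no assignment — with
only two groups the two one-vs-rest contrasts coincide, so every fixed
difference double-hits and is deliberately left unassigned rather than
attributed arbitrarily.

Loci whose minor allele frequency is below 1 % (strict `<`, haploid
counts over non-missing calls; MAF is the frequency of the second most
common allele) are eliminated before specificity assignment. Note the
rule only bites on panels of more than 100 samples: a singleton among
20 samples has MAF 5 % and correctly survives.

## Panel selection

A panel is valid iff its per-group signature rows (the majority allele
of each group at each panel locus) are pairwise distinct; validity is
asserted on construction. Two policies:

* **one-per-group** — per group, the assigned locus with the highest
  F_st (ties broken by lexicographic locus id). Size equals the number
  of groups.
* **minimal** — exhaustive search over all group-assigned loci by
  increasing subset size for the smallest valid panel. The search is
  tractable because group counts are ≤ 8 and a valid panel of size
  (groups − 1) always exists whenever every group is covered (the
  uncovered-residual row is distinct by construction), which caps the
  enumeration depth.

With five groups and one indicator locus per group, minimal selection
returns four loci: dropping any one indicator leaves the residual
group's all-reference row unique. When external knowledge restricts the
candidate cytoplasms (e.g. a sample known sterile can only carry the
C-, H- or T-group plastome), `constrained_panel` discriminates only the
candidate subset, reducing panel size further (three groups:
one-per-group 3, minimal 2).

## KASP design and audit

A KASP assay is two allele-specific primers (FAM/HEX channels) plus a
common reverse primer; discrimination rides on the 3'-terminal base.
Allele primers are suffixes of (left flank + allele) ending exactly at
the first base that differs between the two alleles (for a SNP, the
variant base itself); the common primer is the reverse complement of a
window at the start of the right flank. Primer length is the shortest
in 18–35 nt whose nearest-neighbor Tm (SantaLucia unified parameters,
50 mM Na+, 200 nM primer, via Biopython's MeltingTemp; Wallace 2+4 rule
available as an alternative) reaches the 58 °C annealing target.
Designs are attempted on both strands; the complement-strand design is
used when the given strand cannot reach the target or when its
|Tm(FAM) − Tm(HEX)| balance is strictly better. Insertions longer than
50 bp switch to a two-flank layout (no common primer; the second flank
window anchors inside the insertion), mirroring how very large InDel
assays are printed in published marker tables, and are flagged.
Universal FAM/HEX tails are not prepended (published tables print
tail-less primers); `with_tails` adds them for export.

The auditor classifies every SNP row of a marker table as forward
(3' bases equal the alleles), reverse (equal to the complemented
alleles) or inconsistent, and — where flank sequences are printed —
checks that each primer occurs within the reconstructed local sequence
on either strand. Rows lacking flank data are "not-checkable" rather
than failed, since absence of evidence is not a contradiction. The
audit reports; it never corrects.

## Maternal lineage

Hybrids inherit the maternal plastome unchanged, so the trio verdict is
strict: `maternal=mother` requires the hybrid to match the mother at
every compared (non-missing) panel locus *and* to differ from the
father at one or more. Parents with identical panel signatures yield
`ambiguous` — the information-theoretic limit, never a guess. A
mismatch budget for noisy real data exists but defaults to 0.
Cytoplasm classification matches a sample's panel vector against the
group signature rows; because one group contains both a sterile
cytoplasm and fertile cultivars, calls carry candidate cytoplasm labels
rather than a fertility verdict unless fertility is supplied.

## Synthetic panels

The generator emulates the statistical structure the analysis assumes,
at desk scale by default (20 kb genomes, region lengths in the printed
real-genome proportions, 5 groups × 4 samples; full scale — 140.6 kb,
176 samples — is config-reachable and generates in under a second):

* group-diagnostic SNPs fixed within their group and fixed for the
  other allele everywhere else;
* shared SNPs carried by half the members of two groups (so no
  one-vs-rest contrast approaches the 0.9 threshold);
* singleton rare alleles (never planted on trio parents, so they stay
  singletons after hybrids are added);
* InDels planted as alignment gap blocks of 1–85 bp, spanning the
  published range from 5 bp events to an 83 bp insertion. The pipeline
  consumes alignments, so simulating post-alignment state is faithful
  and avoids bundling an aligner. The first sample never carries a gap
  block: it defines the ungapped reference frame shared with the gene
  map;
* locus intervals separated by more than twice the flank width, so
  every planted flank is invariant by construction;
* trios, reciprocal pairs and CMS-line crosses whose hybrids are
  byte-identical copies of their mothers' sequences.

The background mutation model is *none* (an optional `noise_rate`
exists, default 0), so truth recovery is exact: the test suite asserts,
across ≥ 20 seeds, that called loci equal planted loci in position,
kind, span and genotype vector. Default desk-scale locus counts
(25 diagnostic + 10 shared + 5 rare SNPs + 3 InDels) scale the
full-size inventory to what a 20 kb genome can hold at the required
separation. All randomness flows from one seed through
`numpy.random.SeedSequence.spawn`, one child stream per component, so
adding a component never perturbs earlier draws.

What passing these tests does **not** show about real data: alignment
error, sequencing error and N-runs (absent at noise 0), IR-boundary
shifts between samples, heteroplasmy, and nuclear-plastid transfer
artifacts are all outside the generator's model. The strict concordance
rules are calibrated for clean consensus sequences; real panels may
need the documented mismatch budget.

## Quadripartite detection

The IR pair is found as the longest exact reverse-complement repeat of
at least `min_ir` bases (default 1,000 full scale / 500 desk scale):
31-mers of the sequence are anchored against its reverse complement and
extended to maximal exact matches, with anti-diagonal bookkeeping to
visit each match once; circularity is handled by doubling the sequence.
The longer single-copy segment between the repeats is the LSC, the
shorter the SSC; genes spanning a region boundary count toward the
region containing their start (arbitrary but fixed). Tests enforce
equivalence with a quadratic brute-force oracle on small genomes,
including the behaviour that an internal mismatch shrinks the detected
repeat to the longest exact piece.

## Numerical and degenerate-input choices

* Internal coordinates are 0-based half-open; 1-based appears only in
  VCF/report output. InDels are left-anchored on one reference base per
  VCF convention; an InDel at a position where the reference sample has
  no anchor base is an explicit encoding error.
* Sentinels in marker tables ("/" for no specific type, "-" for the
  deletion allele) are resolved to None / empty string at parse time
  and never propagate inward.
* F_st at a monomorphic locus and density with zero loci raise explicit
  errors rather than returning sentinels; populations of fewer than two
  samples are insufficient data.
* Primer tie-breaks: shortest length meeting Tm, then the given strand
  over the complement unless the complement is strictly better
  balanced.
* A marker-table row with an empty common primer is accepted (and
  flagged) only when flank records are present — the published
  two-flank large-InDel layout; otherwise it is a format error.

## Known limitations

* The minimal-panel search considers group-assigned loci only; a
  cheaper panel mixing unassigned-but-polymorphic loci would not be
  found.
* WC84 is computed for the biallelic collapse; a true multi-allelic
  estimator is out of scope.
* No primer specificity screen against the full genome (no BLAST) and
  no hairpin/dimer thermodynamics; the audit checks internal
  consistency, not amplification success.
* No sub-classification within the H group (its sterile and fertile
  constituents are not separable by the modelled markers).
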
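# Methods

## Biological setting

Alpha- and gamma-gliadins are Q/P-rich seed storage prolamins encoded by
multigene families (*Gli-2*, *Gli-1*) on the group-6 and group-1 chromosomes
of polyploid wheat. Their first repetitive domains concentrate the
celiac-disease-relevant sequences: overlapping HLA-DQ2.5 T-cell 9-mer
epitopes (scanned here in the non-deamidated, glutamine form), the
protease-resistant 33-mer and 26-mer multi-epitope peptides, and the
innate-response peptide p31-43. Bread wheat lines carrying the 1BL/1RS rye
translocation lose the 1BS gamma-gliadin locus and gain rye 40k-γ-secalins,
which co-amplify with the gamma primers. Prolamin genes also pseudogenize at
a high rate through C→T transitions that convert glutamine codons (CAA/CAG)
into stops (TAA/TAG); amplicons whose in-frame translation carries a stop are
counted as pseudogenes and excluded from epitope/type abundance by default.

## Pipeline model and assumptions

* **Merging.** Best ungapped overlap of read 1 and reverse-complemented
  read 2 (min overlap 16, max 5 mismatches); fewest mismatches wins, longest
  overlap on ties. Posterior qualities: `min(Q1+Q2, 41)` at agreements;
  higher-quality base with `|Q1−Q2|` at disagreements. Candidate overlap
  placements come from exact 16-mer seeds with an exhaustive fallback, which
  is a pure optimization: results equal the exhaustive scan.
* **Expected-error filter.** Keep a merged read iff `Σ 10^(−Qi/10) ≤ 1.0`.
  The comparison carries a 1e-9 float slack so that the boundary case (e.g.
  100 bases at Q20, E = 1.0 exactly) is kept regardless of summation order.
* **Denoising.** Greedy centroid clustering in decreasing-abundance order
  (sizes from exact dereplication, ties lexicographic). A unique u is
  absorbed by centroid c at Levenshtein distance d (computed with edlib,
  capped at d ≤ 10; beyond the cap nothing is absorbable) when
  `size(u)/size(c) ≤ β(d) = 1/2^(αd+1)`; among qualifying centroids the
  nearest d wins, then the largest c. Unabsorbed uniques found a centroid if
  size ≥ minsize, else they are discarded. α = 2.0 and minsize = 8 are the
  published defaults of the zero-radius OTU method; the amplicon tool chain
  this mirrors names the method but not its parameters, so both are exposed
  in `DenoiseParams`. Denoising is per sample; pooling happens explicitly in
  the database builder.
* **Database.** Exact-duplicate collapse only: the denoiser already absorbs
  error variants, so near-duplicates that survive it are treated as real
  distinct amplicons. Ids are sha1-derived from the sequence, making output
  independent of sample order. References (annotated with subgenome/secalin
  tags) that duplicate a denoised amplicon annotate it; novel references are
  appended with zero abundance.
* **Reading frame.** The amplicons are primer-anchored mid-gene, so the frame
  is a panel property: the offset minimizing total in-frame stops across the
  panel (pseudogenes are a minority and keep their stops in the chosen
  frame); ties go to the smallest offset, and the inference can be overridden
  in `PipelineParams.frame`.
* **Mapping and identity.** Reads (equivalently their dereplicated uniques)
  are assigned to the best database amplicon with global-alignment identity
  ≥ 0.99, identity = matches / alignment columns (gap columns included).
  Exact hits short-circuit; otherwise identity comes from the minimum-edit
  alignment (edlib cigar). Ties go to the larger aggregate size, then the
  lexicographically smaller id. Reference-proximity annotation uses
  Needleman–Wunsch with match +1 / mismatch −1 / gap −2 and penalized end
  gaps, replacing tree-based subgenome assignment with a directly testable
  criterion of the same intent ("nearest reference"); equidistant references
  are flagged ambiguous rather than resolved.
* **Prevalence filter.** Default semantics: retain an amplicon iff it reaches
  ≥ 0.25% in ≥ 4 samples — the standard low-abundance noise filter. The
  literal alternative ("discard if < 0.25% in ≥ 4 samples") is available as
  `mode="discard_literal"` but with many samples it discards nearly
  everything real. Retained columns are re-normalized to 100 (flagged in the
  output metadata); filtering precedes replicate averaging, and means of
  replicate percentages are reported without further re-normalization.
* **Epitope scanning.** Every window is compared against the catalog at
  Hamming distance ≤ 0 or 1; overlapping occurrences all count. A window that
  exactly matches some epitope is not additionally reported as a one-mismatch
  variant of another epitope of the same length at the same window
  (exact-first suppression — the registries contain near-identical 9-mers, so
  without this rule every exact hit would also appear as a variant of its
  neighbors). One-mismatch scanning is enabled for the alpha panel by default
  and configurable. Types count exact DQ2.5 occurrences per occurrence (so
  the 33-mer contributes six), and p31-43 and the 33-mer/26-mer region
  peptides never contribute to types.
* **Abundance semantics.** Presence-based by default (an amplicon's full
  abundance counts once per epitope it contains, regardless of copy number),
  with a copy-weighted sensitivity mode behind a flag. Variant log2 fold
  changes use a pseudocount ε = 1e-6 percent — far below any reportable
  abundance — so the degenerate 0/0 case returns 0.

## Epitope catalog

The packaged catalog (`gliascan/data/epitope_catalog.tsv`) holds
non-deamidated peptides: 4 alpha-DQ2.5 epitopes, 9 gamma-DQ2.5, the two
shared-sequence secalin entries (sec1 = ω1/hor1, sec2 = hor2, stored once
with multi-source annotation), p31-43, and the 33-mer/26-mer regions. The
33-mer fixture carries six overlapping copies of three alpha epitopes
(a1a ×1, a1b ×2, a2 ×3), and the 26-mer carries γ3/γ4c/γ5 sites, matching
the canonical descriptions. Sub-variant splits (γ2a/γ2b, γ4d) and the
immunogenicity-score column are illustrative; both the catalog and the
score table are plain TSVs meant to be replaced by a project's own registry
compilation (`EpitopeCatalog.from_tsv`). Tests assert scan counts on
fixtures, not registry correctness. The subgenome motif table is likewise a
small illustrative default, consistent with the synthetic generator but not
authoritative for real wheat data.

## AHP ranking

Hierarchy: one first-level criterion with two second-level branches —
epitope abundances and type abundances. Leaf priorities come from pairwise
genotype comparison matrices: `m[i,j] = f(log2(a_i/a_j))` with
`f(x) = clamp(round(|x|)+1, 1, 9)` (reciprocal for negative x; the mapping is
a pluggable choice, as only "transformed into intensity values" is specified
by the method this follows). Priorities are principal right eigenvectors by
power iteration (tol 1e-10, ≤ 1000 iterations); the consistency ratio
CR = ((λmax − n)/(n − 1))/RI(n) is reported, never enforced. Epitope leaf
weights are proportional to the external immunogenicity scores (missing
scores get the panel median); type leaf weights are uniform; both are
overridable vectors. The epitope-vs-type branch weight takes each Saaty
intensity s = 1..9 in favor of epitopes — the 2×2 matrix [[1, s],[1/s, 1]]
gives branch weights (s/(s+1), 1/(s+1)) — producing nine scores per genotype;
the ranking uses their mean, with SE = sample SD / 3.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the package's standing desk-scale study: 12
genotypes (5 bread wheat, 3 bread wheat with the rye translocation, 2 durum,
2 tritordeum — a scaled-down version of a 44-genotype screen), two
replicates each, a 20-amplicon panel in the 201–279 bp alpha range, 25%
pseudogene probability, 15% secalin fraction, Dirichlet(1) genotype
profiles, 50k read pairs of 2×280 bp per sample, and a 1e-3 substitution
error rate (Q35 for correct bases, Q15 at planted errors).

Backbones are built from Q/P-rich 9-mer tiles with interrupting residues;
epitopes are planted as blocks, tandem-overlapped at the epitope's
self-overlap period when copies > 1 (planting three a2 copies reproduces the
33-mer-style repeat, incidentally creating a1b copies — truth is defined as
whatever the scanner finds in the finished sequence, planted or incidental,
so truth always equals the scanner's own semantics). Pseudogenes get a C→T
substitution in a glutamine codon outside planted blocks when possible.
Class masks zero out secalins outside translocation carriers and D-subgenome
amplicons in durum/tritordeum. Panel members are kept at pairwise edit
distance > 10 so distinct amplicons can never absorb each other during
denoising. Replicates re-draw multinomial counts from the same proportions —
no extra biological variance model. The realized multinomial draws are
retained in `SynthTruth.realized_counts`, so tests can distinguish pipeline
error (exactly zero on error-free reads) from the generator's own sampling
noise.

Not emulated: indel sequencing errors, chimeras, quality drift along reads,
length variation between alleles of one amplicon, and real inter-replicate
biological variance. Passing recovery tests therefore demonstrates pipeline
correctness under substitution noise and known truth, not robustness to
every artifact of real sequencing runs.

## Verification strategy and problem sizes

The test suite pairs each operation with an independent oracle: brute-force
window scans for the epitope engine, permutation and enumeration oracles for
the rank tests, dense eigendecomposition for AHP priorities, numpy
correlation/eigenvalue oracles for distances and PCA, and generator truth
for the end-to-end runs. The standing recovery runs use the default
desk-scale conditions: the error-free round trip at 50k read pairs per
sample (pipeline counts must equal the realized multinomial draws exactly;
abundance deviations from expectation must stay within three multinomial
standard errors, σ = 100·√(p(1−p)/n) per cell, with zero-expectation cells
exactly zero), and the denoiser run at a 2e-3 substitution rate and 8k read
pairs per sample (centroid set must equal the planted panel exactly).
`scripts/acceptance.py` re-runs both from a command-line seed; its round
trip disables the prevalence filter because the truth tables are defined on
the unfiltered panel — at some seeds a legitimately rare amplicon crosses
the 0.25% threshold and its removal (plus re-normalization) would register
as mismatch despite exact pipeline behavior.

## Known limitations

* The catalog's sub-variant entries and scores are placeholders pending a
  curated registry file; conclusions about specific real epitopes require
  supplying one.
* Subgenome motif assignment is only as good as the motif table; conflicting
  hits are reported as unknown rather than resolved, mirroring the known
  inhomogeneity of motif-based assignment in this gene family.
* Mapping identity uses the minimum-edit alignment for non-exact hits, which
  can differ marginally from the scoring-matrix alignment used for
  reference proximity; at the 0.99 threshold over ~250 bp amplicons the two
  agree for all substitution-only variants.
* The exact-first suppression rule and per-occurrence type counting are
  documented choices where reasonable alternatives exist (suppress across
  lengths; count unique epitopes once).
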
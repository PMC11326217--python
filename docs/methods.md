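# Methods

## Alleles and homology groups

A pangenome-derived allele (PA) is extracted per annotated gene and
haplotype: exons of one gene are merged whenever consecutive exons are
separated by less than `merge_gap_bp` (default 20,000 bp, reflecting the
range of short-distance regulatory interactions and typical LD blocks),
the merged span receives `flank_bp` (default 5,000 bp) anchor sequence on
each side, and spans shorter than `min_len_bp` (default 15,000 bp) are
padded symmetrically where the contig permits — otherwise flagged
`partial`.  Overlapping intervals on one haplotype merge and pool their
gene labels, which is how proximally duplicated or translocated genes end
up inside a single allele.  Coordinates are 0-based half-open throughout.

PAs are partitioned into homology groups — one genotyping matrix each —
by single-linkage closure over canonical k-mer containment
`|A∩B| / min(|A|,|B|)` at threshold `grouping_similarity` (default 0.2).
Containment rather than Jaccard is used so a truncated duplicate still
joins its source gene's group.  For large cohorts an exact-but-prefiltered
mode restricts containment evaluation to pairs sharing at least one
k-mer of a deterministic 1/4 subsample.

Relative to the reference-locus allele, paralogous PAs with k-mer
similarity ≥ 0.80 are *duplicative*, below that *diverged*; orthologous
PAs are *reference* or *alternative* alleles depending on subgroup
membership.  A second copy of a gene within 20 kb inside one PA marks a
*proximal duplication*; three or more chained proximal copies mark a
*runway duplication*.  Alleles with >5% N bases or (given a repeat mask)
<1 kb non-repetitive sequence are dropped as low-confidence; both cutoffs
are configurable because the underlying notion of "low confidence" is a
data-quality judgement, not a property of the model.

## Matrices

Matrix columns are canonical k-mers (lexicographic min of a window and
its reverse complement; `k` odd, ≤31, packed 2-bit) that occur in at
least one group member and at most `max_background_count` (default 0)
times in the background — all assembly sequence outside the group's
intervals.  Cross-group exclusivity is enforced too: a k-mer claimed by
two groups is ambiguous in a single-pass counter and is dropped from
both.  Entries are multiplicities capped at 255 (overflow logged).
Byte-identical allele sequences are collapsed onto one row with members
tracked, since duplicate rows are algebraically indistinguishable; the
low-level matrix builder retains duplicates and flags them degenerate
instead, for callers that manage rows themselves.  Matrices serialize to
sparse-triplet TSV plus k-mer and row tables; round-trips are
bit-identical.

## Trees, subgroups, major groups

Row distances are weighted Jaccard on multiplicity vectors,
`1 − Σ min/Σ max`: bounded, multiplicity-aware, alignment-free.  Trees
are neighbor-joining (scikit-bio) with midpoint rooting; negative NJ
branch lengths are clamped to zero and ties resolve by row order.
Subgroups are the maximal clades whose intra-clade distance does not
exceed `subgroup_max_intra` (default 0.05); the threshold is a
first-class knob because the right granularity depends on cohort size.
Major groups are single-linkage unions of subgroups with no indel larger
than `sv_size_bp` (default 300 bp) between representatives; missing gap
information splits conservatively, and transitive chains merging through
intermediate alleles are an accepted property of single linkage.

## Genotyping

All matrix k-mers and a single-copy depth panel are counted in one pass
over the reads (reads are joined with `N` separators so windows never
span read boundaries).  The panel consists of k-mers occurring exactly
once in every input haplotype outside the allele intervals; haploid depth
is `median(panel counts)/2` for a diploid sample, overridable.  This is
*k-mer-level* depth: a read of length `L` contributes `L−k+1` windows, so
panel medians run a factor `(L−k+1)/L` below twice the nominal base
coverage.  Because matrix k-mers are attenuated by exactly the same
factor, the normalization is self-consistent and copy-number estimates
are unbiased; no GC correction is attempted.

Fractional copy numbers solve the non-negative least-squares problem
`min_{c≥0} ‖Mᵀc − v/d‖²` (scipy NNLS).  Non-negativity is imposed inside
the solve rather than by post-hoc clamping: copy numbers are physical
counts, and clamped unconstrained solutions are measurably worse against
the enumeration oracle.  Row-rank-deficient matrices are flagged
degenerate — individual entries are then not identifiable, but clade and
subgroup sums still are, and calls report subgroup-level CN.

Integer rounding is recursive on the tree.  The root budget is
`T = round(Σ c*)` (half-up).  At each internal node the integer budget is
split across children by largest-remainder allocation of the children's
fractional clade sums: floors first, leftover units one at a time to the
largest fractional remainders, ties to tree order; a deficit (possible
after root rounding) is taken from the smallest remainders.  The
recursion fixes each leaf's paCN and conserves `Σ paCN = T` exactly.
Negative fractional inputs are clamped to zero and logged.  On random
small instances this allocation stays within 10% of the residual of the
exhaustive best integer solution in ≥95% of cases (validated in the test
suite and acceptance script); an exhaustive search is exponential in the
number of alleles, whereas the tree allocation is linear.

All k-mers are weighted equally in the projection; an inverse-multiplicity
weighting could be added but is off by default.  Reads are FASTQ (plain or
gzip), single-end; alignment formats are out of scope for the core
counter.  No confidence values are attached to calls.

## Cohort statistics

* **HWE** — per subgroup, CN∈{0,1,2} is treated as a diploid genotype with
  allele frequency `p̂ = mean(CN)/2`; observed counts are tested against
  `(q̂², 2p̂q̂, p̂²)·n` by chi-squared (df = 1), switching to the exact
  conditional test when any expected cell is below 5.  Subgroups with more
  than 5% of samples above CN 2 are excluded (and the exclusion logged)
  rather than modeled — amplification states have no natural diploid
  genotype decomposition.  Monomorphic subgroups report p = 1.
* **Trio concordance** — per subgroup and trio, child copies beyond the
  parents' total are false-positive units, `FP = max(0, c−f−m)`.  A parent
  with `CN_p` above `single_hap_max` (the largest per-haplotype CN of that
  subgroup in the database) must transmit at least
  `max(0, CN_p − single_hap_max)`; shortfalls in the child are
  false-negative units.  The F-1 error is `(FP+FN)/(FP+FN+2·concordant)`
  aggregated over trios.  This obligate-transmission bound is exact for
  error-free Mendelian data (error identically 0) and conservative
  otherwise.
* **F-statistic** — each distinct CN state is an unordered allele;
  `F = (H_T − H̄_S)/H_T` with gene diversity `H = 1 − Σf²`, `H̄_S` the
  size-weighted mean within-population diversity.  `F = 0` when `H_T = 0`;
  populations under 2 samples are excluded.
* **mLD** — for two loci with haplotype-state counts, `D_ij = x_ij − p_i q_j`
  normalized by its frequency bound (multiallelic |D′|) and combined as
  `Σ p_i q_j |D′_ij|` ∈ [0,1]; monomorphic loci are undefined.  Pairing of
  loci (e.g. <100 kb apart) is the caller's responsibility.
* **RPD** — mean paralog pairwise divergence over mean ortholog pairwise
  divergence, on substitution-only (alignable) sequence.
* **CN MAE** — mean absolute copy-number difference over unordered sample
  pairs.
* **Saturation** — cumulative fraction of all subgroups discovered after
  `n` genomes, plus the mean fraction of a not-yet-included genome's
  subgroups absent from the first `n` (recapture form); any genome order
  can be supplied, e.g. one population first.
* Multiple testing across subgroups is left to the caller; Bonferroni is
  the intended default.

## Simulator

`SimConfig` defines the study conditions.  Each gene family has a random
ancestor; paralogous loci diverge from it at `paralog_divergence` per
base.  Orthologous variation is founder-structured: each locus carries
`n_founder_alleles` founder alleles (at `founder_divergence` from the
locus ancestor) and each haplotype draws a founder and adds private
substitutions at `ortholog_divergence` — emulating identity-by-descent
allele sharing, which is the premise that makes nearest-neighbor
genotyping meaningful.  On top of this: indel SVs (`sv_rate`,
`sv_size_bp`), gene-conversion tracts copied between paralogs
(`conversion_rate`, `conversion_tract_bp`), whole-gene deletions
(`del_rate`) and extra copies (`cnv_rate`, up to `cnv_max_extra`).  Extra
copies are *translocated* to dedicated distant slots by default so every
copy is its own allele segment; `cnv_mode="tandem"` instead places copies
adjacently (< merge gap) to exercise proximal/runway annotation.  Spacer
sequences between slots are identical across haplotypes, so spacer k-mers
are single-copy in every assembly and supply the depth panel; a planted
repeated segment exercises background exclusion.  Reads are single-end,
uniform, with uniform-random substitution errors (no transition bias, no
GC bias, no indel errors, no instrument profile).  A fixed seed fixes
every output byte.

Desk-scale defaults (kilobase genes, ~16 haplotypes) keep complete
pipeline runs in seconds; extraction parameters scale with them in tests
(k = 21, merge gap 500 bp, flanks 150 bp, minimum allele 400 bp) while
the paper-scale defaults remain on `DatabaseConfig`.  What passing tests
show is therefore structural correctness of the method under the modeled
variation classes — not robustness to assembly errors, repeat-driven
k-mer depletion at human scale, or non-uniform coverage, none of which
the generator emulates.

## Numerical and design notes

* k-mers are packed into `uint64` (2 bits/base); base order A<C<G<T makes
  numeric and lexicographic canonical order agree.  `k` must be odd (no
  palindromic self-canonical windows).
* NNLS is deterministic; NJ tie-breaks follow input row order; the
  largest-remainder tie-break follows tree order — the whole pipeline is
  reproducible bit-for-bit under a fixed seed.
* An all-zero count vector yields copy number 0 (an absent locus is a
  valid call); a group whose every k-mer occurs in the background is
  reported `unsolvable` rather than genotyped.
* Distances between two all-zero rows are undefined and reported as 1
  with a warning.
* The evaluation module ships the exhaustive oracles (support-enumeration
  NNLS, integer grid search) used to validate the solvers; they are
  exponential-time by design and restricted to small instances.

## Known limitations

Confidence values, sub-allele CNV breakpoints, joint multi-sample
genotyping, GC-bias correction and alignment-format input are out of
scope.  The exact-test HWE fallback assumes a diploid locus; CN states
above 2 are excluded, not modeled.  Leave-one-out calls for alleles whose
entire founder cluster is absent from the database land on an essentially
arbitrary distant neighbor — the same behavior expected for genuinely
novel alleles in real data.
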
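# Methods

## Scope and data model

The pipeline consumes the *tabular* outputs of an upstream annotation
toolchain — contig FASTA, Prodigal-dialect GFF3 gene calls, translated
proteins, CheckM-style QC percentages, genome×family (COG/NOG) tables and
genome×sample read-count matrices — and performs the comparative
analysis: streamlining metrics, complex calls, habitat grouping and
between-habitat statistics. Read mapping, HMM searching, ortholog
clustering and phylogenetics are deliberately out of scope; their results
enter as files.

All coordinates are 1-based and inclusive (GFF3 convention) everywhere;
percentages live in files and configs on a 0–100 scale and are converted
to fractions exactly once at read time, which removes the classic 100×
confusion in the α(1−β)/γ size formula.

## Streamlining metrics

- **GC%** is computed over the whole assembly, not coding regions only,
  counting only unambiguous A/C/G/T in both numerator and denominator.
- **Mean intergenic spacer**: genes are sorted by start per contig; the
  gap between neighbours is `start(next) − end(prev) − 1`. Overlapping
  genes would give negative gaps; these are clamped to 0 because a spacer
  is a physical quantity and unclamped negatives would let dense overlaps
  cancel long spacers. Strand is ignored (spacers are defined on linear
  gene order). Contigs with fewer than two genes contribute no pairs;
  a genome with no pairs at all has an *undefined* (missing) mean, never
  zero. Whether partial genes at contig edges should be excluded is not
  settled; we include every CDS as given.
- **N-ARSC / C-ARSC** use the standard side-chain atom counts of the 20
  amino acids (e.g. Gly 0C/0N, Arg 4C/3N, Trp 9C/1N). Residues are pooled
  across the proteome — total side-chain atoms over total residues —
  rather than averaging per-protein means: pooling matches the
  atoms-per-residue definition, is length-unbiased, and makes the value
  invariant to how residues are split into proteins (a tested property).
  Non-standard letters (X, B, Z, U, `*`), common in MAG proteins, are
  skipped entirely.
- **Estimated genome size** is S = α(1−β)/γ. Division by completeness γ
  is the only sensible reading: it inflates a partial assembly to the
  complete-genome estimate, whereas multiplying would shrink it. Hence
  the invariant S ≥ α(1−β), with equality at γ = 1.
- **QC filter**: keep iff contamination < 5% AND completeness > 40%,
  both strict, exactly as stated; the boundary values 5% and 40% are
  rejected.

## Complex calling

Calls are pure counts of *distinct* countable subunit families — copy
number is ignored (calls are idempotent under gene duplication) and
synteny is not required, since assembly fragmentation breaks gene order
in MAGs. cNDH lists 14 nuoA–N families but counts only the 12 nuoA–L
(nuoM/nuoN are often encoded at a distance), threshold 6. nNDH's
orthologous groups are distinct from the canonical complex's, so its 8
nuoABCGHIJK families live in a separate namespace (canonical COG id
suffixed `_n` by default, configurable via the definitions YAML); a
genome can be positive for both NDH variants independently, threshold 5.
NQR uses the six listed nqr COG families, threshold 3 (the subunit prose
count and the family list disagree by one; we take the six listed ids).
Definitions ship as a versioned YAML constants file and can be replaced
on the command line.

## Abundance, clustering, habitat labels

TPM: per sample, `rate_i = c_i/(l_i/1000)`, `TPM_i = 1e6·rate_i/Σrate`;
all-zero columns stay zero rather than dividing 0/0. Log transform is
log₁₀(TPM + 1); the pseudocount is a parameter (any positive value), 1
keeps zero counts at zero log-abundance. Distances are 1 − Pearson r of
log-TPM profiles, clamped to [0, 2] against floating-point spill.
Zero-variance profiles (e.g. genomes never detected) have no defined
correlation; they are excluded from clustering with a warning instead of
being assigned arbitrary values.

Clustering is agglomerative average linkage (UPGMA-style), delegated to
`scipy.cluster.hierarchy.linkage`, cut with `fcluster` at k groups
(k = 2 by default because the analysis targets a two-habitat dichotomy;
k is exposed). The test suite checks the full hierarchy against a naive
O(n³) re-implementation via cophenetic distances on random matrices, and
rerun determinism end-to-end. Habitat labels: per group, mean log-TPM
over SRF/DCM samples minus mean over MES samples; the group with the
larger difference is epipelagic. OMZ samples are excluded from this vote
(the tested dichotomy is epipelagic vs mesopelagic; OMZ waters are
neither) but still contribute to distances. The tree-cut criterion and
pseudocount are design choices exposed as configuration, since neither
is externally fixed.

## Statistics

Mann–Whitney U is two-sided; the exact enumerated null is used when
n_A·n_B ≤ 400 and the pooled data are tie-free, otherwise the normal
approximation with tie and continuity corrections (threshold
configurable in `comparative_stats.EXACT_MWU_MAX_PRODUCT`). Significance
is annotated `**` for p < 0.01 and `*` for p < 0.05. Per-clade
comparisons require at least 2 genomes in both habitat groups — clades
without multiple genomes in both groups carry no information for a
rank test and are skipped with a log entry.

Enrichment uses presence/absence (not copy number) of each family in a
2×2 table against habitat, two-sided Fisher exact p (hypergeometric
tail summation over tables no more probable than the observed one), and
Benjamini–Hochberg correction by default — the field default at
pangenome scale — with Bonferroni/Holm available; families are called
enriched at q < 0.01 in the direction of the higher presence fraction.

## Synthetic data: what it emulates, and what it does not

The generators emulate the *structure* the analysis relies on, at desk
scale:

- **Genomes**: i.i.d. nucleotides at a target GC (so realised GC
  concentrates within ±1% by binomial concentration at ≥100 kb); genes
  packed with geometric intergenic gaps (mean = the spec's `igs_len_mean`)
  and small 1–4 bp overlaps with probability `overlap_prob` (real
  prokaryotic genomes overlap genes; this exercises the clamping rule);
  proteins i.i.d. from a 20-letter weight vector whose implied ARSC
  expectation is recorded as ground truth. Default weights are shaped
  like a typical bacterial proteome (implied N-ARSC ≈ 0.34,
  C-ARSC ≈ 3.1). Default scale is 5 contigs × 10 genes (≈ 50 kb),
  chosen so hundreds of genomes simulate in seconds; all metrics are
  per-residue or per-gap averages, so scale affects only sampling noise.
  Completeness/contamination in simulated QC records are free parameters
  (assessing them from sequence is a CheckM-scale problem, out of scope).
- **Abundances**: two genome blocks × two sample pools; expected counts
  are `depth_effect`-fold higher in the matching pool, proportional to
  genome length (relative to the cohort mean) and to a lognormal
  per-sample library factor (so raw column sums differ and TPM has
  something to correct). Counts are negative-binomial via gamma–Poisson
  mixing with variance μ(1 + φμ); φ → 0 recovers Poisson. Defaults —
  20+20 genomes, 10 epipelagic + 8 mesopelagic samples, 20-fold effect,
  φ = 0.3, base mean 200 reads — give a clearly structured but noisy
  matrix; recovery tests use a 100-fold effect where the bipartition is
  information-theoretically easy and must be recovered exactly.
- **Enrichment tables**: planted families present with probability
  `presence_hi` in the favoured group and `presence_lo` in the other
  (directions alternate), null families at a common 0.5.

What the generators do **not** emulate: codon structure and realistic
oligonucleotide composition, phylogenetically correlated gene content,
read-level sampling, compositionality between genomes within a sample,
or habitat mixtures. Passing tests therefore demonstrate that the
*machinery* is correct (rules, formulas, clustering, test statistics,
error control), not that real genomes will show any particular effect
size.

## Numerical and degenerate-input choices

TPM column sums are checked to 1e−6 relative. Correlation distances are
clamped to [0, 2]. Merge ties in clustering are resolved by scipy's
deterministic ordering, so outputs are reproducible across platforms;
random test matrices are almost surely tie-free. The Fisher oracle
comparison uses the conventional (1 + 1e−7) relative tolerance when
summing tables "at most as probable" as the observed one. Degenerate
inputs fail loudly: all-ambiguous assemblies, empty groups, zero genome
lengths, nonpositive pseudocounts, fewer items than clusters, and
missing SRF/DCM or MES pools (labels would be undeterminable) are all
hard errors.

## Known limitations

- Habitat labeling assumes exactly two groups; more finely resolved
  habitat structure requires interpreting the dendrogram directly.
- The nNDH family namespace is a convention (no public COG ids exist for
  the noncanonical paralogs); real analyses must map their own ortholog
  clusters onto it via the definitions YAML.
- No phylogenetic correction is applied to feature comparisons or
  enrichment (genomes are treated as independent observations).
- The pipeline trusts upstream gene calls and annotations; it does not
  attempt to detect pseudogenes, partial genes at contig edges, or
  annotation errors.
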
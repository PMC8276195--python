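# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `pirnakit`, in the order the pipeline runs them.

## Coordinate and format conventions

Internally every interval is 0-based half-open. Conversion happens only at
the I/O boundary: GTF is written/read 1-based closed (GTF2.2 attribute
style, `key "value";`), BED 0-based half-open, SAM 1-based via pysam.
FASTA/FASTQ sequences are upper-cased and RNA `U` is mapped to DNA `T` on
input. All writers order records deterministically (chromosome, start, end,
id) and use fixed float formatting, so identical inputs yield byte-identical
outputs. FASTQ qualities are carried through trimming for output fidelity
but ignored by the alignment and counting algorithms — at these read
lengths and error rates, quality-aware placement changes essentially
nothing, and the upstream tools whose contracts are re-implemented here
behave the same way.

## Ungapped alignment

Both the annotation realignment (min_match 16, max_mismatch 0, max_loci
100) and read alignment (14 / 1 / 100, splice-free) share one engine: every
end-to-end ungapped placement of the query on either strand is reported,
where a placement needs `len(query) − mismatches ≥ min_match` and
`mismatches ≤ max_mismatch`. A query with more than `max_loci` placements
is treated as unmapped and dropped — the same behaviour a short-read
aligner shows for reads exceeding its multimap cap — and the locus count is
logged.

Candidates come from exact k-mer seeds (k = min(16, L) for exact search;
two disjoint seeds of k = min(16, ⌊L/2⌋) under one allowed mismatch, by the
pigeonhole argument) looked up in a sorted k-mer table of the concatenated
reference, then verified by a vectorised Hamming comparison. `N` never
matches anything, including another `N`. Windows crossing chromosome
boundaries are excluded.

**3′ soft clip.** The adapter trimmer requires a minimum overlap of 3
bases, so a read whose insert ends 1–2 bases short of the read length keeps
a 1–2 nt adapter remnant that end-to-end placement cannot absorb. Read
alignment therefore retries with up to 2 bases clipped from the read's 3′
end — exactly the remnant the trimmer can leave — stopping at the first
clip depth that yields placements. The brute-force oracle used in testing
applies the same policy around its naive full scan.

This exact-seed design is intended for references up to a few megabases
(the synthetic studies use ~1 Mb genomes); seed-and-extend heuristics for
full mammalian genomes are out of scope, and plugging in an external
aligner is a documented escape hatch rather than a feature.

## Annotation forging

Stage order: collapse → realign → length filter (<100 nt, exclusive) →
biotype reclassification → database integration (<69 nt rule, exclusive) →
standard-chromosome filter → coding-overlap exclusion → embedded-piRNA
metadata → region classification → TE intersection → write. Every stage
logs input/output counts to a statistics TSV, and counts are monotone
non-increasing through the filters.

Decisions where the procedure was genuinely open:

- **Collapse** is sequence-level deduplication: one feature per distinct
  sequence, all ids kept as aliases, all genomic placements attached.
- **Integration**: piRNA-database sequences ≥69 nt that are absent from the
  general database are dropped outright (not retained unmerged); the drop
  is logged. When both databases carry a sequence, the general database's
  id becomes the primary id (it is the completing database) and its biotype
  stands; the piRNA-database ids survive as aliases.
- **Reclassification ambiguity**: a sequence the general database lists
  under two different non-piRNA biotypes is flagged `ambiguous`, left as
  piRNA, and logged rather than silently reassigned.
- **Coding-overlap exclusion** is strand-agnostic (any ≥1 bp overlap with a
  protein-coding gene's exon/CDS, or any CDS) and acts per placement: a
  multi-locus sequence loses only its coding-overlapping placements. The
  lenient mode keeps everything and flags overlaps in the GTF attributes.
- **Embedded piRNAs** must be fully contained in a host sncRNA/lncRNA gene
  on the same strand (a fragment of a host transcript is necessarily sense
  to it); the strand requirement can be switched off in the configuration.
- **Region classification** replaces a bump-hunting step with a specified
  single-linkage merge: placements within `region_max_gap` (default
  1,000 bp, exposed as `--region-gap`) on the same chromosome,
  strand-agnostic, form a region; a region overlapping any gene interval is
  `genic`, otherwise `cluster`; a sequence is labelled by the union of its
  regions' labels (`both` when mixed).
- **Standard chromosomes** default to autosomes + X/Y/MT by name pattern
  (`chr` prefix optional); an explicit list can override.

## Quantification

**Trimming.** For each position j of the read, the adapter prefix that fits
the remaining bases is compared; a hit needs overlap ≥3 and mismatches ≤
⌊0.1·overlap⌋, and the leftmost acceptable j wins. Inserts shorter than 15
nt after trimming are discarded and counted.

**Genomic counting.** A placement is assigned to a feature if their
intervals overlap by ≥1 bp on the same strand (reads are assigned
sense-only; antisense placements remain available in the SAM for ping-pong
analysis). A placement overlapping two distinct features is ambiguous and
dropped. Multi-placed reads follow the configured policy — `unique`
(dropped), `all` (+1 each), or `fractional` (+1/n_hits each, the default:
piRNA multimapping makes unique counting lossy, and fractional assignment
preserves totals). Feature-wise, `all ≥ fractional ≥ unique` on any input.

**Transcriptomic EM.** Reads are matched to the annotation FASTA as
ungapped substrings with ≤1 mismatch, sense strand only (the libraries are
stranded and the transcripts are the mature molecules). Equivalence classes
are resolved by the EM update given in the README; convergence is declared
when the largest abundance change, as a fraction of total reads, falls
below `em_tol` (1e-8; at most 1,000 iterations). Expected counts conserve
the mapped-read total to 1e-6 relative, and the log-likelihood trace is
non-decreasing — both are asserted in tests. Bootstrap SDs resample class
counts multinomially (100 rounds by default), which is cheap and adequate
for the descriptive use the SD gets; GC/sequence-bias corrections of the
emulated tool are out of scope.

**Consensus.** A feature is "expressed" in a track when it passes the CPM
filter (below) on that track's counts; the consensus is the union or
intersection of the two sets.

## Filtering, normalisation, exploratory summaries

- `filter_low` keeps features with CPM ≥ 1 in at least `min_samples`
  samples (default: the size of the smallest group). The operation is
  idempotent. A proportional (library-size-dispersion-scaled) variant
  exists but is off by default because its canonical parameters are not
  published.
- Log-CPM adds a prior of 0.5 proportionally to each effective library
  size, keeping log values comparable across depths.
- **TMM / TMMwsp** follow the published trimmed-mean algorithm exactly
  (30 % M-trim, 5 % A-trim, delta-method weights, rescale to geometric mean
  1); the implementation agrees with the reference R implementation to
  ≤1e-6. The TMM reference column is the sample whose upper-quartile count
  fraction is closest to the mean; TMMwsp uses the largest sum of
  square-root counts, as its authors specify for sparse data.
- **RLE** is the plain median-of-ratios factor over features with nonzero
  geometric mean (the emulated R tool additionally divides by library size
  because its factors multiply library sizes; the definition used here is
  the one stated above and is what `cpm` consumes).
- Biotype detection reports, per sample: each biotype's share of the
  annotation universe, the fraction of that biotype detected (count > 0),
  and its share among detected features (sums to 100 % per sample), plus
  count-distribution quartiles.
- MDS uses the root-mean-square of the top 500 largest squared log-ratios
  per sample pair (standard expression-QC practice; the count is
  configurable) with classical Torgerson scaling; PCA is feature-centred
  SVD. Clustering offers ward/complete/average linkage on Euclidean
  distances, with the Pearson sample-correlation matrix emitted alongside.

## Differential expression

One engine serves both count matrices: voom-style precision weights
(lowess of √(residual SD) against mean log2 count, span 0.5, weights =
trend⁻⁴ clipped to [1e-6, 1e6], evaluated at each observation's fitted log
count) feeding weighted least squares and empirical-Bayes variance
moderation with moment-matched prior df (digamma/trigamma inversion on
log s²). This reproduces the reference R implementation to |Δp| < 1e-3 on
negative binomial simulations and is calibrated (null type-I error at
p ≤ 0.05 within [0.035, 0.065] on seeded 3 vs 3 simulations). A second
NB-GLM engine would double the scope without changing the merge logic,
which is method-agnostic and exercised with both matrices.

Optional per-sample quality weights are the inverse mean residual variance
of each sample, normalised to mean 1 — the simplest member of the
quality-weight family, chosen because the original heuristic's exact form
is unpublished.

Cross-track results merge into one table with per-feature consensus labels
at the adjusted-p threshold and union/intersection membership at both raw
and adjusted alpha (both are reported because "significant by both methods"
is ambiguous between the two readings). Up/down classification requires
concordant fold-change signs between tracks; discordant features are
flagged and excluded from the counts rather than silently assigned.
Numerically-zero residual variances (constant features) are clamped to
zero so the moderated t does not manufacture spurious statistics from
float noise.

## Signatures

The position frequency matrix covers positions 1–15; shorter sequences
contribute only to the positions they cover, and each position is
normalised by its own coverage. Logos are drawn as information content
(2 − entropy, in bits) with T rather than U, matching how sequencing
output is reported. Bias tests are exact two-sided binomial tests against
a 0.25 background. Logos are unweighted by abundance by default (weighted
drawing is a flag) because the choice between the two is a presentation
decision, not a statistical one.

**Ping-pong convention.** An overlap of k means the plus-strand read's 5′
end (its leftmost coordinate) and the minus-strand read's 5′ end (its
rightmost coordinate) are k−1 apart with the minus 5′ end downstream:

```
plus   5'-P=========>
minus        <=========M-5'
           |--k--|            k = M − P + 1 ; hallmark k = 10
```

Conventions differ across tools, so this is fixed here and in the code.
Multi-mapped reads contribute 1/n_hits per placement to both ping-pong and
coverage, consistent with fractional counting. z10 compares the 10-nt bin
against the mean and SD (ddof 1) of the other bins and is undefined (NaN,
flagged) with fewer than two nonzero bins.

## Target scanner

Antisense duplexes require perfect complementarity over piRNA positions
2–11 (the seed), ≤4 total mismatches, and ≤4 G:U wobbles outside the seed;
score = matched + 0.5·wobbles. The scheme is this package's own — the tool
that inspired the module does not publish its criteria — and is versioned
in output headers (`pirnakit-seedmatch-1`) so results remain comparable
across runs. Duplex thermodynamics and conservation are deliberately out
of scope.

## Synthetic studies

`simulate.FixtureSpec` defines the study the generators emulate. Defaults:
two 500 kb chromosomes plus a 20 kb non-standard scaffold, ~300 planted
sncRNAs (piRNA clusters, isolated intergenic and intronic piRNAs,
CDS-overlapping piRNAs, host-embedded piRNAs, multi-locus and
over-multimapped sequences, biotype conflicts, over-long and 69–98 nt
database entries, six other biotypes), ten protein-coding genes, six
non-coding hosts, twelve TEs, and 2 groups × 3 samples at 50,000 reads per
sample — a full pipeline run stays under two minutes on one CPU. Tests and
the acceptance script run the same layout scaled to 250 kb chromosomes and
3,000–5,000 reads per sample, which keeps the whole suite under a minute
of simulation time while still exercising every rule; the layout knobs are
part of the spec, not hidden constants.

Expression is gamma-Poisson (negative binomial, dispersion 0.2) around
lognormal baseline means scaled to the read budget; the alphabetically
second group level carries the planted fold changes (20 up / 10 down at
log2FC 2 by default), matching the contrast of the two-group design
matrix. Spike-ins are Poisson — their input is pipetted, not biological —
with means following the dilution design (1:10:100), and periodate
treatment multiplies every non-methylated species (biological
non-piRNAs and the two unmethylated spike-ins) by δ ∈ (0, 1]. Reads are
insert + adapter truncated to 50 nt with iid substitution errors at 1e-3
per base.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: position-dependent and indel sequencing
errors, ligation and PCR bias, UMI structure, isomiR/fragment length
heterogeneity within a feature, genome repeat structure beyond the planted
multi-locus sequences, and contamination. The planted-truth equivalence
results certify the algorithms' correctness under the stated model, not
database quality or wet-lab performance.

Every generator is a pure function of (spec, seed); the same spec produces
byte-identical files, and truth tables (feature fates per forge rule,
expected GTF rows, per-sample true counts, DE truth) are sufficient to
score every downstream module.

## Numerical choices and degenerate inputs

- EM: uniform initialisation; tolerance on abundance fractions, not raw
  counts; empty classes after bootstrap resampling are dropped for that
  round.
- TMM: pairs with a zero in either sample are excluded (TMM) or
  singleton-paired (TMMwsp); an all-zero sample is an error.
- RLE: requires at least one feature positive in all samples; errors
  otherwise.
- BH: step-up with explicit monotonicity enforcement; order-invariant;
  NaN p-values are an error rather than silently propagated.
- Moderated t: trigamma inversion by bracketed root-finding on [1e-8,
  1e8]; infinite prior df (no excess variance in log s²) falls back to the
  normal reference distribution.
- Ties in GTF output ordering are broken by gene id; ties in the TMMwsp
  M-value trim are broken by shrunken M, as in the reference
  implementation.

## Known limitations

- The aligner is exact-seed, mismatch-only (no indels) and meant for
  megabase-scale references.
- One DE engine (voom + moderated t); no NB-GLM quasi-likelihood
  alternative, no designs beyond group + batch.
- The transcriptomic track maps sense-only and without bias correction.
- The target scanner is combinatorial, not thermodynamic.
- SAM text only (no BAM/CRAM emission); plots are deliberately plain, with
  every figure backed by a TSV of its data.
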
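# Methods

## Consensus somatic filtering

Two somatic callers' VCFs for the same tumor are reconciled by matching
decomposed biallelic records on (chrom, pos, ref, alt).  A variant is
retained when it appears in both call sets, is `PASS` in both, and the
tumor shows VAF ≥ `min_vaf` (default 0.1) and depth ≥ `min_depth`
(default 50).  Both thresholds are inclusive: "a minimum of 0.1" is read
as `vaf >= 0.1`.  VAF and depth are always recomputed from the sample's
allele depths (`AD`), never taken from caller-specific INFO fields, so
the rule is caller-agnostic; the retained record carries the first
caller's read support.  Depth gating applies to the tumor sample only.
Indels are matched as written — inputs are assumed caller-normalized
(left-aligned); no re-normalization is attempted.

Capture regions are 0-based half-open intervals (BED dialect); VCF
positions are converted on comparison, so a variant at 1-based position
`end` lies inside `(start, end)` and one at `end + 1` does not.  A
mismatch of chromosome-naming styles (`chr17` vs `17`) between variants
and regions raises an explicit error rather than silently dropping
everything.

## LOH detection

The detector sees only allele fractions, so it detects allelic
imbalance consistent with copy-neutral LOH or deletion without
distinguishing the two (no read-depth segmentation is done).

Candidate loci are germline calls only.  A site is *informative* when
the germline allele fraction lies in `[het_low, het_high]` (default
[0.4, 0.6], both ends inclusive) and the depth gates pass (germline
≥ 10, tumor ≥ 30).  The tumor allele fraction is corrected for tumor
cellularity *p* (default 0.8) before thresholding:

    adj = clamp((VAF_t − (1 − p)·0.5) / p, 0, 1)

This inverts the two-population mixture at a germline-heterozygous
site: contaminating normal cells contribute allele fraction 0.5
regardless of the tumor genotype.  The correction is exactly neutral at
VAF_t = 0.5 and amplifies both signal and binomial noise by 1/p.  How
the original analysis used its cellularity estimate is not specified
anywhere we could follow, so this correction is a declared convention
of this package; `purity_correction=False` (CLI
`--no-purity-correction`) thresholds the raw fraction instead.

A site supports LOH when `|adj − VAF_g| ≥ min_shift` (default 0.3,
inclusive); the sign gives the direction (toward homozygous reference
or alternative), recorded separately because both directions are
evidence.

**Region aggregation.**  Supporting sites are collapsed per chromosome
into maximal runs.  Between two supporting sites a run tolerates up to
`region_max_gap_sites` (default 1) NO_SUPPORT sites; UNINFORMATIVE
sites are transparent — they neither extend nor break a run.  A run is
emitted as a region when it contains ≥ `region_min_sites` (default 3)
supporting sites; its span is first-to-last supporting site.  The
defaults are our choice of a concrete, configurable rule where the
source analysis says only that sites were "aggregated"; they are
deliberately conservative given the false-support rate per informative
site is ~1e-3 under binomial noise at the default depths.

A gene is reported LOH when it overlaps an emitted region or contains
at least one supporting site, UNINFORMATIVE when it contains no
informative site, NO_LOH otherwise.

## Mutational signatures

**Contexts.**  SNVs map to the 96 trinucleotide channels under the
pyrimidine-strand convention (a purine reference base is
reverse-complemented with its flanks).  Indels map to the 83 standard
channels: 1-bp events by the C/T identity of the (complemented) base
and the length of the homopolymer they sit in; ≥2-bp events by the
number of additional copies of the indel sequence in the flanking
sequence; deletions with no adjacent copy by the longest microhomology
shared between the deleted sequence and either breakpoint flank.  When
both a repeat and a microhomology reading apply, the repeat channel
wins, per the published convention.  The repeat/microhomology search
window is ±100 bp.  Unclassifiable variants (non-ACGT context, complex
substitutions, contig edges) are skipped and itemized, so the catalogue
total always equals the number of classified variants.

**Refitting.**  Exposures solve

    min ‖S·e − c‖₂   s.t.  e ≥ 0,  Σe = 1

with `c` the catalogue normalized to proportions and `S` the chosen
subset of reference-signature columns.  SBS and ID catalogues are fit
independently on their own alphabets.  The solver is active-set
nonnegative least squares on the system augmented with a sum-to-one row
weighted 1e4, followed by exact renormalization — deterministic, no
random initialization, and scale-invariant in the catalogue counts.
For an exactly representable catalogue the residual is at machine
precision; for sampled catalogues the solution matches a 0.01-step
simplex grid search to within the grid's own resolution (asserted in
the tests).  Proportion-normalized Euclidean loss was chosen over
count-weighted variants as the plainest reading of refitting against a
proportions profile.  Exposures below 1e-4 are displayed as 0 in
human-readable output but kept in machine output.

**Signature subset.**  The CRC-restricted subset (15 SBS + 5 ID) is
configuration, not code: `data/crc_signatures.yaml` ships a default
list that includes SBS1/SBS3/SBS30 and ID1/ID5/ID6 — the signatures the
study family's tumor reported — and the remaining slots follow commonly
reported CRC signatures.  Reference matrices are read from COSMIC-style
TSVs (channel label column + one column per signature, any row order);
tests use synthetic matrices so the package builds and tests offline.

**HRD rule.**  Positive iff SBS3 exposure > 0.10 or ID6 exposure
> 0.20, both strict; the verdict lists which rule(s) fired and errors
if SBS3/ID6 are absent from the fitted subset.

## Pedigree and SPS criteria

The family table is a long CSV (one row per cancer/polyp event) with
person-level columns repeated.  Obligate carriers count as carriers in
every summary.  Cancer-affected means ≥ 1 cancer diagnosis row; polyp
rows are never malignancies; CRC-affected matches tumor type `CRC`.

WHO-2019 SPS criteria are cumulative over all ages.  Decisions where
the criteria leave room:

* *Proximal to the rectum* = every segment except the rectum (sigmoid
  counts as proximal); the non-proximal label set is configurable.
* Serrated histologies = hyperplastic, SSL, TSA.  Adenomas never count.
* A reported size range (e.g. 6–8 mm) is judged by its lower bound by
  default (`size_rule`: lower_bound | upper_bound | midpoint); unknown
  sizes never satisfy a size threshold.
* An SSL contiguous with a carcinoma carries a `background_lesion`
  flag; it is included by default and excluded with
  `include_lesion_background_ssl = false`.  In the packaged family,
  person 010 meets criterion 1 only when that lesion is included —
  matching the study's own reading — and the proband's "numerous small
  metaplastic polyps" are encoded as a single unknown-size record that
  cannot qualify.

## Synthetic data

Generators are bit-reproducible given (config, seed) and emulate the
statistical structure the detectors rely on, not the genome:

* Heterozygous sites are placed uniformly on one chromosome; germline
  alternate reads are Binomial(depth, 0.5); tumor alternate reads are
  Binomial(depth, μ) with μ = 0.5 outside planted segments and
  μ = p·a + (1 − p)·0.5 inside copy-neutral LOH segments, a ∈ {0, 1}
  the allele retained.  Depths are Poisson around the configured means.
  Defaults mirror the study conditions: cellularity 0.8, germline ~30×,
  tumor ~60×, 500 sites per chromosome.
* Catalogues are Multinomial(n, S·e_true) draws.  Synthetic signature
  matrices are Dirichlet(0.5) columns with pairwise cosine similarity
  capped at 0.7 so recovery tests are well-conditioned by construction.
* Family tables plant genotypes and CRC diagnoses in the pedigree CSV
  schema for round-trip testing.

Not emulated: linkage disequilibrium and non-uniform site spacing,
mapping artifacts, FFPE damage, subclonal heterogeneity, deletion-LOH
(allele fractions alone cannot distinguish it from the copy-neutral
case anyway), and real trinucleotide background frequencies.  Passing
recovery tests therefore demonstrate correctness of the statistical
machinery under the declared noise model, not robustness to artifacts
of real FFPE exome data.

## Problem sizes and verification

The test and acceptance runs use 100 planted + 100 neutral chromosomes
of 500 sites for the LOH operating characteristics (observed: ≥ 95 %
of planted segments recovered with both boundaries inside the local
informative-site gap; 0–2 % of neutral chromosomes yield any region),
50 seeded multinomial mixtures of 10 000 mutations for refit accuracy
(mean absolute exposure error ≈ 0.006), and a 0.01-step simplex grid
as the refit oracle on 2–3 signature problems.  Occasional recovery
misses are single-site boundary slips — the first informative site
inside a segment fails its shift threshold with probability ≈ 0.5–3 %
depending on the germline fraction, placing the recovered edge one
spacing further in.

## Known limitations

* LOH verdicts use a single supporting site as sufficient gene-level
  evidence; with ~1e-3 per-site false support this is acceptable at
  exome site density but would need tightening for genome-scale input.
* The consensus filter takes read support from the first caller rather
  than reconciling disagreeing AD fields.
* ID-83 classification assumes anchored, left-aligned indels; complex
  or unanchored records are skipped (and reported), not normalized.
* The cellularity correction assumes a single clonal tumor population
  and diploid normal contamination.
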
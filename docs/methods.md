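# Methods

This note documents the models and procedures `smmiphet` implements, the
parameters that matter, the design choices made where the design was open,
and what the synthetic-data tests do and do not demonstrate.

## Data model

The unit of capture is the **probe target**: a contiguous genomic interval
(0-based, half-open everywhere in memory; BED on disk) with its reference
sequence and GC fraction. A **tagged read** is one sequenced copy of one
captured molecule: (sample, probe, molecular tag, base calls, base
qualities). Reads sharing (sample, probe, tag) are PCR duplicates of a
single original molecule.

## Tag correction and deduplication

Molecular tags acquire sequencing errors, splitting one molecule into
several apparent tags. Correction is **directional**: within each
(sample, probe) group, any tag within Hamming distance ≤ `max_tag_distance`
(default 1) of a strictly more abundant tag is reassigned to the most
abundant such neighbor (ties broken lexicographically), and the pass is
iterated until no further merge occurs. Running the operation twice
therefore changes nothing. Equal-abundance neighbors never merge. The exact
upstream correction used with smMIP data is not published in detail; this
directional merge is the conservative community standard for UMIs and is
labelled as such.

Deduplication keeps **one read per family, chosen uniformly at random**
rather than building a consensus (consensus is available behind
`method="consensus"` but is off by default). The choice is keyed by a hash
of (sample, probe, tag, seed), so results are reproducible and independent
of input ordering. Random representatives leave base-level errors in place
at roughly the per-read error rate, but remove the allele-fraction bias that
allele-correlated PCR amplification induces — the property the dedup tests
measure.

## Pileups and the six variant filters

Pileups count deduplicated reads per site, masking bases below phred 30
(`min_base_quality`). Candidates are generated for every non-reference
allele with at least one qualifying read — trace-level evidence matters for
the heterogeneity matrix — and carry independent pass/fail status for six
filters:

| filter | rule (defaults) |
|---|---|
| base_quality | enforced structurally: sub-threshold bases never reach the counts |
| min_depth | fails iff masked depth < 30 |
| homopolymer | fails iff a reference single-base run of ≥ 4 abuts or contains the site |
| min_ab | fails iff allele balance < 0.05 (inclusive threshold: 5/100 passes) |
| population_db | fails iff the variant is in the population database **minus** COSMIC |
| control_recurrence | fails iff AB ≥ 0.05 in ≥ 2 distinct control samples |

A variant is **emitted** iff all six pass; candidates failing only `min_ab`
form the **trace** output. All thresholds are inclusive exactly as printed
in the configuration. Two deliberate interpretations: "neighboring"
homopolymer means *adjacent to or containing* the variant base (the window
is a parameter), and the ≥ 30× depth test uses post-mask depth. Multi-allelic
sites are filtered per alternate allele.

## Copy number

Per-probe coverage is the deduplicated read count. A probe is **eligible**
when the control has > 30 reads and its GC is in the closed band
[0.30, 0.60]; a gene is **assayable** with ≥ 15 eligible probes. Tumor
counts are scaled to the control library size (totals over eligible
probes), then 0.5 is added to both scaled-tumor and control counts before
forming the ratio. Placing the pseudocount after scaling keeps the estimate
exactly invariant to a global multiplier on tumor counts and makes
tumor = control give ratios of exactly 1, while still protecting
against zero tumor coverage.

Eligible log2 ratios, ordered by (chromosome, start) with segment boundaries
forced at chromosome breaks, are segmented by **circular binary
segmentation**: the arc (i, j] maximizing the pooled two-sample
|t|-statistic (inside vs outside) is accepted when its permutation p-value
is ≤ `cbs_alpha` (default 0.01, `cbs_n_perm` = 1000) and both circular
pieces have ≥ `cbs_min_width` = 2 points; the algorithm recurses on the
resulting pieces with no undo step. The permutation stream for the stretch
at absolute offset `lo` with length `n` is
`default_rng(SeedSequence(seed, spawn_key=(lo, n)))`, each permutation
ordering the values by the ranks of `n` fresh uniforms — a documented
convention, so an independent implementation can replay it exactly.
Permutation counting stops early once the rejection threshold count is
exceeded (the accept/reject decision is unchanged), and a relative tie
tolerance of 1e-9 on |t| keeps partition-preserving permutations — which
equal the observed statistic in exact arithmetic — counted as ties.

The gene-level ratio *R* is the mean of back-transformed segmented values
over the gene's eligible probes (raw ratios via `use_segmented_R=False`);
the copy estimate is *R* divided by the per-sample median of *R* over
assayable genes, which cancels both library scale and the global inflation
that large amplifications induce. Calls: estimate > 6 highly amplified,
> 3 amplified, otherwise none. Estimates below 1 are never called — the
assay does not measure deletions, by design.

The control denominator is a single **universal control**; with
`universal_control: auto` the pipeline picks the control whose maximum
allele fraction of known pathogenic (COSMIC) variants is lowest — the
contamination diagnostic reported per tumor and warned about above 5 %.

## Heterogeneity classification

Each event observed anywhere in a tumor (an emitted point mutation, or a
gene with copy estimate > 3 in an assayable sample) receives a status in
every region:

- point mutations: `present_high` above 30 % AF; `present` from 5–30 %;
  between 1 % and 5 %, `present` if the call passes all non-AB filters and
  has ≥ 2 supporting reads; `trace` below 1 % with ≥ 2 supporting reads;
  otherwise `absent`. The ≥ 2-read floor (both bands) guards against single
  sequencing-error reads; "absent" means zero qualifying evidence under it.
- amplifications: `present` iff estimate > 3 and the gene is assayable;
  `not_assayable` otherwise when it is not.

The verdict: **truncal** events are present (or present_high) in *all*
regions (the control X is excluded from this logic but reported);
**heterogeneous** events are present in a proper nonempty subset and absent
— trace allowed, `not_assayable` not — elsewhere. A tumor is
`heterogeneous` only when both exist; subset events without truncal
evidence give `indeterminate_cellularity`; truncal events only,
`homogeneous`; nothing, `no_events`. The anchor may be either modality: a
truncal point mutation licenses an amplification heterogeneity call and
vice versa. A heterogeneous event in a gene that also carries a *distinct*
truncal event is flagged a likely passenger; the flag does not change the
verdict. Single-region tumors raise an error: the verdict is undefined.

Mutation spectra collapse each emitted substitution to its
pyrimidine-reference class (G>T ≡ C>A). A tumor is flagged hypermutated
when its distinct emitted somatic count exceeds `hypermutation_multiple`
(default 5) times the cohort median — a configurable stand-in for the
qualitative "an order of magnitude above the median" pattern.

## Synthetic data generator

The generator is the package's study-conditions definition, not a fixture:

- **Panel**: genes laid out two per chromosome in contiguous probe blocks;
  GC drawn from a profile (default uniform(0.2, 0.7)) and realized exactly
  in the generated reference sequence, so eligibility banding is controlled
  by the profile rather than composition noise.
- **Clone tree**: nested clones with per-region cell fractions (child ≤
  parent), carrying point mutations and gene amplifications; a germline
  pseudo-clone is carried by every cell including the control. For a
  mutation at a diploid locus the expected AF is (purity × cell fraction)/2;
  at an amplified locus the denominator becomes the mixture copy number
  A·C + (1−A)·2. A gene amplified to C copies in cell fraction A has
  expected coverage ratio (A·C + (1−A)·2)/2.
- **Reads**: unique molecules per probe ~ Poisson(depth × gc_bias(gc) ×
  ratio) with gc_bias(gc) = exp(−k (gc − 0.45)²), k = 6, shared between
  tumor and control; each molecule carries a mutant allele with probability
  equal to the expected AF; tags are random (collisions logged at the
  birthday rate) or sequential in a collision-free mode for exact
  conservation tests; PCR copies are 1 + Geometric with mean `dup_rate`
  extra copies (optionally allele-biased); base errors are i.i.d. at
  `error_rate` (default 10⁻³) and 2 % of base calls get phred 20. All
  randomness flows from one master seed through named substreams (panel,
  molecules, tags, errors), so stages are independently reproducible.
- **Cohort preset**: 14 tumors of 3–5 regions plus control X over a 10-gene,
  160-probe panel at depth 100 unique molecules/probe: three planted
  heterogeneous tumors (point-mutation heterogeneity with a truncal point
  anchor; subclonal PDGFRA/KIT-type amplification under a truncal EGFR-type
  amplification; single-region amplification under a truncal point
  mutation), one cellularity-confounded tumor (subset amplification, no
  anchor), one hypermutator (16 truncal mutations, 8 C>A-class; clean
  control, so the auto-picked universal control is its X), and nine
  homogeneous tumors with 0–3 truncal mutations (cohort median 2), two of
  them with high-level truncal amplifications. Other controls carry up to
  6 % tumor contamination. Purities are drawn per region (0.35–0.9 by
  scenario); planted subclones occupy whole regions, with a 2 % cell
  fraction in the shared middle region of the point-heterogeneity tumor to
  produce trace-level signal. Amplifications are 10 copies (subclonal,
  high-purity scenarios) or 20 copies (truncal in wide-purity scenarios) so
  that anchor events stay above the 3× call threshold across the purity
  draw — at depth 100 and ≥ 15 probes per gene the gene-level noise is ~3 %,
  so these margins are many standard errors wide.

Problem sizes (depth 100–500, 150–360 probes, 14 tumors, 20–50 replicates)
were chosen as the smallest at which every planted effect sits several
standard errors from its decision threshold; the per-probe unique-molecule
depth of the real assay is not published, so depth is a scenario choice.

**What the generator does not emulate:** indels and rearrangements, real
reference context (mappability, alignment artifacts), strand bias,
quality-score miscalibration, overdispersed capture beyond the GC model,
correlated errors, and subclone spatial gradients within a region. Passing
tests therefore demonstrate the *logic* of the pipeline — filter semantics,
segmentation correctness, the cellularity guard — under the stated
statistical model, not performance on real sequencing data.

## Numerical choices and degenerate inputs

- Deduplication keys and tie-breaks are content hashes (64-bit,
  fixed-key), so all results are independent of row order and stable across
  platforms.
- CBS: zero-variance stretches yield |t| = ∞ when means differ (splits on
  noiseless steps are found exactly) and 0 when all values are equal (no
  split); arcs are enumerated lexicographically and the first maximum wins.
- Ratios: probes with zero tumor coverage survive via the post-scaling
  pseudocount; a sample with zero eligible coverage is an error, as is a
  panel/count probe-set mismatch or an analysis with zero assayable genes.
- Spectra skip non-SNV inputs with a warning rather than failing.

## Known limitations

- The heterogeneity verdict treats passenger-flagged events like any other
  subset event; tumors heterogeneous *only* for passengers are still called
  heterogeneous (flagged). The cohort preset contains no such tumor.
- The trace threshold (< 1 %) and the ≥ 2-read floor are narrative-derived
  conventions, exposed as configuration, not fitted quantities.
- Tag correction is quadratic in the number of distinct tags per probe in
  the worst case; a neighborhood prefilter keeps the common case fast.
- Single-probe genes, single-region tumors and cohorts without controls are
  rejected rather than guessed at.
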
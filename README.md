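# smmiphet

Multi-region tumor heterogeneity analysis for single-molecule molecular
inversion probe (smMIP) capture data.

## The problem

Gliomas — and solid tumors generally — are spatially heterogeneous: a point
mutation or gene amplification found in one biopsy may be missing from an
adjacent one. Deep targeted sequencing of several regions per tumor can map
this, but two artifacts confound the naive comparison:

1. **PCR duplication.** smMIP capture tags every captured molecule with a
   random molecular tag (UMI); reads sharing a tag are copies of one molecule
   and must be collapsed before allele fractions or coverage mean anything.
2. **Tumor cellularity.** A region with few tumor cells loses *every*
   mutation at once. A mutation "private" to two of five regions is only
   evidence of genetic heterogeneity if something else — a truncal event —
   proves the other regions contained tumor at all.

`smmiphet` implements the full analysis:

- **Tag dedup** (`smmiphet.dedup`): directional abundance-based tag
  correction (Hamming distance ≤ 1 by default, iterated to a fixpoint), then
  one read per unique capture event chosen uniformly at random (seeded,
  order-independent).
- **Variant filtering** (`smmiphet.variants`): pileups over probe targets with
  a phred ≥ 30 base mask, candidates at any allele fraction, and six filters —
  base quality, ≥ 30× deduplicated depth, no neighboring reference homopolymer
  run of ≥ 4 bases, allele balance ≥ 5 %, absence from a COSMIC-stripped
  population database, and absence (AB ≥ 5 %) from ≥ 2 control samples.
- **Copy number** (`smmiphet.copynumber`): per-probe coverage ratios versus a
  control tissue (probes eligible when control coverage > 30× and GC in
  30–60 %; genes assayable with ≥ 15 eligible probes), circular binary
  segmentation of log2 ratios with permutation-based split acceptance, the
  gene-level mean ratio *R*, and the copy estimate *R* / median(*R*), called
  **amplified** above 3 and **highly amplified** above 6. Deletions are not
  called.
- **Heterogeneity** (`smmiphet.heterogeneity`): a per-region event-status
  matrix (present_high > 30 % AF, present, trace < 1 %, absent,
  not_assayable), and a verdict per tumor — *heterogeneous* only when a
  truncal event anchors every region and another event is present in a proper
  subset and absent elsewhere; subset events without an anchor give
  *indeterminate_cellularity*. Subset events in genes already truncally
  mutated are flagged as likely passengers, and per-tumor mutation spectra
  (pyrimidine-collapsed, e.g. G>T counted as C>A) flag hypermutators.
- **Synthetic cohorts** (`smmiphet.sim`, `smmiphet.scenarios`): a generator
  for probe panels and tagged reads with truncal/subclonal clone structure,
  purity-scaled allele fractions, GC-dependent capture efficiency, PCR
  duplication over tags, sequencing error, germline variants and contaminated
  controls — plus a 14-tumor preset with three planted heterogeneous tumors.

## Worked example

```bash
smmiphet simulate --scenario cohort --seed 1 --out sim/
smmiphet run --reads sim/reads.tsv --panel sim/panel.bed \
    --popdb sim/popdb.tsv --cosmic sim/cosmic.tsv \
    --sample-sheet sim/sample_sheet.tsv --out results/ --seed 1
```

The run prints the cohort summary (rows abridged, columns as printed):

```
tumor_id  n_regions                   verdict  n_truncal  n_heterogeneous  n_somatic  hypermutation  control_diagnostic amplified_genes
     T05          5             heterogeneous          1                2          0          False            0.011494 EGFR;KIT;PDGFRA
     T06          5             heterogeneous          1                2          1          False            0.000000      KIT;PDGFRA
     T07          4                 no_events          0                0          0          False            0.010989
     T09          5             heterogeneous          1                2          3          False            0.063158
     T12          5               homogeneous         16                0         16           True            0.010989
     T14          5 indeterminate_cellularity          0                1          0          False            0.011364            EGFR
```

Reading it: T09 carries a truncal point mutation in all five regions with
two further high-AF mutations confined to disjoint region pairs — genuine
spatial heterogeneity. T05 and T06 show subclonal receptor-kinase
amplifications anchored by truncal events. T14 has an amplification in two
regions but *no* truncal anchor, so low tumor cellularity in the other
regions cannot be excluded and no heterogeneity is claimed. T12 carries 16
truncal mutations (cohort median is 2) dominated by C>A-class transversions
and is flagged as hypermutated. The `control_diagnostic` column is the
highest allele fraction of known pathogenic variants seen in each tumor's
control tissue — T09's 0.063 triggers a contamination warning in the run
log. Per-tumor JSON reports, event-by-region matrices, per-sample VCFs and
copy-number tables are written under `results/`.

The same pipeline is available as a library call
(`smmiphet.run_pipeline(reads, panel, popdb, cosmic, sheet, config, seed)`),
and every stage (`dedup`, `call-variants`, `copy-number`, `print-config`) as
a subcommand. `smmiphet print-config` dumps every threshold in force.

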
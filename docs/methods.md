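# Methods

## The measurement model

The assay reports exposed single-stranded DNA as priming events: a
barcoded probe anneals to accessible ssDNA, photoactivation frees its 3'
end, and polymerase extends it in situ. After amplification and
sequencing, each informative read pair carries the probe's 5' barcode
segment (2p) on mate 1 and/or the 3' poly-C-derived segment (pC) on
mate 2. We treat the 5' genomic end of the barcode-carrying read as the
priming site: it marks the probe's annealing position at single-base
resolution, and the alignment strand identifies which strand was
single-stranded (the read is the complement of the annealing template).

Quality classes encode primer evidence — A: 2p and pC; B: 2p only; C: pC
only; D: neither — and subclass 1 marks read-through (the fragment is
shorter than the read, so a mate runs into the reverse complement of the
opposite primer). Class D reads carry no barcode and never define sites.
Class C inclusion is a sensitivity/specificity dial: the default merges
A/B/C for maximal sensitivity; `PipelineConfig.strict_ab()` reproduces the
tightened re-analysis (A/B only, non-overlapping mapped length ≥ 30 bp).

## Pipeline stages and their parameters

| stage | parameter | default | rationale |
|---|---|---|---|
| trimming | minimum insert length | 10 bp | shorter inserts are unalignable; gate applied after primer trimming and again after poly-N trimming, per mate |
| trimming | primer mismatch tolerance | ≤1 for segments ≥15 bp | sequencing-error tolerance without false barcode calls; short segments (pC) require exact match |
| alignment filter | min mapped length | 10 bp | joint criteria; all ratios are over the trimmed read length, since alignment consumes trimmed reads |
| alignment filter | min score / read length | 0.4 | |
| alignment filter | min matched / read length | 0.4 | |
| alignment filter | max mismatches / mapped length | 0.1 | inclusive at 0.1 |
| alignment filter | min pair-level non-overlapping mapped length | 20 bp (30 in strict mode) | union of mate intervals minus their overlap |
| duplicates | key | (chrom, read 5' end, strand, mate 5' end) | coordinate-duplicate contract; the best record (score, then mapped length, then lexicographically smallest read id) survives |
| contamination | comparison | alternative score strictly greater | ties retained, conservative toward the target genome |
| mappability | read length / max offset | 20 bp / 10 bp | synthesized reads mapping to a wrong chromosome or >10 bp off mask their origin's 20 bp bin; stride 1 in tests, 20 in the pipeline default |
| site capping | bin / cap | 20 bp / 2×k | k = cells in the sample; 2 homologs per cell; priority A1>A2>B1>B2>C1>C2, then score, then mapped length. The cap limits the count only — retained sites may share a position |
| genic units | GeneExt / Promoter / Downstream | gene ± 2.5 kb / −2 kb…+200 bp / TES + 2.5 kb | strand-mirrored for minus-strand genes; clipped to chromosome bounds; representative transcript = longest by exonic span |
| TSS enrichment | proximal / window | ±1 kb / ±5 kb | FE = width-normalized proximal fraction; FE = 1 under uniformity. The exact published formula is not stated; this definition is ours and is used consistently |
| mito profile | bin / hotspot | 50 bp / z ≥ 2 | sample (n−1) standard deviation; last partial bin kept so bins tile the circle exactly |
| DNAzyme filter | aligned fraction / mismatches / overlap | ≥0.85 (inclusive) / 0 / ≥1 site | fraction is of the query length; hit strand recorded but not required to match the site strand |

Annotation categories are assigned by precedence: promoter <1 kb >
promoter <5 kb > 5' UTR > exon > intron > 3'-proximal > distal intergenic.
Promoter bins cover the 5' upstream flank of the nearest TSS plus the same
+200 bp downstream fringe as the Promoter unit; placing promoter first
mirrors common annotation practice (the category list itself names no
precedence).

Statistical choices: strand ratios use only samples with ≥5 informative
counts; the rank-sum test is exact up to 20 per group, normal
approximation above. "Highly expressed" means strictly above the median
over all genes in the table, zeros included (configurable). Library
normalization scales each sample to the median total priming count.
Epigenome fold enrichment uses the binomial coverage-fraction expectation
(fast); quantile normalization maps scores to (rank−1)/(n−1) with average
ranks for ties. Sequence complexity is Shannon entropy of overlapping
dinucleotide usage normalized by log2(16); the published metric is
unnamed, so values are comparable only within this implementation.

## The synthetic-data generator

The generator defines the study conditions; its defaults are fixed and
are what the tests and the acceptance script run under:

- two 100 kb chromosomes, 24 non-overlapping genes (2–6 kb, 2–4 exons,
  CDS inset to leave UTRs), plus a 16 kb circular mito contig with 10
  genes (80% on the heavy strand, by convention the '+' reference strand)
  and a 700 bp D-loop at 15,300–16,000;
- 200 planted ssDNA regions of 200–1,000 bp; 60% have midpoints within
  ±5 kb of a TSS, drawn from a truncated normal (σ = 2 kb) so the
  aggregate coverage shows the assay's TSS-centered peak; the remainder
  avoid all TSS neighbourhoods;
- each region's strand is the annealing template strand. Regions whose
  midpoint lies in a gene body take the gene strand as template with
  probability bias/(1+bias) (default bias 2.0) and are clipped to the
  gene body, so reads map antisense to the gene that often —
  transcription-bubble ssDNA stays within the transcribed unit;
- 5 reads per region (75 bp pairs, insert 20–60 bp drawn uniformly within
  the region) plus uniform background reads at rate 0.05; classes are
  drawn from the mixture A 0.70 / B 0.20 / C 0.08 / D 0.02, and
  read-through arises geometrically when the fragment is shorter than the
  read. 5% of reads get a poly-N tail to exercise trimming;
- controls are presets, not separate code paths: `probe-laser-` emits
  background only; `probe+laser-` suppresses planted reads to 10% and
  shifts the class mixture to mostly C; `mungbean` keeps each planted
  read with probability 1 − digestion efficiency (default 0.8).

The region length distribution of real ssDNA tracts is not established
(kilobase-scale tracts are reported for transcription bubbles); the
200–1,000 bp default is a configurable choice sized to the toy genome.

What the generator does **not** emulate: base-quality error profiles,
indels or realistic substitution errors (a uniform substitution rate is
available but defaults to 0 because the shipped aligner is exact),
repetitive sequence content, copy-number variation, or doublets. Passing
recovery tests therefore demonstrates the pipeline's bookkeeping
(classification, filtering, capping, strand accounting) and estimator
calibration under clean conditions — not robustness to alignment
artefacts in real repetitive genomes, which is exactly what the
mappability mask and blacklist inputs exist to absorb.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open everywhere internally; GTF is converted
at the I/O boundary; BED is native. Bin grids anchor at coordinate 0 per
chromosome. Z-scores use the sample standard deviation (n−1); a zero SD
yields undefined z and no hotspots. TSS enrichment with no site in the
window is reported as missing (NaN), not zero. Fisher's odds ratio is 0
when no gene is primed and infinite when the off-diagonal is empty; a
zero light-strand count reports an infinite heavy/light ratio. Ties in
the capping priority and in duplicate marking break by lexicographic read
id, making every stage deterministic; a fixed seed reproduces every
output byte-for-byte.

## Problem sizes

The default synthetic study (200 regions, ~1,050 read pairs, 216 kb
genome) runs in under a second; the test suite and the acceptance script
use 20 independent seeds per stochastic claim, chosen so medians are
stable to the reported precision while the whole suite stays fast. The
pipeline mappability mask uses stride 20 on the synthetic genome (the
random genome contains no repeats; tests that verify mask correctness use
stride 1 on genomes with planted duplications).

## Known limitations

- The exact-match toy aligner fulfils the alignment contract for
  synthetic data only; real data needs an external aligner producing
  SAM/BAM, which `samio.records_from_sam` adapts.
- The read-through definition (reverse complement of the opposite primer
  in the mate, or a ≥3 bp partial at the insert 3' end) is our
  operationalization; with a homopolymer pC primer, a genomic base
  identical to the primer's first base is absorbed into the trim, a 1 bp
  ambiguity inherent to homopolymer adapters.
- The background estimator is a ratio of medians and inherits their
  sampling noise; it is reported to one decimal place.
- Differential-priming selection over a perturbation time course is a
  fold-change plus minimum-count rule; no significance model is claimed.
- The 10 bp length gate is applied per mate; whether the published
  pipeline gated per mate or per concatenated pair is not stated.
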
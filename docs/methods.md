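# Methods

This note documents the statistical models, conventions and defaults behind
`tachseq`, and what the synthetic data generator does and does not emulate.

## Coordinates and data model

All coordinates are 0-based, half-open (BED convention). A *tag* is one
aligned single-end read; its 5′ end is the nuclease cut site — `start` for
a plus-strand tag, `end` for a minus-strand tag. Tags without a strand are
rejected rather than defaulted, because the cut-site definition depends on
strand. Gene models use a minimal TSV (gene id, contig, strand, TSS, TTS,
exon blocks); multiple rows per gene id represent alternative TSSs. Genes
absent from the expression table form the "nd" (not detected) class.

## Hotspot detection

**Scan statistic.** For every `small_window` (default 250 bp) window
stepped by `step` (50 bp), the tag count `n` is compared with the count `N`
in a centred `background_window` (200 kb) under a binomial null in which
each background tag falls into the small window independently with
probability `p = small_window / background length`:

    z = (n − N·p) / sqrt(N·p·(1 − p))

Near contig edges the background is clipped and `p` recomputed from the
clipped length — necessary because synthetic contigs are far shorter than
200 kb. Windows with `N = 0`, or with a clipped background no longer than
the small window (`p ≥ 1`, where the binomial degenerates), are skipped.

**Empirical FDR 0%.** The same number of tags is placed uniformly at
random over the (non-mitochondrial) genome `n_randomizations` times
(default 20) and the threshold is the largest z seen in any randomization
plus one ulp: the smallest threshold at which the expected number of
passing windows in a random library is zero. A consequence worth knowing:
the threshold *decreases* with library depth at fixed genome size. In
sparse libraries most background windows are nearly empty and a single
stray tag is many nominal s.d. above its tiny expectation (the discrete
Poisson tail); as counts grow the statistic approaches its Gaussian limit
and the max-over-windows settles near z ≈ 5–6. The unit tests assert this
(decreasing) behaviour.

**Merging and trimming.** Passing windows are merged when their gaps are
at most `small_window`, and each merged interval is trimmed to the span of
the cut sites it contains. This convention is deterministic and
oracle-checkable; published hotspot variants differ here, so the gap is
config-exposed. Tag count, density and the maximum window z are recorded.

**Density units.** Hotspot density is tags per kb per million library tags.
Library-size normalization makes cross-library scatter comparisons
depth-invariant; correlations are computed on `log10(density + 0.1)`
because densities span decades and a linear-scale Pearson r would be
dominated by the strongest hotspots.

**Mode filter.** The called set is filtered by a density threshold at the
mode: a histogram of log10 density with bin width 0.1 is built, and
hotspots below the lower edge of the modal bin (ties resolved toward the
lowest bin) are discarded. Log binning matters: densities span decades, and
linear bins would put the mode at the smallest bin. A single hotspot is
returned unchanged.

**Mitochondrial tags.** Tissue digests carry a visible mitochondrial tag
fraction; it is reported separately (`mito_fraction`) and `chrM` tags are
excluded before hotspot calling, so hotspots are nuclear only.

## Cross-library comparison

Union merging combines hotspots from all sets wherever they overlap by at
least 1 bp; Venn-style pattern counts are taken over merged union intervals
(per-source counting would double-count split/merged regions). The overlap
criterion (≥ 1 bp) is the simplest defensible reading of "identified by
both" and is config-exposed. Quartile parsing sorts by density descending
(ties by contig, start) into four near-equal groups, quartile 1 the most
intense; per-quartile uniqueness is the fraction of a quartile's hotspots
without any ≥ 1 bp overlap in the other sets.

## Sequence bias and CpG islands

Cut-site base frequencies are read strand-relatively: for minus-strand tags
the 2k-base window around the 5′ end is reverse-complemented, so offset 0
is always the first sequenced base and negative offsets lie upstream of the
cut. Tags too close to a contig edge contribute only their in-range
offsets; N bases are excluded per-offset from the denominator.

CpG islands use the classical Gardiner-Garden–Frommer criteria — every
200 bp window (step 1) with GC ≥ 0.5 and CpG observed/expected
`(#CG · 200)/(#C · #G)` ≥ 0.6, merged, kept at ≥ 200 bp — because the
island tracks the assay is usually compared against are built this way.
All three thresholds are config-exposed, and a user-supplied island BED
bypasses the caller.

## Feature annotation

Hotspots are classified by their midpoint with fixed priority
promoter > exon > intron > downstream > distal (promoter = 2 kb upstream of
a TSS, downstream = 2 kb past a TTS, both strand-aware). Midpoint plus
priority is deterministic and testable; a hotspot in one gene's exon and
another's intron is an exon. TSS occupancy uses the literal
point-in-interval rule — a gene is occupied when at least one of its TSS
positions falls inside a hotspot of any provided set. Expression bins are
unit-log₂ bins over detected genes with open-ended extremes (top bin =
more than 16 transcripts per cell) plus a separate "nd" class, or deciles
(undetected genes rank last, ties by gene id). Aggregation profiles tally
cut sites into offset bins around anchor midpoints or strand-oriented
TSSs, averaged per anchor and normalized to tags per bp per million;
heatmap rows are the same quantity before averaging (so column means equal
the aggregate profile) and are not smoothed.

## Synthetic data generator

The generator defines the study conditions for all tests; its defaults are
fixed, not tuned per test.

**Genome.** Contigs are assembled from i.i.d.-base blocks (default 10 kb)
whose GC is drawn from a configurable level set (default 0.3/0.5/0.7,
emulating isochore-like composition). Background CpG is depleted by
composition-preserving adjacent CG→GC swaps (probability 0.9, six passes):
mammalian background sits at CpG observed/expected ≈ 0.2, and without
depletion an i.i.d. background (o/e ≈ 1) would satisfy the island criteria
almost everywhere. Because swaps preserve the base multiset exactly, block
GC statistics are untouched. Planted islands are 500–1500 bp i.i.d.
segments at GC 0.62–0.75 (o/e ≈ 1), recorded as ground truth. An optional
16 kb uniform `chrM` contig supports mitochondrial-fraction reporting
without modelling organelle biology.

**Landscape and genes.** Accessible regions (default 250–1000 bp) are
placed uniformly without overlap; intensity = 1 + LogNormal(ln 10, 1.5), a
median ≈ 11× enrichment with a heavy tail to ~100×, the shape typical of
accessibility hotspot intensity distributions. A configurable fraction of
regions (default 0.5) spawn a gene whose TSS lies inside the region;
expression is `coupling · intensity · exp(ε)`, ε ~ Normal(0, 0.5), and an
equal number of silent genes (0 transcripts) is placed in unplanted
sequence.

**Digestion.** Per fragment, the first cut position is drawn with
probability ∝ landscape rate × enzyme base weight at the cut base; the
second cut is drawn the same way from positions giving a fragment length in
[100, 500] bp (the size-selection window). Base weights are always read on
the strand being cut (reverse complement for minus). A fair coin picks
which fragment end is sequenced; one 36 bp tag is emitted with its 5′ end
at the chosen cut. A Bernoulli `mito_fraction` share of fragments is drawn
uniformly from `chrM` instead. Enzyme presets encode only the
experimentally established *direction* of preference — Benzonase/Cyanase
G/C-skewed (A .15, C .30, G .40, T .15), DNase I T-skewed (A .20, C .15,
G .15, T .50) — with invented magnitudes, fully configurable.

**What the simulator does not emulate**, and hence what passing tests do
not show about real data: positional (multi-offset) cleavage preference
matrices, sequencing error, mappability structure, nucleosome-scale
footprints, paired-end fragments, replicate batch effects, and chromatin
higher-order structure. Tests demonstrate the *pipeline's* correctness and
the qualitative phenomena (bias recovery, GC partitioning,
expression coupling), not quantitative agreement with any tissue.

## Study-scale scenarios

Acceptance-level checks run at desk scale, chosen to keep full runs within
minutes on one CPU while preserving the regimes of interest:

- *Recovery/robustness*: 10 Mb genome, 200 regions, 10⁶ fragments, uniform
  bias. Planted-region sensitivity is scored on the top intensity half,
  precision over all called hotspots; depth robustness compares libraries
  4× apart in depth on union-set log densities.
- *Cross-enzyme comparison*: mixed-GC genome, 300 regions, 2×10⁵ fragments
  per enzyme. The lower depth places the detection limit mid-way through
  the intensity distribution, so enzyme-unique hotspot classes are
  populated — the partial-overlap regime in which GC partitioning and
  quartile-uniqueness gradients are meaningful. At saturating depth both
  enzymes recover essentially all regions and the unique classes vanish.
- *Expression coupling*: 10 Mb, 400 regions (200 expressed + 200 silent
  genes) digested by the two G/C-preferring presets; occupancy is scored
  against either hotspot set and TSS density on the pooled tags, mirroring
  how multi-enzyme digests are combined in practice.

## Determinism

All randomness flows through numpy PCG64 generators seeded explicitly. The
pipeline expands a single global seed into per-stage seeds by a documented
rule (`seed·1000 + stage_id·10 + index`), so stages can be re-run in
isolation; a re-run from the same config reproduces every output file byte
for byte (verified by checksum in the test suite). Manifests contain no
timestamps.

## Known limitations

- The scan assumes tags are independent; PCR duplicates inflate z.
- Hotspot boundaries are window-resolution (step 50 bp) before trimming;
  single-base footprinting is out of scope.
- The FDR-0 rule is conservative by construction (max of N randomizations)
  and its threshold is a random variable of the randomization seed.
- `union_merge` chains overlapping intervals transitively; very dense
  hotspot sets can merge into long union intervals.
- The gene table importer is deliberately minimal; GTF/GFF ingestion and
  BAM parsing are non-goals (convert upstream).
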
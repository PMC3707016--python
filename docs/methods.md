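# Methods notes

This note records the model assumptions, parameter choices, numerical
decisions and known limitations of plasmacnv, in the spirit of a methods
supplement. It states nothing that the test suite or
`scripts/acceptance.py` does not itself compute.

## Reference windows and mappability

A position is *mappable* when the read-length k-mer starting there occurs
exactly once in the genome, counting occurrences on both strands; any k-mer
containing N is unmappable. This exact-uniqueness definition approximates an
aligner-based mappability track; it is slightly stricter (an aligner may
rescue a read with mismatches) and can be switched to forward-strand-only
counting. The implementation uses two independent polynomial rolling hashes
combined into one 64-bit key (collision probability ≈ 1e-6 over a few
million k-mers); a brute-force all-k-mers dictionary oracle verifies it in
the tests on genomes up to ~50 kb. Multi-megabase genomes stream
per-chromosome in tens of MB; a full human genome is feasible but takes
hours and is not needed for the desk-scale validation.

Windows partition the mappable positions in genomic order into equal counts
of floor(total/n) or floor(total/n)+1, with the +1 windows placed last.
Windows never cross chromosome boundaries: each chromosome receives a window
count for which its mappable total decomposes exactly into base/base+1 sized
windows. Such a decomposition exists for almost all genome/window-count
combinations; when a chromosome's total falls in an arithmetic gap (e.g.
1.99 × the base size) no exact decomposition exists *for any* allocation, in
which case that chromosome gets its proportional share of windows split as
evenly as possible and a warning is emitted. Equal counts (±1) are therefore
guaranteed within every chromosome, and globally whenever boundary
arithmetic permits — the test suite checks both. PAR intervals are supplied
as a BED file; no genome-build constants are hard-coded.

## Counting and normalization

Reads are assigned to the window containing their leftmost aligned base;
unmapped, duplicate and secondary/supplementary records are dropped, with a
configurable mapping-quality floor (default 0, since shallow whole-genome
runs are typically counted without one). Total-count normalization uses
reads falling in windows; reads outside any window count toward
`total_reads` only.

GC correction divides the mean-normalized count by a LOWESS fit of count on
window GC fraction — a multiplicative bias model, which matches how library
amplification distorts coverage. LOWESS uses span 0.3 with one robustifying
iteration (statsmodels); the span matters little on smooth synthetic bias
but should be widened if real data have few windows at extreme GC. Ratios
are rescaled to mean exactly 1; windows with missing GC or a non-positive
fitted bias are flagged missing and propagate as NaN.

Control baselines are sex-matched (X/Y windows are dose-dependent) and
require ≥ 2 controls; z-statistics require ≥ 3.

## Segmentation

CBS maximizes the two-sample t statistic between an arc [i, j) and its
complement; scanning all i < j covers circular arcs because a wrap-around
arc is the complement of a linear one with the same |T|. Perfect steps have
zero within-group variance; T is capped at a large sentinel (1e6) so they
rank above any finite statistic and receive the minimal permutation p-value.
Ties in the arc scan resolve to the smallest i, then smallest j — note a
perfect two-level step therefore reports the left piece as the arc; the
implied change point is identical.

Significance is assessed by permutation, p = (1 + #{max |T| ≥ |T_obs|}) /
(n_perm + 1), default 10,000 permutations at α = 0.01. Inside the recursion
the permutation loop stops early once the exceedance count proves p > α
(the accept/reject decision is unchanged; only the reported p is then an
estimate from the permutations seen). Accepted splits recurse into
[0, i), [i, j), [j, n). No post-hoc undo/merge step is applied. Missing
windows are skipped in the statistics but retained in segment coordinates
(a missing run between two pieces joins the segment on its left, so segments
tile each chromosome). Per-chromosome RNG streams are derived from the seed
and a chromosome-name CRC, making output independent of iteration order.

Only CBS is implemented; consensus segmentation across multiple segmenters
is out of scope, and CBS segments are what the segmental z-scores consume.

## z-scores

1-Mbp z windows aggregate the equal-mappability windows whose midpoints fall
in each bin (mean of member ratios); the bin size is configurable, and the
desk-scale experiments use smaller bins scaled to their synthetic genomes.
Cross-validation is mandatory whenever a control is scored against its own
cohort: under the null the leave-one-out z follows √(n/(n−1))·t with n−2
degrees of freedom, which the tests verify by Kolmogorov–Smirnov.
`length_genome` for region z-scores is the total span of the window grid
(the mappable-spanned genome), not the raw assembly size.

The genome-wide score standardizes S = Σ z² against the cross-validated
control S values. Because leave-one-out z-scores have slightly higher
variance than held-out ones, a held-out sample's expected genome-wide z is
slightly negative when the cohort is small; with the 100-control simulated
cohorts used in the calibration experiments the gap is negligible
(variance 1.0312 vs 1.0308). With a 10-member cohort the statistical noise
of the 10 control S values alone moves the held-out mean by ~±0.3, so the
null-calibration and ROC experiments use 100-control cohorts; this also
mirrors the conservatism noted for cross-validated controls (the ROC is, if
anything, underestimated).

Clustering uses Manhattan distance (the sum of per-window |Δz|) with
complete linkage by default (average/single available); missing windows are
dropped pairwise with a warning. Dendrograms export to Newick with
height-difference branch lengths.

## Simulation engine

Controls are drawn per window from Normal(mean, SD) truncated at 0 (ratios
cannot be negative; truncation is negligible at realistic SDs). Cases
multiply the mean by the diluted ratio 1 − λ + λ·ratio. Baseline noise is
calibrated to 3 million reads — the throughput used for a plasma sample on a
benchtop instrument — giving per-window SD √(m/3·10⁶) for m windows
(≈ 1.2 % at the desk-scale m = 400); an overdispersion multiplier is
available for mimicking extra technical variance. The ROC operating point is
the Youden maximum with ties resolved toward specificity.

Synthetic tumor profiles: the prostate-like generator plants a jittered
arm-level loss (8p-like), arm-level gain (8q-like), focal amplification
(AR-like) and a focal 3-Mbp-scale deletion; the "aggressive" cell-line-like
profile has ~50 % of the genome altered including high-amplitude events
(ratio 3 amplifications, near-homozygous losses), as grossly aneuploid
cancer cell lines do. With counting-calibrated noise the 1 % dilution of
that profile yields mean genome-wide z ≈ 7 against a control maximum ≈ 2.7
(computed by `scripts/acceptance.py`).

What the generator does **not** emulate: cfDNA fragment-length biology,
sequencing error, mappability artifacts correlated with GC, inter-individual
copy-number polymorphism, and the broader dispersion of real plasma
libraries. Passing the desk-scale battery therefore demonstrates the
statistical machinery is correct and calibrated under its stated noise
model, not that real-plasma sensitivity will match it; real detection limits
depend on the empirical control SDs.

## Fixture generator

Random A/C/G/T genomes (unique at 150-mers with overwhelming probability at
these sizes) with a maskable PAR-like interval; reads are sampled from
mappable positions with weights proportional to the diluted copy ratio times
a smooth linear GC efficiency (default ±0.6 % per 0.5 GC percentage point,
the magnitude of typical library bias) and written as SAM. Fusion-spanning
reads are drawn across the fused sequence with ≥ 60 bp on each side so both
split halves anchor, in both orientations, and emitted as FASTQ alongside
concordant background reads; the truth JSON stores the leftmost-normalized
junction and its microhomology length.

## Split-read mapping

Only split reads are used: plasma DNA fragments are too short for insert-size
(read-pair) inference. The built-in aligner is exact-seed (k = 20, seeds at
offsets 0/20/40) plus ungapped extension on both strands, unique best hit →
mapq 60, ties → mapq 0; it requires ≥ 90 % identity and is intended for the
synthetic references — real data should come pre-aligned as SAM of the read
halves. Filters: mapq < 25 (so any ambiguous half) and an optional repeat
BED. Same-chromosome, same-strand pairs with implied gap in [0, 1000] bp are
concordant; the 1 kb discordance threshold is this package's choice.
Junction refinement scans every split position of the full read between the
two anchored loci, maximizing total matched bases with ≥ 90 % identity per
side (also a package choice); tying splits are microhomology, resolved to
the leftmost coordinate, with the tie count minus one reported as the
microhomology length. A refined junction joining adjacent reference bases is
a contiguous alignment and is rejected. Calls cluster within 10 bp; support
is the cluster size.

## Desk-scale problem sizes

The validation experiments use 400 z-windows, 100-control cohorts, 500
held-out null samples, 20 tumor profiles per ROC arm, 300-window CBS
profiles with 500–1000 permutations, 20 planted junctions and 10,000
concordant reads for fusion specificity. These sizes give stable pass/fail
margins (binomial SEs well inside the asserted tolerances) while the whole
battery completes in about a minute.

## Known limitations

- Exact k-mer uniqueness understates mappability relative to a
  mismatch-tolerant aligner; full-genome tracks are computable but slow.
- The CLI's region z mode requires per-region read counts via the library;
  the CLI itself operates on window-level tables.
- The built-in fusion aligner is ungapped and exact-seeded: junctions inside
  repeats or with indels near the breakpoint need an external aligner.
- Genome-wide z values between cohorts of different sizes are not directly
  comparable (the S baseline is cohort-specific).
- Tumor-fraction estimation from allele fractions is out of scope.
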
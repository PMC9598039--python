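# Methods

## The screen and its readout

A pooled competitive-growth (dropout) screen measures per-construct fitness
effects by sequencing construct abundances before and after a growth window.
The design modeled here: a library of several hundred target genes with 4–7
inducible knockdown constructs each, partitioned into pools of ~300
constructs; two biological replicates from independent transductions; three
arms per screen (Day0; Day14 untreated; Day14 + Dox); and four spiked-in
controls per pool — two stability controls targeting transcripts absent from
the cells (Renilla/firefly luciferase) and two depletion controls targeting
the essential replication factor Rpa3.

## Simulator

The generator states the screen world explicitly; its defaults are the
design's stated conditions, and the remaining free parameters were fixed
once on realism grounds:

- **Day0 clone abundances**: `a_i ~ representation × LogNormal(0, σ)` with
  `representation = 1000` cells/construct (the screens' stated coverage) and
  `σ = 0.5` (moderate clone-size inequality after transduction and
  selection; the screens do not report the empirical distribution, so this
  is a stand-in, exposed as `baseline_dispersion`). Replicates redraw
  abundances independently — independent transductions — but share the
  per-construct effect `e_i`.
- **Growth law**: effects are total log2 fold-changes over the 14-day
  window; Day14 abundance is `a_i · 2^(e_i·k)` with `k = 1` under Dox,
  `k = λ` (promoter leakiness ∈ [0,1]) untreated, `k = 0` at Day0. This is
  the simplest parameterization consistent with a single-interval readout;
  per-day rates would be indistinguishable here.
- **Sequencing**: each sample is one multinomial draw of `depth` reads over
  its pool's relative abundances. `depth` defaults to 10⁶ reads/sample
  (the screens' stated theoretical depth per initial sample). An optional
  Dirichlet-multinomial `overdispersion` concentration adds biological
  replicate noise for stress tests; the default is pure multinomial.
- **Controls**: depletion controls carry `e = −6` log2 (a strong essential-
  gene knockout phenotype, consistent with their near-complete dropout in
  real screens); stability controls are exactly neutral.
- **Reads**: inline 10-nt sample barcode + constant miR-30 5′ flank + 22-nt
  guide + loop flank, constant quality. Barcodes are drawn with pairwise
  Hamming distance ≥ 3 so one-mismatch demultiplexing stays unambiguous.

What the generator does **not** emulate: PCR jackpotting and amplification
bias, stage-wise genetic drift during the 14 days (drift enters only through
the terminal multinomial), cell-cycle or selection effects, pool
cross-contamination, and sequencing error in the reads themselves. A green
recovery test therefore establishes that the statistics behave correctly
under the stated stochastic model — not that they are robust to every
artifact of real screens.

The original full-scale design reports ~4,800 constructs (≈300/pool) for
658 genes at 4–7 constructs each; those two figures are mutually
inconsistent (658 × 7 < 4,800), so the generator follows the 4–7-per-gene
rule with uniform counts, giving ~3,600 constructs (~230/pool). Pool assignment is greedy
largest-gene-first, keeping pool sizes within one gene of each other, with
all of a gene's constructs in one pool.

## Demultiplexing

Reads are fixed-layout amplicons, so matching is Hamming-only at fixed
offsets: no indel handling, no alignment search. The design is refused up
front if any barcode (or guide) pair is within twice the respective mismatch
tolerance; within that precondition every in-tolerance match is unique, so
matching uses exact lookup tables over Hamming balls. Reads are never
fractionally assigned: short reads and unresolvable barcodes count as
unassigned, resolvable barcodes with unknown or wrong-pool guides as
unmatched; the four tally categories always sum to the number of reads
processed.

## Normalization and trimming

Normalization is strictly within (pool, sample): `log2(count/total × scale +
pseudocount)` with `scale = 10⁶` and `pseudocount = 1`. Adding the
pseudocount **after** scaling makes the transform exactly invariant to
per-sample depth rescaling. Trimming masks rather than deletes: constructs
with raw Day0 count < 30 in a replicate are masked across that (pool,
replicate), and any day-14 cell whose |log2 change vs Day0| exceeds 8 is
masked individually. The two thresholds are stand-ins for unpublished
upstream criteria and are configuration keys; masked cells propagate as
missing values into scoring and trigger its fallbacks.

## Scoring

Per construct and replicate, `FGR = value(Day14Dox) − value(Day14)` and
`BGR = value(Day0) − value(Day14)` (log2-scale differences, i.e. ratios of
normalized read counts). When the untreated Day14 observation is masked, the
fallback `FGR = value(Day14Dox) − value(Day0)` is used and flagged, with BGR
missing for that replicate; a replicate without a usable Day14Dox value is
unscored.

The background statistics `medianBGR` and `MAD = 1.4826 ·
median(|BGR − medianBGR|)` are pooled globally over all constructs and both
replicates of a screen (a per-construct MAD over ≤2 values would be
degenerate); spiked-in controls are included by default, with a switch to
exclude them. `SSMD* = (FGR − medianBGR)/(√2·MAD)`; the alternative
left-to-right reading `(FGR − medianBGR)/MAD·√2` is exactly 2× larger and is
available as `convention="multiply"`. Because the SD cutoff is computed from
the same scores, the two conventions produce identical hit sets — tested.
`AvSSMD*` is the mean of the available replicate scores (one suffices);
`AvSSMD*/Protease` is the unweighted mean over a gene's scored constructs.
No further transform is applied to the score itself.

Degenerate inputs are hard errors rather than silent zeros: no finite BGR,
MAD = 0 (advising a look at trimming/depth), SD from fewer than 2 scores,
and hit calling with a non-positive cutoff.

## Hit selection

`SD_AvSSMD*` is the sample standard deviation (n−1) of all constructs'
AvSSMD*. A gene's `frequency` counts constructs with |AvSSMD*| **strictly**
greater than 1 SD, outliers of either sign counting; a first-filter hit
needs frequency ≥ 2. Direction comes from the sign of the gene-level score.
The expression filter retains a gene only when its expression is strictly
above threshold in **every** configured cell-line table; a gene absent from
a table fails (absence of evidence of expression is treated as
insufficient expression). Cross-screen classes: *depletion* (negative gene
score wherever hit), *mixed* (negative in ≥1 screen, positive in ≥1), and
*enrichment-only*, which is flagged and excluded from the final reported
list — the exclusion is applied at the reporting stage, not at the first
filter. Heatmap rows are ordered by minimum score across screens, then gene
name, with non-hit cells marked `ns`.

## Numerical and design choices

- All tables are pandas frames written as TSV with a fixed float format, so
  reruns under one seed are byte-identical end to end.
- The simulator draws baseline abundances before any arm-level sampling, so
  changing the effect map does not perturb the baseline stream.
- The leakiness acceptance check runs with Dirichlet-multinomial
  overdispersion (concentration 500, ≈1 log2-unit replicate noise). Under
  pure multinomial noise at 3×10⁶ reads the background is so tight that
  e = −6 controls sit far below −1 SD at every λ ≤ 0.5 and the predicted
  monotone degradation is invisible; the overdispersed regime matches the
  between-replicate correlations real screens report (R ≈ 0.6–0.8).
- Statistical helpers come from scipy (Pearson correlation, binomial
  quantiles in tests); the SSMD*/AvSSMD* statistic, normalization, trimming
  and filters are implemented here, and the test suite checks them against
  an independent brute-force loop implementation to 1e-9.

## Limitations

- Under the default noise model the MAD is sequencing-noise only, so scores
  are much larger in magnitude than in published screens (SD_AvSSMD* there:
  ~3–6); comparisons should be made on hit sets and ranks, not raw score
  magnitudes.
- Hamming-only matching cannot recover reads with indels or barcode
  truncations.
- The per-gene aggregate is an unweighted mean; no moderated-variance or
  rank-based gene statistics are provided.
- Venn/region accounting assumes hit tables indexed by a shared gene
  namespace; no symbol harmonization is attempted.
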
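# Methods

## Model

The TET-OFF design stops synthesis of the tagged histone at t = 0, so
the tagged, chromatin-bound population at a locus can only shrink as
incorporated histones dissociate. Assuming a first-order exit process
with locus-specific rate λ (h⁻¹),

    N(t) = N(0) · exp(−λ t),

two timepoints identify the rate. All rate estimation in this package
uses the 0 h → 6 h pair: at 6 h the signal change is already
informative for fast loci while slow loci still retain most of their
signal, and a two-point estimator avoids the regression pathologies of
induction time courses where signal first rises and then falls.

Three per-window quantities are computed on the enriched universe:

* **λ_raw** `= ln((n0+ε)/(n6+ε))/dt`, the raw decay rate in h⁻¹. It may
  be negative when a window gains signal (residual incorporation or
  sampling noise outweighing loss over the interval).
* **λ′out** `= (n0+ε)/((n0+ε)+(n6+ε))`, the dissociation rate scaled to
  [0, 1]. Algebraically this is the logistic of the log count ratio,
  `1/(1+exp(−λ_raw·dt))`: 0.5 means no net change, values above 0.5 net
  loss, 1 complete dissociation. The bounded scale makes windows with
  very different coverage comparable and is the quantity used in all
  profiles, heatmaps and correlations.
* **λ_equ** `= log2((n0+ε)/(i0+ε))`, the equilibrium level: tagged-H3.3
  enrichment over input DNA at 0 h, on a log2 scale (a linear-ratio
  output is available via `log2=False`).

The scaled form was chosen among monotone [0, 1] maps because it is the
logistic of the measured log ratio, reduces to 0.5 at equilibrium, and
needs no tuning constant; it is an interpretation, and `lambda_raw` is
always emitted alongside so nothing is lost.

## Signal extraction

* **Read extension.** Single-end reads carry only a 5′ position; each
  read is extended 150 bp (one nucleosome footprint) from its 5′ end,
  plus strand `[p, p+150)`, minus strand `[p−149, p+1)`, clipped at
  chromosome ends. The floor midpoint of the extension is the dyad — the
  inferred nucleosome centre — and is the counting unit everywhere.
* **Window grids.** Windows tile every chromosome from coordinate 0;
  the last partial window is kept. Counting and filtering default to
  non-overlapping 250 bp windows. Rate tracks are re-expressed in 10-bp
  windows on request by assigning each fine window the value of the
  coarse window containing its midpoint. Promoter-resolution profiles
  use sliding windows (width 50 bp, step 10 bp); overlap then provides
  the smoothing, so the low-pass filter is skipped on sliding grids.
* **Low-pass filter.** Each 250-bp window is replaced by the weighted
  average of itself (weight 1) and its two neighbours (weight 0.5 each),
  divided by the sum of in-bounds weights — 2 in the interior, 1.5 at
  chromosome edges, 1 for a single-window chromosome. Dividing by the
  weight sum preserves constant tracks and the genome-wide total on
  interior windows; the edge divisor avoids attenuating terminal
  windows.
* **Enrichment masking.** Rates are only meaningful where tagged H3.3 is
  actually present at 0 h. A window enters the analysis universe when
  the exact Poisson upper-tail probability of its ChIP count, given the
  library-size-scaled input count (floored at a 0.5 pseudocount),
  survives Benjamini–Hochberg control at α = 0.05 **and** the
  normalized fold change is ≥ 2. The test, α and fold threshold are
  package choices — a minimal standard count-enrichment model — and all
  three are configurable. Windows outside the mask carry NaN through
  every downstream stage.
* **Depth normalization.** Libraries are scaled to a common depth before
  any ratio; the default target is the mean of the two ChIP library
  sizes, which keeps values on the raw count scale so the ε = 0.5
  pseudocount retains its Haldane–Anscombe meaning. Normalization
  between timepoint libraries is required for the ratio to estimate the
  rate rather than the depth difference.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `window` | 250 | bp | counting/rate resolution |
| `resample` | 10 | bp | fine-grid re-expression of rate tracks |
| `extension` | 150 | bp | nucleosome footprint |
| `dt` | 6 | h | decay interval (0 h → 6 h) |
| `eps` | 0.5 | counts | pseudocount guarding empty windows |
| `alpha` | 0.05 | — | BH-FDR level of the enrichment mask |
| `min_fold` | 2 | — | minimum normalized ChIP/input fold |
| proximity cutoff | 5000 | bp | proximal/distal site split (inclusive) |
| genic cutoff | 2000 | bp | genic/non-genic repeat split (inclusive) |

Distance between half-open intervals is the gap in bp; overlapping or
book-ended intervals have distance 0, and cutoffs are inclusive
("within 5 kbp" reads as ≤ 5000). Expression bins use upper-inclusive
boundaries — (30,∞) top10, (10,30] top20, (3,10] medium, (1,3] low,
[0,1] silent — so the verbal FPKM ranges tile [0,∞) without gaps.

## Profiles and summaries

Metaprofiles average a track in bins around point anchors (TSS, TES,
peak or site midpoints). Bin cells average the finite track windows
whose midpoints fall in the bin; with `oriented=True` rows of
minus-strand anchors are reversed so positive offsets always point
downstream of transcription. Bins with no underlying finite windows are
missing, and per-bin support (`n`) is reported; peak localization
ignores bins supported by fewer than 20 % of the best bin's anchors,
because on sparse enriched universes a bin fed by a single anchor is
dominated by sampling extremes. Region summaries pool all windows within
±flank of each site midpoint per feature set (fixed-flank convention;
±5 kb default, i.e. a 10-kb region per site).

Standardization to mean 0, variance 1 (population convention) is
applied when tracks of different dynamic range are overlaid; constant
tracks are rejected rather than silently zeroed.

## The synthetic generator

The generator emulates the study conditions so every stage can be
validated by parameter recovery:

* **Archetypes.** Gene cassettes carry a 50-bp NDR locus occupying
  exactly the band 50–100 bp upstream of the TSS, flanked by promoter
  chromatin (250-bp "tss_flank" loci on both sides — the −1/+1
  nucleosome territory), and a gene-body locus; standalone loci provide
  heterochromatin, distal sites, satellite repeats and low-signal
  background. Default decay ranges order the regimes as observed in
  pluripotent chromatin: ndr λ ∈ [0.2, 0.5] > distal [0.15, 0.35] >
  tss_flank [0.1, 0.25] > gene body [0.02, 0.08] > heterochromatin
  [0, 0.02] h⁻¹. Occupancies couple positively with rates (active
  chromatin: high occupancy, fast exchange), which is what makes the
  simulated rate-vs-equilibrium correlation positive; flattening the
  ranges removes the correlation, and a test asserts both directions.
* **Reads.** Per locus and timepoint, counts are Poisson with mean
  `occupancy0 · depth · exp(−λ t)`. Dyads are uniform within the locus;
  the read 5′ end is derived from the dyad (plus strand dyad−75, minus
  strand dyad+74) so that the standard 150-bp extension recovers the
  dyad inside the locus — the geometry nucleosome-footprint ChIP
  produces. Input libraries are uniform over the genome at 0.02 reads/bp.
  Each (timepoint, replicate) library and each input library draws from
  its own sub-seed spawned deterministically from the master seed, so a
  run is byte-reproducible and replicates are independent.
* **Annotation extras.** Transcripts carry strand, exons and lognormal
  FPKM values for expression stratification; non-satellite repeats are
  placed partly inside gene spans (genic) and partly intergenic; TF peak
  sets bind satellites, other repeats and distal sites with per-factor
  probabilities whose three-factor union reproduces bound fractions of
  ~32 % (non-genic satellites) and ~19 % (other repeats).
* **What it does not emulate.** Sequencing errors, PCR duplicates,
  mappability, chromatin-accessibility bias in the input, fragment-size
  variation, and any within-locus structure beyond uniform dyads.
  Passing recovery tests therefore demonstrates correctness of the
  estimators under the stated noise model, not robustness to every
  artifact of real libraries. The default genome (two chromosomes,
  1 Mb total, ~260 loci, ~40 genes) is sized for second-scale runs;
  all counts and ranges are `GeneratorParams` fields.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open (BED dialect) everywhere.
* ε > 0 guards all logs and ratios; λ′out is well defined even for
  empty windows (0.5, no evidence of change).
* Tracks with zero library size cannot be normalized (error, not NaN).
* Pearson correlation requires ≥ 3 finite pairs and non-constant
  inputs (exact max == min test, robust to float round-off); the
  chi-squared test requires positive margins and applies no continuity
  correction. p-values are reported to float underflow and printed as
  `<1e-300` below that.
* Capacity overflow in the generator (more loci than the genome holds)
  raises an explicit error rather than silently truncating.

## Known limitations

* Rates are two-point estimates; multi-timepoint regression over
  {6, 12, 24, 48} h is out of scope by design, as is estimation of
  incorporation rates from the TET-ON arm (an optional second mask
  input is the only TET-ON hook).
* The enrichment caller is a single-window Poisson test, not a peak
  caller; broad-domain detection and duplicate/mappability corrections
  belong upstream.
* The replicate-concordance universe is the intersection of the
  replicates' enriched windows; union or single-replicate universes
  would give slightly different correlation magnitudes.
* Whether rates should be computed on filtered or raw counts is an open
  choice; the default filters first, and `apply_filter=False`
  (`--no-filter`) switches to raw counts.
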
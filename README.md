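# h3turnover

Genome-wide estimation of histone **H3.3 dissociation rates** and
**equilibrium levels** from TET-OFF tagged-histone ChIP-seq time courses.

## The problem

The histone variant H3.3 is deposited independently of replication at
promoters, enhancers and some heterochromatic sites. In a TET-OFF design,
doxycycline shuts off synthesis of an epitope-tagged H3.3, so the
chromatin-bound tagged signal at every locus decays as previously
incorporated histones dissociate. ChIP-seq snapshots at 0 h and 6 h after
shut-off therefore measure, locus by locus, how fast nucleosomes turn
over. This package turns aligned read positions into per-window decay
rates and asks the downstream questions a chromatin biologist cares
about: where does H3.3 exchange fastest (promoter NDRs, distal regulatory
sites) and slowest (gene bodies, heterochromatin), how does turnover
track transcription, and which repeat elements with fast turnover are
bound by pluripotency factors.

## The model

Reads are extended to the 150 bp nucleosome footprint from their 5′ end;
the floor midpoint of the extension is the **dyad**, counted in fixed
windows (250 bp by default) and smoothed with a weighted three-window
low-pass filter (center weight 1, neighbours 0.5, divided by the
in-bounds weight sum). Windows significantly enriched over input DNA at
0 h (exact Poisson upper tail, Benjamini–Hochberg at 0.05, fold ≥ 2)
form the analysis universe.

With tagged-histone synthesis off, occupancy decays exponentially,
N(t) = N(0)·e^(−λt), so with dt = 6 h and pseudocount ε = 0.5:

    λ_raw = ln((N(0)+ε) / (N(6)+ε)) / dt                 (h⁻¹)
    λ′out = (N(0)+ε) / ((N(0)+ε) + (N(6)+ε))             ∈ [0, 1]
    λ_equ = log2((N(0)+ε) / (I(0)+ε))                    (ChIP/input at 0 h)

λ′out is exactly the logistic 1/(1+e^(−λ_raw·dt)): 0.5 means no net
change, 1 complete dissociation, below 0.5 net gain.

A **synthetic-data generator** lays out a small genome of archetype loci
(promoter NDRs, TSS flanks, gene bodies, heterochromatin, distal sites,
satellite repeats, background) with known per-locus decay rates, draws
Poisson read libraries per timepoint, and keeps the ground truth, so the
whole pipeline is verified end to end by parameter recovery.

## Worked example

```python
from h3turnover import TurnoverModel, build_annotation, simulate_reads

annotation, truth = build_annotation(seed=1)            # synthetic genome
reads = simulate_reads(truth, annotation.chroms, timepoints=(0, 6), seed=1)
model = TurnoverModel.from_reads(reads.library(0), reads.library(6),
                                 reads.input[0], annotation.chroms, window=250)
results = model.fit()
print(results.summary())
```

```
H3.3 turnover model results
===========================
windows (grid 250 bp):      4000
enriched windows (universe): 352
dt = 6.0 h, eps = 0.5, low-pass filter = True

                      mean    median        sd
lambda_out          0.4940    0.5177    0.1398
lambda_raw         -0.0046    0.0118    0.0986
lambda_equ          2.6545    2.5404    1.1435
```

352 of 4,000 windows pass the 0-h enrichment mask; over that universe
the mean scaled dissociation rate is ~0.49 (the synthetic genome mixes
fast NDR/distal loci with slow heterochromatin, so the mean sits near
the no-net-change point 0.5) and the mean equilibrium level is ~2.7,
i.e. ~6.3-fold ChIP enrichment over input. `results.to_frame()` gives
the per-window table, `results.resample(10)` re-expresses rates in
10-bp windows, and `results.plot_rate_vs_equilibrium()` draws the
rate-vs-equilibrium density.

The full pipeline (replicates, classification, profiles, statistics)
runs from the shell:

```sh
h3turnover run --out demo_out --seed 1
```

```
pipeline complete -> demo_out
  replicate_pcc: 0.9014222364625566
  rate_vs_equilibrium_pcc: 0.601417777983262
  truth_spearman: 0.9450483190420843
  satellite_bound_fraction: 0.36666666666666664
  n_enriched_windows: 365
```

Here the two simulated replicates agree at Pearson r ≈ 0.90 in 10-bp
windows, dissociation rates correlate positively with equilibrium levels
(r ≈ 0.60, as expected when active chromatin couples high occupancy with
fast exchange), and the estimated rates rank-correlate with the
generator's true rates at Spearman ρ ≈ 0.95. `demo_out/` contains
bedGraph rate tracks, the per-window table, TSS metaprofiles, the
archetype region-summary matrix, repeat-binding fractions and a JSON
manifest. `h3turnover simulate|count|enrich|rates|classify|profile`
expose the individual stages on BED/bedGraph files.

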
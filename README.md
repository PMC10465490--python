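# barcodewga

Analysis toolkit for **barcoded whole-genome-amplification (barcoded-MDA)
sequencing** of single cells and spatial tumor microniches.

Pooling MDA products before library preparation — by tagging each cell's
amplicons with a 5′ DNA barcode on a fraction of the random-hexamer primers
— reduces N per-sample library preparations to ⌈N / plex⌉ one-pot reactions.
The price is a set of computational problems this package solves end to end,
on real tables or on built-in synthetic data with known truth:

* **Barcode design** — greedy lexicographic selection of fixed-length codes
  with pairwise Hamming distance ≥ d (correcting ⌊(d−1)/2⌋ sequencing
  errors), homopolymer and GC filters.
* **Demultiplexing** — nearest-barcode assignment of the read-2 prefix with
  a configurable mismatch radius, barcoding-status QC, and a two-species
  barcode-swap assessment (a 47:1 barcode split implies a 47:1 asymmetry in
  observed swap rates under uniform swapping).
* **Barcode-bias correction** — read count ∝ efficiency × primer
  concentration, so one observe-and-rebalance cycle
  (cᵢ′ ∝ cᵢ · mean(obs)/obsᵢ, totals conserved) inverts the bias; the CV of
  per-barcode counts converges to the measurement-noise floor.
* **Copy-number analysis** — variable-size bins with equal expected read
  weight, LOWESS GC correction scaled to a diploid mean of 2, circular
  binary segmentation (α = 10⁻¹⁰, min width 5, undo.SD 0.8), MergeLevels-
  style rank-test consolidation (threshold 0.1), Lorenz-curve AUC as the
  amplification-uniformity score.
* **Consensus SNV calling** — a site is confident when ≥ 2 callers support
  it in each of ≥ 2 samples (coincident false positives ≈ FPR² ≈ 10⁻¹⁰);
  per sample a missed site is rescued when its alternate-allele count beats
  the largest other non-reference count (one-sided Fisher exact, p < 10⁻³).
  Allelic-dropout rate (coverage ≥ 10) and per-base false-positive rate
  (bulk coverage ≥ 20) estimators included.
* **Phylogeny & space** — 1/NA/0 variant matrix (NA iff coverage < 5 and
  not detected), NA-rescaled Manhattan distances, balanced-minimum-
  evolution tree (NJ + NNI under Pauplin's length) rooted at an artificial
  diploid taxon, mutation-profile PCA, Moran's I over k-NN spatial weights,
  and majority-vote consolidation of mutations per subclone.
* **SV & kataegis** — breakpoint clustering within 1 kb, two-tier filtering
  (trusted-caller multi-sample tier; all-caller bulk-supported tier, low-MQ
  regions removed), SNV filtering (≥ 6 samples, > 20 supporting reads), and
  kataegis as runs of ≥ 6 mutations with inter-mutation distance ≤ 1 kb.

## Worked example

```python
from barcodewga import design_barcodes, BarcodeConstraints, multiplex_cost
from barcodewga.pipeline import run_pipeline

print(len(design_barcodes(BarcodeConstraints())))   # 110 barcodes
print(multiplex_cost(720, 48))                      # 15 tubes

summary = run_pipeline(seed=1)   # full synthetic experiment, ~3 s
```

`run_pipeline` simulates 12 microniches (4 subclones × 3) on a two-
chromosome 20-Mb genome and runs every stage. With seed 1 it prints:

```
n_cna_segments     : 3        # truncal chr2 loss found in microniche s01
lorenz_auc         : 0.3973   # MDA overdispersion sigma=0.3 pushes it below 0.5
n_confident_sites  : 408      # of 428 truth sites shared by >=2 samples
moran_pc1          : 0.491    # subclones form spatial patches -> strong autocorrelation
moran_pc2          : 0.11
n_sv_clusters      : 10       # exactly the 10 simulated truth SVs
n_kataegis_events  : 1        # the planted truncal cluster
```

and `summary["newick"]` is the rooted tree, which reproduces the generating
clonal hierarchy exactly (Robinson–Foulds distance 0).

A CLI mirrors the library (`barcodewga design-barcodes | demux | balance |
simulate | cna | lorenz | snv-consensus | metrics | phylo | moran |
sv-merge | kataegis | run-all`); every subcommand writes a JSON run
manifest next to its outputs.

## Layout

```
src/barcodewga/
  barcodes.py   barcode design and validation
  demux.py      read demultiplexing, swap assessment, multiplexing cost
  bias.py       bias model, CV, primer-mix rebalancing, depth estimator
  cna.py        binning, GC-LOWESS, CBS, MergeLevels, Lorenz, concordance
  snv.py        consensus calling, Fisher rescue, ADO/FPR/sensitivity
  phylo.py      variant matrix, distances, BME tree, PCA, Moran's I
  svkat.py      SV clustering and tiers, kataegis, rainfall
  simulate.py   synthetic-data generators with truth bundles
  pipeline.py   end-to-end orchestration
  io.py, cli.py, plots.py
docs/methods.md  model and parameter documentation
```
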
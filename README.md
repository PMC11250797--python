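# prc2ageindex

DNA methylation drifts with age in two opposite directions: a diffuse global
loss across the heterochromatic background, and a focused gain inside a small
set of regulatory islands — low-methylated regions (LMRs) — that are bound by
Polycomb Repressive Complex 2 (PRC2, core subunits EZH2 and SUZ12) in
embryonic stem cells. The **PRC2-AgeIndex** exploits the second signal: it is
simply the average methylation of a sample inside the most PRC2-bound LMRs,

```
PRC2-AgeIndex(sample) = mean beta over CpGs in the top-K PRC2-bound LMRs
```

with beta the per-CpG methylation level (methylated reads / total reads) and
K = 1000 by default. Because it averages many CpGs over biologically defined
regions, the index needs no training, works across tissues, and can be read
out from WGBS, RRBS, methylation arrays, and single-cell bisulfite data.

This package is the full pipeline for computing it, for people who work with
bisulfite methylomes:

- **`io`** — methcounts / bedMethyl / array-beta readers, bedGraph signal
  tracks, BED regions, symmetric CpG-dyad merging, sample pooling.
- **`segment`** — LMR calling with a two-state hidden Markov model over
  consecutive CpGs. Emissions are beta-binomial on the (methylated, total)
  read counts, fitted genome-wide by Baum–Welch EM; chains break at CpG
  deserts (> 1 kb without a CpG); decoding reports maximal runs of CpGs with
  low-state posterior ≥ 0.5 holding ≥ 10 CpGs.
- **`ranking`** — per-region ChIP aggregation (base-length-weighted mean per
  factor, averaged across factors), blacklist filtering, top-K selection
  under fold-change (highest) or p-value (lowest) semantics, and a site-level
  path that ranks individual low-methylated CpGs (LMCs) for assays where
  regions cannot be segmented.
- **`ageindex`** — the index itself (CpG-pooled or region-weighted),
  per-chromosome indices, binding-ranked sliding-window profiles, per-region
  old-minus-young deltas, the hypermethylated fraction, and the share of
  genome-wide methylation gain captured by the set.
- **`stats`** — one-sided independent t-tests between groups, age/passage
  correlation, and sample-QC outlier rules.
- **`simulate`** — a synthetic-data generator that plants LMRs, PRC2 targets,
  age effects, and assay downsampling, so every stage is testable against
  known ground truth.
- **`cli`** — `prc2-ageindex` with subcommands `simulate`, `call-lmrs`,
  `rank`, `rank-lmcs`, `index`, `profile`, `delta`, `gain-share`, `compare`,
  `outliers`.

## Worked example

```python
import prc2ageindex as pai

# plant a 2 Mb toy genome: 10 LMRs, 3 of them PRC2 targets
layout = pai.make_layout(chrom_len=2_000_000, n_lmrs=10, target_fraction=0.3, seed=11)
tracks = pai.simulate_chip_tracks(layout, n_factors=2, seed=31)  # "EZH2", "SUZ12"

young = pai.simulate_methylome(layout, age=20, seed=21)
seg = pai.call_lmrs(young)                        # two-state beta-binomial HMM
print(f"called {len(seg.regions)} LMRs "
      f"(fitted means {seg.params.mu_low:.3f} / {seg.params.mu_high:.3f})")
print(f"base-level Jaccard vs planted: "
      f"{pai.base_jaccard(seg.regions, layout.lmr_regions()):.3f}")

scored = pai.aggregate_binding(seg.regions, tracks)
hp = pai.select_top_k(scored, pai.SelectionConfig(k=3))

for age, seed in [(20, 21), (50, 22), (80, 23)]:
    m = pai.simulate_methylome(layout, age=age, seed=seed)
    res = pai.compute_index(m, hp)
    print(f"age {age:3d}: PRC2-AgeIndex = {res.index:.3f} "
          f"({res.n_cpgs_used} CpGs in {res.n_regions_covered} regions)")
```

prints

```
called 10 LMRs (fitted means 0.074 / 0.830)
base-level Jaccard vs planted: 1.000
age  20: PRC2-AgeIndex = 0.129 (1068 CpGs in 3 regions)
age  50: PRC2-AgeIndex = 0.250 (1068 CpGs in 3 regions)
age  80: PRC2-AgeIndex = 0.376 (1068 CpGs in 3 regions)
```

The segmenter recovers the planted islands exactly (Jaccard 1.0), and the
index rises linearly with age — the planted target gain is 0.004 beta/year
over a baseline of 0.05, so ages 20/50/80 sit near 0.13/0.25/0.37.

The same workflow from the shell:

```sh
prc2-ageindex simulate --ages 20,80 --replicates 3 --seed 7 --outdir sim/
prc2-ageindex call-lmrs --in sim/age20_rep1.meth --out lmrs.bed
prc2-ageindex rank --lmrs lmrs.bed --chip sim/chip_factor1.bedgraph \
    --chip sim/chip_factor2.bedgraph --k 6 --out high_prc2.bed
prc2-ageindex index --meth sim/age20_rep1.meth --meth sim/age80_rep1.meth \
    --set high_prc2.bed --out index.tsv
```

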
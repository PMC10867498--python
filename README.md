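# geminate-clock

Fossil-free molecular-clock calibration from trans-Isthmian geminate
species pairs.

Many soft-bodied marine invertebrates (nudibranchs among them) have
essentially no fossil record, so their phylogenies cannot be
time-calibrated the usual way. When a species is split into sister
lineages by a dated physical barrier — a *geminate pair*, here the
Isthmus of Panama, closed ~2.8 Ma — the barrier itself becomes the
calibration: for each locus the divergence rate is

    r = d_min / t_cal        (substitution rate = r / 2)

where `d_min` is the minimum pairwise sequence divergence between the
two clades (the minimum, not the mean, so variation that predates the
split is excluded) and `t_cal` is the barrier age in Myr.

The package implements the full supporting pipeline on per-locus
aligned FASTA inputs:

* pairwise distances with pairwise deletion: p-distance, closed-form
  Tamura–Nei (TN93), and composite-likelihood TN93 with rate
  parameters shared across pairs (the default);
* within/between-clade divergence summaries and per-locus rate tables;
* mitochondrial/nuclear mutation-rate ratios (μm/μn) from gene-tree
  total branch lengths;
* minimum-spanning haplotype networks with mutational-step edges;
* barcode-gap species delimitation (single-linkage at the largest
  distance gap);
* a maximum-likelihood molecular clock test (TN93 + discrete gamma,
  free vs ultrametric branch lengths, chi-square with n − 2 df);
* a coalescent simulator of geminate datasets at known rates, so every
  stage is testable without downloading anything.

## Worked example

Simulate a geminate dataset at the calibrated study rates and refit it:

```python
from geminate_clock import GeminateDivergenceModel, default_config, simulate_geminate

alignments, partition, truth = simulate_geminate(default_config(seed=1))
model = GeminateDivergenceModel(
    alignments, partition,
    geminate_groups=("western_Atlantic", "eastern_Pacific"),
    calibration_myr=2.8,
)
results = model.fit(run_clock_test=False)
print(results.summary())
```

prints

```
Geminate-pair divergence-rate calibration
=========================================================
groups: western_Atlantic vs eastern_Pacific; calibration age: 2.8 Myr; distances: mcl

locus     d_min %  diverg. %/Myr  subst. %/Myr
COI          13.5            4.8           2.4
16S           5.7            2.0           1.0
ANT           0.4            0.1           0.1

gene-tree TBLs: COI=0.1586, 16S=0.06671, ANT=0.00363
mu_m/mu_n = 31.03 (mu_m=0.1126, mu_n=0.00363)
COI: overall divergence mean 7.5% (range 0.0%-14.5%)
16S: overall divergence mean 3.3% (range 0.0%-6.7%)
ANT: overall divergence mean 0.2% (range 0.0%-0.4%)
unique haplotypes (COI): western_Atlantic: 5, eastern_Pacific: 5
barcode-gap clusters (COI): 2 (threshold 7.4%, gap 12.3%)
```

Reading this: the simulated COI minimum inter-basin divergence (13.5%,
one Monte-Carlo draw around the generating 13.7%) divided by the
2.8-Myr split recovers a divergence rate of 4.8%/Myr against the
generating 4.9, and the substitution rate is half of it after
presentation rounding. The μm/μn footer is the ratio of mean
mitochondrial to nuclear gene-tree total branch lengths — here from
internal NJ trees on a single simulated draw of a slow nuclear locus,
so it is noisy; with user-supplied ML gene trees the ratio is whatever
those trees imply. Two barcode-gap clusters are the two basins.

The same stages are available as a CLI (`geminate-clock simulate`,
`distances`, `summarize`, `calibrate`, `network`, `delimit`,
`clocktest`, `run-all`) driven by a YAML config; `run-all` writes the
full report bundle (CSV/TSV/JSON plus a checksummed manifest).

The study's own sequences are GenBank accessions; they are not fetched
or shipped. When the aligned FASTAs are placed in a local directory,
`geminate_clock.real_data.run_real_data_summary` reproduces the
headline statistics from them.

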
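# Methods

`geminate-clock` derives per-locus molecular rates for a geminate
species pair — sister lineages assumed to have been separated by the
rise of the Isthmus of Panama — and runs the supporting analyses
(distances, haplotype network, cluster delimitation, clock test) on the
same multi-locus alignments. This note records the models, the
numerical choices, and what the synthetic-data tests do and do not
demonstrate.

## Rate calibration

For each locus the divergence rate is

    r = d_min / t_cal,

where `d_min` is the *minimum* pairwise distance between members of the
two clades and `t_cal` is the barrier age (default 2.8 Myr, the
shallow-water closure of the Isthmus). The minimum is used instead of
the mean so that polymorphism that predates the split does not inflate
the rate; a mean-based calibration is available behind
`use_mean_divergence=True`. The substitution rate (one lineage's share)
is half the divergence rate.

Reported rates are percentages rounded to one decimal, ties away from
zero, and the substitution rate is computed *from the rounded*
divergence rate (4.9 → 2.45 → 2.5 rather than 4.857/2 → 2.4). This
presentation convention is deliberate and is what the rate table
prints; the unrounded proportions are retained on the
`RateEstimate` objects.

No uncertainty is propagated from the calibration date: the barrier
age enters as a point value. The dominant uncertainty in practice is
the choice of `d_min` (estimator variant and sampling), not arithmetic.

## Distances

All estimators use pairwise deletion: for each pair of sequences,
columns where either member has a gap or ambiguity are dropped. Three
estimators are provided:

* **p** — raw mismatch proportion;
* **tn93** — closed-form Tamura–Nei distance per pair, with base
  frequencies pooled from that pair;
* **mcl** (default) — composite-likelihood TN93: the two
  transition/transversion ratios are shared across all pairs and chosen
  to maximize the sum of pairwise log-likelihoods; base frequencies are
  pooled empirical frequencies (with a +1 pseudocount) and are not
  optimized, which stabilizes the fit at study-scale sample sizes
  (n ≈ 25). Given the shared parameters, each pairwise distance is the
  ML branch length for that pair, found by a vectorized golden-section
  search on [0, 12] substitutions/site; the shared ratios are profiled
  over with Nelder–Mead.

Saturated pairs (a TN93 logarithm argument ≤ 0, or an ML distance at
the upper bound) abort the matrix with an error naming the pair;
silent NaNs would corrupt the downstream minima that feed calibration.

## Gene-tree rate ratio

The total branch length (TBL) of a gene tree is the sum of all its
edge lengths — a proxy for substitutions accumulated across the
sampled history. The mitochondrial/nuclear mutation-rate ratio is the
ratio of arithmetic means, `mu_m/mu_n`, with `mu_m` averaged over the
mitochondrial loci. The ratio is always computed from full-precision
TBLs of whatever trees are supplied (user Newick, or internal NJ
trees); note that recomputing it from *rounded* published TBLs gives a
slightly different value than from unrounded ones, which is expected.

## Haplotype network

Sequences (optionally trimmed to a uniform window first) are collapsed
by strict string identity; ambiguity codes are not merged into
compatible haplotypes, unlike some network tools — this keeps the
collapse order-independent, at the cost of occasionally splitting
haplotypes that differ only by an N. Labels are Roman numerals in
order of first occurrence. The network is the minimum spanning tree of
the complete graph weighted by mutational steps (differing unambiguous
sites), built by Kruskal with edges pre-sorted by (weight, label pair),
so ties resolve lexicographically and the result is deterministic.
Layout in the optional plot is cosmetic and untested.

## Barcode-gap delimitation

Species-level clusters are delimited by a deterministic barcode-gap
procedure: sort the unique pairwise distances, find the widest gap
between consecutive values whose lower edge lies in a prior window
(default [0.005, 0.1], a typical barcode scale), and cut a
single-linkage dendrogram at the gap midpoint. A gap narrower than
half its lower edge is not considered credible and yields a single
cluster with a warning flag. This is a stand-in for probability-scored
partitioners (ASAP, bPTP): it reproduces distance-gap structure but
assigns no significance scores, and with hierarchically nested
structure it reports the level selected by the prior window — the
deepest split by default. Raising the lower prior can only merge
clusters, never split them.

## Clock test

The clock test is a likelihood-ratio comparison on a fixed topology
(neighbor joining on TN93 distances by default; a user tree can be
supplied). Under TN93 with four discrete-gamma rate categories,
branch lengths are optimized for (a) a free model, one parameter per
edge, and (b) a clock model in which the tree is ultrametric,
parameterized by a log root height and a logistic height proportion
per internal node. The gamma shape and the two transition ratios are
estimated under the free model (L-BFGS-B on log-transformed
parameters, branch lengths bounded in [1e-8, 3]) and held fixed for
the clock model, avoiding ambiguity about which parameters the test's
degrees of freedom count. The statistic 2(lnL_free − lnL_clock) is
referred to chi-square with n − 2 degrees of freedom.

The root for the clock model is placed on the outgroup's edge when an
outgroup is named, otherwise at the midpoint. Optimization uses one
data-informed initialization (NJ branch lengths; node heights from
mean tip depths); additional jittered restarts are available via
`n_restarts`. Because the clock optimum is a feasible point of the
free model, the free model is re-polished from the clock solution
whenever the two likelihoods come out within tolerance, which enforces
the nesting inequality lnL_free ≥ lnL_clock by construction; a
residual violation raises an error rather than reporting a negative
statistic.

Likelihoods use Felsenstein pruning over compressed site patterns with
gap/ambiguous tip states marginalized; TN93 transition probabilities
come from the eigendecomposition of the reversible rate matrix, which
vectorizes over branches and rate categories. At the alignment sizes
this package targets (tens of taxa, hundreds of sites) no partial-
likelihood rescaling is needed in double precision.

## Synthetic data

The simulator generates the study design directly: two clades whose
ancestors split `t_split` Myr ago, Kingman coalescent genealogies
within clades (time-scaled so the expected within-clade diversity at
the first locus equals `intra_clade_theta`; rescaled if a draw would
coalesce above 0.95·t_split), optional regional subclades joining at
`region_split_fraction · t_split`, and sequences evolved site by site
under TN93 (optionally with continuous gamma site rates) using exact
transition probabilities per branch. Genealogies are ultrametric in
time and every lineage evolves at the locus substitution rate
(= divergence_rate/2), i.e. a strict clock; `simulate_clock_violation`
scales one sample's pendant branch by a factor. All randomness flows
from a single seeded generator: identical configs and seeds give
bit-identical alignments.

Default design (the study conditions): three loci — COI-like (658 bp,
4.9 %/Myr), 16S-like (459 bp, 2.0 %/Myr), both AT-rich with strong
transition bias, and a slow ANT-like nuclear locus (553 bp,
0.2 %/Myr); split at 2.8 Myr; 12 samples per clade; within-clade
diversity 0.5%.

For the clock-test experiments the configuration emulates the observed
phylogeographic structure of the study system: three deep regional
lineages per basin (region split at 0.4 of the basin split, matching
the observed region-to-basin divergence ratio of roughly 5.4/13.6) and
low within-region diversity (0.5%, the eastern-Pacific level). Under
this design the chi-square reference distribution is well calibrated
(branch lengths sit in the parameter interior); with a flat
low-diversity coalescent instead, many true branch lengths are near
zero and the test becomes conservative — and a "5× accelerated
lineage" whose pendant branch happens to be near zero carries no
signal at all, which bounds any test's power, not just this one's.

What the simulations do **not** emulate: recombination, selection,
migration after the split, ancestral polymorphism above the split
(lineages join exactly at `t_split`, so the true inter-clade path
length equals rate × age by construction), sequencing error, and
alignment error. Passing recovery tests therefore demonstrates
estimator correctness under the geminate model's own assumptions, not
robustness to their violation — in real data, ancestral polymorphism
biases geminate calibrations toward overestimated rates, which is the
usual argument for using the minimum divergence.

## Problem sizes in the shipped tests

The test-suite and acceptance-script simulation sizes (e.g. 50 seeds
for rate recovery at 10 samples/clade; 100 strict-clock and 50
clock-violation replicates at 8 leaves × 658 bp) were chosen as the
smallest designs at which the binomial/Monte-Carlo noise of each check
is comfortably below the tolerance it asserts. One consequence worth
noting: in the μm/μn recovery experiment the nuclear locus is
simulated at 4000 bp rather than a typical single-gene length,
because a locus 30× slower than COI accumulates only ~3 substitutions
over this history at ~550 bp — its estimated gene-tree TBL is then
dominated by Poisson discreteness (and can be exactly zero), which no
estimator can overcome. Lengthening the locus leaves the per-site TBL
expectation unchanged and only shrinks that noise. The same
discreteness applies to any real single-gene nuclear TBL at these
rates, which is a caveat on published μm/μn values, not just
simulated ones.

## Known limitations

* The composite-likelihood distance shares only the two transition
  ratios; MEGA's variant also profiles frequencies differently, so
  third-decimal differences from MEGA output are expected.
* The barcode-gap partitioner reports one partition level, not a
  ranked series as ASAP does.
* The clock LRT's chi-square reference is asymptotic; with many
  near-zero branch lengths it is conservative.
* NJ topologies with long-branch taxa can differ from ML topologies;
  the clock test accepts a user topology where that matters.
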
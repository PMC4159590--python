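# Methods

`island-ark` reconstructs, as one tested pipeline, the computational
analyses used to infer how an island population (the motivating system is
the Orkney common vole, *Microtus arvalis*) was founded from a continental
source: coalescent simulation under a colonization-with-bottlenecks
demography, rejection ABC for the colonization time and candidate-source
ranking, mtDNA diversity/neutrality statistics with mismatch-based
expansion dating, microsatellite summary statistics, and geometric
morphometrics of 2-D landmark data. This note records the models, the
defaults that matter, the numerical choices, and what the synthetic-data
experiments do and do not demonstrate.

## The demographic model

Two populations, continental (current diploid size `N_c`) and island
(`N_o`), diverge at the colonization time `T_col` (generations before
present; one generation per year by default). Eleven parameters:

| parameter | meaning | default prior |
|---|---|---|
| `N_c`, `N_o` | current diploid sizes | log-uniform [10³, 10⁶] |
| `T_col` | colonization time (gen BP) | uniform [100, 10⁴] |
| `N_f`, `d_f` | founder-bottleneck size and duration, ending at `T_col` | log-uniform [10, 10³]; uniform [1, 30] |
| `T_ob`, `N_ob`, `d_ob` | later island bottleneck (onset, size, duration) | onset uniform over the admissible window; size/duration as founder |
| `T_cb`, `N_cb`, `d_cb` | continental bottleneck, before or after `T_col` | onset uniform [0, 10⁴]; size/duration as founder |

Every bottleneck ends in a step recovery (no exponential phases), matching
a founding event followed by rapid growth. Bottleneck intervals within a
population may not overlap; the island bottleneck must close before the
founder phase opens (backwards in time). The prior on `T_ob` is drawn as a
fraction of the window `[0, T_col − d_f − d_ob]` so that every prior draw
is a valid model — no rejection step, no silent truncation bias on the
other parameters.

The size-range and duration choices are this package's reconstruction (the
original study's prior table is not printed in its main text). Two
considerations fix them: effective sizes of abundant small rodents span
roughly 10³–10⁶, and brief bottlenecks are what the step-recovery narrative
describes. They also matter methodologically: the Δ_C source-ranking
statistic (below) is a *mean* distance to the prior-predictive cloud, so it
ranks candidates by how typical their observed configuration is under the
model. It tracks relatedness — the behaviour the original analysis
exhibits — only while the predictive mass sits at mild-to-moderate
source–island divergence. With century-scale bottlenecks at sizes of tens,
the predictive divergence is so extreme that *more* diverged candidates
look more typical and the ranking inverts. All priors are overridable per
parameter.

## Coalescent simulation

Genealogies follow the Kingman coalescent with pairwise rate `1/(2N(t))`
per generation within each population, exponential waiting times, and
population-size change points treated as event boundaries (exact by
memorylessness). At `T_col` all island lineages join the continental
population; there is no migration (a symmetric rate is available as an
explicit argument for sensitivity analysis, default 0).

Microsatellites mutate under the strict symmetric stepwise model: per
branch, Poisson(`μ`·length) mutations of ±1 repeat, root allele 100,
reflecting bounds [50, 150]. Reflection is implemented by folding the
unbounded endpoint into the interval (method of images), which is exact for
a symmetric ±1 walk with bounce-back boundaries. The default rate is
`μ = 2 × 10⁻⁴` per locus per generation, mid-range for dinucleotide
microsatellites. Sequences mutate under infinite sites: Poisson mutations
per branch at `μ_site · L`, each assigned to a distinct uniform column of
an all-A background; requesting more mutations than columns is an error
rather than a silent wrap.

Correctness anchors (all tested): pair TMRCA ≈ 2N; Watterson's
E[S] = θ·a₁; SMM equilibrium pair identity ≈ 1/√(1+2θ); TMRCA
distributions for constant-size, bottleneck and two-population-split
benchmarks agree with msprime within Monte-Carlo error.

## Sequence statistics

Site handling is complete deletion by default: any column containing `-`
or `N` is dropped before counting, and per-site π uses the analysed-site
count (the common default of the standard software for these statistics);
pairwise deletion is available.

* Haplotype diversity `h = n/(n−1)(1 − Σf²)` with Nei's variance; π as
  mean pairwise differences per analysed site with Nei's total variance.
* Tajima's D in the standard 1989 formulation; undefined (NaN, never 0)
  when S = 0.
* Fu's Fs via the Ewens sampling formula with θ estimated by the mean
  pairwise difference; unsigned Stirling numbers of the first kind are
  computed once per n by the triangular recurrence in log space and
  cached. Tail underflow returns signed infinity with a warning.
* R2 (Ramos-Onsins & Rozas) from per-sequence singleton counts.
* The mismatch distribution is fitted by the three-parameter
  sudden-expansion model (geometric equilibrium mixed with a Poisson(τ)
  convolution and decay `exp(−τ(θ₁+1)/θ₁)`), by Nelder–Mead inside bounds
  τ∈[0,50], θ₀∈[0,20], θ₁∈[θ₀,5000] with 10 quantile-spaced restarts; the
  spatial-expansion variant is out of scope. The model curve was verified
  against direct coalescent simulation of the two-epoch history.
* The SSD p-value is a parametric bootstrap: coalescent samples simulated
  in τ (= 2ut) units under the fitted parameters, each refit (3 restarts
  for speed), p = fraction with SSD ≥ observed. The seed is mandatory.
* `expansion_time` converts τ to years: `t = τ/(2 μ_site L) · gen_time`.
  The clock constants are explicit inputs, never hard-coded; with
  τ = 1.3904, μ = 3.27 × 10⁻⁷/site/year and L = 1143 the conversion gives
  ≈ 1860 years — the worked check in the test suite.

## Microsatellite statistics

Unbiased expected heterozygosity `n/(n−1)(1 − Σp²)` over gene copies;
rarefaction allelic richness `Σ_a [1 − C(N−N_a, g)/C(N, g)]` with the
rarefaction base `g` defaulting to the smallest non-missing copy count over
the populations compared (overridable). Hardy–Weinberg tests use Levene's
conditional probability; the null distribution is enumerated exactly when
the genotype-table space is small (≤ 2×10⁵ tables) and otherwise sampled by
Monte-Carlo pairings of the observed gene-copy pool (default 10⁵ steps,
seed mandatory). Multiple testing uses the sequential Holm step-down rule.
F_ST is Weir & Cockerham's θ with multi-locus ratio-of-sums weighting
(never a mean of ratios) and an individual-permutation p-value; small
negative estimates are legitimate for this estimator. Missing genotypes
are excluded locus-wise, never list-wise. A caveat for comparisons against
AMOVA-based software: θ and AMOVA F_ST differ slightly for codominant
data; θ is the headline estimator here.

## ABC

Summary vector (pluggable, this is the default registry): per population
mean expected heterozygosity, mean allele count and mean allele-size
variance over loci; per source–target pair, θ and Goldstein's (δμ)².
Rejection uses Euclidean distance on statistics standardized by the MAD of
the simulated set (MAD, not SD, for robustness to the heavy-tailed
predictive distributions); zero-MAD statistics are dropped with a warning;
the closest ⌈tolerance·M⌉ draws are retained. No regression adjustment is
applied — plain rejection is the baseline. Point estimates are KDE modes
(Gaussian kernel, Silverman bandwidth, 512-point grid), falling back to the
median below 20 retained draws.

Δ_C for candidate C: for each colonized target population, compute the
observed summary vector (C as source), simulate `n_sim` datasets with
matching sample sizes from prior-drawn parameters, and average the
MAD-standardized distances over simulations and targets; the smallest Δ_C
marks the most likely source. Candidates under 19 individuals are refused
unless forced. Simulations draw from the priors, not a fitted posterior: a
posterior-predictive variant was prototyped and discarded because the
11-parameter model can reproduce any single candidate–island pair, leaving
the discrepancy flat across candidates.

## Morphometrics

GPA: configurations are centred and scaled to unit centroid size, rotated
to the iteratively re-estimated mean (SVD, reflections forced out;
biological left/right homology is assumed resolved upstream), mean
re-normalised each round, convergence at 1e-10 or 100 iterations. GPA
output is defined only up to a global rotation, so a canonical orientation
(principal axis of the mean along x, deterministic sign) is applied —
without it, results would depend on specimen order. Semi-landmarks slide
along chord tangents estimated from their curve neighbours (one-sided at
curve ends) by solving the normal equations of the thin-plate-spline
bending-energy quadratic (kernel U(r) = r²log r²) restricted to tangent
directions, against the evolving GPA mean; a 1e-8 ridge handles singular
systems. GPA and sliding alternate until the summed bending energy
stabilises; the loop stops rather than accept an increase, so the recorded
trace is non-increasing. PCA is on the covariance of flattened Procrustes
coordinates (no tangent-space projection, no partial-warp step — equivalent
up to the affine component), with the largest-magnitude loading element
made positive for sign stability. `pc_deformation` renders mean + score ×
loading.

## Synthetic data: what it emulates, what it does not

The generators produce the three input kinds in their standard on-disk
formats (GenePop/FASTA/TPS plus a `truth.yaml`), with defaults mirroring
the motivating study's layout: 14 loci; island samples of 19–26
individuals; a colonization ~5000 generations ago through a few tens of
founders; sequence sets of n = 68 at L = 1143 sites; 18 fixed landmarks
plus 12 semi-landmarks. The default colonization truth
(`N_c = 7500, N_o = 1875, T_col = 5000, N_f = 30, d_f = 10` at
μ = 2×10⁻⁴) was chosen so the equilibrium diversity matches the reported
levels of the real system (source H ≈ 0.7, island H ≈ 0.4–0.6, overall
F_ST ≈ 0.2); note the data identify θ = 4Nμ, not N and μ separately.

The source-ranking study simulates one joint four-deme genealogy: islands
from the true source at `T_col` (with founder bottleneck), a smaller
regional sister deme (N = 2000) splitting at 2·`T_col`, and a small
distant outgroup (N = 500) at 4·`T_col`. Two structural facts shaped this
design and are worth knowing when interpreting results on real data: a
deme that split from the source *after* the colonization is genealogically
exchangeable with the source, so no statistic can prefer one; and under
SMM homoplasy an equal-size deme splitting even twice as early shifts
F_ST(candidate, island) by only ~0.01 — below 14-locus sampling noise.
Candidate panels are therefore informative only insofar as candidates
differ in drift history, which real regional demes do.

What passing does not show: the generators contain no genotyping error, no
null alleles, no aDNA damage, no departure from strict SMM, no gene flow
after colonization, and island "populations" are labelled subsamples of
one panmictic island. Real-data performance degrades with any of these.

## Experiment sizes

The validation experiments run at: 2000 replicates for the pair-TMRCA
check; 300 for Watterson; 3000 loci for SMM equilibrium; 200 replicates
per scenario for neutrality calibration; 20 000 prior draws at tolerance
0.01 with 25 replicate observed studies for ABC recovery (the reference
table is simulated once and shared across replicates — valid for rejection
ABC since the table is independent of the observed data); 50 ranking
studies at n_sim = 100 for Δ_C. `scripts/acceptance.py` reruns the same
experiments at 8000 draws, 150 calibration replicates and 15 ranking
studies with n_sim = 60, sizes chosen so a full from-scratch rerun stays
in the minutes range on one core.

## Known limitations

* The 11-parameter layout and all priors are a reconstruction; an
  alternative reading is a one-type change (`DemographicModel`).
* Fu's Fs needs O(n²) log-Stirling work on first use per n; fine for
  hundreds of sequences, slow beyond.
* The sudden-expansion fit is a least-squares curve fit; its SSD p-value,
  not the fit itself, carries the inferential weight.
* Rejection ABC with this summary set identifies `T_col` only weakly when
  sizes are free (time and size trade off); credible intervals are honest
  about this, point modes should be read with the intervals.
* Sliding uses chord tangents, not analytic curve models; with very sparse
  curves the tangent estimate is rough.
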
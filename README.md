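# island-ark

Inference toolkit for the colonization history of island populations from
multilocus genetic data and tooth-shape morphometrics. The motivating
system is the human-mediated colonization of an offshore archipelago by a
small rodent (the Orkney common vole): a continental source population, a
founding bottleneck a few thousand generations ago, and subsequent
divergence of the islanders in both genes and molar shape. The package is
aimed at population geneticists who want the whole analysis chain —
simulation, statistics, inference, validation — as reusable, tested code
that runs end to end on synthetic data with known truth.

Four analysis layers over shared typed containers:

* **`coalsim`** — two-population Kingman coalescent under an 11-parameter
  demography (current sizes `N_c`, `N_o`; colonization time `T_col`; a
  founder bottleneck `(N_f, d_f)` and independent island and continental
  bottlenecks, each with instantaneous recovery), with strict stepwise
  mutation (SMM) for microsatellites and infinite-sites sequences.
* **`seqstats`** — haplotype/nucleotide diversity, Tajima's *D*, Fu's
  *F*ₛ, Ramos-Onsins & Rozas's *R*₂, the mismatch distribution with the
  Rogers–Harpending sudden-expansion fit (τ, θ₀, θ₁ minimising SSD, with a
  parametric-bootstrap SSD p-value), and the clock conversion
  *t* = τ/(2·μ·L)·(years/generation).
* **`msatstats`** — unbiased heterozygosity, rarefaction allelic richness,
  exact/Monte-Carlo Hardy–Weinberg tests with Holm correction, and
  Weir–Cockerham *F*_ST with permutation p-values.
* **`abc_infer`** — rejection ABC (MAD-standardized Euclidean distance,
  KDE posterior modes) for the colonization parameters, and the Δ_C
  statistic: the mean standardized distance between a candidate source's
  observed summaries and model simulations using it as source — smallest
  Δ_C marks the most likely source.
* **`morpho`** — generalized Procrustes analysis with bending-energy
  sliding of semi-landmarks, centroid size, and shape PCA with
  PC-deformation rendering.

`synthdata` generates all three data kinds (GenePop/FASTA/TPS + truth
files) with the statistical structure each stage assumes; `pipeline` and
the `island-ark` CLI chain the stages from a seeded YAML configuration.

## Worked example

Simulate a colonization study (one continental source, three island
samples, 14 microsatellite loci) and summarise it:

```
$ island-ark synth colonization --seed 11 --out demo
$ island-ark msatstats --genotypes demo/colonization.genepop --format genepop --fst
population  n   A_R_mean  A_R_sd  H_mean  H_sd
island1     23  2.792     0.911   0.387   0.196
island2     26  2.921     0.820   0.384   0.194
island3     19  2.929     0.730   0.400   0.184
source      26  5.606     1.293   0.721   0.072
# overall_FST  0.206538
```

The founder effect is visible exactly as in real island systems: the
islands carry about half the source's heterozygosity and allelic richness,
and a fifth of the total variance lies between populations (*F*_ST ≈ 0.21).

Sequence side — simulate an alignment from a population that expanded
100-fold (n = 68 sequences, 1143 sites, the layout of a typical
mitochondrial study) and test for the expansion signature:

```
$ island-ark synth expansion --seed 11 --out demo2
$ island-ark seqstats --fasta demo2/expansion.fasta
n   S   h         pi        tajimas_d  fus_fs    rozas_r2  mismatch_tau  mismatch_ssd
68  31  0.891572  0.001815  -2.17411   -24.7333  0.029703  2.23151       0.00311248
```

Strongly negative *D* and *F*ₛ, small *R*₂ and a smooth unimodal mismatch
fit (τ ≈ 2.2) are the classic sudden-expansion signature. Converting a
fitted τ to calendar time with an explicit clock:

```python
>>> from island_ark.seqstats import ClockConstants, expansion_time
>>> expansion_time(1.3904, ClockConstants(mu_site=3.27e-7, L=1143, gen_time=1.0))
1860.0121467996928
```

i.e. with a rate of 3.27 × 10⁻⁷ mutations/site/year over 1143 sites, τ =
1.3904 dates an expansion to ~1860 years before present.

ABC inference and source ranking run the same way (`island-ark abc-fit`,
`island-ark abc-rank`), and `island-ark run --config run.yaml` chains
synthetic-data generation, statistics, ABC and morphometrics with explicit
seeds and a checksummed output manifest.

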
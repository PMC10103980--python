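# aneuscore

Calling aneuploid cells from single-cell RNA-seq via expression-inferred
copy-number profiles, plus exponential tumor/tumoroid growth-curve models.

## The problem

Chromosomal instability produces cells whose chromosome content deviates from
the euploid baseline. In droplet scRNA-seq this leaves a dosage footprint:
every gene on a gained (lost) chromosome is, on average, expressed more
(less). `aneuscore` turns that footprint into per-cell aneuploidy calls for
experiments with two cell groups — a *reference* population presumed euploid
(e.g. vehicle-treated cells) and an *observation* population to score.

## Method

1. **QC & normalization.** Cells must express ≥ 1,400 genes with < 15%
   mitochondrial counts; surviving counts are LogNormalized,
   `x(g,i) = ln(1 + c(g,i)/total(i) · 10⁴)`.
2. **Copy-number profile.** Genes are placed in genomic order, centered on the
   reference per-gene mean, clipped at ±3, smoothed by a 101-gene boxcar that
   never crosses chromosome boundaries, and *denoised*: observation values
   within ±1.5 reference SDs of baseline are zeroed. The result is one
   segment per gene on a centered log scale (0 = euploid).
3. **Deviation statistic.** Per segment *s* and cell *i*,
   `dev(i,s) = x(i,s) − mean_cells x(·,s)`; deviations are summed (signed)
   across each chromosome *c* into `D(i,c)`.
4. **Outlier rule.** Per chromosome, the distribution peak `m_c` of D is a
   Gaussian-KDE mode (Silverman bandwidth, 512-point grid) and `s_c` its
   sample SD. Cell *i* is an outlier on *c* when `|D(i,c) − m_c| > 2.5·s_c`,
   and *aneuploid* when flagged on ≥ 1 chromosome. The aneuploid fraction is
   reported per cell group.
5. **Growth models.** Projected tumor area `A = π/4·L·W`; nonlinear
   least-squares fits of `A = A₀·e^{kt}` (tumors) and `A = A₁·e^{k(t−1)}`
   (tumoroids); terminal burden at 125 mm²; responders classified as
   complete (never terminal) or partial (survival ≥ reference median + 7 d).

A synthetic-data generator plants whole-chromosome copy-ratio changes with
known ground truth (gamma-Poisson counts, log-normal gene means and library
sizes) so the whole pipeline is testable end to end; see `docs/methods.md`.

## Worked example

```python
from aneuscore import (SimulationConfig, make_gene_positions, simulate_counts,
                       run_pipeline, simulate_growth_series, fit_exponential)

positions = make_gene_positions(n_chromosomes=8, genes_per_chromosome=250, seed=0)
config = SimulationConfig(aneuploid_fraction=0.34, seed=1)
counts, truth = simulate_counts(config, positions)

table, call = run_pipeline(counts, positions)
planted = (truth.loc[call.aneuploid.index] != 1.0).any(axis=1)
obs = table.cell_group == "observation"
print(f"observation cells scored: {int(obs.sum())}")
print(f"planted aneuploid fraction: {planted[obs].mean():.3f}")
print(f"called aneuploid fraction:  {call.aneuploid_fraction:.3f}")

series = simulate_growth_series(A0=4.0, k=0.3, days=range(4, 17), noise_cv=0.05, seed=3)
fit = fit_exponential(series, model="tumor")
print(f"A0 = {fit.prefactor:.3f} mm^2, k = {fit.k:.3f} /day, RSS = {fit.rss:.2f}")
```

prints

```
observation cells scored: 392
planted aneuploid fraction: 0.352
called aneuploid fraction:  0.324
A0 = 4.473 mm^2, k = 0.292 /day, RSS = 1389.69
```

Of 400 simulated observation cells, 392 pass QC; 35.2% carry a planted
whole-chromosome event and the 2.5-SD rule calls 32.4% aneuploid. The growth
fit recovers the generating parameters (A₀ = 4 mm², k = 0.3/day) from a 5%-CV
noisy series.

The same stages are available on the command line
(`aneuscore simulate | preprocess | infer | score | fit-growth`); rerunning
any stage with the same configuration and seed reproduces its output files
byte for byte.

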
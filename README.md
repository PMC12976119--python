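# ampexp

Habitat-association tests and mitochondrial-barcode diversity analyses for
stream-dwelling amphipods.

Field surveys of amphipods (e.g. *Gammarus* species) typically produce three
kinds of data: presence/absence records at hundreds of stream sites, habitat
covariates read off the stream network (channel slope, Strahler order,
drainage-area class), and COI barcode sequences (658 bp) from a subset of
individuals. `ampexp` implements the statistical pipeline that turns these
into ecological and demographic inference:

* **Stream geometry** — a directed stream-network model with Strahler
  ordering and a reach-based site-slope estimator: end points 100 m up- and
  downstream along the channel, confluence- and spring-aware, returning the
  lower of the two section slopes.
* **Habitat randomization tests** — observed per-category counts (or
  min/mean/median/max of a continuous covariate) at presence sites compared
  against B random site subsets of the same size, with per-direction
  p-values; Monte-Carlo Pearson χ² and Wilcoxon rank-sum contrasts between
  two species; minimum-distance spatial thinning; Spearman-cluster + VIF
  predictor pre-selection.
* **Population genetics** — haplotype collapsing, segregating sites S,
  nucleotide diversity π = Σ<sub>pairs</sub> d<sub>ij</sub> / C(n,2), the
  mismatch distribution, Tajima's D and Fu's Fs with coalescent-simulated
  null distributions.
* **Sudden-expansion inference** — the Rogers–Harpending two-epoch model:
  a population at equilibrium θ₀ = 2N₀u grows instantaneously to θ₁ at
  time τ = 2ut before the present. The expected mismatch distribution is a
  Poisson mixture over the piecewise-exponential pair-coalescence time;
  (τ, θ₀, θ₁) are estimated by least squares (SSD), with Harpending's
  raggedness Hr = Σ(x<sub>i</sub> − x<sub>i−1</sub>)² and parametric-bootstrap
  p-values for both.
* **Haplotype networks** — minimum spanning networks (union of all minimum
  spanning trees over Hamming distances) with cut- or seed-based haplotype
  grouping, one-sequence-per-site deduplication, and CSV/GraphML/NEXUS export.
* **Spatial diversity maps** — per-cell π, haplotype count and sample size
  on a 6.7-km grid, each cell summarised over its 3×3-cell (~20 km) window.
* **Synthetic data** — a dendritic stream-network generator, a logistic
  presence model on slope/temperature/order, and a two-epoch coalescent
  simulator with infinite-sites mutation that doubles as the bootstrap and
  null engine, so the whole pipeline is testable with known ground truth.

## Worked example

Simulate a 50-sequence sample under a strong sudden expansion
(τ = 2, θ₀ = 1, θ₁ = 100) and run the demographic analyses:

```python
from ampexp import synthetic_data as syn, popgen_core as pg, expansion_fit as ef

params = syn.ExpansionParams(theta0=1.0, theta1=100.0, tau=2.0, n=50)
aln = syn.simulate_coalescent_expansion(params, seed=7)

stats = pg.neutrality_stats(aln, reps=1000, seed=8)
print(f"n={stats.n}  S={stats.S}  pi={stats.pi:.3f}  k={stats.k}")
print(f"Tajima's D = {stats.tajimas_d:.3f} (p = {stats.p_d_low:.3f})")
print(f"Fu's Fs    = {stats.fus_fs:.3f} (p = {stats.p_fs:.4f})")

fit = ef.fit_alignment(aln, B=200, seed=9)
print(f"tau-hat = {fit.tau:.3f}")
print(f"SSD = {fit.ssd:.4f} (p = {fit.p_ssd:.3f})  "
      f"Hr = {fit.raggedness:.4f} (p = {fit.p_raggedness:.3f})")
```

Output:

```
n=50  S=47  pi=3.100  k=33
Tajima's D = -2.423 (p = 0.000)
Fu's Fs    = -35.348 (p = 0.0010)
tau-hat = 2.664
SSD = 0.0002 (p = 0.920)  Hr = 0.0248 (p = 0.655)
```

The strongly negative D and Fs (with Fs far more extreme than D) are the
classic expansion signature; the mismatch fit recovers τ near its true
value of 2, and the non-significant SSD/Hr say the sudden-expansion model
fits the data. A full synthetic study — network, sites, presence, placed
sequences — comes from one call:

```sh
ampexp run --seed 1 --out results/demo
```

which writes the site table, alignment, habitat-test results, neutrality
statistics, expansion fit, haplotype network and diversity grid, plus a
JSON manifest with content hashes of every input and output (reruns with
the same seed are byte-identical).

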
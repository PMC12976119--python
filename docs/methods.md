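# Methods

## Scaling conventions

All demographic quantities use the haploid mitochondrial convention of the
mismatch-distribution literature: time t is measured in mutational units
(t = 2ut, with u the per-sequence per-generation mutation rate) and
θ = 2Nu. A pair of lineages coalescing at time t then differs at
Poisson(t) positions. In the two-epoch ("sudden expansion") coalescent,
k lineages coalesce at rate C(k,2)/θ₁ for t < τ and C(k,2)/θ₀ for t ≥ τ,
and mutations fall on each branch as a Poisson process of rate 1/2 per
unit time. θ₀ = 0 is allowed and collapses all surviving lineages at τ
(a star genealogy).

Distances on the stream network are along-channel polyline distances in
projected metres, never Euclidean shortcuts; slopes are percentages
(vertical drop / along-channel distance × 100).

## Site slope

The estimator reproduces a field protocol: end points a fixed reach
(default 100 m) up- and downstream of the site along the channel; a side
whose confluence lies nearer than the reach is dropped when the other
side is clean, or replaced by the branching node at its true distance
when both sides are obstructed; sites within the reach of a spring use
the downstream end point only; with two section slopes the lower is
returned. Design points the protocol leaves open, resolved here:

* an end point falling **exactly** at the reach distance counts as clean
  (obstruction requires a confluence strictly nearer than the reach);
* when one side is invalid (spring or outlet) and the other is
  confluence-obstructed, the branching node is used rather than erroring;
  an error is raised only when no side yields any end point;
* negative raw gradients (elevation rising downhill — DEM noise at
  metre-rounded elevations) are clamped to zero *before* the lower-of-two
  comparison and flagged in the QC report; sites with slopes above 60%
  are flagged too. Nothing is silently edited.

Drainage-size classes use half-open bins [low, high): spring, <10,
10–100, 100–1000, >1000 km². Strahler ordering is standard (two equal
order-k tributaries produce k+1); edges flagged as artificial
side-channels inherit the order of the stream they branch from and do
not participate in junction arithmetic.

## Randomization habitat tests

Observed statistics at the n presence sites are compared with B = 1000
random subsets of size n drawn without replacement from all sites. Two
p-value conventions are computed per direction:

* **raw**: the proportion of subsets strictly more extreme than the
  observation (the field's wording). On discrete category counts this
  form is anticonservative (~7–9% two-sided rejection at the
  0.025-per-tail threshold in our calibration experiments), because tied
  subsets are excluded from both tails;
* **corrected**: the tie-inclusive (#{at least as extreme} + 1)/(B + 1)
  permutation form, which is exchangeable-valid and is what the
  calibration suite checks (measured two-sided rejection 3–5% at
  nominal 5%).

Both are reported so either convention is recoverable; two-sided
significance uses 0.025 per tail. The species contrast is a Pearson χ²
on the 2×K per-category presence-count table (sites hosting both species
appear in both rows), with p from tables simulated under fixed margins,
p = (1 + #{X²ₛᵢₘ ≥ X²ₒᵦₛ})/(B + 1), B = 2000 by default. The rank-sum
contrast uses exact enumeration up to group size 50 without ties, and
the tie- and continuity-corrected normal approximation otherwise.

Spatial thinning (default 2 km) proceeds in three steps: absences within
the minimum distance of any presence are removed; then presences, then
absences, are thinned by breaking violating pairs in order of increasing
distance. The first pass is deterministic (drop the member with more
remaining violations, ties to the higher index — this pass is also the
exposed comparison baseline); subsequent restarts drop a random member,
and the largest retained set wins, so the result never falls below the
deterministic pass. Predictor pre-selection clusters variables by
|Spearman ρ| ≥ 0.7 (connected components), picks one representative per
cluster by a caller-supplied preference order (default: input order), and
drops representatives in reverse preference until all VIF < 3.

## Neutrality statistics

π is the mean pairwise Hamming distance over scored columns; columns
containing N or a gap in any sequence are excluded (complete deletion;
pairwise deletion is available but non-default — common barcode
practice). S, D and Fs use the same masking. Tajima's D follows the
standard a/b/c/e constant system and is undefined (reported missing) at
S = 0. Fu's Fs is ln(S′/(1−S′)) with S′ = Pr(K ≥ k_obs) under the Ewens
sampling formula at θ = π̂, computed from unsigned-Stirling-number
recursions in log space (the pmf sums to 1 within 1e-9 for n ≤ 200);
boundary cases return signed infinity with a flag, never NaN.

Significance is simulation-based: constant-size coalescent replicates
conditional on θ̂ (Watterson's from S for D; π̂ for Fs), 1000 replicates
by default, p = fraction of replicates at least as extreme (lower tail;
the upper tail for D is reported too). Exact conditioning schemes of
legacy software are not public line-by-line, so simulation conditioning
is this package's documented choice. A p-value of zero from a finite
simulation is never reported; the (k+1)/(B+1) bound is used instead.
The common Fs significance convention (test at p < 0.02 for α = 0.05)
is documented but not enforced.

## Sudden-expansion fit

The expected mismatch distribution mixes Poisson(j; t) over the pair
coalescence-time density, evaluated with regularised incomplete gamma
functions in log space (stable for θ₀ → 0, where the ancient-epoch term
degenerates to e^{−τ/θ₁}·Poisson(j; τ)). At τ = 0 or θ₀ = θ₁ it reduces
exactly to the geometric equilibrium distribution θʲ/(1+θ)^{j+1}, and it
matches a 10⁵-pair Monte-Carlo oracle within total-variation 0.005 at
(τ=3, θ₀=1, θ₁=50).

(τ, θ₀, θ₁) minimise the SSD between observed and expected relative
class frequencies over 0..d_max. The search is constrained to genuine
expansions, θ₁ ≥ θ₀, via a (τ, log θ₀, log θ₁/θ₀) parameterisation:
unconstrained, the model can mimic bimodal (clearly non-expansion) data
with a contraction, which destroys the goodness-of-fit test's power.
Optimisation is deterministic multi-start L-BFGS-B (start grid
τ ∈ {0.5,1,2,4,8}, θ₀ ∈ {0.1,1,10}, θ₁ ∈ {1,10,100,1000} clipped to the
feasible region, tolerance 1e-8); the full grid is screened and the six
best starts polished, and the attained SSD never exceeds the SSD at any
grid start. Monomorphic samples return τ̂ = 0 with a degeneracy flag.

Harpending's raggedness is Hr = Σ_{i=1..d}(x_i − x_{i−1})² with d the
maximum observed difference class; a monomorphic distribution is treated
as d = 1 with x₁ = 0 (Hr = 1). Goodness-of-fit p-values come from a
parametric bootstrap: B coalescent samples under the fitted parameters,
each refitted (reduced start grid seeded with the parent fit), with
p = #{statistic ≥ observed}/B. τ̂ recovery at (τ=3, θ₀=1, θ₁=50, n=100)
is within ±25% in the median over 100 replicates, with the expected mild
upward bias of SSD-based τ estimators.

## Haplotype networks

The network is the union of all minimum spanning trees (Kruskal with tie
retention: an edge of weight w is kept iff its endpoints lie in
different components of the strictly-lighter graph). This approximates a
median-joining network at homoplasy level 0 **without median vectors**:
no unsampled haplotypes are inferred, so every displayed node is
observed. With dense sampling of star-like expansion clusters the
approximation is close, but reticulations passing through unsampled
intermediates are absent by construction. Node weights count individuals
or, after one-per-(site, haplotype) deduplication, distinct sites of
occurrence (the circle-size convention that removes sample-size bias).
Haplotype grouping is formalised two ways — an edge-length cut (label
components after removing edges longer than the cut) or nearest-seed
labelling along network paths (ties to the lowest label); published
group delineations are typically visual, and no claim is made that
either mode reproduces any particular hand partition.

## Diversity grid

Samples are binned into half-open square cells (default 6.7 km) with the
origin snapped down to a cell multiple of the bounding-box minimum
(exposed as a parameter; the 3×3 windowing exists precisely to blunt
grid-placement effects). Each cell reports π, haplotype count and sample
size over its Moore neighbourhood; windows with fewer than two sequences
leave π undefined (flagged) rather than zero, keeping empty and
monomorphic cells distinguishable. Edge cells use truncated
neighbourhoods; no wraparound.

## Synthetic data: what it emulates, and what it does not

The generator's defaults describe a realistic single-catchment study:
a ~50 × 50 km extent, 12 headwater sources merging through binary
confluences to one outlet, elevations 500–1800 m at the sources with
log-uniform channel gradients (steep headwaters, gentle lowland reaches,
giving site slopes roughly 0–15%), drainage areas accumulating from
random headwater contributions, and a temperature covariate from a
linear lapse (21 °C at sea level, 6.5 °C/km). Presence follows a
logistic model, by default strongly slope-averse (−1.2 per % slope),
warmth-loving (+0.75 per °C) and order-preferring (+0.35 per level),
with the intercept (−15.5) set so the expected presence fraction on the
default network is ~15% — the size of presence set typical of such
surveys. Barcodes are 658 bp; the default study bundle simulates two
haplotype groups (n = 120 and 80) as independent sudden expansions on a
shared ancestral sequence, separated by 12 fixed private mutations, each
group's samples placed around one geographic centroid with an
exponential distance kernel (decay 12 km).

Deliberate idealisations: no recombination, selection, migration
matrices or finite-sites substitution; infinite-sites collisions abort
rather than degrade (keeping S and π exact for oracles); groups are
merged post hoc, which is a modelling convenience, not a demographic
claim (cross-group position collisions are possible and slightly blur
the planted divergence); real stream networks have braids, culverts and
DEM artefacts the generator does not produce. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
models, not robustness to the full messiness of field data.

## Determinism and problem sizes

Every operation draws from one seeded NumPy generator; the pipeline
derives per-stage seeds from a master seed by stable SHA-256 hashing,
and run manifests omit wall-clock timestamps by default so complete
output bundles are byte-identical across reruns. The default pipeline
configuration (300 sites, 200 sequences, B = 1000 habitat replicates,
200 neutrality replicates, 20 bootstrap refits) completes in a few
seconds; the calibration experiments in the test suite use 2000
coalescent replicates for moment checks, 300 × 200 nested simulations
for test-size checks and 500 meta-replicates for randomization
calibration — sizes chosen to keep Monte-Carlo error well below the
tolerances being asserted.

## Known limitations

* The spatial (migration-structured) expansion model is not implemented;
  only the demographic sudden-expansion model is fitted.
* Median-joining median vectors are not inferred (see above).
* Fu's Fs uses exact Ewens probabilities, which is O(n²) in memory for
  the Stirling table; fine for barcode-scale n (hundreds), not for
  thousands.
* The side-channel Strahler convention (inherit the parent order) is a
  pragmatic reading of agency practice for artificial channels.
* VIF pruning assumes a roughly linear predictor set; no interaction or
  nonlinearity screening is attempted.
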
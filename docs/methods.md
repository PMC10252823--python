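# Methods

This note documents the models, numerical choices and limitations behind
`isoweb`. The package analyses bulk-tissue stable-isotope data
(δ¹³C, δ¹⁵N, both in ‰) from aquatic consumers and their basal resources to
compare food-web structure between communities — the design it targets is a
mangrove-restoration assessment with four areas (three restored, one
reference) sampled over three climatic seasons.

## Isotope corrections

Delta notation is δX = (R_sample/R_standard − 1)·10³ with R the heavy/light
isotope ratio (VPDB for carbon, atmospheric N₂ for nitrogen).

**Lipid normalization.** Lipids are ¹³C-depleted; for aquatic animal tissue
with C:N > 3.5 we apply the standard linear correction
δ¹³C′ = δ¹³C − 3.32 + 0.99·C:N. Tissue at or below C:N 3.5, or samples
without a C:N measurement, pass through unchanged (logged).

**Trophic correction.** Consumers are de-enriched to basal (producer)
isotope space by subtracting (TL − 1)·Δ per isotope, with trophic
discrimination factors Δ = (0.4, 3.4) ‰ per trophic level and guild trophic
levels {piscivore 3.0, zoobenthivore 2.7, planktivore 2.6, omnivore 2.6,
detritivore 2.4}. Correcting all the way to TL 1 keeps the mixing model's
fractionation term at zero mean; correcting to TL 2 instead is available
through the configuration, since published workflows differ on the base
level.

**Source screening.** Redundant basal sources inflate mixing-model
uncertainty. For every source pair we correlate replicate values paired by
order within each area × season cell after centring on the cell mean, so
the statistic measures sample-level redundancy rather than a shared
seasonal trend (all sources track season, which would otherwise flag every
pair). A pair with |r| ≥ 0.6 and p < α on either isotope drops one member;
priority is configurable (the default priority list drops seston, which the
built-in scenario generates as a phytoplankton satellite with r ≈ 0.7).

**Mixing-polygon check.** Consumers outside the convex hull of the sources
cannot be expressed as a mixture. Each Monte-Carlo iteration draws every
source's (δ¹³C, δ¹⁵N) from Normal(μ, σ), forms the hull, and tests each
corrected consumer with a half-plane test (boundary counts as inside,
tolerance 1e-9). Consumers inside in fewer than 5% of iterations are
flagged and excluded from the models.

## Community isotopic-niche metrics

Layman metrics of a community's point cloud: δ¹⁵N range (NR), δ¹³C range
(CR), convex-hull area (TA, via the hull's shoelace area; 0 for collinear
or < 3 points), mean distance to centroid (CD), mean nearest-neighbour
distance (MNND) and its sample (n−1) SD (SDNND). Per-area metrics use one
point per taxon (the taxon's mean corrected signature pooled over seasons);
per-area × season ellipses use individual samples — the two conventions
serve the two reporting granularities and both are exposed.

The standard ellipse area is SEA = π√det(S) with S the sample covariance;
the small-sample correction is SEA_C = SEA·(n−1)/(n−2). The Bayesian
version (SEA_B) samples covariances from the conjugate posterior under a
vague normal–inverse-Wishart prior (ν₀ = 3, Ψ₀ = 10⁻³ I, κ₀ = 10⁻³, prior
mean 0) — with n ≳ 20 the posterior is dominated by the data scatter matrix
and the posterior median area agrees with the closed form to a few
percent. Draws convert to areas π√det(Σ); central 50/75/95% intervals are
reported.

## Bayesian mixing model

For one consumer group (area × season × taxon group) with K sources, the
observation model per consumer j and isotope X is

    δ_jX ~ Normal( Σ_k p_k (μ_kX + λ_X),
                   Σ_k p_k² (σ_kX² + τ_X²) + ε_X² )

with source summaries (μ, σ) season-matched, residual-fractionation mean
λ = 0 and SD τ = (1.3, 1.0) ‰ (consumers are pre-corrected, so the
remaining fractionation is a zero-mean nuisance), and a free residual SD
ε_X with a half-Normal(0, 5 ‰) prior absorbing unmodelled within-group
variation. The prior on the diet vector p is the flat Dirichlet(1,…,1).
This "process + residual" error structure scales source variance by p²,
the standard choice for fully-specified consumer-mixture likelihoods.

**Sampler.** Adaptive random-walk Metropolis on unconstrained coordinates:
K−1 additive log-ratio coordinates of p (the Dirichlet prior transforms
with Jacobian Π p_k) plus the two log residual SDs. All chains run
vectorized in lock-step; during burn-in the per-chain scalar step adapts
toward 30% acceptance (Robbins–Monro) and the proposal covariance adapts to
the pooled empirical covariance of visited states — the posterior is
typically a narrow ridge (see below) that an isotropic walk explores
slowly. Both adaptations freeze at the end of burn-in, so the retained
chain is a valid fixed-kernel Markov chain. The reference profile is
3 chains × 300,000 iterations, 200,000 burn-in, thinning 100; the desk
profile used by the tests and the synthetic study is 30,000/10,000/20
(1,000 retained draws per chain), which the convergence diagnostics accept
for K ≤ 5 well-separated sources.

**Diagnostics.** Split-chain Gelman–Rubin R̂ per diet proportion (each
chain halved; R̂ = √(((n−1)/n·W + B/n)/W)); a fit with any R̂ > 1.1 is
flagged non-converged, never silently returned. Geweke z compares the mean
of the first 10% with the last 50% of a chain using batch-means standard
errors (≈ √n batches); the reported per-parameter value is the most extreme
z across chains.

**Summaries.** Per-source posterior medians and central credible intervals
(default 95%); the report view rounds percentages to integers, raw values
are retained.

**Identifiability.** With two tracers and K = 4 sources the diet simplex
retains K − 1 − 2 = 1 unidentified direction: a one-dimensional ridge of
diets reproduces any attainable consumer mean. The posterior is calibrated
(in the recovery experiment below, 95% intervals cover the truth in ~99% of
cells and all R̂ < 1.03), but point estimates cannot be pinned tightly: with
20 consumers per group, posterior medians land within ±0.10 of the true
proportion in only ~60% of cells, because a 1–2 standard-error drift of the
group mean moves the solution along the ridge — especially here, where the
basal sources differ by less than 0.5 ‰ in δ¹⁵N after correction. Users
should interpret the credible intervals, not the medians alone; this is a
property of the 2-tracer/4-source design, not of the sampler.

## Dietary-niche hypervolumes

A community's dietary niche is the point cloud of posterior median diet
vectors (one point per taxon group × season, K dimensions = retained
sources). All areas are z-standardized together with the pooled mean and
sample SD per dimension — per-area scaling would destroy comparability of
volumes. A draw-based mode (full posterior draws as points) exists but the
medians mode is the default, keeping clouds the same size across areas.

The niche region is a Gaussian product-kernel KDE with per-dimension
Silverman bandwidth h_i = σ_i·(4/((d+2)n))^(1/(d+4)), thresholded at the
density c for which the fraction of KDE-sampled points with f ≥ c equals
the mass quantile (default 0.95). The volume is the importance-sampling
estimate V = (1/M)·Σ_{f(xᵢ)≥c} 1/f(xᵢ) over M = 10,000 KDE samples, and the
region is represented by a uniform cloud obtained by 1/f importance
resampling of the in-region samples. Overlap between two regions is
Sorensen's index 2V∩/(V₁+V₂), with V∩ from cross-membership of the two
uniform clouds (capped at min(V₁, V₂)); the 95% CI bootstraps the
underlying niche points (default 100 replicates, percentile interval).

With ~9 points in 4 dimensions the Silverman bandwidth is large, so
absolute volumes are strongly smoothing-dependent — comparisons and
overlaps between areas built with identical settings are meaningful,
absolute magnitudes are not. On a 2-D standard-Normal benchmark (n = 1000)
the estimator reproduces the analytic 95% highest-density area (18.82)
within ~10%, with a known upward bias of order h² from kernel smoothing.

## Environmental statistics

All environmental variables are log10(x+1)-transformed (pH included — the
blanket transform is the documented convention here; an exclusion list is
configurable) and analysed by PCA of the correlation matrix. Variance
explained is eigenvalue shares in percent; loading columns are unit-norm
eigenvectors oriented so the largest-magnitude element is positive;
variables with |loading| > 0.6 are reported as important. Group
comparisons use the tie-corrected Kruskal–Wallis H (χ²-distributed,
df = k−1) followed, when significant, by Dunn's pairwise z tests with the
pooled-ranking tie term Σ(t³−t) and Bonferroni correction over all pairs.

## The synthetic study

The generator emulates the study design: 4 areas × 3 seasons; five basal
sources with seasonal δ means (C₃ plants −29.0…−26.8 ‰, phytoplankton
−24.0…−18.6 ‰, seston tracking phytoplankton through a shared latent term
targeting r ≈ 0.7, plus season-constant seagrass −13.5 ‰ and epiphytes
−16.5 ‰ end members); ~30 consumer taxa in three groups (22 fish, 3
mollusk, 5 crustacean taxa; invertebrate groups default to 10 individuals
per area × season); per-cell true diet vectors with distinct area
signatures (seagrass-reliant mollusks in the rainy season,
phytoplankton-fuelled dry-season webs, a C₃ signal concentrated in the
reference area); and environmental profiles whose means and SDs encode the
measured seasonal contrasts (deep hypoxic rainy season, cool "nortes",
saline dry season).

Consumers are generated as δX = Σ p_k μ_kX + (TL−1)Δ_X + ε with
ε ~ Normal(0, noise_sd) truncated at ±2 SD. Numerical choices worth
flagging:

* **noise_sd = (1.5, 1.0) ‰.** The within-group scatter must be consistent
  with the mixing model's own error structure (τ = 1.3/1.0 ‰ alone implies
  a predicted consumer SD ≳ 1 ‰); a much tighter generator would simulate
  data the model declares impossible and invalidate coverage statements.
* **Truncation at ±2 SD.** Individual diet heterogeneity is bounded — a
  real consumer cannot sit far outside the isotopic envelope spanned by
  its sources, and unbounded Gaussian tails would occasionally generate
  such impossible tissue values.
* **Depleted seagrass/epiphyte end members.** Mass balance against the
  measured consumer envelope (seagrass-dominated consumers near −15 ‰)
  requires detrital-pool values (−13.5/−16.5 ‰) rather than fresh-blade
  signatures.
* **Source replicates default to 3** per source × area × season, the
  study's leaf-sample replication; configurable.

What the generator does **not** emulate: taxon-level diet variation within
a group (all individuals of a group share one true diet vector),
non-Normal measurement error, covariance between isotopes, missing data,
and concentration dependence (elemental C/N content of sources). Passing
recovery tests therefore demonstrate correctness of the inferential
machinery under the model's own assumptions, not robustness to real-data
violations of them.

## Degenerate inputs and tie-breaks

Collinear point sets give hull area 0 and a degenerate-ellipse flag;
nearest-neighbour ties keep the minimal distance value; constant chains
give Geweke z = 0 with a flag and undefined R̂ with a warning; zero-variance
hypervolume dimensions are dropped with a warning before standardization;
all-identical Kruskal–Wallis data give H = 0 flagged degenerate; Bonferroni
p-values are clipped at 1. Problem sizes throughout the test suite and the
acceptance script (20 recovery groups at 20 consumers, desk MCMC profile,
10,000 KDE samples) are the package's desk-scale defaults, chosen so the
full verification runs on a single CPU in minutes.
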
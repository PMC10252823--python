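# isoweb

Stable-isotope food-web analysis for comparing aquatic communities — built
for restoration assessment, where the question is whether the trophic
structure and dietary niche of restored habitats (here, mangrove tidal
channels) have converged on an unmodified reference habitat.

Given bulk-tissue δ¹³C and δ¹⁵N measurements of consumers (fish, mollusks,
crustaceans) and their basal resources (mangrove C₃ plants, phytoplankton,
seston, epiphytes, seagrass), plus per-site environmental variables, the
package provides the full analysis chain:

1. **Corrections** — lipid normalization of δ¹³C from the C:N ratio
   (δ¹³C′ = δ¹³C − 3.32 + 0.99·C:N, applied when C:N > 3.5) and trophic
   de-enrichment δX′ = δX − (TL − 1)·Δ_X with trophic discrimination
   factors Δ = (0.4, 3.4) ‰ per trophic level.
2. **Source screening and feasibility** — Pearson screening of isotopically
   redundant sources and a Monte-Carlo mixing-polygon check that flags
   consumers no source mixture can explain.
3. **Community niche metrics** — the six Layman metrics (NR, CR, TA, CD,
   MNND, SDNND) and standard ellipse areas SEA = π√det(S), the small-sample
   SEA_C, and the Bayesian SEA_B posterior.
4. **Bayesian mixing model** — dietary proportions p of K sources per
   consumer group under δ_jX ~ N(Σ_k p_k μ_kX, Σ_k p_k²(σ_kX² + τ_X²) + ε_X²)
   with a flat Dirichlet prior, fit by covariance-adaptive Metropolis MCMC
   with Gelman–Rubin and Geweke convergence diagnostics.
5. **Dietary-niche hypervolumes** — Gaussian-kernel hypervolumes over
   z-scored diet proportions and Sorensen overlap 2V∩/(V₁+V₂) between each
   restored community and the reference, with bootstrap CIs.
6. **Environmental statistics** — correlation-matrix PCA of log10(x+1)
   variables, Kruskal–Wallis tests and Dunn–Bonferroni post-hocs.

A synthetic-data generator (`isoweb.synthetic`) reproduces the study design
with known true diets, so the whole chain is testable without field data.
See `docs/methods.md` for models, priors, and numerical choices.

## Worked example

```python
import isoweb

# synthetic study: 4 areas x 3 seasons, 5 sources, known true diets
scenario = isoweb.default_scenario(seed=1)
sources = isoweb.generate_sources(scenario)
consumers, truth = isoweb.generate_consumers(scenario)

screen = isoweb.screen_sources(sources, priority=["seston"])
print(screen.dropped)                    # ['seston']
row = screen.r_matrix.query(
    "source_a == 'phytoplankton' and source_b == 'seston'")
print(row[["isotope", "r"]].round(2).to_string(index=False))
# isotope    r
#    d13c 0.73
#    d15n 0.86

summaries = isoweb.summarize_sources(
    sources[sources.source.isin(screen.retained)])
corrected = isoweb.correct_consumers(consumers, scenario.guilds)

group = corrected.query(
    "area == 'RM2' and season == 'rainy' and taxon_group == 'mollusk'")
res = isoweb.fit_mixing_model(
    group, summaries.query("season == 'rainy'").sort_values("source"),
    settings=isoweb.McmcSettings.desk(seed=2),
    group=("RM2", "rainy", "mollusk"))
print(res.summary()[["source", "median_pct", "ci95_lo_pct",
                     "ci95_hi_pct"]].to_string(index=False))
#        source  median_pct  ci95_lo_pct  ci95_hi_pct
#     C3_plants           6            0           18
#     epiphytes          22            1           66
# phytoplankton           6            0           20
#      seagrass          63           26           82
```

The seston screen reproduces the expected redundancy (r ≈ 0.7 with
phytoplankton on both isotopes), and the rainy-season RM2 mollusks are
recovered as seagrass-dominated (true proportion 0.77, posterior median
63% with a 95% credible interval of 26–82%) — with two tracers and four
sources the posterior interval, not the median, is the reliable statement.

The same analysis runs from the shell:

```bash
isoweb simulate --seed 1 --out data/
isoweb run --simulate --desk-mcmc --seed 1 --out results/
```

`results/` then contains per-stage CSVs (source screening and summaries,
corrected consumers with mixing-polygon probabilities, Layman metrics,
ellipse estimates, mixing summaries and diagnostics, hypervolume overlaps,
environmental tests), figures, and a `summary.json` with the seed and
config hash.

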
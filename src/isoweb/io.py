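"""Tabular IO, analysis configuration, and the end-to-end pipeline.

Canonical interchange format is CSV with a fixed header vocabulary; the
analysis configuration is a YAML file whose unspecified keys fall back to
the published defaults (trophic discrimination factors, trophic levels,
MCMC settings).  :func:`run_pipeline` sequences preprocessing, community
metrics, mixing models, hypervolume overlap and environmental statistics
into one results directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InputError
from . import preprocess, community, mixing, hypervolume as hv, envstats

__all__ = ["SCHEMAS", "AnalysisConfig", "load_samples", "load_config",
           "write_table", "run_pipeline"]

log = logging.getLogger(__name__)

#: Required (and optional) columns per table schema.
SCHEMAS = {
    "consumer": {"required": ["taxon", "taxon_group", "guild", "area",
                              "season", "d13c", "d15n"],
                 "optional": ["sample_id", "c_to_n"]},
    "source": {"required": ["source", "area", "season", "d13c", "d15n"],
               "optional": []},
    "environment": {"required": ["area", "season", "site"],
                    "optional": []},   # plus the 8 numeric variables
}

#: Sanity envelopes for measured isotope values (permil).
D13C_RANGE = (-60.0, 10.0)
D15N_RANGE = (-20.0, 40.0)

TAXON_GROUPS = ("fish", "mollusk", "crustacean")


@dataclass
class AnalysisConfig:
    """Resolved analysis configuration with the published defaults."""

    tdf_per_level: tuple = (0.4, 3.4)
    model_tdf_mean: tuple = (0.0, 0.0)
    model_tdf_sd: tuple = (1.3, 1.0)
    trophic_levels: dict = field(default_factory=lambda: {
        "piscivore": 3.0, "zoobenthivore": 2.7, "planktivore": 2.6,
        "omnivore": 2.6, "detritivore": 2.4})
    mcmc_chains: int = 3
    mcmc_iterations: int = 300_000
    mcmc_burn_in: int = 200_000
    mcmc_thin: int = 100
    credibility: float = 0.95
    hv_mass_quantile: float = 0.95
    hv_point_density: float = 100.0
    hv_bootstrap_reps: int = 100
    pca_loading_threshold: float = 0.6
    alpha: float = 0.05
    screen_r_threshold: float = 0.6
    screen_priority: list = field(default_factory=lambda: ["seston"])
    polygon_iterations: int = 1000
    polygon_threshold: float = 0.05
    reference_area: str = "RefM"
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.mcmc_burn_in < self.mcmc_iterations):
            raise ConfigError("mcmc: burn_in must satisfy 0 <= burn_in < "
                              "iterations")
        if self.mcmc_thin < 1:
            raise ConfigError("mcmc: thin must be >= 1")
        if self.mcmc_chains < 2:
            raise ConfigError("mcmc: chains must be >= 2")
        if not (0.0 < self.credibility < 1.0):
            raise ConfigError("credibility must lie in (0, 1)")
        if any(s < 0 for s in self.model_tdf_sd):
            raise ConfigError("model_tdf_sd: SDs must be >= 0")
        if not (0.0 < self.hv_mass_quantile < 1.0):
            raise ConfigError("hv_mass_quantile must lie in (0, 1)")

    def mcmc_settings(self, seed=None) -> mixing.McmcSettings:
        return mixing.McmcSettings(
            chains=self.mcmc_chains, iterations=self.mcmc_iterations,
            burn_in=self.mcmc_burn_in, thin=self.mcmc_thin,
            seed=self.seed if seed is None else seed)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> AnalysisConfig:
    """Load a YAML config; unspecified keys keep the published defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path}: expected a mapping")
    config = AnalysisConfig()
    for key, value in raw.items():
        if not hasattr(config, key):
            raise ConfigError(f"config: unknown key {key!r}")
        current = getattr(config, key)
        if isinstance(current, tuple):
            value = tuple(value)
        setattr(config, key, value)
    config.validate()
    log.info("resolved config: %s (hash %s)", config.to_dict(),
             config.digest())
    return config


def _check_envelope(df: pd.DataFrame, path) -> None:
    for col, (lo, hi) in (("d13c", D13C_RANGE), ("d15n", D15N_RANGE)):
        vals = df[col].to_numpy(dtype=float)
        bad = np.where(~np.isfinite(vals) | (vals < lo) | (vals > hi))[0]
        if len(bad):
            row = int(bad[0])
            raise InputError(
                f"{path}: row {row + 2}: {col} = {vals[row]!r} outside the "
                f"sanity envelope [{lo}, {hi}]")


def load_samples(path, schema: str, column_map: dict | None = None,
                 vocab: dict | None = None) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema.

    ``schema`` is one of ``consumer``, ``source``, ``environment``.
    ``column_map`` renames real-world export headers onto the canonical
    vocabulary before validation; ``vocab`` optionally restricts
    ``area``/``season``/``guild`` labels to configured sets.
    """
    if schema not in SCHEMAS:
        raise InputError(f"unknown schema {schema!r}")
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in SCHEMAS[schema]["required"]
               if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing} "
                         f"for schema {schema!r}")
    if len(df) == 0:
        warnings.warn(f"{path}: table has a valid header but no rows",
                      stacklevel=2)
        return df
    if schema in ("consumer", "source"):
        for col in ("d13c", "d15n"):
            try:
                df[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise InputError(
                    f"{path}: column {col!r} has unparseable values "
                    f"({exc})") from exc
        _check_envelope(df, path)
    if schema == "consumer":
        bad = ~df["taxon_group"].isin(TAXON_GROUPS)
        if bad.any():
            row = int(np.where(bad)[0][0])
            raise InputError(
                f"{path}: row {row + 2}: unknown taxon_group "
                f"{df['taxon_group'].iloc[row]!r}")
    if vocab:
        for col, allowed in vocab.items():
            if col in df.columns:
                bad = ~df[col].isin(allowed)
                if bad.any():
                    row = int(np.where(bad)[0][0])
                    raise InputError(
                        f"{path}: row {row + 2}: unknown {col} "
                        f"{df[col].iloc[row]!r}")
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


# -- pipeline ---------------------------------------------------------------

def run_pipeline(consumers: pd.DataFrame, sources: pd.DataFrame,
                 env: pd.DataFrame | None, config: AnalysisConfig,
                 out_dir, make_figures: bool = False) -> dict:
    """Run the full analysis and write per-stage outputs to ``out_dir``.

    Stages: source screening and summaries -> consumer correction and
    mixing-polygon check -> Layman metrics and SEA per community -> one
    mixing model per (area, season, taxon group) -> per-area dietary
    hypervolumes and Sorensen overlap against the reference area ->
    environmental PCA / Kruskal-Wallis / Dunn tests.

    Returns a report dict (also written as ``summary.json``).
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"config_hash": config.digest(), "seed": config.seed,
              "stages": {}}
    rng = np.random.default_rng(config.seed)

    def stage_seed():
        return int(rng.integers(0, 2 ** 31))

    # 1. preprocess ---------------------------------------------------------
    screen = preprocess.screen_sources(
        sources, alpha=config.alpha, r_threshold=config.screen_r_threshold,
        priority=config.screen_priority)
    retained = sources[sources["source"].isin(screen.retained)]
    summaries = preprocess.summarize_sources(retained)
    corrected = preprocess.correct_consumers(
        consumers, config.trophic_levels, tdf=config.tdf_per_level)
    polygon_parts = []
    for season, grp in corrected.groupby("season"):
        season_sources = summaries[summaries["season"] == season]
        polygon_parts.append(preprocess.mixing_polygon_check(
            grp, season_sources, n_iter=config.polygon_iterations,
            seed=stage_seed(), threshold=config.polygon_threshold))
    checked = pd.concat(polygon_parts, ignore_index=True)
    write_table(screen.r_matrix, out / "source_screening.csv")
    write_table(summaries, out / "source_summaries.csv")
    write_table(checked, out / "consumers_corrected.csv")
    report["stages"]["preprocess"] = {
        "sources_retained": screen.retained,
        "sources_dropped": screen.dropped,
        "consumers_flagged": int(checked["polygon_excluded"].sum()),
    }
    usable = checked[~checked["polygon_excluded"]]

    # 2. community metrics --------------------------------------------------
    metric_rows, ellipse_rows = [], []
    for area, grp in usable.groupby("area"):
        taxon_means = (grp.groupby("taxon")[["d13c_corr", "d15n_corr"]]
                       .mean().to_numpy())
        if len(taxon_means) >= 2:
            m = community.layman_metrics(taxon_means)
            metric_rows.append({"area": area, "nr": m.nr, "cr": m.cr,
                                "ta": m.ta, "cd": m.cd, "mnnd": m.mnnd,
                                "sdnnd": m.sdnnd, "n_taxa": m.n_points})
    for (area, season), grp in usable.groupby(["area", "season"]):
        pts = grp[["d13c_corr", "d15n_corr"]].to_numpy()
        if len(pts) < 3:
            continue
        try:
            est = community.sea_bayesian(pts, seed=stage_seed())
        except InputError:
            continue
        ellipse_rows.append({
            "area": area, "season": season, "sea": est.sea,
            "sea_c": est.sea_c, "sea_b_median": est.sea_b_median,
            "sea_b_lo95": est.credible_intervals[0.95][0],
            "sea_b_hi95": est.credible_intervals[0.95][1], "n": est.n})
    layman_df = pd.DataFrame(metric_rows)
    ellipse_df = pd.DataFrame(ellipse_rows)
    write_table(layman_df, out / "layman_metrics.csv")
    write_table(ellipse_df, out / "standard_ellipses.csv")
    report["stages"]["community_metrics"] = {
        "areas": layman_df["area"].tolist() if len(layman_df) else []}

    # 3. mixing models ------------------------------------------------------
    settings = config.mcmc_settings(seed=stage_seed())
    results, summary_rows, diag_rows = [], [], []
    for (area, season, group), grp in usable.groupby(
            ["area", "season", "taxon_group"]):
        if len(grp) < 2:
            log.info("mixing: skipping %s (n < 2)", (area, season, group))
            continue
        season_sources = (summaries[summaries["season"] == season]
                          .sort_values("source"))
        res = mixing.fit_mixing_model(
            grp, season_sources, model_tdf_sd=config.model_tdf_sd,
            settings=mixing.McmcSettings(
                chains=settings.chains, iterations=settings.iterations,
                burn_in=settings.burn_in, thin=settings.thin,
                seed=stage_seed()),
            group=(area, season, group))
        results.append(res)
        for i, source in enumerate(res.sources):
            summary_rows.append({
                "area": area, "season": season, "taxon_group": group,
                "source": source, "median": res.medians[i],
                "ci95_lo": res.ci95[i, 0], "ci95_hi": res.ci95[i, 1]})
            diag_rows.append({
                "area": area, "season": season, "taxon_group": group,
                "source": source, "rhat": res.rhat[i],
                "geweke_z": res.geweke_z[i],
                "converged": res.converged})
    mix_df = pd.DataFrame(summary_rows)
    write_table(mix_df, out / "mixing_summaries.csv")
    write_table(pd.DataFrame(diag_rows), out / "mixing_diagnostics.csv")
    report["stages"]["mixing_model"] = {
        "n_groups": len(results),
        "all_converged": bool(all(r.converged for r in results)),
    }

    # 4. hypervolumes -------------------------------------------------------
    areas = sorted({r.group[0] for r in results})
    overlap_rows = []
    if len(areas) < 2:
        log.info("hypervolume: skipped (fewer than 2 areas with mixing "
                 "results)")
        report["stages"]["niche_hypervolume"] = {
            "skipped": "fewer than 2 areas"}
    else:
        point_sets = {}
        for area in areas:
            rs = [r for r in results if r.group[0] == area]
            if len(rs) >= 2:
                point_sets[area] = hv.assemble_niche_points(rs, area=area)
        std_sets, z_params = hv.z_transform(point_sets)
        volumes = {}
        for area, ps in std_sets.items():
            try:
                volumes[area] = hv.build_hypervolume(
                    ps.points, mass_quantile=config.hv_mass_quantile,
                    point_density=config.hv_point_density,
                    seed=stage_seed())
            except InputError as exc:
                log.warning("hypervolume: %s skipped (%s)", area, exc)
        ref = config.reference_area
        for area in sorted(volumes):
            if area == ref or ref not in volumes:
                continue
            res = hv.sorensen_overlap(
                volumes[area], volumes[ref],
                bootstrap_reps=config.hv_bootstrap_reps, seed=stage_seed())
            overlap_rows.append({
                "area": area, "reference": ref, "sorensen": res.sorensen,
                "ci95_lo": res.ci95[0], "ci95_hi": res.ci95[1],
                "volume_area": res.v1, "volume_reference": res.v2,
                "volume_intersection": res.v_intersection})
        overlap_df = pd.DataFrame(overlap_rows)
        write_table(overlap_df, out / "hypervolume_overlap.csv")
        report["stages"]["niche_hypervolume"] = {
            "volumes": {a: v.volume_ for a, v in volumes.items()},
            "z_params": {k: list(v) for k, v in z_params.items()},
            "overlaps": overlap_rows,
        }

    # 5. environmental statistics ------------------------------------------
    if env is not None and len(env):
        pca = envstats.pca_correlation(
            env, loading_threshold=config.pca_loading_threshold)
        kw_rows = []
        for factor in ("season", "area"):
            if env[factor].nunique() < 2:
                log.info("envstats: factor %r has a single level, tests "
                         "skipped", factor)
                continue
            for var in [c for c in env.columns
                        if c not in ("area", "season", "site")]:
                vectors = [g[var].to_numpy()
                           for _, g in env.groupby(factor)]
                labels = [str(k) for k, _ in env.groupby(factor)]
                kw = envstats.kruskal_wallis(vectors)
                row = {"factor": factor, "variable": var, "h": kw.h,
                       "df": kw.df, "p": kw.p}
                if kw.p < config.alpha and not kw.degenerate:
                    dunn = envstats.dunn_bonferroni(vectors, labels=labels)
                    row["significant_pairs"] = "; ".join(
                        f"{a}-{b}" for a, b, _, _, pb in dunn.pairs
                        if pb < config.alpha)
                kw_rows.append(row)
        write_table(pd.DataFrame(kw_rows), out / "environment_tests.csv")
        write_table(pca.loadings.reset_index(names="variable"),
                    out / "pca_loadings.csv")
        report["stages"]["envstats"] = {
            "pca_first_two_axes_pct":
                float(pca.variance_explained[:2].sum()),
            "important_pc1": pca.important_variables.get("PC1", []),
        }

    if make_figures:
        _write_figures(usable, summaries, ellipse_df, report, out)

    with open(out / "summary.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    log.info("pipeline complete: %s", out)
    return report


def _write_figures(consumers, summaries, ellipse_df, report, out) -> None:
    """Biplot, ellipse and PCA figures for the results directory."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, consumers["area"].nunique(),
                             figsize=(4 * consumers["area"].nunique(), 4),
                             sharex=True, sharey=True, squeeze=False)
    for ax, (area, grp) in zip(axes.ravel(), consumers.groupby("area")):
        ax.scatter(grp["d13c_corr"], grp["d15n_corr"], s=12, c="gray",
                   label="consumers")
        ax.errorbar(summaries["mu13"], summaries["mu15"],
                    xerr=summaries["sd13"], yerr=summaries["sd15"],
                    fmt="o", ms=5, lw=1, label="sources")
        ax.set_title(area)
        ax.set_xlabel("$\\delta^{13}$C (‰)")
    axes[0, 0].set_ylabel("$\\delta^{15}$N (‰)")
    axes[0, 0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(out / "biplot.png", dpi=120)
    plt.close(fig)

    if len(ellipse_df):
        fig, ax = plt.subplots(figsize=(7, 4))
        labels = ellipse_df["area"] + "-" + ellipse_df["season"]
        x = np.arange(len(ellipse_df))
        ax.vlines(x, ellipse_df["sea_b_lo95"], ellipse_df["sea_b_hi95"],
                  color="steelblue", lw=4, alpha=0.5)
        ax.plot(x, ellipse_df["sea_b_median"], "ko", label="SEA$_B$ median")
        ax.plot(x, ellipse_df["sea_c"], "rx", label="SEA$_C$")
        ax.set_xticks(x, labels, rotation=60, fontsize=7)
        ax.set_ylabel("ellipse area (‰$^2$)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "ellipses.png", dpi=120)
        plt.close(fig)
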
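"""Isotope corrections and model-ready preprocessing.

Converts raw delta13C / delta15N measurements into the values the mixing
model and niche metrics consume: delta-notation computation, lipid
normalization of delta13C from the tissue C:N ratio, trophic-level
de-enrichment with trophic discrimination factors (TDFs), Pearson screening
of redundant basal sources, per-source summary statistics, and a Monte-Carlo
mixing-polygon feasibility check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import pearsonr

from .errors import ConfigError, GeometryError, InputError

__all__ = [
    "compute_delta", "lipid_normalize", "trophic_correct",
    "correct_consumers", "screen_sources", "summarize_sources",
    "mixing_polygon_check", "points_in_hull", "SourceScreenResult",
]

log = logging.getLogger(__name__)

#: C:N ratio above which lipid normalization is applied (aquatic animal
#: tissue below this is considered lipid-poor and left unchanged).
LIPID_CN_THRESHOLD = 3.5

#: Boundary tolerance of the half-plane point-in-hull test.
HULL_TOL = 1e-9


def compute_delta(r_sample, r_standard):
    """Delta notation: ``(R_sample / R_standard - 1) * 1000`` permil.

    ``R`` is the heavy/light isotope ratio (13C/12C against VPDB,
    15N/14N against atmospheric N2).  Raises on non-positive ratios.
    """
    r_sample = np.asarray(r_sample, dtype=float)
    r_standard = np.asarray(r_standard, dtype=float)
    if np.any(r_sample <= 0) or np.any(r_standard <= 0):
        raise ValueError("isotope ratios must be positive")
    out = (r_sample / r_standard - 1.0) * 1000.0
    return float(out) if out.ndim == 0 else out


def lipid_normalize(d13c: float, c_to_n) -> float:
    """Lipid-normalize a delta13C value from the tissue C:N ratio.

    Applies the linear aquatic-animal correction
    ``d13C_norm = d13C - 3.32 + 0.99 * C:N`` when the C:N ratio exceeds
    3.5 (lipid-rich tissue); below that, or when C:N is missing, the value
    passes through unchanged (with a log message).
    """
    if c_to_n is None or (isinstance(c_to_n, float) and np.isnan(c_to_n)):
        log.warning("lipid_normalize: C:N missing, d13c left unchanged")
        return float(d13c)
    c_to_n = float(c_to_n)
    if c_to_n <= 0:
        raise ValueError(f"C:N ratio must be positive, got {c_to_n}")
    if c_to_n <= LIPID_CN_THRESHOLD:
        return float(d13c)
    return float(d13c) - 3.32 + 0.99 * c_to_n


def trophic_correct(d13c, d15n, tl: float, tdf=(0.4, 3.4)):
    """De-enrich consumer values to basal (trophic level 1) isotope space.

    Subtracts ``(TL - 1) * Delta`` per isotope, where ``Delta`` is the
    per-trophic-level discrimination factor.  With the zero-mean
    fractionation used by the mixing model, corrected consumers are directly
    comparable with source signatures.
    """
    if tl < 1:
        raise ValueError(f"trophic level must be >= 1, got {tl}")
    d13, d15 = tdf
    steps = tl - 1.0
    return (np.asarray(d13c, dtype=float) - steps * d13,
            np.asarray(d15n, dtype=float) - steps * d15)


def correct_consumers(consumers: pd.DataFrame, trophic_levels: dict,
                      tdf=(0.4, 3.4), lipid: bool = True) -> pd.DataFrame:
    """Apply lipid normalization and trophic correction to a consumer table.

    Adds ``d13c_corr``, ``d15n_corr`` and ``corrections_applied`` columns;
    the guild of every row must appear in ``trophic_levels``.
    """
    unknown = sorted(set(consumers["guild"]) - set(trophic_levels))
    if unknown:
        taxa = sorted(set(
            consumers.loc[consumers["guild"].isin(unknown), "taxon"]))
        raise ConfigError(
            f"trophic_levels: no trophic level for guilds {unknown} "
            f"(taxa: {taxa})")
    out = consumers.copy()
    d13c = out["d13c"].to_numpy(dtype=float)
    labels = []
    if lipid and "c_to_n" in out.columns:
        cn = out["c_to_n"].to_numpy(dtype=float)
        applied = np.isfinite(cn) & (cn > LIPID_CN_THRESHOLD)
        d13c = np.where(applied, d13c - 3.32 + 0.99 * cn, d13c)
    else:
        applied = np.zeros(len(out), dtype=bool)
    tl = out["guild"].map(trophic_levels).to_numpy(dtype=float)
    steps = tl - 1.0
    d13c_corr = d13c - steps * tdf[0]
    d15n_corr = out["d15n"].to_numpy(dtype=float) - steps * tdf[1]
    for i in range(len(out)):
        lab = ["trophic"]
        if applied[i]:
            lab.insert(0, "lipid")
        labels.append("+".join(lab))
    out["d13c_corr"] = d13c_corr
    out["d15n_corr"] = d15n_corr
    out["corrections_applied"] = labels
    return out


@dataclass
class SourceScreenResult:
    """Audit trail of the Pearson source-redundancy screen."""

    retained: list
    dropped: list
    r_matrix: pd.DataFrame        # rows: (source_a, source_b, isotope, r, p)
    audit: list = field(default_factory=list)


def screen_sources(sources: pd.DataFrame, alpha: float = 0.05,
                   r_threshold: float = 0.6,
                   pairing=("area", "season"),
                   priority: list | None = None) -> SourceScreenResult:
    """Drop basal sources that are isotopically redundant with another.

    Replicates of two sources are paired by their order within each shared
    ``pairing`` cell (default area x season) after centring on the cell
    mean, so the correlation measures sample-level redundancy rather than a
    shared seasonal trend.  A pair with ``|r| >= r_threshold`` and
    ``p < alpha`` on either isotope flags one member for removal.  Removal
    priority: any source listed in ``priority`` goes first; otherwise the
    member with fewer observations, ties broken by dropping the
    alphabetically later name.
    """
    names = sorted(sources["source"].unique())
    if len(names) < 2:
        raise InputError("screen_sources: need at least two sources")
    pairing = list(pairing)
    counts = sources.groupby("source").size()
    priority = list(priority or [])
    records, drops, audit = [], set(), []

    def residual_pairs(a, b, iso):
        """Within-cell centred replicate pairs of sources a and b."""
        xs, ys = [], []
        ga = sources[sources["source"] == a].groupby(pairing)
        gb = sources[sources["source"] == b].groupby(pairing)
        cells = sorted(set(ga.groups) & set(gb.groups))
        for cell in cells:
            va = ga.get_group(cell)[iso].to_numpy(dtype=float)
            vb = gb.get_group(cell)[iso].to_numpy(dtype=float)
            m = min(len(va), len(vb))
            xs.append(va[:m] - va[:m].mean())
            ys.append(vb[:m] - vb[:m].mean())
        if not cells:
            raise InputError(
                f"screen_sources: sources {a!r}/{b!r} share no "
                f"{tuple(pairing)} cells")
        return np.concatenate(xs), np.concatenate(ys)

    for i, a in enumerate(names):
        for b in names[i + 1:]:
            flagged = False
            for iso in ("d13c", "d15n"):
                x, y = residual_pairs(a, b, iso)
                if len(x) < 3:
                    raise InputError(
                        f"screen_sources: sources {a!r}/{b!r} share fewer "
                        f"than 3 paired observations")
                if np.std(x) == 0 or np.std(y) == 0:
                    r, p = np.nan, np.nan
                else:
                    r, p = pearsonr(x, y)
                records.append({"source_a": a, "source_b": b, "isotope": iso,
                                "r": r, "p": p, "n": len(x)})
                if np.isfinite(r) and abs(r) >= r_threshold and p < alpha:
                    flagged = True
            if flagged:
                victim = _drop_choice(a, b, counts, priority)
                drops.add(victim)
                audit.append(f"dropped {victim!r}: |r| >= {r_threshold} with "
                             f"{a if victim == b else b!r} at alpha={alpha}")
    retained = [n for n in names if n not in drops]
    for line in audit:
        log.info("screen_sources: %s", line)
    return SourceScreenResult(retained=retained, dropped=sorted(drops),
                              r_matrix=pd.DataFrame(records), audit=audit)


def _drop_choice(a, b, counts, priority):
    for name in priority:
        if name in (a, b):
            return name
    if counts[a] != counts[b]:
        return a if counts[a] < counts[b] else b
    return max(a, b)   # tie: drop the alphabetically later source


def summarize_sources(sources: pd.DataFrame,
                      group_by=("source", "season")) -> pd.DataFrame:
    """Mean and sample SD (n-1) per source group per isotope.

    Groups with a single replicate are flagged ``incomplete`` (their SDs are
    undefined) and should be excluded from mixing models.
    """
    group_by = list(group_by)
    g = sources.groupby(group_by)
    out = g.agg(mu13=("d13c", "mean"), sd13=("d13c", lambda v: v.std(ddof=1)),
                mu15=("d15n", "mean"), sd15=("d15n", lambda v: v.std(ddof=1)),
                n=("d13c", "size")).reset_index()
    out["incomplete"] = out["n"] < 2
    if out["incomplete"].any():
        bad = out.loc[out["incomplete"], group_by].to_records(index=False)
        warnings.warn(f"summarize_sources: single-replicate groups flagged "
                      f"incomplete: {list(bad)}", stacklevel=2)
    return out


def points_in_hull(points: np.ndarray, hull_points: np.ndarray,
                   tol: float = HULL_TOL) -> np.ndarray:
    """Half-plane membership test; boundary points count as inside.

    ``hull_points`` are the (possibly redundant) vertices spanning the hull.
    Raises :class:`GeometryError` for degenerate (collinear / <3 point)
    hulls.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    hull_points = np.asarray(hull_points, dtype=float)
    if len(hull_points) < 3:
        raise GeometryError("point-in-hull test needs >= 3 hull points")
    try:
        hull = ConvexHull(hull_points)
    except QhullError as exc:
        raise GeometryError(f"degenerate hull: {exc}") from exc
    a = hull.equations[:, :-1]
    b = hull.equations[:, -1]
    return np.all(points @ a.T + b <= tol, axis=1)


def mixing_polygon_check(consumers: pd.DataFrame, sources: pd.DataFrame,
                         n_iter: int = 1000, seed: int | None = None,
                         threshold: float = 0.05) -> pd.DataFrame:
    """Monte-Carlo feasibility of consumers inside the source mixing polygon.

    For each iteration every source's (delta13C, delta15N) is drawn from
    Normal(mu, sd); the convex hull of the draws is formed and each
    (corrected) consumer point tested for membership.  The returned table
    holds the per-consumer fraction of iterations inside (``p_inside``) and
    an exclusion flag for consumers below ``threshold``.

    ``consumers`` must carry ``d13c_corr``/``d15n_corr`` columns;
    ``sources`` is a summary table with ``mu13, sd13, mu15, sd15`` rows.
    """
    if len(sources) < 3:
        raise GeometryError("mixing polygon needs >= 3 sources")
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100 for a stable estimate")
    rng = np.random.default_rng(seed)
    pts = consumers[["d13c_corr", "d15n_corr"]].to_numpy(dtype=float)
    mu = sources[["mu13", "mu15"]].to_numpy(dtype=float)
    sd = sources[["sd13", "sd15"]].to_numpy(dtype=float)
    sd = np.nan_to_num(sd, nan=0.0)
    inside = np.zeros(len(pts))
    for _ in range(n_iter):
        draw = mu + sd * rng.standard_normal(mu.shape)
        try:
            inside += points_in_hull(pts, draw)
        except GeometryError:
            # collinear draw: zero-area polygon, nothing strictly inside
            continue
    out = consumers.copy()
    out["p_inside"] = inside / n_iter
    out["polygon_excluded"] = out["p_inside"] < threshold
    return out
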
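"""Phenotype quality control, cross means, and broad-sense heritability.

The phenotype table holds replicated offspring counts per F1 cross (default
three replicate vials) plus a mock-treatment control count.  QC follows the
toxicity-assay logic: whole weekly blocks whose mean fecundity lies outside a
target knockdown window are discarded, and crosses whose *control* fecundity
is too low (inviable or poorly fertile lines) are removed before mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HeritabilityEstimate",
    "rep_columns",
    "filter_blocks",
    "filter_controls",
    "cross_means",
    "estimate_heritability",
]


def rep_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("rep")]


def filter_blocks(
    table: pd.DataFrame, min_mean: float, max_mean: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop whole blocks whose across-cross mean fecundity is outside [min, max].

    Returns the filtered table and a per-block report (block, mean_fecundity,
    n_crosses, dropped).
    """
    if not (min_mean < max_mean):
        raise ValueError("min_mean must be below max_mean")
    if table.empty:
        return table.copy(), pd.DataFrame(
            columns=["block", "mean_fecundity", "n_crosses", "dropped"]
        )
    reps = rep_columns(table)
    per_cross = table[reps].mean(axis=1)
    report = (
        pd.DataFrame({"block": table["block"], "m": per_cross})
        .groupby("block", sort=True)
        .agg(mean_fecundity=("m", "mean"), n_crosses=("m", "size"))
        .reset_index()
    )
    report["dropped"] = ~report["mean_fecundity"].between(min_mean, max_mean)
    keep = set(report.loc[~report["dropped"], "block"])
    return table[table["block"].isin(keep)].reset_index(drop=True), report


def filter_controls(table: pd.DataFrame, min_control: int = 50) -> pd.DataFrame:
    """Remove crosses whose mock-treatment control produced fewer than
    ``min_control`` offspring (strictly fewer: a control of exactly
    ``min_control`` is retained).  Missing controls (saturated, uncounted)
    are retained."""
    ctrl = table["control_count"]
    keep = ctrl.isna() | (ctrl >= min_control)
    return table[keep].reset_index(drop=True)


def cross_means(table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean over replicate vials per cross, ordered by cross_id."""
    reps = rep_columns(table)
    if not reps:
        raise ValueError("no replicate columns (rep1, rep2, ...) in table")
    vals = table[reps].to_numpy(dtype=float)
    n_obs = np.sum(~np.isnan(vals), axis=1)
    if (n_obs == 0).any():
        warnings.warn("crosses with zero replicates excluded from means")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(vals, axis=1)
    out = pd.DataFrame({"cross_id": table["cross_id"], "mean": m})[n_obs > 0]
    return out.sort_values("cross_id", kind="stable").reset_index(drop=True)


@dataclass
class HeritabilityEstimate:
    """Broad-sense heritability from a one-way random-effects decomposition.

    ``h2_individual`` = V_g / (V_g + V_e) is the heritability of a single
    replicate measurement; ``h2_cross_means`` = V_g / (V_g + V_e/r) is the
    heritability of the r-replicate cross mean, the quantity the genome scan
    actually maps.
    """

    var_genetic: float
    var_env: float
    h2_individual: float
    h2_cross_means: float
    n_crosses: int
    reps_per_cross: float


def estimate_heritability(table: pd.DataFrame) -> HeritabilityEstimate:
    """One-way ANOVA (moment) estimator of between-cross and within-cross variance.

    With balanced data V_g = (MS_between - MS_within)/r and V_e = MS_within;
    unbalanced data uses the standard coefficient
    n0 = (N - sum(n_i^2)/N) / (k - 1) in place of r.  A negative V_g is
    truncated to zero.
    """
    reps = rep_columns(table)
    vals = table[reps].to_numpy(dtype=float)
    counts = np.sum(~np.isnan(vals), axis=1)
    ok = counts >= 2
    vals, counts = vals[ok], counts[ok]
    k = vals.shape[0]
    if k < 2:
        raise ValueError("need at least two crosses with >= 2 replicates")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        gm = np.nanmean(vals)
        means = np.nanmean(vals, axis=1)
    n_total = counts.sum()
    ss_between = float(np.sum(counts * (means - gm) ** 2))
    ss_within = float(np.nansum((vals - means[:, None]) ** 2))
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (n_total - k)
    n0 = (n_total - np.sum(counts**2) / n_total) / (k - 1)
    var_g = max(0.0, (ms_between - ms_within) / n0)
    var_e = ms_within
    r_bar = float(np.mean(counts))
    if var_g + var_e <= 0:
        warnings.warn("zero total variance; heritability set to 0")
        h2i = h2m = 0.0
    else:
        h2i = var_g / (var_g + var_e)
        h2m = var_g / (var_g + var_e / r_bar)
    return HeritabilityEstimate(
        var_genetic=var_g,
        var_env=var_e,
        h2_individual=h2i,
        h2_cross_means=h2m,
        n_crosses=k,
        reps_per_cross=r_bar,
    )
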
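"""QTL localization and effect estimation.

Around a detected peak the model is refit *without* term dropping so the
degrees of freedom stay constant across the region, and the F statistic is
converted to a LOD score, LOD = (n/2) log10(RSS0/RSS1).  Two interval types
are computed from the LOD curve: the traditional 2-LOD support interval, and
a Bayes credible interval that treats 10^LOD as an unnormalized posterior for
QTL location (the better-calibrated choice for many-founder crosses).
Founder effects at the peak are estimated per parental population on
subpopulation-corrected residuals, and each QTL's share of the cross-mean
heritability is the incremental R-squared of the genotype terms divided by
H2 of cross means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scan import (
    REFERENCE_FOUNDER_INDEX,
    genotype_columns_at,
    drop_underrepresented,
    parent_indices,
    subpop_indicator,
    _rss_rank,
)
from .synthdata import HaplotypeProbSet, N_FOUNDERS

__all__ = [
    "LODCurve",
    "lod_curve",
    "lod_from_f",
    "lod_drop_interval",
    "bayes_credible_interval",
    "FounderEffects",
    "founder_effects",
    "variance_explained",
    "percent_heritability",
]


@dataclass
class LODCurve:
    """LOD scores over a region, constant model df (no term dropping)."""

    grid: pd.DataFrame  # arm, pos_bp, pos_cM (region rows)
    lod: np.ndarray  # (P,) or (P, m) for many phenotype columns
    n: int

    def peak_index(self) -> int:
        return int(np.argmax(self.lod if self.lod.ndim == 1 else self.lod[:, 0]))


def lod_from_f(F, df1: int, df2: int, n: int):
    """Algebraic F -> LOD conversion: (n/2) log10(1 + df1 F / df2)."""
    return (n / 2.0) * np.log10(1.0 + df1 * np.asarray(F, dtype=float) / df2)


def lod_curve(
    y: np.ndarray,
    design: pd.DataFrame,
    probsA: HaplotypeProbSet,
    probsB: HaplotypeProbSet,
    region: np.ndarray | None = None,
    include_subpop: bool = True,
) -> LODCurve:
    """LOD = (n/2) log10(RSS0/RSS1) at every region position, full model.

    ``region`` is an array of grid row indices (default: the whole grid).
    ``y`` may be a vector or an (n, m) matrix of phenotype columns (used for
    coverage simulations).  No genotype terms are dropped, keeping df
    constant; rank deficiency falls back to the pseudo-inverse fit.
    """
    Y = np.asarray(y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n = Y.shape[0]
    pos = np.arange(len(probsA.grid)) if region is None else np.asarray(region)
    pidx = parent_indices(design, probsA, probsB)
    base = [np.ones(n)] + ([subpop_indicator(design)] if include_subpop else [])
    X_null = np.column_stack(base)
    rss0, _ = _rss_rank(X_null, Y)
    lod = np.zeros((len(pos), Y.shape[1]))
    for k, p in enumerate(pos):
        G, _ = genotype_columns_at(int(p), design, probsA, probsB, _parent_idx=pidx)
        rss1, _ = _rss_rank(np.hstack([X_null, G]), Y)
        with np.errstate(divide="ignore"):
            lod[k] = np.where(rss1 > 0, (n / 2.0) * np.log10(rss0 / np.maximum(rss1, 1e-300)),
                              np.inf)
    lod = np.maximum(lod, 0.0)
    return LODCurve(grid=probsA.grid.iloc[pos].reset_index(drop=True),
                    lod=lod[:, 0] if squeeze else lod, n=n)


def _interval_frame(curve: LODCurve, lo: int, hi: int) -> dict:
    g = curve.grid
    return {
        "start_arm": g["arm"].iloc[lo], "end_arm": g["arm"].iloc[hi],
        "start_bp": int(g["pos_bp"].iloc[lo]), "end_bp": int(g["pos_bp"].iloc[hi]),
        "start_cM": float(g["pos_cM"].iloc[lo]), "end_cM": float(g["pos_cM"].iloc[hi]),
        "start_index": lo, "end_index": hi,
    }


def lod_drop_interval(curve: LODCurve, drop: float = 2.0) -> dict:
    """Support interval: positions contiguous with the peak where LOD stays
    within ``drop`` of the maximum (ties at the peak broken leftmost)."""
    lod = curve.lod if curve.lod.ndim == 1 else curve.lod[:, 0]
    if len(lod) == 0:
        raise ValueError("empty LOD curve")
    peak = int(np.argmax(lod))
    if np.allclose(lod, lod[peak]):
        warnings.warn("flat LOD curve; support interval spans the whole region")
        return _interval_frame(curve, 0, len(lod) - 1)
    floor = lod[peak] - drop
    lo = peak
    while lo > 0 and lod[lo - 1] >= floor:
        lo -= 1
    hi = peak
    while hi < len(lod) - 1 and lod[hi + 1] >= floor:
        hi += 1
    return _interval_frame(curve, lo, hi)


def bayes_credible_interval(curve: LODCurve, coverage: float = 0.95) -> dict:
    """Equal-tail credible interval treating 10^LOD as the location posterior.

    Weights w_k = 10^LOD_k are normalized over the region; the interval runs
    from the first grid point whose cumulative mass reaches (1-coverage)/2 to
    the first reaching 1-(1-coverage)/2.
    """
    if not (0 < coverage < 1):
        raise ValueError("coverage must be in (0, 1)")
    lod = curve.lod if curve.lod.ndim == 1 else curve.lod[:, 0]
    w = np.power(10.0, lod - lod.max())  # stabilized
    w = w / w.sum()
    cum = np.cumsum(w)
    alpha = (1.0 - coverage) / 2.0
    lo = int(np.searchsorted(cum, alpha))
    hi = int(np.searchsorted(cum, 1.0 - alpha))
    hi = min(hi, len(lod) - 1)
    return _interval_frame(curve, lo, hi)


@dataclass
class FounderEffects:
    """Per-founder effect estimates for one parental population at a position.

    ``table`` columns: founder, effect, se, n_confident, included.  Effects
    are fit on subpopulation-corrected residuals; founders whose probability
    mass over crosses is not above ``min_sum`` are excluded (reported as
    missing, not zero), and means are suppressed below ``min_obs`` confident
    assignments.
    """

    population: str
    position: tuple[str, int]
    table: pd.DataFrame


def founder_effects(
    y: np.ndarray,
    design: pd.DataFrame,
    probsA: HaplotypeProbSet,
    probsB: HaplotypeProbSet,
    position: tuple[str, int],
    min_sum: float = 4.8,
    confident: float = 0.95,
    min_obs: int = 5,
) -> tuple[FounderEffects, FounderEffects]:
    """Founder-effect estimates at (arm, pos_bp) for pA (paternal) and pB (maternal)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    Xs = np.column_stack([np.ones(n), subpop_indicator(design)])
    beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
    resid = y - Xs @ beta
    out = []
    for probs, parent_col in ((probsA, "paternal"), (probsB, "maternal")):
        pos = probs.position_index(*position)
        G = probs.probs[probs.index_of(design[parent_col]), pos, :]
        sums = G.sum(axis=0)
        included = sums > min_sum
        eff = np.full(N_FOUNDERS, np.nan)
        se = np.full(N_FOUNDERS, np.nan)
        if included.any():
            Gi = G[:, included]
            b, *_ = np.linalg.lstsq(Gi, resid, rcond=None)
            r = resid - Gi @ b
            dof = max(n - Gi.shape[1], 1)
            sigma2 = float(r @ r) / dof
            cov = sigma2 * np.linalg.pinv(Gi.T @ Gi)
            eff[included] = b
            se[included] = np.sqrt(np.maximum(np.diag(cov), 0.0))
        n_conf = (G > confident).sum(axis=0)
        eff = np.where(n_conf >= min_obs, eff, np.nan)  # suppress sparse means
        table = pd.DataFrame(
            {"founder": probs.founders, "effect": eff, "se": se,
             "n_confident": n_conf, "included": included}
        )
        out.append(FounderEffects(population=probs.population, position=position, table=table))
    return out[0], out[1]


def variance_explained(
    y: np.ndarray,
    design: pd.DataFrame,
    probsA: HaplotypeProbSet,
    probsB: HaplotypeProbSet,
    positions: list[tuple[str, int]],
    threshold: float = 4.8,
    adjusted: bool = True,
) -> float:
    """Incremental R^2 of genotype terms at one or several positions, on the
    subpopulation-corrected scale.

    The raw statistic is (RSS_subpop - RSS_full) / RSS_subpop; by default the
    degrees-of-freedom-adjusted version
    1 - (RSS_full/(n-p_full)) / (RSS_subpop/(n-p_subpop)) is reported, since
    with 14 genotype regressors per position the raw R^2 overstates the QTL's
    share by roughly df1/n of the residual variance.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X_null = np.column_stack([np.ones(n), subpop_indicator(design)])
    rss0, rank0 = _rss_rank(X_null, y)
    pidx = parent_indices(design, probsA, probsB)
    blocks = [X_null]
    for arm, bp in positions:
        p = probsA.position_index(arm, bp)
        G, names = genotype_columns_at(p, design, probsA, probsB, _parent_idx=pidx)
        G, _, _ = drop_underrepresented(G, names, threshold)
        blocks.append(G)
    rss1, rank1 = _rss_rank(np.hstack(blocks), y)
    if adjusted and n > rank1:
        r2 = 1.0 - (rss1 / (n - rank1)) / (rss0 / (n - rank0))
    else:
        r2 = (rss0 - rss1) / rss0
    return float(max(0.0, r2))


def percent_heritability(
    y: np.ndarray,
    design: pd.DataFrame,
    probsA: HaplotypeProbSet,
    probsB: HaplotypeProbSet,
    positions: list[tuple[str, int]] | tuple[str, int],
    h2_means: float,
    threshold: float = 4.8,
) -> float:
    """Fraction of cross-mean heritability explained by the QTL genotype(s):
    incremental R^2 over the subpopulation model divided by H2 of cross
    means, capped at 1."""
    if not (0 < h2_means <= 1):
        raise ValueError("h2_means must be in (0, 1]")
    if isinstance(positions, tuple) and len(positions) == 2 and isinstance(positions[0], str):
        positions = [positions]
    r2 = variance_explained(y, design, probsA, probsB, positions, threshold)
    return min(1.0, r2 / h2_means)
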
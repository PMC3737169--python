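"""Probing for multiple linked QTL: local two-position scans and residual re-scans.

A region showing a main peak with a satellite is interrogated two ways:

* fit all admissible pairs of positions in a window around the peak jointly
  (the 28-regressor two-position model) and ask whether any pair is
  substantially more significant than the best single-position model;
* regress out the best single-QTL model and re-scan the genome on the
  residuals, asking whether the satellite survives.

Pairs closer than a minimum genetic separation are excluded (linkage makes
them unidentifiable) and the pair grid is thinned from the bp grid to a
configurable cM step for tractability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scan import (
    drop_underrepresented,
    genome_scan,
    genotype_columns_at,
    parent_indices,
    partial_f_test,
    subpop_indicator,
)
from .synthdata import HaplotypeProbSet

__all__ = ["TwoPositionScan", "scan_2d", "residual_rescan", "single_qtl_residuals"]


@dataclass
class TwoPositionScan:
    """Joint two-position genotype tests over a local pair grid.

    ``pairs`` columns: index1, index2, arm1, pos1_bp, arm2, pos2_bp, cM1,
    cM2, neglog10p.  The statistic is symmetric in the two positions; only
    ordered pairs (cM1 < cM2) are stored.
    """

    region_cm: tuple[float, float]
    pairs: pd.DataFrame

    def best_pair(self) -> pd.Series:
        return self.pairs.loc[self.pairs["neglog10p"].idxmax()]


def _thinned_region(
    probs: HaplotypeProbSet, center: tuple[str, int], region_cm: float, step_cm: float
) -> np.ndarray:
    """Grid row indices within +/- region_cm/2 of center, thinned to ~step_cm."""
    from .scan import chromosome_cm
    from .genmap import chromosome_of

    ci = probs.position_index(*center)
    chroms, cm = chromosome_cm(probs.grid)
    target = chroms[ci]
    sel = np.flatnonzero((chroms == target) & (np.abs(cm - cm[ci]) <= region_cm / 2.0))
    if len(sel) == 0:
        return sel
    thin = [sel[0]]
    for i in sel[1:]:
        if cm[i] - cm[thin[-1]] >= step_cm - 1e-9:
            thin.append(i)
    if ci not in thin:
        thin.append(ci)
    return np.sort(np.unique(thin))


def scan_2d(
    y: np.ndarray,
    design: pd.DataFrame,
    probsA: HaplotypeProbSet,
    probsB: HaplotypeProbSet,
    center: tuple[str, int],
    region_cm: float = 14.0,
    min_sep_cm: float = 2.0,
    threshold: float = 4.8,
    step_cm: float = 0.2,
) -> TwoPositionScan:
    """All-pairs two-position scan in a window around ``center``.

    For every pair of thinned grid positions at least ``min_sep_cm`` apart,
    the joint model with both positions' founder regressors (term dropping
    applied) is tested against the intercept + subpopulation model.
    """
    from .scan import chromosome_cm

    y = np.asarray(y, dtype=float)
    n = len(y)
    idx = _thinned_region(probsA, center, region_cm, step_cm)
    chroms, cm = chromosome_cm(probsA.grid)
    pidx = parent_indices(design, probsA, probsB)
    X_null = np.column_stack([np.ones(n), subpop_indicator(design)])
    cols = {}
    for p in idx:
        G, names = genotype_columns_at(int(p), design, probsA, probsB, _parent_idx=pidx)
        cols[int(p)] = drop_underrepresented(G, names, threshold)[:2]
    rows = []
    for a_i, p1 in enumerate(idx):
        for p2 in idx[a_i + 1:]:
            if cm[p2] - cm[p1] < min_sep_cm:
                continue
            G1, _ = cols[int(p1)]
            G2, _ = cols[int(p2)]
            X_full = np.hstack([X_null, G1, G2])
            _, _, _, nlp = partial_f_test(y, X_full, X_null)
            g = probsA.grid
            rows.append(
                {"index1": int(p1), "index2": int(p2),
                 "arm1": g["arm"].iloc[p1], "pos1_bp": int(g["pos_bp"].iloc[p1]),
                 "arm2": g["arm"].iloc[p2], "pos2_bp": int(g["pos_bp"].iloc[p2]),
                 "cM1": float(cm[p1]), "cM2": float(cm[p2]),
                 "neglog10p": float(nlp)}
            )
    if not rows:
        warnings.warn("no admissible position pairs in region; empty two-position scan")
    lo = float(cm[idx].min()) if len(idx) else np.nan
    hi = float(cm[idx].max()) if len(idx) else np.nan
    return TwoPositionScan(region_cm=(lo, hi), pairs=pd.DataFrame(
        rows, columns=["index1", "index2", "arm1", "pos1_bp", "arm2", "pos2_bp",
                       "cM1", "cM2", "neglog10p"]))


def single_qtl_residuals(
    y: np.ndarray,
    design: pd.DataFrame,
    probsA: HaplotypeProbSet,
    probsB: HaplotypeProbSet,
    qtl_position: tuple[str, int],
    threshold: float = 4.8,
) -> np.ndarray:
    """Residuals of the best single-QTL model (subpopulation + genotype at the QTL)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    p = probsA.position_index(*qtl_position)
    G, names = genotype_columns_at(p, design, probsA, probsB)
    G, _, _ = drop_underrepresented(G, names, threshold)
    X = np.column_stack([np.ones(n), subpop_indicator(design), G])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def residual_rescan(
    y: np.ndarray,
    design: pd.DataFrame,
    probsA: HaplotypeProbSet,
    probsB: HaplotypeProbSet,
    qtl_position: tuple[str, int],
    threshold: float = 4.8,
    span: float = 0.005,
) -> pd.DataFrame:
    """Genome scan on the residuals of the single-QTL model at ``qtl_position``.

    Subpopulation is already absorbed into the residuals, so the re-scan
    model carries only the grand mean and the founder regressors.
    """
    resid = single_qtl_residuals(y, design, probsA, probsB, qtl_position, threshold)
    return genome_scan(design, probsA, probsB, resid, threshold=threshold, span=span,
                       include_subpop=False)
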
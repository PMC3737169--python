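"""Founder-haplotype regression genome scan.

At every grid position the cross-mean phenotype is regressed on the 16
additive founder probabilities (7 paternal + 7 maternal regressors after
omitting the shared founder AB8 as the reference level for each parent, since
the 8 probabilities sum to one) with subpopulation as a covariate:

    y = mu + b_s * S + sum_i b_Ai * G_Ai + sum_i b_Bi * G_Bi

The test statistic is the partial F for the joint genotype effect against the
intercept + subpopulation model, reported as -log10(p).  Founder regressors
whose probability mass summed over crosses is below a threshold (default 4.8,
roughly "fewer than five crosses carry it") are dropped position by position,
so the model degrees of freedom vary along the genome.  The -log10(p) profile
is then smoothed across genetic distance with a tricube local-linear (loess)
smoother, per chromosome (arms of one chromosome are concatenated on the cM
scale so peaks may span a centromere).

All fitting routines accept a matrix of phenotype vectors and fit them
against the shared design in one pass; the permutation module relies on this.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genmap import chromosome_of
from .synthdata import HaplotypeProbSet, N_FOUNDERS

__all__ = [
    "REFERENCE_FOUNDER_INDEX",
    "NEGLOGP_CAP",
    "build_design",
    "drop_underrepresented",
    "fit_genotype_test",
    "genome_scan",
    "scan_many",
    "smooth_neglogp",
    "loess_matrix",
    "loess_smooth",
    "chromosome_cm",
]

#: the shared founder AB8 (index 7) is the omitted reference level per parent
REFERENCE_FOUNDER_INDEX = 7
#: -log10(p) reported for numerically perfect fits
NEGLOGP_CAP = 300.0


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def parent_indices(
    design: pd.DataFrame, probsA: HaplotypeProbSet, probsB: HaplotypeProbSet
) -> tuple[np.ndarray, np.ndarray]:
    return probsA.index_of(design["paternal"]), probsB.index_of(design["maternal"])


def subpop_indicator(design: pd.DataFrame) -> np.ndarray:
    return (design["subpop_combo"] == "A2B1").to_numpy(dtype=float)


def genotype_columns_at(
    pos_index: int,
    design: pd.DataFrame,
    probsA: HaplotypeProbSet,
    probsB: HaplotypeProbSet,
    reference_founder: int = REFERENCE_FOUNDER_INDEX,
    _parent_idx: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, list[str]]:
    """The 14 founder-probability regressors (7 paternal, 7 maternal) at one position."""
    pa, ma = _parent_idx if _parent_idx is not None else parent_indices(design, probsA, probsB)
    keepA = [i for i in range(N_FOUNDERS) if i != reference_founder]
    ga = probsA.probs[pa, pos_index, :][:, keepA]
    gb = probsB.probs[ma, pos_index, :][:, keepA]
    names = [f"A:{probsA.founders[i]}" for i in keepA] + [
        f"B:{probsB.founders[i]}" for i in keepA
    ]
    return np.hstack([ga, gb]), names


def build_design(
    pos_index: int,
    design: pd.DataFrame,
    probsA: HaplotypeProbSet,
    probsB: HaplotypeProbSet,
    reference_founder: int = REFERENCE_FOUNDER_INDEX,
) -> tuple[np.ndarray, list[str]]:
    """Full design matrix at one grid position.

    Columns: intercept, subpopulation indicator, then the 7+7 founder
    probabilities with the reference founder's column omitted per parent.
    """
    G, names = genotype_columns_at(pos_index, design, probsA, probsB, reference_founder)
    n = len(design)
    X = np.column_stack([np.ones(n), subpop_indicator(design), G])
    return X, ["intercept", "subpop", *names]


def drop_underrepresented(
    G: np.ndarray, names: list[str], threshold: float = 4.8
) -> tuple[np.ndarray, list[str], list[str]]:
    """Drop genotype columns whose probability mass summed over crosses is
    below ``threshold`` (strictly less; a sum of exactly ``threshold`` is
    retained).  Returns (kept columns, kept names, dropped names)."""
    sums = G.sum(axis=0)
    keep = sums >= threshold
    dropped = [n for n, k in zip(names, keep) if not k]
    return G[:, keep], [n for n, k in zip(names, keep) if k], dropped


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _rss_rank(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, int]:
    """Residual sum of squares of Y (n,) or (n, m) on X, plus rank(X)."""
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return np.sum(resid**2, axis=0), int(rank)


def partial_f_test(
    Y: np.ndarray, X_full: np.ndarray, X_null: np.ndarray
) -> tuple[np.ndarray, int, int, np.ndarray]:
    """Partial F test of the full model against a nested null model.

    Works column-wise for a matrix of phenotypes.  Returns
    (F, df1, df2, -log10 p); perfect fits are capped at ``NEGLOGP_CAP``.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    rss1, rank_full = _rss_rank(X_full, Y)
    rss0, rank_null = _rss_rank(X_null, Y)
    df1 = rank_full - rank_null
    df2 = n - rank_full
    if df1 <= 0 or df2 <= 0:
        shape = rss1.shape
        nan = np.full(shape, np.nan)
        return nan, df1, df2, nan
    with np.errstate(divide="ignore", invalid="ignore"):
        F = ((rss0 - rss1) / df1) / (rss1 / df2)
    # numerically perfect fits: residual vanishes relative to the null RSS
    perfect = rss1 <= np.maximum(rss0, 1e-300) * 1e-12
    F = np.where(perfect, np.inf, np.maximum(F, 0.0))
    p = stats.f.sf(F, df1, df2)
    with np.errstate(divide="ignore"):
        neglogp = np.where(p > 0, -np.log10(np.maximum(p, 1e-320)), NEGLOGP_CAP)
    neglogp = np.minimum(neglogp, NEGLOGP_CAP)
    return F, df1, df2, neglogp


def fit_genotype_test(
    y: np.ndarray, X: np.ndarray, n_covariates: int = 2
) -> tuple[float, int, int, float]:
    """F test for the joint effect of the genotype columns of a design matrix.

    The first ``n_covariates`` columns (intercept and subpopulation) form the
    null model.  Rank deficiency is handled by the least-squares pseudo-inverse
    with degrees of freedom taken from the numerical rank.
    """
    X = np.asarray(X, dtype=float)
    F, df1, df2, nlp = partial_f_test(np.asarray(y, dtype=float), X, X[:, :n_covariates])
    return float(F), df1, df2, float(nlp)


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------


def scan_many(
    design: pd.DataFrame,
    probsA: HaplotypeProbSet,
    probsB: HaplotypeProbSet,
    Y: np.ndarray,
    threshold: float = 4.8,
    include_subpop: bool = True,
    positions: np.ndarray | None = None,
) -> dict:
    """Run the position-wise genotype F test for one or many phenotype vectors.

    ``Y`` is (n_crosses,) or (n_crosses, m).  Returns a dict of arrays:
    ``neglogp`` (P, m), ``F`` (P, m), ``df1``/``df2`` (P,), ``dropped`` (list
    of lists of dropped term names).  Term dropping depends only on the
    genotype structure, so all phenotype columns share each position's design.
    """
    Y = np.asarray(Y, dtype=float)
    squeeze = Y.ndim == 1
    if squeeze:
        Y = Y[:, None]
    n, m = Y.shape
    if n != len(design):
        raise ValueError("phenotype length does not match cross design")
    pidx = parent_indices(design, probsA, probsB)
    pos = np.arange(len(probsA.grid)) if positions is None else np.asarray(positions)
    s = subpop_indicator(design)
    base_cols = [np.ones(n), s] if include_subpop else [np.ones(n)]
    X_null = np.column_stack(base_cols)
    P = len(pos)
    F = np.full((P, m), np.nan)
    nlp = np.full((P, m), np.nan)
    df1 = np.zeros(P, dtype=int)
    df2 = np.zeros(P, dtype=int)
    dropped_all: list[list[str]] = []
    for k, p in enumerate(pos):
        G, names = genotype_columns_at(int(p), design, probsA, probsB, _parent_idx=pidx)
        G, kept, dropped = drop_underrepresented(G, names, threshold)
        dropped_all.append(dropped)
        if G.shape[1] == 0:
            continue  # untestable position: p recorded as missing
        X_full = np.hstack([X_null, G])
        Fk, d1, d2, nl = partial_f_test(Y, X_full, X_null)
        F[k], df1[k], df2[k], nlp[k] = Fk, d1, d2, nl
    out = {"positions": pos, "F": F, "df1": df1, "df2": df2, "neglogp": nlp,
           "dropped": dropped_all}
    if squeeze:
        out["F"] = out["F"][:, 0]
        out["neglogp"] = out["neglogp"][:, 0]
    return out


def genome_scan(
    design: pd.DataFrame,
    probsA: HaplotypeProbSet,
    probsB: HaplotypeProbSet,
    y: np.ndarray,
    threshold: float = 4.8,
    span: float = 0.005,
    include_subpop: bool = True,
) -> pd.DataFrame:
    """Full genome scan: per-position F test, -log10(p), and loess smoothing.

    Returns a ScanResult frame with columns (arm, pos_bp, pos_cM, F, df1,
    df2, neglog10p, smoothed, dropped_terms).
    """
    res = scan_many(design, probsA, probsB, y, threshold, include_subpop)
    out = probsA.grid.copy()
    out["F"] = res["F"]
    out["df1"] = res["df1"]
    out["df2"] = res["df2"]
    out["neglog10p"] = res["neglogp"]
    out["dropped_terms"] = [",".join(d) for d in res["dropped"]]
    return smooth_neglogp(out, span=span)


# ---------------------------------------------------------------------------
# loess smoothing across genetic distance
# ---------------------------------------------------------------------------


def chromosome_cm(grid: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Chromosome labels and a concatenated cM coordinate per grid row.

    Arms of the same chromosome (e.g. 3L and 3R) are laid end to end on the
    cM scale so smoothing and peak finding can span the centromere.
    """
    arms = grid["arm"].to_numpy()
    cm = grid["pos_cM"].to_numpy(dtype=float)
    chroms = np.array([chromosome_of(a) for a in arms])
    out = cm.copy()
    for c in pd.unique(chroms):
        sel = chroms == c
        arms_c = pd.unique(arms[sel])
        offset = 0.0
        for a in arms_c:
            sa = arms == a
            out[sa] = cm[sa] + offset
            offset = out[sa].max() + (cm[sa][1] - cm[sa][0] if sa.sum() > 1 else 0.0)
    return chroms, out


def loess_matrix(x: np.ndarray, span: float) -> np.ndarray:
    """Linear smoother matrix S for degree-1 tricube loess at the input points.

    The fitted value at x_i is a linear functional of y, so the whole smoother
    is the matrix S with smoothed = S @ y; this lets permutation scans smooth
    hundreds of null profiles with one matmul.  The window holds
    ``max(3, ceil(span * n))`` nearest neighbours (widened to 3 with a warning
    if the span is smaller); weights are tricube in distance scaled by the
    farthest neighbour.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    k = int(np.ceil(span * n))
    if k < 3:
        if span * n < 3 - 1e-9:
            warnings.warn(f"loess window of {span * n:.2f} points widened to 3")
        k = 3
    k = min(k, n)
    S = np.zeros((n, n))
    order = np.argsort(x, kind="stable")
    xs = x[order]
    for ii in range(n):
        # nearest-k window in sorted order, slid inside the boundaries
        left, right = ii, ii
        while right - left + 1 < k:
            if left == 0:
                right += 1
            elif right == n - 1:
                left -= 1
            elif xs[ii] - xs[left - 1] <= xs[right + 1] - xs[ii]:
                left -= 1
            else:
                right += 1
        idx = np.arange(left, right + 1)
        d = np.abs(xs[idx] - xs[ii])
        dmax = d.max()
        if dmax <= 0:
            w = np.ones_like(d)
        else:
            w = (1.0 - (d / dmax) ** 3) ** 3
            if w.sum() <= 0:
                w = np.ones_like(d)
        # weighted degree-1 fit evaluated at xs[ii] is linear in y
        xw = xs[idx]
        sw = w.sum()
        xbar = np.sum(w * xw) / sw
        sxx = np.sum(w * (xw - xbar) ** 2)
        if sxx <= 1e-12 * max(1.0, xs[ii] ** 2):
            coef = w / sw
        else:
            coef = w / sw + w * (xw - xbar) * (xs[ii] - xbar) / sxx
        S[order[ii], order[idx]] = coef
    return S


def loess_smooth(x: np.ndarray, y: np.ndarray, span: float) -> np.ndarray:
    """Degree-1 tricube loess of y (vector or (n, m) matrix) on x."""
    return loess_matrix(x, span) @ np.asarray(y, dtype=float)


def smoother_matrices(grid: pd.DataFrame, span: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-chromosome (row indices, smoother matrix) pairs for a scan grid."""
    chroms, cm = chromosome_cm(grid)
    out = []
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        out.append((idx, loess_matrix(cm[idx], span)))
    return out


def smooth_neglogp(scan: pd.DataFrame, span: float = 0.005) -> pd.DataFrame:
    """Add/replace the ``smoothed`` column: per-chromosome loess of -log10(p)
    across genetic distance.  Untestable positions (missing p) are dropped
    from each local fit and their smoothed value interpolated from the fit."""
    out = scan.copy()
    smoothed = np.full(len(out), np.nan)
    vals = out["neglog10p"].to_numpy(dtype=float)
    for idx, S in smoother_matrices(out, span):
        v = vals[idx]
        ok = np.isfinite(v)
        if ok.all():
            smoothed[idx] = S @ v
        elif ok.sum() >= 3:
            chroms, cm = chromosome_cm(out)
            xs = cm[idx]
            Sg = loess_matrix(xs[ok], span)
            sm = Sg @ v[ok]
            smoothed[idx] = np.interp(xs, xs[ok], sm)
        # else: leave NaN
    out["smoothed"] = smoothed
    return out
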
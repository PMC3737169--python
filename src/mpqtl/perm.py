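"""Permutation genome-wide significance as expected peaks per scan.

Instead of controlling the family-wise error of the single genome-wide
maximum, significance is expressed as the expected number of *distinct
peaks* per genome scan exceeding a threshold under the permutation null:
the -log10(p) value at which permuted scans average 0.05 peaks per genome is
the 5% false-positive threshold, the value averaging 0.5 peaks is the 50%
threshold, and so on up to several expected peaks per scan.

Peaks are local maxima of the smoothed profile found with a windowed peak
finder (default window 50 grid points, signal-to-noise threshold 1 against a
robust MAD noise scale), counted genome-wide per permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scan import scan_many, smoother_matrices
from .synthdata import HaplotypeProbSet

__all__ = [
    "find_peaks_series",
    "find_peaks",
    "NullScans",
    "permute_scan",
    "ThresholdCurve",
    "threshold_curve",
]


def _noise_scale(values: np.ndarray) -> float:
    """Robust noise scale: MAD x 1.4826 (consistent for a normal)."""
    med = np.median(values)
    return float(np.median(np.abs(values - med)) * 1.4826)


def find_peaks_series(
    values: np.ndarray, span: int = 50, snr: float = 1.0, boundary_peaks: bool = False
) -> np.ndarray:
    """Indices of peaks in one series.

    A point is a peak iff it is the (leftmost, for ties) maximum of the
    centred window of ``span`` grid points and its value is at least
    ``snr`` times the MAD noise scale of the series.  Windows are truncated
    at the series ends; points whose window is truncated are only eligible
    when ``boundary_peaks`` is true.  Even spans are incremented with a
    warning; a series shorter than the span yields at most its global
    maximum.
    """
    values = np.asarray(values, dtype=float)
    if span < 3:
        raise ValueError("span must be >= 3")
    if span % 2 == 0:
        warnings.warn(f"even peak span {span} incremented to {span + 1}")
        span += 1
    n = len(values)
    half = span // 2
    floor = snr * _noise_scale(values)
    peaks = []
    if n <= span and not boundary_peaks:
        return np.array([], dtype=int)
    lo_i, hi_i = (0, n) if boundary_peaks else (half, n - half)
    for i in range(lo_i, hi_i):
        w0 = max(0, i - half)
        w1 = min(n, i + half + 1)
        window = values[w0:w1]
        j = int(np.argmax(window))  # argmax takes the leftmost of ties
        if w0 + j == i and values[i] >= floor:
            peaks.append(i)
    return np.array(peaks, dtype=int)


def find_peaks(
    scan: pd.DataFrame,
    column: str = "smoothed",
    span: int = 50,
    snr: float = 1.0,
    boundary_peaks: bool = False,
) -> pd.DataFrame:
    """Peak list for a scan frame: detected per chromosome, pooled genome-wide.

    Returns (arm, pos_bp, pos_cM, height) ordered by genome position.
    """
    from .scan import chromosome_cm

    chroms, _ = chromosome_cm(scan)
    vals = scan[column].to_numpy(dtype=float)
    rows = []
    for c in pd.unique(chroms):
        idx = np.flatnonzero(chroms == c)
        v = vals[idx]
        ok = np.isfinite(v)
        if ok.sum() == 0:
            continue
        sub = idx[ok]
        for k in find_peaks_series(v[ok], span, snr, boundary_peaks):
            r = scan.iloc[sub[k]]
            rows.append(
                {"arm": r["arm"], "pos_bp": int(r["pos_bp"]), "pos_cM": float(r["pos_cM"]),
                 "height": float(v[ok][k])}
            )
    return pd.DataFrame(rows, columns=["arm", "pos_bp", "pos_cM", "height"])


@dataclass
class NullScans:
    """Smoothed -log10(p) profiles of permuted phenotypes on a common grid."""

    grid: pd.DataFrame  # arm, pos_bp, pos_cM
    smoothed: np.ndarray  # (n_positions, n_perm)

    @property
    def n_perm(self) -> int:
        return self.smoothed.shape[1]

    def peak_heights(self, span: int = 50, snr: float = 1.0) -> list[np.ndarray]:
        """Per-permutation arrays of genome-wide peak heights."""
        from .scan import chromosome_cm

        chroms, _ = chromosome_cm(self.grid)
        groups = [np.flatnonzero(chroms == c) for c in pd.unique(chroms)]
        out = []
        for p in range(self.n_perm):
            heights = []
            for idx in groups:
                v = self.smoothed[idx, p]
                ok = np.isfinite(v)
                if ok.sum() == 0:
                    continue
                vv = v[ok]
                heights.extend(vv[find_peaks_series(vv, span, snr)])
            out.append(np.asarray(heights))
        return out


def permute_scan(
    y: np.ndarray,
    design: pd.DataFrame,
    probsA: HaplotypeProbSet,
    probsB: HaplotypeProbSet,
    n_perm: int = 1000,
    span: float = 0.005,
    seed: int = 0,
    threshold: float = 4.8,
) -> NullScans:
    """Genome scans of ``n_perm`` permutations of the cross means.

    The phenotype vector is shuffled across crosses while the genotype and
    subpopulation structure stays fixed (so the null preserves any
    genotype-subpopulation dependence); every permutation gets the full scan
    plus loess smoothing.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    Y = np.column_stack([rng.permutation(y) for _ in range(n_perm)])
    res = scan_many(design, probsA, probsB, Y, threshold=threshold)
    nlp = res["neglogp"]
    smoothed = np.full_like(nlp, np.nan)
    for idx, S in smoother_matrices(probsA.grid, span):
        block = nlp[idx, :]
        if np.isfinite(block).all():
            smoothed[idx, :] = S @ block
        else:  # rare untestable positions: smooth each column on its finite support
            from .scan import loess_matrix, chromosome_cm

            _, cm = chromosome_cm(probsA.grid)
            xs = cm[idx]
            for p in range(nlp.shape[1]):
                v = block[:, p]
                ok = np.isfinite(v)
                if ok.sum() >= 3:
                    sm = loess_matrix(xs[ok], span) @ v[ok]
                    smoothed[idx, p] = np.interp(xs, xs[ok], sm)
    return NullScans(grid=probsA.grid.copy(), smoothed=smoothed)


@dataclass
class ThresholdCurve:
    """Expected peaks per genome scan as a function of the height threshold."""

    thresholds: np.ndarray
    expected_peaks: np.ndarray  # mean over permutations, non-increasing

    def threshold_for_rate(self, rate: float) -> float:
        """Smallest threshold whose expected peak count is <= ``rate``.

        Linear interpolation between grid points; if the requested rate is
        below the curve's reachable minimum the largest grid threshold is
        returned with a warning.
        """
        t, e = self.thresholds, self.expected_peaks
        if rate < e[-1]:
            warnings.warn(
                f"rate {rate} below reachable minimum {e[-1]}; returning max threshold"
            )
            return float(t[-1])
        k = int(np.argmax(e <= rate))  # first index meeting the rate
        if k == 0 or e[k] == rate:
            return float(t[k])
        e0, e1 = e[k - 1], e[k]
        if e0 == e1:
            return float(t[k])
        frac = (e0 - rate) / (e0 - e1)
        return float(t[k - 1] + frac * (t[k] - t[k - 1]))


def threshold_curve(
    null_scans: NullScans,
    span: int = 50,
    snr: float = 1.0,
    thresholds: np.ndarray | None = None,
) -> ThresholdCurve:
    """Expected-peaks-per-scan curve from permutation null scans.

    For each candidate threshold t, the expected count is the mean over
    permutations of the number of genome-wide peaks with height >= t.
    """
    heights = null_scans.peak_heights(span=span, snr=snr)
    if thresholds is None:
        top = max((h.max() for h in heights if h.size), default=1.0)
        thresholds = np.linspace(0.0, top * 1.05 + 1e-9, 200)
    thresholds = np.asarray(thresholds, dtype=float)
    counts = np.zeros((len(heights), len(thresholds)))
    for i, h in enumerate(heights):
        if h.size:
            counts[i] = (h[:, None] >= thresholds[None, :]).sum(axis=0)
    return ThresholdCurve(thresholds=thresholds, expected_peaks=counts.mean(axis=0))
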
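"""Gene-centric single-marker association on inferred cross dosages.

For a biallelic marker (SNP or TE insertion) with known founder alleles, the
probability each RIL carries the minor allele is the dot product of its
additive founder probabilities with the founder allele vector; a cross's
dosage is the sum of the paternal and maternal probabilities (with perfect
certainty 2 = AA, 1 = Aa, 0 = aa).  Each marker is tested with

    y = mu + b_s * S + b_m * M

and its variance explained is the incremental R-squared over the
subpopulation-only model divided by the cross-mean heritability.  A set of
randomly selected SNPs in the QTL's confidence interval provides the null
expectation for markers merely linked to the QTL; per-region multiple testing
uses Bonferroni.  The module also carries the enrichment arithmetic for
candidate genes under mapped peaks (Poisson) and the observed peak-count FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ril_allele_prob",
    "cross_dosage",
    "AssociationResult",
    "single_marker_test",
    "random_snp_null",
    "candidates_beat_null",
    "region_bonferroni",
    "enrichment_pvalue",
    "mappable_genome_length",
    "observed_fdr",
]


def ril_allele_prob(additive_probs: np.ndarray, founder_alleles: np.ndarray) -> np.ndarray:
    """Probability a RIL carries the minor allele at a marker.

    ``additive_probs`` is the RIL's 8-vector (or (n, 8) matrix) of additive
    founder probabilities at the marker's nearest grid position;
    ``founder_alleles`` codes the minor allele as 1.
    """
    a = np.asarray(founder_alleles, dtype=float)
    return np.asarray(additive_probs, dtype=float) @ a


def cross_dosage(paternal_prob, maternal_prob):
    """Cross genotype value on [0, 2]: paternal + maternal minor-allele probability."""
    p = np.asarray(paternal_prob, dtype=float)
    m = np.asarray(maternal_prob, dtype=float)
    tol = 1e-9  # allow float roundoff from probability-row normalization
    if np.any((p < -tol) | (p > 1 + tol)) or np.any((m < -tol) | (m > 1 + tol)):
        raise ValueError("allele probabilities must lie in [0, 1]")
    return np.clip(p, 0.0, 1.0) + np.clip(m, 0.0, 1.0)


@dataclass
class AssociationResult:
    marker_id: str
    beta: float
    se: float
    p_value: float
    r2: float  # incremental R^2 over subpopulation
    varexp: float  # fraction of cross-mean heritability explained
    bonferroni_sig: bool | None = None


def single_marker_test(
    y: np.ndarray,
    subpop: np.ndarray,
    dosage: np.ndarray,
    h2_means: float,
    marker_id: str = "marker",
) -> AssociationResult:
    """OLS fit of y on intercept + subpopulation + marker dosage.

    The marker coefficient's p-value is a two-sided t test; variance explained
    is the incremental R^2 over the subpopulation-only model divided by
    ``h2_means``.
    """
    y = np.asarray(y, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if np.ptp(d) <= 1e-12:
        raise ValueError(f"marker {marker_id!r} is monomorphic across crosses")
    n = len(y)
    X0 = np.column_stack([np.ones(n), np.asarray(subpop, dtype=float)])
    X = np.column_stack([X0, d])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss1 = float(resid @ resid)
    b0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    r0 = y - X0 @ b0
    rss0 = float(r0 @ r0)
    df = n - rank
    sigma2 = rss1 / df
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    se = float(np.sqrt(max(cov[2, 2], 0.0)))
    bm = float(beta[2])
    if se > 0:
        t = bm / se
        p = float(2.0 * stats.t.sf(abs(t), df))
    else:
        p = 0.0 if abs(bm) > 0 else 1.0
    r2 = max(0.0, (rss0 - rss1) / rss0) if rss0 > 0 else 0.0
    varexp = min(1.0, r2 / h2_means)
    return AssociationResult(marker_id=marker_id, beta=bm, se=se, p_value=p, r2=r2,
                             varexp=varexp)


def random_snp_null(
    region_snps: pd.DataFrame,
    n_random: int,
    y: np.ndarray,
    subpop: np.ndarray,
    dosages: np.ndarray,
    h2_means: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Variance explained by randomly selected SNPs linked with a QTL.

    ``region_snps`` indexes the SNPs available in the QTL's widest confidence
    interval and ``dosages`` is the matching (n_crosses, n_snps) dosage
    matrix.  Sampling is without replacement; monomorphic draws are reported
    with NaN.  Returns (marker_id, varexp) per sampled SNP.
    """
    if len(region_snps) == 0:
        raise ValueError("no SNPs in region")
    rng = np.random.default_rng(seed)
    k = min(n_random, len(region_snps))
    if k < n_random:
        warnings.warn(f"only {k} SNPs available in region; sampling all")
    pick = rng.choice(len(region_snps), size=k, replace=False) if k else np.array([], int)
    rows = []
    for j in pick:
        mid = str(region_snps.iloc[j].get("marker_id", f"snp{j}"))
        try:
            res = single_marker_test(y, subpop, dosages[:, j], h2_means, marker_id=mid)
            rows.append({"marker_id": mid, "varexp": res.varexp})
        except ValueError:
            rows.append({"marker_id": mid, "varexp": np.nan})
    return pd.DataFrame(rows, columns=["marker_id", "varexp"])


def candidates_beat_null(candidate_varexp, null_varexp) -> bool:
    """Whether the candidate markers survive the linked-SNP null comparison.

    The candidate set *fails* when at least one randomly selected SNP explains
    more heritability than every candidate.
    """
    cand = np.asarray(candidate_varexp, dtype=float)
    null = np.asarray(null_varexp, dtype=float)
    null = null[np.isfinite(null)]
    if cand.size == 0 or null.size == 0:
        raise ValueError("need at least one candidate and one null marker")
    return bool(np.nanmax(cand) >= null.max())


def region_bonferroni(results: list[AssociationResult], alpha: float = 0.05) -> list[AssociationResult]:
    """Flag per-region Bonferroni significance at alpha / (markers tested)."""
    m = len(results)
    for r in results:
        r.bonferroni_sig = bool(r.p_value < alpha / m) if m else None
    return results


def enrichment_pvalue(n_candidates: int, interval_total_mb: float, mappable_mb: float) -> float:
    """Probability of >= 2 candidate genes under mapped peaks by chance.

    Candidate genes are assumed scattered uniformly over the fine-mappable
    genome, so the count under the peak intervals is Poisson with
    lambda = n_candidates x interval_total_mb / mappable_mb; the p-value is
    1 - P(Poisson(lambda) <= 1).
    """
    if n_candidates < 0 or interval_total_mb < 0:
        raise ValueError("counts and interval lengths must be non-negative")
    if mappable_mb <= 0:
        raise ValueError("mappable_mb must be positive")
    if interval_total_mb > mappable_mb:
        raise ValueError("intervals cannot exceed the mappable genome")
    lam = n_candidates * interval_total_mb / mappable_mb
    return float(stats.poisson.sf(1, lam))


def mappable_genome_length(regions: list[tuple[str, float, float]]) -> float:
    """Total Mb of fine-map-capable genome, merging overlaps within each arm."""
    by_arm: dict[str, list[tuple[float, float]]] = {}
    for arm, start, end in regions:
        if not start < end:
            raise ValueError(f"region on {arm}: start must be below end")
        by_arm.setdefault(arm, []).append((float(start), float(end)))
    total = 0.0
    for arm, ivals in by_arm.items():
        ivals.sort()
        cur_s, cur_e = ivals[0]
        for s, e in ivals[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                total += cur_e - cur_s
                cur_s, cur_e = s, e
        total += cur_e - cur_s
    return total


def observed_fdr(expected_false_positives: float, n_observed_peaks: int) -> float:
    """False discovery rate among observed peaks at a permutation threshold:
    expected false positives / observed peaks, capped at 1."""
    if n_observed_peaks < 1:
        raise ValueError("FDR undefined with zero observed peaks")
    if expected_false_positives < 0:
        raise ValueError("expected false positives must be non-negative")
    return min(1.0, expected_false_positives / n_observed_peaks)
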
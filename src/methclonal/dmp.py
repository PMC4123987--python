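"""Univariate differential methylation between matched sample groups.

Per probe, the recurrence-minus-primary beta differences across matched
pairs are tested with a two-sided Wilcoxon signed-rank test.  The exact
null is used for up to 25 informative pairs — enumerated by dynamic
programming over (doubled) midranks, so tied ranks are handled exactly —
and a normal approximation with continuity and tie correction above that.
Zero differences are dropped before ranking (Wilcoxon's convention); a
probe whose differences are all zero gets p = 1.

P-values are corrected with the Benjamini-Hochberg step-up procedure and
probes are ranked by adjusted p, then by absolute mean methylation
variation (recurrence minus primary), then by probe id.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, SampleAnnotation

__all__ = [
    "DmpResult",
    "paired_wilcoxon",
    "unpaired_wilcoxon",
    "bh_adjust",
    "differential_methylation",
    "rank_dmps",
    "count_significant",
    "EXACT_MAX_N",
]

#: largest number of informative pairs for which the exact null is enumerated
EXACT_MAX_N = 25


@dataclass
class DmpResult:
    """Per-probe differential methylation summary."""

    probe_id: str
    p_raw: float
    q: float
    delta_beta: float
    gene: str | None = None


@lru_cache(maxsize=4096)
def _signed_rank_null(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Counts of sign assignments per doubled rank-sum value.

    ``doubled_ranks`` are 2x the midranks of |differences| (integers even
    with ties).  Entry t of the result counts the sign vectors whose
    positive-rank sum, doubled, equals t; entries sum to 2^n.
    """
    total = int(sum(doubled_ranks))
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled_ranks:
        counts[r:] = counts[r:] + counts[:-r] if r > 0 else 2 * counts[r:]
    return counts


def _exact_two_sided(doubled_ranks: tuple[int, ...], doubled_wplus: int) -> float:
    counts = _signed_rank_null(doubled_ranks)
    n = len(doubled_ranks)
    denom = 2.0**n
    cdf = counts[: doubled_wplus + 1].sum() / denom
    sf = counts[doubled_wplus:].sum() / denom
    return float(min(1.0, 2.0 * min(cdf, sf)))


def _approx_two_sided(ranks: np.ndarray, wplus: float) -> float:
    n = ranks.size
    mu = n * (n + 1) / 4.0
    # tie correction on the variance of the signed-rank sum
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return 1.0
    d = wplus - mu
    # continuity correction shrinks |W+ - mu| by 1/2
    z = (abs(d) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def _paired_wilcoxon_1d(diff: np.ndarray) -> float:
    d = diff[diff != 0.0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = stats.rankdata(np.abs(d))
    wplus = ranks[d > 0].sum()
    if n <= EXACT_MAX_N:
        doubled = tuple(int(x) for x in np.rint(2.0 * ranks))
        return _exact_two_sided(doubled, int(round(2.0 * wplus)))
    return _approx_two_sided(ranks, wplus)


def paired_wilcoxon(a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray | float:
    """Two-sided signed-rank p-value(s) for paired observations.

    ``a`` and ``b`` are aligned value vectors (one test) or matrices with
    one row per probe and one column per pair (one test per row).  With
    ``b`` omitted, ``a`` is taken to be the differences directly.  Exact
    null for up to 25 informative pairs, normal approximation beyond.
    """
    diff = np.asarray(a, dtype=float)
    if b is not None:
        diff = diff - np.asarray(b, dtype=float)
    if np.isnan(diff).any():
        raise ValueError("missing values in paired input; filter probes first")
    if diff.ndim == 1:
        if diff.size < 2:
            raise ValueError("need at least 2 pairs")
        return _paired_wilcoxon_1d(diff)
    if diff.shape[1] < 2:
        raise ValueError("need at least 2 pairs")
    return _paired_wilcoxon_matrix(diff)


def _paired_wilcoxon_matrix(diff: np.ndarray) -> np.ndarray:
    """Row-wise signed-rank p-values, vectorised for the tie-free case."""
    n_probes, n = diff.shape
    p = np.empty(n_probes)
    has_zero = (diff == 0.0).any(axis=1)
    # ties in |d| within a row force the scalar path
    sorted_abs = np.sort(np.abs(diff), axis=1)
    has_tie = (np.diff(sorted_abs, axis=1) == 0.0).any(axis=1)
    slow = has_zero | has_tie
    fast = ~slow
    if fast.any():
        sub = diff[fast]
        ranks = stats.rankdata(np.abs(sub), axis=1)
        wplus = np.where(sub > 0, ranks, 0.0).sum(axis=1)
        if n <= EXACT_MAX_N:
            doubled = tuple(2 * r for r in range(1, n + 1))
            counts = _signed_rank_null(doubled)
            denom = 2.0**n
            cum = np.concatenate([[0.0], np.cumsum(counts)])
            t = np.rint(2.0 * wplus).astype(int)
            cdf = cum[t + 1] / denom
            sf = (cum[-1] - cum[t]) / denom
            p[fast] = np.minimum(1.0, 2.0 * np.minimum(cdf, sf))
        else:
            mu = n * (n + 1) / 4.0
            var = n * (n + 1) * (2 * n + 1) / 24.0
            z = np.maximum((np.abs(wplus - mu) - 0.5), 0.0) / np.sqrt(var)
            p[fast] = np.minimum(1.0, 2.0 * stats.norm.sf(z))
    for i in np.flatnonzero(slow):
        p[i] = _paired_wilcoxon_1d(diff[i])
    return p


def unpaired_wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum (Mann-Whitney) p-value.

    Exact when both groups are small and tie-free; otherwise the normal
    approximation with tie and continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    tie_free = np.unique(combined).size == combined.size
    small = max(a.size, b.size) <= 20
    method = "exact" if (tie_free and small) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def differential_methylation(
    m: BetaMatrix,
    ann: SampleAnnotation,
    cohort: str,
    genes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Probe-level paired testing of recurrences against their primaries.

    Returns a DataFrame with columns probe_id, gene, p_raw, q and
    delta_beta (mean recurrence-minus-primary beta difference), one row
    per complete probe, in probe order.
    """
    pairs = ann.complete_pairs(cohort)
    if len(pairs) < 2:
        raise ValueError("need at least 2 complete pairs")
    pt = m.values[[p for _, p, _ in pairs]].to_numpy()
    rec = m.values[[r for _, _, r in pairs]].to_numpy()
    keep = ~np.isnan(pt).any(axis=1) & ~np.isnan(rec).any(axis=1)
    probe_ids = np.asarray(m.probe_ids)[keep]
    diff = rec[keep] - pt[keep]
    p_raw = _paired_wilcoxon_matrix(diff)
    q = bh_adjust(p_raw)
    out = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene": [genes.get(pid) if genes else None for pid in probe_ids],
            "p_raw": p_raw,
            "q": q,
            "delta_beta": diff.mean(axis=1),
        }
    )
    return out


def rank_dmps(results: pd.DataFrame, top_n: int | None = 50) -> pd.DataFrame:
    """Top probes by adjusted p, then |delta beta| (desc), then probe id."""
    key = results.assign(_absdb=results["delta_beta"].abs())
    ranked = key.sort_values(
        ["q", "_absdb", "probe_id"], ascending=[True, False, True], kind="mergesort"
    ).drop(columns="_absdb")
    if top_n is not None:
        ranked = ranked.head(top_n)
    return ranked.reset_index(drop=True)


def count_significant(results: pd.DataFrame, fdr_level: float = 0.05) -> int:
    """Number of probes with adjusted p strictly below the FDR level."""
    return int((results["q"] < fdr_level).sum())
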
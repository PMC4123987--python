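"""Methylation-similarity clonality scoring and its empirical null.

The methylation-similarity score (MS) of two tumors is the inverse of the
Manhattan distance between their full beta-value profiles.  Clonal pairs
(a recurrence regrown from its primary) conserve methylation and sit at
small distance, hence high MS; independent tumors sit far apart.

To calibrate "high", an empirical null is built from all unrelated
primary x recurrence combinations within a cohort of m matched pairs
(m(m-1) ordered cross pairs).  The decision threshold tau is the order
statistic at rank ceil(0.95 n) of the sorted null scores — the 95%
empirical quantile without interpolation — and a matched pair is called a
true recurrence (TR) exactly when its MS score is strictly above tau,
otherwise a new primary (NP).  Identical profiles have infinite
similarity and are always TR.

The module also provides the unsupervised views of the same signal:
complete-linkage hierarchical clustering on Manhattan distances with
matched-pair adjacency counting, the distance-distribution group
comparisons (matched vs unmatched vs within-role vs normal-vs-normal),
and agreement/correlation with external clonality calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .dmp import unpaired_wilcoxon
from .io import BetaMatrix, PairRecord, SampleAnnotation

__all__ = [
    "NullDistribution",
    "Dendrogram",
    "manhattan_distance",
    "ms_score",
    "empirical_quantile_threshold",
    "null_distribution",
    "classify_pairs",
    "threshold_consistency",
    "FeasibleInterval",
    "hierarchical_cluster",
    "count_adjacent_pairs",
    "distance_group_stats",
    "concordance",
    "Concordance",
    "score_correlation",
]


def manhattan_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Sum of absolute beta differences over all probes."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values; filter to complete probes first")
    return float(np.abs(x - y).sum())


def ms_score(x: np.ndarray, y: np.ndarray) -> float:
    """Methylation-similarity score: 1 / Manhattan distance.

    Identical profiles are maximally clonal; their "infinite similarity"
    is signaled by returning ``math.inf`` rather than raising.
    """
    d = manhattan_distance(x, y)
    return math.inf if d == 0.0 else 1.0 / d


def empirical_quantile_threshold(scores: np.ndarray, q: float = 0.95) -> float:
    """Order statistic at rank ceil(q*n) of the sorted scores (no interpolation)."""
    s = np.sort(np.asarray(scores, dtype=float))
    if s.size == 0:
        raise ValueError("empty score set")
    rank = math.ceil(q * s.size)
    return float(s[max(rank, 1) - 1])


@dataclass
class NullDistribution:
    """MS scores of unrelated PT x recurrence combinations and threshold tau."""

    scores: np.ndarray
    tau: float
    n_unrelated: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.n_unrelated != self.scores.size:
            raise ValueError("n_unrelated does not match scores")
        if not (self.scores.min() <= self.tau <= self.scores.max()):
            raise ValueError("tau outside the observed score range")


def null_distribution(
    m: BetaMatrix, ann: SampleAnnotation, cohort: str, q: float = 0.95
) -> NullDistribution:
    """Empirical MS null from all ordered unrelated cross pairs of one cohort."""
    pairs = ann.complete_pairs(cohort)
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs for an unrelated-pair null")
    complete = ~m.values.isna().any(axis=1)
    vals = m.values.loc[complete]
    pt = {pid: vals[s].to_numpy() for pid, s, _ in pairs}
    rec = {pid: vals[s].to_numpy() for pid, _, s in pairs}
    scores = [
        ms_score(pt[a], rec[b]) for a in pt for b in rec if a != b
    ]
    scores = np.asarray(scores)
    return NullDistribution(
        scores=scores,
        tau=empirical_quantile_threshold(scores, q),
        n_unrelated=scores.size,
    )


def classify_pairs(
    scores: np.ndarray | list[PairRecord], tau: float
) -> list[str]:
    """TR iff the MS score is strictly above tau, else NP.

    Accepts raw scores or :class:`PairRecord` rows (their ``ms_score``
    field is used).  Infinite similarity is always TR.
    """
    if len(scores) and isinstance(scores[0], PairRecord):
        values = [p.ms_score for p in scores]
    else:
        values = list(np.asarray(scores, dtype=float))
    return ["TR" if s > tau else "NP" for s in values]


@dataclass
class FeasibleInterval:
    """Thresholds tau in [lower, upper) reproducing a label column."""

    lower: float
    upper: float

    @property
    def feasible(self) -> bool:
        return self.lower < self.upper

    def contains(self, tau: float) -> bool:
        return self.lower <= tau < self.upper


def threshold_consistency(
    scores: np.ndarray, labels: list[str]
) -> FeasibleInterval:
    """Interval of thresholds under which "TR iff score > tau" yields ``labels``.

    Every NP score must satisfy score <= tau and every TR score > tau, so
    the feasible set is [max NP score, min TR score) — empty (flagged via
    ``feasible``) when some NP scores at or above the smallest TR score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = list(labels)
    if scores.size != len(labels):
        raise ValueError("scores and labels must align")
    np_scores = scores[[l == "NP" for l in labels]]
    tr_scores = scores[[l == "TR" for l in labels]]
    lower = float(np_scores.max()) if np_scores.size else -math.inf
    upper = float(tr_scores.min()) if tr_scores.size else math.inf
    return FeasibleInterval(lower=lower, upper=upper)


@dataclass
class Dendrogram:
    """Complete-linkage merge tree over samples (Manhattan distances)."""

    merges: np.ndarray  # scipy linkage matrix
    leaf_ids: list[str]

    def to_newick(self) -> str:
        """Newick serialization with merge heights as branch lengths."""
        n = len(self.leaf_ids)
        heights = {i: 0.0 for i in range(n)}
        labels = {i: self.leaf_ids[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.merges):
            a, b = int(a), int(b)
            node = n + k
            la = h - heights[a]
            lb = h - heights[b]
            labels[node] = f"({labels[a]}:{la:.6g},{labels[b]}:{lb:.6g})"
            heights[node] = h
        return labels[n + len(self.merges) - 1] + ";"


def hierarchical_cluster(
    m: BetaMatrix, sample_ids: list[str] | None = None
) -> Dendrogram:
    """Agglomerative complete-linkage clustering on Manhattan distances."""
    complete = ~m.values.isna().any(axis=1)
    vals = m.values.loc[complete]
    ids = sample_ids if sample_ids is not None else list(vals.columns)
    x = vals[ids].to_numpy().T  # samples x probes
    if x.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    z = linkage(pdist(x, metric="cityblock"), method="complete")
    return Dendrogram(merges=z, leaf_ids=list(ids))


def count_adjacent_pairs(
    d: Dendrogram, ann: SampleAnnotation, cohort: str
) -> int:
    """Matched pairs whose two samples form a two-leaf clade of the tree.

    Operationalizes "closer to each other than to any other sample": the
    two members must be each other's direct merge partner.
    """
    n = len(d.leaf_ids)
    leaf_pairs = set()
    for a, b, _, _ in d.merges:
        a, b = int(a), int(b)
        if a < n and b < n:
            leaf_pairs.add(frozenset((d.leaf_ids[a], d.leaf_ids[b])))
    count = 0
    for _, pt, rec in ann.complete_pairs(cohort):
        if frozenset((pt, rec)) in leaf_pairs:
            count += 1
    return count


def distance_group_stats(
    m: BetaMatrix, ann: SampleAnnotation, cohort: str
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Distance distributions per sample-pair group, with group comparisons.

    Groups: ``real`` (the m matched pairs), ``artificial`` (all m(m-1)
    unmatched PT x recurrence combinations), ``primary`` (PT x PT),
    ``recurrence`` (REC x REC) and, when the annotation carries normal
    tissues, ``normal`` (normal x normal baseline).  The second return
    value holds two-sided unpaired rank-sum p-values between the groups.
    """
    pairs = ann.complete_pairs(cohort)
    m_pairs = len(pairs)
    complete = ~m.values.isna().any(axis=1)
    vals = m.values.loc[complete]
    pt_ids = [p for _, p, _ in pairs]
    rec_ids = [r for _, _, r in pairs]
    pt = vals[pt_ids].to_numpy().T
    rec = vals[rec_ids].to_numpy().T

    cross = np.abs(pt[:, None, :] - rec[None, :, :]).sum(axis=2)
    real = np.diag(cross)
    off = ~np.eye(m_pairs, dtype=bool)
    groups: dict[str, np.ndarray] = {
        "real": real,
        "artificial": cross[off],
        "primary": pdist(pt, metric="cityblock"),
        "recurrence": pdist(rec, metric="cityblock"),
    }
    normals = ann.normals()
    if normals:
        groups["normal"] = pdist(vals[normals].to_numpy().T, metric="cityblock")

    names = list(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            rows.append((a, b, unpaired_wilcoxon(groups[a], groups[b])))
    tests = pd.DataFrame(rows, columns=["group_a", "group_b", "p_value"])
    return groups, tests


@dataclass
class Concordance:
    """Agreement between two TR/NP label columns over shared pairs."""

    n_agree: int
    n_total: int
    p_value: float
    disagreements: list[str]

    @property
    def fraction(self) -> float:
        return self.n_agree / self.n_total


def concordance(
    labels_a: list[str | None],
    labels_b: list[str | None],
    pair_ids: list[str] | None = None,
) -> Concordance:
    """Pairwise agreement and Fisher exact test on the 2x2 agreement table."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label columns must align")
    ids = pair_ids if pair_ids is not None else [str(i + 1) for i in range(len(labels_a))]
    mask = [a is not None and b is not None for a, b in zip(labels_a, labels_b)]
    a = [x for x, keep in zip(labels_a, mask) if keep]
    b = [x for x, keep in zip(labels_b, mask) if keep]
    kept_ids = [x for x, keep in zip(ids, mask) if keep]
    if not a:
        raise ValueError("no pairs with both labels present")
    table = np.zeros((2, 2), dtype=int)
    for x, y in zip(a, b):
        table[int(x == "NP"), int(y == "NP")] += 1
    n_agree = int(table[0, 0] + table[1, 1])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    disagreements = [i for i, x, y in zip(kept_ids, a, b) if x != y]
    return Concordance(
        n_agree=n_agree, n_total=len(a), p_value=float(p), disagreements=disagreements
    )


def score_correlation(
    ms_scores: np.ndarray, pis_scores: np.ndarray
) -> dict[str, float]:
    """Pearson correlation and least-squares line between two score vectors."""
    x = np.asarray(pis_scores, dtype=float)
    y = np.asarray(ms_scores, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 aligned score pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant score vector")
    r, p = stats.pearsonr(x, y)
    fit = stats.linregress(x, y)
    return {
        "r": float(r),
        "p_value": float(p),
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
    }
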
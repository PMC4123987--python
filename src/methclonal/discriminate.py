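"""Supervised discrimination of primaries from recurrences, pair-aware.

A linear support vector machine is asked to tell primary-tumor profiles
from matched recurrence profiles.  Evaluation is leave-pair-out: each
fold holds out both samples of one patient, and the pair counts as
correct only if both held-out samples are labeled correctly — the
stricter pair-level reading of held-out accuracy.  Dimensionality
reduction (the most significant probes by a paired signed-rank test) and
the margin-parameter choice (inner leave-pair-out over a fixed grid) use
training pairs only, so no information from the held-out pair leaks into
feature selection or tuning.

Chance performance is assessed against a pair-level random guesser,
Binomial(n_pairs, 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC

from .dmp import paired_wilcoxon
from .io import BetaMatrix, SampleAnnotation

__all__ = [
    "CvResult",
    "leave_pair_out_cv",
    "accuracy_pvalue",
    "feature_curve",
    "DEFAULT_C_GRID",
]

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass
class CvResult:
    """Outcome of a leave-pair-out cross-validation run."""

    n_pairs: int
    n_correct_pairs: int
    per_pair: pd.DataFrame  # pair_id, pt_correct, rec_correct, pair_correct
    n_features: int
    p_value: float

    @property
    def accuracy(self) -> float:
        return self.n_correct_pairs / self.n_pairs

    @property
    def sample_accuracy(self) -> float:
        """Fraction of individual held-out samples labeled correctly."""
        pp = self.per_pair
        return float((pp["pt_correct"].sum() + pp["rec_correct"].sum()) / (2 * len(pp)))


def accuracy_pvalue(n_correct: int, n_pairs: int) -> float:
    """One-sided tail P[X >= n_correct] for X ~ Binomial(n_pairs, 1/2)."""
    if not 0 <= n_correct <= n_pairs:
        raise ValueError("n_correct must lie in [0, n_pairs]")
    return float(stats.binom.sf(n_correct - 1, n_pairs, 0.5))


def _select_features(
    pt: np.ndarray, rec: np.ndarray, n_features: int
) -> np.ndarray:
    """Indices of the n_features most significant probes on training pairs.

    Ranked by paired signed-rank p, then by |mean difference| (largest
    first), then by probe index — a deterministic ordering.
    """
    p = paired_wilcoxon(rec, pt)
    absdiff = np.abs((rec - pt).mean(axis=1))
    order = np.lexsort((np.arange(p.size), -absdiff, p))
    return np.sort(order[:n_features])


def _fit_predict(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray, c: float
) -> np.ndarray:
    clf = SVC(kernel="linear", C=c)
    clf.fit(x_train, y_train)
    return clf.predict(x_test)


def _inner_select_c(
    pt: np.ndarray, rec: np.ndarray, c_grid: tuple[float, ...]
) -> float:
    """Inner leave-pair-out accuracy per margin parameter; ties -> smallest C."""
    if len(c_grid) == 1:
        return c_grid[0]
    n = pt.shape[1]
    scores = np.zeros(len(c_grid))
    for j in range(n):
        keep = np.arange(n) != j
        x_train = np.vstack([pt[:, keep].T, rec[:, keep].T])
        y_train = np.concatenate([np.zeros(n - 1), np.ones(n - 1)])
        x_test = np.vstack([pt[:, j], rec[:, j]])
        for k, c in enumerate(c_grid):
            pred = _fit_predict(x_train, y_train, x_test, c)
            scores[k] += float(pred[0] == 0 and pred[1] == 1)
    return c_grid[int(np.argmax(scores))]  # argmax takes the first = smallest C


def leave_pair_out_cv(
    m: BetaMatrix,
    ann: SampleAnnotation,
    cohort: str,
    n_features: int | None = None,
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
) -> CvResult:
    """Pair-level held-out accuracy of a linear SVM separating PT from REC.

    ``n_features=None`` uses every probe (no filtering path).  A value
    above the probe count is clamped with a warning.
    """
    pairs = ann.complete_pairs(cohort)
    if len(pairs) < 3:
        raise ValueError("need at least 3 complete pairs")
    complete = ~m.values.isna().any(axis=1)
    vals = m.values.loc[complete]
    pt_all = vals[[p for _, p, _ in pairs]].to_numpy()  # probes x pairs
    rec_all = vals[[r for _, _, r in pairs]].to_numpy()
    n_probes, n = pt_all.shape
    if n_features is not None and n_features > n_probes:
        import warnings

        warnings.warn(
            f"n_features={n_features} exceeds probe count {n_probes}; clamped"
        )
        n_features = n_probes

    rows = []
    for i in range(n):
        train = np.arange(n) != i
        pt_tr, rec_tr = pt_all[:, train], rec_all[:, train]
        if n_features is not None:
            feats = _select_features(pt_tr, rec_tr, n_features)
        else:
            feats = np.arange(n_probes)
        c = _inner_select_c(pt_tr[feats], rec_tr[feats], c_grid)
        x_train = np.vstack([pt_tr[feats].T, rec_tr[feats].T])
        y_train = np.concatenate([np.zeros(n - 1), np.ones(n - 1)])
        x_test = np.vstack([pt_all[feats, i], rec_all[feats, i]])
        pred = _fit_predict(x_train, y_train, x_test, c)
        pt_ok, rec_ok = bool(pred[0] == 0), bool(pred[1] == 1)
        rows.append((pairs[i][0], pt_ok, rec_ok, pt_ok and rec_ok))

    per_pair = pd.DataFrame(
        rows, columns=["pair_id", "pt_correct", "rec_correct", "pair_correct"]
    )
    n_correct = int(per_pair["pair_correct"].sum())
    return CvResult(
        n_pairs=n,
        n_correct_pairs=n_correct,
        per_pair=per_pair,
        n_features=n_features if n_features is not None else n_probes,
        p_value=accuracy_pvalue(n_correct, n),
    )


def feature_curve(
    m: BetaMatrix,
    ann: SampleAnnotation,
    cohort: str,
    grid: list[int | None],
    c_grid: tuple[float, ...] = DEFAULT_C_GRID,
) -> pd.DataFrame:
    """Held-out accuracy as a function of the number of filtered probes."""
    rows = []
    for nf in grid:
        res = leave_pair_out_cv(m, ann, cohort, n_features=nf, c_grid=c_grid)
        rows.append((res.n_features, res.n_correct_pairs, res.accuracy, res.p_value))
    return pd.DataFrame(
        rows, columns=["n_features", "n_correct_pairs", "accuracy", "p_value"]
    )
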
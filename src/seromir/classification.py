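"""KNN biomarker evaluation: LOOCV reports, marker ranking, K selection.

The classifier is a k-nearest-neighbour majority vote over Euclidean
distances between log2-CPM expression vectors.  Tie-breaking is fully
specified so that results are reproducible: distance ties at the k-th
position are resolved by stable training order (samples canonically
sorted by ID), vote ties by the smallest summed distance to the query
among the tied labels, then by lexicographic label order.

Marker ranking follows the evaluate-then-accumulate scheme: each
candidate miRNA is scored alone by LOOCV, candidates are sorted by the
chosen criterion, and growing prefixes of the sorted list are re-scored
by LOOCV, yielding cumulative accuracy/sensitivity curves.  By default
the ranking is computed once on the full dataset (the curves are
therefore optimistically biased as generalization estimates); a nested
mode re-ranks candidates inside every leave-one-out fold.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .normalization import NormalizedExpression

DEFAULT_K = 11

_LABEL_MAP_2GROUP = {"PC": "cancer", "BTC": "cancer", "HC": "control"}


@dataclasses.dataclass
class ClassifierReport:
    """LOOCV performance of one feature set.

    ``contingency`` is predicted (rows) x true (columns); accuracy is its
    trace over the total, sensitivity(c) the diagonal over the true-class
    column sum, specificity(c) the correctly rejected negatives over all
    negatives of class c.
    """

    feature_set: list[str]
    k: int
    accuracy: float
    sensitivity: pd.Series
    specificity: pd.Series
    contingency: pd.DataFrame
    n_samples: int

    def __post_init__(self) -> None:
        total = int(self.contingency.to_numpy().sum())
        if total != self.n_samples:
            raise ValueError("contingency entries must sum to n_samples")


@dataclasses.dataclass
class MarkerRanking:
    """Per-marker LOOCV scores (sorted) and cumulative-prefix scores."""

    per_marker: pd.DataFrame   # index mirna_id, cols accuracy/sensitivity/specificity
    cumulative: pd.DataFrame   # index prefix length, cols accuracy/sensitivity
    reports: list[ClassifierReport]
    criterion: str


def knn_predict(
    train_expr: np.ndarray,
    train_labels: Sequence[str],
    query: np.ndarray,
    k: int = DEFAULT_K,
) -> str:
    """Majority-vote label of the k nearest training samples (Euclidean).

    Ties at the k-th distance are broken by stable training order; vote
    ties by the smallest summed distance to the query among tied labels,
    then lexicographically.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    train_expr = np.asarray(train_expr, dtype=float)
    labels = np.asarray(train_labels)
    if k > train_expr.shape[0]:
        raise ValueError("k exceeds the number of training samples")
    query = np.asarray(query, dtype=float)
    if query.shape[-1] != train_expr.shape[1]:
        raise ValueError("feature dimensions do not match")
    d = np.sqrt(((train_expr - query) ** 2).sum(axis=1))
    nearest = np.argsort(d, kind="stable")[:k]
    votes: dict[str, int] = {}
    sums: dict[str, float] = {}
    for i in nearest:
        lab = labels[i]
        votes[lab] = votes.get(lab, 0) + 1
        sums[lab] = sums.get(lab, 0.0) + d[i]
    top = max(votes.values())
    tied = [lab for lab, v in votes.items() if v == top]
    if len(tied) == 1:
        return tied[0]
    return min(tied, key=lambda lab: (sums[lab], lab))


def _report_from_predictions(
    predicted: Sequence[str],
    true: Sequence[str],
    feature_set: Sequence[str],
    k: int,
) -> ClassifierReport:
    classes = sorted(set(true))
    cont = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for p, t in zip(predicted, true):
        if p not in cont.index:
            cont.loc[p] = 0
            cont = cont.sort_index()
        cont.loc[p, t] += 1
    n = len(true)
    diag = pd.Series(
        {c: int(cont.loc[c, c]) if c in cont.index else 0 for c in classes}
    )
    col_sums = cont.sum(axis=0)
    row_sums = cont.sum(axis=1).reindex(cont.columns, fill_value=0)
    accuracy = float(diag.sum()) / n
    sensitivity = (diag / col_sums).astype(float)
    tn = n - col_sums - row_sums.reindex(classes, fill_value=0) + diag
    negatives = n - col_sums
    specificity = (tn / negatives.replace(0, np.nan)).astype(float)
    return ClassifierReport(
        feature_set=list(feature_set),
        k=k,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        contingency=cont,
        n_samples=n,
    )


def _feature_matrix(
    expr: NormalizedExpression | pd.DataFrame, feature_set: Sequence[str]
) -> pd.DataFrame:
    mat = expr.log2cpm if isinstance(expr, NormalizedExpression) else expr
    missing = [f for f in feature_set if f not in mat.index]
    if missing:
        raise ValueError(f"features absent from expression matrix: {missing}")
    return mat.loc[list(feature_set)].T  # samples x features


def _align_labels(
    labels: pd.Series | Sequence[str], index: pd.Index
) -> pd.Series:
    """Labels as a Series aligned to ``index`` (sample IDs).

    A Series keyed by sample IDs is reindexed; any other sequence is
    matched positionally and must have the right length.
    """
    if isinstance(labels, pd.Series) and set(index).issubset(labels.index):
        out = labels.reindex(index)
    else:
        if len(labels) != len(index):
            raise ValueError("labels length does not match the sample count")
        out = pd.Series(np.asarray(labels), index=index)
    if out.isna().any():
        missing = out.index[out.isna()].tolist()
        raise ValueError(f"labels missing for samples: {missing}")
    return out


def loocv_report(
    expr: NormalizedExpression | pd.DataFrame,
    labels: pd.Series | Sequence[str],
    feature_set: Sequence[str],
    k: int = DEFAULT_K,
) -> ClassifierReport:
    """Leave-one-out cross-validated KNN report for one feature set.

    Samples are processed in canonical sample-ID order so predictions are
    invariant to the input column ordering.  Every class must have at
    least 2 members (otherwise its held-out samples would have no same
    -class neighbours at all).
    """
    X = _feature_matrix(expr, feature_set)
    labels = _align_labels(labels, X.index)
    counts = labels.value_counts()
    single = counts[counts < 2].index.tolist()
    if single:
        raise ValueError(f"classes with a single member: {single}")
    order = np.argsort(X.index.to_numpy(), kind="stable")
    X = X.iloc[order]
    labels = labels.iloc[order]
    arr = X.to_numpy(dtype=float)
    labs = labels.to_numpy()
    n = arr.shape[0]
    if k > n - 1:
        raise ValueError("k exceeds the LOOCV training size")
    predictions = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        predictions.append(knn_predict(arr[mask], labs[mask], arr[i], k))
    return _report_from_predictions(predictions, labs, feature_set, k)


def _score(report: ClassifierReport, criterion: str, positive: str | None) -> float:
    if criterion == "accuracy":
        return report.accuracy
    if criterion == "sensitivity":
        if positive is not None:
            return float(report.sensitivity.get(positive, 0.0))
        return float(report.sensitivity.mean())
    raise ValueError(f"unknown criterion {criterion!r}")


def rank_and_accumulate(
    expr: NormalizedExpression | pd.DataFrame,
    labels: pd.Series | Sequence[str],
    candidate_set: Sequence[str],
    k: int = DEFAULT_K,
    criterion: str = "accuracy",
    positive_class: str | None = None,
    nested: bool = False,
) -> MarkerRanking:
    """Rank candidate miRNAs by single-feature LOOCV, then score prefixes.

    ``criterion`` is "accuracy" or "sensitivity"; for multi-class tasks
    "sensitivity" uses ``positive_class`` if given (default: "cancer"
    when present among the labels, else the macro average).  Sorting ties
    are broken by higher accuracy, then higher sensitivity, then
    lexicographic miRNA ID.  With ``nested=True`` the cumulative curve is
    computed by re-ranking candidates within each leave-one-out fold
    (honest generalization estimate); the per-marker table always comes
    from the full data.
    """
    if len(candidate_set) == 0:
        raise ValueError("candidate_set must be non-empty")
    mat = expr.log2cpm if isinstance(expr, NormalizedExpression) else expr
    labels = _align_labels(labels, mat.columns)
    if positive_class is None and "cancer" in set(labels):
        positive_class = "cancer"

    individual = {
        m: loocv_report(expr, labels, [m], k) for m in candidate_set
    }
    rows = {
        m: {
            "accuracy": r.accuracy,
            "sensitivity": _score(r, "sensitivity", positive_class),
            "specificity": float(r.specificity.mean()),
        }
        for m, r in individual.items()
    }
    per_marker = pd.DataFrame(rows).T
    if criterion not in ("accuracy", "sensitivity"):
        raise ValueError(f"unknown criterion {criterion!r}")
    ordered = sorted(
        per_marker.index,
        key=lambda m: (
            -per_marker.loc[m, criterion],
            -per_marker.loc[m, "accuracy"],
            -per_marker.loc[m, "sensitivity"],
            m,
        ),
    )
    per_marker = per_marker.loc[ordered]
    per_marker.index.name = "mirna_id"

    if not nested:
        reports = [
            loocv_report(expr, labels, ordered[: i + 1], k)
            for i in range(len(ordered))
        ]
        cumulative = pd.DataFrame(
            {
                "accuracy": [r.accuracy for r in reports],
                "sensitivity": [
                    _score(r, "sensitivity", positive_class) for r in reports
                ],
            },
            index=pd.Index(range(1, len(ordered) + 1), name="n_features"),
        )
    else:
        reports = []
        cumulative = _nested_cumulative(
            expr, labels, list(candidate_set), k, criterion, positive_class
        )
    return MarkerRanking(
        per_marker=per_marker,
        cumulative=cumulative,
        reports=reports,
        criterion=criterion,
    )


def _nested_cumulative(
    expr, labels, candidates, k, criterion, positive_class
) -> pd.DataFrame:
    """Cumulative curves with fold-internal candidate ranking."""
    X = _feature_matrix(expr, candidates)
    labels = _align_labels(labels, X.index)
    order = np.argsort(X.index.to_numpy(), kind="stable")
    X, labels = X.iloc[order], labels.iloc[order]
    n = len(X)
    n_prefix = len(candidates)
    preds = np.empty((n, n_prefix), dtype=object)
    for i in range(n):
        inner = X.drop(X.index[i])
        inner_labels = labels.drop(labels.index[i])
        ranking = rank_and_accumulate(
            inner.T, inner_labels, candidates, k, criterion,
            positive_class, nested=False,
        )
        ordered = list(ranking.per_marker.index)
        for j in range(n_prefix):
            feats = ordered[: j + 1]
            preds[i, j] = knn_predict(
                inner[feats].to_numpy(dtype=float),
                inner_labels.to_numpy(),
                X.iloc[i][feats].to_numpy(dtype=float),
                k,
            )
    recs = [
        _report_from_predictions(preds[:, j], labels.to_numpy(), candidates, k)
        for j in range(n_prefix)
    ]
    return pd.DataFrame(
        {
            "accuracy": [r.accuracy for r in recs],
            "sensitivity": [_score(r, "sensitivity", positive_class) for r in recs],
        },
        index=pd.Index(range(1, n_prefix + 1), name="n_features"),
    )


def select_k_bootstrap(
    expr: NormalizedExpression | pd.DataFrame,
    labels: pd.Series | Sequence[str],
    feature_set: Sequence[str],
    k_grid: Sequence[int] | None = None,
    B: int = 200,
    seed: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose k by bootstrap out-of-bag accuracy and majority-vote share.

    Each replicate resamples the samples with replacement; the out-of-bag
    samples are predicted for every k in ``k_grid`` (default odd 1..21).
    Per k the mean out-of-bag accuracy, its bootstrap standard error and
    the mean winning-vote proportion are reported.  The chosen k is the
    smallest whose mean accuracy is within one standard error of the
    maximum (a documented stand-in for an unstated selection criterion).
    Replicates whose in-bag set misses a class are discarded with a
    warning; more than 50% discarded is an error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if k_grid is None:
        k_grid = list(range(1, 22, 2))
    k_grid = sorted(k_grid)
    X = _feature_matrix(expr, feature_set)
    labels = _align_labels(labels, X.index)
    arr = X.to_numpy(dtype=float)
    labs = labels.to_numpy()
    n = arr.shape[0]
    if max(k_grid) > n:
        raise ValueError("k_grid exceeds the sample count")
    rng = np.random.default_rng(seed)
    classes = set(labs)

    acc = {k: [] for k in k_grid}
    vote = {k: [] for k in k_grid}
    discarded = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if set(labs[idx]) != classes or oob.size == 0:
            discarded += 1
            continue
        train_x, train_y = arr[idx], labs[idx]
        d = np.sqrt(
            ((train_x[None, :, :] - arr[oob][:, None, :]) ** 2).sum(axis=2)
        )
        order = np.argsort(d, axis=1, kind="stable")
        for k in k_grid:
            correct = 0
            shares = []
            for row, q in enumerate(oob):
                nearest = order[row, :k]
                votes: dict[str, int] = {}
                sums: dict[str, float] = {}
                for i in nearest:
                    lab = train_y[i]
                    votes[lab] = votes.get(lab, 0) + 1
                    sums[lab] = sums.get(lab, 0.0) + d[row, i]
                top = max(votes.values())
                tied = [lab for lab, v in votes.items() if v == top]
                pred = tied[0] if len(tied) == 1 else min(
                    tied, key=lambda lab: (sums[lab], lab)
                )
                correct += int(pred == labs[q])
                shares.append(top / k)
            acc[k].append(correct / oob.size)
            vote[k].append(float(np.mean(shares)))
    if discarded:
        warnings.warn(
            f"{discarded}/{B} bootstrap replicates missed a class and were "
            "discarded",
            RuntimeWarning,
        )
    if discarded > B / 2:
        raise ValueError("more than half of the bootstrap replicates discarded")

    kept = len(acc[k_grid[0]])
    table = pd.DataFrame(
        {
            "mean_accuracy": [float(np.mean(acc[k])) for k in k_grid],
            "se_accuracy": [
                float(np.std(acc[k], ddof=1) / np.sqrt(kept)) if kept > 1 else 0.0
                for k in k_grid
            ],
            "mean_vote_share": [float(np.mean(vote[k])) for k in k_grid],
        },
        index=pd.Index(k_grid, name="k"),
    )
    best = table["mean_accuracy"].max()
    se_at_best = float(
        table.loc[table["mean_accuracy"].idxmax(), "se_accuracy"]
    )
    eligible = table.index[table["mean_accuracy"] >= best - se_at_best]
    return int(eligible.min()), table


def two_group_collapse(labels: pd.Series | Sequence[str]) -> pd.Series:
    """Collapse PC/BTC to "cancer" and HC to "control"."""
    s = pd.Series(labels)
    unknown = sorted(set(s) - set(_LABEL_MAP_2GROUP))
    if unknown:
        raise ValueError(f"unknown group labels: {unknown}")
    return s.map(_LABEL_MAP_2GROUP)
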
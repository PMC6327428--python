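"""Repeated k-fold edge-masking cross-validation and ranking metrics.

Known interactions (the positive edges) are partitioned into k folds;
each fold in turn is masked out of the adjacency, the predictor is
refit on the masked network (clustering and similarity included, so no
information leaks from the held-out edges), and the held-out positives
are ranked against every never-interacting pair.  The whole procedure
repeats with fresh random folds and all per-fold metrics are averaged.

Metrics: AUC (midrank convention — the probability that a random
positive outranks a random negative, ties counted 1/2), AUPR (area
under the precision-recall step curve), and the thresholded confusion
metrics sensitivity, specificity, precision, accuracy and F1:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

The default operating point is prevalence-matched: a pair is called
positive when its score reaches the R-th largest score among evaluated
pairs, R being the number of held-out positives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import baselines as _baselines
from .network import InteractionNetwork

__all__ = [
    "ConfusionCounts",
    "CVReport",
    "kfold_edge_splits",
    "mask_edges",
    "confusion_at_threshold",
    "basic_metrics",
    "auc_score",
    "aupr_score",
    "run_cv",
    "PREDICTORS",
]

METRIC_NAMES = [
    "auc",
    "aupr",
    "sensitivity",
    "specificity",
    "precision",
    "accuracy",
    "f1",
]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class CVReport:
    """Per-fold metric records plus their means and standard deviations."""

    per_fold: pd.DataFrame
    config: dict = field(default_factory=dict)

    @property
    def means(self) -> dict[str, float]:
        return {m: float(self.per_fold[m].mean()) for m in METRIC_NAMES}

    @property
    def stds(self) -> dict[str, float]:
        return {m: float(self.per_fold[m].std(ddof=0)) for m in METRIC_NAMES}

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "means": self.means,
            "stds": self.stds,
            "per_fold": self.per_fold.to_dict(orient="records"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    def to_csv(self, path) -> None:
        self.per_fold.to_csv(path, index=False)

    def summary(self) -> str:
        lines = [
            f"{'metric':<14}{'mean':>10}{'sd':>10}",
            "-" * 34,
        ]
        means, stds = self.means, self.stds
        for m in METRIC_NAMES:
            lines.append(f"{m:<14}{means[m]:>10.4f}{stds[m]:>10.4f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# splitting and masking
# ---------------------------------------------------------------------------

def kfold_edge_splits(net: InteractionNetwork, k: int, rng) -> list[np.ndarray]:
    """Partition the positive edges into k folds of near-equal size.

    Returns a list of (f_i x 2) index arrays; fold sizes differ by at
    most one.  Deterministic given the generator state.
    """
    edges = net.positive_edges()
    if len(edges) < k:
        raise ValueError(f"need at least k={k} positive edges, have {len(edges)}")
    perm = rng.permutation(len(edges))
    return [edges[idx] for idx in np.array_split(perm, k)]


def mask_edges(net: InteractionNetwork, test_edges) -> InteractionNetwork:
    """Copy of ``net`` with the given positive edges zeroed out."""
    test_edges = np.asarray(test_edges, dtype=int).reshape(-1, 2)
    masked = net.copy()
    if len(test_edges):
        rows, cols = test_edges[:, 0], test_edges[:, 1]
        if (masked.adjacency[rows, cols] != 1).any():
            raise ValueError("cannot mask a pair that is not a known edge")
        masked.adjacency[rows, cols] = 0
    return masked


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def confusion_at_threshold(scores, labels, threshold: float) -> ConfusionCounts:
    """Tally the confusion counts at ``score >= threshold``."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    pred = s >= threshold
    return ConfusionCounts(
        tp=int((pred & y).sum()),
        tn=int((~pred & ~y).sum()),
        fp=int((pred & ~y).sum()),
        fn=int((~pred & y).sum()),
    )


def basic_metrics(c: ConfusionCounts) -> dict:
    """Thresholded classification metrics from confusion counts.

    Ratios with a zero denominator are reported as 0.0 and listed in the
    returned record's ``undefined`` entry, so degenerate folds never
    abort a long cross-validation.
    """
    if c.total == 0:
        raise ValueError("no evaluated pairs")
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    sensitivity = ratio(c.tp, c.tp + c.fn, "sensitivity")
    specificity = ratio(c.tn, c.tn + c.fp, "specificity")
    precision = ratio(c.tp, c.tp + c.fp, "precision")
    accuracy = (c.tp + c.tn) / c.total
    if precision + sensitivity == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    return {
        "sensitivity": sensitivity,
        "specificity": specificity,
        "precision": precision,
        "accuracy": accuracy,
        "f1": f1,
        "undefined": undefined,
    }


def auc_score(scores, labels) -> float:
    """Area under the ROC curve, midrank (tie = 1/2) convention."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("auc_score needs both classes present")
    ranks = rankdata(s)  # midranks
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def aupr_score(scores, labels) -> float:
    """Area under the precision-recall step curve, descending scores.

    Ties are handled by grouping: the curve is evaluated only at
    distinct thresholds, and the area accumulates
    ``(R_t - R_{t-1}) * P_t`` over threshold steps t.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(float)
    n_pos = y.sum()
    if n_pos == 0:
        raise ValueError("aupr_score needs at least one positive")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    tp_cum = np.cumsum(y_sorted)
    ranks = np.arange(1, len(s) + 1)
    # last index of each distinct-score block
    is_block_end = np.append(s_sorted[1:] != s_sorted[:-1], True)
    tp_b = tp_cum[is_block_end]
    n_b = ranks[is_block_end]
    recall = tp_b / n_pos
    precision = tp_b / n_b
    recall_prev = np.concatenate([[0.0], recall[:-1]])
    return float(((recall - recall_prev) * precision).sum())


# ---------------------------------------------------------------------------
# cross-validation harness
# ---------------------------------------------------------------------------

def _accbn_predictor(net, seed, config):
    from .model import accbn_scores

    return accbn_scores(net, seed=seed, **config)


def _rwr_predictor(net, seed, config):
    params = _baselines.BaselineParams(**config) if config else None
    return _baselines.rwr_scores(net, params)


def _lpbni_predictor(net, seed, config):
    return _baselines.lpbni_scores(net)


PREDICTORS = {
    "accbn": _accbn_predictor,
    "rwr": _rwr_predictor,
    "lpbni": _lpbni_predictor,
}


def run_cv(
    net: InteractionNetwork,
    method: str = "accbn",
    k: int = 5,
    repeats: int = 20,
    seed: int | None = None,
    method_config: dict | None = None,
    threshold: float | None = None,
    max_negatives: int | None = None,
) -> CVReport:
    """Repeated k-fold edge-masking cross-validation.

    For every repeat x fold the test edges are masked, the predictor is
    refit on the masked network, and the held-out positives are scored
    against the never-interacting pairs (all of them by default;
    ``max_negatives`` subsamples for very large networks).  The binary
    operating point defaults to the prevalence-matched top-R rule; pass
    ``threshold`` to override.

    Fully reproducible from ``seed``.
    """
    if method not in PREDICTORS:
        raise ValueError(
            f"unknown method {method!r}; choose one of {sorted(PREDICTORS)}"
        )
    predictor = PREDICTORS[method]
    config = dict(method_config or {})
    rng = np.random.default_rng(seed)
    neg_pairs = np.argwhere(net.adjacency == 0)

    records = []
    for rep in range(repeats):
        folds = kfold_edge_splits(net, k, rng)
        for fold_idx, test_edges in enumerate(folds):
            fold_seed = int(rng.integers(2**31 - 1))
            train = mask_edges(net, test_edges)
            # leakage guard: the predictor must never see a held-out edge
            assert train.adjacency[test_edges[:, 0], test_edges[:, 1]].sum() == 0
            scores = predictor(train, fold_seed, config)

            if max_negatives is not None and len(neg_pairs) > max_negatives:
                sel = rng.choice(len(neg_pairs), size=max_negatives, replace=False)
                negs = neg_pairs[sel]
            else:
                negs = neg_pairs
            eval_pairs = np.vstack([test_edges, negs])
            y = np.concatenate(
                [np.ones(len(test_edges)), np.zeros(len(negs))]
            ).astype(int)
            s = scores.values[eval_pairs[:, 0], eval_pairs[:, 1]]

            if threshold is None:
                R = len(test_edges)
                thr = np.partition(s, len(s) - R)[len(s) - R]
            else:
                thr = threshold
            conf = confusion_at_threshold(s, y, thr)
            rec = basic_metrics(conf)
            record = {
                "repeat": rep,
                "fold": fold_idx,
                "n_test_pos": len(test_edges),
                "n_eval": len(s),
                "threshold": float(thr),
                "auc": auc_score(s, y),
                "aupr": aupr_score(s, y),
                "sensitivity": rec["sensitivity"],
                "specificity": rec["specificity"],
                "precision": rec["precision"],
                "accuracy": rec["accuracy"],
                "f1": rec["f1"],
                "undefined": ";".join(rec["undefined"]),
            }
            records.append(record)

    report = CVReport(
        per_fold=pd.DataFrame.from_records(records),
        config={
            "method": method,
            "k": k,
            "repeats": repeats,
            "seed": seed,
            "threshold": threshold,
            "max_negatives": max_negatives,
            "method_config": {key: repr(v) for key, v in config.items()},
        },
    )
    return report
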
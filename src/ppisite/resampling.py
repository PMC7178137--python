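"""Class re-balancing by RENN editing and instance-hardness-threshold
undersampling.

Interface-residue datasets are heavily imbalanced (non-interface residues
outnumber interface residues several-fold) and the two classes overlap in
feature space, because the surface/interface definitions are hard geometric
thresholds that do not track the functional boundary. Two undersampling
strategies address this:

* **RENN** (repeated edited nearest neighbours): iteratively remove every
  sample whose own label disagrees with the majority of its k = 3 nearest
  neighbours (Euclidean distance), sweeping until a sweep removes nothing.
  Removal is simultaneous within a sweep, so the result does not depend on
  sample order. By default only majority-class (negative) samples are
  removable; ``target="all"`` edits both classes.

* **IHT** (instance hardness threshold): score every sample by its
  *instance hardness* IH = 1 - p(y_i | x_i, h), the complement of the
  probability a trained probabilistic classifier h assigns to the sample's
  own label, estimated out-of-fold (stratified k-fold) to avoid leakage.
  The hardest majority-class samples are then removed until the classes
  reach the requested ratio (1:1 by default).

Feature columns are z-scored internally before distances / estimator
fitting (raw scales are heterogeneous: profile frequencies vs entropies);
the returned sample sets keep the raw values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .features import SampleSet

logger = logging.getLogger(__name__)

__all__ = [
    "ResampleReport",
    "renn_edit",
    "instance_hardness",
    "iht_resample",
    "iht_balance",
    "zscore",
]


@dataclass
class ResampleReport:
    """Before/after class counts and the identity of removed samples."""

    method: str  # "renn" | "iht"
    before_counts: tuple[int, int]  # (positives, negatives)
    after_counts: tuple[int, int]
    removed_ids: list[tuple[str, int]]
    iterations: int | None = None  # renn only
    estimator_spec: str | None = None  # iht only
    parameters: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "before_counts": {
                "positives": self.before_counts[0],
                "negatives": self.before_counts[1],
            },
            "after_counts": {
                "positives": self.after_counts[0],
                "negatives": self.after_counts[1],
            },
            "n_removed": len(self.removed_ids),
            "removed_ids": [list(k) for k in self.removed_ids],
            "iterations": self.iterations,
            "estimator_spec": self.estimator_spec,
            "parameters": self.parameters,
        }


def zscore(X: np.ndarray) -> np.ndarray:
    """Column-wise standardization; zero-variance columns pass through."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _majority_label(y: np.ndarray) -> int:
    pos, neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    return 0 if neg >= pos else 1


def _knn_disagrees(X: np.ndarray, y: np.ndarray, k: int) -> np.ndarray:
    """True where >= ceil(k/2 + eps) ... i.e. a strict majority of the k
    nearest neighbours (excluding self) carries a different label.

    With k = 3 the rule is: removed if 2 or more of the 3 nearest samples
    disagree. Exact duplicate points are handled by excluding each sample's
    own index, not merely zero-distance neighbours.
    """
    n = len(X)
    nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(X)
    _, idx = nn.kneighbors(X)
    disagree = np.zeros(n, dtype=bool)
    needed = k // 2 + 1
    for i in range(n):
        neighbors = [j for j in idx[i] if j != i][:k]
        disagree[i] = int(np.sum(y[neighbors] != y[i])) >= needed
    return disagree


def renn_edit(
    samples: SampleSet,
    k: int = 3,
    target: str = "negatives_only",
    max_iter: int = 100,
    standardize: bool = True,
) -> tuple[SampleSet, ResampleReport]:
    """Repeated edited-nearest-neighbours cleaning.

    Each sweep marks, simultaneously, every removable sample whose k = 3
    nearest neighbours (Euclidean, self excluded) contain two or more
    samples of the other class, then removes all marked samples at once;
    sweeps repeat until nothing is removed or ``max_iter`` is reached.
    ``target="negatives_only"`` (default) restricts removal to the majority
    class so the minority class is untouched; ``target="all"`` edits every
    sample, the literal form of the editing rule.

    Distances are computed on z-scored features (statistics taken once from
    the input set) unless ``standardize=False``.
    """
    if target not in ("negatives_only", "all"):
        raise ValueError(f"unknown target {target!r}")
    if samples.n_samples < k + 1:
        raise ValueError(f"need at least {k + 1} samples for {k}-NN editing")
    before = samples.class_counts
    X = zscore(samples.X) if standardize else np.asarray(samples.X, dtype=float)
    y = samples.y
    majority = _majority_label(y)

    keep = np.arange(samples.n_samples)
    iterations = 0
    while iterations < max_iter:
        iterations += 1
        disagree = _knn_disagrees(X[keep], y[keep], k)
        if target == "negatives_only":
            disagree &= y[keep] == majority
        if not disagree.any():
            break
        remaining = keep[~disagree]
        for cls in (0, 1):
            if np.sum(y[remaining] == cls) == 0:
                raise ValueError(
                    f"RENN editing would empty class {cls}; aborting"
                )
        keep = remaining
        if len(keep) < k + 1:
            break

    removed = sorted(set(range(samples.n_samples)) - set(keep))
    edited = samples.subset(keep)
    report = ResampleReport(
        method="renn",
        before_counts=before,
        after_counts=edited.class_counts,
        removed_ids=[samples.provenance[i] for i in removed],
        iterations=iterations,
        parameters={"k": k, "target": target, "standardize": standardize},
    )
    return edited, report


def instance_hardness(
    samples: SampleSet,
    estimator: str = "logistic",
    folds: int = 5,
    seed: int = 42,
) -> np.ndarray:
    """Per-sample instance hardness IH = 1 - p(y_i | x_i, h) in [0, 1].

    ``h`` is a logistic-regression estimator fitted on z-scored features;
    each sample's probability is taken out-of-fold under a stratified
    ``folds``-fold split with fixed seed, so no sample is scored by a model
    that saw it. Convergence failures are logged, not raised; scores come
    from the estimator's final iterate.
    """
    if estimator != "logistic":
        raise ValueError(f"unknown estimator spec {estimator!r}")
    pos, neg = samples.class_counts
    if pos == 0 or neg == 0:
        raise ValueError("instance hardness requires both classes present")
    if folds < 2:
        raise ValueError("need at least 2 folds")
    X = zscore(samples.X)
    y = samples.y
    proba_own = np.empty(len(y))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        clf = LogisticRegression(max_iter=200, random_state=seed)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            clf.fit(X[train_idx], y[train_idx])
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            logger.warning(
                "hardness estimator did not converge on one fold; "
                "using final iterate"
            )
        p = clf.predict_proba(X[test_idx])
        own_col = np.searchsorted(clf.classes_, y[test_idx])
        proba_own[test_idx] = p[np.arange(len(test_idx)), own_col]
    return np.clip(1.0 - proba_own, 0.0, 1.0)


def iht_resample(
    samples: SampleSet,
    scores: np.ndarray,
    ratio: float = 1.0,
) -> tuple[SampleSet, ResampleReport]:
    """Remove the hardest majority-class samples until the classes reach
    ``ratio`` (majority : minority = ratio : 1; 1.0 gives exact balance).

    Majority samples are sorted by hardness descending, ties broken by
    ascending provenance key; the top ``N_maj - ceil(N_min * ratio)`` are
    removed. The minority class is never touched; a ratio that would
    require removing minority samples is an error.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != samples.n_samples:
        raise ValueError("scores are not aligned with samples")
    pos, neg = samples.class_counts
    majority = _majority_label(samples.y)
    n_maj = neg if majority == 0 else pos
    n_min = pos if majority == 0 else neg
    n_keep_maj = int(np.ceil(n_min * ratio))
    if n_keep_maj > n_maj:
        raise ValueError(
            f"ratio {ratio} would require removing minority samples "
            f"(majority {n_maj} < target {n_keep_maj})"
        )
    maj_idx = np.flatnonzero(samples.y == majority)
    order = sorted(
        maj_idx, key=lambda i: (-scores[i], samples.provenance[i])
    )
    removed = order[: n_maj - n_keep_maj]
    keep_mask = np.ones(samples.n_samples, dtype=bool)
    keep_mask[removed] = False
    balanced = samples.subset(np.flatnonzero(keep_mask))
    report = ResampleReport(
        method="iht",
        before_counts=(pos, neg),
        after_counts=balanced.class_counts,
        removed_ids=[samples.provenance[i] for i in sorted(removed)],
        estimator_spec="logistic",
        parameters={"ratio": ratio},
    )
    return balanced, report


def iht_balance(
    samples: SampleSet,
    ratio: float = 1.0,
    estimator: str = "logistic",
    folds: int = 5,
    seed: int = 42,
) -> tuple[SampleSet, ResampleReport]:
    """Convenience wrapper: score hardness, then undersample to ``ratio``."""
    scores = instance_hardness(samples, estimator=estimator, folds=folds, seed=seed)
    balanced, report = iht_resample(samples, scores, ratio=ratio)
    report.parameters.update({"folds": folds, "seed": seed})
    report.estimator_spec = estimator
    return balanced, report
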
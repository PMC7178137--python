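"""Gradient-boosted tree classification of surface residues.

The predictor is an additive ensemble of K regression trees: the raw score
of a sample is the sum of its leaf values across trees, y_hat = sum_k
f_k(x), trained against the regularized binary-logistic objective
Obj = sum_i l(y_i, y_hat_i) + sum_k Omega(f_k), where Omega penalises tree
complexity (leaf count via gamma, squared leaf weights via lambda).
Training delegates to XGBoost configured to exactly this objective; the
class decision applies the logistic link to the summed score and thresholds
at 0.5.

Cross-validation follows a 10-fold protocol: each fold serves once as the
test set while the other nine train the model, and the pooled confusion
matrix over all folds is evaluated. Two modes handle the interaction with
resampling:

* ``resample_then_split``: the caller's resampler runs once on the full
  dataset before folding. This reproduces the historical protocol in which
  re-balanced sample counts are reported for the whole dataset, but lets
  test-fold information influence training data (a leakage warning is
  logged).
* ``split_then_resample`` (recommended): the resampler is applied to the
  nine training folds only, inside each round.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import xgboost as xgb

from .evaluation import ConfusionMatrix, MetricSet, compute_metrics
from .features import SampleSet
from . import resampling

logger = logging.getLogger(__name__)

__all__ = [
    "BoostedModelConfig",
    "FittedModel",
    "CvPlan",
    "CvResult",
    "train",
    "make_cv_plan",
    "cross_validate",
    "make_iht_resampler",
    "make_renn_resampler",
]


@dataclass
class BoostedModelConfig:
    """Hyperparameters of the boosted ensemble.

    ``n_trees`` is K, the ensemble size; ``gamma`` penalises each
    additional leaf and ``reg_lambda`` the squared leaf weights in the
    regularization term Omega(f). ``base_score`` is pinned at 0.5 (zero
    margin) so a sample's raw score is exactly the sum of its leaf values.
    """

    n_trees: int = 200
    learning_rate: float = 0.1
    max_depth: int = 4
    reg_lambda: float = 1.0
    gamma: float = 0.0
    objective: str = "binary:logistic"
    base_score: float = 0.5
    threshold: float = 0.5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.reg_lambda < 0 or self.gamma < 0:
            raise ValueError("regularization weights must be non-negative")

    def xgb_params(self) -> dict:
        return {
            "objective": self.objective,
            "eta": self.learning_rate,
            "max_depth": self.max_depth,
            "lambda": self.reg_lambda,
            "gamma": self.gamma,
            "base_score": self.base_score,
            "seed": self.seed,
            "nthread": 1,
            "tree_method": "hist",
        }

    @classmethod
    def from_json(cls, path: str | Path) -> "BoostedModelConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


@dataclass
class FittedModel:
    """A trained ensemble plus the configuration and column names used."""

    booster: xgb.Booster
    config: BoostedModelConfig
    feature_names: list[str]

    def _dmatrix(self, X: np.ndarray) -> xgb.DMatrix:
        return xgb.DMatrix(np.asarray(X, dtype=float))

    def predict_margin(self, X: np.ndarray) -> np.ndarray:
        """Raw additive score: the sum of per-tree leaf values."""
        return self.booster.predict(self._dmatrix(X), output_margin=True)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """P(interface) via the logistic link on the summed score."""
        return self.booster.predict(self._dmatrix(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) >= self.config.threshold).astype(int)

    def save(self, directory: str | Path) -> None:
        """Native text dump of the trees plus a JSON sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.booster.save_model(str(directory / "model.json"))
        sidecar = {
            "config": asdict(self.config),
            "feature_names": self.feature_names,
        }
        (directory / "sidecar.json").write_text(json.dumps(sidecar, indent=2) + "\n")

    @classmethod
    def load(cls, directory: str | Path) -> "FittedModel":
        directory = Path(directory)
        booster = xgb.Booster()
        booster.load_model(str(directory / "model.json"))
        sidecar = json.loads((directory / "sidecar.json").read_text())
        return cls(
            booster=booster,
            config=BoostedModelConfig(**sidecar["config"]),
            feature_names=sidecar["feature_names"],
        )


def train(samples: SampleSet, config: BoostedModelConfig | None = None) -> FittedModel:
    """Fit the boosted ensemble on a labeled sample set."""
    if config is None:
        config = BoostedModelConfig()
    pos, neg = samples.class_counts
    if pos == 0 or neg == 0:
        raise ValueError("training data must contain both classes")
    dtrain = xgb.DMatrix(samples.X, label=samples.y)
    booster = xgb.train(
        config.xgb_params(), dtrain, num_boost_round=config.n_trees
    )
    return FittedModel(
        booster=booster, config=config, feature_names=list(samples.feature_names)
    )


@dataclass
class CvPlan:
    """Fold assignment for cross-validation.

    The assignment is a partition: every sample belongs to exactly one
    fold, overall fold sizes differ by at most one, and class proportions
    are preserved per fold (stratified round-robin within each class).
    """

    n_folds: int
    assignment: np.ndarray
    mode: str  # "resample_then_split" | "split_then_resample"
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


def make_cv_plan(
    y: np.ndarray,
    n_folds: int = 10,
    seed: int = 42,
    mode: str = "split_then_resample",
) -> CvPlan:
    if mode not in ("resample_then_split", "split_then_resample"):
        raise ValueError(f"unknown CV mode {mode!r}")
    y = np.asarray(y)
    if len(y) < n_folds:
        raise ValueError("fewer samples than folds")
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(y), dtype=int)
    counter = 0
    # Round-robin within each class, continuing the counter across classes:
    # per-class and overall fold sizes both differ by at most one.
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i in idx:
            assignment[i] = counter % n_folds
            counter += 1
    return CvPlan(n_folds=n_folds, assignment=assignment, mode=mode, seed=seed)


@dataclass
class CvResult:
    plan: CvPlan
    fold_matrices: list[ConfusionMatrix]
    pooled: ConfusionMatrix
    pooled_metrics: MetricSet
    fold_metrics: list[MetricSet] = field(default_factory=list)
    resample_reports: list[dict] = field(default_factory=list)


Resampler = Callable[[SampleSet], tuple[SampleSet, "resampling.ResampleReport"]]


def make_iht_resampler(ratio: float = 1.0, folds: int = 5, seed: int = 42) -> Resampler:
    def _resample(samples: SampleSet):
        return resampling.iht_balance(samples, ratio=ratio, folds=folds, seed=seed)

    return _resample


def make_renn_resampler(
    k: int = 3, target: str = "negatives_only", max_iter: int = 100
) -> Resampler:
    def _resample(samples: SampleSet):
        return resampling.renn_edit(samples, k=k, target=target, max_iter=max_iter)

    return _resample


def cross_validate(
    samples: SampleSet,
    config: BoostedModelConfig | None = None,
    plan: CvPlan | None = None,
    resampler: Resampler | None = None,
    n_folds: int = 10,
    mode: str = "split_then_resample",
    seed: int | None = None,
) -> CvResult:
    """K-fold cross-validation with pooled evaluation.

    In ``resample_then_split`` mode the resampler runs once on the full
    set and the folds are drawn from its output (leakage warning logged);
    in ``split_then_resample`` mode it runs on each round's nine training
    folds only. The pooled confusion matrix accumulates every held-out
    prediction, so pooled TP+FN equals the total positives of the
    evaluated set.
    """
    if config is None:
        config = BoostedModelConfig()
    if seed is None:
        seed = config.seed
    reports: list[dict] = []

    evaluated = samples
    if resampler is not None and (plan.mode if plan else mode) == "resample_then_split":
        logger.warning(
            "resample_then_split applies resampling before folding; held-out "
            "folds influence the resampled training data (information leakage)"
        )
        evaluated, rep = resampler(samples)
        reports.append(rep.as_dict())
    if plan is None:
        plan = make_cv_plan(evaluated.y, n_folds=n_folds, seed=seed, mode=mode)
    if len(plan.assignment) != evaluated.n_samples:
        raise ValueError("CV plan does not cover the evaluated samples")

    fold_cms: list[ConfusionMatrix] = []
    for fold in range(plan.n_folds):
        train_set = evaluated.subset(plan.train_indices(fold))
        test_idx = plan.test_indices(fold)
        if resampler is not None and plan.mode == "split_then_resample":
            train_set, rep = resampler(train_set)
            reports.append({"fold": fold, **rep.as_dict()})
        pos, neg = train_set.class_counts
        if pos == 0 or neg == 0:
            raise ValueError(f"fold {fold}: training data contains a single class")
        model = train(train_set, config)
        y_pred = model.predict(evaluated.X[test_idx])
        fold_cms.append(ConfusionMatrix.from_predictions(evaluated.y[test_idx], y_pred))

    pooled = fold_cms[0]
    for cm in fold_cms[1:]:
        pooled = pooled + cm
    return CvResult(
        plan=plan,
        fold_matrices=fold_cms,
        pooled=pooled,
        pooled_metrics=compute_metrics(pooled),
        fold_metrics=[compute_metrics(cm) for cm in fold_cms],
        resample_reports=reports,
    )
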
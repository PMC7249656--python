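"""Random Forests treatment classification with fixed-ratio subsampling.

Each of the (default 100) trees is trained on an independent 66% subsample of
the training points drawn WITHOUT replacement — a fixed-ratio subsample, not
a bootstrap — and the remaining 34% serve as that tree's out-of-bag (OOB)
set. At each split ``floor(sqrt(p))`` of the p kept predictors are
considered. Tree induction itself is delegated to
:class:`sklearn.tree.DecisionTreeClassifier`; the subsampling, OOB
bookkeeping, error metrics, and vote-proportion prediction are implemented
here (sklearn's bootstrap/OOB machinery is not used).

OOB error metrics
-----------------
For sample ``i`` with OOB treatment-vote fraction ``p_i`` and true label
``y_i``, let ``q_i = p_i`` if ``y_i = 1`` else ``1 - p_i`` (the OOB vote for
the true class). Then::

    rmse            = sqrt(mean (1 - q_i)^2)
    avg_rel_error   = mean (1 - q_i)
    rel_class_error = fraction with q_i < 0.5
                      (ties q_i = 0.5 count as errors for label 1)

Prediction writes a two-band vote raster: band 1 is the fraction of trees
voting non-treatment, band 2 the fraction voting treatment; the bands sum to
1 at every finite cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .features import PredictorStack
from .raster_core import MultibandRaster
from .training import TrainingSet

__all__ = ["RFConfig", "RFModelResult", "VoteRaster",
           "fit_random_forest", "oob_metrics", "predict_vote_raster"]


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 100
    train_ratio: float = 0.66
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_ratio < 1:
            raise ValueError("train_ratio must be in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("need at least one tree")

    def m_try(self, n_predictors: int) -> int:
        """Predictors considered per split: floor(sqrt(p)), at least 1."""
        return max(1, int(np.floor(np.sqrt(n_predictors))))


@dataclass
class RFModelResult:
    trees: list
    feature_names: list[str]
    oob_rmse: float
    oob_avg_rel_error: float
    oob_rel_class_error: float
    oob_votes: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    n_never_oob: int = 0


def _oob_vote_fractions(trees, in_tree, X):
    """Per-sample OOB treatment-vote fraction; nan where never OOB."""
    n = X.shape[0]
    votes = np.zeros(n)
    counts = np.zeros(n)
    for t, tree in enumerate(trees):
        oob = ~in_tree[t]
        if oob.any():
            votes[oob] += tree.predict(X[oob])
            counts[oob] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, votes / counts, np.nan)


def oob_metrics(p: np.ndarray, y: np.ndarray) -> dict:
    """The three OOB error metrics from per-sample OOB vote fractions."""
    ok = np.isfinite(p)
    q = np.where(y[ok] == 1, p[ok], 1.0 - p[ok])
    err = 1.0 - q
    # a tied vote classifies as non-treatment, so it is an error for label 1
    wrong = np.where(y[ok] == 1, q <= 0.5, q < 0.5)
    return {
        "rmse": float(np.sqrt(np.mean(err**2))),
        "avg_rel_error": float(np.mean(err)),
        "rel_class_error": float(np.mean(wrong)),
    }


def fit_random_forest(train: TrainingSet, config: RFConfig = RFConfig()) -> RFModelResult:
    """Fit the ensemble and compute OOB error metrics.

    Deterministic under ``config.seed``: the per-tree subsamples and the
    per-tree sklearn random states all derive from it.
    """
    X, y = train.X, train.y
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    n = X.shape[0]
    n_sub = int(round(config.train_ratio * n))
    m_try = config.m_try(X.shape[1])
    rng = np.random.default_rng(config.seed)
    tree_seeds = rng.integers(0, 2**31 - 1, size=config.n_trees)
    trees = []
    in_tree = np.zeros((config.n_trees, n), dtype=bool)
    for t in range(config.n_trees):
        pick = rng.choice(n, size=n_sub, replace=False)
        in_tree[t, pick] = True
        tree = DecisionTreeClassifier(max_features=m_try,
                                      random_state=int(tree_seeds[t]))
        tree.fit(X[pick], y[pick])
        trees.append(tree)
    p = _oob_vote_fractions(trees, in_tree, X)
    n_never = int(np.sum(~np.isfinite(p)))
    metrics = oob_metrics(p, y)
    return RFModelResult(trees, list(train.predictor_names),
                         metrics["rmse"], metrics["avg_rel_error"],
                         metrics["rel_class_error"], p, n_never)


def predict_vote_raster(result: RFModelResult, stack: PredictorStack) -> "VoteRaster":
    """Two-band vote-proportion raster over the predictor stack.

    Band 2 is the fraction of trees predicting treatment; band 1 the
    complement. Nodata in any kept band propagates to both vote bands.
    """
    names = stack.kept_names
    if names != result.feature_names:
        raise ValueError(
            f"predictor bands {names} do not match training bands "
            f"{result.feature_names}"
        )
    vals = np.stack([stack.raster.band(n) for n in names])
    finite = np.all(np.isfinite(vals), axis=0)
    flat = vals[:, finite].T
    band2 = np.full(stack.raster.grid.shape, np.nan)
    if flat.shape[0] > 0:
        votes = np.zeros(flat.shape[0])
        for tree in result.trees:
            votes += tree.predict(flat)
        band2[finite] = votes / len(result.trees)
    band1 = 1.0 - band2
    raster = MultibandRaster(stack.raster.grid, ["non_treatment", "treatment"],
                             np.stack([band1, band2]))
    return VoteRaster(raster)


@dataclass
class VoteRaster:
    """Two-band class-proportion raster (band 1 non-treatment, band 2 treatment)."""

    raster: MultibandRaster

    def __post_init__(self) -> None:
        if self.raster.band_names != ["non_treatment", "treatment"]:
            raise ValueError("vote raster must have bands "
                             "['non_treatment', 'treatment']")

    @property
    def treatment_band(self) -> np.ndarray:
        return self.raster.band("treatment")
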
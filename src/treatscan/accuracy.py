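"""Independent accuracy assessment of the treatment-vote surface.

The vote raster's treatment band is binarized at fixed thresholds
(conventionally 0.25, 0.5, 0.75; strictly-greater counts as treatment), and
modeled values at stratified validation points (equal numbers inside and
outside the treatment truth polygons) are cross-tabulated against truth in a
2x2 contingency table::

                      true 1   true 0
        modeled 1        a        b
        modeled 0        c        d

From the table: overall accuracy (a+d)/n with its binomial standard error,
user accuracy a/(a+b) and d/(c+d), producer accuracy a/(a+c) and d/(b+d)
(accuracies printed as percentages), and the uncorrected chi-square
n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on 1 degree of freedom. A ROC curve over
the continuous vote values (group-by-score thresholds, trapezoidal AUC —
equivalent to the Mann-Whitney U statistic with ties counted one half)
summarizes separability across all thresholds at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy.stats import chi2 as chi2_dist

from .classify import VoteRaster
from .raster_core import MultibandRaster, PolygonSet

__all__ = ["ContingencyTable2x2", "AccuracyReport", "ROCCurve",
           "binarize_votes", "sample_validation", "contingency",
           "accuracy_report", "roc_auc"]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Modeled-vs-true counts: a=(1,1), b=(1,0), c=(0,1), d=(0,0)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.n == 0:
            raise ValueError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class AccuracyReport:
    overall: float
    user_acc_1: float  # percent
    user_acc_0: float
    producer_acc_1: float
    producer_acc_0: float
    chi_square: float | None
    df: int
    p_value: float | None
    ste: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("overall", "user_acc_1", "user_acc_0", "producer_acc_1",
                 "producer_acc_0", "chi_square", "df", "p_value", "ste")}


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def binarize_votes(votes: VoteRaster, threshold: float) -> MultibandRaster:
    """1 where the treatment band is strictly above the threshold, else 0."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    band = votes.treatment_band
    out = np.where(np.isfinite(band), (band > threshold).astype(float), np.nan)
    return MultibandRaster(votes.raster.grid, ["treatment_binary"], out[None])


def sample_validation(truth: PolygonSet, mask: MultibandRaster,
                      n_per_class: int = 500, seed: int = 0) -> pd.DataFrame:
    """Stratified validation sample: n points in treatment polygons (label 1)
    and n forest points outside them (label 0), uniform per stratum."""
    m = mask.values[0] == 1.0
    rows, cols = np.nonzero(m)
    grid = mask.grid
    xs = grid.origin_x + (cols + 0.5) * grid.cell_size
    ys = grid.origin_y - (rows + 0.5) * grid.cell_size
    if len(truth) == 0:
        raise ValueError("empty truth polygon set")
    union = shapely.union_all(truth.geometries)
    inside = shapely.intersects_xy(union, xs, ys)
    for name, stratum in (("treatment", inside), ("non-treatment", ~inside)):
        if stratum.sum() < n_per_class:
            raise ValueError(f"only {int(stratum.sum())} {name} cells, "
                             f"need {n_per_class}")
    rng = np.random.default_rng(seed)
    pick1 = rng.choice(np.flatnonzero(inside), size=n_per_class, replace=False)
    pick0 = rng.choice(np.flatnonzero(~inside), size=n_per_class, replace=False)
    idx = np.concatenate([pick1, pick0])
    labels = np.concatenate([np.ones(n_per_class, int), np.zeros(n_per_class, int)])
    return pd.DataFrame({"x": xs[idx], "y": ys[idx], "label": labels})


def contingency(modeled: MultibandRaster, samples: pd.DataFrame) -> ContingencyTable2x2:
    """Cross-tabulate modeled binary values at the sample points vs labels.

    Samples landing on nodata are dropped from the table.
    """
    grid = modeled.grid
    rows, cols = grid.index_of(samples["x"].to_numpy(), samples["y"].to_numpy())
    ok = (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
    if not ok.all():
        raise ValueError("sample points off the modeled grid")
    vals = modeled.values[0][rows, cols]
    finite = np.isfinite(vals)
    mod = vals[finite] == 1.0
    true = samples["label"].to_numpy()[finite] == 1
    return ContingencyTable2x2(
        a=int(np.sum(mod & true)), b=int(np.sum(mod & ~true)),
        c=int(np.sum(~mod & true)), d=int(np.sum(~mod & ~true)),
    )


def accuracy_report(t: ContingencyTable2x2) -> AccuracyReport:
    """All printed accuracy statistics of a 2x2 error matrix.

    The chi-square is the uncorrected (no continuity correction) statistic on
    one degree of freedom; it is undefined (reported as None) when any
    marginal is zero. STE is the binomial standard error of the overall
    accuracy, sqrt(p(1-p)/n).
    """
    a, b, c, d, n = t.a, t.b, t.c, t.d, t.n
    overall = (a + d) / n
    marginals = [(a + b), (c + d), (a + c), (b + d)]

    def pct(num, den):
        return 100.0 * num / den if den > 0 else float("nan")

    if all(m > 0 for m in marginals):
        chi = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in marginals])
        p_value = float(chi2_dist.sf(chi, 1))
    else:
        chi = None
        p_value = None
    return AccuracyReport(
        overall=overall,
        user_acc_1=pct(a, a + b), user_acc_0=pct(d, c + d),
        producer_acc_1=pct(a, a + c), producer_acc_0=pct(d, b + d),
        chi_square=chi, df=1, p_value=p_value,
        ste=float(np.sqrt(overall * (1 - overall) / n)),
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> ROCCurve:
    """ROC curve and trapezoidal AUC over continuous scores.

    Thresholds are the distinct score values in descending order (equal
    scores form one threshold step); the curve runs from (0,0) to (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s) != 0), s.size - 1]
    tp = np.cumsum(y == 1)[distinct]
    fp = np.cumsum(y == 0)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=s[distinct], tpr=tpr, fpr=fpr, auc=auc)
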
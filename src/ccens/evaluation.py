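"""Count-prediction metrics and group comparison.

Four metrics summarise how far predicted counts deviate from the truth:

    RMSE = sqrt(mean((c - chat)^2))
    MAE  = mean(|c - chat|)
    MAPE = mean(|c - chat| / |c|)        (reported as a fraction)
    r    = Pearson product-moment correlation

plus a two-sample t-test (Welch by default) for comparing predicted
counts between experimental groups.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

__all__ = ["MetricsReport", "GroupComparison", "rmse", "mae", "mape",
           "pearson_r", "evaluate_model", "compare_groups"]


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    rmse: float
    mae: float
    mape: float
    pearson_r: float
    n: int

    def as_dict(self):
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class GroupComparison:
    group_a_name: str
    group_b_name: str
    mean_a: float
    mean_b: float
    t_stat: float
    p_value: float
    n_a: int
    n_b: int


def _pair(truth, pred):
    t = np.asarray(truth, dtype=float).ravel()
    p = np.asarray(pred, dtype=float).ravel()
    if t.size == 0:
        raise ValueError("empty count vector")
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.size} vs {p.size}")
    if not (np.isfinite(t).all() and np.isfinite(p).all()):
        raise ValueError("count vectors must be finite")
    return t, p


def rmse(truth, pred) -> float:
    t, p = _pair(truth, pred)
    return float(np.sqrt(np.mean((t - p) ** 2)))


def mae(truth, pred) -> float:
    t, p = _pair(truth, pred)
    return float(np.mean(np.abs(t - p)))


def mape(truth, pred) -> float:
    t, p = _pair(truth, pred)
    zeros = np.flatnonzero(t == 0)
    if zeros.size:
        raise ValueError(f"zero true count at index {zeros[0]}: MAPE undefined")
    return float(np.mean(np.abs(t - p) / np.abs(t)))


def pearson_r(x, y) -> float:
    t, p = _pair(x, y)
    if t.size < 2:
        raise ValueError("need at least 2 observations for a correlation")
    if np.ptp(t) == 0 or np.ptp(p) == 0:
        raise ValueError("zero variance: correlation undefined")
    tc, pc = t - t.mean(), p - p.mean()
    return float(np.sum(tc * pc)
                 / np.sqrt(np.sum(tc * tc) * np.sum(pc * pc)))


def evaluate_model(model, test) -> MetricsReport:
    """Predict counts for a test dataset and report all four metrics.

    ``model`` is a NetworkHandle; ``test`` a SyntheticDataset whose
    samples carry integer count labels.
    """
    from .models import predict_counts  # local import to avoid a cycle

    truth = test.counts()
    pred = predict_counts(model, test.images())
    return MetricsReport(rmse=rmse(truth, pred), mae=mae(truth, pred),
                         mape=mape(truth, pred),
                         pearson_r=pearson_r(truth, pred), n=len(truth))


def compare_groups(pred_a, pred_b, variant: str = "welch",
                   name_a: str = "A", name_b: str = "B") -> GroupComparison:
    """Two-sided two-sample t-test on predicted counts.

    Welch's variant (unequal variances) is the default — group sizes in
    the application setting are unequal; Student's pooled-variance
    variant is available for exact-reproduction attempts.
    """
    a = np.asarray(pred_a, dtype=float).ravel()
    b = np.asarray(pred_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    res = stats.ttest_ind(a, b, equal_var=(variant == "student"))
    return GroupComparison(group_a_name=name_a, group_b_name=name_b,
                           mean_a=float(a.mean()), mean_b=float(b.mean()),
                           t_stat=float(res.statistic),
                           p_value=float(res.pvalue),
                           n_a=a.size, n_b=b.size)
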
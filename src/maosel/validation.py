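"""Train/test splitting and the QSAR validation metric battery.

External predictivity of a regression model is summarised by several
squared-correlation variants that differ only in the reference mean and
variance used for the total sum of squares:

    Q2_F1 = 1 - SSE / sum((y_test - mean(y_train))^2)
    Q2_F2 = 1 - SSE / sum((y_test - mean(y_test))^2)
    Q2_F3 = 1 - (SSE/n_test) / (sum((y_train - mean(y_train))^2)/n_train)

with SSE = sum((y_test - y_pred)^2), plus Lin's concordance correlation
coefficient (population variances)

    CCC = 2 cov(o, p) / (var(o) + var(p) + (mean(o) - mean(p))^2),

RMSE/MAE and Pearson r.  Q2_F1 equals Q2_F2 whenever the train and test
means coincide.  Y-randomization (Fisher randomization) refits the model
on permuted activities and requires the real fit to beat the null
distribution at a chosen significance level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass
from typing import Callable, Sequence, TypeVar

import numpy as np

logger = logging.getLogger(__name__)

T = TypeVar("T")


def split_train_test(
    records: Sequence[T], fraction: float = 0.70, seed: int = 0
) -> tuple[list[T], list[T]]:
    """Random, seed-reproducible split with ceil(fraction * n) training items.

    The ceiling convention reproduces the canonical 126 -> 89/37 split at
    fraction 0.70 and gives (5, 5) at n=10, fraction 0.5.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    n = len(records)
    if n < 10:
        raise ValueError("need at least 10 records to split")
    n_train = int(math.ceil(fraction * n))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    train_idx = sorted(order[:n_train].tolist())
    test_idx = sorted(order[n_train:].tolist())
    return [records[i] for i in train_idx], [records[i] for i in test_idx]


def split_report(y_train: Sequence[float], y_test: Sequence[float]) -> dict:
    """Activity-range overlap diagnostics for a split."""
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    lo = max(y_train.min(), y_test.min())
    hi = min(y_train.max(), y_test.max())
    return {
        "train_range": [float(y_train.min()), float(y_train.max())],
        "test_range": [float(y_test.min()), float(y_test.max())],
        "overlap_range": [float(lo), float(hi)] if hi >= lo else None,
        "test_inside_train_range": bool(y_test.min() >= y_train.min() and y_test.max() <= y_train.max()),
    }


def concordance_ccc(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Lin's concordance correlation coefficient (population, 1/n, variances)."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.size != p.size or o.size == 0:
        raise ValueError("observed/predicted must be non-empty and matched")
    cov = np.mean((o - o.mean()) * (p - p.mean()))
    denom = o.var() + p.var() + (o.mean() - p.mean()) ** 2
    if denom == 0:
        raise ValueError("CCC undefined: zero variance and equal means")
    return float(2.0 * cov / denom)


def external_metrics(
    y_train: Sequence[float], y_test: Sequence[float], y_pred_test: Sequence[float]
) -> dict:
    """Q2_F1/F2/F3, CCC, RMSE, MAE, Pearson r and R2_pred on the test set.

    Metrics whose denominator is zero (e.g. constant test activities) are
    reported as None with a reason in the ``undefined`` entry.
    """
    y_train = np.asarray(y_train, dtype=float)
    y_test = np.asarray(y_test, dtype=float)
    y_pred = np.asarray(y_pred_test, dtype=float)
    if y_test.size == 0 or y_train.size == 0:
        raise ValueError("empty input vectors")
    if y_test.size != y_pred.size:
        raise ValueError("y_test and y_pred_test must have the same length")

    sse = float(np.sum((y_test - y_pred) ** 2))
    ss_f1 = float(np.sum((y_test - y_train.mean()) ** 2))
    ss_f2 = float(np.sum((y_test - y_test.mean()) ** 2))
    ss_tr = float(np.sum((y_train - y_train.mean()) ** 2))

    out: dict = {"undefined": {}}
    out["rmse_test"] = float(np.sqrt(sse / y_test.size))
    out["mae_test"] = float(np.mean(np.abs(y_test - y_pred)))

    for name, num, den in (
        ("q2f1", sse, ss_f1),
        ("q2f2", sse, ss_f2),
        ("q2f3", sse / y_test.size, ss_tr / y_train.size),
    ):
        if den == 0:
            out[name] = None
            out["undefined"][name] = "zero reference variance"
        else:
            out[name] = 1.0 - num / den
    try:
        out["ccc_test"] = concordance_ccc(y_test, y_pred)
    except ValueError as exc:
        out["ccc_test"] = None
        out["undefined"]["ccc_test"] = str(exc)
    if y_test.std() == 0 or y_pred.std() == 0:
        out["pearson_r"] = None
        out["r2_pred"] = None
        out["undefined"]["pearson_r"] = "zero variance"
    else:
        r = float(np.corrcoef(y_test, y_pred)[0, 1])
        out["pearson_r"] = r
        out["r2_pred"] = r * r
    return out


@dataclass
class YRandResult:
    passed: bool
    real_r2: float
    null_r2: np.ndarray
    quantile: float  # (1 - alpha) quantile of the null
    alpha: float


def y_randomization(
    X: np.ndarray,
    y: np.ndarray,
    fit_r2: Callable[[np.ndarray, np.ndarray], float],
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> YRandResult:
    """Fisher/Y-randomization test of model significance.

    ``fit_r2(X, y)`` fits the model and returns its training r².  The real
    model passes iff its r² exceeds the (1 - alpha) empirical quantile of
    r² over ``n_perm`` fits on permuted activities.
    """
    if n_perm < 20:
        logger.warning("n_perm=%d is small; the null quantile will be noisy", n_perm)
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    real = float(fit_r2(X, y))
    null = np.array([float(fit_r2(X, y[rng.permutation(y.size)])) for _ in range(n_perm)])
    q = float(np.quantile(null, 1.0 - alpha))
    return YRandResult(passed=real > q, real_r2=real, null_r2=null, quantile=q, alpha=alpha)


def leave_n_out_q2(
    X: np.ndarray,
    y: np.ndarray,
    fit_predict: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    n_out: int = 1,
    rounds: int | None = None,
    seed: int = 0,
) -> float:
    """Leave-n-out cross-validated q² = 1 - PRESS/TSS.

    ``fit_predict(X_train, y_train, X_held)`` returns predictions for the
    held-out rows.  With ``n_out=1`` and ``rounds=None`` the exclusion is
    exhaustive leave-one-out; otherwise ``rounds`` random disjoint-free
    draws of ``n_out`` indices are aggregated.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if not n_out < n / 2:
        raise ValueError("n_out must be below n/2")
    rng = np.random.default_rng(seed)
    press_terms: list[tuple[int, float]] = []
    if n_out == 1 and rounds is None:
        folds = [np.array([i]) for i in range(n)]
    else:
        n_rounds = rounds if rounds is not None else max(n, 20)
        folds = [rng.choice(n, size=n_out, replace=False) for _ in range(n_rounds)]
    for held in folds:
        mask = np.ones(n, dtype=bool)
        mask[held] = False
        preds = np.asarray(fit_predict(X[mask], y[mask], X[held]))
        for idx, pred in zip(held, preds):
            press_terms.append((int(idx), float((y[idx] - pred) ** 2)))
    press = sum(t for _, t in press_terms)
    # TSS over the residuals actually scored, so partial coverage stays comparable
    scored = [i for i, _ in press_terms]
    tss = float(np.sum((y[scored] - y.mean()) ** 2))
    if tss == 0:
        raise ValueError("q2 undefined: zero total sum of squares")
    return 1.0 - press / tss


@dataclass
class ValidationReport:
    """Full statistics battery for one fitted QSAR model."""

    r2_tr: float
    q2_test: float | None  # Q2_F1, the conventional external Q2
    pearson_r_test: float | None
    sd: float
    f_value: float
    p_value: float
    q2f1: float | None
    q2f2: float | None
    q2f3: float | None
    ccc_tr: float | None
    ccc_test: float | None
    rmse_tr: float
    rmse_test: float
    mae_tr: float
    mae_test: float
    r2_pred: float | None
    stability: float | None
    yrand_pass: bool | None
    split_seed: int | None = None

    def to_dict(self) -> dict:
        return asdict(self)
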
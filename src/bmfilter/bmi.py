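"""The Biomarker Identifier (BMI) filter score.

BMI scores each feature x of a two-group (control vs experiment) expression
dataset as

    score(x) = lambda * TP^2 * |delta_diff| * K,

combining three ingredients:

* ``TP^2 = TP_ctr * TP_exp`` — the product of the per-group true-positive
  rates of a one-covariate logistic regression ``group ~ x`` (how well the
  feature alone separates the groups);
* ``delta_diff`` — the signed relative mean difference
  ``(mean_exp - mean_ctr) / |mean_ctr|`` (positive = over-expressed in the
  experiment group, negative = under-expressed);
* ``K = CV_ctr / CV`` — the control-to-overall coefficient-of-variation
  ratio, which credits features that behave *more* consistently once the
  experiment group is included (CV < CV_ctr) and penalizes features that
  become noisier (CV > CV_ctr).

``lambda`` is a pure scaling factor (default 1).  All four factors are
invariant under multiplication of a feature by a positive constant, so BMI
scores do not depend on per-feature measurement scale.

The logistic fit z-standardizes the feature and applies a small L2 ridge to
the slope so that perfectly separable and constant features are well-defined;
TP rates are resubstitution rates on the fitted samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data_model import EXPERIMENT, DataError, ExpressionDataset, ScoreTable

DELTA_MODES = ("exp_vs_ctrl", "all_vs_ctrl")


@dataclass
class BmiConfig:
    """Tunable parameters of the BMI score.

    lambda_ : pure scale factor applied to every score (default 1.0).
    delta_mode : ``exp_vs_ctrl`` uses (mean_exp - mean_ctr)/|mean_ctr|;
        ``all_vs_ctrl`` uses (mean_all - mean_ctr)/|mean_ctr|.
    eps : means with absolute value below this make CV (and delta_diff)
        ill-defined; such features error in strict mode, otherwise score 0.
    ridge : L2 penalty on the logistic slope (never the intercept).
    strict : raise on ill-defined features instead of warning + score 0.
    """

    lambda_: float = 1.0
    delta_mode: str = "exp_vs_ctrl"
    eps: float = 1e-12
    ridge: float = 1e-4
    max_iter: int = 100
    tol: float = 1e-8
    strict: bool = False

    def __post_init__(self) -> None:
        if self.lambda_ <= 0:
            raise ValueError("lambda must be positive")
        if self.delta_mode not in DELTA_MODES:
            raise ValueError(f"delta_mode must be one of {DELTA_MODES}")


@dataclass
class FeatureStats:
    """Per-feature two-group summary statistics (SDs with ddof 1)."""

    feature_id: str
    mean_ctr: float
    mean_exp: float
    mean_all: float
    sd_ctr: float
    sd_all: float
    cv_ctr: float
    cv_all: float
    delta_diff: float
    degenerate: bool = False  # sd_all == 0: no variation at all


@dataclass
class BmiResult:
    """Full per-feature BMI decomposition alongside the ranked table."""

    feature_ids: list[str]
    tp2: np.ndarray
    tp_ctr: np.ndarray
    tp_exp: np.ndarray
    k_ratio: np.ndarray
    delta_diff: np.ndarray
    scores: np.ndarray
    directions: list[str] = field(default_factory=list)


def _group_arrays(data: ExpressionDataset):
    return data.values[:, data.control_mask], data.values[:, data.experiment_mask]


def feature_stats(
    data: ExpressionDataset, feature: str, delta_mode: str = "exp_vs_ctrl"
) -> FeatureStats:
    """Two-group summary statistics for one feature.

    Raises :class:`~bmfilter.data_model.DataError` naming the feature when a
    mean is too close to zero for the coefficient of variation to be defined.
    """
    if delta_mode not in DELTA_MODES:
        raise ValueError(f"delta_mode must be one of {DELTA_MODES}")
    i = data.feature_index(feature)
    ctr = data.values[i, data.control_mask]
    exp = data.values[i, data.experiment_mask]
    if ctr.size < 2 or exp.size < 2:
        raise DataError("both groups need >= 2 samples for variance estimates")
    eps = 1e-12
    mean_ctr, mean_exp = float(ctr.mean()), float(exp.mean())
    allv = data.values[i]
    mean_all = float(allv.mean())
    if abs(mean_ctr) <= eps or abs(mean_all) <= eps:
        raise DataError(f"feature {feature!r}: near-zero mean, CV undefined")
    sd_ctr = float(ctr.std(ddof=1))
    sd_all = float(allv.std(ddof=1))
    ref = mean_exp if delta_mode == "exp_vs_ctrl" else mean_all
    return FeatureStats(
        feature_id=feature,
        mean_ctr=mean_ctr,
        mean_exp=mean_exp,
        mean_all=mean_all,
        sd_ctr=sd_ctr,
        sd_all=sd_all,
        cv_ctr=sd_ctr / abs(mean_ctr),
        cv_all=sd_all / abs(mean_all),
        delta_diff=(ref - mean_ctr) / abs(mean_ctr),
        degenerate=sd_all == 0.0,
    )


# ---------------------------------------------------------------------------
# logistic TP^2 component
# ---------------------------------------------------------------------------

def _irls_logistic(
    X: np.ndarray, y: np.ndarray, ridge: float, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ridge-penalized one-covariate logistic fits.

    ``X`` holds one z-standardized feature per row; ``y`` is the shared binary
    response.  Returns (intercepts, slopes).  The ridge acts on the slope
    only, which keeps separable and constant features finite and convergent.
    Newton/IRLS on the 2x2 penalized Hessian, solved in closed form per row.
    """
    F, _ = X.shape
    b0 = np.zeros(F)
    b1 = np.zeros(F)
    active = np.ones(F, dtype=bool)
    for _ in range(max_iter):
        if not active.any():
            break
        eta = b0[:, None] + b1[:, None] * X
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = p * (1.0 - p)
        r = y[None, :] - p
        g0 = r.sum(axis=1)
        g1 = (r * X).sum(axis=1) - ridge * b1
        h00 = w.sum(axis=1)
        h01 = (w * X).sum(axis=1)
        h11 = (w * X * X).sum(axis=1) + ridge
        det = h00 * h11 - h01 * h01
        det = np.where(det <= 0, 1.0, det)  # guard; ridge keeps det > 0 in practice
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        d0 = np.where(active, d0, 0.0)
        d1 = np.where(active, d1, 0.0)
        b0 += d0
        b1 += d1
        active &= np.maximum(np.abs(d0), np.abs(d1)) >= tol
    return b0, b1


def _tp_rates(
    X: np.ndarray, y: np.ndarray, b0: np.ndarray, b1: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Resubstitution TP rates per group; probability 0.5 ties to experiment."""
    eta = b0[:, None] + b1[:, None] * X
    pred_exp = eta >= 0.0  # p >= 0.5  <=>  eta >= 0
    is_exp = y.astype(bool)
    n_exp = int(is_exp.sum())
    n_ctr = int((~is_exp).sum())
    tp_exp = (pred_exp & is_exp[None, :]).sum(axis=1) / n_exp
    tp_ctr = (~pred_exp & ~is_exp[None, :]).sum(axis=1) / n_ctr
    return tp_ctr, tp_exp


def _standardize_rows(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (values - mu) / sd


def logistic_tp2(
    values: np.ndarray,
    groups: np.ndarray,
    *,
    ridge: float = 1e-4,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> tuple[float, float, float]:
    """Per-group true-positive rates of a single-feature logistic regression.

    Parameters
    ----------
    values
        Per-sample expression of one feature.
    groups
        Per-sample labels (``control``/``experiment`` strings, or 0/1).

    Returns
    -------
    (tp_ctr, tp_exp, tp2) with ``tp2 = tp_ctr * tp_exp``.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if groups.dtype.kind in "OUS":
        y = (groups == EXPERIMENT).astype(int)
    else:
        y = groups.astype(int)
    if y.min() == y.max():
        raise DataError("both groups must be non-empty")
    X = _standardize_rows(values[None, :])
    b0, b1 = _irls_logistic(X, y, ridge, max_iter, tol)
    tp_ctr, tp_exp = _tp_rates(X, y, b0, b1)
    return float(tp_ctr[0]), float(tp_exp[0]), float(tp_ctr[0] * tp_exp[0])


# ---------------------------------------------------------------------------
# the score
# ---------------------------------------------------------------------------

def bmi_scores(
    data: ExpressionDataset, config: BmiConfig | None = None
) -> tuple[BmiResult, ScoreTable]:
    """Score every feature with BMI and return the decomposition + ranked table.

    Degenerate features (no variation at all, or a mean too close to zero for
    the CV to be defined) score 0; in strict mode the latter raise instead.
    """
    cfg = config or BmiConfig()
    values = data.values
    y = data.y
    ctr_mask, exp_mask = data.control_mask, data.experiment_mask

    mean_ctr = values[:, ctr_mask].mean(axis=1)
    mean_exp = values[:, exp_mask].mean(axis=1)
    mean_all = values.mean(axis=1)
    sd_ctr = values[:, ctr_mask].std(axis=1, ddof=1)
    sd_all = values.std(axis=1, ddof=1)

    bad_mean = (np.abs(mean_ctr) <= cfg.eps) | (np.abs(mean_all) <= cfg.eps)
    if bad_mean.any():
        names = [data.feature_ids[i] for i in np.flatnonzero(bad_mean)[:5]]
        msg = f"near-zero mean, CV undefined: {', '.join(names)}"
        if cfg.strict:
            raise DataError(msg)
        warnings.warn(msg + " (scored 0)")
    degenerate = (sd_all == 0.0) | bad_mean

    safe_mc = np.where(bad_mean, 1.0, np.abs(mean_ctr))
    safe_ma = np.where(bad_mean, 1.0, np.abs(mean_all))
    cv_ctr = sd_ctr / safe_mc
    cv_all = sd_all / safe_ma
    ref = mean_exp if cfg.delta_mode == "exp_vs_ctrl" else mean_all
    delta = (ref - mean_ctr) / safe_mc

    X = _standardize_rows(values)
    b0, b1 = _irls_logistic(X, y, cfg.ridge, cfg.max_iter, cfg.tol)
    tp_ctr, tp_exp = _tp_rates(X, y, b0, b1)
    tp2 = tp_ctr * tp_exp

    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.where(degenerate, 0.0, cv_ctr / np.where(cv_all == 0, 1.0, cv_all))
    scores = np.where(degenerate, 0.0, cfg.lambda_ * tp2 * np.abs(delta) * k)
    directions = ["up" if d > 0 else "down" for d in delta]

    result = BmiResult(
        feature_ids=list(data.feature_ids),
        tp2=tp2,
        tp_ctr=tp_ctr,
        tp_exp=tp_exp,
        k_ratio=k,
        delta_diff=delta,
        scores=scores,
        directions=directions,
    )
    table = ScoreTable(
        method="bmi",
        feature_ids=list(data.feature_ids),
        scores=scores,
        directions=directions,
    )
    return result, table
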
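"""Comparator filter methods: information gain, chi-squared, Relief-F,
Welch t, moderated t, and window t.

Each method scores the features of a two-group expression dataset and
returns a :class:`~bmfilter.data_model.ScoreTable`.  The entropy-based
filters (information gain, chi-squared) operate on a supervised
discretization of each feature — Fayyad–Irani recursive entropy
partitioning with the MDL stopping rule by default, equal-width binning as
a label-free alternative.  The t-family methods rank by the absolute
statistic: Welch's unequal-variance t, the empirical-Bayes moderated t
(gene-wise pooled variances shrunk toward an inverse-chi-square prior
fitted across the whole array), and the window t (variances smoothed over
genes of similar average expression).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, polygamma

from .data_model import DataError, ExpressionDataset, ScoreTable


def _directions(mean_diff: np.ndarray) -> list[str]:
    return ["up" if d > 0 else ("down" if d < 0 else "none") for d in mean_diff]


def _group_stats(data: ExpressionDataset):
    ctr = data.values[:, data.control_mask]
    exp = data.values[:, data.experiment_mask]
    return (
        ctr.mean(axis=1), exp.mean(axis=1),
        ctr.var(axis=1, ddof=1), exp.var(axis=1, ddof=1),
        ctr.shape[1], exp.shape[1],
    )


# ---------------------------------------------------------------------------
# supervised discretization (for information gain and chi-squared)
# ---------------------------------------------------------------------------

@dataclass
class Discretization:
    """Per-feature cut points; ``mdl`` may yield zero cuts (single bin)."""

    method: str
    cuts: list[np.ndarray]

    def bin(self, values: np.ndarray, feature_index: int) -> np.ndarray:
        return np.searchsorted(self.cuts[feature_index], values, side="right")


def _entropy_bits(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _mdl_cuts(values: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fayyad–Irani recursive binary partitioning with the MDL criterion.

    Candidate cuts are midpoints between adjacent distinct values; the cut
    minimizing the class-weighted entropy is accepted when the information
    gain exceeds the minimum-description-length cost of encoding it.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    c = y[order]
    cuts: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2:
            return
        seg_c = c[lo:hi]
        seg_v = v[lo:hi]
        cum1 = np.cumsum(seg_c)
        total1 = cum1[-1]
        ent_s = _entropy_bits(np.array([n - total1, total1]))
        if ent_s == 0.0:
            return
        # split after position i (1..n-1) only where the value changes
        pos = np.flatnonzero(seg_v[1:] > seg_v[:-1]) + 1
        if pos.size == 0:
            return
        n1 = pos.astype(float)
        ones1 = cum1[pos - 1].astype(float)
        n2 = n - n1
        ones2 = total1 - ones1

        def ent(k1, ktot):
            with np.errstate(divide="ignore", invalid="ignore"):
                p1 = np.where(ktot > 0, k1 / ktot, 0.0)
            p0 = 1.0 - p1
            t = np.zeros_like(p1)
            m = p1 > 0
            t[m] -= p1[m] * np.log2(p1[m])
            m = p0 > 0
            t[m] -= p0[m] * np.log2(p0[m])
            return t

        e1 = ent(ones1, n1)
        e2 = ent(ones2, n2)
        weighted = (n1 * e1 + n2 * e2) / n
        best = int(np.argmin(weighted))
        gain = ent_s - weighted[best]
        k = 2  # classes present in the segment (ent_s > 0 implies both)
        k1 = 1 if e1[best] == 0.0 and (ones1[best] in (0.0, n1[best])) else 2
        k2 = 1 if e2[best] == 0.0 and (ones2[best] in (0.0, n2[best])) else 2
        delta = math.log2(3**k - 2) - (k * ent_s - k1 * e1[best] - k2 * e2[best])
        if gain <= (math.log2(n - 1) + delta) / n:
            return
        i = int(pos[best])
        cuts.append(float((seg_v[i - 1] + seg_v[i]) / 2.0))
        recurse(lo, lo + i)
        recurse(lo + i, hi)

    recurse(0, len(v))
    return np.array(sorted(cuts))


def discretize(
    data: ExpressionDataset, method: str = "mdl", bins: int = 10
) -> Discretization:
    """Compute per-feature cut points (``mdl`` uses class labels)."""
    if method == "mdl":
        y = data.y
        cuts = [_mdl_cuts(data.values[i], y) for i in range(data.n_features)]
    elif method == "equal_width":
        if bins < 2:
            raise ValueError("equal_width needs bins >= 2")
        cuts = []
        for i in range(data.n_features):
            lo, hi = data.values[i].min(), data.values[i].max()
            if hi <= lo:
                cuts.append(np.array([]))
            else:
                cuts.append(np.linspace(lo, hi, bins + 1)[1:-1])
    else:
        raise ValueError(f"unknown discretization method: {method}")
    return Discretization(method=method, cuts=cuts)


def _contingency(data: ExpressionDataset, disc: Discretization, i: int) -> np.ndarray:
    """bins × 2 (control, experiment) counts with empty bins dropped."""
    b = disc.bin(data.values[i], i)
    y = data.y
    n_bins = len(disc.cuts[i]) + 1
    table = np.zeros((n_bins, 2))
    np.add.at(table, (b, y), 1)
    return table[table.sum(axis=1) > 0]


def info_gain(data: ExpressionDataset, disc: Discretization | None = None) -> ScoreTable:
    """Information gain of the group variable given each discretized feature.

    IG(x) = H(Y) - sum_b p(b) H(Y | X in b), in bits.  Features reduced to a
    single bin carry no information and score 0.
    """
    disc = disc or discretize(data, "mdl")
    y = data.y
    h_y = _entropy_bits(np.bincount(y, minlength=2))
    n = data.n_samples
    scores = np.zeros(data.n_features)
    gs = _group_stats(data)
    mean_diff = gs[1] - gs[0]
    for i in range(data.n_features):
        table = _contingency(data, disc, i)
        if table.shape[0] < 2:
            continue
        cond = sum(table[b].sum() / n * _entropy_bits(table[b]) for b in range(table.shape[0]))
        scores[i] = h_y - cond
    return ScoreTable("ig", list(data.feature_ids), scores, directions=_directions(mean_diff))


def chi_squared(data: ExpressionDataset, disc: Discretization | None = None) -> ScoreTable:
    """Pearson chi-squared statistic of the bins × groups contingency table."""
    disc = disc or discretize(data, "mdl")
    scores = np.zeros(data.n_features)
    gs = _group_stats(data)
    mean_diff = gs[1] - gs[0]
    for i in range(data.n_features):
        table = _contingency(data, disc, i)
        if table.shape[0] < 2:
            continue
        n = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
        mask = expected > 0
        scores[i] = float(((table - expected)[mask] ** 2 / expected[mask]).sum())
    return ScoreTable("chi2", list(data.feature_ids), scores, directions=_directions(mean_diff))


# ---------------------------------------------------------------------------
# Relief-F
# ---------------------------------------------------------------------------

def relief_f(
    data: ExpressionDataset,
    k: int = 10,
    m: int | None = None,
    seed: int | None = None,
) -> ScoreTable:
    """Kononenko Relief-F feature weights.

    For each probed sample, each feature loses the averaged normalized
    difference to the k nearest same-class neighbors (hits) and gains the
    averaged difference to the k nearest other-class neighbors (misses).
    Distances are Manhattan on min-max-normalized features; with two classes
    the miss-class prior weight is 1.  ``m=None`` probes every sample
    deterministically; an integer ``m`` probes a random subset (seeded).
    Constant features have zero range and weight 0.
    """
    y = data.y
    n = data.n_samples
    counts = np.bincount(y, minlength=2)
    if k < 1 or k > counts.min() - 1:
        raise DataError(f"k={k} exceeds smallest class size - 1 ({counts.min() - 1})")

    rng_range = data.values.max(axis=1) - data.values.min(axis=1)
    nonconst = rng_range > 0
    X = np.zeros_like(data.values)
    X[nonconst] = (
        data.values[nonconst] - data.values[nonconst].min(axis=1, keepdims=True)
    ) / rng_range[nonconst, None]

    # pairwise Manhattan distances over normalized features
    from scipy.spatial.distance import cdist

    D = cdist(X.T, X.T, metric="cityblock")
    np.fill_diagonal(D, np.inf)

    if m is None or m >= n:
        probes = np.arange(n)
    else:
        probes = np.random.default_rng(seed).choice(n, size=m, replace=False)

    weights = np.zeros(data.n_features)
    for i in probes:
        same = np.flatnonzero((y == y[i]) & (np.arange(n) != i))
        diff = np.flatnonzero(y != y[i])
        # deterministic ties: stable sort by (distance, index)
        hits = same[np.argsort(D[i, same], kind="stable")[:k]]
        misses = diff[np.argsort(D[i, diff], kind="stable")[:k]]
        weights += np.abs(X[:, misses] - X[:, [i]]).mean(axis=1)
        weights -= np.abs(X[:, hits] - X[:, [i]]).mean(axis=1)
    weights /= len(probes)

    gs = _group_stats(data)
    mean_diff = gs[1] - gs[0]
    return ScoreTable("relieff", list(data.feature_ids), weights,
                      directions=_directions(mean_diff))


# ---------------------------------------------------------------------------
# t-statistic family
# ---------------------------------------------------------------------------

def welch_t(data: ExpressionDataset) -> ScoreTable:
    """Welch's unequal-variance t; ranked by |t|, direction from the sign.

    If both group variances vanish the statistic is undefined: by convention
    it is +inf when the means differ (infinitely reliable difference) and 0
    when they coincide.
    """
    m_ctr, m_exp, v_ctr, v_exp, n_ctr, n_exp = _group_stats(data)
    se2 = v_exp / n_exp + v_ctr / n_ctr
    diff = m_exp - m_ctr
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    t = np.where(se2 == 0, np.where(diff != 0, np.inf, 0.0), np.abs(t))
    return ScoreTable("ttest", list(data.feature_ids), t, directions=_directions(diff))


@dataclass
class ModeratedTParams:
    """Empirical-Bayes variance prior: d0 prior df (may be inf), s0_sq prior variance."""

    d0: float
    s0_sq: float


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex in 1/y)."""
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if -dif / y < 1e-8:
            break
    return y


def estimate_variance_prior(variances: np.ndarray, df: float) -> ModeratedTParams:
    """Fit the scaled inverse-chi-square prior for gene-wise variances.

    Matches the first two moments of log s^2 (whose distribution under the
    model is a shifted log-F) using digamma/trigamma identities; the
    trigamma equation is solved by Newton iteration.  When the observed
    spread of log-variances is no larger than expected from chi-square
    sampling alone, d0 is infinite and s0_sq is the (bias-corrected)
    geometric mean variance.
    """
    s2 = np.asarray(variances, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        raise DataError("need >= 2 positive gene variances to fit the prior")
    z = np.log(s2)
    e = z - float(digamma(df / 2.0)) + math.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0_sq = math.exp(emean)
    return ModeratedTParams(d0=d0, s0_sq=s0_sq)


def pooled_variance(data: ExpressionDataset) -> tuple[np.ndarray, float]:
    """Gene-wise pooled (equal-variance) variances and their common df."""
    _, _, v_ctr, v_exp, n_ctr, n_exp = _group_stats(data)
    df = n_ctr + n_exp - 2
    s2 = ((n_ctr - 1) * v_ctr + (n_exp - 1) * v_exp) / df
    return s2, float(df)


def moderated_t(
    data: ExpressionDataset, params: ModeratedTParams | None = None
) -> tuple[ScoreTable, ModeratedTParams]:
    """Empirical-Bayes moderated t on pooled gene-wise variances.

    Posterior variances s~^2 = (d0*s0^2 + d_g*s_g^2)/(d0 + d_g) shrink each
    gene toward the array-wide prior; the prior (d0, s0^2) is estimated from
    the ensemble of gene variances unless supplied (d0=0 recovers the
    ordinary Student t, d0=inf gives complete shrinkage to s0^2).
    """
    if data.n_features < 2 and params is None:
        raise DataError("moderated t needs >= 2 features to estimate the prior")
    m_ctr, m_exp, _, _, n_ctr, n_exp = _group_stats(data)
    s2, df = pooled_variance(data)
    if params is None:
        params = estimate_variance_prior(s2, df)
    if math.isinf(params.d0):
        s2_post = np.full_like(s2, params.s0_sq)
    else:
        s2_post = (params.d0 * params.s0_sq + df * s2) / (params.d0 + df)
    diff = m_exp - m_ctr
    se2 = s2_post * (1.0 / n_ctr + 1.0 / n_exp)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    t = np.where(se2 == 0, np.where(diff != 0, np.inf, 0.0), np.abs(t))
    table = ScoreTable("modt", list(data.feature_ids), t, directions=_directions(diff))
    return table, params


def window_t(data: ExpressionDataset, window: int = 99) -> ScoreTable:
    """t-statistic with variances smoothed over genes of similar expression.

    Genes are sorted by overall mean; each gene's variance is the moving
    average of pooled gene-wise variances over a ``window``-gene neighborhood
    at its sort position (truncated at the array ends; even windows are
    rounded up to the next odd size).  window=1 recovers the Student t.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        window += 1
    m_ctr, m_exp, _, _, n_ctr, n_exp = _group_stats(data)
    s2, _ = pooled_variance(data)
    mean_all = data.values.mean(axis=1)
    order = np.argsort(mean_all, kind="stable")
    half = window // 2
    nf = data.n_features
    s2_sorted = s2[order]
    csum = np.concatenate([[0.0], np.cumsum(s2_sorted)])
    smoothed_sorted = np.empty(nf)
    for pos in range(nf):
        lo = max(0, pos - half)
        hi = min(nf, pos + half + 1)
        smoothed_sorted[pos] = (csum[hi] - csum[lo]) / (hi - lo)
    smoothed = np.empty(nf)
    smoothed[order] = smoothed_sorted
    diff = m_exp - m_ctr
    se2 = smoothed * (1.0 / n_ctr + 1.0 / n_exp)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
    t = np.where(se2 == 0, np.where(diff != 0, np.inf, 0.0), np.abs(t))
    return ScoreTable("windowt", list(data.feature_ids), t, directions=_directions(diff))
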
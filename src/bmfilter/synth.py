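"""Synthetic two-group expression data with planted differential features.

The generator emulates the shape of an RMA-summarized two-group microarray
study — by default 69 control and 60 experiment samples, mirroring a
bronchoscopy cohort of smokers without and with lung cancer — on a log2-like
scale where per-gene intensities are approximately Gaussian.  Null features
are Normal(base_mean, base_sd^2) in both groups; planted features shift the
experiment-group mean by ``effect`` control-SD units (random recorded sign)
and scale the experiment-group SD by ``var_ratio``, which exercises the
variance-ratio credit/penalty of the BMI score directly.  Values are clipped
at 0.01 to stay strictly positive so coefficients of variation are
well-defined.

Each feature draws from its own counter-based random stream keyed by
(seed, feature index), so enlarging ``n_features`` leaves the values of the
existing features untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import CONTROL, EXPERIMENT, ExpressionDataset, ScoreTable


@dataclass
class SyntheticSpec:
    """Study-shape parameters for the generator.

    n_ctr, n_exp : group sizes (default 69 control / 60 experiment).
    n_features : array size; n_diff of them are planted differential.
    effect : experiment-mean shift for planted features, in control-SD units.
    var_ratio : experiment-to-control SD multiplier for planted features
        (1 = homoscedastic; >1 makes planted features noisier overall).
    base_mean, base_sd : Gaussian baseline on the log2-like expression scale.
    rho, block_size : optional equicorrelation within consecutive feature
        blocks (off by default; independent features).
    """

    n_ctr: int = 69
    n_exp: int = 60
    n_features: int = 2000
    n_diff: int = 20
    effect: float = 1.0
    var_ratio: float = 1.0
    base_mean: float = 8.0
    base_sd: float = 1.0
    seed: int = 0
    rho: float = 0.0
    block_size: int = 10

    def __post_init__(self) -> None:
        if min(self.n_ctr, self.n_exp, self.n_features) < 1:
            raise ValueError("all counts must be positive")
        if not 0 <= self.n_diff <= self.n_features:
            raise ValueError("n_diff must lie in [0, n_features]")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.var_ratio <= 0:
            raise ValueError("var_ratio must be > 0")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Which features were planted, with their true direction and effect."""

    planted: list[str]
    directions: dict[str, str] = field(default_factory=dict)
    effects: dict[str, float] = field(default_factory=dict)


def _feature_id(i: int, n_features: int) -> str:
    width = max(4, len(str(n_features)))
    return f"F{i + 1:0{width}d}"


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, GroundTruth]:
    """Draw one dataset + ground truth; deterministic for a given spec/seed."""
    n = spec.n_ctr + spec.n_exp
    values = np.empty((spec.n_features, n))
    feature_ids = [_feature_id(i, spec.n_features) for i in range(spec.n_features)]
    sample_ids = [f"C{j + 1:03d}" for j in range(spec.n_ctr)] + [
        f"E{j + 1:03d}" for j in range(spec.n_exp)
    ]
    groups = {s: (CONTROL if s.startswith("C") else EXPERIMENT) for s in sample_ids}

    truth = GroundTruth(planted=[])
    for i in range(spec.n_features):
        rng = np.random.default_rng([spec.seed, i])
        planted = i < spec.n_diff
        sign = 1.0
        if planted:
            sign = 1.0 if rng.random() < 0.5 else -1.0
        ctr = rng.normal(spec.base_mean, spec.base_sd, spec.n_ctr)
        if planted:
            exp = rng.normal(
                spec.base_mean + sign * spec.effect * spec.base_sd,
                spec.base_sd * spec.var_ratio,
                spec.n_exp,
            )
        else:
            exp = rng.normal(spec.base_mean, spec.base_sd, spec.n_exp)
        values[i, : spec.n_ctr] = ctr
        values[i, spec.n_ctr:] = exp
        if planted:
            fid = feature_ids[i]
            truth.planted.append(fid)
            truth.directions[fid] = "up" if sign > 0 else "down"
            truth.effects[fid] = sign * spec.effect

    if spec.rho > 0:
        # equicorrelated blocks: mix in a shared per-sample factor per block
        for b0 in range(0, spec.n_features, spec.block_size):
            rng = np.random.default_rng([spec.seed, spec.n_features + b0])
            shared = rng.normal(0.0, spec.base_sd, n)
            blk = slice(b0, min(b0 + spec.block_size, spec.n_features))
            mu = values[blk].mean(axis=1, keepdims=True)
            values[blk] = mu + np.sqrt(1 - spec.rho) * (values[blk] - mu) + np.sqrt(
                spec.rho
            ) * shared

    values = np.maximum(values, 0.01)
    data = ExpressionDataset(
        values=values, feature_ids=feature_ids, sample_ids=sample_ids, groups=groups
    )
    return data, truth


def recovery_report(scores: ScoreTable, truth: GroundTruth, k: int) -> float:
    """Fraction of the planted features found among the top-k ranked."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not truth.planted:
        return float("nan")
    top = set(scores.top(k))
    return sum(f in top for f in truth.planted) / len(truth.planted)


def write_truth(truth: GroundTruth, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("feature_id\tdirection\teffect\n")
        for fid in truth.planted:
            fh.write(f"{fid}\t{truth.directions[fid]}\t{truth.effects[fid]:g}\n")
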
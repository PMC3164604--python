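import numpy as np
import pytest

from bmfilter import ExpressionDataset


def build_dataset(ctr_rows, exp_rows, feature_ids=None):
    """Dataset from per-feature control and experiment value lists."""
    ctr = np.atleast_2d(np.asarray(ctr_rows, dtype=float))
    exp = np.atleast_2d(np.asarray(exp_rows, dtype=float))
    values = np.hstack([ctr, exp])
    nf = values.shape[0]
    fids = feature_ids or [f"f{i + 1}" for i in range(nf)]
    sids = [f"c{j + 1}" for j in range(ctr.shape[1])] + [
        f"e{j + 1}" for j in range(exp.shape[1])
    ]
    groups = {s: ("control" if s.startswith("c") else "experiment") for s in sids}
    return ExpressionDataset(values, fids, sids, groups)


@pytest.fixture
def hand_dataset():
    """Single feature: ctr = 10,12,14 / exp = 20,22,24."""
    return build_dataset([[10, 12, 14]], [[20, 22, 24]])


@pytest.fixture
def small_dataset():
    """5 features x (4+4) samples with one strong and one constant feature."""
    rng = np.random.default_rng(7)
    ctr = rng.normal(8, 1, (5, 4))
    exp = rng.normal(8, 1, (5, 4))
    exp[0] += 5.0  # strong marker
    ctr[1] = exp[1] = 3.0  # constant feature
    return build_dataset(ctr, exp)
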
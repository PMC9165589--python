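from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lvhscreen import LayoutGeometry


@pytest.fixture
def geometry() -> LayoutGeometry:
    return LayoutGeometry()


def _block(gold: int, pred: int, k: int) -> pd.DataFrame:
    return pd.DataFrame({"gold": [gold] * k, "pred": [pred] * k})


@pytest.fixture
def small_cohort() -> pd.DataFrame:
    """40-subject cohort with hand-computed 2x2 counts.

    seamens: tp=4, fn=12, fp=3, tn=21  -> sens 0.25, spec 0.875,
                                          ppv 4/7, npv 21/33
    sl2 column equals gold exactly     -> all four characteristics 1.0
    """
    rng = np.random.default_rng(7)
    gold = np.array([1] * 16 + [0] * 24)
    seamens = np.concatenate([
        np.ones(4, dtype=int), np.zeros(12, dtype=int),   # gold-positives
        np.ones(3, dtype=int), np.zeros(21, dtype=int),   # gold-negatives
    ])
    cornell = np.concatenate([
        np.ones(2, dtype=int), np.zeros(14, dtype=int),
        np.ones(2, dtype=int), np.zeros(22, dtype=int),
    ])
    sl1 = np.zeros(40, dtype=int)
    sl1[0] = 1
    df = pd.DataFrame({
        "subject_id": np.arange(1, 41),
        "sex": np.where(rng.random(40) < 0.5, "M", "F"),
        "gold": gold,
        "seamens": seamens,
        "sl1": sl1,
        "sl2": gold.copy(),
        "cornell": cornell,
    })
    return df
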
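from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from dyeswap.simulate import GeneratorConfig, generate_microarray_experiment

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy_spots() -> pd.DataFrame:
    """Checked-in 50-probe dye-swap spot table (2 bio reps x 2 orientations)."""
    return pd.read_csv(DATA / "toy_spots.tsv", sep="\t")


@pytest.fixture(scope="session")
def toy_truth() -> pd.DataFrame:
    return pd.read_csv(DATA / "toy_truth.tsv", sep="\t", index_col=0)


@pytest.fixture(scope="session")
def small_experiment():
    """One simulated two-treatment comparison pair used by several tests."""
    cfg = GeneratorConfig(n_probes=1000, n_blocks=4, frac_regulated=0.05,
                          frac_shared=0.8, effect_size_log2=2.0, seed=421)
    spots, truth = generate_microarray_experiment(cfg)
    return cfg, spots, truth


def lowess_oracle(m: np.ndarray, a: np.ndarray, frac: float) -> np.ndarray:
    """Independent dense tricube local linear regression (no robustness).

    Brute-force reference for the loess smoother: at every point, weights
    are tricube in distance scaled by the k-th nearest neighbor
    (k = int(frac * n)) and a weighted degree-1 fit is evaluated.
    """
    n = len(a)
    k = max(2, int(frac * n))
    out = np.empty(n)
    for i in range(n):
        d = np.abs(a - a[i])
        h = np.sort(d)[k - 1]
        w = np.clip(1.0 - (d / max(h, 1e-300)) ** 3, 0.0, 1.0) ** 3
        sw = w.sum()
        xw = (w * a).sum() / sw
        yw = (w * m).sum() / sw
        bd = (w * (a - xw) ** 2).sum()
        b = (w * (a - xw) * (m - yw)).sum() / bd if bd > 0 else 0.0
        out[i] = yw + b * (a[i] - xw)
    return out
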
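"""Differential-expression calls from normalized dye-swap log-ratios.

A paired design: each probe contributes one averaged log-ratio per
biological replicate, and the test asks whether the mean log-ratio differs
from zero. Instead of the unstable per-probe variance at n = 2, a pooled
*trimmed* variance is used — per-probe variances inside an empirical
quantile band are averaged, discarding probes with extreme variance. The
trimmed mean is rescaled by the theoretical chi-squared truncation factor
so the pooled estimate stays unbiased under normality (an untrimmed-mean
plug-in would be biased low and inflate the family-wise error rate).
Raw two-sided p-values come from the standard normal reference (the pooled
estimate has thousands of effective degrees of freedom); Bonferroni
adjustment uses the number of signal probes tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from dyeswap.errors import ZeroVarianceError
from dyeswap.normalize import NormalizedMatrix

DEFAULT_TRIM = (0.025, 0.975)
DEFAULT_ALPHA = 0.05

CLASS_UP = "UP"
CLASS_DOWN = "DOWN"
CLASS_NC = "NC"


def chi2_truncation_factor(nu: int, lo: float, hi: float) -> float:
    """Expected value of s^2/sigma^2 given s^2 falls in its (lo, hi) quantile band.

    For s^2 = sigma^2 * X / nu with X ~ chi2(nu), the conditional mean of
    the retained variances is sigma^2 * (F_{nu+2}(q_hi) - F_{nu+2}(q_lo)) / (hi - lo).
    Dividing the trimmed mean by this factor de-biases the pooled estimate.
    """
    qlo, qhi = stats.chi2.ppf([lo, hi], nu)
    return float((stats.chi2.cdf(qhi, nu + 2) - stats.chi2.cdf(qlo, nu + 2)) / (hi - lo))


def classify_probes(calls: pd.DataFrame, alpha: float = DEFAULT_ALPHA) -> pd.Series:
    """Map a call table to a probe -> {UP, NC, DOWN} vector.

    UP iff Bonferroni p < alpha and mean M > 0; DOWN iff Bonferroni
    p < alpha and mean M < 0; otherwise NC (a significant probe with mean
    exactly 0 has no direction and stays NC).
    """
    sig = calls["p_bonferroni"] < alpha
    cls = pd.Series(CLASS_NC, index=calls.index, name="class")
    cls[sig & (calls["mean_M"] > 0)] = CLASS_UP
    cls[sig & (calls["mean_M"] < 0)] = CLASS_DOWN
    return cls


def trimmed_variance_test(
    matrix: NormalizedMatrix,
    trim_quantiles: tuple[float, float] = DEFAULT_TRIM,
    alpha: float = DEFAULT_ALPHA,
    reference: str = "normal",
    df: float | None = None,
    bias_correction: bool = True,
) -> pd.DataFrame:
    """Pooled trimmed-variance test on every signal probe.

    Parameters
    ----------
    matrix
        Normalized comparison; only signal probes (valid in every
        biological replicate) are tested.
    trim_quantiles
        Empirical quantile band of per-probe variances retained in the
        pooled estimate.
    reference
        "normal" (default) or "t"; with "t", ``df`` must be given.
    bias_correction
        Rescale the trimmed mean by the chi-squared truncation factor.

    Returns
    -------
    DataFrame indexed by probe with columns ``mean_M``, ``A_mean``,
    ``stat``, ``p_raw``, ``p_bonferroni``, ``class``, ``has_signal``.
    """
    lo, hi = trim_quantiles
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError("trim quantiles must satisfy 0 <= lo < hi <= 1")
    signal = matrix.signal
    n = signal.shape[1]
    if n < 2:
        raise ValueError("at least 2 biological replicates are required")
    m_tested = len(signal)

    mean_m = signal.mean(axis=1)
    s2 = signal.var(axis=1, ddof=1)
    qlo, qhi = np.quantile(s2.to_numpy(), [lo, hi])
    retained = s2[(s2 >= qlo) & (s2 <= qhi)]
    s2_trim = float(retained.mean()) if len(retained) else float(s2.mean())
    if bias_correction:
        s2_trim /= chi2_truncation_factor(n - 1, lo, hi)

    if s2_trim <= 0.0:
        if (mean_m == 0).all():
            p_raw = pd.Series(1.0, index=signal.index)
            stat = pd.Series(0.0, index=signal.index)
        else:
            raise ZeroVarianceError("pooled trimmed variance is zero with nonzero means")
    else:
        # Precision weights for unbalanced probes: a replicate averaged from
        # k spots has variance proportional to 1/k, so a probe missing one
        # dye-swap member gets a wider standard error than a complete one.
        # w_g = mean_r(k_ref / k_gr) is 1 for complete probes.
        if matrix.spot_counts is not None:
            counts = matrix.spot_counts.reindex(signal.index)
            k_ref = counts.max(axis=0).clip(lower=1)
            w = (k_ref / counts.clip(lower=1)).mean(axis=1)
        else:
            w = pd.Series(1.0, index=signal.index)
        stat = mean_m / np.sqrt(s2_trim * w / n)
        if reference == "normal":
            p_raw = pd.Series(2.0 * stats.norm.sf(np.abs(stat)), index=signal.index)
        elif reference == "t":
            if df is None:
                raise ValueError("reference='t' requires df")
            p_raw = pd.Series(2.0 * stats.t.sf(np.abs(stat), df), index=signal.index)
        else:
            raise ValueError(f"unknown reference {reference!r}")

    calls = pd.DataFrame(
        {
            "mean_M": mean_m,
            "A_mean": matrix.a_mean.reindex(signal.index),
            "stat": stat,
            "p_raw": p_raw,
            "p_bonferroni": np.minimum(1.0, p_raw * m_tested),
        }
    )
    calls["class"] = classify_probes(calls, alpha=alpha)
    calls["has_signal"] = True
    calls.index.name = "probe"
    return calls
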
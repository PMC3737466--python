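"""Array-by-array normalization of two-color spot data.

The chain follows standard practice for spotted arrays: exclude badly
formed features, correct the intensity-dependent dye bias with a loess
smoother on the M-A cloud, subtract the per-block (print-tip) median
log-ratio, then average the dye-swap technical replicates (sign-flipping
the swapped orientation) to one log-ratio per probe and biological
replicate. No background is subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from dyeswap.errors import NormalizationError, NoUsableSpotsError
from dyeswap.simulate import DYE_FORWARD, DYE_SWAPPED

#: Loess span (fraction of points in each local window). Degree-1 local
#: regression with 3 robustness iterations; 0.2 tracks the curvature of
#: typical banana-shaped dye-bias trends without chasing noise.
DEFAULT_SPAN = 0.2
DEFAULT_ROBUST_ITER = 3
DEFAULT_MIN_SPOTS = 100


@dataclass
class NormalizedMatrix:
    """Per-probe normalized log-ratios for one comparison.

    ``m`` is a probe x biological-replicate frame of dye-swap-averaged
    M-values (log2 treatment/control); NaN marks probes with no valid spot
    in that replicate. ``signal`` restricts to probes with at least one
    valid spot in *every* replicate — the unit on which tests are run.
    """

    m: pd.DataFrame
    a_mean: pd.Series
    n_valid_spots: pd.Series
    #: probe x replicate count of spots averaged into each M (dye-swap pairs
    #: reduced to one member have half the precision; the test downweights them)
    spot_counts: pd.DataFrame | None = None

    @property
    def signal(self) -> pd.DataFrame:
        return self.m.dropna(axis=0, how="any")

    @property
    def n_signal(self) -> int:
        return len(self.signal)


def filter_spots(spots: pd.DataFrame) -> pd.DataFrame:
    """Drop invalid-flagged spots and spots with a non-positive channel."""
    keep = spots["valid"] & (spots["ch1"] > 0) & (spots["ch2"] > 0)
    out = spots.loc[keep].copy()
    if out.empty:
        raise NoUsableSpotsError("no usable spots after filtering")
    return out


def compute_ma(spots: pd.DataFrame) -> pd.DataFrame:
    """Attach M = log2(ch1/ch2) and A = mean log2 intensity columns."""
    out = spots.copy()
    l1 = np.log2(out["ch1"].to_numpy(dtype=float))
    l2 = np.log2(out["ch2"].to_numpy(dtype=float))
    out["M"] = l1 - l2
    out["A"] = 0.5 * (l1 + l2)
    return out


def loess_normalize_array(
    array_spots: pd.DataFrame,
    span: float = DEFAULT_SPAN,
    min_spots: int = DEFAULT_MIN_SPOTS,
    robust_iter: int = DEFAULT_ROBUST_ITER,
) -> pd.DataFrame:
    """Subtract the loess trend of M on A for one array.

    Returns the input with ``M`` replaced by the corrected value and the
    fitted trend stored in ``loess_fit``.
    """
    spots = array_spots if "M" in array_spots.columns else compute_ma(array_spots)
    if len(spots) < min_spots:
        raise NormalizationError(
            f"{len(spots)} spots < minimum {min_spots} required to fit the smoother"
        )
    m = spots["M"].to_numpy(dtype=float)
    a = spots["A"].to_numpy(dtype=float)
    if not (np.isfinite(m).all() and np.isfinite(a).all()):
        raise NormalizationError("non-finite intensities in array")
    fit = lowess(m, a, frac=span, it=robust_iter, return_sorted=False)
    out = spots.copy()
    out["loess_fit"] = fit
    out["M"] = m - fit
    return out


def block_median_center(spots: pd.DataFrame) -> pd.DataFrame:
    """Subtract the per-block median M (print-tip correction)."""
    out = spots.copy()
    out["M"] = out["M"] - out.groupby("block")["M"].transform("median")
    return out


def normalize_array(
    array_spots: pd.DataFrame,
    span: float = DEFAULT_SPAN,
    min_spots: int = DEFAULT_MIN_SPOTS,
    robust_iter: int = DEFAULT_ROBUST_ITER,
) -> pd.DataFrame:
    """Loess + block-median normalization for a single array."""
    return block_median_center(
        loess_normalize_array(array_spots, span=span, min_spots=min_spots, robust_iter=robust_iter)
    )


def average_dye_swap(
    forward: pd.DataFrame | None, swapped: pd.DataFrame | None
) -> pd.DataFrame:
    """Average a dye-swap pair to one M per probe on the treatment/control scale.

    The swapped member measures control/treatment, so its raw log-ratio is
    sign-flipped before averaging. Probes present in only one member use
    the available value; ``n_valid_spots`` records how many spots entered.
    """
    parts = []
    if forward is not None and len(forward):
        parts.append(forward.assign(M_tc=forward["M"]))
    if swapped is not None and len(swapped):
        parts.append(swapped.assign(M_tc=-swapped["M"]))
    if not parts:
        raise NoUsableSpotsError("dye-swap pair contains no spots")
    allspots = pd.concat(parts, ignore_index=True)
    grp = allspots.groupby("probe")
    return pd.DataFrame(
        {
            "M": grp["M_tc"].mean(),
            "A": grp["A"].mean(),
            "n_valid_spots": grp["M_tc"].size(),
        }
    )


def normalize_comparison(
    spots: pd.DataFrame,
    span: float = DEFAULT_SPAN,
    min_spots: int = DEFAULT_MIN_SPOTS,
    robust_iter: int = DEFAULT_ROBUST_ITER,
) -> NormalizedMatrix:
    """Full normalization of one treatment-vs-control spot table.

    Filters spots, normalizes each array independently (loess then block
    centering), then collapses each biological replicate's dye-swap pair
    to a single M per probe.
    """
    usable = compute_ma(filter_spots(spots))
    normalized = {
        array_id: normalize_array(sub, span=span, min_spots=min_spots, robust_iter=robust_iter)
        for array_id, sub in usable.groupby("array", sort=True)
    }

    rep_frames: dict[int, pd.DataFrame] = {}
    for rep, sub in usable.groupby("bio_rep", sort=True):
        fwd_ids = sub.loc[sub["dye"] == DYE_FORWARD, "array"].unique()
        swp_ids = sub.loc[sub["dye"] == DYE_SWAPPED, "array"].unique()
        fwd = pd.concat([normalized[a] for a in fwd_ids]) if len(fwd_ids) else None
        swp = pd.concat([normalized[a] for a in swp_ids]) if len(swp_ids) else None
        rep_frames[int(rep)] = average_dye_swap(fwd, swp)

    m = pd.DataFrame({rep: f["M"] for rep, f in rep_frames.items()})
    m.columns.name = "bio_rep"
    a_mean = pd.concat([f["A"] for f in rep_frames.values()], axis=1).mean(axis=1)
    counts = pd.DataFrame({rep: f["n_valid_spots"] for rep, f in rep_frames.items()}).fillna(0).astype(int)
    n_valid = counts.sum(axis=1)
    return NormalizedMatrix(
        m=m.sort_index(),
        a_mean=a_mean.sort_index(),
        n_valid_spots=n_valid.sort_index(),
        spot_counts=counts.sort_index(),
    )
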
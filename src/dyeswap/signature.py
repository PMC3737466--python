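"""Transcriptome signature similarity ranking.

The K most up-regulated and K most down-regulated probes of a comparison
(by mean normalized log-ratio) form a signature; every experiment of a
log-ratio compendium is scored by the Pearson correlation between its
values on the signature genes and the signature's reference log-ratios,
and experiments are ranked by descending correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SignatureRanking:
    signature: pd.Series  # reference mean log-ratio per signature gene
    scores: pd.DataFrame  # per experiment: r, rank, degenerate

    @property
    def ranked_experiments(self) -> list[str]:
        return list(self.scores.sort_values("rank").index)


def signature_rank(de_table: pd.DataFrame, compendium: pd.DataFrame, k: int = 200) -> SignatureRanking:
    """Rank compendium experiments by correlation with a top-K signature.

    Parameters
    ----------
    de_table
        Differential call table with a ``mean_M`` column indexed by probe.
    compendium
        Gene x experiment log-ratio matrix.
    k
        Number of probes taken from each direction (default 200).

    Signature genes missing from the compendium are dropped with a
    warning. Experiments with zero variance on the signature genes have
    undefined correlation; they are flagged and ranked last.
    """
    mean_m = de_table["mean_M"].sort_values()
    if 2 * k > len(mean_m):
        raise ValueError(f"k={k} exceeds available probes per direction ({len(mean_m)})")
    sig = pd.concat([mean_m.tail(k), mean_m.head(k)])

    present = sig.index.intersection(compendium.index)
    if len(present) < len(sig):
        warnings.warn(
            f"{len(sig) - len(present)} signature genes absent from compendium; dropped",
            stacklevel=2,
        )
    if len(present) < 3:
        raise ValueError("fewer than 3 signature genes present in the compendium")
    ref = sig.loc[present].to_numpy(dtype=float)
    sub = compendium.loc[present]

    x = sub.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    rc = ref - ref.mean()
    denom = np.sqrt((xc**2).sum(axis=0)) * np.sqrt((rc**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * rc[:, None]).sum(axis=0) / denom
    scores = pd.DataFrame({"r": r}, index=sub.columns)
    scores["degenerate"] = ~np.isfinite(scores["r"])
    # descending correlation; undefined correlations sort last
    order = scores["r"].fillna(-np.inf).sort_values(ascending=False, kind="stable").index
    scores["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order)
    scores.index.name = "experiment"
    return SignatureRanking(signature=sig.loc[present], scores=scores)
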
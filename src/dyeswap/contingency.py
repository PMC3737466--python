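"""Cross-classification of regulation calls between treatments.

Two treatments' probe-level calls (UP / NC / DOWN) are crossed on their
common signal probes into a 3x3 contingency table. Theoretical counts
under independence are the products of the marginals divided by N, each
cell's enrichment ratio is observed/theoretical, and independence is
tested by the Pearson chi-squared statistic (no continuity correction).
Also provided: the three-treatment joint-cell expectation under mutual
independence, exclusive Venn region counts, and hypergeometric set-overlap
statistics against external gene lists.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from dyeswap.de import CLASS_DOWN, CLASS_NC, CLASS_UP

#: Row/column order used everywhere: treated > control, no change, treated < control.
CLASS_ORDER = [CLASS_UP, CLASS_NC, CLASS_DOWN]

#: Printing convention for vanishingly small p-values.
P_FLOOR = 2.2e-16


def format_p(p: float) -> str:
    return "< 2.2e-16" if p < P_FLOOR else f"{p:.4g}"


def format_ratio(ratio: float) -> str:
    """Display convention for enrichment ratios: two decimals, one decimal
    from 10 upward, bare "0" for an empty cell."""
    if np.isnan(ratio):
        return "undef"
    if ratio == 0:
        return "0"
    if ratio >= 10:
        return f"{ratio:.1f}"
    return f"{ratio:.2f}"


@dataclass
class ContingencyAnalysis:
    treatments: tuple[str, str]
    n_common: int
    observed: pd.DataFrame
    theoretical: pd.DataFrame
    ratio: pd.DataFrame
    row_marginals: pd.Series
    col_marginals: pd.Series
    chi2: float
    df: int
    p: float
    degenerate: bool = False
    warnings: list[str] = field(default_factory=list)

    @property
    def p_string(self) -> str:
        return format_p(self.p)


def contingency_from_counts(
    observed: pd.DataFrame, treatments: tuple[str, str] = ("treatment_1", "treatment_2")
) -> ContingencyAnalysis:
    """Build the full analysis from an observed K x K count table.

    Marginals are the row/column sums of the observed counts; cells whose
    theoretical count is zero are excluded from chi-squared with the
    degrees of freedom reduced to (nonzero rows - 1) x (nonzero cols - 1).
    """
    obs = observed.astype(float)
    n = float(obs.to_numpy().sum())
    if n <= 0:
        raise ValueError("empty contingency table")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    theo = pd.DataFrame(
        np.outer(rows.to_numpy(), cols.to_numpy()) / n, index=obs.index, columns=obs.columns
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = obs / theo
    ratio = ratio.where(theo > 0)

    notes: list[str] = []
    nz = theo.to_numpy() > 0
    degenerate = not nz.all()
    if degenerate:
        notes.append("zero marginal: chi-squared restricted to cells with theoretical > 0")
    small = (theo.to_numpy() < 5) & nz
    if small.any():
        notes.append(f"{int(small.sum())} cells with theoretical count < 5")
        warnings.warn("contingency table has cells with theoretical count < 5", stacklevel=2)

    o, t = obs.to_numpy()[nz], theo.to_numpy()[nz]
    chi2 = float(((o - t) ** 2 / t).sum())
    df = max(1, (int((rows > 0).sum()) - 1) * (int((cols > 0).sum()) - 1))
    p = float(stats.chi2.sf(chi2, df))
    return ContingencyAnalysis(
        treatments=tuple(treatments),
        n_common=int(round(n)),
        observed=observed,
        theoretical=theo,
        ratio=ratio,
        row_marginals=rows,
        col_marginals=cols,
        chi2=chi2,
        df=df,
        p=p,
        degenerate=degenerate,
        warnings=notes,
    )


def build_contingency(
    v1: pd.Series, v2: pd.Series, treatments: tuple[str, str] = ("treatment_1", "treatment_2")
) -> ContingencyAnalysis:
    """Cross two probe -> class vectors on their common probes."""
    for v in (v1, v2):
        if v.index.has_duplicates:
            raise ValueError("class vector contains duplicate probes")
    common = v1.index.intersection(v2.index)
    if common.empty:
        raise ValueError("no common probes between the two class vectors")
    c1 = pd.Categorical(v1.loc[common], categories=CLASS_ORDER)
    c2 = pd.Categorical(v2.loc[common], categories=CLASS_ORDER)
    observed = pd.crosstab(c1, c2, dropna=False)
    observed = observed.reindex(index=CLASS_ORDER, columns=CLASS_ORDER, fill_value=0)
    observed.index.name, observed.columns.name = treatments
    return contingency_from_counts(observed, treatments)


_HEADER = {CLASS_UP: ">", CLASS_NC: "<>", CLASS_DOWN: "<"}


def enrichment_report(analysis: ContingencyAnalysis, decimals: int = 2) -> str:
    """Render an "Observed (Theoretical) ratio" text table."""
    t1, t2 = analysis.treatments
    lines = ["Observed (Theoretical) ratio\t" + "\t".join(f"{t2} {_HEADER[c]} control" for c in CLASS_ORDER) + "\tTotal"]
    for r in CLASS_ORDER:
        obs = [f"{int(analysis.observed.loc[r, c])}" for c in CLASS_ORDER]
        lines.append(f"{t1} {_HEADER[r]} control\t" + "\t".join(obs) + f"\t{int(analysis.row_marginals[r])}")
        lines.append("\t" + "\t".join(f"({analysis.theoretical.loc[r, c]:.{decimals}f})" for c in CLASS_ORDER))
        lines.append("\t" + "\t".join(format_ratio(analysis.ratio.loc[r, c]) for c in CLASS_ORDER))
    lines.append("Total\t" + "\t".join(f"{int(analysis.col_marginals[c])}" for c in CLASS_ORDER) + f"\t{analysis.n_common}")
    lines.append(f"chi-squared = {analysis.chi2:.4g}, df = {analysis.df}, p = {analysis.p_string}")
    return "\n".join(lines)


@dataclass
class TripleOverlapResult:
    n_common: int
    table: pd.DataFrame  # columns: class_1, class_2, class_3, observed, expected, fold

    def cell(self, c1: str, c2: str, c3: str) -> pd.Series:
        t = self.table
        row = t[(t["class_1"] == c1) & (t["class_2"] == c2) & (t["class_3"] == c3)]
        return row.iloc[0]


def triple_overlap(v1: pd.Series, v2: pd.Series, v3: pd.Series) -> TripleOverlapResult:
    """Joint 3-way cross-classification against mutual independence.

    For every joint cell (c1, c2, c3) the expected count is
    N * p1(c1) * p2(c2) * p3(c3) from the marginal class proportions on
    the three-way common probe set.
    """
    common = v1.index.intersection(v2.index).intersection(v3.index)
    if common.empty:
        raise ValueError("no probes common to the three class vectors")
    n = len(common)
    sub = [v.loc[common] for v in (v1, v2, v3)]
    props = [s.value_counts(normalize=True).reindex(CLASS_ORDER, fill_value=0.0) for s in sub]
    joint = pd.Series(list(zip(sub[0], sub[1], sub[2]))).value_counts()
    rows = []
    for c1, c2, c3 in itertools.product(CLASS_ORDER, repeat=3):
        observed = int(joint.get((c1, c2, c3), 0))
        expected = n * props[0][c1] * props[1][c2] * props[2][c3]
        fold = observed / expected if expected > 0 else np.nan
        rows.append((c1, c2, c3, observed, expected, fold))
    table = pd.DataFrame(rows, columns=["class_1", "class_2", "class_3", "observed", "expected", "fold"])
    return TripleOverlapResult(n_common=n, table=table)


def venn_counts(vectors: dict[str, pd.Series], cls: str = CLASS_UP) -> dict[tuple[str, ...], int]:
    """Exclusive Venn region counts for the class-positive sets of 2-3 vectors.

    Returns a mapping from the sorted tuple of member labels to the count
    of probes in exactly that combination of sets.
    """
    if not 2 <= len(vectors) <= 3:
        raise ValueError("venn_counts supports 2 or 3 sets")
    sets = {label: set(v.index[v == cls]) for label, v in vectors.items()}
    labels = sorted(sets)
    regions: dict[tuple[str, ...], int] = {}
    for r in range(1, len(labels) + 1):
        for members in itertools.combinations(labels, r):
            inside = set.intersection(*(sets[m] for m in members))
            outside = set.union(set(), *(sets[m] for m in labels if m not in members))
            regions[members] = len(inside - outside)
    return regions


@dataclass
class SetOverlapResult:
    size_a: int
    size_b: int
    universe: int
    overlap: int
    expected: float
    p_upper: float


def set_overlap(list_a, list_b, universe_size: int) -> SetOverlapResult:
    """Observed vs. hypergeometric-expected overlap of two gene lists.

    The upper-tail p-value is P(X >= overlap) for X hypergeometric with
    ``universe_size`` items, ``|A|`` successes and ``|B|`` draws.
    """
    a, b = set(list_a), set(list_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("list larger than the universe")
    k = len(a & b)
    expected = len(a) * len(b) / universe_size
    p = float(stats.hypergeom.sf(k - 1, universe_size, len(a), len(b)))
    return SetOverlapResult(len(a), len(b), universe_size, k, expected, p)
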
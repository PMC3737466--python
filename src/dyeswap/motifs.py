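"""Exhaustive promoter word over-representation and motif clustering.

Candidate words are all exact 4-10 bp words occurring in at least one
foreground promoter. For each word, promoters are scored present/absent
(at least one occurrence on either strand; a word is identified with its
reverse complement) and the 2x2 present/absent x foreground/background
table is tested with the Pearson chi-squared statistic without continuity
correction. Words below the significance threshold *and* enriched in the
foreground are clustered by greedy single-linkage on best-offset ungapped
similarity, and each cluster is summarized as a position-wise IUPAC
consensus that can be matched against a small catalogue of known plant
cis-elements (CRT/DRE, G-box, ...).

Word counting is vectorized: sequences are 2-bit encoded and every
length-L window becomes an integer code, so presence sets per promoter are
``np.unique`` calls rather than Python loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from dyeswap.errors import InputError
from dyeswap.simulate import reverse_complement

DEFAULT_LENGTHS = range(4, 11)
DEFAULT_P_THRESHOLD = 1e-5

_ENCODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _ENCODE[ord(b)] = i
    _ENCODE[ord(b.lower())] = i

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_SET_TO_IUPAC = {frozenset(v): k for k, v in IUPAC_SETS.items()}
_IUPAC_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def encode(seq: str) -> np.ndarray:
    """Map a sequence to 0-3 integer codes; non-ACGT bases become -1."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _window_codes(codes: np.ndarray, length: int) -> np.ndarray:
    """Integer code of every valid (N-free) length-L window."""
    n = codes.size - length + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    c = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(length):
        win = codes[j : j + n]
        c = c * 4 + np.maximum(win, 0)
        bad |= win < 0
    return c[~bad]


def _revcomp_codes(codes: np.ndarray, length: int) -> np.ndarray:
    rc = np.zeros_like(codes)
    t = codes.copy()
    for _ in range(length):
        rc = rc * 4 + (3 - (t % 4))
        t //= 4
    return rc


def canonical_codes(codes: np.ndarray, length: int) -> np.ndarray:
    """Identify each word with its reverse complement (keep the smaller code)."""
    return np.minimum(codes, _revcomp_codes(codes, length))


def decode(code: int, length: int) -> str:
    out = []
    for _ in range(length):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


def _presence_from_encoded(
    encoded: list[np.ndarray], length: int, both_strands: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Presence counts over pre-encoded sequences in one vectorized pass.

    Window codes of all sequences are tagged with their sequence index and
    deduplicated as combined (code, seq) keys, so per-promoter presence
    needs a single ``np.unique`` instead of one per sequence.
    """
    n_seqs = len(encoded)
    parts = []
    for i, codes in enumerate(encoded):
        c = _window_codes(codes, length)
        if c.size == 0:
            continue
        if both_strands:
            c = canonical_codes(c, length)
        parts.append(c * n_seqs + i)
    if not parts:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    keys = np.unique(np.concatenate(parts))
    return np.unique(keys // n_seqs, return_counts=True)


def word_presence(seqs: list[str], length: int, both_strands: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Distinct (canonical) word codes of a promoter set with presence counts.

    Returns (codes, counts) where counts[i] is the number of sequences
    containing codes[i] at least once on either strand.
    """
    return _presence_from_encoded([encode(s) for s in seqs], length, both_strands)


def chi2_2x2(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Pearson chi-squared (no continuity correction) for 2x2 tables
    [[a, b], [c, d]], vectorized; 0 where a marginal vanishes."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = n * (a * d - b * c) ** 2 / denom
    return np.where(denom > 0, chi2, 0.0)


def enumerate_and_test(
    fg_seqs: dict[str, str] | list[str],
    bg_seqs: dict[str, str] | list[str],
    lengths=DEFAULT_LENGTHS,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    both_strands: bool = True,
    cluster: bool = True,
    cluster_threshold: float = 0.75,
    min_expected: float = 5.0,
) -> pd.DataFrame:
    """Test every foreground word of the given lengths for over-representation.

    Returns one row per candidate word: presence/absence counts in both
    sets, chi-squared, p, the enrichment direction, the significance flag,
    and — for significant words — a cluster id and IUPAC consensus.

    A word is flagged significant when p < ``p_threshold``, its foreground
    presence rate exceeds the background rate, *and* the smallest expected
    cell count of its 2x2 table is at least ``min_expected`` (Cochran's
    validity condition — the chi-squared tail is meaningless for words seen
    a handful of times, which would otherwise flood the output with
    spurious long words).
    """
    fg = list(fg_seqs.values()) if isinstance(fg_seqs, dict) else list(fg_seqs)
    bg = list(bg_seqs.values()) if isinstance(bg_seqs, dict) else list(bg_seqs)
    if not fg:
        raise InputError("foreground promoter set is empty")
    n_fg, n_bg = len(fg), len(bg)
    fg_enc = [encode(s) for s in fg]
    bg_enc = [encode(s) for s in bg]

    frames = []
    for length in lengths:
        fg_codes, fg_counts = _presence_from_encoded(fg_enc, length, both_strands)
        bg_codes, bg_counts = _presence_from_encoded(bg_enc, length, both_strands)
        # background presence for foreground candidates only
        if bg_codes.size:
            pos = np.clip(np.searchsorted(bg_codes, fg_codes), 0, bg_codes.size - 1)
            bg_for_fg = np.where(bg_codes[pos] == fg_codes, bg_counts[pos], 0)
        else:
            bg_for_fg = np.zeros_like(fg_counts)
        frames.append(
            pd.DataFrame(
                {
                    "code": fg_codes,
                    "length": length,
                    "fg_present": fg_counts,
                    "bg_present": bg_for_fg,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    table["word"] = [decode(c, l) for c, l in zip(table["code"], table["length"])]
    table["fg_absent"] = n_fg - table["fg_present"]
    table["bg_absent"] = n_bg - table["bg_present"]
    table["chi2"] = chi2_2x2(
        table["fg_present"], table["fg_absent"], table["bg_present"], table["bg_absent"]
    )
    table["p"] = stats.chi2.sf(table["chi2"], 1)
    fg_rate = table["fg_present"] / n_fg
    bg_rate = table["bg_present"] / n_bg if n_bg else 0.0
    table["enriched"] = fg_rate > bg_rate
    n_total = n_fg + n_bg
    present = table["fg_present"] + table["bg_present"]
    expected_min = (
        pd.concat([present, n_total - present], axis=1).min(axis=1)
        * min(n_fg, n_bg)
        / n_total
    )
    table["significant"] = (
        (table["p"] < p_threshold) & table["enriched"] & (expected_min >= min_expected)
    )

    table["cluster"] = pd.array([pd.NA] * len(table), dtype="Int64")
    table["consensus"] = ""
    if cluster and table["significant"].any():
        sig_words = table.loc[table["significant"], "word"].tolist()
        assignment, consensi = cluster_motifs(sig_words, threshold=cluster_threshold)
        idx = table.index[table["significant"]]
        table.loc[idx, "cluster"] = [assignment[w] for w in sig_words]
        table.loc[idx, "consensus"] = [consensi[assignment[w]] for w in sig_words]
    cols = [
        "word", "length", "fg_present", "fg_absent", "bg_present", "bg_absent",
        "chi2", "p", "enriched", "significant", "cluster", "consensus",
    ]
    return table[cols].sort_values(["p", "word"], kind="stable").reset_index(drop=True)


def _best_alignment(w1: str, w2: str, min_overlap: int = 4) -> tuple[float, int, str]:
    """Best ungapped match fraction between w1 and w2 over all offsets and
    strands. Returns (score, offset of w2 relative to w1, strand)."""
    best = (0.0, 0, "+")
    for cand, strand in ((w2, "+"), (reverse_complement(w2), "-")):
        for off in range(-(len(cand) - min_overlap), len(w1) - min_overlap + 1):
            lo = max(0, off)
            hi = min(len(w1), off + len(cand))
            overlap = hi - lo
            if overlap < min_overlap:
                continue
            matches = sum(1 for i in range(lo, hi) if w1[i] == cand[i - off])
            score = matches / overlap
            if score > best[0]:
                best = (score, off, strand)
    return best


def _consensus(members: list[str], min_overlap: int = 4) -> str:
    """Position-wise IUPAC consensus of words aligned to the longest member."""
    rep = max(members, key=lambda w: (len(w), [-ord(c) for c in w]))
    placed: list[tuple[int, str]] = []
    for w in members:
        score, off, strand = _best_alignment(rep, w, min_overlap)
        placed.append((off, w if strand == "+" else reverse_complement(w)))
    lo = min(off for off, _ in placed)
    hi = max(off + len(w) for off, w in placed)
    cols: list[set] = [set() for _ in range(hi - lo)]
    for off, w in placed:
        for i, b in enumerate(w):
            cols[off - lo + i].add(b)
    return "".join(_SET_TO_IUPAC[frozenset(col)] for col in cols)


def cluster_motifs(
    words: list[str], threshold: float = 0.75, min_overlap: int = 4
) -> tuple[dict[str, int], dict[int, str]]:
    """Greedy single-linkage clustering of significant words.

    Two words link when their best-offset ungapped similarity (match
    fraction over the overlap, both strands, overlap >= ``min_overlap``)
    reaches ``threshold``. Returns (word -> cluster id, cluster id ->
    IUPAC consensus); ids number clusters in order of their first word.
    """
    if not words:
        raise InputError("no significant words to cluster")
    words = list(dict.fromkeys(words))
    parent = list(range(len(words)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(words)):
        for j in range(i + 1, len(words)):
            score, _, _ = _best_alignment(words[i], words[j], min_overlap)
            if score >= threshold:
                parent[find(j)] = find(i)

    roots: dict[int, int] = {}
    assignment: dict[str, int] = {}
    members: dict[int, list[str]] = {}
    for i, w in enumerate(words):
        r = find(i)
        if r not in roots:
            roots[r] = len(roots) + 1
        cid = roots[r]
        assignment[w] = cid
        members.setdefault(cid, []).append(w)
    consensi = {cid: _consensus(ws, min_overlap) for cid, ws in members.items()}
    return assignment, consensi


def _iupac_match_score(consensus: str, pattern: str, min_overlap: int = 4) -> tuple[float, int]:
    """Best-offset compatibility between two IUPAC strings.

    Returns (match fraction over the overlap, overlap length) maximizing
    first the fraction then the overlap, both strands considered — so an
    exact full-length match outranks a shorter perfect sub-overlap.
    """
    best = (0.0, 0)
    for cand in (pattern, pattern.translate(_IUPAC_COMPLEMENT)[::-1]):
        for off in range(-(len(cand) - min_overlap), len(consensus) - min_overlap + 1):
            lo, hi = max(0, off), min(len(consensus), off + len(cand))
            overlap = hi - lo
            if overlap < min_overlap:
                continue
            m = sum(
                1
                for i in range(lo, hi)
                if set(IUPAC_SETS.get(consensus[i], "")) & set(IUPAC_SETS.get(cand[i - off], ""))
            )
            best = max(best, (m / overlap, overlap))
    return best


def load_catalogue(path: str | None = None) -> pd.DataFrame:
    """Load a cis-element catalogue (TSV: name, pattern). The packaged
    default lists common plant stress-response elements."""
    if path is None:
        ref = resources.files("dyeswap.data") / "motif_catalogue.tsv"
        with resources.as_file(ref) as p:
            return pd.read_csv(p, sep="\t", comment="#")
    return pd.read_csv(path, sep="\t", comment="#")


def match_catalogue(
    consensi: dict[int, str] | list[str],
    catalogue: pd.DataFrame | None = None,
    min_overlap: int = 4,
    min_score: float = 0.75,
) -> pd.DataFrame:
    """Closest catalogue entry per cluster consensus.

    Ties on the maximal score are broken alphabetically by entry name and
    flagged. Clusters with no catalogue overlap >= ``min_overlap`` scoring
    at least ``min_score`` are reported unmatched.
    """
    if catalogue is None:
        catalogue = load_catalogue()
    items = consensi.items() if isinstance(consensi, dict) else enumerate(consensi, start=1)
    rows = []
    for cid, cons in items:
        scored = []
        for _, e in catalogue.iterrows():
            frac, overlap = _iupac_match_score(cons, str(e["pattern"]), min_overlap)
            if frac >= min_score and overlap >= min_overlap:
                scored.append((str(e["name"]), str(e["pattern"]), frac, overlap))
        if not scored:
            rows.append((cid, cons, None, None, np.nan, False))
            continue
        best_key = max((s[2], s[3]) for s in scored)
        best = sorted([s for s in scored if (s[2], s[3]) == best_key], key=lambda s: s[0])
        tie = len(best) > 1
        rows.append((cid, cons, best[0][0], best[0][1], best[0][2], tie))
    return pd.DataFrame(
        rows, columns=["cluster", "consensus", "match_name", "match_pattern", "score", "tie"]
    )
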
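"""Synthetic data generator for two-color microarray experiments.

The generator emulates the experimental design of a dye-swap CATMA-style
screen: for every treatment-vs-control comparison it emits ``n_bio_reps``
biological replicates, each hybridized twice with reversed fluorochromes
("four hybridizations per comparison" with the defaults), at spot level.

Spot intensities are built multiplicatively on the log2 scale::

    A_spot = A_gene + jitter                  (log2 abundance, log-normal)
    M_spot = s * effect + bias(A) + block + N(0, noise_sd)
    ch1    = 2 ** (A_spot + M_spot / 2)
    ch2    = 2 ** (A_spot - M_spot / 2)

where ``s`` is +1 on forward arrays and -1 on dye-swapped arrays, ``bias``
is a smooth polynomial in A (the classic banana-shaped M-A artifact that
loess normalization removes) and ``block`` is a per-print-tip additive
offset. Cross-treatment dependence is injected by drawing a configurable
fraction of each treatment's regulated genes from a common latent "pathway"
set with a fixed per-gene sign, so that UP/UP (and DOWN/DOWN) cells of the
downstream contingency tables are enriched above independence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from dyeswap.errors import ConfigError, InputError

SPOT_COLUMNS = ["probe", "array", "block", "bio_rep", "dye", "ch1", "ch2", "valid"]

DYE_FORWARD = "forward"
DYE_SWAPPED = "swapped"

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic microarray experiment.

    Defaults mirror a realistic spotted-array screen: ~1% badly formed
    spots, two biological replicates with dye swap, a quadratic dye-bias
    curve and mild print-tip offsets.
    """

    n_probes: int = 2000
    n_blocks: int = 4
    n_bio_reps: int = 2
    dye_swap: bool = True
    treatments: Sequence[str] = ("edelfosine", "w30")
    frac_regulated: float = 0.05
    frac_shared: float = 0.5
    effect_size_log2: float = 1.5
    effect_size_cv: float = 0.25
    noise_sd_log2: float = 0.3
    dye_bias_coefs: Sequence[float] = (0.4, -0.15, 0.08)
    block_offsets: Sequence[float] | None = None
    block_offset_sd: float = 0.2
    a_mean: float = 10.0
    a_sd: float = 1.5
    a_spot_jitter: float = 0.25
    invalid_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes <= 0 or self.n_blocks <= 0 or self.n_bio_reps <= 0:
            raise ConfigError("counts must be positive")
        if not self.treatments:
            raise ConfigError("at least one treatment is required")
        for name, val in [
            ("frac_regulated", self.frac_regulated),
            ("frac_shared", self.frac_shared),
            ("invalid_rate", self.invalid_rate),
        ]:
            if not 0.0 <= val <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {val}")
        if self.noise_sd_log2 < 0 or self.effect_size_log2 < 0:
            raise ConfigError("scales must be nonnegative")
        if self.block_offsets is not None and len(self.block_offsets) != self.n_blocks:
            raise ConfigError("block_offsets must have one entry per block")


@dataclass
class SyntheticTruth:
    """Ground-truth regulation per probe and treatment.

    ``effects`` is a probe x treatment frame of signed true log2 effects;
    the class of a probe is UP for a positive effect, DOWN for a negative
    one and NC for an exact zero.
    """

    effects: pd.DataFrame

    @property
    def classes(self) -> pd.DataFrame:
        cls = pd.DataFrame("NC", index=self.effects.index, columns=self.effects.columns)
        cls = cls.mask(self.effects > 0, "UP").mask(self.effects < 0, "DOWN")
        return cls

    def regulated(self, treatment: str) -> pd.Index:
        eff = self.effects[treatment]
        return eff.index[eff != 0]


def _probe_ids(n: int) -> np.ndarray:
    width = max(5, len(str(n)))
    return np.array([f"P{i:0{width}d}" for i in range(1, n + 1)])


def _draw_truth(cfg: GeneratorConfig, rng: np.random.Generator) -> SyntheticTruth:
    probes = _probe_ids(cfg.n_probes)
    n_reg = int(round(cfg.frac_regulated * cfg.n_probes))
    effects = pd.DataFrame(0.0, index=probes, columns=list(cfg.treatments))
    if n_reg == 0:
        return SyntheticTruth(effects)

    all_idx = np.arange(cfg.n_probes)
    pathway = rng.choice(all_idx, size=n_reg, replace=False)
    pathway_sign = rng.choice([-1.0, 1.0], size=cfg.n_probes)
    outside = np.setdiff1d(all_idx, pathway)
    n_from_shared = int(round(cfg.frac_shared * n_reg))

    for t in cfg.treatments:
        shared = rng.choice(pathway, size=n_from_shared, replace=False)
        private = rng.choice(outside, size=n_reg - n_from_shared, replace=False)
        chosen = np.concatenate([shared, private])
        signs = np.where(
            np.isin(chosen, pathway),
            pathway_sign[chosen],
            rng.choice([-1.0, 1.0], size=chosen.size),
        )
        mag = rng.normal(cfg.effect_size_log2, cfg.effect_size_cv * cfg.effect_size_log2, chosen.size)
        mag = np.abs(mag)
        effects.loc[probes[chosen], t] = signs * mag
    return SyntheticTruth(effects)


def _dye_bias(a: np.ndarray, coefs: Sequence[float], a_mean: float) -> np.ndarray:
    z = a - a_mean
    out = np.zeros_like(a)
    for k, c in enumerate(coefs):
        out += c * z**k
    return out


def generate_microarray_experiment(
    config: GeneratorConfig,
) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Simulate one spot table per treatment-vs-control comparison.

    Returns a mapping treatment -> spot table (columns ``SPOT_COLUMNS``)
    and the ground truth. Fully reproducible for a fixed ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    truth_rng = np.random.default_rng(ss.spawn(1)[0])
    truth = _draw_truth(config, truth_rng)

    probes = truth.effects.index.to_numpy()
    n = config.n_probes
    blocks = (np.arange(n) * config.n_blocks) // n
    base_a = truth_rng.normal(config.a_mean, config.a_sd, n)

    orientations = [DYE_FORWARD] + ([DYE_SWAPPED] if config.dye_swap else [])
    tables: dict[str, pd.DataFrame] = {}
    for t in config.treatments:
        effect = truth.effects[t].to_numpy()
        rows = []
        for rep in range(1, config.n_bio_reps + 1):
            for dye in orientations:
                rng = np.random.default_rng(ss.spawn(1)[0])
                if config.block_offsets is not None:
                    offsets = np.asarray(config.block_offsets, dtype=float)
                else:
                    offsets = rng.normal(0.0, config.block_offset_sd, config.n_blocks)
                a_spot = base_a + rng.normal(0.0, config.a_spot_jitter, n)
                sign = 1.0 if dye == DYE_FORWARD else -1.0
                m_spot = (
                    sign * effect
                    + _dye_bias(a_spot, config.dye_bias_coefs, config.a_mean)
                    + offsets[blocks]
                    + rng.normal(0.0, config.noise_sd_log2, n)
                )
                valid = rng.random(n) >= config.invalid_rate
                array_id = f"{t}_b{rep}_{'fwd' if dye == DYE_FORWARD else 'swp'}"
                rows.append(
                    pd.DataFrame(
                        {
                            "probe": probes,
                            "array": array_id,
                            "block": blocks,
                            "bio_rep": rep,
                            "dye": dye,
                            "ch1": 2.0 ** (a_spot + m_spot / 2.0),
                            "ch2": 2.0 ** (a_spot - m_spot / 2.0),
                            "valid": valid,
                        }
                    )
                )
        tables[t] = pd.concat(rows, ignore_index=True)
    return tables, truth


def generate_promoter_set(
    n_fg: int,
    n_bg: int,
    length: int = 1000,
    motif: str = "CCGAC",
    plant_rate_fg: float = 0.5,
    plant_rate_bg: float = 0.0,
    base_composition: Sequence[float] = (0.32, 0.18, 0.18, 0.32),
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str], pd.DataFrame]:
    """Simulate foreground/background promoter sets with a planted motif.

    Background residues are i.i.d. draws from ``base_composition`` (default
    AT-rich, as in plant upstream regions). Each selected sequence receives
    exactly one motif copy, substituted at a uniform random position on a
    uniformly chosen strand. Returns (foreground, background, truth) where
    truth records the planted position/strand per sequence.
    """
    motif = motif.upper()
    if not motif or any(b not in "ACGT" for b in motif):
        raise InputError("motif must be a non-empty A/C/G/T word (degenerate planting unsupported)")
    if len(motif) > length:
        raise InputError("motif longer than promoter length")
    for r in (plant_rate_fg, plant_rate_bg):
        if not 0.0 <= r <= 1.0:
            raise InputError("plant rates must be in [0, 1]")
    comp = np.asarray(base_composition, dtype=float)
    if comp.size != 4 or (comp < 0).any() or not np.isclose(comp.sum(), 1.0):
        raise InputError("base_composition must be 4 nonnegative proportions summing to 1")

    rng = np.random.default_rng(seed)
    records: list[tuple[str, str, bool, int, str]] = []

    ascii_lut = np.frombuffer(b"ACGT", dtype=np.uint8)

    def _emit(prefix: str, count: int, rate: float) -> dict[str, str]:
        out: dict[str, str] = {}
        width = max(4, len(str(count)))
        base_rows = ascii_lut[rng.choice(4, size=(count, length), p=comp)]
        for i in range(1, count + 1):
            name = f"{prefix}_{i:0{width}d}"
            seq = base_rows[i - 1].tobytes().decode("ascii")
            planted = bool(rng.random() < rate)
            pos, strand = -1, "."
            if planted:
                pos = int(rng.integers(0, length - len(motif) + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                word = motif if strand == "+" else reverse_complement(motif)
                seq = seq[:pos] + word + seq[pos + len(motif):]
            out[name] = seq
            records.append((name, prefix, planted, pos, strand))
        return out

    fg = _emit("fg", n_fg, plant_rate_fg)
    bg = _emit("bg", n_bg, plant_rate_bg)
    truth = pd.DataFrame(records, columns=["seq_id", "set", "planted", "position", "strand"])
    return fg, bg, truth


def generate_compendium(
    n_experiments: int,
    truth_effects: pd.Series,
    correlated_fraction: float = 0.1,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[str]]:
    """Simulate a gene x experiment log-ratio compendium.

    A ``correlated_fraction`` of experiments is planted: their columns are
    the ground-truth effect vector plus Gaussian noise. The remaining
    columns are independently permuted effect vectors plus noise, so all
    columns share the same marginal distribution but only planted ones
    correlate with the truth.
    """
    if n_experiments <= 0:
        raise ConfigError("n_experiments must be positive")
    if not 0.0 <= correlated_fraction <= 1.0:
        raise ConfigError("correlated_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    eff = truth_effects.to_numpy(dtype=float)
    n_genes = eff.size
    n_planted = int(round(correlated_fraction * n_experiments))
    width = max(3, len(str(n_experiments)))
    names = [f"exp_{i:0{width}d}" for i in range(1, n_experiments + 1)]
    planted = list(rng.choice(names, size=n_planted, replace=False))
    cols = {}
    for name in names:
        if name in planted:
            cols[name] = eff + rng.normal(0.0, noise_sd, n_genes)
        else:
            cols[name] = rng.permutation(eff) + rng.normal(0.0, noise_sd, n_genes)
    mat = pd.DataFrame(cols, index=truth_effects.index)
    return mat, sorted(planted)
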
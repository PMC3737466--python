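"""End-to-end orchestration: simulate -> normalize/DE -> cross-enrichment -> motifs.

Stages communicate through TSV/FASTA intermediates in the output
directory, so every stage can also be run standalone on externally
produced files. The run report contains only deterministic content
(stage summaries, config echo, package version); timings go to the log.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

import dyeswap
from dyeswap import io as dio
from dyeswap.contingency import build_contingency, enrichment_report, triple_overlap
from dyeswap.de import trimmed_variance_test
from dyeswap.errors import ConfigError, DyeswapError
from dyeswap.motifs import DEFAULT_P_THRESHOLD, enumerate_and_test, match_catalogue
from dyeswap.normalize import DEFAULT_MIN_SPOTS, DEFAULT_SPAN, normalize_comparison
from dyeswap.signature import signature_rank
from dyeswap.simulate import (
    GeneratorConfig,
    generate_compendium,
    generate_microarray_experiment,
    generate_promoter_set,
)

log = logging.getLogger("dyeswap")

ALL_STAGES = ("simulate", "de", "xtab", "signature", "motif")


@dataclass
class RunConfig:
    """Flat run configuration; every default is the pipeline's standard value."""

    seed: int = 0
    out_dir: str = "dyeswap_run"
    stages: tuple[str, ...] = ALL_STAGES
    force: bool = False
    # generator
    n_probes: int = 2000
    n_blocks: int = 4
    n_bio_reps: int = 2
    dye_swap: bool = True
    treatments: tuple[str, ...] = ("edelfosine", "w30")
    frac_regulated: float = 0.05
    frac_shared: float = 0.5
    effect_size_log2: float = 1.5
    noise_sd_log2: float = 0.3
    invalid_rate: float = 0.01
    # differential expression
    alpha: float = 0.05
    span: float = DEFAULT_SPAN
    trim_lo: float = 0.025
    trim_hi: float = 0.975
    min_spots: int = DEFAULT_MIN_SPOTS
    # signature
    signature_k: int = 200
    n_experiments: int = 50
    correlated_fraction: float = 0.1
    compendium_noise_sd: float = 0.5
    # motifs
    motif: str = "CCGAC"
    n_fg_promoters: int = 100
    n_bg_promoters: int = 1000
    promoter_length: int = 1000
    plant_rate_fg: float = 0.5
    motif_p_threshold: float = DEFAULT_P_THRESHOLD

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        raw = dio.load_yaml_config(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("stages", "treatments"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(
            n_probes=self.n_probes,
            n_blocks=self.n_blocks,
            n_bio_reps=self.n_bio_reps,
            dye_swap=self.dye_swap,
            treatments=self.treatments,
            frac_regulated=self.frac_regulated,
            frac_shared=self.frac_shared,
            effect_size_log2=self.effect_size_log2,
            noise_sd_log2=self.noise_sd_log2,
            invalid_rate=self.invalid_rate,
            seed=self.seed,
        )


@dataclass
class RunReport:
    sections: dict = field(default_factory=dict)

    def render(self) -> str:
        lines = [f"dyeswap {dyeswap.__version__} run report", "=" * 40]
        for name, content in self.sections.items():
            lines += ["", f"[{name}]"]
            if isinstance(content, str):
                lines.append(content)
            else:
                lines.append(json.dumps(content, indent=2, sort_keys=True, default=str))
        return "\n".join(lines) + "\n"


def _out_path(out_dir: Path, name: str, force: bool) -> Path:
    p = out_dir / name
    if p.exists() and not force:
        raise DyeswapError(f"refusing to overwrite {p} (use force)")
    return p


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DyeswapError(f"stage '{stage}': required input {path.name} is missing "
                           f"(was its producing stage disabled?)")
    return path


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the enabled stages in dependency order and write a report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()
    report.sections["config"] = {
        k: list(v) if isinstance(v, tuple) else v
        for k, v in dataclasses.asdict(config).items()
    }
    report.sections["version"] = dyeswap.__version__

    if "simulate" in config.stages:
        t0 = time.perf_counter()
        gen = config.generator_config()
        spots, truth = generate_microarray_experiment(gen)
        for t, table in spots.items():
            dio.write_spot_table(table, _out_path(out, f"spots_{t}.tsv", config.force))
        dio.write_matrix(truth.effects, _out_path(out, "truth_effects.tsv", config.force))
        compendium, planted = generate_compendium(
            config.n_experiments,
            truth.effects[config.treatments[0]],
            config.correlated_fraction,
            config.compendium_noise_sd,
            seed=config.seed + 1,
        )
        dio.write_matrix(compendium, _out_path(out, "compendium.tsv", config.force))
        (out / "compendium_planted.txt").write_text("\n".join(planted) + "\n")
        fg, bg, ptruth = generate_promoter_set(
            config.n_fg_promoters,
            config.n_bg_promoters,
            config.promoter_length,
            config.motif,
            config.plant_rate_fg,
            seed=config.seed + 2,
        )
        dio.write_fasta(fg, _out_path(out, "promoters_fg.fasta", config.force))
        dio.write_fasta(bg, _out_path(out, "promoters_bg.fasta", config.force))
        ptruth.to_csv(out / "promoter_truth.tsv", sep="\t", index=False)
        log.info("simulate stage done in %.1fs", time.perf_counter() - t0)
        report.sections["simulate"] = {
            "treatments": list(config.treatments),
            "n_probes": config.n_probes,
            "n_arrays_per_comparison": config.n_bio_reps * (2 if config.dye_swap else 1),
            "n_compendium_experiments": config.n_experiments,
        }

    if "de" in config.stages:
        t0 = time.perf_counter()
        de_summary = {}
        for t in config.treatments:
            spots = dio.read_spot_table(_require(out / f"spots_{t}.tsv", "de"))
            norm = normalize_comparison(spots, span=config.span, min_spots=config.min_spots)
            calls = trimmed_variance_test(
                norm, (config.trim_lo, config.trim_hi), alpha=config.alpha
            )
            calls.to_csv(_out_path(out, f"de_{t}.tsv", config.force), sep="\t")
            dio.write_class_vector(calls["class"], _out_path(out, f"classes_{t}.tsv", config.force))
            de_summary[t] = {
                "n_signal": int(norm.n_signal),
                "n_up": int((calls["class"] == "UP").sum()),
                "n_down": int((calls["class"] == "DOWN").sum()),
            }
        log.info("de stage done in %.1fs", time.perf_counter() - t0)
        report.sections["de"] = de_summary

    if "xtab" in config.stages:
        vectors = {
            t: dio.read_class_vector(_require(out / f"classes_{t}.tsv", "xtab"))
            for t in config.treatments
        }
        xtab_text = []
        for t1, t2 in itertools.combinations(config.treatments, 2):
            analysis = build_contingency(vectors[t1], vectors[t2], (t1, t2))
            text = enrichment_report(analysis)
            (out / f"contingency_{t1}_vs_{t2}.txt").write_text(text + "\n")
            xtab_text.append(text)
        if len(config.treatments) >= 3:
            t1, t2, t3 = config.treatments[:3]
            res = triple_overlap(vectors[t1], vectors[t2], vectors[t3])
            res.table.to_csv(out / "triple_overlap.tsv", sep="\t", index=False)
            up = res.cell("UP", "UP", "UP")
            xtab_text.append(
                f"triple (UP,UP,UP): observed {int(up['observed'])}, "
                f"expected {up['expected']:.2f}, fold {up['fold']:.1f}"
            )
        report.sections["cross_enrichment"] = "\n\n".join(xtab_text)

    if "signature" in config.stages:
        de_table = pd.read_csv(
            _require(out / f"de_{config.treatments[0]}.tsv", "signature"), sep="\t", index_col=0
        )
        compendium = dio.read_matrix(_require(out / "compendium.tsv", "signature"))
        k = min(config.signature_k, len(de_table) // 2)
        ranking = signature_rank(de_table, compendium, k=k)
        ranking.scores.sort_values("rank").to_csv(out / "signature_ranking.tsv", sep="\t")
        top = ranking.scores.sort_values("rank").head(10)
        report.sections["signature"] = {
            "k": k,
            "top_10": [
                {"experiment": e, "r": round(float(row["r"]), 4)} for e, row in top.iterrows()
            ],
        }

    if "motif" in config.stages:
        t0 = time.perf_counter()
        fg = dio.read_fasta(_require(out / "promoters_fg.fasta", "motif"))
        bg = dio.read_fasta(_require(out / "promoters_bg.fasta", "motif"))
        table = enumerate_and_test(fg, bg, p_threshold=config.motif_p_threshold)
        table.to_csv(_out_path(out, "motifs.tsv", config.force), sep="\t", index=False)
        sig = table[table["significant"]]
        clusters = sig.groupby("cluster")["consensus"].first().to_dict() if len(sig) else {}
        matches = match_catalogue(clusters) if clusters else pd.DataFrame()
        if len(matches):
            matches.to_csv(out / "motif_clusters.tsv", sep="\t", index=False)
        log.info("motif stage done in %.1fs", time.perf_counter() - t0)
        report.sections["motif"] = {
            "n_words_tested": int(len(table)),
            "n_significant": int(len(sig)),
            "clusters": {
                int(cid): cons for cid, cons in sorted(clusters.items())
            },
        }

    text = report.render()
    (out / "report.txt").write_text(text)
    (out / "report.json").write_text(
        json.dumps(report.sections, indent=2, sort_keys=True, default=str) + "\n"
    )
    return report
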
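"""Tab-separated / FASTA / YAML input-output helpers.

All tables travel as TSV with a header row; promoter sets as FASTA
(written deterministically: fixed order, 60-column wrap); configuration
as a single flat YAML mapping.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from dyeswap.simulate import SPOT_COLUMNS


def write_spot_table(spots: pd.DataFrame, path: str | Path) -> None:
    spots.to_csv(path, sep="\t", index=False, columns=SPOT_COLUMNS)


def read_spot_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"probe": str, "array": str, "dye": str})
    missing = set(SPOT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"spot table missing columns: {sorted(missing)}")
    return df


def write_class_vector(classes: pd.Series, path: str | Path) -> None:
    classes.rename("class").rename_axis("probe").to_csv(path, sep="\t")


def read_class_vector(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return df.set_index(df.columns[0])[df.columns[1]]


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.rename_axis("gene").to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a flat YAML mapping")
    return data


def dump_yaml_config(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
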
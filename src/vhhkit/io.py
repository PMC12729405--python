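"""Interchange formats: curated CSV, FASTA, funnel JSON, analysis TSVs."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .dataset import CANONICAL_COLUMNS, Dataset


def write_curated_csv(dataset: Dataset, path: str | Path) -> None:
    """Curated records in the fixed canonical column order (extras after)."""
    df = dataset.records
    extra = [c for c in df.columns if c not in CANONICAL_COLUMNS]
    df[CANONICAL_COLUMNS + extra].to_csv(path, index=False)


def read_curated_csv(path: str | Path) -> Dataset:
    df = pd.read_csv(path, dtype="object")
    return Dataset(df)


def write_fasta(dataset: Dataset, path: str | Path) -> None:
    """FASTA with headers ``record_id|species|source_db``."""
    records = [
        SeqRecord(
            Seq(str(row["full_sequence"])),
            id=f"{row['record_id']}|{row['species']}|{row['source_db']}",
            description="",
        )
        for _, row in dataset.records.iterrows()
        if isinstance(row["full_sequence"], str) and row["full_sequence"]
    ]
    with open(path, "w") as fh:
        seqio_write(records, fh, "fasta")


def write_funnel_json(dataset: Dataset, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataset.funnel_as_json(), indent=1))


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)
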
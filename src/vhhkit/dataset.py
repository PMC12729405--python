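"""Core record container and funnel accounting for sdAb curation.

A curated single-domain antibody (sdAb/VHH) record carries an identifier,
its species of origin (one of four camelid categories), the full amino-acid
sequence, and the seven framework/CDR region strings whose concatenation
equals the full sequence.  Records travel through the pipeline as rows of a
pandas DataFrame with a fixed canonical schema; every step that removes
records appends an entry to the dataset's *funnel* so that
|output| = |input| - removed holds end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Canonical 20 one-letter amino-acid codes.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
CANONICAL_AA_SET = frozenset(CANONICAL_AA)

#: Gap symbol used inside rectangular region alignments.
GAP = "-"

#: The seven variable-domain regions in N→C order.
REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")
FRAMEWORK_REGIONS = ("FR1", "FR2", "FR3", "FR4")
CDR_REGIONS = ("CDR1", "CDR2", "CDR3")

#: The four accepted species categories plus the sentinel for labels that
#: cannot be resolved (generic "camelid", bare "camel", mixed libraries ...).
SPECIES_LLAMA = "Lama glama"
SPECIES_ALPACA = "Vicugna pacos"
SPECIES_DROMEDARY = "Camelus dromedarius"
SPECIES_BACTRIAN = "Camelus bactrianus"
AMBIGUOUS = "AMBIGUOUS"
ACCEPTED_SPECIES = (
    SPECIES_LLAMA,
    SPECIES_ALPACA,
    SPECIES_DROMEDARY,
    SPECIES_BACTRIAN,
)

#: Fixed column order of the curated interchange CSV.
CANONICAL_COLUMNS = [
    "record_id",
    "source_db",
    "species",
    "full_sequence",
    *REGIONS,
    "antigen",
    "doi",
    "pdb_code",
    "affinity",
    "flags",
]

OPTIONAL_COLUMNS = ("antigen", "doi", "pdb_code", "affinity")

# Provenance flags
FLAG_RECONSTRUCTED = "reconstructed_sequence"
FLAG_FALLBACK_ANNOTATION = "fallback_annotation"
FLAG_REGION_SEQUENCE_MISMATCH = "region_sequence_mismatch"


@dataclass
class FunnelStep:
    """One accounting entry: records entering a step and records removed."""

    step: str
    n_in: int
    removed: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.removed

    def to_dict(self) -> dict:
        return {"step": self.step, "in": self.n_in, "removed": self.removed}


@dataclass
class Dataset:
    """An ordered collection of sdAb records plus its curation funnel.

    ``records`` is a DataFrame with (at least) the canonical columns; absent
    values are pandas NA, never empty strings posing as values.
    """

    records: pd.DataFrame
    funnel: list[FunnelStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def log(self, step: str, n_in: int, removed: int) -> None:
        self.funnel.append(FunnelStep(step, n_in, removed))

    def funnel_as_json(self) -> list[dict]:
        return [s.to_dict() for s in self.funnel]

    def copy(self) -> "Dataset":
        return Dataset(self.records.copy(), list(self.funnel))


def empty_records() -> pd.DataFrame:
    """An empty DataFrame with the canonical schema."""
    return pd.DataFrame({c: pd.Series(dtype="object") for c in CANONICAL_COLUMNS})


def ensure_canonical_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Return *df* with every canonical column present (NA-filled) and the
    canonical columns first, preserving any extra metadata columns after."""
    out = df.copy()
    for col in CANONICAL_COLUMNS:
        if col not in out.columns:
            out[col] = pd.NA
    extra = [c for c in out.columns if c not in CANONICAL_COLUMNS]
    return out[CANONICAL_COLUMNS + extra]


def add_flag(current, flag: str) -> str:
    """Append *flag* to a semicolon-joined flag string, without duplicates."""
    if current is None or pd.isna(current) or current == "":
        return flag
    flags = str(current).split(";")
    if flag in flags:
        return str(current)
    return ";".join(flags + [flag])


def has_flag(current, flag: str) -> bool:
    if current is None or pd.isna(current) or current == "":
        return False
    return flag in str(current).split(";")


def funnel_is_consistent(funnel: list[FunnelStep]) -> bool:
    """Check the chaining invariant: step k+1 starts with step k's survivors."""
    for prev, nxt in zip(funnel, funnel[1:]):
        if nxt.n_in != prev.n_out:
            return False
    return True
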
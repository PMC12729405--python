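"""Reading heterogeneous sdAb source exports and harmonizing them.

Source databases deposit single-domain antibody records under wildly
different schemas.  This module maps each export onto the canonical record
schema, normalizes placeholder values ("NA", "-", empty strings) to absent,
standardizes species labels into the four accepted camelid categories, and
enforces the mandatory-field eligibility rule: an identifier, a resolvable
species, and either a full amino-acid sequence or all seven region strings.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .dataset import (
    ACCEPTED_SPECIES,
    AMBIGUOUS,
    CANONICAL_COLUMNS,
    Dataset,
    REGIONS,
    empty_records,
    ensure_canonical_columns,
)

#: Values treated as "absent" in any field of a source export.
NA_TOKENS = {"", "na", "n/a", "-", "none", "null", "nan"}

MANDATORY_TARGETS = {"record_id", "species"}


class ConfigurationError(ValueError):
    """A source's column_map does not cover the mandatory fields."""


def load_synonym_table(path: str | Path | None = None) -> dict[str, str]:
    """Load the species synonym table (label -> category), lower-cased.

    With no *path*, the table shipped with the package is used.  Canonical
    category names map to themselves so harmonization is idempotent.
    """
    if path is None:
        src = resources.files("vhhkit.data").joinpath("species_synonyms.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, str] = {}
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        label, species = line.split("\t")
        table[label.strip().lower()] = species.strip()
    for sp in ACCEPTED_SPECIES:
        table.setdefault(sp.lower(), sp)
    return table


_DEFAULT_SYNONYMS: dict[str, str] | None = None


def default_synonym_table() -> dict[str, str]:
    global _DEFAULT_SYNONYMS
    if _DEFAULT_SYNONYMS is None:
        _DEFAULT_SYNONYMS = load_synonym_table()
    return _DEFAULT_SYNONYMS


def harmonize_species(raw_label, synonym_table: dict[str, str] | None = None) -> str:
    """Map a raw species annotation to one of the four categories.

    Unseen, generic ("camelid", "mixed library") or underspecified ("Camel",
    which cannot distinguish Bactrian from dromedary origin) labels map to
    ``AMBIGUOUS``; the function never raises on unknown input.
    """
    if synonym_table is None:
        synonym_table = default_synonym_table()
    if raw_label is None or pd.isna(raw_label):
        return AMBIGUOUS
    key = str(raw_label).strip().lower()
    return synonym_table.get(key, AMBIGUOUS)


def _normalize_absent(value):
    if value is None or pd.isna(value):
        return pd.NA
    text = str(value).strip()
    if text.lower() in NA_TOKENS:
        return pd.NA
    return text


def read_source_table(
    path: str | Path,
    source_tag: str,
    column_map: dict[str, str],
    delimiter: str | None = None,
) -> Dataset:
    """Read one source export (CSV/TSV) into the canonical schema.

    *column_map* maps source column names to canonical field names
    (record_id, species, full_sequence, FR1..FR4, CDR1..CDR3, antigen, doi,
    pdb_code, affinity).  It must cover the identifier, the species, and
    either the full sequence or all seven regions; otherwise a
    :class:`ConfigurationError` is raised before any row is ingested.
    Unmapped source columns are carried through verbatim as extra metadata.
    """
    path = Path(path)
    mapped = set(column_map.values())
    missing = MANDATORY_TARGETS - mapped
    if missing:
        raise ConfigurationError(
            f"column_map for source '{source_tag}' lacks mandatory fields: {sorted(missing)}"
        )
    if "full_sequence" not in mapped and not set(REGIONS) <= mapped:
        raise ConfigurationError(
            f"column_map for source '{source_tag}' must map full_sequence or all of {REGIONS}"
        )

    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=delimiter, dtype="object")
    absent = set(column_map) - set(df.columns)
    if absent:
        raise ConfigurationError(
            f"source '{source_tag}' file {path} lacks mapped columns: {sorted(absent)}"
        )
    df = df.rename(columns=column_map)
    df = ensure_canonical_columns(df)
    for col in df.columns:
        if col != "source_db":
            df[col] = df[col].map(_normalize_absent)
    df["source_db"] = source_tag
    ds = Dataset(df.reset_index(drop=True))
    ds.log(f"ingest:{source_tag}", len(df), 0)
    return ds


def read_fasta(
    path: str | Path,
    source_tag: str,
    species_map: dict[str, str] | None = None,
    default_species: str | None = None,
) -> Dataset:
    """Read sequence-only FASTA input.

    The record identifier is the header token up to the first whitespace.
    Species must come from *species_map* (identifier -> raw label) or the
    *default_species* applied to every record; regions are derived later by
    the annotation stage.
    """
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        raw_species = (species_map or {}).get(rid, default_species)
        rows.append(
            {
                "record_id": rid,
                "source_db": source_tag,
                "species": raw_species if raw_species is not None else pd.NA,
                "full_sequence": str(rec.seq).upper(),
            }
        )
    df = ensure_canonical_columns(pd.DataFrame(rows)) if rows else empty_records()
    ds = Dataset(df.reset_index(drop=True))
    ds.log(f"ingest:{source_tag}", len(df), 0)
    return ds


def merge_sources(datasets: list[Dataset]) -> Dataset:
    """Concatenate source datasets into one frame, preserving source tags.

    Per-source counts remain visible in the merged funnel; the merged size
    is exactly the sum of the input sizes (duplicates are resolved later,
    keyed on the full sequence, not here).
    """
    if not datasets:
        return Dataset(empty_records())
    frames = [d.records for d in datasets]
    merged = pd.concat(frames, ignore_index=True)
    merged = ensure_canonical_columns(merged)
    out = Dataset(merged)
    for d in datasets:
        out.funnel.extend(d.funnel)
    out.log("merge", len(merged), 0)
    return out


def harmonize_dataset_species(
    dataset: Dataset, synonym_table: dict[str, str] | None = None
) -> Dataset:
    """Standardize the species column of every record in place (new Dataset)."""
    out = dataset.copy()
    out.records["species"] = out.records["species"].map(
        lambda v: harmonize_species(v, synonym_table)
    )
    return out


def _has_complete_regions(row: pd.Series) -> bool:
    return all(isinstance(row[r], str) and row[r] != "" for r in REGIONS)


def _has_sequence(row: pd.Series) -> bool:
    seq = row["full_sequence"]
    return isinstance(seq, str) and seq != ""


def enforce_mandatory_fields(dataset: Dataset, step_name: str = "mandatory_fields") -> Dataset:
    """Drop records missing an identifier, a resolved species, or sequence data.

    A record survives iff it has a non-empty record_id, a species that is one
    of the four accepted categories (never AMBIGUOUS), and either a full
    sequence or all seven region strings.  Removals are logged to the funnel.
    Records that keep only optional metadata gaps (antigen, DOI, PDB code,
    affinity) are retained.
    """
    df = dataset.records
    n_in = len(df)
    if n_in == 0:
        out = dataset.copy()
        out.log(step_name, 0, 0)
        return out

    has_id = df["record_id"].map(lambda v: isinstance(v, str) and v != "")
    species_ok = df["species"].isin(ACCEPTED_SPECIES)
    seq_ok = df.apply(lambda r: _has_sequence(r) or _has_complete_regions(r), axis=1)
    keep = has_id & species_ok & seq_ok
    out = Dataset(df[keep].reset_index(drop=True), list(dataset.funnel))
    out.log(step_name, n_in, int((~keep).sum()))
    return out
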
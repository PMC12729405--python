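"""Quality-control filters: alphabet, artificial sequences, duplicates.

Some deposited sdAb entries are not genuine protein sequences: residues
sorted alphabetically, or homopolymer/low-complexity strings — artifacts of
sequence obfuscation (e.g. confidentiality).  Others are exact duplicates
deposited by several resources.  Filters run in a fixed order so the
funnel accounting is reproducible:

    canonical alphabet → completeness → duplicate removal → artificial-sequence removal

Every removed record gets at least one :class:`FilterVerdict` naming the
rule that fired.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .dataset import CANONICAL_AA_SET, Dataset, REGIONS

RULE_NON_CANONICAL = "non_canonical_alphabet"
RULE_ALPHABETICAL = "alphabetical_order"
RULE_HOMOPOLYMER = "homopolymer_low_complexity"
RULE_DUPLICATE = "duplicate"
RULE_INCOMPLETE = "incomplete_record"


@dataclass
class FilterVerdict:
    record_id: str
    rule: str
    detail: str = ""


@dataclass
class FilterConfig:
    """Thresholds for the artificial-sequence rules (all configurable).

    ``min_distinct`` keeps the alphabetical-order rule off homopolymers so
    each artifact is attributed to exactly one rule.  ``max_run_length`` and
    ``max_run_fraction`` bound single-residue runs and the modal residue's
    share; genuine VHHs rarely exceed runs of 5.
    """

    min_distinct: int = 5
    max_run_length: int = 10
    max_run_fraction: float = 0.5
    source_priority: tuple[str, ...] = ()


def is_canonical_sequence(sequence: str) -> bool:
    """True iff non-empty and composed only of the 20 canonical residues."""
    if not isinstance(sequence, str) or sequence == "":
        return False
    return set(sequence) <= CANONICAL_AA_SET


def is_alphabetically_ordered(sequence: str, min_distinct: int = 5) -> bool:
    """Detect deliberately sorted residue strings (e.g. "ACDEFGHIKLMNPQRSTVWY").

    Fires only when the whole string is in non-decreasing alphabetical order
    *and* carries at least *min_distinct* distinct residues, so homopolymers
    are left to the low-complexity rule.
    """
    if len(sequence) < 2:
        return False
    if len(set(sequence)) < min_distinct:
        return False
    return all(a <= b for a, b in zip(sequence, sequence[1:]))


def _longest_run(sequence: str) -> int:
    best = run = 1
    for a, b in zip(sequence, sequence[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def is_low_complexity(
    sequence: str, max_run_fraction: float = 0.5, max_run_length: int = 10
) -> bool:
    """Detect homopolymer / low-complexity strings (poly-A, poly-G, ...).

    Fires when the longest single-residue run reaches *max_run_length* or
    the most frequent residue exceeds *max_run_fraction* of the sequence
    (strictly greater: an exactly half-G alternating string passes).
    """
    if sequence == "":
        return False
    if _longest_run(sequence) >= max_run_length:
        return True
    top = Counter(sequence).most_common(1)[0][1]
    return top / len(sequence) > max_run_fraction


def deduplicate(
    dataset: Dataset,
    source_priority: tuple[str, ...] = (),
    step_name: str = "deduplicate",
) -> tuple[Dataset, list[FilterVerdict]]:
    """Keep exactly one record per distinct full sequence.

    The survivor among copies is chosen by *source_priority* (earlier tags
    win; unlisted sources rank after listed ones), then by lexicographic
    record_id, so the outcome is independent of input order.
    """
    df = dataset.records
    n_in = len(df)
    if n_in == 0:
        out = dataset.copy()
        out.log(step_name, 0, 0)
        return out, []

    rank = {tag: i for i, tag in enumerate(source_priority)}

    def sort_key(row):
        return (rank.get(row["source_db"], len(source_priority)), str(row["record_id"]))

    verdicts: list[FilterVerdict] = []
    keep_idx = []
    for seq, grp in df.groupby("full_sequence", sort=False):
        ordered = sorted(grp.index, key=lambda i: sort_key(df.loc[i]))
        keep_idx.append(ordered[0])
        for i in ordered[1:]:
            verdicts.append(
                FilterVerdict(
                    str(df.loc[i, "record_id"]),
                    RULE_DUPLICATE,
                    f"duplicate of {df.loc[ordered[0], 'record_id']}",
                )
            )
    keep_idx = sorted(keep_idx)
    out = Dataset(df.loc[keep_idx].reset_index(drop=True), list(dataset.funnel))
    out.log(step_name, n_in, n_in - len(keep_idx))
    return out, verdicts


def apply_filters(
    dataset: Dataset, config: FilterConfig | None = None
) -> tuple[Dataset, list[FilterVerdict]]:
    """Run the full QC battery in the fixed order, with per-rule accounting.

    Order: canonical alphabet → completeness (full sequence present) →
    exact-duplicate removal → artificial-sequence removal.  The returned
    dataset's funnel gains one entry per step; idempotent by construction.
    """
    config = config or FilterConfig()
    verdicts: list[FilterVerdict] = []
    df = dataset.records
    ds = dataset

    # 1. canonical alphabet
    n_in = len(df)
    ok = df["full_sequence"].map(is_canonical_sequence)
    for _, row in df[~ok].iterrows():
        verdicts.append(FilterVerdict(str(row["record_id"]), RULE_NON_CANONICAL, "ambiguous or empty sequence"))
    ds = Dataset(df[ok].reset_index(drop=True), list(ds.funnel))
    ds.log("qc:canonical_alphabet", n_in, int((~ok).sum()))

    # 2. completeness: every surviving record must carry all seven regions
    df = ds.records
    n_in = len(df)
    complete = df.apply(lambda r: all(isinstance(r[x], str) and r[x] != "" for x in REGIONS), axis=1) if n_in else pd.Series(dtype=bool)
    for _, row in (df[~complete].iterrows() if n_in else ()):
        verdicts.append(FilterVerdict(str(row["record_id"]), RULE_INCOMPLETE, "missing region strings"))
    ds = Dataset(df[complete].reset_index(drop=True) if n_in else df, list(ds.funnel))
    ds.log("qc:completeness", n_in, int((~complete).sum()) if n_in else 0)

    # 3. exact duplicates
    ds, dup_verdicts = deduplicate(ds, config.source_priority, step_name="qc:deduplicate")
    verdicts.extend(dup_verdicts)

    # 4. artificial sequences
    df = ds.records
    n_in = len(df)
    drop = []
    for i, row in df.iterrows():
        seq = row["full_sequence"]
        if is_alphabetically_ordered(seq, config.min_distinct):
            verdicts.append(FilterVerdict(str(row["record_id"]), RULE_ALPHABETICAL, "residues in alphabetical order"))
            drop.append(i)
        elif is_low_complexity(seq, config.max_run_fraction, config.max_run_length):
            verdicts.append(
                FilterVerdict(
                    str(row["record_id"]),
                    RULE_HOMOPOLYMER,
                    f"longest run {_longest_run(seq)}, modal fraction {max(Counter(seq).values()) / len(seq):.2f}",
                )
            )
            drop.append(i)
    ds = Dataset(df.drop(index=drop).reset_index(drop=True), list(ds.funnel))
    ds.log("qc:artificial_sequences", n_in, len(drop))
    return ds, verdicts


def verdicts_to_frame(verdicts: list[FilterVerdict]) -> pd.DataFrame:
    return pd.DataFrame(
        [(v.record_id, v.rule, v.detail) for v in verdicts],
        columns=["record_id", "rule", "detail"],
    )
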
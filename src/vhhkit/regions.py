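"""Region reconstruction and FR/CDR delineation.

A VHH variable domain is split into seven contiguous regions,
FR1-CDR1-FR2-CDR2-FR3-CDR3-FR4, whose concatenation is the full sequence.
Two paths produce a :class:`RegionSet` for a record:

* *externally supplied boundaries* (e.g. from IMGT-style numbering tools),
  ingested as (start, end) pairs and applied verbatim;
* a *motif-anchored fallback heuristic* exploiting the near-invariant
  architecture of camelid VHHs: a canonical Cys late in FR1, a conserved
  Trp opening FR2, a near-fixed FR2/FR3 length, a canonical Cys closing
  FR3, and the W-G-x-G motif opening FR4.

The fallback is deterministic and is tagged with scheme
``anchor-heuristic`` plus a ``fallback_annotation`` provenance flag; it is
not a substitute for a full numbering scheme and carries its own boundary
conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .dataset import CANONICAL_AA_SET, REGIONS


class AnnotationError(ValueError):
    """Raised when neither anchors nor external boundaries delineate a sequence."""


class ReconstructionError(ValueError):
    """Raised when a region set is incomplete and cannot be concatenated."""


@dataclass
class RegionSet:
    """The seven region strings of one record plus the delineation scheme tag."""

    FR1: str | None = None
    CDR1: str | None = None
    FR2: str | None = None
    CDR2: str | None = None
    FR3: str | None = None
    CDR3: str | None = None
    FR4: str | None = None
    scheme: str = "as-deposited"

    def as_dict(self) -> dict[str, str | None]:
        return {r: getattr(self, r) for r in REGIONS}

    def is_complete(self) -> bool:
        return all(isinstance(getattr(self, r), str) and getattr(self, r) != "" for r in REGIONS)

    def boundaries(self) -> list[tuple[int, int]]:
        """0-based half-open (start, end) of each region in N→C order."""
        if not self.is_complete():
            raise ReconstructionError("region set incomplete; no boundaries")
        out, pos = [], 0
        for r in REGIONS:
            seg = getattr(self, r)
            out.append((pos, pos + len(seg)))
            pos += len(seg)
        return out


@dataclass
class AnnotatorConfig:
    """Tunable anchors of the fallback delineation heuristic.

    Windows are 0-based half-open.  ``fr1_cys_window`` is where the canonical
    FR1 cysteine is sought; the FR1/CDR1 junction falls 3 residues after it.
    ``trp_scan_span`` bounds the search for the FR2-opening tryptophan after
    CDR1 starts.  ``fr2_length`` and ``fr3_length`` encode the near-fixed
    framework lengths; ``fr3_cys_offset`` is the canonical Cys position
    within FR3 (the FR3/CDR3 junction falls 3 residues after that Cys).
    ``fr4_motif`` is matched from the C-terminus to anchor FR4.
    """

    fr1_cys_window: tuple[int, int] = (15, 35)
    cys_tail: int = 3  # residues kept after an anchoring Cys
    trp_scan_span: int = 20
    fr2_length: int = 17
    fr3_length: int = 38
    fr3_cys_offset: int = 34
    expected_cdr2_length: int = 8
    min_cdr2_length: int = 3
    min_cdr3_length: int = 3
    fr4_motif: tuple[str, ...] = ("W", "G", None, "G")
    min_length: int = 90
    max_length: int = 180


DEFAULT_ANNOTATOR = AnnotatorConfig()


def reconstruct_full_sequence(regions: RegionSet) -> str:
    """Concatenate FR1..FR4/CDR1..CDR3 into the full sequence.

    Raises :class:`ReconstructionError` if any region is absent or empty, so
    the caller can route the record to annotation or drop it.
    """
    missing = [r for r in REGIONS if not isinstance(getattr(regions, r), str) or getattr(regions, r) == ""]
    if missing:
        raise ReconstructionError(f"missing regions: {missing}")
    return "".join(getattr(regions, r) for r in REGIONS)


def _find_fr4_start(seq: str, motif: tuple[str | None, ...]) -> int | None:
    """Rightmost match of the FR4 anchor motif (None = wildcard position)."""
    k = len(motif)
    for start in range(len(seq) - k, -1, -1):
        if all(m is None or seq[start + i] == m for i, m in enumerate(motif)):
            return start
    return None


def annotate_regions(
    full_sequence: str,
    external_boundaries: list[tuple[int, int]] | None = None,
    config: AnnotatorConfig = DEFAULT_ANNOTATOR,
) -> RegionSet:
    """Delineate the seven regions of a full VHH sequence.

    With *external_boundaries* (seven 0-based half-open (start, end) pairs
    covering the sequence without gaps) the split is applied verbatim and
    tagged ``imgt-external``.  Otherwise the motif-anchored fallback runs:

    1. FR1 ends ``cys_tail`` residues after the first Cys in
       ``fr1_cys_window``.
    2. FR2 begins at the first Trp within ``trp_scan_span`` of CDR1's start
       and has fixed length ``fr2_length``.
    3. FR4 begins at the C-terminal-most W-G-x-G match.
    4. The FR3/CDR3 junction falls ``cys_tail`` residues after the Cys
       closest to its expected canonical position (CDR2 start +
       ``expected_cdr2_length`` + ``fr3_cys_offset``); choosing the
       *closest* rather than the *last* candidate keeps the junction stable
       when a non-canonical cysteine sits inside CDR3.
    5. FR3 is assigned its near-fixed length ``fr3_length``, which fixes the
       CDR2/FR3 junction.

    Raises :class:`AnnotationError` when an anchor cannot be found or the
    resulting segmentation is not strictly increasing.
    """
    seq = full_sequence
    if not (config.min_length <= len(seq) <= config.max_length):
        raise AnnotationError(f"sequence length {len(seq)} outside [{config.min_length}, {config.max_length}]")
    if not set(seq) <= CANONICAL_AA_SET:
        raise AnnotationError("sequence contains non-canonical residues")

    if external_boundaries is not None:
        if len(external_boundaries) != 7:
            raise AnnotationError("external boundaries must give seven (start, end) pairs")
        pos = 0
        parts = []
        for start, end in external_boundaries:
            if start != pos or end <= start:
                raise AnnotationError("external boundaries must tile the sequence contiguously")
            parts.append(seq[start:end])
            pos = end
        if pos != len(seq):
            raise AnnotationError("external boundaries do not cover the full sequence")
        return RegionSet(*parts, scheme="imgt-external")

    # (1) FR1 / CDR1
    lo, hi = config.fr1_cys_window
    window = seq[lo:hi]
    rel = window.find("C")
    if rel < 0:
        raise AnnotationError("no cysteine in the FR1 anchor window")
    cdr1_start = lo + rel + config.cys_tail + 1

    # (2) CDR1 / FR2
    trp_rel = seq[cdr1_start : cdr1_start + config.trp_scan_span].find("W")
    if trp_rel < 0:
        raise AnnotationError("no tryptophan anchor for FR2")
    fr2_start = cdr1_start + trp_rel
    if fr2_start == cdr1_start:
        raise AnnotationError("empty CDR1 under anchor heuristic")
    cdr2_start = fr2_start + config.fr2_length

    # (3) CDR3 / FR4
    fr4_start = _find_fr4_start(seq, config.fr4_motif)
    if fr4_start is None:
        raise AnnotationError("no W-G-x-G anchor for FR4")

    # (4) FR3 / CDR3: Cys closest to the expected canonical position
    target = cdr2_start + config.expected_cdr2_length + config.fr3_cys_offset
    cys_lo = cdr2_start + config.min_cdr2_length
    cys_hi = fr4_start - config.min_cdr3_length - config.cys_tail - 1
    candidates = [i for i in range(cys_lo, max(cys_lo, cys_hi) + 1) if i < len(seq) and seq[i] == "C"]
    if not candidates:
        raise AnnotationError("no cysteine anchor for the FR3/CDR3 junction")
    fr3_cys = min(candidates, key=lambda i: (abs(i - target), i))
    cdr3_start = fr3_cys + config.cys_tail + 1

    # (5) near-fixed FR3 length fixes the CDR2/FR3 junction
    fr3_start = cdr3_start - config.fr3_length

    cuts = [0, cdr1_start, fr2_start, cdr2_start, fr3_start, cdr3_start, fr4_start, len(seq)]
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise AnnotationError(f"degenerate segmentation {cuts}")
    parts = [seq[a:b] for a, b in zip(cuts, cuts[1:])]
    return RegionSet(*parts, scheme="anchor-heuristic")


# Region-length sanity bounds used by validation (min, max), in residues.
REGION_LENGTH_BOUNDS = {
    "FR1": (15, 35),
    "FR2": (10, 25),
    "FR3": (25, 50),
    "FR4": (5, 15),
    "CDR1": (3, 20),
    "CDR2": (3, 20),
    "CDR3": (1, 40),
}


@dataclass
class ValidationReport:
    """Report-only consistency checks for one record."""

    record_id: str
    concatenation_matches: bool
    length_warnings: list[str] = field(default_factory=list)
    fr1_has_cys: bool = True
    fr3_has_cys: bool = True

    @property
    def ok(self) -> bool:
        return (
            self.concatenation_matches
            and not self.length_warnings
            and self.fr1_has_cys
            and self.fr3_has_cys
        )


def validate_region_consistency(record: pd.Series) -> ValidationReport:
    """Check a curated record's regions against its full sequence.

    Verifies (i) that the seven regions concatenate to the full sequence,
    (ii) region lengths against empirical sanity bounds, and (iii) presence
    of the canonical cysteines in FR1 and FR3.  Never raises; degraded
    records are only reported.
    """
    concat = "".join(str(record[r]) for r in REGIONS)
    report = ValidationReport(
        record_id=str(record["record_id"]),
        concatenation_matches=(concat == str(record["full_sequence"])),
        fr1_has_cys="C" in str(record["FR1"]),
        fr3_has_cys="C" in str(record["FR3"]),
    )
    for region, (lo, hi) in REGION_LENGTH_BOUNDS.items():
        n = len(str(record[region]))
        if not lo <= n <= hi:
            report.length_warnings.append(f"{region} length {n} outside [{lo}, {hi}]")
    return report


def read_external_boundaries(path) -> dict[str, list[tuple[int, int]]]:
    """Ingest external numbering output as TSV (record_id, region, start, end).

    Coordinates in the file are 1-based inclusive (the biologist-facing
    convention); they are converted to the 0-based half-open convention used
    internally.  Returns a mapping record_id -> seven (start, end) pairs in
    region order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"record_id": "object"})
    out: dict[str, list[tuple[int, int]]] = {}
    for rid, grp in df.groupby("record_id"):
        by_region = {row["region"]: (int(row["start"]) - 1, int(row["end"])) for _, row in grp.iterrows()}
        missing = [r for r in REGIONS if r not in by_region]
        if missing:
            raise AnnotationError(f"external boundaries for {rid} missing {missing}")
        out[str(rid)] = [by_region[r] for r in REGIONS]
    return out
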
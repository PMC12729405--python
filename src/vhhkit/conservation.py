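"""Per-column conservation and Shannon entropy of region alignments.

Instead of a conventional multiple sequence alignment (which introduces
artifacts in hypervariable loops), each region is analyzed independently:
the region strings of a cohort are padded with "-" to the length of the
longest member, forming a rectangular matrix.  For each column *j* the
per-residue counts n(a, j) exclude gaps; with N(j) = Σ_a n(a, j):

* consensus_j      = argmax_a n(a, j)       (alphabetical tie-break)
* cons_freq_j      = max_a n(a, j) / N(j)
* H_j              = −Σ_a (n/N) log2 (n/N)  in bits, 0 ≤ H ≤ log2 20 ≈ 4.32

Columns that are entirely gaps (N = 0) report missing statistics rather
than zeros.  The same machinery runs globally and per species cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import CANONICAL_AA, CANONICAL_AA_SET, Dataset, GAP, REGIONS

_AA_BYTES = np.frombuffer(CANONICAL_AA.encode(), dtype=np.uint8)
_LOG2_20 = float(np.log2(20))


@dataclass
class RegionAlignment:
    """Rectangular gap-padded matrix of one region for one cohort."""

    region: str
    cohort: str
    rows: list[str]
    width: int

    def __len__(self) -> int:
        return len(self.rows)

    def matrix(self) -> np.ndarray:
        """(n_rows, width) uint8 byte matrix; empty alignments give (0, 0)."""
        if not self.rows:
            return np.zeros((0, 0), dtype=np.uint8)
        return np.frombuffer("".join(self.rows).encode(), dtype=np.uint8).reshape(
            len(self.rows), self.width
        )


def pad_sequences(strings: list[str], width: int | None = None, side: str = "right") -> list[str]:
    """Pad strings with the gap symbol to a common width.

    ``side`` is one of right (default: region starts stay aligned at column
    0), left, or center.
    """
    if width is None:
        width = max((len(s) for s in strings), default=0)
    out = []
    for s in strings:
        fill = width - len(s)
        if side == "right":
            out.append(s + GAP * fill)
        elif side == "left":
            out.append(GAP * fill + s)
        elif side == "center":
            left = fill // 2
            out.append(GAP * left + s + GAP * (fill - left))
        else:
            raise ValueError(f"unknown padding side {side!r}")
    return out


def _clean(sequence: str) -> str:
    """Replace any residual non-canonical character by the gap symbol."""
    return "".join(c if c in CANONICAL_AA_SET else GAP for c in sequence)


def build_region_alignment(
    records: Dataset | pd.DataFrame,
    region: str,
    cohort: str = "all",
    padding_side: str = "right",
) -> RegionAlignment:
    """Pad one region's strings for one cohort into a rectangular alignment.

    ``cohort`` is a species category or ``"all"``.  An empty cohort yields
    an empty alignment of width 0.
    """
    df = records.records if isinstance(records, Dataset) else records
    if cohort != "all":
        df = df[df["species"] == cohort]
    strings = [_clean(str(s)) for s in df[region].tolist()]
    rows = pad_sequences(strings, side=padding_side)
    width = max((len(s) for s in strings), default=0)
    return RegionAlignment(region=region, cohort=cohort, rows=rows, width=width)


@dataclass
class ColumnStats:
    """Gap-excluded per-column statistics of an alignment."""

    j: int
    counts: dict[str, int]
    n: int                      # N(j): total non-gap count
    consensus: str              # "-" when the column is all gaps
    consensus_frequency: float  # NaN when N(j) = 0
    entropy: float              # bits; NaN when N(j) = 0
    coverage: float             # N(j) / number of rows


def _column_counts(alignment: RegionAlignment) -> np.ndarray:
    """(width, 20) matrix of per-column canonical-residue counts."""
    mat = alignment.matrix()
    if mat.size == 0:
        return np.zeros((alignment.width, 20), dtype=np.int64)
    return (mat[:, :, None] == _AA_BYTES[None, None, :]).sum(axis=0)


def _stats_from_counts(counts: np.ndarray, n_rows: int) -> pd.DataFrame:
    """Vectorized consensus/entropy from a (width, 20) count matrix."""
    totals = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals[:, None]
        logp = np.zeros_like(p)
        np.log2(p, where=counts > 0, out=logp)
        entropy = -(p * logp).sum(axis=1)
        cons_idx = counts.argmax(axis=1)  # ties: lowest index = alphabetical
        cons_freq = counts.max(axis=1) / totals
    consensus = np.array(list(CANONICAL_AA))[cons_idx]
    empty = totals == 0
    consensus = np.where(empty, GAP, consensus)
    cons_freq = np.where(empty, np.nan, cons_freq)
    entropy = np.where(empty, np.nan, entropy)
    return pd.DataFrame(
        {
            "position": np.arange(len(totals)),
            "n": totals,
            "consensus": consensus,
            "consensus_frequency": cons_freq,
            "entropy": entropy,
            "coverage": totals / n_rows if n_rows else np.nan,
        }
    )


def column_stats(alignment: RegionAlignment, j: int) -> ColumnStats:
    """Statistics of column *j* (0-based); raises IndexError out of range."""
    if not 0 <= j < alignment.width:
        raise IndexError(f"column {j} out of range for width {alignment.width}")
    counts = _column_counts(alignment)[j]
    table = _stats_from_counts(counts[None, :], len(alignment.rows)).iloc[0]
    return ColumnStats(
        j=j,
        counts={a: int(c) for a, c in zip(CANONICAL_AA, counts) if c > 0},
        n=int(table["n"]),
        consensus=str(table["consensus"]),
        consensus_frequency=float(table["consensus_frequency"]),
        entropy=float(table["entropy"]),
        coverage=float(table["coverage"]),
    )


def alignment_profile(alignment: RegionAlignment) -> pd.DataFrame:
    """Per-column statistics table for a whole alignment."""
    counts = _column_counts(alignment)
    table = _stats_from_counts(counts, len(alignment.rows))
    table.insert(0, "region", alignment.region)
    table.insert(0, "cohort", alignment.cohort)
    table["position_1based"] = table["position"] + 1
    return table


def region_profile(
    records: Dataset | pd.DataFrame,
    regions: tuple[str, ...] = REGIONS,
    stratify_by_species: bool = False,
    padding_side: str = "right",
) -> pd.DataFrame:
    """Column statistics for the requested regions, pooled and/or by species.

    Returns a long-format table (cohort, region, position, ...) with one row
    per (cohort, column).  With ``stratify_by_species`` each species present
    in the data forms its own cohort in addition to the pooled "all" cohort.
    """
    df = records.records if isinstance(records, Dataset) else records
    cohorts = ["all"]
    if stratify_by_species:
        cohorts += sorted(df["species"].dropna().unique())
    frames = []
    for cohort in cohorts:
        for region in regions:
            aln = build_region_alignment(df, region, cohort, padding_side)
            if aln.width == 0:
                continue
            frames.append(alignment_profile(aln))
    if not frames:
        return pd.DataFrame(
            columns=["cohort", "region", "position", "n", "consensus",
                     "consensus_frequency", "entropy", "coverage", "position_1based"]
        )
    return pd.concat(frames, ignore_index=True)


def mean_region_summary(profile: pd.DataFrame, weight_by_coverage: bool = False) -> pd.DataFrame:
    """Per (cohort, region) mean consensus frequency and entropy.

    Averages run over columns with N(j) ≥ 1 only; with
    ``weight_by_coverage`` each column is weighted by its coverage so that
    sparsely populated tail columns (from length variation) count less.
    """
    covered = profile[profile["n"] >= 1]
    rows = []
    for (cohort, region), grp in covered.groupby(["cohort", "region"], sort=False):
        w = grp["coverage"].to_numpy() if weight_by_coverage else np.ones(len(grp))
        rows.append(
            {
                "cohort": cohort,
                "region": region,
                "n_columns": len(grp),
                "mean_consensus_frequency": float(np.average(grp["consensus_frequency"], weights=w)),
                "mean_entropy": float(np.average(grp["entropy"], weights=w)),
            }
        )
    return pd.DataFrame(rows)


def heatmap_matrix(profile: pd.DataFrame, region: str, value: str = "consensus_frequency") -> pd.DataFrame:
    """Wide matrix (rows = cohorts, columns = 1-based positions) for one region."""
    sub = profile[profile["region"] == region]
    return sub.pivot(index="cohort", columns="position_1based", values=value)


def max_entropy_bits() -> float:
    """Upper bound of per-column entropy over the 20-residue alphabet."""
    return _LOG2_20
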
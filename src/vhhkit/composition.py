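"""Amino-acid composition, Lys/Cys distributions, length statistics,
and the non-parametric group-comparison battery.

Composition is length-weighted pooling over sequences:

    f(a) = Σ_i n(a, i) / Σ_i L_i

over the N sequences in scope (a region of a cohort, or full sequences),
reported as fractions internally and percentages (100 f(a)) in outputs.
Lysine and cysteine get a dedicated per-region view because they are the
usual bioconjugation handles (amine- and thiol-directed chemistry): for
each (cohort, region) we emit the residue's relative frequency, its mean
count per sequence, and the fraction of sequences carrying at least one
copy.

Group comparisons follow the conventional non-parametric battery for
non-normal cohort data: Shapiro–Wilk normality per group, Kruskal–Wallis
omnibus, and all pairwise Mann–Whitney tests with Holm adjustment; cohorts
below a minimum size are reported as excluded rather than silently dropped.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from Bio.SeqUtils import molecular_weight
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import CANONICAL_AA, Dataset, REGIONS


def _frame(records: Dataset | pd.DataFrame) -> pd.DataFrame:
    return records.records if isinstance(records, Dataset) else records


def _scope_series(df: pd.DataFrame, scope: str, cohort: str) -> pd.Series:
    if cohort != "all":
        df = df[df["species"] == cohort]
    col = "full_sequence" if scope in ("global", "full") else scope
    return df[col].dropna().astype(str)


@dataclass
class CompositionProfile:
    """Relative residue frequencies for one (cohort, scope)."""

    cohort: str
    scope: str              # "global" or a region name
    frequencies: dict[str, float]
    n_total: int            # total residues counted, Σ L_i
    n_sequences: int

    def as_percent(self) -> dict[str, float]:
        return {a: 100.0 * f for a, f in self.frequencies.items()}


def aa_frequency(
    records: Dataset | pd.DataFrame, scope: str = "global", cohort: str = "all"
) -> CompositionProfile:
    """Length-weighted residue frequencies f(a) = Σ n(a,i) / Σ L_i.

    ``scope`` is "global" (full sequences) or a region name; ``cohort`` a
    species category or "all".  An empty scope yields an all-zero profile
    with n_total = 0.
    """
    seqs = _scope_series(_frame(records), scope, cohort)
    counts: Counter = Counter()
    total = 0
    for s in seqs:
        counts.update(s)
        total += len(s)
    freqs = {a: (counts.get(a, 0) / total if total else 0.0) for a in CANONICAL_AA}
    return CompositionProfile(cohort, scope, freqs, total, len(seqs))


def composition_table(
    records: Dataset | pd.DataFrame, stratify_by_species: bool = True
) -> pd.DataFrame:
    """Long table (cohort, region, residue, frequency_percent) over all scopes."""
    df = _frame(records)
    cohorts = ["all"] + (sorted(df["species"].dropna().unique()) if stratify_by_species else [])
    rows = []
    for cohort in cohorts:
        for scope in ("global", *REGIONS):
            prof = aa_frequency(df, scope, cohort)
            for a, pct in prof.as_percent().items():
                rows.append({"cohort": cohort, "region": prof.scope, "residue": a,
                             "frequency_percent": pct, "n_sequences": prof.n_sequences})
    return pd.DataFrame(rows)


def residue_region_distribution(
    records: Dataset | pd.DataFrame, residue: str, stratify_by_species: bool = True
) -> pd.DataFrame:
    """Three per-(cohort, region) metrics for one residue.

    * ``frequency`` — the residue's share of all residues in the region;
    * ``mean_count`` — average copies per sequence;
    * ``presence`` — fraction of sequences with at least one copy.
    """
    df = _frame(records)
    cohorts = ["all"] + (sorted(df["species"].dropna().unique()) if stratify_by_species else [])
    rows = []
    for cohort in cohorts:
        for region in REGIONS:
            seqs = _scope_series(df, region, cohort)
            n = len(seqs)
            if n == 0:
                rows.append({"cohort": cohort, "region": region, "n_sequences": 0,
                             "frequency": 0.0, "mean_count": 0.0, "presence": 0.0})
                continue
            per_seq = seqs.map(lambda s: s.count(residue))
            total_res = int(seqs.map(len).sum())
            rows.append(
                {
                    "cohort": cohort,
                    "region": region,
                    "n_sequences": n,
                    "frequency": float(per_seq.sum() / total_res) if total_res else 0.0,
                    "mean_count": float(per_seq.mean()),
                    "presence": float((per_seq > 0).mean()),
                }
            )
    return pd.DataFrame(rows)


WATER_DA = 18.015


def sequence_mw_kda(sequence: str) -> float:
    """Molecular weight in kDa from average residue masses plus one water."""
    return molecular_weight(sequence, seq_type="protein", monoisotopic=False) / 1000.0


@dataclass
class LengthStats:
    cohort: str
    scope: str          # region name or "full"
    n: int
    mean: float
    sd: float           # sample (n-1) standard deviation
    rsd: float          # percent, 100 * sd / mean
    min: int
    max: int
    mw_mean: float | None = None   # kDa, full-sequence scope only
    mw_sd: float | None = None


def length_stats(
    records: Dataset | pd.DataFrame, scope: str = "full", cohort: str = "all"
) -> LengthStats | None:
    """Mean / sample SD / RSD / range of lengths for one (cohort, scope).

    For the full-sequence scope, per-sequence molecular weight (average
    residue masses + one water, in kDa) is summarized too.  Empty cohorts
    return None (the row is omitted from reports).
    """
    seqs = _scope_series(_frame(records), scope, cohort)
    if len(seqs) == 0:
        return None
    lengths = seqs.map(len).to_numpy(dtype=float)
    mean = float(lengths.mean())
    sd = float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0
    out = LengthStats(
        cohort=cohort,
        scope=scope,
        n=len(lengths),
        mean=mean,
        sd=sd,
        rsd=100.0 * sd / mean if mean else 0.0,
        min=int(lengths.min()),
        max=int(lengths.max()),
    )
    if scope in ("full", "global"):
        mws = np.array([sequence_mw_kda(s) for s in seqs])
        out.mw_mean = float(mws.mean())
        out.mw_sd = float(mws.std(ddof=1)) if len(mws) > 1 else 0.0
    return out


def length_stats_table(records: Dataset | pd.DataFrame) -> pd.DataFrame:
    """Length statistics for every (cohort, scope) with data."""
    df = _frame(records)
    cohorts = ["all"] + sorted(df["species"].dropna().unique())
    rows = []
    for cohort in cohorts:
        for scope in ("full", *REGIONS):
            st = length_stats(df, scope, cohort)
            if st is not None:
                rows.append(vars(st))
    return pd.DataFrame(rows)


def significance_label(p: float) -> str:
    """Conventional significance tiers: * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    """Result of the non-parametric comparison battery for one variable."""

    variable: str
    groups: list[str]
    group_sizes: dict[str, int]
    normality_p: dict[str, float]
    omnibus_p: float | None
    pairwise: pd.DataFrame       # group_a, group_b, u_statistic, p_raw, p_holm, label
    excluded_groups: dict[str, str] = field(default_factory=dict)
    skipped_reason: str | None = None


def compare_groups(
    values_by_group: dict[str, np.ndarray | list],
    variable: str = "value",
    min_n: int = 50,
) -> GroupComparison:
    """Shapiro–Wilk, Kruskal–Wallis, and Holm-adjusted pairwise Mann–Whitney.

    Groups with fewer than *min_n* observations are excluded from testing
    but reported in ``excluded_groups`` (e.g. a 35-member cohort at the
    default min_n = 50).  With fewer than two eligible groups, testing is
    skipped with a reason.
    """
    arrays = {g: np.asarray(v, dtype=float) for g, v in values_by_group.items()}
    excluded = {g: f"n = {len(v)} < min_n = {min_n}" for g, v in arrays.items() if len(v) < min_n}
    eligible = {g: v for g, v in arrays.items() if g not in excluded}

    result = GroupComparison(
        variable=variable,
        groups=sorted(eligible),
        group_sizes={g: len(v) for g, v in arrays.items()},
        normality_p={},
        omnibus_p=None,
        pairwise=pd.DataFrame(columns=["group_a", "group_b", "u_statistic", "p_raw", "p_holm", "label"]),
        excluded_groups=excluded,
    )
    if len(eligible) < 2:
        result.skipped_reason = f"only {len(eligible)} group(s) with n >= {min_n}"
        return result

    for g, v in eligible.items():
        result.normality_p[g] = float(stats.shapiro(v).pvalue)

    result.omnibus_p = float(stats.kruskal(*eligible.values()).pvalue)

    pairs = list(combinations(sorted(eligible), 2))
    rows = []
    for a, b in pairs:
        u = stats.mannwhitneyu(eligible[a], eligible[b], alternative="two-sided")
        rows.append({"group_a": a, "group_b": b, "u_statistic": float(u.statistic), "p_raw": float(u.pvalue)})
    table = pd.DataFrame(rows)
    table["p_holm"] = multipletests(table["p_raw"], method="holm")[1]
    table["label"] = table["p_holm"].map(significance_label)
    result.pairwise = table
    return result


def compare_region_lengths(
    records: Dataset | pd.DataFrame, region: str, min_n: int = 50
) -> GroupComparison:
    """Species comparison of one region's lengths (or full-sequence lengths)."""
    df = _frame(records)
    col = "full_sequence" if region == "full" else region
    groups = {
        sp: grp[col].dropna().astype(str).map(len).to_numpy()
        for sp, grp in df.groupby("species")
    }
    return compare_groups(groups, variable=f"{region}_length", min_n=min_n)
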
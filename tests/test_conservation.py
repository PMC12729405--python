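"""Per-column consensus/entropy against a brute-force oracle, plus
alignment construction and summary invariants."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest

from vhhkit.conservation import (
    RegionAlignment,
    alignment_profile,
    build_region_alignment,
    column_stats,
    heatmap_matrix,
    max_entropy_bits,
    mean_region_summary,
    pad_sequences,
    region_profile,
)
from vhhkit.dataset import CANONICAL_AA, CANONICAL_COLUMNS, Dataset, GAP

LOG2_20 = math.log2(20)


def brute_force_column(residues):
    """Independent tally: (consensus, consensus_freq, entropy_bits) or Nones.

    Pure-Python Counter/log2 implementation, gap-excluding, alphabetical
    tie-break — shares no code with the vectorized path.
    """
    counts = Counter(r for r in residues if r != GAP)
    n = sum(counts.values())
    if n == 0:
        return GAP, None, None
    consensus = min(counts, key=lambda a: (-counts[a], a))
    freq = counts[consensus] / n
    entropy = -sum((c / n) * math.log2(c / n) for c in counts.values())
    return consensus, freq, entropy


def _alignment(rows, region="CDR3", cohort="all"):
    width = max(len(r) for r in rows)
    return RegionAlignment(region=region, cohort=cohort, rows=pad_sequences(rows, width), width=width)


class TestColumnStats:
    def test_uniform_column_reaches_maximal_entropy(self):
        aln = _alignment(list(CANONICAL_AA))
        st = column_stats(aln, 0)
        assert st.entropy == pytest.approx(LOG2_20, abs=1e-12)
        assert st.entropy == pytest.approx(4.3219, abs=1e-4)
        assert max_entropy_bits() == pytest.approx(LOG2_20)

    def test_constant_column_has_zero_entropy_full_consensus(self):
        st = column_stats(_alignment(["A", "A", "A", "A"]), 0)
        assert st.consensus == "A"
        assert st.consensus_frequency == 1.0
        assert st.entropy == 0.0

    def test_two_thirds_majority_column(self):
        st = column_stats(_alignment(["A", "A", "C"]), 0)
        assert st.consensus == "A"
        assert st.consensus_frequency == pytest.approx(2 / 3)
        assert st.entropy == pytest.approx(0.9183, abs=1e-4)

    def test_gap_only_column_reported_missing(self):
        st = column_stats(_alignment(["AC", "A"]), 1)
        assert st.n == 1  # one C, one gap
        st_all_gap = column_stats(_alignment(["A" + GAP, "A" + GAP]), 1)
        assert st_all_gap.n == 0
        assert st_all_gap.consensus == GAP
        assert math.isnan(st_all_gap.consensus_frequency)
        assert math.isnan(st_all_gap.entropy)

    def test_out_of_range_column_raises(self):
        with pytest.raises(IndexError):
            column_stats(_alignment(["AC"]), 5)

    def test_oracle_equivalence_on_random_small_columns(self):
        """1,000 random columns of ≤8 rows: vectorized stats match the
        brute-force tally to 1e-12."""
        rng = np.random.default_rng(42)
        alphabet = list(CANONICAL_AA) + [GAP]
        for _ in range(1000):
            n_rows = int(rng.integers(1, 9))
            col = [alphabet[i] for i in rng.integers(0, len(alphabet), size=n_rows)]
            st = column_stats(_alignment(col), 0)
            consensus, freq, entropy = brute_force_column(col)
            assert st.consensus == consensus
            if freq is None:
                assert math.isnan(st.consensus_frequency) and math.isnan(st.entropy)
            else:
                assert st.consensus_frequency == pytest.approx(freq, abs=1e-12)
                assert st.entropy == pytest.approx(entropy, abs=1e-12)

    def test_entropy_bounds_hold_on_generated_data(self, clean_repertoire):
        ds, _ = clean_repertoire
        profile = region_profile(ds)
        covered = profile[profile["n"] >= 1]
        assert (covered["entropy"] >= 0).all()
        assert (covered["entropy"] <= LOG2_20 + 1e-12).all()
        assert (covered["consensus_frequency"] > 0).all()
        assert (covered["consensus_frequency"] <= 1).all()
        # entropy 0 exactly where the consensus is unanimous
        zero = covered["entropy"] == 0
        assert (covered.loc[zero, "consensus_frequency"] == 1).all()


class TestBuildAlignment:
    def test_right_padding_to_longest(self):
        df = pd.DataFrame({"species": ["Lama glama"] * 2, "CDR3": ["ACD", "ACDE"]})
        aln = build_region_alignment(df, "CDR3")
        assert aln.rows == ["ACD" + GAP, "ACDE"]
        assert aln.width == 4

    def test_equal_lengths_introduce_no_gaps(self):
        df = pd.DataFrame({"species": ["Lama glama"] * 3, "CDR3": ["ACD", "EFG", "HIK"]})
        aln = build_region_alignment(df, "CDR3")
        assert all(GAP not in row for row in aln.rows)

    def test_empty_cohort_yields_empty_alignment(self):
        df = pd.DataFrame({"species": ["Lama glama"], "CDR3": ["ACD"]})
        aln = build_region_alignment(df, "CDR3", cohort="Vicugna pacos")
        assert len(aln) == 0 and aln.width == 0

    def test_residual_ambiguity_masked_as_gap(self):
        df = pd.DataFrame({"species": ["Lama glama"], "CDR3": ["AXD"]})
        aln = build_region_alignment(df, "CDR3")
        assert aln.rows == ["A" + GAP + "D"]

    def test_gap_stripped_rows_equal_inputs(self, clean_repertoire):
        ds, _ = clean_repertoire
        aln = build_region_alignment(ds, "CDR3")
        originals = ds.records["CDR3"].tolist()
        assert [row.rstrip(GAP) for row in aln.rows] == originals


class TestRegionProfile:
    def test_permutation_invariance(self, clean_repertoire):
        ds, _ = clean_repertoire
        shuffled = Dataset(ds.records.sample(frac=1, random_state=3).reset_index(drop=True))
        p1 = region_profile(ds, regions=("FR1",))
        p2 = region_profile(shuffled, regions=("FR1",))
        pd.testing.assert_frame_equal(p1, p2)

    def test_pooled_counts_are_sum_of_cohort_counts(self, clean_repertoire):
        ds, _ = clean_repertoire
        profile = region_profile(ds, regions=("CDR1",), stratify_by_species=True)
        pooled = profile[profile["cohort"] == "all"].set_index("position")["n"]
        by_sp = (
            profile[profile["cohort"] != "all"].groupby("position")["n"].sum()
        )
        assert (pooled == by_sp).all()

    def test_duplicate_rows_cannot_raise_entropy_where_consensus(self):
        rows = ["ACDY", "ACDF", "ACEY"]
        base = alignment_profile(_alignment(rows))
        dup = alignment_profile(_alignment(rows + ["ACDY"]))
        # consensus identity unchanged
        assert list(base["consensus"]) == list(dup["consensus"])
        # the duplicated row matches the consensus at columns 0-2
        for j in range(3):
            assert dup.loc[j, "entropy"] <= base.loc[j, "entropy"] + 1e-12

    def test_framework_consensus_recovery(self, clean_repertoire, default_profiles):
        """Frameworks generated at 98% per-position consensus: the mean FR
        consensus frequency lands within 3 SE of the analytic expectation."""
        ds, manifest = clean_repertoire
        profile = region_profile(ds, regions=("FR1", "FR3"), stratify_by_species=True)
        for sp in ("Lama glama", "Vicugna pacos"):
            n = manifest.species_params[sp]["n"]
            for fr in ("FR1", "FR3"):
                expected = manifest.species_params[sp]["framework_conservation"][fr]
                sub = profile[(profile["cohort"] == sp) & (profile["region"] == fr)]
                observed = sub["consensus_frequency"].mean()
                rate = manifest.species_params[sp]["framework_substitution_rate"]
                se = math.sqrt(rate * (1 - rate) / n / len(sub))
                assert abs(observed - expected) <= 3 * se + 1e-9


class TestMeanSummary:
    def test_single_column_summary_equals_column(self):
        profile = alignment_profile(_alignment(["A", "A", "C"]))
        summary = mean_region_summary(profile)
        assert summary.loc[0, "mean_consensus_frequency"] == pytest.approx(2 / 3)
        assert summary.loc[0, "mean_entropy"] == pytest.approx(0.9183, abs=1e-4)

    def test_unweighted_mean_of_mixed_columns(self):
        profile = alignment_profile(_alignment(["AY", "AF"]))  # H = {0, 1}
        summary = mean_region_summary(profile)
        assert summary.loc[0, "mean_entropy"] == pytest.approx(0.5)

    def test_framework_conservation_ordering_recovered(self, clean_repertoire):
        """FR4 (fully anchored, shortest) is generated more conserved than
        FR2 (which carries the variable-length CDR neighbourhood); the
        summary recovers FR4 > FR2 conservation, the published ordering."""
        ds, _ = clean_repertoire
        profile = region_profile(ds, regions=("FR2", "FR4"))
        summary = mean_region_summary(profile).set_index("region")
        assert (
            summary.loc["FR4", "mean_consensus_frequency"]
            > summary.loc["FR2", "mean_consensus_frequency"]
        )

    def test_heatmap_matrix_layout(self, clean_repertoire):
        ds, _ = clean_repertoire
        profile = region_profile(ds, regions=("FR4",), stratify_by_species=True)
        mat = heatmap_matrix(profile, "FR4")
        assert "all" in mat.index
        assert mat.shape[1] == 11  # FR4 width
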
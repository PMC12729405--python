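"""Residue composition, Lys/Cys distributions, length statistics, and the
non-parametric comparison battery."""

import math

import numpy as np
import pandas as pd
import pytest

from vhhkit.composition import (
    aa_frequency,
    compare_groups,
    compare_region_lengths,
    composition_table,
    length_stats,
    residue_region_distribution,
    sequence_mw_kda,
    significance_label,
)
from vhhkit.dataset import CANONICAL_AA, CANONICAL_COLUMNS, Dataset
from vhhkit.simulate import RoundedNormalLaw


def _dataset(rows):
    df = pd.DataFrame(rows)
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    return Dataset(df)


class TestAaFrequency:
    def test_single_sequence(self):
        ds = _dataset([{"record_id": "1", "species": "Lama glama", "full_sequence": "GGSS"}])
        prof = aa_frequency(ds)
        assert prof.frequencies["G"] == 0.5
        assert prof.frequencies["S"] == 0.5
        assert sum(prof.frequencies.values()) == pytest.approx(1.0, abs=1e-12)

    def test_length_weighted_pooling_not_per_sequence_averaging(self):
        ds = _dataset(
            [
                {"record_id": "1", "species": "Lama glama", "full_sequence": "GG"},
                {"record_id": "2", "species": "Lama glama", "full_sequence": "SSSS"},
            ]
        )
        prof = aa_frequency(ds)
        # pooled Σn/ΣL gives 2/6 and 4/6 — not the per-sequence mean (0.5, 0.5)
        assert prof.frequencies["G"] == pytest.approx(2 / 6)
        assert prof.frequencies["S"] == pytest.approx(4 / 6)

    def test_empty_scope_gives_zero_profile(self):
        ds = _dataset([{"record_id": "1", "species": "Lama glama", "full_sequence": "GG"}])
        prof = aa_frequency(ds, cohort="Vicugna pacos")
        assert prof.n_total == 0
        assert all(f == 0.0 for f in prof.frequencies.values())

    def test_normalization_and_pooling_consistency(self, clean_repertoire):
        """Global frequencies equal region frequencies combined with
        region-residue-count weights; every profile sums to 1."""
        ds, _ = clean_repertoire
        global_prof = aa_frequency(ds, "global")
        assert sum(global_prof.frequencies.values()) == pytest.approx(1.0, abs=1e-12)
        regions = [aa_frequency(ds, r) for r in
                   ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3", "FR4")]
        total = sum(p.n_total for p in regions)
        assert total == global_prof.n_total
        for a in CANONICAL_AA:
            combined = sum(p.frequencies[a] * p.n_total for p in regions) / total
            assert combined == pytest.approx(global_prof.frequencies[a], abs=1e-12)

    def test_cdr_composition_recovers_generating_weights(self, clean_repertoire, default_profiles):
        ds, _ = clean_repertoire
        sp = "Lama glama"
        prof = aa_frequency(ds, "CDR2", sp)
        profile = default_profiles[sp]
        for a in ("G", "S", "Y", "K"):
            expected = profile.expected_region_residue_frequency("CDR2", a)
            se = math.sqrt(expected * (1 - expected) / prof.n_total)
            assert abs(prof.frequencies[a] - expected) <= 3 * se + 1e-9

    def test_duplicating_records_leaves_frequencies_unchanged(self):
        rows = [
            {"record_id": "1", "species": "Lama glama", "full_sequence": "GGSSY"},
            {"record_id": "2", "species": "Lama glama", "full_sequence": "AATT"},
        ]
        base = aa_frequency(_dataset(rows))
        doubled = aa_frequency(_dataset(rows + [dict(r, record_id=r["record_id"] + "d") for r in rows]))
        assert base.frequencies == doubled.frequencies


class TestResidueRegionDistribution:
    def test_forced_arithmetic_single_cys_fr1(self):
        rows = [
            {"record_id": str(i), "species": "Lama glama", "FR1": "C" + "A" * 24}
            for i in range(4)
        ]
        table = residue_region_distribution(_dataset(rows), "C", stratify_by_species=False)
        fr1 = table[table["region"] == "FR1"].iloc[0]
        assert fr1["frequency"] == pytest.approx(1 / 25)
        assert fr1["mean_count"] == 1.0
        assert fr1["presence"] == 1.0

    def test_absent_residue_all_zero(self):
        rows = [{"record_id": "1", "species": "Lama glama", "FR1": "AAAA"}]
        table = residue_region_distribution(_dataset(rows), "W", stratify_by_species=False)
        fr1 = table[table["region"] == "FR1"].iloc[0]
        assert fr1["frequency"] == 0.0 and fr1["mean_count"] == 0.0 and fr1["presence"] == 0.0

    def test_cys_presence_recovers_species_contrast(self, clean_repertoire, default_profiles):
        """CDR3 Cys presence ≈0.8 in camels vs ≈0.1 in llamas (3 SE)."""
        ds, manifest = clean_repertoire
        table = residue_region_distribution(ds, "C")
        for sp in ("Camelus dromedarius", "Lama glama"):
            expected = default_profiles[sp].expected_cys_presence("CDR3")
            n = manifest.species_params[sp]["n"]
            row = table[(table["cohort"] == sp) & (table["region"] == "CDR3")].iloc[0]
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(row["presence"] - expected) <= 3 * se

    def test_lysine_concentrated_in_fr3(self, clean_repertoire):
        """FR3 is the most lysine-enriched region, FR2 second among FRs."""
        ds, _ = clean_repertoire
        table = residue_region_distribution(ds, "K", stratify_by_species=False)
        freq = table.set_index("region")["frequency"]
        assert freq["FR3"] == freq[["FR1", "FR2", "FR3", "FR4"]].max()
        assert freq["FR2"] > freq["FR1"]
        assert freq["FR2"] > freq["FR4"]


class TestLengthStats:
    def test_degenerate_equal_lengths(self):
        rows = [{"record_id": str(i), "species": "Lama glama", "CDR1": "A" * 10} for i in range(3)]
        st = length_stats(_dataset(rows), "CDR1")
        assert (st.mean, st.sd, st.rsd) == (10.0, 0.0, 0.0)

    def test_sample_standard_deviation_closed_form(self):
        rows = [
            {"record_id": "1", "species": "Lama glama", "CDR3": "A" * 8},
            {"record_id": "2", "species": "Lama glama", "CDR3": "A" * 12},
        ]
        st = length_stats(_dataset(rows), "CDR3")
        assert st.mean == 10.0
        assert st.sd == pytest.approx(2.8284, abs=1e-4)
        assert st.rsd == pytest.approx(28.28, abs=0.01)

    def test_empty_cohort_omitted(self):
        rows = [{"record_id": "1", "species": "Lama glama", "CDR3": "AAA"}]
        assert length_stats(_dataset(rows), "CDR3", cohort="Vicugna pacos") is None

    def test_molecular_weight_of_typical_vhh(self, clean_repertoire):
        """Full-length sdAbs of ~124 residues weigh ≈13.6 kDa (average
        residue masses + one water)."""
        ds, _ = clean_repertoire
        st = length_stats(ds, "full")
        assert 120 <= st.mean <= 128
        assert st.mw_mean == pytest.approx(13.6, abs=0.9)
        # ~110 Da per residue correspondence
        assert 1000 * st.mw_mean / st.mean == pytest.approx(110, abs=8)

    def test_mw_scales_with_sequence(self):
        assert sequence_mw_kda("G" * 100) < sequence_mw_kda("W" * 100)


class TestCompareGroups:
    def test_identical_groups_show_no_significance(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(15, 4, size=200)
        res = compare_groups({"a": vals, "b": vals.copy()}, min_n=50)
        assert res.pairwise.loc[0, "p_raw"] > 0.9
        assert res.pairwise.loc[0, "label"] == "ns"

    def test_small_group_excluded_not_silently_dropped(self):
        rng = np.random.default_rng(6)
        groups = {
            "big1": rng.normal(0, 1, 200),
            "big2": rng.normal(0, 1, 200),
            "tiny": rng.normal(0, 1, 35),
        }
        res = compare_groups(groups, min_n=50)
        assert "tiny" in res.excluded_groups
        assert "35" in res.excluded_groups["tiny"]
        assert set(res.groups) == {"big1", "big2"}
        assert res.omnibus_p is not None

    def test_fewer_than_two_eligible_groups_skips_with_reason(self):
        res = compare_groups({"a": np.arange(10), "b": np.arange(10)}, min_n=50)
        assert res.skipped_reason is not None
        assert res.pairwise.empty

    def test_mean_shift_detected_below_0_001(self):
        """A +1.0-residue CDR1 mean shift at n = 300/group is detected with
        Holm-adjusted p < 0.001 (the llama-vs-alpaca CDR1 contrast)."""
        rng = np.random.default_rng(7)
        base = RoundedNormalLaw(8.4, 1.4)
        shifted = RoundedNormalLaw(9.4, 1.4)
        res = compare_groups(
            {"alpaca-like": base.sample(rng, 300), "llama-like": shifted.sample(rng, 300)},
            min_n=50,
        )
        assert res.pairwise.loc[0, "p_holm"] < 0.001
        assert res.pairwise.loc[0, "label"] == "***"

    def test_holm_adjustment_monotone_and_not_below_raw(self):
        rng = np.random.default_rng(8)
        groups = {g: rng.normal(mu, 1, 120) for g, mu in
                  [("a", 0.0), ("b", 0.2), ("c", 0.5), ("d", 0.0)]}
        res = compare_groups(groups, min_n=50)
        table = res.pairwise
        assert (table["p_holm"] >= table["p_raw"] - 1e-15).all()
        ordered = table.sort_values("p_raw")["p_holm"].to_numpy()
        assert (np.diff(ordered) >= -1e-15).all()

    def test_region_length_comparison_from_records(self, clean_repertoire):
        ds, _ = clean_repertoire
        res = compare_region_lengths(ds, "CDR3", min_n=50)
        assert res.omnibus_p is not None
        assert len(res.pairwise) == 6  # all pairs of four species
        assert set(res.normality_p) == set(res.groups)

    @pytest.mark.parametrize("p,label", [(0.04, "*"), (0.005, "**"), (0.0005, "***"), (0.2, "ns")])
    def test_significance_tiers(self, p, label):
        assert significance_label(p) == label


def test_composition_table_reports_percentages(clean_repertoire):
    ds, _ = clean_repertoire
    table = composition_table(ds, stratify_by_species=False)
    glob = table[(table["cohort"] == "all") & (table["region"] == "global")]
    assert glob["frequency_percent"].sum() == pytest.approx(100.0, abs=1e-9)
    top = glob.nlargest(3, "frequency_percent")["residue"].tolist()
    assert "G" in top and "S" in top  # glycine/serine-rich repertoires
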
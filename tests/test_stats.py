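import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from shmscope.calling import MutationCall, SYN, NSYN
from shmscope.grouping import ClonalGroup
from shmscope.pipeline import analyze_group, analyze_sequences
from shmscope.stats import (
    compare_cdr_fr,
    mutability_from_counts,
    pooled_frequency,
    region_frequency_table,
    pooled_region_summary,
    substitution_spectrum,
    tandem_fraction,
    tandem_table,
    tissue_stratified_table,
)

from conftest import make_region_map, make_seq

TABLE5A_OCC = {"G": 2895, "C": 2834, "A": 3498, "T": 3368}
TABLE5A_OBS = {"G": 77, "C": 85, "A": 64, "T": 57}


class TestMutability:
    def test_published_scale_counts(self):
        table, tests = mutability_from_counts(TABLE5A_OCC, TABLE5A_OBS)
        rows = table.set_index("base")
        assert rows.loc["G", "expected"] == pytest.approx(65.05, abs=0.005)
        assert rows.loc["C", "expected"] == pytest.approx(63.68, abs=0.005)
        assert round(rows.loc["G", "mutability_index"], 2) == 1.18
        assert round(rows.loc["C", "mutability_index"], 2) == 1.33
        assert round(rows.loc["A", "mutability_index"], 2) == 0.81
        assert round(rows.loc["T", "mutability_index"], 2) == 0.75
        assert tests["GC"]["chisq_p"] == pytest.approx(0.0022, abs=2e-4)
        assert tests["AT"]["chisq_p"] == pytest.approx(0.0068, abs=2e-4)

    def test_observed_equal_expected_gives_unit_indices(self):
        table, tests = mutability_from_counts(
            {"G": 100, "C": 100, "A": 100, "T": 100},
            {"G": 5, "C": 5, "A": 5, "T": 5},
        )
        mi = table.set_index("base")["mutability_index"]
        assert all(mi[b] == pytest.approx(1.0) for b in "GCAT")
        assert tests["GC"]["chisq_stat"] == pytest.approx(0.0)

    def test_zero_expected_reports_na(self):
        table, _ = mutability_from_counts(
            {"G": 0, "C": 10, "A": 10, "T": 10}, {"G": 0, "C": 1, "A": 1, "T": 1}
        )
        assert np.isnan(table.set_index("base").loc["G", "mutability_index"])

    @given(
        st.lists(st.integers(min_value=1, max_value=500), min_size=4, max_size=4),
        st.lists(st.integers(min_value=0, max_value=50), min_size=4, max_size=4),
    )
    def test_conservation_and_weighted_mean(self, occs, obss):
        occurrence = dict(zip("GCAT", occs))
        observed = dict(zip("GCAT", obss))
        table, _ = mutability_from_counts(occurrence, observed)
        body = table[table.base != "Total"]
        # expected counts conserve the observed total
        assert body.expected.sum() == pytest.approx(body.observed.sum())
        # occurrence-weighted mean MI is exactly 1 when any mutation exists
        if sum(obss) > 0:
            weighted = (body.occurrence * body.mutability_index).sum() / body.occurrence.sum()
            assert weighted == pytest.approx(1.0)


class TestPooledFrequencies:
    def test_published_fr_sums(self):
        assert round(pooled_frequency([70, 39, 83], [3075, 2091, 5049]), 4) == 0.0188

    def test_pooled_is_ratio_of_sums_not_mean_of_ratios(self):
        mutations = [10, 0]
        nucleotides = [100, 900]
        pooled = pooled_frequency(mutations, nucleotides)
        assert pooled == pytest.approx(0.01)
        mean_of_ratios = np.mean([10 / 100, 0 / 900])
        assert pooled != pytest.approx(mean_of_ratios)

    def test_empty_denominator(self):
        assert pooled_frequency([], []) == 0.0


def two_member_group(rows, tissues=("THY", "THY")):
    rm = make_region_map(fr1=6, cdr1=21, fr2=6, cdr2=3, fr3=6, cdr3=6, j=6, c=3)
    members = [
        make_seq(row, seq_id=f"tV1_{t}{i:02d}_x", tissue=t, region_map=rm)
        for i, (row, t) in enumerate(zip(rows, tissues))
    ]
    return ClonalGroup("tV1.g1", "tV1", "I1", "", members)


BASE57 = "ACGTAC" + "GCA" * 7 + "GGTTAA" + "CCC" + "ATATAT" + "TGCAAA" + "GGTGGT" + "GGC"


class TestRegionTable:
    def test_single_cdr1_mutation_frequency(self):
        mutant = BASE57[:8] + "T" + BASE57[9:]  # column 8 is inside CDR1
        g = two_member_group([BASE57, mutant])
        a = analyze_group(g)
        table = region_frequency_table([a])
        row = table[(table.region == "CDR1")].iloc[0]
        assert row.total_nucleotides == 42  # 21 columns x 2 members
        assert row.total_mutations == 1
        assert row.freq_pct == pytest.approx(100 / 42)

    def test_zero_mutation_group_emits_zero_rows(self):
        g = two_member_group([BASE57, BASE57])
        table = region_frequency_table([analyze_group(g)])
        assert len(table) == 8
        assert (table.total_mutations == 0).all()
        assert (table.freq_pct == 0).all()

    def test_pooled_summary_is_count_ratio(self, default_bundle):
        table = default_bundle.tables["region_freq"]
        pooled = default_bundle.tables["region_pooled"]
        fr = pooled[pooled.region == "FR"].iloc[0]
        sub = table[table.region.isin(["FR1", "FR2", "FR3"])]
        assert fr.freq == pytest.approx(
            sub.total_mutations.sum() / sub.total_nucleotides.sum()
        )


class TestTandem:
    def test_published_scale_fractions(self):
        assert round(tandem_fraction(73, 192), 1) == 38.0
        assert round(tandem_fraction(41, 81), 1) == 50.6

    def test_zero_mutations_give_zero_not_nan(self):
        assert tandem_fraction(0, 0) == 0.0

    def test_run_plus_point(self):
        # three adjacent FR1 mutations plus one point mutation
        mutant = "TTT" + BASE57[3:8] + "T" + BASE57[9:]
        g = two_member_group([BASE57, mutant, BASE57], tissues=("THY",) * 3)
        a = analyze_group(g)
        table = tandem_table([a])
        total_fr = table[(table.group_id == "Total") & (table.region_class == "FR")].iloc[0]
        assert total_fr.runs2 == 0 and total_fr.runs3 == 1
        assert total_fr.tandem_bases == 3
        assert total_fr.all_mutations == 3
        total_cdr = table[(table.group_id == "Total") & (table.region_class == "CDR")].iloc[0]
        assert total_cdr.all_mutations == 1
        assert total_cdr.tandem_freq_pct == 0.0


def call(cons, obs, region="FR1", seq_id="s", column=0, effect=SYN, in_hotspot=False):
    return MutationCall(
        seq_id=seq_id, column=column, consensus_base=cons, observed_base=obs,
        region=region, effect=effect,
        base_class="GC" if cons in "GC" else "AT", in_hotspot=in_hotspot,
    )


class TestSpectrum:
    def test_transition_fraction(self):
        calls = [call("G", "A"), call("C", "T"), call("A", "C")]
        spec = substitution_spectrum(calls)
        assert spec["transition_pct"] == pytest.approx(100 * 2 / 3)
        assert spec["gc_mutation_pct"] == pytest.approx(100 * 2 / 3)

    def test_ca_gt_transversions(self):
        spec = substitution_spectrum([call("G", "T")])
        assert spec["ca_gt_transversion_pct"] == 100.0
        assert spec["transition_pct"] == 0.0

    def test_empty(self):
        assert substitution_spectrum([])["n"] == 0

    def test_transition_bias_recovery(self):
        """Simulated 2:1 transition bias is recovered from the call spectrum."""
        from shmscope.simulate import SimulationConfig, generate_dataset

        cfg = SimulationConfig(seed=88, n_founders=50, members_min=5, members_max=5)
        bundle = analyze_sequences(generate_dataset(cfg).sequences)
        spec = bundle.summary["substitution_spectrum"]
        assert spec["n"] > 1500
        assert spec["transition_pct"] == pytest.approx(50.0, abs=5.0)


class TestTissue:
    def test_identical_tissue_compositions_give_half_p(self):
        groups = []
        for i in range(3):
            mutant = BASE57[:1] + "G" + BASE57[2:]
            g = two_member_group([BASE57, mutant, BASE57, mutant],
                                 tissues=("THY", "THY", "PBL", "PBL"))
            g = ClonalGroup(f"g{i}", "tV1", "I1", "", g.members)
            groups.append(analyze_group(g))
        table, tests = tissue_stratified_table(groups)
        assert tests["FR"] == pytest.approx(0.5)

    def test_single_group_class_skips_test(self, caplog):
        g = two_member_group([BASE57, BASE57], tissues=("THY", "THY"))
        with caplog.at_level("WARNING"):
            _, tests = tissue_stratified_table([analyze_group(g)])
        assert np.isnan(tests["FR"])
        assert "skipped" in caplog.text

    def test_counts_split_by_tissue(self):
        mutant = BASE57[:1] + "G" + BASE57[2:]  # one FR1 mutation on the PBL member
        g = two_member_group([BASE57, BASE57, mutant], tissues=("THY", "THY", "PBL"))
        table, _ = tissue_stratified_table([analyze_group(g)])
        per = table[(table.tissue_class == "periphery")
                    & (table.region_class == "FR")
                    & (table.mutation_type == "ALL")].iloc[0]
        thy = table[(table.tissue_class == "thymus")
                    & (table.region_class == "FR")
                    & (table.mutation_type == "ALL")].iloc[0]
        assert per.mutations == 1 and thy.mutations == 0
        assert per.total_nucleotides == 18  # FR columns x 1 member
        assert thy.total_nucleotides == 36


class TestCompareCdrFr:
    def build_groups(self, cdr_heavy: bool, n=4):
        analyses = []
        for i in range(n):
            if cdr_heavy:
                mutant = BASE57[:8] + "T" + BASE57[9:10] + "G" + BASE57[11:]
            else:
                mutant = BASE57
            g = two_member_group([BASE57, mutant, BASE57])
            g = ClonalGroup(f"g{i}", "tV1", "I1", "", g.members)
            analyses.append(analyze_group(g))
        return analyses

    def test_strong_cdr_excess_is_significant(self):
        assert compare_cdr_fr(self.build_groups(cdr_heavy=True))["ALL"] < 0.05

    def test_identical_frequencies_give_half(self):
        assert compare_cdr_fr(self.build_groups(cdr_heavy=False))["ALL"] == pytest.approx(0.5)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            compare_cdr_fr(self.build_groups(cdr_heavy=True, n=1))
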
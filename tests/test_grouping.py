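import random

import pytest

from shmscope.grouping import (
    count_unique_joins,
    extract_cdr3j_key,
    group_by_cdr3j,
    infer_junction_boundaries,
    assign_families_by_identity,
    JunctionBoundary,
)

from conftest import make_region_map, make_seq


def seq_with_key(cdr3, j, seq_id="tV1_THY01_x", individual="I1", fr2=None):
    """39-column toy sequence with controlled CDR3 (6 cols) and J (6 cols)."""
    assert len(cdr3) == 6 and len(j) == 6
    body = "ACGTAC" + "GCA" + (fr2 or "GGTTAA") + "CCC" + "ATATAT"
    return make_seq(body + cdr3 + j + "GGC", seq_id=seq_id, individual=individual)


class TestCdr3jKey:
    def test_gap_stripping(self):
        rm = make_region_map(cdr3=5, j=3, c=2)
        residues = "A" * 24 + "TG-CA" + "GGT" + "CC"
        seq = make_seq(residues, region_map=rm)
        assert extract_cdr3j_key(seq) == "TGCAGGT"

    def test_all_gap_interval_gives_empty_key(self):
        seq = seq_with_key("------", "------")
        assert extract_cdr3j_key(seq) == ""

    def test_key_ignores_v_segment_columns(self):
        a = seq_with_key("TGCAAA", "GGTGGT", fr2="GGTTAA")
        b = seq_with_key("TGCAAA", "GGTGGT", fr2="GGTTCC")
        assert extract_cdr3j_key(a) == extract_cdr3j_key(b)


class TestGrouping:
    def make_seqs(self):
        keys = [("TGCAAA", "GGTGGT")] * 3 + [("TGCCCC", "GGTGGT"), ("TGCGGG", "GGTGGT")]
        return [
            seq_with_key(c, j, seq_id=f"tV1_THY{i:02d}_x") for i, (c, j) in enumerate(keys)
        ]

    def test_exact_partition(self):
        groups, singles = group_by_cdr3j(self.make_seqs())
        assert len(groups) == 1 and groups[0].size == 3
        assert len(singles) == 2

    def test_same_key_different_individuals_not_merged(self):
        seqs = [
            seq_with_key("TGCAAA", "GGTGGT", seq_id="tV1_THY01_x", individual="I1"),
            seq_with_key("TGCAAA", "GGTGGT", seq_id="tV1_THY02_x", individual="I2"),
        ]
        groups, singles = group_by_cdr3j(seqs)
        assert groups == [] and len(singles) == 2

    def test_permutation_invariance(self):
        seqs = self.make_seqs()
        base_groups, base_singles = group_by_cdr3j(seqs)
        base_partition = {frozenset(m.seq_id for m in g.members) for g in base_groups}
        rng = random.Random(3)
        for _ in range(5):
            shuffled = seqs[:]
            rng.shuffle(shuffled)
            groups, singles = group_by_cdr3j(shuffled)
            assert {frozenset(m.seq_id for m in g.members) for g in groups} == base_partition
            assert {s.seq_id for s in singles} == {s.seq_id for s in base_singles}

    def test_group_members_share_key_and_family(self, default_bundle):
        for g in default_bundle.groups:
            assert {m.family_id for m in g.members} == {g.family_id}
            assert {extract_cdr3j_key(m) for m in g.members} == {g.cdr3j_key}

    def test_zero_shm_recovers_truth_partition_exactly(self):
        from shmscope.simulate import SimulationConfig, generate_dataset

        ds = generate_dataset(
            SimulationConfig(seed=21, n_founders=50, per_base_rate=0.0,
                             insertion_prob=0.0)
        )
        truth = {}
        for row in ds.truth.lineages.itertuples():
            truth.setdefault(row.founder_id, set()).add(row.seq_id)
        groups, singles = group_by_cdr3j(ds.sequences)
        recovered = {frozenset(m.seq_id for m in g.members) for g in groups}
        recovered |= {frozenset({s.seq_id}) for s in singles}
        assert recovered == {frozenset(v) for v in truth.values()}

    def test_default_shm_grouping_refines_truth(self, default_dataset):
        # CDR3-J protection on: groups must still match truth founders exactly
        truth = {}
        for row in default_dataset.truth.lineages.itertuples():
            truth.setdefault(row.founder_id, set()).add(row.seq_id)
        groups, singles = group_by_cdr3j(default_dataset.sequences)
        recovered = {frozenset(m.seq_id for m in g.members) for g in groups}
        recovered |= {frozenset({s.seq_id}) for s in singles}
        assert recovered == {frozenset(v) for v in truth.values()}


class TestJunctionBoundaries:
    def build(self, a_row, b_row, rm):
        return [
            make_seq(a_row, seq_id="tV1_THY01_x", individual="I1", region_map=rm),
            make_seq(a_row, seq_id="tV1_THY02_x", individual="I1", region_map=rm),
            make_seq(b_row, seq_id="tV1_SPV01_x", individual="I2", region_map=rm),
            make_seq(b_row, seq_id="tV1_SPV02_x", individual="I2", region_map=rm),
        ]

    def test_constructed_divergent_block(self):
        # identical through col 19, divergent 20-27, identical 28-39
        rm = make_region_map(fr1=6, cdr1=3, fr2=6, cdr2=3, fr3=2, cdr3=8, j=8, c=3)
        shared_v = "ACGTACGCAGGTTAACCCAT"  # 20 cols
        shared_j = "TTAAGGCCTTAA"  # cols 28..39
        a = shared_v + "AAAAAAAA"[:8] + shared_j[:12]
        b = shared_v + "CCCCCCCC"[:8] + shared_j[:12]
        seqs = self.build(a[:39], b[:39], rm)
        boundary = infer_junction_boundaries(seqs)
        assert boundary.v_end == 20
        assert boundary.j_start == 28

    def test_identical_everywhere_falls_back_to_cdr3_start(self):
        rm = make_region_map()
        row = "ACGTACGCAGGTTAACCCATATATTGCAAAGGTGGTGGC"
        seqs = self.build(row, row, rm)
        boundary = infer_junction_boundaries(seqs)
        cdr3_start = rm.interval("CDR3")[0]
        assert boundary.v_end == boundary.j_start == cdr3_start

    def test_single_individual_is_an_error(self):
        seqs = [
            seq_with_key("TGCAAA", "GGTGGT", seq_id="tV1_THY01_x"),
            seq_with_key("TGCAAA", "GGTGGT", seq_id="tV1_THY02_x"),
        ]
        with pytest.raises(ValueError, match="germline boundary"):
            infer_junction_boundaries(seqs)

    def test_simulated_trim_point_recovery(self):
        """Regression band measured on this estimator: junction N-base
        coincidences between individuals cap accuracy below perfect."""
        from shmscope.simulate import SimulationConfig, generate_dataset

        ok = tot = 0
        rep = 0
        while tot < 100:
            cfg = SimulationConfig(seed=7000 + rep, n_founders=2, n_v_genes=1,
                                   n_j_genes=1, n_individuals=2)
            rep += 1
            ds = generate_dataset(cfg)
            lin = ds.truth.lineages
            for fam, rm in ds.region_maps.items():
                seqs = [s for s in ds.sequences if s.family_id == fam]
                if len({s.individual_id for s in seqs}) < 2:
                    continue
                sub = lin[lin.family_id == fam].drop_duplicates("founder_id")
                total_ins = rm.interval("FR3")[1] - (cfg.v_length_nt - 9)
                v_cov = sub.groupby("individual_id").v_trim.min()
                truth_v = sorted(
                    (cfg.v_length_nt - t for t in v_cov), reverse=True
                )[1] + total_ins
                j_cov = sub.groupby("individual_id").j_trim.min()
                truth_j = rm.interval("J")[0] + sorted(j_cov)[1]
                b = infer_junction_boundaries(seqs)
                tot += 1
                if abs(b.v_end - truth_v) <= 2 and abs(b.j_start - truth_j) <= 2:
                    ok += 1
        assert ok / tot >= 0.85


class TestUniqueJoins:
    def test_counts_and_range(self):
        rm = make_region_map()
        boundary = JunctionBoundary("tV1", 24, 30)
        rows = {
            "a": "------",  # empty join
            "b": "A-----",
            "c": "A-----",
            "d": "GGT---",
        }
        seqs = [
            make_seq("ACGTACGCAGGTTAACCCATATAT" + join + "GGTGGTGGCAAAAAA"[:15],
                     seq_id=f"tV1_THY0{i}_x", region_map=rm)
            for i, join in enumerate(rows.values())
        ]
        stats = count_unique_joins(seqs, boundary)
        assert stats.n_total == 4
        assert stats.n_unique == 3
        assert stats.fraction_unique == pytest.approx(0.75)
        assert stats.length_range == (0, 3)

    def test_all_identical_joins(self):
        rm = make_region_map()
        boundary = JunctionBoundary("tV1", 24, 30)
        seqs = [
            make_seq("A" * 39, seq_id=f"tV1_THY0{i}_x", region_map=rm)
            for i in range(5)
        ]
        stats = count_unique_joins(seqs, boundary)
        assert stats.n_unique == 1
        assert stats.fraction_unique == pytest.approx(1 / 5)

    @staticmethod
    def raw_join_fraction(np_max, seed, n=200):
        """Unique-junction fraction over independent rearrangements of one V-J
        pair (no dataset-level collision rejection)."""
        import numpy as np

        from shmscope.simulate import (
            SimulationConfig, make_germline_locus, simulate_rearrangement,
        )

        cfg = SimulationConfig(seed=seed, n_v_genes=1, n_j_genes=1, np_max=np_max)
        rng = np.random.default_rng(seed)
        locus = make_germline_locus(cfg, rng)
        joins = [
            simulate_rearrangement(locus, cfg, rng, i).naive[cfg.v_length_nt - 9 :]
            for i in range(n)
        ]
        return len(set(joins)) / len(joins)

    def test_uniqueness_rises_with_np_length(self):
        """More non-templated bases -> more distinct junctions."""
        fractions = [self.raw_join_fraction(np_max, seed=31) for np_max in (1, 6, 12)]
        assert fractions[0] < fractions[1] < fractions[2]

    def test_default_conditions_mostly_unique_junctions(self):
        """At default trimming and N/P lengths most junctions are unique."""
        assert self.raw_join_fraction(12, seed=37) >= 0.6


class TestIdentityClustering:
    def flat_map(self):
        # one-region map so V interval spans the whole 100-column alignment
        from shmscope.io import RegionMap

        return RegionMap(
            "tV1",
            (("FR1", 0, 30), ("CDR1", 30, 36), ("FR2", 36, 60), ("CDR2", 60, 66),
             ("FR3", 66, 90), ("CDR3", 90, 94), ("J", 94, 98), ("C", 98, 100)),
        )

    def mutate(self, base, positions):
        swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
        out = list(base)
        for p in positions:
            out[p] = swap[out[p]]
        return "".join(out)

    def test_identical_sequences_cluster_together(self):
        rm = self.flat_map()
        base = ("ACGT" * 25)
        seqs = [
            make_seq(base, seq_id=f"tV1_THY0{i}_x", region_map=rm) for i in range(2)
        ]
        labels = assign_families_by_identity(seqs)
        fams = {labels[s.seq_id] for s in seqs}
        assert len(fams) == 1

    def test_threshold_straddle(self):
        # V interval is 90 columns; 12 mismatches -> 86.7% identity:
        # same family (>=85%), different subfamilies (<90%)
        rm = self.flat_map()
        base = "ACGT" * 25
        other = self.mutate(base, range(12))
        seqs = [
            make_seq(base, seq_id="tV1_THY01_x", region_map=rm),
            make_seq(other, seq_id="tV1_THY02_x", region_map=rm),
        ]
        labels = assign_families_by_identity(seqs)
        (fam_a, sub_a), (fam_b, sub_b) = labels["tV1_THY01_x"], labels["tV1_THY02_x"]
        assert fam_a == fam_b
        assert sub_a != sub_b

    def test_transitive_merge_matches_brute_force(self):
        # A~B and B~C above threshold, A~C far below: single linkage
        # chains all three into one family.
        rm = self.flat_map()
        base = "ACGT" * 25
        a = base
        b = self.mutate(base, range(0, 12))       # A~B 86.7%
        c = self.mutate(b, range(12, 24))          # B~C 86.7%, A~C 73.3%
        seqs = [
            make_seq(s, seq_id=f"tV1_THY0{i}_x", region_map=rm)
            for i, s in enumerate((a, b, c))
        ]
        labels = assign_families_by_identity(seqs)
        assert len({labels[s.seq_id][0] for s in seqs}) == 1

        # brute-force check of the pairwise identities driving the merge
        def identity(x, y):
            cols = [(p, q) for p, q in zip(x[:90], y[:90]) if p != "-" and q != "-"]
            return sum(p == q for p, q in cols) / len(cols)

        assert identity(a, b) >= 0.85
        assert identity(b, c) >= 0.85
        assert identity(a, c) < 0.85
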
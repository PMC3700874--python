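"""OTU binning, rarefaction, subsampling and shared-richness accounting."""

import math

import numpy as np
import pandas as pd
import pytest

from aquibiome import otu as om
from aquibiome.synthetic_data import gen_sequences


def brute_force_average_linkage(ids, dist, cutoff):
    """Naive UPGMA oracle: merge the closest cluster pair while its
    average inter-cluster distance stays at or below the cutoff."""
    clusters = [{i} for i in range(len(ids))]

    def avg(ca, cb):
        return np.mean([dist[i, j] for i in ca for j in cb])

    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                d = avg(clusters[x], clusters[y])
                if best is None or d < best[0]:
                    best = (d, x, y)
        if best[0] > cutoff:
            break
        _, x, y = best
        clusters[x] = clusters[x] | clusters[y]
        del clusters[y]
    return {frozenset(ids[i] for i in c) for c in clusters}


def partition_from_assignment(assignment):
    groups = {}
    for sid, otu_id in assignment.items():
        groups.setdefault(otu_id, set()).add(sid)
    return {frozenset(g) for g in groups.values()}


class TestFastaIO:
    def test_read_two_records(self, tmp_path):
        p = tmp_path / "two.fa"
        p.write_text(">Chm94B_ATT|c1\nACGT\n>Chm94B_ATT|c2\nacgtt\n")
        recs = om.read_fasta(p)
        assert [r.id for r in recs] == ["Chm94B_ATT|c1", "Chm94B_ATT|c2"]
        assert recs[0].sample_id == "Chm94B_ATT"
        assert recs[1].residues == "ACGTT"  # uppercased

    def test_round_trip_identity(self, tmp_path):
        recs, _ = gen_sequences(3, 4, 0.02, 0.3, length=60, seed=5,
                                sample_cycle=("s1", "s2"))
        p = tmp_path / "rt.fa"
        om.write_fasta(recs, p)
        again = om.read_fasta(p, sample_pattern=r"^(?P<sample>$)")
        assert [(r.id, r.residues) for r in again] == [
            (r.id, r.residues) for r in recs
        ]

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">a|1\nACGT\n>a|1\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            om.read_fasta(p)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            om.SequenceRecord("x", "s", "")


class TestPairwiseDistance:
    def test_identity_and_simple_mismatch(self):
        assert om.pairwise_distance("ACGT", "ACGT") == 0.0
        assert om.pairwise_distance("ACGT", "ACGA") == pytest.approx(0.25)

    def test_symmetry_on_random_pairs(self, rng):
        bases = np.array(list("ACGT-"))
        for _ in range(20):
            a = "".join(rng.choice(bases, size=30))
            b = "".join(rng.choice(bases, size=30))
            if set(a) == {"-"} or set(b) == {"-"}:
                continue
            for mode in ("aligned", "global"):
                assert om.pairwise_distance(a, b, mode) == pytest.approx(
                    om.pairwise_distance(b, a, mode)
                )

    def test_gap_columns_convention(self):
        # gap-gap ignored; gap-base counts as a difference
        assert om.pairwise_distance("A-C-", "A-CG") == pytest.approx(1 / 3)

    def test_aligned_length_mismatch(self):
        with pytest.raises(ValueError, match="equal lengths"):
            om.pairwise_distance("ACGT", "ACG")

    def test_global_mode_counts_indels(self):
        # NW of ACGT vs ACG: one terminal gap over 4 columns
        assert om.pairwise_distance("ACGT", "ACG", mode="global") == pytest.approx(
            0.25
        )


class TestClustering:
    def test_identical_sequences_one_otu(self):
        recs = [om.SequenceRecord(f"s{i}", "lib1", "ACGTACGT") for i in range(5)]
        table, assignment = om.cluster_average_neighbor(recs)
        assert len(table.otus) == 1
        assert table.counts.iloc[0, 0] == 5
        assert len(set(assignment.values())) == 1

    def test_separated_pair_stays_apart(self):
        a = om.SequenceRecord("a", "lib1", "A" * 10)
        b = om.SequenceRecord("b", "lib1", "A" * 9 + "C")  # d = 0.1 > 0.03
        table, _ = om.cluster_average_neighbor([a, b], cutoff=0.03)
        assert len(table.otus) == 2

    def test_cutoff_extremes(self):
        recs = [
            om.SequenceRecord("a", "l", "AAAA"),
            om.SequenceRecord("b", "l", "AAAA"),
            om.SequenceRecord("c", "l", "CCCC"),
        ]
        t0, _ = om.cluster_average_neighbor(recs, cutoff=0.0)
        assert len(t0.otus) == 2  # one OTU per distinct sequence
        t1, _ = om.cluster_average_neighbor(recs, cutoff=1.0)
        assert len(t1.otus) == 1

    def test_richness_non_increasing_in_cutoff(self):
        recs, _ = gen_sequences(4, 5, 0.02, 0.2, length=120, seed=9)
        richness = [
            len(om.cluster_average_neighbor(recs, cutoff=c)[0].otus)
            for c in (0.0, 0.01, 0.05, 0.2, 1.0)
        ]
        assert richness == sorted(richness, reverse=True)

    def test_planted_partition_recovered(self):
        recs, truth = gen_sequences(
            5, 6, within_divergence=0.01, between_divergence=0.10,
            length=200, seed=11, sample_cycle=("s1", "s2", "s3"),
        )
        table, assignment = om.cluster_average_neighbor(recs, cutoff=0.03)
        planted = {}
        for sid, c in truth.items():
            planted.setdefault(c, set()).add(sid)
        assert partition_from_assignment(assignment) == {
            frozenset(g) for g in planted.values()
        }
        assert table.library_sizes().sum() == 30

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_upgma_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        length = 40
        bases = np.array(list("ACGT"))
        recs = []
        anchor = rng.integers(0, 4, size=length)
        for i in range(n):
            seq = anchor.copy()
            k = rng.integers(0, 6)
            sites = rng.choice(length, size=k, replace=False)
            seq[sites] = (seq[sites] + rng.integers(1, 4, size=k)) % 4
            recs.append(om.SequenceRecord(f"s{i:02d}", "lib", "".join(bases[seq])))
        d = om.distance_matrix(recs)
        cutoff = 0.05
        expected = brute_force_average_linkage([r.id for r in recs], d, cutoff)
        _, assignment = om.cluster_average_neighbor(recs, cutoff=cutoff)
        assert partition_from_assignment(assignment) == expected

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            om.cluster_average_neighbor(
                [om.SequenceRecord("a", "l", "ACGT")], cutoff=1.5
            )


class TestCollectorsCurve:
    def test_degenerate_pools(self):
        constant = om.collectors_curve([7], seed=0)
        assert constant == [(k, 1) for k in range(1, 8)]
        diagonal = om.collectors_curve([1, 1, 1, 1], seed=0)
        assert diagonal == [(k, k) for k in range(1, 5)]

    def test_monotone_and_final_richness(self, rng):
        counts = rng.integers(0, 10, size=25)
        counts[0] = 3
        curve = om.collectors_curve(counts, seed=4)
        vals = [v for _, v in curve]
        assert vals == sorted(vals)
        assert vals[-1] == int((counts > 0).sum())

    def test_mean_over_shuffles_matches_rarefaction(self):
        counts = [10, 5, 3, 1, 1]
        depth = 8
        means = []
        for s in range(100):
            curve = om.collectors_curve(counts, seed=s)
            means.append(curve[depth - 1][1])
        expected = om.expected_richness(counts, depth)
        se = np.std(means, ddof=1) / math.sqrt(len(means))
        assert np.mean(means) == pytest.approx(expected, abs=3 * se + 1e-9)


class TestSubsample:
    def _table(self):
        counts = pd.DataFrame(
            {"OTU_1": [12, 3], "OTU_2": [0, 8], "OTU_3": [5, 5]},
            index=["s1", "s2"],
        )
        return om.OtuTable(counts)

    def test_full_depth_preserves_pool(self):
        table = self._table()
        sub = om.subsample_table(table, ["s1", "s2"], depth=33, seed=1)
        assert sub.pooled_counts().sum() == 33
        assert (
            sub.counts.iloc[0].reindex(table.otus, fill_value=0)
            == table.pooled_counts()
        ).all()

    def test_richness_never_increases(self):
        table = self._table()
        for seed in range(10):
            sub = om.subsample_table(table, ["s1", "s2"], depth=5, seed=seed)
            assert sub.richness() <= table.richness()

    def test_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            om.subsample_table(self._table(), ["s1"], depth=1000, seed=0)

    def test_seed_reproducibility(self):
        table = self._table()
        a = om.subsample_table(table, ["s1", "s2"], depth=10, seed=42)
        b = om.subsample_table(table, ["s1", "s2"], depth=10, seed=42)
        pd.testing.assert_frame_equal(a.counts, b.counts)

    def test_mean_richness_matches_rarefaction_closed_form(self):
        counts = pd.DataFrame(
            [[20, 9, 4, 2, 1, 1, 0, 3]], index=["s1"],
            columns=[f"OTU_{i}" for i in range(8)],
        )
        counts = counts.loc[:, counts.sum() > 0]
        table = om.OtuTable(counts)
        depth = 12
        rich = [
            om.subsample_table(table, ["s1"], depth, seed=s).richness()
            for s in range(200)
        ]
        expected = om.expected_richness(table.pooled_counts(), depth)
        se = np.std(rich, ddof=1) / math.sqrt(len(rich))
        assert np.mean(rich) == pytest.approx(expected, abs=2 * se)


class TestSharedRichness:
    def test_disjoint_and_identical(self):
        counts = pd.DataFrame(
            {"OTU_1": [4, 0], "OTU_2": [0, 6]}, index=["a", "b"]
        )
        got = om.shared_richness(om.OtuTable(counts), ["a"], ["b"])
        assert got["shared_otus"] == 0
        assert got["pct_seqs_in_shared_a"] == 0.0

        same = pd.DataFrame({"OTU_1": [4, 4], "OTU_2": [6, 6]}, index=["a", "b"])
        got = om.shared_richness(om.OtuTable(same), ["a"], ["b"])
        assert got["pct_otus_shared_a"] == 100.0
        assert got["pct_seqs_in_shared_b"] == 100.0

    def test_hand_counted_example(self):
        counts = pd.DataFrame(
            {"OTU_1": [5, 0], "OTU_2": [5, 2], "OTU_3": [0, 8]},
            index=["A", "B"],
        )
        got = om.shared_richness(om.OtuTable(counts), ["A"], ["B"])
        assert got == {
            "otus_a": 2, "otus_b": 2, "shared_otus": 1,
            "pct_otus_shared_a": 50.0, "pct_otus_shared_b": 50.0,
            "pct_seqs_in_shared_a": 50.0, "pct_seqs_in_shared_b": 20.0,
        }

    def test_symmetry_under_group_swap(self):
        counts = pd.DataFrame(
            {"OTU_1": [5, 1], "OTU_2": [2, 2], "OTU_3": [0, 8]},
            index=["A", "B"],
        )
        t = om.OtuTable(counts)
        ab = om.shared_richness(t, ["A"], ["B"])
        ba = om.shared_richness(t, ["B"], ["A"])
        assert ab["otus_a"] == ba["otus_b"]
        assert ab["pct_seqs_in_shared_a"] == ba["pct_seqs_in_shared_b"]

    def test_overlapping_groups_rejected(self):
        counts = pd.DataFrame({"OTU_1": [1, 1]}, index=["A", "B"])
        with pytest.raises(ValueError, match="overlap"):
            om.shared_richness(om.OtuTable(counts), ["A"], ["A", "B"])
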
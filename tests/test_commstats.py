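"""Bray-Curtis, ANOSIM, SIMPER and NMDS against independent oracles."""

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import braycurtis as scipy_bc
from scipy.stats import rankdata

from aquibiome import commstats as cs
from aquibiome.otu import OtuTable
from aquibiome.synthetic_data import CommunitySpec, gen_otu_table


def random_table(rng, n_samples=6, n_otus=12):
    counts = rng.integers(0, 30, size=(n_samples, n_otus))
    counts[:, 0] += 1  # no all-zero samples
    df = pd.DataFrame(
        counts,
        index=[f"s{i}" for i in range(n_samples)],
        columns=[f"OTU_{j}" for j in range(n_otus)],
    )
    df = df.loc[:, df.sum() > 0]
    return OtuTable(df)


class TestBrayCurtis:
    def test_identical_and_disjoint_rows(self):
        counts = pd.DataFrame(
            {"OTU_1": [3, 3, 0], "OTU_2": [1, 1, 0], "OTU_3": [0, 0, 9]},
            index=["a", "b", "c"],
        )
        dm = cs.bray_curtis(OtuTable(counts))
        assert dm.values[0, 1] == pytest.approx(0.0)
        assert dm.values[0, 2] == pytest.approx(1.0)

    def test_hand_example(self):
        df = pd.DataFrame([[1, 2, 0], [3, 0, 0]], index=["x", "y"],
                          columns=["o1", "o2", "o3"])
        dm = cs.bray_curtis(df)
        assert dm.values[0, 1] == pytest.approx(2.0 / 3.0)

    def test_matches_scipy_on_random_tables(self, rng):
        table = random_table(rng)
        dm = cs.bray_curtis(table)
        x = table.counts.to_numpy(float)
        for i in range(x.shape[0]):
            for j in range(x.shape[0]):
                assert dm.values[i, j] == pytest.approx(
                    0.0 if i == j else scipy_bc(x[i], x[j]), abs=1e-12
                )

    def test_invariant_under_count_scaling_after_normalization(self, rng):
        table = random_table(rng)
        rel = table.relative_abundance()
        scaled = table.counts.mul([1, 10, 3, 7, 2, 5], axis=0)
        rel_scaled = scaled.div(scaled.sum(axis=1), axis=0)
        np.testing.assert_allclose(
            cs.bray_curtis(rel).values, cs.bray_curtis(rel_scaled).values,
            atol=1e-12,
        )

    def test_all_zero_sample_named(self):
        counts = pd.DataFrame({"OTU_1": [1, 0]}, index=["good", "bad"])
        table = OtuTable.__new__(OtuTable)  # bypass the table invariant
        table.counts = counts
        table.sample_meta = None
        table.otu_meta = None
        with pytest.raises(ValueError, match="bad"):
            cs.bray_curtis(table)


def brute_force_anosim(values, labels):
    """Exhaustive ANOSIM oracle: rank once, enumerate all distinct label
    assignments, count those with R at least the observed."""
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(values[iu])
    m = n * (n - 1) // 2

    def r_stat(lab):
        lab = np.asarray(lab)
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)

    observed = r_stat(labels)
    perms = sorted(set(itertools.permutations(labels)))
    count = sum(1 for p in perms if r_stat(p) >= observed - 1e-12)
    return observed, count / len(perms), len(perms)


class TestAnosim:
    def test_perfect_separation_gives_r_one(self):
        # distances: within < between everywhere
        n = 6
        labels = ["A"] * 3 + ["B"] * 3
        d = np.full((n, n), 0.9)
        for i in range(n):
            for j in range(n):
                if labels[i] == labels[j]:
                    d[i, j] = 0.1
        np.fill_diagonal(d, 0.0)
        dm = cs.DistanceMatrix(tuple("abcdef"), d)
        res = cs.anosim(dm, dict(zip("abcdef", labels)), n_perms=999, seed=0)
        assert res.R == pytest.approx(1.0)
        assert res.band is cs.AnosimBand.DISTINCT
        assert res.exhaustive  # 20 distinct assignments ≤ 999

    def test_two_groups_of_three_matches_exhaustive_oracle(self, rng):
        for _ in range(5):
            vals = np.zeros((6, 6))
            iu = np.triu_indices(6, k=1)
            v = rng.random(len(iu[0]))
            vals[iu] = v
            vals += vals.T
            labels = ["A", "A", "A", "B", "B", "B"]
            dm = cs.DistanceMatrix(tuple("abcdef"), vals)
            res = cs.anosim(dm, dict(zip("abcdef", labels)), n_perms=999, seed=1)
            r_exp, p_exp, n_exp = brute_force_anosim(vals, labels)
            assert res.exhaustive and res.n_perms == n_exp == 20
            assert res.R == pytest.approx(r_exp, abs=1e-12)
            assert res.p == pytest.approx(p_exp, abs=1e-12)

    def test_null_expectation_near_zero(self, rng):
        table = random_table(rng, n_samples=10, n_otus=30)
        dm = cs.bray_curtis(table)
        rs = []
        for s in range(40):
            perm = rng.permutation(["A"] * 5 + ["B"] * 5)
            res = cs.anosim(dm, dict(zip(dm.labels, perm)), n_perms=99, seed=s)
            rs.append(res.R)
        assert abs(np.mean(rs)) < 0.1

    def test_rank_invariance_under_monotone_transform(self, rng):
        table = random_table(rng, n_samples=8)
        dm = cs.bray_curtis(table)
        groups = dict(zip(dm.labels, ["A"] * 4 + ["B"] * 4))
        base = cs.anosim(dm, groups, n_perms=99, seed=7)
        squared = cs.DistanceMatrix(dm.labels, dm.values ** 2)
        rooted = cs.DistanceMatrix(dm.labels, np.sqrt(dm.values))
        for t in (squared, rooted):
            res = cs.anosim(t, groups, n_perms=99, seed=7)
            assert res.R == pytest.approx(base.R, abs=1e-12)

    def test_null_p_values_roughly_uniform(self):
        # under random labels p ≤ 0.05 should occur at about the 5% rate
        spec = CommunitySpec(
            n_wells={"HS": 2, "LS": 2, "NS": 2}, effects=(), n_otus=60,
            library_size=80,
        )
        hits = 0
        n_runs = 60
        for s in range(n_runs):
            table = gen_otu_table(dataclasses.replace(spec, seed=s))
            dm = cs.bray_curtis(table)
            groups = {
                smp: str(table.sample_meta.loc[smp, "fraction"])
                for smp in table.samples
            }
            res = cs.anosim(dm, groups, n_perms=199, seed=s)
            if res.p <= 0.05:
                hits += 1
        assert hits / n_runs <= 0.15

    def test_agrees_with_skbio(self, rng):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        table = random_table(rng, n_samples=8)
        dm = cs.bray_curtis(table)
        groups = ["A"] * 4 + ["B"] * 4
        ours = cs.anosim(dm, dict(zip(dm.labels, groups)), n_perms=999, seed=3)
        theirs = skbio_stats.anosim(
            skbio_stats.DistanceMatrix(dm.values, dm.labels),
            grouping=list(groups), permutations=999,
        )
        assert ours.R == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_singleton_group_rejected(self, rng):
        table = random_table(rng, n_samples=5)
        dm = cs.bray_curtis(table)
        with pytest.raises(ValueError, match="singleton"):
            cs.anosim(dm, dict(zip(dm.labels, ["A", "A", "A", "A", "B"])),
                      n_perms=99, seed=0)


class TestSimper:
    def test_single_discriminating_otu(self):
        # on raw counts the groups differ in exactly one OTU, which must
        # then account for all of the dissimilarity
        counts = pd.DataFrame(
            {"OTU_1": [10, 10, 10, 10], "OTU_2": [10, 10, 0, 0]},
            index=["a1", "a2", "b1", "b2"],
        )
        res = cs.simper(
            OtuTable(counts), ["a1", "a2"], ["b1", "b2"], normalize=False
        )
        assert res.table.index[0] == "OTU_2"
        assert res.table.loc["OTU_2", "percent"] == pytest.approx(100.0)
        # normalization spreads the compositional shift across both OTUs
        # equally here, so the contributions tie and split 50/50
        res_norm = cs.simper(OtuTable(counts), ["a1", "a2"], ["b1", "b2"])
        assert res_norm.table["percent"].to_numpy() == pytest.approx([50.0, 50.0])

    def test_identical_groups_degenerate(self):
        counts = pd.DataFrame(
            {"OTU_1": [5, 5, 5, 5], "OTU_2": [2, 2, 2, 2]},
            index=["a1", "a2", "b1", "b2"],
        )
        res = cs.simper(OtuTable(counts), ["a1", "a2"], ["b1", "b2"])
        assert res.degenerate
        assert res.total_dissimilarity == pytest.approx(0.0)
        assert res.table["percent"].isna().all()

    def test_hand_computed_pair_average(self):
        # 2 samples per group, 3 OTUs; oracle: average |x-y|/sum over the
        # 4 cross pairs of relative-abundance rows
        counts = pd.DataFrame(
            [[6, 3, 1], [5, 4, 1], [1, 2, 7], [2, 2, 6]],
            index=["a1", "a2", "b1", "b2"], columns=["o1", "o2", "o3"],
        )
        table = OtuTable(counts)
        rel = table.relative_abundance()
        expected = np.zeros(3)
        for i in ["a1", "a2"]:
            for j in ["b1", "b2"]:
                x, y = rel.loc[i].to_numpy(), rel.loc[j].to_numpy()
                expected += np.abs(x - y) / (x + y).sum()
        expected /= 4
        res = cs.simper(table, ["a1", "a2"], ["b1", "b2"])
        got = res.table["contribution"].reindex(["o1", "o2", "o3"]).to_numpy()
        np.testing.assert_allclose(got, expected, atol=1e-15)

    def test_contributions_conserve_bray_curtis(self, rng):
        table = random_table(rng, n_samples=6, n_otus=15)
        rel = table.relative_abundance()
        ga, gb = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        res = cs.simper(table, ga, gb)
        dm = cs.bray_curtis(rel)
        pair_bc = [
            dm.values[dm.labels.index(i), dm.labels.index(j)]
            for i in ga for j in gb
        ]
        assert res.total_dissimilarity == pytest.approx(
            np.mean(pair_bc), abs=1e-12
        )
        assert res.table["percent"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_overlapping_groups_rejected(self, toy_table):
        with pytest.raises(ValueError, match="overlap"):
            cs.simper(toy_table, ["a1", "a2"], ["a2", "b1"])


class TestNmds:
    def test_euclidean_square_embeds_with_low_stress(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = cs.DistanceMatrix(("a", "b", "c", "d"), d)
        res = cs.nmds(dm, n_restarts=10, seed=0)
        assert res.stress < 0.01

    def test_stress_history_monotone_non_increasing(self, rng):
        table = random_table(rng, n_samples=7)
        dm = cs.bray_curtis(table)
        res = cs.nmds(dm, n_restarts=5, seed=2)
        hist = np.array(res.stress_history)
        assert (np.diff(hist) <= 1e-12).all()

    def test_two_cluster_geometry_recovered(self):
        # 8 samples, two tight clusters
        n = 8
        d = np.full((n, n), 0.9)
        for i in range(n):
            for j in range(n):
                if (i < 4) == (j < 4):
                    d[i, j] = 0.02 + 0.005 * abs(i - j)
                else:
                    d[i, j] = 0.9 + 0.005 * ((i + j) % 4)
        np.fill_diagonal(d, 0.0)
        d = (d + d.T) / 2
        labels = tuple(f"s{i}" for i in range(n))
        dm = cs.DistanceMatrix(labels, d)
        res = cs.nmds(dm, n_restarts=10, seed=1)
        coords = res.coordinates.to_numpy()
        cd = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        within = [cd[i, j] for i in range(n) for j in range(n)
                  if i < j and (i < 4) == (j < 4)]
        between = [cd[i, j] for i in range(n) for j in range(n)
                   if i < j and (i < 4) != (j < 4)]
        assert max(within) < min(between)

        sklearn_manifold = pytest.importorskip("sklearn.manifold")
        ref = sklearn_manifold.MDS(
            n_components=2, metric=False, dissimilarity="precomputed",
            random_state=0, n_init=4, normalized_stress=False,
        ).fit_transform(d)
        rd = np.linalg.norm(ref[:, None] - ref[None, :], axis=-1)
        r_within = [rd[i, j] for i in range(n) for j in range(n)
                    if i < j and (i < 4) == (j < 4)]
        r_between = [rd[i, j] for i in range(n) for j in range(n)
                     if i < j and (i < 4) != (j < 4)]
        assert max(r_within) < min(r_between)  # same grouping as reference

    def test_too_few_samples_rejected(self):
        dm = cs.DistanceMatrix(("a", "b", "c"), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="at least 4"):
            cs.nmds(dm)
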
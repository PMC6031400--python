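"""Clustering, coverage, rarefaction, overlap and novelty statistics."""

import collections

import numpy as np
import pandas as pd
import pytest

from ureotype.otu_pipeline import (OTU, ReadSet, Unique, build_otu_table,
                                   dereplicate, diversity_stats,
                                   goods_coverage, greedy_cluster,
                                   novelty_classification, quality_filter,
                                   rank_otus, rarefaction, shared_otus)
from ureotype.threshold_calibration import pairwise_identity

from conftest import mutate_seq
from oracles import greedy_replay, rarefaction_subsampling


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestQualityFilter:
    def test_clean_reads_pass_unchanged(self, rng):
        rs = ReadSet("s", [(f"r{i}", random_seq(rng, 250)) for i in range(10)])
        out, log = quality_filter(rs, min_len=200)
        assert out.reads == rs.reads
        assert log["retained"] == 10 and log["too_short"] == 0

    def test_all_removed_when_min_len_too_high(self, rng):
        rs = ReadSet("s", [(f"r{i}", random_seq(rng, 100)) for i in range(5)])
        with pytest.warns(UserWarning, match="no reads"):
            out, log = quality_filter(rs, min_len=200)
        assert out.reads == [] and log["too_short"] == 5

    def test_mixed_violations_accounted(self, rng):
        good = [(f"g{i}", random_seq(rng, 300)) for i in range(6)]
        short = [(f"s{i}", random_seq(rng, 50)) for i in range(3)]
        enned = [(f"n{i}", "N" * 30 + random_seq(rng, 270)) for i in range(2)]
        rs = ReadSet("s", good + short + enned)
        out, log = quality_filter(rs, min_len=200, max_n_fraction=0.05)
        assert log == {"input": 11, "too_short": 3, "too_many_n": 2,
                       "retained": 6}
        assert len(out.reads) == 6


class TestDereplicate:
    def test_identical_reads_collapse(self, rng):
        seq = random_seq(rng, 100)
        rs = ReadSet("s", [(f"r{i}", seq) for i in range(7)])
        uniq = dereplicate(rs)
        assert len(uniq) == 1 and uniq[0].size == 7

    def test_distinct_reads_stay_apart(self, rng):
        rs = ReadSet("s", [(f"r{i}", random_seq(rng, 100)) for i in range(6)])
        uniq = dereplicate(rs)
        assert [u.size for u in uniq] == [1] * 6
        assert [u.sequence for u in uniq] == sorted(u.sequence for u in uniq)

    def test_sizes_match_hash_count_oracle(self, rng):
        pool = [random_seq(rng, 60) for _ in range(5)]
        reads = [(f"r{i}", pool[int(rng.integers(0, 5))]) for i in range(40)]
        counter = collections.Counter(seq for _, seq in reads)
        uniq = dereplicate(ReadSet("s", reads))
        assert {u.sequence: u.size for u in uniq} == dict(counter)
        assert sum(u.size for u in uniq) == 40
        sizes = [u.size for u in uniq]
        assert sizes == sorted(sizes, reverse=True)


def make_uniques(seqs):
    return [Unique(s, 1, [("s", f"r{i}")]) for i, s in enumerate(seqs)]


class TestGreedyCluster:
    def test_identical_sequences_one_otu(self, rng):
        s = random_seq(rng, 100)
        otus = greedy_cluster(dereplicate(ReadSet("s", [("a", s), ("b", s)])),
                              91.0)
        assert len(otus) == 1 and otus[0].size == 2

    def test_pair_straddling_threshold(self, rng):
        """Two sequences at 90% identity split at threshold 91 and merge
        at 89."""
        a = random_seq(rng, 100)
        b = mutate_seq(a, rng.choice(100, 10, replace=False))
        assert pairwise_identity(a, b) == pytest.approx(90.0)
        assert len(greedy_cluster(make_uniques([a, b]), 91.0)) == 2
        assert len(greedy_cluster(make_uniques([a, b]), 89.0)) == 1

    def test_members_within_threshold_of_centroid(self, small_study):
        readsets = [ReadSet(s, r) for s, r in small_study.reads.items()]
        otus = greedy_cluster(dereplicate(readsets), 91.0)
        for otu in otus[:5]:
            for sample, rid in otu.members[:3]:
                seq = dict(small_study.reads[sample])[rid]
                assert pairwise_identity(seq, otu.representative) >= 91.0

    def test_matches_bruteforce_replay_oracle(self, rng):
        """Greedy clustering of mutated sequence families reproduces an
        independent replay that knows only the DP identity routine."""
        for seed in range(50):
            r = np.random.default_rng(seed)
            n_fam = int(r.integers(2, 5))
            ancestors = ["".join(r.choice(list("ACGT"), 50))
                         for _ in range(n_fam)]
            seqs = []
            for _ in range(int(r.integers(5, 16))):
                anc = ancestors[int(r.integers(0, n_fam))]
                s = mutate_seq(anc, r.choice(50, int(r.integers(0, 3)),
                                             replace=False))
                if r.random() < 0.2:
                    p = int(r.integers(5, 45))
                    s = s[:p] + s[p + 1:]
                seqs.append(s)
            otus = greedy_cluster(make_uniques(seqs), 91.0)
            got = [[int(rid[1:]) for _, rid in o.members] for o in otus]
            assert got == greedy_replay(seqs, 91.0)

    def test_threshold_monotonicity(self, rng):
        anc = random_seq(rng, 80)
        seqs = [mutate_seq(anc, rng.choice(80, k, replace=False))
                for k in (0, 2, 4, 6, 8, 10, 12)]
        counts = [len(greedy_cluster(make_uniques(seqs), t))
                  for t in (85, 88, 91, 94, 97, 99)]
        assert counts == sorted(counts)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            greedy_cluster([], 45.0)
        assert greedy_cluster([], 91.0) == []


class TestOtuTable:
    def test_row_sums_equal_sample_reads(self):
        otu = OTU("OTU0001", "ACGT" * 20,
                  [("A", f"a{i}") for i in range(3)]
                  + [("B", f"b{i}") for i in range(5)])
        table = build_otu_table([otu], ["A", "B"])
        assert list(table.counts.sum(axis=1)) == [3, 5]

    def test_empty_otu_list(self):
        table = build_otu_table([], ["A"])
        assert table.counts.shape == (1, 0)

    def test_unknown_sample_rejected(self):
        otu = OTU("OTU0001", "ACGT" * 20, [("Z", "r1")])
        with pytest.raises(ValueError, match="unknown sample"):
            build_otu_table([otu], ["A"])

    def test_error_free_clustering_recovers_truth_table(self, small_study):
        """With no read errors and well-separated genomes, the clustered
        table equals the simulator's truth table up to OTU relabeling."""
        readsets = [ReadSet(s, r) for s, r in small_study.reads.items()]
        otus = greedy_cluster(dereplicate(readsets), 91.0)
        table = build_otu_table(otus, sorted(small_study.reads))
        # map each OTU to its source genome through read provenance
        for otu in otus:
            genomes = {small_study.provenance[rid] for _, rid in otu.members}
            assert len(genomes) == 1  # no merging, no splitting
            gid = genomes.pop()
            for site in table.samples:
                assert table.counts.loc[site, otu.otu_id] == \
                    small_study.truth_tables[site].get(gid, 0)

    def test_read_conservation_through_filter_and_table(self, small_study):
        rs = ReadSet("site1", small_study.reads["site1"])
        filtered, log = quality_filter(rs, min_len=100)
        otus = greedy_cluster(dereplicate(filtered), 91.0)
        table = build_otu_table(otus, ["site1"])
        assert log["input"] == int(table.counts.loc["site1"].sum()) \
            + log["too_short"] + log["too_many_n"]


class TestCoverageRarefaction:
    def test_goods_coverage_formula_cases(self):
        assert goods_coverage([90, 1] + [1] * 9) == pytest.approx(1 - 10 / 100)
        assert goods_coverage([1, 1, 1]) == 0.0
        assert goods_coverage([5, 3, 2]) == 1.0
        with pytest.raises(ValueError):
            goods_coverage([0, 0])

    def test_rarefaction_endpoints(self):
        counts = [10, 5, 3, 1, 1]
        n = sum(counts)
        curve = dict(rarefaction(counts, [1, n]))
        assert curve[1] == pytest.approx(1.0)
        assert curve[n] == pytest.approx(5.0)

    def test_rarefaction_depth_beyond_total_rejected(self):
        with pytest.raises(ValueError):
            rarefaction([3, 2], [6])

    def test_rarefaction_matches_subsampling_oracle(self, rng):
        counts = rng.integers(1, 40, size=12)
        n = int(counts.sum())
        d = n // 2
        expected = dict(rarefaction(counts, [d]))[d]
        draws = rarefaction_subsampling(counts, d, 10_000, rng)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se

    def test_diversity_stats_consistent(self, small_study):
        readsets = [ReadSet(s, r) for s, r in small_study.reads.items()]
        otus = greedy_cluster(dereplicate(readsets), 91.0)
        table = build_otu_table(otus, sorted(small_study.reads))
        for s in diversity_stats(table):
            row = table.counts.loc[s.sample_id]
            assert s.richness == int((row > 0).sum()) <= s.n_reads
            assert 0 <= s.goods_coverage <= 1
            assert s.rarefaction_curve[-1][1] == pytest.approx(s.richness)


class TestSharedAndRanking:
    def presence_table(self, presence):
        otus = sorted({o for s in presence.values() for o in s})
        df = pd.DataFrame(0, index=list(presence), columns=otus)
        for s, os_ in presence.items():
            df.loc[s, list(os_)] = 1
        from ureotype.otu_pipeline import OTUTable
        return OTUTable(df, {}, 91.0)

    def test_two_sample_overlap(self):
        table = self.presence_table({"s1": {"A", "B"}, "s2": {"B", "C"}})
        core, specific, sets = shared_otus(table)
        assert core == {"B"}
        assert specific == {"s1": 1, "s2": 1}
        assert sets == {"s1": {"A"}, "s2": {"C"}}

    def test_single_sample_degenerate(self):
        table = self.presence_table({"s1": {"A", "B"}})
        core, specific, _ = shared_otus(table)
        assert core == {"A", "B"} and specific == {"s1": 2}

    def test_simulated_core_recovered(self, small_study, small_config):
        readsets = [ReadSet(s, r) for s, r in small_study.reads.items()]
        otus = greedy_cluster(dereplicate(readsets), 91.0)
        table = build_otu_table(otus, sorted(small_study.reads))
        core, _, _ = shared_otus(table)
        # identify core genomes that drew >=1 read at every site
        expected = {g for g in small_study.true_core_otus
                    if all(g in t for t in small_study.truth_tables.values())}
        by_genome = {next(iter({small_study.provenance[r] for _, r in o.members}))
                     : o.otu_id for o in otus}
        assert core == {by_genome[g] for g in expected}

    def test_rank_otus_ordering_and_tie_break(self):
        from ureotype.otu_pipeline import OTUTable
        df = pd.DataFrame({"b": [5, 5], "a": [5, 5], "c": [10, 1]},
                          index=["s1", "s2"])
        table = OTUTable(df, {}, 91.0)
        top = rank_otus(table, 2)
        assert list(top.index) == ["c", "a"]  # 11 first; tie a<b
        assert top.loc["c", "s1"] == pytest.approx(100 * 10 / 20)

    def test_rank_more_than_available_warns(self):
        from ureotype.otu_pipeline import OTUTable
        df = pd.DataFrame({"a": [3]}, index=["s1"])
        with pytest.warns(UserWarning, match="returning all"):
            top = rank_otus(OTUTable(df, {}, 91.0), 5)
        assert len(top) == 1

    def test_rank_agrees_with_sort_oracle(self, rng):
        from ureotype.otu_pipeline import OTUTable
        df = pd.DataFrame(rng.integers(0, 20, size=(4, 12)),
                          index=list("wxyz"),
                          columns=[f"o{i:02d}" for i in range(12)])
        table = OTUTable(df, {}, 91.0)
        top = rank_otus(table, 5)
        totals = df.sum(axis=0)
        expected = sorted(df.columns, key=lambda c: (-totals[c], c))[:5]
        assert list(top.index) == expected


class TestNovelty:
    def test_verbatim_reference_not_novel(self, rng):
        rep = random_seq(rng, 120)
        otu = OTU("OTU0001", rep, [("s", "r1")])
        df = novelty_classification([otu], {"ref1": rep}, 91.0)
        assert df.loc["OTU0001", "best_identity"] == 100.0
        assert not df.loc["OTU0001", "below_threshold"]

    def test_unrelated_reference_is_novel(self, rng):
        otu = OTU("OTU0001", random_seq(rng, 120), [("s", "r1")])
        ref = {f"ref{i}": random_seq(rng, 120) for i in range(3)}
        df = novelty_classification([otu], ref, 91.0)
        assert df.loc["OTU0001", "best_identity"] < 80.0
        assert bool(df.loc["OTU0001", "below_threshold"])

    def test_flags_follow_constructed_divergence(self, rng):
        """References at 4% vs 12% divergence land on opposite sides of
        the 91% species threshold."""
        rep = random_seq(rng, 200)
        near = mutate_seq(rep, rng.choice(200, 8, replace=False))
        far = mutate_seq(rep, rng.choice(200, 24, replace=False))
        df_near = novelty_classification([OTU("o", rep, [("s", "r")])],
                                         {"near": near}, 91.0)
        df_far = novelty_classification([OTU("o", rep, [("s", "r")])],
                                        {"far": far}, 91.0)
        assert not df_near["below_threshold"].iloc[0]
        assert df_far["below_threshold"].iloc[0]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            novelty_classification([], {}, 91.0)
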
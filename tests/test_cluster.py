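"""Greedy identity clustering against an independent alignment oracle."""

import random
from functools import lru_cache

import pytest

from repeatomekit import cluster_table, greedy_cluster, pairwise_identity, write_clstr
from repeatomekit.cluster import reverse_complement


def oracle_identity(a: str, b: str) -> float:
    """Independent recursive (score, matches) alignment, forward strand only.

    Same scoring scheme (match +1, mismatch -1, gap -2, end gaps penalized)
    but a different formulation from the implementation's iterative DP.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> tuple[int, int]:
        if i == len(a) and j == len(b):
            return (0, 0)
        options = []
        if i < len(a) and j < len(b):
            s, m = best(i + 1, j + 1)
            hit = 1 if a[i] == b[j] else 0
            options.append((s + (1 if hit else -1), m + hit))
        if i < len(a):
            s, m = best(i + 1, j)
            options.append((s - 2, m))
        if j < len(b):
            s, m = best(i, j + 1)
            options.append((s - 2, m))
        return max(options)

    return min(1.0, best(0, 0)[1] / min(len(a), len(b)))


def random_seq(rnd: random.Random, length: int) -> str:
    return "".join(rnd.choice("ACGT") for _ in range(length))


class TestPairwiseIdentity:
    def test_self_identity_is_one(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 1.0

    def test_disjoint_alphabets_forward_only(self):
        # forward strand: no base of poly-A matches poly-T
        assert pairwise_identity("AAAA", "TTTT", both_strands=False) == 0.0

    def test_reverse_complement_recovers_strand_flips(self):
        seq = "ACGTTGCAAC"
        assert pairwise_identity(seq, reverse_complement(seq)) == 1.0

    def test_substring_identity_uses_shorter_length(self):
        assert pairwise_identity("ACGTACGT", "ACGT") == 1.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_recursive_oracle_on_random_pairs(self, seed):
        rnd = random.Random(seed)
        a = random_seq(rnd, rnd.randint(3, 12))
        b = random_seq(rnd, rnd.randint(3, 12))
        assert pairwise_identity(a, b, both_strands=False) == pytest.approx(
            oracle_identity(a, b)
        )

    def test_symmetry(self):
        rnd = random.Random(1)
        a, b = random_seq(rnd, 30), random_seq(rnd, 25)
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))


class TestGreedyCluster:
    def test_identical_sequences_form_one_cluster(self):
        clusters = greedy_cluster({"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGT"})
        assert len(clusters) == 1
        assert clusters[0].size == 3
        assert clusters[0].representative == "a"  # tie broken by name

    def test_unrelated_sequences_stay_separate(self):
        clusters = greedy_cluster(
            {"a": "AAAA" * 12 + "AA", "t": "TTTT" * 12 + "TT"},
            threshold=0.5,
            both_strands=False,
        )
        assert len(clusters) == 2
        assert all(c.size == 1 for c in clusters)

    def test_representative_is_longest_member(self):
        clusters = greedy_cluster({"short": "ACGTAC", "long": "ACGTACGTACGT"})
        for cluster in clusters:
            rep_len = {"short": 6, "long": 12}[cluster.representative]
            assert all(
                rep_len >= {"short": 6, "long": 12}[name]
                for name, _ in cluster.members
            )

    def test_random_input_satisfies_greedy_invariants(self):
        rnd = random.Random(7)
        seqs = {f"s{i:02d}": random_seq(rnd, 60) for i in range(15)}
        threshold = 0.5
        clusters = greedy_cluster(seqs, threshold=threshold)
        # partition: every sequence in exactly one cluster
        members = [name for c in clusters for name, _ in c.members]
        assert sorted(members) == sorted(seqs)
        # member identity >= threshold, re-verified independently
        for cluster in clusters:
            rep = seqs[cluster.representative]
            for name, ident in cluster.members:
                recomputed = max(
                    oracle_identity(rep, seqs[name]),
                    oracle_identity(rep, reverse_complement(seqs[name])),
                )
                assert recomputed == pytest.approx(ident)
                assert ident >= threshold
        # greedy guarantee: representatives are mutually below threshold
        reps = [seqs[c.representative] for c in clusters]
        for i, earlier in enumerate(reps):
            for later in reps[i + 1 :]:
                ident = max(
                    oracle_identity(earlier, later),
                    oracle_identity(earlier, reverse_complement(later)),
                )
                assert ident < threshold

    def test_shuffled_input_yields_identical_clusters(self):
        rnd = random.Random(3)
        items = [(f"s{i}", random_seq(rnd, 40)) for i in range(12)]
        base = greedy_cluster(items)
        shuffled = items[:]
        rnd.shuffle(shuffled)
        assert greedy_cluster(shuffled) == base

    def test_cluster_count_monotone_in_threshold(self):
        rnd = random.Random(11)
        seqs = {f"s{i}": random_seq(rnd, 50) for i in range(10)}
        loose = greedy_cluster(seqs, threshold=0.3)
        strict = greedy_cluster(seqs, threshold=0.7)
        assert len(loose) <= len(strict)

    @pytest.mark.parametrize("bad", [0.0, -0.5, 1.5])
    def test_threshold_domain(self, bad):
        with pytest.raises(ValueError):
            greedy_cluster({"a": "ACGT"}, threshold=bad)

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            greedy_cluster([("a", "ACGT"), ("a", "ACGG")])

    def test_desk_scale_guard(self):
        with pytest.raises(ValueError, match="out of scope"):
            greedy_cluster({f"s{i}": "ACGT" for i in range(501)})


class TestClusterOutput:
    def test_clstr_and_tsv_formats(self):
        seqs = {"a": "ACGTACGTACGT", "b": "ACGTACGTACGA"}
        clusters = greedy_cluster(seqs)
        clstr = write_clstr(clusters, {k: len(v) for k, v in seqs.items()})
        assert clstr.startswith(">Cluster 0")
        assert "*" in clstr  # representative marker
        tsv = cluster_table(clusters)
        assert tsv.splitlines()[0] == "cluster_id\tmember\tidentity\tis_representative"
        assert len(tsv.splitlines()) == 3
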
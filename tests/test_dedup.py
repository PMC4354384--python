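"""Integer encodings, chunked mismatch counting and greedy duplicate collapse."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from rdprep.dedup import (
    MAX_CHUNK_LEN,
    MAX_PREFIX_LEN,
    ChunkCode,
    DedupPolicy,
    UnsupportedLengthError,
    build_consensus,
    cluster_by_prefix,
    collapse_cluster,
    count_mismatches,
    decode_prefix,
    dedup_reads,
    encode_chunk,
    encode_prefix,
    leftmost_mismatch,
)

from conftest import make_read

ALPHABET = "ACGTN"


def hamming(a, b):
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


class TestPrefixEncoding:
    @pytest.mark.parametrize(
        "seq,k,value",
        [
            ("AAAAAAA", 7, 0),
            ("CA", 2, 5),
            ("ACGTN", 5, 194),  # 1*125 + 2*25 + 3*5 + 4
            ("N" * 27, 27, 5**27 - 1),
        ],
    )
    def test_known_values(self, seq, k, value):
        assert encode_prefix(seq, k) == value

    def test_capacity_limits(self):
        assert MAX_PREFIX_LEN == 27 and MAX_CHUNK_LEN == 19
        assert 5**MAX_PREFIX_LEN - 1 <= 2**64 - 1 < 5 ** (MAX_PREFIX_LEN + 1) - 1
        assert 10**MAX_CHUNK_LEN - 1 <= 2**64 - 1 < 10 ** (MAX_CHUNK_LEN + 1) - 1

    def test_too_long_prefix_rejected(self):
        with pytest.raises(UnsupportedLengthError):
            encode_prefix("A" * 28, 28)

    def test_sequence_shorter_than_k_rejected(self):
        with pytest.raises(ValueError):
            encode_prefix("ACG", 4)

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet=ALPHABET, min_size=1, max_size=27))
    def test_encode_decode_round_trip(self, seq):
        assert decode_prefix(encode_prefix(seq, len(seq)), len(seq)) == seq

    @settings(max_examples=200, derandomize=True)
    @given(
        st.text(alphabet=ALPHABET, min_size=8, max_size=8),
        st.text(alphabet=ALPHABET, min_size=8, max_size=8),
    )
    def test_order_preserving_on_lexicographic_order(self, a, b):
        # lexicographic with A<C<G<T<N equals digit-string order
        ra, rb = a.translate(str.maketrans(ALPHABET, "01234")), b.translate(
            str.maketrans(ALPHABET, "01234")
        )
        assert (encode_prefix(a, 8) < encode_prefix(b, 8)) == (ra < rb)


class TestChunkEncoding:
    @pytest.mark.parametrize(
        "sub,value", [("CA", 10), ("AAAA", 0), ("NT", 43), ("N" * 19, int("4" * 19))]
    )
    def test_known_values(self, sub, value):
        assert encode_chunk(sub).value == value

    def test_too_long_chunk_rejected(self):
        with pytest.raises(UnsupportedLengthError):
            encode_chunk("A" * 20)

    def test_equal_codes_have_no_mismatch(self):
        assert leftmost_mismatch(encode_chunk("ACGT"), encode_chunk("ACGT")) is None

    @pytest.mark.parametrize(
        "a,b,pos", [("AT", "CT", 0), ("CT", "CA", 1), ("CA", "AN", 0)]
    )
    def test_leftmost_mismatch_positions(self, a, b, pos):
        # last case: |10-04|=6 — magnitude alone reads one place too far right
        assert leftmost_mismatch(encode_chunk(a), encode_chunk(b)) == pos

    def test_length_mismatch_is_contract_violation(self):
        with pytest.raises(ValueError):
            leftmost_mismatch(encode_chunk("AC"), encode_chunk("ACG"))

    def test_leftmost_mismatch_exhaustive_short(self):
        for n in (1, 2, 3):
            for a in itertools.product(ALPHABET, repeat=n):
                for b in itertools.product(ALPHABET, repeat=n):
                    sa, sb = "".join(a), "".join(b)
                    expected = next(
                        (i for i, (x, y) in enumerate(zip(sa, sb)) if x != y), None
                    )
                    got = leftmost_mismatch(encode_chunk(sa), encode_chunk(sb))
                    assert got == expected, (sa, sb)


class TestCountMismatches:
    def test_exhaustive_up_to_length_three(self):
        for n in (1, 2, 3):
            for a in itertools.product(ALPHABET, repeat=n):
                for b in itertools.product(ALPHABET, repeat=n):
                    sa, sb = "".join(a), "".join(b)
                    assert count_mismatches(sa, sb, n) == hamming(sa, sb), (sa, sb)

    @pytest.mark.parametrize("length", [4, 5, 6, 75])
    def test_randomized_against_hamming(self, length):
        rng = random.Random(1234 + length)
        for _ in range(400):
            a = "".join(rng.choice(ALPHABET) for _ in range(length))
            b = list(a)
            for pos in rng.sample(range(length), rng.randint(0, min(6, length))):
                b[pos] = rng.choice(ALPHABET)
            b = "".join(b)
            assert count_mismatches(a, b, length, chunk_len=19) == hamming(a, b)

    def test_early_stop_exceeds_limit(self):
        a, b = "A" * 30, "C" * 3 + "A" * 24 + "GGG"
        got = count_mismatches(a, b, 1)
        assert got > 1  # exact value beyond the limit is unspecified

    def test_identical_suffixes(self):
        assert count_mismatches("ACGTN" * 4, "ACGTN" * 4, 0) == 0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="indel"):
            count_mismatches("ACGT", "ACG", 1)

    def test_chunk_boundaries_do_not_lose_mismatches(self):
        # mismatches straddling the 19-base chunk boundary
        a = "A" * 40
        b = "A" * 18 + "C" + "A" * 0 + "C" + "A" * 20
        assert count_mismatches(a, b, 40, chunk_len=19) == hamming(a, b) == 2


class TestClustering:
    def test_shared_prefix_groups(self):
        reads = [
            make_read("AAAACCCC", rid="a"),
            make_read("AAAAGGGG", rid="b"),
            make_read("TTTTCCCC", rid="c"),
            make_read("GGGGCCCC", rid="d"),
        ]
        clusters, short = cluster_by_prefix(reads, 4)
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 1, 2] and short == []
        two = next(c for c in clusters if len(c.members) == 2)
        assert two.members == [0, 1]  # ascending original index

    def test_empty_library(self):
        assert cluster_by_prefix([], 5) == ([], [])

    def test_short_reads_set_aside(self):
        reads = [make_read("ACG"), make_read("ACGTACGT")]
        clusters, short = cluster_by_prefix(reads, 5)
        assert short == [0] and [c.members for c in clusters] == [[1]]

    def test_matches_hash_grouping_oracle(self):
        rng = random.Random(99)
        for k in (3, 8):
            reads = [
                make_read("".join(rng.choice("ACGT") for _ in range(10)), rid=f"r{i}")
                for i in range(300)
            ]
            clusters, _ = cluster_by_prefix(reads, k)
            expected = {}
            for i, r in enumerate(reads):
                expected.setdefault(r.seq[:k], []).append(i)
            got = {decode_prefix(c.key, k): c.members for c in clusters}
            assert got == expected


class TestConsensus:
    def test_identical_members(self):
        x = make_read("ACGT", rid="s")
        assert build_consensus([x, x]).seq == "ACGT"

    def test_majority_overrides_seed(self):
        seed = make_read("ACGT", rid="s")
        dup = make_read("ACGA")
        assert build_consensus([seed, dup, dup]).seq == "ACGA"

    def test_tie_resolves_to_seed(self):
        seed = make_read("ACGT", rid="s")
        other = make_read("ACGA")
        cons = build_consensus([seed, other])
        assert cons.seq == "ACGT" and cons.id == "s" and cons.qual == seed.qual


class TestCollapse:
    def mk_cluster(self, seqs, k):
        reads = [make_read(s, rid=f"r{i}") for i, s in enumerate(seqs)]
        clusters, _ = cluster_by_prefix(reads, k)
        assert len(clusters) == 1
        return clusters[0], reads

    def test_identical_reads_collapse_to_one(self):
        cluster, reads = self.mk_cluster(["AAAACGCG"] * 4, 4)
        reps, removed = collapse_cluster(cluster, reads, DedupPolicy(4, 0))
        assert len(reps) == 1 and removed == 3

    def test_near_and_far_members_split(self):
        s = "AAAA" + "CCCCCCCC"
        near = "AAAA" + "CCCCCCCG"  # 1 mismatch
        far = "AAAA" + "GGGGGCCC"  # 5 mismatches
        cluster, reads = self.mk_cluster([s, near, far], 4)
        reps, removed = collapse_cluster(cluster, reads, DedupPolicy(4, 1))
        assert len(reps) == 2 and removed == 1

    def test_singleton_unchanged(self):
        cluster, reads = self.mk_cluster(["ACGTACGT"], 4)
        reps, removed = collapse_cluster(cluster, reads, DedupPolicy(4, 1))
        assert removed == 0 and reps[0][1] is reads[0]

    def test_unequal_lengths_never_duplicates(self):
        reads = [make_read("AAAACCCC", rid="a"), make_read("AAAACCCCG", rid="b")]
        clusters, _ = cluster_by_prefix(reads, 4)
        (cluster,) = clusters
        reps, removed = collapse_cluster(cluster, reads, DedupPolicy(4, 8))
        assert len(reps) == 2 and removed == 0


def random_library(rng, n, length=30):
    return [
        make_read("".join(rng.choice("ACGTN") for _ in range(length)), rid=f"r{i}")
        for i in range(n)
    ]


class TestDedupLibrary:
    def test_exact_dedup_oracle_at_full_length_prefix(self):
        rng = random.Random(7)
        # duplicated full sequences of length 27 = k, m=0: exact-string dedup
        base = random_library(rng, 40, length=27)
        lib = base + [base[i] for i in (0, 0, 3, 5, 5, 5)]
        deduped, stats = dedup_reads(lib, DedupPolicy(27, 0))
        assert sorted(r.seq for r in deduped) == sorted({r.seq for r in lib})
        assert stats.removed == len(lib) - len({r.seq for r in lib})

    def test_representatives_pairwise_distance_exceeds_m(self):
        rng = random.Random(11)
        lib = random_library(rng, 200, length=20)
        # add clustered near-duplicates
        for i in range(0, 50, 5):
            s = list(lib[i].seq)
            s[15] = "A" if s[15] != "A" else "C"
            lib.append(make_read("".join(s), rid=f"d{i}"))
        for k, m in [(5, 1), (5, 3), (10, 2)]:
            deduped, _ = dedup_reads(lib, DedupPolicy(k, m))
            groups = {}
            for r in deduped:
                groups.setdefault(r.seq[:k], []).append(r.seq)
            for seqs in groups.values():
                for a, b in itertools.combinations(seqs, 2):
                    if len(a) == len(b):
                        assert hamming(a[k:], b[k:]) > m

    def test_removed_monotone_in_mismatch_allowance(self):
        rng = random.Random(13)
        lib = random_library(rng, 150, length=30)
        for i in range(0, 60, 3):
            s = list(lib[i].seq)
            for pos in rng.sample(range(10, 30), rng.randint(0, 3)):
                s[pos] = rng.choice("ACGT")
            lib.append(make_read("".join(s), rid=f"d{i}"))
        removed = [
            dedup_reads(lib, DedupPolicy(10, m))[1].removed for m in (0, 1, 3)
        ]
        assert removed[0] <= removed[1] <= removed[2]

    def test_deterministic_output(self, tmp_path):
        from rdprep.dedup import dedup_library
        from rdprep.fastq import write_fastq

        rng = random.Random(17)
        lib = random_library(rng, 100, length=25)
        src = tmp_path / "in.fastq"
        write_fastq(lib, src)
        out1, out2 = tmp_path / "o1.fastq", tmp_path / "o2.fastq"
        dedup_library(src, out1, DedupPolicy(10, 1))
        dedup_library(src, out2, DedupPolicy(10, 1))
        assert out1.read_bytes() == out2.read_bytes()

    def test_output_order_follows_original_indices(self):
        lib = [
            make_read("AAAAACCCC", rid="0"),
            make_read("GGGGGCCCC", rid="1"),
            make_read("AAAAACCCC", rid="2"),
            make_read("TT", rid="3"),  # shorter than k: passthrough
        ]
        deduped, stats = dedup_reads(lib, DedupPolicy(5, 0))
        assert [r.id for r in deduped] == ["0", "1", "3"]
        assert stats.short_reads == 1
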
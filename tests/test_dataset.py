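"""Dataset construction: clustering, identity, splitting and leakage purge."""

import itertools

import numpy as np
import pytest

from remhom import (
    DatasetConfig,
    DomainRecord,
    LabelSpace,
    SplitDataset,
    assemble_splits,
    greedy_identity_cluster,
    load_split,
    pairwise_identity,
    parse_cluster_tsv,
    purge_cross_set_homologs,
    save_split,
    select_superfamilies,
    select_top_k_superfamilies,
    undersample_other,
)

AA = list("ACDEFGHIKLMNPQRSTVWY")


def random_seq(rng, length, alphabet=AA):
    return "".join(rng.choice(list(alphabet), size=length))


def mutate(rng, seq, n_mut, alphabet=AA):
    s = list(seq)
    for pos in rng.choice(len(s), size=n_mut, replace=False):
        s[pos] = rng.choice([a for a in alphabet if a != s[pos]])
    return "".join(s)


# ---------------------------------------------------------------------------
# cluster TSV parsing
# ---------------------------------------------------------------------------

class TestParseClusterTsv:
    def test_direct_transcription(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("A\tA\nA\tB\nC\tC\n")
        cm = parse_cluster_tsv(p, 0.2)
        assert dict(cm.assignments) == {"A": "A", "B": "A", "C": "C"}

    def test_representative_self_assigned(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("A\tB\n")
        cm = parse_cluster_tsv(p, 0.2)
        assert dict(cm.assignments) == {"A": "A", "B": "A"}

    def test_malformed_line_names_lineno(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("A\tA\nA\tB\tX\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_cluster_tsv(p, 0.2)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("")
        with pytest.raises(ValueError):
            parse_cluster_tsv(p, 0.2)


# ---------------------------------------------------------------------------
# pairwise identity vs an independent DP oracle
# ---------------------------------------------------------------------------

def nw_optimal_identities(a: str, b: str) -> set:
    """All identity values achievable on maximum-score global alignments
    (match +1, mismatch 0, linear gap -1), by full DP + traceback DFS."""
    n, m = len(a), len(b)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        H[i][0] = -i
    for j in range(1, m + 1):
        H[0][j] = -j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            diag = H[i - 1][j - 1] + (1 if a[i - 1] == b[j - 1] else 0)
            H[i][j] = max(diag, H[i - 1][j] - 1, H[i][j - 1] - 1)
    results = set()
    stack = [(n, m, 0, 0)]  # i, j, matches, columns
    while stack:
        i, j, matches, cols = stack.pop()
        if i == 0 and j == 0:
            results.add((matches, cols))
            continue
        if i > 0 and j > 0:
            step = 1 if a[i - 1] == b[j - 1] else 0
            if H[i][j] == H[i - 1][j - 1] + step:
                stack.append((i - 1, j - 1, matches + step, cols + 1))
        if i > 0 and H[i][j] == H[i - 1][j] - 1:
            stack.append((i - 1, j, matches, cols + 1))
        if j > 0 and H[i][j] == H[i][j - 1] - 1:
            stack.append((i, j - 1, matches, cols + 1))
    return {m_ / c for m_, c in results}


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACDE", "ACDE") == 1.0

    def test_no_matches(self):
        assert pairwise_identity("ACDE", "WYHK") == 0.0

    def test_textbook_pair_matches_dp_oracle(self):
        value = pairwise_identity("HEAGAWGHEE", "PAWHEAE")
        assert value == pytest.approx(5 / 11)
        assert value in nw_optimal_identities("HEAGAWGHEE", "PAWHEAE")

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACDE")

    def test_random_pairs_on_optimal_paths(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            a = random_seq(rng, int(rng.integers(2, 9)))
            b = random_seq(rng, int(rng.integers(2, 9)))
            achievable = nw_optimal_identities(a, b)
            got = pairwise_identity(a, b)
            assert any(abs(got - v) < 1e-12 for v in achievable)
            assert pairwise_identity(b, a) == pytest.approx(got)


# ---------------------------------------------------------------------------
# greedy clustering
# ---------------------------------------------------------------------------

def single_linkage_cluster_count(seqs, threshold):
    """Brute-force all-pairs single-linkage components at a threshold."""
    n = len(seqs)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(n), 2):
        if pairwise_identity(seqs[i], seqs[j]) >= threshold:
            parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


def make_records(seqs, superfamily="1.10.8.10", source="pdb", prefix="d"):
    return [
        DomainRecord(f"{prefix}{i}", s, superfamily, source)
        for i, s in enumerate(seqs)
    ]


class TestGreedyIdentityCluster:
    def test_identical_pair_merges(self):
        recs = make_records(["ACDEFGHIKL", "ACDEFGHIKL"])
        cm = greedy_identity_cluster(recs, 0.2)
        assert len(cm.representatives) == 1

    def test_unrelated_pair_stays_split(self):
        recs = make_records(["AAAAAAAAAA", "WYWYWYWYWY"])
        cm = greedy_identity_cluster(recs, 0.2)
        assert len(cm.representatives) == 2

    def test_mutation_families_match_single_linkage_oracle(self):
        rng = np.random.default_rng(7)
        base1 = random_seq(rng, 50, "ACDEFGHIK")
        base2 = random_seq(rng, 50, "LMNPQRSTV")
        seqs = [mutate(rng, base1, 2, "ACDEFGHIK") for _ in range(5)]
        seqs += [mutate(rng, base2, 2, "LMNPQRSTV") for _ in range(5)]
        cm = greedy_identity_cluster(make_records(seqs), 0.5)
        assert len(cm.representatives) == single_linkage_cluster_count(seqs, 0.5)

    def test_members_reach_their_representative(self):
        rng = np.random.default_rng(11)
        base = random_seq(rng, 40)
        seqs = [mutate(rng, base, int(rng.integers(1, 6))) for _ in range(8)]
        seqs += [random_seq(rng, 40) for _ in range(4)]
        recs = make_records(seqs)
        by_id = {r.domain_id: r for r in recs}
        cm = greedy_identity_cluster(recs, 0.5)
        for member, rep in cm.assignments.items():
            if member != rep:
                assert pairwise_identity(
                    by_id[member].sequence, by_id[rep].sequence
                ) >= 0.5


# ---------------------------------------------------------------------------
# superfamily selection and split assembly
# ---------------------------------------------------------------------------

def identity_cluster_map(records):
    """Every record its own representative (already non-redundant)."""
    from remhom import ClusterMap

    return ClusterMap({r.domain_id: r.domain_id for r in records}, 0.2)


def family_fixture(rep_counts):
    """PDB records with the given number of representatives per family."""
    rng = np.random.default_rng(0)
    records = []
    for f, (family, count) in enumerate(rep_counts.items()):
        for i in range(count):
            records.append(
                DomainRecord(
                    f"f{f}_{i}", random_seq(rng, 30), family, "pdb"
                )
            )
    return records


class TestSelectSuperfamilies:
    def test_threshold_partitions_families(self):
        recs = family_fixture({"1.10.8.10": 3, "2.60.40.10": 1})
        named, other = select_superfamilies(recs, identity_cluster_map(recs), 2)
        assert named == ["1.10.8.10"] and other == ["2.60.40.10"]

    def test_all_families_named(self):
        recs = family_fixture({"1.10.8.10": 2, "2.60.40.10": 3})
        named, other = select_superfamilies(recs, identity_cluster_map(recs), 2)
        assert len(named) == 2 and other == []

    def test_counted_fixture(self):
        counts = {
            "1.10.8.10": 3, "1.20.5.110": 2, "2.60.40.10": 2,
            "3.40.50.300": 1, "3.30.70.100": 1, "2.40.50.140": 1,
        }
        recs = family_fixture(counts)
        named, other = select_superfamilies(recs, identity_cluster_map(recs), 2)
        assert len(named) == 3 and len(other) == 3

    def test_gene3d_source_rejected(self):
        rec = DomainRecord("g1", "ACDEF", "1.10.8.10", "gene3d")
        with pytest.raises(ValueError):
            select_superfamilies([rec], identity_cluster_map([rec]), 2)


class TestAssembleSplits:
    def _records(self, rng, family, n, source, prefix):
        return [
            DomainRecord(f"{prefix}{i}", random_seq(rng, 30), family, source)
            for i in range(n)
        ]

    def test_two_reps_split_one_each(self):
        rng = np.random.default_rng(0)
        pdb = self._records(rng, "1.10.8.10", 2, "pdb", "p")
        g3d = self._records(rng, "1.10.8.10", 5, "gene3d", "g")
        split = assemble_splits(pdb, g3d, ["1.10.8.10"], DatasetConfig(seed=3))
        assert len(split.test) == 1 and len(split.validation) == 1

    def test_five_reps_alternate(self):
        rng = np.random.default_rng(0)
        pdb = self._records(rng, "1.10.8.10", 5, "pdb", "p")
        split = assemble_splits(pdb, [], ["1.10.8.10"], DatasetConfig(seed=3))
        assert sorted([len(split.test), len(split.validation)]) == [2, 3]

    def test_non_named_gene3d_relabelled_other(self):
        rng = np.random.default_rng(0)
        pdb = self._records(rng, "1.10.8.10", 2, "pdb", "p")
        stray = self._records(rng, "9.99.99.99", 1, "gene3d", "s")
        split = assemble_splits(
            pdb, stray, ["1.10.8.10"], DatasetConfig(seed=3)
        )
        assert split.train[0].superfamily == "other"

    def test_underpopulated_family_raises(self):
        rng = np.random.default_rng(0)
        pdb = self._records(rng, "1.10.8.10", 1, "pdb", "p")
        with pytest.raises(ValueError, match="1.10.8.10"):
            assemble_splits(pdb, [], ["1.10.8.10"], DatasetConfig(seed=3))


# ---------------------------------------------------------------------------
# leakage purge
# ---------------------------------------------------------------------------

TRAIN_ALPHABET = "ACDEFG"
TEST_ALPHABET = "HIKLMN"
VAL_ALPHABET = "PQRSTV"


def leaky_split(n_train=60, n_test=30, n_val=30, n_leaks=3, seed=0):
    """Split whose sets use disjoint alphabets (cross-set identity 0) with
    ``n_leaks`` near-duplicates of test sequences planted in train/val."""
    rng = np.random.default_rng(seed)
    families = ["1.10.8.10", "2.60.40.10", "3.40.50.300"]

    def recs(n, alphabet, source, prefix):
        return [
            DomainRecord(
                f"{prefix}{i}", random_seq(rng, 40, alphabet),
                families[i % 3], source,
            )
            for i in range(n)
        ]

    n_train_leaks = max(0, n_leaks - 1)
    n_val_leaks = 1 if n_leaks else 0
    test = recs(n_test, TEST_ALPHABET, "pdb", "t")
    val = recs(n_val - n_val_leaks, VAL_ALPHABET, "pdb", "v")
    train = recs(n_train - n_train_leaks, TRAIN_ALPHABET, "gene3d", "r")
    leak_ids = []
    for k in range(n_leaks):
        leaked = mutate(rng, test[k].sequence, 2, TEST_ALPHABET)
        if k < n_leaks - 1:
            rec = DomainRecord(f"leak_train_{k}", leaked, families[k % 3], "gene3d")
            train.append(rec)
        else:
            rec = DomainRecord(f"leak_val_{k}", leaked, families[k % 3], "pdb")
            val.append(rec)
        leak_ids.append(rec.domain_id)
    split = SplitDataset(
        train, val, test, LabelSpace(tuple(families), has_other=True)
    )
    split.validate()
    return split, set(leak_ids)


def cross_set_pairs(split):
    yield from ((a, b) for a in split.train for b in split.test)
    yield from ((a, b) for a in split.train for b in split.validation)
    yield from ((a, b) for a in split.validation for b in split.test)


class TestPurgeCrossSetHomologs:
    def test_identical_train_record_removed(self):
        split, _ = leaky_split(n_train=5, n_test=3, n_val=3, n_leaks=0)
        dup = DomainRecord("dup", split.test[0].sequence, "1.10.8.10", "gene3d")
        split.train.append(dup)
        purged = purge_cross_set_homologs(split, 0.2)
        assert "dup" not in {r.domain_id for r in purged.train}
        assert len(purged.train) == 5

    def test_clean_split_unchanged(self):
        split, _ = leaky_split(n_train=10, n_test=5, n_val=5, n_leaks=0)
        purged = purge_cross_set_homologs(split, 0.2)
        assert [r.domain_id for r in purged.train] == [
            r.domain_id for r in split.train
        ]
        assert [r.domain_id for r in purged.validation] == [
            r.domain_id for r in split.validation
        ]

    def test_planted_leaks_exactly_removed_oracle(self):
        split, leak_ids = leaky_split(n_train=30, n_test=15, n_val=15, n_leaks=3)
        # oracle: recompute which records an exhaustive all-pairs scan flags
        flagged = {
            a.domain_id
            for a, b in cross_set_pairs(split)
            if pairwise_identity(a.sequence, b.sequence) >= 0.2
        }
        assert flagged == leak_ids
        purged = purge_cross_set_homologs(split, 0.2)
        surviving = {r.domain_id for part in (purged.train, purged.validation,
                                              purged.test) for r in part}
        assert leak_ids & surviving == set()
        removed = {
            r.domain_id
            for part in (split.train, split.validation)
            for r in part
        } - surviving
        assert removed == leak_ids

    def test_test_set_never_shrinks(self):
        split, _ = leaky_split(n_leaks=3)
        purged = purge_cross_set_homologs(split, 0.2)
        assert [r.domain_id for r in purged.test] == [
            r.domain_id for r in split.test
        ]

    def test_leakage_invariant_post_purge(self):
        split, _ = leaky_split(n_train=20, n_test=10, n_val=10, n_leaks=2)
        purged = purge_cross_set_homologs(split, 0.2)
        assert all(
            pairwise_identity(a.sequence, b.sequence) < 0.2
            for a, b in cross_set_pairs(purged)
        )


# ---------------------------------------------------------------------------
# under-sampling and top-k
# ---------------------------------------------------------------------------

def other_heavy_split(n_other=100, seed=0):
    rng = np.random.default_rng(seed)
    train = [
        DomainRecord(f"o{i}", random_seq(rng, 20), "other", "gene3d")
        for i in range(n_other)
    ]
    train += [
        DomainRecord(f"n{i}", random_seq(rng, 20), "1.10.8.10", "gene3d")
        for i in range(10)
    ]
    test = [DomainRecord("t0", random_seq(rng, 20), "1.10.8.10", "pdb")]
    val = [DomainRecord("v0", random_seq(rng, 20), "1.10.8.10", "pdb")]
    split = SplitDataset(train, val, test, LabelSpace(("1.10.8.10",), True))
    split.validate()
    return split


class TestUndersampleOther:
    def test_reduces_to_target(self):
        out = undersample_other(other_heavy_split(), 10, seed=0)
        assert sum(r.superfamily == "other" for r in out.train) == 10
        assert sum(r.superfamily != "other" for r in out.train) == 10

    def test_target_above_count_is_noop(self):
        split = other_heavy_split()
        out = undersample_other(split, 1000, seed=0)
        assert len(out.train) == len(split.train)

    def test_seed_determinism(self):
        a = undersample_other(other_heavy_split(), 10, seed=5)
        b = undersample_other(other_heavy_split(), 10, seed=5)
        assert [r.domain_id for r in a.train] == [r.domain_id for r in b.train]

    def test_auto_target_uses_median_named_count(self):
        out = undersample_other(other_heavy_split(), "auto", seed=0)
        assert sum(r.superfamily == "other" for r in out.train) == 10


def three_family_split():
    rng = np.random.default_rng(0)
    fams = {"1.10.8.10": 30, "2.60.40.10": 20, "3.40.50.300": 10}
    train = [
        DomainRecord(f"{f}_{i}", random_seq(rng, 20), f, "gene3d")
        for f, n in fams.items()
        for i in range(n)
    ]
    train += [
        DomainRecord(f"oth{i}", random_seq(rng, 20), "other", "gene3d")
        for i in range(5)
    ]
    test = [
        DomainRecord(f"t_{f}", random_seq(rng, 20), f, "pdb") for f in fams
    ]
    val = [
        DomainRecord(f"v_{f}", random_seq(rng, 20), f, "pdb") for f in fams
    ]
    split = SplitDataset(train, val, test, LabelSpace(tuple(sorted(fams)), True))
    split.validate()
    return split


class TestSelectTopK:
    def test_k_equals_all_drops_only_other(self):
        split = three_family_split()
        out = select_top_k_superfamilies(split, 3)
        assert not out.label_space.has_other
        assert len(out.train) == 60

    def test_k_one_keeps_most_populous(self):
        out = select_top_k_superfamilies(three_family_split(), 1)
        assert out.label_space.labels == ("1.10.8.10",)

    def test_counts_from_fixture(self):
        out = select_top_k_superfamilies(three_family_split(), 2)
        assert set(out.label_space.labels) == {"1.10.8.10", "2.60.40.10"}

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            select_top_k_superfamilies(three_family_split(), 0)


# ---------------------------------------------------------------------------
# serialization determinism
# ---------------------------------------------------------------------------

def test_split_serialization_is_byte_identical(tmp_path):
    split, _ = leaky_split(n_train=8, n_test=4, n_val=4, n_leaks=0)
    save_split(split, tmp_path / "a")
    save_split(split, tmp_path / "b")
    for name in ("train.fasta", "validation.fasta", "test.fasta", "manifest.json"):
        assert (tmp_path / "a" / name).read_bytes() == (
            tmp_path / "b" / name
        ).read_bytes()
    loaded = load_split(tmp_path / "a")
    assert [r.domain_id for r in loaded.test] == [
        r.domain_id for r in split.test
    ]
    assert loaded.label_space.labels == split.label_space.labels
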
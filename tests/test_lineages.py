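import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from crispr_memory.datasets import ArrayRecord
from crispr_memory.lineages import (
    build_lineages,
    cluster_repeats,
    dereplicate_sequences,
    is_nested,
    lineage_consistency_metrics,
    spacer_keys,
)
from crispr_memory.seq import canonical, random_seq, revcomp
from crispr_memory.simulate import (
    SimulationConfig,
    emit_observed_dataset,
    generate_community,
)


def make_array(array_id, spacer_ids, cluster="R0", subject="S1", timepoint=0,
               orientation="unknown"):
    return ArrayRecord(
        array_id=array_id, subject=subject, sample=f"{subject}_t{timepoint}",
        timepoint=timepoint, repeat_id="r1", spacer_ids=tuple(spacer_ids),
        orientation=orientation, repeat_cluster=cluster)


SPACERS = {f"s{i}": ("ACGT" * 8) + f"{b1}{b2}"
           for i, (b1, b2) in enumerate(
               (a, b) for a in "ACGT" for b in "ACGT")}


class TestDereplicate:
    def test_exact_duplicates_collapse(self):
        id_map, _ = dereplicate_sequences({"a": "ACGT", "b": "ACGT", "c": "TTTT"})
        assert id_map["a"] == id_map["b"] != id_map["c"]
        assert len(set(id_map.values())) == 2

    def test_revcomp_kept_distinct_but_paired(self):
        id_map, pairs = dereplicate_sequences({"a": "AACG", "b": revcomp("AACG")})
        assert id_map["a"] != id_map["b"]
        assert pairs == {frozenset({"a", "b"})}

    def test_idempotent(self):
        seqs = {"a": "ACGT", "b": "ACGT", "c": "GGTA"}
        id_map, _ = dereplicate_sequences(seqs)
        canon = {cid: seqs[cid] for cid in set(id_map.values())}
        id_map2, _ = dereplicate_sequences(canon)
        assert id_map2 == {cid: cid for cid in canon}


class TestClusterRepeats:
    def test_identical_repeats_one_cluster(self):
        assignment = cluster_repeats({"r1": "ACGT" * 8, "r2": "ACGT" * 8})
        assert len(set(assignment.values())) == 1

    def test_identity_threshold(self, rng):
        base = random_seq(31, rng)

        def mutated(n):
            out = list(base)
            for i in range(n):
                out[i * 7] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i * 7]]
            return "".join(out)

        # 4 differences: 27/31 = 87.1% < 90% -> separate clusters
        four = cluster_repeats({"r1": base, "r2": mutated(4)})
        assert len(set(four.values())) == 2
        # 2 differences: 29/31 = 93.5% > 90% -> one cluster
        two = cluster_repeats({"r1": base, "r2": mutated(2)})
        assert len(set(two.values())) == 1

    def test_order_invariance(self, rng):
        repeats = {f"r{i}": random_seq(31, rng) for i in range(8)}
        repeats["r8"] = repeats["r0"]
        a = cluster_repeats(dict(sorted(repeats.items())))
        b = cluster_repeats(dict(sorted(repeats.items(), reverse=True)))
        assert a == b


class TestIsNested:
    def test_subset_same_cluster(self):
        a = make_array("a", ["s1", "s2"])
        b = make_array("b", ["s1", "s2", "s3"])
        assert is_nested(a, b, SPACERS)
        assert not is_nested(b, a, SPACERS)

    def test_different_repeat_cluster(self):
        a = make_array("a", ["s1", "s2"], cluster="R0")
        b = make_array("b", ["s1", "s2", "s3"], cluster="R1")
        assert not is_nested(a, b, SPACERS)

    def test_strand_insensitive(self):
        seqs = dict(SPACERS)
        seqs["s2rc"] = revcomp(SPACERS["s2"])
        a = make_array("a", ["s1", "s2rc"])
        b = make_array("b", ["s1", "s2", "s3"])
        assert is_nested(a, b, seqs)


def brute_force_lineages(arrays, spacer_seqs):
    """Independent O(n^2) all-pairs implementation with the same tie rules."""
    keys = {a.array_id: spacer_keys(a, spacer_seqs) for a in arrays}
    by_id = {a.array_id: a for a in arrays}

    def tie_key(rec):
        return (rec.timepoint, -rec.n_spacers, rec.array_id)

    properly_nested = set()
    for a in arrays:
        for b in arrays:
            if a.array_id == b.array_id:
                continue
            if (a.repeat_cluster == b.repeat_cluster
                    and keys[a.array_id] < keys[b.array_id]):
                properly_nested.add(a.array_id)
                break
    maximal = [a for a in arrays if a.array_id not in properly_nested]
    # identical-keyset maximal arrays tie; one representative per class
    reps = {}
    for a in maximal:
        cls = (a.repeat_cluster, keys[a.array_id])
        if cls not in reps or tie_key(a) < tie_key(reps[cls]):
            reps[cls] = a
    rep_list = list(reps.values())
    assignment = {}
    for a in arrays:
        if a.array_id in {r.array_id for r in rep_list}:
            assignment[a.array_id] = a.array_id
            continue
        candidates = [r for r in rep_list
                      if r.repeat_cluster == a.repeat_cluster
                      and keys[a.array_id] <= keys[r.array_id]]
        best = min(candidates, key=lambda r: (
            -len(keys[a.array_id] & keys[r.array_id]),
            -len(keys[r.array_id]), r.array_id))
        assignment[a.array_id] = best.array_id
    return assignment


def random_arrays(rng, n, n_spacer_pool=10, n_clusters=2):
    pool = [f"s{i}" for i in range(n_spacer_pool)]
    arrays = []
    for i in range(n):
        size = int(rng.integers(1, 6))
        ids = list(rng.choice(pool, size=size, replace=False))
        arrays.append(make_array(
            f"a{i:03d}", ids, cluster=f"R{int(rng.integers(n_clusters))}",
            timepoint=int(rng.integers(5))))
    return arrays


class TestBuildLineages:
    def test_all_identical_one_lineage(self):
        arrays = [make_array(f"a{i}", ["s1", "s2"], timepoint=i) for i in range(4)]
        lineages = build_lineages(arrays, SPACERS)
        assert len(lineages) == 1
        assert lineages[0].representative == "a0"  # earliest timepoint wins
        assert lineages[0].members == {f"a{i}" for i in range(4)}

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            arrays = random_arrays(rng, int(rng.integers(5, 31)))
            got = build_lineages(arrays, SPACERS)
            expected = brute_force_lineages(arrays, SPACERS)
            got_map = {m: l.representative for l in got for m in l.members}
            assert got_map == expected

    def test_partition_property(self):
        rng = np.random.default_rng(9)
        arrays = random_arrays(rng, 40)
        lineages = build_lineages(arrays, SPACERS)
        seen = [m for l in lineages for m in l.members]
        assert sorted(seen) == sorted(a.array_id for a in arrays)

    def test_representative_maximality(self):
        rng = np.random.default_rng(10)
        arrays = random_arrays(rng, 40)
        by_id = {a.array_id: a for a in arrays}
        for lineage in build_lineages(arrays, SPACERS):
            rep_keys = spacer_keys(by_id[lineage.representative], SPACERS)
            for member in lineage.members:
                assert spacer_keys(by_id[member], SPACERS) <= rep_keys

    def test_synthetic_recovery(self):
        cfg = SimulationConfig(
            n_subjects=1, n_samples_per_subject=10, n_lineages_per_subject=5,
            n_mge=10, mge_len=400, gain_rate=0.5, loss_rate=0.0,
            truncation_prob=0.3, detection_prob=1.0, min_initial_size=5,
            rng_seed=3)
        truth = generate_community(cfg)
        ds = emit_observed_dataset(truth)
        for rec in ds.arrays:
            rec.repeat_cluster = rec.repeat_id  # distinct random repeats
        lineages = build_lineages(ds.arrays, ds.spacers)
        got = {}
        for lineage in lineages:
            for member in lineage.members:
                got[member] = lineage.lineage_id
        ids = sorted(got)
        ari = adjusted_rand_score(
            [truth.observed_membership[a] for a in ids],
            [got[a] for a in ids])
        assert ari >= 0.95


class TestConsistencyMetrics:
    def _metrics(self, arrays, seqs=SPACERS):
        lineages = build_lineages(arrays, seqs)
        assert len(lineages) == 1
        return lineage_consistency_metrics(
            lineages[0], {a.array_id: a for a in arrays}, seqs)

    def test_subsequence_consistent(self):
        arrays = [make_array("a", ["s1", "s2", "s3"]),
                  make_array("b", ["s1", "s3"], timepoint=1)]
        counts = self._metrics(arrays)
        assert counts["order_inconsistent_pairs"] == 0

    def test_whole_array_reversal_consistent(self):
        arrays = [make_array("a", ["s1", "s2", "s3"]),
                  make_array("b", ["s2", "s1"], timepoint=1)]
        counts = self._metrics(arrays)
        assert counts["order_inconsistent_pairs"] == 0

    def test_internal_rearrangement_inconsistent(self):
        arrays = [make_array("a", ["s1", "s2", "s3"]),
                  make_array("b", ["s1", "s3", "s2"], timepoint=1)]
        counts = self._metrics(arrays)
        assert counts["order_inconsistent_pairs"] == 1

    def test_mixed_strand_inversion(self):
        seqs = dict(SPACERS)
        seqs["s2rc"] = revcomp(SPACERS["s2"])
        arrays = [make_array("a", ["s1", "s2", "s3"]),
                  make_array("b", ["s1", "s2rc", "s3"], timepoint=1)]
        counts = self._metrics(arrays, seqs)
        assert counts["inversion_pairs"] == 1
        assert counts["order_inconsistent_pairs"] == 0

    def test_singleton_lineage_zero_counts(self):
        arrays = [make_array("a", ["s1", "s2"])]
        lineages = build_lineages(arrays, SPACERS)
        counts = lineage_consistency_metrics(
            lineages[0], {a.array_id: a for a in arrays}, SPACERS)
        assert counts == {"order_inconsistent_pairs": 0, "inversion_pairs": 0,
                          "orientation_inconsistent_pairs": 0, "total_pairs": 0}

    def test_no_rearrangement_generator_guarantee(self, small_truth):
        ds = emit_observed_dataset(small_truth, detection_prob=1.0,
                                   truncation_prob=0.4,
                                   rng=np.random.default_rng(6))
        for rec in ds.arrays:
            rec.repeat_cluster = rec.repeat_id
        arrays_by_id = {rec.array_id: rec for rec in ds.arrays}
        for subject in ds.subjects:
            subject_arrays = [r for r in ds.arrays if r.subject == subject]
            for lineage in build_lineages(subject_arrays, ds.spacers):
                counts = lineage_consistency_metrics(lineage, arrays_by_id, ds.spacers)
                assert counts["order_inconsistent_pairs"] == 0
                assert counts["inversion_pairs"] == 0
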
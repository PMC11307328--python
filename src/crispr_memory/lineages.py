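"""Array dereplication, repeat clustering, and nesting-based lineage building.

An array is nested within another when both carry repeats from the same
cluster and every spacer of the former (strand-insensitively) occurs in the
latter; spacer order is deliberately not consulted at this step. Lineages
are the arrays nested within a shared representative — an array not nested
within any other. Strict nesting never merges partially overlapping arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from crispr_memory.datasets import ArrayRecord
from crispr_memory.seq import as_bytes, canonical, revcomp

__all__ = [
    "Lineage",
    "dereplicate_sequences",
    "cluster_repeats",
    "spacer_keys",
    "is_nested",
    "build_lineages",
    "lineage_consistency_metrics",
]


@dataclass
class Lineage:
    """A representative array plus every array strictly nested within it."""

    lineage_id: str
    representative: str
    members: set[str]
    subject: str
    spacer_universe: frozenset[str]  # strand-insensitive spacer keys

    def __post_init__(self) -> None:
        assert self.representative in self.members


# ---------------------------------------------------------------------------
# Dereplication and repeat clustering

def dereplicate_sequences(seqs: Mapping[str, str], identity: float = 1.0,
                          ) -> tuple[dict[str, str], set[frozenset[str]]]:
    """Map every id of an identical sequence to one canonical id.

    Only exact (100%) identity collapses ids; exact reverse complements are
    kept distinct but cross-referenced as strand pairs in the second return
    value (pairs of canonical ids). The canonical id for a sequence group is
    the id of the lexicographically smallest (id) among holders of that
    exact sequence, chosen deterministically.
    """
    if identity != 1.0:
        raise NotImplementedError("dereplication is defined at 100% identity")
    by_seq: dict[str, list[str]] = {}
    for sid in sorted(seqs):
        by_seq.setdefault(seqs[sid].upper(), []).append(sid)
    canon_of_seq = {seq: ids[0] for seq, ids in by_seq.items()}
    id_map = {sid: canon_of_seq[seqs[sid].upper()] for sid in seqs}

    strand_pairs: set[frozenset[str]] = set()
    for seq, canon_id in canon_of_seq.items():
        rc = revcomp(seq)
        if rc != seq and rc in canon_of_seq:
            strand_pairs.add(frozenset({canon_id, canon_of_seq[rc]}))
    return id_map, strand_pairs


def _repeats_similar(a: str, b: str, min_identity: float,
                     min_coverage: float) -> bool:
    """True when some ungapped sliding overlap (either strand) exceeds both
    thresholds; coverage is overlap length over the longer sequence."""
    arr_a = as_bytes(a)
    longer = max(len(a), len(b))
    for cand in (b, revcomp(b)):
        arr_b = as_bytes(cand)
        for shift in range(-len(cand) + 1, len(a)):
            lo_a = max(0, shift)
            hi_a = min(len(a), shift + len(cand))
            overlap = hi_a - lo_a
            if overlap <= 0 or overlap / longer <= min_coverage:
                continue
            matches = int((arr_a[lo_a:hi_a] == arr_b[lo_a - shift:hi_a - shift]).sum())
            if matches / overlap > min_identity:
                return True
    return False


def cluster_repeats(repeats: Mapping[str, str], min_identity: float = 0.90,
                    min_coverage: float = 0.90) -> dict[str, str]:
    """Greedy single-linkage-to-seed clustering of (dereplicated) repeats.

    Seeds are processed longest-first (ties broken lexicographically by
    sequence then id); a repeat joins the first seed whose best ungapped
    sliding overlap exceeds both thresholds on either strand. Returns a map
    repeat id -> cluster seed id; deterministic for any input order.
    """
    order = sorted(repeats, key=lambda rid: (-len(repeats[rid]), repeats[rid], rid))
    seeds: list[str] = []
    assignment: dict[str, str] = {}
    for rid in order:
        seq = repeats[rid].upper()
        placed = False
        for seed_id in seeds:
            if _repeats_similar(repeats[seed_id].upper(), seq,
                                min_identity, min_coverage):
                assignment[rid] = seed_id
                placed = True
                break
        if not placed:
            seeds.append(rid)
            assignment[rid] = rid
    return assignment


# ---------------------------------------------------------------------------
# Nesting and lineage construction

def spacer_keys(record: ArrayRecord, spacer_seqs: Mapping[str, str]) -> frozenset[str]:
    """Strand-insensitive spacer identity keys for one array."""
    return frozenset(canonical(spacer_seqs[sid].upper()) for sid in record.spacer_ids)


def is_nested(a: ArrayRecord, b: ArrayRecord,
              spacer_seqs: Mapping[str, str]) -> bool:
    """True iff a's spacers (strand-insensitive) are a subset of b's and the
    two arrays fall in the same repeat cluster. Order is not consulted."""
    if a.repeat_cluster is None or b.repeat_cluster is None:
        raise ValueError("repeat_cluster must be assigned before nesting tests")
    if a.repeat_cluster != b.repeat_cluster:
        return False
    return spacer_keys(a, spacer_seqs) <= spacer_keys(b, spacer_seqs)


def _representative_tie_key(rec: ArrayRecord) -> tuple:
    # earliest timepoint, then most spacers, then lexicographic id
    return (rec.timepoint, -rec.n_spacers, rec.array_id)


def build_lineages(arrays: Sequence[ArrayRecord],
                   spacer_seqs: Mapping[str, str],
                   subject: str | None = None) -> list[Lineage]:
    """Partition one subject's arrays into lineages by strict nesting.

    Representatives are the arrays not strictly nested within any other
    array (ties among identical spacer sets resolved by earliest timepoint,
    then most spacers, then id). Every other array joins the representative
    it is nested within; when several qualify it joins the one sharing most
    spacers, then the larger representative, then the lexicographically
    smallest id.
    """
    if not arrays:
        return []
    if subject is None:
        subject = arrays[0].subject
    if any(rec.subject != subject for rec in arrays):
        raise ValueError("build_lineages expects arrays from a single subject")

    keys = {rec.array_id: spacer_keys(rec, spacer_seqs) for rec in arrays}
    by_id = {rec.array_id: rec for rec in arrays}

    # group arrays with identical (repeat cluster, spacer key set)
    groups: dict[tuple, list[ArrayRecord]] = {}
    for rec in arrays:
        if rec.repeat_cluster is None:
            raise ValueError(f"array {rec.array_id} lacks a repeat cluster")
        groups.setdefault((rec.repeat_cluster, keys[rec.array_id]), []).append(rec)

    group_list = list(groups.items())
    representatives: list[ArrayRecord] = []
    for (cluster, keyset), members in group_list:
        properly_nested = any(
            o_cluster == cluster and keyset < o_keyset
            for (o_cluster, o_keyset), _ in group_list
        )
        if not properly_nested:
            representatives.append(min(members, key=_representative_tie_key))

    lineages: dict[str, Lineage] = {}
    rep_ids = {rec.array_id for rec in representatives}
    for rep in sorted(representatives, key=lambda r: r.array_id):
        lineages[rep.array_id] = Lineage(
            lineage_id=f"{subject}_lin_{rep.array_id}",
            representative=rep.array_id,
            members={rep.array_id},
            subject=subject,
            spacer_universe=keys[rep.array_id],
        )

    for rec in arrays:
        if rec.array_id in rep_ids:
            continue
        candidates = [
            rep for rep in representatives
            if rep.repeat_cluster == rec.repeat_cluster
            and keys[rec.array_id] <= keys[rep.array_id]
        ]
        if not candidates:  # cannot happen: a maximal superset always exists
            raise AssertionError(f"array {rec.array_id} has no representative")
        best = min(
            candidates,
            key=lambda rep: (
                -len(keys[rec.array_id] & keys[rep.array_id]),
                -len(keys[rep.array_id]),
                rep.array_id,
            ),
        )
        lin = lineages[best.array_id]
        lin.members.add(rec.array_id)
        lin.spacer_universe = lin.spacer_universe | keys[rec.array_id]
    return sorted(lineages.values(), key=lambda l: l.lineage_id)


# ---------------------------------------------------------------------------
# Consistency metrics

def _shared_order(rec: ArrayRecord, shared: set[str],
                  spacer_seqs: Mapping[str, str]) -> list[str]:
    out = []
    for sid in rec.spacer_ids:
        key = canonical(spacer_seqs[sid].upper())
        if key in shared:
            out.append(key)
    return out


def lineage_consistency_metrics(lineage: Lineage,
                                arrays: Mapping[str, ArrayRecord],
                                spacer_seqs: Mapping[str, str]) -> dict[str, int]:
    """Pairwise order/inversion/orientation inconsistency counts.

    For every member pair sharing >= 2 spacers: the pair is order-
    inconsistent when the shared spacers appear in different relative order
    even after reversing one whole array (assembly strand is arbitrary); an
    inversion pair has shared spacers on mixed strands relative to each
    other; an orientation-inconsistent pair has two predicted orientations
    that conflict with the order-consistent alignment of the pair.
    """
    members = sorted(lineage.members)
    counts = {
        "order_inconsistent_pairs": 0,
        "inversion_pairs": 0,
        "orientation_inconsistent_pairs": 0,
        "total_pairs": 0,
    }
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            a, b = arrays[members[i]], arrays[members[j]]
            keys_a = {canonical(spacer_seqs[s].upper()) for s in a.spacer_ids}
            keys_b = {canonical(spacer_seqs[s].upper()) for s in b.spacer_ids}
            shared = keys_a & keys_b
            counts["total_pairs"] += 1
            if len(shared) < 2:
                continue
            order_a = _shared_order(a, shared, spacer_seqs)
            order_b = _shared_order(b, shared, spacer_seqs)
            forward_ok = order_a == order_b
            reverse_ok = order_a == order_b[::-1]
            if not (forward_ok or reverse_ok):
                counts["order_inconsistent_pairs"] += 1

            # strand relation per shared spacer: same sequence vs revcomp
            seq_a = {canonical(spacer_seqs[s].upper()): spacer_seqs[s].upper()
                     for s in a.spacer_ids}
            seq_b = {canonical(spacer_seqs[s].upper()): spacer_seqs[s].upper()
                     for s in b.spacer_ids}
            relations = {seq_a[k] == seq_b[k] for k in shared}
            if len(relations) > 1:
                counts["inversion_pairs"] += 1

            if a.orientation != "unknown" and b.orientation != "unknown":
                same_orient = a.orientation == b.orientation
                if forward_ok and not reverse_ok and not same_orient:
                    counts["orientation_inconsistent_pairs"] += 1
                elif reverse_ok and not forward_ok and same_orient:
                    counts["orientation_inconsistent_pairs"] += 1
    return counts
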
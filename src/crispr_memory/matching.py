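"""Protospacer search: ungapped spacer-vs-subject matching on both strands.

Matching is exact-coordinate Hamming comparison at every admissible offset.
At 95% identity on ~34-nt queries, gapped placements cannot satisfy the
coverage requirement, so the ungapped scan reproduces a short-query search
in this regime while remaining oracle-verifiable. Partial coverage is only
admitted where the query overhangs a subject end (contig edge); interior
partial matches are never generated. Ambiguity codes count as mismatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from crispr_memory.config import Parameters
from crispr_memory.datasets import Contig
from crispr_memory.errors import ProvenanceError, ValidationError
from crispr_memory.seq import as_bytes, revcomp

__all__ = [
    "MatchHit",
    "find_matches",
    "mask_crispr_regions",
    "flag_promiscuous_spacers",
    "local_protospacer_scan",
    "hits_to_frame",
]

MIN_QUERY_LEN = 8


@dataclass(frozen=True)
class MatchHit:
    """One spacer placement on a subject sequence (0-based, half-open)."""

    spacer_id: str
    subject_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    mismatches: int
    identity: float
    coverage: float

    @property
    def accuracy(self) -> str:
        if self.mismatches == 0 and self.coverage == 1.0:
            return "identical"
        return "highly_similar"


def _scan_full(spacer_arr: np.ndarray, subject_arr: np.ndarray) -> np.ndarray:
    """Mismatch count of the spacer against every full-length window."""
    L = spacer_arr.size
    n = subject_arr.size
    if n < L:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(subject_arr, L)
    return (windows != spacer_arr).sum(axis=1)


def find_matches(spacer: str, subject: str, min_identity: float = 0.95,
                 min_coverage: float = 0.95, spacer_id: str = "query",
                 subject_id: str = "subject") -> list[MatchHit]:
    """All placements of a spacer (either strand) passing identity/coverage.

    Identity is aligned matches divided by the full spacer length; coverage
    is aligned length divided by spacer length. Coverage < 1 occurs only
    when the spacer overhangs a subject end. Hits are sorted by (start,
    end, strand) and deduplicated keeping the lowest-mismatch record.
    """
    spacer = spacer.upper()
    subject = subject.upper()
    L = len(spacer)
    if L < MIN_QUERY_LEN:
        raise ValidationError(f"query too short: {L} < {MIN_QUERY_LEN} nt")
    if not subject:
        return []
    subject_arr = as_bytes(subject)
    n = len(subject)
    min_overlap = int(np.ceil(min_coverage * L))

    hits: dict[tuple[int, int, str], MatchHit] = {}

    def _add(start: int, end: int, strand: str, mismatches: int) -> None:
        overlap = end - start
        identity = (overlap - mismatches) / L
        coverage = overlap / L
        if identity < min_identity or coverage < min_coverage:
            return
        key = (start, end, strand)
        prev = hits.get(key)
        if prev is None or mismatches < prev.mismatches:
            hits[key] = MatchHit(spacer_id, subject_id, start, end, strand,
                                 mismatches, identity, coverage)

    max_mm = int(np.floor((1.0 - min_identity) * L))
    for strand, query in (("+", spacer), ("-", revcomp(spacer))):
        q_arr = as_bytes(query)
        mm = _scan_full(q_arr, subject_arr)
        # full-length placements
        for off in np.nonzero(mm <= max_mm)[0]:
            _add(int(off), int(off) + L, strand, int(mm[off]))
        # edge overhangs: overlap in [min_overlap, L)
        if min_overlap < L:
            for overlap in range(min_overlap, L):
                # query overhangs the left subject end: query suffix aligns
                if overlap <= n:
                    mism = int((q_arr[L - overlap:] != subject_arr[:overlap]).sum())
                    _add(0, overlap, strand, mism)
                    # query overhangs the right subject end: query prefix aligns
                    mism = int((q_arr[:overlap] != subject_arr[n - overlap:]).sum())
                    _add(n - overlap, n, strand, mism)

    return sorted(hits.values(), key=lambda h: (h.start, h.end, h.strand))


def scan_spacers(spacers: Mapping[str, str], subjects: Mapping[str, str],
                 min_identity: float = 0.95, min_coverage: float = 0.95,
                 seed_len: int = 12) -> list[MatchHit]:
    """Hit-identical batch version of :func:`find_matches` over many subjects.

    Uses a k-mer index with pigeonhole block seeds: a full-length placement
    with <= allowed mismatches must contain one exact block, so seeding on
    ``allowed + 1`` blocks finds every hit that the exhaustive scan reports
    (falls back to the sliding scan when blocks are shorter than the seed).
    Edge-overhang placements are checked directly per subject end.
    """
    index: dict[str, list[tuple[str, int]]] = {}
    for subject_id in sorted(subjects):
        seq = subjects[subject_id].upper()
        for i in range(len(seq) - seed_len + 1):
            index.setdefault(seq[i:i + seed_len], []).append((subject_id, i))

    hits: list[MatchHit] = []
    for spacer_id in sorted(spacers):
        spacer = spacers[spacer_id].upper()
        L = len(spacer)
        if L < MIN_QUERY_LEN:
            raise ValidationError(f"query too short: {L} < {MIN_QUERY_LEN} nt")
        max_mm = int(np.floor((1.0 - min_identity) * L))
        n_blocks = max_mm + 1
        block = L // n_blocks
        if block < seed_len:
            for subject_id in sorted(subjects):
                hits.extend(find_matches(spacer, subjects[subject_id],
                                         min_identity, min_coverage,
                                         spacer_id, subject_id))
            continue
        min_overlap = int(np.ceil(min_coverage * L))
        best: dict[tuple[str, int, int, str], MatchHit] = {}

        def _add(subject_id: str, start: int, end: int, strand: str, mm: int) -> None:
            overlap = end - start
            if (overlap - mm) / L < min_identity or overlap / L < min_coverage:
                return
            key = (subject_id, start, end, strand)
            prev = best.get(key)
            if prev is None or mm < prev.mismatches:
                best[key] = MatchHit(spacer_id, subject_id, start, end, strand,
                                     mm, (overlap - mm) / L, overlap / L)

        for strand, query in (("+", spacer), ("-", revcomp(spacer))):
            candidates: set[tuple[str, int]] = set()
            for b in range(n_blocks):
                seed_start = b * block
                for subject_id, pos in index.get(
                        query[seed_start:seed_start + seed_len], ()):
                    start = pos - seed_start
                    if 0 <= start <= len(subjects[subject_id]) - L:
                        candidates.add((subject_id, start))
            for subject_id, start in candidates:
                window = subjects[subject_id].upper()[start:start + L]
                mm = sum(a != b for a, b in zip(query, window))
                if mm <= max_mm:
                    _add(subject_id, start, start + L, strand, mm)
            # edge overhangs
            if min_overlap < L:
                for subject_id in sorted(subjects):
                    seq = subjects[subject_id].upper()
                    n = len(seq)
                    for overlap in range(min_overlap, min(L, n + 1)):
                        edge_mm = overlap - int(np.ceil(min_identity * L))
                        if edge_mm < 0:
                            continue
                        left = seq[:overlap]
                        q_suffix = query[L - overlap:]
                        if edge_mm == 0:
                            if q_suffix == left:
                                _add(subject_id, 0, overlap, strand, 0)
                        else:
                            mm = sum(a != b for a, b in zip(q_suffix, left))
                            _add(subject_id, 0, overlap, strand, mm)
                        right = seq[n - overlap:]
                        q_prefix = query[:overlap]
                        if edge_mm == 0:
                            if q_prefix == right:
                                _add(subject_id, n - overlap, n, strand, 0)
                        else:
                            mm = sum(a != b for a, b in zip(q_prefix, right))
                            _add(subject_id, n - overlap, n, strand, mm)
        hits.extend(sorted(best.values(),
                           key=lambda h: (h.subject_id, h.start, h.end, h.strand)))
    return hits


def hits_to_frame(hits: Iterable[MatchHit]) -> pd.DataFrame:
    rows = [
        {
            "spacer_id": h.spacer_id, "subject_id": h.subject_id,
            "start": h.start, "end": h.end, "strand": h.strand,
            "mismatches": h.mismatches, "identity": h.identity,
            "coverage": h.coverage, "accuracy": h.accuracy,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=["spacer_id", "subject_id", "start", "end", "strand",
                 "mismatches", "identity", "coverage", "accuracy"],
    )


def mask_crispr_regions(hits: Sequence[MatchHit],
                        known_array_intervals: Mapping[str, Sequence[tuple[int, int]]],
                        repeat_hits: Mapping[str, Sequence[tuple[int, int]]],
                        margin: int = 100) -> tuple[list[MatchHit], list[tuple[MatchHit, str]]]:
    """Drop hits inside known CRISPR arrays or near known repeat hits.

    A hit is removed if it overlaps any known array interval on its subject,
    or lies within ``margin`` nt of any repeat hit. Returns the surviving
    hits and a log of (hit, reason) removals.
    """
    if margin < 0:
        raise ValidationError(f"margin must be >= 0, got {margin}")
    kept: list[MatchHit] = []
    removed: list[tuple[MatchHit, str]] = []
    for hit in hits:
        reason = None
        for lo, hi in known_array_intervals.get(hit.subject_id, ()):
            if hit.start < hi and lo < hit.end:
                reason = "inside_known_array"
                break
        if reason is None:
            for lo, hi in repeat_hits.get(hit.subject_id, ()):
                if hit.start < hi and lo < hit.end:
                    reason = "overlaps_repeat_hit"
                    break
                distance = lo - hit.end if hit.end <= lo else hit.start - hi
                if distance <= margin:
                    reason = "near_repeat_hit"
                    break
        if reason is None:
            kept.append(hit)
        else:
            removed.append((hit, reason))
    return kept, removed


def flag_promiscuous_spacers(hit_table: pd.DataFrame,
                             absolute_cap: int = 1000,
                             ratio: float = 10.0,
                             ) -> tuple[pd.DataFrame, list[str]]:
    """Remove spacers with anomalously many hits.

    A spacer is flagged when its total hit count exceeds
    ``max(absolute_cap, ratio x next-highest count)``. With a single spacer
    in the table the ratio rule cannot apply; the absolute cap still does.
    """
    if hit_table.empty:
        return hit_table, []
    counts = hit_table.groupby("spacer_id").size().sort_values(ascending=False)
    flagged: list[str] = []
    for spacer_id, count in counts.items():
        others = counts.drop(spacer_id)
        threshold = float(absolute_cap)
        if not others.empty:
            threshold = max(threshold, ratio * float(others.max()))
        if count > threshold:
            flagged.append(spacer_id)
    kept = hit_table[~hit_table["spacer_id"].isin(flagged)].reset_index(drop=True)
    return kept, sorted(flagged)


def local_protospacer_scan(spacers: Mapping[str, str],
                           contigs: Mapping[str, Contig],
                           subject_id: str,
                           params: Parameters,
                           spacer_subjects: Mapping[str, str] | None = None,
                           known_array_intervals: Mapping[str, Sequence[tuple[int, int]]] | None = None,
                           repeat_hits: Mapping[str, Sequence[tuple[int, int]]] | None = None,
                           ) -> pd.DataFrame:
    """Search spacers against the contigs of one subject (all samples pooled).

    ``spacer_subjects`` restricts each spacer to its own subject; when
    omitted, all given spacers are assumed to belong to ``subject_id``.
    Masking and promiscuity filtering are applied before returning.
    """
    local_contigs: list[Contig] = []
    for contig in contigs.values():
        if contig.subject is None:
            raise ProvenanceError(f"contig {contig.contig_id} lacks subject annotation")
        if contig.subject == subject_id:
            local_contigs.append(contig)

    queries = {
        spacer_id: seq for spacer_id, seq in sorted(spacers.items())
        if spacer_subjects is None or spacer_subjects.get(spacer_id) == subject_id
    }
    all_hits = scan_spacers(
        queries, {c.contig_id: c.seq for c in local_contigs},
        min_identity=params.protospacer_min_identity,
        min_coverage=params.protospacer_min_coverage,
    )
    kept, _ = mask_crispr_regions(all_hits, known_array_intervals or {},
                                  repeat_hits or {}, params.repeat_mask_margin)
    table = hits_to_frame(kept)
    table, _ = flag_promiscuous_spacers(table, params.promiscuity_cap,
                                        params.promiscuity_ratio)
    return table
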
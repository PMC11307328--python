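"""Spacer target classification.

Each spacer is assigned one target class (lytic/non-lysogenic phage,
lysogenic phage, plasmid, other MGE, ambiguous, unknown), an accuracy tier
(identical, highly similar, none), taxonomic tags, and a local-adaptation
flag. Spacers without database hits but with local protospacers are rescued
by a neighborhood homology search against the MGE database.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from crispr_memory.config import Parameters
from crispr_memory.datasets import Contig, MgeRecord
from crispr_memory.errors import CoordinateError, ValidationError
from crispr_memory.matching import MatchHit
from crispr_memory.seq import revcomp

__all__ = [
    "TargetAssignment",
    "TARGET_CLASSES",
    "annotate_lifestyle_and_tags",
    "assign_from_mgedb",
    "assign_from_neighborhood",
    "flag_local_adaptation",
    "assignments_to_frame",
]

logger = logging.getLogger(__name__)

TARGET_CLASSES = (
    "lytic_or_nonlysogenic_phage",
    "lysogenic_phage",
    "plasmid",
    "other_mge",
    "ambiguous",
    "unknown",
)


@dataclass
class TargetAssignment:
    spacer_id: str
    target_class: str = "unknown"
    accuracy: str = "none"  # identical | highly_similar | none
    locally_adapted: bool = False
    tags: set[str] = field(default_factory=set)
    supporting_hits: list[str] = field(default_factory=list)


def _effective_class(mge: MgeRecord) -> str:
    """Collapse (class, lifestyle) into the spacer target-class vocabulary.

    Lifestyle refines viral records only; plasmids and other MGE are never
    relabeled by integrase evidence.
    """
    if mge.mge_class == "virus":
        if mge.lifestyle == "lysogenic":
            return "lysogenic_phage"
        return "lytic_or_nonlysogenic_phage"
    if mge.mge_class == "plasmid":
        return "plasmid"
    return "other_mge"


def annotate_lifestyle_and_tags(mge_db: Mapping[str, MgeRecord],
                                lifestyle: Mapping[str, str] | None = None,
                                crass_ids: Iterable[str] = (),
                                infant_ids: Iterable[str] = (),
                                ) -> dict[str, MgeRecord]:
    """Attach lifestyle labels and crass-like/infant-gut tags to MGE records.

    Viral records missing from the lifestyle table default to
    lytic_or_nonlysogenic with a warning. Tags referencing unknown MGE ids
    raise KeyError.
    """
    lifestyle = dict(lifestyle or {})
    for tagged in (*crass_ids, *infant_ids):
        if tagged not in mge_db:
            raise KeyError(f"tag refers to unknown MGE id {tagged}")
    crass = set(crass_ids)
    infant = set(infant_ids)
    out: dict[str, MgeRecord] = {}
    n_defaulted = 0
    for mge_id, rec in mge_db.items():
        ls = rec.lifestyle
        if mge_id in lifestyle:
            ls = lifestyle[mge_id]
        if rec.mge_class == "virus" and ls is None:
            ls = "lytic_or_nonlysogenic"
            n_defaulted += 1
        out[mge_id] = MgeRecord(
            mge_id=mge_id, seq=rec.seq, mge_class=rec.mge_class, lifestyle=ls,
            crass_like=rec.crass_like or mge_id in crass,
            infant_gut=rec.infant_gut or mge_id in infant,
        )
    if n_defaulted:
        logger.warning("defaulted lifestyle to lytic_or_nonlysogenic for %d viral records",
                       n_defaulted)
    return out


def assign_from_mgedb(spacer_id: str, hits: Sequence[MatchHit],
                      mge_db: Mapping[str, MgeRecord]) -> TargetAssignment:
    """Class consensus over MGE-database hits.

    The class is the unique effective class among hit MGEs; any conflict
    yields ``ambiguous``. Accuracy is the best tier over all hits. Tags are
    the union over hit MGEs.
    """
    if not hits:
        return TargetAssignment(spacer_id=spacer_id)
    classes: set[str] = set()
    tags: set[str] = set()
    best_accuracy = "highly_similar"
    supporting = []
    for hit in hits:
        mge = mge_db.get(hit.subject_id)
        if mge is None:
            raise ValidationError(f"hit references unannotated MGE {hit.subject_id}")
        classes.add(_effective_class(mge))
        if mge.crass_like:
            tags.add("crass_like")
        if mge.infant_gut:
            tags.add("infant_gut")
        if hit.accuracy == "identical":
            best_accuracy = "identical"
        supporting.append(f"{hit.subject_id}:{hit.start}-{hit.end}{hit.strand}")
    target_class = classes.pop() if len(classes) == 1 else "ambiguous"
    return TargetAssignment(
        spacer_id=spacer_id, target_class=target_class, accuracy=best_accuracy,
        tags=tags, supporting_hits=sorted(supporting),
    )


# ---------------------------------------------------------------------------
# Neighborhood rescue

def _kmer_anchored_score(query: str, subject: str, k: int = 16) -> int:
    """Best additive homology score (+1 per matched nt) between query and
    subject using exact k-mer anchors extended to maximal exact segments."""
    best = 0
    subject_index: dict[str, list[int]] = {}
    for i in range(len(subject) - k + 1):
        subject_index.setdefault(subject[i:i + k], []).append(i)
    for q in (query, revcomp(query)):
        seen: set[tuple[int, int]] = set()
        for i in range(0, len(q) - k + 1):
            for j in subject_index.get(q[i:i + k], ()):
                # extend to the maximal exact segment on this diagonal
                lo_q, lo_s = i, j
                while lo_q > 0 and lo_s > 0 and q[lo_q - 1] == subject[lo_s - 1]:
                    lo_q -= 1
                    lo_s -= 1
                if (lo_q - lo_s, lo_q) in seen:
                    continue
                hi_q, hi_s = i + k, j + k
                while hi_q < len(q) and hi_s < len(subject) and q[hi_q] == subject[hi_s]:
                    hi_q += 1
                    hi_s += 1
                seen.add((lo_q - lo_s, lo_q))
                best = max(best, hi_q - lo_q)
    return best


def significance_floor(n_query: int, n_subject: int, evalue: float) -> int:
    """Minimum exact-segment length whose expected random occurrence count
    in a uniform-ACGT comparison of these sizes is below ``evalue``."""
    if n_query <= 0 or n_subject <= 0:
        return 1
    return max(1, math.ceil(math.log(n_query * n_subject / evalue, 4)))


def assign_from_neighborhood(local_hit: MatchHit, contig: Contig,
                             mge_db: Mapping[str, MgeRecord],
                             params: Parameters) -> str:
    """Rescue a class for an unclassified spacer via its protospacer
    neighborhood.

    Extracts the flanked window around the local protospacer (clipped at
    contig ends), scores it against every MGE record with a k-mer-anchored
    exact-extension score, keeps hits scoring at least ``score_ratio`` of
    the best significant hit, and returns the unique class among them
    (conflict -> ambiguous, nothing significant -> unknown).
    """
    if not (0 <= local_hit.start < local_hit.end <= len(contig.seq)):
        raise CoordinateError(
            f"protospacer {local_hit.start}-{local_hit.end} outside contig "
            f"{contig.contig_id} (length {len(contig.seq)})")
    flank = params.neighborhood_flank_target
    lo = max(0, local_hit.start - flank)
    hi = min(len(contig.seq), local_hit.end + flank)
    neighborhood = contig.seq[lo:hi]

    scores: dict[str, int] = {}
    for mge_id, mge in mge_db.items():
        floor = significance_floor(len(neighborhood), len(mge.seq),
                                   params.neighborhood_evalue_analog)
        score = _kmer_anchored_score(neighborhood, mge.seq)
        if score >= floor:
            scores[mge_id] = score
    if not scores:
        return "unknown"
    best = max(scores.values())
    kept_classes = {
        _effective_class(mge_db[mge_id])
        for mge_id, score in scores.items()
        if score >= params.neighborhood_score_ratio * best
    }
    return kept_classes.pop() if len(kept_classes) == 1 else "ambiguous"


def flag_local_adaptation(assignments: Mapping[str, TargetAssignment],
                          local_hits: pd.DataFrame) -> dict[str, TargetAssignment]:
    """Set locally_adapted on every spacer with >= 1 surviving local hit."""
    locally = set(local_hits["spacer_id"]) if not local_hits.empty else set()
    for spacer_id, assignment in assignments.items():
        assignment.locally_adapted = spacer_id in locally
    return dict(assignments)


def assignments_to_frame(assignments: Mapping[str, TargetAssignment]) -> pd.DataFrame:
    rows = [
        {
            "spacer_id": a.spacer_id,
            "target_class": a.target_class,
            "accuracy": a.accuracy,
            "locally_adapted": str(a.locally_adapted).lower(),
            "tags": ",".join(sorted(a.tags)) if a.tags else ".",
            "supporting_hits": ",".join(a.supporting_hits) if a.supporting_hits else ".",
        }
        for a in sorted(assignments.values(), key=lambda a: a.spacer_id)
    ]
    return pd.DataFrame(rows, columns=["spacer_id", "target_class", "accuracy",
                                       "locally_adapted", "tags", "supporting_hits"])
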
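"""State-string encoding, alignment, similarity network, and clustering.

Each episode's timeline is encoded over a six-letter alphabet covering the
presence/absence combinations of (lineage, spacer, target) — the two
combinations with a spacer but no lineage are unreachable. Strings are
trimmed of empty states at both ends, internal empty runs collapse to a
single letter, and all pairs are globally aligned with affine gap scoring
(1 match, -2 mismatch, -2 gap open, -1 gap extend). Normalized positive
scores form an undirected similarity network clustered by a two-level
map-equation partition (best of N trials).
"""

from __future__ import annotations

import random as _random
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import igraph
import networkx as nx

from crispr_memory.dynamics import SpacerEpisode
from crispr_memory.errors import EmptyStateStringError, ValidationError

__all__ = [
    "StateString",
    "LETTER_OF_STATE",
    "encode_states",
    "encode_trajectory",
    "align_state_strings",
    "build_similarity_network",
    "cluster_network",
    "summarize_cluster",
]

# (lineage, spacer, target) -> letter; spacer implies lineage, so exactly
# six of the eight combinations are reachable
LETTER_OF_STATE = {
    (False, False, False): "A",  # empty
    (False, False, True): "B",   # target only
    (True, False, False): "C",   # lineage only
    (True, False, True): "D",    # lineage + target
    (True, True, False): "E",    # lineage + spacer
    (True, True, True): "F",     # lineage + spacer + target
}

ALPHABET = "ABCDEF"
EMPTY = "A"


@dataclass
class StateString:
    episode_id: str
    letters: str
    sample_indices: tuple[int, ...]  # timeline indices retained per letter


def encode_states(raw: Sequence[str]) -> tuple[str, tuple[int, ...]]:
    """Trim empty letters from both ends; collapse internal empty runs.

    Returns the compacted string and, per retained letter, the index of the
    contributing raw state (the first of a collapsed run).
    """
    if any(c not in ALPHABET for c in raw):
        raise ValidationError(f"letters must be in {ALPHABET}")
    non_empty = [i for i, c in enumerate(raw) if c != EMPTY]
    if not non_empty:
        raise EmptyStateStringError("trajectory has no non-empty state")
    lo, hi = non_empty[0], non_empty[-1]
    letters: list[str] = []
    indices: list[int] = []
    for i in range(lo, hi + 1):
        if raw[i] == EMPTY and letters and letters[-1] == EMPTY:
            continue
        letters.append(raw[i])
        indices.append(i)
    return "".join(letters), tuple(indices)


def encode_trajectory(episode: SpacerEpisode) -> StateString:
    """Encode one episode's full timeline as a compacted state string."""
    raw: list[str] = []
    for lineage, spacer, target in zip(
            episode.lineage_present, episode.spacer_present, episode.target_present):
        if spacer and not lineage:
            raise ValidationError(
                f"episode {episode.episode_id}: spacer present without lineage")
        raw.append(LETTER_OF_STATE[(lineage, spacer, target)])
    letters, indices = encode_states(raw)
    return StateString(episode_id=episode.episode_id, letters=letters,
                       sample_indices=indices)


# ---------------------------------------------------------------------------
# Alignment

NEG_INF = float("-inf")


def align_state_strings(s1: str, s2: str, match: int = 1, mismatch: int = -2,
                        gap_open: int = -2, gap_extend: int = -1) -> float:
    """Optimal global alignment score with affine gaps (Gotoh DP).

    A gap of length g costs gap_open + (g - 1) * gap_extend; end gaps are
    penalized. An empty string aligns as one pure gap of the other string's
    length (score 0 when both are empty).
    """
    n, m = len(s1), len(s2)

    def gap_cost(length: int) -> float:
        return 0.0 if length == 0 else gap_open + (length - 1) * gap_extend

    if n == 0 or m == 0:
        return gap_cost(max(n, m))

    # M: align i,j; X: gap in s2 (s1 char consumed); Y: gap in s1
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_cost(i)
    for j in range(1, m + 1):
        Y[0][j] = gap_cost(j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if s1[i - 1] == s2[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def build_similarity_network(strings: Mapping[str, str], match: int = 1,
                             mismatch: int = -2, gap_open: int = -2,
                             gap_extend: int = -1,
                             keep_zero: bool = False) -> nx.Graph:
    """Undirected similarity network over state strings.

    Edge weight is the alignment score normalized by the longer string's
    length; non-positive weights are discarded (``keep_zero`` retains exact
    zeros). Every string is a node even when isolated.
    """
    graph = nx.Graph()
    ids = sorted(strings)
    graph.add_nodes_from(ids)
    for a_idx in range(len(ids)):
        for b_idx in range(a_idx + 1, len(ids)):
            a, b = ids[a_idx], ids[b_idx]
            score = align_state_strings(strings[a], strings[b], match, mismatch,
                                        gap_open, gap_extend)
            weight = score / max(len(strings[a]), len(strings[b]))
            if weight > 0 or (keep_zero and weight == 0):
                graph.add_edge(a, b, weight=weight)
    return graph


def cluster_network(graph: nx.Graph, trials: int = 200,
                    seed: int = 0) -> dict[str, int]:
    """Two-level map-equation community detection (best of ``trials``).

    Deterministic for a given seed; isolated nodes become singleton
    clusters. Returns node -> cluster id (0-based, ordered by decreasing
    cluster size then smallest member).
    """
    nodes = sorted(graph.nodes)
    if not nodes:
        return {}
    index = {node: i for i, node in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    weights = [float(graph.edges[u, v].get("weight", 1.0)) for u, v in graph.edges]
    g = igraph.Graph(n=len(nodes), edges=edges, directed=False)

    state = _random.getstate()
    try:
        _random.seed(seed)
        clustering = g.community_infomap(
            edge_weights=weights if edges else None, trials=trials)
    finally:
        _random.setstate(state)

    groups: dict[int, list[str]] = {}
    for node, community in zip(nodes, clustering.membership):
        groups.setdefault(community, []).append(node)
    ordered = sorted(groups.values(), key=lambda members: (-len(members), min(members)))
    return {node: cid for cid, members in enumerate(ordered) for node in members}


# ---------------------------------------------------------------------------
# Cluster summaries

def summarize_cluster(member_ids: Sequence[str],
                      strings: Mapping[str, str],
                      episode_classes: Mapping[str, str] | None = None,
                      global_class_freq: Mapping[str, float] | None = None) -> dict:
    """Occupancy, transition, and class-association summary of one cluster.

    Transitions between adjacent non-empty letters are direct; transitions
    spanning a collapsed empty letter are indirect. Probabilities are
    row-normalized over total (direct + indirect) counts per source state.
    """
    if not member_ids:
        raise ValidationError("cluster must be non-empty")
    occupancy: Counter[str] = Counter()
    direct: Counter[tuple[str, str]] = Counter()
    indirect: Counter[tuple[str, str]] = Counter()
    for eid in member_ids:
        s = strings[eid]
        occupancy.update(s)
        i = 0
        while i < len(s) - 1:
            a, b = s[i], s[i + 1]
            if a != EMPTY and b != EMPTY:
                direct[(a, b)] += 1
                i += 1
            elif b == EMPTY and i + 2 < len(s):
                indirect[(a, s[i + 2])] += 1
                i += 2
            else:
                i += 1

    totals: Counter[str] = Counter()
    for (a, _), c in direct.items():
        totals[a] += c
    for (a, _), c in indirect.items():
        totals[a] += c
    transitions = {}
    for a, b in sorted(set(direct) | set(indirect)):
        total = direct[(a, b)] + indirect[(a, b)]
        transitions[f"{a}->{b}"] = {
            "direct": direct[(a, b)],
            "indirect": indirect[(a, b)],
            "total": total,
            "probability": total / totals[a],
        }

    summary = {
        "n_members": len(member_ids),
        "occupancy": dict(sorted(occupancy.items())),
        "transitions": transitions,
    }
    if episode_classes is not None:
        comp: Counter[str] = Counter(episode_classes[eid] for eid in member_ids
                                     if eid in episode_classes)
        total = sum(comp.values())
        composition = {cls: count / total for cls, count in sorted(comp.items())}
        summary["class_composition"] = composition
        if global_class_freq:
            summary["class_association"] = {
                cls: (frac / global_class_freq[cls] if global_class_freq.get(cls) else None)
                for cls, frac in composition.items()
            }
    return summary
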
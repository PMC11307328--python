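"""Acquisition episodes and immunity-effect statistics.

An episode is the longitudinal record of one spacer-target pair within one
CRISPR lineage. Episodes are eligible when the spacer first appears
strictly later than its lineage and is present in at least two samples;
samples where the lineage is undetected are excluded from phase statistics.
Retained samples split into four phases: before, acquisition,
after-with-spacer, and after-no-spacer. Abundances are max-normalized per
target series; medians carry percentile-bootstrap CIs and prevalences carry
exact Clopper-Pearson CIs.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from crispr_memory.config import Parameters
from crispr_memory.datasets import ArrayRecord, Dataset
from crispr_memory.errors import ValidationError
from crispr_memory.lineages import Lineage
from crispr_memory.positions import clopper_pearson
from crispr_memory.seq import canonical

__all__ = [
    "SpacerEpisode",
    "PHASES",
    "select_episodes",
    "episodes_from_truth",
    "target_abundance_series",
    "normalize_by_max",
    "phase_assignment",
    "phase_statistics",
    "diversity_analysis",
]

logger = logging.getLogger(__name__)

PHASES = ("before", "acquisition", "after_with_spacer", "after_no_spacer")

DEFAULT_TEST_PAIRS = (
    ("before", "acquisition"),
    ("before", "after_with_spacer"),
    ("before", "after_no_spacer"),
    ("after_with_spacer", "after_no_spacer"),
)


@dataclass
class SpacerEpisode:
    episode_id: str
    spacer_key: str           # strand-insensitive canonical spacer sequence
    lineage_id: str
    target_id: str
    subject: str
    timepoints: list[int]     # full subject timeline
    lineage_present: list[bool]
    spacer_present: list[bool]
    target_present: list[bool]
    abundance: list[float]    # raw per-sample abundance (full timeline)
    acquisition_sample: int

    def retained(self) -> list[int]:
        """Indices of lineage-present samples (phase statistics domain)."""
        return [i for i, p in enumerate(self.lineage_present) if p]


# ---------------------------------------------------------------------------
# Episode selection

def _lineage_presence(lineage: Lineage, arrays: Mapping[str, ArrayRecord],
                      timepoints: Sequence[int],
                      spacer_seqs: Mapping[str, str],
                      ) -> tuple[list[bool], dict[str, list[bool]]]:
    """Per-sample lineage presence and per-spacer-key presence vectors."""
    present = [False] * len(timepoints)
    t_index = {t: i for i, t in enumerate(timepoints)}
    key_presence: dict[str, list[bool]] = {}
    for array_id in lineage.members:
        rec = arrays[array_id]
        i = t_index[rec.timepoint]
        present[i] = True
        for sid in rec.spacer_ids:
            key = canonical(spacer_seqs[sid].upper())
            key_presence.setdefault(key, [False] * len(timepoints))[i] = True
    return present, key_presence


def select_episodes(dataset: Dataset, lineages: Sequence[Lineage],
                    local_hits: pd.DataFrame,
                    spacer_targets: Mapping[str, Sequence[str]],
                    params: Parameters) -> list[SpacerEpisode]:
    """Build eligible episodes for every (spacer, target) pair with a local
    protospacer.

    ``spacer_targets`` maps spacer ids to the abundance-table target ids
    their protospacers belong to (resolved from reference-database hits).
    Eligibility: the spacer's first appearance is strictly later than its
    lineage's, and the spacer is observed in >= ``min_spacer_samples``
    samples. Episodes whose target series is all zero are excluded.
    """
    arrays = {rec.array_id: rec for rec in dataset.arrays}
    local_spacers = set(local_hits["spacer_id"]) if not local_hits.empty else set()

    # canonical key -> target ids, restricted to locally adapted spacers
    key_targets: dict[str, set[str]] = {}
    for spacer_id in sorted(local_spacers):
        targets = spacer_targets.get(spacer_id, ())
        if not targets:
            continue
        key = canonical(dataset.spacers[spacer_id].upper())
        key_targets.setdefault(key, set()).update(targets)

    abundance = dataset.abundance
    episodes: list[SpacerEpisode] = []
    for lineage in sorted(lineages, key=lambda l: l.lineage_id):
        timeline = dataset.timepoints[lineage.subject]
        present, key_presence = _lineage_presence(
            lineage, arrays, timeline, dataset.spacers)
        first_lineage = present.index(True)
        for key in sorted(key_presence):
            if key not in key_targets:
                continue
            spacer_vec = key_presence[key]
            n_present = sum(spacer_vec)
            if n_present < params.min_spacer_samples:
                continue
            first_spacer = spacer_vec.index(True)
            if first_spacer <= first_lineage:
                continue
            for target_id in sorted(key_targets[key]):
                series = target_abundance_series(
                    target_id, lineage.subject, timeline, abundance)
                if not any(v > 0 for v in series):
                    logger.info("episode %s/%s/%s: all-zero target series, excluded",
                                lineage.lineage_id, key[:8], target_id)
                    continue
                episodes.append(SpacerEpisode(
                    episode_id=f"ep_{lineage.lineage_id}_{target_id}_{key[:8]}",
                    spacer_key=key, lineage_id=lineage.lineage_id,
                    target_id=target_id, subject=lineage.subject,
                    timepoints=list(timeline),
                    lineage_present=list(present),
                    spacer_present=list(spacer_vec),
                    target_present=[v > 0 for v in series],
                    abundance=list(series),
                    acquisition_sample=timeline[first_spacer],
                ))
    return episodes


def episodes_from_truth(truth, min_spacer_samples: int = 2) -> list[SpacerEpisode]:
    """Build episodes directly from generator ground truth (no observation
    layer): one per (planted spacer, source MGE) pair per lineage, applying
    the same eligibility rules as :func:`select_episodes`.
    """
    abundance = truth.abundance
    series_cache: dict[tuple[str, str], list[float]] = {}
    episodes: list[SpacerEpisode] = []
    for lin in truth.lineages:
        timeline = list(truth.timepoints[lin.subject])
        lineage_present = [bool(lin.arrays.get(t)) for t in timeline]
        if not any(lineage_present):
            continue
        first_lineage = lineage_present.index(True)
        per_spacer: dict[tuple[str, str], list[bool]] = {}
        for i, t in enumerate(timeline):
            for spacer in lin.arrays.get(t, ()):
                if spacer.source_mge is None:
                    continue
                per_spacer.setdefault(
                    (spacer.seq, spacer.source_mge),
                    [False] * len(timeline))[i] = True
        for (seq, mge_id), vec in sorted(per_spacer.items()):
            if sum(vec) < min_spacer_samples:
                continue
            first_spacer = vec.index(True)
            if first_spacer <= first_lineage:
                continue
            cache_key = (mge_id, lin.subject)
            if cache_key not in series_cache:
                series_cache[cache_key] = target_abundance_series(
                    mge_id, lin.subject, timeline, abundance)
            series = series_cache[cache_key]
            if not any(v > 0 for v in series):
                continue
            episodes.append(SpacerEpisode(
                episode_id=f"ep_{lin.lineage_id}_{mge_id}_{canonical(seq)[:8]}",
                spacer_key=canonical(seq), lineage_id=lin.lineage_id,
                target_id=mge_id, subject=lin.subject,
                timepoints=timeline, lineage_present=list(lineage_present),
                spacer_present=list(vec),
                target_present=[v > 0 for v in series],
                abundance=list(series),
                acquisition_sample=timeline[first_spacer]))
    return episodes


# ---------------------------------------------------------------------------
# Abundance

def target_abundance_series(target_id: str, subject: str,
                            timepoints: Sequence[int],
                            abundance: pd.DataFrame | None) -> list[float]:
    """Per-sample relative abundance of one target; undetected samples are 0."""
    if abundance is None:
        return [0.0] * len(timepoints)
    mask = (abundance["target_id"] == target_id) & (abundance["subject"] == subject)
    sub = abundance.loc[mask].set_index("timepoint")["abundance"]
    return [float(sub.get(t, 0.0)) for t in timepoints]


def abundance_from_read_counts(mapped_reads: int, neighborhood_len: int,
                               total_reads: int) -> float:
    """Real-data adapter: mapped reads / neighborhood length / total reads.

    The neighborhood length is the clipped length actually mapped against
    (shorter than 2 x flank + protospacer near contig ends).
    """
    if total_reads <= 0:
        raise ValidationError("total read count must be positive")
    if neighborhood_len <= 0:
        raise ValidationError("neighborhood length must be positive")
    return mapped_reads / (neighborhood_len * total_reads)


def neighborhood_interval(start: int, end: int, contig_len: int,
                          flank: int = 2000) -> tuple[int, int]:
    """Protospacer neighborhood clipped at contig ends (0-based half-open)."""
    if not (0 <= start < end <= contig_len):
        raise ValidationError("protospacer interval outside contig")
    return max(0, start - flank), min(contig_len, end + flank)


def normalize_by_max(series: Sequence[float]) -> np.ndarray:
    """Divide by the series maximum; zeros are preserved."""
    arr = np.asarray(series, dtype=float)
    peak = arr.max() if arr.size else 0.0
    if peak <= 0:
        raise ValidationError("cannot max-normalize an all-zero series")
    return arr / peak


# ---------------------------------------------------------------------------
# Phases

def phase_assignment(episode: SpacerEpisode) -> dict[int, str]:
    """Phase label per retained (lineage-present) sample index."""
    acq_idx = episode.timepoints.index(episode.acquisition_sample)
    labels: dict[int, str] = {}
    for i in episode.retained():
        if i < acq_idx:
            labels[i] = "before"
        elif i == acq_idx:
            labels[i] = "acquisition"
        elif episode.spacer_present[i]:
            labels[i] = "after_with_spacer"
        else:
            labels[i] = "after_no_spacer"
    return labels


def _bootstrap_median_ci(values: np.ndarray, n_bootstraps: int, level: float,
                         rng: np.random.Generator) -> tuple[float, float]:
    n = values.size
    idx = rng.integers(0, n, size=(n_bootstraps, n))
    medians = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(medians, alpha)),
            float(np.quantile(medians, 1.0 - alpha)))


def phase_statistics(episodes: Sequence[SpacerEpisode],
                     n_bootstraps: int = 2000, level: float = 0.95,
                     rng: np.random.Generator | None = None,
                     test_pairs: Sequence[tuple[str, str]] = DEFAULT_TEST_PAIRS,
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pooled per-phase summaries plus pairwise rank/count tests.

    Returns (phase table, tests table). Abundances are max-normalized per
    episode target series, pooled across episodes per phase. Medians carry
    percentile-bootstrap CIs; prevalences carry Clopper-Pearson CIs.
    Mann-Whitney compares abundances and Fisher's exact test compares
    detection counts for each requested phase pair; empty phases skip their
    comparisons with a log entry.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    pooled: dict[str, list[float]] = {phase: [] for phase in PHASES}
    detected: dict[str, list[bool]] = {phase: [] for phase in PHASES}
    for episode in episodes:
        norm = normalize_by_max(episode.abundance)
        labels = phase_assignment(episode)
        for i, phase in labels.items():
            pooled[phase].append(float(norm[i]))
            detected[phase].append(episode.target_present[i])

    rows = []
    for phase in PHASES:
        values = np.asarray(pooled[phase], dtype=float)
        n = values.size
        if n == 0:
            rows.append({"phase": phase, "n": 0, "median": np.nan,
                         "ci_lo": np.nan, "ci_hi": np.nan,
                         "prevalence": np.nan, "prev_ci_lo": np.nan,
                         "prev_ci_hi": np.nan})
            continue
        ci_lo, ci_hi = _bootstrap_median_ci(values, n_bootstraps, level, rng)
        k = sum(detected[phase])
        p_lo, p_hi = clopper_pearson(k, n, level)
        rows.append({"phase": phase, "n": n, "median": float(np.median(values)),
                     "ci_lo": ci_lo, "ci_hi": ci_hi, "prevalence": k / n,
                     "prev_ci_lo": p_lo, "prev_ci_hi": p_hi})
    phase_df = pd.DataFrame(rows, columns=["phase", "n", "median", "ci_lo", "ci_hi",
                                           "prevalence", "prev_ci_lo", "prev_ci_hi"])

    test_rows = []
    for a, b in test_pairs:
        va = np.asarray(pooled[a], dtype=float)
        vb = np.asarray(pooled[b], dtype=float)
        if va.size == 0 or vb.size == 0:
            logger.info("phase comparison %s vs %s skipped (empty phase)", a, b)
            continue
        mw = stats.mannwhitneyu(va, vb, alternative="two-sided")
        ka, kb = sum(detected[a]), sum(detected[b])
        table = [[ka, va.size - ka], [kb, vb.size - kb]]
        fisher = stats.fisher_exact(table)
        test_rows.append({"pair": f"{a}_vs_{b}", "mw_statistic": float(mw.statistic),
                          "mw_p": float(mw.pvalue),
                          "fisher_odds": float(fisher[0]), "fisher_p": float(fisher[1])})
    tests_df = pd.DataFrame(test_rows, columns=["pair", "mw_statistic", "mw_p",
                                                "fisher_odds", "fisher_p"])
    return phase_df, tests_df


# ---------------------------------------------------------------------------
# Lineage diversity / selective sweeps

def diversity_analysis(lineages: Sequence[Lineage], dataset: Dataset,
                       local_hits: pd.DataFrame,
                       spacer_targets: Mapping[str, Sequence[str]],
                       n_bootstraps: int = 2000, level: float = 0.95,
                       rng: np.random.Generator | None = None,
                       ) -> dict[str, pd.DataFrame]:
    """Active/inactive lineage diversity and the co-sampled-target statistic.

    A lineage is active when any of its spacers has a surviving local hit.
    Returns three tables: ``diversity`` (distinct-array counts per lineage),
    ``arrays_by_presence`` (arrays per lineage in samples with/without its
    targeted MGE), and ``sweep`` (observed % of arrays carrying a cognate
    spacer for a co-sampled MGE vs the expectation under uniform random
    draws of member arrays, both with bootstrap CIs).
    """
    if rng is None:
        rng = np.random.default_rng(0)
    arrays = {rec.array_id: rec for rec in dataset.arrays}
    local_spacers = set(local_hits["spacer_id"]) if not local_hits.empty else set()
    key_targets: dict[str, set[str]] = {}
    for spacer_id in sorted(local_spacers):
        key = canonical(dataset.spacers[spacer_id].upper())
        key_targets.setdefault(key, set()).update(spacer_targets.get(spacer_id, ()))

    def array_keys(rec: ArrayRecord) -> frozenset[str]:
        return frozenset(canonical(dataset.spacers[s].upper()) for s in rec.spacer_ids)

    diversity_rows = []
    presence_rows = []
    observed_slots: list[tuple[Lineage, int, list[str]]] = []
    any_active = False
    for lineage in sorted(lineages, key=lambda l: l.lineage_id):
        active_keys = {k for k in lineage.spacer_universe if key_targets.get(k)}
        active = bool(active_keys)
        any_active = any_active or active
        distinct = len({array_keys(arrays[a]) for a in lineage.members})
        diversity_rows.append({"lineage_id": lineage.lineage_id,
                               "active": str(active).lower(),
                               "n_distinct_arrays": distinct})
        if not active:
            continue
        lineage_targets = set().union(*(key_targets[k] for k in active_keys))
        timeline = dataset.timepoints[lineage.subject]
        members_by_t: dict[int, list[str]] = {}
        for a in lineage.members:
            members_by_t.setdefault(arrays[a].timepoint, []).append(a)
        for t, member_ids in sorted(members_by_t.items()):
            present_targets = {
                tg for tg in lineage_targets
                if target_abundance_series(tg, lineage.subject, [t],
                                           dataset.abundance)[0] > 0
            }
            presence_rows.append({
                "lineage_id": lineage.lineage_id, "timepoint": t,
                "mge_present": str(bool(present_targets)).lower(),
                "n_arrays": len(set(member_ids)),
            })
            if present_targets:
                observed_slots.append((lineage, t, sorted(set(member_ids))))

    if not any_active:
        logger.info("diversity analysis skipped: no active lineages")
        return {
            "diversity": pd.DataFrame(diversity_rows,
                                      columns=["lineage_id", "active", "n_distinct_arrays"]),
            "arrays_by_presence": pd.DataFrame(
                columns=["lineage_id", "timepoint", "mge_present", "n_arrays"]),
            "sweep": pd.DataFrame(columns=["quantity", "value", "ci_lo", "ci_hi"]),
        }

    # observed: fraction of arrays (in slots with a co-sampled target) that
    # carry a cognate spacer for an MGE present in the same sample
    _targets_cache: dict[str, set[str]] = {}

    def targets_hit_by(rec: ArrayRecord) -> set[str]:
        cached = _targets_cache.get(rec.array_id)
        if cached is None:
            cached = set()
            for k in array_keys(rec):
                cached |= key_targets.get(k, set())
            _targets_cache[rec.array_id] = cached
        return cached

    flags: list[bool] = []
    randomized_pool: list[tuple[Lineage, int, str]] = []
    for lineage, t, member_ids in observed_slots:
        present_targets = {
            tg
            for k in lineage.spacer_universe
            for tg in key_targets.get(k, set())
            if target_abundance_series(tg, lineage.subject, [t],
                                       dataset.abundance)[0] > 0
        }
        for a in member_ids:
            flags.append(bool(targets_hit_by(arrays[a]) & present_targets))
            randomized_pool.append((lineage, t, a))

    flags_arr = np.asarray(flags, dtype=bool)
    alpha = (1.0 - level) / 2.0

    def pct_ci(values: np.ndarray) -> tuple[float, float, float]:
        pct = 100.0 * values.mean()
        idx = rng.integers(0, values.size, size=(n_bootstraps, values.size))
        boots = 100.0 * values[idx].mean(axis=1)
        return pct, float(np.quantile(boots, alpha)), float(np.quantile(boots, 1 - alpha))

    obs_pct, obs_lo, obs_hi = pct_ci(flags_arr)

    # expectation: redraw each slot's arrays uniformly from the lineage's
    # whole member pool (all samples), keeping slot sizes fixed
    member_pool = {
        lin.lineage_id: sorted(lin.members)
        for lin, _, _ in observed_slots
        for lin in [lin]
    }
    present_by_slot = []
    for lineage, t, member_ids in observed_slots:
        present_targets = {
            tg
            for k in lineage.spacer_universe
            for tg in key_targets.get(k, set())
            if target_abundance_series(tg, lineage.subject, [t],
                                       dataset.abundance)[0] > 0
        }
        present_by_slot.append((lineage.lineage_id, present_targets, len(member_ids)))

    hits_per_boot = np.zeros(n_bootstraps)
    total = 0
    for lineage_id, present_targets, size in present_by_slot:
        pool = member_pool[lineage_id]
        flag_vec = np.array(
            [bool(targets_hit_by(arrays[a]) & present_targets) for a in pool],
            dtype=bool)
        draws = rng.integers(0, len(pool), size=(n_bootstraps, size))
        hits_per_boot += flag_vec[draws].sum(axis=1)
        total += size
    exp_samples = (100.0 * hits_per_boot / total if total
                   else np.full(n_bootstraps, np.nan))
    exp_pct = float(np.nanmean(exp_samples))
    exp_lo = float(np.nanquantile(exp_samples, alpha))
    exp_hi = float(np.nanquantile(exp_samples, 1 - alpha))

    sweep = pd.DataFrame(
        [
            {"quantity": "observed_pct_targeting_cosampled_mge", "value": obs_pct,
             "ci_lo": obs_lo, "ci_hi": obs_hi},
            {"quantity": "expected_pct_targeting_cosampled_mge", "value": exp_pct,
             "ci_lo": exp_lo, "ci_hi": exp_hi},
        ],
        columns=["quantity", "value", "ci_lo", "ci_hi"],
    )
    return {
        "diversity": pd.DataFrame(diversity_rows,
                                  columns=["lineage_id", "active", "n_distinct_arrays"]),
        "arrays_by_presence": pd.DataFrame(
            presence_rows,
            columns=["lineage_id", "timepoint", "mge_present", "n_arrays"]),
        "sweep": sweep,
    }
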
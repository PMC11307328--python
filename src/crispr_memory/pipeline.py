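"""Stage orchestration: simulate -> lineages -> targets -> positions ->
dynamics -> trajectories.

Each stage consumes the in-memory products of its upstream stages and
appends its result tables to the run; one deterministic manifest records
parameters, seed, and output checksums. Requesting a stage whose inputs are
missing raises a dependency error naming the missing upstream stage unless
``auto_deps`` is set (the CLI sets it).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from crispr_memory import dynamics as dyn
from crispr_memory import lineages as lin
from crispr_memory import matching, positions, targets, trajectories
from crispr_memory.config import Parameters
from crispr_memory.datasets import Dataset, write_results
from crispr_memory.errors import DependencyError, ValidationError
from crispr_memory.simulate import (
    CommunityTruth,
    SimulationConfig,
    emit_observed_dataset,
    generate_community,
)

__all__ = ["PipelineState", "run_pipeline", "STAGES"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "lineages", "targets", "positions", "dynamics", "trajectories")

_DEPS: dict[str, tuple[str, ...]] = {
    "simulate": (),
    "lineages": (),       # needs a dataset (from simulate or from disk)
    "targets": (),
    "positions": ("targets",),
    "dynamics": ("lineages", "targets"),
    "trajectories": ("dynamics",),
}


@dataclass
class PipelineState:
    params: Parameters
    dataset: Dataset | None = None
    truth: CommunityTruth | None = None
    lineage_list: list[lin.Lineage] | None = None
    consistency: pd.DataFrame | None = None
    local_hits: pd.DataFrame | None = None
    db_hits: pd.DataFrame | None = None
    assignments: dict[str, targets.TargetAssignment] | None = None
    spacer_targets: dict[str, list[str]] | None = None
    episodes: list[dyn.SpacerEpisode] | None = None
    phase_stats: pd.DataFrame | None = None
    tests: pd.DataFrame | None = None
    diversity: dict[str, pd.DataFrame] | None = None
    strings: dict[str, str] | None = None
    clusters: dict[str, int] | None = None
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    summaries: dict | None = None

    def _satisfied(self, stage: str) -> bool:
        return {
            "simulate": self.dataset is not None,
            "lineages": self.lineage_list is not None,
            "targets": self.assignments is not None,
            "positions": "positional_profile" in self.tables,
            "dynamics": self.episodes is not None,
            "trajectories": self.clusters is not None,
        }[stage]


def _stage_rng(params: Parameters, stage: str) -> np.random.Generator:
    return np.random.default_rng([params.rng_seed, STAGES.index(stage)])


# ---------------------------------------------------------------------------
# Stage implementations

def _run_simulate(state: PipelineState, sim_config: SimulationConfig | None) -> None:
    config = sim_config or SimulationConfig(rng_seed=state.params.rng_seed)
    truth = generate_community(config)
    state.truth = truth
    state.dataset = emit_observed_dataset(truth)
    logger.info("simulate: %d subjects, %d observed arrays, %d MGE",
                len(state.dataset.subjects), len(state.dataset.arrays),
                len(state.dataset.mge_db))


def _run_lineages(state: PipelineState) -> None:
    ds = state.dataset
    assert ds is not None
    params = state.params
    repeat_map, _ = lin.dereplicate_sequences(ds.repeats)
    canon_repeats = {rid: ds.repeats[rid] for rid in set(repeat_map.values())}
    cluster_map = lin.cluster_repeats(canon_repeats, params.repeat_cluster_identity,
                                      params.repeat_cluster_coverage)
    for rec in ds.arrays:
        rec.repeat_cluster = cluster_map[repeat_map[rec.repeat_id]]

    all_lineages: list[lin.Lineage] = []
    for subject in ds.subjects:
        subject_arrays = [rec for rec in ds.arrays if rec.subject == subject]
        if subject_arrays:
            all_lineages.extend(lin.build_lineages(subject_arrays, ds.spacers, subject))
    state.lineage_list = all_lineages

    arrays_by_id = {rec.array_id: rec for rec in ds.arrays}
    consistency_rows = []
    for lineage in all_lineages:
        counts = lin.lineage_consistency_metrics(lineage, arrays_by_id, ds.spacers)
        consistency_rows.append({"lineage_id": lineage.lineage_id, **counts})
    state.consistency = pd.DataFrame(
        consistency_rows,
        columns=["lineage_id", "order_inconsistent_pairs", "inversion_pairs",
                 "orientation_inconsistent_pairs", "total_pairs"])

    state.tables["lineages"] = pd.DataFrame(
        [
            {"lineage_id": l.lineage_id, "representative": l.representative,
             "subject": l.subject, "n_members": len(l.members),
             "members": ",".join(sorted(l.members))}
            for l in all_lineages
        ],
        columns=["lineage_id", "representative", "subject", "n_members", "members"])
    presence_rows = []
    for lineage in all_lineages:
        present = sorted({arrays_by_id[a].timepoint for a in lineage.members})
        for t in present:
            presence_rows.append({"lineage_id": lineage.lineage_id, "timepoint": t})
    state.tables["lineage_presence"] = pd.DataFrame(
        presence_rows, columns=["lineage_id", "timepoint"])
    state.tables["consistency"] = state.consistency
    logger.info("lineages: %d lineages from %d arrays",
                len(all_lineages), len(ds.arrays))


def _run_targets(state: PipelineState) -> None:
    ds = state.dataset
    assert ds is not None
    params = state.params

    spacer_map, _ = lin.dereplicate_sequences(ds.spacers)
    unique_ids = sorted(set(spacer_map.values()))

    # reference-database scan
    db_hit_objs: dict[str, list[matching.MatchHit]] = {sid: [] for sid in unique_ids}
    db_hits_flat = matching.scan_spacers(
        {sid: ds.spacers[sid] for sid in unique_ids},
        {mge_id: rec.seq for mge_id, rec in ds.mge_db.items()},
        params.protospacer_min_identity, params.protospacer_min_coverage)
    for hit in db_hits_flat:
        db_hit_objs[hit.spacer_id].append(hit)
    assignments: dict[str, targets.TargetAssignment] = {}
    for sid in unique_ids:
        assignments[sid] = targets.assign_from_mgedb(sid, db_hit_objs[sid], ds.mge_db)

    # local scans per subject (a spacer belongs to the subjects whose arrays
    # carry it; the scan is restricted to that subject's contigs)
    spacer_subject_ids: dict[str, set[str]] = {}
    for rec in ds.arrays:
        for sid in rec.spacer_ids:
            spacer_subject_ids.setdefault(spacer_map[sid], set()).add(rec.subject)
    local_frames = []
    for subject in ds.subjects:
        subject_spacers = {
            sid: ds.spacers[sid]
            for sid, subjects in spacer_subject_ids.items() if subject in subjects
        }
        if not subject_spacers or not ds.contigs:
            continue
        frame = matching.local_protospacer_scan(
            subject_spacers, ds.contigs, subject, params)
        if not frame.empty:
            frame.insert(0, "subject", subject)
            local_frames.append(frame)
    local_hits = (pd.concat(local_frames, ignore_index=True) if local_frames
                  else pd.DataFrame(columns=["subject", "spacer_id", "subject_id",
                                             "start", "end", "strand", "mismatches",
                                             "identity", "coverage", "accuracy"]))

    # neighborhood rescue for unknown-class spacers with local protospacers
    for sid in unique_ids:
        if assignments[sid].target_class != "unknown":
            continue
        rows = local_hits[local_hits["spacer_id"] == sid]
        if rows.empty:
            continue
        row = rows.iloc[0]
        hit = matching.MatchHit(
            spacer_id=sid, subject_id=row["subject_id"], start=int(row["start"]),
            end=int(row["end"]), strand=row["strand"],
            mismatches=int(row["mismatches"]), identity=float(row["identity"]),
            coverage=float(row["coverage"]))
        contig = ds.contigs[row["subject_id"]]
        assignments[sid].target_class = targets.assign_from_neighborhood(
            hit, contig, ds.mge_db, params)

    targets.flag_local_adaptation(assignments, local_hits)

    # propagate to duplicate spacer ids
    for sid, canon in spacer_map.items():
        if sid != canon:
            a = assignments[canon]
            assignments[sid] = targets.TargetAssignment(
                spacer_id=sid, target_class=a.target_class, accuracy=a.accuracy,
                locally_adapted=a.locally_adapted, tags=set(a.tags),
                supporting_hits=list(a.supporting_hits))

    state.assignments = assignments
    state.local_hits = local_hits
    db_rows = [h for sid in unique_ids for h in db_hit_objs[sid]]
    state.db_hits = matching.hits_to_frame(db_rows)
    state.spacer_targets = {
        sid: sorted({h.subject_id for h in db_hit_objs[sid]}) for sid in unique_ids
    }
    for sid, canon in spacer_map.items():
        state.spacer_targets.setdefault(sid, state.spacer_targets[canon])

    state.tables["hits"] = local_hits
    state.tables["db_hits"] = state.db_hits
    state.tables["assignments"] = targets.assignments_to_frame(assignments)
    logger.info("targets: %d unique spacers, %d local hits, %d db hits",
                len(unique_ids), len(local_hits), len(state.db_hits))


def _run_positions(state: PipelineState) -> None:
    ds = state.dataset
    assert ds is not None and state.assignments is not None
    params = state.params
    eligible = positions.eligibility_filter(
        ds.arrays, params.min_spacers_oriented, params.min_arrays_per_subtype)

    pooled_positions: list[float] = []
    flags_local: list[bool] = []
    regions: list[str] = []
    phage_denominator: list[bool] = []
    lysogenic_focal: list[bool] = []
    for rec in eligible:
        pos = positions.normalized_positions(rec)
        reg = positions.region_assignment(rec)
        for sid, p, r in zip(rec.spacer_ids, pos, reg):
            assignment = state.assignments[sid]
            pooled_positions.append(float(p))
            flags_local.append(assignment.locally_adapted)
            regions.append(r)
            phage_denominator.append(assignment.target_class in
                                     ("lytic_or_nonlysogenic_phage", "lysogenic_phage"))
            lysogenic_focal.append(assignment.target_class == "lysogenic_phage")

    profile = positions.sliding_window_density(
        pooled_positions, flags_local, params.window_width_frac,
        params.window_step_frac, n_arrays=len(eligible), flag_name="locally_adapted")
    state.tables["positional_profile"] = pd.DataFrame({
        "flag": profile.flag,
        "window_center": profile.centers,
        "density": profile.density,
        "n": profile.n_in_window,
    })
    state.tables["region_enrichment"] = positions.region_enrichment(
        regions, lysogenic_focal, phage_denominator, params.ci_level)
    logger.info("positions: %d eligible arrays, %d pooled spacers",
                len(eligible), len(pooled_positions))


def _run_dynamics(state: PipelineState) -> None:
    ds = state.dataset
    assert ds is not None and state.lineage_list is not None
    assert state.local_hits is not None and state.spacer_targets is not None
    params = state.params
    rng = _stage_rng(params, "dynamics")
    episodes = dyn.select_episodes(ds, state.lineage_list, state.local_hits,
                                   state.spacer_targets, params)
    state.episodes = episodes
    if episodes:
        phase_df, tests_df = dyn.phase_statistics(
            episodes, params.n_bootstraps, params.ci_level, rng)
    else:
        phase_df = pd.DataFrame(columns=["phase", "n", "median", "ci_lo", "ci_hi",
                                         "prevalence", "prev_ci_lo", "prev_ci_hi"])
        tests_df = pd.DataFrame(columns=["pair", "mw_statistic", "mw_p",
                                         "fisher_odds", "fisher_p"])
    state.phase_stats = phase_df
    state.tests = tests_df
    state.diversity = dyn.diversity_analysis(
        state.lineage_list, ds, state.local_hits, state.spacer_targets,
        params.n_bootstraps, params.ci_level, rng)

    state.tables["episodes"] = pd.DataFrame(
        [
            {"episode_id": e.episode_id, "lineage_id": e.lineage_id,
             "target_id": e.target_id, "subject": e.subject,
             "acquisition_sample": e.acquisition_sample,
             "n_spacer_samples": sum(e.spacer_present)}
            for e in episodes
        ],
        columns=["episode_id", "lineage_id", "target_id", "subject",
                 "acquisition_sample", "n_spacer_samples"])
    state.tables["phase_stats"] = phase_df
    state.tables["tests"] = tests_df
    state.tables["diversity"] = state.diversity["diversity"]
    state.tables["arrays_by_presence"] = state.diversity["arrays_by_presence"]
    state.tables["sweep"] = state.diversity["sweep"]
    logger.info("dynamics: %d eligible episodes", len(episodes))


def _run_trajectories(state: PipelineState) -> None:
    assert state.episodes is not None
    params = state.params
    strings: dict[str, str] = {}
    for episode in state.episodes:
        strings[episode.episode_id] = trajectories.encode_trajectory(episode).letters
    state.strings = strings

    graph = trajectories.build_similarity_network(
        strings, params.align_match, params.align_mismatch,
        params.align_gap_open, params.align_gap_extend)
    clusters = trajectories.cluster_network(graph, params.community_trials,
                                            seed=params.rng_seed)
    state.clusters = clusters

    ds = state.dataset
    episode_classes = {}
    if ds is not None:
        for episode in state.episodes:
            mge = ds.mge_db.get(episode.target_id)
            episode_classes[episode.episode_id] = (
                targets._effective_class(mge) if mge is not None else "unknown")
    n = len(episode_classes)
    global_freq: dict[str, float] = {}
    for cls in episode_classes.values():
        global_freq[cls] = global_freq.get(cls, 0.0) + 1.0 / n if n else 0.0

    summaries = {}
    members_by_cluster: dict[int, list[str]] = {}
    for eid, cid in clusters.items():
        members_by_cluster.setdefault(cid, []).append(eid)
    for cid, members in sorted(members_by_cluster.items()):
        summaries[str(cid)] = trajectories.summarize_cluster(
            sorted(members), strings, episode_classes, global_freq)
    state.summaries = summaries

    state.tables["trajectories"] = pd.DataFrame(
        sorted(strings.items()), columns=["episode_id", "state_string"])
    state.tables["network"] = pd.DataFrame(
        sorted((u, v, d["weight"]) if u <= v else (v, u, d["weight"])
               for u, v, d in graph.edges(data=True)),
        columns=["i", "j", "weight"])
    state.tables["clusters"] = pd.DataFrame(
        sorted(clusters.items()), columns=["episode_id", "cluster"])
    logger.info("trajectories: %d strings, %d clusters",
                len(strings), len(members_by_cluster))


_RUNNERS = {
    "lineages": _run_lineages,
    "targets": _run_targets,
    "positions": _run_positions,
    "dynamics": _run_dynamics,
    "trajectories": _run_trajectories,
}


# ---------------------------------------------------------------------------

def run_pipeline(params: Parameters, stages: Iterable[str],
                 dataset: Dataset | None = None,
                 sim_config: SimulationConfig | None = None,
                 outdir: str | Path | None = None,
                 state: PipelineState | None = None,
                 auto_deps: bool = False) -> dict:
    """Run the requested stages in dependency order; return the manifest.

    Stages not requested must already be satisfied in ``state`` (or by the
    provided dataset); otherwise a DependencyError names the missing
    upstream stage. With ``auto_deps`` missing dependencies are added
    automatically.
    """
    requested = set(stages)
    unknown = requested - set(STAGES)
    if unknown:
        raise ValidationError(f"unknown stage(s): {sorted(unknown)}")
    if state is None:
        state = PipelineState(params=params)
    if dataset is not None:
        state.dataset = dataset

    if auto_deps:
        changed = True
        while changed:
            changed = False
            for stage in list(requested):
                for dep in _DEPS[stage]:
                    if dep not in requested and not state._satisfied(dep):
                        requested.add(dep)
                        changed = True
            if any(s != "simulate" for s in requested) and state.dataset is None \
                    and "simulate" not in requested:
                requested.add("simulate")
                changed = True

    ordered = [s for s in STAGES if s in requested]
    for stage in ordered:
        for dep in _DEPS[stage]:
            if dep not in requested and not state._satisfied(dep):
                raise DependencyError(
                    f"stage '{stage}' requires missing upstream stage '{dep}'")
        if stage != "simulate" and state.dataset is None and "simulate" not in requested:
            raise DependencyError(
                f"stage '{stage}' requires a dataset; run 'simulate' or provide one")

    for stage in ordered:
        if stage == "simulate":
            _run_simulate(state, sim_config)
        else:
            _RUNNERS[stage](state)

    manifest: dict = {"stages": ordered, "rng_seed": params.rng_seed}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if "simulate" in ordered and state.truth is not None and state.dataset is not None:
            from crispr_memory.datasets import write_dataset
            from crispr_memory.simulate import _write_truth

            write_dataset(state.dataset, outdir / "dataset")
            _write_truth(state.truth, outdir / "dataset" / "truth")
        written = write_results(state.tables, outdir, params=params)
        manifest.update(written)
        if state.summaries is not None:
            with open(outdir / "cluster_summary.json", "w") as fh:
                json.dump(state.summaries, fh, indent=2, sort_keys=True)
                fh.write("\n")
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return manifest
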
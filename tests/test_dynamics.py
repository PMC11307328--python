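import numpy as np
import pandas as pd
import pytest

from crispr_memory.config import Parameters
from crispr_memory.dynamics import (
    SpacerEpisode,
    abundance_from_read_counts,
    diversity_analysis,
    neighborhood_interval,
    normalize_by_max,
    phase_assignment,
    phase_statistics,
    select_episodes,
    target_abundance_series,
)
from crispr_memory.errors import ValidationError
from crispr_memory.datasets import ArrayRecord, Dataset
from crispr_memory.lineages import Lineage
from crispr_memory.seq import canonical


def make_episode(timepoints, lineage, spacer, abundance, episode_id="ep1"):
    return SpacerEpisode(
        episode_id=episode_id, spacer_key="K", lineage_id="L", target_id="T",
        subject="S", timepoints=list(timepoints),
        lineage_present=list(lineage), spacer_present=list(spacer),
        target_present=[a > 0 for a in abundance], abundance=list(abundance),
        acquisition_sample=timepoints[spacer.index(True)],
    )


class TestTargetAbundance:
    def test_read_count_arithmetic(self):
        assert abundance_from_read_counts(100, 4000, 10 ** 6) == pytest.approx(2.5e-8)

    def test_zero_total_reads(self):
        with pytest.raises(ValidationError):
            abundance_from_read_counts(10, 4000, 0)

    def test_neighborhood_clipping(self):
        # protospacer 500 nt from the contig start: upstream flank clipped
        lo, hi = neighborhood_interval(500, 534, 100_000, flank=2000)
        assert (lo, hi) == (0, 2534)
        assert hi - lo == 2534

    def test_undetected_sample_zero(self):
        table = pd.DataFrame({
            "target_id": ["T"], "subject": ["S"], "timepoint": [2],
            "abundance": [0.5]})
        series = target_abundance_series("T", "S", [0, 1, 2, 3], table)
        assert series == [0.0, 0.0, 0.5, 0.0]


class TestNormalizeByMax:
    def test_example(self):
        np.testing.assert_allclose(normalize_by_max([2, 4, 0, 1]),
                                   [0.5, 1.0, 0.0, 0.25])

    def test_constant_series(self):
        np.testing.assert_allclose(normalize_by_max([3, 3, 3]), [1, 1, 1])

    def test_scale_invariance(self, rng):
        x = rng.random(10) + 0.1
        np.testing.assert_allclose(normalize_by_max(x), normalize_by_max(7.3 * x))

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            normalize_by_max([0.0, 0.0])


class TestPhaseAssignment:
    def test_textbook_example(self):
        # lineage at t=1..6, spacer at t=3 and t=5
        episode = make_episode(
            [1, 2, 3, 4, 5, 6],
            [True] * 6,
            [False, False, True, False, True, False],
            [1.0] * 6)
        labels = phase_assignment(episode)
        by_t = {episode.timepoints[i]: phase for i, phase in labels.items()}
        assert by_t == {1: "before", 2: "before", 3: "acquisition",
                        4: "after_no_spacer", 5: "after_with_spacer",
                        6: "after_no_spacer"}

    def test_no_after_no_spacer_when_always_present(self):
        episode = make_episode(
            [0, 1, 2, 3], [True] * 4, [False, True, True, True], [1.0] * 4)
        assert "after_no_spacer" not in phase_assignment(episode).values()

    def test_lineage_absent_samples_unlabeled(self):
        episode = make_episode(
            [0, 1, 2, 3], [True, False, True, True],
            [False, False, True, True], [1.0] * 4)
        labels = phase_assignment(episode)
        assert 1 not in labels
        assert len(labels) == 3

    def test_partition_of_retained_samples(self):
        episode = make_episode(
            [0, 1, 2, 3, 4], [True, True, False, True, True],
            [False, True, False, False, True], [1.0] * 5)
        labels = phase_assignment(episode)
        assert sorted(labels) == episode.retained()


class TestPhaseStatistics:
    def test_constant_bootstrap_ci_width_zero(self):
        episodes = [make_episode([0, 1, 2], [True] * 3,
                                 [False, True, True], [2.0, 2.0, 2.0])]
        phase_df, _ = phase_statistics(episodes, n_bootstraps=100,
                                       rng=np.random.default_rng(0))
        before = phase_df[phase_df["phase"] == "before"].iloc[0]
        assert before["ci_lo"] == before["ci_hi"] == before["median"] == 1.0

    def test_planted_effect_direction(self):
        rng = np.random.default_rng(42)
        episodes = []
        for i in range(120):
            base = rng.lognormal(0, 1, size=8)
            abundance = list(base)
            spacer = [False, False, False, True, True, True, True, True]
            for j in range(4, 8):
                abundance[j] *= 0.3
            episodes.append(make_episode(
                list(range(8)), [True] * 8, spacer, abundance,
                episode_id=f"ep{i}"))
        phase_df, tests_df = phase_statistics(
            episodes, n_bootstraps=500, rng=np.random.default_rng(1))
        med = phase_df.set_index("phase")["median"]
        assert med["after_with_spacer"] < med["before"]
        row = tests_df[tests_df["pair"] == "before_vs_after_with_spacer"].iloc[0]
        assert row["mw_p"] < 1e-4

    def test_empty_phase_comparison_skipped(self):
        episodes = [make_episode([0, 1], [True, True], [False, True], [1.0, 2.0])]
        phase_df, tests_df = phase_statistics(episodes, n_bootstraps=50,
                                              rng=np.random.default_rng(0))
        assert phase_df.set_index("phase").loc["after_with_spacer", "n"] == 0
        assert "before_vs_after_with_spacer" not in set(tests_df["pair"])


def _toy_dataset_and_lineage(spacer_by_t, abundances, n_timepoints=5):
    """One lineage observed at every timepoint; spacer_by_t maps timepoint ->
    spacer ids carried by the array at that timepoint."""
    spacers = {"spA": "A" * 34, "spB": "C" * 34}
    arrays = []
    for t in range(n_timepoints):
        arrays.append(ArrayRecord(
            array_id=f"a{t}", subject="S", sample=f"S_t{t}", timepoint=t,
            repeat_id="r", spacer_ids=tuple(spacer_by_t[t])))
    ds = Dataset(
        subjects=["S"], timepoints={"S": list(range(n_timepoints))},
        arrays=arrays, spacers=spacers, repeats={"r": "G" * 31},
        abundance=pd.DataFrame(
            [{"target_id": "T", "subject": "S", "timepoint": t, "abundance": a}
             for t, a in enumerate(abundances)]),
    )
    lineage = Lineage(
        lineage_id="L", representative=f"a{n_timepoints - 1}",
        members={f"a{t}" for t in range(n_timepoints)}, subject="S",
        spacer_universe=frozenset(canonical(s) for s in spacers.values()))
    local_hits = pd.DataFrame({"spacer_id": ["spA"]})
    spacer_targets = {"spA": ["T"]}
    return ds, lineage, local_hits, spacer_targets


class TestSelectEpisodes:
    def test_spacer_from_first_sample_excluded(self):
        ds, lineage, hits, targets = _toy_dataset_and_lineage(
            {t: ["spA", "spB"] for t in range(5)}, [1.0] * 5)
        episodes = select_episodes(ds, [lineage], hits, targets, Parameters())
        assert episodes == []  # no pre-acquisition baseline

    def test_single_sample_spacer_excluded(self):
        spacer_by_t = {0: ["spB"], 1: ["spB"], 2: ["spA", "spB"],
                       3: ["spB"], 4: ["spB"]}
        ds, lineage, hits, targets = _toy_dataset_and_lineage(spacer_by_t, [1.0] * 5)
        episodes = select_episodes(ds, [lineage], hits, targets, Parameters())
        assert episodes == []

    def test_eligible_episode_selected(self):
        spacer_by_t = {0: ["spB"], 1: ["spB"], 2: ["spA", "spB"],
                       3: ["spA", "spB"], 4: ["spB"]}
        ds, lineage, hits, targets = _toy_dataset_and_lineage(spacer_by_t, [1.0] * 5)
        episodes = select_episodes(ds, [lineage], hits, targets, Parameters())
        assert len(episodes) == 1
        ep = episodes[0]
        assert ep.acquisition_sample == 2
        assert ep.target_id == "T"
        labels = phase_assignment(ep)
        phases = [labels[i] for i in sorted(labels)]
        assert phases == ["before", "before", "acquisition",
                          "after_with_spacer", "after_no_spacer"]

    def test_all_zero_target_series_excluded(self):
        spacer_by_t = {0: ["spB"], 1: ["spB"], 2: ["spA", "spB"],
                       3: ["spA", "spB"], 4: ["spB"]}
        ds, lineage, hits, targets = _toy_dataset_and_lineage(spacer_by_t, [0.0] * 5)
        episodes = select_episodes(ds, [lineage], hits, targets, Parameters())
        assert episodes == []


class TestDiversityAnalysis:
    def test_inactive_lineage_only_in_inactive_distribution(self):
        ds, lineage, hits, targets = _toy_dataset_and_lineage(
            {t: ["spA", "spB"] for t in range(5)}, [1.0] * 5)
        inactive = Lineage(
            lineage_id="L2", representative="a0", members={"a0"},
            subject="S", spacer_universe=frozenset({canonical("C" * 34)}))
        out = diversity_analysis([lineage, inactive], ds, hits, targets,
                                 n_bootstraps=50, rng=np.random.default_rng(0))
        div = out["diversity"].set_index("lineage_id")
        assert div.loc["L", "active"] == "true"
        assert div.loc["L2", "active"] == "false"
        assert set(out["arrays_by_presence"]["lineage_id"]) == {"L"}

    def test_every_array_immune_observed_equals_expected_100(self):
        ds, lineage, hits, targets = _toy_dataset_and_lineage(
            {t: ["spA", "spB"] for t in range(5)}, [1.0] * 5)
        out = diversity_analysis([lineage], ds, hits, targets,
                                 n_bootstraps=50, rng=np.random.default_rng(0))
        sweep = out["sweep"].set_index("quantity")["value"]
        assert sweep["observed_pct_targeting_cosampled_mge"] == pytest.approx(100.0)
        assert sweep["expected_pct_targeting_cosampled_mge"] == pytest.approx(100.0)

    def test_no_active_lineages_skipped(self):
        ds, lineage, hits, targets = _toy_dataset_and_lineage(
            {t: ["spB"] for t in range(5)}, [1.0] * 5)
        inactive = Lineage(
            lineage_id="L2", representative="a0", members={"a0"},
            subject="S", spacer_universe=frozenset({canonical("C" * 34)}))
        out = diversity_analysis([inactive], ds,
                                 pd.DataFrame(columns=["spacer_id"]), {},
                                 n_bootstraps=50, rng=np.random.default_rng(0))
        assert out["sweep"].empty

    def test_sweep_scenario_observed_above_expected(self):
        # lineage of two array variants: the immune variant (carrying spA)
        # dominates exactly when the target is present
        abundances = [0.0, 1.0, 0.0, 1.0, 0.0, 1.0]
        spacer_by_t = {0: ["spB"], 1: ["spA"], 2: ["spB"],
                       3: ["spA"], 4: ["spB"], 5: ["spA"]}
        ds, lineage, hits, targets = _toy_dataset_and_lineage(
            spacer_by_t, abundances, n_timepoints=6)
        out = diversity_analysis([lineage], ds, hits, targets,
                                 n_bootstraps=400, rng=np.random.default_rng(0))
        sweep = out["sweep"].set_index("quantity")["value"]
        assert sweep["observed_pct_targeting_cosampled_mge"] == pytest.approx(100.0)
        assert sweep["expected_pct_targeting_cosampled_mge"] < 75.0
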
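import numpy as np
import pytest
from scipy import stats

from crispr_memory.datasets import MgeRecord
from crispr_memory.errors import DegenerateDataError, ValidationError
from crispr_memory.seq import canonical, revcomp
from crispr_memory.simulate import (
    SimulationConfig,
    emit_observed_dataset,
    evolve_lineage,
    fit_truncated_powerlaw,
    generate_community,
    generate_mge_pool,
    sample_array_sizes,
    simulate_abundances,
    truncated_powerlaw_loglik,
    TrueSpacer,
)


def pmf_mean(alpha, cutoff, kmax=10_000):
    """Independent oracle: mean by direct summation of the normalized pmf."""
    k = np.arange(1, kmax + 1, dtype=float)
    w = k ** (-alpha) * np.exp(-k / cutoff)
    w /= w.sum()
    return float((k * w).sum())


class TestSampleArraySizes:
    def test_empty(self, rng):
        assert sample_array_sizes(0, 2.0, 100.0, rng).size == 0

    def test_mean_matches_summation_oracle(self):
        rng = np.random.default_rng(2024)
        draws = sample_array_sizes(100_000, 2.0, 100.0, rng)
        expected = pmf_mean(2.0, 100.0)
        assert abs(draws.mean() - expected) / expected < 0.02

    def test_extreme_damping_all_ones(self, rng):
        draws = sample_array_sizes(1000, 2.0, 1e-6, rng)
        assert (draws == 1).all()

    def test_nonnormalizable_rejected(self, rng):
        with pytest.raises(ValidationError):
            sample_array_sizes(10, 0.9, np.inf, rng)

    def test_all_at_least_one(self, rng):
        assert (sample_array_sizes(5000, 1.5, 30.0, rng) >= 1).all()


class TestFitTruncatedPowerlaw:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(99)
        draws = sample_array_sizes(50_000, 2.0, 100.0, rng)
        fit = fit_truncated_powerlaw(draws)
        assert 1.9 <= fit.alpha <= 2.1
        assert 80.0 <= fit.cutoff <= 120.0
        assert not fit.at_boundary

    def test_mle_beats_true_parameters(self):
        rng = np.random.default_rng(7)
        draws = sample_array_sizes(5000, 2.0, 50.0, rng)
        fit = fit_truncated_powerlaw(draws)
        assert fit.loglik >= truncated_powerlaw_loglik(draws, 2.0, 50.0) - 1e-6

    def test_pure_powerlaw_hits_boundary(self):
        rng = np.random.default_rng(11)
        draws = sample_array_sizes(20_000, 2.5, np.inf, rng)
        fit = fit_truncated_powerlaw(draws)
        assert fit.at_boundary

    def test_degenerate_data(self):
        with pytest.raises(DegenerateDataError):
            fit_truncated_powerlaw(np.full(200, 3))

    def test_too_few_observations(self):
        with pytest.raises(ValidationError):
            fit_truncated_powerlaw([1, 2, 3])


def _mge_pool(rng, n=5, length=300):
    cfg = SimulationConfig(n_mge=n, mge_len=length)
    return generate_mge_pool(cfg, rng)


class TestEvolveLineage:
    def test_static_without_gain_or_loss(self, rng):
        initial = [TrueSpacer(seq="ACGT" * 9) for _ in range(4)]
        arrays, events = evolve_lineage(initial, range(6), 0.0, 0.0,
                                        _mge_pool(rng), 34, rng)
        assert events == []
        for t in range(6):
            assert arrays[t] == tuple(initial)

    def test_relative_order_preserved(self, rng):
        pool = _mge_pool(rng)
        initial = [TrueSpacer(seq=f"{'ACGT' * 8}{pair}")
                   for pair in ("AA", "CC", "GG", "TT", "AG", "CT")]
        arrays, _ = evolve_lineage(initial, range(10), 1.0, 0.15, pool, 34, rng)
        for t in range(9):
            a, b = arrays[t], arrays[t + 1]
            shared = [s.seq for s in a if s.seq in {x.seq for x in b}]
            shared_in_b = [s.seq for s in b if s.seq in {x.seq for x in a}]
            assert shared == shared_in_b

    def test_gain_counts_poisson(self):
        rng = np.random.default_rng(5)
        n_steps = 10
        totals = []
        for _ in range(200):
            pool = _mge_pool(rng)
            initial = [TrueSpacer(seq="A" * 34)]
            arrays, events = evolve_lineage(initial, range(n_steps + 1), 1.0, 0.0,
                                            pool, 34, rng)
            totals.append(len(events))
            assert len(arrays[n_steps]) == 1 + len(events)
        # mean of 200 Poisson(10) draws: CI half-width ~ 3 sigma/sqrt(200)
        assert abs(np.mean(totals) - 10.0) < 3 * np.sqrt(10.0 / 200)

    def test_empty_initial_rejected(self, rng):
        with pytest.raises(ValidationError):
            evolve_lineage([], range(3), 0.5, 0.1, _mge_pool(rng), 34, rng)


class TestGenerateMgePool:
    def test_pure_plasmid_mix(self, rng):
        cfg = SimulationConfig(n_mge=20, mge_class_mix={"plasmid": 1.0})
        pool = generate_mge_pool(cfg, rng)
        assert all(m.mge_class == "plasmid" for m in pool.values())

    def test_no_crass_when_frac_zero(self, rng):
        cfg = SimulationConfig(n_mge=40, crass_frac=0.0)
        pool = generate_mge_pool(cfg, rng)
        assert not any(m.crass_like for m in pool.values())

    def test_bad_mix_rejected(self):
        with pytest.raises(ValidationError):
            SimulationConfig(mge_class_mix={"plasmid": 0.7})

    def test_planted_strand_balance(self):
        from crispr_memory.simulate import _sample_protospacer
        rng = np.random.default_rng(3)
        pool = _mge_pool(rng)
        placements = []
        n = 10_000
        for _ in range(n):
            _sample_protospacer(pool, 34, rng, placements)
        minus = sum(1 for _, _, strand, _ in placements if strand == "-")
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n, 0.5)
        assert lo <= minus <= hi

    def test_planted_protospacer_recoverable(self, rng):
        from crispr_memory.simulate import _sample_protospacer
        pool = _mge_pool(rng)
        placements = []
        sp = _sample_protospacer(pool, 34, rng, placements)
        mge_id, offset, strand, seq = placements[0]
        window = pool[mge_id].seq[offset:offset + 34]
        assert seq == (revcomp(window) if strand == "-" else window)
        assert sp.seq == seq


class TestSimulateAbundances:
    def _truth(self, seed, multiplier, boost, noise):
        cfg = SimulationConfig(
            n_subjects=2, n_samples_per_subject=8, n_lineages_per_subject=2,
            n_mge=10, mge_len=400, gain_rate=0.8, loss_rate=0.0,
            immunity_multiplier=multiplier, acquisition_boost=boost,
            noise_sigma=noise, rng_seed=seed)
        return generate_community(cfg)

    def test_neutral_equals_baseline(self):
        t_eff = self._truth(8, 0.3, 3.0, 0.0)
        t_null = self._truth(8, 1.0, 1.0, 0.0)
        # same seed => same genealogy and same baseline draws
        eff = t_eff.abundance.set_index(["target_id", "subject", "timepoint"])
        null = t_null.abundance.set_index(["target_id", "subject", "timepoint"])
        ratio = eff["abundance"] / null["abundance"]
        assert set(np.round(ratio, 12)) <= {0.3, 1.0, 3.0}
        assert (ratio == 1.0).sum() > 0

    def test_zero_multiplier_zeroes_with_spacer_samples(self):
        truth = self._truth(9, 0.0, 1.0, 0.0)
        null = self._truth(9, 1.0, 1.0, 0.0)
        ratio = (truth.abundance["abundance"] / null.abundance["abundance"])
        assert set(np.round(ratio, 12)) <= {0.0, 1.0}
        assert (ratio == 0.0).sum() > 0

    def test_multiplier_ratio_exact(self):
        t_eff = self._truth(10, 0.3, 1.0, 0.0)
        t_null = self._truth(10, 1.0, 1.0, 0.0)
        ratio = t_eff.abundance["abundance"] / t_null.abundance["abundance"]
        suppressed = ratio[np.round(ratio, 12) == 0.3]
        assert len(suppressed) > 0


class TestEmitObservedDataset:
    def test_perfect_observation_matches_truth(self, small_truth):
        ds = emit_observed_dataset(small_truth, detection_prob=1.0,
                                   truncation_prob=0.0,
                                   rng=np.random.default_rng(0))
        truth_counts = {}
        for lin in small_truth.lineages:
            for t, arr in lin.arrays.items():
                if arr:
                    truth_counts[(lin.lineage_id, t)] = [s.seq for s in arr]
        assert len(ds.arrays) == len(truth_counts)
        for rec in ds.arrays:
            lineage_id = small_truth.observed_membership[rec.array_id]
            true_seqs = truth_counts[(lineage_id, rec.timepoint)]
            observed = [ds.spacers[sid] for sid in rec.spacer_ids]
            forward = [canonical(s) for s in observed]
            expected = [canonical(s) for s in true_seqs]
            assert forward == expected or forward == expected[::-1]

    def test_truncation_is_terminal_run(self, small_truth):
        rng = np.random.default_rng(4)
        ds = emit_observed_dataset(small_truth, detection_prob=1.0,
                                   truncation_prob=1.0, rng=rng)
        for rec in ds.arrays:
            lineage_id = small_truth.observed_membership[rec.array_id]
            lin = next(l for l in small_truth.lineages if l.lineage_id == lineage_id)
            true_keys = [canonical(s.seq) for s in lin.arrays[rec.timepoint]]
            obs_keys = [canonical(ds.spacers[sid]) for sid in rec.spacer_ids]
            if obs_keys[0] != true_keys[0] or len(obs_keys) != len(true_keys):
                pass  # orientation flip handled below
            candidates = [true_keys, true_keys[::-1]]
            ok = any(
                obs == cand[i:i + len(obs)]
                for cand in candidates
                for obs in [obs_keys]
                for i in (0, len(cand) - len(obs))
                if i >= 0
            )
            assert ok, rec.array_id

    def test_detection_fraction_binomial(self):
        cfg = SimulationConfig(
            n_subjects=4, n_samples_per_subject=15, n_lineages_per_subject=5,
            n_mge=8, mge_len=300, gain_rate=0.0, loss_rate=0.0, rng_seed=17)
        truth = generate_community(cfg)
        n_true = sum(1 for lin in truth.lineages
                     for arr in lin.arrays.values() if arr)
        assert n_true >= 300
        ds = emit_observed_dataset(truth, detection_prob=0.8, truncation_prob=0.0,
                                   rng=np.random.default_rng(2))
        lo, hi = stats.binom.ppf([0.005, 0.995], n_true, 0.8)
        assert lo <= len(ds.arrays) <= hi

    def test_determinism(self, small_config):
        t1 = generate_community(small_config)
        t2 = generate_community(small_config)
        d1 = emit_observed_dataset(t1)
        d2 = emit_observed_dataset(t2)
        assert [r.array_id for r in d1.arrays] == [r.array_id for r in d2.arrays]
        assert d1.spacers == d2.spacers
        assert {c: d1.contigs[c].seq for c in d1.contigs} == \
               {c: d2.contigs[c].seq for c in d2.contigs}
        assert d1.abundance.equals(d2.abundance)
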
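"""Synthetic longitudinal community generator with ground truth.

Generates host lineages whose CRISPR arrays evolve by leader-end spacer
gain and random spacer loss, an MGE pool carrying planted protospacers
(strand-randomized), abundance series with configurable immunity effects,
and an observation layer (detection dropout, terminal truncation,
strand-randomized array emission) emulating metagenomic incompleteness.

Array sizes follow a discrete truncated power law
P(k) ~ k^(-alpha) * exp(-k / cutoff) on k >= 1, sampled by inverse-CDF
lookup; the matching maximum-likelihood fitter recovers the parameters by
grid search plus Nelder-Mead refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import logsumexp

from crispr_memory.datasets import (
    ArrayRecord,
    Contig,
    Dataset,
    MgeRecord,
    write_dataset,
)
from crispr_memory.errors import DegenerateDataError, ValidationError
from crispr_memory.seq import random_seq, revcomp

__all__ = [
    "SimulationConfig",
    "CommunityTruth",
    "sample_array_sizes",
    "truncated_powerlaw_loglik",
    "fit_truncated_powerlaw",
    "PowerlawFit",
    "evolve_lineage",
    "generate_mge_pool",
    "generate_community",
    "simulate_abundances",
    "emit_observed_dataset",
]

FINAL_CLASSES = ("lytic_or_nonlysogenic_phage", "lysogenic_phage", "plasmid", "other_mge")


@dataclass
class SimulationConfig:
    n_subjects: int = 4
    n_samples_per_subject: int = 12
    n_lineages_per_subject: int = 3
    size_alpha: float = 2.0
    size_cutoff: float = 100.0
    spacer_len: int = 34
    repeat_len: int = 31
    gain_rate: float = 0.5
    loss_rate: float = 0.02
    n_mge: int = 30
    mge_len: int = 2000
    mge_class_mix: dict[str, float] = field(default_factory=lambda: {
        "lytic_or_nonlysogenic_phage": 0.4,
        "lysogenic_phage": 0.3,
        "plasmid": 0.2,
        "other_mge": 0.1,
    })
    crass_frac: float = 0.2
    infant_frac: float = 0.1
    immunity_multiplier: float = 0.3
    acquisition_boost: float = 3.0
    noise_sigma: float = 0.0
    detection_prob: float = 1.0
    truncation_prob: float = 0.2
    detection_floor_quantile: float = 0.1
    local_target_frac: float = 0.6
    oriented_frac: float = 0.7
    contig_flank: int = 300
    n_decoy_contigs: int = 2
    min_initial_size: int = 2
    subtypes: tuple[str, ...] = ("I-C", "I-E", "II-A")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("crass_frac", "infant_frac", "detection_prob", "truncation_prob",
                     "loss_rate", "detection_floor_quantile", "local_target_frac",
                     "oriented_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name} must lie in [0, 1], got {v!r}")
        total = sum(self.mge_class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"mge_class_mix must sum to 1, sums to {total}")
        unknown = set(self.mge_class_mix) - set(FINAL_CLASSES)
        if unknown:
            raise ValidationError(f"unknown class(es) in mge_class_mix: {sorted(unknown)}")
        if self.size_alpha <= 1.0 and not np.isfinite(self.size_cutoff):
            raise ValidationError("size_alpha <= 1 with infinite cutoff is non-normalizable")
        if self.size_cutoff < 0:
            raise ValidationError("size_cutoff must be positive")


# ---------------------------------------------------------------------------
# Truncated power law

def _log_pmf_weights(alpha: float, cutoff: float, kmax: int) -> np.ndarray:
    k = np.arange(1, kmax + 1, dtype=float)
    logw = -alpha * np.log(k)
    if np.isfinite(cutoff):
        logw = logw - k / cutoff
    return logw


def sample_array_sizes(n: int, alpha: float, cutoff: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Draw n integer sizes >= 1 from P(k) ~ k^(-alpha) exp(-k/cutoff)."""
    if alpha <= 1.0 and not np.isfinite(cutoff):
        raise ValidationError("alpha <= 1 requires a finite cutoff")
    if n == 0:
        return np.empty(0, dtype=int)
    if np.isfinite(cutoff):
        kmax = int(max(1000, 50 * max(cutoff, 1.0)))
    else:
        kmax = 1_000_000
    kmax = min(kmax, 1_000_000)
    logw = _log_pmf_weights(alpha, cutoff, kmax)
    logw -= logw.max()
    w = np.exp(logw)
    cdf = np.cumsum(w)
    cdf /= cdf[-1]
    u = rng.random(n)
    return np.searchsorted(cdf, u, side="left") + 1


def truncated_powerlaw_loglik(sizes: Sequence[int], alpha: float,
                              cutoff: float, kmax: int | None = None) -> float:
    """Exact discrete log-likelihood of the truncated power-law family."""
    sizes = np.asarray(sizes, dtype=float)
    if kmax is None:
        kmax = int(max(1000, 10 * sizes.max()))
    logw = _log_pmf_weights(alpha, cutoff, kmax)
    log_z = logsumexp(logw)
    return float(-alpha * np.log(sizes).sum() - sizes.sum() / cutoff
                 - sizes.size * log_z)


@dataclass
class PowerlawFit:
    alpha: float
    cutoff: float
    loglik: float
    at_boundary: bool


def fit_truncated_powerlaw(sizes: Sequence[int],
                           cutoff_max: float = 1e5) -> PowerlawFit:
    """Discrete MLE of (alpha, cutoff) by grid search plus refinement.

    A cutoff estimate landing at the search ceiling (pure power-law regime)
    is reported with ``at_boundary=True``.
    """
    sizes = np.asarray(sizes, dtype=int)
    if sizes.size < 100:
        raise ValidationError("need >= 100 observations to fit")
    if (sizes < 1).any():
        raise ValidationError("all sizes must be >= 1")
    if np.unique(sizes).size == 1:
        raise DegenerateDataError("all observations identical; fit is degenerate")

    kmax = int(max(1000, 10 * sizes.max()))
    sum_log = float(np.log(sizes).sum())
    sum_k = float(sizes.sum())
    n = sizes.size
    log_k = np.log(np.arange(1, kmax + 1, dtype=float))
    k_arr = np.arange(1, kmax + 1, dtype=float)

    def negll(alpha: float, log_cutoff: float) -> float:
        cutoff = math.exp(log_cutoff)
        logw = -alpha * log_k - k_arr / cutoff
        log_z = logsumexp(logw)
        return alpha * sum_log + sum_k / cutoff + n * log_z

    alphas = np.linspace(1.05, 3.5, 30)
    log_cutoffs = np.linspace(math.log(2.0), math.log(cutoff_max), 25)
    best = None
    for a in alphas:
        for lc in log_cutoffs:
            value = negll(a, lc)
            if best is None or value < best[0]:
                best = (value, a, lc)
    assert best is not None

    res = minimize(
        lambda x: negll(x[0], x[1]), x0=[best[1], best[2]],
        method="Nelder-Mead",
        bounds=[(1.0001, 10.0), (math.log(1.0), math.log(cutoff_max))],
    )
    alpha_hat = float(res.x[0])
    cutoff_hat = float(math.exp(res.x[1]))
    # cutoff unidentified (pure power-law regime): pinning it at the search
    # ceiling costs almost no likelihood, or the optimum sits at the ceiling
    res_pure = minimize_scalar(
        lambda a: negll(a, math.log(cutoff_max)), bounds=(1.0001, 10.0),
        method="bounded")
    at_boundary = (cutoff_hat >= 0.98 * cutoff_max
                   or float(res_pure.fun) <= float(res.fun) + 2.0)
    return PowerlawFit(alpha=alpha_hat, cutoff=cutoff_hat,
                       loglik=float(-res.fun), at_boundary=at_boundary)


# ---------------------------------------------------------------------------
# Truth containers

@dataclass(frozen=True)
class TrueSpacer:
    seq: str
    source_mge: str | None = None   # None: background spacer, no planted target
    mge_offset: int | None = None
    mge_strand: str | None = None   # '+': spacer equals MGE window; '-': revcomp


@dataclass
class AcquisitionEvent:
    subject: str
    lineage_id: str
    timepoint: int
    spacer: TrueSpacer


@dataclass
class LineageTruth:
    lineage_id: str
    subject: str
    repeat_seq: str
    subtype: str
    oriented: bool
    # timepoint -> ordered leader->trailer true array (may be empty after losses)
    arrays: dict[int, tuple[TrueSpacer, ...]] = field(default_factory=dict)


@dataclass
class CommunityTruth:
    config: SimulationConfig
    timepoints: dict[str, list[int]]
    mge_db: dict[str, MgeRecord]
    lineages: list[LineageTruth]
    acquisitions: list[AcquisitionEvent]
    # (mge_id, offset, strand, spacer_seq) for every planted protospacer
    placements: list[tuple[str, int, str, str]] = field(default_factory=list)
    # columns: target_id, subject, timepoint, abundance (noise-free unless set)
    abundance: pd.DataFrame | None = None
    # filled by emit_observed_dataset: observed array id -> true lineage id
    observed_membership: dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Generators

def generate_mge_pool(config: SimulationConfig,
                      rng: np.random.Generator) -> dict[str, MgeRecord]:
    """Random MGE records with classes, lifestyle flags, and tags."""
    if config.n_mge < 1:
        raise ValidationError("n_mge must be >= 1")
    config.validate()
    classes = list(config.mge_class_mix)
    probs = np.array([config.mge_class_mix[c] for c in classes])
    pool: dict[str, MgeRecord] = {}
    for i in range(config.n_mge):
        mge_id = f"mge{i:04d}"
        final_class = classes[int(rng.choice(len(classes), p=probs))]
        if final_class in ("lytic_or_nonlysogenic_phage", "lysogenic_phage"):
            mge_class = "virus"
            lifestyle = ("lysogenic" if final_class == "lysogenic_phage"
                         else "lytic_or_nonlysogenic")
            crass = bool(rng.random() < config.crass_frac)
            infant = bool(rng.random() < config.infant_frac)
        else:
            mge_class = final_class
            lifestyle = None
            crass = False
            infant = False
        pool[mge_id] = MgeRecord(
            mge_id=mge_id, seq=random_seq(config.mge_len, rng),
            mge_class=mge_class, lifestyle=lifestyle,
            crass_like=crass, infant_gut=infant,
        )
    return pool


def _sample_protospacer(mge_pool: Mapping[str, MgeRecord],
                        spacer_len: int, rng: np.random.Generator,
                        placements: list[tuple[str, int, str, str]],
                        ) -> TrueSpacer:
    """Copy a spacer from a random protospacer window of a random MGE.

    The planted protospacer sits on a random strand: with probability 0.5
    the spacer is the reverse complement of the MGE window.
    """
    mge_ids = sorted(mge_pool)
    mge = mge_pool[mge_ids[int(rng.integers(len(mge_ids)))]]
    offset = int(rng.integers(0, len(mge.seq) - spacer_len + 1))
    window = mge.seq[offset:offset + spacer_len]
    strand = "-" if rng.random() < 0.5 else "+"
    spacer_seq = revcomp(window) if strand == "-" else window
    placements.append((mge.mge_id, offset, strand, spacer_seq))
    return TrueSpacer(seq=spacer_seq, source_mge=mge.mge_id,
                      mge_offset=offset, mge_strand=strand)


def evolve_lineage(initial_array: Sequence[TrueSpacer], timeline: Sequence[int],
                   gain_rate: float, loss_rate: float,
                   mge_pool: Mapping[str, MgeRecord], spacer_len: int,
                   rng: np.random.Generator,
                   placements: list[tuple[str, int, str, str]] | None = None,
                   lineage_id: str = "lineage", subject: str = "subject",
                   ) -> tuple[dict[int, tuple[TrueSpacer, ...]], list[AcquisitionEvent]]:
    """Evolve one lineage along its timeline by leader-end gain and loss.

    Gains prepend a spacer copied from an MGE protospacer window (random
    strand); losses remove spacers independently without reordering
    survivors. Every gain is logged as a candidate acquisition event.
    """
    if not initial_array:
        raise ValidationError("initial array must be non-empty")
    if placements is None:
        placements = []
    arrays: dict[int, tuple[TrueSpacer, ...]] = {}
    events: list[AcquisitionEvent] = []
    current = tuple(initial_array)
    for step, t in enumerate(timeline):
        if step > 0:
            if loss_rate > 0 and current:
                keep = rng.random(len(current)) >= loss_rate
                current = tuple(s for s, k in zip(current, keep) if k)
            n_gains = int(rng.poisson(gain_rate)) if gain_rate > 0 else 0
            for _ in range(n_gains):
                new = _sample_protospacer(mge_pool, spacer_len, rng, placements)
                current = (new,) + current
                events.append(AcquisitionEvent(
                    subject=subject, lineage_id=lineage_id, timepoint=t, spacer=new))
        arrays[t] = current
    return arrays, events


def generate_community(config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> CommunityTruth:
    """Generate the full ground-truth community (lineages, MGE, abundance)."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    mge_pool = generate_mge_pool(config, rng)
    placements: list[tuple[str, int, str, str]] = []

    timepoints = {
        f"S{si:02d}": list(range(config.n_samples_per_subject))
        for si in range(config.n_subjects)
    }
    lineages: list[LineageTruth] = []
    acquisitions: list[AcquisitionEvent] = []
    for subject in sorted(timepoints):
        for li in range(config.n_lineages_per_subject):
            lineage_id = f"{subject}_true{li:02d}"
            size = int(sample_array_sizes(1, config.size_alpha,
                                          config.size_cutoff, rng)[0])
            size = max(size, config.min_initial_size)
            initial: list[TrueSpacer] = []
            for _ in range(size):
                if rng.random() < config.local_target_frac:
                    initial.append(_sample_protospacer(
                        mge_pool, config.spacer_len, rng, placements))
                else:
                    initial.append(TrueSpacer(seq=random_seq(config.spacer_len, rng)))
            arrays, events = evolve_lineage(
                initial, timepoints[subject], config.gain_rate, config.loss_rate,
                mge_pool, config.spacer_len, rng, placements,
                lineage_id=lineage_id, subject=subject)
            lineages.append(LineageTruth(
                lineage_id=lineage_id, subject=subject,
                repeat_seq=random_seq(config.repeat_len, rng),
                subtype=config.subtypes[int(rng.integers(len(config.subtypes)))],
                oriented=bool(rng.random() < config.oriented_frac),
                arrays=arrays,
            ))
            acquisitions.extend(events)

    truth = CommunityTruth(
        config=config, timepoints=timepoints, mge_db=mge_pool,
        lineages=lineages, acquisitions=acquisitions, placements=placements,
    )
    truth.abundance = simulate_abundances(
        truth, config.immunity_multiplier, config.acquisition_boost,
        config.noise_sigma, rng)
    return truth


def simulate_abundances(truth: CommunityTruth, immunity_multiplier: float,
                        acquisition_boost: float, noise_sigma: float,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Per-(MGE, subject, sample) abundance with planted immunity effects.

    Baseline is lognormal(0, 1) per MGE per sample. At each acquisition
    sample the target's abundance is multiplied by ``acquisition_boost``;
    in strictly later samples where any cognate spacer is present in the
    true arrays it is multiplied by ``immunity_multiplier`` (applied once
    per sample regardless of how many cognate spacers are present).
    Multiplicative lognormal noise is applied last.
    """
    # first appearance of each cognate spacer within its lineage, and the
    # samples where it is present; the multiplier applies strictly after the
    # spacer's first appearance, once per sample regardless of multiplicity
    acquired_at: dict[tuple[str, str], set[int]] = {}
    suppressed: set[tuple[str, str, int]] = set()
    for lin in truth.lineages:
        first_seen: dict[str, int] = {}
        for t in sorted(lin.arrays):
            for spacer in lin.arrays[t]:
                if spacer.source_mge is None:
                    continue
                if spacer.seq not in first_seen:
                    first_seen[spacer.seq] = t
                elif t > first_seen[spacer.seq]:
                    suppressed.add((lin.subject, spacer.source_mge, t))
    for event in truth.acquisitions:
        if event.spacer.source_mge is not None:
            acquired_at.setdefault(
                (event.subject, event.spacer.source_mge), set()).add(event.timepoint)

    rows = []
    for subject in sorted(truth.timepoints):
        for mge_id in sorted(truth.mge_db):
            acq_times = acquired_at.get((subject, mge_id), set())
            for t in truth.timepoints[subject]:
                value = float(rng.lognormal(mean=0.0, sigma=1.0))
                if t in acq_times:
                    value *= acquisition_boost
                elif (subject, mge_id, t) in suppressed:
                    value *= immunity_multiplier
                if noise_sigma > 0:
                    value *= float(rng.lognormal(mean=0.0, sigma=noise_sigma))
                rows.append({"target_id": mge_id, "subject": subject,
                             "timepoint": t, "abundance": value})
    return pd.DataFrame(rows, columns=["target_id", "subject", "timepoint", "abundance"])


# ---------------------------------------------------------------------------
# Observation layer

class _SeqRegistry:
    """Deterministic sequence -> id assignment in first-seen order."""

    def __init__(self, prefix: str) -> None:
        self.prefix = prefix
        self._ids: dict[str, str] = {}

    def get(self, seq: str) -> str:
        if seq not in self._ids:
            self._ids[seq] = f"{self.prefix}{len(self._ids):06d}"
        return self._ids[seq]

    def as_dict(self) -> dict[str, str]:
        return {sid: seq for seq, sid in self._ids.items()}


def emit_observed_dataset(truth: CommunityTruth, detection_prob: float | None = None,
                          truncation_prob: float | None = None,
                          rng: np.random.Generator | None = None,
                          outdir: str | Path | None = None) -> Dataset:
    """Apply the observation layer and assemble a Dataset (optionally on disk).

    Each true array is independently detected; detected arrays may lose a
    geometric-length terminal run from one end; emission strand is
    randomized (reverse-complemented arrays list spacers in reverse order
    as reverse-complemented sequences). Contigs are emitted per sample for
    every MGE whose abundance exceeds the detection floor (a fixed quantile
    of that sample's abundances), embedding the MGE in random flanks.
    """
    config = truth.config
    if detection_prob is None:
        detection_prob = config.detection_prob
    if truncation_prob is None:
        truncation_prob = config.truncation_prob
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)

    spacer_reg = _SeqRegistry("sp")
    repeat_reg = _SeqRegistry("rep")
    arrays: list[ArrayRecord] = []
    truth.observed_membership = {}

    for lin in truth.lineages:
        repeat_id = repeat_reg.get(lin.repeat_seq)
        for t in truth.timepoints[lin.subject]:
            true_arr = lin.arrays.get(t, ())
            if not true_arr:
                continue
            if rng.random() >= detection_prob:
                continue
            spacers = list(true_arr)
            if len(spacers) > 1 and rng.random() < truncation_prob:
                run = min(int(rng.geometric(0.5)), len(spacers) - 1)
                if rng.random() < 0.5:
                    spacers = spacers[run:]      # leader-end truncation
                else:
                    spacers = spacers[:-run]     # trailer-end truncation
            flipped = bool(rng.random() < 0.5)
            if flipped:
                seqs = [revcomp(s.seq) for s in reversed(spacers)]
                orientation = "reverse" if lin.oriented else "unknown"
            else:
                seqs = [s.seq for s in spacers]
                orientation = "forward" if lin.oriented else "unknown"
            array_id = f"arr_{lin.lineage_id}_t{t:02d}"
            record = ArrayRecord(
                array_id=array_id, subject=lin.subject,
                sample=f"{lin.subject}_t{t:02d}", timepoint=t,
                repeat_id=repeat_id,
                spacer_ids=tuple(spacer_reg.get(s) for s in seqs),
                orientation=orientation, subtype=lin.subtype,
            )
            arrays.append(record)
            truth.observed_membership[array_id] = lin.lineage_id

    # contigs + observed abundance with detection floor
    contigs: dict[str, Contig] = {}
    observed_rows = []
    abundance = truth.abundance
    assert abundance is not None
    for subject in sorted(truth.timepoints):
        for t in truth.timepoints[subject]:
            mask = (abundance["subject"] == subject) & (abundance["timepoint"] == t)
            sample_ab = abundance.loc[mask]
            floor = (float(np.quantile(sample_ab["abundance"],
                                       config.detection_floor_quantile))
                     if config.detection_floor_quantile > 0 else 0.0)
            for row in sample_ab.itertuples(index=False):
                detected = row.abundance > floor or config.detection_floor_quantile == 0
                observed_rows.append({
                    "target_id": row.target_id, "subject": subject,
                    "timepoint": t,
                    "abundance": row.abundance if detected else 0.0,
                })
                if detected:
                    cid = f"ctg_{subject}_t{t:02d}_{row.target_id}"
                    flanks = (random_seq(config.contig_flank, rng),
                              random_seq(config.contig_flank, rng))
                    contigs[cid] = Contig(
                        contig_id=cid,
                        seq=flanks[0] + truth.mge_db[row.target_id].seq + flanks[1],
                        subject=subject, sample=str(t))
            for d in range(config.n_decoy_contigs):
                cid = f"ctg_{subject}_t{t:02d}_decoy{d}"
                contigs[cid] = Contig(
                    contig_id=cid, seq=random_seq(config.mge_len, rng),
                    subject=subject, sample=str(t))

    spacers = spacer_reg.as_dict()
    repeats = repeat_reg.as_dict()
    ds = Dataset(
        subjects=sorted(truth.timepoints),
        timepoints={s: list(t) for s, t in truth.timepoints.items()},
        arrays=arrays, spacers=spacers, repeats=repeats, contigs=contigs,
        mge_db=dict(truth.mge_db),
        abundance=pd.DataFrame(observed_rows,
                               columns=["target_id", "subject", "timepoint", "abundance"]),
    )
    ds.validate()

    if outdir is not None:
        outdir = Path(outdir)
        write_dataset(ds, outdir)
        _write_truth(truth, outdir / "truth")
    return ds


def _write_truth(truth: CommunityTruth, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {"subject": e.subject, "lineage_id": e.lineage_id,
             "timepoint": e.timepoint, "spacer_seq": e.spacer.seq,
             "target_mge": e.spacer.source_mge or "."}
            for e in truth.acquisitions
        ],
        columns=["subject", "lineage_id", "timepoint", "spacer_seq", "target_mge"],
    ).to_csv(outdir / "planted_events.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"mge_id": m, "offset": o, "strand": s, "spacer_seq": q}
         for m, o, s, q in truth.placements],
        columns=["mge_id", "offset", "strand", "spacer_seq"],
    ).to_csv(outdir / "placements.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"array_id": a, "lineage_id": l}
         for a, l in sorted(truth.observed_membership.items())],
        columns=["array_id", "lineage_id"],
    ).to_csv(outdir / "lineage_members.tsv", sep="\t", index=False)
    if truth.abundance is not None:
        truth.abundance.to_csv(outdir / "true_abundance.tsv", sep="\t", index=False)
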
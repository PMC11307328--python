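"""Dataset containers and readers/writers for the tabular/FASTA exchange formats.

All tables are tab-separated UTF-8 with a header row and ``.`` for missing
values. Sequence coordinates are 0-based, half-open; strands are ``+``/``-``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from crispr_memory.config import Parameters
from crispr_memory.errors import (
    DuplicateKeyError,
    MissingSequenceError,
    ValidationError,
)

__all__ = [
    "ArrayRecord",
    "Contig",
    "MgeRecord",
    "Dataset",
    "read_fasta",
    "write_fasta",
    "read_array_table",
    "write_array_table",
    "read_dataset",
    "write_dataset",
    "write_results",
]

MISSING = "."

ORIENTATIONS = ("forward", "reverse", "unknown")


@dataclass
class ArrayRecord:
    """One assembled CRISPR array observed in one sample."""

    array_id: str
    subject: str
    sample: str
    timepoint: int
    repeat_id: str
    spacer_ids: tuple[str, ...]
    orientation: str = "unknown"
    subtype: str | None = None
    cas_adjacent: bool = False
    repeat_cluster: str | None = None

    def __post_init__(self) -> None:
        self.spacer_ids = tuple(self.spacer_ids)
        if len(self.spacer_ids) < 1:
            raise ValidationError(f"array {self.array_id} has no spacers")
        if self.orientation not in ORIENTATIONS:
            raise ValidationError(
                f"array {self.array_id}: orientation must be one of {ORIENTATIONS}"
            )

    @property
    def n_spacers(self) -> int:
        return len(self.spacer_ids)


@dataclass
class Contig:
    """A local assembly fragment with subject/sample provenance."""

    contig_id: str
    seq: str
    subject: str | None = None
    sample: str | None = None


@dataclass
class MgeRecord:
    """One mobile-genetic-element reference sequence with annotations."""

    mge_id: str
    seq: str
    mge_class: str = "other_mge"  # virus | plasmid | other_mge
    lifestyle: str | None = None  # lysogenic | lytic_or_nonlysogenic (viral only)
    crass_like: bool = False
    infant_gut: bool = False


@dataclass
class Dataset:
    """In-memory view of one study: subjects, arrays, sequences, references."""

    subjects: list[str] = field(default_factory=list)
    timepoints: dict[str, list[int]] = field(default_factory=dict)
    arrays: list[ArrayRecord] = field(default_factory=list)
    spacers: dict[str, str] = field(default_factory=dict)
    repeats: dict[str, str] = field(default_factory=dict)
    contigs: dict[str, Contig] = field(default_factory=dict)
    mge_db: dict[str, MgeRecord] = field(default_factory=dict)
    # columns: target_id, subject, timepoint, abundance
    abundance: pd.DataFrame | None = None
    read_totals: dict[str, int] = field(default_factory=dict)

    def validate(self) -> None:
        for subject, tps in self.timepoints.items():
            if list(tps) != sorted(set(tps)):
                raise ValidationError(f"timepoints for {subject} not strictly increasing")
        for rec in self.arrays:
            if rec.subject not in self.timepoints:
                raise ValidationError(f"array {rec.array_id}: unknown subject {rec.subject}")
            if rec.timepoint not in self.timepoints[rec.subject]:
                raise ValidationError(
                    f"array {rec.array_id}: timepoint {rec.timepoint} not in "
                    f"{rec.subject}'s timeline"
                )
        if self.abundance is not None:
            if (self.abundance["abundance"] < 0).any():
                raise ValidationError("negative abundance value")
            if not self.abundance["abundance"].map(lambda v: v == v and abs(v) != float("inf")).all():
                raise ValidationError("non-finite abundance value")


# ---------------------------------------------------------------------------
# FASTA helpers

def read_fasta(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise DuplicateKeyError(f"duplicate FASTA id {rec.id} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path,
                descriptions: Mapping[str, str] | None = None) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description=(descriptions or {}).get(name, ""))
        for name, seq in seqs.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Array table

_ARRAY_COLUMNS = [
    "array_id", "subject", "sample", "timepoint", "repeat_id",
    "spacer_ids", "orientation", "subtype", "cas_adjacent",
]


def read_array_table(tsv: str | Path, fasta: str | Path,
                     ) -> tuple[list[ArrayRecord], dict[str, str], dict[str, str]]:
    """Read an array table plus companion FASTA of repeat and spacer sequences.

    Returns the records, the spacer id->sequence map, and the repeat
    id->sequence map. Spacer order is preserved exactly as listed.
    """
    seqs = read_fasta(fasta)
    df = pd.read_csv(tsv, sep="\t", dtype=str, na_values=[MISSING], keep_default_na=False)
    required = {"array_id", "subject", "sample", "timepoint", "repeat_id", "spacer_ids"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValidationError(f"array table missing column(s): {sorted(missing_cols)}")

    records: list[ArrayRecord] = []
    spacers: dict[str, str] = {}
    repeats: dict[str, str] = {}
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        array_id = row.array_id
        if array_id in seen:
            raise DuplicateKeyError(f"duplicate array_id {array_id}")
        seen.add(array_id)
        spacer_ids = tuple(row.spacer_ids.split(","))
        for sid in spacer_ids:
            if sid not in seqs:
                raise MissingSequenceError(f"spacer {sid} (array {array_id}) not in FASTA")
            spacers[sid] = seqs[sid]
        repeat_id = row.repeat_id
        if repeat_id not in seqs:
            raise MissingSequenceError(f"repeat {repeat_id} (array {array_id}) not in FASTA")
        repeats[repeat_id] = seqs[repeat_id]
        orientation = getattr(row, "orientation", None)
        if orientation is None or pd.isna(orientation):
            orientation = "unknown"
        subtype = getattr(row, "subtype", None)
        if subtype is not None and pd.isna(subtype):
            subtype = None
        cas = getattr(row, "cas_adjacent", "false")
        records.append(ArrayRecord(
            array_id=array_id, subject=row.subject, sample=row.sample,
            timepoint=int(row.timepoint), repeat_id=repeat_id,
            spacer_ids=spacer_ids, orientation=orientation, subtype=subtype,
            cas_adjacent=str(cas).lower() == "true",
        ))
    return records, spacers, repeats


def write_array_table(arrays: Iterable[ArrayRecord], tsv: str | Path,
                      fasta: str | Path, spacers: Mapping[str, str],
                      repeats: Mapping[str, str]) -> None:
    rows = []
    used_spacers: dict[str, str] = {}
    used_repeats: dict[str, str] = {}
    for rec in arrays:
        rows.append({
            "array_id": rec.array_id,
            "subject": rec.subject,
            "sample": rec.sample,
            "timepoint": rec.timepoint,
            "repeat_id": rec.repeat_id,
            "spacer_ids": ",".join(rec.spacer_ids),
            "orientation": rec.orientation,
            "subtype": rec.subtype if rec.subtype is not None else MISSING,
            "cas_adjacent": str(rec.cas_adjacent).lower(),
        })
        for sid in rec.spacer_ids:
            used_spacers[sid] = spacers[sid]
        used_repeats[rec.repeat_id] = repeats[rec.repeat_id]
    df = pd.DataFrame(rows, columns=_ARRAY_COLUMNS)
    df.to_csv(tsv, sep="\t", index=False)
    combined = dict(sorted(used_repeats.items()))
    combined.update(sorted(used_spacers.items()))
    write_fasta(combined, fasta)


# ---------------------------------------------------------------------------
# Whole-dataset round trip

def write_dataset(ds: Dataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_array_table(ds.arrays, outdir / "arrays.tsv", outdir / "array_seqs.fasta",
                      ds.spacers, ds.repeats)
    write_fasta(dict(sorted(ds.spacers.items())), outdir / "spacers.fasta")
    write_fasta(dict(sorted(ds.repeats.items())), outdir / "repeats.fasta")

    samples = pd.DataFrame(
        [(s, t) for s in ds.subjects for t in ds.timepoints[s]],
        columns=["subject", "timepoint"],
    )
    samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)

    contig_seqs = {c.contig_id: c.seq for c in ds.contigs.values()}
    descriptions = {
        c.contig_id: f"subject={c.subject or MISSING} timepoint={c.sample or MISSING}"
        for c in ds.contigs.values()
    }
    write_fasta(dict(sorted(contig_seqs.items())), outdir / "contigs.fasta", descriptions)

    write_fasta({m.mge_id: m.seq for m in sorted(ds.mge_db.values(), key=lambda m: m.mge_id)},
                outdir / "mge.fasta")
    ann = pd.DataFrame(
        [
            {
                "mge_id": m.mge_id,
                "class": m.mge_class,
                "lifestyle": m.lifestyle if m.lifestyle is not None else MISSING,
                "crass_like": str(m.crass_like).lower(),
                "infant_gut": str(m.infant_gut).lower(),
            }
            for m in sorted(ds.mge_db.values(), key=lambda m: m.mge_id)
        ],
        columns=["mge_id", "class", "lifestyle", "crass_like", "infant_gut"],
    )
    ann.to_csv(outdir / "mge_annotations.tsv", sep="\t", index=False)

    if ds.abundance is not None:
        ds.abundance.sort_values(["target_id", "subject", "timepoint"]).to_csv(
            outdir / "abundance.tsv", sep="\t", index=False)


def read_dataset(indir: str | Path) -> Dataset:
    indir = Path(indir)
    arrays, spacers, repeats = read_array_table(
        indir / "arrays.tsv", indir / "array_seqs.fasta")
    # standalone FASTAs may carry spacers/repeats never used in an array
    if (indir / "spacers.fasta").exists():
        spacers = {**read_fasta(indir / "spacers.fasta"), **spacers}
    if (indir / "repeats.fasta").exists():
        repeats = {**read_fasta(indir / "repeats.fasta"), **repeats}

    samples = pd.read_csv(indir / "samples.tsv", sep="\t")
    subjects = sorted(samples["subject"].unique())
    timepoints = {
        s: sorted(samples.loc[samples["subject"] == s, "timepoint"].astype(int))
        for s in subjects
    }

    contigs: dict[str, Contig] = {}
    if (indir / "contigs.fasta").exists():
        for rec in SeqIO.parse(str(indir / "contigs.fasta"), "fasta"):
            meta = dict(
                part.split("=", 1) for part in rec.description.split()[1:]
                if "=" in part
            )
            subject = meta.get("subject")
            sample = meta.get("timepoint")
            contigs[rec.id] = Contig(
                contig_id=rec.id, seq=str(rec.seq).upper(),
                subject=None if subject == MISSING else subject,
                sample=None if sample == MISSING else sample,
            )

    mge_db: dict[str, MgeRecord] = {}
    if (indir / "mge.fasta").exists():
        mge_seqs = read_fasta(indir / "mge.fasta")
        ann = pd.read_csv(indir / "mge_annotations.tsv", sep="\t", dtype=str,
                          na_values=[MISSING], keep_default_na=False)
        for row in ann.itertuples(index=False):
            mge_db[row.mge_id] = MgeRecord(
                mge_id=row.mge_id, seq=mge_seqs[row.mge_id],
                mge_class=row[1],
                lifestyle=None if pd.isna(row.lifestyle) else row.lifestyle,
                crass_like=str(row.crass_like).lower() == "true",
                infant_gut=str(row.infant_gut).lower() == "true",
            )

    abundance = None
    if (indir / "abundance.tsv").exists():
        abundance = pd.read_csv(indir / "abundance.tsv", sep="\t")

    ds = Dataset(
        subjects=subjects, timepoints=timepoints, arrays=arrays,
        spacers=spacers, repeats=repeats, contigs=contigs, mge_db=mge_db,
        abundance=abundance,
    )
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# Result tables and manifest

def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def write_results(tables: Mapping[str, pd.DataFrame], outdir: str | Path,
                  params: Parameters | None = None,
                  inputs: Iterable[str | Path] = ()) -> dict:
    """Write result tables as TSV plus a deterministic run manifest.

    The manifest records parameters (including the seed), input checksums,
    and output checksums; no timestamps, so reruns are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    output_checksums: dict[str, str] = {}
    for name, table in sorted(tables.items()):
        path = outdir / f"{name}.tsv"
        table.to_csv(path, sep="\t", index=False, na_rep=MISSING)
        output_checksums[f"{name}.tsv"] = _sha256(path)
    manifest = {
        "parameters": params.to_dict() if params is not None else None,
        "rng_seed": params.rng_seed if params is not None else None,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "outputs": output_checksums,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
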
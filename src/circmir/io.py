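"""Readers and writers for the pipeline's file formats.

Sequence data travel as FASTA/FASTQ (gzip transparently handled, reference
classes encoded as ``class=miRNA`` in the description line); tabular data as
TSV with genes as rows and samples as columns; dendrograms as Newick; run
summaries as JSON. Every file written here starts with comment lines
recording the tool version, the seed and a configuration hash, and readers
skip those lines. Writing then reading any object yields an identical
in-memory object; malformed inputs raise :class:`ParseError` naming the
offending line or record.
"""

from __future__ import annotations

import gzip
import hashlib
import io as _io
import json
from pathlib import Path
from typing import IO, Iterator, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .synth import Read, ReadSet, RefEntry, SmallRNAReference
from .valstats import NEGATIVE_LABEL, POSITIVE_LABEL, PcrTable

__all__ = [
    "ParseError",
    "read_fasta_fastq",
    "write_reads_fasta",
    "write_reads_fastq",
    "read_reference_fasta",
    "write_reference_fasta",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_pcr_tsv",
    "write_pcr_tsv",
    "write_newick",
    "write_summary_json",
    "validate_sample_consistency",
]

METADATA_COLUMNS = [
    "cohort", "er", "pr", "her2", "inflammatory", "regimen",
    "pcr_status", "relapse", "follow_up_years",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line or record."""


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def _config_hash(config: Mapping | None) -> str:
    payload = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def _header_lines(seed: int | None = None, config: Mapping | None = None) -> list[str]:
    return [
        f"# circmir {__version__}",
        f"# seed: {'' if seed is None else seed}",
        f"# config-sha1: {_config_hash(config)}",
    ]


# ---------------------------------------------------------------- sequences

def read_fasta_fastq(path: str | Path) -> ReadSet:
    """Load reads from FASTA or FASTQ (gzip allowed), format by extension."""
    path = Path(path)
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    reads: list[Read] = []
    with _open_text(path) as fh:
        try:
            for i, rec in enumerate(SeqIO.parse(fh, fmt)):
                reads.append(Read(rec.id, str(rec.seq).upper()))
        except ValueError as exc:
            raise ParseError(
                f"{path}: malformed {fmt} near record {len(reads) + 1}: {exc}"
            ) from exc
    return ReadSet(reads, {})


def _write_seq_records(records, path: str | Path, fmt: str) -> None:
    with _open_text(path, "wt") as fh:
        SeqIO.write(records, fh, fmt)


def write_reads_fasta(reads: ReadSet, path: str | Path) -> None:
    _write_seq_records(
        (SeqRecord(Seq(r.sequence), id=r.read_id, description="") for r in reads.reads),
        path, "fasta",
    )


def write_reads_fastq(reads: ReadSet, path: str | Path) -> None:
    """FASTQ with a constant dummy quality of 'I' (Phred 40)."""
    def records() -> Iterator[SeqRecord]:
        for r in reads.reads:
            rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
            rec.letter_annotations["phred_quality"] = [40] * len(r.sequence)
            yield rec

    _write_seq_records(records(), path, "fastq")


def write_reference_fasta(ref: SmallRNAReference, path: str | Path) -> None:
    _write_seq_records(
        (
            SeqRecord(Seq(e.sequence), id=e.entry_id, description=f"class={e.rna_class}")
            for e in ref.entries
        ),
        path, "fasta",
    )


def read_reference_fasta(path: str | Path) -> SmallRNAReference:
    entries: list[RefEntry] = []
    with _open_text(path) as fh:
        for i, rec in enumerate(SeqIO.parse(fh, "fasta")):
            fields = dict(
                part.split("=", 1) for part in rec.description.split() if "=" in part
            )
            if "class" not in fields:
                raise ParseError(
                    f"{path}: record {i + 1} ({rec.id}) lacks a class= tag"
                )
            entries.append(RefEntry(rec.id, fields["class"], str(rec.seq).upper()))
    return SmallRNAReference(entries)


# ------------------------------------------------------------------- tables

def _read_table_lines(path: str | Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """TSV rows with their 1-based physical line numbers, comments skipped."""
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
            else:
                if len(fields) != len(header):
                    raise ParseError(
                        f"{path}: line {lineno}: expected {len(header)} fields, "
                        f"got {len(fields)}"
                    )
                rows.append((lineno, fields))
    if header is None:
        raise ParseError(f"{path}: empty table")
    return header, rows


def write_counts_tsv(
    m: pd.DataFrame, path: str | Path,
    seed: int | None = None, config: Mapping | None = None,
) -> None:
    with _open_text(path, "wt") as fh:
        for line in _header_lines(seed, config):
            fh.write(line + "\n")
        m.to_csv(fh, sep="\t", index_label="gene")


def read_counts_tsv(path: str | Path, dtype: str = "int") -> pd.DataFrame:
    """Genes x samples count matrix; non-integer counts or duplicates are errors."""
    header, rows = _read_table_lines(path)
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise ParseError(f"{path}: duplicate sample ids in header")
    genes, data = [], []
    for lineno, fields in rows:
        gene, vals = fields[0], fields[1:]
        parsed = []
        for s, v in zip(samples, vals):
            try:
                parsed.append(int(v) if dtype == "int" else float(v))
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-{'integer' if dtype == 'int' else 'numeric'}"
                    f" count {v!r} for gene {gene} / sample {s}"
                ) from exc
        genes.append(gene)
        data.append(parsed)
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise ParseError(f"{path}: duplicate gene ids: {dupes}")
    return pd.DataFrame(
        np.asarray(data, dtype=np.int64 if dtype == "int" else float),
        index=pd.Index(genes, name="gene"),
        columns=pd.Index(samples, name="sample"),
    )


def read_normalized_tsv(path: str | Path) -> pd.DataFrame:
    return read_counts_tsv(path, dtype="float")


_BOOL_OUT = {"relapse": (POSITIVE_LABEL, NEGATIVE_LABEL), "inflammatory": ("yes", "no")}


def write_metadata_tsv(
    metadata: pd.DataFrame, path: str | Path,
    seed: int | None = None, config: Mapping | None = None,
) -> None:
    out = metadata.copy()
    for col, (true_s, false_s) in _BOOL_OUT.items():
        if col in out.columns:
            out[col] = np.where(out[col].astype(bool), true_s, false_s)
    with _open_text(path, "wt") as fh:
        for line in _header_lines(seed, config):
            fh.write(line + "\n")
        out.to_csv(fh, sep="\t", index_label="sample", na_rep="")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    header, rows = _read_table_lines(path)
    cols = header[1:]
    samples, data = [], []
    for lineno, fields in rows:
        samples.append(fields[0])
        data.append(fields[1:])
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample ids: {dupes}")
    df = pd.DataFrame(data, index=pd.Index(samples, name="sample"), columns=cols)
    df = df.replace("", np.nan)
    for col, (true_s, false_s) in _BOOL_OUT.items():
        if col in df.columns:
            bad = ~df[col].isin([true_s, false_s])
            if bad.any():
                raise ParseError(
                    f"{path}: column {col!r} must be {true_s!r}/{false_s!r}; "
                    f"offending samples: {list(df.index[bad])[:5]}"
                )
            df[col] = df[col] == true_s
    if "follow_up_years" in df.columns:
        df["follow_up_years"] = df["follow_up_years"].astype(float)
    return df


def write_pcr_tsv(
    pcr: PcrTable, path: str | Path,
    seed: int | None = None, config: Mapping | None = None,
) -> None:
    """Tidy qPCR table: one row per (sample, gene) with the Ct value."""
    tidy = pcr.ct.stack().reset_index()
    tidy.columns = ["sample", "gene", "ct"]
    with _open_text(path, "wt") as fh:
        for line in _header_lines(seed, config):
            fh.write(line + "\n")
        fh.write(f"# reference: {pcr.reference}\n")
        tidy.to_csv(fh, sep="\t", index=False)


def read_pcr_tsv(path: str | Path) -> PcrTable:
    reference = None
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("# reference:"):
                reference = line.split(":", 1)[1].strip()
    header, rows = _read_table_lines(path)
    if header != ["sample", "gene", "ct"]:
        raise ParseError(f"{path}: expected columns sample/gene/ct, got {header}")
    recs = []
    for lineno, (sample, gene, ct) in ((ln, f) for ln, f in rows):
        try:
            recs.append((sample, gene, float(ct)))
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-numeric Ct {ct!r}") from exc
    tidy = pd.DataFrame(recs, columns=["sample", "gene", "ct"])
    ct = tidy.pivot(index="sample", columns="gene", values="ct")
    ct = ct[list(dict.fromkeys(tidy["gene"]))]  # preserve gene order on disk
    ct.columns.name = None
    kwargs = {"reference": reference} if reference else {}
    return PcrTable(ct=ct, **kwargs)


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick + "\n")


def write_summary_json(summary: Mapping, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serialisable: {type(o)}")

    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True, default=default) + "\n")


def validate_sample_consistency(
    counts: pd.DataFrame, metadata: pd.DataFrame, pcr: PcrTable | None = None
) -> None:
    """Pre-flight check that every table refers to the same sample ids."""
    problems = []
    missing_meta = [s for s in counts.columns if s not in metadata.index]
    if missing_meta:
        problems.append(f"samples in counts but not metadata: {missing_meta}")
    if pcr is not None:
        missing_pcr = [s for s in pcr.ct.index if s not in metadata.index]
        if missing_pcr:
            problems.append(f"samples in PCR table but not metadata: {missing_pcr}")
    if problems:
        raise ParseError("; ".join(problems))
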
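"""Small-RNA read annotation and counting.

Reads are size-selected (15-52 nt by default, the library's size-selection
window), then assigned to a small-RNA class and — for miRNAs — a mature miRNA
id by exact contiguous substring matching against a class-tagged reference.
Multi-class matches are resolved by a fixed priority
(miRNA > tRNA > rRNA > scRNA > snRNA > snoRNA > other) and ties within the
winning class by the lexicographically smallest entry id, with the read
flagged ambiguous; each read contributes a count of exactly one so count
matrices stay integral for the negative-binomial tests downstream.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synth import SMALL_RNA_CLASSES, ReadSet, SmallRNAReference

__all__ = [
    "ReadAssignment",
    "CompositionSummary",
    "size_select",
    "assign_read",
    "annotate_sample",
    "count_sample",
    "build_count_matrix",
]

_VALID_CHARS = frozenset("ACGTUN")


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    status: str  # "assigned" | "unassigned" | "size_excluded"
    rna_class: str | None = None
    entry_id: str | None = None
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.status not in ("assigned", "unassigned", "size_excluded"):
            raise ValueError(f"invalid status {self.status!r}")
        if self.status == "assigned" and (self.rna_class is None or self.entry_id is None):
            raise ValueError("assigned reads need a class and an entry id")
        if self.status != "assigned" and self.rna_class is not None:
            raise ValueError("only assigned reads carry a class")


@dataclass(frozen=True)
class CompositionSummary:
    """Per-class fractions of assigned reads plus bookkeeping totals."""

    fractions: Mapping[str, float]
    n_total: int
    n_assigned: int
    n_unassigned: int
    n_size_excluded: int

    def __post_init__(self) -> None:
        if self.n_total != self.n_assigned + self.n_unassigned + self.n_size_excluded:
            raise ValueError("read counts do not add up")
        if self.n_assigned > 0:
            s = sum(self.fractions.values())
            if abs(s - 1.0) > 1e-9:
                raise ValueError(f"assigned-read fractions must sum to 1, got {s}")


def size_select(reads: ReadSet, min_len: int = 15, max_len: int = 52) -> ReadSet:
    """Retain exactly the reads with min_len <= length <= max_len, in order."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    kept = [r for r in reads.reads if min_len <= len(r.sequence) <= max_len]
    prov = {r.read_id: reads.provenance[r.read_id] for r in kept} if reads.provenance else {}
    return ReadSet(kept, prov)


def _normalize(sequence: str) -> str:
    return sequence.upper().replace("U", "T")


def assign_read(
    sequence: str, ref: SmallRNAReference, read_id: str = ""
) -> ReadAssignment:
    """Assign one read by exact substring search against the reference.

    The read is assigned iff it occurs as an exact contiguous substring of at
    least one reference entry. The winning class is the highest-priority class
    with a match; within it the lexicographically smallest entry id wins and
    ``ambiguous`` records whether more than one entry of that class matched.
    Characters outside {A,C,G,T,U,N} make the read unassigned, never fatal.
    """
    if not sequence:
        raise ValueError("empty read sequence")
    seq = _normalize(sequence)
    if not set(seq) <= _VALID_CHARS:
        return ReadAssignment(read_id, "unassigned")
    for rna_class in SMALL_RNA_CLASSES:
        hits = [e.entry_id for e in ref.by_class(rna_class) if seq in e.sequence]
        if hits:
            return ReadAssignment(
                read_id,
                "assigned",
                rna_class=rna_class,
                entry_id=min(hits),
                ambiguous=len(hits) > 1,
            )
    return ReadAssignment(read_id, "unassigned")


def annotate_sample(
    reads: ReadSet,
    ref: SmallRNAReference,
    min_len: int = 15,
    max_len: int = 52,
) -> list[ReadAssignment]:
    """Size-select then assign every read of one sample.

    Reads outside the size window get status ``size_excluded``; the rest go
    through :func:`assign_read`.
    """
    out: list[ReadAssignment] = []
    for r in reads.reads:
        if not (min_len <= len(r.sequence) <= max_len):
            out.append(ReadAssignment(r.read_id, "size_excluded"))
        else:
            out.append(assign_read(r.sequence, ref, read_id=r.read_id))
    return out


def count_sample(
    assignments: Sequence[ReadAssignment],
) -> tuple[dict[str, int], CompositionSummary]:
    """Mature-miRNA counts and class composition for one sample.

    Composition fractions are computed over assigned reads only; with zero
    assigned reads the fractions are empty (flagged by ``n_assigned == 0``).
    """
    mirna_counts: Counter[str] = Counter()
    class_counts: Counter[str] = Counter()
    n_unassigned = n_size_excluded = 0
    for a in assignments:
        if a.status == "assigned":
            class_counts[a.rna_class] += 1
            if a.rna_class == "miRNA":
                mirna_counts[a.entry_id] += 1
        elif a.status == "unassigned":
            n_unassigned += 1
        else:
            n_size_excluded += 1
    n_assigned = sum(class_counts.values())
    fractions = (
        {c: class_counts[c] / n_assigned for c in class_counts} if n_assigned else {}
    )
    summary = CompositionSummary(
        fractions=fractions,
        n_total=len(assignments),
        n_assigned=n_assigned,
        n_unassigned=n_unassigned,
        n_size_excluded=n_size_excluded,
    )
    return dict(mirna_counts), summary


def build_count_matrix(
    per_sample_counts: Sequence[Mapping[str, int]],
    sample_ids: Sequence[str],
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Assemble per-sample miRNA counts into a genes x samples integer matrix.

    The gene universe is the union of observed ids (or an explicit ``genes``
    list); absent entries are zero-filled. Duplicate sample ids are an error.
    """
    if len(per_sample_counts) != len(sample_ids):
        raise ValueError("one count mapping per sample id required")
    if len(set(sample_ids)) != len(sample_ids):
        dupes = [s for s in sample_ids if list(sample_ids).count(s) > 1]
        raise ValueError(f"duplicate sample ids: {sorted(set(dupes))}")
    if genes is None:
        universe: set[str] = set()
        for c in per_sample_counts:
            universe.update(c)
        gene_list = sorted(universe)
    else:
        gene_list = list(genes)
    mat = np.zeros((len(gene_list), len(sample_ids)), dtype=np.int64)
    gene_pos = {g: i for i, g in enumerate(gene_list)}
    for j, counts in enumerate(per_sample_counts):
        for g, v in counts.items():
            if g in gene_pos:
                mat[gene_pos[g], j] = v
    return pd.DataFrame(mat, index=pd.Index(gene_list, name="gene"),
                        columns=pd.Index(list(sample_ids), name="sample"))
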
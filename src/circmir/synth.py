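"""Synthetic inputs for the circulating small-RNA workflow.

The study this package models profiled all circulating small RNAs in
pre-treatment sera of 42 stage II-III breast-cancer patients treated with
neoadjuvant chemotherapy (NCT), but deposited no raw data. This module
therefore generates every input the pipeline consumes, under controlled seeds:

* a class-tagged small-RNA reference (miRNA / tRNA / rRNA / scRNA / snRNA /
  snoRNA / other) standing in for miRBase plus genome annotation;
* reads drawn as exact substrings of reference entries, with the serum
  class mixture (~50% miRNA, ~28% tRNA, ~8.8% scRNA, ~4.4% rRNA, ~0.6% snRNA,
  ~0.4% snoRNA, remainder other);
* a miRNA x sample negative-binomial count matrix with planted group effects
  (by default miR-375 down and miR-122 up in relapsing patients, at the
  log2-fold magnitudes the sequencing cohort reported) plus matched clinical
  metadata;
* mock qPCR Ct tables linearly related to the normalised log2 counts.

Counts are NB with a single common dispersion (variance = mu + phi*mu^2), the
same family the differential tests assume, so parameter recovery is
well-posed. Library sizes are log-normal around ``mean_library_size`` to force
non-trivial normalisation, and baseline relative abundances are log-normal so
a few genes dominate, mimicking the wide dynamic range seen in serum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .valstats import PcrTable, PCR_REFERENCE_GENE

__all__ = [
    "SMALL_RNA_CLASSES",
    "DEFAULT_CLASS_MIXTURE",
    "DEFAULT_LENGTH_RANGES",
    "DEFAULT_N_PER_CLASS",
    "DEFAULT_PLANTED_EFFECTS",
    "RefEntry",
    "SmallRNAReference",
    "Read",
    "ReadSet",
    "SimulationConfig",
    "make_reference",
    "simulate_reads",
    "simulate_cohort",
    "simulate_pcr",
]

# priority order used downstream for multi-class matches
SMALL_RNA_CLASSES = ("miRNA", "tRNA", "rRNA", "scRNA", "snRNA", "snoRNA", "other")

# Serum small-RNA composition; the six annotated classes cover 92.2% of reads,
# the remaining 7.8% is lumped into "other".
DEFAULT_CLASS_MIXTURE: dict[str, float] = {
    "miRNA": 0.50,
    "tRNA": 0.28,
    "scRNA": 0.088,
    "rRNA": 0.044,
    "snRNA": 0.006,
    "snoRNA": 0.004,
    "other": 0.078,
}

DEFAULT_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "miRNA": (18, 25),
    "tRNA": (70, 90),
    "rRNA": (90, 150),
    "scRNA": (80, 130),
    "snRNA": (90, 150),
    "snoRNA": (60, 120),
    "other": (40, 80),
}

DEFAULT_N_PER_CLASS: dict[str, int] = {
    "miRNA": 60,
    "tRNA": 25,
    "rRNA": 12,
    "scRNA": 10,
    "snRNA": 8,
    "snoRNA": 8,
    "other": 12,
}

# Canonical mature sequences (DNA alphabet) of the three miRNAs the workflow
# names explicitly: the two outcome markers and the PCR reference gene.
CANONICAL_MIRNAS: dict[str, str] = {
    "hsa-miR-375": "TTTGTTCGTTCGGCTCGCGTGA",
    "hsa-miR-122": "TGGAGTGTGACAATGGTGTTTG",
    "hsa-miR-16": "TAGCAGCACGTAAATATTGGCG",
}

# Relapse-contrast effect magnitudes (log2) of the two markers; miR-16 is
# always left unplanted because it serves as the PCR normalisation reference.
DEFAULT_PLANTED_EFFECTS: dict[str, tuple[str, float]] = {
    "hsa-miR-375": ("relapse", -1.90),
    "hsa-miR-122": ("relapse", +1.35),
}

_DNA = np.array(list("ACGT"))


class RefEntry(NamedTuple):
    entry_id: str
    rna_class: str
    sequence: str


@dataclass
class SmallRNAReference:
    """Class-tagged small-RNA reference sequences."""

    entries: list[RefEntry]

    def __post_init__(self) -> None:
        ids = [e.entry_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("reference ids must be unique")
        seqs = [e.sequence for e in self.entries]
        if any(not s for s in seqs):
            raise ValueError("reference sequences must be non-empty")
        if len(set(seqs)) != len(seqs):
            raise ValueError("no two reference entries may share a sequence")
        for e in self.entries:
            if e.rna_class not in SMALL_RNA_CLASSES:
                raise ValueError(f"unknown small-RNA class {e.rna_class!r}")
            if e.rna_class == "miRNA" and not (18 <= len(e.sequence) <= 25):
                raise ValueError(f"miRNA entry {e.entry_id} must be 18-25 nt")

    def by_class(self, rna_class: str) -> list[RefEntry]:
        # cached: annotation scans this per read
        grouped = getattr(self, "_grouped", None)
        if grouped is None:
            grouped = {}
            for e in self.entries:
                grouped.setdefault(e.rna_class, []).append(e)
            object.__setattr__(self, "_grouped", grouped)
        return grouped.get(rna_class, [])

    def get(self, entry_id: str) -> RefEntry:
        for e in self.entries:
            if e.entry_id == entry_id:
                return e
        raise KeyError(entry_id)

    @property
    def ids(self) -> list[str]:
        return [e.entry_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


class Read(NamedTuple):
    read_id: str
    sequence: str


@dataclass
class ReadSet:
    """Simulated reads plus their true source entries (for truth-checking only)."""

    reads: list[Read]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for r in self.reads:
            if len(r.sequence) < 1:
                raise ValueError(f"read {r.read_id} has an empty sequence")
        missing = [r.read_id for r in self.reads if r.read_id not in self.provenance]
        if missing and self.provenance:
            raise ValueError(f"provenance missing for reads: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class SimulationConfig:
    """Conditions for one synthetic cohort.

    Defaults reproduce the study conditions: 42 samples, 11/42 relapsing, the
    serum class mixture, the relapse-contrast planted effects, a common NB
    dispersion of 0.2 and a mean library size of 500,000 miRNA-assigned reads.
    """

    n_samples: int = 42
    relapse_fraction: float = 11 / 42
    class_mixture: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURE)
    )
    planted_effects: Mapping[str, tuple[str, float] | Sequence[tuple[str, float]]] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_EFFECTS)
    )
    dispersion: float = 0.2
    mean_library_size: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        if not (0.0 < self.relapse_fraction < 1.0):
            raise ValueError("relapse_fraction must lie in (0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture fractions must sum to 1, got {total}")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_DNA, size=length))


def make_reference(
    n_per_class: Mapping[str, int] | None = None,
    length_ranges: Mapping[str, tuple[int, int]] | None = None,
    seed: int = 0,
) -> SmallRNAReference:
    """Generate a deterministic class-tagged mini-reference.

    The miRNA class always contains hsa-miR-375, hsa-miR-122 and hsa-miR-16
    (their canonical mature sequences) when at least three miRNA entries are
    requested. Sequences are pairwise distinct and no entry is a substring of
    another, so exact-substring annotation is unambiguous across classes.
    """
    n_per_class = dict(DEFAULT_N_PER_CLASS if n_per_class is None else n_per_class)
    ranges = dict(DEFAULT_LENGTH_RANGES)
    if length_ranges:
        ranges.update(length_ranges)
    for cls, (lo, hi) in ranges.items():
        if lo < 1 or lo > hi:
            raise ValueError(f"impossible length range {lo}-{hi} for class {cls!r}")
    if any(n < 0 for n in n_per_class.values()):
        raise ValueError("n_per_class values must be >= 0")

    rng = np.random.default_rng(seed)
    entries: list[RefEntry] = []
    seqs: list[str] = []

    def admissible(candidate: str) -> bool:
        return not any(candidate in s or s in candidate for s in seqs)

    n_mirna = n_per_class.get("miRNA", 0)
    for name, seq in list(CANONICAL_MIRNAS.items())[: min(3, n_mirna)]:
        entries.append(RefEntry(name, "miRNA", seq))
        seqs.append(seq)

    for cls in SMALL_RNA_CLASSES:
        n = n_per_class.get(cls, 0)
        lo, hi = ranges[cls]
        have = len([e for e in entries if e.rna_class == cls])
        for i in range(have, n):
            for _attempt in range(1000):
                seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
                if admissible(seq):
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError(f"could not draw a unique sequence for class {cls}")
            prefix = "hsa-miR-sim" if cls == "miRNA" else f"{cls}-sim"
            entries.append(RefEntry(f"{prefix}-{i:03d}", cls, seq))
            seqs.append(seq)
    return SmallRNAReference(entries)


def simulate_reads(
    ref: SmallRNAReference,
    mixture: Mapping[str, float] | None = None,
    n_reads: int = 10_000,
    len_range: tuple[int, int] = (15, 52),
    seed: int = 0,
) -> ReadSet:
    """Draw reads as exact contiguous substrings of reference entries.

    Classes are sampled multinomially with the given mixture; within a class
    the source entry is uniform. Read lengths are uniform over the admissible
    intersection of ``len_range`` with the entry length. No sequencing errors
    are introduced (annotation downstream is exact-match).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    mixture = dict(DEFAULT_CLASS_MIXTURE if mixture is None else mixture)
    total = sum(mixture.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"mixture fractions must sum to 1, got {total}")
    classes = [c for c, f in mixture.items() if f > 0]
    pools = {c: ref.by_class(c) for c in classes}
    empty = [c for c in classes if not pools[c]]
    if empty:
        raise ValueError(f"mixture names classes absent from the reference: {empty}")
    lo_req, hi_req = len_range
    if lo_req < 1 or lo_req > hi_req:
        raise ValueError(f"impossible read length range {len_range}")

    rng = np.random.default_rng(seed)
    probs = np.array([mixture[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    class_draw = rng.choice(len(classes), size=n_reads, p=probs)

    reads: list[Read] = []
    provenance: dict[str, str] = {}
    for i, ci in enumerate(class_draw):
        pool = pools[classes[ci]]
        entry = pool[int(rng.integers(len(pool)))]
        seq_len = len(entry.sequence)
        lo = min(lo_req, seq_len)
        hi = min(hi_req, seq_len)
        rl = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, seq_len - rl + 1))
        rid = f"read_{i + 1:07d}"
        reads.append(Read(rid, entry.sequence[start : start + rl]))
        provenance[rid] = entry.entry_id
    return ReadSet(reads, provenance)


_STATUS_COLS = ("er", "pr", "her2")


def _covariate_vector(metadata: pd.DataFrame, name: str) -> np.ndarray:
    """0/1 indicator for a planted-effect covariate."""
    if name == "relapse":
        return metadata["relapse"].to_numpy(dtype=float)
    if name == "inflammatory":
        return metadata["inflammatory"].to_numpy(dtype=float)
    if name == "pcr":
        return (metadata["pcr_status"] == "pCR").to_numpy(dtype=float)
    if name in _STATUS_COLS:
        return (metadata[name] == "+").to_numpy(dtype=float)
    raise ValueError(f"unknown covariate {name!r} in planted_effects")


def _exact_split(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """Boolean vector with exactly k True entries in random positions."""
    flags = np.zeros(n, dtype=bool)
    flags[rng.permutation(n)[:k]] = True
    return flags


def _cohort_metadata(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_samples
    samples = [f"S{i + 1:02d}" for i in range(n)]
    relapse = _exact_split(rng, n, round(n * cfg.relapse_fraction))
    # cohort composition proportions: HER2+ 23/42, ER+ 21/42, PR+ 14/42,
    # inflammatory 10/42; regimen C == trastuzumab arm == the HER2+ patients,
    # the rest split A:B = 7:12; pCR 12/23 among HER2+ and 2/19 among HER2-.
    her2 = _exact_split(rng, n, round(n * 23 / 42))
    er = _exact_split(rng, n, round(n * 21 / 42))
    pr = _exact_split(rng, n, round(n * 14 / 42))
    inflammatory = _exact_split(rng, n, round(n * 10 / 42))

    regimen = np.full(n, "C", dtype=object)
    neg_idx = np.flatnonzero(~her2)
    n_a = round(len(neg_idx) * 7 / 19)
    shuffled = rng.permutation(neg_idx)
    regimen[shuffled[:n_a]] = "A"
    regimen[shuffled[n_a:]] = "B"

    pcr_status = np.full(n, "non-pCR", dtype=object)
    pos_idx = np.flatnonzero(her2)
    pcr_pos = rng.permutation(pos_idx)[: round(len(pos_idx) * 12 / 23)]
    pcr_status[pcr_pos] = "pCR"
    neg_pcr = rng.permutation(neg_idx)[: round(len(neg_idx) * 2 / 19)]
    pcr_status[neg_pcr] = "pCR"

    return pd.DataFrame(
        {
            "cohort": "training",
            "er": np.where(er, "+", "-"),
            "pr": np.where(pr, "+", "-"),
            "her2": np.where(her2, "+", "-"),
            "inflammatory": inflammatory,
            "regimen": regimen,
            "pcr_status": pcr_status,
            "relapse": relapse,
        },
        index=pd.Index(samples, name="sample"),
    )


def simulate_cohort(
    cfg: SimulationConfig, ref: SmallRNAReference
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a miRNA x sample count matrix and matched clinical metadata.

    Counts for gene g in sample s are NB with mean
    ``library_size_s * a_g * 2^(sum of planted effects active in s)`` and
    common dispersion ``cfg.dispersion`` (variance mu + phi*mu^2), drawn via
    the gamma-Poisson mixture. ``a_g`` are log-normal baseline relative
    abundances normalised to sum to one; library sizes are log-normal
    (sigma=0.3) around ``cfg.mean_library_size``. Deterministic per seed.
    """
    genes = [e.entry_id for e in ref.by_class("miRNA")]
    if not genes:
        raise ValueError("reference contains no miRNA entries")
    effects: dict[str, list[tuple[str, float]]] = {}
    for gene, eff in cfg.planted_effects.items():
        if gene not in genes:
            raise ValueError(f"planted effect names unknown miRNA {gene!r}")
        pairs = [eff] if isinstance(eff[0], str) else list(eff)
        effects[gene] = [(str(c), float(v)) for c, v in pairs]

    rng = np.random.default_rng(cfg.seed)
    metadata = _cohort_metadata(cfg, rng)

    n_genes, n = len(genes), cfg.n_samples
    baseline = rng.lognormal(mean=0.0, sigma=1.5, size=n_genes)
    baseline /= baseline.sum()
    libsizes = rng.lognormal(mean=math.log(cfg.mean_library_size), sigma=0.3, size=n)

    log2_shift = np.zeros((n_genes, n))
    for gi, gene in enumerate(genes):
        for cov, size in effects.get(gene, []):
            log2_shift[gi] += size * _covariate_vector(metadata, cov)

    mu = baseline[:, None] * libsizes[None, :] * np.exp2(log2_shift)
    shape = 1.0 / cfg.dispersion
    lam = rng.gamma(shape=shape, scale=mu / shape)
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                             columns=metadata.index)
    return counts_df, metadata


def simulate_pcr(
    norm: pd.DataFrame,
    genes: Sequence[str],
    noise_sd: float = 0.5,
    seed: int = 0,
    intercept: float = 36.0,
    slope: float = 0.95,
) -> PcrTable:
    """Mock qPCR Ct values linearly related to normalised log2 counts.

    ``Ct = intercept - slope * log2_value + N(0, noise_sd)`` with slope > 0, so
    -Ct correlates with sequencing abundance, as observed when the two
    platforms were compared. ``genes`` must include the miR-16 reference gene
    and every gene must be a row of ``norm`` (genes x samples).
    """
    if slope <= 0:
        raise ValueError("slope must be positive")
    genes = list(genes)
    missing = [g for g in genes if g not in norm.index]
    if missing:
        raise ValueError(f"genes missing from the normalised matrix: {missing}")
    if PCR_REFERENCE_GENE not in genes:
        raise ValueError(f"gene list must include the reference {PCR_REFERENCE_GENE}")
    rng = np.random.default_rng(seed)
    log2_vals = norm.loc[genes].to_numpy(dtype=float).T  # samples x genes
    noise = rng.normal(0.0, noise_sd, size=log2_vals.shape) if noise_sd > 0 else 0.0
    ct = intercept - slope * log2_vals + noise
    table = pd.DataFrame(ct, index=norm.columns, columns=genes)
    table.index.name = "sample"
    return PcrTable(ct=table, reference=PCR_REFERENCE_GENE)
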
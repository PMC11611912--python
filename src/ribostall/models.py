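"""Core domain types shared across the pipeline.

Coordinates are 0-based half-open throughout the library; SAM I/O converts
to and from the 1-based inclusive convention at the boundary.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

# Standard genetic code; stops are translated to '*'.
_TABLE = CodonTable.unambiguous_dna_by_id[1]

CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in sorted(CODON_TO_AA):
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], ())
    AA_TO_CODONS[CODON_TO_AA[_codon]] += (_codon,)

SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in sorted(CODON_TO_AA) if CODON_TO_AA[c] != "*"
)
STOP_CODONS: tuple[str, ...] = tuple(_TABLE.stop_codons)

NUCLEOTIDES = "ACGT"


def translate(nt_seq: str) -> str:
    """Translate a CDS, keeping the terminal stop as '*'."""
    if len(nt_seq) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    return str(Seq(nt_seq).translate())


def revcomp(nt_seq: str) -> str:
    return str(Seq(nt_seq).reverse_complement())


@dataclass(frozen=True)
class GeneModel:
    """A CDS with its nucleotide and translated amino-acid sequence.

    ``aa_seq`` retains the terminal '*' so that codon indices line up with
    ``nt_seq`` codons one-to-one, including the stop codon.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_start: int
    cds_end: int
    nt_seq: str
    aa_seq: str = ""

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        if len(self.nt_seq) != self.cds_end - self.cds_start:
            raise ValueError("nt_seq length does not match CDS coordinates")
        if not self.aa_seq:
            object.__setattr__(self, "aa_seq", translate(self.nt_seq))
        if len(self.aa_seq) * 3 != len(self.nt_seq):
            raise ValueError("aa_seq length does not match nt_seq")

    @classmethod
    def from_cds(
        cls,
        gene_id: str,
        nt_seq: str,
        chrom: str | None = None,
        strand: str = "+",
        cds_start: int = 0,
    ) -> "GeneModel":
        return cls(
            gene_id=gene_id,
            chrom=chrom if chrom is not None else gene_id,
            strand=strand,
            cds_start=cds_start,
            cds_end=cds_start + len(nt_seq),
            nt_seq=nt_seq,
        )

    @property
    def n_codons(self) -> int:
        return len(self.aa_seq)

    def codon(self, index: int) -> str:
        return self.nt_seq[3 * index : 3 * index + 3]


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError("sequence and quality lengths differ")


@dataclass(frozen=True)
class Footprint:
    """A decomposed ribosome-protected fragment with its UMI and barcode."""

    id: str
    fragment: str
    umi: str
    barcode: str


class RejectReason(enum.Enum):
    NO_ADAPTER = "NO_ADAPTER"
    TOO_SHORT = "TOO_SHORT"
    MALFORMED = "MALFORMED"


@dataclass(frozen=True)
class AlignmentRecord:
    """A uniquely mapped fragment on a reference sequence.

    ``start``/``end`` are 0-based half-open on the reference; for a
    minus-strand alignment the read's 3' end is at ``start``.
    """

    read_id: str
    gene_id: str
    start: int
    end: int
    strand: str = "+"

    @property
    def fragment_length(self) -> int:
        return self.end - self.start

    @property
    def three_prime(self) -> int:
        """Reference position (inclusive) of the read's 3'-terminal base."""
        return self.end - 1 if self.strand == "+" else self.start


class OccupancyProfile:
    """Per-gene A-site density at nucleotide and codon resolution."""

    def __init__(self, gene_id: str, n_nt: int, nt_counts=None):
        if n_nt % 3 != 0:
            raise ValueError("profile length must be a whole number of codons")
        self.gene_id = gene_id
        if nt_counts is None:
            self.nt_counts = np.zeros(n_nt, dtype=np.int64)
        else:
            self.nt_counts = np.asarray(nt_counts, dtype=np.int64).copy()
            if self.nt_counts.shape != (n_nt,):
                raise ValueError("nt_counts length mismatch")

    @property
    def codon_counts(self) -> np.ndarray:
        return self.nt_counts.reshape(-1, 3).sum(axis=1)

    @property
    def n_codons(self) -> int:
        return len(self.nt_counts) // 3

    @property
    def total_reads(self) -> int:
        return int(self.nt_counts.sum())

    def add(self, nt_index: int) -> None:
        self.nt_counts[nt_index] += 1

    def copy(self) -> "OccupancyProfile":
        return OccupancyProfile(self.gene_id, len(self.nt_counts), self.nt_counts)

    def __repr__(self) -> str:  # pragma: no cover
        return f"OccupancyProfile({self.gene_id!r}, total={self.total_reads})"


@dataclass
class PauseParams:
    """Sliding-window pause-scoring parameters.

    Defaults follow the PausePred settings used for bacterial footprint
    libraries: two 1000-nt windows, a fold-change threshold of 20 and a
    minimum of 5% covered positions in the window.
    """

    w1: int = 1000
    w2: int = 1000
    min_score: float = 20.0
    min_cov: float = 0.05

    def __post_init__(self) -> None:
        if self.w1 < 3 or self.w2 < 3:
            raise ValueError("window lengths must be >= 3 nt")
        if self.min_score <= 1:
            raise ValueError("min_score must exceed 1")
        if not (0 < self.min_cov <= 1):
            raise ValueError("min_cov must lie in (0, 1]")


@dataclass(frozen=True)
class PauseSite:
    gene_id: str
    nt_position: int
    asite_codon: int
    score: float
    coverage: float


@dataclass(frozen=True)
class TrimerRecord:
    """E/P/A-site amino-acid trimer with pause and background frequencies."""

    trimer: str
    freq_pause: float
    freq_background: float
    enrichment: float
    flagged: bool = False  # nonzero pause frequency over zero background


@dataclass(frozen=True)
class AsymmetryResult:
    gene_id: str
    motif: str
    motif_codon_span: tuple[int, int]
    upstream_sum: int
    downstream_sum: int
    asymmetry_score: float
    flank: int


class DependencyLabel(enum.Enum):
    DEPENDENT = "DEPENDENT"
    INDEPENDENT = "INDEPENDENT"
    INDUCED = "INDUCED"


@dataclass(frozen=True)
class DependencyCall:
    gene_id: str
    motif: str
    as_wt: float
    as_mut: float
    label: DependencyLabel


@dataclass(frozen=True)
class LoopAnnotation:
    seq_id: str
    loop: str
    loop_len: int
    tip: str | None
    label: str  # EFP / EFPL / OTHER


@dataclass(frozen=True)
class LoopRegionSpec:
    ref_id: str
    ref_loop_seq: str
    # 1-based inclusive alignment column interval
    msa_columns: tuple[int, int]
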
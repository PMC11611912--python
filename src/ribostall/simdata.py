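"""Synthetic transcriptomes and footprint libraries with planted stalls.

The simulator emulates MNase footprint libraries: 20-40 nt fragments whose
3' end sits a fixed offset downstream of the ribosomal A site, a
multiplicative dwell-time model with one multiplier per A-site codon,
abortive drop-off expressed as a downstream density scale (1 - d), PCR
duplicates that copy fragment and UMI, and the raw-read layout

    QQQ - fragment - NNNNN(UMI) - BBBBB(barcode) - adapter

so that the downstream preprocessing can be exercised end to end against a
per-read truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .models import (
    AA_TO_CODONS,
    NUCLEOTIDES,
    SENSE_CODONS,
    STOP_CODONS,
    AlignmentRecord,
    GeneModel,
    RawRead,
)

DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCTGAA"


@dataclass(frozen=True)
class PlantedMotif:
    """A stall trimer planted at a specific A-site codon.

    The trimer occupies codons ``codon_index - 2 .. codon_index`` (E, P and
    A sites of the stalled ribosome).  ``stall_multiplier`` scales the dwell
    weight of the A-site codon; ``dropoff_prob`` scales all downstream
    codons by ``1 - dropoff_prob``.
    """

    gene_id: str
    codon_index: int
    trimer: str
    stall_multiplier: float = 1.0
    dropoff_prob: float = 0.0
    esite_first_nt: str | None = None

    def __post_init__(self) -> None:
        if len(self.trimer) != 3:
            raise ValueError("trimer must be three residues")
        if "*" in self.trimer:
            raise ValueError("trimer may not contain a stop symbol")
        if self.stall_multiplier < 1:
            raise ValueError("stall multiplier must be >= 1")
        if not (0 <= self.dropoff_prob <= 1):
            raise ValueError("dropoff_prob must lie in [0, 1]")
        if self.esite_first_nt is not None and self.esite_first_nt not in NUCLEOTIDES:
            raise ValueError("esite_first_nt must be one of A/C/G/T")


@dataclass
class SimConfig:
    """Simulation parameters.

    Defaults are the end-to-end study conditions: 20 genes of 300 codons,
    mean depth 50 reads per codon, fragment lengths uniform on 20-40 nt,
    a 20% PCR duplication rate, and the 11-nt 3'-end A-site offset.
    """

    n_genes: int = 20
    gene_len_codons: int = 300
    planted_motifs: list[PlantedMotif] = field(default_factory=list)
    depth: float = 50.0
    read_len_range: tuple[int, int] = (20, 40)
    dup_rate: float = 0.2
    asite_offset: int = 11
    barcode: str = "ACGTC"
    adapter: str = DEFAULT_ADAPTER
    ramp_codons: int = 0
    ramp_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.read_len_range = (int(self.read_len_range[0]), int(self.read_len_range[1]))
        if isinstance(self.planted_motifs, list):
            self.planted_motifs = [
                m if isinstance(m, PlantedMotif) else PlantedMotif(**m)
                for m in self.planted_motifs
            ]
        self.validate()

    def validate(self) -> None:
        min_len, max_len = self.read_len_range
        if min_len < self.asite_offset + 1:
            raise ValueError("minimum read length must be >= asite_offset + 1")
        if min_len > max_len:
            raise ValueError("read_len_range must be (min, max) with min <= max")
        if self.n_genes < 1 or self.gene_len_codons < 4:
            raise ValueError("need at least one gene of >= 4 codons")
        if 3 * self.gene_len_codons < max_len:
            raise ValueError("gene shorter than the maximum read length")
        if not (0 <= self.dup_rate < 1):
            raise ValueError("dup_rate must lie in [0, 1)")
        if len(self.barcode) != 5:
            raise ValueError("barcode must be 5 nt")
        if self.ramp_codons < 0 or self.ramp_factor <= 0:
            raise ValueError("invalid initiation ramp")
        for m in self.planted_motifs:
            if not (2 <= m.codon_index <= self.gene_len_codons - 2):
                raise ValueError(
                    f"planted codon_index {m.codon_index} outside [2, gene_len - 2]"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    gene_id: str
    asite_nt: int
    asite_codon: int
    umi: str
    fragment: str
    duplicate_of: str | None = None


@dataclass
class TruthTable:
    motifs: list[PlantedMotif]
    reads: list[ReadTruth]

    def asite_codon_histogram(self, gene: GeneModel) -> np.ndarray:
        hist = np.zeros(gene.n_codons, dtype=np.int64)
        for r in self.reads:
            if r.gene_id == gene.gene_id:
                hist[r.asite_codon] += 1
        return hist


def _choose_codon(rng: np.random.Generator, aa: str, first_nt: str | None = None) -> str:
    codons = AA_TO_CODONS.get(aa)
    if not codons:
        raise ValueError(f"unknown amino acid {aa!r}")
    if first_nt is not None:
        codons = tuple(c for c in codons if c[0] == first_nt)
        if not codons:
            raise ValueError(f"no codon for {aa!r} starting with {first_nt!r}")
    return codons[rng.integers(len(codons))]


def make_transcriptome(cfg: SimConfig) -> list[GeneModel]:
    """Generate random CDSs with every planted trimer at its requested span.

    Each gene starts with ATG, ends with a stop codon and contains no
    internal stops.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    by_gene: dict[str, list[PlantedMotif]] = {}
    for m in cfg.planted_motifs:
        by_gene.setdefault(m.gene_id, []).append(m)

    genes: list[GeneModel] = []
    n = cfg.gene_len_codons
    for g in range(cfg.n_genes):
        gene_id = f"g{g + 1}"
        codons = ["ATG"]
        codons += [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n - 2)]
        codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
        for m in by_gene.get(gene_id, []):
            span = range(m.codon_index - 2, m.codon_index + 1)
            if span[0] == 0 and m.trimer[0] != "M":
                raise ValueError("planted trimer would overwrite the start codon")
            for offset, aa in zip(span, m.trimer):
                first = m.esite_first_nt if offset == m.codon_index - 2 else None
                codons[offset] = _choose_codon(rng, aa, first)
        genes.append(GeneModel.from_cds(gene_id, "".join(codons)))
    unknown = set(by_gene) - {g.gene_id for g in genes}
    if unknown:
        raise ValueError(f"planted motifs reference unknown genes: {sorted(unknown)}")
    return genes


def dwell_weights(gene: GeneModel, cfg: SimConfig, rescue: bool = False) -> np.ndarray:
    """Per-codon dwell weights: baseline 1, stall multiplier at planted
    A-site codons, downstream codons scaled by (1 - d) past a drop-off
    motif.  ``rescue=True`` neutralizes planted stalls and drop-off,
    emulating a strain in which the rescue factor is active."""
    w = np.ones(gene.n_codons, dtype=float)
    if cfg.ramp_codons:
        w[: cfg.ramp_codons] *= cfg.ramp_factor
    if rescue:
        return w
    for m in cfg.planted_motifs:
        if m.gene_id != gene.gene_id:
            continue
        w[m.codon_index] *= m.stall_multiplier
        w[m.codon_index + 1 :] *= 1.0 - m.dropoff_prob
    return w


def _feasible_mask(gene: GeneModel, cfg: SimConfig) -> np.ndarray:
    """Codons whose footprint fits the gene: the 3' end (A-site nt +
    offset) must lie inside the gene and leave room for the minimum read
    length upstream."""
    min_len, _ = cfg.read_len_range
    n_nt = len(gene.nt_seq)
    codons = np.arange(gene.n_codons)
    end3 = 3 * codons + cfg.asite_offset  # A-site nt = first nt of the codon
    return (end3 <= n_nt - 1) & (end3 + 1 >= min_len)


def simulate_footprints(
    genes: list[GeneModel], cfg: SimConfig, rescue: bool = False
) -> tuple[list[RawRead], list[AlignmentRecord], TruthTable]:
    """Sample a footprint library from the dwell model.

    Returns raw reads (full layout, constant 'I' qualities), the matching
    error-free alignments, and a per-read truth table.  PCR duplicates copy
    fragment and UMI under a fresh read id.
    """
    if cfg.depth <= 0:
        raise ValueError("depth must be positive")
    min_len, max_len = cfg.read_len_range
    rng = np.random.default_rng(cfg.seed + 1)

    raw: list[RawRead] = []
    alignments: list[AlignmentRecord] = []
    truth_reads: list[ReadTruth] = []

    for gene in genes:
        n_nt = len(gene.nt_seq)
        w = dwell_weights(gene, cfg, rescue=rescue)
        mask = _feasible_mask(gene, cfg)
        w = np.where(mask, w, 0.0)
        total_w = w.sum()
        if total_w == 0:
            raise ValueError(f"no feasible footprint positions in {gene.gene_id}")
        n_reads = int(round(cfg.depth * int(mask.sum())))
        counts = rng.multinomial(n_reads, w / total_w)
        serial = 0
        for codon in np.nonzero(counts)[0]:
            asite_nt = 3 * int(codon)
            end3 = asite_nt + cfg.asite_offset
            hi = min(max_len, end3 + 1)
            for _ in range(int(counts[codon])):
                length = int(rng.integers(min_len, hi + 1))
                start = end3 + 1 - length
                fragment = gene.nt_seq[start : end3 + 1]
                umi = "".join(NUCLEOTIDES[i] for i in rng.integers(4, size=5))
                read_id = f"{gene.gene_id}|r{serial}"
                serial += 1
                copies = [(read_id, None)]
                if cfg.dup_rate and rng.random() < cfg.dup_rate:
                    dup_id = f"{gene.gene_id}|r{serial}"
                    serial += 1
                    copies.append((dup_id, read_id))
                for rid, dup_of in copies:
                    prefix = "".join(NUCLEOTIDES[i] for i in rng.integers(4, size=3))
                    seq = prefix + fragment + umi + cfg.barcode + cfg.adapter
                    raw.append(RawRead(rid, seq, "I" * len(seq)))
                    alignments.append(
                        AlignmentRecord(rid, gene.gene_id, start, end3 + 1, "+")
                    )
                    truth_reads.append(
                        ReadTruth(rid, gene.gene_id, asite_nt, int(codon), umi,
                                  fragment, dup_of)
                    )
    return raw, alignments, TruthTable(list(cfg.planted_motifs), truth_reads)


# ---------------------------------------------------------------------------
# text outputs

def write_truth_tsv(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#motif\tgene_id\tasite_codon\ttrimer\tstall_multiplier\tdropoff_prob\n")
        for m in truth.motifs:
            fh.write(
                f"#motif\t{m.gene_id}\t{m.codon_index}\t{m.trimer}"
                f"\t{m.stall_multiplier}\t{m.dropoff_prob}\n"
            )
        fh.write("read_id\tgene_id\tasite_nt\tasite_codon\tumi\tduplicate_of\n")
        for r in truth.reads:
            fh.write(
                f"{r.read_id}\t{r.gene_id}\t{r.asite_nt}\t{r.asite_codon}"
                f"\t{r.umi}\t{r.duplicate_of or '.'}\n"
            )


def simulate_to_dir(cfg: SimConfig, out_dir: str | Path, rescue: bool = False) -> dict:
    """Run the simulator and write FASTA / FASTQ / SAM / truth TSV."""
    from . import io as rio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genes = make_transcriptome(cfg)
    raw, alignments, truth = simulate_footprints(genes, cfg, rescue=rescue)
    rio.write_fasta(genes, out / "transcriptome.fa")
    rio.write_fastq(raw, out / "reads.fastq")
    rio.write_sam(alignments, genes, out / "alignments.sam")
    rio.write_gene_table(genes, out / "genes.tsv")
    write_truth_tsv(truth, out / "truth.tsv")
    return {
        "genes": len(genes),
        "reads": len(raw),
        "duplicates": sum(1 for r in truth.reads if r.duplicate_of is not None),
    }
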
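"""File-format boundaries: FASTA, FASTQ, SAM and the BED-like gene table.

FASTQ parsing goes through Biopython's fast four-line iterator; SAM I/O
goes through pysam (1-based POS per the SAM standard, converted to the
library's 0-based half-open coordinates at this boundary).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .models import AlignmentRecord, GeneModel, RawRead


# --- FASTA -----------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genes: Iterable[GeneModel], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(g.nt_seq), id=g.gene_id, description="") for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")


# --- FASTQ -----------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[RawRead]:
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield RawRead(title.split()[0], seq, qual)


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


# --- gene table ------------------------------------------------------------

_GENE_COLUMNS = ("gene_id", "chrom", "start", "end", "strand")


def write_gene_table(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_GENE_COLUMNS) + "\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.cds_start}\t{g.cds_end}\t{g.strand}\n")


def read_gene_table(path: str | Path, sequences: dict[str, str]) -> list[GeneModel]:
    """Load CDS models from a BED-like TSV plus reference sequences.

    ``sequences`` maps chrom names to nucleotide strings; minus-strand CDSs
    are reverse-complemented so that ``nt_seq`` reads 5'->3' in the coding
    direction.
    """
    from .models import revcomp

    genes: list[GeneModel] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: header.index(name) for name in _GENE_COLUMNS}
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom = parts[idx["chrom"]]
            start, end = int(parts[idx["start"]]), int(parts[idx["end"]])
            strand = parts[idx["strand"]]
            if chrom not in sequences:
                raise ValueError(f"chrom {chrom!r} absent from FASTA")
            nt = sequences[chrom][start:end]
            if strand == "-":
                nt = revcomp(nt)
            genes.append(
                GeneModel(
                    gene_id=parts[idx["gene_id"]],
                    chrom=chrom,
                    strand=strand,
                    cds_start=start,
                    cds_end=end,
                    nt_seq=nt,
                )
            )
    return genes


# --- SAM -------------------------------------------------------------------

def write_sam(
    alignments: Iterable[AlignmentRecord],
    genes: Iterable[GeneModel],
    path: str | Path,
) -> None:
    genes = list(genes)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": g.gene_id, "LN": len(g.nt_seq)} for g in genes],
    }
    seq_by_gene = {g.gene_id: g.nt_seq for g in genes}
    with pysam.AlignmentFile(str(path), "w", header=header) as sam:
        for aln in alignments:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = aln.read_id
            a.reference_name = aln.gene_id
            a.reference_start = aln.start  # pysam converts to 1-based POS on write
            a.mapping_quality = 255
            length = aln.end - aln.start
            a.cigarstring = f"{length}M"
            frag = seq_by_gene[aln.gene_id][aln.start : aln.end]
            a.flag = 0 if aln.strand == "+" else 16
            a.query_sequence = frag
            sam.write(a)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    records: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for a in sam:
            if a.is_unmapped:
                continue
            records.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    gene_id=a.reference_name,
                    start=a.reference_start,
                    end=a.reference_end,
                    strand="-" if a.is_reverse else "+",
                )
            )
    return records
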
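"""Contaminant filtering, unique mapping, A-site assignment and profiles.

Mapping is exact-substring and unique-hit: a fragment retained only if it
occurs exactly once across both strands of the transcriptome, a stand-in
for single-hit short-read alignment of error-free reads.  The A site is
placed a fixed offset (default 11 nt) upstream of the footprint's 3' end,
measured along the read's own 5'->3' direction.
"""

from __future__ import annotations

import bisect
import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .models import AlignmentRecord, Footprint, GeneModel, OccupancyProfile, revcomp


class MappingResult(enum.Enum):
    UNMAPPED = "UNMAPPED"
    MULTIMAPPED = "MULTIMAPPED"


class OutOfCds(enum.Enum):
    OUT_OF_CDS = "OUT_OF_CDS"


OUT_OF_CDS = OutOfCds.OUT_OF_CDS


# --- contaminant filtering --------------------------------------------------

def filter_contaminants(
    footprints: Iterable[Footprint], contaminant_seqs: Iterable[str]
) -> tuple[list[Footprint], int]:
    """Drop fragments that occur exactly in any contaminant, either strand.

    Returns (retained footprints, number removed).
    """
    seqs = [s.upper() for s in contaminant_seqs]
    haystack = "#".join(seqs + [revcomp(s) for s in seqs])
    retained: list[Footprint] = []
    removed = 0
    if not haystack:
        return list(footprints), 0
    for fp in footprints:
        if fp.fragment in haystack:
            removed += 1
        else:
            retained.append(fp)
    return retained, removed


# --- unique exact-match mapping ---------------------------------------------

class TranscriptomeIndex:
    """Exact-substring search over a set of CDS sequences, both strands."""

    def __init__(self, genes: Sequence[GeneModel]):
        self.genes = list(genes)
        self._offsets: list[int] = []
        parts: list[str] = []
        pos = 0
        for g in self.genes:
            self._offsets.append(pos)
            parts.append(g.nt_seq)
            pos += len(g.nt_seq) + 1
        # '#' separators prevent matches spanning gene boundaries
        self._text = "#".join(parts)
        self._cache: dict[str, AlignmentRecord | MappingResult] = {}

    def _occurrences(self, query: str, limit: int) -> list[int]:
        hits: list[int] = []
        start = 0
        while len(hits) < limit:
            pos = self._text.find(query, start)
            if pos == -1:
                break
            hits.append(pos)
            start = pos + 1
        return hits

    def _locate(self, text_pos: int, length: int) -> tuple[str, int, int]:
        i = bisect.bisect_right(self._offsets, text_pos) - 1
        gene = self.genes[i]
        start = text_pos - self._offsets[i]
        return gene.gene_id, start, start + length

    def map_unique(self, fragment: str) -> AlignmentRecord | MappingResult:
        cached = self._cache.get(fragment)
        if cached is not None:
            return cached
        fwd = self._occurrences(fragment, 2)
        rc = revcomp(fragment)
        rev = self._occurrences(rc, 2)
        loci: list[tuple[str, int, int, str]] = []
        for pos in fwd:
            loci.append((*self._locate(pos, len(fragment)), "+"))
        for pos in rev:
            loci.append((*self._locate(pos, len(fragment)), "-"))
        # a self-reverse-complementary fragment hits the same locus twice
        unique_loci = {(g, s, e) for g, s, e, _ in loci}
        if len(unique_loci) == 0:
            result: AlignmentRecord | MappingResult = MappingResult.UNMAPPED
        elif len(unique_loci) > 1:
            result = MappingResult.MULTIMAPPED
        else:
            g, s, e, strand = loci[0]
            result = AlignmentRecord("", g, s, e, strand)
        self._cache[fragment] = result
        return result


def map_unique(
    fragment: str, index: TranscriptomeIndex
) -> AlignmentRecord | MappingResult:
    return index.map_unique(fragment)


# --- A-site assignment ------------------------------------------------------

def assign_asite(
    aln: AlignmentRecord, gene: GeneModel, offset: int = 11
) -> int | OutOfCds:
    """Codon index of the A site, or OUT_OF_CDS.

    The A-site nucleotide lies ``offset`` nt upstream of the 3'-terminal
    base in the read's 5'->3' orientation; on the minus strand upstream
    runs toward larger reference coordinates.
    """
    if offset >= aln.fragment_length:
        raise ValueError("offset must be smaller than the fragment length")
    if aln.strand == "+":
        asite_nt = aln.three_prime - offset
        if not (gene.cds_start <= asite_nt < gene.cds_end):
            return OUT_OF_CDS
        return (asite_nt - gene.cds_start) // 3
    asite_nt = aln.three_prime + offset
    if not (gene.cds_start <= asite_nt < gene.cds_end):
        return OUT_OF_CDS
    return (gene.cds_end - 1 - asite_nt) // 3


def asite_nt_in_cds(aln: AlignmentRecord, gene: GeneModel, offset: int = 11) -> int | OutOfCds:
    """A-site position in coding-strand CDS coordinates (0-based nt)."""
    if offset >= aln.fragment_length:
        raise ValueError("offset must be smaller than the fragment length")
    if aln.strand == "+":
        asite_nt = aln.three_prime - offset
        if not (gene.cds_start <= asite_nt < gene.cds_end):
            return OUT_OF_CDS
        return asite_nt - gene.cds_start
    asite_nt = aln.three_prime + offset
    if not (gene.cds_start <= asite_nt < gene.cds_end):
        return OUT_OF_CDS
    return gene.cds_end - 1 - asite_nt


# --- profiles ---------------------------------------------------------------

@dataclass
class FilterLog:
    """Read-count bookkeeping through the filtering stages."""

    input: int = 0
    contaminant: int = 0
    duplicates: int = 0
    unmapped: int = 0
    multimapped: int = 0
    out_of_cds: int = 0
    retained: int = 0

    def balances(self) -> bool:
        return self.retained == (
            self.input
            - self.contaminant
            - self.duplicates
            - self.unmapped
            - self.multimapped
            - self.out_of_cds
        )


def build_profiles(
    alignments: Iterable[AlignmentRecord],
    genes: Sequence[GeneModel],
    offset: int = 11,
    log: FilterLog | None = None,
) -> dict[str, OccupancyProfile]:
    """Accumulate A-site counts per gene; OUT_OF_CDS reads are logged."""
    by_id = {g.gene_id: g for g in genes}
    profiles = {
        g.gene_id: OccupancyProfile(g.gene_id, len(g.nt_seq)) for g in genes
    }
    for aln in alignments:
        gene = by_id[aln.gene_id]
        nt = asite_nt_in_cds(aln, gene, offset)
        if nt is OUT_OF_CDS:
            if log is not None:
                log.out_of_cds += 1
            continue
        profiles[gene.gene_id].add(nt)
        if log is not None:
            log.retained += 1
    return profiles


def aggregate_replicates(
    profile_sets: Sequence[dict[str, OccupancyProfile]]
) -> dict[str, OccupancyProfile]:
    """Element-wise sum of replicate profiles over a shared gene universe."""
    if not profile_sets:
        raise ValueError("no replicates given")
    universe = set(profile_sets[0])
    for ps in profile_sets[1:]:
        if set(ps) != universe:
            raise ValueError("replicates cover different gene sets")
    out: dict[str, OccupancyProfile] = {}
    for gene_id in profile_sets[0]:
        total = profile_sets[0][gene_id].copy()
        for ps in profile_sets[1:]:
            if len(ps[gene_id].nt_counts) != len(total.nt_counts):
                raise ValueError(f"profile length mismatch for {gene_id}")
            total.nt_counts += ps[gene_id].nt_counts
        out[gene_id] = total
    return out


# --- metagene ---------------------------------------------------------------

def metagene(
    profiles: dict[str, OccupancyProfile],
    anchor: str = "START",
    window: int = 50,
    min_gene_reads: int = 1,
) -> np.ndarray:
    """Mean normalized codon occupancy aligned at the start or stop codon.

    Each qualifying gene's codon counts are scaled to mean 1 over the gene
    before averaging, so the curve reads as relative occupancy.
    """
    if anchor not in ("START", "STOP"):
        raise ValueError("anchor must be START or STOP")
    rows = []
    for profile in profiles.values():
        if profile.total_reads < min_gene_reads:
            continue
        counts = profile.codon_counts.astype(float)
        if len(counts) < window:
            raise ValueError("window exceeds gene length")
        counts = counts / counts.mean()
        rows.append(counts[:window] if anchor == "START" else counts[-window:])
    if not rows:
        raise ValueError("no genes pass min_gene_reads")
    return np.mean(rows, axis=0)
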
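"""End-to-end orchestration: FASTQ -> footprints -> profiles -> pauses ->
motif statistics -> dependency calls.

`run_stall_study` simulates a matched pair of libraries from one
transcriptome — a wild type in which the rescue factor is active (planted
stall multipliers neutralized) and a deletion mutant in which planted
stalls and drop-off act — and carries both through the full analysis, the
way a factor-dependency Ribo-seq experiment is evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import io as rio
from .models import (
    AsymmetryResult,
    DependencyCall,
    GeneModel,
    OccupancyProfile,
    PauseParams,
    PauseSite,
    TrimerRecord,
)
from .motifstats import asymmetry_score, dependency_call, trimer_enrichment
from .occupancy import (
    FilterLog,
    MappingResult,
    TranscriptomeIndex,
    build_profiles,
    filter_contaminants,
)
from .pausecall import call_pauses
from .readproc import dedup_umi, process_reads
from .simdata import PlantedMotif, SimConfig, make_transcriptome, simulate_footprints


@dataclass
class LibraryResult:
    profiles: dict[str, OccupancyProfile]
    log: FilterLog
    n_raw_reads: int = 0
    rejects: dict = field(default_factory=dict)
    pause_sites: list[PauseSite] = field(default_factory=list)


def analyze_library(
    fastq_path: str | Path,
    genes: Sequence[GeneModel],
    adapter: str,
    offset: int = 11,
    contaminants: Sequence[str] = (),
    min_len_after_trim: int = 30,
    index: TranscriptomeIndex | None = None,
) -> LibraryResult:
    """Raw FASTQ to occupancy profiles with full read bookkeeping.

    ``log.input`` counts decomposed footprints; raw reads rejected at
    decomposition are tallied separately in ``rejects``.
    """
    reads = list(rio.read_fastq(fastq_path))
    footprints, rejects = process_reads(
        reads, adapter=adapter, min_len_after_trim=min_len_after_trim
    )
    log = FilterLog(input=len(footprints))
    footprints, removed = filter_contaminants(footprints, contaminants)
    log.contaminant = removed
    deduped = dedup_umi(footprints)
    log.duplicates = len(footprints) - len(deduped)
    index = index or TranscriptomeIndex(genes)
    alignments = []
    for fp in deduped:
        result = index.map_unique(fp.fragment)
        if result is MappingResult.UNMAPPED:
            log.unmapped += 1
        elif result is MappingResult.MULTIMAPPED:
            log.multimapped += 1
        else:
            alignments.append(
                type(result)(fp.id, result.gene_id, result.start, result.end, result.strand)
            )
    profiles = build_profiles(alignments, genes, offset=offset, log=log)
    return LibraryResult(
        profiles=profiles, log=log, n_raw_reads=len(reads), rejects=dict(rejects)
    )


def reference_study_config(seed: int = 7) -> tuple[SimConfig, dict[str, tuple[int, int]]]:
    """The package's reference end-to-end validation scenario.

    Twenty genes of 300 codons at depth 50 with 20% PCR duplication.
    Fifteen genes carry one planted stall (multiplier 50, drop-off 0.3):
    twelve DPN motifs (Asp in the E site, whose codons all start with G)
    and three PPN motifs (Pro, C-starting), so the expected guanosine
    fraction at the first E-site codon position is 0.8.  Five genes are
    motif-free controls, evaluated at a mid-gene span.

    Returns the simulation config and the control spans.
    """
    motifs = []
    for i in range(15):
        trimer = "DPN" if i < 12 else "PPN"
        motifs.append(
            PlantedMotif(f"g{i + 1}", 60 + 12 * i, trimer, 50.0, dropoff_prob=0.3)
        )
    cfg = SimConfig(
        n_genes=20,
        gene_len_codons=300,
        planted_motifs=motifs,
        depth=50.0,
        dup_rate=0.2,
        seed=seed,
    )
    control_spans = {f"g{i}": (148, 151) for i in range(16, 21)}
    return cfg, control_spans


@dataclass
class StallStudyResult:
    genes: list[GeneModel]
    wt: LibraryResult
    mut: LibraryResult
    pause_sites: list[PauseSite]
    trimers: list[TrimerRecord]
    asymmetry_wt: dict[str, AsymmetryResult]
    asymmetry_mut: dict[str, AsymmetryResult]
    dependency: dict[str, DependencyCall]


def run_stall_study(
    cfg: SimConfig,
    workdir: str | Path,
    pause_params: PauseParams | None = None,
    flank: int = 25,
    pseudocount: float = 0.5,
    theta: float = 2.0,
    control_spans: dict[str, tuple[int, int]] | None = None,
) -> StallStudyResult:
    """Simulate WT and mutant libraries and run the full analysis.

    Asymmetry and dependency are evaluated at every planted motif span and
    at the supplied ``control_spans`` (gene -> codon span) for motif-free
    genes.
    """
    pause_params = pause_params or PauseParams()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    genes = make_transcriptome(cfg)
    index = TranscriptomeIndex(genes)

    results: dict[str, LibraryResult] = {}
    for name, rescue in (("wt", True), ("mut", False)):
        raw, _, _ = simulate_footprints(genes, cfg, rescue=rescue)
        fastq = workdir / f"{name}.fastq"
        rio.write_fastq(raw, fastq)
        results[name] = analyze_library(
            fastq, genes, adapter=cfg.adapter, offset=cfg.asite_offset, index=index
        )

    pause_sites = call_pauses(results["mut"].profiles, pause_params)
    trimers = trimer_enrichment(pause_sites, results["mut"].profiles, genes)

    spans: dict[str, tuple[int, int, str]] = {}
    for m in cfg.planted_motifs:
        spans[m.gene_id] = (m.codon_index - 2, m.codon_index + 1, m.trimer)
    for gene_id, (start, end) in (control_spans or {}).items():
        spans.setdefault(gene_id, (start, end, ""))

    asym_wt: dict[str, AsymmetryResult] = {}
    asym_mut: dict[str, AsymmetryResult] = {}
    calls: dict[str, DependencyCall] = {}
    for gene_id, (start, end, motif) in spans.items():
        asym_wt[gene_id] = asymmetry_score(
            results["wt"].profiles[gene_id], (start, end), flank, pseudocount, motif
        )
        asym_mut[gene_id] = asymmetry_score(
            results["mut"].profiles[gene_id], (start, end), flank, pseudocount, motif
        )
        calls[gene_id] = dependency_call(
            asym_wt[gene_id].asymmetry_score,
            asym_mut[gene_id].asymmetry_score,
            theta,
            gene_id=gene_id,
            motif=motif,
        )

    return StallStudyResult(
        genes=genes,
        wt=results["wt"],
        mut=results["mut"],
        pause_sites=pause_sites,
        trimers=trimers,
        asymmetry_wt=asym_wt,
        asymmetry_mut=asym_mut,
        dependency=calls,
    )
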
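"""Stall-motif statistics: E/P/A trimer enrichment at pause sites, E-site
codon nucleotide bias, occupancy asymmetry around motifs, and rescue-factor
dependency calls from wild-type vs mutant asymmetry scores.
"""

from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Sequence

import numpy as np

from .models import (
    NUCLEOTIDES,
    AsymmetryResult,
    DependencyCall,
    DependencyLabel,
    GeneModel,
    OccupancyProfile,
    PauseSite,
    TrimerRecord,
)


def ribosome_trimer(gene: GeneModel, asite_codon: int) -> str | None:
    """E-, P- and A-site residues of a ribosome paused at ``asite_codon``.

    None when the trimer would reach past the start codon or contain a
    stop symbol.
    """
    if asite_codon < 2 or asite_codon >= gene.n_codons:
        return None
    trimer = gene.aa_seq[asite_codon - 2 : asite_codon + 1]
    if "*" in trimer:
        return None
    return trimer


def trimer_enrichment(
    pause_sites: Sequence[PauseSite],
    profiles: dict[str, OccupancyProfile],
    genes: Sequence[GeneModel],
) -> list[TrimerRecord]:
    """Trimer frequencies at pause sites over an occupancy-weighted background.

    The pause frequency counts each reported site once; the background
    frequency weights every codon position by its A-site read count, i.e.
    by how often ribosomes actually covered it.  Records are sorted by
    enrichment, descending; a trimer observed at pause sites but absent
    from the background is flagged (infinite enrichment).
    """
    by_id = {g.gene_id: g for g in genes}
    pause_counts: Counter = Counter()
    for site in pause_sites:
        trimer = ribosome_trimer(by_id[site.gene_id], site.asite_codon)
        if trimer is not None:
            pause_counts[trimer] += 1
    n_pause = sum(pause_counts.values())
    if n_pause == 0:
        raise ValueError("no pause site has a defined trimer")

    bg_weights: Counter = Counter()
    for gene_id, profile in profiles.items():
        gene = by_id[gene_id]
        counts = profile.codon_counts
        for codon in np.nonzero(counts)[0]:
            trimer = ribosome_trimer(gene, int(codon))
            if trimer is not None:
                bg_weights[trimer] += int(counts[codon])
    total_bg = sum(bg_weights.values())
    if total_bg == 0:
        raise ValueError("background occupancy is empty")

    records = []
    for trimer in sorted(set(pause_counts) | set(bg_weights)):
        fp = pause_counts.get(trimer, 0) / n_pause
        fb = bg_weights.get(trimer, 0) / total_bg
        if fb > 0:
            rho, flagged = fp / fb, False
        else:
            rho, flagged = math.inf, fp > 0
        records.append(TrimerRecord(trimer, fp, fb, rho, flagged))
    records.sort(key=lambda r: (-r.enrichment, r.trimer))
    return records


def esite_first_nt_bias(
    pause_sites: Sequence[PauseSite], genes: Sequence[GeneModel]
) -> tuple[np.ndarray, float]:
    """Per-position nucleotide frequencies of the E-site codon at pause sites.

    Returns a 3x4 matrix (codon position x A/C/G/T, rows summing to 1) and
    the guanosine fraction at the first codon position.
    """
    by_id = {g.gene_id: g for g in genes}
    matrix = np.zeros((3, 4), dtype=float)
    n = 0
    for site in pause_sites:
        gene = by_id[site.gene_id]
        c = site.asite_codon
        if c < 2:
            continue
        codon = gene.codon(c - 2)
        for pos, nt in enumerate(codon):
            matrix[pos, NUCLEOTIDES.index(nt)] += 1
        n += 1
    if n == 0:
        raise ValueError("no pause site with asite_codon >= 2")
    matrix /= n
    g_fraction = float(matrix[0, NUCLEOTIDES.index("G")])
    return matrix, g_fraction


def asymmetry_score(
    profile: OccupancyProfile,
    motif_codon_span: tuple[int, int],
    flank: int = 25,
    pseudocount: float = 0.5,
    motif: str = "",
    min_flank: int = 5,
) -> AsymmetryResult:
    """Downstream/upstream occupancy ratio around a motif span.

    AS = (downstream flank sum + a) / (upstream flank sum + a) over
    ``flank`` codons on each side, the motif span itself excluded; flanks
    are clipped at the CDS ends but must keep at least ``min_flank``
    codons each.  AS < 1 indicates accumulation upstream, i.e. stalling.
    """
    start, end = motif_codon_span
    counts = profile.codon_counts
    n = len(counts)
    if not (0 <= start < end <= n):
        raise ValueError("motif span outside the CDS")
    up_lo = max(0, start - flank)
    down_hi = min(n, end + flank)
    if start - up_lo < min_flank or down_hi - end < min_flank:
        raise ValueError("flanks too short after clipping")
    upstream = int(counts[up_lo:start].sum())
    downstream = int(counts[end:down_hi].sum())
    score = (downstream + pseudocount) / (upstream + pseudocount)
    if upstream + downstream == 0 and pseudocount == 0:
        raise ValueError("both flanks empty and no pseudocount")
    return AsymmetryResult(
        gene_id=profile.gene_id,
        motif=motif,
        motif_codon_span=(start, end),
        upstream_sum=upstream,
        downstream_sum=downstream,
        asymmetry_score=score,
        flank=flank,
    )


def dependency_call(
    as_wt: float,
    as_mut: float,
    theta: float = 2.0,
    gene_id: str = "",
    motif: str = "",
) -> DependencyCall:
    """Classify a motif by comparing mutant vs wild-type asymmetry.

    DEPENDENT: the stall appears when the factor is absent
    (AS_mut <= AS_wt / theta).  INDUCED: the pause is relieved when the
    factor is absent (AS_mut >= AS_wt * theta).  Otherwise INDEPENDENT.
    """
    if theta <= 1:
        raise ValueError("theta must exceed 1")
    if as_wt <= 0 or as_mut <= 0:
        raise ValueError("asymmetry scores must be positive")
    if as_mut <= as_wt / theta:
        label = DependencyLabel.DEPENDENT
    elif as_mut >= as_wt * theta:
        label = DependencyLabel.INDUCED
    else:
        label = DependencyLabel.INDEPENDENT
    return DependencyCall(gene_id, motif, as_wt, as_mut, label)


# --- tabular exports --------------------------------------------------------

def trimer_table(records: Iterable[TrimerRecord]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "trimer": r.trimer,
                "freq_pause": r.freq_pause,
                "freq_background": r.freq_background,
                "enrichment": r.enrichment,
                "flagged": r.flagged,
            }
            for r in records
        ]
    )


def asymmetry_table(results: Iterable[AsymmetryResult]):
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "gene_id": r.gene_id,
                "motif": r.motif,
                "span_start": r.motif_codon_span[0],
                "span_end": r.motif_codon_span[1],
                "upstream_sum": r.upstream_sum,
                "downstream_sum": r.downstream_sum,
                "asymmetry_score": r.asymmetry_score,
                "log2_asymmetry_score": math.log2(r.asymmetry_score),
            }
        )
    return pd.DataFrame(rows)


def dependency_table(calls: Iterable[DependencyCall]):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "motif": c.motif,
                "as_wt": c.as_wt,
                "as_mut": c.as_mut,
                "label": c.label.value,
            }
            for c in calls
        ]
    )
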
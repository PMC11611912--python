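"""KOW-domain beta3-omega-beta4 loop extraction and EF-P/EfpL classification.

The loop between beta strands 3 and 4 of the KOW domain contacts the CCA
end of the P-site tRNA.  Canonical EF-P carries a seven-residue loop with
a functionalized lysine (or arginine) at its tip; EfpL-type paralogs carry
an extended loop of more than seven residues with an unmodified arginine
at the tip.  Classification is a pure function of the loop extracted from
a user-supplied multiple sequence alignment.
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment

from .models import LoopAnnotation, LoopRegionSpec

GAP_CHARS = set("-.")

EFP_LABEL = "EFP"
EFPL_LABEL = "EFPL"
OTHER_LABEL = "OTHER"

# Maximum loop length of a canonical EF-P; anything longer with an R tip
# is EfpL-type.
CANONICAL_LOOP_MAX = 7


def read_msa(path: str | Path, fmt: str | None = None) -> dict[str, str]:
    """Load an aligned FASTA or Stockholm file as id -> aligned row."""
    path = Path(path)
    if fmt is None:
        fmt = "stockholm" if path.suffix.lower() in (".sto", ".stk", ".stockholm") else "fasta"
    alignment = AlignIO.read(str(path), fmt)
    return msa_to_dict(alignment)


def msa_to_dict(alignment: MultipleSeqAlignment | dict[str, str]) -> dict[str, str]:
    if isinstance(alignment, dict):
        return {k: str(v).upper() for k, v in alignment.items()}
    return {rec.id: str(rec.seq).upper() for rec in alignment}


def _ungapped_with_columns(row: str) -> tuple[str, list[int]]:
    """(residue string, 1-based alignment column per residue)."""
    residues: list[str] = []
    columns: list[int] = []
    for col, ch in enumerate(row, start=1):
        if ch not in GAP_CHARS:
            residues.append(ch)
            columns.append(col)
    return "".join(residues), columns


def locate_loop_columns(
    msa: dict[str, str] | MultipleSeqAlignment, ref_id: str, ref_loop_seq: str
) -> LoopRegionSpec:
    """Minimal alignment-column interval spelling the reference loop.

    The loop sequence must occur exactly once in the ungapped reference
    row; the returned columns are 1-based inclusive.
    """
    rows = msa_to_dict(msa)
    if ref_id not in rows:
        raise KeyError(f"reference {ref_id!r} absent from alignment")
    ref_loop_seq = ref_loop_seq.upper()
    residues, columns = _ungapped_with_columns(rows[ref_id])
    first = residues.find(ref_loop_seq)
    if first == -1:
        raise ValueError(f"loop {ref_loop_seq!r} not found in reference row")
    if residues.find(ref_loop_seq, first + 1) != -1:
        raise ValueError(f"loop {ref_loop_seq!r} occurs more than once in reference row")
    start_col = columns[first]
    end_col = columns[first + len(ref_loop_seq) - 1]
    return LoopRegionSpec(ref_id, ref_loop_seq, (start_col, end_col))


def extract_loop(
    msa: dict[str, str] | MultipleSeqAlignment, spec: LoopRegionSpec, seq_id: str
) -> str:
    """Non-gap residues of one row within the loop column interval."""
    rows = msa_to_dict(msa)
    if seq_id not in rows:
        raise KeyError(f"{seq_id!r} absent from alignment")
    lo, hi = spec.msa_columns
    region = rows[seq_id][lo - 1 : hi]
    return "".join(ch for ch in region if ch not in GAP_CHARS)


def tip_residue(loop: str) -> str | None:
    """The apical residue, operationalized as the middle position
    ceil(L/2) (1-based); None for an empty loop."""
    if not loop:
        return None
    return loop[math.ceil(len(loop) / 2) - 1]


def classify_loop(loop: str) -> str:
    """EFPL iff the loop exceeds seven residues with an R tip; EFP for a
    canonical loop of one to seven residues; OTHER otherwise."""
    n = len(loop)
    if n > CANONICAL_LOOP_MAX:
        return EFPL_LABEL if tip_residue(loop) == "R" else OTHER_LABEL
    if 1 <= n <= CANONICAL_LOOP_MAX:
        return EFP_LABEL
    return OTHER_LABEL


def annotate_loop(seq_id: str, loop: str) -> LoopAnnotation:
    return LoopAnnotation(
        seq_id=seq_id,
        loop=loop,
        loop_len=len(loop),
        tip=tip_residue(loop),
        label=classify_loop(loop),
    )


def classify_msa(
    msa: dict[str, str] | MultipleSeqAlignment, ref_id: str, ref_loop_seq: str
) -> list[LoopAnnotation]:
    rows = msa_to_dict(msa)
    spec = locate_loop_columns(rows, ref_id, ref_loop_seq)
    return [annotate_loop(seq_id, extract_loop(rows, spec, seq_id)) for seq_id in rows]


def position_frequency_matrix(loops: list[str]) -> np.ndarray:
    """Residue frequencies per loop position for equal-length loops (a
    plain-matrix stand-in for a sequence logo)."""
    lengths = {len(l) for l in loops}
    if len(lengths) != 1:
        raise ValueError("loops must share one length")
    (length,) = lengths
    alphabet = sorted({ch for l in loops for ch in l})
    matrix = np.zeros((length, len(alphabet)))
    for loop in loops:
        for pos, ch in enumerate(loop):
            matrix[pos, alphabet.index(ch)] += 1
    return matrix / len(loops)


def write_loop_tsv(annotations: list[LoopAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tloop\tloop_len\ttip\tlabel\n")
        for a in annotations:
            fh.write(f"{a.seq_id}\t{a.loop}\t{a.loop_len}\t{a.tip or '.'}\t{a.label}\n")
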
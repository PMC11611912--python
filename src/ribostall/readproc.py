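"""Raw-read decomposition and UMI deduplication.

Raw footprint reads follow the layout

    QQQ - fragment - NNNNN(UMI) - BBBBB(barcode) - adapter

The first three untemplated bases are dropped, the adapter located by exact
match (a trailing partial adapter at the read end is also recognized), and
the remainder split from the 3' end into fragment | UMI | barcode.  Reads
without an adapter and reads shorter than 30 nt after trimming are
discarded, mirroring a cutadapt run with ``-u 3 -a <adapter>`` followed by
a length filter.  Adapter matching is exact: the pipeline targets
error-free synthetic reads and documents rather than emulates cutadapt's
error tolerance.
"""

from __future__ import annotations

from collections import Counter
from pathlib import Path
from typing import Iterable

from .models import Footprint, RawRead, RejectReason
from .simdata import DEFAULT_ADAPTER


def _find_adapter(seq: str, adapter: str) -> int:
    """Start of the adapter in ``seq``, or -1.

    A full-adapter occurrence anywhere wins; otherwise the longest proper
    adapter prefix terminating the read counts as a (partial) occurrence.
    """
    pos = seq.find(adapter)
    if pos != -1:
        return pos
    max_k = min(len(adapter) - 1, len(seq))
    for k in range(max_k, 0, -1):
        if seq.endswith(adapter[:k]):
            return len(seq) - k
    return -1


def decompose_read(
    read: RawRead,
    adapter: str = DEFAULT_ADAPTER,
    n_untemplated: int = 3,
    umi_len: int = 5,
    barcode_len: int = 5,
    min_len_after_trim: int = 30,
) -> Footprint | RejectReason:
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if len(read.sequence) < n_untemplated + umi_len + barcode_len:
        return RejectReason.MALFORMED
    rem = read.sequence[n_untemplated:]
    pos = _find_adapter(rem, adapter)
    if pos == -1:
        return RejectReason.NO_ADAPTER
    trimmed = rem[:pos]
    if len(trimmed) < min_len_after_trim:
        return RejectReason.TOO_SHORT
    tail = umi_len + barcode_len
    if len(trimmed) <= tail:
        return RejectReason.MALFORMED
    fragment = trimmed[:-tail]
    umi = trimmed[-tail : -barcode_len] if barcode_len else trimmed[-tail:]
    barcode = trimmed[-barcode_len:] if barcode_len else ""
    return Footprint(read.id, fragment, umi, barcode)


def dedup_umi(footprints: Iterable[Footprint]) -> list[Footprint]:
    """Collapse PCR duplicates, keeping the first record per (UMI, fragment).

    The fragment sequence is part of the key so that distinct molecules
    that happen to share a UMI are not collapsed.
    """
    seen: set[tuple[str, str]] = set()
    kept: list[Footprint] = []
    for fp in footprints:
        key = (fp.umi, fp.fragment)
        if key not in seen:
            seen.add(key)
            kept.append(fp)
    return kept


def process_reads(
    reads: Iterable[RawRead],
    adapter: str = DEFAULT_ADAPTER,
    min_len_after_trim: int = 30,
    **kwargs,
) -> tuple[list[Footprint], Counter]:
    """Decompose a read stream; returns footprints and rejection tallies."""
    footprints: list[Footprint] = []
    rejects: Counter = Counter()
    for read in reads:
        out = decompose_read(
            read, adapter=adapter, min_len_after_trim=min_len_after_trim, **kwargs
        )
        if isinstance(out, Footprint):
            footprints.append(out)
        else:
            rejects[out] += 1
    return footprints, rejects


def write_rejection_report(rejects: Counter, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("reason\tcount\n")
        for reason in RejectReason:
            fh.write(f"{reason.value}\t{rejects.get(reason, 0)}\n")
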
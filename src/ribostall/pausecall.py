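"""Sliding-window pause scoring and pause-site calling.

The score at nucleotide i is the mean, over the two window sizes, of the
fold change of the count at i relative to the mean count in a window
centered at i — the focal position excluded, the window clipped at the
gene ends.  A site is reported when the score reaches the fold-change
threshold and the larger clipped window is sufficiently covered.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .models import OccupancyProfile, PauseParams, PauseSite


def _window_bounds(i: int, half: int, n: int) -> tuple[int, int]:
    """Inclusive bounds of the clipped window centered at i."""
    return max(0, i - half), min(n - 1, i + half)


def pause_score(
    profile: OccupancyProfile, i: int, params: PauseParams | None = None
) -> tuple[float | None, float]:
    """(score, coverage) at nucleotide i; score is None where undefined.

    The score is undefined when either window's mean (excluding i) is zero.
    Coverage is the fraction of non-focal positions with at least one count
    in the larger clipped window.
    """
    params = params or PauseParams()
    counts = profile.nt_counts
    n = len(counts)
    if n == 0:
        raise ValueError("empty profile")
    folds = []
    for w in (params.w1, params.w2):
        lo, hi = _window_bounds(i, w // 2, n)
        total = int(counts[lo : hi + 1].sum()) - int(counts[i])
        size = hi - lo  # window positions excluding i
        mean = total / size if size else 0.0
        folds.append(counts[i] / mean if mean > 0 else None)
    w_big = max(params.w1, params.w2)
    lo, hi = _window_bounds(i, w_big // 2, n)
    nonzero = int(np.count_nonzero(counts[lo : hi + 1])) - (1 if counts[i] else 0)
    size = hi - lo
    coverage = nonzero / size if size else 0.0
    if any(f is None for f in folds):
        return None, coverage
    return (folds[0] + folds[1]) / 2.0, coverage


def _scores_vector(
    counts: np.ndarray, params: PauseParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (scores, coverage, defined-mask) over all positions."""
    n = len(counts)
    c = counts.astype(float)
    csum = np.concatenate(([0.0], np.cumsum(c)))
    idx = np.arange(n)
    fold_sum = np.zeros(n)
    defined = np.ones(n, dtype=bool)
    for w in (params.w1, params.w2):
        half = w // 2
        lo = np.maximum(0, idx - half)
        hi = np.minimum(n - 1, idx + half)
        total = csum[hi + 1] - csum[lo] - c
        size = hi - lo
        mean = np.where(size > 0, total / np.maximum(size, 1), 0.0)
        ok = mean > 0
        defined &= ok
        fold_sum += np.where(ok, c / np.where(ok, mean, 1.0), 0.0)
    scores = np.where(defined, fold_sum / 2.0, np.nan)

    w_big = max(params.w1, params.w2)
    half = w_big // 2
    lo = np.maximum(0, idx - half)
    hi = np.minimum(n - 1, idx + half)
    nz = np.concatenate(([0.0], np.cumsum((counts > 0).astype(float))))
    nonzero = nz[hi + 1] - nz[lo] - (counts > 0)
    size = hi - lo
    coverage = np.where(size > 0, nonzero / np.maximum(size, 1), 0.0)
    return scores, coverage, defined


def call_pauses(
    profiles: dict[str, OccupancyProfile] | Iterable[OccupancyProfile],
    params: PauseParams | None = None,
) -> list[PauseSite]:
    """Report every position with score >= min_score and coverage >= min_cov.

    Sites are reported per nucleotide with the codon index annotated;
    adjacent super-threshold positions are not merged.
    """
    params = params or PauseParams()
    if isinstance(profiles, dict):
        profiles = profiles.values()
    sites: list[PauseSite] = []
    for profile in sorted(profiles, key=lambda p: p.gene_id):
        scores, coverage, defined = _scores_vector(profile.nt_counts, params)
        hit = defined & (scores >= params.min_score) & (coverage >= params.min_cov)
        for i in np.nonzero(hit)[0]:
            sites.append(
                PauseSite(
                    gene_id=profile.gene_id,
                    nt_position=int(i),
                    asite_codon=int(i) // 3,
                    score=float(scores[i]),
                    coverage=float(coverage[i]),
                )
            )
    return sites


def write_pause_tsv(sites: list[PauseSite], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tnt_position\tcodon\tscore\tcoverage\n")
        for s in sites:
            fh.write(
                f"{s.gene_id}\t{s.nt_position}\t{s.asite_codon}"
                f"\t{s.score:.6g}\t{s.coverage:.6g}\n"
            )
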
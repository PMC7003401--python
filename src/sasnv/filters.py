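"""False-positive removal for consensus pairs: indel filter, masking
filter and multi-locus filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align

from .consensus import ConsensusPair

__all__ = [
    "FilterParams",
    "MaskingResult",
    "indel_filter",
    "masking_filter",
    "multi_locus_filter",
]


@dataclass(frozen=True)
class FilterParams:
    e: float = 0.1
    mask_discard_threshold: int = 5
    match_score: int = 1
    mismatch_penalty: int = -1
    gap_penalty: int = -2
    count_tumour_events: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.e < 1.0:
            raise ValueError("e must lie in [0, 1)")
        if self.mask_discard_threshold < 1:
            raise ValueError("mask_discard_threshold must be >= 1")


@lru_cache(maxsize=8)
def _aligner(match: int, mismatch: int, gap: int) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = match
    a.mismatch_score = mismatch
    a.open_gap_score = gap
    a.extend_gap_score = gap
    # end gaps are free: only internal gaps indicate an indel between T and C
    a.end_gap_score = 0
    return a


def _best_gapless_score(
    t: np.ndarray, c: np.ndarray, match: int, mismatch: int
) -> int:
    """Best end-gap-free score over all gapless relative placements
    (vectorised over every shift with at least one overlapping column)."""
    nt, nc = len(t), len(c)
    pad = np.full(nt + 2 * nc - 2, 255, dtype=np.uint8)
    pad[nc - 1 : nc - 1 + nt] = t
    windows = np.lib.stride_tricks.sliding_window_view(pad, nc)
    matches = (windows == c).sum(axis=1)          # 255 never equals a base
    overlap = (windows != 255).sum(axis=1)
    scores = matches * match + (overlap - matches) * mismatch
    return int(scores.max())


def indel_filter(pair: ConsensusPair, params: FilterParams) -> bool:
    """True (keep) iff an optimal global alignment of T against C (free end
    gaps) needs no internal gap; pairs whose optimum requires a gap stem
    from somatic indels and are discarded."""
    if len(pair.t_codes) == 0 or len(pair.c_codes) == 0:
        return True
    gapless = _best_gapless_score(
        pair.t_codes, pair.c_codes, params.match_score, params.mismatch_penalty
    )
    # a perfect gapless overlap cannot be beaten by any gapped alignment
    if gapless >= min(len(pair.t_codes), len(pair.c_codes)) * params.match_score:
        return True
    aligner = _aligner(
        params.match_score, params.mismatch_penalty, params.gap_penalty
    )
    optimal = aligner.score(pair.T, pair.C)
    return gapless >= optimal


@dataclass
class MaskingResult:
    masked_t: np.ndarray
    event_columns: list[int]  # T-frame columns where masking fired

    @property
    def n_events(self) -> int:
        return len(self.event_columns)


def _event_columns(ratios: np.ndarray, e: float) -> np.ndarray:
    """Columns where >= 2 bases exceed ratio threshold e (strict)."""
    return np.flatnonzero((ratios > e).sum(axis=0) > 1)


def masking_filter(pair: ConsensusPair, params: FilterParams) -> MaskingResult:
    """Replace ``T_j`` with ``C_j`` at columns whose control frequency
    matrix shows more than one base above allele-ratio ``e`` (likely
    heterozygous SNP sites); columns without control counts are skipped.
    The pair's ``masking_events`` counter is updated; T itself is left
    untouched for reporting."""
    masked = pair.t_codes.copy()
    lo, hi = pair.overlap()
    events: list[int] = []
    if hi > lo:
        fc = pair.fc.slice(lo - pair.offset_tc, hi - pair.offset_tc)
        cols = _event_columns(fc.ratios(), params.e)
        for j in cols.tolist():
            t_col = lo + j
            masked[t_col] = pair.c_codes[t_col - pair.offset_tc]
            events.append(t_col)
    pair.masking_events = len(events)
    return MaskingResult(masked, events)


def multi_locus_filter(pair: ConsensusPair, params: FilterParams) -> bool:
    """True (keep) iff fewer than ``mask_discard_threshold`` distinct
    columns trigger masking events across the pair's frequency matrices.

    Pairs built over exact genomic repeats mix reads from multiple loci, so
    many columns of F^c and/or F^t carry two substantial alleles; such
    pairs are discarded wholesale."""
    lo, hi = pair.overlap()
    event_cols: set[int] = set()
    if hi > lo:
        fc = pair.fc.slice(lo - pair.offset_tc, hi - pair.offset_tc)
        event_cols.update((lo + _event_columns(fc.ratios(), params.e)).tolist())
    if params.count_tumour_events:
        event_cols.update(_event_columns(pair.ft.ratios(), params.e).tolist())
    return len(event_cols) < params.mask_discard_threshold
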
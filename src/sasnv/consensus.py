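"""Consensus-pair construction: phred-filtered tumour consensus from a
variant block, control consensus from reads recruited through exact
``min_prefix``-character matches in the primary suffix array.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seq import decode, encode, pack_kmers, revcomp_codes
from .gsa import GSA, Origin, SegmentCorpus, VariantBlock

__all__ = [
    "FrequencyMatrix",
    "ConsensusPair",
    "RecruitedAlignment",
    "dedupe_blocks",
    "frequency_matrix",
    "consensus_string",
    "recruit_control",
    "assemble_pair",
]

DEFAULT_PHRED_THRESHOLD = 35


@dataclass
class FrequencyMatrix:
    """Per-column base tallies of a gapless alignment.

    ``counts[b, j]`` counts bases with phred >= threshold in column j
    (rows in fixed A, C, G, T order); ``any_phred[b, j]`` counts all bases.
    """

    counts: np.ndarray
    any_phred: np.ndarray

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def slice(self, lo: int, hi: int) -> "FrequencyMatrix":
        return FrequencyMatrix(self.counts[:, lo:hi], self.any_phred[:, lo:hi])

    def reverse_complement(self) -> "FrequencyMatrix":
        return FrequencyMatrix(
            self.counts[::-1, ::-1].copy(), self.any_phred[::-1, ::-1].copy()
        )

    def ratios(self) -> np.ndarray:
        """counts normalised by column sums (0 where the column is empty)."""
        s = self.counts.sum(axis=0, dtype=np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = self.counts / s
        r[:, s == 0] = 0.0
        return r


@dataclass
class RecruitedAlignment:
    """Control reads placed in the tumour-consensus coordinate frame."""

    corpus: SegmentCorpus
    rows: np.ndarray       # corpus rows of recruited control reads
    flipped: np.ndarray    # bool: read used as its reverse complement
    shifts: np.ndarray     # column of the read's first (possibly flipped) base

    @property
    def size(self) -> int:
        return len(self.rows)


@dataclass
class ConsensusPair:
    """Tumour consensus ``T`` and control consensus ``C`` for one block.

    ``offset_tc`` is the T-frame column of C's first character, so T
    position x corresponds to C index ``x - offset_tc`` (it is negative
    when C extends left of T, the common case).
    """

    t_codes: np.ndarray
    c_codes: np.ndarray
    ft: FrequencyMatrix
    fc: FrequencyMatrix
    offset_tc: int
    source_block: VariantBlock | None = None
    n_recruited: int = 0
    masking_events: int = 0

    @property
    def T(self) -> str:
        return decode(self.t_codes)

    @property
    def C(self) -> str:
        return decode(self.c_codes)

    def overlap(self) -> tuple[int, int]:
        """T-frame column interval [lo, hi) covered by both T and C."""
        lo = max(0, self.offset_tc)
        hi = min(len(self.t_codes), self.offset_tc + len(self.c_codes))
        return lo, max(lo, hi)


# ---------------------------------------------------------------- blocks


def _block_serial(block: VariantBlock) -> tuple:
    return (block.member_key(), tuple(block.shifts.tolist()), block.anchor)


def dedupe_blocks(blocks: Sequence[VariantBlock]) -> list[VariantBlock]:
    """Keep one block per distinct member *read* set: blocks containing the
    same reads carry identical information even when anchors or member
    orientations differ (a section and its reverse-complement mirror yield
    the same reads).  Among duplicates the lexicographically smallest
    serialisation survives; survivors retain first-appearance order."""
    best: dict[tuple, VariantBlock] = {}
    order: list[tuple] = []
    for b in blocks:
        key = b.read_key()
        if key not in best:
            best[key] = b
            order.append(key)
        elif _block_serial(b) < _block_serial(best[key]):
            best[key] = b
    return [best[k] for k in order]


# ------------------------------------------------------------ alignments


def _gather_alignment(
    corpus: SegmentCorpus,
    rows: np.ndarray,
    flipped: np.ndarray,
    shifts: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Flatten a gapless alignment into parallel (code, phred, column)
    arrays; flipped members contribute their reverse complement."""
    rows = np.asarray(rows, dtype=np.int64)
    lengths = corpus.lengths[rows]
    total = int(lengths.sum())
    bounds = np.zeros(len(rows) + 1, dtype=np.int64)
    np.cumsum(lengths, out=bounds[1:])
    within = np.arange(total, dtype=np.int64) - np.repeat(bounds[:-1], lengths)
    flip_e = np.repeat(np.asarray(flipped, dtype=bool), lengths)
    len_e = np.repeat(lengths, lengths)
    src = np.where(flip_e, len_e - 1 - within, within)
    gidx = np.repeat(corpus.starts[rows], lengths) + src
    codes = corpus.codes[gidx]
    phred = corpus.phred[gidx]
    codes[flip_e] = 3 - codes[flip_e]
    cols = np.repeat(np.asarray(shifts, dtype=np.int64), lengths) + within
    width = int((np.asarray(shifts) + lengths).max()) if len(rows) else 0
    return codes, phred, cols, width


def frequency_matrix(
    corpus: SegmentCorpus,
    rows: np.ndarray,
    flipped: np.ndarray,
    shifts: np.ndarray,
    p: int = DEFAULT_PHRED_THRESHOLD,
    width: int | None = None,
) -> FrequencyMatrix:
    """Tally a gapless alignment into a 4 x width frequency matrix pair:
    phred-filtered counts (>= p) and unfiltered counts."""
    codes, phred, cols, w = _gather_alignment(corpus, rows, flipped, shifts)
    if width is None:
        width = w
    slot = cols * 4 + codes
    any_phred = np.bincount(slot, minlength=4 * width).reshape(width, 4).T
    ok = phred >= p
    counts = np.bincount(slot[ok], minlength=4 * width).reshape(width, 4).T
    return FrequencyMatrix(
        counts.astype(np.int64), any_phred.astype(np.int64)
    )


def block_frequency_matrix(
    block: VariantBlock, p: int = DEFAULT_PHRED_THRESHOLD
) -> FrequencyMatrix:
    flipped = np.zeros(block.size, dtype=bool)  # aux rows store oriented codes
    return frequency_matrix(block.corpus, block.member_rows, flipped, block.shifts, p)


def _consensus_codes(F: FrequencyMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-column consensus base over the full matrix width plus the
    any-phred coverage mask.  Tie rules: largest phred-filtered count, then
    largest any-phred count among the tied bases, then lexicographically
    smallest base; all-zero filtered columns fall back to any-phred counts
    (the same key realises the fallback)."""
    counts = F.counts.astype(np.int64)
    anyp = F.any_phred.astype(np.int64)
    bonus = np.array([3, 2, 1, 0], dtype=np.int64)[:, None]
    key = counts * (1 << 26) + anyp * 4 + bonus
    base = np.argmax(key, axis=0).astype(np.uint8)
    covered = anyp.sum(axis=0) > 0
    return base, covered


def consensus_string(F: FrequencyMatrix) -> str:
    """Consensus of an alignment's frequency matrix, trimmed of leading and
    trailing zero-coverage columns.  Raises if coverage is not contiguous."""
    base, covered = _consensus_codes(F)
    idx = np.flatnonzero(covered)
    if len(idx) == 0:
        return ""
    lo, hi = int(idx[0]), int(idx[-1]) + 1
    if not covered[lo:hi].all():
        raise ValueError("alignment coverage is not contiguous")
    return decode(base[lo:hi])


# ----------------------------------------------------------- recruitment


def _ragged_take(lo: np.ndarray, hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Expand [lo_i, hi_i) interval lists into (flat indices, source i)."""
    counts = hi - lo
    total = int(counts.sum())
    src = np.repeat(np.arange(len(lo), dtype=np.int64), counts)
    bounds = np.zeros(len(lo) + 1, dtype=np.int64)
    np.cumsum(counts, out=bounds[1:])
    flat = np.repeat(lo, counts) + (np.arange(total, dtype=np.int64) - np.repeat(bounds[:-1], counts))
    return flat, src


def _candidates_for(
    query: np.ndarray, gsa: GSA, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """(control-entry GSA indices, query positions) of control suffixes
    whose first k characters equal query[q:q+k]."""
    if len(query) < k or len(gsa) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    qkeys = pack_kmers(query, k)
    lo, hi = gsa.find_key_interval(qkeys)
    flat, src = _ragged_take(lo, hi)
    is_control = (
        gsa.corpus.origin[gsa.seg_row[flat].astype(np.int64)]
        == int(Origin.CONTROL)
    )
    return flat[is_control], src[is_control]


def _extension_length(
    t_codes: np.ndarray, read_codes: np.ndarray, shift: int
) -> int:
    """Number of agreeing positions between a placed read and T over their
    overlap (>= k for any seeded candidate)."""
    lo = max(0, shift)
    hi = min(len(t_codes), shift + len(read_codes))
    if hi <= lo:
        return 0
    return int(
        (t_codes[lo:hi] == read_codes[lo - shift : hi - shift]).sum()
    )


def recruit_control(
    t_codes: np.ndarray | str,
    gsa: GSA,
    k: int | None = None,
) -> RecruitedAlignment:
    """Recruit control reads sharing a k-character exact match with T (or
    its reverse complement) via suffix-array interval search.

    Forward matches at T position q with suffix offset o are placed at
    shift q - o; reverse-strand recruits are reverse-complemented first.  A
    read matching at multiple placements keeps the one with the longest
    agreement with T; unresolved ties drop the read.
    """
    if isinstance(t_codes, str):
        t_codes = encode(t_codes)
    if k is None:
        k = gsa.min_prefix

    ent_f, q_f = _candidates_for(t_codes, gsa, k)
    rows_f = gsa.seg_row[ent_f].astype(np.int64)
    shifts_f = q_f - gsa.offset[ent_f]
    flip_f = np.zeros(len(ent_f), dtype=bool)

    rc = revcomp_codes(t_codes)
    ent_r, q_r = _candidates_for(rc, gsa, k)
    rows_r = gsa.seg_row[ent_r].astype(np.int64)
    # r[o:o+k] == rc(T)[q:q+k]  =>  rc(r) matches T at |T| - q - len(r) + o
    lens_r = gsa.corpus.lengths[rows_r]
    shifts_r = len(t_codes) - q_r - lens_r + gsa.offset[ent_r]
    flip_r = np.ones(len(ent_r), dtype=bool)

    rows = np.concatenate([rows_f, rows_r])
    shifts = np.concatenate([shifts_f, shifts_r])
    flips = np.concatenate([flip_f, flip_r])
    if len(rows) == 0:
        e = np.empty(0, np.int64)
        return RecruitedAlignment(gsa.corpus, e, e.astype(bool), e)

    # dedupe (row, flip, shift) triples via one composite integer key
    SHIFT_BIAS = 1 << 24
    composite = (
        (rows.astype(np.int64) << np.int64(26))
        | (flips.astype(np.int64) << np.int64(25))
        | (shifts + SHIFT_BIAS)
    )
    composite = np.unique(composite)
    rows_u = composite >> np.int64(26)
    flips_u = ((composite >> np.int64(25)) & 1).astype(bool)
    shifts_u = (composite & ((1 << 25) - 1)) - SHIFT_BIAS

    # resolve reads recruited at multiple placements
    keep = np.ones(len(rows_u), dtype=bool)
    uniq, first, counts = np.unique(rows_u, return_index=True, return_counts=True)
    for r, f0, c in zip(uniq[counts > 1], first[counts > 1], counts[counts > 1]):
        idx = np.flatnonzero(rows_u == r)
        exts = []
        for i in idx:
            rc_codes = gsa.corpus.seg_codes(int(rows_u[i]))
            placed = revcomp_codes(rc_codes) if flips_u[i] else rc_codes
            exts.append(_extension_length(t_codes, placed, int(shifts_u[i])))
        best = max(exts)
        winners = [i for i, e in zip(idx, exts) if e == best]
        keep[idx] = False
        if len(winners) == 1:
            keep[winners[0]] = True
    rows_u, flips_u, shifts_u = rows_u[keep], flips_u[keep], shifts_u[keep]
    order = np.lexsort((shifts_u, flips_u, rows_u))
    return RecruitedAlignment(
        gsa.corpus, rows_u[order], flips_u[order], shifts_u[order]
    )


# ---------------------------------------------------------------- pairs


def assemble_pair(
    block: VariantBlock,
    primary_gsa: GSA,
    p: int = DEFAULT_PHRED_THRESHOLD,
) -> ConsensusPair | None:
    """Build the (T, C) consensus pair for a deduplicated block, or None
    when no control read shares a ``min_prefix``-mer with T (pairs without
    control evidence are discarded)."""
    ft_full = block_frequency_matrix(block, p)
    t_full, t_cov = _consensus_codes(ft_full)
    t_idx = np.flatnonzero(t_cov)
    t_lo, t_hi = int(t_idx[0]), int(t_idx[-1]) + 1
    t_codes = t_full[t_lo:t_hi]
    ft = ft_full.slice(t_lo, t_hi)

    recruited = recruit_control(t_codes, primary_gsa)
    if recruited.size == 0:
        return None
    c_lo_frame = int(recruited.shifts.min())
    fc_full = frequency_matrix(
        recruited.corpus,
        recruited.rows,
        recruited.flipped,
        recruited.shifts - c_lo_frame,
        p,
    )
    c_full, c_cov = _consensus_codes(fc_full)
    # keep the contiguous covered run best overlapping T ([0, |T|) in the
    # shifted frame corresponds to columns -c_lo_frame ..)
    runs = _coverage_runs(c_cov)
    t_span = (-c_lo_frame, -c_lo_frame + len(t_codes))
    best = max(
        runs,
        key=lambda r: (min(r[1], t_span[1]) - max(r[0], t_span[0]), -r[0]),
    )
    c_lo, c_hi = best
    c_codes = c_full[c_lo:c_hi]
    fc = fc_full.slice(c_lo, c_hi)
    # C frame origin in T coordinates:
    c_origin_t = c_lo_frame + c_lo
    # c_index = t_index - offset_tc  =>  offset_tc = c_origin_t
    return ConsensusPair(
        t_codes=t_codes,
        c_codes=c_codes,
        ft=ft,
        fc=fc,
        offset_tc=c_origin_t,
        source_block=block,
        n_recruited=int(recruited.size),
    )


def dump_pairs_tsv(pairs: Sequence[ConsensusPair], path: str) -> None:
    """Debug dump: one row per pair with T, C, their relative offset and
    flattened frequency matrices."""

    def flat(m: np.ndarray) -> str:
        return ";".join(",".join(str(x) for x in col) for col in m.T.tolist())

    with open(path, "w") as fh:
        fh.write("T\tC\toffset_tc\tn_recruited\tmasking_events\tFt\tFc\n")
        for p in pairs:
            fh.write(
                f"{p.T}\t{p.C}\t{p.offset_tc}\t{p.n_recruited}\t"
                f"{p.masking_events}\t{flat(p.ft.counts)}\t{flat(p.fc.counts)}\n"
            )


def _coverage_runs(covered: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(covered)
    if len(idx) == 0:
        return [(0, 0)]
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))
    return list(zip(starts.tolist(), ends.tolist()))
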
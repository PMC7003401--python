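"""Read preprocessing: N-splitting and the optional exact-match tumour
read filter (emfilter).

The exact-match filter discards a tumour read iff the read (or its reverse
complement) occurs as an exact, full-length, gapless substring of the
reference.  Control reads are never filtered.  The built-in backend searches
a sorted k-mer index of the reference instead of shelling out to an external
aligner; any callable with the same signature can be plugged in.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

from ._seq import encode
from .gsa import Origin, Orientation, ReadSegment, SegmentCorpus
from .reference import ReferenceIndex

__all__ = ["split_on_n", "exact_match_filter", "segments_from_reads"]

MIN_SEGMENT_LEN = 30


def split_on_n(
    sequence: str,
    phred: np.ndarray,
    min_len: int = MIN_SEGMENT_LEN,
) -> list[tuple[str, np.ndarray, int]]:
    """Split a read at 'N' characters, keeping maximal N-free substrings of
    length >= ``min_len`` in left-to-right order.

    Returns ``(subsequence, phred_slice, offset_in_read)`` triples.
    """
    phred = np.asarray(phred, dtype=np.uint8)
    if len(phred) != len(sequence):
        raise ValueError("phred scores must align to bases")
    out: list[tuple[str, np.ndarray, int]] = []
    start = 0
    seq = sequence.upper()
    n = len(seq)
    while start < n:
        cut = seq.find("N", start)
        if cut == -1:
            cut = n
        if cut - start >= min_len:
            out.append((seq[start:cut], phred[start:cut], start))
        start = cut + 1
    return out


def segments_from_reads(
    reads: Iterable[tuple[str, str, np.ndarray]],
    origin: Origin,
    min_len: int = MIN_SEGMENT_LEN,
    id_start: int = 0,
) -> list[ReadSegment]:
    """Turn ``(read_id, sequence, phred)`` records into N-free ReadSegments."""
    segments: list[ReadSegment] = []
    next_id = id_start
    for read_id, seq, phred in reads:
        for sub, sub_phred, offset in split_on_n(seq, phred, min_len):
            segments.append(
                ReadSegment(
                    segment_id=next_id,
                    sequence=sub,
                    phred=sub_phred,
                    origin=origin,
                    orientation=Orientation.FORWARD,
                    source_read_id=f"{read_id}/{offset}" if offset else read_id,
                )
            )
            next_id += 1
    return segments


def exact_match_filter(
    tumour: SegmentCorpus | Sequence[ReadSegment],
    reference: np.ndarray | str | ReferenceIndex,
    matcher: Callable[[SegmentCorpus], np.ndarray] | None = None,
) -> tuple[SegmentCorpus, int]:
    """Drop tumour reads that exactly match the reference on either strand.

    Returns the kept corpus and the number of discarded reads.  ``matcher``
    may supply an alternative aligner backend returning a per-row boolean
    match mask; the default searches the built-in reference k-mer index.
    Control reads must not be passed through this filter.
    """
    if not isinstance(tumour, SegmentCorpus):
        tumour = SegmentCorpus.from_segments(list(tumour))
    if matcher is None:
        if isinstance(reference, ReferenceIndex):
            index = reference
        else:
            ref_codes = encode(reference) if isinstance(reference, str) else reference
            index = ReferenceIndex([("ref", ref_codes)])
        matcher = index.exact_match_mask
    mask = matcher(tumour)
    kept = tumour.subset(np.flatnonzero(~mask))
    return kept, int(mask.sum())
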
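"""Generalised suffix arrays with origin tracking, section partitioning,
tumour-enrichment search and variant-block construction.

The array indexes every suffix of length >= ``min_prefix`` of every segment
(and of reverse complements when requested).  Two construction backends are
available:

``exact``
    Naive comparison sort producing the full lexicographic order with
    deterministic tie-break ``(segment_id, orientation, offset)`` for
    identical suffixes.  Used for small corpora and as the reference
    implementation in tests.

``grouped``
    Vectorised radix-style sort on the packed ``min_prefix``-character
    prefix of each suffix (a single stable uint64 argsort).  Entries are
    grouped exactly as in the full order -- every downstream operation
    (sections, enrichment, extraction, block alignment, control
    recruitment) depends only on these prefix groups -- but the order of
    entries *inside* a group is the deterministic corpus enumeration
    order rather than full lexicographic order.  This is what makes
    deep-coverage inputs tractable.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from typing import Iterator, Sequence

import numpy as np

from ._seq import decode, encode, pack_kmers

__all__ = [
    "Origin",
    "Orientation",
    "ReadSegment",
    "SegmentCorpus",
    "DetectionParams",
    "GSA",
    "Sections",
    "Section",
    "VariantBlock",
    "build_gsa",
    "split_sections",
    "enriched_sections",
    "extract_block_reads",
    "variant_blocks",
]

# corpora with at most this many suffixes default to the exact backend
_EXACT_BACKEND_MAX_SUFFIXES = 200_000


class Origin(IntEnum):
    TUMOUR = 0
    CONTROL = 1


class Orientation(IntEnum):
    FORWARD = 0
    REVCOMP = 1


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds controlling suffix-array based SNV detection."""

    min_prefix: int = 30
    e_cont: float = 0.0
    pmss: int = 2
    amss: int = 4

    def __post_init__(self) -> None:
        if self.min_prefix < 1:
            raise ValueError("min_prefix must be >= 1")
        if not 0.0 <= self.e_cont < 1.0:
            raise ValueError("e_cont must lie in [0, 1)")
        if self.pmss < 1:
            raise ValueError("pmss must be >= 1")
        if self.amss < 1:
            raise ValueError("amss must be >= 1")


@dataclass
class ReadSegment:
    """An N-free read substring with per-base phred scores."""

    segment_id: int
    sequence: str
    phred: np.ndarray
    origin: Origin
    orientation: Orientation = Orientation.FORWARD
    source_read_id: str = ""

    def __post_init__(self) -> None:
        self.phred = np.asarray(self.phred, dtype=np.uint8)
        if "N" in self.sequence or "n" in self.sequence:
            raise ValueError("ReadSegment sequence must be N-free")
        if len(self.phred) != len(self.sequence):
            raise ValueError("phred length must equal sequence length")


class SegmentCorpus:
    """Column-oriented store for a collection of read segments.

    Segments live in one concatenated code array; per-segment metadata
    (origin, orientation, original segment id) is kept in parallel arrays.
    """

    def __init__(
        self,
        codes: np.ndarray,
        starts: np.ndarray,
        phred: np.ndarray,
        origin: np.ndarray,
        orientation: np.ndarray,
        segment_ids: np.ndarray,
        names: list[str] | None = None,
    ):
        self.codes = codes
        self.starts = starts  # length n_segments + 1
        self.phred = phred
        self.origin = origin
        self.orientation = orientation
        self.segment_ids = segment_ids
        self.names = names
        self._lengths: np.ndarray | None = None

    # ------------------------------------------------------------------
    @classmethod
    def from_segments(cls, segments: Sequence[ReadSegment]) -> "SegmentCorpus":
        n = len(segments)
        lengths = np.fromiter((len(s.sequence) for s in segments), dtype=np.int64, count=n)
        starts = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(lengths, out=starts[1:])
        codes = np.empty(starts[-1], dtype=np.uint8)
        phred = np.empty(starts[-1], dtype=np.uint8)
        for i, seg in enumerate(segments):
            codes[starts[i] : starts[i + 1]] = encode(seg.sequence)
            phred[starts[i] : starts[i + 1]] = seg.phred
        origin = np.fromiter((int(s.origin) for s in segments), dtype=np.uint8, count=n)
        orientation = np.fromiter(
            (int(s.orientation) for s in segments), dtype=np.uint8, count=n
        )
        ids = np.fromiter((s.segment_id for s in segments), dtype=np.int64, count=n)
        names = [s.source_read_id for s in segments]
        return cls(codes, starts, phred, origin, orientation, ids, names)

    @classmethod
    def from_matrix(
        cls,
        codes2d: np.ndarray,
        phred2d: np.ndarray,
        origin: Origin,
        id_offset: int = 0,
    ) -> "SegmentCorpus":
        """Fast path for fixed-length reads stored as an (n, L) matrix."""
        n, L = codes2d.shape
        starts = np.arange(n + 1, dtype=np.int64) * L
        origins = np.full(n, int(origin), dtype=np.uint8)
        orients = np.zeros(n, dtype=np.uint8)
        ids = np.arange(id_offset, id_offset + n, dtype=np.int64)
        return cls(
            np.ascontiguousarray(codes2d).reshape(-1),
            starts,
            np.ascontiguousarray(phred2d).reshape(-1),
            origins,
            orients,
            ids,
            None,
        )

    @staticmethod
    def concatenate(parts: Sequence["SegmentCorpus"]) -> "SegmentCorpus":
        codes = np.concatenate([p.codes for p in parts])
        lengths = np.concatenate([np.diff(p.starts) for p in parts])
        starts = np.zeros(len(lengths) + 1, dtype=np.int64)
        np.cumsum(lengths, out=starts[1:])
        phred = np.concatenate([p.phred for p in parts])
        origin = np.concatenate([p.origin for p in parts])
        orientation = np.concatenate([p.orientation for p in parts])
        ids = np.concatenate([p.segment_ids for p in parts])
        names: list[str] | None = None
        if all(p.names is not None for p in parts):
            names = [n for p in parts for n in p.names]  # type: ignore[union-attr]
        return SegmentCorpus(codes, starts, phred, origin, orientation, ids, names)

    # ------------------------------------------------------------------
    @property
    def n_segments(self) -> int:
        return len(self.starts) - 1

    @property
    def lengths(self) -> np.ndarray:
        if self._lengths is None:
            self._lengths = np.diff(self.starts)
        return self._lengths

    def seg_codes(self, row: int) -> np.ndarray:
        return self.codes[self.starts[row] : self.starts[row + 1]]

    def seg_phred(self, row: int) -> np.ndarray:
        return self.phred[self.starts[row] : self.starts[row + 1]]

    def segment(self, row: int) -> ReadSegment:
        return ReadSegment(
            segment_id=int(self.segment_ids[row]),
            sequence=decode(self.seg_codes(row)),
            phred=self.seg_phred(row).copy(),
            origin=Origin(int(self.origin[row])),
            orientation=Orientation(int(self.orientation[row])),
            source_read_id=self.names[row] if self.names else "",
        )

    def subset(self, rows: np.ndarray) -> "SegmentCorpus":
        rows = np.asarray(rows, dtype=np.int64)
        lengths = self.lengths[rows]
        starts = np.zeros(len(rows) + 1, dtype=np.int64)
        np.cumsum(lengths, out=starts[1:])
        # gather the ragged byte ranges
        idx = np.repeat(self.starts[rows], lengths) + (
            np.arange(starts[-1], dtype=np.int64) - np.repeat(starts[:-1], lengths)
        )
        names = [self.names[r] for r in rows.tolist()] if self.names else None
        return SegmentCorpus(
            self.codes[idx],
            starts,
            self.phred[idx],
            self.origin[rows],
            self.orientation[rows],
            self.segment_ids[rows],
            names,
        )

    def with_revcomp(self) -> "SegmentCorpus":
        """Append the reverse complement of every segment (same segment id,
        flipped orientation, reversed phred)."""
        lengths = self.lengths
        n = self.n_segments
        total = self.starts[-1]
        # reverse each segment in place: global index total-1-i maps segments
        # in reverse row order, so flip rows afterwards via subset ordering
        rev_codes = (3 - self.codes)[::-1]
        rev_phred = self.phred[::-1]
        rev_starts = np.zeros(n + 1, dtype=np.int64)
        np.cumsum(lengths[::-1], out=rev_starts[1:])
        rc = SegmentCorpus(
            rev_codes,
            rev_starts,
            rev_phred,
            self.origin[::-1].copy(),
            self.orientation[::-1].copy(),
            self.segment_ids[::-1].copy(),
            list(reversed(self.names)) if self.names else None,
        )
        rc = rc.subset(np.arange(n - 1, -1, -1))
        rc.orientation = (1 - rc.orientation).astype(np.uint8)
        return SegmentCorpus.concatenate([self, rc])


# ----------------------------------------------------------------------


class GSA:
    """A constructed generalised suffix array.

    Entries are index-parallel numpy arrays: ``pos`` (global position in the
    corpus code array), ``seg_row`` (corpus row), ``offset`` (suffix offset
    within its segment) and ``keys`` (packed first-``min_prefix`` characters,
    non-decreasing).
    """

    def __init__(
        self,
        corpus: SegmentCorpus,
        min_prefix: int,
        includes_revcomp: bool,
        pos: np.ndarray,
        seg_row: np.ndarray,
        offset: np.ndarray,
        keys: np.ndarray,
        backend: str,
    ):
        self.corpus = corpus
        self.min_prefix = min_prefix
        self.includes_revcomp = includes_revcomp
        self.pos = pos
        self.seg_row = seg_row
        self.offset = offset
        self.keys = keys
        self.backend = backend
        self._lcp: np.ndarray | None = None
        self._entry_origin: np.ndarray | None = None
        self._section_dir: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self.pos)

    # -- inspection helpers (small-scale / debugging use) ---------------
    def suffix(self, i: int) -> str:
        row = int(self.seg_row[i])
        return decode(self.corpus.codes[self.pos[i] : self.corpus.starts[row + 1]])

    def suffix_codes(self, i: int) -> np.ndarray:
        row = int(self.seg_row[i])
        return self.corpus.codes[self.pos[i] : self.corpus.starts[row + 1]]

    def entries(self) -> list[tuple[int, int]]:
        ids = self.corpus.segment_ids[self.seg_row]
        return list(zip(ids.tolist(), self.offset.tolist()))

    def origin_of(self, i: int) -> Origin:
        return Origin(int(self.corpus.origin[self.seg_row[i]]))

    @property
    def entry_origin(self) -> np.ndarray:
        if self._entry_origin is None:
            self._entry_origin = self.corpus.origin[self.seg_row]
        return self._entry_origin

    @property
    def lcp(self) -> np.ndarray:
        """Adjacent longest-common-prefix lengths; ``lcp[i]`` relates suffix
        ``i-1`` and suffix ``i`` (``lcp[0] == 0``).  Computed on demand."""
        if self._lcp is None:
            self._lcp = self._compute_lcp()
        return self._lcp

    def _compute_lcp(self) -> np.ndarray:
        n = len(self)
        lcp = np.zeros(n, dtype=np.int64)
        starts = self.corpus.starts
        codes = self.corpus.codes
        ends = starts[self.seg_row.astype(np.int64) + 1]
        for i in range(1, n):
            a, ae = int(self.pos[i - 1]), int(ends[i - 1])
            b, be = int(self.pos[i]), int(ends[i])
            m = min(ae - a, be - b)
            # compare in strided chunks
            d = 0
            while d < m:
                step = min(256, m - d)
                x = codes[a + d : a + d + step]
                y = codes[b + d : b + d + step]
                neq = np.nonzero(x != y)[0]
                if len(neq):
                    d += int(neq[0])
                    break
                d += step
            lcp[i] = d
        return lcp

    def _section_directory(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(distinct sorted prefix keys, interval lo, interval hi) -- a
        compact directory for interval search, far smaller than the full
        entry array."""
        if self._section_dir is None:
            n = len(self)
            if n == 0:
                e = np.empty(0, dtype=np.int64)
                self._section_dir = (np.empty(0, np.uint64), e, e)
            else:
                breaks = np.flatnonzero(self.keys[1:] != self.keys[:-1]) + 1
                lo = np.concatenate(([0], breaks))
                hi = np.concatenate((breaks, [n]))
                self._section_dir = (self.keys[lo], lo, hi)
        return self._section_dir

    def find_key_interval(self, keys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """[lo, hi) GSA index intervals of entries whose first
        ``min_prefix`` characters equal each packed query key."""
        keys = np.asarray(keys, dtype=np.uint64)
        dkeys, dlo, dhi = self._section_directory()
        if len(dkeys) == 0:
            z = np.zeros(len(keys), dtype=np.int64)
            return z, z.copy()
        idx = np.minimum(
            np.searchsorted(dkeys, keys, "left"), len(dkeys) - 1
        )
        hit = dkeys[idx] == keys
        lo = np.where(hit, dlo[idx], 0)
        hi = np.where(hit, dhi[idx], 0)
        return lo, hi

    def to_tsv(self, path: str) -> None:
        origin = self.entry_origin
        ids = self.corpus.segment_ids[self.seg_row]
        lcp = self.lcp
        with open(path, "w") as fh:
            fh.write("rank\tsegment_id\toffset\torigin\tlcp\n")
            for i in range(len(self)):
                fh.write(
                    f"{i}\t{ids[i]}\t{self.offset[i]}\t"
                    f"{Origin(int(origin[i])).name}\t{lcp[i]}\n"
                )


def _pos_dtype(corpus: SegmentCorpus):
    return np.int32 if corpus.starts[-1] < 2**31 - 1 else np.int64


def _enumerate_positions(corpus: SegmentCorpus, min_prefix: int) -> np.ndarray:
    """Global start positions of every suffix of length >= min_prefix, in
    corpus enumeration order ((row, offset) ascending)."""
    counts = np.maximum(corpus.lengths - min_prefix + 1, 0)
    total = int(counts.sum())
    dt = _pos_dtype(corpus)
    bounds = np.zeros(corpus.n_segments + 1, dtype=np.int64)
    np.cumsum(counts, out=bounds[1:])
    pos = np.arange(total, dtype=dt)
    pos -= np.repeat(bounds[:-1], counts).astype(dt)
    pos += np.repeat(corpus.starts[:-1], counts).astype(dt)
    return pos


def _rows_offsets_of(
    corpus: SegmentCorpus, pos: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-entry corpus row and suffix offset, derived from positions via a
    position->row map (chunked to cap transient memory)."""
    rowmap = np.repeat(
        np.arange(corpus.n_segments, dtype=np.uint32), corpus.lengths
    )
    rows = rowmap[pos]
    del rowmap
    offsets = np.empty(len(pos), dtype=np.int32)
    starts = corpus.starts
    step = 8_000_000
    for lo in range(0, len(pos), step):
        hi = min(lo + step, len(pos))
        offsets[lo:hi] = pos[lo:hi] - starts[rows[lo:hi].astype(np.int64)]
    return rows, offsets


def build_gsa(
    corpus: SegmentCorpus | Sequence[ReadSegment],
    include_revcomp: bool = False,
    min_prefix: int = 30,
    backend: str = "auto",
) -> GSA:
    """Build a generalised suffix array over all suffixes of length
    >= ``min_prefix`` (adding reverse complements when requested)."""
    if not isinstance(corpus, SegmentCorpus):
        corpus = SegmentCorpus.from_segments(list(corpus))
    if include_revcomp:
        corpus = corpus.with_revcomp()
    pos = _enumerate_positions(corpus, min_prefix)

    if backend == "auto":
        backend = "exact" if len(pos) <= _EXACT_BACKEND_MAX_SUFFIXES else "grouped"
    if backend == "grouped" and min_prefix > 30:
        raise ValueError("grouped backend supports min_prefix <= 30")

    if len(pos) == 0:
        empty = np.empty(0, dtype=np.int64)
        return GSA(
            corpus, min_prefix, include_revcomp, empty, empty, empty,
            np.empty(0, dtype=np.uint64), backend,
        )

    if backend == "exact":
        rows, offsets = _rows_offsets_of(corpus, pos)
        order = _sort_exact(corpus, pos, rows, offsets)
        pos = pos[order]
        rows = rows[order]
        offsets = offsets[order]
        if min_prefix <= 30:
            keys = pack_kmers(corpus.codes, min_prefix)[pos.astype(np.int64)]
        else:  # long prefixes: derive grouping labels by direct comparison
            keys = _long_prefix_group_keys(corpus, pos, rows, min_prefix)
    elif backend == "grouped":
        allkeys = pack_kmers(corpus.codes, min_prefix)
        keys = allkeys[pos]
        del allkeys
        order = np.argsort(keys, kind="stable")
        keys = keys[order]
        pos = pos[order]
        del order
        rows, offsets = _rows_offsets_of(corpus, pos)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return GSA(corpus, min_prefix, include_revcomp, pos, rows, offsets, keys, backend)


def _sort_exact(
    corpus: SegmentCorpus, pos: np.ndarray, rows: np.ndarray, offsets: np.ndarray
) -> np.ndarray:
    seqs = [corpus.seg_codes(r).tobytes() for r in range(corpus.n_segments)]
    ids = corpus.segment_ids
    orient = corpus.orientation

    def key(i: int):
        r = int(rows[i])
        o = int(offsets[i])
        return (seqs[r][o:], int(ids[r]), int(orient[r]), o)

    return np.asarray(sorted(range(len(pos)), key=key), dtype=np.int64)


def _long_prefix_group_keys(
    corpus: SegmentCorpus, pos: np.ndarray, rows: np.ndarray, min_prefix: int
) -> np.ndarray:
    """Group labels (as pseudo-keys) for sorted suffixes when the prefix does
    not fit a packed uint64: adjacent entries get equal labels iff their
    first ``min_prefix`` characters match."""
    n = len(pos)
    keys = np.zeros(n, dtype=np.uint64)
    label = 0
    codes = corpus.codes
    for i in range(1, n):
        a, b = int(pos[i - 1]), int(pos[i])
        if not np.array_equal(codes[a : a + min_prefix], codes[b : b + min_prefix]):
            label += 1
        keys[i] = label
    return keys


# ----------------------------------------------------------------------


@dataclass
class Section:
    """A maximal GSA interval whose suffixes share a >= min_prefix prefix."""

    lo: int
    hi: int
    tumour_suffixes: int
    control_suffixes: int
    prefix_len: int | None = None

    @property
    def size(self) -> int:
        return self.hi - self.lo


class Sections:
    """Array-backed collection of sections over one GSA."""

    def __init__(self, gsa: GSA, lo: np.ndarray, hi: np.ndarray,
                 n_tumour: np.ndarray, n_control: np.ndarray):
        self.gsa = gsa
        self.lo = lo
        self.hi = hi
        self.n_tumour = n_tumour
        self.n_control = n_control

    def __len__(self) -> int:
        return len(self.lo)

    def __getitem__(self, i: int) -> Section:
        return Section(
            int(self.lo[i]),
            int(self.hi[i]),
            int(self.n_tumour[i]),
            int(self.n_control[i]),
            self.prefix_len(i),
        )

    def __iter__(self) -> Iterator[Section]:
        for i in range(len(self)):
            yield self[i]

    def prefix_len(self, i: int) -> int:
        """Exact shared-prefix length of section ``i`` (min adjacent LCP over
        the run; suffix length for singleton sections)."""
        lo, hi = int(self.lo[i]), int(self.hi[i])
        if hi - lo == 1:
            row = int(self.gsa.seg_row[lo])
            return int(self.gsa.corpus.starts[row + 1] - self.gsa.pos[lo])
        return int(self.gsa.lcp[lo + 1 : hi].min())

    def select(self, mask: np.ndarray) -> "Sections":
        return Sections(
            self.gsa, self.lo[mask], self.hi[mask],
            self.n_tumour[mask], self.n_control[mask],
        )


def split_sections(gsa: GSA) -> Sections:
    """Partition the GSA into maximal runs of entries sharing a common
    prefix of length >= ``min_prefix`` (equivalently: adjacent LCP >=
    min_prefix throughout the run).  Singleton runs are size-1 sections."""
    n = len(gsa)
    if n == 0:
        e = np.empty(0, dtype=np.int64)
        return Sections(gsa, e, e, e, e)
    _, lo, hi = gsa._section_directory()
    is_tum = gsa.entry_origin == int(Origin.TUMOUR)
    cum = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(is_tum, dtype=np.int64, out=cum[1:])
    n_tumour = cum[hi] - cum[lo]
    n_control = (hi - lo) - n_tumour
    return Sections(gsa, lo, hi, n_tumour, n_control)


def enriched_sections(sections: Sections, params: DetectionParams) -> Sections:
    """Sections considered enriched for tumour-read-derived suffixes.

    A section qualifies when (a) it holds at least ``pmss`` tumour-derived
    suffixes and (b) the fraction of control-derived suffixes does not
    exceed ``e_cont`` (with the default ``e_cont == 0`` the section must be
    tumour-exclusive; raising ``e_cont`` tolerates tumour-in-normal
    contamination).
    """
    t = sections.n_tumour
    c = sections.n_control
    mask = (t >= params.pmss) & (c <= params.e_cont * (t + c))
    return sections.select(mask)


def extract_block_reads(enriched: Sections, gsa: GSA) -> np.ndarray:
    """Corpus rows of tumour segments contributing >= 1 suffix to >= 1
    enriched section (deduplicated; control segments never extracted)."""
    if len(enriched) == 0:
        return np.empty(0, dtype=np.int64)
    spans = [gsa.seg_row[lo:hi] for lo, hi in zip(enriched.lo, enriched.hi)]
    rows = np.unique(np.concatenate(spans))
    rows = rows[gsa.corpus.origin[rows] == int(Origin.TUMOUR)]
    return rows


@dataclass
class VariantBlock:
    """Gapless multi-read alignment induced by an auxiliary-array section.

    ``member_rows`` index into ``corpus``; member ``i``'s read occupies
    alignment columns ``[shifts[i], shifts[i] + len_i)`` and its section
    suffix starts at column ``anchor`` for every member.
    """

    corpus: SegmentCorpus
    member_rows: np.ndarray
    shifts: np.ndarray
    anchor: int

    @property
    def size(self) -> int:
        return len(self.member_rows)

    @property
    def width(self) -> int:
        return int((self.shifts + self.corpus.lengths[self.member_rows]).max())

    def members(self) -> list[tuple[int, Orientation, int]]:
        ids = self.corpus.segment_ids[self.member_rows]
        orients = self.corpus.orientation[self.member_rows]
        return [
            (int(i), Orientation(int(o)), int(s))
            for i, o, s in zip(ids, orients, self.shifts)
        ]

    def member_key(self) -> tuple:
        """Canonical identity of the member set (segment id + orientation)."""
        ids = self.corpus.segment_ids[self.member_rows]
        orients = self.corpus.orientation[self.member_rows]
        return tuple(sorted(zip(ids.tolist(), orients.tolist())))

    def read_key(self) -> tuple:
        """Canonical identity of the member *read* set, ignoring
        orientation -- a section and its reverse-complement mirror induce
        blocks over the same reads."""
        return tuple(sorted(set(self.corpus.segment_ids[self.member_rows].tolist())))


def variant_blocks(aux_gsa: GSA, params: DetectionParams) -> list[VariantBlock]:
    """One block per auxiliary-array section holding >= ``amss`` suffixes.

    Shifts place every member's section suffix at the same anchor column
    (``shift = anchor - suffix_offset`` with ``anchor = max`` member offset,
    so the leftmost alignment column is 0).
    """
    sections = split_sections(aux_gsa)
    mask = (sections.hi - sections.lo) >= params.amss
    blocks: list[VariantBlock] = []
    corpus = aux_gsa.corpus
    ids = corpus.segment_ids
    orients = corpus.orientation
    for lo, hi in zip(sections.lo[mask], sections.hi[mask]):
        rows = aux_gsa.seg_row[lo:hi]
        offs = aux_gsa.offset[lo:hi]
        anchor = int(offs.max())
        shifts = anchor - offs
        # canonical member order: (segment_id, orientation, shift)
        order = np.lexsort((shifts, orients[rows], ids[rows]))
        blocks.append(
            VariantBlock(corpus, rows[order].astype(np.int64),
                         shifts[order].astype(np.int64), anchor)
        )
    return blocks
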
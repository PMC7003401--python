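from __future__ import annotations

import numpy as np
import pytest

from sasnv._seq import decode, revcomp
from sasnv.gsa import Origin, Orientation, ReadSegment, SegmentCorpus


def make_segment(
    seq: str,
    origin: Origin = Origin.TUMOUR,
    segment_id: int = 0,
    phred: int | np.ndarray = 40,
    source_read_id: str = "",
) -> ReadSegment:
    q = (
        np.full(len(seq), phred, dtype=np.uint8)
        if np.isscalar(phred)
        else np.asarray(phred, dtype=np.uint8)
    )
    return ReadSegment(segment_id, seq, q, origin, Orientation.FORWARD, source_read_id)


def make_corpus(*specs) -> SegmentCorpus:
    """specs: (seq, origin) or ReadSegment; ids assigned by position."""
    segs = []
    for i, s in enumerate(specs):
        if isinstance(s, ReadSegment):
            segs.append(s)
        else:
            seq, origin = s
            segs.append(make_segment(seq, origin, segment_id=i))
    return SegmentCorpus.from_segments(segs)


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return decode(rng.integers(0, 4, length).astype(np.uint8))


def random_segments(
    rng: np.random.Generator,
    n: int,
    min_len: int = 30,
    max_len: int = 80,
    alphabet: int = 4,
) -> list[ReadSegment]:
    segs = []
    for i in range(n):
        L = int(rng.integers(min_len, max_len + 1))
        seq = decode(rng.integers(0, alphabet, L).astype(np.uint8))
        origin = Origin(int(rng.integers(0, 2)))
        q = rng.integers(20, 41, L).astype(np.uint8)
        segs.append(ReadSegment(i, seq, q, origin))
    return segs


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------
# canonical dual-array strand fixture: one somatic SNV covered by exactly
# two forward-sequenced and two reverse-sequenced tumour reads, plus
# ref-allele control coverage.  Detectable at pmss=2 (strand groups occupy
# disjoint primary sections of 2 suffixes each) and missed at pmss=4.


class DualStrandFixture:
    def __init__(self, seed: int = 77):
        rng = np.random.default_rng(seed)
        self.ref = random_sequence(rng, 1200)
        self.snv_pos = 600
        ref_base = self.ref[self.snv_pos]
        self.alt_base = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
        self.chrom = "fix1"
        var = (
            self.ref[: self.snv_pos] + self.alt_base + self.ref[self.snv_pos + 1 :]
        )
        self.variant_hap = var
        L = 60
        segs: list[ReadSegment] = []
        sid = 0
        # tumour: 2 forward + 2 reverse-complemented variant reads
        for start in (560, 565):
            segs.append(
                make_segment(var[start : start + L], Origin.TUMOUR, sid)
            )
            sid += 1
        for start in (570, 575):
            segs.append(
                make_segment(revcomp(var[start : start + L]), Origin.TUMOUR, sid)
            )
            sid += 1
        # control: tile the reference densely on both strands
        for start in range(0, len(self.ref) - L + 1, 10):
            seq = self.ref[start : start + L]
            if start % 20:
                seq = revcomp(seq)
            segs.append(make_segment(seq, Origin.CONTROL, sid))
            sid += 1
        self.segments = segs
        self.corpus = SegmentCorpus.from_segments(segs)

    @property
    def expected_call(self) -> tuple[str, int, str, str]:
        return (
            self.chrom,
            self.snv_pos,
            self.ref[self.snv_pos],
            self.alt_base,
        )


@pytest.fixture(scope="session")
def dual_strand_fixture() -> DualStrandFixture:
    return DualStrandFixture()
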
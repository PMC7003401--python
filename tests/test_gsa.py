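import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_corpus, make_segment, random_segments
from sasnv.gsa import (
    DetectionParams,
    GSA,
    Origin,
    Orientation,
    ReadSegment,
    SegmentCorpus,
    build_gsa,
    enriched_sections,
    extract_block_reads,
    split_sections,
    variant_blocks,
)

# ------------------------------------------------------------- oracles


def oracle_suffixes(segments, min_prefix):
    """Brute force: every suffix of length >= min_prefix as a plain string,
    sorted with the (suffix, segment_id, orientation, offset) key."""
    out = []
    for row, seg in enumerate(segments):
        for off in range(len(seg.sequence) - min_prefix + 1):
            out.append(
                (
                    seg.sequence[off:],
                    seg.segment_id,
                    int(seg.orientation),
                    off,
                )
            )
    out.sort()
    return out


def oracle_lcp(a: str, b: str) -> int:
    n = 0
    while n < min(len(a), len(b)) and a[n] == b[n]:
        n += 1
    return n


def oracle_sections(sorted_suffixes, min_prefix):
    """Maximal runs with pairwise-adjacent LCP >= min_prefix."""
    runs = []
    start = 0
    for i in range(1, len(sorted_suffixes) + 1):
        if i == len(sorted_suffixes) or oracle_lcp(
            sorted_suffixes[i - 1][0], sorted_suffixes[i][0]
        ) < min_prefix:
            runs.append((start, i))
            start = i
    return runs


# ----------------------------------------------------------- build_gsa


def test_build_gsa_single_segment_order():
    g = build_gsa([make_segment("ACA")], min_prefix=1)
    assert [g.suffix(i) for i in range(len(g))] == ["A", "ACA", "CA"]
    assert g.entries() == [(0, 2), (0, 0), (0, 1)]


def test_build_gsa_palindrome_revcomp():
    g = build_gsa([make_segment("ACGT")], include_revcomp=True, min_prefix=4)
    assert [g.suffix(i) for i in range(len(g))] == ["ACGT", "ACGT"]
    assert g.entries() == [(0, 0), (0, 0)]


def test_build_gsa_empty_corpus():
    g = build_gsa([], min_prefix=30)
    assert len(g) == 0
    assert len(split_sections(g)) == 0


def test_build_gsa_random_matches_oracle(rng):
    segs = random_segments(rng, 20, min_len=30, max_len=50)
    g = build_gsa(segs, min_prefix=5, backend="exact")
    oracle = oracle_suffixes(segs, 5)
    assert [g.suffix(i) for i in range(len(g))] == [s[0] for s in oracle]
    assert g.entries() == [(s[1], s[3]) for s in oracle]
    for i in range(1, len(g)):
        assert g.lcp[i] == oracle_lcp(oracle[i - 1][0], oracle[i][0])


def test_backends_agree_on_sections(rng):
    # repeat-rich alphabet to force deep shared prefixes
    segs = random_segments(rng, 40, min_len=30, max_len=70, alphabet=2)
    ge = build_gsa(segs, min_prefix=8, backend="exact")
    gg = build_gsa(segs, min_prefix=8, backend="grouped")
    se, sg = split_sections(ge), split_sections(gg)
    assert np.array_equal(se.lo, sg.lo) and np.array_equal(se.hi, sg.hi)
    assert np.array_equal(se.n_tumour, sg.n_tumour)
    assert np.array_equal(se.n_control, sg.n_control)
    for lo, hi in zip(se.lo.tolist(), se.hi.tolist()):
        a = set(zip(ge.seg_row[lo:hi].tolist(), ge.offset[lo:hi].tolist()))
        b = set(zip(gg.seg_row[lo:hi].tolist(), gg.offset[lo:hi].tolist()))
        assert a == b


@given(st.integers(0, 10**6))
@settings(max_examples=20, deadline=None)
def test_property_grouped_matches_exact_sections(seed):
    # includes single-letter alphabets: heavily tied suffixes stress the
    # grouping equivalence between backends
    rng = np.random.default_rng(seed)
    alphabet = int(rng.integers(1, 4))
    segs = random_segments(rng, int(rng.integers(2, 10)), min_len=30,
                           max_len=50, alphabet=alphabet)
    mp = int(rng.integers(1, 31))
    rc = bool(rng.integers(0, 2))
    ge = build_gsa(segs, include_revcomp=rc, min_prefix=mp, backend="exact")
    gg = build_gsa(segs, include_revcomp=rc, min_prefix=mp, backend="grouped")
    se, sg = split_sections(ge), split_sections(gg)
    assert np.array_equal(se.lo, sg.lo) and np.array_equal(se.hi, sg.hi)
    assert np.array_equal(se.n_tumour, sg.n_tumour)
    for lo, hi in zip(se.lo.tolist(), se.hi.tolist()):
        a = sorted(zip(ge.seg_row[lo:hi].tolist(), ge.offset[lo:hi].tolist()))
        b = sorted(zip(gg.seg_row[lo:hi].tolist(), gg.offset[lo:hi].tolist()))
        assert a == b


@given(st.integers(0, 10_000))
@settings(max_examples=25, deadline=None)
def test_property_exact_backend_equals_oracle(seed):
    rng = np.random.default_rng(seed)
    segs = random_segments(rng, int(rng.integers(1, 12)), min_len=5, max_len=40,
                           alphabet=int(rng.integers(2, 5)))
    mp = int(rng.integers(1, 8))
    g = build_gsa(segs, min_prefix=mp, backend="exact")
    oracle = oracle_suffixes(segs, mp)
    assert [g.suffix(i) for i in range(len(g))] == [s[0] for s in oracle]
    secs = split_sections(g)
    runs = oracle_sections(oracle, mp)
    assert list(zip(secs.lo.tolist(), secs.hi.tolist())) == runs


# ------------------------------------------------------ split_sections


def test_sections_runs_partition(rng):
    # two 31-base segments sharing a 30-char prefix Z: the offset-0
    # suffixes have adjacent LCP 30 (one section of 2), the offset-1
    # suffixes share only 29 characters and stay singletons
    from conftest import random_sequence

    Z = random_sequence(rng, 30)
    s1, s2 = Z + "A", Z + "C"
    g = build_gsa(
        [make_segment(s, segment_id=i) for i, s in enumerate([s1, s2])],
        min_prefix=30,
        backend="exact",
    )
    assert len(g) == 4
    secs = split_sections(g)
    assert sorted(s.size for s in secs) == [1, 1, 2]
    big = next(s for s in secs if s.size == 2)
    assert {int(g.offset[i]) for i in range(big.lo, big.hi)} == {0}
    assert big.prefix_len == 30


def test_sections_all_singletons(rng):
    segs = random_segments(rng, 15, min_len=30, max_len=40)
    g = build_gsa(segs, min_prefix=30)
    secs = split_sections(g)
    if (g.lcp[1:] < 30).all():
        assert len(secs) == len(g)
        assert all(s.size == 1 for s in secs)


def test_sections_identical_kmers_single_section():
    k = 7
    seq = "ACGTACGTACGTACGTACGTACGTACGTAC"  # 30-mer
    segs = [make_segment(seq, Origin.TUMOUR, i) for i in range(k)]
    g = build_gsa(segs, min_prefix=30)
    secs = split_sections(g)
    assert len(secs) == 1
    assert secs[0].size == k
    assert secs[0].prefix_len >= 30


def test_section_prefix_len_soundness(rng):
    segs = random_segments(rng, 30, min_len=30, max_len=60, alphabet=3)
    g = build_gsa(segs, min_prefix=10, backend="exact")
    for s in split_sections(g):
        assert s.prefix_len >= 10
        lo, hi = s.lo, s.hi
        assert oracle_lcp(g.suffix(lo), g.suffix(hi - 1)) >= 10


def test_every_entry_in_exactly_one_section(rng):
    segs = random_segments(rng, 25, min_len=30, max_len=60)
    g = build_gsa(segs, min_prefix=12)
    secs = split_sections(g)
    spans = sorted(zip(secs.lo.tolist(), secs.hi.tolist()))
    assert spans[0][0] == 0 and spans[-1][1] == len(g)
    for (a, b), (c, d) in zip(spans, spans[1:]):
        assert b == c


# --------------------------------------------------- enriched_sections


def _sections_with_counts(counts):
    """Build a minimal Sections-like object from (tumour, control) pairs."""
    from sasnv.gsa import Sections

    t = np.array([c[0] for c in counts], dtype=np.int64)
    c = np.array([c[1] for c in counts], dtype=np.int64)
    lo = np.arange(len(counts), dtype=np.int64)
    hi = lo + t + c
    return Sections(None, lo, hi, t, c)


@pytest.mark.parametrize(
    "tumour,control,e_cont,pmss,expect",
    [
        (2, 0, 0.0, 2, True),    # tumour-exclusive with pmss suffixes
        (1, 0, 0.0, 2, False),   # below pmss
        (3, 3, 0.5, 2, True),    # control fraction 0.5 allowed at e_cont=0.5
        (3, 4, 0.5, 2, False),   # control fraction 4/7 > 0.5
        (5, 1, 0.0, 2, False),   # any control suffix disqualifies at e_cont=0
        (4, 0, 0.0, 4, True),
    ],
)
def test_enriched_section_boundaries(tumour, control, e_cont, pmss, expect):
    secs = _sections_with_counts([(tumour, control)])
    params = DetectionParams(e_cont=e_cont, pmss=pmss)
    assert (len(enriched_sections(secs, params)) == 1) is expect


def test_enrichment_monotone_in_pmss(rng):
    counts = [
        (int(rng.integers(0, 6)), int(rng.integers(0, 6))) for _ in range(50)
    ]
    secs = _sections_with_counts(counts)
    prev = None
    for pmss in (1, 2, 3, 4, 5):
        got = len(enriched_sections(secs, DetectionParams(pmss=pmss)))
        if prev is not None:
            assert got <= prev
        prev = got


# ------------------------------------------------- extract_block_reads


def _enriched_of(corpus, params):
    g = build_gsa(corpus, min_prefix=params.min_prefix)
    return enriched_sections(split_sections(g), params), g


def test_extract_dedups_reads():
    seq = "GATTACAGATTACAGATTACAGATTACAGA"  # 30
    # one tumour read contributes suffixes to one section twice via two
    # copies of the same 30-mer
    long = seq + "TTTTTTTTTT" + seq
    corpus = make_corpus((long, Origin.TUMOUR), (seq, Origin.TUMOUR))
    params = DetectionParams(pmss=2)
    enriched, g = _enriched_of(corpus, params)
    rows = extract_block_reads(enriched, g)
    assert sorted(g.corpus.segment_ids[rows].tolist()) == [0, 1]


def test_extract_empty_when_no_enriched():
    seq = "GATTACAGATTACAGATTACAGATTACAGA"
    corpus = make_corpus((seq, Origin.TUMOUR), (seq, Origin.CONTROL))
    params = DetectionParams(pmss=2, e_cont=0.0)
    enriched, g = _enriched_of(corpus, params)
    assert len(extract_block_reads(enriched, g)) == 0


def test_extract_never_returns_control(rng):
    segs = random_segments(rng, 40, min_len=30, max_len=60)
    g = build_gsa(segs, min_prefix=10)
    enriched = enriched_sections(split_sections(g), DetectionParams(
        min_prefix=10, pmss=1, e_cont=0.9))
    rows = extract_block_reads(enriched, g)
    assert (g.corpus.origin[rows] == int(Origin.TUMOUR)).all()


# ------------------------------------------------------ variant_blocks


def test_variant_block_shifts():
    core = "ACGGATTACCAGGATCCAATTGGCCAATTG"  # 30-mer
    rng = np.random.default_rng(0)
    from conftest import random_sequence

    reads = []
    for off in (0, 5, 10, 15):
        prefix = random_sequence(rng, off)
        suffix = random_sequence(rng, 20 - off)
        reads.append(make_segment(prefix + core + suffix, Origin.TUMOUR, len(reads)))
    g = build_gsa(reads, include_revcomp=True, min_prefix=30)
    blocks = variant_blocks(g, DetectionParams(amss=4))
    target = [
        b for b in blocks
        if sorted(s for _, _, s in b.members()) == [0, 5, 10, 15]
        and all(o == Orientation.FORWARD for _, o, _ in b.members())
    ]
    assert target, "expected a block anchored on the shared 30-mer"
    b = target[0]
    by_id = {m[0]: m[2] for m in b.members() if m[1] == Orientation.FORWARD}
    assert by_id == {0: 15, 1: 10, 2: 5, 3: 0}
    # brute-force column check: the shared 30-mer occupies the same columns
    for seg_id, orient, shift in b.members():
        if orient == Orientation.FORWARD:
            seq = reads[seg_id].sequence
            assert seq[b.anchor - shift : b.anchor - shift + 30] == core


def test_variant_blocks_threshold():
    core = "ACGGATTACCAGGATCCAATTGGCCAATTG"
    reads = [make_segment(core, Origin.TUMOUR, i) for i in range(3)]
    g = build_gsa(reads, include_revcomp=True, min_prefix=30)
    # 3 reads + revcomps: the forward section holds 3 suffixes < amss=4
    blocks = variant_blocks(g, DetectionParams(amss=4))
    assert blocks == []
    blocks = variant_blocks(g, DetectionParams(amss=3))
    assert len(blocks) >= 1


def test_amss_monotonicity(rng):
    segs = random_segments(rng, 30, min_len=30, max_len=45, alphabet=2)
    for s in segs:
        s.origin = Origin.TUMOUR
    g = build_gsa(segs, include_revcomp=True, min_prefix=8)
    prev = None
    for amss in (1, 2, 3, 4, 6):
        got = len(variant_blocks(g, DetectionParams(min_prefix=8, amss=amss)))
        if prev is not None:
            assert got <= prev
        prev = got


# ------------------------------------------------- dual-array recovery


def test_dual_array_strand_fixture(dual_strand_fixture):
    fx = dual_strand_fixture
    params2 = DetectionParams(pmss=2, amss=4)
    params4 = DetectionParams(pmss=4, amss=4)
    g = build_gsa(fx.corpus, min_prefix=30)
    secs = split_sections(g)
    # with pmss=2 the two strand groups are recovered...
    rows2 = extract_block_reads(enriched_sections(secs, params2), g)
    assert sorted(g.corpus.segment_ids[rows2].tolist()) == [0, 1, 2, 3]
    # ...with pmss=4 the disjoint 2-suffix sections all fail
    rows4 = extract_block_reads(enriched_sections(secs, params4), g)
    assert len(rows4) == 0
    # auxiliary array with reverse complements merges both strand groups
    aux = build_gsa(fx.corpus.subset(rows2), include_revcomp=True, min_prefix=30)
    blocks = variant_blocks(aux, params2)
    assert any(b.size >= 4 for b in blocks)


def test_gsa_tsv_dump(tmp_path, rng):
    segs = random_segments(rng, 5, min_len=30, max_len=40)
    g = build_gsa(segs, min_prefix=30)
    out = tmp_path / "gsa.tsv"
    g.to_tsv(str(out))
    lines = out.read_text().splitlines()
    assert lines[0].split("\t") == ["rank", "segment_id", "offset", "origin", "lcp"]
    assert len(lines) == len(g) + 1
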
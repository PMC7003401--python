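"""Paired tumour-control read simulation with implanted SNVs (isolated and
short-range clustered) plus truth bookkeeping and call-set evaluation.

The simulator substitutes a two-level phred model for an empirical error
profile: correctly sequenced bases receive ``phred_high`` (>= the consensus
threshold), error bases receive ``phred_low`` (< threshold) except for a
configurable miscalibrated fraction that keeps ``phred_high`` so downstream
phred filtering is exercised imperfectly.  Paired-end structure is modelled
as independent single-end reads; the caller never uses pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._seq import BASES, decode, encode

__all__ = [
    "SimConfig",
    "TruthSNV",
    "ReadSet",
    "EvalResult",
    "make_reference",
    "implant_variants",
    "simulate_reads",
    "evaluate_calls",
    "write_fastq",
    "write_fasta",
    "write_truth_vcf",
    "read_truth_vcf",
]

_READ_CHUNK = 100_000  # error-mask generation chunk (rows)


@dataclass(frozen=True)
class SimConfig:
    ref_length: int = 200_000
    gc_fraction: float = 0.5
    coverage: float = 30.0
    read_length: int = 100
    per_base_error_rate: float = 5e-4
    phred_high: int = 40
    phred_low: int = 20
    miscalled_high_fraction: float = 0.05
    n_snvs: int = 0
    allele_frequencies: tuple[float, ...] = (0.5,)
    ssrsc_count: int = 0
    ssrsc_k_range: tuple[int, int] = (2, 20)
    ssrsc_window: int = 100
    germline_snp_rate: float = 0.0
    chrom: str = "sim1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ref_length < 1000:
            raise ValueError("ref_length must be >= 1000")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")
        if self.read_length > self.ref_length:
            raise ValueError("read_length cannot exceed ref_length")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        for af in self.allele_frequencies:
            if not 0.0 < af <= 1.0:
                raise ValueError("allele frequencies must lie in (0, 1]")
        klo, khi = self.ssrsc_k_range
        if not 2 <= klo <= khi:
            raise ValueError("ssrsc_k_range must satisfy 2 <= lo <= hi")
        if self.ssrsc_window < 2:
            raise ValueError("ssrsc_window must be >= 2")
        if not 0.0 <= self.per_base_error_rate < 1.0:
            raise ValueError("per_base_error_rate must lie in [0, 1)")


@dataclass(frozen=True)
class TruthSNV:
    chrom: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str
    af: float
    cluster_id: int | None = None

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ValueError("alt must differ from ref")


@dataclass
class ReadSet:
    """Fixed-length reads as (n, L) code/phred matrices, in sequenced
    orientation.  ``start``/``strand`` record simulation provenance."""

    codes: np.ndarray
    phred: np.ndarray
    start: np.ndarray
    strand: np.ndarray
    name_prefix: str = "r"

    @property
    def n_reads(self) -> int:
        return self.codes.shape[0]

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    def sequences(self) -> Iterable[str]:
        for row in self.codes:
            yield decode(row)


def make_reference(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random reference sequence with expected GC fraction ``gc``."""
    if length < 1000:
        raise ValueError("reference length must be >= 1000")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return decode(codes)


def _cycle_afs(afs: Sequence[float], i: int) -> float:
    return float(afs[i % len(afs)])


def implant_variants(
    ref: str, config: SimConfig, rng: np.random.Generator | None = None
) -> list[TruthSNV]:
    """Choose somatic SNV sites: ``n_snvs`` isolated sites plus
    ``ssrsc_count`` clusters of k SNVs inside one ``ssrsc_window``.

    Isolated sites sit >= ssrsc_window from any other variant; clusters are
    separated from all other variants by >= ssrsc_window.  Allele
    frequencies cycle through ``config.allele_frequencies`` (one AF per
    isolated site / per cluster).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    W = config.ssrsc_window
    slot = 3 * W
    margin = config.read_length
    usable = len(ref) - 2 * margin
    n_anchors = config.n_snvs + config.ssrsc_count
    if n_anchors == 0:
        return []
    n_slots = usable // slot
    if n_slots < n_anchors:
        raise ValueError(
            f"reference too short: need {n_anchors} variant slots of "
            f"{slot} bp, have {n_slots}"
        )
    ref_codes = encode(ref)
    chosen = rng.permutation(n_slots)[:n_anchors]
    chosen.sort()
    # interleave isolated sites and clusters deterministically
    kinds = np.array([0] * config.n_snvs + [1] * config.ssrsc_count)
    rng.shuffle(kinds)
    truth: list[TruthSNV] = []
    klo, khi = config.ssrsc_k_range
    iso_i = 0
    clu_i = 0
    for slot_i, kind in zip(chosen.tolist(), kinds.tolist()):
        anchor = margin + slot_i * slot
        if kind == 0:
            pos = anchor + int(rng.integers(0, W))
            af = _cycle_afs(config.allele_frequencies, iso_i)
            alt = int((ref_codes[pos] + rng.integers(1, 4)) % 4)
            truth.append(
                TruthSNV(config.chrom, pos, BASES[ref_codes[pos]], BASES[alt], af)
            )
            iso_i += 1
        else:
            k = int(rng.integers(klo, khi + 1))
            offs = np.sort(rng.choice(W, size=k, replace=False))
            af = _cycle_afs(config.allele_frequencies, clu_i)
            for off in offs.tolist():
                pos = anchor + off
                alt = int((ref_codes[pos] + rng.integers(1, 4)) % 4)
                truth.append(
                    TruthSNV(
                        config.chrom, pos, BASES[ref_codes[pos]], BASES[alt],
                        af, cluster_id=clu_i,
                    )
                )
            clu_i += 1
    truth.sort(key=lambda t: t.pos)
    return truth


def _sample_dataset(
    rng: np.random.Generator,
    ref_codes: np.ndarray,
    config: SimConfig,
    germline: list[tuple[int, int]],
    somatic: list[tuple[int, int, float]],
) -> ReadSet:
    L = config.read_length
    n = int(round(config.coverage * len(ref_codes) / L))
    starts = rng.integers(0, len(ref_codes) - L + 1, size=n, dtype=np.int64)
    starts.sort()  # sorted starts -> fast per-site row lookup; order is
    # irrelevant downstream and keeps determinism
    strand = rng.integers(0, 2, size=n, dtype=np.uint8)
    codes = ref_codes[starts[:, None] + np.arange(L, dtype=np.int64)[None, :]]

    def rows_covering(pos: int) -> np.ndarray:
        lo = np.searchsorted(starts, pos - L + 1, "left")
        hi = np.searchsorted(starts, pos, "right")
        return np.arange(lo, hi)

    # germline heterozygous SNPs: haplotype 1 of 2, per read
    if germline:
        hap = rng.integers(0, 2, size=n, dtype=np.uint8)
        for pos, alt in germline:
            rows = rows_covering(pos)
            rows = rows[hap[rows] == 1]
            codes[rows, pos - starts[rows]] = alt
    # somatic variants: a read reports the tumour haplotype at a covered
    # site with probability equal to the site's allele frequency; one draw
    # per read keeps co-located variants haplotype-consistent
    if somatic:
        u = rng.random(n)
        for pos, alt, af in somatic:
            rows = rows_covering(pos)
            rows = rows[u[rows] < af]
            codes[rows, pos - starts[rows]] = alt

    phred = np.full((n, L), config.phred_high, dtype=np.uint8)
    eps = config.per_base_error_rate
    if eps > 0:
        for lo in range(0, n, _READ_CHUNK):
            hi = min(lo + _READ_CHUNK, n)
            err = rng.random((hi - lo, L)) < eps
            r, c = np.nonzero(err)
            if len(r) == 0:
                continue
            shift = rng.integers(1, 4, size=len(r)).astype(np.uint8)
            codes[lo + r, c] = (codes[lo + r, c] + shift) % 4
            q = np.full(len(r), config.phred_low, dtype=np.uint8)
            high = rng.random(len(r)) < config.miscalled_high_fraction
            q[high] = config.phred_high
            phred[lo + r, c] = q

    # reverse-strand reads are emitted as sequenced (reverse complement)
    rc = np.flatnonzero(strand == 1)
    codes[rc] = 3 - codes[rc, ::-1]
    phred[rc] = phred[rc, ::-1]
    return ReadSet(codes, phred, starts, strand)


def simulate_reads(
    ref: str,
    truth: Sequence[TruthSNV],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ReadSet, ReadSet, list[tuple[int, int]]]:
    """Simulate (tumour, control) read sets plus the shared germline SNP
    list (``(pos, alt_code)`` pairs).  Deterministic for a fixed config."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    ref_codes = encode(ref)
    somatic_pos = {t.pos for t in truth}
    germline: list[tuple[int, int]] = []
    if config.germline_snp_rate > 0:
        n_snp = rng.binomial(len(ref_codes), config.germline_snp_rate)
        cand = rng.choice(len(ref_codes), size=n_snp, replace=False)
        for pos in sorted(int(p) for p in cand):
            if pos in somatic_pos:
                continue
            alt = int((ref_codes[pos] + rng.integers(1, 4)) % 4)
            germline.append((pos, alt))
    somatic = [(t.pos, BASES.index(t.alt_base), t.af) for t in truth]
    tumour = _sample_dataset(rng, ref_codes, config, germline, somatic)
    tumour.name_prefix = "t"
    control = _sample_dataset(rng, ref_codes, config, germline, [])
    control.name_prefix = "c"
    return tumour, control, germline


# ---------------------------------------------------------------- metrics


@dataclass
class EvalResult:
    precision: float
    recall: float
    hits: int
    fp: int
    fn: int
    k_recall: dict[int, float] = field(default_factory=dict)
    k_precision: dict[int, float] = field(default_factory=dict)
    k_hits: dict[int, int] = field(default_factory=dict)
    k_total: dict[int, int] = field(default_factory=dict)
    k_fp: dict[int, int] = field(default_factory=dict)
    precision_defined: bool = True

    def pooled_k_recall(self, k_min: int) -> float:
        """hits/total pooled over all cluster sizes >= k_min."""
        tot = sum(v for k, v in self.k_total.items() if k >= k_min)
        hit = sum(v for k, v in self.k_hits.items() if k >= k_min)
        return hit / tot if tot else 0.0


def _cluster_calls(
    positions: Sequence[int], window: int
) -> list[list[int]]:
    """Greedy left-to-right chaining: a call joins the open cluster while it
    lies within ``window`` of the cluster's first member."""
    out: list[list[int]] = []
    cur: list[int] = []
    cur_anchor = None
    for i, p in enumerate(positions):
        if cur_anchor is None or p - cur_anchor >= window:
            if cur:
                out.append(cur)
            cur = [i]
            cur_anchor = p
        else:
            cur.append(i)
    if cur:
        out.append(cur)
    return out


def evaluate_calls(
    calls: Sequence[tuple[str, int, str, str]],
    truth: Sequence[TruthSNV],
    window: int = 100,
) -> EvalResult:
    """Score a call set against truth.

    A call is a hit iff ``(chrom, pos, alt)`` matches a truth record
    exactly.  ``k_recall[k] = k_hits / k_total`` counts detected SNVs in
    truth clusters of size k; ``k_precision[k] = k_hits / (k_fp + k_hits)``
    where ``k_fp`` counts false-positive calls falling inside genuine
    k-cluster spans plus the members of reported k-clusters composed
    entirely of false positives.
    """
    truth_key = {(t.chrom, t.pos, t.alt_base): t for t in truth}
    seen = set()
    hits = 0
    fp_calls: list[tuple[str, int, str, str]] = []
    hit_truth: set[tuple[str, int, str]] = set()
    for call in calls:
        key = (call[0], call[1], call[3])
        if key in seen:
            continue
        seen.add(key)
        if key in truth_key:
            hits += 1
            hit_truth.add(key)
        else:
            fp_calls.append(call)
    fp = len(fp_calls)
    fn = len(truth) - hits
    precision_defined = (hits + fp) > 0
    precision = hits / (hits + fp) if precision_defined else 0.0
    recall = hits / (hits + fn) if truth else 0.0

    # --- cluster-size-stratified metrics
    clusters: dict[tuple[str, int], list[TruthSNV]] = {}
    for t in truth:
        if t.cluster_id is not None:
            clusters.setdefault((t.chrom, t.cluster_id), []).append(t)
    k_total: dict[int, int] = {}
    k_hits: dict[int, int] = {}
    k_fp: dict[int, int] = {}
    cluster_spans: list[tuple[str, int, int, int]] = []  # chrom, lo, hi, k
    for members in clusters.values():
        k = len(members)
        k_total[k] = k_total.get(k, 0) + k
        det = sum(
            1 for m in members if (m.chrom, m.pos, m.alt_base) in hit_truth
        )
        k_hits[k] = k_hits.get(k, 0) + det
        lo = min(m.pos for m in members)
        hi = max(m.pos for m in members)
        cluster_spans.append((members[0].chrom, lo, hi, k))
    # false positives inside genuine k-cluster spans
    for call in fp_calls:
        for chrom, lo, hi, k in cluster_spans:
            if call[0] == chrom and lo <= call[1] <= hi:
                k_fp[k] = k_fp.get(k, 0) + 1
                break
    # reported clusters made entirely of false positives
    by_chrom: dict[str, list[tuple[int, bool]]] = {}
    for call in calls:
        key = (call[0], call[1], call[3])
        by_chrom.setdefault(call[0], []).append((call[1], key in truth_key))
    for chrom, items in by_chrom.items():
        items = sorted(set(items))
        positions = [p for p, _ in items]
        for idx_cluster in _cluster_calls(positions, window):
            if len(idx_cluster) < 2:
                continue
            if all(not items[i][1] for i in idx_cluster):
                k = len(idx_cluster)
                k_fp[k] = k_fp.get(k, 0) + k
    k_recall = {k: k_hits.get(k, 0) / k_total[k] for k in k_total}
    k_precision = {
        k: (
            k_hits.get(k, 0) / (k_fp.get(k, 0) + k_hits.get(k, 0))
            if (k_fp.get(k, 0) + k_hits.get(k, 0))
            else 0.0
        )
        for k in set(k_total) | set(k_fp)
    }
    return EvalResult(
        precision, recall, hits, fp, fn,
        k_recall, k_precision, k_hits, k_total, k_fp, precision_defined,
    )


# ---------------------------------------------------------------- file IO


def write_fasta(path: str, name: str, seq: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def write_fastq(path: str, reads: ReadSet) -> None:
    with open(path, "w") as fh:
        for i in range(reads.n_reads):
            seq = decode(reads.codes[i])
            qual = (reads.phred[i] + 33).tobytes().decode("ascii")
            fh.write(f"@{reads.name_prefix}{i}\n{seq}\n+\n{qual}\n")


def write_truth_vcf(path: str, truth: Sequence[TruthSNV], contig: str,
                    contig_length: int) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={contig_length}>\n")
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Allele frequency">\n')
        fh.write('##INFO=<ID=CLUSTER,Number=1,Type=Integer,Description="Cluster label">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for t in sorted(truth, key=lambda t: (t.chrom, t.pos)):
            info = f"AF={t.af:g}"
            if t.cluster_id is not None:
                info += f";CLUSTER={t.cluster_id}"
            fh.write(
                f"{t.chrom}\t{t.pos + 1}\t.\t{t.ref_base}\t{t.alt_base}\t.\tPASS\t{info}\n"
            )


def read_truth_vcf(path: str) -> list[TruthSNV]:
    out: list[TruthSNV] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, _q, _f, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(
                kv.split("=", 1) for kv in info.split(";") if "=" in kv
            )
            out.append(
                TruthSNV(
                    chrom,
                    int(pos) - 1,
                    ref,
                    alt,
                    float(fields.get("AF", 1.0)),
                    int(fields["CLUSTER"]) if "CLUSTER" in fields else None,
                )
            )
    return out
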
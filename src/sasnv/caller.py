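"""SNV calling from filtered consensus pairs: map the control consensus to
the reference, compare the (masked) tumour consensus against it, compute
each variant's reference coordinate as ``mu = m + i`` and emit VCF.

``i`` is the 0-based index of the mismatch column in the control
consensus's own frame (the only reading that stays exact when T and C
start at different columns); ``m`` is C's 0-based leftmost mapping
coordinate.  Emitted VCF positions are 1-based (``mu + 1``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._seq import BASES, revcomp_codes
from .consensus import ConsensusPair
from .reference import MappingResult, ReferenceIndex

__all__ = [
    "SNVCall",
    "map_control",
    "call_snvs",
    "merge_calls",
    "write_vcf",
    "read_calls_vcf",
]

DEFAULT_MIN_ALT_SUPPORT = 4


@dataclass
class SNVCall:
    chrom: str
    mu: int  # 0-based reference coordinate
    ref_base: str
    alt_base: str
    support: int = 1
    multiallelic: bool = False

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.mu, self.ref_base, self.alt_base)


def map_control(
    c_codes: np.ndarray,
    index: ReferenceIndex,
    max_mismatches: int = 5,
) -> MappingResult | None:
    """Gapless best placement of the control consensus on the reference;
    ambiguous (tied) placements map to None and the pair is skipped."""
    return index.map_gapless(np.asarray(c_codes, dtype=np.uint8), max_mismatches)


def call_snvs(
    pair: ConsensusPair,
    mapping: MappingResult,
    masked_t: np.ndarray | None = None,
    min_alt_support: int = DEFAULT_MIN_ALT_SUPPORT,
) -> list[SNVCall]:
    """Single-character T/C mismatches over the jointly covered columns.

    On a minus-strand mapping both consensus sequences are
    reverse-complemented first so that ``i`` counts along the forward
    genome.  A mismatch is reported only when the tumour frequency matrix
    supports the tumour base with >= ``min_alt_support`` phred-filtered
    reads at that column.
    """
    t = pair.t_codes if masked_t is None else masked_t
    c = pair.c_codes
    ft = pair.ft
    offset = pair.offset_tc
    if mapping.strand == "-":
        t = revcomp_codes(t)
        c = revcomp_codes(c)
        ft = ft.reverse_complement()
        offset = len(pair.t_codes) - len(pair.c_codes) - pair.offset_tc
        # note: len(t) unchanged by masking, so offsets stay valid
    calls: list[SNVCall] = []
    # C frame indices covered by T: c_idx = t_idx - offset
    lo = max(0, offset)
    hi = min(len(t), offset + len(c))
    if hi <= lo:
        return calls
    t_seg = t[lo:hi]
    c_seg = c[lo - offset : hi - offset]
    for j in np.flatnonzero(t_seg != c_seg).tolist():
        t_idx = lo + j
        i = t_idx - offset
        alt = int(t_seg[j])
        if int(ft.counts[alt, t_idx]) < min_alt_support:
            continue
        calls.append(
            SNVCall(
                chrom=mapping.chrom,
                mu=mapping.m + i,
                ref_base=BASES[int(c_seg[j])],
                alt_base=BASES[alt],
            )
        )
    return calls


def merge_calls(calls: Sequence[SNVCall]) -> list[SNVCall]:
    """Merge identical (chrom, mu, ref, alt) records, summing support;
    conflicting alts at one site are kept and flagged multiallelic.
    Output sorted by (chrom, mu, ref, alt)."""
    merged: dict[tuple, SNVCall] = {}
    for call in calls:
        key = call.key()
        if key in merged:
            merged[key].support += call.support
        else:
            merged[key] = SNVCall(*key, support=call.support)
    out = sorted(merged.values(), key=lambda c: c.key())
    by_site: dict[tuple[str, int], int] = {}
    for c in out:
        by_site[(c.chrom, c.mu)] = by_site.get((c.chrom, c.mu), 0) + 1
    for c in out:
        if by_site[(c.chrom, c.mu)] > 1:
            c.multiallelic = True
    return out


def write_vcf(
    path: str,
    calls: Sequence[SNVCall],
    contigs: Mapping[str, int],
    params: Mapping[str, object] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sasnv\n")
        if params:
            kv = ",".join(f"{k}={v}" for k, v in sorted(params.items()))
            fh.write(f"##sasnv_params={kv}\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            '##INFO=<ID=SUPPORT,Number=1,Type=Integer,'
            'Description="Consensus pairs reporting the call">\n'
        )
        fh.write(
            '##INFO=<ID=MULTIALLELIC,Number=0,Type=Flag,'
            'Description="Another alt allele was called at this site">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = f"SUPPORT={c.support}"
            if c.multiallelic:
                info += ";MULTIALLELIC"
            fh.write(
                f"{c.chrom}\t{c.mu + 1}\t.\t{c.ref_base}\t{c.alt_base}\t.\tPASS\t{info}\n"
            )


def read_calls_vcf(path: str) -> list[SNVCall]:
    out: list[SNVCall] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, _q, _f, info = line.rstrip("\n").split("\t")[:8]
            support = 1
            for kv in info.split(";"):
                if kv.startswith("SUPPORT="):
                    support = int(kv.split("=", 1)[1])
            out.append(SNVCall(chrom, int(pos) - 1, ref, alt, support,
                               "MULTIALLELIC" in info))
    return out
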
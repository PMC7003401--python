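"""Reference genome k-mer index: exact full-read containment queries (for
the exact-match prefilter) and gapless seed-and-extend mapping of control
consensus sequences.  This is the built-in backend of the pluggable aligner
interface; an external aligner can replace it by matching the two public
method contracts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._seq import encode, pack_kmers, pack_kmers_at, revcomp_codes, revcomp_keys
from .gsa import SegmentCorpus

__all__ = ["MappingResult", "ReferenceIndex"]

SEED_K = 30


@dataclass(frozen=True)
class MappingResult:
    chrom: str
    m: int  # 0-based leftmost reference coordinate of the aligned sequence
    strand: str  # '+' or '-'
    mismatches: int
    unique: bool = True


class ReferenceIndex:
    def __init__(self, contigs: Sequence[tuple[str, str | np.ndarray]],
                 seed_k: int = SEED_K):
        self.names = [n for n, _ in contigs]
        seqs = [encode(s) if isinstance(s, str) else np.asarray(s, np.uint8)
                for _, s in contigs]
        self.k = seed_k
        lengths = np.array([len(s) for s in seqs], dtype=np.int64)
        self.bounds = np.zeros(len(seqs) + 1, dtype=np.int64)
        np.cumsum(lengths, out=self.bounds[1:])
        self.codes = (np.concatenate(seqs) if seqs
                      else np.empty(0, np.uint8))
        # seed positions whose k-mer window stays inside one contig
        pos_parts = [
            np.arange(self.bounds[i], self.bounds[i + 1] - seed_k + 1)
            for i in range(len(seqs))
            if lengths[i] >= seed_k
        ]
        pos = (np.concatenate(pos_parts) if pos_parts
               else np.empty(0, np.int64))
        if len(self.codes) >= seed_k:
            keys = pack_kmers(self.codes, seed_k)[pos]
        else:
            keys = np.empty(0, np.uint64)
        order = np.argsort(keys, kind="stable")
        self._keys = keys[order]
        self._pos = pos[order]

    # ------------------------------------------------------------------
    def contig_of(self, gpos: int) -> tuple[int, int]:
        idx = int(np.searchsorted(self.bounds, gpos, "right")) - 1
        return idx, int(gpos - self.bounds[idx])

    def _seed_positions(self, keys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self._keys, keys, "left")
        hi = np.searchsorted(self._keys, keys, "right")
        counts = hi - lo
        total = int(counts.sum())
        src = np.repeat(np.arange(len(keys), dtype=np.int64), counts)
        cum = np.zeros(len(keys) + 1, dtype=np.int64)
        np.cumsum(counts, out=cum[1:])
        flat = np.repeat(lo, counts) + (
            np.arange(total, dtype=np.int64) - np.repeat(cum[:-1], counts)
        )
        return self._pos[flat], src

    def _candidate_starts(self, codes: np.ndarray) -> np.ndarray:
        """Global positions where a full gapless alignment of ``codes``
        could start, from every seed k-mer hit (deduplicated, in-bounds,
        single-contig)."""
        if len(codes) < self.k:
            return np.empty(0, np.int64)
        qkeys = pack_kmers(codes, self.k)
        gpos, q = self._seed_positions(qkeys)
        starts = gpos - q
        if len(starts) == 0:
            return starts
        starts = np.unique(starts)
        cidx = np.searchsorted(self.bounds, starts, "right") - 1
        ok = (starts >= self.bounds[cidx]) & (
            starts + len(codes) <= self.bounds[cidx + 1]
        )
        return starts[ok]

    def _mismatch_counts(self, codes: np.ndarray, starts: np.ndarray) -> np.ndarray:
        out = np.empty(len(starts), dtype=np.int64)
        for i, s in enumerate(starts.tolist()):
            out[i] = int((self.codes[s : s + len(codes)] != codes).sum())
        return out

    # ------------------------------------------------------------------
    def _verify_exact(self, probe: np.ndarray, start: int) -> bool:
        cidx = int(np.searchsorted(self.bounds, start, "right")) - 1
        if start < self.bounds[cidx] or start + len(probe) > self.bounds[cidx + 1]:
            return False
        return bool(np.array_equal(self.codes[start : start + len(probe)], probe))

    def exact_match_mask(self, corpus: SegmentCorpus) -> np.ndarray:
        """Per-row mask: read occurs exactly (full-length, gapless, either
        strand) within a single reference contig.

        Only reads whose leading k-mer (forward read, or forward-genome
        k-mer of the reverse complement) hits the seed index are verified
        base-by-base, so reads carrying any variation stay cheap.
        """
        n = corpus.n_segments
        mask = np.zeros(n, dtype=bool)
        if n == 0 or len(self.codes) < self.k:
            return mask
        lengths = corpus.lengths
        rows_ok = np.flatnonzero(lengths >= self.k)
        if len(rows_ok) == 0:
            return mask
        fwd_first = pack_kmers_at(corpus.codes, corpus.starts[rows_ok], self.k)
        # first k-mer of the reverse complement == revcomp of the tail k-mer
        tail = pack_kmers_at(
            corpus.codes, corpus.starts[rows_ok + 1] - self.k, self.k
        )
        rc_first = revcomp_keys(tail, self.k)
        uniform = len(np.unique(lengths)) == 1
        for keys, is_rc in ((fwd_first, False), (rc_first, True)):
            lo = np.searchsorted(self._keys, keys, "left")
            hi = np.searchsorted(self._keys, keys, "right")
            hit = np.flatnonzero((hi > lo) & ~mask[rows_ok])
            if uniform and len(hit):
                # batch-verify the first candidate of every hit; the seed
                # k-mer is nearly always locus-unique so this resolves the
                # vast majority in one vectorised comparison
                L = int(lengths[rows_ok[0]])
                rows = rows_ok[hit]
                probes = corpus.codes[
                    corpus.starts[rows][:, None] + np.arange(L, dtype=np.int64)
                ]
                if is_rc:
                    probes = 3 - probes[:, ::-1]
                starts = self._pos[lo[hit]]
                cidx = np.searchsorted(self.bounds, starts, "right") - 1
                in_bounds = starts + L <= self.bounds[cidx + 1]
                ok = np.zeros(len(hit), dtype=bool)
                ib = np.flatnonzero(in_bounds)
                if len(ib):
                    ref_win = self.codes[
                        starts[ib][:, None] + np.arange(L, dtype=np.int64)
                    ]
                    ok[ib] = (ref_win == probes[ib]).all(axis=1)
                mask[rows[ok]] = True
                # slow path: first candidate failed but others exist
                rest = np.flatnonzero(~ok & (hi[hit] - lo[hit] > 1))
            else:
                rest = np.arange(len(hit))
            for j in rest.tolist():
                i = int(hit[j])
                r = int(rows_ok[i])
                if mask[r]:
                    continue
                codes = corpus.seg_codes(r)
                probe = revcomp_codes(codes) if is_rc else codes
                for s in self._pos[lo[i] : hi[i]].tolist():
                    if self._verify_exact(probe, int(s)):
                        mask[r] = True
                        break
        return mask

    def map_gapless(
        self, codes: np.ndarray, max_mismatches: int = 5
    ) -> MappingResult | None:
        """Best gapless placement of ``codes`` on either strand: fewest
        mismatches wins, ties are ambiguous (None), mismatch count must not
        exceed ``max_mismatches``."""
        candidates: list[tuple[int, int, str]] = []  # (mismatches, gpos, strand)
        for strand, probe in (("+", codes), ("-", revcomp_codes(codes))):
            starts = self._candidate_starts(probe)
            if len(starts):
                mm = self._mismatch_counts(probe, starts)
                for s, m in zip(starts.tolist(), mm.tolist()):
                    candidates.append((m, s, strand))
        if not candidates:
            return None
        candidates.sort()
        best = candidates[0]
        if best[0] > max_mismatches:
            return None
        if len(candidates) > 1 and candidates[1][0] == best[0]:
            return None  # ambiguous placement
        cidx, local = self.contig_of(best[1])
        return MappingResult(self.names[cidx], local, best[2], best[0])
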
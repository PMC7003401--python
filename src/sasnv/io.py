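"""FASTQ/FASTA ingestion (gz-transparent) built on Biopython's fast
low-level parsers."""

from __future__ import annotations

import gzip
from typing import IO, Iterator

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .gsa import Origin, SegmentCorpus
from .preprocess import MIN_SEGMENT_LEN, segments_from_reads

__all__ = ["open_text", "read_fasta", "read_fastq_corpus"]


def open_text(path: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str) -> list[tuple[str, str]]:
    with open_text(path) as fh:
        records = [(name.split()[0], seq.upper()) for name, seq in SimpleFastaParser(fh)]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def _fastq_records(path: str) -> Iterator[tuple[str, str, np.ndarray]]:
    with open_text(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            phred = np.frombuffer(qual.encode("ascii"), dtype=np.uint8) - 33
            yield title.split()[0], seq, phred


def read_fastq_corpus(
    path: str, origin: Origin, min_len: int = MIN_SEGMENT_LEN, id_start: int = 0
) -> SegmentCorpus:
    """Read a FASTQ file into an N-split segment corpus."""
    segments = segments_from_reads(_fastq_records(path), origin, min_len, id_start)
    if not segments:
        # empty corpus with the right dtypes
        z = np.zeros(0, dtype=np.int64)
        return SegmentCorpus(
            np.zeros(0, np.uint8), np.zeros(1, np.int64), np.zeros(0, np.uint8),
            np.zeros(0, np.uint8), np.zeros(0, np.uint8), z, [],
        )
    return SegmentCorpus.from_segments(segments)
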
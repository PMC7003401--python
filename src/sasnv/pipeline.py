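"""End-to-end orchestration of the five calling stages:
preprocessing -> suffix-array SNV detection -> consensus pairs ->
filtering -> coordinate calling.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import caller as caller_mod
from . import consensus as cons
from . import filters as filt
from .caller import SNVCall, merge_calls
from .gsa import (
    DetectionParams,
    Origin,
    SegmentCorpus,
    build_gsa,
    enriched_sections,
    extract_block_reads,
    split_sections,
    variant_blocks,
)
from .preprocess import exact_match_filter
from .reference import ReferenceIndex
from .simulate import ReadSet

__all__ = ["PipelineConfig", "RunReport", "run_caller", "corpus_from_readset"]

logger = logging.getLogger("sasnv.pipeline")


class _StageTimer:
    def __init__(self) -> None:
        self.t = time.perf_counter()

    def lap(self, stage: str) -> None:
        now = time.perf_counter()
        logger.debug("stage %-18s %6.1fs", stage, now - self.t)
        self.t = now


@dataclass(frozen=True)
class PipelineConfig:
    detection: DetectionParams = field(default_factory=DetectionParams)
    filters: filt.FilterParams = field(default_factory=filt.FilterParams)
    phred_threshold: int = cons.DEFAULT_PHRED_THRESHOLD
    min_alt_support: int = caller_mod.DEFAULT_MIN_ALT_SUPPORT
    max_mismatches: int = 5
    emfilter: bool = False
    gsa_backend: str = "auto"


@dataclass
class RunReport:
    tumour_reads_in: int = 0
    tumour_reads_kept: int = 0
    emfilter_discarded: int = 0
    control_reads: int = 0
    primary_suffixes: int = 0
    sections: int = 0
    enriched: int = 0
    extracted_reads: int = 0
    blocks: int = 0
    blocks_deduped: int = 0
    pairs: int = 0
    pairs_no_mismatch: int = 0
    discarded_no_control: int = 0
    discarded_indel: int = 0
    discarded_multilocus: int = 0
    discarded_unmapped: int = 0
    calls: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def corpus_from_readset(reads: ReadSet, origin: Origin, id_offset: int = 0) -> SegmentCorpus:
    return SegmentCorpus.from_matrix(reads.codes, reads.phred, origin, id_offset)


def run_caller(
    tumour: SegmentCorpus,
    control: SegmentCorpus,
    contigs: Sequence[tuple[str, str]],
    config: PipelineConfig = PipelineConfig(),
    index: ReferenceIndex | None = None,
) -> tuple[list[SNVCall], RunReport]:
    """Run the full caller over preprocessed (N-free) tumour and control
    corpora against ``contigs``; returns merged calls plus stage counts."""
    report = RunReport(
        tumour_reads_in=tumour.n_segments, control_reads=control.n_segments
    )
    timer = _StageTimer()
    if index is None:
        index = ReferenceIndex(contigs)
        timer.lap("reference_index")

    if config.emfilter:
        tumour, n_discarded = exact_match_filter(tumour, index)
        report.emfilter_discarded = n_discarded
        timer.lap("emfilter")
    report.tumour_reads_kept = tumour.n_segments

    combined = SegmentCorpus.concatenate([tumour, control])
    # make segment ids unique across the two origins
    combined.segment_ids = np.arange(combined.n_segments, dtype=np.int64)

    params = config.detection
    primary = build_gsa(
        combined, include_revcomp=False, min_prefix=params.min_prefix,
        backend=config.gsa_backend,
    )
    report.primary_suffixes = len(primary)
    timer.lap("primary_gsa")
    sections = split_sections(primary)
    report.sections = len(sections)
    enriched = enriched_sections(sections, params)
    report.enriched = len(enriched)
    rows = extract_block_reads(enriched, primary)
    report.extracted_reads = len(rows)
    timer.lap("sections")

    calls: list[SNVCall] = []
    if len(rows):
        aux_corpus = combined.subset(rows)
        aux = build_gsa(
            aux_corpus, include_revcomp=True, min_prefix=params.min_prefix,
            backend=config.gsa_backend,
        )
        blocks = variant_blocks(aux, params)
        report.blocks = len(blocks)
        blocks = cons.dedupe_blocks(blocks)
        report.blocks_deduped = len(blocks)
        timer.lap("blocks")

        for block in blocks:
            pair = cons.assemble_pair(block, primary, config.phred_threshold)
            if pair is None:
                report.discarded_no_control += 1
                continue
            report.pairs += 1
            lo, hi = pair.overlap()
            if hi <= lo or np.array_equal(
                pair.t_codes[lo:hi],
                pair.c_codes[lo - pair.offset_tc : hi - pair.offset_tc],
            ):
                # no T/C mismatch: filters can only mask or discard and the
                # support rule only removes, so this pair cannot produce a
                # call -- skip the filter/mapping work (output-preserving)
                report.pairs_no_mismatch += 1
                continue
            if not filt.indel_filter(pair, config.filters):
                report.discarded_indel += 1
                logger.debug("pair %d discarded: INDEL", report.pairs)
                continue
            mask = filt.masking_filter(pair, config.filters)
            if not filt.multi_locus_filter(pair, config.filters):
                report.discarded_multilocus += 1
                logger.debug(
                    "pair %d discarded: MULTILOCUS (%d events)",
                    report.pairs, pair.masking_events,
                )
                continue
            mapping = caller_mod.map_control(
                pair.c_codes, index, config.max_mismatches
            )
            if mapping is None:
                report.discarded_unmapped += 1
                logger.debug("pair %d discarded: UNMAPPED_OR_AMBIGUOUS",
                             report.pairs)
                continue
            calls.extend(
                caller_mod.call_snvs(
                    pair, mapping, mask.masked_t, config.min_alt_support
                )
            )
        timer.lap("pairs")
    merged = merge_calls(calls)
    report.calls = len(merged)
    return merged, report
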
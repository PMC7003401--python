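"""Desk-scale replicas of the two simulation experiments used for
validation: the rare-SNV allele-frequency series and the clustered-SNV
(sSRSC) benchmark.  Shared between the test suite and the acceptance
report script.
"""

from __future__ import annotations

import gc
import logging
from dataclasses import dataclass, field

from .gsa import DetectionParams, Origin
from .pipeline import PipelineConfig, corpus_from_readset, run_caller
from .simulate import (
    EvalResult,
    SimConfig,
    evaluate_calls,
    implant_variants,
    make_reference,
    simulate_reads,
)

logger = logging.getLogger("sasnv.experiments")

# mean allele frequencies of the targeted deep-sequencing series, from 50%
# down to below 1% (the "<1%" dataset uses 0.5%)
RARE_SNV_AFS = (0.50, 0.25, 0.10, 0.05, 0.02, 0.01, 0.005)


def rare_snv_config(af: float, seed: int) -> SimConfig:
    return SimConfig(
        ref_length=200_000,
        coverage=500,
        read_length=100,
        n_snvs=40,
        allele_frequencies=(af,),
        per_base_error_rate=5e-4,
        germline_snp_rate=5e-4,
        seed=seed,
    )


def ssrsc_config(seed: int) -> SimConfig:
    return SimConfig(
        ref_length=1_000_000,
        coverage=30,
        read_length=100,
        n_snvs=0,
        ssrsc_count=50,
        ssrsc_k_range=(2, 20),
        ssrsc_window=100,
        allele_frequencies=(0.5,),
        per_base_error_rate=5e-4,
        germline_snp_rate=5e-4,
        seed=seed,
    )


def _pipeline_config(pmss: int) -> PipelineConfig:
    return PipelineConfig(
        detection=DetectionParams(pmss=pmss), emfilter=True
    )


@dataclass
class DatasetResult:
    af: float
    seed: int
    truth_count: int
    by_pmss: dict[int, EvalResult] = field(default_factory=dict)


def run_simulated_dataset(
    cfg: SimConfig, pmss_values: tuple[int, ...] = (2,)
) -> DatasetResult:
    """Simulate one paired dataset and run the caller once per pMSS value
    (the simulation is shared across runs)."""
    ref = make_reference(cfg.ref_length, cfg.gc_fraction, cfg.seed)
    truth = implant_variants(ref, cfg)
    tumour, control, _ = simulate_reads(ref, truth, cfg)
    t_corpus = corpus_from_readset(tumour, Origin.TUMOUR)
    c_corpus = corpus_from_readset(control, Origin.CONTROL)
    result = DatasetResult(
        af=cfg.allele_frequencies[0], seed=cfg.seed, truth_count=len(truth)
    )
    for pmss in pmss_values:
        calls, report = run_caller(
            t_corpus, c_corpus, [(cfg.chrom, ref)], _pipeline_config(pmss)
        )
        result.by_pmss[pmss] = evaluate_calls(
            [(c.chrom, c.mu, c.ref_base, c.alt_base) for c in calls],
            truth,
            window=cfg.ssrsc_window,
        )
        logger.info(
            "af=%g seed=%d pmss=%d: hits=%d fp=%d fn=%d",
            result.af, cfg.seed, pmss,
            result.by_pmss[pmss].hits,
            result.by_pmss[pmss].fp,
            result.by_pmss[pmss].fn,
        )
    del tumour, control, t_corpus, c_corpus
    gc.collect()
    return result


def rare_snv_experiment(
    seed_base: int = 1, low_af_pmss4: bool = True
) -> list[DatasetResult]:
    """The allele-frequency series: one dataset per mean AF, seeds
    ``seed_base .. seed_base+6``, called with defaults (pMSS=2) and -- for
    the AF <= 1% datasets -- additionally with pMSS=4."""
    out = []
    for i, af in enumerate(RARE_SNV_AFS):
        pmss_values: tuple[int, ...] = (2,)
        if low_af_pmss4 and af <= 0.01:
            pmss_values = (2, 4)
        cfg = rare_snv_config(af, seed_base + i)
        out.append(run_simulated_dataset(cfg, pmss_values))
    return out


def ssrsc_experiment(seed: int = 11) -> DatasetResult:
    return run_simulated_dataset(ssrsc_config(seed), (2,))


def pooled_precision(results: list[DatasetResult], pmss: int = 2) -> float:
    hits = sum(r.by_pmss[pmss].hits for r in results)
    fp = sum(r.by_pmss[pmss].fp for r in results)
    return hits / (hits + fp) if hits + fp else 0.0


def pooled_recall(results: list[DatasetResult], pmss: int) -> float:
    hits = sum(r.by_pmss[pmss].hits for r in results)
    total = sum(r.truth_count for r in results)
    return hits / total if total else 0.0
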
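"""End-to-end synthetic study: simulate -> map -> quantify -> call responders.

Ties the modules together the way the study analysed its data, and scores
the run against the simulator's ground truth (UPR-gene sensitivity, false
responder rate among well-expressed null genes, read-placement recovery,
expression rank recovery).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import TranscriptModel
from .config import SimulationConfig
from .diffexpr import (DEFAULT_CUTOFF, LogRatioResult, combine_replicates,
                       compare, estimate_noise, geneset_overlap,
                       quantile_normalize)
from .quantify import ExpressionMatrix, build_matrix, quantify_sample
from .splitmap import build_suffix_index, map_reads
from .synthdata import (GroundTruth, make_reference, simulate_reads,
                        simulate_true_expression)


@dataclass
class StudyResult:
    matrix: ExpressionMatrix            # raw median-coverage expression
    normalized: ExpressionMatrix
    nu: float
    comparisons: dict[str, list[LogRatioResult]]
    mapping_stats: dict[str, dict]
    truth: GroundTruth
    upr_sensitivity: float
    null_responder_rate: float
    expression_spearman: float
    ethanol_induced: set[str]
    tg_induced: set[str]


def _eligible_true_origin(truth: GroundTruth, models: list[TranscriptModel],
                          config: SimulationConfig) -> dict[str, np.ndarray]:
    """Per sample: which reads have all three parts inside single exons."""
    by_tid = {m.transcript_id: m for m in models}
    p = config.part_length
    out = {}
    for sample, org in truth.read_origins.items():
        ok = np.zeros(len(org["offset"]), dtype=bool)
        for i, (ti, off) in enumerate(zip(org["transcript_idx"], org["offset"])):
            m = by_tid[truth.transcripts[ti]]
            good = True
            for j in range(3):
                a = int(off) + config.trim + j * p
                b = a + p - 1
                if m.block_of(a) != m.block_of(b):
                    good = False
                    break
            ok[i] = good
        out[sample] = ok
    return out


def expected_left_coordinate(model: TranscriptModel, offset: int,
                             trim: int) -> int:
    """Genomic coordinate of the first trimmed base of a read at this offset."""
    return model.to_genomic(offset + trim)


def run_study(config: SimulationConfig,
              cutoff: float = DEFAULT_CUTOFF,
              max_gap: int = 100_000) -> StudyResult:
    genome, models = make_reference(config)
    expr_truth = simulate_true_expression(config, [m.gene_id for m in models])
    reads, truth = simulate_reads(genome, models, expr_truth.true_expression,
                                  config)
    truth.upr_genes = expr_truth.upr_genes
    truth.noise_genes = expr_truth.noise_genes

    index = build_suffix_index(genome)
    chrom_lengths = {name: len(seq) for name, seq in genome.items()}

    per_sample = {}
    mapping_stats = {}
    for sample, rs in reads.items():
        table, stats = map_reads(index, rs.codes, max_gap=max_gap,
                                 trim=config.trim)
        mapping_stats[sample] = stats
        per_sample[sample] = quantify_sample(table, models, chrom_lengths)

    matrix = build_matrix(per_sample, truth.metadata)
    normalized = quantile_normalize(matrix)
    nu = estimate_noise(normalized).nu
    comparisons = compare(normalized, nu, cutoff=cutoff)

    # --- truth scoring ---
    # "well-expressed" null genes sit clearly above the noise floor: true
    # expression at least 3x the noise-gene scale. Genes below that are the
    # population the nu-regularization is designed to silence, not the
    # population the cutoff's specificity is judged on.
    upr = truth.upr_genes
    floor = 3.0 * float(np.exp(config.noise_meanlog))
    baseline_level = truth.true_expression[
        [s for s, c in zip(truth.metadata.index, truth.metadata["condition"])
         if c == "control"]
    ].mean(axis=1)
    well_expressed_null = {
        g for g in matrix.values.index
        if g not in upr and g not in truth.noise_genes
        and baseline_level[g] >= floor
    }
    sens_hits = total_upr = 0
    null_hits = total_null = 0
    for results in comparisons.values():
        for r in results:
            if r.gene_id in upr:
                total_upr += 1
                sens_hits += r.responder and r.direction == "up"
            elif r.gene_id in well_expressed_null:
                total_null += 1
                null_hits += r.responder
    sensitivity = sens_hits / total_upr if total_upr else float("nan")
    null_rate = null_hits / total_null if total_null else float("nan")

    true_mean = truth.true_expression.mean(axis=1)
    est_mean = matrix.values.mean(axis=1).reindex(true_mean.index)
    positive = true_mean > 0
    rho = float(sps.spearmanr(true_mean[positive], est_mean[positive]).statistic)

    ethanol_sets = [
        {r.gene_id for r in results if r.responder and r.direction == "up"}
        for label, results in comparisons.items() if label.startswith("etoh")
    ]
    ethanol_induced = combine_replicates(ethanol_sets, mode="all")
    tg_induced = set()
    for label, results in comparisons.items():
        if label.startswith("tg"):
            tg_induced = {r.gene_id for r in results
                          if r.responder and r.direction == "up"}

    return StudyResult(
        matrix=matrix, normalized=normalized, nu=nu, comparisons=comparisons,
        mapping_stats=mapping_stats, truth=truth,
        upr_sensitivity=float(sensitivity),
        null_responder_rate=float(null_rate),
        expression_spearman=rho,
        ethanol_induced=ethanol_induced, tg_induced=tg_induced,
    )


def upr_overlap_counts(result: StudyResult) -> dict[str, int]:
    """UPR gene-set members induced by ethanol, by the transgene, and both."""
    upr = result.truth.upr_genes
    eth = result.ethanol_induced & upr
    tg = result.tg_induced & upr
    return {
        "ethanol_induced": len(eth),
        "tg_induced": len(tg),
        "intersection": len(eth & tg),
    }


def placement_recovery(config: SimulationConfig,
                       max_gap: int = 100_000) -> dict[str, float]:
    """Fraction of junction-free reads uniquely placed at their true origin."""
    genome, models = make_reference(config)
    expr = simulate_true_expression(config, [m.gene_id for m in models])
    reads, truth = simulate_reads(genome, models, expr.true_expression, config)
    index = build_suffix_index(genome)
    by_tid = {m.transcript_id: m for m in models}
    eligible = _eligible_true_origin(truth, models, config)

    n_eligible = n_recovered = 0
    for sample, rs in reads.items():
        table, _ = map_reads(index, rs.codes, max_gap=max_gap, trim=config.trim)
        org = truth.read_origins[sample]
        placed_left = np.full(len(rs), -1, dtype=np.int64)
        placed_chrom = np.full(len(rs), -1, dtype=np.int64)
        placed_left[table.read_indices] = table.starts[:, 0]
        placed_chrom[table.read_indices] = table.chrom_idx
        for i in np.nonzero(eligible[sample])[0]:
            m = by_tid[truth.transcripts[org["transcript_idx"][i]]]
            n_eligible += 1
            want = expected_left_coordinate(m, int(org["offset"][i]), config.trim)
            ci = index.chrom_names.index(m.chromosome)
            if placed_chrom[i] == ci and placed_left[i] == want:
                n_recovered += 1
    return {
        "eligible": float(n_eligible),
        "recovered": float(n_recovered),
        "fraction": n_recovered / n_eligible if n_eligible else float("nan"),
    }
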
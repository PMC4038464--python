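"""Placement -> per-transcript coverage -> median expression.

A placed 32 bp part increments depth by one at every exonic base it
overlaps; intronic bases and strand are ignored. The expression estimate of
a transcript is the median of its per-exonic-base coverage — zeros included,
even-length medians as the mean of the two middle order statistics. The
estimator is deliberately length-free: no TPM/FPKM normalisation.

For genes carrying several transcripts the longest transcript represents the
gene by default; ``mode="union"`` quantifies over the union of exons instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .splitmap import Placement, PlacementTable


@dataclass
class CoverageProfile:
    """Per-exonic-base read-part depth of one transcript, in genomic order."""

    transcript_id: str
    depth: np.ndarray

    def __len__(self) -> int:
        return len(self.depth)


@dataclass
class ExpressionMatrix:
    """Genes x samples non-negative expression with sample metadata."""

    values: pd.DataFrame
    metadata: pd.DataFrame  # index = sample, columns: condition, pair

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any() or self.values.columns.duplicated().any():
            raise ValueError("gene and sample labels must be unique")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")

    def to_tsv(self, path, meta_path=None) -> None:
        self.values.to_csv(path, sep="\t")
        if meta_path is not None:
            self.metadata.to_csv(meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, path, meta_path) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t", index_col=0,
                           dtype={"pair": str}, keep_default_na=False)
        return cls(values=values, metadata=meta)


# -- coverage ----------------------------------------------------------------


def compute_coverage(placements, model: TranscriptModel) -> CoverageProfile:
    """Reference per-transcript coverage from an iterable of placements.

    Each placed part contributes +1 to every exonic base it overlaps
    (partial overlaps count only the overlapping bases).
    """
    depth = np.zeros(model.spliced_length, dtype=np.int64)
    offsets = np.cumsum([0] + [e - s for s, e in model.exons])
    for pl in placements:
        if pl.chromosome != model.chromosome:
            continue
        p = pl.part_length
        for s in pl.part_starts:
            if s is None:
                continue
            for ei, (es, ee) in enumerate(model.exons):
                lo = max(s, es)
                hi = min(s + p, ee)
                if lo < hi:
                    base = offsets[ei] + (lo - es)
                    depth[base: base + (hi - lo)] += 1
    return CoverageProfile(transcript_id=model.transcript_id, depth=depth)


def genome_depth(table: PlacementTable,
                 chrom_lengths: dict[str, int]) -> dict[str, np.ndarray]:
    """Per-base part depth for every chromosome (difference-array cumsum)."""
    diffs = {name: np.zeros(chrom_lengths[name] + 1, dtype=np.int64)
             for name in chrom_lengths}
    p = table.part_length
    for ci, name in enumerate(table.chrom_names):
        mask = table.chrom_idx == ci
        if not mask.any():
            continue
        starts = table.starts[mask].ravel()
        starts = starts[starts >= 0]
        d = diffs[name]
        np.add.at(d, np.clip(starts, 0, len(d) - 1), 1)
        np.add.at(d, np.clip(starts + p, 0, len(d) - 1), -1)
    return {name: np.cumsum(d[:-1]) for name, d in diffs.items()}


def coverage_from_depth(depth_by_chrom: dict[str, np.ndarray],
                        model: TranscriptModel) -> CoverageProfile:
    if model.chromosome not in depth_by_chrom:
        raise ValueError(f"chromosome {model.chromosome!r} absent from depth; "
                         "placements and annotation must share a reference")
    d = depth_by_chrom[model.chromosome]
    depth = np.concatenate([d[s:e] for s, e in model.exons])
    return CoverageProfile(transcript_id=model.transcript_id, depth=depth)


def median_expression(profile: CoverageProfile) -> float:
    """Median of coverage across the transcript (zeros included)."""
    if len(profile) == 0:
        raise ValueError(f"empty coverage profile for {profile.transcript_id}")
    return float(np.median(profile.depth))


# -- gene-level assembly -----------------------------------------------------


def _gene_representatives(models: list[TranscriptModel],
                          mode: str) -> dict[str, TranscriptModel]:
    by_gene: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_gene.setdefault(m.gene_id, []).append(m)
    reps = {}
    for gid, ms in by_gene.items():
        if mode == "longest" or len(ms) == 1:
            reps[gid] = max(ms, key=lambda m: (m.spliced_length, m.transcript_id))
        elif mode == "union":
            intervals = sorted(iv for m in ms for iv in m.exons)
            merged: list[list[int]] = []
            for s, e in intervals:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            reps[gid] = TranscriptModel(
                gene_id=gid, transcript_id=f"{gid}.union",
                chromosome=ms[0].chromosome, strand=ms[0].strand,
                exons=tuple((s, e) for s, e in merged),
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return reps


def quantify_sample(table: PlacementTable, models: list[TranscriptModel],
                    chrom_lengths: dict[str, int],
                    mode: str = "longest") -> dict[str, float]:
    """Median-coverage expression of every gene for one sample."""
    depth = genome_depth(table, chrom_lengths)
    reps = _gene_representatives(models, mode)
    return {gid: median_expression(coverage_from_depth(depth, rep))
            for gid, rep in reps.items()}


def build_matrix(per_sample: dict[str, dict[str, float]],
                 metadata: pd.DataFrame) -> ExpressionMatrix:
    """Assemble per-sample gene expression dicts into an ExpressionMatrix."""
    samples = list(per_sample)
    universes = {s: set(v) for s, v in per_sample.items()}
    reference = universes[samples[0]]
    for s, u in universes.items():
        if u != reference:
            offenders = sorted(reference ^ u)
            raise ValueError(
                f"gene universe mismatch for sample {s!r}: {offenders[:10]}"
            )
    missing = set(samples) - set(metadata.index)
    if missing:
        raise ValueError(f"samples missing from metadata: {sorted(missing)}")
    genes = sorted(reference)
    values = pd.DataFrame(
        {s: [per_sample[s][g] for g in genes] for s in samples},
        index=pd.Index(genes, name="gene"),
    )
    return ExpressionMatrix(values=values, metadata=metadata.loc[samples])
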
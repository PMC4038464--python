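"""Differential expression by noise-regularized natural-log ratios.

The procedure: quantile-normalize the expression matrix so every sample
shares the same order statistics; estimate the noise level nu as the peak of
the pooled expression distribution (histogram of ln(1+x), modal bin center);
add nu to every expression value before taking natural-log ratios, which
shrinks the apparent fold change of weakly expressed genes so they cannot
dominate the responder list; call a gene a responder when |ln ratio| >= 0.2
(inclusive). No p-values are attached — the cutoff is the test.

Comparisons follow the study design: the transgenic sample against the mean
of the controls, and each ethanol-treated sample against its paired control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .quantify import ExpressionMatrix

DEFAULT_CUTOFF = 0.2


@dataclass(frozen=True)
class NoiseEstimate:
    """The peak of the pooled expression distribution (expression units)."""

    nu: float
    bin_width_ln: float  # width of the ln(1+x) histogram bins

    def __post_init__(self) -> None:
        if self.nu < 0:
            raise ValueError("noise level must be non-negative")


@dataclass(frozen=True)
class LogRatioResult:
    gene_id: str
    comparison: str
    ln_ratio: float
    responder: bool
    direction: str  # "up" | "down" | "flat"
    degenerate: bool = False


# -- quantile normalization --------------------------------------------------


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the across-sample mean order statistics.

    Ties within a sample receive the mean of the normalized values of their
    tied ranks, so for tie-free data every sorted column equals the
    reference vector exactly and the operation is idempotent; tied runs are
    collapsed onto their group mean instead. With a single sample the matrix
    is returned unchanged (with a warning): there is nothing to normalize
    against.
    """
    values = matrix.values
    if values.shape[1] < 2:
        warnings.warn("quantile normalization skipped: fewer than 2 samples")
        return ExpressionMatrix(values=values.copy(), metadata=matrix.metadata)
    arr = values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    ref_cum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        order = np.argsort(arr[:, j], kind="stable")
        col_sorted = arr[order, j]
        # tie group [s, e): value = mean(reference[s:e])
        boundaries = np.concatenate([[0], np.nonzero(np.diff(col_sorted))[0] + 1,
                                     [len(col_sorted)]])
        normalized = np.empty_like(col_sorted)
        for s, e in zip(boundaries[:-1], boundaries[1:]):
            normalized[s:e] = (ref_cum[e] - ref_cum[s]) / (e - s)
        out[order, j] = normalized
    return ExpressionMatrix(
        values=pd.DataFrame(out, index=values.index, columns=values.columns),
        metadata=matrix.metadata,
    )


# -- noise peak --------------------------------------------------------------


def estimate_noise(matrix: ExpressionMatrix, n_bins: int = 100) -> NoiseEstimate:
    """Peak of the pooled expression distribution as the system noise level.

    Pools all (post-normalization) values, histograms ln(1+x) into ``n_bins``
    equal bins over [min, max], and returns exp(center of the fullest
    bin) - 1; count ties break toward the lower bin.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    pooled = matrix.values.to_numpy(dtype=float).ravel()
    if pooled.size == 0:
        raise ValueError("cannot estimate noise from an empty matrix")
    ln = np.log1p(pooled)
    lo, hi = float(ln.min()), float(ln.max())
    if lo == hi:
        return NoiseEstimate(nu=float(pooled[0]), bin_width_ln=0.0)
    counts, edges = np.histogram(ln, bins=n_bins, range=(lo, hi))
    peak = int(np.argmax(counts))  # argmax takes the first = lower bin on ties
    center = (edges[peak] + edges[peak + 1]) / 2.0
    return NoiseEstimate(nu=float(np.expm1(center)),
                         bin_width_ln=float(edges[1] - edges[0]))


# -- regularized ratios ------------------------------------------------------


def regularized_log_ratio(case_value: float, control_values, nu: float) -> float:
    """ln((case + nu) / (mean(controls) + nu)).

    The additive noise term shrinks ratios of weakly expressed genes toward
    zero. The degenerate all-zero case with nu = 0 maps to 0.0; callers that
    need to flag it should test for it explicitly (see :func:`compare`).
    """
    if nu < 0:
        raise ValueError("nu must be >= 0")
    controls = np.asarray(control_values, dtype=float)
    if controls.size == 0:
        raise ValueError("control_values must be non-empty")
    if case_value < 0 or (controls < 0).any():
        raise ValueError("expression values must be non-negative")
    num = case_value + nu
    den = float(controls.mean()) + nu
    if num == 0.0 and den == 0.0:
        return 0.0
    return float(np.log(num / den))


def call_responders(results: list[LogRatioResult],
                    cutoff: float = DEFAULT_CUTOFF) -> list[LogRatioResult]:
    """Re-flag results at a new cutoff: responder iff |ln ratio| >= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    out = []
    for r in results:
        responder = abs(r.ln_ratio) >= cutoff and not r.degenerate
        direction = ("up" if r.ln_ratio > 0 else "down") if responder else "flat"
        out.append(LogRatioResult(gene_id=r.gene_id, comparison=r.comparison,
                                  ln_ratio=r.ln_ratio, responder=responder,
                                  direction=direction, degenerate=r.degenerate))
    return out


def compare(matrix: ExpressionMatrix, nu: float,
            cutoff: float = DEFAULT_CUTOFF) -> dict[str, list[LogRatioResult]]:
    """All study comparisons: transgenic vs mean(controls), ethanol vs pair.

    Returns ``{comparison label: [LogRatioResult per gene]}``.
    """
    meta = matrix.metadata
    controls = meta.index[meta["condition"] == "control"]
    comparisons: dict[str, tuple[str, list[str]]] = {}
    for s in meta.index[meta["condition"] == "transgenic"]:
        comparisons[f"{s}_vs_control_mean"] = (s, list(controls))
    for s in meta.index[meta["condition"] == "ethanol"]:
        pair = meta.loc[s, "pair"]
        mates = [c for c in controls if meta.loc[c, "pair"] == pair]
        if len(mates) != 1:
            raise ValueError(f"sample {s!r}: expected exactly one paired "
                             f"control with pair key {pair!r}, found {mates}")
        comparisons[f"{s}_vs_{mates[0]}"] = (s, mates)

    out: dict[str, list[LogRatioResult]] = {}
    for label, (case, ctrls) in comparisons.items():
        results = []
        for gene in matrix.values.index:
            cv = float(matrix.values.loc[gene, case])
            ctl = matrix.values.loc[gene, ctrls].to_numpy(dtype=float)
            degenerate = nu == 0.0 and cv == 0.0 and ctl.mean() == 0.0
            ratio = regularized_log_ratio(cv, ctl, nu)
            results.append(LogRatioResult(gene_id=gene, comparison=label,
                                          ln_ratio=ratio, responder=False,
                                          direction="flat",
                                          degenerate=degenerate))
        out[label] = call_responders(results, cutoff)
    return out


# -- gene-set overlap --------------------------------------------------------


@dataclass
class OverlapSummary:
    geneset_name: str
    induced: dict[str, list[str]]              # comparison/group -> member list
    intersections: dict[tuple[str, str], list[str]]

    @property
    def induced_counts(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.induced.items()}

    @property
    def intersection_counts(self) -> dict[tuple[str, str], int]:
        return {k: len(v) for k, v in self.intersections.items()}


def combine_replicates(flag_sets: list[set[str]], mode: str = "all") -> set[str]:
    """Merge per-replicate induced-gene sets: 'all' (default) or 'any'."""
    if not flag_sets:
        return set()
    if mode == "all":
        return set.intersection(*flag_sets)
    if mode == "any":
        return set.union(*flag_sets)
    raise ValueError(f"unknown mode {mode!r}")


def geneset_overlap(flags_by_comparison: dict[str, list[LogRatioResult]],
                    geneset: set[str],
                    geneset_name: str = "geneset") -> OverlapSummary:
    """Induced gene-set members per comparison, plus pairwise intersections."""
    if not geneset:
        raise ValueError("geneset is empty")
    induced: dict[str, list[str]] = {}
    for label, results in flags_by_comparison.items():
        up = {r.gene_id for r in results if r.responder and r.direction == "up"}
        induced[label] = sorted(up & geneset)
    labels = list(induced)
    intersections = {
        (a, b): sorted(set(induced[a]) & set(induced[b]))
        for i, a in enumerate(labels) for b in labels[i + 1:]
    }
    return OverlapSummary(geneset_name=geneset_name, induced=induced,
                          intersections=intersections)


# -- GO term assignment ------------------------------------------------------


@dataclass
class GoAnnotation:
    """Ranked GO terms per gene, with a human-orthologue fallback.

    Relevance ranks are consumed as data, never computed: the primary term of
    a gene is its rank-1 entry, falling back to the rank-1 term of its mapped
    human orthologue when the gene's own list is empty.
    """

    terms: dict[str, list[tuple[str, int]]]           # gene -> [(term, rank)]
    orthologs: dict[str, str]                          # gene -> human gene
    human_terms: dict[str, list[tuple[str, int]]]

    def __post_init__(self) -> None:
        for table in (self.terms, self.human_terms):
            for gene, entries in table.items():
                ranks = [r for _, r in entries]
                if len(ranks) != len(set(ranks)):
                    raise ValueError(f"duplicate GO ranks for gene {gene!r}")


def _read_ranked_terms(path) -> dict[str, list[tuple[str, int]]]:
    out: dict[str, list[tuple[str, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 columns "
                    f"(gene, term, rank), got {len(cols)}"
                )
            gene, term, rank = cols
            try:
                rank_i = int(rank)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: rank {rank!r} not an integer")
            out.setdefault(gene, []).append((term, rank_i))
    for entries in out.values():
        entries.sort(key=lambda tr: tr[1])
    return out


def load_go_annotation(terms_path, orthologs_path, human_terms_path) -> GoAnnotation:
    orthologs: dict[str, str] = {}
    with open(orthologs_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 2:
                raise ValueError(f"{orthologs_path}: line {lineno}: expected 2 columns")
            orthologs[cols[0]] = cols[1]
    return GoAnnotation(terms=_read_ranked_terms(terms_path),
                        orthologs=orthologs,
                        human_terms=_read_ranked_terms(human_terms_path))


def assign_go_term(gene: str, annotation: GoAnnotation) -> str:
    """Rank-1 term of the gene, else of its human orthologue, else 'unannotated'."""
    own = annotation.terms.get(gene, [])
    if own:
        return own[0][0]
    human = annotation.orthologs.get(gene)
    if human:
        fallback = annotation.human_terms.get(human, [])
        if fallback:
            return fallback[0][0]
    return "unannotated"


# -- export ------------------------------------------------------------------


def results_frame(flags_by_comparison: dict[str, list[LogRatioResult]]) -> pd.DataFrame:
    rows = [
        {"gene": r.gene_id, "comparison": r.comparison, "ln_ratio": r.ln_ratio,
         "responder": r.responder, "direction": r.direction}
        for results in flags_by_comparison.values() for r in results
    ]
    return pd.DataFrame(rows)


def ratio_matrix(flags_by_comparison: dict[str, list[LogRatioResult]]) -> pd.DataFrame:
    """Genes x comparisons matrix of ln ratios (heat-map-ready export)."""
    frame = results_frame(flags_by_comparison)
    return frame.pivot(index="gene", columns="comparison", values="ln_ratio")
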
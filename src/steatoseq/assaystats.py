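"""Assay-level statistics: qPCR dCt, incidence tests, t-tests, shape metrics.

The qPCR quantity is the comparative-threshold value
dCt = 2^-(Ct_gene - Ct_ref) with rpp0 as the reference gene; fold changes
are ratios of median dCt. Steatosis incidence (present/absent per larva) is
tested with Fisher's exact test, two-sided by the minimum-likelihood
convention — the sum of hypergeometric probabilities of all margin-fixed
tables no more likely than the observed one — with chi-square available as a
secondary statistic. Small clutch counts make the exact test the defensible
primary choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from skimage import measure as _sk_measure

_TIE_RTOL = 1e-7  # relative slack on the "no more likely" comparison


# -- qPCR --------------------------------------------------------------------


def dct(ct_gene: float, ct_ref: float) -> float:
    """Comparative-threshold value 2^-(Ct_gene - Ct_ref)."""
    if not (math.isfinite(ct_gene) and math.isfinite(ct_ref)):
        raise ValueError("Ct values must be finite")
    return 2.0 ** (-(ct_gene - ct_ref))


def fold_change(case_dcts, control_dcts) -> float | None:
    """median(case dCt) / median(control dCt); None when the control median is 0."""
    case = np.asarray(case_dcts, dtype=float)
    control = np.asarray(control_dcts, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValueError("dCt lists must be non-empty")
    denom = float(np.median(control))
    if denom == 0.0:
        return None
    return float(np.median(case)) / denom


# -- incidence ---------------------------------------------------------------


@dataclass(frozen=True)
class IncidenceTable:
    """2x2 counts: rows = groups, columns = (positive, negative)."""

    a: int  # group A positive
    b: int  # group A negative
    c: int  # group B positive
    d: int  # group B negative
    group_labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")


def _hypergeom_logpmf(k: np.ndarray, n: int, r1: int, m: int) -> np.ndarray:
    """log P(X=k) for X ~ Hypergeom(total n, successes m, draws r1)."""
    lg = math.lgamma
    out = np.empty(len(k))
    for i, kk in enumerate(k):
        out[i] = (lg(r1 + 1) - lg(kk + 1) - lg(r1 - kk + 1)
                  + lg(n - r1 + 1) - lg(m - kk + 1) - lg(n - r1 - (m - kk) + 1)
                  - (lg(n + 1) - lg(m + 1) - lg(n - m + 1)))
    return out


def fisher_exact(table: IncidenceTable) -> tuple[float | None, float]:
    """(odds ratio, two-sided exact p) by the minimum-likelihood convention.

    p sums the hypergeometric probabilities of every table with the observed
    margins whose probability is <= that of the observed table (within a
    1e-7 relative tolerance on the comparison). A zero margin fixes p = 1.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    odds = (a * d) / (b * c) if b * c != 0 else None
    r1, r2 = a + b, c + d
    m = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or m == 0 or m == n:
        return odds, 1.0
    support = np.arange(max(0, m - r2), min(r1, m) + 1)
    logpmf = _hypergeom_logpmf(support, n, r1, m)
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()
    observed = pmf[np.searchsorted(support, a)]
    p = float(pmf[pmf <= observed * (1.0 + _TIE_RTOL)].sum())
    return odds, min(p, 1.0)


def chi_square(table: IncidenceTable,
               correction: bool = False) -> tuple[float, float]:
    """Secondary chi-square statistic (Yates correction optional)."""
    obs = np.array([[table.a, table.b], [table.c, table.d]])
    res = sps.chi2_contingency(obs, correction=correction)
    return float(res.statistic), float(res.pvalue)


# -- t-test family -----------------------------------------------------------


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    note: str = ""


def _degenerate(effect: float) -> TTestResult:
    if effect == 0.0:
        return TTestResult(t=0.0, df=float("nan"), p=1.0, note="zero variance")
    return TTestResult(t=math.copysign(float("inf"), effect), df=float("nan"),
                       p=0.0, note="zero variance, nonzero effect")


def t_test_unpaired(x, y, equal_var: bool = True) -> TTestResult:
    """Two-sample t-test, equal-variance Student by default (Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        return _degenerate(float(x.mean() - y.mean()))
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    df = (len(x) + len(y) - 2) if equal_var else float(res.df)
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def t_test_paired(x, y) -> TTestResult:
    """Paired t-test on the within-pair differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    if len(x) < 2:
        raise ValueError("paired test needs >= 2 pairs")
    diffs = x - y
    if diffs.var(ddof=1) == 0.0:
        return _degenerate(float(diffs.mean()))
    res = sps.ttest_rel(x, y)
    return TTestResult(t=float(res.statistic), df=float(len(x) - 1),
                       p=float(res.pvalue))


def t_test_one_sample(x, null_value: float = 0.0) -> TTestResult:
    """One-sample t-test against a stated null (default 0, the ln-fold scale)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("one-sample test needs n >= 2")
    if x.var(ddof=1) == 0.0:
        return _degenerate(float(x.mean() - null_value))
    res = sps.ttest_1samp(x, null_value)
    return TTestResult(t=float(res.statistic), df=float(len(x) - 1),
                       p=float(res.pvalue))


# -- band densitometry -------------------------------------------------------


@dataclass(frozen=True)
class BandPair:
    """Spliced/unspliced band intensities from gel densitometry."""

    spliced: float
    unspliced: float

    def __post_init__(self) -> None:
        if self.spliced < 0 or self.unspliced < 0:
            raise ValueError("band intensities must be >= 0")
        if self.spliced == 0 and self.unspliced == 0:
            raise ValueError("at least one band must be nonzero")


def splicing_fraction(bands: BandPair) -> float:
    """Percent spliced: 100 * spliced / (spliced + unspliced)."""
    return 100.0 * bands.spliced / (bands.spliced + bands.unspliced)


# -- shape -------------------------------------------------------------------

_MOORE = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))


def _chain_perimeter(mask: np.ndarray) -> float:
    """Moore boundary trace through pixel centers; diagonal steps weigh sqrt(2)."""
    ys, xs = np.nonzero(mask)
    order = np.lexsort((xs, ys))
    start = (int(ys[order[0]]), int(xs[order[0]]))

    def inside(y: int, x: int) -> bool:
        return 0 <= y < mask.shape[0] and 0 <= x < mask.shape[1] and mask[y, x]

    def next_step(cur: tuple[int, int], backtrack: int):
        for i in range(8):
            d = (backtrack + 1 + i) % 8
            cy, cx = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if inside(cy, cx):
                return d, (cy, cx)
        return None, None

    # search starts from the west neighbour of the top-left boundary pixel
    first_dir, first_next = next_step(start, 6)
    if first_next is None:
        return 0.0  # isolated pixel
    length = math.sqrt(2.0) if first_dir % 2 else 1.0
    cur, backtrack = first_next, (first_dir + 4) % 8
    while True:
        d, nxt = next_step(cur, backtrack)
        # stop when the trace re-enters the start pixel and repeats the
        # first move (Jacob's criterion), so shapes that touch the start
        # pixel twice are traced fully
        if cur == start and (d, nxt) == (first_dir, first_next):
            break
        length += math.sqrt(2.0) if d % 2 else 1.0
        cur, backtrack = nxt, (d + 4) % 8
    return length


_KULPA = 0.9481  # calibration factor making chain length unbiased for lines


@dataclass
class ShapeMask:
    """A single traced region; circularity = 4*pi*area / perimeter^2."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        labels = _sk_measure.label(self.mask, connectivity=2)
        n = labels.max()
        if n == 0:
            raise ValueError("mask is empty")
        if n > 1:
            raise ValueError(f"mask has {n} connected components; trace one region")

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def circularity(mask: ShapeMask, perimeter: str = "chain") -> float:
    """4*pi*area/perimeter^2; 1 for an ideal circle, < 1 for elongated shapes.

    ``perimeter="chain"`` (default) measures the 8-connected boundary chain
    with diagonal steps weighted sqrt(2); this overestimates a smooth
    contour by a few percent, so digitized disks score ~0.9 rather than 1.
    ``perimeter="calibrated"`` applies the Kulpa correction factor (0.9481),
    centering digitized disks at ~1 at the cost of biasing polygonal shapes.
    """
    if mask.area < 10:
        raise ValueError("region too small (area must be >= 10 px)")
    p = _chain_perimeter(mask.mask)
    if perimeter == "calibrated":
        p *= _KULPA
    elif perimeter != "chain":
        raise ValueError(f"unknown perimeter estimator {perimeter!r}")
    if p <= 0:
        raise ValueError("degenerate perimeter")
    return 4.0 * math.pi * mask.area / p ** 2


# -- normalisation -----------------------------------------------------------


def normalize_to_protein(measure: float, protein: float) -> float:
    """Assay value per unit protein (Bradford/BCA denominator)."""
    if protein <= 0:
        raise ValueError("protein concentration must be > 0")
    return measure / protein


def lipid_fraction_percent(lipid_counts: float, total_counts: float) -> float:
    """Percent of label in the lipid fraction: 100 * lipid / total lysate."""
    if total_counts <= 0:
        raise ValueError("total counts must be > 0")
    return 100.0 * lipid_counts / total_counts
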
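"""Quantile normalization, noise-peak estimation and regularized ratios."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from steatoseq.diffexpr import (LogRatioResult, assign_go_term,
                                call_responders, combine_replicates, compare,
                                estimate_noise, geneset_overlap,
                                load_go_annotation, quantile_normalize,
                                ratio_matrix, regularized_log_ratio)
from steatoseq.quantify import ExpressionMatrix
from steatoseq.synthdata import sample_metadata


def _matrix(arr, samples=None, meta=None):
    arr = np.asarray(arr, dtype=float)
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    if meta is None:
        meta = pd.DataFrame(
            {"condition": ["control"] * len(samples), "pair": [""] * len(samples)},
            index=pd.Index(samples, name="sample"))
    values = pd.DataFrame(arr, columns=samples,
                          index=pd.Index([f"g{i}" for i in range(arr.shape[0])],
                                         name="gene"))
    return ExpressionMatrix(values=values, metadata=meta)


def naive_quantile_normalize(arr):
    """Independent rank/average implementation (loops, no shortcuts)."""
    arr = np.asarray(arr, dtype=float)
    n, k = arr.shape
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(k):
        col = arr[:, j]
        for i in range(n):
            less = np.sum(col < col[i])
            ties = np.sum(col == col[i])
            tied_ranks = range(less, less + ties)
            out[i, j] = np.mean([reference[r] for r in tied_ranks])
    return out


# -- quantile normalization --------------------------------------------------


def test_qn_two_column_example():
    m = quantile_normalize(_matrix([[1, 4], [2, 5], [3, 6]]))
    np.testing.assert_allclose(m.values.to_numpy(),
                               [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])


def test_qn_preserves_rank_order():
    m = quantile_normalize(_matrix([[3, 40], [1, 60], [2, 50]]))
    col = m.values.to_numpy()
    assert col[1, 0] < col[2, 0] < col[0, 0]
    assert col[0, 1] < col[2, 1] < col[1, 1]


def test_qn_sorted_columns_identical(rng):
    arr = rng.lognormal(2, 1, size=(40, 5))
    out = quantile_normalize(_matrix(arr)).values.to_numpy()
    ref = np.sort(out[:, 0])
    for j in range(out.shape[1]):
        np.testing.assert_array_equal(np.sort(out[:, j]), ref)


def test_qn_idempotent(rng):
    # tie-free matrix: with ties the tie-averaging rule replaces a run of
    # reference values by their mean, so sorted vectors (and hence exact
    # idempotence) only coincide for distinct values
    arr = rng.lognormal(2, 1, size=(30, 4))
    once = quantile_normalize(_matrix(arr))
    twice = quantile_normalize(once)
    np.testing.assert_allclose(once.values.to_numpy(),
                               twice.values.to_numpy(), atol=1e-12)


@pytest.mark.parametrize("trial", range(5))
def test_qn_matches_naive_oracle(rng, trial):
    arr = rng.integers(0, 30, size=(25, 4)).astype(float)  # plenty of ties
    out = quantile_normalize(_matrix(arr)).values.to_numpy()
    np.testing.assert_allclose(out, naive_quantile_normalize(arr), atol=1e-12)


def test_qn_constant_column_gets_reference_mean(rng):
    arr = np.column_stack([np.full(10, 7.0), np.arange(10, dtype=float)])
    out = quantile_normalize(_matrix(arr)).values.to_numpy()
    reference = np.sort(arr, axis=0).mean(axis=1)
    np.testing.assert_allclose(out[:, 0], np.full(10, reference.mean()))


def test_qn_single_sample_warns_and_passes_through():
    m = _matrix([[1.0], [2.0]])
    with pytest.warns(UserWarning):
        out = quantile_normalize(m)
    pd.testing.assert_frame_equal(out.values, m.values)


# -- noise estimation --------------------------------------------------------


def test_noise_all_values_equal():
    assert estimate_noise(_matrix(np.full((5, 3), 5.0))).nu == 5.0


def test_noise_empty_matrix_errors():
    with pytest.raises(ValueError):
        estimate_noise(_matrix(np.empty((0, 2))))


def test_noise_requires_enough_bins():
    with pytest.raises(ValueError):
        estimate_noise(_matrix([[1.0, 2.0]]), n_bins=5)


def test_noise_peak_matches_kde_mode(rng):
    """On a mixture with a dominant low-expression mass the histogram-mode
    estimator lands within one bin width (ln scale) of a dense-KDE mode."""
    from scipy.stats import gaussian_kde
    noise = rng.lognormal(1.8, 0.3, size=600)
    signal = rng.lognormal(4.0, 1.0, size=400)
    pooled = np.concatenate([noise, signal])
    est = estimate_noise(_matrix(pooled.reshape(-1, 2)))
    ln = np.log1p(pooled)
    grid = np.linspace(ln.min(), ln.max(), 4000)
    # bandwidth well below the cluster width (~0.26 on the ln scale) so the
    # dense-grid KDE resolves the noise peak rather than smearing it
    kde_mode = grid[np.argmax(gaussian_kde(ln, bw_method=0.05)(grid))]
    assert abs(math.log1p(est.nu) - kde_mode) <= est.bin_width_ln


# -- regularized ratios ------------------------------------------------------


def test_ratio_closed_forms():
    assert regularized_log_ratio(10, [10], 3.7) == 0.0
    assert abs(regularized_log_ratio(20, [10], 0) - math.log(2)) < 1e-12
    assert abs(regularized_log_ratio(20, [10], 10) - math.log(1.5)) < 1e-12
    # two controls are averaged
    assert abs(regularized_log_ratio(20, [5, 15], 0) - math.log(2)) < 1e-12


def test_ratio_degenerate_all_zero():
    assert regularized_log_ratio(0.0, [0.0], 0.0) == 0.0


def test_ratio_antisymmetry(rng):
    for _ in range(200):
        case, ctrl, nu = rng.uniform(0.1, 100, 3)
        assert abs(regularized_log_ratio(case, [ctrl], nu)
                   + regularized_log_ratio(ctrl, [case], nu)) < 1e-12


@settings(max_examples=300, deadline=None, derandomize=True)
@given(case=st.floats(1e-6, 1e4), ctrl=st.floats(1e-6, 1e4),
       nu=st.floats(1e-9, 1e4))
def test_ratio_shrinkage_property(case, ctrl, nu):
    """Adding noise always shrinks a nonzero ratio toward zero."""
    raw = regularized_log_ratio(case, [ctrl], 0.0)
    reg = regularized_log_ratio(case, [ctrl], nu)
    if raw != 0.0:
        assert abs(reg) < abs(raw)


# -- responder calling -------------------------------------------------------


def _result(lr):
    return LogRatioResult("g", "c", lr, False, "flat")


@pytest.mark.parametrize("lr,responder,direction", [
    (0.2, True, "up"),          # inclusive cutoff
    (0.1999, False, "flat"),
    (-0.25, True, "down"),
    (-0.2, True, "down"),
])
def test_responder_cutoff_inclusive(lr, responder, direction):
    out = call_responders([_result(lr)], cutoff=0.2)[0]
    assert out.responder is responder and out.direction == direction


def test_responder_cutoff_must_be_positive():
    with pytest.raises(ValueError):
        call_responders([], cutoff=0.0)


# -- comparisons and overlap -------------------------------------------------


def test_compare_study_design():
    arr = np.array([[10, 10, 30, 30, 30],
                    [10, 12, 10, 12, 11]], dtype=float)
    values = pd.DataFrame(arr, columns=list(sample_metadata().index),
                          index=["upr1", "null1"])
    m = ExpressionMatrix(values=values, metadata=sample_metadata())
    comps = compare(m, nu=0.0)
    assert set(comps) == {"tg_1_vs_control_mean", "etoh_1_vs_ctrl_1",
                          "etoh_2_vs_ctrl_2"}
    tg = {r.gene_id: r for r in comps["tg_1_vs_control_mean"]}
    assert tg["upr1"].responder and tg["upr1"].direction == "up"
    assert abs(tg["upr1"].ln_ratio - math.log(3)) < 1e-12
    assert not tg["null1"].responder


def test_geneset_overlap_counts():
    flags = {
        "A": call_responders([_result(0.5), LogRatioResult("h", "A", 0.5, False, "flat"),
                              LogRatioResult("k", "A", -0.5, False, "flat")]),
        "B": call_responders([_result(0.5), LogRatioResult("h", "B", 0.05, False, "flat")]),
    }
    summary = geneset_overlap(flags, {"g", "h"}, "upr")
    assert summary.induced_counts == {"A": 2, "B": 1}
    assert summary.intersection_counts[("A", "B")] == 1
    for (a, b), n in summary.intersection_counts.items():
        assert n <= min(summary.induced_counts[a], summary.induced_counts[b])


def test_geneset_overlap_empty_set_errors():
    with pytest.raises(ValueError):
        geneset_overlap({}, set())


def test_geneset_disjoint_gives_zero():
    flags = {"A": call_responders([_result(0.5)])}
    summary = geneset_overlap(flags, {"other"})
    assert summary.induced_counts == {"A": 0}


def test_combine_replicates_modes():
    sets = [{"a", "b"}, {"b", "c"}]
    assert combine_replicates(sets, "all") == {"b"}
    assert combine_replicates(sets, "any") == {"a", "b", "c"}
    with pytest.raises(ValueError):
        combine_replicates(sets, "mean")


def test_ratio_matrix_shape():
    flags = {"A": [LogRatioResult("g", "A", 0.3, False, "flat")],
             "B": [LogRatioResult("g", "B", -0.1, False, "flat")]}
    mat = ratio_matrix(flags)
    assert mat.shape == (1, 2)


# -- GO assignment -----------------------------------------------------------


def _write_go(tmp_path):
    (tmp_path / "terms.tsv").write_text(
        "gene1\tGO:a\t1\ngene1\tGO:b\t2\ngene3\tGO:z\t3\ngene3\tGO:y\t1\n")
    (tmp_path / "orth.tsv").write_text("gene2\tHUMAN2\ngene4\tHUMAN4\n")
    (tmp_path / "human.tsv").write_text("HUMAN2\tGO:c\t1\n")
    return load_go_annotation(tmp_path / "terms.tsv", tmp_path / "orth.tsv",
                              tmp_path / "human.tsv")


def test_go_rank_one_term(tmp_path):
    ann = _write_go(tmp_path)
    assert assign_go_term("gene1", ann) == "GO:a"
    assert assign_go_term("gene3", ann) == "GO:y"


def test_go_orthologue_fallback(tmp_path):
    ann = _write_go(tmp_path)
    assert assign_go_term("gene2", ann) == "GO:c"


def test_go_unannotated(tmp_path):
    ann = _write_go(tmp_path)
    assert assign_go_term("gene4", ann) == "unannotated"  # orthologue lacks terms
    assert assign_go_term("nope", ann) == "unannotated"


def test_go_malformed_row_reports_line(tmp_path):
    (tmp_path / "bad.tsv").write_text("gene1\tGO:a\t1\ngene2\tGO:b\n")
    (tmp_path / "orth.tsv").write_text("")
    (tmp_path / "human.tsv").write_text("")
    with pytest.raises(ValueError, match="line 2"):
        load_go_annotation(tmp_path / "bad.tsv", tmp_path / "orth.tsv",
                           tmp_path / "human.tsv")
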
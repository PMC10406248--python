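"""Scoring suite vs independent brute-force oracles."""

import math

import numpy as np
import pytest

from strokewmh.metrics import (
    cluster_metrics,
    cohort_report,
    icc_agreement,
    score_subject,
    voxel_metrics,
)
from strokewmh.volumes import LabelMask

from .conftest import random_mask


def _mask(arr):
    return LabelMask(np.asarray(arr, dtype=bool), role="WMH_AUTO")


def _gold(arr):
    return LabelMask(np.asarray(arr, dtype=bool), role="WMH_GOLD")


# ---------------------------------------------------------------------------
# oracles


def brute_cluster_metrics(gold, auto, connectivity=26):
    """Explicit set-based cluster pairing oracle."""
    from scipy import ndimage

    struct = ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])
    g_lab, n_g = ndimage.label(gold, structure=struct)
    a_lab, n_a = ndimage.label(auto, structure=struct)
    g_sets = [set(map(tuple, np.argwhere(g_lab == i))) for i in range(1, n_g + 1)]
    a_sets = [set(map(tuple, np.argwhere(a_lab == i))) for i in range(1, n_a + 1)]
    a_vox = set(map(tuple, np.argwhere(auto)))
    g_vox = set(map(tuple, np.argwhere(gold)))
    g_matched = [s for s in g_sets if s & a_vox]
    a_matched = [s for s in a_sets if s & g_vox]
    fdrc = (n_a - len(a_matched)) / n_a if n_a else math.nan
    fnrc = (n_g - len(g_matched)) / n_g if n_g else math.nan
    mta = (len(g_vox) + len(a_vox)) / 2
    if mta == 0:
        return fdrc, fnrc, math.nan, math.nan
    unmatched = sum(len(s) for s in g_sets if not (s & a_vox)) + sum(
        len(s) for s in a_sets if not (s & g_vox)
    )
    matched_g = set().union(*g_matched) if g_matched else set()
    matched_a = set().union(*a_matched) if a_matched else set()
    outline = len(matched_g) + len(matched_a) - 2 * len(g_vox & a_vox)
    return fdrc, fnrc, unmatched / mta, outline / mta


def anova_icc_a1(x, y):
    """Hand-coded two-way ANOVA decomposition for ICC(A,1), k=2 raters."""
    data = np.column_stack([x, y]).astype(float)
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))


# ---------------------------------------------------------------------------
# voxel level


def test_identical_masks_perfect_scores():
    arr = np.zeros((5, 5, 5), dtype=bool)
    arr[1:3, 1:3, 1:3] = True
    si, fdr, fnr = voxel_metrics(_gold(arr), _mask(arr.copy()))
    assert (si, fdr, fnr) == (1.0, 0.0, 0.0)


def test_printed_toy_mask_example():
    # G has 4 voxels, A has 6, 3 shared
    g = np.zeros((4, 4, 1), dtype=bool)
    a = np.zeros((4, 4, 1), dtype=bool)
    g[0, 0:4, 0] = True  # 4 voxels
    a[0, 0:3, 0] = True  # 3 shared
    a[1, 0:3, 0] = True  # 3 extra
    si, fdr, fnr = voxel_metrics(_gold(g), _mask(a))
    assert si == pytest.approx(0.6)
    assert fdr == pytest.approx(0.5)
    assert fnr == pytest.approx(0.25)


def test_disjoint_masks():
    g = np.zeros((4, 4, 4), dtype=bool)
    a = np.zeros((4, 4, 4), dtype=bool)
    g[0, 0, 0] = a[3, 3, 3] = True
    si, fdr, fnr = voxel_metrics(_gold(g), _mask(a))
    assert (si, fdr, fnr) == (0.0, 1.0, 1.0)


def test_undefined_metrics_are_nan_flagged():
    g = np.zeros((3, 3, 3), dtype=bool)
    a = np.zeros((3, 3, 3), dtype=bool)
    a[1, 1, 1] = True
    si, fdr, fnr = voxel_metrics(_gold(g), _mask(a))
    assert math.isnan(si) and math.isnan(fnr) and fdr == 1.0
    g2 = np.zeros((3, 3, 3), dtype=bool)
    g2[0, 0, 0] = True
    si2, fdr2, fnr2 = voxel_metrics(_gold(g2), _mask(np.zeros((3, 3, 3), dtype=bool)))
    assert math.isnan(fdr2) and si2 == 0.0 and fnr2 == 1.0
    score = score_subject(_gold(g), _mask(a), "s")
    assert "SI" in score.undefined and "FNR" in score.undefined


def test_si_equals_algebraic_identity(rng):
    for _ in range(20):
        g, a = random_mask(rng).data, random_mask(rng).data
        if not g.any() or not a.any():
            continue
        si, _, _ = voxel_metrics(_gold(g), _mask(a))
        assert si == pytest.approx(
            2 * (g & a).sum() / (g.sum() + a.sum())
        )


# ---------------------------------------------------------------------------
# cluster level


def test_two_cluster_half_false_detection():
    a = np.zeros((8, 8, 1), dtype=bool)
    a[0:2, 0:2, 0] = True  # overlaps gold
    a[6:8, 6:8, 0] = True  # spurious
    g = np.zeros((8, 8, 1), dtype=bool)
    g[0:2, 0:2, 0] = True
    fdrc, fnrc, der, oer = cluster_metrics(_gold(g), _mask(a))
    assert fdrc == 0.5 and fnrc == 0.0
    # DER: the 4 spurious voxels over MTA=(4+8)/2=6
    assert der == pytest.approx(4 / 6)
    assert oer == pytest.approx(0.0)


def test_shifted_cluster_outline_error():
    g = np.zeros((10, 10, 1), dtype=bool)
    g[1:3, 1:5, 0] = True  # 8 voxels
    a = np.zeros((10, 10, 1), dtype=bool)
    a[1:3, 3:7, 0] = True  # shifted, overlap = 4
    fdrc, fnrc, der, oer = cluster_metrics(_gold(g), _mask(a))
    assert (fdrc, fnrc, der) == (0.0, 0.0, 0.0)
    assert oer == pytest.approx(1.0)  # (8 + 8 - 2*4) / 8


def test_cluster_metrics_match_brute_force(rng):
    for _ in range(40):
        g = random_mask(rng, (16, 16, 16), p=0.08).data
        a = random_mask(rng, (16, 16, 16), p=0.08).data
        ours = cluster_metrics(_gold(g), _mask(a))
        oracle = brute_cluster_metrics(g, a)
        for x, y in zip(ours, oracle):
            if math.isnan(x) or math.isnan(y):
                assert math.isnan(x) and math.isnan(y)
            else:
                assert x == pytest.approx(y, abs=1e-12)


def test_metrics_invariant_to_joint_translation(rng):
    g = np.zeros((12, 12, 12), dtype=bool)
    a = np.zeros((12, 12, 12), dtype=bool)
    g[2:5, 2:5, 2:5] = True
    a[3:6, 2:5, 2:5] = True
    base = score_subject(_gold(g), _mask(a), "s")
    gs, as_ = np.roll(g, 3, axis=2), np.roll(a, 3, axis=2)
    shifted = score_subject(_gold(gs), _mask(as_), "s")
    for m in ("SI", "FDR", "FNR", "FDRc", "FNRc", "DER", "OER"):
        assert getattr(base, m) == pytest.approx(getattr(shifted, m))


# ---------------------------------------------------------------------------
# ICC


def test_icc_identical_lists_is_one():
    v = [10.0, 25.0, 40.0, 55.0]
    assert icc_agreement(v, v) == pytest.approx(1.0)


def test_icc_constant_offset_penalized_matches_anova():
    gold = [10.0, 20.0, 30.0, 40.0]
    auto = [20.0, 30.0, 40.0, 50.0]
    ours = icc_agreement(gold, auto)
    assert ours < 1.0
    assert ours == pytest.approx(anova_icc_a1(gold, auto), abs=1e-10)


def test_icc_matches_anova_oracle_on_random_data(rng):
    for _ in range(20):
        n = int(rng.integers(4, 30))
        x = rng.normal(50, 10, n)
        y = x + rng.normal(0, 3, n)
        assert icc_agreement(x, y) == pytest.approx(anova_icc_a1(x, y), abs=1e-10)


def test_icc_limit_to_one_as_noise_vanishes(rng):
    x = rng.normal(100, 30, 200)
    assert icc_agreement(x, x + rng.normal(0, 1e-4, 200)) == pytest.approx(1.0, abs=1e-6)


def test_icc_input_validation():
    with pytest.raises(ValueError):
        icc_agreement([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        icc_agreement([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])


# ---------------------------------------------------------------------------
# cohort report


def test_single_subject_report_means(rng):
    g, a = random_mask(rng).data, random_mask(rng).data
    rep = cohort_report([(_gold(g), _mask(a))])
    assert rep.means["SI"] == pytest.approx(rep.scores[0].SI)
    assert math.isnan(rep.icc)  # < 3 subjects


def test_cohort_mean_is_arithmetic(rng):
    pairs = []
    for _ in range(4):
        pairs.append((random_mask(rng, p=0.3), random_mask(rng, p=0.3)))
    pairs = [(_gold(g.data), _mask(a.data)) for g, a in pairs]
    rep = cohort_report(pairs)
    sis = [s.SI for s in rep.scores if not math.isnan(s.SI)]
    assert rep.means["SI"] == pytest.approx(np.mean(sis))


def test_report_column_order():
    g = np.zeros((4, 4, 4), dtype=bool)
    g[1, 1, 1] = True
    rep = cohort_report([(_gold(g), _mask(g.copy()))] * 3)
    df = rep.to_frame()
    assert list(df.columns[1:8]) == ["SI", "FDR", "FNR", "FDRc", "FNRc", "DER", "OER"]
    assert list(rep.summary().keys()) == [
        "SI", "FDR", "FNR", "FDRc", "FNRc", "DER", "OER", "ICC",
    ]


def test_undefined_subjects_excluded_from_means():
    g1 = np.zeros((4, 4, 4), dtype=bool)
    g1[1, 1, 1] = True
    empty = np.zeros((4, 4, 4), dtype=bool)
    rep = cohort_report([
        (_gold(g1), _mask(g1.copy())),   # SI = 1
        (_gold(g1), _mask(empty)),       # FDR undefined
    ])
    assert rep.means["FDR"] == 0.0
    assert rep.n_undefined["FDR"] == 1
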
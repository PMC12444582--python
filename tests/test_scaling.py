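import math

import numpy as np
import pytest

from glcmlaws import (
    compute_features,
    contrast_from_asm,
    diagonal_split,
    effective_levels,
    estimate_gradient,
    predict_all,
    predict_asm,
    predict_contrast,
    predict_correlation,
    predict_idm,
    refine_gradient,
)

from conftest import sawtooth_glcm

GRID = [
    (ng, nabla, d)
    for ng in (4, 7, 8, 16)
    for nabla in range(1, min(8, ng))
    for d in range(1, 9)
]


class TestSymmetryQuantities:
    @pytest.mark.parametrize(
        "ng,nabla,expected",
        [(7, 2, 4), (4, 1, 4), (256, 3, 86), (256, 1, 256), (9, 4, 3), (8, 7, 2)],
    )
    def test_effective_levels(self, ng, nabla, expected):
        assert effective_levels(ng, nabla) == expected
        assert effective_levels(ng, -nabla) == expected

    def test_effective_levels_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            effective_levels(4, 4)
        with pytest.raises(ValueError):
            effective_levels(1, 1)

    @pytest.mark.parametrize(
        "ng,nabla,d,m1,m2,k_above,k_below",
        [
            (4, 1, 1, 3, 1, 1, -3),
            (7, 2, 1, 3, 1, 2, -6),
            (4, 1, 3, 1, 3, 3, -1),
        ],
    )
    def test_diagonal_split_examples(self, ng, nabla, d, m1, m2, k_above, k_below):
        s = diagonal_split(ng, nabla, d)
        assert (s.m1, s.m2, s.k_above, s.k_below) == (m1, m2, k_above, k_below)
        assert not s.degenerate
        assert s.m1 + s.m2 == effective_levels(ng, nabla)

    def test_diagonal_split_degenerate_whole_period(self):
        s = diagonal_split(4, 1, 4)
        assert s.degenerate
        assert (s.m1, s.m2) == (0, 0)

    def test_split_counts_match_generated_matrix(self):
        """m1/m2 and the offsets are literally where the nonzero entries sit."""
        for ng, nabla, d in [(4, 1, 1), (7, 2, 1), (16, 3, 2), (9, 4, 1)]:
            g = sawtooth_glcm(n_levels=ng, nabla=nabla, d=d)
            s = diagonal_split(ng, nabla, d)
            i, j = np.nonzero(g.counts)
            offsets = j - i
            assert np.sum(offsets == s.k_above) == s.m1
            assert np.sum(offsets == s.k_below) == s.m2
            assert len(i) == effective_levels(ng, nabla)


class TestFeaturePredictions:
    @pytest.mark.parametrize(
        "ng,nabla,d,field,expected",
        [
            (4, 1, 1, "f1", 0.25),
            (7, 2, 1, "f1", 0.25),
            (256, 1, 1, "f1", 1 / 256),
            (4, 1, 1, "f2", 3.0),
            (7, 2, 1, "f2", 12.0),
            (4, 1, 1, "f3", -0.2),
            (7, 2, 1, "f3", -0.2),  # correlation is gradient-magnitude independent
            (4, 1, 1, "f5_abs", 0.4375),
            (4, 1, 1, "f5_sq", 0.4),
        ],
    )
    def test_worked_examples(self, ng, nabla, d, field, expected):
        assert getattr(predict_all(ng, nabla, d), field) == pytest.approx(expected)

    def test_whole_period_displacement_is_trivial(self):
        p = predict_all(7, 2, 4)  # d == n_tilde
        assert p.degenerate
        assert p.f2 == 0.0
        assert p.f3 == 1.0
        assert p.f5_abs == 1.0 and p.f5_sq == 1.0
        assert p.f1 == pytest.approx(0.25)  # f1 is d-independent even here

    @pytest.mark.parametrize("ng,nabla,d", GRID)
    def test_predictions_match_measured_cyclic_features(self, ng, nabla, d):
        """Closed forms equal brute-force measurement on whole-period images."""
        p = predict_all(ng, nabla, d)
        fs = compute_features(sawtooth_glcm(n_levels=ng, nabla=nabla, d=d, periods=2))
        assert fs.f1_asm == pytest.approx(p.f1, abs=1e-12)
        assert fs.f2_contrast == pytest.approx(p.f2, abs=1e-12)
        assert fs.f5_idm_abs == pytest.approx(p.f5_abs, abs=1e-12)
        assert fs.f5_idm_sq == pytest.approx(p.f5_sq, abs=1e-12)
        if p.degenerate:
            assert fs.f3_correlation == pytest.approx(1.0, abs=1e-12)
        else:
            assert fs.f3_correlation == pytest.approx(p.f3, abs=1e-12)

    def test_sign_invariance(self):
        for ng, nabla, d in [(4, 1, 1), (7, 2, 3), (16, 5, 2)]:
            pos, neg = predict_all(ng, nabla, d), predict_all(ng, -nabla, d)
            assert pos == neg
            fs = compute_features(sawtooth_glcm(n_levels=ng, nabla=-nabla, d=d))
            assert fs.f1_asm == pytest.approx(pos.f1, abs=1e-12)
            assert fs.f2_contrast == pytest.approx(pos.f2, abs=1e-12)

    def test_contrast_symmetric_in_d_with_interior_maximum(self):
        nt = effective_levels(16, 1)
        vals = [predict_contrast(16, 1, d) for d in range(0, nt + 1)]
        for d in range(nt + 1):
            assert vals[d] == pytest.approx(predict_contrast(16, 1, nt - d))
        assert max(vals) == vals[nt // 2] == 1 * (nt // 2) * (nt - nt // 2)

    def test_asm_monotonicity(self):
        # decreasing in Ng at fixed gradient
        f1_by_ng = [predict_asm(ng, 2) for ng in (8, 16, 64, 256)]
        assert f1_by_ng == sorted(f1_by_ng, reverse=True)
        # non-decreasing in the gradient at fixed Ng (strict modulo floor ties)
        f1_by_nabla = [predict_asm(256, nabla) for nabla in range(1, 8)]
        assert f1_by_nabla == sorted(f1_by_nabla)

    def test_correlation_approaches_one_for_fine_quantization(self):
        # 1 - f3 = 6*d*(nt-d)/((nt-1)(nt+1)) ~ 6d/nt for fine quantization
        gaps = [1 - predict_correlation(ng, 1, 2) for ng in (8, 64, 512, 4096)]
        assert gaps == sorted(gaps, reverse=True)
        assert gaps[-1] == pytest.approx(12 / 4096, rel=1e-3)

    def test_idm_variants_order(self):
        for ng, nabla, d in [(16, 1, 1), (256, 3, 4), (7, 2, 1)]:
            assert predict_idm(ng, nabla, d, "squared") <= predict_idm(ng, nabla, d, "abs")


class TestInversion:
    @pytest.mark.parametrize("ng,nabla,d", [(4, 1, 1), (7, 2, 1), (16, 3, 2), (256, 5, 4)])
    def test_contrast_from_asm_consistency(self, ng, nabla, d):
        f1 = predict_asm(ng, nabla)
        assert contrast_from_asm(f1, nabla, d) == pytest.approx(predict_contrast(ng, nabla, d))

    def test_contrast_from_asm_vanishes_at_full_period(self):
        assert contrast_from_asm(0.25, 1, 4) == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "f1,ng,expected",
        [(0.25, 7, {2}), (0.25, 4, {1}), (1 / 3, 9, {3, 4})],
    )
    def test_estimate_gradient_examples(self, f1, ng, expected):
        assert estimate_gradient(f1, ng) == expected

    def test_estimate_gradient_empty_when_inconsistent(self):
        # Ng=4 admits n_tilde in {2, 4} only; f1=1/3 has no gradient solution
        assert estimate_gradient(1 / 3, 4) == set()

    def test_recovery_over_grid(self):
        for ng in (4, 7, 8, 16, 256):
            for nabla in range(1, min(8, ng)):
                assert nabla in estimate_gradient(predict_asm(ng, nabla), ng)

    def test_refine_gradient_disambiguates_with_contrast(self):
        # Ng=9: Energy alone cannot split gradients 3 and 4, Contrast can
        f1 = predict_asm(9, 3)
        assert estimate_gradient(f1, 9) == {3, 4}
        assert refine_gradient(f1, predict_contrast(9, 3, 1), 9, d=1) == {3}
        assert refine_gradient(f1, predict_contrast(9, 4, 1), 9, d=1) == {4}

    def test_estimate_gradient_rejects_bad_f1(self):
        with pytest.raises(ValueError):
            estimate_gradient(0.0, 8)
        with pytest.raises(ValueError):
            contrast_from_asm(1.5, 1, 1)
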
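import numpy as np
import pytest

from conftest import exhaustive_crf_minimum
from cootseg import (
    ClickSet,
    CrfParams,
    ProbabilityPair,
    crf_energy,
    fuse,
    graph_cut_refine,
    refinement_cue_maps,
)
from cootseg.exceptions import ConstraintError, DomainError


def make_pair(pf):
    pf = np.asarray(pf, dtype=np.float64)
    return ProbabilityPair(pf, 1.0 - pf)


class TestRefinementCueMaps:
    def test_hand_computed_distances(self):
        # uniform 1x3 strip: Df at col1 = 0? use explicit intensities [0,1,3]
        maps = refinement_cue_maps(
            np.array([[0.0, 1.0, 3.0]]), ClickSet(fg=[(0, 0)], bg=[(0, 2)]), connectivity=4
        )
        # middle pixel: Df=1, Db=2
        assert maps.Ef[0, 1] == pytest.approx(np.exp(-1) / (np.exp(-1) + np.exp(-2)), abs=1e-9)
        assert maps.Ef[0, 1] == pytest.approx(0.73106, abs=1e-5)
        assert maps.alpha[0, 1] == pytest.approx(0.36788, abs=1e-5)

    def test_fg_click_pixel(self):
        maps = refinement_cue_maps(
            np.array([[0.0, 1.0, 3.0]]), ClickSet(fg=[(0, 0)], bg=[(0, 2)]), connectivity=4
        )
        assert maps.alpha[0, 0] == 1.0
        assert maps.Ef[0, 0] > 0.5

    def test_empty_side_uses_fixed_distance(self, rng):
        img = rng.random((5, 5))
        maps = refinement_cue_maps(img, ClickSet(fg=[(2, 2)]))
        # background side empty: Eb ~ 0 everywhere, Ef ~ 1
        np.testing.assert_allclose(maps.Ef, 1.0, atol=1e-12)

    def test_no_clicks_neutral_and_flagged(self, rng):
        maps = refinement_cue_maps(rng.random((4, 4)), ClickSet())
        assert maps.no_clicks
        np.testing.assert_allclose(maps.Ef, 0.5)
        np.testing.assert_allclose(maps.alpha, 0.0, atol=1e-300)

    def test_ef_eb_sum_to_one(self, rng):
        img = rng.random((8, 8)) * 10
        maps = refinement_cue_maps(img, ClickSet(fg=[(1, 1)], bg=[(6, 6)]))
        np.testing.assert_allclose(maps.Ef + maps.Eb, 1.0, atol=1e-12)


class TestFuse:
    def test_alpha_zero_leaves_P(self, rng):
        P = make_pair(rng.random((4, 4)))
        maps = refinement_cue_maps(rng.random((4, 4)), ClickSet())
        R = fuse(P, maps)
        np.testing.assert_allclose(R.Pf, P.Pf, atol=1e-12)

    def test_alpha_one_returns_E_at_clicks(self, rng):
        img = rng.random((5, 5)) * 10
        clicks = ClickSet(fg=[(2, 2)], bg=[(0, 0)])
        maps = refinement_cue_maps(img, clicks)
        P = make_pair(rng.random((5, 5)))
        R = fuse(P, maps)
        assert R.Pf[2, 2] == pytest.approx(maps.Ef[2, 2], abs=1e-12)
        assert R.Pf[0, 0] == pytest.approx(maps.Ef[0, 0], abs=1e-12)

    def test_hand_computed_fusion_value(self):
        # Df=1, Db=2, Pf=0.5: alpha = e^-1, Ef = e^-1/(e^-1+e^-2),
        # Rf = (1-alpha)*0.5 + alpha*Ef = 0.58500...
        maps = refinement_cue_maps(
            np.array([[0.0, 1.0, 3.0]]), ClickSet(fg=[(0, 0)], bg=[(0, 2)]), connectivity=4
        )
        P = make_pair(np.full((1, 3), 0.5))
        R = fuse(P, maps)
        alpha = np.exp(-1.0)
        ef = np.exp(-1.0) / (np.exp(-1.0) + np.exp(-2.0))
        assert R.Pf[0, 1] == pytest.approx((1 - alpha) * 0.5 + alpha * ef, abs=1e-12)
        assert R.Pf[0, 1] == pytest.approx(0.58500, abs=1e-5)

    def test_normalization_preserved(self, rng):
        img = rng.random((6, 6)) * 5
        maps = refinement_cue_maps(img, ClickSet(fg=[(0, 0)], bg=[(5, 5)]))
        P = make_pair(rng.random((6, 6)))
        R = fuse(P, maps)
        np.testing.assert_allclose(R.Pf + R.Pb, 1.0, atol=1e-9)


class TestCrfEnergy:
    def test_unary_only_symmetric_half(self):
        R = make_pair(np.full((3, 3), 0.5))
        e = crf_energy(np.zeros((3, 3), dtype=np.uint8), R, np.zeros((3, 3)), None, CrfParams(lam=0.0))
        assert e == pytest.approx(9 * np.log(2.0))

    def test_uniform_image_equal_labels_no_pairwise(self):
        R = make_pair(np.full((4, 4), 0.7))
        params = CrfParams(lam=2.0, sigma=1.0)
        e_unary = crf_energy(np.ones((4, 4), dtype=np.uint8), R, np.zeros((4, 4)), None, params)
        assert e_unary == pytest.approx(16 * -np.log(0.7))

    def test_hand_computed_two_pixel_case(self):
        R = make_pair(np.array([[0.9], [0.1]]))
        e = crf_energy(
            np.array([[1], [0]]), R, np.zeros((2, 1)), None, CrfParams(lam=1.0, sigma=1.0)
        )
        assert e == pytest.approx(-2 * np.log(0.9) + 1.0, abs=1e-9)
        assert e == pytest.approx(1.21072, abs=1e-5)

    def test_click_violation_raises(self):
        R = make_pair(np.full((3, 3), 0.5))
        with pytest.raises(ConstraintError):
            crf_energy(
                np.zeros((3, 3), dtype=np.uint8),
                R,
                np.zeros((3, 3)),
                ClickSet(fg=[(1, 1)]),
                CrfParams(),
            )


class TestGraphCut:
    def test_lambda_zero_is_threshold(self, rng):
        pf = rng.random((6, 6))
        mask = graph_cut_refine(make_pair(pf), rng.random((6, 6)), None, CrfParams(lam=0.0))
        np.testing.assert_array_equal(mask.values, (pf > 0.5).astype(np.uint8))

    def test_contradictory_clicks_rejected(self, rng):
        P = make_pair(rng.random((4, 4)))
        clicks = ClickSet(fg=[(1, 1)])
        clicks.bg = [(1, 1)]  # bypass the ClickSet guard to hit the solver's check
        with pytest.raises(DomainError):
            graph_cut_refine(P, rng.random((4, 4)), clicks, CrfParams())

    def test_bg_click_overrides_high_probability(self, rng):
        pf = np.full((5, 5), 0.95)
        img = rng.random((5, 5))
        for lam in (0.0, 2.0, 10.0):
            mask = graph_cut_refine(
                make_pair(pf), img, ClickSet(bg=[(2, 2)]), CrfParams(lam=lam, sigma=1.0)
            )
            assert mask.values[2, 2] == 0

    def test_fg_click_overrides_low_probability(self, rng):
        pf = np.full((5, 5), 0.05)
        mask = graph_cut_refine(
            make_pair(pf), rng.random((5, 5)), ClickSet(fg=[(2, 2)]), CrfParams(lam=1.0, sigma=1.0)
        )
        assert mask.values[2, 2] == 1

    @pytest.mark.parametrize("lam", [0.0, 0.5, 2.0])
    def test_attains_exhaustive_minimum_on_3x3(self, lam, rng):
        params = CrfParams(lam=lam, sigma=0.7)
        for _ in range(20):
            pf = rng.uniform(0.05, 0.95, (3, 3))
            img = rng.random((3, 3))
            P = make_pair(pf)
            cut = graph_cut_refine(P, img, None, params)
            e_cut = crf_energy(cut, P, img, None, params)
            e_min, _ = exhaustive_crf_minimum(P, img, params)
            assert e_cut == pytest.approx(e_min, abs=1e-9)

    def test_energy_not_above_reference_labelings(self, rng):
        params = CrfParams(lam=1.5, sigma=0.5)
        for _ in range(10):
            pf = rng.uniform(0.02, 0.98, (7, 7))
            img = rng.random((7, 7)) * 3
            P = make_pair(pf)
            cut = graph_cut_refine(P, img, None, params)
            e_cut = crf_energy(cut, P, img, None, params)
            for ref in (
                (pf > 0.5).astype(np.uint8),
                np.zeros((7, 7), dtype=np.uint8),
                np.ones((7, 7), dtype=np.uint8),
            ):
                assert e_cut <= crf_energy(ref, P, img, None, params) + 1e-9
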
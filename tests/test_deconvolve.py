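"""Forward model fidelity, Step-2 inversion, and NNLS composition."""

import numpy as np
import pytest

from dropsig.deconvolve import (CompositionEstimator, ForwardModel,
                                SignatureDeconvolver, deconvolve_pipeline,
                                estimate_composition, forward_droplet_profile,
                                solve_single_cell_profile)
from dropsig.occupancy import OccupancyModel
from dropsig.signatures import SignatureProfile


def hardcoded_three_marker_forward(s, n, p1, p2):
    """Literal transcription of the published eight-equation system (M=3).

    Independent oracle for the generalized forward model; kept as a
    direct term-by-term copy, not derived from the package code.
    """
    s1, s2, s3, s4, s5, s6, s7, s8 = s
    n1, n2, n3, n4, n5, n6, n7, n8 = n
    d1 = p1 * n1 * s1 + p2 * n1 * s1**2
    d2 = (p1 * (n2 * s1 + (n1 + n2) * s2)
          + p2 * (n2 * s1**2 + (n1 + n2) * (s2**2 + s1 * s2)))
    d3 = (p1 * (n3 * s1 + (n1 + n3) * s3)
          + p2 * (n3 * s1**2 + (n1 + n3) * (s3**2 + s1 * s3)))
    d4 = (p1 * (n4 * s1 + (n3 + n4) * s2 + (n2 + n4) * s3
                + (n1 + n2 + n3 + n4) * s4)
          + p2 * (n4 * s1**2 + (n3 + n4) * (s2**2 + s1 * s2)
                  + (n2 + n4) * (s3**2 + s1 * s3)
                  + (n1 + n2 + n3 + n4) * (s4**2 + (s1 + s2 + s3) * s4 + s2 * s3)))
    d5 = (p1 * (n5 * s1 + (n1 + n5) * s5)
          + p2 * (n5 * s1**2 + (n1 + n5) * (s5**2 + s1 * s5)))
    d6 = (p1 * (n6 * s1 + (n5 + n6) * s2 + (n2 + n6) * s5
                + (n1 + n2 + n5 + n6) * s6)
          + p2 * (n6 * s1**2 + (n5 + n6) * (s2**2 + s1 * s2)
                  + (n2 + n6) * (s5**2 + s1 * s5)
                  + (n1 + n2 + n5 + n6) * (s6**2 + (s1 + s2 + s5) * s6 + s2 * s5)))
    d7 = (p1 * (n7 * s1 + (n5 + n7) * s3 + (n3 + n7) * s5
                + (n1 + n3 + n5 + n7) * s7)
          + p2 * (n7 * s1**2 + (n5 + n7) * (s3**2 + s1 * s3)
                  + (n3 + n7) * (s5**2 + s1 * s5)
                  + (n1 + n3 + n5 + n7) * (s7**2 + (s1 + s3 + s5) * s7 + s3 * s5)))
    d8 = (p1 * (n8 * s1 + (n7 + n8) * s2 + (n6 + n8) * s3
                + (n5 + n6 + n7 + n8) * s4 + (n4 + n8) * s5
                + (n3 + n4 + n7 + n8) * s6 + (n2 + n4 + n6 + n8) * s7 + s8)
          + p2 * (n8 * s1**2 + (n7 + n8) * (s2**2 + s1 * s2)
                  + (n6 + n8) * (s3**2 + s1 * s3)
                  + (n5 + n6 + n7 + n8) * (s4**2 + s4 * (s1 + s2 + s3) + s2 * s3)
                  + (n4 + n8) * (s5**2 + s1 * s5)
                  + (n3 + n4 + n7 + n8) * (s6**2 + s6 * (s1 + s2 + s5) + s2 * s5)
                  + (n2 + n4 + n6 + n8) * (s7**2 + s7 * (s1 + s3 + s5) + s3 * s5)
                  + s2 * s7 + s3 * s6 + s4 * (s5 + s6 + s7) + s6 * s7 + s8))
    return np.array([d1, d2, d3, d4, d5, d6, d7, d8])


def _model(n, lam, variant="verbatim"):
    return ForwardModel(SignatureProfile(n, role="ambient", renormalize=True),
                        OccupancyModel(lam), variant)


class TestForwardModel:
    def test_matches_hardcoded_equations_on_random_inputs(self):
        """Generalized model == literal eight-equation system to 1e-12."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            s = rng.dirichlet(np.ones(8))
            n = rng.dirichlet(np.ones(8))
            lam = rng.uniform(0.05, 2.0)
            model = _model(n, lam)
            p1, p2 = model.occupancy.p1, model.occupancy.p2
            expected = hardcoded_three_marker_forward(s, n, p1, p2)
            np.testing.assert_allclose(model.predict(s), expected, atol=1e-12)

    def test_identity_limit_no_ambient_no_doublets(self):
        # point-mass ambient on all-negative and lambda -> 0 leaves s unchanged
        rng = np.random.default_rng(0)
        s = rng.dirichlet(np.ones(8))
        n = np.zeros(8); n[0] = 1.0
        d = _model(n, 1e-9).predict(s)
        np.testing.assert_allclose(d, s, atol=1e-8)

    def test_single_marker_hand_expansion(self):
        # M=1 analogue expanded by hand: n=(0.9,0.1), s=(0.5,0.5), lambda=0.2
        d = _model([0.9, 0.1], 0.2).predict([0.5, 0.5])
        np.testing.assert_allclose(d, [0.4295454545, 0.5477272727], atol=1e-9)
        assert d.sum() == pytest.approx(0.9772727273, abs=1e-9)

    def test_verbatim_mass_deficit_and_multinomial_conservation(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            s = rng.dirichlet(np.ones(8))
            n = rng.dirichlet(np.ones(8))
            lam = rng.uniform(0.05, 2.0)
            mv = _model(n, lam, "verbatim")
            p1, p2 = mv.occupancy.p1, mv.occupancy.p2
            assert mv.predict(s).sum() == pytest.approx(
                p1 + p2 * (1 + np.sum(s**2)) / 2, abs=1e-12)
            mm = _model(n, lam, "multinomial")
            assert mm.predict(s).sum() == pytest.approx(1.0, abs=1e-12)

    def test_no_doublets_conserves_probability(self):
        rng = np.random.default_rng(4)
        s = rng.dirichlet(np.ones(8))
        n = rng.dirichlet(np.ones(8))
        d = _model(n, 1e-12).predict(s)  # p2 ~ 0
        assert d.sum() == pytest.approx(1.0, abs=1e-9)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            _model([0.5, 0.5], 0.2).predict([0.25] * 4)

    def test_generic_beyond_three_markers(self):
        # M=2: cross-check one entry by hand; pair (2,3) combines to 4
        n = np.array([0.7, 0.1, 0.1, 0.1])
        s = np.array([0.4, 0.3, 0.2, 0.1])
        model = _model(n, 0.5)
        p1, p2 = model.occupancy.p1, model.occupancy.p2
        d4 = (p1 * (n[3] * s[0] + (n[2] + n[3]) * s[1] + (n[1] + n[3]) * s[2]
                    + n.sum() * s[3])
              + p2 * (n[3] * s[0]**2 + (n[2] + n[3]) * (s[1]**2 + s[0] * s[1])
                      + (n[1] + n[3]) * (s[2]**2 + s[0] * s[2])
                      + n.sum() * (s[3]**2 + (s[0] + s[1] + s[2]) * s[3] + s[1] * s[2])))
        assert model.predict(s)[3] == pytest.approx(d4, abs=1e-12)


class TestSolve:
    def test_round_trip_recovers_s(self):
        """forward then solve recovers s to L-inf < 1e-8 (100 seeds)."""
        worst = 0.0
        for seed in range(1, 101):
            rng = np.random.default_rng(seed)
            s = rng.dirichlet(np.ones(8))
            n = rng.dirichlet(np.ones(8))
            model = _model(n, 0.2)
            res = solve_single_cell_profile(model.predict(s), n, 0.2)
            worst = max(worst, float(np.max(np.abs(res.s - s))))
        assert worst < 1e-8

    def test_identity_case_immediate(self):
        rng = np.random.default_rng(10)
        d = rng.dirichlet(np.ones(8))
        n = np.zeros(8); n[0] = 1.0
        res = solve_single_cell_profile(d, n, 1e-9)
        np.testing.assert_allclose(res.s, d, atol=1e-8)
        assert res.converged

    def test_multinomial_round_trip(self):
        rng = np.random.default_rng(8)
        s = rng.dirichlet(np.ones(8))
        n = rng.dirichlet(np.ones(8))
        model = _model(n, 0.4, "multinomial")
        res = solve_single_cell_profile(model.predict(s), n, 0.4,
                                        variant="multinomial")
        np.testing.assert_allclose(res.s, s, atol=1e-8)

    def test_estimator_front(self):
        rng = np.random.default_rng(12)
        s = rng.dirichlet(np.ones(8))
        n = rng.dirichlet(np.ones(8))
        d = _model(n, 0.2).predict(s)
        dec = SignatureDeconvolver().fit(d, n, 0.2)
        np.testing.assert_allclose(dec.s_, s, atol=1e-8)
        assert dec.converged_ and dec.residual_ < 1e-9
        assert dec.get_params()["variant"] == "verbatim"


class TestComposition:
    def _refs(self):
        r1 = np.zeros(8); r1[4] = 0.9; r1[0] = 0.1
        r2 = np.zeros(8); r2[2] = 0.9; r2[0] = 0.1
        r3 = np.zeros(8); r3[1] = 0.9; r3[0] = 0.1
        return [r1, r2, r3]

    def test_pure_population(self):
        refs = self._refs()
        est = estimate_composition(refs[0], refs)
        np.testing.assert_allclose(est.weights, [1, 0, 0], atol=1e-10)
        assert est.residual < 1e-10

    def test_even_mixture_exact(self):
        refs = self._refs()
        s = 0.5 * refs[0] + 0.5 * refs[1]
        est = estimate_composition(s, refs)
        np.testing.assert_allclose(est.weights, [0.5, 0.5, 0.0], atol=1e-10)

    def test_kkt_conditions(self):
        # active-set optimum: zero weights have non-negative gradient,
        # positive weights have (near-)zero gradient
        rng = np.random.default_rng(21)
        refs = self._refs()
        R = np.column_stack(refs)
        for _ in range(25):
            s = rng.dirichlet(np.ones(8))
            est = estimate_composition(s, refs, normalize=False)
            grad = R.T @ (R @ est.raw_weights - s)
            for w, g in zip(est.raw_weights, grad):
                if w > 1e-12:
                    assert abs(g) < 1e-8
                else:
                    assert g > -1e-8

    def test_multinomial_noise_recovery(self):
        # noisy mixtures of well-separated profiles: weights near truth
        rng = np.random.default_rng(33)
        refs = self._refs()
        truth = np.array([0.899, 0.100, 0.001])
        s_true = np.column_stack(refs) @ truth
        errs = []
        for _ in range(100):
            counts = rng.multinomial(100_000, s_true)
            est = estimate_composition(counts / counts.sum(), refs)
            errs.append(est.weights - truth)
        errs = np.asarray(errs)
        mean_err = errs.mean(axis=0)
        se = errs.std(axis=0, ddof=1) / np.sqrt(len(errs))
        assert np.all(np.abs(mean_err) < 3 * np.maximum(se, 1e-6))

    def test_estimator_front(self):
        refs = self._refs()
        est = CompositionEstimator(references=refs).fit(refs[1])
        np.testing.assert_allclose(est.weights_, [0, 1, 0], atol=1e-10)


class TestPipeline:
    def test_pure_population_no_ambient(self):
        r = np.zeros(8); r[4] = 0.9; r[0] = 0.1
        n = np.zeros(8); n[0] = 1.0
        d = _model(n, 0.2).predict(r)
        out = deconvolve_pipeline((d, n, 0.2), [r])
        np.testing.assert_allclose(out["mixture"].weights, [1.0], atol=1e-8)

    def test_no_step2_bypasses_correction(self):
        r = np.zeros(8); r[4] = 0.9; r[0] = 0.1
        n = np.zeros(8); n[0] = 1.0
        d = _model(n, 0.2).predict(r)
        out = deconvolve_pipeline((d, n, 0.2), [r], step2=False)
        np.testing.assert_allclose(out["s"], d)
        assert out["diagnostics"]["step2"] is False

    def test_missing_constituent_raises_residual(self):
        rng = np.random.default_rng(17)
        r1 = np.zeros(8); r1[4] = 0.9; r1[0] = 0.1
        r2 = np.zeros(8); r2[2] = 0.9; r2[0] = 0.1
        n = np.zeros(8); n[0] = 1.0
        s_true = 0.6 * r1 + 0.4 * r2
        d = _model(n, 0.2).predict(s_true)
        full = deconvolve_pipeline((d, n, 0.2), [r1, r2])
        partial = deconvolve_pipeline((d, n, 0.2), [r1])
        assert partial["mixture"].residual > 10 * max(full["mixture"].residual, 1e-12)
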
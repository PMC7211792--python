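"""Constitutive models: energies, conversions, and the neo-Hookean fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palpquant.fem import ForceProfile
from palpquant.materials import (
    CANCEROUS_NODULE,
    HEALTHY_PROSTATE,
    DeformationState,
    FitConvergenceError,
    NeoHookeanMaterial,
    OgdenMaterial,
    fit_neo_hookean,
    material_from_yaml,
    material_to_yaml,
    neo_hookean_energy,
    ogden_energy,
    ogden_from_modulus,
    young_from_c1,
)

stretch = st.floats(min_value=0.5, max_value=2.0)


def uniaxial(lam):
    return DeformationState.uniaxial(lam)


class TestOgdenEnergy:
    @pytest.mark.parametrize("mat", [HEALTHY_PROSTATE, CANCEROUS_NODULE,
                                     OgdenMaterial(mu=(0.01,), alpha=(2.0,))])
    def test_zero_at_reference(self, mat):
        assert ogden_energy(DeformationState.identity(), mat) == 0.0

    def test_cancer_energy_doubles_healthy(self):
        s = DeformationState((1.2, 1.2**-0.5, 1.2**-0.5))
        wh = ogden_energy(s, HEALTHY_PROSTATE)
        wc = ogden_energy(s, CANCEROUS_NODULE)
        assert wc == pytest.approx(2.0 * wh, rel=1e-12)

    def test_hand_evaluated_value(self):
        # (2*0.01/4) * (1.1^2 + 1.1^-2 + 1 - 3), confirmed by a symbolic oracle
        s = DeformationState((1.1, 1.0 / 1.1, 1.0))
        w = ogden_energy(s, OgdenMaterial(mu=(0.01,), alpha=(2.0,)))
        assert w == pytest.approx(1.8223140495867769e-4, rel=1e-12)

    def test_symbolic_oracle(self):
        sympy = pytest.importorskip("sympy")
        l1, l2 = 1.3, 0.9
        s = DeformationState((l1, l2, 1.0 / (l1 * l2)))
        mat = HEALTHY_PROSTATE
        lam = sympy.symbols("l1 l2 l3")
        expr = sum(
            2 * mu / a**2 * (lam[0] ** a + lam[1] ** a + lam[2] ** a - 3)
            for mu, a in zip(mat.mu, mat.alpha)
        )
        expected = float(expr.subs(dict(zip(lam, s.principal_stretches))))
        assert ogden_energy(s, mat) == pytest.approx(expected, rel=1e-10)

    @settings(deadline=None, max_examples=50)
    @given(l1=stretch, l2=stretch)
    def test_permutation_invariance(self, l1, l2):
        l3 = 1.0 / (l1 * l2)
        perms = [(l1, l2, l3), (l2, l3, l1), (l3, l1, l2), (l2, l1, l3)]
        vals = [ogden_energy(DeformationState(p), HEALTHY_PROSTATE) for p in perms]
        assert np.allclose(vals, vals[0], rtol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(l1=stretch, l2=stretch, factor=st.floats(min_value=0.1, max_value=10))
    def test_linear_in_mu(self, l1, l2, factor):
        s = DeformationState((l1, l2, 1.0 / (l1 * l2)))
        w = ogden_energy(s, HEALTHY_PROSTATE)
        ws = ogden_energy(s, HEALTHY_PROSTATE.scaled(factor))
        assert ws == pytest.approx(factor * w, rel=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(l1=stretch, l2=stretch)
    def test_reduces_to_neo_hookean(self, l1, l2):
        c1 = 4.0e-3
        s = DeformationState((l1, l2, 1.0 / (l1 * l2)))
        w_ogden = ogden_energy(s, OgdenMaterial(mu=(2 * c1,), alpha=(2.0,)))
        w_nh = neo_hookean_energy(s, NeoHookeanMaterial(c1=c1))
        assert w_ogden == pytest.approx(w_nh, rel=1e-13, abs=1e-18)

    def test_small_strain_tangent_is_young_modulus(self):
        # d^2/dlam^2 of the uniaxial energy at lam=1 equals E = 3*sum(mu_i)
        for mat in (HEALTHY_PROSTATE, CANCEROUS_NODULE):
            h = 1e-4
            w = [ogden_energy(uniaxial(1.0 + k * h), mat) for k in (-1, 0, 1)]
            e_num = (w[0] - 2 * w[1] + w[2]) / h**2
            assert e_num == pytest.approx(3.0 * sum(mat.mu), rel=1e-3)

    def test_incompressible_contract(self):
        s = DeformationState((1.1, 1.0 / 1.1, 1.0), jel=1.2)
        with pytest.raises(ValueError, match="jel"):
            ogden_energy(s, HEALTHY_PROSTATE)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            DeformationState((1.0, -1.0, -1.0))
        with pytest.raises(ValueError):
            DeformationState((1.5, 1.0, 1.0))  # product != 1
        with pytest.raises(ValueError):
            OgdenMaterial(mu=(0.01,), alpha=(0.0,))
        with pytest.raises(ValueError):
            OgdenMaterial(mu=(-0.01,), alpha=(2.0,))  # mu0 <= 0
        with pytest.raises(ValueError):
            OgdenMaterial(mu=(0.01, 0.01), alpha=(2.0,))


class TestNeoHookean:
    def test_reference_state(self):
        assert neo_hookean_energy(DeformationState.identity(),
                                  NeoHookeanMaterial(1e-2)) == 0.0

    def test_direct_substitution(self):
        s = DeformationState.from_first_invariant(3.5)
        w = neo_hookean_energy(s, NeoHookeanMaterial(c1=4.6898e-3))
        assert w == pytest.approx(2.3449e-3, rel=1e-4)

    def test_uniaxial_value(self):
        s = uniaxial(1.1)  # I1 = 1.21 + 2/1.1
        w = neo_hookean_energy(s, NeoHookeanMaterial(c1=0.01))
        assert w == pytest.approx(2.8182e-4, rel=1e-4)

    def test_compressible_state_rejected(self):
        s = DeformationState((1.1, 1 / 1.1, 1.0), jel=1.1)
        with pytest.raises(ValueError):
            neo_hookean_energy(s, NeoHookeanMaterial(1e-2))


class TestConversions:
    def test_published_modulus_rescaling(self):
        cancer = ogden_from_modulus(HEALTHY_PROSTATE, 20.0, 40.0)
        assert cancer.mu == pytest.approx((0.04238, -0.02240), rel=1e-12)
        assert cancer.alpha == HEALTHY_PROSTATE.alpha

    def test_identity_and_linear_scaling(self):
        same = ogden_from_modulus(HEALTHY_PROSTATE, 20.0, 20.0)
        assert same == HEALTHY_PROSTATE
        tripled = ogden_from_modulus(
            OgdenMaterial(mu=(0.02,), alpha=(2.0,)), 10.0, 30.0
        )
        assert tripled.mu == pytest.approx((0.06,))

    def test_nonpositive_moduli_rejected(self):
        with pytest.raises(ValueError):
            ogden_from_modulus(HEALTHY_PROSTATE, 0.0, 40.0)

    @pytest.mark.parametrize(
        "c1, expected_3sf",
        [(4.6898e-3, 28.1), (6.5872e-3, 39.5), (1.0 / 6000.0, 1.0)],
    )
    def test_young_from_c1(self, c1, expected_3sf):
        e = young_from_c1(NeoHookeanMaterial(c1=c1))
        assert float(f"{e:.3g}") == expected_3sf


def _linear_oracle(positions, depths):
    """Analytic indentation oracle: forces exactly proportional to C1 (as
    for incompressible hyperelasticity under displacement control), with a
    smooth position/depth shape."""
    x = np.asarray(positions)

    def forward(c1):
        return [
            ForceProfile(
                indentation_depth=d,
                positions=x,
                forces=c1 * d**1.5 * (10.0 + np.exp(-((x - 30.0) ** 2) / 200.0)),
            )
            for d in depths
        ]

    return forward


class TestNeoHookeanFit:
    positions = np.linspace(14, 46, 9)
    depths = (2.0, 4.0, 6.0)

    def test_noiseless_closed_loop(self):
        forward = _linear_oracle(self.positions, self.depths)
        for c1_true in (1e-3, 5e-3, 2e-2):
            fit = fit_neo_hookean(forward(c1_true), forward, init_c1=3e-3)
            assert fit.material.c1 == pytest.approx(c1_true, rel=1e-3)
            assert fit.max_error < 1e-6

    def test_duplicated_data_same_estimate(self):
        forward = _linear_oracle(self.positions, self.depths)
        measured = forward(5e-3)

        def forward_dup(c1):
            return forward(c1) + forward(c1)

        f1 = fit_neo_hookean(measured, forward)
        f2 = fit_neo_hookean(measured + measured, forward_dup)
        assert f2.material.c1 == pytest.approx(f1.material.c1, rel=1e-9)

    def test_noise_bias_monte_carlo(self):
        forward = _linear_oracle(self.positions, self.depths)
        c1_true = 5e-3
        clean = forward(c1_true)
        fmax = max(p.forces.max() for p in clean)
        estimates = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            noisy = [
                ForceProfile(
                    indentation_depth=p.indentation_depth,
                    positions=p.positions,
                    forces=np.clip(
                        p.forces + rng.normal(0, 0.02 * fmax, len(p)), 1e-9, None
                    ),
                )
                for p in clean
            ]
            estimates.append(fit_neo_hookean(noisy, forward).material.c1)
        assert np.mean(estimates) == pytest.approx(c1_true, rel=0.02)

    def test_error_statistics_ordering(self):
        forward = _linear_oracle(self.positions, self.depths)
        measured = forward(5e-3)
        noisy = [
            ForceProfile(p.indentation_depth, p.positions, p.forces * 1.01)
            for p in measured
        ]
        fit = fit_neo_hookean(noisy, forward)
        assert fit.min_error <= fit.mean_error <= fit.max_error
        assert fit.young_modulus_kpa == pytest.approx(6000 * fit.material.c1)

    def test_zero_forces_rejected(self):
        forward = _linear_oracle(self.positions, self.depths)
        bad = [
            ForceProfile(2.0, self.positions, np.zeros_like(self.positions))
        ]
        with pytest.raises(ValueError, match="zero"):
            fit_neo_hookean(bad, forward)


class TestYaml:
    @pytest.mark.parametrize(
        "mat", [HEALTHY_PROSTATE, NeoHookeanMaterial(c1=4.6898e-3)]
    )
    def test_round_trip(self, mat):
        assert material_from_yaml(material_to_yaml(mat)) == mat

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            material_from_yaml("model: mooney_rivlin\nc1: 1.0\n")
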
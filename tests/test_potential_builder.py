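"""Assembly of the interaction potential from its terms."""

import math

import numpy as np
import pytest

import porefpt as p


def uniform_density(grid, value, kind="effective"):
    return p.ChargeDensityProfile(grid=grid, values=np.full(len(grid), value),
                                  kind=kind)


class TestElectrokinetic:
    def test_zero_voltage_is_zero(self):
        grid = np.linspace(0.0, 10.0, 21)
        UE = p.electrokinetic_term(uniform_density(grid, 1.0), 0.0)
        np.testing.assert_array_equal(UE.U, 0.0)

    def test_uniform_density_gives_linear_potential(self):
        # sigma = +1 e-/nm at V = thermal voltage => slope exactly 1 kBT/nm
        grid = np.linspace(0.0, 10.0, 21)
        UE = p.electrokinetic_term(uniform_density(grid, 1.0), 25.693)
        np.testing.assert_allclose(UE.U, grid, rtol=1e-12)
        assert UE.U[0] == 0.0

    def test_sign_bilinearity(self):
        grid = np.linspace(0.0, 10.0, 21)
        sigma = np.random.default_rng(5).normal(size=21)
        up = p.electrokinetic_term(
            p.ChargeDensityProfile(grid, sigma, "effective"), 40.0)
        dn = p.electrokinetic_term(
            p.ChargeDensityProfile(grid, -sigma, "effective"), -40.0)
        np.testing.assert_allclose(up.U, dn.U)

    def test_requires_effective_density(self):
        grid = np.linspace(0.0, 1.0, 5)
        with pytest.raises(ValueError, match="effective"):
            p.electrokinetic_term(uniform_density(grid, 1.0, kind="native"),
                                  10.0)


class TestFreeEntropy:
    def test_midpoint_value(self):
        grid = np.linspace(0.0, 40.0, 201)
        US = p.entropy_free_term(grid, 40.0, nu=0.59)
        mid = US.U[100]
        assert mid == pytest.approx(0.59 * 2.0 * math.log(0.5), rel=1e-12)

    def test_symmetry(self):
        grid = np.linspace(0.0, 40.0, 201)
        US = p.entropy_free_term(grid, 40.0)
        np.testing.assert_allclose(US.U, US.U[::-1], atol=1e-12)

    def test_endpoints_regularized_to_half_spacing(self):
        grid = np.linspace(0.0, 40.0, 201)
        US = p.entropy_free_term(grid, 40.0)
        h = grid[1] - grid[0]
        edge = h / (2 * 40.0)
        assert np.isfinite(US.U).all()
        assert US.U[0] == pytest.approx(
            0.59 * (math.log(edge) + math.log1p(-edge)))

    def test_boltzmann_weights_integrable_on_refinement(self):
        # e^{+-US} stay integrable despite the logarithmic divergences:
        # trapezoid estimates converge under grid refinement.  The bounded
        # weight e^{+US} settles below 0.1%; the integrable-singular e^{-US}
        # ~ x^{-nu} converges more slowly, so successive refinements must
        # shrink the change.
        L, laa = 40.0, 0.4
        for sign, tol in ((+1.0, 1e-3), (-1.0, None)):
            vals = []
            for factor in (2.0, 4.0, 8.0):
                n = int(round(factor * L / laa)) + 1
                grid = np.linspace(0.0, L, n)
                US = p.entropy_free_term(grid, L)
                vals.append(np.trapezoid(np.exp(sign * US.U), grid))
            d1 = abs(vals[1] - vals[0]) / vals[-1]
            d2 = abs(vals[2] - vals[1]) / vals[-1]
            assert d2 < d1
            if tol is not None:
                assert d1 < tol


class TestTetheredEntropy:
    def setup_method(self):
        self.L = 60.0
        self.grid = np.linspace(0.0, self.L, 301)
        self.pore = p.PoreModel(2.355)

    def test_finite_everywhere_even_with_zero_tether_distance(self):
        cfg = p.EntropyConfig(tethered=True, lt=0.0)
        US = p.entropy_tethered_term(self.grid, self.L, self.pore, cfg)
        assert np.isfinite(US.U).all()

    def test_diverges_as_translocated_length_vanishes(self):
        # U rises steeply and monotonically approaching x = Lp/2 from above
        # (nC -> 0+): the first valid points decrease away from the edge
        cfg = p.EntropyConfig(tethered=True, lt=1.0)
        US = p.entropy_tethered_term(self.grid, self.L, self.pore, cfg)
        valid = np.flatnonzero(
            (self.grid > self.pore.Lp / 2) & (self.grid < self.L - self.pore.Lp / 2)
        )
        near_edge = US.U[valid[:5]]
        assert near_edge[0] > 20.0
        assert np.all(np.diff(near_edge) < 0)

    def test_minimum_shifted_to_zero(self):
        cfg = p.EntropyConfig(tethered=True, lt=2.0)
        US = p.entropy_tethered_term(self.grid, self.L, self.pore, cfg)
        assert US.U.min() == pytest.approx(0.0, abs=1e-12)

    def test_clamped_outside_valid_range(self):
        cfg = p.EntropyConfig(tethered=True, lt=2.0)
        US = p.entropy_tethered_term(self.grid, self.L, self.pore, cfg)
        valid = (self.grid > self.pore.Lp / 2) & (
            self.grid < self.L - self.pore.Lp / 2)
        first = np.flatnonzero(valid)[0]
        assert US.U[0] == pytest.approx(US.U[first] + 25.0)

    def test_kuhn_length_changes_values_not_domain(self):
        cfg1 = p.EntropyConfig(tethered=True, lt=2.0, b=0.6)
        cfg2 = p.EntropyConfig(tethered=True, lt=2.0, b=1.2)
        U1 = p.entropy_tethered_term(self.grid, self.L, self.pore, cfg1)
        U2 = p.entropy_tethered_term(self.grid, self.L, self.pore, cfg2)
        wall1 = U1.U == U1.U[0]
        wall2 = U2.U == U2.U[0]
        assert np.isfinite(U2.U).all() and not np.allclose(U1.U, U2.U)
        # clamping domain is set by Lp alone
        assert np.array_equal(np.flatnonzero(wall1), np.flatnonzero(wall2))

    def test_contour_shorter_than_pore_rejected(self):
        cfg = p.EntropyConfig(tethered=True)
        with pytest.raises(ValueError, match="exceed"):
            p.entropy_tethered_term(np.linspace(0, 2, 11), 2.0,
                                    p.PoreModel(5.0), cfg)


class TestAuxiliaryTerms:
    grid = np.linspace(0.0, 100.0, 201)

    def test_constant_force(self):
        UF = p.constant_force_term(0.1, self.grid)
        assert UF.U[100] == pytest.approx(5.0)
        assert UF.U[-1] - UF.U[0] == pytest.approx(0.1 * 100.0)
        np.testing.assert_array_equal(
            p.constant_force_term(0.0, self.grid).U, 0.0)

    def test_gaussian_peak_and_half_width(self):
        EG, xG, sG = 3.0, 30.0, 5.0
        x_half = xG + sG * math.sqrt(2.0 * math.log(2.0))
        grid = np.sort(np.append(self.grid, [x_half]))
        UG = p.gaussian_term(EG, xG, sG, grid)
        i_pk = np.argmin(np.abs(grid - xG))
        assert UG.U[i_pk] == pytest.approx(EG)
        i_h = np.argmin(np.abs(grid - x_half))
        assert UG.U[i_h] == pytest.approx(EG / 2.0, rel=1e-9)

    def test_attractive_gaussian_allowed(self):
        UG = p.gaussian_term(-5.0, 30.0, 2.0, self.grid)
        assert UG.U.min() == pytest.approx(-5.0, rel=1e-6)

    def test_barrier_center_and_asymptotes(self):
        UB = p.barrier_term(4.0, 50.0, 2.0, self.grid)
        assert UB.U[100] == pytest.approx(0.0, abs=1e-12)
        assert UB.U[-1] == pytest.approx(4.0, rel=1e-6)
        assert UB.U[0] == pytest.approx(-4.0, rel=1e-6)

    def test_opposed_barriers_make_smoothed_box(self):
        up = p.barrier_term(2.0, 30.0, 2.0, self.grid)
        dn = p.barrier_term(-2.0, 70.0, 2.0, self.grid)
        box = p.total_potential([up, dn])
        assert box.U[np.argmin(np.abs(self.grid - 50.0))] == pytest.approx(
            4.0, rel=1e-4)
        assert abs(box.U[0]) < 1e-3 and abs(box.U[-1]) < 1e-3

    @pytest.mark.parametrize("factory", [
        lambda g: p.gaussian_term(1.0, 5.0, 0.0, g),
        lambda g: p.barrier_term(1.0, 5.0, -1.0, g),
    ])
    def test_nonpositive_widths_rejected(self, factory):
        with pytest.raises(ValueError, match="positive"):
            factory(self.grid)


class TestTotalPotential:
    grid = np.linspace(0.0, 100.0, 201)

    def test_empty_sum_is_zero(self):
        U = p.total_potential([], grid=self.grid)
        np.testing.assert_array_equal(U.U, 0.0)

    def test_single_term_identity(self):
        UG = p.gaussian_term(2.0, 30.0, 5.0, self.grid)
        np.testing.assert_array_equal(p.total_potential([UG]).U, UG.U)

    def test_opposite_terms_cancel(self):
        a = p.gaussian_term(2.0, 30.0, 5.0, self.grid)
        b = p.gaussian_term(-2.0, 30.0, 5.0, self.grid)
        np.testing.assert_allclose(p.total_potential([a, b]).U, 0.0,
                                   atol=1e-14)

    def test_addition_commutes(self):
        terms = [p.gaussian_term(2.0, 30.0, 5.0, self.grid),
                 p.barrier_term(1.0, 50.0, 3.0, self.grid),
                 p.constant_force_term(0.05, self.grid)]
        forward = p.total_potential(terms).U
        backward = p.total_potential(terms[::-1]).U
        np.testing.assert_allclose(forward, backward, atol=1e-14)

    def test_mismatched_grids_rejected(self):
        a = p.gaussian_term(1.0, 5.0, 1.0, np.linspace(0, 10, 21))
        b = p.gaussian_term(1.0, 5.0, 1.0, np.linspace(0, 10, 41))
        with pytest.raises(ValueError, match="mismatch"):
            p.total_potential([a, b])

    def test_neutralized_configuration_gives_zero_potential(self):
        # entropy off, EOF slope and intercept zero: U = 0 at every voltage
        seq = p.parse_sequence("A" * 100, laa=1.0)
        for V in (-100.0, 0.0, 50.0):
            U = p.build_potential(
                seq, p.PoreModel(2.355), p.EofModel(0.0, 0.0),
                p.EntropyConfig(use_entropy=False), (), V)
            np.testing.assert_allclose(U.U, 0.0, atol=1e-12)


class TestAuxiliaryForceSpec:
    def test_dispatch(self):
        grid = np.linspace(0.0, 10.0, 21)
        aux = p.AuxiliaryForce("gaussian",
                               {"EG": 2.0, "xG": 5.0, "sG": 1.0})
        np.testing.assert_allclose(aux.term(grid).U,
                                   p.gaussian_term(2.0, 5.0, 1.0, grid).U)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            p.AuxiliaryForce("quartic", {})

    def test_missing_parameters_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            p.AuxiliaryForce("barrier", {"EB": 1.0})

    def test_pn_conversion(self):
        assert p.pn_per_nm_to_kbt(4.114) == pytest.approx(1.0)
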
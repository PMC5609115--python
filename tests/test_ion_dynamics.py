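import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nadyn.constants import FARADAY
from nadyn.ion_dynamics import (
    BufferSpec,
    DiffusionOperator,
    DiffusionSpec,
    NCXSpec,
    PumpSpec,
    accumulation_rate,
    ca_balance_rate,
    diffusion_step,
    ncx_current,
    pump_current_kinetic,
    pump_current_steady_state,
    pump_flux_steady_state,
    pump_occupancy_equilibrium,
)
from nadyn.membrane import nernst
from nadyn.morphology import Morphology, RegionTag, Segment
from nadyn.presets import CA_PUMP, NA_PUMP, NCX

T_BODY = 310.15


def na_pump(density=5e-12):
    return PumpSpec(
        NA_PUMP["k1"], NA_PUMP["k2"], NA_PUMP["k3"], NA_PUMP["k4"],
        total_density=density, stoichiometry=3, charge_per_cycle=1.0,
    )


def ca_pump(density=1e-12):
    return PumpSpec(
        CA_PUMP["k1"], CA_PUMP["k2"], CA_PUMP["k3"], CA_PUMP["k4"],
        total_density=density, stoichiometry=1, charge_per_cycle=2.0,
    )


def ncx_spec(i_max=NCX["i_max"]):
    return NCXSpec(i_max=i_max, gamma=NCX["gamma"], km_na=NCX["km_na"],
                   km_ca=NCX["km_ca"], k_sat=NCX["k_sat"])


class TestAccumulationRate:
    def test_zero_current_zero_rate(self):
        assert accumulation_rate(0.0, 1, 1000.0) == 0.0

    def test_dimensional_oracle(self):
        # 1 nA inward into 1000 um^3 for 1 ms:
        # 1e-12 C / 96485 C/mol / 1e-12 L = 1.0364e-2 mM
        expected = 1e-12 / FARADAY / 1e-12 * 1e3
        assert expected == pytest.approx(1.0364e-2, rel=1e-3)
        assert accumulation_rate(1.0, 1, 1000.0) == pytest.approx(expected, rel=1e-12)

    def test_doubling_volume_halves_rate(self):
        r1 = accumulation_rate(1.0, 1, 1000.0)
        r2 = accumulation_rate(1.0, 1, 2000.0)
        assert r2 == pytest.approx(r1 / 2.0, rel=1e-12)

    def test_divalent_halves_rate(self):
        assert accumulation_rate(1.0, 2, 1000.0) == pytest.approx(
            accumulation_rate(1.0, 1, 1000.0) / 2.0, rel=1e-12
        )

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(ValueError):
            accumulation_rate(1.0, 1, 0.0)


def _two_seg_morph():
    return Morphology([
        Segment(0, None, 50.0, 2.0, RegionTag.DENDRITE_DISTAL),
        Segment(1, 0, 50.0, 2.0, RegionTag.DENDRITE_DISTAL),
    ])


def _line_morph(n, dx=1.0, diameter=1.0):
    segs = [Segment(0, None, dx, diameter, RegionTag.DENDRITE_DISTAL)]
    for k in range(1, n):
        segs.append(Segment(k, k - 1, dx, diameter, RegionTag.DENDRITE_DISTAL))
    return Morphology(segs)


class TestDiffusion:
    def test_uniform_concentration_unchanged(self):
        morph = _two_seg_morph()
        out = diffusion_step(np.array([12.0, 12.0]), morph, DiffusionSpec(), 1.0)
        assert out == pytest.approx([12.0, 12.0], rel=1e-14)

    @pytest.mark.parametrize("dt", [0.01, 1.0, 100.0, 1e4])
    def test_two_seg_conservation_and_symmetry(self, dt):
        morph = _two_seg_morph()
        c0 = np.array([10.0, 20.0])
        out = diffusion_step(c0, morph, DiffusionSpec(), dt)
        assert out.sum() == pytest.approx(30.0, rel=1e-14)  # equal volumes
        assert out[0] <= out[1] + 1e-12
        long = diffusion_step(c0, morph, DiffusionSpec(), 1e6)
        assert long == pytest.approx([15.0, 15.0], abs=1e-6)

    def test_mass_conserved_to_machine_precision_random_tree(self, rng):
        segs = [Segment(0, None, 10.0, 3.0, RegionTag.SOMA)]
        for k in range(1, 25):
            parent = int(rng.integers(0, k))
            segs.append(
                Segment(k, parent, float(rng.uniform(2, 30)),
                        float(rng.uniform(0.5, 4)), RegionTag.DENDRITE_DISTAL)
            )
        morph = Morphology(segs)
        op = DiffusionOperator(morph, 0.3)
        c = rng.uniform(1.0, 50.0, size=25)
        amount0 = float((c * op.volume).sum())
        for _ in range(200):
            c = op.step(c, 0.5)
        amount1 = float((c * op.volume).sum())
        assert amount1 == pytest.approx(amount0, rel=1e-13)

    def test_point_load_matches_gaussian_kernel(self):
        # sealed uniform cylinder, delta load in the center, free diffusion:
        # profile at t must match the 1-D Green's function
        n, dx, d_coeff, t_end = 301, 1.0, 0.3, 50.0
        morph = _line_morph(n, dx=dx)
        op = DiffusionOperator(morph, d_coeff)
        c = np.zeros(n)
        c[n // 2] = 1.0 / dx  # unit amount per unit cross-section
        dt = 0.1
        for _ in range(int(t_end / dt)):
            c = op.step(c, dt)
        x = (np.arange(n) - n // 2) * dx
        kernel = np.exp(-(x**2) / (4 * d_coeff * t_end)) / math.sqrt(
            4 * math.pi * d_coeff * t_end
        )
        rms = np.sqrt(np.mean((c - kernel) ** 2)) / kernel.max()
        assert rms < 0.02

    def test_spine_correction_slows_dendritic_spread(self):
        morph = _line_morph(20, dx=2.0)
        c0 = np.zeros(20)
        c0[0] = 100.0
        fast = diffusion_step(c0, morph, DiffusionSpec(spine_correction=False), 100.0)
        slow = diffusion_step(c0, morph, DiffusionSpec(spine_correction=True), 100.0)
        assert slow[0] > fast[0]  # load stays put
        assert slow[5] < fast[5]

    def test_disconnected_morphology_rejected(self):
        # a disconnected segment set cannot even form a Morphology (two
        # roots), so the flux-form operator always sees a spanning tree
        with pytest.raises(Exception):
            Morphology([
                Segment(0, None, 10, 1, RegionTag.SOMA),
                Segment(1, None, 10, 1, RegionTag.DENDRITE_DISTAL),
            ])
        op = DiffusionOperator(_two_seg_morph(), 0.3)
        assert op.src.size == 1  # one edge spans two segments


class TestNaKPump:
    def test_zero_current_at_equilibrium_concentration(self):
        spec = na_pump()
        na_eq = 150.0 * spec.equilibrium_ratio
        assert na_eq == pytest.approx(10.0, rel=1e-3)
        assert pump_current_steady_state(na_eq, 150.0, spec) == pytest.approx(
            0.0, abs=1e-15
        )

    def test_saturation_limit(self):
        spec = na_pump()
        sat = FARADAY / 3.0 * spec.total_density * spec.k3 * 1e6
        assert pump_current_steady_state(1e6, 150.0, spec) == pytest.approx(
            sat, rel=1e-3
        )

    def test_monotone_nondecreasing(self):
        spec = na_pump()
        grid = np.linspace(0.5, 100.0, 400)
        cur = pump_current_steady_state(grid, 150.0, spec)
        assert np.all(np.diff(cur) >= 0)

    def test_slope_larger_at_30_than_10(self):
        # steep rise above ~20 mM
        spec = na_pump()

        def slope(na):
            h = 1e-3
            return (
                pump_current_steady_state(na + h, 150.0, spec)
                - pump_current_steady_state(na - h, 150.0, spec)
            ) / (2 * h)

        assert slope(30.0) > slope(10.0)

    def test_kinetic_equilibrium_matches_closed_form(self):
        # spec example: agreement to <0.1% after relaxation at fixed Na
        spec = na_pump()
        for na in (5.0, 15.0, 25.0, 40.0):
            occ = pump_occupancy_equilibrium(10.0, 150.0, spec)  # start off-balance
            cur = None
            for _ in range(5000):
                cur, occ = pump_current_kinetic(occ, na, 150.0, spec, 0.05)
            ref = pump_current_steady_state(na, 150.0, spec)
            assert cur == pytest.approx(ref, rel=1e-3, abs=1e-12)

    def test_kinetic_relaxation_monotone_after_step(self):
        spec = na_pump()
        occ = pump_occupancy_equilibrium(10.0, 150.0, spec)
        currents = []
        for _ in range(400):
            cur, occ = pump_current_kinetic(occ, 30.0, 150.0, spec, 0.1)
            currents.append(cur)
        diffs = np.diff(currents)
        assert np.all(diffs <= 1e-15) or np.all(diffs >= -1e-15)
        assert currents[-1] == pytest.approx(
            pump_current_steady_state(30.0, 150.0, spec), rel=1e-3
        )

    def test_zero_density_zero_current(self):
        spec = na_pump(density=0.0)
        cur, occ = pump_current_kinetic(0.0, 30.0, 150.0, spec, 0.1)
        assert cur == 0.0

    def test_occupancy_out_of_range_rejected(self):
        spec = na_pump()
        with pytest.raises(ValueError):
            pump_current_kinetic(2 * spec.total_density, 10.0, 150.0, spec, 0.1)

    def test_equilibrium_scaling(self):
        spec = na_pump().with_equilibrium_scaled(0.25)
        na_eq = 150.0 * spec.equilibrium_ratio
        assert na_eq == pytest.approx(2.5, rel=1e-3)

    @given(na=st.floats(0.1, 200.0))
    @settings(max_examples=100, deadline=None)
    def test_current_sign_follows_equilibrium(self, na):
        spec = na_pump()
        cur = pump_current_steady_state(na, 150.0, spec)
        if na > 10.001:
            assert cur > 0
        elif na < 9.999:
            assert cur < 0


class TestNCX:
    def test_reversal_at_3ena_minus_2eca(self):
        spec = ncx_spec()
        na_i, ca_i = 15.0, 1e-4
        e_na = nernst(na_i, 150.0, 1, T_BODY)
        e_ca = nernst(ca_i, 2.0, 2, T_BODY)
        v_rev = 3 * e_na - 2 * e_ca
        i = ncx_current(na_i, 150.0, ca_i, 2.0, v_rev, T_BODY, spec)
        scale = abs(ncx_current(na_i, 150.0, ca_i, 2.0, v_rev + 20.0, T_BODY, spec))
        assert abs(i) / scale < 1e-9

    def test_reversal_potential_value(self):
        # Na 15/150 mM, Ca 1e-4/2 mM, 310.15 K -> about -80.1 mV
        e_na = nernst(15.0, 150.0, 1, T_BODY)
        e_ca = nernst(1e-4, 2.0, 2, T_BODY)
        assert 3 * e_na - 2 * e_ca == pytest.approx(-80.1, abs=0.1)

    def test_zero_imax_zero_current(self):
        spec = ncx_spec(i_max=0.0)
        assert ncx_current(15.0, 150.0, 1e-4, 2.0, -70.0, T_BODY, spec) == 0.0

    def test_extrudes_calcium_above_reversal_ca(self):
        # forward mode (Ca out, negative sign) when Ca_i is high
        spec = ncx_spec()
        assert ncx_current(10.0, 150.0, 1e-2, 2.0, -70.0, T_BODY, spec) < 0

    def test_elevated_na_drives_ca_influx(self):
        spec = ncx_spec()
        lo = ncx_current(10.0, 150.0, 1e-4, 2.0, -70.0, T_BODY, spec)
        hi = ncx_current(40.0, 150.0, 1e-4, 2.0, -70.0, T_BODY, spec)
        assert hi > lo

    def test_gamma_bounds_enforced(self):
        with pytest.raises(ValueError):
            NCXSpec(i_max=1.0, gamma=1.5)


class TestCaBalance:
    def test_buffer_at_equilibrium_contributes_nothing(self):
        buf = BufferSpec(total_buffer=0.1, k_on=1.0, k_off=1e-3)
        ca = 5e-5
        bound = buf.total_buffer * ca / (ca + buf.k_off / buf.k_on)
        base = ca_balance_rate(
            ca, 10.0, -70.0, na_o=150.0, ca_o=2.0, temperature=T_BODY,
            ncx=ncx_spec(0.0), ca_pump=ca_pump(0.0),
        )
        with_buf = ca_balance_rate(
            ca, 10.0, -70.0, na_o=150.0, ca_o=2.0, temperature=T_BODY,
            ncx=ncx_spec(0.0), ca_pump=ca_pump(0.0),
            buffer=buf, bound_buffer=bound,
        )
        assert with_buf == pytest.approx(base, abs=1e-15)

    def test_pump_only_equilibrium(self):
        # with the exchanger silenced, Ca relaxes to Ca_o * k2 k4 / (k1 k3)
        cp = ca_pump(1e-12)
        target = 2.0 * cp.k2 * cp.k4 / (cp.k1 * cp.k3)
        ca = 5e-4
        for _ in range(400000):
            rate = ca_balance_rate(
                ca, 10.0, -70.0, na_o=150.0, ca_o=2.0, temperature=T_BODY,
                ncx=ncx_spec(0.0), ca_pump=cp, area_over_volume=4.0,
            )
            ca = max(ca + rate * 5.0, 1e-9)
        assert ca == pytest.approx(target, rel=1e-3)

    def test_rate_zero_at_stable_state(self):
        from nadyn.analytics import stable_state_ca

        cp = ca_pump(1e-12)
        spec = ncx_spec()
        ca_star = stable_state_ca(25.0, -70.0, T_BODY, 2.0, spec, cp)
        rate = ca_balance_rate(
            ca_star, 25.0, -70.0, na_o=150.0, ca_o=2.0, temperature=T_BODY,
            ncx=spec, ca_pump=cp, area_over_volume=4.0,
        )
        # compare against the magnitude of the individual terms
        pump_term = (
            pump_flux_steady_state(ca_star, 2.0, cp) * 4.0 * 1e10
        )
        assert abs(rate) < 1e-9 * abs(pump_term) + 1e-18


class TestMassBalanceBookkeeping:
    def test_pump_charge_is_one_third_of_na_flux(self):
        # 3 Na+ out per unit of outward charge: the closed-form current and
        # molar flux must satisfy I = (F/3) * flux exactly
        spec = na_pump()
        for na in (12.0, 20.0, 35.0):
            flux = pump_flux_steady_state(na, 150.0, spec)
            cur = pump_current_steady_state(na, 150.0, spec)
            assert cur == pytest.approx(FARADAY / 3.0 * flux * 1e6, rel=1e-12)
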
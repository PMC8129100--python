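"""Force laws, schedule, displacement rule and equilibrium analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroaggsim import model_core as mc


class TestForceMagnitude:
    @pytest.mark.parametrize(
        "d, strength, tau, expected",
        [
            (0.0, 1.0, 320.0, 1.0),  # exponent is 0
            (320.0, 1.0, 320.0, 0.01),  # drops to 1% of maximum at tau
            (160.0, 1.0, 320.0, 0.01 ** 0.5),  # closed form at tau/2
        ],
    )
    def test_values(self, d, strength, tau, expected):
        assert mc.force_magnitude(d, strength, tau) == pytest.approx(expected, rel=1e-12)

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            mc.force_magnitude(10.0, 1.0, 0.0)
        with pytest.raises(ValueError):
            mc.force_magnitude(10.0, 1.0, -5.0)

    def test_log_linear_decay(self):
        """log F is linear in d with slope ln(0.01)/tau."""
        tau = 137.0
        d = np.linspace(0, 4 * tau, 50)
        logf = np.log(mc.force_magnitude(d, 2.5, tau))
        slope, intercept = np.polyfit(d, logf, 1)
        assert slope == pytest.approx(math.log(0.01) / tau, rel=1e-9)
        assert intercept == pytest.approx(math.log(2.5), rel=1e-9)
        assert np.all(np.diff(mc.force_magnitude(d, 2.5, tau)) < 0)


class TestMovementFreedom:
    def test_midpoint_and_tails(self):
        sched = mc.StiffnessSchedule(total_time=350, stiffening_delay=300, stiffening_constant=20)
        assert mc.movement_freedom(300, sched) == pytest.approx(0.5)
        assert mc.movement_freedom(0, sched) == pytest.approx(1.0, abs=1e-6)
        # one stiffening constant past the delay: 1 - e/(1+e)
        expected = 1 - math.e / (1 + math.e)
        assert mc.movement_freedom(320, sched) == pytest.approx(expected, rel=1e-12)

    def test_monotone_and_bounded(self):
        sched = mc.StiffnessSchedule()
        t = np.linspace(0, 350, 200)
        k = mc.movement_freedom(t, sched)
        assert np.all(k > 0) and np.all(k < 1)
        assert np.all(np.diff(k) <= 0)
        assert mc.movement_freedom(-1e6, sched) == pytest.approx(1.0)
        assert mc.movement_freedom(1e6, sched) == pytest.approx(0.0)


class TestDisplace:
    def test_gravity_only(self):
        out = mc.displace(np.zeros(3), k=1.0, g=1e-4)
        assert np.allclose(out, [0, 0, -1e-4])

    def test_frozen(self):
        out = mc.displace(np.array([5.0, -3.0, 2.0]), k=0.0, g=0.0)
        assert np.allclose(out, 0.0)

    def test_linearity(self):
        out = mc.displace(np.array([2.0, -1.0, 3.0]), k=0.5, g=0.0)
        assert np.allclose(out, [1.0, -0.5, 1.5])

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            mc.displace(np.zeros(3), k=1.5, g=0.0)


def _equilibrium_brute(A_eff, tau_a, R, tau_r, grid=0.01, dmax=500.0):
    """Sign-change scan of the total pairwise force curve."""
    d = np.arange(0.0, dmax, grid)
    total = A_eff * 0.01 ** (d / tau_a) - R * 0.01 ** (d / tau_r)
    sign = np.sign(total)
    idx = np.where(np.diff(sign) != 0)[0]
    if len(idx) == 0:
        return 0.0 if total[0] == 0 else None
    return d[idx[0]]


class TestEquilibriumDistance:
    @pytest.mark.parametrize(
        "A, tau_a, R, tau_r, expected",
        [
            (1.0, 320.0, 2.27, 140.0, 44.3),  # initial parameter set
            (1.0, 320.0, 2.27, 200.0, 94.9),  # optimized parameter set
            (1.0, 320.0, 1.0, 140.0, 0.0),  # forces equal at d = 0
        ],
    )
    def test_known_values(self, A, tau_a, R, tau_r, expected):
        assert mc.equilibrium_distance(A, tau_a, R, tau_r) == pytest.approx(expected, abs=0.05)

    def test_against_brute_force_scan(self, rng):
        """Closed form agrees with a 0.01-um sign-change scan of the curve."""
        for _ in range(25):
            tau_a = rng.uniform(100, 400)
            tau_r = rng.uniform(50, 300)
            if abs(tau_a - tau_r) < 5:
                continue
            A = rng.uniform(0.5, 2.0)
            # pick R so d* lands in (5, 400)
            target = rng.uniform(5, 400)
            R = mc.repulsion_for_equilibrium(target, A, tau_a, tau_r)
            d_closed = mc.equilibrium_distance(A, tau_a, R, tau_r)
            d_brute = _equilibrium_brute(A, tau_a, R, tau_r)
            assert d_brute is not None
            assert abs(d_closed - d_brute) <= 0.011

    def test_degenerate_taus(self):
        with pytest.raises(ValueError):
            mc.equilibrium_distance(1.0, 200.0, 1.0, 200.0)
        with pytest.raises(ValueError):
            mc.equilibrium_distance(1.0, 200.0, 2.0, 200.0)

    def test_negative_equilibrium_rejected(self):
        # R < A_eff with tau_r < tau_a implies a crossing at negative d
        with pytest.raises(ValueError):
            mc.equilibrium_distance(1.0, 320.0, 0.5, 140.0)


class TestRepulsionForEquilibrium:
    @pytest.mark.parametrize(
        "target, A, tau_a, tau_r, expected",
        [
            (70.0, 1.0, 320.0, 140.0, 3.652),
            (44.3, 1.0, 320.0, 140.0, 2.27),
            (0.0, 1.0, 320.0, 140.0, 1.0),
        ],
    )
    def test_known_values(self, target, A, tau_a, tau_r, expected):
        assert mc.repulsion_for_equilibrium(target, A, tau_a, tau_r) == pytest.approx(
            expected, abs=5e-3
        )

    @settings(deadline=None, max_examples=60)
    @given(
        target=st.floats(0.0, 400.0),
        A=st.floats(0.1, 5.0),
        tau_a=st.floats(50.0, 400.0),
        ratio=st.floats(0.2, 0.9),
    )
    def test_round_trip(self, target, A, tau_a, ratio):
        """equilibrium_distance inverts repulsion_for_equilibrium exactly."""
        tau_r = tau_a * ratio
        R = mc.repulsion_for_equilibrium(target, A, tau_a, tau_r)
        if target == 0.0:
            assert R == pytest.approx(A)
        else:
            assert mc.equilibrium_distance(A, tau_a, R, tau_r) == pytest.approx(
                target, rel=1e-9
            )


class TestNetForce:
    def test_pair_at_equilibrium_is_balanced(self):
        params = mc.ForceParameters()
        d_star = mc.equilibrium_distance(
            params.A * params.AS[("N", "N")], params.tau_a, params.R, params.tau_r
        )
        pos = np.array([[0.0, 0, 0], [d_star, 0, 0]])
        types = np.array([0, 0])
        f = mc.net_force(0, pos, types, None, params)
        assert np.linalg.norm(f) == pytest.approx(0.0, abs=1e-12)

    def test_pair_beyond_equilibrium_attracts(self):
        params = mc.ForceParameters()
        d_star = mc.equilibrium_distance(params.A, params.tau_a, params.R, params.tau_r)
        pos = np.array([[0.0, 0, 0], [2 * d_star, 0, 0]])
        types = np.array([0, 0])
        f0 = mc.net_force(0, pos, types, None, params)
        f1 = mc.net_force(1, pos, types, None, params)
        assert f0[0] > 0 and f1[0] < 0  # each pulled toward the other

    def test_anchor_only(self):
        """Single cell, one anchor at distance tau_s below: force 0.01*S."""
        params = mc.ForceParameters(A=0.0, R=0.0)
        pos = np.array([[0.0, 0.0, params.tau_s]])
        anchors = np.array([[0.0, 0.0]])
        f = mc.net_force(0, pos, np.array([0]), anchors, params)
        assert np.allclose(f, [0, 0, -0.01 * params.S], atol=1e-15)

    def test_antisymmetry_and_AS_ratio(self):
        params = mc.ForceParameters(S=0.0)
        pos = np.array([[0.0, 0, 0], [50.0, 30.0, 10.0]])
        nn = np.array([0, 0])
        f0 = mc.net_force(0, pos, nn, None, params)
        f1 = mc.net_force(1, pos, nn, None, params)
        assert np.allclose(f0, -f1)
        # neuron-astrocyte pair: attraction parts differ by AS_NA / AS_AN
        na = np.array([0, 1])
        d = np.linalg.norm(pos[1] - pos[0])
        rep = mc.force_magnitude(d, params.R, params.tau_r)
        attr = mc.force_magnitude(d, params.A, params.tau_a)
        u = (pos[1] - pos[0]) / d
        f_n = mc.net_force(0, pos, na, None, params)
        f_a = mc.net_force(1, pos, na, None, params)
        assert np.allclose(f_n, (params.AS[("N", "A")] * attr - rep) * u)
        assert np.allclose(f_a, -(params.AS[("A", "N")] * attr - rep) * u)

    def test_coincident_cells_separate(self, rng):
        params = mc.ForceParameters()
        pos = np.zeros((2, 3))
        f = mc.net_force(0, pos, np.array([0, 0]), None, params, rng=rng)
        assert np.all(np.isfinite(f))
        assert np.linalg.norm(f) == pytest.approx(params.R)


class TestParameterTypes:
    def test_preset_values(self):
        params, sched = mc.get_preset("optimized")
        assert (params.A, params.tau_a, params.R, params.tau_r) == (1.0, 320.0, 2.27, 200.0)
        assert (params.S, params.tau_s, params.g) == (0.01, 30.0, 1e-4)
        assert params.AS == {("N", "N"): 1.0, ("N", "A"): 0.9, ("A", "N"): 0.8, ("A", "A"): 0.7}
        assert (sched.total_time, sched.stiffening_delay, sched.stiffening_constant) == (350, 300.0, 20.0)
        initial, _ = mc.get_preset("initial")
        assert initial.tau_r == 140.0
        assert initial.to_dict() == {**params.to_dict(), "tau_r": 140.0}

    def test_serialization_round_trip(self):
        params = mc.ForceParameters(R=3.1, tau_r=150.0).with_AS(1.0, 0.8, 0.9, 0.6)
        assert mc.ForceParameters.from_dict(params.to_dict()) == params
        sched = mc.StiffnessSchedule(total_time=100, stiffening_delay=80, stiffening_constant=5)
        assert mc.StiffnessSchedule.from_dict(sched.to_dict()) == sched

    def test_validation(self):
        with pytest.raises(ValueError):
            mc.ForceParameters(A=-1.0)
        with pytest.raises(ValueError):
            mc.ForceParameters(tau_a=0.0)
        with pytest.raises(ValueError):
            mc.ForceParameters(AS={("N", "N"): 1.0})
        with pytest.raises(ValueError):
            mc.StiffnessSchedule(stiffening_constant=0.0)
        with pytest.raises(KeyError):
            mc.get_preset("bogus")
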
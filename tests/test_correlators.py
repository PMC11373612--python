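import numpy as np
import pytest

from ratepaths import (
    CommittorProfile,
    CorrelationSeries,
    DividingSurface,
    PlateauNotFoundError,
    SimParams,
    ThermoState,
    Trajectory,
    committor_correlation,
    correlation_derivative,
    equilibrium_profile,
    estimate_correlation,
    extract_flux,
    indicator_correlation,
    make_potential,
    population_correlation,
    position_correlation,
    restricted_committor_correlation,
    sample_dividing_surface,
    transmission_coefficient,
    tst_rate,
)
from ratepaths.units import KCAL_PER_MOL_IN_AMU_A2_PS2 as E_CONV


def make_series_traj(x, dt=1.0):
    """Wrap a plain numpy series as a Trajectory with unit frame spacing."""
    x = np.asarray(x, dtype=float)
    sp = SimParams("brownian", dt=dt, n_steps=len(x) - 1, seed=0)
    return Trajectory(np.arange(len(x)) * dt, x, None, sp,
                      "synthetic", ThermoState(1.0, 1.0))


class StepCommittor:
    """Exact Heaviside committor (z >= z† belongs to B), duck-typed."""

    def __init__(self, z_dagger=0.0):
        self.z_dagger = z_dagger

    def interp(self, z):
        return (np.asarray(z) >= self.z_dagger).astype(float)


@pytest.fixture(scope="module")
def two_state_chain():
    """Synthetic ±1 telegraph series with switching probability 0.1/frame."""
    rng = np.random.default_rng(77)
    flips = rng.random(200_000 - 1) < 0.1
    signs = np.where(flips, -1.0, 1.0)
    states = -np.cumprod(np.concatenate([[1.0], signs]))
    return make_series_traj(states)


def test_constant_observable(two_state_chain):
    cs = estimate_correlation(two_state_chain, lambda z: np.full_like(z, 3.0),
                              lags=[0.0, 1.0, 5.0])
    assert np.allclose(cs.values, 9.0)
    assert np.allclose(cs.stderr, 0.0)


def test_lag_zero_is_second_moment(two_state_chain):
    cs = estimate_correlation(two_state_chain, lambda z: z, lags=[0.0])
    assert cs.values[0] == pytest.approx(np.mean(two_state_chain.positions**2),
                                         rel=1e-6)


def test_ar1_autocorrelation_recovered():
    """AR(1) series with known ⟨x(0)x(t)⟩ = a^t."""
    rng = np.random.default_rng(5)
    a = 0.9
    n = 400_000
    x = np.empty(n)
    x[0] = 0.0
    noise = rng.standard_normal(n - 1) * np.sqrt(1 - a * a)
    for i in range(1, n):
        x[i] = a * x[i - 1] + noise[i - 1]
    traj = make_series_traj(x)
    lags = np.arange(0.0, 21.0, 1.0)
    cs = estimate_correlation(traj, lambda z: z, lags)
    expected = a ** lags
    assert np.all(np.abs(cs.values - expected) < 4 * np.maximum(cs.stderr, 1e-4))


def test_lag_validation(two_state_chain):
    with pytest.raises(ValueError, match="multiples"):
        estimate_correlation(two_state_chain, lambda z: z, [0.5])
    with pytest.raises(ValueError, match="length"):
        estimate_correlation(two_state_chain, lambda z: z, [1e9])


class TestIndicatorAndPopulation:
    def test_zero_lag_and_longtime(self, two_state_chain):
        ds = DividingSurface("position", 0.0)
        cs = indicator_correlation(two_state_chain, ds, [0.0, 1.0, 50.0, 100.0])
        assert cs.values[0] == 0.0
        # telegraph decorrelates within ~1/(2p) = 5 frames; C_BB -> pA pB
        H = (two_state_chain.positions >= 0).astype(float)
        pApB = H.mean() * (1 - H.mean())
        assert cs.values[-1] == pytest.approx(pApB, rel=0.05)

    def test_population_identity(self, two_state_chain):
        ds = DividingSurface("position", 0.0)
        lags = [0.0, 1.0, 5.0, 20.0]
        cbb = indicator_correlation(two_state_chain, ds, lags)
        cpop = population_correlation(two_state_chain, ds, lags)
        H = (two_state_chain.positions >= 0).astype(float)
        pApB = H.mean() * (1 - H.mean())
        assert np.allclose(cpop.values, 1.0 - cbb.values / pApB, atol=1e-12)

    def test_single_state_trajectory_rejected(self):
        traj = make_series_traj(np.ones(100))
        with pytest.raises(ValueError, match="never visits"):
            indicator_correlation(traj, DividingSurface("position", 0.0), [0.0, 1.0])


def test_position_correlation_limits(two_state_chain):
    cs = position_correlation(two_state_chain, lags=[0.0, 1.0, 50.0, 100.0])
    assert cs.values[0] == 0.0
    H = (two_state_chain.positions >= 0).astype(float)
    assert cs.values[-1] == pytest.approx(H.mean() * (1 - H.mean()), rel=0.05)
    with pytest.raises(ValueError, match="variance"):
        position_correlation(make_series_traj(np.full(100, 2.0)), lags=[0.0, 1.0])


def test_step_committor_reproduces_indicator(two_state_chain):
    """A Heaviside committor makes C_qq identical to C_BB, bit for bit."""
    ds = DividingSurface("position", 0.0)
    lags = np.arange(0.0, 11.0)
    cbb = indicator_correlation(two_state_chain, ds, lags)
    cqq = committor_correlation(two_state_chain, StepCommittor(0.0), lags)
    assert np.array_equal(cbb.values, cqq.values)
    assert np.array_equal(cbb.stderr, cqq.stderr)


class TestRestrictedCorrelator:
    def test_zero_lag(self, two_state_chain):
        cs = restricted_committor_correlation(
            two_state_chain, StepCommittor(0.0), lags=[0.0, 1.0])
        assert cs.values[0] == 0.0

    def test_indicator_committor_reduces_to_crossing_probability(
            self, two_state_chain):
        """With q = H_B the integrand is H_A(0)H_B(t): the A->B crossing
        probability, computed here independently with numpy."""
        lags = [0.0, 1.0, 3.0]
        cs = restricted_committor_correlation(
            two_state_chain, StepCommittor(0.0), lags=lags)
        H = (two_state_chain.positions >= 0).astype(float)
        for lag, got in zip((0, 1, 3), cs.values):
            ref = np.mean((1 - H[: len(H) - lag if lag else None])
                          * (H[lag:] if lag else H))
            assert got == pytest.approx(ref, rel=1e-12)

    def test_requires_committor_surface(self, two_state_chain):
        with pytest.raises(ValueError, match="committor-kind"):
            restricted_committor_correlation(
                two_state_chain, StepCommittor(0.0),
                DividingSurface("position", 0.0), lags=[0.0, 1.0])


class TestDerivativeAndFlux:
    @staticmethod
    def series(lags, values, stderr=None, blocks=None):
        lags = np.asarray(lags, float)
        values = np.asarray(values, float)
        stderr = np.zeros_like(values) if stderr is None else stderr
        return CorrelationSeries(lags, values, stderr, "synthetic", 1, blocks)

    def test_linear_series(self):
        t = np.arange(0.0, 30.0)
        cs = self.series(t, 2.5e-4 * t)
        d = correlation_derivative(cs)
        assert np.allclose(d.values, 2.5e-4, atol=1e-18)
        rate = extract_flux(cs)
        assert rate.J_AB == pytest.approx(2.5e-4, rel=1e-12)
        assert rate.plateau_time == 0.0

    def test_quadratic_series_exact_central_difference(self):
        t = np.arange(0.0, 20.0)
        d = correlation_derivative(self.series(t, 0.3 * t**2))
        assert np.allclose(d.values[1:-1], 2 * 0.3 * t[1:-1], atol=1e-12)

    def test_transient_plus_slope(self):
        """c(1 − e^{−t/τc}) + s·t has derivative → s for t ≫ τc."""
        t = np.arange(0.0, 60.0, 0.5)
        tau_c, s, c = 2.0, 1e-4, 0.05
        cs = self.series(t, c * (1 - np.exp(-t / tau_c)) + s * t,
                         stderr=np.full(t.size, 1e-7))
        d = correlation_derivative(cs)
        assert d.values[-10] == pytest.approx(s, rel=0.01)
        rate = extract_flux(cs, rel_tol=0.05, window=10)
        assert rate.plateau_time > 3 * tau_c  # transient excluded
        assert rate.J_AB == pytest.approx(s, rel=0.02)

    def test_no_plateau_raises(self):
        t = np.arange(0.0, 40.0)
        cs = self.series(t, np.sqrt(t))  # derivative decays forever
        with pytest.raises(PlateauNotFoundError):
            extract_flux(cs, window=10)

    def test_nonuniform_lags_rejected(self):
        cs = self.series([0.0, 1.0, 3.0], [0.0, 1.0, 2.0])
        with pytest.raises(ValueError, match="uniform"):
            correlation_derivative(cs)


def test_tst_rate_flat_closed_form():
    """Uniform ρ = 1/L, p_A = 1/2: k_TST = (2/L)·sqrt(kBT/2πm)."""
    th = ThermoState(0.5915, 1.0, 20.0)
    pot = make_potential("flat", domain=(-7.0, 7.0))
    prof = equilibrium_profile(pot, th, 0.01)
    k = tst_rate(prof, th, 0.0)
    expected = (2.0 / 14.0) * np.sqrt(th.kBT * E_CONV / th.mass / (2 * np.pi))
    assert k == pytest.approx(expected, rel=1e-9)
    with pytest.raises(ValueError):
        tst_rate(prof, ThermoState(0.5915, 1.0), 0.0)


def test_transmission_ballistic_limit():
    """No friction, no noise, no force: forward shots stay in B, backward shots
    never return — κ(t) is constant and equals its sample κ(0⁺) ≈ 1."""
    th = ThermoState(0.5915, 1.0, 20.0)
    pot = make_potential("flat", domain=(-1e6, 1e6))
    shots = sample_dividing_surface(th, 0.0, 4000, seed=13)
    ks = transmission_coefficient(shots, pot, th, t_max=0.05, dt=0.001,
                                  seed=13, noise_scale=0.0, friction=0.0)
    assert ks.values[0] == 1.0
    assert np.allclose(ks.values[1:], ks.values[1], atol=1e-12)
    assert ks.values[1] == pytest.approx(1.0, abs=0.05)
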
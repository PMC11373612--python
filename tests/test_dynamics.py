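import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from ratepaths import (
    SimParams,
    ThermoState,
    equilibrium_profile,
    first_passage_times,
    make_potential,
    sample_dividing_surface,
    shoot_committor,
    simulate_batch,
    simulate_brownian,
    simulate_langevin,
)
from ratepaths.dynamics import TrajectoryEscapeError
from ratepaths.units import KCAL_PER_MOL_IN_AMU_A2_PS2 as E_CONV


def test_seed_determinism(thermo):
    pot = make_potential("narrow")
    sp = SimParams("brownian", dt=0.005, n_steps=5000, stride=5, seed=42)
    a = simulate_brownian(pot, thermo, sp)
    b = simulate_brownian(pot, thermo, sp)
    assert np.array_equal(a.positions, b.positions)
    spl = SimParams("langevin", dt=0.001, n_steps=5000, stride=5, seed=42)
    c = simulate_langevin(pot, thermo, spl)
    d = simulate_langevin(pot, thermo, spl)
    assert np.array_equal(c.positions, d.positions)
    assert np.array_equal(c.velocities, d.velocities)


def test_zero_noise_flat_is_static(flat_pot):
    th = ThermoState(0.5915, 1.0)
    sp = SimParams("brownian", dt=0.005, n_steps=100, seed=0,
                   initial_position=1.5, noise_scale=0.0)
    traj = simulate_brownian(flat_pot, th, sp)
    assert np.all(traj.positions == 1.5)


def test_single_step_displacement_formula(flat_pot):
    """One Euler–Maruyama step on a flat potential is exactly sqrt(2 D dt)·G."""
    th = ThermoState(0.5915, 1.0)
    sp = SimParams("brownian", dt=0.005, n_steps=1, seed=7)
    traj = simulate_brownian(flat_pot, th, sp)
    G = np.random.default_rng(7).standard_normal((1, 1))[0, 0]
    assert traj.positions[1] - traj.positions[0] == pytest.approx(
        np.sqrt(2 * 1.0 * 0.005) * G, abs=1e-15
    )


def test_langevin_free_flight_limit(flat_pot):
    """Zero noise, zero force, zero friction: constant-velocity free flight."""
    th = ThermoState(0.5915, 1.0, 20.0)
    sp = SimParams("langevin", dt=0.001, n_steps=50, seed=0,
                   initial_position=0.0, initial_velocity=2.0,
                   noise_scale=0.0, friction=0.0)
    traj = simulate_langevin(flat_pot, th, sp)
    assert np.allclose(np.diff(traj.positions), 2.0 * 0.001, atol=1e-13)
    assert np.allclose(traj.velocities, 2.0, atol=1e-13)


def test_langevin_velocity_variance(thermo):
    pot = make_potential("broad")
    sp = SimParams("langevin", dt=0.001, n_steps=400_000, stride=10, seed=3)
    trajs = simulate_batch(pot, thermo, sp, 4)
    v = np.concatenate([t.velocities for t in trajs])
    assert v.var() == pytest.approx(thermo.kBT * E_CONV / thermo.mass, rel=0.02)


def test_free_diffusion_msd(flat_pot):
    """MSD slope on the flat potential equals 2D within 5% for lags <= 1 ps."""
    th = ThermoState(0.5915, 1.0)
    big = make_potential("flat", domain=(-2000.0, 2000.0))
    sp = SimParams("brownian", dt=0.005, n_steps=400_000, stride=1, seed=11)
    traj = simulate_brownian(big, th, sp)
    x = traj.positions
    lags = np.arange(20, 201, 20)  # 0.1 .. 1 ps
    msd = np.array([np.mean((x[l:] - x[:-l]) ** 2) for l in lags])
    slope = np.polyfit(lags * 0.005, msd, 1)[0]
    assert slope == pytest.approx(2.0 * th.D, rel=0.05)


def test_equilibrium_recovery_chisquare(thermo, quad):
    """Long BD sampling reproduces the quadrature Boltzmann density."""
    from scipy.stats import chisquare

    pot = make_potential("narrow")
    sp = SimParams("brownian", dt=0.005, n_steps=4_000_000, stride=1000, seed=5)
    trajs = simulate_batch(pot, thermo, sp, 2)  # 2 x 20 ns, samples every 5 ps
    samples = np.concatenate([t.positions[1:] for t in trajs])
    prof = quad["narrow"].profile
    edges = np.linspace(-11.5, 11.5, 47)
    counts, _ = np.histogram(samples, edges)
    cdf = cumulative_trapezoid(prof.density, prof.grid, initial=0.0)
    p_bin = np.diff(np.interp(edges, prof.grid, cdf))
    expected = p_bin / p_bin.sum() * counts.sum()
    keep = expected >= 5
    merged_obs = np.append(counts[keep], counts[~keep].sum())
    merged_exp = np.append(expected[keep], expected[~keep].sum())
    stat, p = chisquare(merged_obs, merged_exp * merged_obs.sum() / merged_exp.sum())
    assert p > 0.01


def test_escape_raises_with_step_index():
    pot = make_potential("flat", domain=(-1.0, 1.0))
    th = ThermoState(0.5915, 1.0)
    sp = SimParams("brownian", dt=0.005, n_steps=10_000, seed=1)
    with pytest.raises(TrajectoryEscapeError, match="step"):
        simulate_brownian(pot, th, sp)


class TestShootCommittor:
    def test_near_boundary_and_symmetry(self, thermo):
        pot = make_potential("narrow")
        sp = SimParams("brownian", dt=0.005, n_steps=1, seed=21)
        df = shoot_committor(pot, thermo, sp, [-6.95, 0.0], n_shots=300)
        q_lo = df.loc[df.position == -6.95, "q_hat"].item()
        assert q_lo < 0.05  # immediate absorption at z1
        row = df.loc[df.position == 0.0]
        assert abs(row.q_hat.item() - 0.5) < 3 * row.stderr.item() + 1e-9

    def test_matches_quadrature_committor(self, thermo, quad):
        pot = make_potential("narrow")
        sp = SimParams("brownian", dt=0.005, n_steps=1, seed=22)
        starts = [-2.0, 0.0, 2.0]
        df = shoot_committor(pot, thermo, sp, starts, n_shots=600)
        q_ref = quad["narrow"].committor.interp(np.array(starts))
        for (_, row), qr in zip(df.iterrows(), q_ref):
            assert abs(row.q_hat - qr) < 3 * max(row.stderr, 1e-3)

    def test_start_outside_interval_rejected(self, thermo):
        pot = make_potential("narrow")
        sp = SimParams("brownian", dt=0.005, n_steps=1, seed=1)
        with pytest.raises(ValueError):
            shoot_committor(pot, thermo, sp, [-7.5], n_shots=10)


class TestFirstPassage:
    def test_flat_double_absorbing_matches_oracle(self):
        """MFPT to either edge of [-7, 7]: T(x) = (a² - x²)/2D, averaged over
        equilibrium-in-source starts (independent closed-form oracle)."""
        pot = make_potential("flat", domain=(-8.0, 8.0))
        th = ThermoState(0.5915, 1.0)
        sp = SimParams("brownian", dt=0.005, n_steps=1, seed=31)
        src = (-1.0, 1.0)
        df = first_passage_times(pot, th, sp, src, (-7.0, 7.0), n_samples=250)
        assert not df.censored.any()
        # oracle: uniform starts on [-1, 1] -> mean of (49 - x^2)/2
        x = np.linspace(*src, 2001)
        oracle = np.mean((49.0 - x**2) / 2.0)
        se = df.time.std(ddof=1) / np.sqrt(len(df))
        assert abs(df.time.mean() - oracle) < 3 * se

    def test_narrow_mfpt_matches_quadrature_rate(self, thermo, quad):
        """Mean first passage A -> z2 equals 1/k_AB from quadrature."""
        pot = make_potential("narrow")
        sp = SimParams("brownian", dt=0.005, n_steps=1, seed=32)
        df = first_passage_times(pot, thermo, sp, (-12.0, -4.0), 7.0, n_samples=80)
        assert not df.censored.any()
        mfpt_ref = 1.0 / quad["narrow"].k_AB
        se = df.time.std(ddof=1) / np.sqrt(len(df))
        assert abs(df.time.mean() - mfpt_ref) < 3 * se

    def test_target_inside_source_rejected(self, thermo):
        pot = make_potential("narrow")
        sp = SimParams("brownian", dt=0.005, n_steps=1, seed=1)
        with pytest.raises(ValueError):
            first_passage_times(pot, thermo, sp, (-5.0, 5.0), 0.0, n_samples=1)


def test_dividing_surface_sampling(thermo):
    z, v = sample_dividing_surface(thermo, 0.3, 40_000, seed=9)
    assert np.all(z == 0.3)
    kBT_m = thermo.kBT * E_CONV / thermo.mass
    se = np.sqrt(kBT_m / len(v))
    assert abs(v.mean()) < 3 * se
    half_mean = np.sqrt(kBT_m / (2 * np.pi))  # ⟨v θ(v)⟩ for a Maxwellian
    vp = v * (v > 0)
    assert abs(vp.mean() - half_mean) < 3 * vp.std() / np.sqrt(len(v))
    with pytest.raises(ValueError):
        sample_dividing_surface(ThermoState(0.5915, 1.0), 0.0, 10)


def test_langevin_bd_overdamped_consistency(thermo):
    """Beyond the velocity relaxation time, Langevin position statistics match
    Brownian dynamics for the same potential."""
    from ratepaths.correlators import DividingSurface, position_correlation

    pot = make_potential("broad")
    spb = SimParams("brownian", dt=0.005, n_steps=4_000_000, stride=10, seed=51)
    spl = SimParams("langevin", dt=0.001, n_steps=20_000_000, stride=50, seed=52)
    bd = simulate_batch(pot, thermo, spb, 4)  # 4 x 20 ns each
    lv = simulate_batch(pot, thermo, spl, 4)
    # start at 1 ps (~12 velocity relaxation times): the inertial MSD offset
    # ~2D·tau_v decays like tau_v/t and is still ~4% of C_zz at 0.5 ps
    lags = np.arange(0.0, 8.01, 1.0)
    ds = DividingSurface("position", 0.0)

    def per_walker(trajs):
        # per-walker estimates so that the spread also reflects the noisy
        # normalization (few barrier transitions per walker at this scale)
        vals = np.array([position_correlation([t], ds, lags).values for t in trajs])
        return vals.mean(axis=0), vals.std(axis=0, ddof=1) / np.sqrt(len(trajs))

    mb, eb = per_walker(bd)
    ml, el = per_walker(lv)
    err = np.sqrt(eb**2 + el**2)
    assert np.all(np.abs(mb[1:] - ml[1:]) < 3 * err[1:] + 1e-12)
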
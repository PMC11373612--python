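# ratepaths

Transition rates of two-state stochastic systems, computed three consistent
ways:

1. **Committor / transition-path-theory flux** — the exact 1D committor
   q(z) by quadrature and the steady-state reactive flux
   J_AB = ∫ q′(z) D ρ_eq(z) q′(z) dz = D / (Z_full · Z_barrier);
2. **Markov-propagator spectral analysis** — a binned transition matrix at
   lag τ, its eigenvalues λ_k = e^(−μ_k τ), the implied global relaxation
   rate μ₂ = J_AB/(p_A p_B), and the eigenvector model committor;
3. **Activated-dynamics / correlation-function estimators** — the limiting
   slopes of the indicator (C_BB), position (C_zz), committor (C_qq) and
   indicator-restricted committor (C_ABqq) time-correlation functions, plus
   the transmission-coefficient correction κ to the transition-state-theory
   rate, k_AB = κ·k_TST.

It is aimed at people studying barrier-crossing kinetics — committor-based
rate theory, Markov state models, reactive flux — who want a small, fully
reproducible testbed where all three routes can be computed exactly or to
controlled statistical precision and compared.

Three 1D double-well benchmark systems are built in, with the potential

    W(z) = (z/9.51)^12 + h·exp(−(z/w)^p) + c        [kcal/mol, z in Å]

and (h, w, p, c) = (3.3, 0.6, 2, −3.2) "narrow", (3.3, 4.0, 2, −3.3)
"medium", (3.2, 7.0, 16, −3.2) "broad": a steep confining wall plus a
central bump whose width sets whether the free-energy barrier is sharp or
flat.  Default thermodynamics: k_BT = 0.5915 kcal/mol, D = 1 Å²/ps,
m = 20 amu, committor boundaries z₁ = −7 Å, z₂ = +7 Å.  A seeded
Euler–Maruyama Brownian integrator and a BAOAB Langevin integrator (friction
fixed by the Einstein relation γ = k_BT/mD) generate the trajectories; the
inner loops are numba-compiled, so microsecond-scale 1D runs take seconds to
minutes.

## Worked example

```python
import numpy as np
import ratepaths as rp

pot = rp.make_potential("broad")
th = rp.ThermoState(kBT=0.5915, D=1.0, mass=20.0)

# route 1: exact quadrature
res = rp.TwoStateModel(pot, th, z1=-7.0, z2=7.0).fit()
print(res.summary())

# routes 2 and 3: 200 ns of Brownian dynamics (5 walkers x 40 ns)
sp = rp.SimParams("brownian", dt=0.005, n_steps=8_000_000, stride=10, seed=103)
trajs = rp.simulate_batch(pot, th, sp, 5)

cs = rp.committor_correlation(trajs, res.committor, np.arange(0.0, 60.01, 0.5))
rate = rp.extract_flux(cs, pA=res.pA)
print(f"C_qq slope: J_AB = {rate.J_AB:.3e} +/- {rate.J_err:.1e} ps^-1")

print(rp.MarkovStateModel(trajs, 120, lag=0.5).fit().summary())
```

prints

```
                    value  units
quantity
pA           5.000000e-01
pB           5.000000e-01
J_AB         1.210920e-04  ps^-1
k_AB         2.421840e-04  ps^-1
k_BA         2.421840e-04  ps^-1
mu2          4.843680e-04  ps^-1
tau_star     2.064546e+03     ps
p_reactive   3.130512e-03
tau_transit  2.585235e+01     ps
z_dagger    -2.181827e-14      A

C_qq slope: J_AB = 1.314e-04 +/- 1.4e-05 ps^-1
                         value
quantity
lag (ps)              0.500000
n_bins (occupied)   113.000000
lambda_2              0.999757
mu_2 (1/ps)           0.000485
tau_star (ps)      2061.582487
mu_3/mu_2           143.600893
```

Reading this: the exact diffusive flux over the broad barrier is
1.21×10⁻⁴ ps⁻¹, so with symmetric wells (p_A = p_B = ½) the global
relaxation time is τ* = 1/μ₂ ≈ 2065 ps, and a reactive crossing takes
⟨τ_r⟩ ≈ 26 ps on average.  The committor-correlation slope estimated from
0.2 µs of simulation agrees within its ~10% statistical error, and the MSM
gives the same relaxation time (2062 ps) with a spectral gap μ₃/μ₂ ≈ 144 —
a clean two-state system.

## Command line

```sh
ratepaths committor --potential narrow --z1 -7 --z2 7 --out q.csv
ratepaths simulate  --config run.toml --out traj.h5
ratepaths correlate --traj traj.h5 --estimators bb,zz,qq --committor q.csv --out corr/
ratepaths msm       --traj traj.h5 --lag 0.5 --bins 120 --out msm.h5
ratepaths run       --config run.toml          # full pipeline
```

Experiments are described by one TOML file (sections `potential`, `thermo`,
`simulation`, `committor`, `correlators`, `msm`, `output`); unknown keys are
rejected.  Microsecond-scale protocols require an explicit `--full-scale`
flag on `ratepaths run`.

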
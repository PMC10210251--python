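"""Shared fixtures.

The expensive TAMD/OTFP runs are session-scoped and reused by both the
module tests and the acceptance suite, so the whole battery of recovery
checks costs one set of simulations.
"""

import numpy as np
import pytest

import tamdkit as tk


@pytest.fixture(scope="session")
def harmonic_tamd():
    """TAMD run on V = (k/2) x^2, k = 2, with the reference spring and
    friction settings and auxiliary temperature 2000 K; 1e6 force samples
    thinned from 16e6 steps."""
    pot = tk.make_harmonic(2.0)
    cv = tk.CollectiveVariableMap.coordinate_z(pot, [0])
    params = tk.TamdParams(kappa=1500.0, gamma_bar=800.0, T_bar=2000.0,
                           physical=tk.LangevinParams(temperature=310.0,
                                                      seed=3))
    traj = tk.tamd_run(pot, cv, params, n_steps=16_000_000, save_every=16)
    return {"potential": pot, "cv": cv, "params": params, "traj": traj,
            "k": 2.0, "k_eff": 2.0 * 1500.0 / 1502.0}


@pytest.fixture(scope="session")
def double_well_tamd():
    """TAMD run on the h=6, a=2 double well at auxiliary temperature
    6000 K, plus the solved 1D surface."""
    pot = tk.make_double_well(6.0, 2.0, 1.0)
    cv = tk.CollectiveVariableMap(kind="coordinate_z", selections=((0,),),
                                  M=1)
    params = tk.TamdParams(kappa=1500.0, gamma_bar=800.0, T_bar=6000.0,
                           physical=tk.LangevinParams(temperature=310.0,
                                                      seed=5))
    traj = tk.tamd_run(pot, cv, params, n_steps=16_000_000, save_every=16)
    grid = tk.ChapeauGrid.from_spacing([-4.0], [4.0], 0.25)
    tk.accumulate(grid, traj.z_frames, tk.mean_force_samples(traj, 1500.0))
    fes = tk.solve_fes(grid)
    return {"potential": pot, "cv": cv, "params": params, "traj": traj,
            "fes": fes, "height": 6.0, "half_separation": 2.0}


@pytest.fixture(scope="session")
def filter2d():
    """Three replica two-CV TAMD runs on the self-confined toy filter
    (2e6 kept-scale samples each) with the matching 2D quadrature oracle."""
    pot = tk.make_toy_filter(n_ions=1, z_domain=(3.0, 18.0))
    cv = tk.CollectiveVariableMap.coordinate_z(pot, [0, 1])
    beta = tk.beta(310.0)
    gz = np.arange(3.0, 18.0 + 1e-9, 0.25)
    gg = np.arange(-1.5, 1.5 + 1e-9, 0.25)
    oracle = tk.marginal_fe_oracle(pot, cv, beta, (gz, gg), n_quad=21)

    # estimator settings for the toy recovery: a softer tether (tracking
    # blur sqrt(kT/kappa) ~ 0.05 A, far below the 0.25 A grid) cuts the
    # force-sample noise sqrt(kappa kT) six-fold, and an overdamped
    # physical thermostat tightens the adiabatic separation; neither
    # changes the free energy being measured
    kappa = 250.0

    def one_replica(seed):
        params = tk.TamdParams(
            kappa=kappa, gamma_bar=800.0, T_bar=6000.0,
            physical=tk.LangevinParams(temperature=310.0, friction=10.0,
                                       seed=seed))
        traj = tk.tamd_run(pot, cv, params, n_steps=320_000_000,
                           save_every=160, x0=[0.0, 0.0, 5.0, 1.0])
        grid = tk.ChapeauGrid.from_spacing([3.0, -1.5], [18.0, 1.5], 0.25)
        tk.accumulate(grid, traj.z_frames,
                      tk.mean_force_samples(traj, kappa))
        return traj, grid, tk.solve_fes(grid, provenance={"seed": seed})

    replicas = [one_replica(seed) for seed in (11, 12, 13)]
    return {"potential": pot, "cv": cv, "oracle": oracle, "kappa": kappa,
            "replicas": replicas}


@pytest.fixture(scope="session")
def benchmark():
    """Benchmark surface with dense-grid oracles and its 0.05-gridded FES."""
    pot = tk.make_benchmark_surface()
    minima = tk.grid_minima(pot, n=1000)
    a, b = minima[0][0], minima[1][0]
    saddle_xy, saddle_e = tk.grid_minimax_saddle(pot, a, b, n=1000)
    fes = tk.FreeEnergySurface.from_callable(
        pot, tk.BENCHMARK_BOUNDS[:, 0], tk.BENCHMARK_BOUNDS[:, 1], 0.05)
    return {"potential": pot, "minima": minima, "saddle_xy": saddle_xy,
            "saddle_e": saddle_e, "fes": fes, "spacing": 0.05}


@pytest.fixture(scope="session")
def synthetic_structure():
    return tk.make_synthetic_filter_structure()
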
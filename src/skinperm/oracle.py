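"""Brute-force flux oracle: discrete master-equation permeability.

The resistance-integral pipeline is validated against a physically
independent computation: the permeant is modeled as a continuous-time
Markov chain hopping on the depth grid, with nearest-neighbor rates

    k_{i -> i+1} = D_{i+1/2} / dz^2 * exp(-(G_{i+1} - G_i) / 2kT)

(symmetric exponent splitting; any detailed-balance-consistent splitting
has the same continuum limit, and this one is second-order accurate).
A source at z1 holds unit concentration (relative to the G = 0 water
reference) and z2 is absorbing; the steady-state flux per unit source
concentration is the single-layer permeability.  On fine grids this must
agree with the resistance integral — the two computations share nothing
but the profiles.

The solve is done in activity variables u_i = p_i exp(+G_i/kT), which makes
the linear system a symmetric weighted-Laplacian (series-of-conductances)
problem: edge conductance c_i = D_{i+1/2}/dz^2 * exp(-(G_i + G_{i+1})/2kT).
This is numerically benign even with 60+ kJ/mol barriers.

A two-state (position × protonation) variant adds vertical exchange edges
with attempt rate nu, satisfying detailed balance with respect to the
Henderson-Hasselbalch-shifted free energies.  For nu -> infinity it must
converge to the dynamic-protonation (boltzmann-combined) pipeline; for
nu = 0 it is the sum of the two single-state fluxes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.sparse import csc_matrix
from scipy.sparse.linalg import spsolve

from .constants import NM_PER_PS_TO_CM_PER_S
from .profiles import SpatialProfile
from .protonation import Environment

__all__ = [
    "RateModel",
    "build_rate_model",
    "flux_permeability_1d",
    "two_state_flux_permeability",
    "gillespie_splitting_kp",
]


@dataclass(frozen=True)
class RateModel:
    """Nearest-neighbor hopping chain on a uniform depth grid.

    ``k_fwd[i]`` is the i -> i+1 rate and ``k_bwd[i]`` the i+1 -> i rate
    (1/ps); both satisfy detailed balance with respect to exp(-G/kT).
    """

    z: np.ndarray
    free_energy: np.ndarray
    diffusion: np.ndarray
    kT: float
    k_fwd: np.ndarray
    k_bwd: np.ndarray

    @property
    def dz(self) -> float:
        return float(self.z[1] - self.z[0])

    def detailed_balance_residual(self) -> float:
        """max |k_fwd w_i - k_bwd w_{i+1}| / (k_fwd w_i), w = exp(-G/kT).

        Computed in log space; zero (to rounding) for a valid model.
        """
        log_flux_f = np.log(self.k_fwd) - self.free_energy[:-1] / self.kT
        log_flux_b = np.log(self.k_bwd) - self.free_energy[1:] / self.kT
        return float(np.max(np.abs(np.expm1(log_flux_b - log_flux_f))))


def _uniform_dz(z: np.ndarray) -> float:
    dz = np.diff(z)
    if dz.max() > dz.min() * 1.01:
        raise ValueError("oracle requires a uniform grid (within 1%)")
    return float(dz.mean())


def build_rate_model(G: SpatialProfile, D: SpatialProfile,
                     env: Environment) -> RateModel:
    """Construct hopping rates from a PMF and a diffusion profile."""
    if not G.same_grid(D):
        raise ValueError("G and D must share one grid")
    if np.any(D.value <= 0):
        raise ValueError("diffusion must be strictly positive")
    dz = _uniform_dz(G.z)
    kT = env.kT
    d_mid = 0.5 * (D.value[:-1] + D.value[1:])
    dG = np.diff(G.value)
    k_fwd = d_mid / dz**2 * np.exp(-dG / (2.0 * kT))
    k_bwd = d_mid / dz**2 * np.exp(+dG / (2.0 * kT))
    return RateModel(z=G.z, free_energy=G.value, diffusion=D.value,
                     kT=kT, k_fwd=k_fwd, k_bwd=k_bwd)


def _edge_conductances(model: RateModel) -> np.ndarray:
    """Symmetric edge conductances c_i = k_fwd[i] exp(-G_i/kT)."""
    g = model.free_energy
    d_mid = 0.5 * (model.diffusion[:-1] + model.diffusion[1:])
    return d_mid / model.dz**2 * np.exp(-(g[:-1] + g[1:]) / (2.0 * model.kT))


def flux_permeability_1d(G: SpatialProfile, D: SpatialProfile,
                         env: Environment) -> float:
    """Single-layer permeability (cm/s) from the steady-state chain flux.

    Solves the interior steady state as a tridiagonal system with the
    source node fixed at unit reference concentration (activity u_0 = dz)
    and the sink absorbing (u_N = 0), then returns flux / concentration.
    """
    model = build_rate_model(G, D, env)
    c = _edge_conductances(model)
    if np.any(c <= 0) or not np.all(np.isfinite(c)):
        raise ValueError("disconnected or non-finite chain: singular system")
    n_int = model.z.size - 2
    if n_int < 1:
        raise ValueError("grid too small for an interior steady state")
    u0 = model.dz  # unit source concentration × cell width, G=0 reference
    diag = c[:-1] + c[1:]
    ab = np.zeros((3, n_int))
    ab[0, 1:] = -c[1:-1]
    ab[1, :] = diag
    ab[2, :-1] = -c[1:-1]
    b = np.zeros(n_int)
    b[0] = c[0] * u0
    u = solve_banded((1, 1), ab, b)
    flux = c[0] * (u0 - u[0])  # 1/ps, per unit reference concentration 1/nm
    return float(flux * NM_PER_PS_TO_CM_PER_S)


def two_state_flux_permeability(
    G_n: SpatialProfile,
    D_n: SpatialProfile,
    G_c: SpatialProfile,
    D_c: SpatialProfile,
    exchange_rate: float,
    env: Environment,
) -> float:
    """Single-layer permeability of the coupled two-state chain (cm/s).

    The state space is (depth index, protonation state).  Spatial edges use
    each state's own PMF/diffusion; vertical protonation-exchange edges at
    depth i have conductance nu exp(-(G_n,i + G_c,i)/2kT), i.e. attempt
    rate ``exchange_rate`` with symmetric detailed-balance splitting
    against the (already HH-shifted) free energies.  Both boundary columns
    hold their states at Boltzmann populations relative to one unit of
    G = 0 reference concentration; the returned value is total steady flux
    into the sink per that unit concentration.
    """
    model_n = build_rate_model(G_n, D_n, env)
    model_c = build_rate_model(G_c, D_c, env)
    if model_n.z.size != model_c.z.size:
        raise ValueError("both states must share one grid")
    if exchange_rate < 0:
        raise ValueError("exchange_rate must be >= 0")
    npts = model_n.z.size
    dz = model_n.dz
    kT = env.kT
    c_n = _edge_conductances(model_n)
    c_c = _edge_conductances(model_c)
    c_x = exchange_rate * np.exp(
        -(model_n.free_energy + model_c.free_energy) / (2.0 * kT)
    )

    n_int = npts - 2
    n_unk = 2 * n_int  # interior u for both states; [neutral..., charged...]
    rows, cols, vals = [], [], []
    b = np.zeros(n_unk)
    u0 = dz

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for s, c_sp in enumerate((c_n, c_c)):
        off = s * n_int
        for i in range(n_int):  # grid node i+1
            diag = c_sp[i] + c_sp[i + 1] + c_x[i + 1]
            add(off + i, off + i, diag)
            if i > 0:
                add(off + i, off + i - 1, -c_sp[i])
            else:
                b[off + i] += c_sp[0] * u0
            if i < n_int - 1:
                add(off + i, off + i + 1, -c_sp[i + 1])
            # vertical coupling to the other state, same grid node
            other = (1 - s) * n_int + i
            add(off + i, other, -c_x[i + 1])
    mat = csc_matrix((vals, (rows, cols)), shape=(n_unk, n_unk))
    u = spsolve(mat, b)
    flux = c_n[0] * (u0 - u[0]) + c_c[0] * (u0 - u[n_int])
    return float(flux * NM_PER_PS_TO_CM_PER_S)


def gillespie_splitting_kp(
    G: SpatialProfile,
    D: SpatialProfile,
    env: Environment,
    n_walkers: int = 2000,
    seed: int = 0,
) -> float:
    """Stochastic (kinetic Monte Carlo) estimate of the single-layer Kp.

    Secondary cross-check for coarse grids: the steady flux equals
    k_{0->1} p_0 P_split, where P_split is the probability that a walker
    released at node 1 reaches the sink before returning to the source.
    P_split depends only on the embedded jump chain, which is sampled
    directly.  Noisy by construction — use the linear solve for anything
    quantitative.
    """
    model = build_rate_model(G, D, env)
    rng = np.random.default_rng(seed)
    npts = model.z.size
    p_right = model.k_fwd[1:] / (model.k_fwd[1:] + model.k_bwd[:-1])
    hits = 0
    for _ in range(n_walkers):
        i = 1
        while 0 < i < npts - 1:
            i += 1 if rng.random() < p_right[i - 1] else -1
        hits += i == npts - 1
    p_split = hits / n_walkers
    p0 = model.dz * np.exp(-model.free_energy[0] / model.kT)
    flux = model.k_fwd[0] * p0 * p_split
    return float(flux * NM_PER_PS_TO_CM_PER_S)
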
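"""Seeded synthetic PMF/diffusion generator emulating adaptive-bias output.

The generator builds noiseless ground-truth profiles with the qualitative
anatomy of an ionizable permeant in a lamellar lipid barrier (half
coordinate, water at large z):

* neutral state — a moderate free-energy well in the lipid chain region
  and a modest headgroup feature; values approach 0 (the water reference)
  in the aqueous region;
* charged state — a deep well centered in the polar headgroup window
  (2.9-3.3 nm) and a high (>= 60 kJ/mol) barrier across the dense chain
  region, reflecting that ionized species sit at the headgroups and
  essentially cannot cross the chains;
* diffusion — a positive baseline with a dip in the packed chain region.

Replicates emulate finite-sampling variability: the ground truth plus
smooth correlated noise (Gaussian-process-like, correlation length 0.2 nm,
chosen to interact meaningfully with the 0.2 nm median filter) plus small
per-point jitter.  Diffusion profiles carry multiplicative lognormal noise.
Artificial spikes are injected at the two outermost points of each edge of
both PMF replicates and diffusion profiles, so the edge-repair and
median-filter stages have real work to do.  Every profile records its
noiseless ground truth in ``meta["ground_truth"]``.

All randomness flows from a single integer seed via numpy's Generator;
identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .profiles import ReplicateSet, SpatialProfile
from .protonation import PermeantSpec, StateProfiles

__all__ = [
    "GeneratorParams",
    "PRESETS",
    "preset_permeant",
    "generate_state_profiles",
    "generate_raw_unsymmetrized",
    "ground_truth_profiles",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Settings of the synthetic profile generator (half grid [0, z_max]).

    Amplitudes are in kJ/mol, lengths in nm, diffusion in nm^2/ps.  The
    defaults are the generator's study conditions and are not tuned per
    run: chain well -6 at 1.5 nm for the neutral state, +3 headgroup bump;
    charged-state headgroup well -12 at 3.1 nm and a 65 kJ/mol chain
    barrier; replicate noise 1.0 kJ/mol smooth + 0.1 kJ/mol white.
    """

    z_max: float = 5.2
    spacing: float = 0.01
    # neutral-state anatomy
    neutral_well_depth: float = 6.0
    neutral_well_center: float = 1.5
    neutral_well_width: float = 0.8
    neutral_head_height: float = 3.0
    # charged-state anatomy
    charged_head_well_depth: float = 12.0
    charged_head_center: float = 3.1
    charged_head_width: float = 0.18
    charged_chain_barrier: float = 65.0
    charged_chain_center: float = 1.2
    charged_chain_width: float = 0.9
    # replicate noise
    n_replicates: int = 5
    noise_sigma: float = 1.0
    noise_corr_length: float = 0.2
    jitter_sigma: float = 0.1
    # diffusion
    d_baseline: float = 0.05
    d_chain_dip: float = 0.8  # fractional depth of the chain-region dip
    d_noise_sigma: float = 0.15  # lognormal sigma
    # injected edge artifacts
    edge_spike_kj: float = 8.0
    edge_spike_factor: float = 5.0
    n_edge_spike: int = 2

    def __post_init__(self):
        for name in (
            "neutral_well_depth", "charged_head_well_depth",
            "charged_chain_barrier", "d_baseline", "spacing", "z_max",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.d_chain_dip < 1:
            raise ValueError("d_chain_dip must be in [0, 1)")

    def grid(self) -> np.ndarray:
        n = round(self.z_max / self.spacing)
        return np.linspace(0.0, self.z_max, n + 1)


#: Preset permeant identities shipped with the generator (generator
#: conventions, not measurements of any real compound).
PRESETS = {
    "acid_like": PermeantSpec(
        name="acid_like", pka=4.2, acid_class="acid",
        dg_hyd_neutral=-40.0, dg_hyd_charged=-260.0,
    ),
    "base_like": PermeantSpec(
        name="base_like", pka=8.0, acid_class="base",
        dg_hyd_neutral=-40.0, dg_hyd_charged=-260.0,
    ),
}


def preset_permeant(name: str) -> PermeantSpec:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def _gauss(z, center, width):
    return np.exp(-((z - center) ** 2) / (2.0 * width**2))


def _truth_pmf(z: np.ndarray, params: GeneratorParams, state: str) -> np.ndarray:
    if state == "neutral":
        g = (
            -params.neutral_well_depth
            * _gauss(z, params.neutral_well_center, params.neutral_well_width)
            + params.neutral_head_height * _gauss(z, params.charged_head_center, 0.25)
        )
    elif state == "charged":
        g = (
            -params.charged_head_well_depth
            * _gauss(z, params.charged_head_center, params.charged_head_width)
            + params.charged_chain_barrier
            * _gauss(z, params.charged_chain_center, params.charged_chain_width)
        )
    else:
        raise ValueError(f"unknown state {state!r}")
    return g


def _truth_diffusion(z: np.ndarray, params: GeneratorParams) -> np.ndarray:
    dip = params.d_chain_dip * _gauss(z, params.charged_chain_center, 1.0)
    return params.d_baseline * (1.0 - dip)


def _smooth_noise(rng, n, sigma, corr_length, spacing):
    """Stationary Gaussian noise with ~Gaussian autocorrelation and
    marginal sd ``sigma`` (white noise filtered by a Gaussian kernel)."""
    if sigma == 0:
        return np.zeros(n)
    sig_pts = max(corr_length / spacing, 1e-9)
    white = rng.standard_normal(n)
    smooth = gaussian_filter1d(white, sigma=sig_pts, mode="nearest")
    kernel = gaussian_filter1d(
        np.eye(1, 2 * int(4 * sig_pts) + 3, int(4 * sig_pts) + 1)[0],
        sigma=sig_pts,
    )
    return smooth * (sigma / np.sqrt(np.sum(kernel**2)))


def _spike_pmf(values: np.ndarray, params: GeneratorParams, rng) -> np.ndarray:
    k = params.n_edge_spike
    if k == 0:
        return values
    v = values.copy()
    v[:k] += params.edge_spike_kj * (1.0 + rng.random(k))
    v[-k:] += params.edge_spike_kj * (1.0 + rng.random(k))
    return v


def generate_state_profiles(
    params: GeneratorParams = GeneratorParams(),
    seed: int = 0,
) -> tuple[StateProfiles, StateProfiles]:
    """Generate raw (noisy, spiked) neutral and charged state profiles.

    Each returned :class:`StateProfiles` carries the noisy replicate PMFs
    (``.replicates``), their plain average as ``.pmf``, and a noisy
    diffusion profile; the corresponding noiseless curves sit in each
    profile's ``meta["ground_truth"]``.  Feed the output through the
    preprocessing stages before quantitative use.
    """
    rng = np.random.default_rng(seed)
    z = params.grid()
    out = []
    for state in ("neutral", "charged"):
        truth_g = _truth_pmf(z, params, state)
        reps = []
        for _ in range(params.n_replicates):
            noise = _smooth_noise(
                rng, z.size, params.noise_sigma,
                params.noise_corr_length, params.spacing,
            )
            jitter = (
                params.jitter_sigma * rng.standard_normal(z.size)
                if params.jitter_sigma > 0 else 0.0
            )
            values = _spike_pmf(truth_g + noise + jitter, params, rng)
            reps.append(
                SpatialProfile(z=z, value=values, label="pmf", state=state,
                               meta={"ground_truth": truth_g.copy()})
            )
        rep_set = ReplicateSet(tuple(reps))
        truth_d = _truth_diffusion(z, params)
        d_noise = np.exp(
            params.d_noise_sigma * rng.standard_normal(z.size)
            - params.d_noise_sigma**2 / 2.0
        )
        d_values = truth_d * d_noise
        k = params.n_edge_spike
        if k:
            d_values = d_values.copy()
            d_values[:k] *= params.edge_spike_factor
            d_values[-k:] *= params.edge_spike_factor
        diffusion = SpatialProfile(
            z=z, value=d_values, label="diffusion", state=state,
            meta={"ground_truth": truth_d.copy()},
        )
        mean_pmf = SpatialProfile(
            z=z, value=rep_set.values().mean(axis=0), label="pmf",
            state=state, meta={"ground_truth": truth_g.copy()},
        )
        out.append(
            StateProfiles(pmf=mean_pmf, diffusion=diffusion, state=state,
                          replicates=rep_set)
        )
    return out[0], out[1]


def ground_truth_profiles(state: StateProfiles) -> StateProfiles:
    """Noiseless StateProfiles recovered from generator metadata."""
    g = state.pmf.meta.get("ground_truth")
    d = state.diffusion.meta.get("ground_truth")
    if g is None or d is None:
        raise ValueError("profiles carry no generator ground truth")
    return StateProfiles(
        pmf=replace(state.pmf, value=np.asarray(g), sem=None),
        diffusion=replace(state.diffusion, value=np.asarray(d), sem=None),
        state=state.state,
    )


def generate_raw_unsymmetrized(
    params: GeneratorParams = GeneratorParams(),
    seed: int = 0,
    state: str = "neutral",
    odd_amplitude: float = 0.0,
) -> SpatialProfile:
    """Full-range [-z_max, z_max] PMF with independent noise on each side.

    The underlying truth is even (the mirrored half-profile); each side
    receives its own smooth-noise draw, so symmetrization has a nontrivial
    variance-reduction task.  ``odd_amplitude`` optionally injects an odd
    sin(pi z / z_max) contamination that symmetrization must annihilate.
    ``meta["ground_truth"]`` holds the even truth on the full grid.
    """
    rng = np.random.default_rng(seed)
    half = params.grid()
    z = np.concatenate([-half[::-1], half[1:]])
    truth_half = _truth_pmf(half, params, state)
    truth = np.concatenate([truth_half[::-1], truth_half[1:]])
    noise = _smooth_noise(rng, z.size, params.noise_sigma,
                          params.noise_corr_length, params.spacing)
    values = truth + noise
    if odd_amplitude:
        values = values + odd_amplitude * np.sin(np.pi * z / params.z_max)
    return SpatialProfile(z=z, value=values, label="pmf", state=state,
                          meta={"ground_truth": truth})
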
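"""Inhomogeneous solubility-diffusion permeability through a stacked barrier.

The permeation resistance of one simulated system is the integral

    R_single = ∫ exp(ΔG_rel.water(z)/kT) / D(z) dz

evaluated by the trapezoidal rule on a uniform ~0.01 nm grid, where
ΔG_rel.water is the PMF relative to water (shifted so it is never below 0)
and D the local diffusion coefficient.  The skin's barrier is modeled as
n_layers (30 +- 6) such systems in series, so R_total = n_layers R_single
and the permeability coefficient is K_P = 1/R_total, reported in cm/s.

Two pH models are provided: the *dynamic-protonation* route (combined
two-state PMF and diffusion profile) and the classical *pH-partition*
baseline, K_P(pH) = neutral_fraction(pH) × K_P(neutral), which assumes only
the neutral species permeates.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import PS_PER_NM_TO_S_PER_CM
from .profiles import SpatialProfile
from .protonation import (
    Environment,
    PermeantSpec,
    StateProfiles,
    combine_diffusion,
    combine_pmf,
    common_zero_shift,
    hh_shift,
    neutral_fraction,
    state_probabilities,
)

__all__ = [
    "PermeabilityResult",
    "resistance_integral",
    "permeability",
    "ph_partition_kp",
    "neutral_only_kp",
    "dynamic_kp",
    "kp_uncertainty",
    "ph_scan",
]


@dataclass(frozen=True)
class PermeabilityResult:
    """Permeability through the n-layer barrier, with provenance.

    kp is in cm/s; r_single and r_total in s/cm.  ``kp_layer_range`` is the
    (low, high) kp implied by the +-n_layers_spread systematic layer-count
    uncertainty — reported separately from the statistical sem because it is
    a systematic term.  ``kp_replicates`` / ``sem_log10_kp`` are filled by
    :func:`kp_uncertainty`.
    """

    kp: float
    r_single: float
    r_total: float
    ph: float = np.nan
    mode: str = "dynamic"
    n_layers: int = 1
    kp_layer_range: tuple[float, float] | None = None
    kp_replicates: tuple[float, ...] | None = None
    log10_kp_mean: float | None = None
    sem_log10_kp: float | None = None
    intermediates: dict | None = None

    @property
    def kp_single(self) -> float:
        """Single-layer permeability 1/r_single (cm/s)."""
        return 1.0 / self.r_single

    @property
    def log10_kp(self) -> float:
        return float(np.log10(self.kp))


def _check_uniform(z: np.ndarray, rtol: float = 0.01) -> float:
    dz = np.diff(z)
    if dz.max() > dz.min() * (1.0 + rtol):
        raise ValueError(
            f"grid is not uniform within {rtol:.0%} "
            f"(dz range [{dz.min():.3e}, {dz.max():.3e}] nm)"
        )
    return float(dz.mean())


def resistance_integral(
    pmf: SpatialProfile,
    diffusion: SpatialProfile,
    env: Environment,
    half: bool | None = None,
) -> float:
    """Single-system permeation resistance in s/cm (trapezoidal rule).

    The PMF must satisfy the zero-shift convention (never below ~0, up to
    the kT ln 2 dip a combined PMF may carry).  ``half=None`` auto-detects a
    symmetrized half-profile (grid starting at z >= 0 while the environment
    spans negative z) and doubles the integral accordingly.
    """
    if not pmf.same_grid(diffusion):
        raise ValueError("pmf and diffusion must share one grid")
    if np.any(diffusion.value <= 0):
        raise ValueError("diffusion must be strictly positive")
    _check_uniform(pmf.z)
    kT = env.kT
    integrand = np.exp(pmf.value / kT) / diffusion.value
    r_ps_per_nm = np.trapezoid(integrand, pmf.z)
    if half is None:
        half = pmf.z[0] > -pmf.spacing and env.z1 < 0
    if half:
        r_ps_per_nm *= 2.0
    return float(r_ps_per_nm * PS_PER_NM_TO_S_PER_CM)


def permeability(
    r_single: float,
    env: Environment,
    ph: float = np.nan,
    mode: str = "dynamic",
    intermediates: dict | None = None,
) -> PermeabilityResult:
    """Scale a single-system resistance to the n-layer barrier.

    Serial-resistance model: R_total = n_layers R_single, K_P = 1/R_total.
    The layer-count spread (default 30 +- 6) is reported as a deterministic
    kp range.
    """
    if r_single <= 0:
        raise ValueError("r_single must be > 0")
    n = env.n_layers
    r_total = n * r_single
    lo_n, hi_n = n + env.n_layers_spread, max(1, n - env.n_layers_spread)
    return PermeabilityResult(
        kp=1.0 / r_total,
        r_single=r_single,
        r_total=r_total,
        ph=ph,
        mode=mode,
        n_layers=n,
        kp_layer_range=(1.0 / (lo_n * r_single), 1.0 / (hi_n * r_single)),
        intermediates=intermediates,
    )


def ph_partition_kp(
    kp_neutral: float, spec: PermeantSpec, ph: float, env: Environment
) -> PermeabilityResult:
    """pH-partition baseline: K_P(pH) = f_neutral(pH) × K_P(neutral)."""
    if kp_neutral <= 0:
        raise ValueError("kp_neutral must be > 0")
    frac = neutral_fraction(spec, ph)
    kp = frac * kp_neutral
    r_total = 1.0 / kp
    return PermeabilityResult(
        kp=kp,
        r_single=r_total / env.n_layers,
        r_total=r_total,
        ph=ph,
        mode="ph_partition",
        n_layers=env.n_layers,
        intermediates={"neutral_fraction": frac},
    )


def neutral_only_kp(neutral: StateProfiles, env: Environment) -> PermeabilityResult:
    """Permeability of the neutral species alone (its PMF zero-shifted)."""
    pmf = neutral.pmf
    gmin = float(pmf.value.min())
    if gmin < 0:
        pmf = pmf.shift(-gmin)
    r = resistance_integral(pmf, neutral.diffusion, env)
    return permeability(r, env, mode="neutral_only")


def dynamic_kp(
    neutral: StateProfiles,
    charged: StateProfiles,
    spec: PermeantSpec,
    ph: float,
    env: Environment,
    mode: str = "boltzmann",
    rezero_combined: bool = False,
) -> PermeabilityResult:
    """Dynamic-protonation permeability at one pH.

    Chains the protocol: Henderson-Hasselbalch shift of the charged PMF ->
    common zero shift -> state probabilities -> combined PMF (boltzmann or
    weighted) -> combined diffusion -> resistance integral -> n-layer
    permeability.  The intermediate profiles are kept on the result for
    inspection.
    """
    pmf_c = hh_shift(charged.pmf, spec, ph, env)
    pmf_n, pmf_c = common_zero_shift(neutral.pmf, pmf_c)
    p_n, p_c = state_probabilities(pmf_n, pmf_c, env)
    g = combine_pmf(pmf_n, pmf_c, env, mode=mode, rezero=rezero_combined)
    d = combine_diffusion(neutral.diffusion, charged.diffusion, p_n, p_c)
    r_single = resistance_integral(g, d, env)
    return permeability(
        r_single, env, ph=ph, mode="dynamic",
        intermediates={
            "pmf_neutral_shifted": pmf_n,
            "pmf_charged_shifted": pmf_c,
            "pmf_combined": g,
            "diffusion_combined": d,
            "p_charged": p_c,
            "combination_mode": mode,
        },
    )


def kp_uncertainty(
    neutral: StateProfiles,
    charged: StateProfiles,
    spec: PermeantSpec,
    ph: float,
    env: Environment,
    mode: str = "boltzmann",
    pairing: str = "matched",
) -> PermeabilityResult:
    """Replicate-resolved dynamic permeability with log10-Kp uncertainty.

    Each PMF replicate pair (replicate i of each state for ``matched``, or
    every cross pairing for ``all``) is pushed through the full dynamic
    pipeline; Kp is log-normally distributed under additive PMF noise, so
    the mean and SEM are computed on log10 Kp.  The headline kp is the
    replicate-averaged-profile estimate (the average PMF is the central
    estimate; the replicate spread supplies the error bar).  With fewer
    than 2 replicates the sem is reported as None (undefined), never zero.
    """
    if neutral.replicates is None or charged.replicates is None:
        raise ValueError("both states need PMF replicates")
    reps_n, reps_c = neutral.replicates, charged.replicates
    if pairing == "matched":
        if reps_n.n != reps_c.n:
            raise ValueError("matched pairing needs equal replicate counts")
        pairs = list(zip(reps_n.profiles, reps_c.profiles))
    elif pairing == "all":
        pairs = list(itertools.product(reps_n.profiles, reps_c.profiles))
    else:
        raise ValueError(f"unknown pairing {pairing!r}")

    kps = []
    for pn, pc in pairs:
        res = dynamic_kp(
            StateProfiles(pmf=pn, diffusion=neutral.diffusion, state="neutral"),
            StateProfiles(pmf=pc, diffusion=charged.diffusion, state="charged"),
            spec, ph, env, mode=mode,
        )
        kps.append(res.kp)
    kps = np.asarray(kps)
    log10 = np.log10(kps)
    n_eff = reps_n.n if pairing == "matched" else min(reps_n.n, reps_c.n)
    sem = float(np.std(log10, ddof=1) / np.sqrt(n_eff)) if len(kps) > 1 else None

    central = dynamic_kp(neutral, charged, spec, ph, env, mode=mode)
    return PermeabilityResult(
        kp=central.kp,
        r_single=central.r_single,
        r_total=central.r_total,
        ph=ph,
        mode="dynamic",
        n_layers=env.n_layers,
        kp_layer_range=central.kp_layer_range,
        kp_replicates=tuple(kps),
        log10_kp_mean=float(log10.mean()),
        sem_log10_kp=sem,
        intermediates=central.intermediates,
    )


def ph_scan(
    neutral: StateProfiles,
    charged: StateProfiles,
    spec: PermeantSpec,
    ph_list,
    env: Environment,
    mode: str = "boltzmann",
) -> pd.DataFrame:
    """Dynamic and pH-partition permeabilities over a list of pH values.

    Returns a tidy table with one dynamic and one ph_partition row per pH,
    in input order (duplicates preserved).
    """
    ph_list = list(ph_list)
    if not ph_list:
        raise ValueError("ph_list must be non-empty")
    kp_n = neutral_only_kp(neutral, env).kp
    have_reps = neutral.replicates is not None and charged.replicates is not None
    rows = []
    for ph in ph_list:
        if have_reps:
            dyn = kp_uncertainty(neutral, charged, spec, ph, env, mode=mode)
        else:
            dyn = dynamic_kp(neutral, charged, spec, ph, env, mode=mode)
        part = ph_partition_kp(kp_n, spec, ph, env)
        for res in (dyn, part):
            rows.append(
                {
                    "permeant": spec.name,
                    "pH": ph,
                    "mode": res.mode,
                    "Kp_cm_per_s": res.kp,
                    "log10Kp": res.log10_kp,
                    "sem_log10Kp": res.sem_log10_kp,
                    "R_s_per_cm": res.r_total,
                }
            )
    return pd.DataFrame(rows)
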
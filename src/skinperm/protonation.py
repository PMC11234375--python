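"""Henderson-Hasselbalch combination of neutral- and charged-state profiles.

A weak acid or base permeates a lipid barrier in a mixture of its neutral
and ionized forms.  Given the two states' PMFs (each calibrated so that a
point's value is the transfer free energy from water to that depth) and
their local diffusion-coefficient profiles, the dynamic-protonation
construction is:

1. Shift the charged-state PMF by the constant kT ln(10) s (pKa - pH),
   with s = +1 for an acid and s = -1 for a base, so that bulk-water
   populations obey the Henderson-Hasselbalch ratio
   charged:neutral = 10^(s (pH - pKa)).
2. Shift both PMFs by one common constant so the global minimum is >= 0
   (required by the resistance integral's absolute-scale convention; the
   state difference is untouched).
3. Build the combined PMF from the probability of being in either state:
   G(z) = -kT ln[e^(-G_n/kT) + e^(-G_c/kT)]  (``boltzmann`` mode), or the
   probability-weighted average p_n G_n + p_c G_c (``weighted`` mode).
   The two differ by an entropy-like term bounded by kT ln 2.
4. Build the combined diffusion profile as the probability-weighted average
   D(z) = p_n(z) D_n(z) + p_c(z) D_c(z).

All Boltzmann factors are evaluated in log space: charged-state barriers
exceed 100 kJ/mol and naive exponentials would overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .constants import HEADGROUP_WINDOW_NM, thermal_energy
from .profiles import ReplicateSet, SpatialProfile

__all__ = [
    "PermeantSpec",
    "Environment",
    "StateProfiles",
    "calibrate_to_hydration",
    "hh_shift",
    "neutral_fraction",
    "common_zero_shift",
    "state_probabilities",
    "combine_pmf",
    "combine_diffusion",
    "ionized_fraction_profile",
]

LN10 = np.log(10.0)


@dataclass(frozen=True)
class PermeantSpec:
    """Chemical identity of an ionizable permeant.

    ``acid_class`` is ``"acid"`` (HA <-> A- + H+, charged above pKa) or
    ``"base"`` (BH+ <-> B + H+, charged below pKa).  The hydration free
    energies (kJ/mol, vacuum -> water) calibrate the raw PMFs of the two
    states to a common water reference.
    """

    name: str
    pka: float
    acid_class: str
    dg_hyd_neutral: float = 0.0
    dg_hyd_charged: float = 0.0

    def __post_init__(self):
        if not np.isfinite(self.pka):
            raise ValueError("pKa must be finite")
        if self.acid_class not in ("acid", "base"):
            raise ValueError(
                f"acid_class must be 'acid' or 'base', got {self.acid_class!r}"
            )

    @property
    def s(self) -> int:
        """Sign convention of the Henderson-Hasselbalch shift."""
        return +1 if self.acid_class == "acid" else -1


@dataclass(frozen=True)
class Environment:
    """Thermodynamic and numerical run parameters.

    Defaults are the barrier simulation's conditions: skin temperature
    305.15 K, 30 +- 6 stacked lipid layers, integration bounds +-5.2 nm on
    a 0.01 nm grid.
    """

    temperature: float = 305.15
    n_layers: int = 30
    n_layers_spread: int = 6
    z1: float = -5.2
    z2: float = 5.2
    spacing: float = 0.01

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.z2 <= self.z1:
            raise ValueError("z2 must exceed z1")
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")

    @property
    def kT(self) -> float:
        """Thermal energy in kJ/mol."""
        return thermal_energy(self.temperature)


@dataclass(frozen=True)
class StateProfiles:
    """Calibrated PMF and diffusion profile for one protonation state."""

    pmf: SpatialProfile
    diffusion: SpatialProfile
    state: str = "neutral"
    replicates: ReplicateSet | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if not self.pmf.same_grid(self.diffusion):
            raise ValueError("pmf and diffusion must share one grid")


def calibrate_to_hydration(raw_pmf: SpatialProfile, dg_hyd: float) -> SpatialProfile:
    """Re-reference a vacuum-referenced PMF to the water (hydrated) state.

    The raw PMF and the hydration free energy share the decoupled/vacuum
    reference, so subtracting dg_hyd makes every point the transfer free
    energy from water to depth z.
    """
    return raw_pmf.shift(-dg_hyd)


def hh_shift(
    pmf_charged: SpatialProfile,
    spec: PermeantSpec,
    ph: float,
    env: Environment,
) -> SpatialProfile:
    """Apply the Henderson-Hasselbalch constant shift to the charged PMF.

    Adds kT ln(10) s (pKa - pH); the neutral PMF is the reference and is
    never shifted.  After the shift, the bulk-water charged:neutral
    population ratio is exactly 10^(s (pH - pKa)).
    """
    shift = env.kT * LN10 * spec.s * (spec.pka - ph)
    out = pmf_charged.shift(shift)
    return out.with_value(out.value, sem=out.sem,
                          meta=dict(out.meta, hh_shift_kj_mol=shift, ph=ph))


def neutral_fraction(spec: PermeantSpec, ph: float) -> float:
    """Bulk-solution neutral fraction at the given pH.

    Acid: 1/(1 + 10^(pH - pKa)); base: 1/(1 + 10^(pKa - pH)).  Evaluated
    through the logistic function for numerical robustness at extreme pH.
    """
    return float(expit(-LN10 * spec.s * (ph - spec.pka)))


def common_zero_shift(
    pmf_n: SpatialProfile, pmf_c: SpatialProfile
) -> tuple[SpatialProfile, SpatialProfile]:
    """Shift both PMFs by one constant so the global minimum is >= 0.

    If the joint minimum is already >= 0 the profiles pass through
    unchanged.  The difference pmf_c - pmf_n is exactly invariant.
    """
    if not pmf_n.same_grid(pmf_c):
        raise ValueError("PMFs must share one grid")
    gmin = min(float(pmf_n.value.min()), float(pmf_c.value.min()))
    if gmin >= 0.0:
        return pmf_n, pmf_c
    return pmf_n.shift(-gmin), pmf_c.shift(-gmin)


def state_probabilities(
    pmf_n: SpatialProfile, pmf_c: SpatialProfile, env: Environment
) -> tuple[np.ndarray, np.ndarray]:
    """Local Boltzmann probabilities of the neutral and charged states.

    p_c(z) = 1 / (1 + exp((G_c - G_n)/kT)) via the logistic function, and
    p_n = 1 - p_c, so the two sum to 1 exactly and no exponential can
    overflow.  Invariant under any common additive constant.
    """
    if not pmf_n.same_grid(pmf_c):
        raise ValueError("PMFs must share one grid")
    delta = (pmf_c.value - pmf_n.value) / env.kT
    p_c = expit(-delta)
    return 1.0 - p_c, p_c


def combine_pmf(
    pmf_n: SpatialProfile,
    pmf_c: SpatialProfile,
    env: Environment,
    mode: str = "boltzmann",
    rezero: bool = False,
) -> SpatialProfile:
    """Combined PMF of the two-state (dynamic-protonation) permeant.

    ``boltzmann``: G = -kT ln[e^(-G_n/kT) + e^(-G_c/kT)] — the free energy
    of being in either state; lies at or below min(G_n, G_c), reaching
    min - kT ln 2 when the states are degenerate.
    ``weighted``: G = p_n G_n + p_c G_c — the probability-weighted mean.

    With ``rezero`` the combined profile is raised so its minimum is 0
    (off by default: the combination step follows the zero-shift step and
    may legitimately dip below zero by at most kT ln 2).
    """
    if not pmf_n.same_grid(pmf_c):
        raise ValueError("PMFs must share one grid")
    kT = env.kT
    if mode == "boltzmann":
        g = -kT * np.logaddexp(-pmf_n.value / kT, -pmf_c.value / kT)
    elif mode == "weighted":
        p_n, p_c = state_probabilities(pmf_n, pmf_c, env)
        g = p_n * pmf_n.value + p_c * pmf_c.value
    else:
        raise ValueError(f"unknown combination mode {mode!r}")
    if rezero:
        g = g - min(g.min(), 0.0)
    return SpatialProfile(
        z=pmf_n.z.copy(), value=g, label="pmf", state="combined",
        meta={"mode": mode, "rezeroed": rezero},
    )


def combine_diffusion(
    d_n: SpatialProfile,
    d_c: SpatialProfile,
    p_n: np.ndarray,
    p_c: np.ndarray,
) -> SpatialProfile:
    """Probability-weighted diffusion profile D = p_n D_n + p_c D_c."""
    if not d_n.same_grid(d_c):
        raise ValueError("diffusion profiles must share one grid")
    if not np.allclose(p_n + p_c, 1.0, rtol=0, atol=1e-12):
        raise ValueError("state probabilities must sum to 1")
    d = p_n * d_n.value + p_c * d_c.value
    return SpatialProfile(z=d_n.z.copy(), value=d, label="diffusion",
                          state="combined")


def ionized_fraction_profile(
    pmf_n: SpatialProfile,
    pmf_c: SpatialProfile,
    spec: PermeantSpec,
    ph: float,
    env: Environment,
) -> SpatialProfile:
    """Depth-resolved probability of the ionized (charged) state.

    Takes *calibrated* PMFs, applies the Henderson-Hasselbalch shift for
    the requested pH, and returns p_c(z).  The metadata records the pH, the
    headgroup window (nm) and the mean ionized fraction inside it — charged
    species localize at the polar headgroups, which is the quantity of
    interest when reporting these profiles.
    """
    shifted_c = hh_shift(pmf_c, spec, ph, env)
    _, p_c = state_probabilities(pmf_n, shifted_c, env)
    lo, hi = HEADGROUP_WINDOW_NM
    window = (np.abs(pmf_n.z) >= lo) & (np.abs(pmf_n.z) <= hi)
    mean_head = float(p_c[window].mean()) if window.any() else np.nan
    return SpatialProfile(
        z=pmf_n.z.copy(), value=p_c, label="ionized_fraction",
        state="combined",
        meta={
            "ph": ph,
            "headgroup_window_nm": HEADGROUP_WINDOW_NM,
            "mean_ionized_fraction_headgroup": mean_head,
        },
    )
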
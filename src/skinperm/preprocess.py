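"""Profile clean-up: symmetrization, median filtering, edge repair, averaging.

The barrier system is symmetric across z = 0, so full-range profiles on
[-L, L] are folded onto [0, L] by averaging the two halves.  Local
diffusion-coefficient curves are denoised with a rolling median of fixed
physical width (default 0.2 nm).  Adaptive-bias sampling leaves artificial
spikes at the very edges of the PMF grid; these are repaired by copying the
nearest interior value outward (default: the two outermost points on each
side).  Independent replicate PMFs are averaged pointwise with the standard
error of the mean attached.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .profiles import ReplicateSet, SpatialProfile

__all__ = [
    "symmetrize",
    "mirror_extend",
    "rolling_median",
    "fix_edge_spikes",
    "average_replicates",
]


def symmetrize(profile: SpatialProfile) -> SpatialProfile:
    """Fold a profile spanning [-L, L] onto [0, L] by averaging +z and -z.

    Points are paired by nearest |z| (within half a grid spacing); unpaired
    points (z = 0, or an asymmetric leftover point) pass through unchanged.
    Pair sems combine as sqrt(s+^2 + s-^2)/2, the sem of the mean of two
    independent estimates.  Even functions are fixed points; odd components
    cancel exactly.
    """
    z = profile.z
    spacing = profile.spacing
    if not np.isfinite(spacing):
        raise ValueError("cannot symmetrize a single-point profile")
    if abs(z[0] + z[-1]) >= 2.0 * spacing:
        raise ValueError(
            f"grid span [{z[0]:g}, {z[-1]:g}] nm is grossly asymmetric "
            "about 0; refusing to symmetrize"
        )
    za = np.abs(z)
    order = np.argsort(za, kind="stable")
    tol = spacing / 2.0
    out_z, out_v, out_s = [], [], []
    has_sem = profile.sem is not None
    i = 0
    idx = order
    while i < idx.size:
        group = [idx[i]]
        while i + 1 < idx.size and za[idx[i + 1]] - za[group[0]] < tol:
            i += 1
            group.append(idx[i])
        i += 1
        out_z.append(float(np.mean(za[group])))
        out_v.append(float(np.mean(profile.value[group])))
        if has_sem:
            s = profile.sem[group]
            # sem of the mean of k independent points
            out_s.append(float(np.sqrt(np.sum(s**2)) / len(group)))
    sem = np.asarray(out_s) if has_sem else None
    return replace(
        profile, z=np.asarray(out_z), value=np.asarray(out_v), sem=sem
    )


def mirror_extend(profile: SpatialProfile) -> SpatialProfile:
    """Extend a half-profile on [0, L] to the even full profile on [-L, L]."""
    z = profile.z
    if z[0] < 0:
        raise ValueError("mirror_extend expects a profile on [0, L]")
    skip = 1 if np.isclose(z[0], 0.0) else 0
    full_z = np.concatenate([-z[::-1], z[skip:]])
    full_v = np.concatenate([profile.value[::-1], profile.value[skip:]])
    sem = None
    if profile.sem is not None:
        sem = np.concatenate([profile.sem[::-1], profile.sem[skip:]])
    return replace(profile, z=full_z, value=full_v, sem=sem)


def rolling_median(profile: SpatialProfile, width: float = 0.2) -> SpatialProfile:
    """Rolling median with a window of fixed physical width (nm).

    Each point is replaced by the median of all points whose z lies within
    +-width/2; the window truncates at the boundaries and the grid is
    unchanged.  Defining the window by width rather than point count makes
    the filter invariant to grid spacing.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    z, v = profile.z, profile.value
    half = width / 2.0
    lo = np.searchsorted(z, z - half, side="left")
    hi = np.searchsorted(z, z + half, side="right")
    out = np.array([np.median(v[a:b]) for a, b in zip(lo, hi)])
    return replace(profile, value=out)


def fix_edge_spikes(profile: SpatialProfile, n_edge: int = 2) -> SpatialProfile:
    """Replace the ``n_edge`` outermost values on each side by their
    nearest interior neighbor's value.

    With the default n_edge = 2 on a 0.01 nm grid this sets the points at
    0.005/0.015 nm to the 0.025 nm value and 5.200/5.210 nm to the 5.19 nm
    value, removing sampling-boundary artifacts.  n_edge = 0 is the identity.
    """
    if n_edge < 0:
        raise ValueError("n_edge must be >= 0")
    if n_edge == 0:
        return profile
    if profile.n <= 2 * n_edge:
        raise ValueError(
            f"profile has {profile.n} points, too few for n_edge={n_edge}"
        )
    v = profile.value.copy()
    v[:n_edge] = v[n_edge]
    v[-n_edge:] = v[-(n_edge + 1)]
    sem = None
    if profile.sem is not None:
        sem = profile.sem.copy()
        sem[:n_edge] = sem[n_edge]
        sem[-n_edge:] = sem[-(n_edge + 1)]
    return replace(profile, value=v, sem=sem)


def average_replicates(reps: ReplicateSet) -> SpatialProfile:
    """Pointwise mean of replicates with sem = sample sd / sqrt(n).

    For n = 1 the sem is zero and ``meta['single_replicate']`` is set, so
    downstream consumers can distinguish "no spread" from "no information".
    """
    vals = reps.values()
    n = reps.n
    mean = vals.mean(axis=0)
    if n > 1:
        sem = vals.std(axis=0, ddof=1) / np.sqrt(n)
        meta = dict(reps.profiles[0].meta)
    else:
        sem = np.zeros_like(mean)
        meta = dict(reps.profiles[0].meta, single_replicate=True)
    first = reps.profiles[0]
    return SpatialProfile(
        z=reps.z.copy(), value=mean, sem=sem,
        label=first.label, state=first.state, meta=meta,
    )
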
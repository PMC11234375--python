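"""1D spatial profiles across the lipid barrier: containers and I/O.

A :class:`SpatialProfile` holds one tabulated function of membrane depth z —
a potential of mean force (PMF, kJ/mol), a local diffusion coefficient
(nm^2/ps) or a friction profile (ps/nm^2) — with an optional per-point
standard error.  Profiles are read from and written to whitespace-separated
text in two dialects:

``xvg``
    Lines starting with ``#`` or ``@`` are comments/metadata (the common
    output convention of biased-MD analysis tools); data rows have 2 or 3
    numeric columns ``z value [sem]``.
``tsv``
    Same column layout; only ``#`` comment lines are tolerated.

Units are never guessed from file headers — they are declared by the caller
and canonical internally (nm, kJ/mol, nm^2/ps).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SpatialProfile",
    "ReplicateSet",
    "read_profile",
    "write_profile",
    "resample_uniform",
    "friction_to_diffusion",
]

#: Grids closer than this (nm) are considered identical.
GRID_ATOL_NM = 1e-9

_UNITS = {"pmf": "kJ/mol", "diffusion": "nm^2/ps", "friction": "ps/nm^2"}


@dataclass(frozen=True)
class SpatialProfile:
    """One tabulated profile value(z) on a strictly increasing depth grid.

    Parameters
    ----------
    z : array of depth values in nm, strictly increasing.
    value : profile values; kJ/mol for PMFs, nm^2/ps for diffusion,
        ps/nm^2 for friction.
    sem : optional per-point standard error of the mean, same units as
        ``value``, elementwise >= 0.
    label : kind tag, one of ``pmf``, ``diffusion``, ``friction`` (free text
        is allowed but positivity is enforced for diffusion/friction).
    state : protonation tag: ``neutral``, ``charged`` or ``combined``.
    meta : free-form metadata (ground truth arrays, pH, flags ...); not
        compared for equality and not written to disk.
    """

    z: np.ndarray
    value: np.ndarray
    sem: np.ndarray | None = None
    label: str = "pmf"
    state: str = "neutral"
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        z = np.asarray(self.z, dtype=float)
        value = np.asarray(self.value, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "value", value)
        if z.ndim != 1 or value.shape != z.shape:
            raise ValueError(
                f"z and value must be equal-length 1D arrays, got shapes "
                f"{z.shape} and {value.shape}"
            )
        if z.size < 1:
            raise ValueError("profile must contain at least one point")
        dz = np.diff(z)
        bad = np.nonzero(dz <= 0)[0]
        if bad.size:
            i = int(bad[0]) + 1
            raise ValueError(
                f"depth grid must be strictly increasing; first violation at "
                f"index {i} (z[{i - 1}]={z[i - 1]:g}, z[{i}]={z[i]:g})"
            )
        if self.sem is not None:
            sem = np.asarray(self.sem, dtype=float)
            object.__setattr__(self, "sem", sem)
            if sem.shape != z.shape:
                raise ValueError("sem must match z in length")
            if np.any(sem < 0):
                raise ValueError("sem must be elementwise >= 0")
        if self.label in ("diffusion", "friction") and np.any(value <= 0):
            raise ValueError(f"{self.label} values must be strictly > 0")
        if not np.all(np.isfinite(value)):
            raise ValueError("profile values must be finite")

    @property
    def n(self) -> int:
        return self.z.size

    @property
    def spacing(self) -> float:
        """Median grid spacing in nm."""
        return float(np.median(np.diff(self.z))) if self.n > 1 else np.nan

    def with_value(self, value, sem=None, **overrides) -> "SpatialProfile":
        """Copy with new values (and optionally sem/label/state/meta)."""
        return replace(self, value=np.asarray(value, float), sem=sem, **overrides)

    def shift(self, constant: float) -> "SpatialProfile":
        """Add a constant to the profile values (sem unchanged)."""
        return replace(self, value=self.value + constant)

    def same_grid(self, other: "SpatialProfile", atol: float = GRID_ATOL_NM) -> bool:
        return self.z.shape == other.z.shape and bool(
            np.allclose(self.z, other.z, rtol=0.0, atol=atol)
        )


@dataclass(frozen=True)
class ReplicateSet:
    """Independent replicate profiles on one common grid."""

    profiles: tuple[SpatialProfile, ...]

    def __post_init__(self):
        profiles = tuple(self.profiles)
        object.__setattr__(self, "profiles", profiles)
        if len(profiles) < 1:
            raise ValueError("ReplicateSet needs at least one profile")
        ref = profiles[0]
        for k, p in enumerate(profiles[1:], start=1):
            if not ref.same_grid(p):
                raise ValueError(f"replicate {k} grid differs from replicate 0")

    @property
    def n(self) -> int:
        return len(self.profiles)

    @property
    def z(self) -> np.ndarray:
        return self.profiles[0].z

    def values(self) -> np.ndarray:
        """(n, npoints) matrix of replicate values."""
        return np.vstack([p.value for p in self.profiles])


def _comment_prefixes(dialect: str) -> tuple[str, ...]:
    if dialect == "xvg":
        return ("#", "@")
    if dialect == "tsv":
        return ("#",)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'xvg' or 'tsv'")


def read_profile(
    path: str | Path,
    dialect: str = "xvg",
    label: str = "pmf",
    state: str = "neutral",
) -> SpatialProfile:
    """Read a 2- or 3-column profile file.

    Column layout is ``z_nm value [sem]``.  Comment lines per dialect are
    skipped.  Raises on non-numeric rows (with the 1-based line number) and
    on non-monotonic grids (with the first offending index).
    """
    prefixes = _comment_prefixes(dialect)
    path = Path(path)
    rows: list[tuple[float, ...]] = []
    ncol = None
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(prefixes):
                continue
            parts = stripped.split()
            try:
                nums = tuple(float(x) for x in parts)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric data on line {lineno}: {stripped!r}"
                ) from exc
            if len(nums) not in (2, 3):
                raise ValueError(
                    f"{path}: expected 2 or 3 columns on line {lineno}, "
                    f"got {len(nums)}"
                )
            if ncol is None:
                ncol = len(nums)
            elif len(nums) != ncol:
                raise ValueError(
                    f"{path}: inconsistent column count on line {lineno}"
                )
            rows.append(nums)
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    data = np.asarray(rows, dtype=float)
    sem = data[:, 2] if data.shape[1] == 3 else None
    return SpatialProfile(z=data[:, 0], value=data[:, 1], sem=sem,
                          label=label, state=state)


def write_profile(profile: SpatialProfile, path: str | Path,
                  dialect: str = "xvg") -> None:
    """Write a profile as whitespace-separated text (round-trip safe).

    A single ``#`` header line names the columns and units; values are
    written with 17 significant digits so that read -> write -> read is an
    identity to well below 1e-12 relative error.
    """
    _comment_prefixes(dialect)  # validates the dialect name
    path = Path(path)
    unit = _UNITS.get(profile.label, "a.u.")
    cols = [profile.z, profile.value]
    header = f"# z_nm\t{profile.label}_{unit.replace('/', '_per_')}"
    if profile.sem is not None:
        cols.append(profile.sem)
        header += "\tsem"
    with path.open("w") as fh:
        fh.write(header + "\n")
        for row in zip(*cols):
            fh.write("\t".join(f"{x:.17g}" for x in row) + "\n")


def resample_uniform(profile: SpatialProfile, spacing: float) -> SpatialProfile:
    """Linearly interpolate onto a uniform grid over [z_min, z_max].

    Endpoints are preserved exactly.  The number of intervals is the nearest
    integer to span/spacing, so the realized spacing is the closest uniform
    spacing to the requested one.  The sem, if present, is interpolated
    linearly as well (a deliberately simple, conservative treatment).
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if profile.n < 2:
        raise ValueError("profile must span at least 2 points")
    span = float(profile.z[-1] - profile.z[0])
    if spacing > span:
        raise ValueError(
            f"spacing {spacing} nm exceeds the profile span {span:g} nm"
        )
    n_int = max(1, round(span / spacing))
    grid = np.linspace(profile.z[0], profile.z[-1], n_int + 1)
    value = np.interp(grid, profile.z, profile.value)
    sem = None
    if profile.sem is not None:
        sem = np.interp(grid, profile.z, profile.sem)
    return replace(profile, z=grid, value=value, sem=sem)


def friction_to_diffusion(g: SpatialProfile) -> SpatialProfile:
    """Einstein relation D(z) = 1/g(z), with first-order sem propagation.

    sem_D = sem_g / g^2.  Applying the transform twice returns the original
    profile (involution), which the tests exploit.
    """
    if np.any(g.value <= 0):
        raise ValueError("friction/diffusion values must be strictly > 0")
    new_label = {"friction": "diffusion", "diffusion": "friction"}.get(
        g.label, "diffusion"
    )
    sem = None
    if g.sem is not None:
        sem = g.sem / g.value**2
    return replace(g, value=1.0 / g.value, sem=sem, label=new_label)
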
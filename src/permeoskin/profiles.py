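"""One-dimensional profiles across the bilayer normal and their preprocessing.

A :class:`Profile` is a point-sampled function on a strictly increasing
z-grid (nm): a potential of mean force (kJ/mol), a friction metric
(ps nm^-2), a local diffusion coefficient (nm^2/ps), or a cumulative
permeation resistance. Every preprocessing step appends a record to
``Profile.metadata["steps"]`` so downstream reports carry full provenance.

Raw adaptive-bias free-energy outputs need a small amount of repair before
they can enter the permeability integral: spatial symmetrization artifacts
leave spikes at the outermost grid points (removed by ``repair_edges``),
friction-derived diffusion curves are noisy (smoothed with a 0.2 nm rolling
median), and the PMF is shifted so that its minimum is never below zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

VALID_KINDS = ("pmf", "friction", "diffusion", "resistance")


class ProfileParseError(ValueError):
    """Raised when a profile file cannot be parsed."""


class ProfileValidationError(ValueError):
    """Raised when profile data violate an invariant."""


@dataclass
class Profile:
    """A sampled 1-D profile along the bilayer normal.

    Parameters
    ----------
    z : ndarray
        Strictly increasing positions in nm.
    values : ndarray
        Sampled values; units depend on ``kind`` (pmf: kJ/mol,
        friction: ps nm^-2, diffusion: nm^2/ps, resistance: h/cm).
    kind : str
        One of ``pmf``, ``friction``, ``diffusion``, ``resistance``.
    metadata : dict
        Free-form provenance. Preprocessing functions append to
        ``metadata["steps"]``.
    """

    z: np.ndarray
    values: np.ndarray
    kind: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in VALID_KINDS:
            raise ProfileValidationError(
                f"unknown profile kind {self.kind!r}; expected one of {VALID_KINDS}"
            )
        if self.z.ndim != 1 or self.values.ndim != 1:
            raise ProfileValidationError("z and values must be one-dimensional")
        if self.z.shape != self.values.shape:
            raise ProfileValidationError(
                f"z and values length mismatch: {self.z.size} vs {self.values.size}"
            )
        if self.z.size < 2:
            raise ProfileValidationError("profile needs at least 2 samples")
        if not np.all(np.isfinite(self.z)) or not np.all(np.isfinite(self.values)):
            raise ProfileValidationError(
                "profile contains NaN/inf samples; missing data are rejected, "
                "not imputed"
            )
        if not np.all(np.diff(self.z) > 0):
            raise ProfileValidationError("z grid must be strictly increasing")

    def __len__(self) -> int:
        return int(self.z.size)

    @property
    def spacing(self) -> float:
        """Smallest grid spacing, nm."""
        return float(np.min(np.diff(self.z)))

    def replace(self, *, values: np.ndarray | None = None, kind: str | None = None,
                step: str | None = None, **extra) -> "Profile":
        """Copy with new values/kind, appending ``step`` to provenance."""
        meta = dict(self.metadata)
        meta["steps"] = list(meta.get("steps", []))
        if step is not None:
            meta["steps"].append(step)
        meta.update(extra)
        return Profile(
            z=self.z.copy(),
            values=self.values.copy() if values is None else np.asarray(values, float),
            kind=self.kind if kind is None else kind,
            metadata=meta,
        )

    def interp(self, z: np.ndarray | float) -> np.ndarray:
        """Linear interpolation of the profile at positions ``z`` (no extrapolation)."""
        z = np.asarray(z, dtype=float)
        if np.any(z < self.z[0] - 1e-12) or np.any(z > self.z[-1] + 1e-12):
            raise ProfileValidationError(
                "requested positions outside the sampled grid; no extrapolation"
            )
        return np.interp(z, self.z, self.values)


@dataclass(frozen=True)
class BilayerGeometry:
    """z-bands of the ceramide bilayer model.

    The default domain [0, 5.21] nm spans a single stacked-bilayer repeat
    unit. The headgroup band sits around z ~ 3.2 nm, the ceramide sphingoid
    chain region at 4-5 nm (the main permeability barrier), and the ceramide
    fatty-acid chain region around z ~ 2.1 nm.
    """

    z_min: float = 0.0
    z_max: float = 5.21
    midpoint: float = 2.605
    headgroup_region: tuple[float, float] = (2.9, 3.5)
    sphingoid_region: tuple[float, float] = (4.0, 5.0)
    fatty_acid_region: tuple[float, float] = (1.6, 2.6)

    def __post_init__(self) -> None:
        regions = [self.headgroup_region, self.sphingoid_region, self.fatty_acid_region]
        for lo, hi in regions:
            if not (self.z_min <= lo < hi <= self.z_max):
                raise ProfileValidationError(
                    f"region ({lo}, {hi}) not within [{self.z_min}, {self.z_max}]"
                )
        for i, (lo_i, hi_i) in enumerate(regions):
            for lo_j, hi_j in regions[i + 1:]:
                if max(lo_i, lo_j) < min(hi_i, hi_j):
                    raise ProfileValidationError("bilayer regions must be disjoint")

    def classify(self, z: float) -> str:
        """Region label for a position: headgroup, sphingoid, fatty_acid or tail."""
        if self.headgroup_region[0] <= z <= self.headgroup_region[1]:
            return "headgroup"
        if self.sphingoid_region[0] <= z <= self.sphingoid_region[1]:
            return "sphingoid"
        if self.fatty_acid_region[0] <= z <= self.fatty_acid_region[1]:
            return "fatty_acid"
        return "tail"


def read_profile(path, kind: str, dialect: str = "xvg") -> Profile:
    """Read a two-column profile file.

    Parameters
    ----------
    path : str or Path
        File with two numeric columns (z in nm, value).
    kind : str
        Profile tag: ``pmf``, ``friction`` or ``diffusion``. Units are taken
        from the caller's declaration, never guessed from headers.
    dialect : {"xvg", "csv"}
        ``xvg``: whitespace-separated, lines starting with ``#`` or ``@``
        ignored. ``csv``: comma-separated with an optional ``z,value`` header.
    """
    if dialect not in ("xvg", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    zs: list[float] = []
    vs: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if dialect == "xvg":
                if line.startswith("#") or line.startswith("@"):
                    continue
                parts = line.split()
            else:
                if lineno == 1 and line.lower().replace(" ", "").startswith("z,"):
                    continue
                parts = line.split(",")
            if len(parts) < 2:
                raise ProfileParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
            try:
                zs.append(float(parts[0]))
                vs.append(float(parts[1]))
            except ValueError as exc:
                raise ProfileParseError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if len(zs) < 2:
        raise ProfileParseError(f"{path}: fewer than 2 data rows")
    return Profile(
        z=np.array(zs), values=np.array(vs), kind=kind,
        metadata={"source": str(path), "dialect": dialect, "steps": []},
    )


def write_profile(profile: Profile, path, dialect: str = "csv") -> None:
    """Write a profile; csv round-trips bit-identically via repr floats."""
    with open(path, "w") as fh:
        if dialect == "csv":
            fh.write("z,value\n")
            for z, v in zip(profile.z, profile.values):
                fh.write(f"{float(z)!r},{float(v)!r}\n")
        elif dialect == "xvg":
            fh.write(f"# kind: {profile.kind}\n@    title \"profile\"\n")
            for z, v in zip(profile.z, profile.values):
                fh.write(f"{float(z)!r} {float(v)!r}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def friction_to_diffusion(g: Profile) -> Profile:
    """Invert a friction metric profile: D(z) = 1/g(z).

    The adaptive-bias sampler estimates a position-dependent friction
    g(z) (ps nm^-2); its pointwise reciprocal is the local diffusion
    coefficient (nm^2/ps).
    """
    if g.kind != "friction":
        raise ProfileValidationError(f"expected a friction profile, got {g.kind!r}")
    if np.any(g.values <= 0):
        raise ProfileValidationError("friction must be strictly positive to invert")
    return g.replace(values=1.0 / g.values, kind="diffusion", step="friction_to_diffusion")


def rolling_median(p: Profile, width: float = 0.2) -> Profile:
    """Rolling median over a fixed z-window (default 0.2 nm).

    Each output sample is the median of all input samples whose z lies
    within +-width/2 of the sample position; the grid is unchanged. Used to
    denoise friction-derived diffusion curves.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if width < p.spacing:
        warnings.warn(
            f"rolling-median width {width} nm is below the grid spacing "
            f"{p.spacing:.4g} nm; returning the profile unchanged",
            stacklevel=2,
        )
        return p.replace(step=f"rolling_median(width={width}, identity)")
    half = width / 2.0
    out = np.empty_like(p.values)
    # windows found by bisection on the sorted grid; O(n log n) overall
    lo = np.searchsorted(p.z, p.z - half, side="left")
    hi = np.searchsorted(p.z, p.z + half, side="right")
    for i in range(p.z.size):
        out[i] = np.median(p.values[lo[i]:hi[i]])
    return p.replace(values=out, step=f"rolling_median(width={width})")


def repair_edges(p: Profile, n_points: int = 2) -> Profile:
    """Replace the outermost samples with their nearest interior value.

    Spatial symmetrization of the sampling leaves artificial spikes at the
    first and last grid points of a PMF; the first ``n_points`` values are
    set to the value at index ``n_points`` and the last ``n_points`` to the
    value at index ``-(n_points+1)``.
    """
    if n_points < 0:
        raise ValueError("n_points must be >= 0")
    if n_points == 0:
        return p.replace(step="repair_edges(n_points=0)")
    if len(p) < 2 * n_points + 2:
        raise ProfileValidationError(
            f"profile too short ({len(p)} samples) for edge repair with "
            f"n_points={n_points}"
        )
    out = p.values.copy()
    out[:n_points] = out[n_points]
    out[-n_points:] = out[-(n_points + 1)]
    return p.replace(values=out, step=f"repair_edges(n_points={n_points})")


def symmetrize(p: Profile, geometry: BilayerGeometry | None = None,
               midpoint: float | None = None) -> Profile:
    """Mirror-average a profile about the bilayer midpoint.

    The output at distance d from the midpoint is the mean of the input at
    midpoint-d and midpoint+d, with linear interpolation where the mirror
    image of a grid point falls between samples. The result is exactly
    mirror-symmetric, and the operation is idempotent.
    """
    if midpoint is None:
        midpoint = (geometry or BilayerGeometry()).midpoint
    if not (p.z[0] <= midpoint <= p.z[-1]):
        raise ProfileValidationError("grid must cover both sides of the midpoint")
    mirror_z = np.clip(2.0 * midpoint - p.z, p.z[0], p.z[-1])
    mirrored = np.interp(mirror_z, p.z, p.values)
    out = 0.5 * (p.values + mirrored)
    return p.replace(values=out, step=f"symmetrize(midpoint={midpoint})")


def shift_pmf(p: Profile) -> Profile:
    """Shift a PMF so its minimum is never below zero.

    If min(values) < 0 a constant is added so the minimum becomes exactly 0;
    nonnegative minima are kept as they are. The applied shift is recorded
    in ``metadata["pmf_shift"]``; a profile carrying this key is min-anchored
    and no longer calibrated to a formulation solvation free energy.
    """
    if p.kind != "pmf":
        raise ProfileValidationError(f"expected a pmf profile, got {p.kind!r}")
    vmin = float(np.min(p.values))
    shift = -vmin if vmin < 0 else 0.0
    return p.replace(
        values=p.values + shift,
        step=f"shift_pmf(shift={shift:.6g})",
        pmf_shift=shift,
    )
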
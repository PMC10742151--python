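"""Core data containers for scattering models, curves and distributions.

Units follow small-angle scattering convention: coordinates and distances
in nanometres, momentum transfer ``s = 4π sinθ/λ`` in inverse nanometres,
intensities in arbitrary units. All containers validate their invariants
on construction so downstream numerics can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidModelError, InvalidParameterError

__all__ = [
    "ParticleModel",
    "ConformationEnsemble",
    "ScatteringCurve",
    "DetectorGeometry",
    "DetectorImage",
    "PairDistribution",
]


@dataclass(frozen=True)
class ParticleModel:
    """A set of point scatterers: coordinates (nm) plus scattering weights.

    The model is the source of calculated intensity (Debye sum), radius of
    gyration and maximum intra-particle distance Dmax.
    """

    points: np.ndarray
    weights: np.ndarray | None = None
    label: str = ""

    def __post_init__(self) -> None:
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 1:
            raise InvalidModelError("points must be a non-empty (n, 3) array")
        if not np.all(np.isfinite(pts)):
            raise InvalidModelError("coordinates must be finite")
        if self.weights is None:
            w = np.ones(pts.shape[0])
        else:
            w = np.asarray(self.weights, dtype=float)
        if w.shape != (pts.shape[0],) or not np.all(np.isfinite(w)):
            raise InvalidModelError("weights must be finite, one per point")
        if np.any(w <= 0):
            raise InvalidModelError("weights must be positive")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "weights", w)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def translated(self, offset: np.ndarray) -> "ParticleModel":
        return ParticleModel(self.points + np.asarray(offset, dtype=float),
                             self.weights, self.label)


@dataclass(frozen=True)
class ConformationEnsemble:
    """Ordered collection of conformer models, labeled 1..n."""

    models: tuple[ParticleModel, ...]

    def __post_init__(self) -> None:
        models = tuple(self.models)
        if len(models) < 1:
            raise InvalidParameterError("ensemble needs at least one model")
        object.__setattr__(self, "models", models)

    @property
    def labels(self) -> list[int]:
        return list(range(1, len(self.models) + 1))

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)


@dataclass(frozen=True)
class ScatteringCurve:
    """(s, I, σ) triples on a strictly increasing momentum-transfer grid."""

    s: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None
    wavelength: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        i = np.asarray(self.I, dtype=float)
        sig = (np.zeros_like(s) if self.sigma is None
               else np.asarray(self.sigma, dtype=float))
        if s.ndim != 1 or s.shape != i.shape or sig.shape != s.shape:
            raise InvalidParameterError("s, I, sigma must be equal-length 1-D")
        if s.size and np.any(np.diff(s) <= 0):
            raise InvalidParameterError("s grid must be strictly increasing")
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(i))
                and np.all(np.isfinite(sig))):
            raise InvalidParameterError("curve columns must be finite")
        if np.any(sig < 0):
            raise InvalidParameterError("sigma must be non-negative")
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "I", i)
        object.__setattr__(self, "sigma", sig)

    def __len__(self) -> int:
        return self.s.size

    def truncated(self, s_max: float) -> "ScatteringCurve":
        """Restrict the curve to s ≤ s_max."""
        keep = self.s <= s_max
        return ScatteringCurve(self.s[keep], self.I[keep], self.sigma[keep],
                               self.wavelength, self.label)


def grids_match(a: ScatteringCurve, b: ScatteringCurve,
                rtol: float = 1e-9) -> bool:
    """Whether two curves share the same s grid to within ``rtol``."""
    return a.s.shape == b.s.shape and np.allclose(a.s, b.s, rtol=rtol, atol=0.0)


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat 2-D detector geometry: distance (mm), λ (nm), beam center (px),
    pixel pitch (mm)."""

    sample_detector_distance: float
    wavelength: float
    beam_center: tuple[float, float]
    pixel_pitch: float

    def __post_init__(self) -> None:
        if (self.sample_detector_distance <= 0 or self.wavelength <= 0
                or self.pixel_pitch <= 0):
            raise InvalidParameterError("geometry parameters must be positive")
        if not all(np.isfinite(self.beam_center)):
            raise InvalidParameterError("beam center must be finite")

    def s_of_pixels(self, shape: tuple[int, int]) -> np.ndarray:
        """Momentum transfer s (nm⁻¹) at every pixel of an image of ``shape``.

        The radial distance on the detector subtends scattering angle 2θ,
        and s = 4π sinθ / λ.
        """
        rows, cols = np.indices(shape)
        dr = (rows - self.beam_center[0]) * self.pixel_pitch
        dc = (cols - self.beam_center[1]) * self.pixel_pitch
        radius_mm = np.hypot(dr, dc)
        two_theta = np.arctan2(radius_mm, self.sample_detector_distance)
        return 4.0 * np.pi * np.sin(two_theta / 2.0) / self.wavelength


@dataclass(frozen=True)
class DetectorImage:
    """2-D detector counts plus the geometry that maps pixels to s."""

    counts: np.ndarray
    geometry: DetectorGeometry

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.size == 0:
            raise InvalidParameterError("counts must be a non-empty 2-D grid")
        if not np.all(np.isfinite(counts)):
            raise InvalidParameterError("counts must be finite")
        object.__setattr__(self, "counts", counts)


@dataclass(frozen=True)
class PairDistribution:
    """Pair-distance distribution p(r) on [0, d_max_support], unit area.

    ``fit_chi2``, ``alpha`` and ``fit`` are populated when the distribution
    comes from the indirect transform of an experimental curve.
    """

    r: np.ndarray
    p: np.ndarray
    d_max_support: float
    fit_chi2: float | None = None
    alpha: float | None = None
    fit: ScatteringCurve | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        p = np.asarray(self.p, dtype=float)
        if r.shape != p.shape or r.ndim != 1 or r.size < 2:
            raise InvalidParameterError("r and p must be matching 1-D arrays")
        if np.any(np.diff(r) <= 0):
            raise InvalidParameterError("r grid must be increasing")
        if p[0] != 0.0 or p[-1] != 0.0:
            raise InvalidParameterError("p must vanish at both endpoints")
        if np.any(p < 0):
            raise InvalidParameterError("p must be non-negative")
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "p", p)
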
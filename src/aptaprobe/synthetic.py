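"""Synthetic data generators for the whole pipeline.

Emulates the three kinds of raw data the analysis consumes, so every
downstream stage is testable without beamline or microscope access:

* conformer ensembles — semi-flexible self-avoiding bead chains standing
  in for molecular-dynamics conformers, with monomer Dmax in the ~9–19 nm
  range typical of small nucleic-acid probes;
* solution scattering — exact Debye intensities on an s grid of
  0.2–6.0 nm⁻¹ (1-D curves and 2-D detector frames) with
  multiplicative-plus-high-angle noise;
* AFM topography — frames with Gaussian surface roughness of
  0.1–0.3 nm RMS bearing compact caps (0.5–7 nm) and layered patches
  (1–3 nm).

Every generator is a pure function of its inputs and one integer seed;
no global random state is touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .afm import TopographyImage
from .errors import GenerationFailureError, InvalidParameterError, EmptyRangeError
from .models import (
    ConformationEnsemble,
    DetectorGeometry,
    DetectorImage,
    ParticleModel,
    ScatteringCurve,
)
from .saxs import debye_intensity, _sinc  # noqa: F401  (sinc reused in tests)
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "GeneratorConfig",
    "ObjectSpec",
    "generate_chain_model",
    "generate_sized_chain",
    "generate_ensemble",
    "make_oligomer",
    "simulate_scattering",
    "simulate_detector_image",
    "simulate_topography",
    "grid_scene",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunables of the synthetic generators, with one master seed.

    Bead geometry (n_beads × bond_length with directional stiffness) is
    sized so a monomer chain has Dmax of order 10 nm while keeping Debye
    sums instant. Scattering defaults cover s in 0.2–6.0 nm⁻¹.
    Topography defaults give 25 µm² frames (5 µm edge) with 0.2 nm RMS
    roughness.
    """

    seed: int = 0
    n_beads: int = 80
    bond_length: float = 0.4          # nm
    stiffness: float = 1.2            # directional persistence of the chain
    perturbation_scale: float = 0.5   # nm RMS conformer displacement
    noise_fraction: float = 0.02      # fractional intensity noise
    s_min: float = 0.2                # nm^-1
    s_max: float = 6.0                # nm^-1
    n_s: int = 120
    frame_edge: float = 5.0           # µm
    pixel_size: float = 19.53125      # nm/pixel -> 256 px at 5 µm
    roughness_rms: float = 0.2        # nm

    def __post_init__(self) -> None:
        if not (0 < self.s_min < self.s_max):
            raise InvalidParameterError("need 0 < s_min < s_max")
        if self.n_beads < 1:
            raise InvalidParameterError("n_beads must be >= 1")
        if self.noise_fraction < 0:
            raise InvalidParameterError("noise_fraction must be >= 0")
        if self.roughness_rms < 0:
            raise InvalidParameterError("roughness_rms must be >= 0")
        if self.bond_length <= 0:
            raise InvalidParameterError("bond_length must be positive")
        if self.n_s < 2 or self.frame_edge <= 0 or self.pixel_size <= 0:
            raise InvalidParameterError("n_s >= 2, frame_edge > 0, pixel_size > 0")

    @property
    def s_grid(self) -> np.ndarray:
        return np.linspace(self.s_min, self.s_max, self.n_s)

    @property
    def frame_pixels(self) -> int:
        return int(round(self.frame_edge * 1000.0 / self.pixel_size))

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))


@dataclass(frozen=True)
class ObjectSpec:
    """One synthetic surface object: center (row, col in px), peak height
    (nm), lateral Gaussian/plateau radius (nm), compact or layered."""

    center: tuple[float, float]
    height: float
    lateral_sigma: float
    kind: str = "compact"

    def __post_init__(self) -> None:
        if self.height <= 0 or self.lateral_sigma <= 0:
            raise InvalidParameterError("height and lateral_sigma must be positive")
        if self.kind not in ("compact", "layered"):
            raise InvalidParameterError("kind must be 'compact' or 'layered'")


def _random_unit(rng: np.random.Generator, n: int = 1) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_chain_model(config: GeneratorConfig) -> ParticleModel:
    """Grow a semi-flexible self-avoiding bead chain.

    Consecutive beads are exactly ``bond_length`` apart; each new
    direction is the previous one plus an isotropic kick, normalized,
    with ``stiffness`` controlling persistence. Non-consecutive beads are
    kept at least 0.5·bond_length apart; chain growth restarts on a dead
    end within a bounded retry budget.
    """
    n, b = config.n_beads, config.bond_length
    rng = np.random.default_rng(config.seed)
    min_sep = 0.5 * b
    for _restart in range(80):
        pts = np.zeros((n, 3))
        direction = _random_unit(rng)[0]
        failed = False
        for i in range(1, n):
            for _attempt in range(200):
                kick = _random_unit(rng)[0]
                direction_new = config.stiffness * direction + kick
                direction_new /= np.linalg.norm(direction_new)
                cand = pts[i - 1] + b * direction_new
                if i >= 2:
                    d = np.linalg.norm(pts[:i - 1] - cand, axis=1)
                    if d.min() < min_sep:
                        continue
                pts[i] = cand
                direction = direction_new
                break
            else:
                failed = True
                break
        if not failed:
            return ParticleModel(pts[:n], np.ones(n), label="chain")
    raise GenerationFailureError("could not place a self-avoiding chain")


def generate_sized_chain(config: GeneratorConfig,
                         dmax_range: tuple[float, float] = (9.0, 11.5),
                         max_tries: int = 50) -> ParticleModel:
    """Generate a chain whose Dmax falls inside ``dmax_range`` (nm).

    The raw chain generator produces a distribution of sizes; study
    scenarios fix the monomer scale (~10 nm maximum size, the typical
    small nucleic-acid probe), so derived seeds are scanned until a
    chain of the right size appears.
    """
    from .saxs import dmax_from_model

    lo, hi = dmax_range
    if not (0 <= lo < hi):
        raise InvalidParameterError("need 0 <= lo < hi in dmax_range")
    for k in range(max_tries):
        model = generate_chain_model(replace(config, seed=config.seed + 1000 * k))
        if lo <= dmax_from_model(model) <= hi:
            return model
    raise GenerationFailureError(
        f"no chain with Dmax in {dmax_range} after {max_tries} tries")


def _smooth_along_chain(noise: np.ndarray, window: int = 7) -> np.ndarray:
    kernel = np.ones(window) / window
    return np.apply_along_axis(
        lambda col: np.convolve(col, kernel, mode="same"), 0, noise)


def generate_ensemble(base: ParticleModel, n_conformers: int,
                      perturbation_scale: float, seed: int) -> ConformationEnsemble:
    """Perturb a base chain into an ordered conformer ensemble.

    Conformer 1 is the unperturbed base. Each further conformer adds a
    smooth random displacement field (iid Gaussian smoothed along the
    chain, rescaled to RMS ``perturbation_scale``), then restores the
    original bond lengths by walking the chain and projecting each bond
    onto its perturbed direction.
    """
    if n_conformers < 1:
        raise InvalidParameterError("n_conformers must be >= 1")
    if perturbation_scale < 0:
        raise InvalidParameterError("perturbation_scale must be >= 0")
    rng = np.random.default_rng(seed)
    bonds = np.linalg.norm(np.diff(base.points, axis=0), axis=1)
    models = [ParticleModel(base.points, base.weights, label="model 1")]
    for k in range(2, n_conformers + 1):
        disp = _smooth_along_chain(rng.normal(size=base.points.shape))
        rms = np.sqrt(np.mean(np.sum(disp ** 2, axis=1)))
        if rms > 0 and perturbation_scale > 0:
            disp *= perturbation_scale / rms
        else:
            disp[:] = 0.0
        target = base.points + disp
        pts = np.empty_like(target)
        pts[0] = target[0]
        for i in range(1, pts.shape[0]):
            step = target[i] - pts[i - 1]
            norm = np.linalg.norm(step)
            if norm == 0.0:
                step = np.array([1.0, 0.0, 0.0])
                norm = 1.0
            pts[i] = pts[i - 1] + bonds[i - 1] * step / norm
        models.append(ParticleModel(pts, base.weights, label=f"model {k}"))
    return ConformationEnsemble(tuple(models))


def make_oligomer(base: ParticleModel, copies: int,
                  offset: np.ndarray) -> ParticleModel:
    """Union of ``copies`` replicas translated by multiples of ``offset``.

    Emulates a high-order oligomer of the monomer model. Overlapping
    replicas (inter-replica distance < 0.1 nm) trigger a warning, not an
    error.
    """
    if copies < 1:
        raise InvalidParameterError("copies must be >= 1")
    offset = np.asarray(offset, dtype=float)
    if copies > 1 and np.linalg.norm(offset) == 0.0:
        raise InvalidParameterError("offset must be nonzero for copies > 1")
    parts = [base.points + k * offset for k in range(copies)]
    for a in range(copies):
        for bdx in range(a + 1, copies):
            if cdist(parts[a], parts[bdx]).min() < 0.1:
                warnings.warn("oligomer replicas overlap (min distance < 0.1 nm)",
                              stacklevel=2)
    points = np.vstack(parts)
    weights = np.tile(base.weights, copies)
    return ParticleModel(points, weights, label=f"{base.label or 'model'}x{copies}")


def simulate_scattering(model: ParticleModel,
                        config: GeneratorConfig) -> ScatteringCurve:
    """Noisy 1-D scattering curve of a model on the configured s grid.

    The true intensity is the exact Debye sum; the per-point uncertainty
    is σ(s) = noise_fraction · I(s) · (1 + s/s_max), mimicking the worse
    signal-to-noise at high angle, and the reported I is drawn from
    N(I_true, σ). The σ column stores the model σ exactly.
    """
    s = config.s_grid
    true = debye_intensity(model, s).I
    sigma = config.noise_fraction * true * (1.0 + s / config.s_max)
    rng = np.random.default_rng(config.seed)
    noisy = rng.normal(true, sigma) if config.noise_fraction > 0 else true.copy()
    return ScatteringCurve(s, noisy, sigma, label=model.label)


def _debye_values(model: ParticleModel, s_flat: np.ndarray,
                  chunk: int = 4_000_000) -> np.ndarray:
    """Debye intensity at arbitrary (unsorted) s values."""
    w = model.weights
    out = np.full(s_flat.size, np.sum(w * w))
    if model.n_points > 1:
        d = pdist(model.points)
        iu, ju = np.triu_indices(model.n_points, k=1)
        pw = 2.0 * w[iu] * w[ju]
        step = max(1, chunk // max(s_flat.size, 1))
        for start in range(0, d.size, step):
            stop = min(start + step, d.size)
            out += pw[start:stop] @ _sinc(np.outer(d[start:stop], s_flat))
    return out


def simulate_detector_image(model: ParticleModel, geometry: DetectorGeometry,
                            config: GeneratorConfig,
                            shape: tuple[int, int] = (128, 128)) -> DetectorImage:
    """Noisy 2-D detector frame of an isotropic scatterer.

    Every pixel maps to s through the geometry (s = 4π sinθ/λ) and gets
    the Debye intensity there plus the same noise model as the 1-D
    simulator — azimuthally symmetric in expectation.
    """
    if not (0 <= geometry.beam_center[0] < shape[0]
            and 0 <= geometry.beam_center[1] < shape[1]):
        raise InvalidParameterError("beam center must lie inside the image")
    s_map = geometry.s_of_pixels(shape)
    in_range = (s_map >= config.s_min) & (s_map <= config.s_max)
    if not in_range.any():
        raise EmptyRangeError("no pixel falls inside [s_min, s_max]")
    true = _debye_values(model, s_map.ravel()).reshape(shape)
    sigma = config.noise_fraction * true * (1.0 + s_map / config.s_max)
    rng = np.random.default_rng(config.seed)
    counts = rng.normal(true, sigma) if config.noise_fraction > 0 else true
    return DetectorImage(counts, geometry)


def _render_objects(shape: tuple[int, int], objects: list[ObjectSpec],
                    pixel_size: float) -> np.ndarray:
    field = np.zeros(shape)
    rows, cols = np.indices(shape)
    for obj in objects:
        r0, c0 = obj.center
        if not (0 <= r0 < shape[0] and 0 <= c0 < shape[1]):
            raise InvalidParameterError("object center outside the frame")
        sig_px = obj.lateral_sigma / pixel_size
        d2 = (rows - r0) ** 2 + (cols - c0) ** 2
        if obj.kind == "compact":
            # Gaussian cap truncated at 4 sigma so scenes stay separable
            cap = obj.height * np.exp(-d2 / (2.0 * sig_px ** 2))
            cap[d2 > (4.0 * sig_px) ** 2] = 0.0
        else:
            # plateau of radius lateral_sigma with a ~2-pixel cosine edge
            d = np.sqrt(d2)
            edge = max(2.0, 0.1 * sig_px)
            ramp = np.clip((sig_px + edge - d) / edge, 0.0, 1.0)
            cap = obj.height * 0.5 * (1.0 - np.cos(np.pi * np.minimum(ramp, 1.0)))
            cap[ramp >= 1.0] = obj.height
        field = np.maximum(field, cap)
    return field


def simulate_topography(objects: list[ObjectSpec], config: GeneratorConfig,
                        tilt: tuple[float, float] = (0.0, 0.0),
                        label: str = "") -> TopographyImage:
    """Render a topography frame: roughness + optional plane tilt + objects.

    The background is Gaussian roughness of RMS ``roughness_rms`` plus a
    plane with slopes ``tilt`` (nm per µm along rows/cols). Objects sit
    on top of the background (combined by maximum among themselves).
    Frame area S_fr (µm²) is recorded in the image metadata.
    """
    n_px = config.frame_pixels
    shape = (n_px, n_px)
    rng = np.random.default_rng(config.seed)
    background = (rng.normal(0.0, config.roughness_rms, size=shape)
                  if config.roughness_rms > 0 else np.zeros(shape))
    um_per_px = config.pixel_size / 1000.0
    rows, cols = np.indices(shape)
    plane = tilt[0] * rows * um_per_px + tilt[1] * cols * um_per_px
    heights = background + plane + _render_objects(shape, objects, config.pixel_size)
    return TopographyImage(heights, config.pixel_size, label=label)


def grid_scene(heights: np.ndarray, config: GeneratorConfig,
               lateral_sigma: float = 100.0, seed: int = 0,
               kind: str = "compact") -> list[ObjectSpec]:
    """Place objects of the given heights on a jittered grid.

    Cells are sized so truncated objects never touch, which keeps
    detected component counts equal to the number of specs.
    """
    heights = np.asarray(heights, dtype=float)
    n = heights.size
    if n == 0:
        return []
    n_px = config.frame_pixels
    g = int(np.ceil(np.sqrt(n)))
    cell = n_px / g
    margin = 4.0 * lateral_sigma / config.pixel_size + 2.0
    if cell <= 2.0 * margin:
        raise InvalidParameterError(
            "too many/too wide objects for the frame; shrink lateral_sigma")
    rng = np.random.default_rng(seed)
    specs: list[ObjectSpec] = []
    order = rng.permutation(g * g)[:n]
    for h, slot in zip(heights, order):
        gr, gc = divmod(int(slot), g)
        jitter = rng.uniform(-(cell / 2 - margin), cell / 2 - margin, size=2)
        center = (gr * cell + cell / 2 + jitter[0],
                  gc * cell + cell / 2 + jitter[1])
        specs.append(ObjectSpec(center, float(h), lateral_sigma, kind))
    return specs
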
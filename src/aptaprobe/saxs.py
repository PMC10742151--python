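"""Small-angle scattering processing.

Covers the reduction and characterization chain for solution scattering:
radial averaging of 2-D detector frames, background subtraction, exact
Debye intensities from bead models, Guinier Rg estimation, and the
pair-distance distribution p(r) from models (direct histogram) and from
curves (regularized indirect transform in the role GNOM plays in beamline
pipelines).

Conventions: s in nm⁻¹, distances in nm, I in arbitrary units.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import lsq_linear
from scipy.spatial import ConvexHull
from scipy.spatial.distance import cdist, pdist

from .errors import (
    EmptyRangeError,
    GridMismatchError,
    InsufficientDataError,
    InvalidModelError,
    InvalidParameterError,
    InvalidUncertaintyError,
    NoGuinierRegionError,
    RegularizationFailureError,
)
from .models import (
    DetectorImage,
    PairDistribution,
    ParticleModel,
    ScatteringCurve,
    grids_match,
)

__all__ = [
    "debye_intensity",
    "rg_from_model",
    "dmax_from_model",
    "radial_average",
    "subtract_background",
    "guinier_fit",
    "pr_from_model",
    "pr_from_curve",
    "estimate_dmax",
]

# Below this |x| the direct ratio sin(x)/x loses digits to cancellation;
# the 3-term Taylor series is exact to double precision there.
_SINC_SERIES_CUTOFF = 1e-4


def _sinc(x: np.ndarray) -> np.ndarray:
    """sin(x)/x with sinc(0) = 1, series-evaluated near zero."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < _SINC_SERIES_CUTOFF
    xs = x[small]
    out[small] = 1.0 - xs * xs / 6.0 * (1.0 - xs * xs / 20.0)
    xb = x[~small]
    out[~small] = np.sin(xb) / xb
    return out


def debye_intensity(model: ParticleModel, s_grid: np.ndarray,
                    chunk_pairs: int = 2_000_000) -> ScatteringCurve:
    """Orientationally averaged intensity of a point-scatterer model.

    Debye formula: I(s) = Σ_i Σ_j w_i w_j sin(s·d_ij)/(s·d_ij), the exact
    spherical average for a rigid set of point scatterers. At s = 0 this
    reduces to (Σ w)². The double sum is evaluated over unique pairs in
    chunks to bound memory; the returned σ column is zero (the curve is
    noiseless by construction).
    """
    if model is None or model.n_points < 1:
        raise InvalidModelError("model must contain at least one point")
    s = np.asarray(s_grid, dtype=float)
    if s.ndim != 1 or s.size < 1 or np.any(s < 0):
        raise InvalidParameterError("s grid must be 1-D and non-negative")

    w = model.weights
    intensity = np.full(s.size, np.sum(w * w))
    n = model.n_points
    if n > 1:
        dists = pdist(model.points)
        iu, ju = np.triu_indices(n, k=1)
        pair_w = 2.0 * w[iu] * w[ju]
        for start in range(0, dists.size, max(1, chunk_pairs // max(s.size, 1))):
            stop = min(start + max(1, chunk_pairs // max(s.size, 1)), dists.size)
            block = _sinc(np.outer(dists[start:stop], s))
            intensity += pair_w[start:stop] @ block
    return ScatteringCurve(s, intensity, np.zeros_like(s), label=model.label)


def rg_from_model(model: ParticleModel) -> float:
    """Radius of gyration: weighted RMS distance from the weighted centroid."""
    w = model.weights
    center = np.average(model.points, axis=0, weights=w)
    sq = np.sum((model.points - center) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=w)))


def dmax_from_model(model: ParticleModel, exact_limit: int = 2_000) -> float:
    """Maximum pairwise distance; exact all-pairs up to ``exact_limit``
    points, convex-hull reduction (still exact) above."""
    pts = model.points
    if pts.shape[0] == 1:
        return 0.0
    if pts.shape[0] > exact_limit:
        try:
            # hull reduction is exact: the farthest pair lies on the hull
            pts = pts[ConvexHull(pts).vertices]
        except Exception:
            pass  # degenerate (coplanar/collinear) clouds fall back to all pairs
    return float(pdist(pts).max())


def radial_average(image: DetectorImage, n_bins: int) -> ScatteringCurve:
    """Azimuthal average of a detector frame onto a 1-D s grid.

    Each pixel maps to s through the geometry; bins are uniform in s over
    the occupied range. The bin value is the plain mean of pixel counts,
    its σ the standard error of that mean (floored at machine epsilon so
    the curve remains usable in weighted fits); empty bins are dropped.
    The reported s of a bin is the mean pixel s inside it.
    """
    if n_bins < 2:
        raise InvalidParameterError("n_bins must be at least 2")
    s_map = image.geometry.s_of_pixels(image.counts.shape).ravel()
    counts = image.counts.ravel()
    if s_map.size == 0:
        raise EmptyRangeError("image has no pixels")
    edges = np.linspace(s_map.min(), s_map.max() * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(s_map, edges) - 1, 0, n_bins - 1)

    n_pix = np.bincount(idx, minlength=n_bins)
    occupied = n_pix > 0
    if not occupied.any():
        raise EmptyRangeError("all radial bins are empty")
    sum_i = np.bincount(idx, weights=counts, minlength=n_bins)
    sum_i2 = np.bincount(idx, weights=counts * counts, minlength=n_bins)
    sum_s = np.bincount(idx, weights=s_map, minlength=n_bins)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sum_i / n_pix
        var = np.maximum(sum_i2 / n_pix - mean ** 2, 0.0)
        sem = np.sqrt(var / n_pix)
    eps = np.finfo(float).eps
    s_out = (sum_s / n_pix)[occupied]
    order = np.argsort(s_out)
    return ScatteringCurve(
        s_out[order],
        mean[occupied][order],
        np.maximum(sem[occupied][order], eps),
        wavelength=image.geometry.wavelength,
    )


def subtract_background(sample: ScatteringCurve,
                        background: ScatteringCurve) -> ScatteringCurve:
    """Point-wise background subtraction with quadrature error propagation.

    Requires identical s grids — no silent interpolation, which would
    change σ and hence every downstream χ².
    """
    if not grids_match(sample, background):
        raise GridMismatchError("sample and background are on different s grids")
    return ScatteringCurve(
        sample.s,
        sample.I - background.I,
        np.sqrt(sample.sigma ** 2 + background.sigma ** 2),
        sample.wavelength,
        sample.label,
    )


def guinier_fit(curve: ScatteringCurve, srg_limit: float = 1.3,
                max_iter: int = 100) -> tuple[float, float, int]:
    """Guinier estimate of Rg from the low-angle limit I ≈ I0·exp(−s²Rg²/3).

    Performs a weighted linear fit of ln I against s² and iterates the
    fitting window to self-consistency with s·Rg ≤ ``srg_limit``. Weights
    are (I/σ)² where σ is available (the delta-method variance of ln I),
    uniform otherwise. Returns (Rg, I0, number of points used).
    """
    positive = curve.I > 0
    s = curve.s[positive]
    i = curve.I[positive]
    sig = curve.sigma[positive]
    if s.size < 5:
        raise InsufficientDataError("need at least 5 points with I > 0")

    x = s * s
    y = np.log(i)
    weights = (i / sig) ** 2 if np.all(sig > 0) else np.ones_like(i)

    def fit(mask: np.ndarray) -> tuple[float, float]:
        slope, intercept = np.polyfit(x[mask], y[mask], 1, w=np.sqrt(weights[mask]))
        return slope, intercept

    mask = np.zeros_like(s, dtype=bool)
    mask[:max(5, min(10, s.size))] = True
    prev_key = None
    slope = intercept = 0.0
    for _ in range(max_iter):
        slope, intercept = fit(mask)
        if slope > 0 and not np.isclose(slope, 0.0, atol=1e-12):
            raise NoGuinierRegionError("positive low-angle slope; Rg undefined")
        rg = float(np.sqrt(max(-3.0 * slope, 0.0)))
        if rg == 0.0:
            new_mask = np.ones_like(mask)  # flat curve: every point qualifies
        else:
            new_mask = s * rg <= srg_limit
        if new_mask.sum() < 5:
            new_mask = np.zeros_like(mask)
            new_mask[:5] = True
        key = new_mask.tobytes()
        if key == prev_key or np.array_equal(new_mask, mask):
            mask = new_mask
            break
        prev_key = mask.tobytes()
        mask = new_mask
    slope, intercept = fit(mask)
    if slope > 1e-12:
        raise NoGuinierRegionError("positive low-angle slope; Rg undefined")
    rg = float(np.sqrt(max(-3.0 * slope, 0.0)))
    return rg, float(np.exp(intercept)), int(mask.sum())


def pr_from_model(model: ParticleModel, bin_width: float,
                  chunk: int = 2000) -> PairDistribution:
    """Pair-distance distribution of a model by direct histogramming.

    All inter-point distances, weighted by w_i·w_j, binned at ~``bin_width``
    over [0, Dmax] and normalized to unit area (trapezoid rule on the
    returned grid, which is zero-padded at r = 0 and r = Dmax).
    """
    if bin_width <= 0:
        raise InvalidParameterError("bin_width must be positive")
    dmax = dmax_from_model(model)
    if dmax == 0.0:
        r = np.array([0.0, bin_width])
        return PairDistribution(r, np.zeros_like(r), 0.0)

    n_bins = max(1, int(np.ceil(dmax / bin_width)))
    edges = np.linspace(0.0, dmax, n_bins + 1)
    hist = np.zeros(n_bins)
    pts, w = model.points, model.weights
    n = pts.shape[0]
    uniform = bool(np.all(w == w[0]))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        # each unordered pair once: block rows against all later points,
        # plus the within-block upper triangle
        d_cross = cdist(pts[start:stop], pts[stop:]).ravel()
        d_in = pdist(pts[start:stop]) if stop - start > 1 else np.empty(0)
        if uniform:
            h, _ = np.histogram(np.concatenate([d_cross, d_in]), bins=edges)
            hist += w[0] * w[0] * h
        else:
            iu, ju = np.triu_indices(stop - start, k=1)
            ww = np.concatenate([np.outer(w[start:stop], w[stop:]).ravel(),
                                 w[start + iu] * w[start + ju]])
            h, _ = np.histogram(np.concatenate([d_cross, d_in]),
                                bins=edges, weights=ww)
            hist += h

    centers = 0.5 * (edges[:-1] + edges[1:])
    r = np.concatenate([[0.0], centers, [dmax]])
    p = np.concatenate([[0.0], hist, [0.0]])
    area = np.trapezoid(p, r)
    if area > 0:
        p = p / area
    return PairDistribution(r, p, dmax)


def _second_difference_matrix(n: int) -> np.ndarray:
    d2 = np.zeros((n - 2, n))
    for k in range(n - 2):
        d2[k, k:k + 3] = (1.0, -2.0, 1.0)
    return d2


def _pr_design(s: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Forward operator K with I(s) = K @ p: trapezoid discretization of
    I(s) = 4π ∫ p(r) sinc(s r) dr."""
    dr = np.gradient(r)
    trap = dr.copy()
    trap[0] *= 0.5
    trap[-1] *= 0.5
    return 4.0 * np.pi * _sinc(np.outer(s, r)) * trap[None, :]


def pr_forward(pr: PairDistribution, s_grid: np.ndarray,
               scale: float = 1.0) -> ScatteringCurve:
    """Forward-transform a p(r) to an intensity curve (σ column zero)."""
    s = np.asarray(s_grid, dtype=float)
    return ScatteringCurve(s, scale * (_pr_design(s, pr.r) @ pr.p))


def pr_from_curve(curve: ScatteringCurve, d_max_support: float,
                  alpha: float | str = "auto",
                  n_r: int = 101) -> PairDistribution:
    """Regularized indirect transform of a scattering curve to p(r).

    Solves I(s) = 4π ∫₀^Dmax p(r) sinc(sr) dr by σ-weighted least squares
    on a fixed r grid with endpoint constraints p(0) = p(Dmax) = 0, a
    second-difference smoothness penalty of weight ``alpha``, and
    non-negativity (bounded least squares). ``alpha="auto"`` picks the
    elbow of a 10-point logarithmic L-curve scan. The returned
    distribution is normalized to unit area; its ``fit`` / ``fit_chi2``
    fields carry the forward-transformed fit and its reduced χ² against
    the input curve.
    """
    if d_max_support <= 0:
        raise InvalidParameterError("d_max_support must be positive")
    if isinstance(alpha, str):
        if alpha != "auto":
            raise InvalidParameterError("alpha must be a number or 'auto'")
    elif alpha < 0:
        raise InvalidParameterError("alpha must be non-negative")
    if np.any(curve.sigma <= 0):
        raise InvalidUncertaintyError("indirect transform needs sigma > 0")

    r = np.linspace(0.0, d_max_support, n_r)
    design = _pr_design(curve.s, r)[:, 1:-1]  # endpoints pinned to zero
    wts = 1.0 / curve.sigma
    a_data = design * wts[:, None]
    b_data = curve.I * wts
    d2 = _second_difference_matrix(n_r)[:, 1:-1]
    # scale so alpha ~ 1 balances data misfit against curvature
    d2_scale = np.linalg.norm(a_data) / max(np.linalg.norm(d2), 1e-300)

    def solve(a: float):
        stacked = np.vstack([a_data, np.sqrt(a) * d2_scale * d2])
        rhs = np.concatenate([b_data, np.zeros(d2.shape[0])])
        res = lsq_linear(stacked, rhs, bounds=(0.0, np.inf),
                         method="bvls", tol=1e-12)
        if not np.all(np.isfinite(res.x)):
            raise RegularizationFailureError(
                "singular indirect-transform system; try a larger alpha")
        return res.x

    if alpha == "auto":
        alphas = np.logspace(-6, 3, 10)
        rho, eta, sols = [], [], []
        for a in alphas:
            x = solve(a)
            sols.append(x)
            rho.append(np.log(max(np.linalg.norm(a_data @ x - b_data), 1e-300)))
            eta.append(np.log(max(np.linalg.norm(d2 @ x), 1e-300)))
        rho, eta = np.array(rho), np.array(eta)
        # discrete curvature of the L-curve; endpoints excluded
        curv = np.full(len(alphas), -np.inf)
        for k in range(1, len(alphas) - 1):
            d1r, d1e = rho[k + 1] - rho[k - 1], eta[k + 1] - eta[k - 1]
            d2r = rho[k + 1] - 2 * rho[k] + rho[k - 1]
            d2e = eta[k + 1] - 2 * eta[k] + eta[k - 1]
            denom = (d1r * d1r + d1e * d1e) ** 1.5
            if denom > 0:
                curv[k] = (d1r * d2e - d1e * d2r) / denom
        pick = int(np.argmax(curv)) if np.isfinite(curv).any() else len(alphas) // 2
        alpha_used = float(alphas[pick])
        x = sols[pick]
    else:
        alpha_used = float(alpha)
        x = solve(alpha_used)

    # bounded solver can leave ~1e-16 negatives at active bounds
    p_full = np.concatenate([[0.0], np.maximum(x, 0.0), [0.0]])
    fit_i = _pr_design(curve.s, r) @ p_full
    n = curve.s.size
    chi2 = float(np.sum(((curve.I - fit_i) / curve.sigma) ** 2) / max(n - 1, 1))
    fit_curve = ScatteringCurve(curve.s, fit_i)

    area = np.trapezoid(p_full, r)
    if area > 0:
        p_full = p_full / area
    return PairDistribution(r, p_full, float(d_max_support),
                            fit_chi2=chi2, alpha=alpha_used, fit=fit_curve)


def _edge_pileup(pr: PairDistribution, tail_fraction: float = 0.1) -> float:
    """Mean p(r) over the outer ``tail_fraction`` of the support, relative
    to the p(r) maximum. Large values flag a truncated support: mass the
    data demand beyond Dmax piles up against the endpoint constraint."""
    tail = pr.r >= (1.0 - tail_fraction) * pr.d_max_support
    peak = pr.p.max()
    return float(np.mean(pr.p[tail]) / peak) if peak > 0 else 0.0


def estimate_dmax(curve: ScatteringCurve,
                  d_min: float, d_max: float,
                  n_candidates: int = 12,
                  plateau_factor: float = 1.10,
                  max_edge_fraction: float = 0.10,
                  alpha: float | str = "auto",
                  return_scan: bool = False):
    """Estimate Dmax from a curve by scanning the p(r) support.

    Supports shorter than the true Dmax truncate p(r) and fit poorly;
    supports at or beyond it reach a χ² plateau. Two refinements make the
    plateau onset robust: (1) the plateau tolerance is the larger of a
    relative band (``plateau_factor`` × best) and an additive band of two
    reduced-χ² noise standard deviations, 2·√(2/(N−1)), so the noise-
    biased scan minimum cannot exclude the true support; (2) a candidate
    must also show a cleanly decaying p(r) — its endpoint pile-up (mean p
    over the outer 10% of the support, relative to the peak) must stay
    below ``max_edge_fraction``, which flags truncated supports. If no
    candidate passes both, the χ² band alone decides. Returns (Dmax
    estimate, its p(r)), plus the full scan as a third element when
    ``return_scan`` is set.
    """
    if not (0 < d_min < d_max):
        raise InvalidParameterError("need 0 < d_min < d_max")
    candidates = np.linspace(d_min, d_max, n_candidates)
    results = [pr_from_curve(curve, d, alpha=alpha) for d in candidates]
    chi2s = np.array([res.fit_chi2 for res in results])
    best = chi2s.min()
    band = max((plateau_factor - 1.0) * best,
               2.0 * np.sqrt(2.0 / max(len(curve) - 1, 1)))
    in_plateau = chi2s <= best + band
    accepted = in_plateau & np.array(
        [_edge_pileup(res) < max_edge_fraction for res in results])
    if accepted.any():
        idx = int(np.argmax(accepted))
    else:
        accepted = in_plateau
        idx = int(np.argmax(in_plateau))
    if return_scan:
        scan = [(float(d), res, bool(ok))
                for d, res, ok in zip(candidates, results, accepted)]
        return float(candidates[idx]), results[idx], scan
    return float(candidates[idx]), results[idx]
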
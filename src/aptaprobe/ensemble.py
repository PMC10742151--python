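"""Conformer ranking against experimental scattering curves.

Every conformer of an ensemble is scored with the reduced discrepancy

    χ² = 1/(N−1) · Σ_j [(I_exp(s_j) − c·I_calc(s_j)) / σ(s_j)]²

where the scale factor c overlays the calculated curve onto the
experimental one by least squares,

    c = Σ_j I_exp·I_calc/σ² / Σ_j I_calc²/σ².

The best conformer is the χ² minimizer; comparing the experimental
Rg/Dmax with the ensemble's per-conformer values then flags solutions
whose particles are much larger than any plausible monomer conformation
(oligomer/aggregate formation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import (
    GridMismatchError,
    InsufficientDataError,
    InvalidParameterError,
    InvalidUncertaintyError,
    UndefinedScaleError,
)
from .models import ConformationEnsemble, ScatteringCurve, grids_match
from .saxs import debye_intensity, dmax_from_model, rg_from_model

__all__ = [
    "FitResult",
    "FitTable",
    "EnsembleSummary",
    "OligomerAssessment",
    "optimal_scale",
    "chi_squared",
    "rank_ensemble",
    "structural_parameter_summary",
    "assess_oligomeric_state",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitResult:
    """One conformer's row: scale c, χ², Rg (nm), Dmax (nm)."""

    label: int
    c: float
    chi2: float
    rg: float
    dmax: float
    error: str | None = None


@dataclass(frozen=True)
class FitTable:
    """Per-conformer fit results in ensemble order plus the χ²-best label."""

    rows: tuple[FitResult, ...]
    best_label: int

    def best(self) -> FitResult:
        return next(row for row in self.rows if row.label == self.best_label)


@dataclass(frozen=True)
class EnsembleSummary:
    """Unweighted ensemble statistics of the structural parameters."""

    mean_dmax: float
    sd_dmax: float
    mean_rg: float
    sd_rg: float
    max_dmax: float


@dataclass(frozen=True)
class OligomerAssessment:
    """Experimental vs ensemble sizes and the resulting verdict."""

    exp_rg: float
    exp_dmax: float
    ensemble_mean_dmax: float
    ensemble_max_dmax: float
    ratio: float
    verdict: str  # "monomer-compatible" | "aggregation-suspected"


def _check_pair(exp: ScatteringCurve, calc: ScatteringCurve) -> None:
    if not grids_match(exp, calc):
        raise GridMismatchError("experimental and calculated grids differ")
    if np.any(exp.sigma <= 0):
        raise InvalidUncertaintyError("sigma must be positive on all fitted points")


def optimal_scale(exp: ScatteringCurve, calc: ScatteringCurve,
                  use_printed_formula: bool = False) -> float:
    """Least-squares scale factor c overlaying calc onto exp.

    The default is the unique minimizer of the reduced discrepancy over c.
    ``use_printed_formula`` switches to the variant sometimes printed with
    first-power σ weighting and I_exp² in the denominator; it is kept only
    for comparison and is not a least-squares minimizer.
    """
    _check_pair(exp, calc)
    if np.all(calc.I == 0):
        raise UndefinedScaleError("calculated curve is identically zero")
    if use_printed_formula:
        num = np.sum(exp.I * calc.I / exp.sigma)
        den = np.sum(exp.I ** 2 / exp.sigma)
        if den == 0:
            raise UndefinedScaleError("degenerate printed-formula denominator")
        return float(num / den)
    w = 1.0 / exp.sigma ** 2
    return float(np.sum(w * exp.I * calc.I) / np.sum(w * calc.I ** 2))


def chi_squared(exp: ScatteringCurve, calc: ScatteringCurve,
                c: float | str = "auto") -> float:
    """Reduced discrepancy between experimental and scaled calculated curves.

    ``c="auto"`` fits the optimal scale first, so the result is the best
    achievable discrepancy for this model.
    """
    _check_pair(exp, calc)
    if len(exp) < 2:
        raise InsufficientDataError("chi-squared needs at least 2 points")
    scale = optimal_scale(exp, calc) if isinstance(c, str) and c == "auto" else float(c)
    resid = (exp.I - scale * calc.I) / exp.sigma
    return float(np.sum(resid ** 2) / (len(exp) - 1))


def rank_ensemble(ensemble: ConformationEnsemble, exp: ScatteringCurve,
                  s_max: float | None = None,
                  use_printed_formula: bool = False) -> FitTable:
    """Score every conformer against the experimental curve (Debye sum →
    optimal scale → χ²) together with its Rg and Dmax.

    The best label is the χ² argmin; exact ties go to the lowest label.
    A conformer whose fit fails is kept as a flagged row (NaN statistics)
    rather than aborting the whole table. ``s_max`` optionally truncates
    the fitted range, since point-scatterer models are least faithful at
    high angle.
    """
    curve = exp if s_max is None else exp.truncated(s_max)
    rows: list[FitResult] = []
    for label, model in zip(ensemble.labels, ensemble.models):
        try:
            calc = debye_intensity(model, curve.s)
            c = optimal_scale(curve, calc, use_printed_formula=use_printed_formula)
            chi2 = chi_squared(curve, calc, c)
            rows.append(FitResult(label, c, chi2,
                                  rg_from_model(model), dmax_from_model(model)))
        except Exception as exc:  # noqa: BLE001 - flagged row by contract
            log.warning("conformer %d failed to fit: %s", label, exc)
            rows.append(FitResult(label, np.nan, np.nan, np.nan, np.nan,
                                  error=str(exc)))
    chi2s = np.array([row.chi2 for row in rows])
    if np.all(np.isnan(chi2s)):
        raise InsufficientDataError("every conformer failed to fit")
    best_idx = int(np.nanargmin(chi2s))  # first occurrence = lowest label
    return FitTable(tuple(rows), rows[best_idx].label)


def structural_parameter_summary(ensemble: ConformationEnsemble) -> EnsembleSummary:
    """Unweighted mean/SD of per-conformer Dmax and Rg (sample SD, 0 for n=1)."""
    dmax = np.array([dmax_from_model(m) for m in ensemble.models])
    rg = np.array([rg_from_model(m) for m in ensemble.models])
    sd = (lambda x: float(np.std(x, ddof=1)) if x.size > 1 else 0.0)
    return EnsembleSummary(float(dmax.mean()), sd(dmax),
                           float(rg.mean()), sd(rg), float(dmax.max()))


def assess_oligomeric_state(exp_rg: float, exp_dmax: float,
                            summary: EnsembleSummary,
                            threshold_ratio: float = 1.3) -> OligomerAssessment:
    """Compare experimental particle size with the monomer ensemble.

    Aggregation is suspected when the experimental Dmax (or Rg) exceeds
    ``threshold_ratio`` times the ensemble mean — the situation where the
    scattering particle is significantly larger than any monomer
    conformation. The default 1.3 sits between a monomer-consistent ratio
    (~1.0–1.15) and the ~1.9 of a genuinely oligomeric solution.
    """
    if threshold_ratio <= 0:
        raise InvalidParameterError("threshold_ratio must be positive")
    if exp_rg <= 0 or exp_dmax <= 0:
        raise InvalidParameterError("experimental sizes must be positive")
    if summary.mean_dmax <= 0 or summary.mean_rg <= 0:
        raise InvalidParameterError("ensemble means must be positive")
    ratio = exp_dmax / summary.mean_dmax
    suspected = (exp_dmax > threshold_ratio * summary.mean_dmax
                 or exp_rg > threshold_ratio * summary.mean_rg)
    verdict = "aggregation-suspected" if suspected else "monomer-compatible"
    return OligomerAssessment(exp_rg, exp_dmax, summary.mean_dmax,
                              summary.max_dmax, ratio, verdict)
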
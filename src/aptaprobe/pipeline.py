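"""End-to-end probe-assessment workflow.

Stages mirror the experimental design: ``simulate`` writes synthetic
inputs (conformer ensemble, scattering curves, topography frames);
``saxs`` reduces a curve, ranks the ensemble by χ² and assesses the
oligomeric state; ``afm`` detects objects before/after incubation and
calls complex formation; ``report`` merges everything into one document.

Each stage is a plain function over a validated :class:`PipelineConfig`;
the CLI in :mod:`aptaprobe.cli` is a thin shell around them. One master
seed drives every random draw, so two runs with an identical config are
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from importlib.metadata import version as pkg_version
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import afm, io, saxs, synthetic
from .ensemble import (
    assess_oligomeric_state,
    rank_ensemble,
    structural_parameter_summary,
)
from .errors import ConfigurationMismatchError, DependencyError, InvalidParameterError
from .models import PairDistribution, ScatteringCurve

__all__ = [
    "PipelineConfig",
    "load_config",
    "characterize_curve",
    "run_simulate",
    "run_saxs_stage",
    "run_afm_stage",
    "run_report",
]

log = logging.getLogger("aptaprobe")


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeneratorBlock(_Strict):
    n_beads: int = 80
    bond_length: float = 0.4
    stiffness: float = 1.2
    perturbation_scale: float = 0.5
    noise_fraction: float = 0.02
    s_min: float = 0.2
    s_max: float = 6.0
    n_s: int = 120
    frame_edge: float = 5.0
    pixel_size: float = 19.53125
    roughness_rms: float = 0.2


class SimulateBlock(_Strict):
    n_conformers: int = Field(default=20, ge=1)
    oligomer_copies: int = Field(default=2, ge=1)
    n_frames: int = Field(default=16, ge=1)
    n_objects_per_frame: int = Field(default=12, ge=0)
    probe_height: float = 1.2       # nm, bare-probe objects
    complex_height: float = 2.0     # nm, probe-target complexes
    height_spread: float = 0.15     # nm, 1-sigma of object heights
    lateral_sigma: float = 100.0    # nm
    tilt: float = 0.3               # nm per um substrate tilt


class FitBlock(_Strict):
    s_max: float | None = None
    use_printed_formula: bool = False
    threshold_ratio: float = 1.3
    # Dmax support scan: candidate p(r) supports between lo and hi x Rg,
    # solved at a fixed moderate regularization weight (the chi^2 plateau
    # onset, not the p(r) shape, is what the scan reads off)
    dmax_scan_lo: float = 1.5
    dmax_scan_hi: float = 5.0
    dmax_scan_alpha: float = 1.0
    dmax_candidates: int = 12


class AfmBlock(_Strict):
    k_sigma: float = 3.0
    min_area: float = 800.0         # nm^2
    bin_width: float = 0.2          # nm
    threshold: float = 1.4          # nm
    min_shift_fraction: float = 20.0


class PipelineConfig(_Strict):
    seed: int = 0
    generator: GeneratorBlock = GeneratorBlock()
    simulate: SimulateBlock = SimulateBlock()
    fit: FitBlock = FitBlock()
    afm: AfmBlock = AfmBlock()

    def generator_config(self, seed: int | None = None) -> synthetic.GeneratorConfig:
        return synthetic.GeneratorConfig(
            seed=self.seed if seed is None else seed,
            **self.generator.model_dump())

    def content_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Load and strictly validate a YAML/JSON pipeline config
    (unknown keys are fatal)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return PipelineConfig.model_validate(data)


def _provenance(config: PipelineConfig, stage: str,
                inputs: dict[str, str] | None = None) -> dict:
    try:
        ver = pkg_version("aptaprobe")
    except Exception:
        ver = "unknown"
    return {"stage": stage, "seed": config.seed,
            "config_hash": config.content_hash(), "version": ver,
            "inputs": inputs or {}}


def _write_provenance(config: PipelineConfig, stage: str, out_dir: Path,
                      inputs: dict[str, str] | None = None) -> None:
    (out_dir / f"provenance_{stage}.json").write_text(
        json.dumps(_provenance(config, stage, inputs), indent=2, sort_keys=True))


def _file_hash(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def characterize_curve(curve: ScatteringCurve,
                       fit: FitBlock | None = None,
                       ) -> tuple[float, float, PairDistribution]:
    """Experimental Rg, Dmax and p(r) from a reduced curve.

    A Guinier fit seeds the p(r) support scan between ``dmax_scan_lo`` ×
    Rg and ``dmax_scan_hi`` × Rg; supports shorter than the true Dmax
    truncate p(r) and fit the curve poorly, so the Dmax estimate is the
    onset of the fit-χ² plateau (with an endpoint-pile-up veto). When the
    estimate lands near the scan cap — the signature of a particle much
    larger than the Guinier window can resolve, since the Guinier Rg
    saturates once s_min·Rg exceeds the fit limit — the scan is extended
    and repeated. The reported Rg is the real-space value from the
    second moment of the recovered p(r), Rg² = ∫r²p(r)dr / 2, which
    remains accurate for particles too large for the Guinier window.
    Returns (Rg, Dmax, the p(r) at the chosen support).
    """
    fit = fit or FitBlock()
    rg_guinier, _i0, _n = saxs.guinier_fit(curve)
    if rg_guinier <= 0:
        raise InvalidParameterError("Guinier Rg is zero; cannot scan Dmax")
    lo = fit.dmax_scan_lo * rg_guinier
    hi = fit.dmax_scan_hi * rg_guinier
    for _ in range(4):
        dmax, pr, scan = saxs.estimate_dmax(
            curve, lo, hi, n_candidates=fit.dmax_candidates,
            alpha=fit.dmax_scan_alpha, return_scan=True)
        if dmax <= 0.85 * hi:
            break
        hi *= 1.6

    def real_space_rg(p: PairDistribution) -> float:
        return float(np.sqrt(np.trapezoid(p.r**2 * p.p, p.r) / 2.0))

    accepted = [res for _, res, ok in scan if ok]
    rg_real = (float(np.mean([real_space_rg(res) for res in accepted]))
               if accepted else real_space_rg(pr))
    log.debug("Rg (Guinier) %.3g nm, Rg (real-space) %.3g nm, Dmax %.3g nm",
              rg_guinier, rg_real, dmax)
    return rg_real, dmax, pr


def _timed(stage: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            result = fn(*args, **kwargs)
            log.info("stage %s: done in %.2f s", stage, time.perf_counter() - t0)
            return result
        inner.__name__ = fn.__name__
        inner.__doc__ = fn.__doc__
        return inner
    return wrap


@_timed("simulate")
def run_simulate(config: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the synthetic study inputs.

    Products: ``ensemble.pdb`` (conformers), ``monomer_exp.dat`` and
    ``oligomer_exp.dat`` (noisy curves from a monomer conformer and from
    an oligomer of it), and ``before/``/``after/`` topography frame sets
    (bare probes vs probe–target complexes).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gen = config.generator_config()
    sim = config.simulate
    rng = np.random.default_rng(config.seed)

    base = synthetic.generate_sized_chain(gen)
    ensemble = synthetic.generate_ensemble(
        base, sim.n_conformers, gen.perturbation_scale, seed=config.seed + 1)
    paths: dict[str, Path] = {"ensemble": out / "ensemble.pdb"}
    io.write_ensemble_pdb(ensemble, paths["ensemble"])

    monomer = ensemble.models[0]
    dmax = saxs.dmax_from_model(monomer)
    oligomer = synthetic.make_oligomer(monomer, sim.oligomer_copies,
                                       np.array([dmax, 0.0, 0.0]))
    paths["monomer_curve"] = out / "monomer_exp.dat"
    paths["oligomer_curve"] = out / "oligomer_exp.dat"
    io.write_curve(synthetic.simulate_scattering(
        monomer, gen.with_seed(config.seed + 2)), paths["monomer_curve"])
    io.write_curve(synthetic.simulate_scattering(
        oligomer, gen.with_seed(config.seed + 3)), paths["oligomer_curve"])

    for phase, mean_h in (("before", sim.probe_height),
                          ("after", sim.complex_height)):
        phase_dir = out / phase
        phase_dir.mkdir(exist_ok=True)
        paths[phase] = phase_dir
        for k in range(sim.n_frames):
            frame_seed = int(rng.integers(0, 2**31 - 1))
            heights = np.abs(rng.normal(mean_h, sim.height_spread,
                                        size=sim.n_objects_per_frame))
            scene = synthetic.grid_scene(heights, gen,
                                         lateral_sigma=sim.lateral_sigma,
                                         seed=frame_seed)
            frame = synthetic.simulate_topography(
                scene, gen.with_seed(frame_seed),
                tilt=(sim.tilt, -sim.tilt), label=f"{phase}_{k:02d}")
            io.write_topography(frame, phase_dir / f"frame_{k:02d}.txt")
    _write_provenance(config, "simulate", out)
    return paths


@_timed("saxs")
def run_saxs_stage(config: PipelineConfig, curve_path: str | Path,
                   ensemble_path: str | Path, out_dir: str | Path,
                   background_path: str | Path | None = None) -> dict:
    """Reduce a curve and rank the ensemble against it.

    Order: background subtraction (if a background curve is given) →
    Guinier fit → indirect transform p(r) → per-conformer χ² ranking →
    ensemble statistics → oligomeric-state assessment. Writes
    ``fit_table.csv``, ``pr.csv`` and ``assessment.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    curve = io.read_curve(curve_path)
    log.info("curve %s: %d points, hash %s", curve_path, len(curve),
             _file_hash(Path(curve_path)))
    if background_path is not None:
        curve = saxs.subtract_background(curve, io.read_curve(background_path))
        log.info("background subtracted: %s", background_path)
    ensemble = io.read_ensemble_pdb(ensemble_path)
    log.info("ensemble %s: %d conformers, hash %s", ensemble_path,
             len(ensemble), _file_hash(Path(ensemble_path)))

    exp_rg, exp_dmax, pr = characterize_curve(curve, config.fit)
    table = rank_ensemble(ensemble, curve, s_max=config.fit.s_max,
                          use_printed_formula=config.fit.use_printed_formula)
    summary = structural_parameter_summary(ensemble)
    assessment = assess_oligomeric_state(exp_rg, exp_dmax, summary,
                                         config.fit.threshold_ratio)

    io.write_fit_table(table, out / "fit_table.csv")
    io.write_pair_distribution(pr, out / "pr.csv")
    best = table.best()
    result = {
        "exp_rg_nm": exp_rg, "exp_dmax_nm": exp_dmax,
        "pr_fit_chi2": pr.fit_chi2, "pr_alpha": pr.alpha,
        "best_model": best.label, "best_chi2": best.chi2,
        "best_rg_nm": best.rg, "best_dmax_nm": best.dmax,
        "ensemble_mean_dmax_nm": summary.mean_dmax,
        "ensemble_sd_dmax_nm": summary.sd_dmax,
        "ensemble_mean_rg_nm": summary.mean_rg,
        "ensemble_max_dmax_nm": summary.max_dmax,
        "size_ratio": assessment.ratio,
        "verdict": assessment.verdict,
    }
    (out / "assessment.json").write_text(json.dumps(result, indent=2, sort_keys=True))
    _write_provenance(config, "saxs", out,
                      {"curve": _file_hash(Path(curve_path)),
                       "ensemble": _file_hash(Path(ensemble_path))})
    log.info("best model %d (chi2 %.3g), verdict %s",
             best.label, best.chi2, assessment.verdict)
    return result


def _read_frames(directory: Path) -> list[afm.TopographyImage]:
    files = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() in (".txt", ".dat", ".tif", ".tiff"))
    if not files:
        raise DependencyError(f"no topography frames found in {directory}")
    frames = [io.read_topography(p) for p in files]
    px = {round(f.pixel_size, 9) for f in frames}
    if len(px) > 1:
        raise ConfigurationMismatchError(
            f"frames in {directory} disagree on pixel_size: {sorted(px)}")
    return frames


@_timed("afm")
def run_afm_stage(config: PipelineConfig, before_dir: str | Path,
                  after_dir: str | Path, out_dir: str | Path) -> dict:
    """Detect objects on before/after frame sets and call complex formation.

    Per frame: plane flattening → robust-threshold detection. Objects are
    aggregated across frames; counts are normalized per 400 µm²
    (N400 = N·400/(n·S_fr)) and the before/after ρ(h) shift at the
    configured height threshold decides the call.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    opts = config.afm
    results = {}
    dists = {}
    for tag, directory in (("before", Path(before_dir)), ("after", Path(after_dir))):
        frames = _read_frames(directory)
        objects = []
        for frame in frames:
            flat = afm.flatten_background(frame)
            objects.extend(afm.detect_objects(flat, k_sigma=opts.k_sigma,
                                              min_area=opts.min_area))
        counts = afm.normalize_count(len(objects), len(frames),
                                     frames[0].frame_area)
        dist = afm.height_distribution(objects, bin_width=opts.bin_width)
        dists[tag] = dist
        io.write_objects(objects, out / f"objects_{tag}.csv")
        io.write_height_distribution(dist, out / f"rho_{tag}.csv")
        results[tag] = {"n_objects": counts.n_objects,
                        "n_frames": counts.n_frames,
                        "frame_area_um2": counts.frame_area,
                        "n400": counts.n400}
        log.info("%s: %d objects on %d frames (N400 = %.2f)",
                 tag, counts.n_objects, counts.n_frames, counts.n400)

    call = afm.call_complex_formation(dists["before"], dists["after"],
                                      threshold=opts.threshold,
                                      min_shift_fraction=opts.min_shift_fraction)
    results["call"] = {"threshold_nm": call.threshold,
                       "fraction_above_before_pct": call.fraction_above_before,
                       "fraction_above_after_pct": call.fraction_above_after,
                       "verdict": call.verdict}
    (out / "afm_call.json").write_text(json.dumps(results, indent=2, sort_keys=True))
    _write_provenance(config, "afm", out)
    log.info("complex-formation call: %s", call.verdict)
    return results


@_timed("report")
def run_report(config: PipelineConfig, in_dir: str | Path,
               out_path: str | Path) -> dict:
    """Merge stage outputs into one probe report (JSON + text summary).

    Raises a dependency error naming any stage output that is missing.
    """
    in_dir = Path(in_dir)
    needed = {"assessment": in_dir / "assessment.json",
              "fit_table": in_dir / "fit_table.csv",
              "afm_call": in_dir / "afm_call.json"}
    missing = [str(p) for p in needed.values() if not p.exists()]
    if missing:
        raise DependencyError("missing stage outputs: " + ", ".join(missing))
    assessment = json.loads(needed["assessment"].read_text())
    afm_call = json.loads(needed["afm_call"].read_text())
    ranking = [line.strip() for line in
               needed["fit_table"].read_text().splitlines() if line.strip()]
    report = {
        "provenance": _provenance(config, "report",
                                  {k: _file_hash(p) for k, p in needed.items()}),
        "saxs": assessment,
        "afm": afm_call,
        "ranking_csv": ranking,
        "summary": (f"best model {assessment['best_model']} "
                    f"(chi2 = {assessment['best_chi2']:.3g}); "
                    f"oligomeric state: {assessment['verdict']}; "
                    f"AFM call: {afm_call['call']['verdict']}"),
    }
    out_path = Path(out_path)
    out_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    summary_path = out_path.with_suffix(".txt")
    summary_path.write_text(report["summary"] + "\n")
    log.info("%s", report["summary"])
    return report
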
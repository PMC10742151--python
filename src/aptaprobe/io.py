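"""File formats: PDB conformers, 3-column .dat curves, height maps,
CSV/JSON tables and reports.

Conventions:
* PDB files carry one MODEL per conformer with beads as pseudo-atoms;
  coordinates are stored in Å on disk (PDB convention) and nm in memory.
* Curves are whitespace 3-column ASCII with a ``# s[1/nm] I sigma`` header.
* Height maps are either float TIFF (with a JSON sidecar for pixel size)
  or text matrices whose header comments carry the metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from biotite.structure import Atom, array as atom_array, stack as atom_stack
from biotite.structure.io.pdb import PDBFile

from .afm import DetectedObject, HeightDistribution, TopographyImage
from .ensemble import FitTable
from .errors import DataError, InvalidUncertaintyError
from .models import ConformationEnsemble, PairDistribution, ParticleModel, ScatteringCurve

__all__ = [
    "write_ensemble_pdb",
    "read_ensemble_pdb",
    "write_curve",
    "read_curve",
    "write_topography",
    "read_topography",
    "write_fit_table",
    "write_pair_distribution",
    "write_objects",
    "write_height_distribution",
]

_NM_PER_ANGSTROM = 0.1


def _model_to_atoms(model: ParticleModel):
    atoms = []
    for i, (x, y, z) in enumerate(model.points / _NM_PER_ANGSTROM, start=1):
        atoms.append(Atom([x, y, z], atom_name="CA", res_name="BEA",
                          res_id=i, chain_id="A", element="C", hetero=True,
                          occupancy=float(model.weights[i - 1])))
    return atom_array(atoms)


def write_ensemble_pdb(ensemble: ConformationEnsemble, path: str | Path) -> None:
    """Write conformers as a multi-MODEL PDB with beads as pseudo-atoms."""
    arrays = [_model_to_atoms(m) for m in ensemble.models]
    stack = atom_stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_ensemble_pdb(path: str | Path,
                      use_occupancy_weights: bool = False) -> ConformationEnsemble:
    """Read a multi-MODEL PDB as a conformer ensemble (coordinates → nm).

    Atoms become unit-weight point scatterers unless
    ``use_occupancy_weights`` maps the occupancy column to weights.
    """
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None, extra_fields=["occupancy"])
    if stack.stack_depth() == 0:
        raise DataError(f"no MODEL records in {path}")
    models = []
    for k in range(stack.stack_depth()):
        arr = stack[k]
        weights = (np.asarray(arr.occupancy, dtype=float)
                   if use_occupancy_weights else None)
        models.append(ParticleModel(arr.coord * _NM_PER_ANGSTROM, weights,
                                    label=f"model {k + 1}"))
    return ConformationEnsemble(tuple(models))


def write_curve(curve: ScatteringCurve, path: str | Path) -> None:
    """Write a curve as 3-column ASCII: ``# s[1/nm] I sigma``."""
    np.savetxt(path, np.column_stack([curve.s, curve.I, curve.sigma]),
               header="s[1/nm] I sigma")


def read_curve(path: str | Path, label: str = "") -> ScatteringCurve:
    """Read a 3-column .dat curve; a missing σ column is an error."""
    data = np.loadtxt(path, ndmin=2)
    if data.shape[1] < 3:
        raise InvalidUncertaintyError(
            f"{path}: expected 3 columns (s, I, sigma), got {data.shape[1]} "
            f"(first data line lacks an uncertainty column)")
    return ScatteringCurve(data[:, 0], data[:, 1], data[:, 2],
                           label=label or Path(path).stem)


def write_topography(image: TopographyImage, path: str | Path) -> None:
    """Write a height map as float32 TIFF (+ JSON sidecar) or text matrix."""
    path = Path(path)
    meta = {"pixel_size_nm": image.pixel_size,
            "frame_area_um2": image.frame_area, "label": image.label}
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.heights.astype(np.float32))
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
    else:
        header = (f"pixel_size_nm: {image.pixel_size}\n"
                  f"frame_area_um2: {image.frame_area}\nlabel: {image.label}")
        np.savetxt(path, image.heights, header=header)


def read_topography(path: str | Path) -> TopographyImage:
    """Read a TIFF or text-matrix height map with its metadata."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        heights = np.asarray(tifffile.imread(path), dtype=float)
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise DataError(f"missing metadata sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
    else:
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if ":" in line:
                    key, _, value = line.lstrip("# ").partition(":")
                    meta[key.strip()] = value.strip()
        heights = np.loadtxt(path, ndmin=2)
    try:
        pixel_size = float(meta["pixel_size_nm"])
    except (KeyError, ValueError) as exc:
        raise DataError(f"{path}: missing or invalid pixel_size_nm") from exc
    return TopographyImage(heights, pixel_size,
                           label=str(meta.get("label", path.stem)))


def fit_table_frame(table: FitTable) -> pd.DataFrame:
    return pd.DataFrame(
        [{"model": row.label, "chi2": row.chi2, "c": row.c,
          "rg_nm": row.rg, "dmax_nm": row.dmax} for row in table.rows])


def write_fit_table(table: FitTable, path: str | Path) -> None:
    """Write the ranking as CSV: ``model,chi2,c,rg_nm,dmax_nm``."""
    fit_table_frame(table).to_csv(path, index=False)


def write_pair_distribution(pr: PairDistribution, path: str | Path) -> None:
    """Write p(r) as CSV with header ``r,p``."""
    pd.DataFrame({"r": pr.r, "p": pr.p}).to_csv(path, index=False)


def write_objects(objects: list[DetectedObject], path: str | Path) -> None:
    """Write an object table: ``id,row,col,height_nm,area_nm2,morphology``."""
    rows = []
    for i, obj in enumerate(objects, start=1):
        r, c = obj.centroid
        rows.append({"id": i, "row": r, "col": c, "height_nm": obj.height,
                     "area_nm2": obj.area, "morphology": obj.morphology})
    pd.DataFrame(rows, columns=["id", "row", "col", "height_nm",
                                "area_nm2", "morphology"]).to_csv(path, index=False)


def write_height_distribution(dist: HeightDistribution, path: str | Path) -> None:
    """Write ρ(h) as CSV with header ``bin_left_nm,rho_percent``."""
    pd.DataFrame({"bin_left_nm": dist.bin_edges[:-1],
                  "rho_percent": dist.rho}).to_csv(path, index=False)
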
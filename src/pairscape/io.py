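"""File formats: PDB structures and '#'-headed TSV numeric artifacts.

Every writer emits a provenance header (tool version, config hash, seed)
so each artifact records how it was produced.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .errors import ParseError
from .free_energy.grids import GridSpec, MeanForceGrid
from .free_energy.surface import FESurface
from .landscape import FEProfile
from .nucleic_geometry import AtomRecord

__all__ = [
    "read_pdb", "write_pdb", "config_hash", "write_tsv", "read_tsv",
    "write_samples_tsv", "read_samples_tsv", "write_meanforce_tsv",
    "read_meanforce_tsv", "write_fes_tsv", "read_fes_tsv",
    "write_profile_tsv", "read_profile_tsv", "write_pair_params_tsv",
]


# --------------------------------------------------------------------------
# PDB

def _guess_element(name: str) -> str:
    stripped = name.strip()
    if stripped[:1].isdigit():
        stripped = stripped[1:]
    return stripped[:1].upper()


def read_pdb(path) -> list[list[AtomRecord]]:
    """All models of a PDB file as lists of AtomRecords.

    Files without MODEL records yield a single model.  Malformed ATOM
    records raise :class:`ParseError` naming the line.
    """
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    in_model = False
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            rec = line[:6]
            if rec == "MODEL ":
                if current and not in_model:
                    models.append(current)
                current = []
                in_model = True
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError("truncated ATOM record", line=ln)
                try:
                    name = line[12:16].strip()
                    resname = line[17:20].strip()
                    chain = line[21].strip() or "A"
                    resseq = int(line[22:26])
                    xyz = (float(line[30:38]), float(line[38:46]),
                           float(line[46:54]))
                    element = line[76:78].strip() or _guess_element(name)
                except ValueError as exc:
                    raise ParseError(f"bad ATOM record: {exc}", line=ln) from None
                current.append(AtomRecord(name=name, element=element,
                                          position=np.array(xyz),
                                          residue_index=resseq,
                                          residue_name=resname,
                                          chain_id=chain))
    if current:
        models.append(current)
    if not models:
        raise ParseError(f"no atoms found in {path}")
    return models


def write_pdb(structure, path, remarks: list[str] | None = None) -> None:
    """Write one model (list of atoms) or several (list of lists)."""
    models = structure
    if models and isinstance(models[0], AtomRecord):
        models = [models]
    with open(path, "w") as fh:
        fh.write(f"REMARK   generated by pairscape {__version__}\n")
        for r in remarks or []:
            fh.write(f"REMARK   {r}\n")
        multi = len(models) > 1
        for mi, atoms in enumerate(models, start=1):
            if multi:
                fh.write(f"MODEL     {mi:4d}\n")
            for i, a in enumerate(atoms, start=1):
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                fh.write(
                    f"ATOM  {i:5d} {name:<4s} {a.residue_name:<3s} "
                    f"{a.chain_id[:1]}{a.residue_index:4d}    "
                    f"{a.position[0]:8.3f}{a.position[1]:8.3f}"
                    f"{a.position[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element:>2s}\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# --------------------------------------------------------------------------
# TSV with provenance header

def config_hash(config) -> str:
    blob = yaml.safe_dump(config, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _header_lines(meta: dict) -> list[str]:
    lines = [f"# pairscape {__version__}"]
    for k, v in meta.items():
        if isinstance(v, (dict, list, tuple)):
            v = json.dumps(v)
        lines.append(f"# {k}={v}")
    return lines


def write_tsv(path, columns: dict[str, np.ndarray],
              meta: dict | None = None) -> None:
    names = list(columns)
    data = np.column_stack([np.asarray(columns[n], dtype=float) for n in names])
    lines = _header_lines(meta or {})
    lines.append("# columns: " + "\t".join(names))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, data, delimiter="\t", fmt="%.10g")


def read_tsv(path):
    """Returns (meta dict, column-name list, 2D data array)."""
    meta, names = {}, None
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for ln, line in enumerate(lines, start=1):
        if line.startswith("#"):
            text = line[1:].strip()
            if text.startswith("columns:"):
                names = text.split(":", 1)[1].split()
            elif "=" in text:
                k, v = text.split("=", 1)
                try:
                    meta[k.strip()] = json.loads(v)
                except json.JSONDecodeError:
                    meta[k.strip()] = v
        elif line.strip():
            try:
                body.append([float(x) for x in line.split()])
            except ValueError:
                raise ParseError("non-numeric TSV row", line=ln) from None
    data = np.array(body) if body else np.empty((0, len(names or [])))
    return meta, names or [], data


# --------------------------------------------------------------------------
# domain-specific artifacts

def _spec_meta(spec: GridSpec) -> dict:
    return {"spec": {"mins": list(spec.mins), "maxs": list(spec.maxs),
                     "nbins": list(spec.nbins),
                     "periodic": list(spec.periodic)}}


def _spec_from_meta(meta) -> GridSpec:
    s = meta["spec"]
    return GridSpec(tuple(s["mins"]), tuple(s["maxs"]), tuple(s["nbins"]),
                    tuple(bool(p) for p in s["periodic"]))


def write_samples_tsv(path, values, forces, meta: dict | None = None) -> None:
    values = np.atleast_2d(np.asarray(values, dtype=float).T).T
    forces = np.atleast_2d(np.asarray(forces, dtype=float).T).T
    cols = {"frame": np.arange(len(values))}
    for d in range(values.shape[1]):
        cols[f"value{d}"] = values[:, d]
    for d in range(forces.shape[1]):
        cols[f"force{d}"] = forces[:, d]
    write_tsv(path, cols, meta)


def read_samples_tsv(path):
    meta, names, data = read_tsv(path)
    vcols = [i for i, n in enumerate(names) if n.startswith("value")]
    fcols = [i for i, n in enumerate(names) if n.startswith("force")]
    return meta, data[:, vcols], (data[:, fcols] if fcols else None)


def write_meanforce_tsv(path, grid: MeanForceGrid,
                        meta: dict | None = None) -> None:
    centers = grid.spec.center_grid()
    cols = {}
    for d in range(grid.spec.dims):
        cols[f"center{d}"] = centers[:, d]
    cols["n"] = grid.count.astype(float)
    for d in range(grid.spec.dims):
        cols[f"mean_force{d}"] = grid.mean[d]
    for d in range(grid.spec.dims):
        cols[f"m2_{d}"] = grid.m2[d]
    if grid.g is not None:
        cols["g"] = grid.g
    m = dict(meta or {})
    m.update(_spec_meta(grid.spec))
    write_tsv(path, cols, m)


def read_meanforce_tsv(path) -> MeanForceGrid:
    meta, names, data = read_tsv(path)
    spec = _spec_from_meta(meta)
    d = spec.dims
    grid = MeanForceGrid.empty(spec)
    col = {n: i for i, n in enumerate(names)}
    grid.count[:] = data[:, col["n"]].astype(np.int64)
    for k in range(d):
        grid.mean[k] = data[:, col[f"mean_force{k}"]]
        grid.m2[k] = data[:, col[f"m2_{k}"]]
    if "g" in col:
        grid.g = data[:, col["g"]]
    return grid


def write_fes_tsv(path, surface: FESurface, meta: dict | None = None) -> None:
    centers = surface.spec.center_grid()
    cols = {}
    for d in range(surface.spec.dims):
        cols[f"center{d}"] = centers[:, d]
    cols["value"] = np.where(surface.mask, np.nan, surface.value)
    cols["stderr"] = surface.stderr
    cols["mask"] = surface.mask.astype(float)
    m = dict(meta or {})
    m.update(_spec_meta(surface.spec))
    write_tsv(path, cols, m)


def read_fes_tsv(path) -> FESurface:
    meta, names, data = read_tsv(path)
    spec = _spec_from_meta(meta)
    col = {n: i for i, n in enumerate(names)}
    mask = data[:, col["mask"]] > 0.5
    value = data[:, col["value"]]
    value = np.where(mask, np.inf, value)
    return FESurface(spec, np.where(mask, 0.0, value), data[:, col["stderr"]],
                     mask)


def write_profile_tsv(path, profile: FEProfile,
                      meta: dict | None = None) -> None:
    m = dict(meta or {})
    m.update({"axis": profile.axis_name, "units": profile.units,
              "temperature": profile.temperature})
    write_tsv(path, {
        "center": profile.centers,
        "value": np.where(profile.mask, np.nan, profile.value),
        "stderr": profile.stderr,
        "mask": profile.mask.astype(float),
    }, m)


def read_profile_tsv(path) -> FEProfile:
    meta, names, data = read_tsv(path)
    col = {n: i for i, n in enumerate(names)}
    mask = data[:, col["mask"]] > 0.5
    return FEProfile(axis_name=str(meta.get("axis", "cv")),
                     units=str(meta.get("units", "")),
                     centers=data[:, col["center"]],
                     value=np.where(mask, np.nan, data[:, col["value"]]),
                     stderr=data[:, col["stderr"]], mask=mask,
                     temperature=float(meta.get("temperature", 300.0)))


def write_pair_params_tsv(path, params_list, meta: dict | None = None) -> None:
    """Per-pair parameter table: pair_index + six parameters + scheme flag."""
    rows = np.array([[i + 1, p.shear, p.stretch, p.stagger, p.buckle,
                      p.propeller, p.opening, 1.0 if p.simple else 0.0]
                     for i, p in enumerate(params_list)])
    names = ["pair_index", "shear", "stretch", "stagger", "buckle",
             "propeller", "opening", "scheme"]
    write_tsv(path, {n: rows[:, i] for i, n in enumerate(names)}, meta)
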
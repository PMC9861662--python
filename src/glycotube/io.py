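"""Coordinate readers/writers and run configuration.

PDB (angstrom) and GRO (nm) go through MDAnalysis; extended XYZ, which
carries the box in a ``Lattice="..."`` comment field, is implemented
here.  A light pre-validation pass reports the first malformed line of a
PDB/GRO file, since the criterion for a useful parse error is that it
names the offending line.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trajectory import Trajectory

PDB_PRECISION = 1e-3  # angstrom
GRO_PRECISION = 1e-3  # nm


class CoordinateFormatError(ValueError):
    """Malformed coordinate file; message carries the line number."""


def _suffix_format(path, fmt=None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = Path(path).suffix.lower().lstrip(".")
    if suffix in ("pdb", "gro", "xyz"):
        return suffix
    raise CoordinateFormatError(f"{path}: unrecognized coordinate format")


def _prevalidate_pdb(path):
    n_atoms = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if line.startswith(("ATOM", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise CoordinateFormatError(
                        f"{path}:{ln}: truncated atom record"
                    )
                try:
                    float(line[30:38]), float(line[38:46]), float(line[46:54])
                except ValueError as err:
                    raise CoordinateFormatError(
                        f"{path}:{ln}: unparseable coordinates"
                    ) from err
                n_atoms += 1
    if n_atoms == 0:
        raise CoordinateFormatError(f"{path}:1: no atom records found")


def _prevalidate_gro(path):
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 3:
        raise CoordinateFormatError(f"{path}:{len(lines)}: file too short for GRO")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as err:
        raise CoordinateFormatError(f"{path}:2: expected atom count") from err
    expected = 2 + n_atoms + 1
    if len(lines) < expected:
        raise CoordinateFormatError(
            f"{path}:{len(lines)}: file ends before atom {len(lines) - 2} of {n_atoms}"
        )
    for k in range(n_atoms):
        ln = 3 + k
        line = lines[2 + k].rstrip("\n")
        if len(line) < 44:
            raise CoordinateFormatError(f"{path}:{ln}: truncated atom line")
        try:
            float(line[20:28]), float(line[28:36]), float(line[36:44])
        except ValueError as err:
            raise CoordinateFormatError(
                f"{path}:{ln}: unparseable coordinates"
            ) from err


def write_coordinates(path, atoms: pd.DataFrame, frames, box=None, fmt=None):
    """Write one or more frames; format from the suffix unless given.

    ``frames`` is (n_atoms, 3) or (n_frames, n_atoms, 3) in angstrom;
    ``box`` orthorhombic edge lengths in angstrom.
    """
    fmt = _suffix_format(path, fmt)
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None, :, :]
    if fmt == "xyz":
        _write_xyz(path, atoms, frames, box)
        return
    import MDAnalysis as mda

    n = len(atoms)
    resids_raw = atoms["resid"].to_numpy() if "resid" in atoms else np.zeros(n, int)
    molids = atoms["molid"].to_numpy() if "molid" in atoms else np.zeros(n, int)
    # unique residue per (molid, resid) pair, in order of appearance
    keys = list(zip(molids, resids_raw))
    uniq: dict = {}
    resindex = np.empty(n, dtype=int)
    for i, k in enumerate(keys):
        resindex[i] = uniq.setdefault(k, len(uniq))
    n_res = len(uniq)
    resnames = np.empty(n_res, dtype=object)
    resid_out = np.empty(n_res, dtype=int)
    for i, ridx in enumerate(resindex):
        resnames[ridx] = atoms["resname"].iloc[i] if "resname" in atoms else "MOL"
        resid_out[ridx] = ridx + 1

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, n_residues=n_res, atom_resindex=resindex,
                               trajectory=True)
        u.add_TopologyAttr("names", atoms["name"].astype(str).tolist())
        u.add_TopologyAttr("elements", atoms["element"].astype(str).tolist())
        u.add_TopologyAttr("resnames", resnames.tolist())
        u.add_TopologyAttr("resids", resid_out.tolist())
        if box is not None:
            u.dimensions = [box[0], box[1], box[2], 90.0, 90.0, 90.0]
        if len(frames) == 1:
            u.atoms.positions = frames[0]
            u.atoms.write(str(path))
        else:
            with mda.Writer(str(path), n, multiframe=True) as w:
                for f in frames:
                    u.atoms.positions = f
                    w.write(u.atoms)


def read_coordinates(path, fmt=None):
    """Read frames and atom metadata from PDB, GRO or extended XYZ.

    Returns (frames (n_frames, n_atoms, 3) angstrom, atoms DataFrame,
    box or None).  Malformed files raise :class:`CoordinateFormatError`
    naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _suffix_format(path, fmt)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "pdb":
        _prevalidate_pdb(path)
    elif fmt == "gro":
        _prevalidate_gro(path)
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        frames = np.array([u.atoms.positions.copy().astype(float)
                           for _ in u.trajectory])
        names = [str(x) for x in getattr(u.atoms, "names", [""] * len(u.atoms))]
        try:
            elements = [str(x) for x in u.atoms.elements]
        except AttributeError:
            elements = [n[:1] for n in names]
        try:
            resnames = [str(x) for x in u.atoms.resnames]
            resids = [int(x) for x in u.atoms.resids]
        except AttributeError:
            resnames = ["MOL"] * len(u.atoms)
            resids = [1] * len(u.atoms)
        box = None
        if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
            box = np.array(u.dimensions[:3], dtype=float)
    atoms = pd.DataFrame(
        dict(name=names, element=elements, resname=resnames, resid=resids)
    )
    return frames, atoms, box


def _write_xyz(path, atoms: pd.DataFrame, frames, box):
    elements = atoms["element"].astype(str).tolist()
    with open(path, "w") as fh:
        for f in frames:
            fh.write(f"{len(elements)}\n")
            if box is not None:
                lat = (f'Lattice="{box[0]:.6f} 0.0 0.0 0.0 {box[1]:.6f} 0.0 '
                       f'0.0 0.0 {box[2]:.6f}" ')
            else:
                lat = ""
            fh.write(f"{lat}Properties=species:S:1:pos:R:3\n")
            for el, (x, y, z) in zip(elements, f):
                fh.write(f"{el:<2s} {x:15.8f} {y:15.8f} {z:15.8f}\n")


def _read_xyz(path):
    frames = []
    elements = None
    box = None
    with open(path) as fh:
        lines = fh.readlines()
    ln = 0
    while ln < len(lines):
        if not lines[ln].strip():
            ln += 1
            continue
        try:
            n = int(lines[ln].strip())
        except ValueError as err:
            raise CoordinateFormatError(
                f"{path}:{ln + 1}: expected atom count"
            ) from err
        comment = lines[ln + 1] if ln + 1 < len(lines) else ""
        if 'Lattice="' in comment:
            vals = comment.split('Lattice="')[1].split('"')[0].split()
            m = np.array([float(v) for v in vals]).reshape(3, 3)
            box = np.diag(m)
        coords = []
        els = []
        for k in range(n):
            idx = ln + 2 + k
            if idx >= len(lines):
                raise CoordinateFormatError(
                    f"{path}:{len(lines)}: file ends before atom {k + 1} of {n}"
                )
            parts = lines[idx].split()
            if len(parts) < 4:
                raise CoordinateFormatError(f"{path}:{idx + 1}: short atom line")
            els.append(parts[0])
            try:
                coords.append([float(p) for p in parts[1:4]])
            except ValueError as err:
                raise CoordinateFormatError(
                    f"{path}:{idx + 1}: unparseable coordinates"
                ) from err
        if elements is None:
            elements = els
        frames.append(coords)
        ln += 2 + n
    if not frames:
        raise CoordinateFormatError(f"{path}:1: empty file")
    atoms = pd.DataFrame(
        dict(name=elements, element=elements,
             resname=["MOL"] * len(elements), resid=[1] * len(elements))
    )
    return np.array(frames, dtype=float), atoms, box


def write_trajectory(path, traj: Trajectory, fmt=None):
    write_coordinates(path, traj.atoms, traj.positions, traj.box, fmt)
    sidecar = Path(str(path) + ".times.csv")
    pd.DataFrame(dict(frame=np.arange(traj.n_frames), time_ps=traj.times)).to_csv(
        sidecar, index=False
    )


def write_topology(path, model):
    """Plain-text bonded-topology table for an :class:`~glycotube.fcnt.FcntModel`.

    Sections: [atoms] index name element charge sp3; [bonds] i j periodic;
    optional [angles] and [dihedrals] with their periodic flags.
    """
    with open(path, "w") as fh:
        fh.write("[atoms]\n# index name element charge_e sp3\n")
        for i in range(model.n_atoms):
            fh.write(
                f"{i:6d} {model.names[i]:<6s} {model.elements[i]:<2s} "
                f"{model.charges[i]: 12.8f} {int(model.sp3[i])}\n"
            )
        fh.write("\n[bonds]\n# i j periodic\n")
        for (i, j), per in zip(model.bonds, model.bond_periodic):
            fh.write(f"{i:6d} {j:6d} {int(per)}\n")
        if model.angles is not None:
            fh.write("\n[angles]\n# i j k periodic\n")
            for (i, j, k), per in zip(model.angles, model.angle_periodic):
                fh.write(f"{i:6d} {j:6d} {k:6d} {int(per)}\n")
        if model.dihedrals is not None:
            fh.write("\n[dihedrals]\n# i j k l periodic\n")
            for (i, j, k, l), per in zip(model.dihedrals, model.dihedral_periodic):
                fh.write(f"{i:6d} {j:6d} {k:6d} {l:6d} {int(per)}\n")


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Seeded end-to-end pipeline configuration; YAML round-trippable."""

    chirality_n: int = 17
    cells: int = 14
    group_kind: str = "carboxylate"
    coverage: float = 0.02
    glycan_kind: str = "GlcNAc"  # residue code or HA / Ch
    copies: int = 5
    box_xy: float = 55.0
    ionic_strength: float = 0.15
    n_frames: int = 200
    facing: str = "A"
    build_seed: int = 1
    assemble_seed: int = 2
    trajectory_seed: int = 3
    output_dir: str = "glycotube_run"
    log_level: str = "INFO"
    analyses: tuple = ("rdf", "orientation", "detach", "hbond", "conformation")

    def to_yaml(self, path):
        data = dataclasses.asdict(self)
        data["analyses"] = list(data["analyses"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "analyses" in data:
            data["analyses"] = tuple(data["analyses"])
        return cls(**data)
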
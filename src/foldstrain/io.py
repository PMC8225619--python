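"""Ensemble persistence and standard-format I/O.

Structures are written as single-chain PDB files (chain A, 1-based
numbering) with the coarse atom set N, H, CA, C, O and the side-chain
pseudo-atom as CB; every residue is written as ALA for downstream-tool
compatibility.  An ensemble directory holds one PDB per member plus a
JSON manifest with seeds, build reports and configuration.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from . import geometry as geo
from .backbone import BackboneStructure
from .blueprint import Blueprint
from .sampler import BuildReport, Ensemble

_ELEMENTS = {"N": "N", "H": "H", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def structure_to_atom_array(s: BackboneStructure) -> struc.AtomArray:
    n = len(s)
    na = len(geo.ATOM_ORDER)
    arr = struc.AtomArray(n * na)
    arr.coord = s.coords.reshape(-1, 3).astype(np.float32)
    arr.chain_id = np.full(n * na, "A")
    arr.res_id = np.repeat(np.arange(1, n + 1), na)
    arr.res_name = np.full(n * na, "ALA")
    arr.atom_name = np.tile(np.array(geo.ATOM_ORDER), n)
    arr.element = np.tile(np.array([_ELEMENTS[a] for a in geo.ATOM_ORDER]),
                          n)
    arr.hetero = np.zeros(n * na, dtype=bool)
    return arr


def write_structure(s: BackboneStructure, path) -> None:
    pdb = PDBFile()
    pdb.set_structure(structure_to_atom_array(s))
    pdb.write(str(path))


def read_structure(path) -> BackboneStructure:
    """Read one coarse-model PDB written by :func:`write_structure`."""
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    res_ids = np.unique(arr.res_id)
    n = len(res_ids)
    coords = np.zeros((n, len(geo.ATOM_ORDER), 3))
    for k, rid in enumerate(res_ids):
        mask = arr.res_id == rid
        names = arr.atom_name[mask]
        xyz = arr.coord[mask]
        for a, atom in enumerate(geo.ATOM_ORDER):
            hits = np.nonzero(names == atom)[0]
            if len(hits) == 0:
                raise ValueError(
                    f"{path}: residue {rid} is missing atom {atom}")
            coords[k, a] = xyz[hits[0]]
    torsions = geo.measure_torsions(coords)
    return BackboneStructure(torsions, coords)


def write_ensemble(ensemble: Ensemble, path) -> None:
    """Write an ensemble directory: member PDBs plus manifest.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for k, member in enumerate(ensemble):
        write_structure(member, path / f"model_{k:04d}.pdb")
    manifest = ensemble.manifest()
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)


def read_ensemble(path, blueprint: Blueprint | None = None) -> Ensemble:
    """Read an ensemble directory written by :func:`write_ensemble` (or
    any directory of coarse-model PDB files, for metrics-only use)."""
    import warnings

    path = Path(path)
    members = []
    for pdb_path in sorted(path.glob("*.pdb")):
        members.append(read_structure(pdb_path))
    if not members:
        warnings.warn(f"{path}: no PDB files found, empty ensemble",
                      stacklevel=2)
    lengths = {len(m) for m in members}
    if len(lengths) > 1:
        raise ValueError(f"{path}: members differ in length: "
                         f"{sorted(lengths)}")
    seed = None
    manifest_path = path / "manifest.json"
    if manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        seed = manifest.get("seed")
        for m, prov in zip(members, manifest.get("members", [])):
            m.provenance.update(prov if isinstance(prov, dict) else {})
    ens = Ensemble(blueprint, members, seed=seed)
    return ens


def write_metrics(metrics, path_prefix) -> None:
    """Write a metrics JSON summary and per-bond / per-member TSVs."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}_summary.json", "w") as fh:
        json.dump(metrics.summary(), fh, indent=1)
    with open(f"{prefix}_bonds.tsv", "w") as fh:
        fh.write("bond\tprobability\n")
        for k, p in enumerate(metrics.bond_probabilities, start=1):
            fh.write(f"{k}\t{'' if np.isnan(p) else round(float(p), 4)}\n")
    with open(f"{prefix}_members.tsv", "w") as fh:
        fh.write("member\tterminal_helix_distance\tbend_angle\n")
        for k, (d, b) in enumerate(zip(metrics.distances,
                                       metrics.bend_angles)):
            fh.write(f"{k}\t{d:.2f}\t{b:.2f}\n")
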
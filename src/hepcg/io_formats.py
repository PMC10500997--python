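"""Readers/writers: PDB trace models, coordinate tables, configs, run logs.

The trace dialect writes one pseudo-atom per glycosidic-oxygen anchor (atom
name ``O4``) and one per site center (atom name ``SIT``), with 1-based
residue numbering and alternating IDS/SGN residue names; trajectories become
standard multi-MODEL PDB files.  Coordinates are Å everywhere; internal
arrays are 0-based, PDB numbering 1-based.
"""

from __future__ import annotations

import json
import subprocess
import time

import numpy as np
import pandas as pd
import yaml
from biotite.structure import AtomArray, stack
from biotite.structure.io.pdb import PDBFile

from .dynamics import RunConfig, Trajectory
from .errors import FormatError
from .params import CGParameters
from .topology import HeparinChain, chain_from_anchors

__all__ = [
    "write_trace_pdb",
    "read_trace_pdb",
    "read_trace_anchors",
    "config_to_yaml",
    "config_from_yaml",
    "write_trajectory_table",
    "read_trajectory_table",
    "write_run_log",
]

_RES_NAMES = ("IDS", "SGN")  # IdoA2S / GlcNS6S


def _frame_to_atom_array(anchors: np.ndarray) -> AtomArray:
    anchors = np.asarray(anchors, float)
    if not np.all(np.isfinite(anchors)):
        raise FormatError("non-finite coordinates cannot be written")
    dp = anchors.shape[0] - 1
    sites = 0.5 * (anchors[:-1] + anchors[1:])
    n_atoms = (dp + 1) + dp
    arr = AtomArray(n_atoms)
    coords = np.empty((n_atoms, 3))
    idx = 0
    for k in range(dp):
        for name, xyz, element in (("O4", anchors[k], "O"), ("SIT", sites[k], "C")):
            arr.atom_name[idx] = name
            arr.res_id[idx] = k + 1
            arr.res_name[idx] = _RES_NAMES[k % 2]
            arr.element[idx] = element
            arr.chain_id[idx] = "A"
            arr.hetero[idx] = True
            coords[idx] = xyz
            idx += 1
    arr.atom_name[idx] = "O4"
    arr.res_id[idx] = dp + 1
    arr.res_name[idx] = _RES_NAMES[dp % 2]
    arr.element[idx] = "O"
    arr.chain_id[idx] = "A"
    arr.hetero[idx] = True
    coords[idx] = anchors[dp]
    arr.coord = coords
    return arr


def write_trace_pdb(obj, path) -> None:
    """Write a chain, trajectory or anchor array (stack) as a trace PDB.

    One MODEL block per frame for trajectories; fixed-width PDB records via
    biotite, re-readable by standard viewers.
    """
    if isinstance(obj, HeparinChain):
        frames = [obj.anchors]
    elif isinstance(obj, Trajectory):
        frames = list(obj.frames)
    else:
        arr = np.asarray(obj, float)
        frames = [arr] if arr.ndim == 2 else list(arr)
    models = [_frame_to_atom_array(f) for f in frames]
    structure = models[0] if len(models) == 1 else stack(models)
    pdb = PDBFile()
    pdb.set_structure(structure)
    pdb.write(str(path))


def read_trace_anchors(path) -> list:
    """Anchor coordinate arrays (one per MODEL) from a trace or all-atom PDB.

    Anchors are the ``O4`` atoms in file order; any other atoms (full
    all-atom files included) are ignored.
    """
    try:
        pdb = PDBFile.read(str(path))
        structure = pdb.get_structure()
    except Exception as exc:
        raise FormatError(f"unreadable PDB file {path}: {exc}") from exc
    if structure.array_length() == 0:
        raise FormatError(f"no atom records in {path}")
    mask = structure.atom_name == "O4"
    if not mask.any():
        raise FormatError(
            f"no O4 anchor atoms found in {path}; "
            "expected a trace or all-atom heparin structure"
        )
    return [np.asarray(coords[mask], float) for coords in structure.coord]


def read_trace_pdb(path, params: CGParameters | None = None):
    """Chain(s) from a trace PDB; a single chain if the file has one MODEL,
    otherwise a list of chains (one per MODEL)."""
    params = params or CGParameters()
    chains = [chain_from_anchors(a, params) for a in read_trace_anchors(path)]
    return chains[0] if len(chains) == 1 else chains


# ----------------------------------------------------------------------
# configs / tables / logs
# ----------------------------------------------------------------------

def config_to_yaml(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_from_yaml(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"malformed run configuration in {path}")
    return RunConfig.from_dict(data)


def write_trajectory_table(traj: Trajectory, path) -> None:
    """Compact long-format coordinate table (frame, time_fs, anchor, x, y, z)."""
    nf, na, _ = traj.frames.shape
    df = pd.DataFrame(
        {
            "frame": np.repeat(np.arange(nf), na),
            "time_fs": np.repeat(traj.times, na),
            "anchor": np.tile(np.arange(na), nf),
            "x": traj.frames[:, :, 0].ravel(),
            "y": traj.frames[:, :, 1].ravel(),
            "z": traj.frames[:, :, 2].ravel(),
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_trajectory_table(path) -> np.ndarray:
    """Frame stack (n_frames, n_anchors, 3) from a coordinate table."""
    df = pd.read_csv(path)
    nf = df["frame"].nunique()
    na = df["anchor"].nunique()
    return df[["x", "y", "z"]].to_numpy().reshape(nf, na, 3)


def write_run_log(path, config: RunConfig, params: CGParameters, note: str = "") -> None:
    """Structured run log: seed, parameter hash, package/git provenance."""
    try:
        describe = subprocess.run(
            ["git", "describe", "--always", "--dirty"],
            capture_output=True, text=True, timeout=5,
        ).stdout.strip() or None
    except Exception:
        describe = None
    try:
        from importlib.metadata import version

        pkg_version = version("hepcg")
    except Exception:
        pkg_version = None
    log = {
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "seed": config.seed,
        "config": config.to_dict(),
        "param_hash": params.param_hash(),
        "package_version": pkg_version,
        "git_describe": describe,
        "note": note,
    }
    with open(path, "w") as fh:
        json.dump(log, fh, indent=2)
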
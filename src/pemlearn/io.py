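"""File formats: multi-frame XYZ, record tables (CSV/HDF5), PEM and model stores.

The record table has one row per (geometry, state): ``geometry_id``,
``state``, ``energy_ev`` and flattened multipole components ``dip_{x,y,z}``,
``quad_{xx,...,zz}`` (9, row-major), ``oct_{xxx,...,zzz}`` (27).  Energies are
stored in eV; a ``hartree`` flag converts on read.  The same columns appear
as an HDF5 table; round trips are exact.
"""

from __future__ import annotations

import itertools
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .constants import HARTREE_TO_EV
from .diabatization import PEM, AdiabaticRecord
from .krr import KernelWorkspace, KRRModel
from .representations import Geometry

_AXES = "xyz"
DIP_COLS = [f"dip_{a}" for a in _AXES]
QUAD_COLS = [f"quad_{a}{b}" for a, b in itertools.product(_AXES, repeat=2)]
OCT_COLS = [f"oct_{a}{b}{c}" for a, b, c in itertools.product(_AXES, repeat=3)]


# -- XYZ ---------------------------------------------------------------------


def read_xyz(path) -> list[Geometry]:
    """Read a (multi-frame) standard XYZ file: count line, comment, records."""
    lines = Path(path).read_text().splitlines()
    geometries = []
    k = 0
    frame = 0
    while k < len(lines):
        if not lines[k].strip():
            k += 1
            continue
        n = int(lines[k].strip())
        block = lines[k + 2 : k + 2 + n]
        labels, coords = [], []
        for line in block:
            parts = line.split()
            labels.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        geometries.append(Geometry(atom_labels=tuple(labels), coords=np.array(coords), id=frame))
        frame += 1
        k += 2 + n
    return geometries


def write_xyz(path, geometries: list[Geometry], comment: str = "") -> None:
    with open(path, "w") as fh:
        for geom in geometries:
            fh.write(f"{geom.n_atoms}\n{comment or f'frame {geom.id}'}\n")
            for label, (x, y, z) in zip(geom.atom_labels, geom.coords):
                fh.write(f"{label} {x:.12f} {y:.12f} {z:.12f}\n")


# -- adiabatic record tables -------------------------------------------------


def records_to_frame(records: list[AdiabaticRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        for s in range(rec.n_states):
            row = {"geometry_id": rec.geometry_id, "state": s, "energy_ev": rec.energies[s]}
            row.update(zip(DIP_COLS, rec.dipoles[s]))
            if rec.quadrupoles is not None:
                row.update(zip(QUAD_COLS, rec.quadrupoles[s].ravel()))
            if rec.octupoles is not None:
                row.update(zip(OCT_COLS, rec.octupoles[s].ravel()))
            rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(
    df: pd.DataFrame, manifold: tuple[int, int] | None = None, hartree: bool = False
) -> list[AdiabaticRecord]:
    """Rebuild records; ``manifold=(lo, hi)`` keeps states lo..hi inclusive.

    Raises if geometries carry inconsistent state counts within the manifold.
    """
    records = []
    state_counts = {}
    for gid, group in df.groupby("geometry_id"):
        group = group.sort_values("state")
        if manifold is not None:
            group = group[(group["state"] >= manifold[0]) & (group["state"] <= manifold[1])]
        state_counts[gid] = len(group)
        energies = group["energy_ev"].to_numpy(dtype=float)
        if hartree:
            energies = energies * HARTREE_TO_EV
        dip = group[DIP_COLS].to_numpy(dtype=float)
        quad = octu = None
        if set(QUAD_COLS) <= set(group.columns) and group[QUAD_COLS].notna().all().all():
            quad = group[QUAD_COLS].to_numpy(dtype=float).reshape(-1, 3, 3)
        if set(OCT_COLS) <= set(group.columns) and group[OCT_COLS].notna().all().all():
            octu = group[OCT_COLS].to_numpy(dtype=float).reshape(-1, 3, 3, 3)
        records.append(
            AdiabaticRecord(
                energies=energies,
                dipoles=dip,
                quadrupoles=quad,
                octupoles=octu,
                geometry_id=int(gid),
            )
        )
    if len(set(state_counts.values())) > 1:
        from collections import Counter

        modal = Counter(state_counts.values()).most_common(1)[0][0]
        bad = sorted(g for g, c in state_counts.items() if c != modal)
        raise ValueError(f"inconsistent state counts across geometries: {bad}")
    return records


def write_records_csv(path, records: list[AdiabaticRecord]) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path, manifold=None, hartree: bool = False) -> list[AdiabaticRecord]:
    return frame_to_records(pd.read_csv(path), manifold=manifold, hartree=hartree)


def write_records_hdf5(path, records: list[AdiabaticRecord]) -> None:
    df = records_to_frame(records)
    with h5py.File(path, "w") as fh:
        grp = fh.create_group("records")
        for col in df.columns:
            grp.create_dataset(col, data=df[col].to_numpy())


def read_records_hdf5(path, manifold=None, hartree: bool = False) -> list[AdiabaticRecord]:
    with h5py.File(path, "r") as fh:
        grp = fh["records"]
        df = pd.DataFrame({col: grp[col][...] for col in grp})
    return frame_to_records(df, manifold=manifold, hartree=hartree)


def read_dataset(
    xyz_path,
    records_path,
    fmt: str = "csv",
    manifold: tuple[int, int] | None = None,
    hartree: bool = False,
) -> tuple[list[Geometry], list[AdiabaticRecord]]:
    """Load a geometry ensemble (multi-frame XYZ) with its record table.

    Checks that geometry counts agree and that all geometries share the
    chosen manifold's state count (energies converted to eV).
    """
    geometries = read_xyz(xyz_path)
    reader = read_records_csv if fmt == "csv" else read_records_hdf5
    records = reader(records_path, manifold=manifold, hartree=hartree)
    if len(geometries) != len(records):
        raise ValueError(
            f"{len(geometries)} geometries but {len(records)} record groups"
        )
    return geometries, records


# -- PEM and model stores ----------------------------------------------------


def write_pems(path, pems: list[PEM]) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("U", data=np.array([p.U for p in pems]))
        fh.create_dataset("T", data=np.array([p.T for p in pems]))
        fh.create_dataset("geometry_id", data=np.array([p.geometry_id for p in pems]))
        fh.create_dataset("degenerate", data=np.array([p.degenerate for p in pems]))


def read_pems(path) -> list[PEM]:
    with h5py.File(path, "r") as fh:
        U, T = fh["U"][...], fh["T"][...]
        gids, deg = fh["geometry_id"][...], fh["degenerate"][...]
    return [
        PEM(U=U[k], T=T[k], geometry_id=int(gids[k]), degenerate=bool(deg[k]))
        for k in range(len(U))
    ]


def write_model(path, model: KRRModel) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("X", data=model.workspace.X)
        fh.create_dataset("alpha", data=model.alpha)
        fh.attrs["sigma"] = model.sigma
        fh.attrs["lambda"] = model.lam
        fh.attrs["y_mean"] = model.y_mean
        fh.attrs["target_label"] = model.target_label
        fh.attrs["kernel"] = "gaussian exp(-d^2/(2 sigma^2))"


def read_model(path) -> KRRModel:
    with h5py.File(path, "r") as fh:
        ws = KernelWorkspace(fh["X"][...], float(fh.attrs["sigma"]), float(fh.attrs["lambda"]))
        return KRRModel(
            workspace=ws,
            alpha=fh["alpha"][...],
            y_mean=float(fh.attrs["y_mean"]),
            target_label=str(fh.attrs["target_label"]),
        )


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
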
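"""File I/O: scattering CSV tables, PDB coordinate files, tidy outputs.

PDB parsing is delegated to Biopython (``Bio.PDB``); multi-model files
become frame sequences and disordered atoms resolve to the highest-occupancy
altloc (ties keep the first conformer, i.e. 'A').  Writing uses plain
fixed-width ATOM records — sufficient for the Cα/pseudo-lipid frames this
package produces.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ParseError
from .geometry import Frame
from .saxs import ScatteringCurve

__all__ = [
    "read_scattering_csv",
    "write_profile_csv",
    "read_pdb",
    "write_pdb",
    "write_json",
    "events_to_csv",
]


def read_scattering_csv(path, q_unit: str = "A^-1", label: str | None = None) -> ScatteringCurve:
    """Read a q/intensity[/sigma] table (CSV or TSV, with header).

    ``q_unit`` may be ``"A^-1"`` (default) or ``"nm^-1"`` (converted by
    x 0.1).  Column names are matched case-insensitively to q, intensity
    (or I), and sigma (or sigma_I, err).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower().strip(): c for c in df.columns}
    qcol = cols.get("q")
    icol = cols.get("intensity") or cols.get("i")
    scol = cols.get("sigma") or cols.get("sigma_i") or cols.get("err")
    if qcol is None or icol is None:
        raise ParseError(f"{path}: need columns q and intensity, found {list(df.columns)}")
    q = df[qcol].to_numpy(dtype=float)
    if q_unit == "nm^-1":
        q = q * 0.1
    elif q_unit != "A^-1":
        raise InvalidParameterError(f"unknown q unit {q_unit!r}")
    sigma = df[scol].to_numpy(dtype=float) if scol is not None else None
    return ScatteringCurve(
        q, df[icol].to_numpy(dtype=float), sigma, label=label or path.stem
    )


def write_profile_csv(path, z, rho) -> None:
    """Two-column electron-density profile: z (A), rho (arbitrary units)."""
    pd.DataFrame({"z": np.asarray(z), "rho": np.asarray(rho)}).to_csv(path, index=False)


def read_pdb(path) -> list[Frame]:
    """Parse a (multi-model) PDB file into a list of :class:`Frame`.

    Altloc policy: Biopython's highest-occupancy conformer (first on ties).
    Malformed files raise :class:`ParseError`.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionException

    parser = PDBParser(QUIET=True, PERMISSIVE=False)
    try:
        structure = parser.get_structure(Path(path).stem, str(path))
    except (PDBConstructionException, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from None
    frames = []
    for model in structure:
        names, resnames, resids, chains, xyz = [], [], [], [], []
        for chain in model:
            for residue in chain:
                for atom in residue:
                    # disordered atoms expose the highest-occupancy child
                    names.append(atom.get_name())
                    resnames.append(residue.get_resname().strip())
                    resids.append(residue.get_id()[1])
                    chains.append(chain.get_id())
                    xyz.append(atom.get_coord())
        if names:
            frames.append(
                Frame(
                    names=np.array(names, dtype=object),
                    resnames=np.array(resnames, dtype=object),
                    resids=np.array(resids),
                    chains=np.array(chains, dtype=object),
                    xyz=np.asarray(xyz, dtype=float),
                )
            )
    if not frames:
        raise ParseError(f"{path}: no atoms found")
    return frames


def write_pdb(path, frames) -> None:
    """Write one or more frames as (multi-model) fixed-width PDB ATOM records."""
    if isinstance(frames, Frame):
        frames = [frames]
    with open(path, "w") as fh:
        multi = len(frames) > 1
        for mi, frame in enumerate(frames, 1):
            if multi:
                fh.write(f"MODEL     {mi:4d}\n")
            for i in range(len(frame)):
                name = str(frame.names[i])
                pad = name if len(name) >= 4 else f" {name:<3s}"
                x, y, z = frame.xyz[i]
                fh.write(
                    f"ATOM  {(i + 1) % 100000:5d} {pad}{'':1s}{str(frame.resnames[i])[:3]:>3s} "
                    f"{str(frame.chains[i])[:1]:1s}{int(frame.resids[i]):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_json(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def events_to_csv(path, ideal) -> None:
    """Idealized events as CSV (state, start_ms, duration_ms)."""
    start = 0.0
    rows = []
    for state, dur in ideal.events:
        rows.append({"state": state, "start_ms": start, "duration_ms": dur})
        start += dur
    pd.DataFrame(rows).to_csv(path, index=False)
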
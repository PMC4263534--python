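"""Stress tables and B-factor-annotated PDB structure files.

The stress table is delimited text with one row per (frame, atom): time,
atom index, residue id, the per-term stresses, the total, and the hydrostatic
pressure, all in kbar.  The PDB writer places a per-atom or per-residue value
in the B-factor column (columns 61–66, %6.2f, clamped to ±999.99) of standard
ATOM records built from reference coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_io import ForceFieldTopology
from .stress_engine import TrajectoryStress

__all__ = ["write_stress_table", "write_pdb_bfactor", "stress_dataframe",
           "OutputManifest"]

logger = logging.getLogger("atomstress")

_BFACTOR_LIMIT = 999.99


@dataclass
class OutputManifest:
    prefix: str
    stress_table: Path | None = None
    pdb_files: dict[str, Path] = field(default_factory=dict)
    split_tables: dict[str, Path] = field(default_factory=dict)

    def all_paths(self) -> list[Path]:
        paths = [self.stress_table] if self.stress_table else []
        return paths + list(self.pdb_files.values()) + list(self.split_tables.values())


def stress_dataframe(stress: TrajectoryStress,
                     topology: ForceFieldTopology) -> pd.DataFrame:
    """Long-form table: one row per (frame, atom), stresses in kbar."""
    n_frames, n_sel = next(iter(stress.terms.values())).shape
    resids = topology.residue_ids[stress.atom_indices]
    data = {
        "time_ps": np.repeat(stress.times, n_sel),
        "atom_index": np.tile(stress.atom_indices, n_frames),
        "residue_id": np.tile(resids, n_frames),
    }
    for term, arr in stress.terms.items():
        data[f"{term}_kbar"] = arr.ravel()
    total = stress.total
    data["total_kbar"] = total.ravel()
    data["hydrostatic_pressure_kbar"] = (-total).ravel()
    return pd.DataFrame(data)


def write_stress_table(stress: TrajectoryStress, topology: ForceFieldTopology,
                       path) -> int:
    """Write the per-(frame, atom) stress table; returns the row count."""
    df = stress_dataframe(stress, topology)
    if df.empty:
        raise ValueError("empty selection: no stress rows to write")
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    return len(df)


def write_pdb_bfactor(topology: ForceFieldTopology, coordinates: np.ndarray,
                      values: dict[int, float], mode: str, path) -> int:
    """Write ATOM records with `values` (kbar) in the B-factor column.

    ``mode="atom"`` keys values by atom index; ``mode="residue"`` keys by
    residue id and stamps the residue value on every member atom.
    Coordinates are in nm and written in Å.  Returns the atom count written.
    """
    if mode not in ("atom", "residue"):
        raise ValueError(f"mode must be 'atom' or 'residue', got {mode!r}")
    lines = []
    clamped = 0
    for a in topology.atoms:
        key = a.index if mode == "atom" else a.residue_id
        if key not in values:
            raise KeyError(f"no value for atom {a.index} (key {key}, mode {mode})")
        v = float(values[key])
        if abs(v) > _BFACTOR_LIMIT:
            clamped += 1
            v = np.sign(v) * _BFACTOR_LIMIT
        x, y, z = coordinates[a.index] * 10.0
        element = "".join(c for c in a.name if c.isalpha())[:1].upper() or "C"
        lines.append(
            f"ATOM  {a.index + 1:>5d} {a.name[:4]:<4s} {a.residue_name[:3]:>3s} A"
            f"{a.residue_id % 10000:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}"
            f"{v:6.2f}          {element:>2s}"
        )
    if clamped:
        logger.warning("%d B-factor values clamped to ±%.2f in %s",
                       clamped, _BFACTOR_LIMIT, path)
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
    return len(topology.atoms)
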
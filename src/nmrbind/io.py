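"""Tables, coordinate models and run configuration.

CSV tables are UTF-8 with a header row; columns are validated against a
schema (name -> dtype) and non-numeric cells are reported with their row
number (locale decimal commas therefore fail loudly rather than silently
reading as text).  Coordinates are read from PDB files through gemmi:
first model only, alternate location 'A', author residue numbering
throughout.  Run configurations are YAML mappings validated against the
known keys before any computation starts.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import gemmi
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "read_table",
    "write_table",
    "StructureModel",
    "read_structure",
    "RunConfig",
    "load_config",
    "provenance",
    "UnsupportedFormatError",
]


class UnsupportedFormatError(ValueError):
    """Input file is not in a supported format."""


def read_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Read a CSV against a column schema; errors carry row numbers."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    out = {}
    for col, typ in schema.items():
        if typ in (float, int):
            conv = pd.to_numeric(df[col], errors="coerce")
            bad = conv.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad)[0]) + 2  # 1-based incl. header
                raise ValueError(
                    f"{path.name}: non-numeric value {df[col][bad].iloc[0]!r} "
                    f"in column {col!r} at line {row} (decimal commas are not "
                    "accepted; use '.')"
                )
            out[col] = conv.astype(typ) if typ is int else conv
        else:
            out[col] = df[col]
    return pd.DataFrame(out)


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


@dataclass
class StructureModel:
    """Atomic coordinates exposing internuclear vectors for RDC fitting.

    First model only; altloc '' or 'A'; residues keyed by author number.
    """

    _atoms: dict[tuple[int, str], np.ndarray]
    name: str = "model"

    @classmethod
    def from_gemmi(cls, structure: gemmi.Structure, name: str = "model"):
        atoms: dict[tuple[int, str], np.ndarray] = {}
        if len(structure) == 0:
            raise ValueError("structure contains no model")
        model = structure[0]
        for chain in model:
            for res in chain:
                seqid = res.seqid.num
                for atom in res:
                    if atom.altloc not in ("", "A"):
                        continue
                    key = (seqid, atom.name)
                    atoms.setdefault(
                        key, np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                    )
        return cls(_atoms=atoms, name=name)

    def position(self, residue_id: int, atom: str) -> np.ndarray:
        try:
            return self._atoms[(residue_id, atom)]
        except KeyError:
            raise KeyError(f"atom {atom!r} of residue {residue_id} not in model")

    def internuclear_vector(
        self, residue_id: int, coupling_type: str
    ) -> tuple[np.ndarray, float]:
        """Unit vector and distance (A) for one coupling.

        "NH": N(i) -> amide H(i).  "CH": carbonyl C(i-1) -> amide H(i),
        the two-bond pair read out through the carbonyl.
        """
        if coupling_type == "NH":
            a = self.position(residue_id, "N")
            b = self._h_position(residue_id)
        elif coupling_type == "CH":
            a = self.position(residue_id - 1, "C")
            b = self._h_position(residue_id)
        else:
            raise ValueError(f"unknown coupling type {coupling_type!r}")
        d = b - a
        r = float(np.linalg.norm(d))
        if r == 0.0:
            raise ValueError(f"coincident atoms for residue {residue_id}")
        return d / r, r

    def _h_position(self, residue_id: int) -> np.ndarray:
        for name in ("H", "HN"):
            if (residue_id, name) in self._atoms:
                return self._atoms[(residue_id, name)]
        raise KeyError(f"atom 'H' of residue {residue_id} not in model")

    @property
    def residues(self) -> set[int]:
        return {rid for rid, _ in self._atoms}


def read_structure(path: str | Path) -> StructureModel:
    """Read a PDB file (first model, altloc A).  mmCIF is rejected
    explicitly — export to PDB first."""
    path = Path(path)
    head = path.read_text(errors="replace")[:2048]
    if path.suffix.lower() in (".cif", ".mmcif") or head.lstrip().startswith("data_"):
        raise UnsupportedFormatError(
            f"{path.name}: mmCIF input is not supported; provide PDB format"
        )
    st = gemmi.read_pdb(str(path))
    return StructureModel.from_gemmi(st, name=path.stem)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "datasets", "seed", "out_dir", "use_delta_ex", "r2_bound_scale",
    "delta_ex_sigma_floor", "grid_span", "grid_steps", "log_level",
}
_DATASET_KEYS = {
    "name", "cpmg_csv", "delta_ex_csv", "jdp_total_uM", "hsc_total_uM",
    "t_relax",
}


@dataclass
class RunConfig:
    """Validated run configuration for the binding fit CLI."""

    datasets: list[dict[str, Any]]
    seed: int = 0
    out_dir: str = "."
    use_delta_ex: bool = True
    r2_bound_scale: float = 5.0
    delta_ex_sigma_floor: float = 0.002
    grid_span: float = 0.3
    grid_steps: int = 7
    raw: dict[str, Any] = field(default_factory=dict)


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ValueError(f"{path.name}: config must be a YAML mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"{path.name}: unknown config key(s) {sorted(unknown)}")
    datasets = raw.get("datasets")
    if not datasets:
        raise ValueError(f"{path.name}: config needs a non-empty 'datasets' list")
    for i, ds in enumerate(datasets):
        bad = set(ds) - _DATASET_KEYS
        if bad:
            raise ValueError(f"{path.name}: dataset {i}: unknown key(s) {sorted(bad)}")
        for req in ("cpmg_csv", "jdp_total_uM", "hsc_total_uM"):
            if req not in ds:
                raise ValueError(f"{path.name}: dataset {i}: missing {req!r}")
    kwargs = {k: v for k, v in raw.items() if k in _KNOWN_KEYS and k != "log_level"}
    return RunConfig(**kwargs, raw=raw)


def provenance(seed: int, config: dict | None = None) -> dict:
    """Provenance block written into every CLI output."""
    from . import __version__

    blob = yaml.safe_dump(config or {}, sort_keys=True).encode()
    return {
        "package": "nmrbind",
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
    }
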
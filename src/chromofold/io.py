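"""Shared I/O: conformation writers, TSV tables with metadata, flat config.

Deterministic plumbing for the whole package: every table written here
carries a JSON sidecar recording the package version, the resolved
configuration and the master seed, so any result file can be regenerated
from its own metadata.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("chromofold")

NM_TO_ANGSTROM = 10.0


@dataclass
class RunConfig:
    """Resolved run configuration: parameters, master seed, outputs."""

    params: Dict[str, Any] = field(default_factory=dict)
    master_seed: int = 0
    output: Optional[str] = None
    log_level: str = "INFO"


def parse_config(
    path: Optional[Union[str, Path]] = None,
    flags: Optional[Mapping[str, Any]] = None,
    allowed_keys: Optional[Iterable[str]] = None,
    defaults: Optional[Mapping[str, Any]] = None,
) -> RunConfig:
    """Merge a flat YAML config file with command-line flag overrides.

    Flags win over file values (each override is logged); unknown keys are a
    hard error listing the accepted keys. ``seed``, ``out`` and
    ``log_level`` are always accepted and routed to the corresponding
    RunConfig fields.
    """
    reserved = {"seed", "out", "log_level"}
    accepted = set(allowed_keys or []) | reserved
    merged: Dict[str, Any] = dict(defaults or {})

    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must be a flat key-value mapping")
        _check_keys(data, accepted)
        merged.update(data)

    if flags:
        for key, value in flags.items():
            if value is None:
                continue
            _check_keys({key: value}, accepted)
            if key in merged and merged[key] != value:
                logger.info(
                    "flag override: %s = %r (file had %r)", key, value, merged[key]
                )
            merged[key] = value

    seed = int(merged.pop("seed", 0))
    out = merged.pop("out", None)
    log_level = str(merged.pop("log_level", "INFO"))
    _validate_params(merged)
    cfg = RunConfig(
        params=merged, master_seed=seed, output=out, log_level=log_level
    )
    logger.debug("resolved config: %s", cfg)
    return cfg


def _check_keys(data: Mapping[str, Any], accepted: set) -> None:
    unknown = set(data) - accepted
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; accepted keys are "
            f"{sorted(accepted)}"
        )


def _validate_params(params: Mapping[str, Any]) -> None:
    """Range checks for parameters whose physical sign is fixed."""
    positive = (
        "lp",
        "lp_initial",
        "lp_final",
        "contour_length",
        "nuclear_size",
        "linker_bp",
        "capture_radius",
    )
    for key in positive:
        if key in params and params[key] is not None and params[key] <= 0:
            raise ValueError(f"{key} must be positive, got {params[key]}")


def write_xyz(
    coordinates: np.ndarray,
    path: Union[str, Path],
    comment: str = "",
    element: str = "C",
) -> None:
    """Minimal XYZ: count line, comment line, one ``element x y z`` per bead."""
    coords = np.asarray(coordinates, dtype=float)
    lines = [str(len(coords)), comment]
    for x, y, z in coords:
        lines.append(f"{element} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_xyz(path: Union[str, Path]) -> np.ndarray:
    """Read the coordinates back from a minimal XYZ file."""
    lines = Path(path).read_text().splitlines()
    n = int(lines[0])
    coords = np.empty((n, 3))
    for i, line in enumerate(lines[2 : 2 + n]):
        parts = line.split()
        coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
    return coords


def write_pdb(coordinates_nm: np.ndarray, path: Union[str, Path]) -> None:
    """Minimal PDB: one HETATM per bead, nm converted to angstrom.

    1-based serials and residue numbers, single chain A, element C. Intended
    for quick visualization of bead-polymer conformations only.
    """
    coords = np.asarray(coordinates_nm, dtype=float) * NM_TO_ANGSTROM
    lines = []
    for i, (x, y, z) in enumerate(coords, start=1):
        lines.append(
            f"HETATM{i:>5}  C   BEA A{i:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_table(
    rows: Union[pd.DataFrame, Sequence[Mapping[str, Any]]],
    schema: Sequence[str],
    path: Union[str, Path],
    metadata: Optional[Mapping[str, Any]] = None,
) -> None:
    """Tab-separated table with a fixed column order plus a JSON sidecar.

    The schema fixes the column set and order; rows with missing or extra
    columns are a hard error. An empty result still writes the header line.
    The sidecar ``<path>.meta.json`` records the package version and any
    metadata passed in (config, seeds).
    """
    from . import __version__

    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows))
        if df.empty:
            df = pd.DataFrame(columns=list(schema))
    if set(df.columns) != set(schema):
        raise ValueError(
            f"schema mismatch: table has {sorted(df.columns)}, "
            f"schema is {list(schema)}"
        )
    df = df[list(schema)]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {"package": "chromofold", "version": __version__}
    sidecar.update(metadata or {})
    Path(str(path) + ".meta.json").write_text(
        json.dumps(sidecar, indent=1, default=str) + "\n"
    )
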
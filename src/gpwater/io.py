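"""File formats: extended XYZ trajectories, CSV scalar logs, configs.

Extended XYZ is used for all geometry/trajectory output: a plain-text,
ecosystem-standard format (comment line carries ``Lattice=...`` and arbitrary
``key=value`` metadata).  Only the subset this package writes is parsed:
orthorhombic lattices and per-atom species + positions.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_extxyz", "read_extxyz", "load_config_file", "dump_json"]

_KV_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _format_value(v) -> str:
    if isinstance(v, (list, tuple, np.ndarray)):
        flat = np.asarray(v).ravel()
        return '"' + " ".join(f"{x:.10g}" for x in flat) + '"'
    if isinstance(v, float):
        return f"{v:.10g}"
    s = str(v)
    return f'"{s}"' if " " in s else s


def write_extxyz(path, frames, mode: str = "w") -> None:
    """Write frames as extended XYZ.

    Each frame is ``(coords (n,3), elements list, info dict)``; an optional
    ``info["Lattice"]`` may be a scalar cubic box length or a 3x3 matrix.
    """
    path = Path(path)
    with open(path, mode) as fh:
        for coords, elements, info in frames:
            coords = np.asarray(coords, dtype=float)
            info = dict(info or {})
            lat = info.pop("Lattice", None)
            parts = []
            if lat is not None:
                lat = np.asarray(lat, dtype=float)
                if lat.ndim == 0:
                    lat = np.eye(3) * float(lat)
                parts.append(f'Lattice={_format_value(lat)}')
            parts.append("Properties=species:S:1:pos:R:3")
            for k, v in info.items():
                parts.append(f"{k}={_format_value(v)}")
            fh.write(f"{len(coords)}\n{' '.join(parts)}\n")
            for el, xyz in zip(elements, coords):
                fh.write(f"{el} {xyz[0]:.10f} {xyz[1]:.10f} {xyz[2]:.10f}\n")


def read_extxyz(path) -> list[dict]:
    """Read an extended-XYZ file into frames.

    Returns a list of dicts with keys ``coords`` (n,3), ``elements`` (list of
    str), ``info`` (header metadata; ``Lattice`` as a 3x3 array when present,
    numeric scalars converted to float).
    """
    frames = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        nat = int(lines[i].strip())
        header = lines[i + 1]
        info = {}
        for key, quoted, bare in _KV_RE.findall(header):
            raw = quoted if quoted else bare
            if key == "Lattice":
                info[key] = np.fromstring(raw, sep=" ").reshape(3, 3)
            elif key == "Properties":
                info[key] = raw
            else:
                try:
                    info[key] = float(raw)
                except ValueError:
                    info[key] = raw
        elements, coords = [], np.empty((nat, 3))
        for a in range(nat):
            tok = lines[i + 2 + a].split()
            elements.append(tok[0])
            coords[a] = [float(x) for x in tok[1:4]]
        frames.append({"coords": coords, "elements": elements, "info": info})
        i += 2 + nat
    return frames


def load_config_file(path) -> dict:
    """Load a YAML or JSON run configuration into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        import yaml
        return yaml.safe_load(text)
    return json.loads(text)


def dump_json(path, obj) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")


def write_scalar_log(path, records: list[dict]) -> None:
    pd.DataFrame(records).to_csv(path, index=False)


def read_scalar_log(path) -> pd.DataFrame:
    return pd.read_csv(path)
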
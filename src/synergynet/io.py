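"""On-disk formats: network specs (JSON), data tables (CSV), results (TSV).

Formats are deliberately plain text and diff-friendly.  Network JSON uses
Python ``repr`` floats, so write -> read round-trips are exact (well beyond
the 12 significant digits the format guarantees); serialization is
canonical (sorted keys, fixed separators), so re-serialization is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bayesnet import BayesNet, Cpt, Realization, validate_network
from .errors import ParseError, StructureError
from .info import DataMatrix

__all__ = [
    "read_network",
    "write_network",
    "network_to_json",
    "network_from_json",
    "read_data_csv",
    "write_data_csv",
    "write_mi_matrix_tsv",
    "write_realization",
    "read_realization",
    "write_sidecar",
]


def network_to_json(net: BayesNet) -> str:
    """Canonical JSON text for a network spec."""
    payload = {
        "nodes": list(net.nodes),
        "cpts": {
            node: {
                "parents": list(cpt.parents),
                "rows": {
                    "".join(str(b) for b in combo): prob
                    for combo, prob in sorted(cpt.rows.items())
                },
            }
            for node, cpt in net.cpts.items()
        },
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def network_from_json(text: str) -> BayesNet:
    """Parse and validate a network spec from JSON text."""
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"network spec is not valid JSON: {exc}") from None
    if not isinstance(payload, dict):
        raise ParseError("network spec must be a JSON object")
    for key in ("nodes", "cpts"):
        if key not in payload:
            raise ParseError(f"network spec missing field {key!r}")
    nodes = payload["nodes"]
    if not isinstance(nodes, list) or not all(isinstance(x, str) for x in nodes):
        raise ParseError("field 'nodes' must be a list of strings")
    cpts_raw = payload["cpts"]
    if not isinstance(cpts_raw, dict):
        raise ParseError("field 'cpts' must be an object")
    cpts: dict[str, Cpt] = {}
    for node, entry in cpts_raw.items():
        if not isinstance(entry, dict) or "parents" not in entry or "rows" not in entry:
            raise ParseError(f"cpts[{node!r}] must have fields 'parents' and 'rows'")
        parents = entry["parents"]
        if not isinstance(parents, list) or not all(isinstance(p, str) for p in parents):
            raise ParseError(f"cpts[{node!r}].parents must be a list of strings")
        rows_raw = entry["rows"]
        if not isinstance(rows_raw, dict):
            raise ParseError(f"cpts[{node!r}].rows must be an object")
        rows: dict[tuple[int, ...], float] = {}
        for key, prob in rows_raw.items():
            if not isinstance(key, str) or any(c not in "01" for c in key):
                raise ParseError(
                    f"cpts[{node!r}].rows key {key!r} is not a parent bit-string"
                )
            if len(key) != len(parents):
                raise ParseError(
                    f"cpts[{node!r}].rows key {key!r} does not match "
                    f"{len(parents)} parent(s)"
                )
            if not isinstance(prob, (int, float)) or isinstance(prob, bool):
                raise ParseError(f"cpts[{node!r}].rows[{key!r}] must be a number")
            rows[tuple(int(c) for c in key)] = float(prob)
        cpts[node] = Cpt(parents=tuple(parents), rows=rows)
    net = BayesNet(nodes=tuple(nodes), cpts=cpts)
    violations = validate_network(net)
    if violations:
        raise StructureError("invalid network spec: " + "; ".join(violations))
    return net


def write_network(net: BayesNet, path) -> None:
    Path(path).write_text(network_to_json(net))


def read_network(path) -> BayesNet:
    return network_from_json(Path(path).read_text())


def write_data_csv(data: DataMatrix, path) -> None:
    """Header of column labels, one row per subject, 0/1 cells."""
    data.frame.to_csv(path, index=False)


def read_data_csv(path) -> DataMatrix:
    """Strict CSV parse; errors name the offending row and column."""
    path = Path(path)
    with path.open() as fh:
        header_line = fh.readline()
    if not header_line.strip():
        raise ParseError(f"{path}: empty file")
    header = [h.strip() for h in header_line.rstrip("\n").split(",")]
    if all(h in ("0", "1", "") for h in header):
        raise ParseError(f"{path}: missing header row (first line looks like data)")
    dupes = sorted({h for h in header if header.count(h) > 1})
    if dupes:
        raise ParseError(f"{path}: duplicate header label(s): {dupes}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    values = frame.to_numpy()
    ok = np.isin(values, ("0", "1"))
    if not ok.all():
        r, c = np.argwhere(~ok)[0]
        raise ParseError(
            f"{path}: non-binary cell {values[r, c]!r} at row {r + 1}, "
            f"column {header[c]!r}"
        )
    return DataMatrix.from_frame(frame.astype(np.int8))


def write_mi_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    """Pairwise-MI matrix as TSV, labels on both axes, bits to 6 decimals."""
    matrix.to_csv(path, sep="\t", float_format="%.6f")


def write_realization(realization: Realization, path) -> None:
    payload = {"states": realization.states, "noises": realization.noises}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_realization(path) -> Realization:
    try:
        payload = json.loads(Path(path).read_text())
        return Realization(
            states={k: int(v) for k, v in payload["states"].items()},
            noises={k: float(v) for k, v in payload["noises"].items()},
        )
    except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"{path}: not a realization file: {exc}") from None


def write_sidecar(out_path, command: str, seed: int | None, params: dict) -> Path:
    """Write ``<out>.meta.json`` recording tool version, seed and config hash.

    The sidecar is sufficient to reproduce the artifact; no timestamp is
    included so repeated identical runs stay byte-identical.
    """
    from . import __version__

    canonical = json.dumps(params, sort_keys=True, default=str)
    meta = {
        "tool": "synergynet",
        "version": __version__,
        "command": command,
        "seed": seed,
        "params": json.loads(canonical),
        "config_sha256": hashlib.sha256(canonical.encode()).hexdigest(),
    }
    sidecar = Path(str(out_path) + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return sidecar
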
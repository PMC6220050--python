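"""Serialization, run manifests and tabular output.

Every CLI run writes its outputs plus exactly one ``manifest.json``
recording the subcommand, the fully resolved configuration, the master
seed, the package version, and a digest of every file written — enough to
reproduce deterministic runs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path

import numpy as np

__all__ = ["RunManifest", "write_table", "to_plain", "file_digest"]


def to_plain(obj):
    """Recursively convert dataclasses/arrays to JSON/YAML-safe values."""
    if is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_plain(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


@dataclass
class RunManifest:
    subcommand: str
    config: dict
    master_seed: int
    package_version: str = ""
    file_digests: dict = field(default_factory=dict)

    def record(self, path: str | Path) -> None:
        path = Path(path)
        self.file_digests[path.name] = file_digest(path)

    def write(self, out_dir: str | Path) -> Path:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__
        target = Path(out_dir) / "manifest.json"
        with open(target, "w") as fh:
            json.dump(to_plain(asdict(self)), fh, indent=1, sort_keys=True)
        return target

    @staticmethod
    def read(out_dir: str | Path) -> "RunManifest":
        with open(Path(out_dir) / "manifest.json") as fh:
            data = json.load(fh)
        return RunManifest(**data)


def write_table(
    path: str | Path,
    columns: dict,
    params: dict | None = None,
) -> None:
    """Delimited table with a header comment recording the parameters."""
    path = Path(path)
    names = list(columns)
    arrays = [np.asarray(columns[n]) for n in names]
    with open(path, "w") as fh:
        if params:
            fh.write("# " + json.dumps(to_plain(params), sort_keys=True) + "\n")
        fh.write("# " + "\t".join(names) + "\n")
        for row in zip(*arrays):
            fh.write("\t".join(f"{v:.6f}" if isinstance(v, (float, np.floating)) else str(v) for v in row) + "\n")
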
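"""TSV readers/writers and the run manifest.

All tabular files are UTF-8, tab-delimited, with a header row and '.' for
missing values. The group file pairs marker ids with dense group indices and
round-trips with :class:`~bayesrrc.annotate.MarkerGrouping`.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import MarkerGrouping

__all__ = ["read_phenotype", "write_phenotype", "read_groups", "write_groups",
           "write_truth", "read_regions", "write_regions", "RunManifest"]

_TSV = dict(sep="\t", na_rep=".", index=False)


def write_phenotype(path, values, ids=None) -> None:
    ids = ids if ids is not None else [f"ind{i}" for i in range(len(values))]
    pd.DataFrame({"FID": ids, "IID": ids, "value": values}).to_csv(path, **_TSV)


def read_phenotype(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t", na_values=".")
    if "value" not in df.columns:  # tolerate headerless FID IID VALUE
        df = pd.read_csv(path, sep=r"\s+", header=None, names=["FID", "IID", "value"])
    return df["value"].to_numpy(float)


def write_groups(path, grouping: MarkerGrouping, marker_ids) -> None:
    pd.DataFrame({"marker_id": marker_ids,
                  "group_index": grouping.group_index}).to_csv(path, **_TSV)


def read_groups(path, marker_ids) -> MarkerGrouping:
    """Read a (marker id, group index) file covering every marker.

    Missing markers and non-dense group indices are rejected with the
    offending entries named.
    """
    df = pd.read_csv(path, sep="\t")
    lookup = dict(zip(df["marker_id"].astype(str), df["group_index"].astype(int)))
    missing = [str(m) for m in marker_ids if str(m) not in lookup]
    if missing:
        raise ValueError(f"group file is missing markers: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    index = np.array([lookup[str(m)] for m in marker_ids], dtype=int)
    uniq = np.unique(index)
    expected = np.arange(len(uniq))
    if index.min() < 0 or not np.array_equal(uniq, expected):
        raise ValueError(f"group indices must be dense 0..G-1; saw {uniq.tolist()[:20]}")
    p = len(marker_ids)
    filler = np.full(p, ".")
    labels = [("group", str(g), ".") for g in expected]
    return MarkerGrouping(filler, filler, filler, index, labels)


def write_truth(path, truth, marker_ids, group_index=None) -> None:
    df = truth.to_frame(marker_ids)
    if group_index is not None:
        df.insert(1, "group_index", group_index)
    df.to_csv(path, **_TSV)


def write_regions(path, regions) -> None:
    regions.to_frame().to_csv(path, **_TSV)


def read_regions(path):
    from .annotate import RegionSet

    df = pd.read_csv(path, sep="\t")
    members = [[int(v) for v in str(m).split(",")] if str(m) not in (".", "nan", "")
               else [] for m in df["marker_indices"]]
    kind = df["kind"].iloc[0] if len(df) else "unknown"
    return RegionSet(df["region_id"].tolist(), members, kind, {"path": str(path)})


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every CLI output."""

    command: str
    config: dict
    seeds: list
    inputs: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    version: str = ""
    created: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__

    def add_input(self, path) -> None:
        p = Path(path)
        if p.exists():
            self.inputs[str(p)] = _digest(p)

    @property
    def manifest_id(self) -> str:
        payload = json.dumps({"command": self.command, "config": self.config,
                              "seeds": self.seeds, "inputs": self.inputs},
                             sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def save(self, path) -> None:
        payload = {"manifest_id": self.manifest_id, "command": self.command,
                   "config": self.config, "seeds": self.seeds,
                   "inputs": self.inputs, "timings": self.timings,
                   "version": self.version, "created": self.created}
        Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
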
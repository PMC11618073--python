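"""Reading and writing fluorescence trace files and run manifests.

The interchange format is deliberately plain: one tab-separated file per
molecule (columns ``frame  time_s  excitation  donor  acceptor  red``,
header row, '.' decimal, UTF-8) plus a ``manifest.json`` holding the run
parameters, the seed, and per-molecule ground truth when the traces are
simulated.  Text files are greppable and diffable, which is worth more
at single-molecule data volumes than a binary container.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FORMAT_VERSION = "1.0"
REQUIRED_COLUMNS = ["frame", "time_s", "excitation", "donor", "acceptor", "red"]
EXCITATION_LABELS = {"G", "R", "B"}


class TraceFormatError(ValueError):
    """Raised when a trace file violates the documented format."""


@dataclass
class Trace:
    """Per-frame multi-channel intensity record for one molecule."""

    molecule_id: str
    frames: pd.DataFrame
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frames.columns]
        if missing:
            raise TraceFormatError(f"{self.molecule_id}: missing columns {missing}")
        t = self.frames["time_s"].to_numpy(dtype=float)
        if len(t) > 1:
            dt = np.diff(t)
            if (dt <= 0).any():
                bad = int(np.flatnonzero(dt <= 0)[0]) + 2  # +2: header + 1-based
                raise TraceFormatError(
                    f"{self.molecule_id}: time not strictly increasing at data line {bad}"
                )
            if np.ptp(dt) > 1e-6:
                raise TraceFormatError(f"{self.molecule_id}: frame spacing is not constant")
        bad_exc = set(self.frames["excitation"].unique()) - EXCITATION_LABELS
        if bad_exc:
            raise TraceFormatError(f"{self.molecule_id}: unknown excitation labels {sorted(bad_exc)}")
        for col in ("donor", "acceptor", "red"):
            vals = self.frames[col].to_numpy(dtype=float)
            if not np.isfinite(vals[~np.isnan(vals)]).all():
                raise TraceFormatError(f"{self.molecule_id}: non-finite counts in {col}")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def frame_time(self) -> float:
        if "frame_time" in self.metadata:
            return float(self.metadata["frame_time"])
        t = self.frames["time_s"].to_numpy()
        return float(t[1] - t[0]) if len(t) > 1 else 0.1


@dataclass
class Manifest:
    """Run parameters plus per-molecule ground truth for simulated data."""

    preset: str
    seed: int
    params: dict[str, Any] = field(default_factory=dict)
    optics: dict[str, Any] = field(default_factory=dict)
    molecules: list[dict[str, Any]] = field(default_factory=list)
    version: str = FORMAT_VERSION

    def molecule(self, molecule_id: str) -> dict[str, Any]:
        for m in self.molecules:
            if m["molecule_id"] == molecule_id:
                return m
        raise KeyError(molecule_id)

    def to_dict(self) -> dict[str, Any]:
        return {
            "version": self.version,
            "preset": self.preset,
            "seed": self.seed,
            "params": self.params,
            "optics": self.optics,
            "molecules": self.molecules,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "Manifest":
        if "version" not in d:
            raise TraceFormatError("manifest missing version string")
        return cls(
            preset=d.get("preset", ""),
            seed=int(d.get("seed", 0)),
            params=d.get("params", {}),
            optics=d.get("optics", {}),
            molecules=d.get("molecules", []),
            version=d["version"],
        )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, frozenset):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_traces(
    traces: Iterable[Trace],
    manifest: Manifest | None,
    path: str | Path,
    overwrite: bool = False,
) -> Path:
    """Write one TSV per molecule plus ``manifest.json`` under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for tr in traces:
        fname = path / f"{tr.molecule_id}.tsv"
        if fname.exists() and not overwrite:
            raise FileExistsError(f"{fname} exists; pass overwrite=True to replace")
        df = tr.frames[REQUIRED_COLUMNS]
        df.to_csv(fname, sep="\t", index=False, float_format="%.6g")
    if manifest is not None:
        mpath = path / "manifest.json"
        if mpath.exists() and not overwrite:
            raise FileExistsError(f"{mpath} exists; pass overwrite=True to replace")
        mpath.write_text(json.dumps(manifest.to_dict(), indent=1, default=_json_default))
    return path


def read_manifest(path: str | Path) -> Manifest:
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    return Manifest.from_dict(json.loads(path.read_text()))


def read_traces(path: str | Path, frame_time: float | None = None) -> list[Trace]:
    """Read a directory (or a single TSV file) of traces.

    Malformed files raise :class:`TraceFormatError` naming the violation
    and line; an empty directory returns an empty list with a warning.
    """
    path = Path(path)
    files = [path] if path.is_file() else sorted(path.glob("*.tsv"))
    if not files:
        warnings.warn(f"no trace files found under {path}", stacklevel=2)
        logger.warning("no trace files found under %s", path)
        return []
    meta: dict[str, Any] = {}
    if path.is_dir() and (path / "manifest.json").exists():
        m = read_manifest(path)
        meta = {"preset": m.preset, **m.optics}
    traces = []
    for f in files:
        df = pd.read_csv(f, sep="\t")
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise TraceFormatError(f"{f.name}: missing required columns {missing}")
        md = dict(meta)
        if frame_time is not None:
            md["frame_time"] = frame_time
        traces.append(Trace(molecule_id=f.stem, frames=df, metadata=md))
    return traces
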
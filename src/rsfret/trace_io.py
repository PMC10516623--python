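"""Reading and writing single-molecule intensity traces.

Two on-disk dialects are supported:

``binary_traces``
    The de-facto TIRF-lab layout: little-endian ``int32`` frame count L,
    ``int16`` channel count C = 2N (donor/acceptor interleaved per
    molecule), followed by C*L ``int16`` values in frame-major order
    (frame 0 of every channel, then frame 1, ...).  Total file size is
    exactly ``4 + 2 + 2*C*L`` bytes.

``csv_long``
    Long-form delimited text with columns
    ``molecule_id, frame, donor, acceptor`` — the lossless archival format
    (float counts allowed).

Both dialects carry a structured-text metadata sidecar (JSON, same
basename, ``.meta.json`` suffix) holding the frame interval, condition
metadata, molecule ids and per-molecule event frames.
"""

from __future__ import annotations

import json
import logging
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_FRAME_INTERVAL = 0.075  # seconds; 20 frames per 1.5 s movie

INT16_MIN, INT16_MAX = -32768, 32767


class TraceFormatError(ValueError):
    """Raised when an on-disk trace file violates its dialect."""


@dataclass
class IntensityTrace:
    """Donor/acceptor counts per frame for one immobilized molecule.

    ``event_frame`` marks a buffer injection (ligand flow-in or the start
    of helicase unwinding).  ``truth`` is the simulator's ground-truth
    annotation (archetype, realized rates, state path, bleach times) and
    is absent for experimental data.
    """

    molecule_id: str
    donor: np.ndarray
    acceptor: np.ndarray
    frame_interval: float
    event_frame: int | None = None
    truth: dict | None = None

    def __post_init__(self):
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.ndim != 1 or self.acceptor.ndim != 1:
            raise ValueError("donor/acceptor must be 1-D series")
        if len(self.donor) != len(self.acceptor):
            raise ValueError(
                f"donor/acceptor length mismatch for {self.molecule_id}: "
                f"{len(self.donor)} vs {len(self.acceptor)}"
            )
        if len(self.donor) < 1:
            raise ValueError("trace must contain at least one frame")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be positive")
        if not (np.isfinite(self.donor).all() and np.isfinite(self.acceptor).all()):
            raise ValueError(f"non-finite counts in trace {self.molecule_id}")
        if self.event_frame is not None and not (0 <= self.event_frame < len(self.donor)):
            raise ValueError("event_frame outside trace")

    def __len__(self) -> int:
        return len(self.donor)

    @property
    def total(self) -> np.ndarray:
        return self.donor + self.acceptor

    @property
    def times(self) -> np.ndarray:
        """Frame start times in seconds."""
        return np.arange(len(self)) * self.frame_interval


@dataclass
class TraceEnsemble:
    """An ordered collection of traces sharing one frame interval."""

    traces: list[IntensityTrace]
    condition: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.traces:
            dt = self.traces[0].frame_interval
            for t in self.traces:
                if t.frame_interval != dt:
                    raise ValueError("all traces must share frame_interval")
        ids = [t.molecule_id for t in self.traces]
        if len(set(ids)) != len(ids):
            raise ValueError("molecule_ids must be unique within an ensemble")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    def __getitem__(self, i):
        return self.traces[i]

    @property
    def frame_interval(self) -> float:
        if not self.traces:
            raise ValueError("empty ensemble has no frame interval")
        return self.traces[0].frame_interval


# ---------------------------------------------------------------------------
# sidecar metadata


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def _write_sidecar(ensemble: TraceEnsemble, path: Path) -> None:
    meta = {
        "frame_interval": ensemble.frame_interval,
        "condition": ensemble.condition,
        "molecule_ids": [t.molecule_id for t in ensemble.traces],
        "event_frames": [t.event_frame for t in ensemble.traces],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, default=float))


def _read_sidecar(path: Path) -> dict | None:
    sp = _sidecar_path(path)
    if not sp.exists():
        return None
    return json.loads(sp.read_text())


# ---------------------------------------------------------------------------
# readers / writers


def read_traces(path: str | Path, dialect: str = "binary_traces",
                frame_interval: float | None = None) -> TraceEnsemble:
    """Read a trace file in the given dialect.

    If a metadata sidecar is present it supplies frame interval, molecule
    ids, event frames and condition metadata; otherwise ``frame_interval``
    (or the 0.075 s default, with a warning) is used.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("binary_traces", "csv_long"):
        raise ValueError(f"unknown dialect {dialect!r}")
    meta = _read_sidecar(path)
    if meta is not None:
        dt = meta["frame_interval"]
    elif frame_interval is not None:
        dt = frame_interval
    else:
        warnings.warn(
            f"no metadata sidecar for {path.name}; assuming frame interval "
            f"{DEFAULT_FRAME_INTERVAL} s"
        )
        dt = DEFAULT_FRAME_INTERVAL

    if dialect == "binary_traces":
        raw = path.read_bytes()
        if len(raw) < 6:
            raise TraceFormatError(f"{path.name}: header truncated ({len(raw)} bytes)")
        n_frames = struct.unpack("<i", raw[:4])[0]
        n_channels = struct.unpack("<h", raw[4:6])[0]
        if n_frames < 1 or n_channels < 2:
            raise TraceFormatError(
                f"{path.name}: implausible header L={n_frames}, C={n_channels}"
            )
        if n_channels % 2 != 0:
            raise TraceFormatError(
                f"{path.name}: odd channel count {n_channels} "
                "(channels must be donor/acceptor pairs)"
            )
        expected = 2 * n_frames * n_channels
        payload = len(raw) - 6
        if payload != expected:
            raise TraceFormatError(
                f"{path.name}: payload is {payload} bytes, expected {expected} "
                f"(L={n_frames}, C={n_channels})"
            )
        data = np.frombuffer(raw, dtype="<i2", offset=6).reshape(n_frames, n_channels)
        n_mol = n_channels // 2
        ids = _molecule_ids(meta, n_mol)
        evf = _event_frames(meta, n_mol)
        traces = [
            IntensityTrace(ids[i], data[:, 2 * i].astype(float),
                           data[:, 2 * i + 1].astype(float), dt, event_frame=evf[i])
            for i in range(n_mol)
        ]
    else:  # csv_long
        df = pd.read_csv(path, sep=None, engine="python")
        required = {"molecule_id", "frame", "donor", "acceptor"}
        if not required.issubset(df.columns):
            raise TraceFormatError(
                f"{path.name}: csv_long requires columns {sorted(required)}"
            )
        lengths = df.groupby("molecule_id", sort=False).size()
        if lengths.nunique() > 1:
            raise TraceFormatError(
                f"{path.name}: mixed trace lengths {sorted(set(lengths))}"
            )
        order = list(dict.fromkeys(df["molecule_id"]))
        ids_meta = meta.get("molecule_ids") if meta else None
        if ids_meta and all(str(i) in {str(o) for o in order} for i in ids_meta):
            order = ids_meta
        evf_map = {}
        if meta and meta.get("event_frames"):
            evf_map = dict(zip(meta["molecule_ids"], meta["event_frames"]))
        traces = []
        for mid in order:
            sub = df[df["molecule_id"].astype(str) == str(mid)].sort_values("frame")
            traces.append(
                IntensityTrace(str(mid), sub["donor"].to_numpy(),
                               sub["acceptor"].to_numpy(), dt,
                               event_frame=evf_map.get(mid))
            )

    condition = meta.get("condition", {}) if meta else {}
    return TraceEnsemble(traces, condition=condition)


def _molecule_ids(meta: dict | None, n_mol: int) -> list[str]:
    if meta and meta.get("molecule_ids") and len(meta["molecule_ids"]) == n_mol:
        return [str(i) for i in meta["molecule_ids"]]
    return [f"mol_{i:04d}" for i in range(n_mol)]


def _event_frames(meta: dict | None, n_mol: int) -> list[int | None]:
    if meta and meta.get("event_frames") and len(meta["event_frames"]) == n_mol:
        return [None if e is None else int(e) for e in meta["event_frames"]]
    return [None] * n_mol


def write_traces(ensemble: TraceEnsemble, path: str | Path,
                 dialect: str = "binary_traces", strict: bool = False) -> Path:
    """Write an ensemble to disk; returns the path written.

    In the binary dialect, counts outside the int16 range are clipped with
    a logged warning by default; ``strict=True`` raises instead.  PIFE
    spikes in simulated traces can exceed int16, hence the clip policy.
    """
    path = Path(path)
    if len(ensemble) == 0:
        raise ValueError("refusing to write an empty ensemble")
    if dialect not in ("binary_traces", "csv_long"):
        raise ValueError(f"unknown dialect {dialect!r}")
    lengths = {len(t) for t in ensemble}
    if dialect == "binary_traces":
        if len(lengths) > 1:
            raise TraceFormatError("binary_traces requires equal-length traces")
        L = lengths.pop()
        n_mol = len(ensemble)
        data = np.empty((L, 2 * n_mol), dtype=float)
        for i, t in enumerate(ensemble):
            data[:, 2 * i] = t.donor
            data[:, 2 * i + 1] = t.acceptor
        rounded = np.rint(data)
        out_of_range = (rounded < INT16_MIN) | (rounded > INT16_MAX)
        if out_of_range.any():
            if strict:
                raise ValueError(
                    f"{int(out_of_range.sum())} counts outside int16 range "
                    "(strict mode)"
                )
            log.warning("clipping %d counts to int16 range in %s",
                        int(out_of_range.sum()), path.name)
            rounded = np.clip(rounded, INT16_MIN, INT16_MAX)
        with open(path, "wb") as fh:
            fh.write(struct.pack("<i", L))
            fh.write(struct.pack("<h", 2 * n_mol))
            fh.write(rounded.astype("<i2").tobytes())
    else:
        rows = []
        for t in ensemble:
            rows.append(pd.DataFrame({
                "molecule_id": t.molecule_id,
                "frame": np.arange(len(t)),
                "donor": t.donor,
                "acceptor": t.acceptor,
            }))
        pd.concat(rows, ignore_index=True).to_csv(path, index=False)
    _write_sidecar(ensemble, path)
    return path


def write_results_table(records: Sequence[dict], path: str | Path,
                        float_digits: int = 6) -> Path:
    """Write homogeneous per-record results as delimited text.

    All records must share one schema (same keys); column order follows the
    first record.  With an empty record list no schema can be inferred, so
    an empty file is written — use :func:`write_results_table_with_schema`
    for a header-only file.
    """
    path = Path(path)
    records = list(records)
    if records:
        schema = list(records[0].keys())
        for i, r in enumerate(records):
            if list(r.keys()) != schema:
                raise ValueError(
                    f"record {i} schema {list(r.keys())} != {schema}"
                )
        df = pd.DataFrame(records, columns=schema)
    else:
        df = pd.DataFrame()
    df.to_csv(path, index=False, float_format=f"%.{float_digits}g")
    return path


def write_results_table_with_schema(records: Iterable[dict], schema: Sequence[str],
                                    path: str | Path, float_digits: int = 6) -> Path:
    """As :func:`write_results_table` but with an explicit schema, so an
    empty record list yields a header-only file."""
    path = Path(path)
    records = list(records)
    for i, r in enumerate(records):
        if list(r.keys()) != list(schema):
            raise ValueError(f"record {i} schema {list(r.keys())} != {list(schema)}")
    pd.DataFrame(records, columns=list(schema)).to_csv(
        path, index=False, float_format=f"%.{float_digits}g")
    return path
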
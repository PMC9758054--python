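"""Plain-text artifacts: annotated constructs, traces, calls, categories.

Everything is TSV with a ``#``-prefixed header block carrying schema
version, units, the coordinate convention and the run seed, so every file
is self-describing and round-trips exactly.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .construct import Annotation, UnzipConstruct
from .traces import PeakCall, Trace

SCHEMA_VERSION = "1"

_SCHEMAS = {
    "annotations": ["name", "start", "end", "kind"],
    "trace": ["time_s", "force_pN", "extension_nm"],
    "traces": ["trace_id", "time_s", "force_pN", "extension_nm"],
    "calls": ["trace_id", "position_bp", "sign", "amplitude_pN", "width_bp"],
    "categories": ["chamber_id", "trace_id", "phase", "category"],
    "classified": [
        "chamber_id",
        "trace_id",
        "phase",
        "label",
        "motor_pos_bp",
        "dcas_pos_bp",
        "flags",
    ],
}


def write_table(df: pd.DataFrame, path: str | Path, kind: str, meta: dict | None = None) -> None:
    cols = _SCHEMAS[kind]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{kind} table is missing column {missing[0]!r}")
    header = {
        "schema": f"{kind}/v{SCHEMA_VERSION}",
        "coordinates": "unzip frame, 0-based half-open, bp",
        "units": "pN, nm, bp, s",
        **(meta or {}),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, columns=cols)


def read_table(path: str | Path, kind: str) -> tuple[pd.DataFrame, dict]:
    meta: dict[str, str] = {}
    lines: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition(":")
                meta[key.strip()] = val.strip()
            else:
                lines.append(line)
    df = pd.read_csv(_io.StringIO("".join(lines)), sep="\t")
    cols = _SCHEMAS[kind]
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"{path}: schema {kind!r} requires column {c!r}")
    _validate_rows(df, kind, path)
    return df[cols], meta


def _validate_rows(df: pd.DataFrame, kind: str, path) -> None:
    numeric = {
        "annotations": ["start", "end"],
        "trace": ["time_s", "force_pN", "extension_nm"],
        "traces": ["time_s", "force_pN", "extension_nm"],
        "calls": ["position_bp", "amplitude_pN", "width_bp"],
        "categories": [],
        "classified": [],
    }[kind]
    for col in numeric:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            # +2 for the header row of the data block (1-based)
            line = int(np.flatnonzero(bad)[0]) + 2
            raise ValueError(
                f"{path}: malformed value in column {col!r} at data line {line}"
            )


# -- constructs -------------------------------------------------------------


def write_construct(
    construct: UnzipConstruct, fasta_path: str | Path, annot_path: str | Path
) -> None:
    rec = SeqRecord(
        Seq(construct.sequence),
        id="unzip_segment",
        description=(
            f"arm_bp={construct.arm_bp} direction={construct.direction}"
        ),
    )
    Path(fasta_path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write([rec], str(fasta_path), "fasta")
    df = pd.DataFrame(
        [(a.name, a.start, a.end, a.kind) for a in construct.annotations],
        columns=["name", "start", "end", "kind"],
    )
    write_table(df, annot_path, "annotations")


def read_construct(fasta_path: str | Path, annot_path: str | Path) -> UnzipConstruct:
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{fasta_path}: expected exactly one record")
    rec = records[0]
    fields = dict(
        kv.split("=", 1) for kv in rec.description.split() if "=" in kv
    )
    if "arm_bp" not in fields or "direction" not in fields:
        raise ValueError(
            f"{fasta_path}: description must carry arm_bp=... direction=..."
        )
    df, _ = read_table(annot_path, "annotations")
    anns = [
        Annotation(str(r["name"]), int(r["start"]), int(r["end"]), str(r["kind"]))
        for r in df.to_dict("records")
    ]
    return UnzipConstruct(
        str(rec.seq), int(fields["arm_bp"]), fields["direction"], anns
    )


# -- traces and calls -------------------------------------------------------


def traces_to_frame(traces: dict[str, Trace]) -> pd.DataFrame:
    frames = []
    for tid, tr in traces.items():
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": tid,
                    "time_s": tr.time_s,
                    "force_pN": tr.force_pN,
                    "extension_nm": tr.extension_nm,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_traces(df: pd.DataFrame, rate_hz: float, loading_mode: str) -> dict[str, Trace]:
    out: dict[str, Trace] = {}
    for tid, grp in df.groupby("trace_id", sort=False):
        out[str(tid)] = Trace(
            time_s=grp.time_s.to_numpy(float),
            force_pN=grp.force_pN.to_numpy(float),
            extension_nm=grp.extension_nm.to_numpy(float),
            rate_hz=rate_hz,
            loading_mode=loading_mode,
        )
    return out


def calls_to_frame(calls_by_trace: dict[str, list[PeakCall]]) -> pd.DataFrame:
    rows = [
        (tid, c.position_bp, c.sign, c.amplitude_pN, c.width_bp)
        for tid, calls in calls_by_trace.items()
        for c in calls
    ]
    return pd.DataFrame(
        rows, columns=["trace_id", "position_bp", "sign", "amplitude_pN", "width_bp"]
    )


# -- config -----------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
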
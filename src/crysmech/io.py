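"""Delimited-text I/O for traces and event tables.

Traces are written as tab-separated text with a commented ``key=value``
header (columns ``time_s, stage_nm, extension_nm, force_pN``); the
ground-truth event log of synthetic traces goes into a ``.truth.csv``
sidecar.  Generic two/three-column delimited recordings from other sources
can be loaded with a column mapping.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .simulate import ForceExtensionTrace, TruthEvent

TRACE_COLUMNS = ("time_s", "stage_nm", "extension_nm", "force_pN")


def trace_path(out_dir, trace_id: str) -> Path:
    return Path(out_dir) / f"{trace_id}.tsv"


def write_trace(trace: ForceExtensionTrace, path) -> Path:
    """Write a trace as TSV (+ ``.truth.csv`` sidecar when truth is present)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# trace_id={trace.trace_id}\n")
        for key, val in trace.metadata.items():
            fh.write(f"# {key}={val}\n")
        fh.write("\t".join(TRACE_COLUMNS) + "\n")
        np.savetxt(fh, np.column_stack([trace.time, trace.stage_position,
                                        trace.extension, trace.force]),
                   fmt="%.7g", delimiter="\t")
    if trace.truth is not None:
        rows = [{"rupture_time_s": ev.time_s, "unit_label": ev.unit_label,
                 "class": ev.class_label, "force_pN": ev.force_pN,
                 "delta_Lc_nm": ev.delta_Lc_nm, "pathway": ev.pathway}
                for ev in trace.truth]
        pd.DataFrame(rows, columns=["rupture_time_s", "unit_label", "class",
                                    "force_pN", "delta_Lc_nm", "pathway"]
                     ).to_csv(path.with_suffix(".truth.csv"), index=False)
    return path


def _parse_metadata(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, val = body.split("=", 1)
                for cast in (int, float):
                    try:
                        val = cast(val)
                        break
                    except ValueError:
                        continue
                if val == "True":
                    val = True
                elif val == "False":
                    val = False
                meta[key.strip()] = val
    return meta


def read_trace(path, load_truth: bool = True) -> ForceExtensionTrace:
    """Read a trace written by :func:`write_trace`."""
    path = Path(path)
    meta = _parse_metadata(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing trace columns {missing}")
    truth = None
    sidecar = path.with_suffix(".truth.csv")
    if load_truth and sidecar.exists():
        tdf = pd.read_csv(sidecar)
        truth = [TruthEvent(index=-1, time_s=row.rupture_time_s,
                            unit_label=row.unit_label, class_label=row["class"],
                            force_pN=row.force_pN, delta_Lc_nm=row.delta_Lc_nm,
                            pathway=row.pathway)
                 for _, row in tdf.iterrows()]
    trace_id = str(meta.pop("trace_id", path.stem))
    return ForceExtensionTrace(
        time=df["time_s"].to_numpy(), stage_position=df["stage_nm"].to_numpy(),
        extension=df["extension_nm"].to_numpy(), force=df["force_pN"].to_numpy(),
        metadata=meta, truth=truth, trace_id=trace_id)


def read_force_extension(path, extension_col="extension_nm",
                         force_col="force_pN", time_col=None,
                         sep=None) -> ForceExtensionTrace:
    """Load a generic delimited recording via a column mapping.

    Columns may be named or given as integer positions.  Without a time
    column, sample index is used; the stage position is reconstructed as
    extension + force/k_c only when a ``spring_constant_pN_nm`` metadata
    entry exists, otherwise extension is used (strictly increasing input
    required)."""
    path = Path(path)
    meta = _parse_metadata(path)
    df = pd.read_csv(path, sep=sep, comment="#", engine="python")

    def col(spec):
        if isinstance(spec, int):
            return df.iloc[:, spec].to_numpy(dtype=float)
        return df[spec].to_numpy(dtype=float)

    ext = col(extension_col)
    force = col(force_col)
    time = col(time_col) if time_col is not None else np.arange(len(ext), dtype=float)
    kc = meta.get("spring_constant_pN_nm")
    stage = ext + force / kc if kc else ext.copy()
    return ForceExtensionTrace(time=time, stage_position=stage, extension=ext,
                               force=force, metadata=meta, truth=None,
                               trace_id=path.stem)


def write_events(events_by_trace: dict, path, gate_by_trace: dict | None = None) -> Path:
    """Write an events CSV: one row per unfolding event across traces."""
    rows = []
    for tid, events in events_by_trace.items():
        gated = None
        if gate_by_trace is not None and tid in gate_by_trace:
            gated = gate_by_trace[tid].accepted
        for ev in events:
            rows.append({"trace_id": tid, "index": ev.index,
                         "force_pN": ev.rupture_force,
                         "Lc_before_nm": ev.Lc_before, "Lc_after_nm": ev.Lc_after,
                         "delta_Lc_nm": ev.delta_Lc, "class": ev.class_label,
                         "gated": gated})
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=["trace_id", "index", "force_pN", "Lc_before_nm",
                                "Lc_after_nm", "delta_Lc_nm", "class", "gated"]
                 ).to_csv(path, index=False)
    return path


def read_events(path) -> dict:
    """Read an events CSV back into {trace_id: [UnfoldingEvent, ...]}."""
    from .analyze import UnfoldingEvent

    df = pd.read_csv(path)
    out: dict[str, list] = {}
    for _, row in df.iterrows():
        ev = UnfoldingEvent(index=int(row["index"]),
                            rupture_force=float(row["force_pN"]),
                            Lc_before=float(row["Lc_before_nm"]),
                            Lc_after=float(row["Lc_after_nm"]),
                            delta_Lc=float(row["delta_Lc_nm"]),
                            class_label=str(row["class"]))
        out.setdefault(str(row["trace_id"]), []).append(ev)
    return out
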
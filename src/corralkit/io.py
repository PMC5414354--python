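"""Readers and writers for the tabular text formats the pipeline exchanges.

Traces travel as tidy tables (corral_id, time_s, intensity); tracks as
TrackMate-style CSV (TRACK_ID, FRAME, POSITION_X, POSITION_Y in μm);
binding events, FCS curves and lane profiles as two-or-more-column tables;
ground truth as a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .activity import IntensityTrace
from .binding import BindingEventStream
from .diffusion import TrackSet
from .synthetic import GroundTruth


def write_traces(traces: list[IntensityTrace], path: str | Path) -> None:
    rows = [
        {"corral_id": tr.corral_id, "time_s": t, "intensity": v}
        for tr in traces
        for t, v in zip(tr.times, tr.values)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_traces(path: str | Path) -> list[IntensityTrace]:
    df = pd.read_csv(path)
    traces = []
    for cid, grp in df.groupby("corral_id", sort=False):
        t = grp["time_s"].to_numpy(float)
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        traces.append(IntensityTrace(str(cid), t, grp["intensity"].to_numpy(float), dt))
    return traces


def write_tracks(tracks: TrackSet, path: str | Path) -> None:
    rows = [
        {"TRACK_ID": i, "FRAME": int(f), "POSITION_X": x, "POSITION_Y": y}
        for i, trk in enumerate(tracks.tracks)
        for f, x, y in trk
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks(path: str | Path, frame_interval: float) -> TrackSet:
    """Read TrackMate-style CSV; non-numeric extra header rows (as in real
    TrackMate exports) are dropped."""
    df = pd.read_csv(path)
    for col in ("TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"):
        if col not in df.columns:
            raise ValueError(f"missing column {col}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.dropna(subset=["TRACK_ID", "FRAME", "POSITION_X", "POSITION_Y"])
    tracks = [
        grp.sort_values("FRAME")[["FRAME", "POSITION_X", "POSITION_Y"]].to_numpy(float)
        for _, grp in df.groupby("TRACK_ID", sort=True)
    ]
    return TrackSet(tracks, frame_interval)


def write_events(streams: list[BindingEventStream], path: str | Path) -> None:
    rows = [
        {
            "construct": s.construct, "membrane": s.membrane,
            "concentration_nM": s.concentration, "field_id": s.field_id,
            "duration_s": s.duration, "event_time_s": t,
        }
        for s in streams
        for t in s.event_times
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_events(path: str | Path) -> list[BindingEventStream]:
    df = pd.read_csv(path)
    streams = []
    keys = ["construct", "membrane", "concentration_nM", "field_id", "duration_s"]
    for vals, grp in df.groupby(keys, sort=False):
        construct, membrane, conc, fid, dur = vals
        streams.append(
            BindingEventStream(
                construct=str(construct), membrane=str(membrane),
                concentration=float(conc), duration=float(dur),
                event_times=grp["event_time_s"].to_numpy(float), field_id=str(fid),
            )
        )
    return streams


def write_fcs(lags: np.ndarray, g: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"lag_s": lags, "G": g}).to_csv(path, index=False)


def read_fcs(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["lag_s"].to_numpy(float), df["G"].to_numpy(float)


def read_stack(path: str | Path) -> np.ndarray:
    """Read a TIFF image stack as a (frames, rows, cols) array."""
    import tifffile

    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_stack(stack: np.ndarray, path: str | Path) -> None:
    import tifffile

    tifffile.imwrite(path, np.asarray(stack))


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "enzyme_counts": truth.enzyme_counts,
        "state_paths": {
            cid: {"breakpoint_times": sp.breakpoint_times, "turnovers": sp.turnovers}
            for cid, sp in truth.state_paths.items()
        },
        "species_labels": truth.species_labels,
        "arrival_rate": truth.arrival_rate,
        "d": truth.d,
        "density": truth.density,
    }
    Path(path).write_text(json.dumps(payload, indent=1))
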
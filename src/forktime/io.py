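"""Readers and writers for the pipeline's on-disk formats.

Movies are OME-TIFF with axes TCZYX (written/read via tifffile); all tables
are tidy CSV handled by pandas; configurations are YAML snapshots of the
dataclasses.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .foci import CellTrace, SpotDetection, Track
from .kinetics import ReplicationEvent
from .simulate import AcquisitionConfig, MovieStack, ScenarioConfig

MOVIE_AXES = "TCZYX"


def write_movie(path, movie: MovieStack) -> None:
    """Write a movie as OME-TIFF with TCZYX axes; config as YAML sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.data, ome=True, metadata={"axes": MOVIE_AXES})
    sidecar = path.with_suffix(path.suffix + ".yaml")
    sidecar.write_text(yaml.safe_dump(dataclasses.asdict(movie.config)))


def read_movie(path) -> MovieStack:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
    if axes != MOVIE_AXES:
        # tolerate squeezed singleton axes by reshaping via the sidecar config
        data = data.reshape([-1])  # will be reshaped below
    sidecar = path.with_suffix(path.suffix + ".yaml")
    if sidecar.exists():
        cfg = AcquisitionConfig(**yaml.safe_load(sidecar.read_text()))
    else:
        raise FileNotFoundError(f"missing acquisition sidecar {sidecar}")
    shape = (cfg.n_frames, 2, cfg.n_z, cfg.ny, cfg.nx)
    return MovieStack(data=np.asarray(data, dtype=np.float32).reshape(shape), config=cfg)


def scenario_to_yaml(scenario: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(scenario)))


def scenario_from_yaml(path) -> ScenarioConfig:
    return ScenarioConfig(**yaml.safe_load(Path(path).read_text()))


def acquisition_from_yaml(path) -> AcquisitionConfig:
    return AcquisitionConfig(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# tidy tables


def traces_to_frame(traces: list[CellTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        for chan, y in (("green", tr.intensity_green), ("red", tr.intensity_red)):
            for t, v in zip(tr.times, y):
                rows.append((tr.cell_id, chan, float(t), float(v)))
    return pd.DataFrame(rows, columns=["cell_id", "channel", "t_min", "intensity"])


def frame_to_traces(df: pd.DataFrame, provenance: str = "measured") -> list[CellTrace]:
    traces = []
    for cid, sub in df.groupby("cell_id", sort=True):
        piv = sub.pivot_table(index="t_min", columns="channel", values="intensity")
        piv = piv.sort_index()
        traces.append(
            CellTrace(
                cell_id=str(cid),
                times=piv.index.to_numpy(dtype=float),
                intensity_green=piv.get("green", pd.Series(np.nan, index=piv.index)).to_numpy(),
                intensity_red=piv.get("red", pd.Series(np.nan, index=piv.index)).to_numpy(),
                provenance=provenance,
            )
        )
    return traces


def detections_to_frame(dets: list[SpotDetection]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (d.frame, d.channel, *d.position, d.raw_score, d.intensity, d.clipped)
            for d in dets
        ],
        columns=["frame", "channel", "z", "y", "x", "raw_score", "intensity", "clipped"],
    )


def frame_to_detections(df: pd.DataFrame) -> list[SpotDetection]:
    return [
        SpotDetection(
            frame=int(r.frame), channel=str(r.channel),
            position=(float(r.z), float(r.y), float(r.x)),
            raw_score=float(r.raw_score), intensity=float(r.intensity),
            clipped=bool(r.clipped),
        )
        for r in df.itertuples()
    ]


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    frames = []
    for tid, tr in enumerate(tracks):
        df = detections_to_frame(tr.detections)
        df.insert(0, "track_id", tid)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["track_id", "frame", "channel", "z", "y", "x",
                     "raw_score", "intensity", "clipped"]
        )
    return pd.concat(frames, ignore_index=True)


def frame_to_tracks(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for _, sub in df.groupby("track_id", sort=True):
        dets = frame_to_detections(sub.sort_values("frame"))
        frames = [d.frame for d in dets]
        gaps = [f for f in range(frames[0], frames[-1] + 1) if f not in set(frames)]
        tracks.append(Track(channel=dets[0].channel, detections=dets, gaps=gaps))
    return tracks


def events_to_frame(events: list[ReplicationEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cell_id": ev.cell_id,
                "t_mid_green": ev.t_mid_green,
                "t_mid_red": ev.t_mid_red,
                "delta_t": ev.delta_t,
                "distance_kb": ev.distance_kb,
                "rate": ev.rate,
                "qc_pass": ev.qc_pass,
                "qc_reasons": ";".join(ev.qc_reasons),
            }
            for ev in events
        ]
    )


def fits_to_frame(events: list[ReplicationEvent]) -> pd.DataFrame:
    rows = []
    for ev in events:
        for fit in (ev.fit_green, ev.fit_red):
            if fit is None:
                continue
            rows.append(
                {
                    "cell_id": ev.cell_id,
                    "channel": fit.channel,
                    "B": fit.B,
                    "A": fit.A,
                    "t_mid": fit.t_mid,
                    "tau": fit.tau,
                    "bleach_rate": fit.bleach_rate,
                    "r_squared": fit.r_squared,
                    "converged": fit.converged,
                }
            )
    return pd.DataFrame(rows)


def frame_to_events(df: pd.DataFrame) -> list[ReplicationEvent]:
    events = []
    for r in df.itertuples():
        reasons = [s for s in str(getattr(r, "qc_reasons", "") or "").split(";") if s]
        events.append(
            ReplicationEvent(
                cell_id=str(r.cell_id),
                t_mid_green=float(r.t_mid_green),
                t_mid_red=float(r.t_mid_red),
                delta_t=float(r.delta_t),
                distance_kb=float(r.distance_kb),
                rate=float(r.rate),
                qc_pass=bool(r.qc_pass),
                qc_reasons=reasons,
            )
        )
    return events


def ground_truth_to_frame(gts) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(g) for g in gts])
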
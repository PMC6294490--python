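"""Convenience drivers chaining the movie-analysis stages.

``movie_to_traces`` runs detection, intensity measurement, per-channel
tracking and green/red pairing on a :class:`~forktime.simulate.MovieStack`;
``movie_to_events`` continues through sigmoid fitting and QC.  These are the
same stages the CLI exposes individually.
"""

from __future__ import annotations

from . import foci, kinetics
from .geometry import DEFAULT_DISTANCE_KB
from .simulate import MovieStack

__all__ = ["movie_to_traces", "movie_to_events"]


def movie_to_traces(
    movie: MovieStack,
    *,
    k_sigma: float = 5.0,
    max_displacement: float = 0.8,
    max_gap: int = 2,
    min_track_length: int = 5,
    pairing_radius: float = 2.0,
) -> tuple[list[foci.CellTrace], list[foci.Track]]:
    """Detect, measure, track and pair foci; returns (traces, unpaired)."""
    acq = movie.config
    params = foci.DetectionParams(
        sigma_z_vox=acq.psf_sigma_z / acq.z_step,
        sigma_xy_vox=acq.psf_sigma_xy / acq.pixel_size,
        k_sigma=k_sigma,
    )
    iparams = foci.IntensityParams(z_step=acq.z_step, pixel_size=acq.pixel_size)
    per_chan: dict[str, list[foci.SpotDetection]] = {c: [] for c in foci.CHANNELS}
    for f in range(acq.n_frames):
        for c, chan in enumerate(foci.CHANNELS):
            vol = movie.data[f, c]
            dets = foci.detect_spots(vol, params, frame=f, channel=chan)
            for d in dets:
                d.intensity, d.clipped = foci.measure_intensity(vol, d.position, iparams)
            per_chan[chan].extend(dets)
    tracks = {
        chan: foci.link_tracks(
            per_chan[chan],
            max_displacement=max_displacement,
            max_gap=max_gap,
            z_step=acq.z_step,
            pixel_size=acq.pixel_size,
            min_length=min_track_length,
        )
        for chan in foci.CHANNELS
    }
    return foci.assemble_cell_traces(
        tracks["green"],
        tracks["red"],
        pairing_radius=pairing_radius,
        n_frames=acq.n_frames,
        frame_interval=acq.frame_interval,
        z_step=acq.z_step,
        pixel_size=acq.pixel_size,
    )


def movie_to_events(
    movie: MovieStack,
    *,
    distance_kb: float = DEFAULT_DISTANCE_KB,
    criteria: kinetics.QCCriteria = kinetics.QCCriteria(),
    **trace_kwargs,
) -> tuple[list[kinetics.ReplicationEvent], list[kinetics.ReplicationEvent]]:
    """Full movie analysis; returns (qc_passed, qc_failed) events."""
    traces, _ = movie_to_traces(movie, **trace_kwargs)
    events = [kinetics.fit_trace(tr, distance_kb=distance_kb) for tr in traces]
    return kinetics.qc_filter(events, criteria)
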
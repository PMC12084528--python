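"""Frame-to-frame bead linking, repeat averaging and quality control.

The flow is designed so every bead is imaged in at least two consecutive
bead frames.  A detection's position in the next bead frame is predicted
from its decoded velocity (beads do not measurably accelerate on the
frame timescale); detections are greedily linked within a pixel
tolerance, repeats of each dye are averaged, and beads are kept only if
they were seen at least twice with per-dye repeat CVs at or below a
threshold (20% by default) — a fluorescence-only stand-in for the
scatter gates a flow cytometer would use to reject junk events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demod import BeadDetection
from .simulate import ExcitationSchedule


@dataclass
class TrackedBead:
    """Detections of one physical bead across consecutive bead frames."""

    detections: list[BeadDetection]
    b1_mean: float = np.nan
    b2_mean: float = np.nan
    cv1: float = np.nan
    cv2: float = np.nan
    included: bool = False
    exclusion_reason: str = ""

    @property
    def channel(self) -> int:
        return self.detections[0].n

    @property
    def frames(self) -> list[int]:
        return [d.m for d in self.detections]


def predict_location(x_c: float, v_c: float,
                     schedule: ExcitationSchedule) -> float:
    """Predicted streak start in the next bead frame.

    ``x_predicted = x_c + v_c * dt`` with ``dt = T1 + T2 + dead_time``
    in HDR mode (one substrate frame sits between bead frames) and
    ``dt = T1 + dead_time`` otherwise.
    """
    return x_c + v_c * schedule.bead_frame_interval


def _split_long_track(dets: list[BeadDetection],
                      schedule: ExcitationSchedule,
                      max_len: int) -> list[list[BeadDetection]]:
    """Split a chain longer than a bead can physically persist at the
    largest prediction residual, recursively."""
    if len(dets) <= max_len:
        return [dets]
    residuals = [
        abs(dets[i + 1].x_c - predict_location(dets[i].x_c, dets[i].v_c,
                                               schedule))
        for i in range(len(dets) - 1)
    ]
    cut = int(np.argmax(residuals)) + 1
    return (_split_long_track(dets[:cut], schedule, max_len)
            + _split_long_track(dets[cut:], schedule, max_len))


def link_detections(detections: list[BeadDetection],
                    schedule: ExcitationSchedule,
                    match_tolerance: float,
                    trace_length: int | None = None) -> list[TrackedBead]:
    """Greedily link per-frame detections into per-bead tracks.

    Within each channel, frames are visited in order; each open track's
    next position is predicted from its last detection and the nearest
    unmatched detection within ``match_tolerance`` pixels extends it.
    Unmatched detections open new (possibly singleton) tracks.  Tracks
    longer than the number of bead frames a bead can physically occupy
    in the field of view are split at the largest prediction residual.
    """
    by_channel: dict[int, dict[int, list[BeadDetection]]] = {}
    for d in detections:
        by_channel.setdefault(d.n, {}).setdefault(d.m, []).append(d)

    tracks: list[list[BeadDetection]] = []
    for channel in sorted(by_channel):
        frames = sorted(by_channel[channel])
        open_tracks: list[list[BeadDetection]] = []
        for mi, m in enumerate(frames):
            dets = sorted(by_channel[channel][m], key=lambda d: d.x_c)
            # close tracks whose last frame is not the previous bead frame
            still_open = []
            for t in open_tracks:
                if frames.index(t[-1].m) == mi - 1:
                    still_open.append(t)
                else:
                    tracks.append(t)
            open_tracks = still_open

            preds = [predict_location(t[-1].x_c, t[-1].v_c, schedule)
                     for t in open_tracks]
            used = [False] * len(dets)
            matched_tracks = []
            for t, pred in sorted(zip(open_tracks, preds),
                                  key=lambda tp: tp[1]):
                best_j, best_err = -1, match_tolerance
                for j, d in enumerate(dets):
                    if used[j]:
                        continue
                    err = abs(d.x_c - pred)
                    if err <= best_err:
                        best_j, best_err = j, err
                if best_j >= 0:
                    used[best_j] = True
                    t.append(dets[best_j])
                    matched_tracks.append(t)
                else:
                    tracks.append(t)
            open_tracks = matched_tracks
            for j, d in enumerate(dets):
                if not used[j]:
                    open_tracks.append([d])
        tracks.extend(open_tracks)

    if trace_length is not None:
        out: list[list[BeadDetection]] = []
        for t in tracks:
            v = np.mean([d.v_c for d in t])
            dt = schedule.bead_frame_interval
            max_len = max(2, int(np.ceil(trace_length / (v * dt))) + 1)
            out.extend(_split_long_track(t, schedule, max_len))
        tracks = out

    return [TrackedBead(detections=t) for t in tracks]


def average_and_qc(tracks: list[TrackedBead],
                   cv_threshold: float = 0.20) -> list[TrackedBead]:
    """Average repeat measurements per dye and apply the inclusion rules.

    A bead is included only if it was detected in at least two frames
    and both per-dye repeat CVs (sample SD over mean) are at or below
    ``cv_threshold``.  Tracks are annotated in place and all returned;
    filter on ``included`` for the analysis set.
    """
    for t in tracks:
        b1 = np.array([d.b1 for d in t.detections], dtype=float)
        b2 = np.array([d.b2 for d in t.detections], dtype=float)
        t.b1_mean = float(b1.mean())
        t.b2_mean = float(b2.mean())
        if len(t.detections) < 2:
            t.included = False
            t.exclusion_reason = "singleton"
            continue
        t.cv1 = float(b1.std(ddof=1) / b1.mean()) if b1.mean() > 0 else np.inf
        t.cv2 = float(b2.std(ddof=1) / b2.mean()) if b2.mean() > 0 else np.inf
        if max(t.cv1, t.cv2) > cv_threshold:
            t.included = False
            t.exclusion_reason = "high_cv"
        else:
            t.included = True
            t.exclusion_reason = ""
    return tracks


def tracks_to_frame(tracks: list[TrackedBead]) -> pd.DataFrame:
    """Tabulate tracks: one row per track with means, CVs and QC flags."""
    rows = []
    for i, t in enumerate(tracks):
        rows.append({
            "track_id": i,
            "channel": t.channel,
            "n_detections": len(t.detections),
            "first_frame": t.detections[0].m,
            "x_first": t.detections[0].x_c,
            "v_mean": float(np.mean([d.v_c for d in t.detections])),
            "b1_mean": t.b1_mean,
            "b2_mean": t.b2_mean,
            "cv1": t.cv1,
            "cv2": t.cv2,
            "included": t.included,
            "exclusion_reason": t.exclusion_reason,
        })
    return pd.DataFrame(rows, columns=[
        "track_id", "channel", "n_detections", "first_frame", "x_first",
        "v_mean", "b1_mean", "b2_mean", "cv1", "cv2", "included",
        "exclusion_reason"])
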
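"""End-to-end orchestration: frames in, detections/tracks/calls out.

``decode_stack`` runs the full decoding chain on a frame stack:
preprocessing each bead frame into normalized channel traces, matched-
filter decoding of every trace, frame-to-frame linking with repeat
averaging and CV-based quality control, then digital substrate calling
against the adjacent substrate frames.  ``match_tracks_to_truth`` maps
decoded tracks back onto a simulator ground-truth table for accuracy
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calls import (DropletCall, call_droplet, substrate_threshold,
                    substrate_window, window_signal)
from .config import RunConfig
from .demod import BeadDetection, decode_trace
from .preprocess import FrameStack, frame_to_traces, smooth_background
from .track import TrackedBead, average_and_qc, link_detections, \
    tracks_to_frame


@dataclass
class DecodeResult:
    detections: list[BeadDetection]
    tracks: list[TrackedBead]
    track_table: pd.DataFrame
    calls: list[DropletCall]
    call_table: pd.DataFrame


def detections_to_frame(detections: list[BeadDetection]) -> pd.DataFrame:
    rows = [{
        "m": d.m, "n": d.n, "x_c": d.x_c, "v_c": d.v_c,
        "p1": d.p1, "p2": d.p2, "b1": d.b1, "b2": d.b2,
        "snr": d.snr, "flags": ";".join(d.flags),
    } for d in detections]
    return pd.DataFrame(rows, columns=["m", "n", "x_c", "v_c", "p1", "p2",
                                       "b1", "b2", "snr", "flags"])


def decode_stack(stack: FrameStack, backgrounds: dict[str, np.ndarray],
                 config: RunConfig, bank=None) -> DecodeResult:
    """Run preprocessing, decoding, tracking, QC and substrate calling.

    ``backgrounds`` maps frame role to a background frame (expected
    counts); measured backgrounds should be averaged over several
    bead-free frames upstream and are Gaussian-smoothed here before
    division.
    """
    geometry = config.geometry
    schedule = config.schedule
    if bank is None:
        bank = config.mask_bank()
    bg = {role: smooth_background(img) for role, img in backgrounds.items()}

    bead_frames = stack.frame_indices("bead")
    traces_by_frame: dict[int, np.ndarray] = {}
    detections: list[BeadDetection] = []
    for m in bead_frames:
        traces = frame_to_traces(stack.frames[m], bg["bead"], geometry,
                                 stack.calibration)
        traces_by_frame[m] = traces
        for n in range(geometry.n_channels):
            detections.extend(
                decode_trace(traces[n], bank, m=m, n=n,
                             k_mad=config.detection_k_mad))

    tracks = link_detections(detections, schedule,
                             config.match_tolerance_px(),
                             trace_length=geometry.trace_length)
    tracks = average_and_qc(tracks, config.cv_threshold)
    track_table = tracks_to_frame(tracks)

    calls: list[DropletCall] = []
    substrate_frames = stack.frame_indices("substrate")
    if substrate_frames:
        sub_traces = {m: frame_to_traces(stack.frames[m], bg["substrate"],
                                         geometry, stack.calibration)
                      for m in substrate_frames}
        threshold, _ = compute_substrate_threshold(
            detections, sub_traces, geometry, schedule,
            n_sigma=config.substrate_n_sigma)
        calls = call_tracks(tracks, sub_traces, schedule, geometry,
                            threshold)
    call_table = pd.DataFrame(
        [{"track_id": c.track_id, "signal": c.signal,
          "threshold": c.threshold, "positive": c.positive}
         for c in calls],
        columns=["track_id", "signal", "threshold", "positive"])

    return DecodeResult(detections=detections, tracks=tracks,
                        track_table=track_table, calls=calls,
                        call_table=call_table)


def compute_substrate_threshold(detections, sub_traces, geometry, schedule,
                                n_sigma: float = 4.0,
                                nominal_v: float | None = None,
                                ) -> tuple[float, np.ndarray]:
    """Threshold from bead-free background windows in substrate frames.

    Windows of the nominal substrate-streak length are tiled over every
    channel, excluding (with one window length of margin) any region
    where a bead detected in an adjacent bead frame could have left a
    substrate streak; the threshold is ``mean + n_sigma * SD`` of the
    remaining windows' baseline-subtracted sums.
    """
    if nominal_v is None:
        if detections:
            nominal_v = float(np.median([d.v_c for d in detections]))
        else:
            nominal_v = geometry.trace_length / 3 / schedule.t1
    win_len = max(int(round(nominal_v * schedule.t2)), 1)

    # exclusion intervals per (substrate frame, channel)
    excluded: dict[tuple[int, int], list[tuple[float, float]]] = {}
    for d in detections:
        length = d.v_c * schedule.t2
        succ = d.x_c + d.v_c * schedule.t1   # streak in frame m+1's slot?
        for m_sub, start in ((d.m + 1, succ), (d.m - 1, d.x_c - length)):
            excluded.setdefault((m_sub, d.n), []).append(
                (start - win_len, start + length + win_len))

    sums = []
    for m, traces in sorted(sub_traces.items()):
        for n in range(geometry.n_channels):
            spans = excluded.get((m, n), [])
            trace = traces[n]
            for lo in range(0, geometry.trace_length - win_len, win_len):
                hi = lo + win_len
                if any(lo < b and hi > a for a, b in spans):
                    continue
                sums.append(window_signal(trace, (lo, win_len)))
    return substrate_threshold(np.asarray(sums), n_sigma), np.asarray(sums)


def call_tracks(tracks, sub_traces, schedule, geometry,
                threshold: float) -> list[DropletCall]:
    """Digital substrate call per included track.

    Both the preceding and the succeeding substrate frame of every
    detection are checked; the droplet is positive if any in-bounds
    window's signal exceeds the threshold.
    """
    calls = []
    for i, t in enumerate(tracks):
        if not t.included:
            continue
        best = -np.inf
        windows = []
        for d in t.detections:
            for direction, m_sub in (("preceding", d.m - 1),
                                     ("succeeding", d.m + 1)):
                if m_sub not in sub_traces:
                    continue
                w = substrate_window(d, schedule, direction,
                                     geometry.trace_length)
                if w is None:
                    continue
                windows.append(w)
                best = max(best, window_signal(sub_traces[m_sub][d.n], w))
        if not np.isfinite(best):
            continue  # no in-bounds window: no-call
        call = call_droplet(best, threshold, track_id=i)
        call.windows = windows
        calls.append(call)
    return calls


def match_tracks_to_truth(track_table: pd.DataFrame, truth: pd.DataFrame,
                          tolerance_px: float = 10.0) -> pd.DataFrame:
    """Attach true bead identity to decoded tracks by position.

    A track matches a truth bead when it sits in the same channel,
    starts in the bead's first designated frame, and its first decoded
    streak start lies within ``tolerance_px`` of the true one.  Returns
    the track table with ``bead_id``, ``true_group``, ``true_b1/b2`` and
    ``true_hrp`` columns (NaN where unmatched).
    """
    tt = track_table.copy()
    tt["bead_id"] = -1
    tt["true_group"] = pd.NA
    tt["true_b1"] = np.nan
    tt["true_b2"] = np.nan
    tt["true_hrp"] = pd.NA
    used = set()
    truth_idx = {}
    for r in truth.itertuples():
        truth_idx.setdefault((r.channel, r.frame), []).append(r)
    for i, row in tt.iterrows():
        cands = truth_idx.get((row["channel"], row["first_frame"]), [])
        best, best_err = None, tolerance_px
        for r in cands:
            if r.bead_id in used:
                continue
            err = abs(row["x_first"] - r.x0_px)
            if err <= best_err:
                best, best_err = r, err
        if best is not None:
            used.add(best.bead_id)
            tt.loc[i, ["bead_id", "true_group", "true_b1", "true_b2",
                       "true_hrp"]] = [best.bead_id, best.group, best.b1,
                                       best.b2, best.hrp_positive]
    return tt
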
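"""Digital substrate calling, population gating and accuracy reporting.

Substrate (HRP) calling: each decoded bead's location and velocity fix
where its droplet's substrate streak must lie in the adjacent substrate
frames — the streak of length ``v*T2`` ends exactly where the bead
streak begins (succeeding-frame geometry mirrored for the preceding
frame).  The baseline-subtracted normalized intensity summed over that
window is compared to a threshold set 4 standard deviations above the
mean of bead-free background window sums, giving the digital on/off
droplet call.

Gating: bead populations are classified by simple closed regions in the
``(b1, b2)`` intensity plane.  Gates may be fit programmatically as
per-group covariance ellipses at a fixed Mahalanobis radius or loaded
from a polygon file; classification is point-in-polygon with points in
no gate labelled unclassified and points in several gates ambiguous
(excluded from accuracy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Point, Polygon

from .demod import BeadDetection
from .simulate import ExcitationSchedule

UNCLASSIFIED = "unclassified"
AMBIGUOUS = "ambiguous"


# ---------------------------------------------------------------------------
# substrate calling


@dataclass
class DropletCall:
    """Digital substrate call for one tracked bead's droplet."""

    track_id: int
    signal: float          # best (max) baseline-subtracted window sum
    threshold: float
    positive: bool
    windows: list[tuple[int, int]] = field(default_factory=list)


def substrate_window(bead: BeadDetection, schedule: ExcitationSchedule,
                     direction: str,
                     trace_length: int) -> tuple[int, int] | None:
    """Expected substrate-streak window in the adjacent substrate frame.

    For the *preceding* substrate frame the streak ends where the bead
    streak starts: ``[x_c - v*T2, x_c]``.  For the *succeeding* frame it
    starts where the bead streak ends: ``[x_c + v*T1, x_c + v*(T1+T2)]``.
    Returns ``(start, length)`` in pixels clipped to the trace, or
    ``None`` (no-call) when the window is degenerate or fully outside.
    """
    if direction not in ("preceding", "succeeding"):
        raise ValueError("direction must be 'preceding' or 'succeeding'")
    if bead.v_c <= 0:
        return None
    length = bead.v_c * schedule.t2
    if direction == "preceding":
        start = bead.x_c - length
    else:
        start = bead.x_c + bead.v_c * schedule.t1
    lo = int(round(max(start, 0)))
    hi = int(round(min(start + length, trace_length)))
    if hi - lo < 1:
        return None
    return lo, hi - lo


def window_signal(trace: np.ndarray, window: tuple[int, int]) -> float:
    """Baseline-subtracted normalized intensity summed over a window.

    The trace median (~1 after background normalization) is the
    baseline, so bead-free windows sum to ~0 regardless of length.
    """
    trace = np.asarray(trace, dtype=float)
    lo, length = window
    return float(np.sum(trace[lo:lo + length] - np.median(trace)))


def substrate_threshold(background_sums: np.ndarray,
                        n_sigma: float = 4.0) -> float:
    """Digital threshold: mean + ``n_sigma`` SD of bead-free window sums."""
    background_sums = np.asarray(background_sums, dtype=float)
    if background_sums.size < 30:
        raise ValueError(
            f"need >= 30 background window sums, got {background_sums.size}"
        )
    return float(background_sums.mean()
                 + n_sigma * background_sums.std(ddof=1))


def call_droplet(signal: float, threshold: float,
                 track_id: int = -1) -> DropletCall:
    """Digital presence/absence call: positive iff ``signal > threshold``."""
    if not (np.isfinite(signal) and np.isfinite(threshold)):
        raise ValueError("signal and threshold must be finite")
    return DropletCall(track_id=track_id, signal=float(signal),
                       threshold=float(threshold),
                       positive=bool(signal > threshold))


# ---------------------------------------------------------------------------
# gating


@dataclass
class GateSet:
    """Labelled simple polygons in the ``(b1, b2)`` intensity plane."""

    polygons: dict[str, Polygon]

    def __post_init__(self) -> None:
        for label, poly in self.polygons.items():
            if not poly.is_valid or not poly.is_simple:
                raise ValueError(f"gate {label!r} is not a simple polygon")

    @property
    def labels(self) -> list[str]:
        return list(self.polygons)

    @classmethod
    def fit_ellipses(cls, b1: np.ndarray, b2: np.ndarray,
                     labels: np.ndarray, radius: float = 3.0,
                     n_vertices: int = 64) -> "GateSet":
        """Fit per-group covariance-ellipse gates at a Mahalanobis radius.

        A reproducible stand-in for manually drawn gates: each group's
        gate is the ellipse of its empirical mean and covariance scaled
        to ``radius`` Mahalanobis units, discretised to a polygon.
        """
        b1 = np.asarray(b1, dtype=float)
        b2 = np.asarray(b2, dtype=float)
        labels = np.asarray(labels)
        polys = {}
        for lab in pd.unique(labels):
            pts = np.c_[b1[labels == lab], b2[labels == lab]]
            if len(pts) < 3:
                raise ValueError(f"group {lab!r} has fewer than 3 points")
            mu = pts.mean(axis=0)
            cov = np.cov(pts.T)
            w, V = np.linalg.eigh(cov)
            w = np.maximum(w, 1e-12)
            theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
            circle = np.c_[np.cos(theta), np.sin(theta)]
            ring = mu + radius * circle * np.sqrt(w) @ V.T
            polys[str(lab)] = Polygon(ring)
        return cls(polys)

    # -- persistence --------------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        d = {lab: list(map(list, poly.exterior.coords[:-1]))
             for lab, poly in self.polygons.items()}
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GateSet":
        d = json.loads(Path(path).read_text())
        return cls({lab: Polygon(coords) for lab, coords in d.items()})


def classify(b1: np.ndarray, b2: np.ndarray, gates: GateSet) -> np.ndarray:
    """Assign each ``(b1, b2)`` point to the unique gate containing it.

    Points inside no gate are ``"unclassified"``; points inside more
    than one are ``"ambiguous"`` and excluded from accuracy downstream.
    """
    b1 = np.asarray(b1, dtype=float)
    b2 = np.asarray(b2, dtype=float)
    out = np.empty(b1.size, dtype=object)
    items = list(gates.polygons.items())
    for i, (x, y) in enumerate(zip(b1, b2)):
        p = Point(x, y)
        hits = [lab for lab, poly in items if poly.covers(p)]
        if len(hits) == 1:
            out[i] = hits[0]
        elif not hits:
            out[i] = UNCLASSIFIED
        else:
            out[i] = AMBIGUOUS
    return out


# ---------------------------------------------------------------------------
# accuracy


@dataclass
class TruthTable:
    """Confusion of true vs called population, and classification accuracy.

    ``accuracy`` is the fraction of *gated* beads (those assigned a
    unique population) whose call matches their true group.
    """

    confusion: pd.DataFrame
    accuracy: float
    n_gated: int
    n_total: int


def truth_table(called: np.ndarray, true_labels: np.ndarray) -> TruthTable:
    """Cross-tabulate calls against truth and compute accuracy."""
    called = np.asarray(called, dtype=object)
    true_labels = np.asarray(true_labels, dtype=object)
    if called.size != true_labels.size:
        raise ValueError("label arrays differ in length")
    confusion = pd.crosstab(pd.Series(true_labels, name="true"),
                            pd.Series(called, name="called"), dropna=False)
    gated = ~np.isin(called, [UNCLASSIFIED, AMBIGUOUS])
    n_gated = int(gated.sum())
    correct = int(np.sum(called[gated] == true_labels[gated]))
    accuracy = correct / n_gated if n_gated else np.nan
    return TruthTable(confusion=confusion, accuracy=accuracy,
                      n_gated=n_gated, n_total=int(called.size))


def compare_positive_negative(values_positive: np.ndarray,
                              values_negative: np.ndarray) -> dict:
    """Two-sample summary of bead dye intensity for HRP-positive vs
    negative droplets (Welch t-test; no significance decision encoded).

    The substrate reaction happens in the droplet, not in the bead dyes,
    so under the imaging model the two groups share a distribution.
    """
    pos = np.asarray(values_positive, dtype=float)
    neg = np.asarray(values_negative, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    if pos.size > 1 and neg.size > 1 and (pos.std() > 0 or neg.std() > 0):
        t, p = stats.ttest_ind(pos, neg, equal_var=False)
    else:
        t, p = np.nan, np.nan
    return {
        "mean_positive": float(pos.mean()),
        "mean_negative": float(neg.mean()),
        "difference": float(pos.mean() - neg.mean()),
        "t_statistic": float(t),
        "p_value": float(p),
        "n_positive": int(pos.size),
        "n_negative": int(neg.size),
    }
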
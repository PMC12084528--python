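"""Matched-filter decoding of MLS-encoded channel traces.

For each normalized trace ``S(x)`` the decoder correlates against the
superimposed template ``MLS1(v, x) + MLS2(v, x)`` over a grid of
candidate velocities, producing the correlation matrix ``Psi(x, v)``
whose global maximum identifies the bead's velocity ``v_c`` and streak
start ``x_c``.  The two single-code correlations evaluated at
``(v_c, x_c)`` give raw peaks ``(p1, p2)``, which a 2x2 crosstalk
inversion converts into dye intensities ``(b1, b2)``: time bins where
both lasers are on make each code's matched filter pick up part of the
other dye's emission, so the raw peaks are a known linear mixture of the
true intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

from .mls import MaskBank, OverlapCounts


@dataclass
class CorrelationMap:
    """Correlation of one trace against the superimposed mask bank.

    ``psi[i, k]`` is the inner product at velocity index ``i`` and lag
    ``k``; lags where the mask would overhang the trace are ``-inf``.
    """

    psi: np.ndarray
    bank: MaskBank

    def best(self) -> tuple[int, int, float]:
        """Global argmax as ``(velocity_index, lag, value)``; ties break
        to the lowest velocity then the smallest lag."""
        flat = int(np.argmax(self.psi))
        i, k = np.unravel_index(flat, self.psi.shape)
        return int(i), int(k), float(self.psi[i, k])


@dataclass
class BeadDetection:
    """One decoded bead in one frame."""

    m: int                 # frame index
    n: int                 # channel index
    x_c: int               # streak start lag, pixels
    v_c: float             # decoded speed (bank units, px/ms by default)
    p1: float              # raw single-code correlation peaks
    p2: float
    b1: float              # crosstalk-corrected dye intensities
    b2: float
    snr: float
    flags: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class CrosstalkMatrix:
    """Linear map from dye intensities ``(b1, b2)`` to raw peaks ``(p1, p2)``.

    ``forward = M @ (b1, b2)``; the decoder applies the cached inverse.
    """

    matrix: np.ndarray
    inverse: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        if M.shape != (2, 2):
            raise ValueError("crosstalk matrix must be 2x2")
        det = np.linalg.det(M)
        if abs(det) < 1e-12 * max(1.0, float(np.abs(M).max()) ** 2):
            raise ValueError("crosstalk matrix is singular")
        object.__setattr__(self, "matrix", M)
        object.__setattr__(self, "inverse", np.linalg.inv(M))

    def forward(self, b1: float, b2: float) -> tuple[float, float]:
        p = self.matrix @ np.array([b1, b2])
        return float(p[0]), float(p[1])

    def invert(self, p1: float, p2: float) -> tuple[float, float]:
        b = self.inverse @ np.array([p1, p2])
        return float(b[0]), float(b[1])

    @classmethod
    def from_counts(cls, counts: OverlapCounts, bit_extent: float,
                    duty1: float = 1.0, duty2: float = 1.0) -> "CrosstalkMatrix":
        """Analytic matrix from on-bit/overlap counts and the bit extent:
        ``[[n1*d1, o*d2], [o*d1, n2*d2]] * bit_extent``."""
        M = np.array([[counts.n1 * duty1, counts.o * duty2],
                      [counts.o * duty1, counts.n2 * duty2]]) * bit_extent
        return cls(M)

    @classmethod
    def from_masks(cls, mask1: np.ndarray, mask2: np.ndarray,
                   duty1: float = 1.0, duty2: float = 1.0) -> "CrosstalkMatrix":
        """Exact matrix from the pixel-sampled templates' Gram products;
        coincides with :meth:`from_counts` for integer bit extents and
        absorbs nearest-pixel sampling effects for fractional ones."""
        L = max(mask1.size, mask2.size)
        m1 = np.zeros(L)
        m1[:mask1.size] = mask1
        m2 = np.zeros(L)
        m2[:mask2.size] = mask2
        g11, g12, g22 = m1 @ m1, m1 @ m2, m2 @ m2
        M = np.array([[g11 * duty1, g12 * duty2],
                      [g12 * duty1, g22 * duty2]])
        return cls(M)


def build_crosstalk_matrix(counts: OverlapCounts, bit_extent: float,
                           duty1: float = 1.0,
                           duty2: float = 1.0) -> CrosstalkMatrix:
    """Build the 2x2 crosstalk matrix and its cached inverse."""
    return CrosstalkMatrix.from_counts(counts, bit_extent, duty1, duty2)


def robust_sigma(trace: np.ndarray) -> float:
    """Robust per-pixel noise estimate: 1.4826 x the median absolute
    deviation from the median.  Streaks occupy at most roughly half the
    trace, so the MAD sees mostly background pixels."""
    trace = np.asarray(trace, dtype=float)
    med = np.median(trace)
    return float(1.4826 * np.median(np.abs(trace - med)))


def detection_threshold(trace: np.ndarray, mask_power: float,
                        k: float = 6.0, floor: float = 1e-6) -> float:
    """Matched-filter peak threshold for one correlation vector.

    The correlation of pure background noise of per-pixel sigma with a
    template of power ``sum(mask**2)`` has standard deviation
    ``sigma * sqrt(mask_power)``; the threshold is ``k`` of those, with
    a small absolute floor so noiseless all-zero traces never trigger.
    """
    return max(k * robust_sigma(trace) * float(np.sqrt(mask_power)), floor)


def scan_velocity(trace: np.ndarray, bank: MaskBank, k_mad: float = 6.0
                  ) -> tuple[CorrelationMap, float, int] | None:
    """Velocity search: correlate the trace with the superimposed mask at
    every grid velocity and take the global correlation maximum.

    Returns ``(map, v_c, x_c)`` when the maximum clears the matched-
    filter noise threshold at its own velocity, else ``None``.  The
    trace's median is subtracted first (normalized background sits at 1;
    the masks are non-negative).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0 or not np.all(np.isfinite(trace)):
        raise ValueError("trace must be non-empty and finite")
    centred = trace - np.median(trace)
    cmap = CorrelationMap(psi=bank.correlation_matrix(centred), bank=bank)
    i, k, value = cmap.best()
    if value <= detection_threshold(trace, bank.mask_power[i], k_mad):
        return None
    return cmap, float(bank.velocity_grid[i]), k


def locate_all_peaks(psi_at_vc: np.ndarray, min_separation: int,
                     threshold: float) -> list[int]:
    """Local maxima of a correlation vector above ``threshold``, with
    smaller peaks suppressed within ``min_separation`` lags (default use:
    one mask length, so two resolved beads cannot share support)."""
    vec = np.asarray(psi_at_vc, dtype=float)
    finite = np.isfinite(vec)
    if not finite.any():
        return []
    work = np.where(finite, vec, np.min(vec[finite]) - 1.0)
    peaks, props = _signal.find_peaks(work, height=threshold,
                                      distance=max(int(min_separation), 1))
    if peaks.size == 0:
        # a peak at the array boundary has no left/right neighbour for
        # find_peaks; fall back to the argmax if it clears the threshold
        k = int(np.argmax(work))
        if work[k] > threshold and finite[k]:
            return [k]
        return []
    order = np.argsort(props["peak_heights"])[::-1]
    return [int(p) for p in peaks[order]]


def quantify_bead(trace: np.ndarray, bank: MaskBank, v_index: int, x_c: int,
                  xtalk: CrosstalkMatrix, m: int = -1, n: int = -1,
                  snr: float = np.nan) -> BeadDetection:
    """Quantify one bead: single-code correlation peaks at ``(v_c, x_c)``
    and their crosstalk-corrected dye intensities.

    The raw peaks are inner products of the baseline-subtracted trace
    window with the unit-amplitude single-code templates at the decoded
    velocity.  Negative corrected intensities are clamped to zero and
    flagged.
    """
    trace = np.asarray(trace, dtype=float)
    mask1 = bank.masks1[v_index]
    mask2 = bank.masks2[v_index]
    L = max(mask1.size, mask2.size)
    flags: list[str] = []
    if x_c < 0 or x_c + L > trace.size:
        raise ValueError("mask support extends past the trace at x_c")
    seg = trace[x_c:x_c + L] - np.median(trace)
    p1 = float(seg[:mask1.size] @ mask1)
    p2 = float(seg[:mask2.size] @ mask2)
    b1, b2 = xtalk.invert(p1, p2)
    if b1 < 0 or b2 < 0:
        flags.append("negative_intensity")
        b1, b2 = max(b1, 0.0), max(b2, 0.0)
    return BeadDetection(m=m, n=n, x_c=int(x_c),
                         v_c=float(bank.velocity_grid[v_index]),
                         p1=p1, p2=p2, b1=b1, b2=b2, snr=snr, flags=flags)


def decode_trace(trace: np.ndarray, bank: MaskBank, m: int = -1, n: int = -1,
                 k_mad: float = 6.0, min_separation: int | None = None,
                 refine_velocity: bool = True) -> list[BeadDetection]:
    """Decode every resolvable bead in one normalized channel trace.

    Runs the velocity scan, locates all peaks at the best velocity, and
    quantifies each.  When several beads share a channel their speeds can
    differ slightly, so each peak's velocity is refined as the argmax
    over the grid within one bit extent of its lag.  Peaks whose mask
    support would overhang the trace are rejected (edge policy).
    """
    hit = scan_velocity(trace, bank, k_mad)
    if hit is None:
        return []
    cmap, _, _ = hit
    i_best, _, _ = cmap.best()
    if min_separation is None:
        min_separation = int(bank.mask_lengths[i_best])
    threshold = detection_threshold(trace, bank.mask_power[i_best], k_mad)
    peaks = locate_all_peaks(cmap.psi[i_best], min_separation, threshold)

    out: list[BeadDetection] = []
    for x_c in peaks:
        vi = i_best
        if refine_velocity:
            half = max(int(np.ceil(bank.bit_extent[i_best])), 1)
            lo, hi = max(x_c - half, 0), min(x_c + half + 1,
                                             cmap.psi.shape[1])
            window = cmap.psi[:, lo:hi]
            vi, kk = np.unravel_index(int(np.argmax(window)), window.shape)
            vi = int(vi)
            x_c = lo + int(kk)
        L = int(bank.mask_lengths[vi])
        if x_c + L > trace.size:
            continue  # truncated streak: cannot be quantified
        sigma_corr = detection_threshold(trace, bank.mask_power[vi],
                                         k=1.0)
        snr = cmap.psi[vi, x_c] / sigma_corr if sigma_corr > 0 else np.inf
        xt = CrosstalkMatrix.from_masks(bank.masks1[vi], bank.masks2[vi],
                                        duty1=bank.duty1)
        det = quantify_bead(trace, bank, vi, x_c, xt, m=m, n=n, snr=snr)
        out.append(det)
    out.sort(key=lambda d: d.x_c)
    return out
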
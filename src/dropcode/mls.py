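"""Maximal-length sequences and velocity-dependent excitation masks.

A bead moving at velocity ``v`` through a channel during an exposure of
duration ``T`` leaves a streak of length ``v*T`` pixels.  When the
excitation laser is switched according to a binary maximal-length sequence
(m-sequence, MLS) spanning the exposure, the streak carries the sequence
stretched to the streak length.  Because m-sequences have near-ideal
auto- and cross-correlation, correlating a channel trace with a bank of
velocity-scaled masks acts as a matched filter: the correlation peak
localises the bead and identifies its speed, and the peak magnitudes of
the two single-code correlations carry the two dye intensities.

This module provides the LFSR sequence generator, the mask renderer, the
pre-FFT'd :class:`MaskBank` used by the decoder, and the plain
inner-product correlation kernel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
from scipy import signal


@dataclass(frozen=True)
class MlsCode:
    """A binary maximal-length sequence with its generator parameters.

    Parameters
    ----------
    order : int
        LFSR register length ``r``; the sequence has period ``2**r - 1``.
    taps : tuple of int
        Exponents of the feedback (primitive) polynomial, excluding the
        constant term, e.g. ``(6, 1)`` for ``x^6 + x + 1``.
    seed : int
        Initial register state, nonzero, ``< 2**order``.
    bits : ndarray of uint8
        The 0/1 sequence of length ``2**order - 1``.
    """

    order: int
    taps: tuple[int, ...]
    seed: int
    bits: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        object.__setattr__(self, "bits", bits)
        object.__setattr__(self, "taps", tuple(sorted(self.taps, reverse=True)))
        if bits.size != 2**self.order - 1:
            raise ValueError(
                f"expected {2**self.order - 1} bits for order {self.order}, "
                f"got {bits.size}"
            )

    def __len__(self) -> int:
        return int(self.bits.size)

    @property
    def n_on(self) -> int:
        """Number of 1-bits; ``2**(order-1)`` for a true m-sequence."""
        return int(self.bits.sum())

    def signed(self) -> np.ndarray:
        """The +-1 encoding (1 -> +1, 0 -> -1) used for correlation audits."""
        return self.bits.astype(np.int64) * 2 - 1

    def to_dict(self) -> dict:
        return {
            "order": self.order,
            "taps": list(self.taps),
            "seed": self.seed,
            "bits": "".join(map(str, self.bits.tolist())),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MlsCode":
        bits = np.frombuffer(d["bits"].encode(), dtype=np.uint8) - ord("0")
        return cls(order=int(d["order"]), taps=tuple(d["taps"]),
                   seed=int(d["seed"]), bits=bits.copy())


@dataclass(frozen=True)
class OverlapCounts:
    """On-bit counts of a code pair and their position-wise overlap."""

    n1: int
    n2: int
    o: int

    def __post_init__(self) -> None:
        if not 0 <= self.o <= min(self.n1, self.n2):
            raise ValueError("overlap count outside [0, min(n1, n2)]")


def generate_mls(order: int, taps: Sequence[int], seed: int) -> MlsCode:
    """Generate an m-sequence from a Fibonacci LFSR.

    ``taps`` are the exponents of a primitive polynomial over GF(2)
    (constant term implied).  The register is clocked ``2**order - 1``
    times; the output stream is the bit shifted out each step.

    Raises
    ------
    ValueError
        If ``seed`` is zero (the LFSR absorbing state), if a tap is out
        of range, or if the taps are not primitive (detected by the state
        returning to the seed before the full period elapses).
    """
    if order < 2:
        raise ValueError("order must be >= 2")
    if seed == 0:
        raise ValueError("degenerate LFSR state: seed must be nonzero")
    taps = tuple(sorted(set(int(t) for t in taps), reverse=True))
    if not taps or taps[0] != order or any(t < 1 for t in taps):
        raise ValueError(
            f"taps must include the order {order} and lie in [1, {order}]"
        )
    period = 2**order - 1
    if seed >= 2**order:
        raise ValueError(f"seed must be < 2**{order}")

    state = int(seed)
    bits = np.empty(period, dtype=np.uint8)
    for i in range(period):
        bits[i] = state & 1
        fb = 0
        for t in taps:
            fb ^= (state >> (order - t)) & 1
        state = (state >> 1) | (fb << (order - 1))
        if state == seed and i < period - 1:
            raise ValueError(
                f"taps {taps} are not primitive: period {i + 1} < {period}"
            )
    if state != seed:
        raise ValueError(f"taps {taps} do not produce a periodic sequence")
    code = MlsCode(order=order, taps=taps, seed=seed, bits=bits)
    if code.n_on != 2 ** (order - 1):
        raise ValueError("sequence violates the m-sequence balance property")
    return code


def overlap_counts(code1: MlsCode, code2: MlsCode) -> OverlapCounts:
    """Count on-bits of each code and positions where both are on.

    The overlap ``o`` drives the crosstalk between the two single-code
    correlation peaks: time bins where both lasers are on contribute the
    other dye's emission to each code's matched filter.
    """
    if len(code1) != len(code2):
        raise ValueError(
            f"code length mismatch: {len(code1)} vs {len(code2)}"
        )
    both = code1.bits & code2.bits
    return OverlapCounts(n1=code1.n_on, n2=code2.n_on, o=int(both.sum()))


def bit_extent_px(velocity: float, exposure: float, pixel_scale: float,
                  n_bits: int) -> float:
    """Pixels spanned by one MLS bit: ``velocity * exposure / (scale * bits)``."""
    return velocity * exposure / (pixel_scale * n_bits)


def render_mask(code: MlsCode, velocity: float, exposure: float,
                pixel_scale: float = 1.0, amplitude: float = 1.0) -> np.ndarray:
    """Render the expected streak template for one code at one velocity.

    The exposure spans exactly the full code, so each bit lasts
    ``exposure / len(code)`` and covers ``velocity * bit_duration /
    pixel_scale`` pixels.  Bit boundaries are assigned to the nearest
    pixel; the template is piecewise-constant 0/``amplitude``.

    Returns a vector of length ``round(velocity * exposure / pixel_scale)``.
    """
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    if exposure <= 0 or pixel_scale <= 0:
        raise ValueError("exposure and pixel_scale must be positive")
    support = velocity * exposure / pixel_scale
    n_px = int(round(support))
    if n_px < len(code):
        # fewer pixels than bits: bits drop out, template degenerates
        raise ValueError(
            f"mask support {n_px} px shorter than the {len(code)}-bit code"
        )
    edges = np.round(np.arange(len(code) + 1) * support / len(code)).astype(int)
    mask = np.zeros(n_px, dtype=float)
    for j in range(len(code)):
        if code.bits[j]:
            mask[edges[j]:edges[j + 1]] = amplitude
    return mask


def correlate(trace: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Sliding inner product of ``mask`` against ``trace`` (valid lags).

    ``out[k] = sum_i mask[i] * trace[k + i]`` for
    ``k = 0 .. len(trace) - len(mask)``.  Correlations are raw inner
    products, not normalised: the peak magnitude carries the streak
    amplitude, which is the quantity decoded into dye intensities.

    A mask longer than the trace yields an empty array.
    """
    trace = np.asarray(trace, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if mask.size > trace.size:
        import warnings

        warnings.warn("mask longer than trace: no valid lags", stacklevel=2)
        return np.empty(0)
    return signal.correlate(trace, mask, mode="valid", method="auto")


class MaskBank:
    """Superimposed and single-code mask templates over a velocity grid.

    For each candidate velocity the bank stores the two single-code
    templates and precomputes the FFT of the superimposed template
    ``MLS1(v, x) + MLS2(v, x)`` so a whole-trace correlation against all
    velocities is a single batched spectral multiply.

    Parameters
    ----------
    code1, code2 : MlsCode
        The blue and green excitation codes.
    velocity_grid : ndarray
        Candidate speeds in pixels per unit time (default grids use 500
        linearly spaced speeds spanning 0.5x-1.5x a nominal speed).
    exposure : float
        Bead-frame exposure; one full code per exposure.
    trace_length : int
        Length of the channel traces the bank will be correlated with.
    duty1 : float
        Duty-cycle amplitude factor applied to code 1 in the superimposed
        template (the blue laser is PWM-dimmed to balance the two dyes'
        use of the camera's dynamic range).
    """

    def __init__(self, code1: MlsCode, code2: MlsCode,
                 velocity_grid: np.ndarray, exposure: float,
                 trace_length: int, pixel_scale: float = 1.0,
                 duty1: float = 1.0):
        self.code1 = code1
        self.code2 = code2
        self.velocity_grid = np.asarray(velocity_grid, dtype=float)
        if self.velocity_grid.ndim != 1 or self.velocity_grid.size == 0:
            raise ValueError("velocity_grid must be a non-empty 1-D array")
        if np.any(self.velocity_grid <= 0):
            raise ValueError("velocities must be positive")
        self.exposure = float(exposure)
        self.trace_length = int(trace_length)
        self.pixel_scale = float(pixel_scale)
        self.duty1 = float(duty1)

        self.masks1: list[np.ndarray] = []
        self.masks2: list[np.ndarray] = []
        self.bit_extent = np.empty(self.velocity_grid.size)
        for i, v in enumerate(self.velocity_grid):
            m1 = render_mask(code1, v, exposure, pixel_scale)
            m2 = render_mask(code2, v, exposure, pixel_scale)
            self.masks1.append(m1)
            self.masks2.append(m2)
            self.bit_extent[i] = bit_extent_px(v, exposure, pixel_scale,
                                               len(code1))
        self.mask_lengths = np.array([m.size for m in self.masks1])
        if np.any(self.mask_lengths > self.trace_length):
            raise ValueError(
                "fastest mask exceeds the trace length; shrink the grid or "
                "lengthen the channel"
            )

        # batched spectra of the superimposed templates, reversed for
        # correlation-via-convolution
        self._nfft = int(2 ** np.ceil(np.log2(self.trace_length
                                              + self.mask_lengths.max())))
        self._mask_fft = np.zeros((self.velocity_grid.size,
                                   self._nfft // 2 + 1), dtype=complex)
        self.mask_power = np.empty(self.velocity_grid.size)
        for i, (m1, m2) in enumerate(zip(self.masks1, self.masks2)):
            sup = self.duty1 * m1 + m2
            self.mask_power[i] = float(sup @ sup)
            self._mask_fft[i] = np.conj(np.fft.rfft(sup, self._nfft))

    @property
    def n_velocities(self) -> int:
        return int(self.velocity_grid.size)

    def superimposed(self, i: int) -> np.ndarray:
        """Superimposed template ``duty1*MLS1 + MLS2`` at grid index ``i``."""
        return self.duty1 * self.masks1[i] + self.masks2[i]

    def correlation_matrix(self, trace: np.ndarray) -> np.ndarray:
        """Correlate ``trace`` with every superimposed template at once.

        Returns an ``(n_velocities, trace_length)`` matrix whose entry
        ``[i, k]`` is the inner product of the template at velocity ``i``
        with the trace window starting at lag ``k``; lags where the
        template would overhang the trace are ``-inf``.
        """
        trace = np.asarray(trace, dtype=float)
        if trace.size != self.trace_length:
            raise ValueError(
                f"trace length {trace.size} != bank trace_length "
                f"{self.trace_length}"
            )
        tf = np.fft.rfft(trace, self._nfft)
        psi = np.fft.irfft(self._mask_fft * tf, self._nfft)[:, :self.trace_length]
        for i, L in enumerate(self.mask_lengths):
            last = self.trace_length - int(L)
            psi[i, last + 1:] = -np.inf
        return psi

    def index_of(self, velocity: float) -> int:
        """Grid index closest to ``velocity``."""
        return int(np.argmin(np.abs(self.velocity_grid - velocity)))


def linear_velocity_grid(nominal: float, n: int = 500,
                         lo: float = 0.5, hi: float = 1.5) -> np.ndarray:
    """Linearly spaced candidate speeds covering ``[lo, hi] * nominal``."""
    if nominal <= 0:
        raise ValueError("nominal velocity must be positive")
    return np.linspace(lo * nominal, hi * nominal, n)


# ---------------------------------------------------------------------------
# fixture codes


def default_codes() -> tuple[MlsCode, MlsCode]:
    """The repository's 63-bit code pair, loaded from the recorded fixture.

    Code 1 (blue laser) comes from x^6 + x + 1, code 2 (green laser)
    from x^6 + x^5 + 1, both seeded with register state 000001.  The
    pair's cross-correlation is audited in the test suite.
    """
    with resources.files("dropcode.data").joinpath("mls_codes.json").open() as f:
        d = json.load(f)
    return MlsCode.from_dict(d["mls1"]), MlsCode.from_dict(d["mls2"])
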
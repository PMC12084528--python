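"""Ground-truthed synthetic HDR videos of MLS-encoded bead streaks.

The simulator emulates a parallel-channel droplet imager: dual-dye beads
flow single-file through 76 horizontal microfluidic channels while the
blue and green excitation lasers are switched by two 63-bit maximal-length
sequences during a long "bead" exposure (T1 = 41.5 ms), and a continuous
red laser probes the droplet's enzymatic substrate during a short
"substrate" exposure (T2 = 10 ms).  Frames alternate between the two
roles (HDR mode).  A moving bead therefore leaves an MLS-barcoded streak
of length v*T1 in bead frames and, if its droplet is HRP-positive, a
solid streak of length v*T2 in the adjacent substrate frames.

Intensities are expressed in *normalized* units: a streak of amplitude B
raises the local pixel value to ``background * (1 + B)``, so dividing by
the background frame recovers B independent of the (non-uniform)
illumination.  Pixels are 16-bit (0-65535) with optional Poisson shot
noise and Gaussian read noise.

Units: lengths in micrometres, times in milliseconds, velocities in
µm/ms (numerically equal to mm/s).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mls import MlsCode, render_mask
from .preprocess import FrameStack

UINT16_MAX = 65535


# ---------------------------------------------------------------------------
# geometry / schedule / population


@dataclass(frozen=True)
class ChannelGeometry:
    """Imaging geometry of the parallel-channel detection region.

    The frame is ``frame_shape = (height, width)`` pixels; channels run
    horizontally (along the image width), which maps the 23-mm imaged
    channel length onto the 960-pixel width.  ``n_channels`` channel
    strips of ``channel_width_px`` rows each are centred within equal
    vertical bins of ``pitch_px`` rows.
    """

    n_channels: int = 76
    frame_shape: tuple[int, int] = (720, 960)
    channel_length_um: float = 23000.0
    channel_pitch_um: float = 110.0
    channel_width_px: int = 7

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.n_channels * self.pitch_px > self.frame_shape[0]:
            raise ValueError("channel band exceeds the frame height")
        if self.channel_width_px > self.pitch_px:
            raise ValueError("channel_width_px exceeds the channel pitch")

    @property
    def pixel_scale(self) -> float:
        """µm per pixel along the channel (flow) axis."""
        return self.channel_length_um / self.frame_shape[1]

    @property
    def pitch_px(self) -> int:
        """Rows per channel bin (vertical pitch in pixels)."""
        return self.frame_shape[0] // self.n_channels

    @property
    def band_offset(self) -> int:
        """First row of the channel band (band vertically centred)."""
        return (self.frame_shape[0] - self.n_channels * self.pitch_px) // 2

    @property
    def trace_length(self) -> int:
        return self.frame_shape[1]

    def channel_rows(self, n: int) -> slice:
        """Row slice of channel ``n`` (0-based, top to bottom)."""
        if not 0 <= n < self.n_channels:
            raise IndexError(f"channel {n} outside 0..{self.n_channels - 1}")
        top = (self.band_offset + n * self.pitch_px
               + (self.pitch_px - self.channel_width_px) // 2)
        return slice(top, top + self.channel_width_px)


@dataclass(frozen=True)
class ExcitationSchedule:
    """Exposure timing: bead frames (MLS lasers) vs substrate frames (red).

    ``frame_pattern`` is ``"hdr"`` (strict bead/substrate alternation,
    starting with a bead frame) or ``"bead"`` (bead frames only).
    ``blue_duty`` is the PWM duty cycle dimming the blue laser; it scales
    the rendered MLS1 amplitude multiplicatively (the PWM carrier runs
    far above the pixel integration scale).
    """

    t1: float = 41.5
    t2: float = 10.0
    frame_pattern: str = "hdr"
    blue_duty: float = 0.5
    dead_time: float = 0.0

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("exposures must be positive")
        if self.frame_pattern not in ("hdr", "bead"):
            raise ValueError("frame_pattern must be 'hdr' or 'bead'")
        if not 0 < self.blue_duty <= 1:
            raise ValueError("blue_duty must be in (0, 1]")

    @property
    def hdr(self) -> bool:
        return self.frame_pattern == "hdr"

    @property
    def bead_frame_interval(self) -> float:
        """Time between starts of consecutive bead frames."""
        if self.hdr:
            return self.t1 + self.t2 + self.dead_time
        return self.t1 + self.dead_time

    def roles(self, n_frames: int) -> list[str]:
        if self.hdr:
            return ["bead" if i % 2 == 0 else "substrate"
                    for i in range(n_frames)]
        return ["bead"] * n_frames

    def exposures(self, n_frames: int) -> np.ndarray:
        return np.array([self.t1 if r == "bead" else self.t2
                         for r in self.roles(n_frames)])

    def start_times(self, n_frames: int) -> np.ndarray:
        exp = self.exposures(n_frames) + self.dead_time
        starts = np.concatenate([[0.0], np.cumsum(exp)[:-1]])
        return starts


@dataclass(frozen=True)
class GroupSpec:
    """One bead population: mean dye amplitudes (normalized units) and CVs."""

    mean_b1: float
    mean_b2: float
    cv1: float = 0.20
    cv2: float = 0.20

    def __post_init__(self) -> None:
        if self.mean_b1 <= 0 or self.mean_b2 <= 0:
            raise ValueError("group means must be positive")
        if self.cv1 < 0 or self.cv2 < 0:
            raise ValueError("CVs must be non-negative")


@dataclass(frozen=True)
class NoiseModel:
    """Camera noise: Poisson shot noise on expected counts + Gaussian read."""

    shot: bool = True
    read_sd: float = 50.0


@dataclass(frozen=True)
class PopulationModel:
    """Bead populations, droplet statistics and imaging noise levels.

    Amplitudes are in normalized units (multiples of the local
    background); the default five-group layout spans the 2-D intensity
    map with group C brightest in both dyes, group A dimmest in blue and
    group E dimmest in green.
    """

    groups: dict[str, GroupSpec] = field(default_factory=lambda: {
        "A": GroupSpec(0.20, 0.80),
        "B": GroupSpec(0.55, 1.60),
        "C": GroupSpec(1.60, 1.60),
        "D": GroupSpec(1.60, 0.55),
        "E": GroupSpec(0.80, 0.20),
    })
    hrp_positive_fraction: float = 0.01
    droplet_diameter_um: float = 80.0
    droplet_diameter_cv: float = 0.06
    velocity_mean: float = 23000.0 / 3 / 41.5   # design speed, µm/ms
    velocity_cv: float = 0.05
    background_level: float = 17000.0           # bead-frame counts
    substrate_background_level: float = 5000.0  # substrate-frame counts
    substrate_amplitude: float = 2.0            # normalized, positive droplets
    frame_jitter_cv: float = 0.05               # per-appearance intensity CV
    noise: NoiseModel = field(default_factory=NoiseModel)

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("population model needs at least one group")
        if not 0 <= self.hrp_positive_fraction <= 1:
            raise ValueError("hrp_positive_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# closed-form design calculators


def streak_length(velocity: float, exposure: float) -> float:
    """Length of the streak left by an object at ``velocity`` during
    ``exposure``: simply ``velocity * exposure``."""
    if velocity < 0:
        raise ValueError("velocity must be non-negative")
    return velocity * exposure


def design_velocity(channel_length_um: float = 23000.0, t1: float = 41.5,
                    streak_fraction: float = 1.0 / 3.0) -> float:
    """Nominal droplet speed making the bead streak a given fraction of
    the channel length during the bead exposure."""
    return channel_length_um * streak_fraction / t1


def expected_positive_spacing(positive_fraction: float,
                              droplet_diameter: float) -> float:
    """Mean distance between positive droplets in a single-file train.

    With a fraction ``p`` of droplets positive, successive positives are
    on average ``1/p`` droplets apart, i.e. ``diameter / p`` in length
    (8 mm for 1% positives of 80-µm droplets): sparse enough that two
    positive substrate streaks rarely overlap in one exposure.
    """
    if not 0 < positive_fraction <= 1:
        raise ValueError("positive_fraction must be in (0, 1]")
    if droplet_diameter <= 0:
        raise ValueError("droplet_diameter must be positive")
    return droplet_diameter / positive_fraction


# ---------------------------------------------------------------------------
# ground truth sampling


def sample_beads(model: PopulationModel, n_beads: int, seed: int,
                 geometry: ChannelGeometry | None = None,
                 schedule: ExcitationSchedule | None = None,
                 codes_len: int = 63) -> pd.DataFrame:
    """Draw a ground-truth bead table for :func:`render_video`.

    Beads are spread sparsely over channels and frame pairs (at most one
    bead enters a given channel per two bead-frame cycles, emulating a
    dilute bead suspension where visible beads rarely share a channel)
    and positioned so each bead's streak is fully inside the field of
    view for two consecutive bead frames, matching an exposure/flow
    design in which every bead is imaged at least twice.

    Returns a DataFrame with one row per bead: ``bead_id, group,
    channel, frame`` (stack index of the first fully-visible bead
    frame), ``x0_px`` (streak start at that frame's start, pixels),
    ``velocity`` (µm/ms), ``v_px`` (px/ms), ``b1, b2`` (true normalized
    amplitudes) and ``hrp_positive``.
    """
    if n_beads <= 0:
        raise ValueError("n_beads must be positive")
    geometry = geometry or ChannelGeometry()
    schedule = schedule or ExcitationSchedule()
    rng = np.random.default_rng(seed)

    labels = list(model.groups)
    group = np.array([labels[i % len(labels)] for i in range(n_beads)])
    rng.shuffle(group)

    v_um = rng.normal(model.velocity_mean,
                      model.velocity_cv * model.velocity_mean, n_beads)
    v_um = np.clip(v_um, 0.2 * model.velocity_mean, 2.0 * model.velocity_mean)
    v_px = v_um / geometry.pixel_scale

    # slot assignment: channel cycles fastest, one bead per channel per
    # two bead-frame cycles so consecutive-frame appearances never share
    # a channel with another bead
    slots = rng.permutation(n_beads)
    channel = slots % geometry.n_channels
    block = slots // geometry.n_channels
    frames_per_cycle = 2 if schedule.hdr else 1
    frame = block * 2 * frames_per_cycle  # stack index of first bead frame

    dt = schedule.bead_frame_interval
    span = v_px * (dt + schedule.t1)  # start of frame k to streak end, k+1
    L = geometry.trace_length
    max_x0 = L - span
    if np.any(max_x0 <= 1):
        raise ValueError(
            "velocity too high for two full appearances in the field of view"
        )
    x0 = rng.uniform(1.0, max_x0)

    b1 = np.empty(n_beads)
    b2 = np.empty(n_beads)
    for lab, spec in model.groups.items():
        idx = group == lab
        k = int(idx.sum())
        b1[idx] = rng.normal(spec.mean_b1, spec.cv1 * spec.mean_b1, k)
        b2[idx] = rng.normal(spec.mean_b2, spec.cv2 * spec.mean_b2, k)
    np.clip(b1, 1e-6, None, out=b1)
    np.clip(b2, 1e-6, None, out=b2)

    hrp = rng.random(n_beads) < model.hrp_positive_fraction

    return pd.DataFrame({
        "bead_id": np.arange(n_beads),
        "group": group,
        "channel": channel,
        "frame": frame,
        "x0_px": x0,
        "velocity": v_um,
        "v_px": v_px,
        "b1": b1,
        "b2": b2,
        "hrp_positive": hrp,
        "edge": False,
    })


# ---------------------------------------------------------------------------
# backgrounds and rendering


def illumination_profile(shape: tuple[int, int], nonuniformity: float = 0.15,
                         seed: int = 0) -> np.ndarray:
    """Smooth 2-D excitation profile, mean ~1, mimicking top-hat-diffused
    laser illumination with residual large-scale non-uniformity."""
    h, w = shape
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w]
    cy = h * (0.4 + 0.2 * rng.random())
    cx = w * (0.4 + 0.2 * rng.random())
    sy = h * (0.8 + 0.4 * rng.random())
    sx = w * (0.8 + 0.4 * rng.random())
    bump = np.exp(-(((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2))
    profile = 1.0 + nonuniformity * (bump - bump.mean())
    return profile / profile.mean()


def make_backgrounds(geometry: ChannelGeometry, model: PopulationModel,
                     nonuniformity: float = 0.15,
                     seed: int = 0) -> dict[str, np.ndarray]:
    """Expected (noiseless) background count images per frame role."""
    profile = illumination_profile(geometry.frame_shape, nonuniformity, seed)
    return {
        "bead": model.background_level * profile,
        "substrate": model.substrate_background_level * profile,
    }


def _add_streak(signal: np.ndarray, rows: slice, profile: np.ndarray,
                x_start: float) -> None:
    """Accumulate a 1-D streak profile into a channel strip, clipped to
    the frame; ``x_start`` may be fractional or negative."""
    L = signal.shape[1]
    x0 = int(round(x_start))
    lo = max(x0, 0)
    hi = min(x0 + profile.size, L)
    if hi <= lo:
        return
    signal[rows, lo:hi] += profile[lo - x0:hi - x0]


def render_video(geometry: ChannelGeometry, schedule: ExcitationSchedule,
                 codes: tuple[MlsCode, MlsCode], truth: pd.DataFrame,
                 background: dict[str, np.ndarray] | None = None,
                 seed: int = 0, n_frames: int | None = None,
                 noise: NoiseModel | None = None,
                 substrate_amplitude: float = 2.0,
                 frame_jitter_cv: float = 0.0) -> FrameStack:
    """Render the frame stack implied by a ground-truth bead table.

    Bead frames receive ``B1*duty*MLS1(v,x) + B2*MLS2(v,x)`` streaks in
    normalized units on top of the background; substrate frames receive
    solid streaks of length ``v*T2`` only for HRP-positive droplets.
    Pixel counts are ``background * (1 + signal)``, optionally shot- and
    read-noised, clipped to the 16-bit range.

    ``frame_jitter_cv`` adds an independent multiplicative factor to each
    dye's amplitude at every appearance, emulating the frame-to-frame
    measurement variability of a real instrument (defocus, position in
    the channel depth, illumination flicker) that repeat averaging is
    designed to suppress.

    Beads whose streak leaves the field of view in a frame are rendered
    truncated and marked ``edge`` in the returned stack's truth copy.
    """
    code1, code2 = codes
    if background is None:
        model = PopulationModel()
        background = make_backgrounds(geometry, model, seed=seed)
    if n_frames is None:
        per_cycle = 2 if schedule.hdr else 1
        last = int(truth["frame"].max()) if len(truth) else 0
        n_frames = last + 2 * per_cycle
    rng = np.random.default_rng(seed)

    roles = schedule.roles(n_frames)
    starts = schedule.start_times(n_frames)
    truth = truth.copy()
    truth["edge"] = False

    # per-bead reference time: start of its first fully-visible bead frame
    t_ref = (starts[truth["frame"].to_numpy(dtype=int)] if len(truth)
             else np.empty(0))
    if frame_jitter_cv > 0 and len(truth):
        jitter = rng.normal(1.0, frame_jitter_cv,
                            (len(truth), n_frames, 2)).clip(0.1)
    else:
        jitter = np.ones((max(len(truth), 1), n_frames, 2))

    frames = np.empty((n_frames,) + geometry.frame_shape, dtype=np.uint16)
    L = geometry.trace_length
    for m in range(n_frames):
        sig = np.zeros(geometry.frame_shape)
        t_s = starts[m]
        for i, bead in enumerate(truth.itertuples()):
            v = bead.v_px
            x_s = bead.x0_px + v * (t_s - t_ref[i])
            if roles[m] == "bead":
                length = v * schedule.t1
                if x_s + length < 0 or x_s > L:
                    continue
                m1 = render_mask(code1, v, schedule.t1)
                m2 = render_mask(code2, v, schedule.t1)
                n_px = max(m1.size, m2.size)
                prof = np.zeros(n_px)
                j1, j2 = jitter[i, m]
                prof[:m1.size] += bead.b1 * j1 * schedule.blue_duty * m1
                prof[:m2.size] += bead.b2 * j2 * m2
                # flag truncation only in the bead's two designated
                # appearances; partial streaks while entering/leaving the
                # FOV in other frames are expected and rendered as-is
                designated = (bead.frame, bead.frame + (2 if schedule.hdr
                                                        else 1))
                if (x_s < 0 or x_s + n_px > L) and m in designated:
                    truth.loc[truth["bead_id"] == bead.bead_id, "edge"] = True
            else:
                if not bead.hrp_positive:
                    continue
                length = v * schedule.t2
                if x_s + length < 0 or x_s > L:
                    continue
                n_px = max(int(round(length)), 1)
                prof = np.full(n_px, substrate_amplitude)
            _add_streak(sig, geometry.channel_rows(bead.channel), prof, x_s)

        expected = background[roles[m]] * (1.0 + sig)
        if noise is not None and noise.shot:
            img = rng.poisson(expected).astype(float)
        else:
            img = expected.copy()
        if noise is not None and noise.read_sd > 0:
            img += rng.normal(0.0, noise.read_sd, img.shape)
        frames[m] = np.clip(np.round(img), 0, UINT16_MAX).astype(np.uint16)

    return FrameStack(frames=frames, roles=roles,
                      exposures=schedule.exposures(n_frames),
                      start_times=starts, truth=truth)


def simulate_run(model: PopulationModel, n_beads: int, seed: int,
                 geometry: ChannelGeometry | None = None,
                 schedule: ExcitationSchedule | None = None,
                 codes: tuple[MlsCode, MlsCode] | None = None,
                 nonuniformity: float = 0.15,
                 ) -> tuple[FrameStack, dict[str, np.ndarray], pd.DataFrame]:
    """Convenience wrapper: sample beads, build backgrounds, render.

    Returns ``(stack, backgrounds, truth)``; all randomness derives from
    ``seed`` so reruns are bit-identical.
    """
    from .mls import default_codes

    geometry = geometry or ChannelGeometry()
    schedule = schedule or ExcitationSchedule()
    codes = codes or default_codes()
    if n_beads == 0:
        truth = pd.DataFrame(columns=["bead_id", "group", "channel", "frame",
                                      "x0_px", "velocity", "v_px", "b1",
                                      "b2", "hrp_positive", "edge"])
    else:
        truth = sample_beads(model, n_beads, seed, geometry, schedule)
    background = make_backgrounds(geometry, model, nonuniformity, seed=seed)
    stack = render_video(geometry, schedule, codes, truth, background,
                         seed=seed + 1, noise=model.noise,
                         substrate_amplitude=model.substrate_amplitude,
                         frame_jitter_cv=model.frame_jitter_cv)
    return stack, background, stack.truth
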
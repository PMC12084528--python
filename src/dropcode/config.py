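"""Run configuration: every tunable of the simulate/decode pipeline in
one serialisable object.

Defaults reproduce the reference imaging design: 76 channels, 63-bit
codes from the recorded fixture pair, T1 = 41.5 ms bead exposure with
50% blue duty, T2 = 10 ms substrate exposure, a 500-point velocity grid,
a 20% repeat-CV quality cut and a 4-sigma substrate threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .mls import MaskBank, default_codes, linear_velocity_grid
from .simulate import (ChannelGeometry, ExcitationSchedule, GroupSpec,
                       NoiseModel, PopulationModel, design_velocity)


@dataclass
class RunConfig:
    geometry: ChannelGeometry = field(default_factory=ChannelGeometry)
    schedule: ExcitationSchedule = field(default_factory=ExcitationSchedule)
    population: PopulationModel = field(default_factory=PopulationModel)
    n_velocities: int = 500
    velocity_lo: float = 0.5     # grid bounds as multiples of nominal speed
    velocity_hi: float = 1.5
    detection_k_mad: float = 6.0
    cv_threshold: float = 0.20
    substrate_n_sigma: float = 4.0
    gate_radius: float = 3.0     # Mahalanobis radius of fitted ellipse gates
    match_tolerance_bits: float = 2.0   # linking tolerance, in bit extents
    n_beads: int = 500
    seed: int = 0

    # -- derived helpers ----------------------------------------------------

    @property
    def nominal_velocity_px(self) -> float:
        """Design speed in px/ms on this geometry's pixel scale."""
        v_um = design_velocity(self.geometry.channel_length_um,
                               self.schedule.t1)
        return v_um / self.geometry.pixel_scale

    def velocity_grid(self) -> np.ndarray:
        return linear_velocity_grid(self.nominal_velocity_px,
                                    self.n_velocities,
                                    self.velocity_lo, self.velocity_hi)

    def mask_bank(self) -> MaskBank:
        c1, c2 = default_codes()
        return MaskBank(c1, c2, self.velocity_grid(), self.schedule.t1,
                        self.geometry.trace_length,
                        duty1=self.schedule.blue_duty)

    def match_tolerance_px(self) -> float:
        bit_extent = (self.nominal_velocity_px * self.schedule.t1) / 63
        return self.match_tolerance_bits * bit_extent

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["population"]["groups"] = {
            k: dataclasses.asdict(v) for k, v in self.population.groups.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        geo_d = dict(d.pop("geometry", {}))
        if "frame_shape" in geo_d:
            geo_d["frame_shape"] = tuple(geo_d["frame_shape"])
        geo = ChannelGeometry(**geo_d)
        sched = ExcitationSchedule(**d.pop("schedule", {}))
        pop_d = dict(d.pop("population", {}))
        if "groups" in pop_d:
            pop_d["groups"] = {k: GroupSpec(**v)
                               for k, v in pop_d["groups"].items()}
        if "noise" in pop_d and isinstance(pop_d["noise"], dict):
            pop_d["noise"] = NoiseModel(**pop_d["noise"])
        pop = PopulationModel(**pop_d)
        return cls(geometry=geo, schedule=sched, population=pop, **d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             default_flow_style=None))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
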
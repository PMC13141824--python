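"""Run configuration: experiment constants plus per-stage parameter
blocks, loadable from YAML and re-emitted (resolved) alongside every run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import yaml

from .detection import DetectionParams
from .physics import (DEFAULT_FIELD_T, DEFAULT_VISCOSITY, FieldProtocol,
                      MediumParams)
from .tracking import TrackingParams
from .uturn import UTurnParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with experiment defaults.

    ``pixel_size_um`` is the image scale (µm per pixel), ``frame_rate``
    the acquisition rate (Hz).  ``drag_convention`` selects the rotational
    drag form ("paper": 8 pi^2 eta R^3, "sphere": 8 pi eta R^3).
    """

    pixel_size_um: float = 0.25
    frame_rate: float = 50.0
    viscosity: float = DEFAULT_VISCOSITY
    field: FieldProtocol = dc_field(default_factory=FieldProtocol)
    drag_convention: str = "paper"
    seed: int = 0
    detection: DetectionParams = dc_field(default_factory=DetectionParams)
    tracking: TrackingParams = dc_field(default_factory=TrackingParams)
    uturn: UTurnParams = dc_field(default_factory=UTurnParams)

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel size and frame rate must be > 0")
        # keep the tracker's metric conversion in sync
        object.__setattr__(self, "tracking", TrackingParams(
            **{**asdict(self.tracking),
               "pixel_size_um": self.pixel_size_um,
               "frame_rate": self.frame_rate}))

    @property
    def medium(self) -> MediumParams:
        return MediumParams(viscosity=self.viscosity)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["field"] = {"magnitude_T": self.field.magnitude,
                      "axis": list(self.field.axis),
                      "mode": self.field.mode,
                      "reversal_times_s": list(self.field.reversal_times)}
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        fp = data.pop("field", None)
        kwargs = {}
        for name, klass in (("detection", DetectionParams),
                            ("tracking", TrackingParams),
                            ("uturn", UTurnParams)):
            if name in data:
                kwargs[name] = klass(**data.pop(name))
        if fp is not None:
            kwargs["field"] = FieldProtocol(
                magnitude=float(fp.get("magnitude_T", DEFAULT_FIELD_T)),
                axis=tuple(fp.get("axis", (1.0, 0.0))),
                mode=fp.get("mode", "static"),
                reversal_times=tuple(fp.get("reversal_times_s", ())))
        kwargs.update(data)
        return cls(**kwargs)
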
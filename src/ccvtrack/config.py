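"""Run configuration: every stage's parameters in one validated record.

Defaults are the pipeline's standard operating point: 5 a.u. intensity
threshold, accepted widths 1–15 px, 3 px link radius, 5-frame maximum
gap, 5-frame minimum track length, 50 px rolling ball, speckle feature
size 20, mask blur σ = 5, 4 radial bins, 1 s frame interval.  Configs
round-trip losslessly through JSON.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

from .detect import DetectionParams
from .io import read_json, write_json
from .link import LinkParams
from .motion import Calibration

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    detection: DetectionParams = field(default_factory=DetectionParams)
    linking: LinkParams = field(default_factory=LinkParams)
    calibration: Calibration = field(default_factory=Calibration)
    msd_lags: tuple[int, ...] = (1, 2, 3, 4)
    ac_reversal_min: float = 150.0
    ac_forward_max: float = 30.0
    rolling_ball_radius: float = 50.0
    speckle_feature_size: int = 20
    mask_blur_sigma: float = 5.0
    mask_intensity_window: tuple[float, float] = (3.0, 30.0)
    radial_bins: int = 4
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["msd_lags"] = list(self.msd_lags)
        d["mask_intensity_window"] = list(self.mask_intensity_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, typ in (("detection", DetectionParams), ("linking", LinkParams),
                         ("calibration", Calibration)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        if "msd_lags" in d:
            d["msd_lags"] = tuple(d["msd_lags"])
        if "mask_intensity_window" in d:
            d["mask_intensity_window"] = tuple(d["mask_intensity_window"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        write_json(path, self.to_dict())

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(read_json(path))
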
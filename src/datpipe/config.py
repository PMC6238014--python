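"""Run configuration: resolved settings echoed into every report."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Paths and quantification settings for a pipeline run.

    Windows are minutes post injection; striatal weights are the fixed
    delineation volumes in mL; the SN search box is in mm.
    """

    dyn_path: str | None = None
    labels_path: str | None = None
    timing_path: str | None = None
    spect_path: str | None = None
    out_dir: str = "out"
    logan_window: tuple = (27.0, 75.0)
    suvr_window: tuple = (51.0, 75.0)
    v_caudate_ml: float = 2.0
    v_putamen_ml: float = 2.5
    sn_box_mm: tuple = (17.0, 13.0, 10.0)
    sn_threshold_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for window in (self.logan_window, self.suvr_window):
            if not (0 <= window[0] < window[1]):
                raise ValueError(f"invalid window {window}")

    def validate_paths(self, require: tuple = ()) -> None:
        for name in require:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"config field {name} is required")
            if not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value} does not exist")

    def to_dict(self) -> dict:
        return asdict(self)

    def updated(self, **kw) -> "RunConfig":
        return replace(self, **kw)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("logan_window", "suvr_window", "sn_box_mm"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
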
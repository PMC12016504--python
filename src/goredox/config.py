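"""Run configuration: every tunable the pipeline exposes, with defaults.

Unknown keys are rejected rather than ignored so a typo in a config file
cannot silently fall back to a default.  Every output JSON embeds the full
effective configuration (after defaults) for exact replay.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from .errors import ConfigError
from .sampling import (
    DEFAULT_MAX_GLARE_FRACTION,
    DEFAULT_MIN_POINTS,
    DEFAULT_S_THRESHOLD,
    DEFAULT_V_THRESHOLD,
    Roi,
)
from .image_core import DEFAULT_BOX_SIDE
from .stats import ALTERNATIVES, DEFAULT_ALPHA, DEFAULT_B


@dataclass(frozen=True)
class RunConfig:
    """Effective configuration of a measurement / analysis run."""

    roi: Roi | None = None
    box_side: int = DEFAULT_BOX_SIDE
    min_points: int = DEFAULT_MIN_POINTS
    glare_v_threshold: float = DEFAULT_V_THRESHOLD
    glare_s_threshold: float = DEFAULT_S_THRESHOLD
    max_glare_fraction: float = DEFAULT_MAX_GLARE_FRACTION
    bootstrap_B: int = DEFAULT_B
    bootstrap_seed: int = 0
    bootstrap_alternative: str = "two-sided"
    calibration_fit_range: tuple[float, float] = (0.06, 0.12)
    alpha: float = DEFAULT_ALPHA
    # "darkening": reduction lowers V, signal = baseline − value;
    # "brightening": signal = value − baseline
    signal_direction: str = "darkening"

    def __post_init__(self) -> None:
        if self.box_side <= 0 or self.box_side % 2 != 0:
            raise ConfigError("box_side must be a positive even integer")
        if self.min_points < 1:
            raise ConfigError("min_points must be >= 1")
        for name in ("glare_v_threshold", "glare_s_threshold", "max_glare_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.bootstrap_B < 1:
            raise ConfigError("bootstrap_B must be >= 1")
        if self.bootstrap_alternative not in ALTERNATIVES:
            raise ConfigError(f"bootstrap_alternative must be one of {ALTERNATIVES}")
        lo, hi = self.calibration_fit_range
        if not lo < hi:
            raise ConfigError("calibration_fit_range must be (lo, hi) with lo < hi")
        if not 0.0 < self.alpha <= 1.0:
            raise ConfigError("alpha must lie in (0, 1]")
        if self.signal_direction not in ("darkening", "brightening"):
            raise ConfigError("signal_direction must be 'darkening' or 'brightening'")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(data)
        if kwargs.get("roi") is not None:
            roi = kwargs["roi"]
            if isinstance(roi, dict):
                extra = set(roi) - {"top", "left", "height", "width"}
                if extra:
                    raise ConfigError(f"unknown roi keys: {sorted(extra)}")
                kwargs["roi"] = Roi(**roi)
        if "calibration_fit_range" in kwargs:
            kwargs["calibration_fit_range"] = tuple(kwargs["calibration_fit_range"])
        try:
            return cls(**kwargs)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ConfigError(f"malformed config JSON {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ConfigError("config JSON must be an object")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["calibration_fit_range"] = list(self.calibration_fit_range)
        return d
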
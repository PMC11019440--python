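"""Acquisition and analysis configuration.

All tunable knobs of the pipeline live in a single :class:`AcquisitionParams`
ledger so a run is fully described by one small YAML/TOML file.  Defaults
reproduce the reference acquisition: 100 fps brightfield recordings through a
20x objective on a camera with 6.5 um physical pixels, i.e. a sample-plane
scale of 0.325 um/pixel.

``um_per_pixel`` is always the SAMPLE-PLANE scale, because velocities must be
expressed in sample-plane um/s.  Configs may alternatively supply the pair
``camera_pixel_um`` + ``magnification`` and the scale is derived as their
ratio.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple, Union

import yaml

from .core import ValidationError


class ConfigError(ValidationError):
    """Malformed or out-of-range configuration."""


@dataclass
class AcquisitionParams:
    # acquisition geometry
    frame_rate: float = 100.0          # FR, frames/s
    um_per_pixel: float = 0.325        # gamma, sample-plane um/pixel (6.5/20)

    # detection
    sensitivity: float = 0.6           # S in [0,1]; accumulator threshold 1-S
    head_radius_range: Tuple[float, float] = (2.0, 6.0)  # pixels
    gaussian_sigma: float = 1.0        # px
    opening_radius: int = 2            # px, disk structuring element
    wiener_window: int = 5             # px, adaptive Wiener window
    invert: bool = False               # set for dark-head brightfield dialects
    noise_floor_k: float = 5.0         # abs peak gate, multiples of noise MAD

    # linking
    max_link_distance: float = 4.2     # D, um
    gap_max_frames: int = 5            # G, frames
    gap_max_distance: float = 8.5      # D_gapclosing, um
    split_factor: float = 5.0          # anomalous-jump split multiple

    # track filters
    min_track_length: int = 100        # points
    min_vsl: float = 2.0               # um/s
    min_lin: float = 10.0              # percent

    # circular-trajectory criterion
    circle_residual_tol: float = 0.15  # rms residual / radius
    circle_min_turning: float = 2.0 * math.pi  # rad
    circle_max_radius: float = 100.0   # um

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.frame_rate > 0:
            raise ConfigError("frame_rate must be > 0")
        if not self.um_per_pixel > 0:
            raise ConfigError("um_per_pixel must be > 0")
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ConfigError("sensitivity must lie in [0, 1]")
        for name in ("max_link_distance", "gap_max_distance", "min_vsl",
                     "gaussian_sigma", "circle_max_radius"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.gap_max_frames < 0:
            raise ConfigError("gap_max_frames must be >= 0")
        if not self.split_factor > 1:
            raise ConfigError("split_factor must be > 1")
        if self.min_track_length < 2:
            raise ConfigError("min_track_length must be >= 2")
        lo, hi = self.head_radius_range
        if not (0 < lo <= hi):
            raise ConfigError("head_radius_range must satisfy 0 < min <= max")
        if self.opening_radius < 0 or self.wiener_window < 1:
            raise ConfigError("filter window parameters out of range")
        if not 0 <= self.min_lin <= 100:
            raise ConfigError("min_lin must lie in [0, 100]")

    def replace(self, **kwargs) -> "AcquisitionParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["head_radius_range"] = list(self.head_radius_range)
        return d


_FIELDS = {f.name for f in dataclasses.fields(AcquisitionParams)}
_ALT_KEYS = {"camera_pixel_um", "magnification"}


def _params_from_mapping(data: dict, source: str) -> AcquisitionParams:
    if not isinstance(data, dict):
        raise ConfigError(f"{source}: config root must be a mapping")
    data = dict(data)
    unknown = set(data) - _FIELDS - _ALT_KEYS
    if unknown:
        raise ConfigError(
            f"{source}: unknown configuration key(s): {', '.join(sorted(unknown))}")
    if _ALT_KEYS & set(data):
        if not _ALT_KEYS <= set(data):
            raise ConfigError(
                f"{source}: camera_pixel_um and magnification must be given together")
        if "um_per_pixel" in data:
            raise ConfigError(
                f"{source}: give either um_per_pixel or the "
                "camera_pixel_um/magnification pair, not both")
        cam = float(data.pop("camera_pixel_um"))
        mag = float(data.pop("magnification"))
        if cam <= 0 or mag <= 0:
            raise ConfigError(f"{source}: camera_pixel_um and magnification must be > 0")
        data["um_per_pixel"] = cam / mag
    if "head_radius_range" in data:
        rr = data["head_radius_range"]
        try:
            data["head_radius_range"] = (float(rr[0]), float(rr[1]))
        except (TypeError, IndexError, ValueError) as exc:
            raise ConfigError(
                f"{source}: head_radius_range must be a (min, max) pair") from exc
    try:
        return AcquisitionParams(**data)
    except TypeError as exc:
        raise ConfigError(f"{source}: {exc}") from exc


def load_config(path: Union[str, Path, None] = None, **overrides) -> AcquisitionParams:
    """Read an :class:`AcquisitionParams` from a YAML or TOML file.

    Any omitted field keeps its default.  Keyword ``overrides`` (e.g. from
    CLI flags) take precedence over file values.  ``path=None`` returns the
    defaults, possibly overridden.
    """
    data: dict = {}
    source = "<defaults>"
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        source = str(path)
        text = path.read_text()
        if path.suffix.lower() == ".toml":
            import tomllib
            try:
                data = tomllib.loads(text)
            except tomllib.TOMLDecodeError as exc:
                raise ConfigError(f"{source}: TOML parse error: {exc}") from exc
        else:
            try:
                data = yaml.safe_load(text) or {}
            except yaml.YAMLError as exc:
                raise ConfigError(f"{source}: YAML parse error: {exc}") from exc
    data.update(overrides)
    return _params_from_mapping(data, source)


def write_config(params: AcquisitionParams, path: Union[str, Path]) -> None:
    """Write a params object as YAML; round-trips through :func:`load_config`."""
    path = Path(path)
    path.write_text(yaml.safe_dump(params.to_dict(), sort_keys=True))
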
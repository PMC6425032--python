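"""Shared containers and I/O helpers.

The central container is :class:`ImageStack`, a thin wrapper around a numpy
array carrying the physical calibration (pixel size, frame interval, z step)
that every downstream measurement needs.  Stacks round-trip through
multi-page TIFF with a JSON metadata sidecar; ground-truth sidecars written
by the synthetic generators use the same ``<name>.truth.json`` convention.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "write_truth_json", "read_truth_json"]


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays and dataclasses to JSON types."""
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_truth_json(truth, path) -> Path:
    """Write a ground-truth sidecar next to a generated dataset.

    ``path`` may be the data file (``movie.tif`` -> ``movie.truth.json``) or
    an explicit ``*.truth.json`` path.
    """
    path = Path(path)
    if not path.name.endswith(".truth.json"):
        path = path.with_suffix("").with_suffix("") if path.suffix else path
        path = path.parent / (Path(path).stem + ".truth.json")
    path.write_text(json.dumps(_jsonable(truth), indent=1))
    return path


def read_truth_json(path) -> dict:
    return json.loads(Path(path).read_text())


@dataclass
class ImageStack:
    """An image time series or volume with physical calibration.

    Parameters
    ----------
    data
        Array with axes ``(T, Y, X)`` for a movie or ``(Z, Y, X)`` for a
        volume; single frames are stored as ``(1, Y, X)``.
    pixel_size_um
        Lateral pixel size in micrometres.
    frame_interval_s
        Time between frames in seconds (movies only).
    z_step_um
        Axial step in micrometres (volumes only).
    channel
        Free-form channel label, e.g. ``"actin"`` or ``"membrane"``.
    """

    data: np.ndarray
    pixel_size_um: float
    frame_interval_s: float | None = None
    z_step_um: float | None = None
    channel: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError(f"ImageStack expects (T|Z, Y, X) data, got shape {self.data.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.frame_interval_s is not None and self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self):
        return self.data.shape

    def save(self, path) -> Path:
        """Write as multi-page TIFF plus ``<name>.json`` metadata sidecar."""
        path = Path(path)
        tifffile.imwrite(path, np.asarray(self.data, dtype=np.float32),
                         photometric="minisblack")
        meta = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "z_step_um": self.z_step_um,
            "channel": self.channel,
            **self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(_jsonable(meta), indent=1))
        return path

    @classmethod
    def load(cls, path) -> "ImageStack":
        path = Path(path)
        data = tifffile.imread(path)
        meta = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        known = {k: meta.pop(k, None) for k in ("pixel_size_um", "frame_interval_s", "z_step_um", "channel")}
        if known["pixel_size_um"] is None:
            known["pixel_size_um"] = 1.0
        return cls(data=data, meta=meta, **known)
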
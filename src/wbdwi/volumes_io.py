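"""Domain types for volumetric DWI data and NIfTI readers/writers.

Conventions used throughout the package:

* In-memory axis order is ``(slice, row, column)`` with slice index 0 the
  most **superior** slice; voxel indexing is 0-based.
* ``VoxelGeometry.spacing_mm`` is ordered ``(row, column, slice)`` in mm.
* NIfTI (``.nii``/``.nii.gz``) is the sole volumetric format.  Array axis
  ``i`` of the in-memory volume maps to NIfTI array axis ``i``; voxel
  spacings are stored in the header zooms (slice, row, column order to
  match the array axes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml

IN_PLANE_AXES = ("row", "column")

#: map from phase-encode axis name to in-memory array axis index
AXIS_INDEX = {"row": 1, "column": 2}


@dataclass(frozen=True)
class VoxelGeometry:
    """Voxel spacing and in-plane phase-encode axis of an acquisition.

    Parameters
    ----------
    spacing_mm : tuple of float
        Voxel dimensions in mm, ordered ``(row, column, slice)``.
    phase_encode_axis : {"row", "column"}
        In-plane axis along which EPI distortions and inter-station
        shifts occur.
    """

    spacing_mm: tuple[float, float, float]
    phase_encode_axis: str = "row"

    def __post_init__(self) -> None:
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacings must be three positive reals, got {self.spacing_mm}")
        if self.phase_encode_axis not in IN_PLANE_AXES:
            raise ValueError(
                f"phase_encode_axis must be one of {IN_PLANE_AXES}, got {self.phase_encode_axis!r}"
            )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def phase_axis_index(self) -> int:
        """Array axis index (in (slice, row, column) order) of the phase-encode axis."""
        return AXIS_INDEX[self.phase_encode_axis]


def _check_intensities(intensities: np.ndarray) -> np.ndarray:
    # keep float64 in memory; files are written float32 (see write_volume)
    arr = np.asarray(intensities)
    if arr.dtype != np.float32:
        arr = arr.astype(np.float64)
    if arr.ndim != 3:
        raise ValueError(f"intensities must be 3-D, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("intensities contain non-finite values")
    if np.any(arr < 0):
        raise ValueError("intensities must be non-negative")
    return arr


@dataclass
class StationVolume:
    """One axial imaging station at a single b-value."""

    intensities: np.ndarray
    geometry: VoxelGeometry
    b_value: float
    station_index: int = 0

    def __post_init__(self) -> None:
        self.intensities = _check_intensities(self.intensities)
        if self.b_value < 0:
            raise ValueError(f"b_value must be >= 0, got {self.b_value}")
        if self.station_index < 0:
            raise ValueError(f"station_index must be >= 0, got {self.station_index}")

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]


@dataclass
class WholeBodyVolume:
    """Fused multi-station volume on a single voxel grid.

    ``station_boundaries`` holds the slice index at which each station
    after the first begins (strictly increasing, within the slice range).
    """

    intensities: np.ndarray
    geometry: VoxelGeometry
    b_value: float
    station_boundaries: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.dtype != np.float32:
            arr = arr.astype(np.float64)
        if arr.ndim != 3:
            raise ValueError(f"intensities must be 3-D, got shape {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities contain non-finite values")
        self.intensities = arr
        bounds = list(self.station_boundaries)
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError(f"station_boundaries must be strictly increasing: {bounds}")
        if any(not (0 < b < arr.shape[0]) for b in bounds):
            raise ValueError(f"station_boundaries out of slice range: {bounds}")
        self.station_boundaries = bounds

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class DWIStudy:
    """A two-b-value whole-body study (the input to ADC estimation)."""

    low_b_volume: WholeBodyVolume
    high_b_volume: WholeBodyVolume
    b_low: float
    b_high: float

    def __post_init__(self) -> None:
        if not (self.b_high > self.b_low >= 0):
            raise ValueError(f"need b_high > b_low >= 0, got b_low={self.b_low}, b_high={self.b_high}")
        if self.low_b_volume.shape != self.high_b_volume.shape:
            raise ValueError(
                "low/high b-value volumes must share grid shape: "
                f"{self.low_b_volume.shape} vs {self.high_b_volume.shape}"
            )
        if self.low_b_volume.geometry != self.high_b_volume.geometry:
            raise ValueError("low/high b-value volumes must share geometry")

    @property
    def geometry(self) -> VoxelGeometry:
        return self.low_b_volume.geometry


# ---------------------------------------------------------------------------
# NIfTI I/O


def write_volume(volume, path: str | Path) -> Path:
    """Write a volume (StationVolume / WholeBodyVolume / bare array + geometry wrapper)
    to NIfTI, losslessly for float32 data.

    The affine is diagonal with the voxel spacings in array-axis order
    (slice, row, column); no anatomical orientation is asserted.
    """
    path = Path(path)
    arr = np.asarray(volume.intensities)
    if not np.all(np.isfinite(arr)):
        raise ValueError("refusing to write non-finite data")
    geom = volume.geometry
    zooms = (geom.spacing_mm[2], geom.spacing_mm[0], geom.spacing_mm[1])
    affine = np.diag([*zooms, 1.0])
    if arr.dtype.kind in "iub":
        img = nib.Nifti1Image(arr.astype(np.int32), affine)
    else:
        img = nib.Nifti1Image(arr.astype(np.float32), affine)
    img.header.set_zooms(zooms)
    nib.save(img, str(path))
    return path


def write_label_volume(labels: np.ndarray, geometry: VoxelGeometry, path: str | Path) -> Path:
    """Write an integer label/mask volume to NIfTI."""

    class _Wrapper:
        intensities = np.asarray(labels, dtype=np.int32)

    w = _Wrapper()
    w.geometry = geometry
    return write_volume(w, path)


def read_volume(
    path: str | Path,
    b_value: float = 0.0,
    phase_encode_axis: str = "row",
    station_index: int = 0,
) -> StationVolume:
    """Read a NIfTI volume written by this package (or any 3-D NIfTI)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[1]), float(zooms[2]), float(zooms[0]))  # back to (row, col, slice)
    geom = VoxelGeometry(spacing_mm=spacing, phase_encode_axis=phase_encode_axis)
    return StationVolume(
        intensities=np.asarray(arr, dtype=np.float32),
        geometry=geom,
        b_value=b_value,
        station_index=station_index,
    )


def read_label_volume(path: str | Path) -> np.ndarray:
    img = nib.load(str(Path(path)))
    return np.asarray(img.dataobj).astype(np.int64)


def read_station_series(config: dict | str | Path) -> dict[str, list[StationVolume]]:
    """Read a multi-station two-b-value study from a config.

    The config (dict, or path to a YAML/JSON file) declares::

        b_low: 50
        b_high: 900
        phase_encode_axis: row
        stations:            # superior -> inferior order
          - low: station0_b50.nii.gz
            high: station0_b900.nii.gz
          - low: station1_b50.nii.gz
            high: station1_b900.nii.gz

    Relative paths resolve against the config file's directory.

    Returns
    -------
    dict with keys ``"low"`` and ``"high"``, each a list of
    :class:`StationVolume` sorted superior→inferior (station_index 0, 1, ...).
    """
    base = Path(".")
    if not isinstance(config, dict):
        cfg_path = Path(config)
        if not cfg_path.exists():
            raise FileNotFoundError(f"no such study config: {cfg_path}")
        base = cfg_path.parent
        with open(cfg_path) as fh:
            config = yaml.safe_load(fh)

    b_low = float(config["b_low"])
    b_high = float(config["b_high"])
    if not b_high > b_low:
        raise ValueError(f"config must declare b_high > b_low, got {b_low}, {b_high}")
    pe_axis = config.get("phase_encode_axis", "row")

    stations: Sequence[dict] = config["stations"]
    out: dict[str, list[StationVolume]] = {"low": [], "high": []}
    shapes: dict[str, tuple] = {}
    for idx, entry in enumerate(stations):
        for key, b in (("low", b_low), ("high", b_high)):
            p = Path(entry[key])
            if not p.is_absolute():
                p = base / p
            vol = read_volume(p, b_value=b, phase_encode_axis=pe_axis, station_index=idx)
            in_plane = vol.intensities.shape[1:]
            if key in shapes and shapes[key] != in_plane:
                raise ValueError(
                    f"inconsistent in-plane matrix at station {idx} ({key} b-value): "
                    f"{in_plane} vs {shapes[key]} (axes: row, column)"
                )
            shapes[key] = in_plane
            out[key].append(vol)
    return out
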
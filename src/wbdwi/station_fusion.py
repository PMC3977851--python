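"""Inter-station harmonization and fusion of multi-station WBDWI data.

Whole-body DWI is acquired as a stack of axial stations.  Receiver gain
differs between stations, and EPI distortion displaces each station along
the in-plane phase-encode axis.  This module corrects both effects by
matching the cumulative intensity histograms of the abutting boundary
slabs (a pure multiplicative gain, estimated as a quantile–quantile
linear fit through the origin) and finding the integer phase-encode
displacement minimizing the mean-square intensity difference across the
boundary, then concatenates the corrected stations superior→inferior.

Corrections are estimated once, on the low-b volume, and applied to both
b-values of a study: a gain applied to only one b-value would corrupt
the ADC map, whereas a joint scaling leaves ADC invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from wbdwi.volumes_io import StationVolume, WholeBodyVolume

DEFAULT_SLAB_SLICES = 3
DEFAULT_N_QUANTILES = 64
DEFAULT_SEARCH_RADIUS = 5


@dataclass(frozen=True)
class StationCorrection:
    """Multiplicative gain and integer phase-encode shift for one station."""

    gain: float
    shift_voxels: int

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")


def estimate_gain(
    boundary_slab_a: np.ndarray,
    boundary_slab_b: np.ndarray,
    n_quantiles: int = DEFAULT_N_QUANTILES,
) -> float:
    """Gain ``g`` such that ``g * slab_b`` matches ``slab_a`` in cumulative histogram.

    ``g`` minimizes ``sum_k (q_a[k] - g * q_b[k])**2`` over a common grid
    of quantiles of the nonzero voxels of each slab (a quantile–quantile
    linear fit through the origin).  Scale-equivariant:
    ``estimate_gain(a, c*b) == estimate_gain(a, b) / c``.
    """
    if n_quantiles < 8:
        raise ValueError(f"n_quantiles must be >= 8, got {n_quantiles}")
    a = np.asarray(boundary_slab_a, dtype=np.float64).ravel()
    b = np.asarray(boundary_slab_b, dtype=np.float64).ravel()
    a = a[a > 0]
    b = b[b > 0]
    if a.size == 0 or b.size == 0:
        raise ValueError("degenerate boundary: all-zero slab")
    probs = (np.arange(n_quantiles) + 0.5) / n_quantiles
    qa = np.quantile(a, probs)
    qb = np.quantile(b, probs)
    denom = float(np.dot(qb, qb))
    if denom == 0.0:
        raise ValueError("degenerate boundary: zero quantile function")
    return float(np.dot(qa, qb) / denom)


def _translate(slab: np.ndarray, shift: int, axis: int) -> np.ndarray:
    """Integer translation with zero fill (no wraparound)."""
    if shift == 0:
        return slab
    out = np.zeros_like(slab)
    src = [slice(None)] * slab.ndim
    dst = [slice(None)] * slab.ndim
    if shift > 0:
        dst[axis] = slice(shift, None)
        src[axis] = slice(None, -shift)
    else:
        dst[axis] = slice(None, shift)
        src[axis] = slice(-shift, None)
    out[tuple(dst)] = slab[tuple(src)]
    return out


def _overlap_mse(a: np.ndarray, b: np.ndarray, shift: int, axis: int) -> float:
    """Mean-square difference between ``a`` and ``b`` translated by ``shift``,
    over the in-bounds overlap region only."""
    n = a.shape[axis]
    if shift >= 0:
        sl_a = slice(shift, n)
        sl_b = slice(0, n - shift)
    else:
        sl_a = slice(0, n + shift)
        sl_b = slice(-shift, n)
    idx_a = [slice(None)] * a.ndim
    idx_b = [slice(None)] * a.ndim
    idx_a[axis] = sl_a
    idx_b[axis] = sl_b
    diff = a[tuple(idx_a)] - b[tuple(idx_b)]
    return float(np.mean(diff * diff))


def estimate_shift(
    boundary_slab_a: np.ndarray,
    boundary_slab_b: np.ndarray,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
    phase_axis: int = 1,
) -> int:
    """Integer displacement along the phase-encode axis minimizing the
    mean-square intensity difference over the overlap region.

    Ties are broken toward 0, then toward the negative shift.  If slab_b
    equals slab_a translated by ``+k``, the returned correction is ``-k``.
    """
    a = np.asarray(boundary_slab_a, dtype=np.float64)
    b = np.asarray(boundary_slab_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"slab shapes differ: {a.shape} vs {b.shape}")
    if search_radius < 1:
        raise ValueError(f"search_radius must be >= 1, got {search_radius}")
    if search_radius >= a.shape[phase_axis]:
        raise ValueError(
            f"search_radius {search_radius} exceeds slab extent {a.shape[phase_axis]} "
            f"along axis {phase_axis}"
        )
    candidates = range(-search_radius, search_radius + 1)
    # apply candidate shift s to slab_b, compare to slab_a on overlap
    best = min(candidates, key=lambda s: (_overlap_mse(a, b, s, phase_axis), abs(s), s))
    return int(best)


def _shifted_by(intensities: np.ndarray, shift: int, phase_axis: int) -> np.ndarray:
    return _translate(intensities, shift, phase_axis)


def fuse_stations(
    stations: list[StationVolume],
    corrections: list[StationCorrection] | None = None,
    slab_slices: int = DEFAULT_SLAB_SLICES,
    n_quantiles: int = DEFAULT_N_QUANTILES,
    search_radius: int = DEFAULT_SEARCH_RADIUS,
) -> tuple[WholeBodyVolume, list[StationCorrection]]:
    """Fuse stations superior→inferior into a single whole-body volume.

    The most superior station is the reference.  Each subsequent station
    is corrected relative to its already-corrected superior neighbor:
    gain from cumulative-histogram matching of the abutting boundary
    slabs, then the integer phase-encode shift, estimated in turn for
    each station.

    Parameters
    ----------
    stations
        Stations of one b-value, sorted superior→inferior.
    corrections
        If given (length ``len(stations) - 1``), these corrections are
        applied instead of being estimated — used to re-apply the low-b
        corrections to the high-b volume of the same study.

    Returns
    -------
    (WholeBodyVolume, list of StationCorrection)
        The fused volume and the per-station corrections (one per
        station after the first).
    """
    if not stations:
        raise ValueError("need at least one station")
    in_plane = {s.intensities.shape[1:] for s in stations}
    if len(in_plane) > 1:
        raise ValueError(f"inconsistent in-plane shapes across stations: {sorted(in_plane)}")

    geom = stations[0].geometry
    b_value = stations[0].b_value
    phase_axis = geom.phase_axis_index

    if corrections is not None and len(corrections) != len(stations) - 1:
        raise ValueError(
            f"need {len(stations) - 1} corrections for {len(stations)} stations, "
            f"got {len(corrections)}"
        )

    blocks = [np.asarray(stations[0].intensities, dtype=np.float64)]
    applied: list[StationCorrection] = []
    boundaries: list[int] = []
    n_slices = stations[0].n_slices

    for k, station in enumerate(stations[1:]):
        arr = np.asarray(station.intensities, dtype=np.float64)
        if corrections is not None:
            corr = corrections[k]
        else:
            slab_a = blocks[-1][-slab_slices:]
            slab_b = arr[:slab_slices]
            gain = estimate_gain(slab_a, slab_b, n_quantiles=n_quantiles)
            shift = estimate_shift(
                slab_a, gain * slab_b, search_radius=search_radius, phase_axis=phase_axis
            )
            corr = StationCorrection(gain=gain, shift_voxels=shift)
        corrected = _shifted_by(corr.gain * arr, corr.shift_voxels, phase_axis)
        boundaries.append(n_slices)
        n_slices += station.n_slices
        blocks.append(corrected)
        applied.append(corr)

    fused = np.concatenate(blocks, axis=0)
    return (
        WholeBodyVolume(
            intensities=fused,
            geometry=geom,
            b_value=b_value,
            station_boundaries=boundaries,
        ),
        applied,
    )
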
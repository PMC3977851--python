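"""Disease-VOI segmentation: threshold, GrowCut editing, MRF smoothing,
connected components, superior cutoff and VOI exclusion.

The segmentation chain mirrors a radiologist's workflow on computed-DWI
images: a manually chosen global threshold isolates hyperintense voxels;
a seeded 3-D GrowCut cellular automaton removes normal structures that
retain signal (e.g. spleen); a two-class Markov-random-field model with
a Potts spatial prior probabilistically smooths the classification,
suppressing salt noise and thin residual-fat bands; connected components
become volumes of interest (VOIs); everything superior to a chosen
cervical cutoff slice is discarded; individual VOIs can be excluded.

All operations are deterministic: identical inputs and parameters give
bit-identical masks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

UNLABELED = 0
FOREGROUND = 1
BACKGROUND = 2

_OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]
_OFFSETS_6 = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


# ---------------------------------------------------------------------------
# Thresholding


def threshold_volume(cdwi, tau: float) -> np.ndarray:
    """Strict global threshold: mask of voxels with intensity > tau."""
    if tau < 0:
        raise ValueError(f"tau must be >= 0, got {tau}")
    values = getattr(cdwi, "values", cdwi)
    return np.asarray(values) > tau


# ---------------------------------------------------------------------------
# GrowCut


@dataclass
class SeedMap:
    """Seed labels for GrowCut: 0 unlabeled, 1 foreground, 2 background.

    ``initial_strengths`` defaults to 1.0 at seeds and 0 elsewhere.
    """

    labels: np.ndarray
    initial_strengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.isin(labels, (UNLABELED, FOREGROUND, BACKGROUND)).all():
            raise ValueError("seed labels must be 0 (unlabeled), 1 (foreground) or 2 (background)")
        self.labels = labels.astype(np.int8)
        if self.initial_strengths is None:
            self.initial_strengths = (self.labels != UNLABELED).astype(np.float64)
        else:
            s = np.asarray(self.initial_strengths, dtype=np.float64)
            if s.shape != self.labels.shape:
                raise ValueError("initial_strengths shape mismatch")
            if np.any((s < 0) | (s > 1)):
                raise ValueError("initial_strengths must lie in [0, 1]")
            self.initial_strengths = s


@dataclass
class GrowCutState:
    """Final state of the cellular automaton."""

    labels: np.ndarray
    strengths: np.ndarray
    features: np.ndarray
    iterations: int
    converged: bool


def _neighbor_views(padded: np.ndarray, shape, offset):
    dz, dy, dx = offset
    nz, ny, nx = shape
    return padded[1 + dz : 1 + dz + nz, 1 + dy : 1 + dy + ny, 1 + dx : 1 + dx + nx]


def growcut_3d(
    feature_volume: np.ndarray,
    seeds: SeedMap | np.ndarray,
    max_iters: int = 500,
) -> GrowCutState:
    """Seeded two-class GrowCut segmentation by cellular automaton.

    Each voxel p carries a label and a strength ``theta in [0, 1]``.  At
    every (synchronous) iteration every labeled 26-neighbor q attacks p
    with force ``g(|C_p - C_q|) * theta_q`` where
    ``g(x) = 1 - x / max|C|`` (monotonically decreasing, ``g(0) = 1``);
    if the force strictly exceeds ``theta_p``, p adopts q's label and
    the attacking strength.  All updates within one iteration are
    computed from the previous iteration's state.  Stops when no label
    changes, or after ``max_iters``.
    """
    if not isinstance(seeds, SeedMap):
        seeds = SeedMap(labels=seeds)
    C = np.asarray(feature_volume, dtype=np.float64)
    if C.ndim != 3:
        raise ValueError(f"feature volume must be 3-D, got shape {C.shape}")
    if not np.all(np.isfinite(C)):
        raise ValueError("feature volume must be finite")
    if seeds.labels.shape != C.shape:
        raise ValueError("seed shape does not match feature volume")
    if not np.any(seeds.labels != UNLABELED):
        raise ValueError("no seeds at all: at least one labeled voxel required")

    max_c = float(np.max(np.abs(C)))
    inv_max_c = 1.0 / max_c if max_c > 0 else 0.0  # uniform volume: g == 1 everywhere

    labels = seeds.labels.copy()
    theta = seeds.initial_strengths.copy()
    shape = C.shape

    converged = False
    iteration = 0
    for iteration in range(1, max_iters + 1):
        # pad with unlabeled/zero-strength border cells (cannot attack)
        Lp = np.pad(labels, 1, constant_values=UNLABELED)
        Tp = np.pad(theta, 1, constant_values=0.0)
        Cp = np.pad(C, 1, constant_values=0.0)

        best_force = theta.copy()
        best_label = labels.copy()
        for off in _OFFSETS_26:
            q_label = _neighbor_views(Lp, shape, off)
            q_theta = _neighbor_views(Tp, shape, off)
            q_c = _neighbor_views(Cp, shape, off)
            g = 1.0 - np.abs(C - q_c) * inv_max_c
            force = np.where(q_label != UNLABELED, g * q_theta, 0.0)
            win = force > best_force
            best_force = np.where(win, force, best_force)
            best_label = np.where(win, q_label, best_label)

        n_changed = int(np.sum(best_label != labels))
        labels = best_label.astype(np.int8)
        theta = best_force
        if n_changed == 0:
            converged = True
            break

    return GrowCutState(
        labels=labels,
        strengths=theta,
        features=C,
        iterations=iteration,
        converged=converged,
    )


def _box_slices(box) -> tuple[slice, slice, slice]:
    """Normalize a box given as ((z0, z1), (y0, y1), (x0, x1)) half-open."""
    if len(box) != 3:
        raise ValueError("box must have three (start, stop) pairs")
    return tuple(slice(int(lo), int(hi)) for lo, hi in box)


def _check_nested(fg_box, bg_box, shape) -> None:
    for (f0, f1), (b0, b1), n in zip(fg_box, bg_box, shape):
        if not (0 <= b0 < b1 <= n):
            raise ValueError(f"bg_box {bg_box} out of volume bounds {shape}")
        if not (b0 < f0 and f1 < b1):
            raise ValueError(f"fg_box {fg_box} must be strictly inside bg_box {bg_box}")
        if f0 >= f1:
            raise ValueError(f"empty fg_box {fg_box}")


def remove_region_growcut(
    mask: np.ndarray,
    cdwi,
    fg_box,
    bg_box,
    max_iters: int = 500,
) -> np.ndarray:
    """Remove a normal structure (e.g. spleen) from the disease mask.

    Voxels inside ``fg_box`` seed the structure; voxels on the surface of
    ``bg_box`` seed background.  GrowCut runs on the computed-DWI feature
    restricted to the ``bg_box`` interior, and voxels it labels
    foreground are cleared from the mask.  Boxes are half-open index
    ranges ``((z0, z1), (y0, y1), (x0, x1))`` with fg strictly inside bg.
    """
    values = getattr(cdwi, "values", cdwi)
    values = np.asarray(values, dtype=np.float64)
    _check_nested(fg_box, bg_box, values.shape)
    bg_sl = _box_slices(bg_box)

    sub = values[bg_sl]
    seed_labels = np.zeros(sub.shape, dtype=np.int8)
    # background seeds: surface shell of the bg box
    seed_labels[0, :, :] = BACKGROUND
    seed_labels[-1, :, :] = BACKGROUND
    seed_labels[:, 0, :] = BACKGROUND
    seed_labels[:, -1, :] = BACKGROUND
    seed_labels[:, :, 0] = BACKGROUND
    seed_labels[:, :, -1] = BACKGROUND
    fg_rel = tuple(
        slice(f0 - b0, f1 - b0) for (f0, f1), (b0, _) in zip(fg_box, bg_box)
    )
    seed_labels[fg_rel] = FOREGROUND

    state = growcut_3d(sub, seed_labels, max_iters=max_iters)
    out = np.array(mask, dtype=bool, copy=True)
    region = out[bg_sl]
    region[state.labels == FOREGROUND] = False
    out[bg_sl] = region
    return out


# ---------------------------------------------------------------------------
# Markov-random-field smoothing


@dataclass
class MRFParams:
    """Two-class Gaussian-likelihood + Potts-prior MRF parameters.

    ``beta`` is the label-disagreement penalty in log-likelihood units;
    ``beta = 0`` reduces to per-voxel maximum-likelihood classification.
    Class statistics left as ``None`` are estimated from the initial
    labeling (inside vs outside voxels).
    """

    class_means: tuple[float, float] | None = None  # (mu_background, mu_disease)
    class_stddevs: tuple[float, float] | None = None
    beta: float = 1.5
    max_iterations: int = 20
    neighborhood: int = 6  # 6 (face) or 26 (full)
    sigma_floor: float = 1e-6
    #: number of estimate-stats/ICM rounds when statistics are estimated
    #: from the mask (interleaved parameter re-estimation a la Besag);
    #: ignored when class statistics are provided explicitly
    stat_passes: int = 2

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")
        if self.neighborhood not in (6, 26):
            raise ValueError("neighborhood must be 6 or 26")
        if self.class_stddevs is not None and any(s <= 0 for s in self.class_stddevs):
            raise ValueError("class stddevs must be > 0")


def _neg_log_gaussian(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return 0.5 * ((x - mu) / sigma) ** 2 + np.log(sigma) + 0.5 * np.log(2.0 * np.pi)


def _pairwise_disagreements(labels: np.ndarray, offsets) -> int:
    total = 0
    # count each unordered pair once: use only "positive" half of the offsets
    half = [o for o in offsets if o > (0, 0, 0)]
    for dz, dy, dx in half:
        a = labels[max(dz, 0) : labels.shape[0] + min(dz, 0),
                   max(dy, 0) : labels.shape[1] + min(dy, 0),
                   max(dx, 0) : labels.shape[2] + min(dx, 0)]
        b = labels[max(-dz, 0) : labels.shape[0] + min(-dz, 0),
                   max(-dy, 0) : labels.shape[1] + min(-dy, 0),
                   max(-dx, 0) : labels.shape[2] + min(-dx, 0)]
        total += int(np.sum(a != b))
    return total


def mrf_energy(
    intensity: np.ndarray,
    labels: np.ndarray,
    means: tuple[float, float],
    stddevs: tuple[float, float],
    beta: float,
    neighborhood: int = 6,
) -> float:
    """Potts-model energy E(l) = sum_p -log N(I_p; mu_lp, sigma_lp) + beta * #{p~q : l_p != l_q}."""
    I = np.asarray(intensity, dtype=np.float64)
    d0 = _neg_log_gaussian(I, means[0], stddevs[0])
    d1 = _neg_log_gaussian(I, means[1], stddevs[1])
    data = float(np.sum(np.where(labels, d1, d0)))
    offsets = _OFFSETS_6 if neighborhood == 6 else _OFFSETS_26
    return data + beta * _pairwise_disagreements(np.asarray(labels, dtype=np.int8), offsets)


def _estimate_class_stats(
    intensity: np.ndarray, mask: np.ndarray, sigma_floor: float
) -> tuple[tuple[float, float], tuple[float, float]]:
    inside = intensity[mask]
    outside = intensity[~mask]
    if inside.size == 0 or outside.size == 0:
        raise ValueError("initial mask must contain both classes to estimate statistics")
    means = (float(outside.mean()), float(inside.mean()))
    stds = [float(outside.std()), float(inside.std())]
    for i, s in enumerate(stds):
        if s <= 0:
            warnings.warn(
                f"class {i} has zero intensity variance; using sigma floor {sigma_floor}",
                stacklevel=3,
            )
            stds[i] = sigma_floor
    return means, (stds[0], stds[1])


def _icm(I: np.ndarray, means, stds, params: MRFParams):
    """One ICM round: ML initialization, then active-set raster sweeps."""
    d0 = _neg_log_gaussian(I, means[0], stds[0])
    d1 = _neg_log_gaussian(I, means[1], stds[1])
    # flipping voxel p to disease changes the data term by delta_data = d1 - d0
    delta_data = d1 - d0

    labels = d1 < d0  # ML initialization; ties -> background
    offsets = _OFFSETS_6 if params.neighborhood == 6 else _OFFSETS_26
    shape = I.shape
    energies = [mrf_energy(I, labels, means, stds, params.beta, params.neighborhood)]
    converged = params.beta == 0 or labels.size == 0
    sweeps = 0

    if not converged:
        lab = labels.astype(np.int8)
        for sweeps in range(1, params.max_iterations + 1):
            # vectorized candidate detection under the sweep-start labeling
            Lp = np.pad(lab, 1, constant_values=0)
            n_disease = np.zeros(shape, dtype=np.int16)
            n_valid = np.zeros(shape, dtype=np.int16)
            vp = np.pad(np.ones(shape, dtype=np.int16), 1, constant_values=0)
            for off in offsets:
                n_disease += _neighbor_views(Lp, shape, off)
                n_valid += _neighbor_views(vp, shape, off)
            # local energy of label 1 minus label 0 at each voxel
            local_delta = delta_data + params.beta * (n_valid - 2 * n_disease)
            cand = np.flatnonzero((lab == 0) & (local_delta < 0) | (lab == 1) & (local_delta > 0))
            if cand.size == 0:
                converged = True
                sweeps -= 1
                break
            n_flips = 0
            nz, ny, nx = shape
            for flat in cand:  # raster order (flatnonzero is sorted)
                z, rem = divmod(int(flat), ny * nx)
                y, x = divmod(rem, nx)
                nd = 0
                nv = 0
                for dz, dy, dx in offsets:
                    qz, qy, qx = z + dz, y + dy, x + dx
                    if 0 <= qz < nz and 0 <= qy < ny and 0 <= qx < nx:
                        nv += 1
                        nd += lab[qz, qy, qx]
                ld = delta_data[z, y, x] + params.beta * (nv - 2 * nd)
                cur = lab[z, y, x]
                new = 1 if ld < 0 else (0 if ld > 0 else cur)
                if new != cur:
                    lab[z, y, x] = new
                    n_flips += 1
            energies.append(
                mrf_energy(I, lab.astype(bool), means, stds, params.beta, params.neighborhood)
            )
            if n_flips == 0:
                converged = True
                break
        labels = lab.astype(bool)
    return labels, energies, sweeps, converged


def mrf_smooth(
    intensity_volume: np.ndarray,
    initial_mask: np.ndarray,
    params: MRFParams | None = None,
    return_info: bool = False,
):
    """MRF relabeling by iterated conditional modes (ICM).

    The labeling approximately minimizing

        E(l) = sum_p -log N(I_p; mu_{l_p}, sigma_{l_p}) + beta * sum_{p~q} [l_p != l_q]

    is found by ICM started from the per-voxel maximum-likelihood
    classification.  Sweeps visit, in raster order, the voxels whose
    single-site flip lowers the energy under the sweep-start labeling,
    re-evaluating each flip against the labels current at its turn;
    sweeps repeat until no voxel flips or ``max_iterations``.  Energy is
    non-increasing across accepted flips within a round.  With
    ``beta = 0`` the result is exactly the maximum-likelihood
    classification.

    When class statistics are estimated from the mask (not provided),
    estimation and ICM are interleaved for ``params.stat_passes``
    rounds: the initial threshold mask is typically contaminated by the
    very artifacts the smoothing removes, so statistics re-estimated
    from the first smoothed labeling separate the classes much better.

    Returns the smoothed boolean mask, plus an info dict (class stats,
    per-sweep energies of the final round, convergence flag) when
    ``return_info`` is set.
    """
    params = params or MRFParams()
    I = np.asarray(intensity_volume, dtype=np.float64)
    mask = np.asarray(initial_mask, dtype=bool)
    if I.shape != mask.shape:
        raise ValueError("intensity and initial mask shapes differ")

    provided = params.class_means is not None and params.class_stddevs is not None
    n_passes = 1 if provided else max(1, params.stat_passes)

    energy_history: list[list[float]] = []
    labels = mask
    means = stds = None
    sweeps = 0
    converged = False
    for _ in range(n_passes):
        if provided:
            means, stds = params.class_means, params.class_stddevs
        else:
            if not labels.any() or labels.all():
                break  # degenerate labeling: keep previous result
            means, stds = _estimate_class_stats(I, labels, params.sigma_floor)
        labels, energies, sweeps, converged = _icm(I, means, stds, params)
        energy_history.append(energies)

    if return_info:
        info = {
            "class_means": means,
            "class_stddevs": stds,
            "energies": energy_history[-1] if energy_history else [],
            "energy_history": energy_history,
            "sweeps": sweeps,
            "converged": converged,
        }
        return labels, info
    return labels


# ---------------------------------------------------------------------------
# Connected components / VOIs


@dataclass
class VOISet:
    """Labeled 3-D segmentation: 0 = background, k >= 1 = component id.

    Component ids are contiguous from 1, ordered by decreasing voxel
    count with ties broken by first-encountered raster order.
    """

    label_volume: np.ndarray
    counts: dict[int, int]
    excluded_ids: set[int] = field(default_factory=set)

    @property
    def n_components(self) -> int:
        return len(self.counts)

    @property
    def included_ids(self) -> list[int]:
        return [k for k in sorted(self.counts) if k not in self.excluded_ids]

    def included_mask(self) -> np.ndarray:
        if not self.counts:
            return np.zeros(self.label_volume.shape, dtype=bool)
        mask = self.label_volume > 0
        for k in self.excluded_ids:
            mask &= self.label_volume != k
        return mask

    @property
    def n_voxels_included(self) -> int:
        return int(sum(self.counts[k] for k in self.included_ids))


def connected_components(mask: np.ndarray) -> VOISet:
    """26-connectivity 3-D component labeling of a boolean mask.

    Ids are reassigned 1..k by decreasing voxel count; ties broken by
    first-encountered raster order.  An empty mask gives an empty VOISet.
    """
    mask = np.asarray(mask, dtype=bool)
    structure = np.ones((3, 3, 3), dtype=bool)
    raw, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return VOISet(label_volume=np.zeros(mask.shape, dtype=np.int32), counts={})
    flat = raw.ravel()
    counts = np.bincount(flat, minlength=n + 1)
    uniq, first_idx = np.unique(flat, return_index=True)
    first = dict(zip(uniq.tolist(), first_idx.tolist()))
    order = sorted(range(1, n + 1), key=lambda k: (-counts[k], first[k]))
    remap = np.zeros(n + 1, dtype=np.int32)
    for new_id, old_id in enumerate(order, start=1):
        remap[old_id] = new_id
    relabeled = remap[raw]
    out_counts = {new_id: int(counts[old_id]) for new_id, old_id in enumerate(order, start=1)}
    return VOISet(label_volume=relabeled, counts=out_counts)


def apply_superior_cutoff(obj, cutoff_slice: int):
    """Clear everything strictly superior to ``cutoff_slice``.

    Slice 0 is the most superior slice, so slices with index
    ``< cutoff_slice`` are cleared; the cutoff slice itself is retained.
    Works on a boolean mask or a :class:`VOISet` (component bookkeeping
    is recomputed; exclusions are carried over by component identity of
    the surviving voxels).
    """
    if isinstance(obj, VOISet):
        n_slices = obj.label_volume.shape[0]
    else:
        n_slices = np.asarray(obj).shape[0]
    if not (0 <= cutoff_slice < n_slices):
        raise ValueError(f"cutoff_slice {cutoff_slice} out of range [0, {n_slices})")

    if not isinstance(obj, VOISet):
        out = np.array(obj, dtype=bool, copy=True)
        out[:cutoff_slice] = False
        return out

    old_labels = np.array(obj.label_volume, copy=True)
    old_labels[:cutoff_slice] = 0
    excluded_mask = np.isin(old_labels, sorted(obj.excluded_ids)) if obj.excluded_ids else None
    new = connected_components(old_labels > 0)
    new_excluded: set[int] = set()
    if excluded_mask is not None and excluded_mask.any():
        for k in new.counts:
            comp = new.label_volume == k
            if excluded_mask[comp].any():
                new_excluded.add(k)
    new.excluded_ids = new_excluded
    return new


def exclude_vois(voiset: VOISet, ids) -> VOISet:
    """Mark components as excluded from all downstream metrics."""
    ids = {int(i) for i in (ids if np.iterable(ids) else [ids])}
    unknown = ids - set(voiset.counts)
    if unknown:
        raise ValueError(
            f"unknown VOI ids {sorted(unknown)}; valid ids: {sorted(voiset.counts)}"
        )
    return replace(voiset, excluded_ids=set(voiset.excluded_ids) | ids)


def include_vois(voiset: VOISet, ids) -> VOISet:
    """Re-include previously excluded components (inverse of exclude_vois)."""
    ids = {int(i) for i in (ids if np.iterable(ids) else [ids])}
    unknown = ids - set(voiset.counts)
    if unknown:
        raise ValueError(
            f"unknown VOI ids {sorted(unknown)}; valid ids: {sorted(voiset.counts)}"
        )
    return replace(voiset, excluded_ids=set(voiset.excluded_ids) - ids)
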
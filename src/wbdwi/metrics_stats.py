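"""Tumor-burden metrics (tDV, gADC histogram descriptors) and the
rank-based group statistics used for response assessment.

tDV (total diffusion volume) is the segmented disease volume in
milliliters.  gADC (global ADC) is the pooled distribution of valid ADC
values over **all** included disease components — a single global
distribution, not per-lesion averages — summarized by the sample median,
unbiased variance, adjusted Fisher–Pearson skewness, and bias-corrected
*excess* (Fisher) kurtosis.  Response comparisons use the Mann-Whitney U
test between responder and non-responder groups (one-sided for median
gADC, where treatment is expected to raise ADC; two-sided otherwise)
and the Wilcoxon signed-rank test for paired pre/post change, with
exact small-sample p-values by direct enumeration.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from wbdwi.cdwi import ADCMap
from wbdwi.segmentation import VOISet
from wbdwi.volumes_io import VoxelGeometry

#: combined sample size at or below which rank tests use exact enumeration
MANN_WHITNEY_EXACT_MAX_N = 12
WILCOXON_EXACT_MAX_N = 15

HISTOGRAM_RANGE = (0.0, 3.0e-3)  # mm^2/s
HISTOGRAM_BINS = 100


@dataclass
class TumorMetrics:
    """tDV and gADC histogram descriptors for one study timepoint.

    ``gadc_*`` values are in mm²/s (variance in (mm²/s)²); skewness and
    kurtosis are dimensionless; kurtosis is excess (Fisher) kurtosis.
    Degenerate distributions (zero variance) carry NaN skewness/kurtosis
    with ``moments_defined`` False.
    """

    tdv_ml: float
    gadc_median: float
    gadc_variance: float
    gadc_skewness: float
    gadc_kurtosis: float
    n_voxels: int
    moments_defined: bool = True
    histogram_edges: list[float] = field(default_factory=list)
    histogram_counts: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TumorMetrics":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def compute_tdv(voiset: VOISet, geometry: VoxelGeometry) -> float:
    """Total diffusion volume in milliliters of all included components."""
    return voiset.n_voxels_included * geometry.voxel_volume_mm3 / 1000.0


def _pooled_adc(adc_map: ADCMap, voiset: VOISet) -> np.ndarray:
    mask = voiset.included_mask() & adc_map.validity_mask
    return adc_map.values[mask]


def gadc_statistics(adc_map: ADCMap, voiset: VOISet) -> dict:
    """Pooled gADC histogram statistics over all included components.

    Raises on an empty VOI (no included voxel with a valid ADC value).
    Statistics are computed on the raw pooled values; the histogram
    (100 bins over 0–3.0×10⁻³ mm²/s by default) is for display only.
    """
    values = _pooled_adc(adc_map, voiset)
    if values.size == 0:
        raise ValueError("empty VOI: no included voxels with valid ADC")
    var = float(np.var(values, ddof=1)) if values.size > 1 else 0.0
    # numerically constant distributions have undefined shape moments
    scale = float(np.max(np.abs(values))) or 1.0
    defined = var > (1e-9 * scale) ** 2
    if defined:
        skew = float(stats.skew(values, bias=False))
        kurt = float(stats.kurtosis(values, fisher=True, bias=False))
    else:
        skew = float("nan")
        kurt = float("nan")
    counts, edges = np.histogram(values, bins=HISTOGRAM_BINS, range=HISTOGRAM_RANGE)
    return {
        "gadc_median": float(np.median(values)),
        "gadc_variance": var,
        "gadc_skewness": skew,
        "gadc_kurtosis": kurt,
        "n_voxels": int(values.size),
        "moments_defined": defined,
        "histogram_edges": edges.tolist(),
        "histogram_counts": counts.tolist(),
    }


def compute_metrics(adc_map: ADCMap, voiset: VOISet, geometry: VoxelGeometry) -> TumorMetrics:
    """Full per-study metrics: tDV plus pooled gADC statistics."""
    g = gadc_statistics(adc_map, voiset)
    return TumorMetrics(tdv_ml=compute_tdv(voiset, geometry), **g)


# ---------------------------------------------------------------------------
# Rank tests


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of group a over b (ties counted 1/2)."""
    a = a[:, None]
    return float(np.sum(a > b) + 0.5 * np.sum(a == b))


def mann_whitney(
    group_a_values,
    group_b_values,
    tail: str = "two_sided",
    exact_max_n: int = MANN_WHITNEY_EXACT_MAX_N,
) -> tuple[float, float]:
    """Mann-Whitney U test between two independent groups.

    Exact permutation p-value by enumerating all group assignments when
    ``n_a + n_b <= exact_max_n``; tie-corrected normal approximation
    otherwise.  ``tail`` is ``"two_sided"`` or ``"one_sided_greater"``
    (alternative: group a stochastically greater than group b).

    Returns ``(U, p)`` with U the statistic of group a.
    """
    a = np.asarray(group_a_values, dtype=np.float64)
    b = np.asarray(group_b_values, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if tail not in ("two_sided", "one_sided_greater"):
        raise ValueError(f"unknown tail {tail!r}")

    u_obs = _u_statistic(a, b)
    n_a, n_b = a.size, b.size

    if n_a + n_b <= exact_max_n:
        pooled = np.concatenate([a, b])
        n = pooled.size
        mu = n_a * n_b / 2.0
        count = 0
        total = 0
        for idx_a in itertools.combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(idx_a)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if tail == "one_sided_greater":
                if u >= u_obs - 1e-12:
                    count += 1
            else:
                if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
                    count += 1
        return u_obs, count / total

    alternative = "greater" if tail == "one_sided_greater" else "two-sided"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mid-ranked |d| and signs after dropping zero differences."""
    d = diffs[diffs != 0]
    ranks = stats.rankdata(np.abs(d))
    return ranks, np.sign(d)


def wilcoxon_paired(
    pre_values,
    post_values,
    tail: str = "two_sided",
    exact_max_n: int = WILCOXON_EXACT_MAX_N,
) -> float:
    """Wilcoxon signed-rank test on paired pre/post values.

    Differences ``post - pre``; zero differences dropped; ties
    mid-ranked.  Exact p by enumerating all 2^m sign patterns for
    ``m <= exact_max_n`` nonzero differences, normal approximation
    otherwise.  ``tail`` ``"one_sided_greater"`` tests the alternative
    that post exceeds pre.  All-zero differences give p = 1 (warned).
    """
    pre = np.asarray(pre_values, dtype=np.float64)
    post = np.asarray(post_values, dtype=np.float64)
    if pre.size != post.size:
        raise ValueError("pre and post must have equal lengths")
    if pre.size < 5:
        raise ValueError("need at least 5 pairs")
    if tail not in ("two_sided", "one_sided_greater"):
        raise ValueError(f"unknown tail {tail!r}")

    diffs = post - pre
    ranks, signs = _signed_ranks(diffs)
    m = ranks.size
    if m == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 1.0

    w_obs = float(np.sum(ranks[signs > 0]))
    mu = float(np.sum(ranks)) / 2.0

    if m <= exact_max_n:
        count = 0
        total = 1 << m
        for pattern in range(total):
            w = 0.0
            for i in range(m):
                if pattern & (1 << i):
                    w += ranks[i]
            if tail == "one_sided_greater":
                if w >= w_obs - 1e-12:
                    count += 1
            else:
                if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
                    count += 1
        return count / total

    sigma2 = float(np.sum(ranks**2)) / 4.0
    z = (w_obs - mu) / np.sqrt(sigma2)
    if tail == "one_sided_greater":
        return float(stats.norm.sf(z))
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Cohort response report


@dataclass
class ResponseComparison:
    """Group-level comparison of per-patient treatment changes."""

    table: pd.DataFrame
    group_summary: pd.DataFrame
    tests: dict[str, dict]
    small_sample: bool


#: metrics compared between groups and their test tails
RESPONSE_METRICS = {
    "percent_change_tdv": "two_sided",
    "delta_gadc_median": "one_sided_greater",
    "delta_gadc_variance": "two_sided",
    "delta_gadc_skewness": "two_sided",
    "delta_gadc_kurtosis": "two_sided",
}


def _metric_deltas(pre: TumorMetrics, post: TumorMetrics) -> dict:
    if pre.tdv_ml <= 0:
        raise ValueError("percent change in tDV undefined for pre-treatment tDV = 0")
    return {
        "percent_change_tdv": 100.0 * (post.tdv_ml - pre.tdv_ml) / pre.tdv_ml,
        "delta_gadc_median": post.gadc_median - pre.gadc_median,
        "delta_gadc_variance": post.gadc_variance - pre.gadc_variance,
        "delta_gadc_skewness": post.gadc_skewness - pre.gadc_skewness,
        "delta_gadc_kurtosis": post.gadc_kurtosis - pre.gadc_kurtosis,
    }


def response_report(cohort: pd.DataFrame | list[dict]) -> ResponseComparison:
    """Compare treatment changes between responder and non-responder groups.

    ``cohort`` rows carry ``patient_id``, ``group`` ("responder" /
    "non-responder") and either in-memory metrics (``pre_metrics``,
    ``post_metrics`` TumorMetrics) or paths (``pre_metrics_path``,
    ``post_metrics_path`` to metrics JSON).  Patients missing a
    timepoint are excluded with a warning.  Mann-Whitney p-values are
    one-sided (responders greater) for Δ median gADC and two-sided for
    every other metric.
    """
    if isinstance(cohort, pd.DataFrame):
        rows = cohort.to_dict("records")
    else:
        rows = list(cohort)

    records = []
    for row in rows:
        pre = row.get("pre_metrics")
        post = row.get("post_metrics")
        if pre is None and row.get("pre_metrics_path"):
            pre = TumorMetrics.from_json(row["pre_metrics_path"])
        if post is None and row.get("post_metrics_path"):
            post = TumorMetrics.from_json(row["post_metrics_path"])
        if pre is None or post is None:
            warnings.warn(
                f"patient {row.get('patient_id')} missing a timepoint; excluded",
                stacklevel=2,
            )
            continue
        rec = {"patient_id": row["patient_id"], "group": row["group"]}
        rec.update(_metric_deltas(pre, post))
        records.append(rec)

    table = pd.DataFrame.from_records(records)
    if table.empty:
        raise ValueError("no patients with both timepoints")

    responders = table[table["group"] == "responder"]
    nonresponders = table[table["group"] != "responder"]
    small = len(responders) < 2 or len(nonresponders) < 2

    summary = table.groupby("group")[list(RESPONSE_METRICS)].agg(["median", "min", "max"])

    tests: dict[str, dict] = {}
    for metric, tail in RESPONSE_METRICS.items():
        a = responders[metric].to_numpy()
        b = nonresponders[metric].to_numpy()
        if a.size == 0 or b.size == 0:
            tests[metric] = {"U": float("nan"), "p": float("nan"), "tail": tail}
            continue
        u, p = mann_whitney(a, b, tail=tail)
        tests[metric] = {"U": u, "p": p, "tail": tail, "small_sample": small}

    return ResponseComparison(table=table, group_summary=summary, tests=tests, small_sample=small)
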
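"""Fleet-surveillance statistics over the QC registry.

The operations here mirror what a multi-center QC program needs once the
per-image metrics exist: one-sided Tukey-fence outlier screening of SDNR
(which catches out-of-spec phantom inserts), a paired test for systematic
horizontal-vs-vertical MTF asymmetry (which catches poorly cut Cu edges),
empirical percentile thresholds across systems, Gaussian-kernel density
summaries, and a recommender that ties the evidence back to data sets.

Quantile convention (used consistently by the outlier rule and the
percentile thresholds): linear interpolation of order statistics with the
p-quantile at rank p*(n-1), 0-based -- i.e. numpy's default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .iq_metrics import IQResult
from .registry import QCRegistry

__all__ = [
    "ThresholdConfig",
    "OutlierReport",
    "AsymmetryResult",
    "DensityCurve",
    "SuspectRecommendation",
    "iqr_upper_outliers",
    "hv_mtf_asymmetry",
    "percentile_threshold",
    "evaluate_thresholds",
    "density_estimate",
    "flag_suspect_datasets",
]


@dataclass(frozen=True)
class ThresholdConfig:
    """Minimum-performance thresholds (empirical 75%-of-systems levels)."""

    hmtf50_min: float = 1.2   # lp/mm
    sdnr_min: float = 7.5
    dprime03_min: float = 3.4
    percentile_exceeding: float = 0.75

    def __post_init__(self) -> None:
        if min(self.hmtf50_min, self.sdnr_min, self.dprime03_min) <= 0:
            raise ValueError("thresholds must be > 0")
        if not 0 < self.percentile_exceeding < 1:
            raise ValueError("percentile_exceeding must lie in (0, 1)")


@dataclass(frozen=True)
class OutlierReport:
    metric: str
    q1: float
    q3: float
    iqr: float
    upper_fence: float
    outlier_indices: tuple[int, ...]
    implicated_dataset_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class AsymmetryResult:
    group_id: str
    median_h: float
    median_v: float
    n: int
    paired_t: float
    p_value: float
    alpha: float
    significant: bool
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class DensityCurve:
    grid: np.ndarray
    density: np.ndarray
    stratum: str = ""
    bandwidth: float = 0.0


@dataclass(frozen=True)
class SuspectRecommendation:
    dataset_id: str
    reason: str  # "sdnr_upper_outlier" | "hv_mtf_asymmetry"
    evidence: dict


def iqr_upper_outliers(values, metric: str = "", dataset_ids=None) -> OutlierReport:
    """One-sided Tukey rule: outlier iff value > Q3 + 1.5*(Q3 - Q1).

    Quartiles by linear interpolation of order statistics.  Strictness
    matters: a constant list has IQR 0 and nothing strictly above the fence.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 4 or not np.isfinite(vals).all():
        raise ValueError("too few (or non-finite) values: need >= 4")
    q1, q3 = np.quantile(vals, [0.25, 0.75])  # rank p*(n-1) convention
    iqr = q3 - q1
    fence = q3 + 1.5 * iqr
    idx = tuple(int(i) for i in np.nonzero(vals > fence)[0])
    implicated = ()
    if dataset_ids is not None:
        implicated = tuple(sorted({dataset_ids[i] for i in idx}))
    return OutlierReport(metric=metric, q1=float(q1), q3=float(q3),
                         iqr=float(iqr), upper_fence=float(fence),
                         outlier_indices=idx, implicated_dataset_ids=implicated)


def hv_mtf_asymmetry(h_values, v_values, alpha: float = 0.01,
                     group_id: str = "") -> AsymmetryResult:
    """Paired t-test of horizontal vs vertical MTF50 observations.

    t = mean(d) / (SD(d)/sqrt(n)) on differences d = H - V, two-sided p from
    the t distribution with n-1 df.  Degenerate cases: all-zero differences
    give t = 0, p = 1; zero-variance differences with non-zero mean give
    p = 0 with a flag.
    """
    h = np.asarray(h_values, dtype=float)
    v = np.asarray(v_values, dtype=float)
    if h.shape != v.shape or h.size < 3:
        raise ValueError("need >= 3 paired observations")
    d = h - v
    n = d.size
    flags: list[str] = []
    sd = d.std(ddof=1)
    if sd == 0:
        if np.allclose(d, 0):
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = math.inf * np.sign(d.mean()), 0.0
            flags.append("zero_variance_differences")
    else:
        t_stat = d.mean() / (sd / math.sqrt(n))
        p = 2.0 * stats.t.sf(abs(t_stat), df=n - 1)
    return AsymmetryResult(group_id=group_id,
                           median_h=float(np.median(h)),
                           median_v=float(np.median(v)), n=n,
                           paired_t=float(t_stat), p_value=float(p),
                           alpha=alpha, significant=bool(p < alpha),
                           flags=tuple(flags))


def percentile_threshold(per_system_values, exceeding: float = 0.75) -> float:
    """Value such that a fraction ``exceeding`` of systems lies at or above it.

    The (1 - exceeding)-quantile under the same rank p*(n-1) convention as
    the outlier rule.  Input is one representative value per system
    (conventionally the median over that system's exposures).
    """
    vals = np.asarray(per_system_values, dtype=float)
    if vals.size < 4:
        raise ValueError("too few systems: need >= 4")
    if not 0 < exceeding < 1:
        raise ValueError("exceeding must lie in (0, 1)")
    return float(np.quantile(vals, 1.0 - exceeding))


def evaluate_thresholds(iq, cfg: ThresholdConfig | None = None) -> dict:
    """Check a result (IQResult or metric mapping) against minimum thresholds.

    Boundary-inclusive: a metric exactly at its threshold passes.  Missing
    or non-finite metrics are marked not-evaluable and flag the overall
    verdict.
    """
    cfg = cfg or ThresholdConfig()
    metrics = iq.to_dict() if isinstance(iq, IQResult) else dict(iq)
    checks = {"HMTF50": cfg.hmtf50_min, "SDNR": cfg.sdnr_min,
              "DPRIME_03": cfg.dprime03_min}
    result: dict = {"checks": {}, "not_evaluable": [], "overall_pass": True,
                    "flagged": False}
    for name, minimum in checks.items():
        value = metrics.get(name)
        if value is None or not np.isfinite(value):
            result["not_evaluable"].append(name)
            result["flagged"] = True
            result["overall_pass"] = False
            continue
        ok = bool(value >= minimum)
        result["checks"][name] = {"value": float(value), "min": minimum, "pass": ok}
        if not ok:
            result["overall_pass"] = False
    return result


def density_estimate(values, grid_size: int = 256, stratum: str = "") -> DensityCurve:
    """Gaussian-kernel density (Silverman bandwidth) on a uniform grid.

    The grid spans the data range extended by three bandwidths, so the
    trapezoid integral of the curve is 1 to within ~1e-3.  A zero-variance
    stratum degenerates to a delta-like spike (with a warning).
    """
    vals = np.asarray(values, dtype=float)
    if vals.size < 5:
        raise ValueError("need >= 5 values per stratum")
    sd = vals.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance stratum: returning delta-like spike",
                      stacklevel=2)
        h = max(abs(vals[0]) * 1e-6, 1e-12)
        grid = np.linspace(vals[0] - 6 * h, vals[0] + 6 * h, grid_size)
        dens = np.exp(-0.5 * ((grid - vals[0]) / h) ** 2) / (h * math.sqrt(2 * math.pi))
        return DensityCurve(grid=grid, density=dens, stratum=stratum, bandwidth=h)
    kde = stats.gaussian_kde(vals, bw_method="silverman")
    h = float(kde.factor * sd)
    grid = np.linspace(vals.min() - 3 * h, vals.max() + 3 * h, grid_size)
    return DensityCurve(grid=grid, density=kde(grid), stratum=stratum, bandwidth=h)


def flag_suspect_datasets(registry: QCRegistry, alpha: float = 0.01,
                          domination_frac: float = 0.5
                          ) -> list[SuspectRecommendation]:
    """Recommend data sets for exclusion, with evidence; never deletes.

    Two mechanisms are screened, matching the anomalies that actually occur
    in practice:

    * ``sdnr_upper_outlier`` -- a data set whose exposures dominate the
      one-sided SDNR outlier group (fraction above the fence >=
      ``domination_frac``), the signature of an over-thick Al insert;
    * ``hv_mtf_asymmetry`` -- a data set with a significant paired H/V
      MTF50 difference at ``alpha``, the signature of poorly cut ("blunt")
      Cu edges.

    Exclusion itself remains a manual registry action.
    """
    recs: list[SuspectRecommendation] = []
    datasets = [ds for ds in registry.datasets.values() if not ds.excluded]

    # SDNR screening, pooled within each image-type stratum
    for stratum in ("raw", "processed"):
        members = [ds for ds in datasets if ds.setup.image_type == stratum]
        values, ids = [], []
        for ds in members:
            for rec in ds.records:
                values.append(rec.iq.sdnr)
                ids.append(ds.dataset_id)
        if len(values) < 4:
            continue
        report = iqr_upper_outliers(values, metric="SDNR", dataset_ids=ids)
        counts: dict[str, int] = {}
        for i in report.outlier_indices:
            counts[ids[i]] = counts.get(ids[i], 0) + 1
        for ds in members:
            n = len(ds.records)
            if n and counts.get(ds.dataset_id, 0) / n >= domination_frac:
                recs.append(SuspectRecommendation(
                    dataset_id=ds.dataset_id, reason="sdnr_upper_outlier",
                    evidence={"stratum": stratum,
                              "upper_fence": report.upper_fence,
                              "n_outlying": counts[ds.dataset_id],
                              "n_exposures": n}))

    # H/V asymmetry screening, per data set
    for ds in datasets:
        pairs = [(r.iq.hmtf50, r.iq.vmtf50) for r in ds.records
                 if r.iq.hmtf50 is not None and r.iq.vmtf50 is not None]
        if len(pairs) < 3:
            continue
        h, v = zip(*pairs)
        result = hv_mtf_asymmetry(h, v, alpha=alpha, group_id=ds.dataset_id)
        if result.significant:
            recs.append(SuspectRecommendation(
                dataset_id=ds.dataset_id, reason="hv_mtf_asymmetry",
                evidence={"p_value": result.p_value, "paired_t": result.paired_t,
                          "median_h": result.median_h,
                          "median_v": result.median_v, "n": result.n}))
    return sorted(recs, key=lambda r: (r.dataset_id, r.reason))
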
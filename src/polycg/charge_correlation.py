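"""Charge-parameter correlation: x = NCPR − f·M/Rg and its linear fits.

The free parameter f is found by 1-D search maximizing an aggregate of the
per-series R² values (default: mean over the fitted peptide-length series),
on a grid over [0, 0.1] at 1e-5 resolution followed by bounded refinement.
Ties resolve to the smallest f.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

F_SEARCH_RANGE = (0.0, 0.1)
F_GRID_STEP = 1.0e-5
LOW_R2_THRESHOLD = 0.5


class FitError(ValueError):
    pass


@dataclass
class ComponentRecord:
    """Descriptors and normalized contact counts for one transport component."""

    name: str
    ncpr: float  # e per residue
    dipole_M: float  # e.nm
    rg: float  # nm
    ct_normalized: dict  # series label (e.g. "PR20") -> normalized Ct
    group: str = "general"

    def __post_init__(self):
        if self.rg <= 0:
            raise FitError(f"{self.name}: radius of gyration must be positive")


@dataclass
class CorrelationDataset:
    records: list
    group: str = "general"
    ground_truth: dict = field(default_factory=dict)

    def series_labels(self) -> list:
        labels = set()
        for r in self.records:
            labels.update(r.ct_normalized)
        return sorted(labels)

    def series_arrays(self, label):
        recs = [r for r in self.records if label in r.ct_normalized]
        if not recs:
            raise FitError(f"no records carry series {label!r}")
        return (
            np.asarray([r.ncpr for r in recs]),
            np.asarray([r.dipole_M for r in recs]),
            np.asarray([r.rg for r in recs]),
            np.asarray([r.ct_normalized[label] for r in recs]),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for label, y in r.ct_normalized.items():
                rows.append(
                    {
                        "name": r.name,
                        "group": r.group,
                        "series": label,
                        "ncpr": r.ncpr,
                        "dipole_M": r.dipole_M,
                        "rg": r.rg,
                        "ct_normalized": y,
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group: str = "general") -> "CorrelationDataset":
        records = []
        for name, grp in df.groupby("name", sort=True):
            first = grp.iloc[0]
            records.append(
                ComponentRecord(
                    name=str(name),
                    ncpr=float(first["ncpr"]),
                    dipole_M=float(first["dipole_M"]),
                    rg=float(first["rg"]),
                    ct_normalized={
                        str(row["series"]): float(row["ct_normalized"])
                        for _, row in grp.iterrows()
                    },
                    group=str(first.get("group", group)),
                )
            )
        return cls(records=records, group=group)


@dataclass
class SeriesFit:
    slope: float
    intercept: float
    r_squared: float
    low_quality: bool = False


@dataclass
class FitResult:
    f: float
    series: dict  # label -> SeriesFit
    aggregate_r_squared: float
    aggregation: str
    group: str = "general"


# ----------------------------------------------------------------------
def charge_parameter(ncpr, dipole_M, rg, f):
    """x = NCPR − f·M/Rg (e per residue)."""
    rg = np.asarray(rg, dtype=float)
    if (rg <= 0).any():
        raise FitError("radius of gyration must be positive")
    return np.asarray(ncpr, dtype=float) - f * np.asarray(dipole_M, dtype=float) / rg


def fit_line(x, y):
    """Ordinary least squares; returns (slope, intercept, R²).

    A constant y gives slope 0 and R² defined as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise FitError("need at least 3 points for a line fit")
    if np.ptp(x) == 0:
        raise FitError("x values are degenerate (all equal)")
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    sxy = ((x - xm) * (y - ym)).sum()
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_tot = ((y - ym) ** 2).sum()
    if ss_tot == 0.0:
        return float(slope), float(intercept), 0.0
    ss_res = ((y - slope * x - intercept) ** 2).sum()
    return float(slope), float(intercept), float(1.0 - ss_res / ss_tot)


def _series_r2_vectorized(f_values, ncpr, m_over_rg, y):
    """R² of the OLS fit of y on (ncpr − f·M/Rg), for many f at once."""
    x = ncpr[None, :] - f_values[:, None] * m_over_rg[None, :]
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean()
    dx = x - xm
    dy = y - ym
    sxx = (dx**2).sum(axis=1)
    syy = float((dy**2).sum())
    sxy = (dx * dy[None, :]).sum(axis=1)
    if syy == 0.0:
        return np.zeros(len(f_values))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(sxx > 0, sxy**2 / (sxx * syy), 0.0)
    return r2


def _aggregate(r2_matrix, how):
    if how == "mean":
        return r2_matrix.mean(axis=0)
    if how == "min":
        return r2_matrix.min(axis=0)
    raise FitError(f"unknown aggregation rule {how!r}")


def optimize_f(
    dataset: CorrelationDataset,
    lengths=("PR20", "PR50"),
    f_range=F_SEARCH_RANGE,
    grid_step=F_GRID_STEP,
    aggregation="mean",
    low_r2_threshold=LOW_R2_THRESHOLD,
) -> FitResult:
    """Maximize aggregate fit quality over f; report per-series fits at the optimum."""
    arrays = {}
    for label in lengths:
        ncpr, m, rg, y = dataset.series_arrays(label)
        if len(y) < 3:
            raise FitError(f"series {label!r} has fewer than 3 components")
        arrays[label] = (ncpr, m / rg, y)

    grid = np.arange(f_range[0], f_range[1] + grid_step / 2, grid_step)
    r2 = np.stack(
        [_series_r2_vectorized(grid, a, mr, y) for a, mr, y in arrays.values()]
    )
    agg = _aggregate(r2, aggregation)
    best = int(np.argmax(agg))  # argmax takes the first (smallest-f) maximum

    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]

    def neg_agg(f):
        vals = [
            _series_r2_vectorized(np.array([f]), a, mr, y)[0]
            for a, mr, y in arrays.values()
        ]
        return -_aggregate(np.asarray(vals)[:, None], aggregation)[0]

    f_best = grid[best]
    score_best = agg[best]
    if hi > lo:
        res = minimize_scalar(neg_agg, bounds=(lo, hi), method="bounded",
                              options={"xatol": grid_step * 1e-3})
        if -res.fun > score_best:
            f_best, score_best = float(res.x), float(-res.fun)

    series = {}
    for label, (ncpr, m_over_rg, y) in arrays.items():
        x = ncpr - f_best * m_over_rg
        slope, intercept, r_sq = fit_line(x, y)
        series[label] = SeriesFit(
            slope=slope,
            intercept=intercept,
            r_squared=r_sq,
            low_quality=r_sq < low_r2_threshold,
        )
    return FitResult(
        f=float(f_best),
        series=series,
        aggregate_r_squared=float(score_best),
        aggregation=aggregation,
        group=dataset.group,
    )
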
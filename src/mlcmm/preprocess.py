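"""Quantile normalization of biomarkers to the standard-normal scale.

Biomarkers enter the mixture model as ``z = Phi^{-1}(Ghat(y))`` where
``Ghat`` is the plug-in marginal CDF of the pooled training values
(all subjects, all visits) for that biomarker.  The map is fitted once
on the training cohort and frozen: sequential updates and forecasts for
new patients reuse it, and forecasts are reported on the original scale
through the inverse map.

Conventions (the data give no reason to prefer others, so they are
fixed here): plug-in ECDF ``rank/(n+1)`` so the transform stays finite
at the extremes; mid-ranks for ties; linear interpolation of the ECDF
between training values for unseen inputs; clamping to
``[1/(n+1), n/(n+1)]`` beyond the training range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .longdata import LongCohort

__all__ = [
    "QuantileMap",
    "DegenerateDistributionError",
    "fit_quantile_map",
    "fit_all_maps",
    "transform",
    "inverse_transform",
    "transform_cohort",
    "save_maps",
    "load_maps",
]


class DegenerateDistributionError(ValueError):
    """Fewer than two distinct training values for a biomarker."""


@dataclass(frozen=True)
class QuantileMap:
    """Frozen empirical quantile-normalization map for one biomarker."""

    k_name: str
    sorted_values: np.ndarray  # ascending, ties kept

    def __post_init__(self):
        v = np.asarray(self.sorted_values, dtype=float)
        if v.size == 0 or (np.diff(v) < 0).any():
            raise ValueError("sorted_values must be nonempty and ascending")
        object.__setattr__(self, "sorted_values", v)

    @property
    def n(self) -> int:
        return self.sorted_values.size

    def _grid(self) -> tuple[np.ndarray, np.ndarray]:
        """Distinct training values and their mid-rank ECDF levels."""
        v = self.sorted_values
        uniq, counts = np.unique(v, return_counts=True)
        # mid-rank of a tie group = mean of the 1-based ranks it occupies
        hi = np.cumsum(counts)
        lo = hi - counts + 1
        midrank = (lo + hi) / 2.0
        return uniq, midrank / (self.n + 1)


def fit_quantile_map(cohort: LongCohort, k_name: str) -> QuantileMap:
    """Fit the pooled empirical quantile map for biomarker ``k_name``."""
    if k_name not in cohort.k_names:
        raise KeyError(f"biomarker {k_name!r} not in cohort {cohort.k_names}")
    values = np.sort(cohort.visits[k_name].to_numpy(dtype=float))
    if np.unique(values).size < 2:
        raise DegenerateDistributionError(
            f"biomarker {k_name!r} has fewer than 2 distinct training values"
        )
    return QuantileMap(k_name=k_name, sorted_values=values)


def fit_all_maps(cohort: LongCohort) -> dict[str, QuantileMap]:
    return {k: fit_quantile_map(cohort, k) for k in cohort.k_names}


def transform(qmap: QuantileMap, y) -> np.ndarray | float:
    """Map original-scale values to the standard-normal scale."""
    y = np.asarray(y, dtype=float)
    scalar = y.ndim == 0
    u, p = qmap._grid()
    lo, hi = 1.0 / (qmap.n + 1), qmap.n / (qmap.n + 1)
    probs = np.interp(np.atleast_1d(y), u, p, left=lo, right=hi)
    z = stats.norm.ppf(np.clip(probs, lo, hi))
    return float(z[0]) if scalar else z


def inverse_transform(qmap: QuantileMap, z) -> np.ndarray | float:
    """Map standard-normal-scale values back to the original scale.

    Beyond the training range the output is clamped to the observed
    min/max training value.
    """
    z = np.asarray(z, dtype=float)
    scalar = z.ndim == 0
    u, p = qmap._grid()
    probs = stats.norm.cdf(np.atleast_1d(z))
    y = np.interp(probs, p, u, left=u[0], right=u[-1])
    return float(y[0]) if scalar else y


def transform_cohort(cohort: LongCohort,
                     maps: dict[str, QuantileMap]) -> LongCohort:
    """Return a cohort whose biomarker columns are quantile-normalized."""
    visits = cohort.visits.copy()
    for k in cohort.k_names:
        visits[k] = transform(maps[k], visits[k].to_numpy(dtype=float))
    return LongCohort(visits=visits, baselines=cohort.baselines,
                      k_names=cohort.k_names)


def save_maps(maps: dict[str, QuantileMap], path) -> None:
    """Serialize fitted maps to a long CSV (``k_name,value``)."""
    frames = [pd.DataFrame({"k_name": m.k_name, "value": m.sorted_values})
              for m in maps.values()]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_maps(path) -> dict[str, QuantileMap]:
    df = pd.read_csv(path)
    out = {}
    for k, grp in df.groupby("k_name", sort=False):
        out[str(k)] = QuantileMap(k_name=str(k),
                                  sorted_values=np.sort(grp["value"].to_numpy(float)))
    return out
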